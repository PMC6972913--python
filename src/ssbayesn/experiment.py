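"""Experiment orchestration: simulate -> mask -> priors -> fit -> evaluate.

A single structured config drives everything; each replicate runs the full
pipeline (population simulation, masking, base-variance estimation,
single- and multi-trait fits of the requested models at every region
mode, prediction and validation metrics) and the tidy per-replicate
results are aggregated into one results table. Replicates are seeded
deterministically from the experiment seed and are resumable (a replicate
whose results file already exists is skipped).
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import pedsim
from .evaluate import accuracy, bias_slope, pev_from_chain
from .mcmc import ChainOptions, GenomicModelData, gibbs_bayesn0, predict_gebv_direct
from .regions import (derive_priors_multitrait, derive_priors_singletrait,
                      estimate_base_variances, partition_regions)
from .relationship import PedigreeGraph, partition_blocks
from .singlestep import (build_ss_system, gibbs_ssbayesn0,
                         predict_gebv_singlestep_chain, predict_gebv_singlestep,
                         run_sssnpblup)

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "run_experiment", "run_replicate", "simulate_replicate"]

DEFAULT_CONFIG = {
    "scenario": "G9",
    "replicates": 2,
    "seed": 1,
    "simulation": {
        # desk-scale layout proportional to the full design
        # (full scale: 2200 founders, 5 chromosomes, 11k SNPs, 200 QTL,
        #  200 males / 2000 females, 5 generations)
        "n_founders": 330,
        "n_chr": 2,
        "snps_per_chr": 150,
        "ld_rho": 0.7,
        "maf_beta": [1.0, 1.0],
        "n_males": 30,
        "n_females": 300,
        "n_generations": 3,
        "n_qtl": 30,
        "qtl_mean_maf": 0.15,
        "maf_tol": 0.01,
        "p_pleiotropic": 0.82,
        "h2": [0.1, 0.4],
    },
    "mask": {
        "train_generations": [1, 2],
        "val_generation": 3,
        "n_geno_females": 80,
        "n_val_genotyped": 150,
    },
    "regions": [{"mode": "fixed_n", "region_size": 50}],
    "models": ["bayesn0", "ssbayesn0", "sssnpb1", "sssnpb2"],
    "analyses": ["multi", "single"],
    "chain": {"n_iter": 1500, "burn_in": 500, "thin": 5},
    "base_chain": {"n_iter": 1000, "burn_in": 400, "thin": 5},
    "pcg": {"tol": 1e-12, "max_iter": 20000},
    "pev": False,
}


def _merge(base: dict, override: Optional[dict]) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def simulate_replicate(cfg: dict, seed: int):
    """One simulated, masked data set. Returns (pop, qtl, traits, masked)."""
    sim = cfg["simulation"]
    panel = pedsim.simulate_founders(
        sim["n_founders"], n_chr=sim["n_chr"], snps_per_chr=sim["snps_per_chr"],
        maf_beta=tuple(sim.get("maf_beta", (1.0, 1.0))),
        ld_rho=sim["ld_rho"], seed=seed)
    pop = pedsim.forward_breed(panel, n_generations=sim["n_generations"],
                               n_males=sim["n_males"], n_females=sim["n_females"],
                               seed=seed + 1)
    qtl = pedsim.select_qtl(pop, sim["n_qtl"], target_mean_maf=sim["qtl_mean_maf"],
                            tol=sim["maf_tol"], seed=seed + 2)
    qtl = pedsim.assign_qtl_groups(qtl, sim["p_pleiotropic"], seed=seed + 3)
    if cfg["scenario"] == "G9":
        qtl = pedsim.simulate_effects_g9(qtl, seed=seed + 4)
    elif cfg["scenario"] == "N5":
        qtl = pedsim.simulate_effects_n5(qtl, seed=seed + 4)
    else:
        raise ValueError(f"unknown scenario {cfg['scenario']!r}")
    traits = pedsim.simulate_phenotypes(pop, qtl, h2=tuple(sim["h2"]), seed=seed + 5)
    m = cfg["mask"]
    design = pedsim.MaskDesign(
        train_generations=tuple(m["train_generations"]),
        val_generation=m["val_generation"],
        n_geno_females=m["n_geno_females"],
        n_val_genotyped=m["n_val_genotyped"])
    masked = pedsim.apply_mask(pop, traits, design, seed=seed + 6)
    return pop, qtl, traits, masked


def _prepare(pop, qtl, masked):
    """Shared preprocessing: analysis markers, blocks, centered genotypes."""
    keep = qtl.analysis_snps(pop.n_snp)
    ped = PedigreeGraph.from_population(pop)
    blocks = partition_blocks(ped, masked.genotyped)
    M_raw = pop.genotypes[np.ix_(blocks.genotyped_idx, keep)].astype(float)
    p = M_raw.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)  # drop markers monomorphic in genotyped animals
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("dropping %d monomorphic markers", n_dropped)
    return keep[poly], blocks, M_raw[:, poly], p[poly]


def run_replicate(cfg: dict, rep: int, out_dir: Optional[Path] = None) -> pd.DataFrame:
    """Run every requested model on one simulated replicate; returns the
    tidy metric table (one row per method x trait x animal group)."""
    seed = int(cfg["seed"]) + 10_000 * rep
    t0 = time.time()
    pop, qtl, traits, masked = simulate_replicate(cfg, seed)
    keep, blocks, M_raw, p = _prepare(pop, qtl, masked)
    chrom = pop.chrom[keep]
    M_g = M_raw - 2 * p
    g_idx, n_idx = blocks.genotyped_idx, blocks.nongenotyped_idx

    gp = masked.phenotyped[g_idx]  # genotyped & phenotyped
    y_g = traits.phenotypes[g_idx][gp]
    M_gp = M_g[gp]

    bc = cfg["base_chain"]
    base_multi = estimate_base_variances(
        y_g, M_gp, p, mode="multi", n_iter=bc["n_iter"], burn_in=bc["burn_in"],
        thin=bc["thin"], seed=seed + 7)
    base_single = [
        estimate_base_variances(y_g[:, [t]], M_gp, p, mode="single",
                                n_iter=bc["n_iter"], burn_in=bc["burn_in"],
                                thin=bc["thin"], seed=seed + 8 + t)
        for t in range(2)
    ]

    val = masked.validation
    val_nong = (pop.generation == cfg["mask"]["val_generation"]) & ~masked.genotyped
    anim_of_ss = np.concatenate([n_idx, g_idx])  # ss output -> pedigree order

    cc = cfg["chain"]
    opts = ChainOptions(n_iter=cc["n_iter"], burn_in=cc["burn_in"],
                        thin=cc["thin"], seed=seed + 9)
    rows = []

    def add_metrics(method, trait_cols, gebv_all, groups, pev_all=None):
        """gebv_all: (n_anim, len(trait_cols)) in pedigree order (NaN where
        undefined); pev_all optional with the same layout."""
        for ci, t in enumerate(trait_cols):
            tname = "LH"[t]
            for gname, sel in groups.items():
                if not np.any(sel):
                    continue
                gv = gebv_all[sel, ci]
                if np.isnan(gv).any():
                    continue
                row = {
                    "replicate": rep, "method": method, "trait": tname,
                    "group": gname,
                    "accuracy": accuracy(traits.tbv[sel, t], gv),
                    "bias": bias_slope(traits.tbv[sel, t], gv),
                }
                if pev_all is not None:
                    row["pev"] = float(np.nanmean(pev_all[sel, ci]))
                rows.append(row)

    for rspec in cfg["regions"]:
        rmap = partition_regions(chrom, mode=rspec["mode"],
                                 region_size=rspec.get("region_size", 100))
        rtag = rspec["mode"] if rspec["mode"] != "fixed_n" else \
            f"fixed{rspec.get('region_size', 100)}"
        for analysis in cfg["analyses"]:
            variants = [([0, 1], "MT")] if analysis == "multi" else \
                [([0], "ST"), ([1], "ST")]
            for cols, tag in variants:
                if analysis == "multi":
                    priors = derive_priors_multitrait(base_multi[0], base_multi[1], p)
                else:
                    t = cols[0]
                    priors = derive_priors_singletrait(base_single[t][0],
                                                       base_single[t][1], p)
                suffix = f"{tag}-{rtag}" if analysis == "multi" else \
                    f"{tag}{'LH'[cols[0]]}-{rtag}"

                chain_b = None
                if {"bayesn0", "sssnpb1"} & set(cfg["models"]):
                    data = GenomicModelData(y=y_g[:, cols], M=M_gp,
                                            regions=rmap, priors=priors)
                    chain_b = gibbs_bayesn0(data, opts)
                if "bayesn0" in cfg["models"]:
                    gebv = np.full((pop.n_ind, len(cols)), np.nan)
                    gebv[g_idx] = M_g @ chain_b.mean_alpha()
                    pev = None
                    if cfg["pev"]:
                        per_cycle = predict_gebv_direct(M_g, chain_b,
                                                        per_cycle=True)
                        pev = np.full((pop.n_ind, len(cols)), np.nan)
                        pev[g_idx] = per_cycle.var(axis=0, ddof=1)
                    add_metrics(f"bayesn0-{suffix}", cols, gebv,
                                {"genotyped": val}, pev_all=pev)

                sys_needed = {"ssbayesn0", "sssnpb1", "sssnpb2"} & set(cfg["models"])
                if sys_needed:
                    system = build_ss_system(masked.y_obs[:, cols],
                                             masked.genotyped, masked.phenotyped,
                                             M_raw, blocks, rmap, priors)
                chain_ss = None
                if {"ssbayesn0", "sssnpb2"} & set(cfg["models"]):
                    chain_ss = gibbs_ssbayesn0(system, opts)
                if "ssbayesn0" in cfg["models"]:
                    g_ss = predict_gebv_singlestep_chain(system, chain_ss)
                    gebv = np.full((pop.n_ind, len(cols)), np.nan)
                    gebv[anim_of_ss] = g_ss
                    pev = None
                    if cfg["pev"]:
                        per_cycle = predict_gebv_singlestep_chain(
                            system, chain_ss, per_cycle=True)
                        pev = np.full((pop.n_ind, len(cols)), np.nan)
                        pev[anim_of_ss] = per_cycle.var(axis=0, ddof=1)
                    add_metrics(f"ssbayesn0-{suffix}", cols, gebv,
                                {"genotyped": val, "nongenotyped": val_nong},
                                pev_all=pev)
                for name, src_chain, vsrc in (
                        ("sssnpb1", chain_b, "bayesn0"),
                        ("sssnpb2", chain_ss, "ssbayesn0")):
                    if name not in cfg["models"]:
                        continue
                    sol = run_sssnpblup(system, src_chain, varsource=vsrc,
                                        M_for_G0=M_gp,
                                        tol=cfg["pcg"]["tol"],
                                        max_iter=cfg["pcg"]["max_iter"])
                    mug = sol["mu_star"][1] if system.has_mug else \
                        np.zeros(len(cols))
                    g_ss = predict_gebv_singlestep(system, mug, sol["alpha"],
                                                   sol["eps"])
                    gebv = np.full((pop.n_ind, len(cols)), np.nan)
                    gebv[anim_of_ss] = g_ss
                    add_metrics(f"{name}-{suffix}", cols, gebv,
                                {"genotyped": val, "nongenotyped": val_nong})

    df = pd.DataFrame(rows)
    df["seed"] = seed
    logger.info("replicate %d finished in %.1f s (%d result rows)",
                rep, time.time() - t0, len(df))
    if out_dir is not None:
        df.to_csv(Path(out_dir) / f"replicate_{rep:03d}.tsv", sep="\t",
                  index=False)
    return df


def run_experiment(config: Optional[dict] = None, out_dir="results",
                   dry_run: bool = False) -> Optional[pd.DataFrame]:
    """Run all replicates of an experiment config and aggregate results.

    With ``dry_run`` the resolved plan is printed and nothing executes.
    Replicates are independent, deterministically seeded, and resumable:
    existing per-replicate result files are loaded instead of recomputed.
    A failed replicate is logged and skipped; the run continues.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    if dry_run:
        print(json.dumps(cfg, indent=2, default=str))
        return None
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(cfg, indent=2, default=str))
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger(__package__).addHandler(fh)
    frames = []
    try:
        for rep in range(cfg["replicates"]):
            cached = out / f"replicate_{rep:03d}.tsv"
            if cached.exists():
                logger.info("replicate %d: loading cached results", rep)
                frames.append(pd.read_csv(cached, sep="\t"))
                continue
            try:
                frames.append(run_replicate(cfg, rep, out_dir=out))
            except Exception:  # noqa: BLE001 - one bad replicate must not kill the run
                logger.exception("replicate %d failed; continuing", rep)
    finally:
        logging.getLogger(__package__).removeHandler(fh)
        fh.close()
    if not frames:
        raise RuntimeError("no replicate produced results")
    results = pd.concat(frames, ignore_index=True)
    results.to_csv(out / "results.tsv", sep="\t", index=False)
    summary = (results.groupby(["method", "trait", "group"])["accuracy"]
               .agg(["mean", "std", "count"]).reset_index())
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(
        summary.to_json(orient="records", indent=2))
    return results
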