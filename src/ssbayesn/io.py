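"""Plain-text I/O for simulated data sets and chain persistence.

Pedigree, genotypes, phenotypes, mask flags, marker and region maps are
written as TSV (0 codes an unknown parent in exported pedigrees; missing
phenotypes are empty cells). Posterior chains are stored as an ``.npz``
container with named arrays plus a JSON sidecar of the chain options.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mcmc import ChainOptions, PosteriorChain

__all__ = [
    "write_pedigree", "read_pedigree",
    "write_genotypes", "read_genotypes", "read_plink_raw",
    "write_phenotypes", "read_phenotypes",
    "write_mask", "read_mask",
    "write_marker_map", "write_region_map",
    "save_chain", "load_chain",
]


def write_pedigree(path, pop) -> None:
    """TSV: id, sire, dam, sex (M/F), generation; ids 1-based, 0 unknown."""
    df = pd.DataFrame({
        "id": np.arange(pop.n_ind) + 1,
        "sire": pop.sire + 1,
        "dam": pop.dam + 1,
        "sex": np.where(pop.sex == 0, "M", "F"),
        "generation": pop.generation,
    })
    df.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"id", "sire", "dam"}
    if not need <= set(df.columns):
        raise ValueError(f"pedigree file needs columns {sorted(need)}")
    return df


def write_genotypes(path, genotypes: np.ndarray, snp_ids=None) -> None:
    """TSV matrix of allele counts 0/1/2 with a SNP-id header row."""
    k = genotypes.shape[1]
    cols = snp_ids if snp_ids is not None else [f"snp{j + 1}" for j in range(k)]
    pd.DataFrame(genotypes, columns=cols).to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy()


def read_plink_raw(path) -> np.ndarray:
    """Additive coding from a PLINK ``--recode A`` style file: the six
    leading metadata columns are dropped, NA imputed to the column mean."""
    df = pd.read_csv(path, sep=r"\s+")
    meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
            if c in df.columns]
    M = df.drop(columns=meta).to_numpy(dtype=float)
    if np.isnan(M).any():
        col_mean = np.nanmean(M, axis=0)
        idx = np.where(np.isnan(M))
        M[idx] = col_mean[idx[1]]
    return M


def write_phenotypes(path, y_obs: np.ndarray, trait_names=("trait_L", "trait_H")) -> None:
    """TSV with one row per animal; masked phenotypes are empty cells."""
    df = pd.DataFrame(y_obs, columns=list(trait_names))
    df.insert(0, "id", np.arange(len(df)) + 1)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_phenotypes(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df.drop(columns=["id"]).to_numpy(dtype=float)


def write_mask(path, masked) -> None:
    df = pd.DataFrame({
        "id": np.arange(masked.genotyped.size) + 1,
        "genotyped": masked.genotyped.astype(int),
        "phenotyped": masked.phenotyped.astype(int),
        "validation": masked.validation.astype(int),
    })
    df.to_csv(path, sep="\t", index=False)


def read_mask(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_marker_map(path, chrom, index, snp_ids=None) -> None:
    k = len(chrom)
    ids = snp_ids if snp_ids is not None else [f"snp{j + 1}" for j in range(k)]
    pd.DataFrame({"snp": ids, "chr": chrom, "index": index}).to_csv(
        path, sep="\t", index=False)


def write_region_map(path, chrom, regions) -> None:
    k = regions.region_of_snp.size
    pd.DataFrame({
        "snp": [f"snp{j + 1}" for j in range(k)],
        "chr": chrom,
        "region": regions.region_of_snp,
    }).to_csv(path, sep="\t", index=False)


def save_chain(path, chain: PosteriorChain) -> None:
    """Persist a chain as npz (named datasets) + a JSON options sidecar."""
    path = Path(path)
    arrays = {"mu": chain.mu, "alpha": chain.alpha, "B": chain.B,
              "R0": chain.R0}
    if chain.eps is not None:
        arrays["eps"] = chain.eps
    if chain.G0 is not None:
        arrays["G0"] = chain.G0
    if chain.region_sizes is not None:
        arrays["region_sizes"] = chain.region_sizes
    np.savez_compressed(path, **arrays)
    if chain.options is not None:
        side = path.with_suffix(".json")
        side.write_text(json.dumps({
            "n_iter": chain.options.n_iter,
            "burn_in": chain.options.burn_in,
            "thin": chain.options.thin,
            "seed": chain.options.seed,
        }, indent=2))


def load_chain(path) -> PosteriorChain:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as z:
        opts = None
        side = path.with_suffix(".json")
        if side.exists():
            opts = ChainOptions(**json.loads(side.read_text()))
        return PosteriorChain(
            mu=z["mu"], alpha=z["alpha"], B=z["B"], R0=z["R0"],
            eps=z["eps"] if "eps" in z else None,
            G0=z["G0"] if "G0" in z else None,
            options=opts,
            region_sizes=z["region_sizes"] if "region_sizes" in z else None,
        )
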