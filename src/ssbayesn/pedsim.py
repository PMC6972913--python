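"""Forward-in-time simulation of a dairy-cattle-like breeding population.

The generator produces founder haplotypes with tunable linkage
disequilibrium, five (by default) generations of random mating with a 1:10
sire:dam ratio, a QTL set with a target mean minor allele frequency,
bivariate QTL effects under two scenarios (correlated gammas, "G9", or a
bivariate normal, "N5"), phenotypes for a low- and a high-heritability
trait, and the genotype/phenotype masking design used to define training
and validation sets.

Founder haplotypes are synthetic: allele frequencies are drawn from a Beta
law and each haplotype is a first-order Markov chain along the chromosome,
so adjacent markers are in LD with a tunable correlation and chromosomes
are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "HaplotypePanel",
    "SimPopulation",
    "QtlSet",
    "TraitData",
    "MaskDesign",
    "MaskedData",
    "simulate_founders",
    "forward_breed",
    "select_qtl",
    "assign_qtl_groups",
    "simulate_effects_g9",
    "simulate_effects_n5",
    "simulate_phenotypes",
    "apply_mask",
]

PLEIOTROPIC, L_ONLY, H_ONLY = 0, 1, 2


@dataclass
class HaplotypePanel:
    """Founder haplotypes plus the marker map.

    ``haplotypes`` has shape (2 * n_ind, n_snp); rows 2i and 2i+1 belong to
    individual i. ``chrom``/``index`` give each SNP's chromosome id and
    within-chromosome index (sorted). ``morgan`` is the genetic length of
    each chromosome in Morgans.
    """

    haplotypes: np.ndarray
    chrom: np.ndarray
    index: np.ndarray
    morgan: np.ndarray

    @property
    def n_ind(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_snp(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class SimPopulation:
    """A simulated population: complete pedigree, haplotypes and genotypes.

    Parent codes are -1 for unknown (founders). ``sex`` is 0 for males and
    1 for females. ``genotypes`` holds allele counts 0/1/2 and always
    equals the sum of the two haplotype rows of each animal.
    """

    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    generation: np.ndarray
    haplotypes: np.ndarray
    genotypes: np.ndarray
    chrom: np.ndarray
    index: np.ndarray
    morgan: np.ndarray

    @property
    def n_ind(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snp(self) -> int:
        return self.genotypes.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Population-wide allele frequency p_j of the counted allele."""
        return self.genotypes.mean(axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)


@dataclass
class QtlSet:
    """Selected QTL, their group labels and bivariate additive effects.

    ``group`` is 0 (pleiotropic), 1 (trait-L only) or 2 (trait-H only);
    None until :func:`assign_qtl_groups` has run. ``effects`` is (n_qtl, 2)
    with columns (gamma_L, gamma_H); None until effects are simulated.
    Trait-L-only QTL have gamma_H == 0 and vice versa.
    """

    indices: np.ndarray
    mean_maf: float
    group: Optional[np.ndarray] = None
    effects: Optional[np.ndarray] = None

    @property
    def n_qtl(self) -> int:
        return self.indices.size

    def analysis_snps(self, n_snp: int) -> np.ndarray:
        """Indices of markers kept for analysis (QTL are excluded)."""
        keep = np.ones(n_snp, dtype=bool)
        keep[self.indices] = False
        return np.flatnonzero(keep)


@dataclass
class TraitData:
    """True breeding values, phenotypes and residual variances (L, H)."""

    tbv: np.ndarray  # (n_ind, 2)
    phenotypes: np.ndarray  # (n_ind, 2)
    residual_var: np.ndarray  # (2,)


@dataclass
class MaskDesign:
    """Which animals keep genotypes / phenotypes in the released data.

    The default mirrors the training/validation layout of the simulated
    Holstein-like design: early generations contribute pedigree only; in
    each training generation every male is genotyped (no phenotype), a
    random subset of females is genotyped and phenotyped and the remaining
    females are phenotyped only; in the validation generation a random
    subset of animals is genotyped but carries no phenotype.
    """

    train_generations: tuple = (3, 4)
    val_generation: int = 5
    n_geno_females: int = 500
    n_val_genotyped: int = 500

    @classmethod
    def none(cls) -> "MaskDesign":
        """Sentinel design: nothing masked (all genotyped + phenotyped)."""
        d = cls(train_generations=(), val_generation=-1,
                n_geno_females=0, n_val_genotyped=0)
        d._unmasked = True
        return d


@dataclass
class MaskedData:
    """Boolean flags per animal after applying a :class:`MaskDesign`."""

    genotyped: np.ndarray
    phenotyped: np.ndarray
    validation: np.ndarray
    y_obs: np.ndarray  # (n_ind, 2), NaN where masked


def _check_finite(name, value):
    if not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must be finite, got {value!r}")


def simulate_founders(
    n_ind: int,
    n_chr: int = 5,
    snps_per_chr: int = 400,
    maf_beta: tuple = (1.0, 1.0),
    ld_rho: float = 0.7,
    morgan_per_chr: float = 1.0,
    seed: int = 0,
) -> HaplotypePanel:
    """Simulate a founder haplotype panel with LD between adjacent SNPs.

    Allele frequencies are Beta(*maf_beta*) draws (clipped away from the
    boundaries so every locus segregates). Haplotype alleles follow a
    first-order Markov chain along each chromosome with Pearson
    correlation ``ld_rho`` between adjacent allele indicators; chromosomes
    are independent.
    """
    if n_ind < 2:
        raise ValueError(f"n_ind must be >= 2, got {n_ind}")
    if snps_per_chr < 1:
        raise ValueError(f"snps_per_chr must be >= 1, got {snps_per_chr}")
    if n_chr < 1:
        raise ValueError(f"n_chr must be >= 1, got {n_chr}")
    _check_finite("ld_rho", ld_rho)
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError(f"ld_rho must be in [0, 1), got {ld_rho}")
    a, b = maf_beta
    _check_finite("maf_beta", np.asarray(maf_beta, dtype=float))
    if a <= 0 or b <= 0:
        raise ValueError(f"maf_beta shape parameters must be > 0, got {maf_beta}")
    _check_finite("morgan_per_chr", morgan_per_chr)
    if morgan_per_chr <= 0:
        raise ValueError(f"morgan_per_chr must be > 0, got {morgan_per_chr}")

    rng = np.random.default_rng(seed)
    k = n_chr * snps_per_chr
    p = np.clip(rng.beta(a, b, size=k), 0.03, 0.97)
    nh = 2 * n_ind
    hap = np.empty((nh, k), dtype=np.uint8)
    for c in range(n_chr):
        lo = c * snps_per_chr
        hap[:, lo] = rng.random(nh) < p[lo]
        for j in range(lo + 1, lo + snps_per_chr):
            pj, pm = p[j], p[j - 1]
            slope = ld_rho * np.sqrt(pj * (1 - pj) / (pm * (1 - pm)))
            cond = np.clip(pj + slope * (hap[:, j - 1] - pm), 0.0, 1.0)
            hap[:, j] = rng.random(nh) < cond
    chrom = np.repeat(np.arange(n_chr), snps_per_chr)
    index = np.tile(np.arange(snps_per_chr), n_chr)
    morgan = np.full(n_chr, float(morgan_per_chr))
    return HaplotypePanel(hap, chrom, index, morgan)


def _meiosis(hap_pair: np.ndarray, chrom_slices, genetic_pos, morgan, rng) -> np.ndarray:
    """Form one gamete from a (2, k) haplotype pair, Haldane recombination."""
    k = hap_pair.shape[1]
    gamete = np.empty(k, dtype=np.uint8)
    for (sl, pos, length) in zip(chrom_slices, genetic_pos, morgan):
        n_cross = rng.poisson(length)
        start = rng.integers(2)
        if n_cross == 0:
            gamete[sl] = hap_pair[start, sl]
            continue
        cross = np.sort(rng.random(n_cross) * length)
        parity = (start + np.searchsorted(cross, pos)) % 2
        seg = hap_pair[:, sl]
        gamete[sl] = np.where(parity == 0, seg[0], seg[1])
    return gamete


def forward_breed(
    panel: HaplotypePanel,
    n_generations: int = 5,
    n_males: int = 200,
    n_females: int = 2000,
    seed: int = 0,
) -> SimPopulation:
    """Random mating forward of a founder panel.

    Each generation keeps exactly ``n_males`` males and ``n_females``
    females among the parents. Every sire is mated to ten distinct dams
    (dams are partitioned at random, one offspring each) and additionally
    repeats one mating with one of his ten dams, so each non-founder
    generation has ``n_females + n_males`` offspring. Gametes recombine
    under the Haldane model (Poisson crossovers, expectation one per
    Morgan). The pedigree is complete back to the founders.
    """
    if n_females != 10 * n_males:
        raise ValueError(
            "the mating scheme requires a 1:10 sire:dam ratio "
            f"(n_females == 10 * n_males); got {n_males} males, {n_females} females"
        )
    if panel.n_ind < n_males + n_females:
        raise ValueError(
            f"panel has {panel.n_ind} founders but {n_males + n_females} parents are needed"
        )
    rng = np.random.default_rng(seed)
    n0 = panel.n_ind
    k = panel.n_snp
    n_chr = panel.morgan.size

    chrom_slices = []
    genetic_pos = []
    for c in range(n_chr):
        cols = np.flatnonzero(panel.chrom == c)
        sl = slice(cols[0], cols[-1] + 1)
        chrom_slices.append(sl)
        m = cols.size
        genetic_pos.append((np.arange(m) + 0.5) / m * panel.morgan[c])

    # founder sexes: a random subset of exactly n_males is male
    sex0 = np.ones(n0, dtype=np.int8)
    males0 = rng.choice(n0, size=n_males, replace=False)
    sex0[males0] = 0

    sire = [np.full(n0, -1, dtype=np.int64)]
    dam = [np.full(n0, -1, dtype=np.int64)]
    sex = [sex0]
    gen = [np.zeros(n0, dtype=np.int64)]
    haps = [panel.haplotypes.copy()]

    offset_prev = 0
    n_prev = n0
    sex_prev = sex0
    for g in range(1, n_generations + 1):
        prev_ids = offset_prev + np.arange(n_prev)
        sires_g = prev_ids[sex_prev == 0]
        dams_g = prev_ids[sex_prev == 1]
        if sires_g.size < n_males or dams_g.size < n_females:
            raise ValueError("previous generation lacks enough males or females")
        sires_g = rng.permutation(sires_g)[:n_males]
        dams_g = rng.permutation(dams_g)[:n_females]
        dam_chunks = dams_g.reshape(n_males, 10)
        s_list = np.repeat(sires_g, 10)
        d_list = dam_chunks.reshape(-1)
        # one repeat mating per sire with one of his ten dams
        repeat_d = dam_chunks[np.arange(n_males), rng.integers(0, 10, n_males)]
        s_list = np.concatenate([s_list, sires_g])
        d_list = np.concatenate([d_list, repeat_d])
        n_off = s_list.size  # n_females + n_males

        hap_all = np.vstack(haps) if len(haps) > 1 else haps[0]
        off_h = np.empty((2 * n_off, k), dtype=np.uint8)
        for i in range(n_off):
            sp = hap_all[2 * s_list[i]:2 * s_list[i] + 2]
            dp = hap_all[2 * d_list[i]:2 * d_list[i] + 2]
            off_h[2 * i] = _meiosis(sp, chrom_slices, genetic_pos, panel.morgan, rng)
            off_h[2 * i + 1] = _meiosis(dp, chrom_slices, genetic_pos, panel.morgan, rng)

        sex_g = np.ones(n_off, dtype=np.int8)
        sex_g[rng.choice(n_off, size=n_males, replace=False)] = 0

        sire.append(s_list)
        dam.append(d_list)
        sex.append(sex_g)
        gen.append(np.full(n_off, g, dtype=np.int64))
        haps.append(off_h)
        offset_prev += n_prev
        n_prev = n_off
        sex_prev = sex_g

    hap_full = np.vstack(haps)
    genotypes = (hap_full[0::2].astype(np.uint8) + hap_full[1::2]).astype(np.uint8)
    return SimPopulation(
        sire=np.concatenate(sire),
        dam=np.concatenate(dam),
        sex=np.concatenate(sex),
        generation=np.concatenate(gen),
        haplotypes=hap_full,
        genotypes=genotypes,
        chrom=panel.chrom.copy(),
        index=panel.index.copy(),
        morgan=panel.morgan.copy(),
    )


def select_qtl(
    pop: SimPopulation,
    n_qtl: int = 200,
    target_mean_maf: float = 0.15,
    tol: float = 0.005,
    seed: int = 0,
    max_swaps: int = 200_000,
) -> QtlSet:
    """Randomly select QTL subject to a target mean minor allele frequency.

    Starts from a plain random draw among segregating SNPs and performs
    random pair swaps, accepting a swap whenever it moves the mean MAF
    towards ``target_mean_maf``. Swapping continues into a band well inside
    ``tol`` (a fifth of it) so the achieved mean is centered on the target
    rather than stopping at the tolerance edge; the guarantee remains
    |mean - target| <= tol.
    """
    maf = pop.maf
    candidates = np.flatnonzero(maf > 0)
    if candidates.size < n_qtl:
        raise ValueError(f"only {candidates.size} segregating SNPs for {n_qtl} QTL")
    rng = np.random.default_rng(seed)
    sel = rng.choice(candidates, size=n_qtl, replace=False)
    in_sel = np.zeros(pop.n_snp, dtype=bool)
    in_sel[sel] = True
    rest = candidates[~in_sel[candidates]]
    cur = maf[sel].mean()
    best = abs(cur - target_mean_maf)
    inner = 0.2 * tol
    swaps = 0
    while best > inner and swaps < max_swaps and rest.size > 0:
        i = rng.integers(n_qtl)
        j = rng.integers(rest.size)
        new = cur + (maf[rest[j]] - maf[sel[i]]) / n_qtl
        if abs(new - target_mean_maf) < best:
            sel[i], rest[j] = rest[j], sel[i]
            cur = new
            best = abs(cur - target_mean_maf)
        swaps += 1
    if best > tol:
        raise RuntimeError(
            f"could not reach mean MAF {target_mean_maf} +- {tol}; "
            f"best achieved {cur:.4f}"
        )
    sel = np.sort(sel)
    return QtlSet(indices=sel, mean_maf=float(maf[sel].mean()))


def assign_qtl_groups(qtl: QtlSet, p_pleiotropic: float = 0.82, seed: int = 0) -> QtlSet:
    """Assign each QTL to pleiotropic / trait-L-only / trait-H-only groups.

    floor(p * n) QTL are pleiotropic; the remainder is split in half
    between L-only and H-only, with an odd leftover going to L-only.
    Assignment of which QTL lands in which group is random.
    """
    if not (0.0 <= p_pleiotropic <= 1.0):
        raise ValueError(f"p_pleiotropic must be in [0, 1], got {p_pleiotropic}")
    n = qtl.n_qtl
    n_p = int(np.floor(p_pleiotropic * n))
    rem = n - n_p
    n_l = rem - rem // 2  # odd leftover goes to the L-only group
    n_h = rem // 2
    rng = np.random.default_rng(seed)
    group = np.concatenate([
        np.full(n_p, PLEIOTROPIC, dtype=np.int8),
        np.full(n_l, L_ONLY, dtype=np.int8),
        np.full(n_h, H_ONLY, dtype=np.int8),
    ])
    rng.shuffle(group)
    return QtlSet(indices=qtl.indices, mean_maf=qtl.mean_maf, group=group,
                  effects=qtl.effects)


@lru_cache(maxsize=None)
def _copula_rho(shape: float, target_pearson: float) -> float:
    """Gaussian-copula correlation that yields a target Pearson correlation
    for two Gamma(shape) marginals (scale cancels). Solved with 64-node
    Gauss-Hermite quadrature and Brent's method."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    w = weights / np.sqrt(2 * np.pi)

    def _gq(z):
        # clip away from 1.0 so the gamma quantile stays finite at the
        # outermost nodes (their quadrature weight is negligible anyway)
        u = np.clip(stats.norm.cdf(z), 1e-16, 1 - 1e-12)
        return stats.gamma.ppf(u, shape)

    f = _gq(nodes)
    mu = shape
    var = shape

    def pearson(rho_z):
        z2 = rho_z * nodes[:, None] + np.sqrt(1 - rho_z**2) * nodes[None, :]
        f2 = _gq(z2)
        exy = np.einsum("i,j,i,ij->", w, w, f, f2)
        return (exy - mu * mu) / var

    lo, hi = 0.0, 0.999999
    if pearson(hi) < target_pearson:
        raise ValueError(f"target correlation {target_pearson} not attainable")
    return float(optimize.brentq(lambda r: pearson(r) - target_pearson, lo, hi,
                                 xtol=1e-6))


def simulate_effects_g9(
    qtl: QtlSet,
    gamma_shape: float = 0.4,
    gamma_scale: float = 1.66,
    rho: float = 0.9,
    p_pos_corr: float = 0.78,
    seed: int = 0,
) -> QtlSet:
    """Scenario G9: pleiotropic effects are correlated gamma variables.

    Effect magnitudes of pleiotropic QTL have Gamma(shape, scale) marginals
    with Pearson correlation ``rho`` (Gaussian copula, calibrated on the
    raw scale). A fraction ``p_pos_corr`` of pleiotropic QTL keeps both
    effects on a common random sign (positive effect correlation); for the
    remainder the sign of one randomly chosen trait is switched (negative
    correlation). Single-trait QTL get one gamma draw with random sign and
    zero on the other trait.
    """
    if qtl.group is None:
        raise ValueError("QTL groups must be assigned before simulating effects")
    if not (-1.0 < rho < 1.0):
        raise ValueError(f"rho must be in (-1, 1), got {rho}")
    if gamma_shape <= 0 or gamma_scale <= 0:
        raise ValueError("gamma_shape and gamma_scale must be > 0")
    rng = np.random.default_rng(seed)
    n = qtl.n_qtl
    eff = np.zeros((n, 2))
    pleio = np.flatnonzero(qtl.group == PLEIOTROPIC)
    n_p = pleio.size
    if n_p:
        rho_z = _copula_rho(float(gamma_shape), float(rho)) if rho > 0 else 0.0
        z1 = rng.standard_normal(n_p)
        z2 = rho_z * z1 + np.sqrt(1 - rho_z**2) * rng.standard_normal(n_p)
        x1 = stats.gamma.ppf(stats.norm.cdf(z1), gamma_shape, scale=gamma_scale)
        x2 = stats.gamma.ppf(stats.norm.cdf(z2), gamma_shape, scale=gamma_scale)
        common_sign = rng.choice([-1.0, 1.0], size=n_p)
        eff[pleio, 0] = x1 * common_sign
        eff[pleio, 1] = x2 * common_sign
        n_pos = int(np.floor(p_pos_corr * n_p))
        neg = rng.permutation(n_p)[n_pos:]
        which = rng.integers(0, 2, size=neg.size)
        eff[pleio[neg], which] *= -1.0
    for grp, col in ((L_ONLY, 0), (H_ONLY, 1)):
        idx = np.flatnonzero(qtl.group == grp)
        draws = rng.gamma(gamma_shape, gamma_scale, size=idx.size)
        eff[idx, col] = draws * rng.choice([-1.0, 1.0], size=idx.size)
    return QtlSet(indices=qtl.indices, mean_maf=qtl.mean_maf, group=qtl.group,
                  effects=eff)


def simulate_effects_n5(qtl: QtlSet, rho: float = 0.5, seed: int = 0) -> QtlSet:
    """Scenario N5: pleiotropic effects from a standard bivariate normal
    with correlation ``rho``; single-trait QTL get independent N(0, 1)."""
    if qtl.group is None:
        raise ValueError("QTL groups must be assigned before simulating effects")
    if not (-1.0 < rho < 1.0):
        raise ValueError(f"rho must be in (-1, 1), got {rho}")
    rng = np.random.default_rng(seed)
    n = qtl.n_qtl
    eff = np.zeros((n, 2))
    pleio = np.flatnonzero(qtl.group == PLEIOTROPIC)
    z1 = rng.standard_normal(pleio.size)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(pleio.size)
    eff[pleio, 0] = z1
    eff[pleio, 1] = z2
    for grp, col in ((L_ONLY, 0), (H_ONLY, 1)):
        idx = np.flatnonzero(qtl.group == grp)
        eff[idx, col] = rng.standard_normal(idx.size)
    return QtlSet(indices=qtl.indices, mean_maf=qtl.mean_maf, group=qtl.group,
                  effects=eff)


def simulate_phenotypes(
    pop: SimPopulation,
    qtl: QtlSet,
    h2: tuple = (0.1, 0.4),
    seed: int = 0,
) -> TraitData:
    """True breeding values and phenotypes for the two traits.

    g_t = M_qtl gamma_t for every animal. Residual variances are set from
    the realized genetic variance in the founder generation,
    sigma2_e = var(g_gen0) (1 - h2) / h2, and residuals are drawn
    independently per trait (zero residual covariance). y = g + e.
    """
    if qtl.effects is None:
        raise ValueError("QTL effects must be simulated before phenotypes")
    h2 = np.asarray(h2, dtype=float)
    if np.any(h2 <= 0) or np.any(h2 > 1):
        raise ValueError(f"heritabilities must be in (0, 1], got {h2}")
    rng = np.random.default_rng(seed)
    M_qtl = pop.genotypes[:, qtl.indices].astype(float)
    g = M_qtl @ qtl.effects  # (n_ind, 2)
    founders = pop.generation == 0
    var_g0 = g[founders].var(axis=0, ddof=1)
    sigma2_e = var_g0 * (1.0 - h2) / h2
    e = rng.standard_normal(g.shape) * np.sqrt(sigma2_e)
    return TraitData(tbv=g, phenotypes=g + e, residual_var=sigma2_e)


def apply_mask(
    pop: SimPopulation,
    traits: TraitData,
    design: Optional[MaskDesign] = None,
    seed: int = 0,
) -> MaskedData:
    """Mask genotypes/phenotypes according to the training/validation design.

    With ``design=None`` nothing is masked. Otherwise: generations before
    the training ones contribute pedigree only; in training generations
    all males are genotyped without phenotypes, ``n_geno_females`` random
    females are genotyped + phenotyped, remaining females are phenotyped
    only; in the validation generation ``n_val_genotyped`` random animals
    are genotyped and none has a phenotype.
    """
    n = pop.n_ind
    if design is None or getattr(design, "_unmasked", False):
        ones = np.ones(n, dtype=bool)
        return MaskedData(genotyped=ones.copy(), phenotyped=ones.copy(),
                          validation=np.zeros(n, dtype=bool),
                          y_obs=traits.phenotypes.copy())
    rng = np.random.default_rng(seed)
    genotyped = np.zeros(n, dtype=bool)
    phenotyped = np.zeros(n, dtype=bool)
    validation = np.zeros(n, dtype=bool)
    for g in design.train_generations:
        in_g = pop.generation == g
        males = np.flatnonzero(in_g & (pop.sex == 0))
        females = np.flatnonzero(in_g & (pop.sex == 1))
        if females.size < design.n_geno_females:
            raise ValueError(
                f"generation {g} has {females.size} females; "
                f"{design.n_geno_females} genotyped females requested"
            )
        genotyped[males] = True
        gf = rng.choice(females, size=design.n_geno_females, replace=False)
        genotyped[gf] = True
        phenotyped[females] = True
    val_pool = np.flatnonzero(pop.generation == design.val_generation)
    if val_pool.size < design.n_val_genotyped:
        raise ValueError(
            f"validation generation {design.val_generation} has {val_pool.size} "
            f"animals; {design.n_val_genotyped} genotyped requested"
        )
    vg = rng.choice(val_pool, size=design.n_val_genotyped, replace=False)
    genotyped[vg] = True
    validation[vg] = True
    y_obs = np.where(phenotyped[:, None], traits.phenotypes, np.nan)
    return MaskedData(genotyped=genotyped, phenotyped=phenotyped,
                      validation=validation, y_obs=y_obs)
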