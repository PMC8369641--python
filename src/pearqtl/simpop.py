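"""Synthetic pear breeding populations with sugar-conversion genetics.

Emulates the structure of a fruit-breeding GWAS panel: a cultivar
collection plus many biparental F1 full-sib families, genotyped at tag
SNPs on 17 chromosomes, with linkage disequilibrium decaying over a few
hundred kilobases and a handful of large-effect QTLs that convert
sucrose into hexoses in mature fruit.

Founder haplotypes come from a first-order copying chain: a latent
Gaussian AR(1) process along each chromosome, thresholded at the
per-marker allele-frequency quantile.  The chain's correlation length is
calibrated so the expected pairwise dosage r² at ``ld_range_bp``
equals the requested level (0.2 by default, the point where LD decays
past usefulness for tagging).  Progeny are produced by Poisson
crossovers on a Haldane (no-interference) map.

The trait model is generative rather than multivariate-normal: a latent
total sugar pool T is split into sucrose and hexoses by a conversion
score c (logistic in the conversion-QTL dosages), and the hexose pool is
split into fructose and glucose by a share h.  This reproduces the
signature of the real material — one locus that raises sucrose while
lowering fructose+glucose with total sugar nearly unchanged, and the
strong negative sucrose-glucose correlation.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .geno_io import FamilyStructure, GenotypeMatrix

__all__ = [
    "SimConfig", "QTLSpec", "SugarTraitModel", "HaplotypePanel",
    "simulate_founders", "simulate_meiosis", "build_population",
    "assign_qtl_effects", "simulate_sugar_phenotypes", "encode_harvest_day",
    "pear_default_config", "pear_default_trait_model", "simulate_pear_study",
]


class SimError(ValueError):
    pass


# 17 default F1 family sizes (two smallest real families merged so that
# all sizes sit in [28, 121] and the total F1 count is 1112).
PEAR_FAMILY_SIZES = (106, 62, 47, 78, 38, 36, 70, 51, 100, 62, 121, 49, 39,
                     74, 72, 46, 61)


@dataclass
class SimConfig:
    """Population-level simulation settings.

    Defaults mirror a Japanese-pear breeding panel: 106 cultivars, 17 F1
    families of 28-121 individuals (1112 F1, 1218 total), 17 chromosomes
    with ~205 tag SNPs each (~3500 genome-wide), and mean r² decaying to
    0.2 by 250 kb.
    """

    n_founders: int = 13
    n_cultivars: int = 106
    family_sizes: tuple[int, ...] = PEAR_FAMILY_SIZES
    family_size_bounds: tuple[int, int] = (28, 121)
    n_chromosomes: int = 17
    chrom_length_bp: int = 30_000_000
    chrom_length_morgans: float = 1.0
    n_markers_per_chrom: int = 205
    ld_range_bp: int = 250_000
    ld_target_r2: float = 0.2
    maf_range: tuple[float, float] = (0.05, 0.95)
    chrom0_fraction: float = 0.0  # fraction of markers relabelled to the fictive chromosome "0"
    cultivar_generations: int = 2
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_founders, self.n_cultivars, self.n_chromosomes,
                  self.n_markers_per_chrom)
        if any(c < 1 for c in counts):
            raise SimError("all counts must be >= 1")
        lo, hi = self.family_size_bounds
        for s in self.family_sizes:
            if not (lo <= s <= hi):
                raise SimError(
                    f"family size {s} outside declared bounds [{lo}, {hi}]")
        if not (0.0 < self.ld_target_r2 < 1.0):
            raise SimError("ld_target_r2 must be in (0,1)")


@dataclass
class QTLSpec:
    """A simulated QTL.

    ``mode='direct'`` adds ``a * dosage`` to the target trait, with ``a``
    chosen so the realised variance share equals ``target_pve``.
    ``mode='conversion'`` acts on a latent logistic channel:
    ``channel='suc_to_hex'`` shifts the sucrose-to-hexose conversion
    score, ``channel='fru_to_glc'`` shifts the hexose split toward
    glucose; the logit effect is obtained from ``target_pve`` by a delta-
    method linearisation at the channel mean.  ``allele=+1`` puts the
    effect on the alternate allele; ``-1`` flips it.
    """

    chromosome: int
    position: int
    mode: str = "direct"
    target_traits: tuple[str, ...] = ()
    target_pve: float = 0.1
    allele: int = 1
    channel: str = "suc_to_hex"

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_pve < 1.0):
            raise SimError("target_pve must be in [0, 1)")
        if self.mode not in ("direct", "conversion"):
            raise SimError(f"unknown QTL mode {self.mode!r}")


@dataclass
class HaplotypePanel:
    """Founder haplotypes (founders x 2 x markers, alleles in {0,1})."""

    haplotypes: np.ndarray
    markers: pd.DataFrame  # chrom, pos, gpos (Morgans), ref, alt

    def __post_init__(self) -> None:
        for chrom, idx in self.markers.groupby("chrom", sort=False).groups.items():
            if str(chrom) == "0":  # unassigned scaffolds carry no position order
                continue
            pos = self.markers["pos"].to_numpy()[np.asarray(idx)]
            if np.any(np.diff(pos) <= 0):
                raise SimError("marker positions must be strictly increasing "
                               "within a chromosome")

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]


def _binormal_p11(q1: np.ndarray, q2: np.ndarray, rho: float,
                  n_quad: int = 64) -> np.ndarray:
    """P(Z1 < q1, Z2 < q2) for standard bivariate normal, correlation rho.

    Gauss-Legendre quadrature over z1 in (-8, q1); vectorised over pairs.
    """
    lo = -8.0
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    # map nodes to (lo, q1) per pair
    half = (q1 - lo) / 2.0
    mid = (q1 + lo) / 2.0
    z = mid[:, None] + half[:, None] * nodes[None, :]
    s = max(np.sqrt(max(1.0 - rho * rho, 1e-12)), 1e-6)
    inner = stats.norm.cdf((q2[:, None] - rho * z) / s)
    return half * np.sum(weights[None, :] * stats.norm.pdf(z) * inner, axis=1)


def _indicator_r2(p1: np.ndarray, p2: np.ndarray, rho: float) -> np.ndarray:
    """Squared correlation of threshold indicators under latent corr rho."""
    q1 = stats.norm.ppf(p1)
    q2 = stats.norm.ppf(p2)
    p11 = _binormal_p11(q1, q2, rho)
    cov = p11 - p1 * p2
    return cov ** 2 / (p1 * (1 - p1) * p2 * (1 - p2))


def _calibrate_latent_rho(freqs: np.ndarray, target_r2: float,
                          rng: np.random.Generator) -> float:
    """Latent AR correlation at ld_range_bp hitting the structural r² target."""
    k = min(len(freqs), 400)
    p1 = rng.choice(freqs, size=k, replace=True)
    p2 = rng.choice(freqs, size=k, replace=True)

    def gap(rho: float) -> float:
        return float(np.mean(_indicator_r2(p1, p2, rho))) - target_r2

    hi = 1.0 - 1e-9
    if gap(hi) < 0:
        raise SimError(
            "LD calibration failure: target r² unattainable for these allele "
            "frequencies (no positive root)")
    return float(optimize.brentq(gap, 1e-6, hi, xtol=1e-6))


def simulate_founders(config: SimConfig,
                      latent_rho: float | None = None) -> HaplotypePanel:
    """Generate founder haplotypes by the calibrated copying chain.

    Per-marker allele frequencies are drawn from a U-shaped Beta(0.5,0.5)
    truncated to ``maf_range``.  A latent standard-normal AR(1) along each
    chromosome (correlation exp(-d/L) between markers d bp apart) is
    thresholded at the frequency quantile.  L is calibrated so the
    expected pairwise r² at ``ld_range_bp`` — including the finite-panel
    sampling floor 1/(2*n_founders - 1) — equals ``ld_target_r2``.
    Deterministic given ``config.seed``.

    ``latent_rho`` bypasses calibration and fixes the copying correlation
    at ``ld_range_bp`` directly (0 forces independent markers) — a
    diagnostic hook, not part of the study preset.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m_chr = config.n_markers_per_chrom
    n_hap = 2 * config.n_founders

    # allele frequencies: truncated arcsine-like Beta(0.5, 0.5)
    a, b = config.maf_range
    dist = stats.beta(0.5, 0.5)
    u = rng.uniform(dist.cdf(a), dist.cdf(b), size=config.n_chromosomes * m_chr)
    freqs = dist.ppf(u)

    if latent_rho is not None:
        rho_star = float(latent_rho)
    else:
        # structural target after removing the finite-panel floor
        floor = 1.0 / (n_hap - 1) if n_hap > 1 else 0.0
        if config.ld_target_r2 <= floor:
            raise SimError(
                "LD calibration failure: target r² is at or below the "
                "sampling floor of this founder count (no positive root)")
        target = (config.ld_target_r2 - floor) / (1.0 - floor)
        rho_star = _calibrate_latent_rho(freqs, target, rng)
    L = (-config.ld_range_bp / np.log(rho_star)
         if 0.0 < rho_star < 1.0 else 0.0)

    chroms, poss, gposs = [], [], []
    haps = np.empty((n_hap, config.n_chromosomes * m_chr), dtype=np.int8)
    col = 0
    for c in range(1, config.n_chromosomes + 1):
        pos = np.sort(rng.choice(
            np.arange(1, config.chrom_length_bp + 1), size=m_chr, replace=False))
        gpos = pos / config.chrom_length_bp * config.chrom_length_morgans
        pk = freqs[(c - 1) * m_chr:c * m_chr]
        qk = stats.norm.ppf(pk)
        z = np.empty((n_hap, m_chr))
        z[:, 0] = rng.standard_normal(n_hap)
        d = np.diff(pos)
        rho = np.exp(-d / L) if L > 0 else np.zeros(len(d))
        eps = rng.standard_normal((n_hap, m_chr - 1))
        for k in range(1, m_chr):
            z[:, k] = rho[k - 1] * z[:, k - 1] + np.sqrt(1 - rho[k - 1] ** 2) * eps[:, k - 1]
        haps[:, col:col + m_chr] = (z < qk[None, :]).astype(np.int8)
        chroms.extend([str(c)] * m_chr)
        poss.extend(pos.tolist())
        gposs.extend(gpos.tolist())
        col += m_chr

    markers = pd.DataFrame({
        "chrom": chroms, "pos": np.array(poss, dtype=int),
        "gpos": np.array(gposs), "ref": "A", "alt": "C",
    })
    if config.chrom0_fraction > 0:
        n0 = int(round(config.chrom0_fraction * len(markers)))
        pick = rng.choice(len(markers), size=n0, replace=False)
        markers.loc[pick, "chrom"] = "0"
    hap3 = haps.reshape(config.n_founders, 2, -1)
    return HaplotypePanel(hap3, markers)


def _chrom_slices(markers: pd.DataFrame) -> list[np.ndarray]:
    return [np.asarray(ix) for _, ix in
            markers.groupby("chrom", sort=False).groups.items()]


def simulate_meiosis(parent_haplotypes: np.ndarray, markers: pd.DataFrame,
                     chrom_lengths_m: dict[str, float],
                     rng: np.random.Generator) -> np.ndarray:
    """One gamete from a parent's two haplotypes.

    Crossover counts are Poisson with rate equal to the chromosome's
    genetic length in Morgans, crossover points uniform on the genetic
    map, no interference (Haldane).  A zero-length chromosome transmits a
    single randomly chosen haplotype.
    """
    gamete = np.empty(parent_haplotypes.shape[1], dtype=np.int8)
    for idx in _chrom_slices(markers):
        chrom = str(markers["chrom"].iloc[idx[0]])
        gpos = markers["gpos"].to_numpy()[idx]
        length = chrom_lengths_m.get(chrom, float(gpos.max() - gpos.min()) if len(gpos) else 0.0)
        phase0 = rng.integers(0, 2)
        if length <= 0:
            gamete[idx] = parent_haplotypes[phase0, idx]
            continue
        n_co = rng.poisson(length)
        if n_co == 0:
            gamete[idx] = parent_haplotypes[phase0, idx]
            continue
        xpts = np.sort(rng.uniform(gpos.min(), gpos.min() + length, size=n_co))
        phase = (phase0 + np.searchsorted(xpts, gpos, side="right")) % 2
        gamete[idx] = np.where(phase == 0,
                               parent_haplotypes[0, idx],
                               parent_haplotypes[1, idx])
    return gamete


def _offspring(mother: np.ndarray, father: np.ndarray, markers: pd.DataFrame,
               lengths: dict[str, float], rng: np.random.Generator) -> np.ndarray:
    g1 = simulate_meiosis(mother, markers, lengths, rng)
    g2 = simulate_meiosis(father, markers, lengths, rng)
    return np.stack([g1, g2])


def build_population(config: SimConfig, panel: HaplotypePanel
                     ) -> tuple[GenotypeMatrix, FamilyStructure]:
    """Cultivar collection plus F1 full-sib families from the founder panel.

    Cultivars are the founders advanced ``cultivar_generations`` rounds of
    random crossing (a stand-in for the unrecorded pedigree of a breeding
    program); each F1 family is the full-sib progeny of a random pair of
    distinct cultivars.  Dosage = sum of the two inherited gametic
    alleles at every marker.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_001]))
    markers = panel.markers
    lengths = {str(c): config.chrom_length_morgans
               for c in range(1, config.n_chromosomes + 1)}
    lengths["0"] = config.chrom_length_morgans  # relabelled markers keep their map

    current = [panel.haplotypes[i] for i in range(panel.n_founders)]
    for gen in range(config.cultivar_generations):
        nxt = []
        for _ in range(config.n_cultivars):
            i, j = rng.choice(len(current), size=2, replace=False)
            nxt.append(_offspring(current[i], current[j], markers, lengths, rng))
        current = nxt
    cultivars = current
    if len(cultivars) != config.n_cultivars:
        # zero generations: sample cultivars directly from founders
        idx = rng.choice(len(cultivars), size=config.n_cultivars, replace=True)
        cultivars = [cultivars[i] for i in idx]

    rows = [h.sum(axis=0) for h in cultivars]
    ids = [f"CUL{i + 1:03d}" for i in range(config.n_cultivars)]
    labels = ["collection"] * config.n_cultivars

    for f, size in enumerate(config.family_sizes, start=1):
        i, j = rng.choice(config.n_cultivars, size=2, replace=False)
        mother, father = cultivars[i], cultivars[j]
        fam = f"F{f:02d}"
        for k in range(size):
            child = _offspring(mother, father, markers, lengths, rng)
            rows.append(child.sum(axis=0))
            ids.append(f"{fam}_{k + 1:03d}")
            labels.append(fam)

    dosage = np.array(rows, dtype=float)
    g = GenotypeMatrix(dosage, markers[["chrom", "pos", "ref", "alt"]].copy()
                       .reset_index(drop=True), ids)
    # keep genetic positions available to downstream code
    g.markers["gpos"] = markers["gpos"].to_numpy()
    fam = FamilyStructure(pd.Series(labels, index=ids, name="family"))
    return g, fam


def assign_qtl_effects(qtl: QTLSpec, genotypes: GenotypeMatrix,
                       current_pheno_variance: float,
                       marker_index: int | None = None) -> float:
    """Additive effect size hitting the QTL's target variance share.

    a = sqrt(target_pve * Var(y) / Var(dosage)); the realised share of a
    trait with total variance ``current_pheno_variance`` then equals
    ``target_pve`` in expectation.
    """
    j = _resolve_marker(genotypes, qtl) if marker_index is None else marker_index
    x = genotypes.dosage[:, j]
    vx = float(np.var(x))
    if vx == 0.0:
        raise SimError(f"QTL marker at Chr{qtl.chromosome}:{qtl.position} is "
                       "monomorphic in this population")
    if qtl.target_pve == 0.0:
        return 0.0
    return float(qtl.allele) * float(
        np.sqrt(qtl.target_pve * current_pheno_variance / vx))


def _resolve_marker(g: GenotypeMatrix, qtl: QTLSpec) -> int:
    """Index of the marker nearest the QTL position on its chromosome."""
    mask = g.markers["chrom"].to_numpy() == str(qtl.chromosome)
    if not mask.any():
        raise SimError(f"no markers on chromosome {qtl.chromosome}")
    idx = np.flatnonzero(mask)
    pos = g.markers["pos"].to_numpy()[idx]
    return int(idx[np.argmin(np.abs(pos - qtl.position))])


# --- trait model -----------------------------------------------------------

#: (mean, phenotypic variance) anchors per trait, in trait units.
PEAR_TRAIT_STATS = {
    "SUC": (43.1, 355.6), "FRU": (40.6, 91.9), "GLC": (14.9, 64.3),
    "SOR": (32.2, 56.5), "TSC": (130.7, 125.2), "HarT": (62.0, 330.0),
    "FruW": (394.2, 14400.0), "FruH": (4.8, 1.2), "SSC": (13.8, 1.65),
    "Aci": (4.9, 0.12),
}

PEAR_HERITABILITIES = {
    "SUC": 0.64, "FRU": 0.69, "GLC": 0.71, "SOR": 0.76, "TSC": 0.33,
    "HarT": 0.70, "FruW": 0.55, "FruH": 0.50, "Aci": 0.60,
}


@dataclass
class SugarTraitModel:
    """Parameters of the generative sugar-trait model.

    ``heritabilities`` are narrow-ish targets enforced by a noise top-up
    (TSC, the exact sum of the four sugars, is emergent).
    ``family_variance`` is the family-deviation share of channel
    phenotypic variance.  ``split_coupling`` is the logit-h loading on
    logit-c deviations: conversion toward hexoses also tilts the hexose
    pool toward glucose, which the real material requires.
    """

    trait_stats: dict = field(default_factory=lambda: dict(PEAR_TRAIT_STATS))
    heritabilities: dict = field(default_factory=lambda: dict(PEAR_HERITABILITIES))
    family_variance: float = 0.05
    conversion_qtls: tuple[QTLSpec, ...] = ()
    direct_qtls: tuple[QTLSpec, ...] = ()
    conversion_mean: float = 0.5625     # mean sucrose->hexose score c
    hexose_split_mean: float = 0.733    # mean fructose share h of the hexose pool
    split_coupling: float = -0.95
    polygene_var_c: float = 0.22        # logit-scale polygenic variance of c
    polygene_var_h: float = 0.02
    noise_var_c: float = 0.13           # logit-scale environmental variance of c
    noise_var_h: float = 0.01
    n_polygenes: int = 200
    ssc_noise_sd: float = 0.50

    def validate(self) -> None:
        for t, h2 in self.heritabilities.items():
            if not (0.0 < h2 <= 1.0):
                raise SimError(f"heritability of {t} outside (0, 1]")


def pear_default_trait_model() -> SugarTraitModel:
    """Preset emulating the pear panel's QTL architecture.

    Conversion QTL on chromosome 7 (sucrose -> hexose, ~23.5% of SUC
    variance), hexose-split QTL on chromosome 11 (fructose -> glucose,
    ~21.7% of GLC variance), a direct fructose QTL on chromosome 4
    (~12.7%), harvest-time QTLs on chromosomes 3 and 15, and an acidity
    QTL on chromosome 6.
    """
    return SugarTraitModel(
        conversion_qtls=(
            QTLSpec(7, 24_000_000, mode="conversion", channel="suc_to_hex",
                    target_traits=("SUC", "FRU", "GLC"), target_pve=0.235,
                    allele=-1),
            QTLSpec(11, 27_000_000, mode="conversion", channel="fru_to_glc",
                    target_traits=("GLC", "FRU"), target_pve=0.217, allele=1),
        ),
        direct_qtls=(
            QTLSpec(4, 20_000_000, mode="direct", target_traits=("FRU",),
                    target_pve=0.127),
            QTLSpec(3, 21_000_000, mode="direct", target_traits=("HarT",),
                    target_pve=0.165),
            QTLSpec(15, 11_000_000, mode="direct", target_traits=("HarT",),
                    target_pve=0.203),
            QTLSpec(6, 14_000_000, mode="direct", target_traits=("Aci",),
                    target_pve=0.131),
        ),
    )


def pear_default_config(seed: int = 0) -> SimConfig:
    return SimConfig(seed=seed)


def _polygenic(rng: np.random.Generator, g: GenotypeMatrix, n_loci: int,
               var_target: float) -> np.ndarray:
    """Small random additive effects at random markers, scaled to var_target."""
    if var_target <= 0:
        return np.zeros(g.n_individuals)
    m = g.n_markers
    loci = rng.choice(m, size=min(n_loci, m), replace=False)
    u = rng.standard_normal(len(loci))
    val = g.dosage[:, loci] @ u
    v = val.var()
    if v == 0:
        return np.zeros(g.n_individuals)
    return (val - val.mean()) * np.sqrt(var_target / v)


def _family_effects(rng: np.random.Generator, codes: np.ndarray,
                    var_target: float) -> np.ndarray:
    if var_target <= 0:
        return np.zeros(len(codes))
    eff = rng.normal(0.0, np.sqrt(var_target), size=codes.max() + 1)
    return eff[codes]


@dataclass
class SimulatedPhenotypes:
    phenotypes: pd.DataFrame       # individuals x traits
    genetic_values: pd.DataFrame   # same shape, environmental noise zeroed
    qtl_markers: dict              # trait-channel -> marker index


def simulate_sugar_phenotypes(model: SugarTraitModel, genotypes: GenotypeMatrix,
                              families: FamilyStructure, seed: int = 0
                              ) -> SimulatedPhenotypes:
    """Draw all ten fruit traits for a simulated population.

    The latent total sugar pool T (= TSC) carries polygenes, family
    deviations and noise; conversion score c and hexose share h are
    logistic channels carrying the conversion QTLs; SOR is an independent
    channel; SUC/FRU/GLC partition (T - SOR); TSC is the exact sum.
    Environmental noise is topped up per trait so realised heritability
    matches the target.  Non-sugar traits are independent polygenic
    channels; SSC tracks TSC with a small refractometer error.
    """
    model.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11_003]))
    n = genotypes.n_individuals
    codes = families.codes_for(genotypes.ids)
    st = model.trait_stats
    h2 = model.heritabilities

    qtl_markers: dict[str, int] = {}

    def channel_effects(channel: str, mean_level: float) -> tuple[np.ndarray, float]:
        """Summed centered QTL contributions on a logit channel."""
        total = np.zeros(n)
        for q in model.conversion_qtls:
            if q.channel != channel:
                continue
            j = _resolve_marker(genotypes, q)
            qtl_markers[f"{channel}:{q.chromosome}"] = j
            x = genotypes.dosage[:, j]
            if x.var() == 0:
                raise SimError("conversion QTL marker does not segregate")
            trait = q.target_traits[0] if q.target_traits else "SUC"
            _, vy = st[trait]
            # delta-method: trait sensitivity to the logit channel
            t_minus_s = st["TSC"][0] - st["SOR"][0]
            cbar = model.conversion_mean
            hbar = model.hexose_split_mean
            if channel == "suc_to_hex":
                sens = t_minus_s * cbar * (1 - cbar)  # |dSUC/d logit c|
            else:
                sens = t_minus_s * cbar * hbar * (1 - hbar)  # |dGLC/d logit h|
            a_logit = np.sqrt(q.target_pve * vy / x.var()) / sens
            total += q.allele * a_logit * (x - x.mean())
        return total, mean_level

    # --- latent channels ---------------------------------------------------
    mu_T, var_T = st["TSC"]
    fam_var_T = model.family_variance * var_T
    gen_T = (_polygenic(rng, genotypes, model.n_polygenes,
                        max(h2["TSC"] * var_T - fam_var_T, 0.0))
             + _family_effects(rng, codes, fam_var_T))
    for q in model.direct_qtls:
        if q.target_traits == ("TSC",):
            j = _resolve_marker(genotypes, q)
            qtl_markers[f"TSC:{q.chromosome}"] = j
            a = assign_qtl_effects(q, genotypes, var_T, marker_index=j)
            x = genotypes.dosage[:, j]
            gen_T = gen_T + a * (x - x.mean())
    e_T = rng.normal(0.0, np.sqrt(max((1 - h2["TSC"]) * var_T, 0.0)), n)
    T = mu_T + gen_T + e_T
    T_gen = mu_T + gen_T

    qc, cbar = channel_effects("suc_to_hex", model.conversion_mean)
    qh, hbar = channel_effects("fru_to_glc", model.hexose_split_mean)
    poly_c = _polygenic(rng, genotypes, model.n_polygenes, model.polygene_var_c)
    poly_h = _polygenic(rng, genotypes, model.n_polygenes, model.polygene_var_h)
    e_c = rng.normal(0.0, np.sqrt(model.noise_var_c), n)
    e_h = rng.normal(0.0, np.sqrt(model.noise_var_h), n)

    def expit(v: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-v))

    logit = lambda p: np.log(p / (1 - p))
    eta_c_gen = logit(cbar) + qc + poly_c
    eta_c = eta_c_gen + e_c
    coup = model.split_coupling
    eta_h_gen = logit(hbar) + coup * (eta_c_gen - logit(cbar)) + qh + poly_h
    eta_h = logit(hbar) + coup * (eta_c - logit(cbar)) + qh + poly_h + e_h
    c, c_gen = expit(eta_c), expit(eta_c_gen)
    hshare, h_gen = expit(eta_h), expit(eta_h_gen)

    mu_S, var_S = st["SOR"]
    fam_var_S = model.family_variance * var_S
    gen_SOR = (_polygenic(rng, genotypes, model.n_polygenes,
                          max(h2["SOR"] * var_S - fam_var_S, 0.0))
               + _family_effects(rng, codes, fam_var_S))
    SOR_gen = mu_S + gen_SOR
    SOR = SOR_gen + rng.normal(0.0, np.sqrt((1 - h2["SOR"]) * var_S), n)

    pool = T - SOR
    pool_gen = T_gen - SOR_gen
    raw = {
        "SUC": pool * (1 - c),
        "FRU": pool * c * hshare,
        "GLC": pool * c * (1 - hshare),
        "SOR": SOR,
    }
    gen = {
        "SUC": pool_gen * (1 - c_gen),
        "FRU": pool_gen * c_gen * h_gen,
        "GLC": pool_gen * c_gen * (1 - h_gen),
        "SOR": SOR_gen,
    }

    # direct QTLs on individual sugars (e.g. the fructose transporter locus)
    for q in model.direct_qtls:
        for t in q.target_traits:
            if t in ("SUC", "FRU", "GLC", "SOR"):
                j = _resolve_marker(genotypes, q)
                qtl_markers[f"{t}:{q.chromosome}"] = j
                a = assign_qtl_effects(q, genotypes, st[t][1], marker_index=j)
                x = genotypes.dosage[:, j]
                raw[t] = raw[t] + a * (x - x.mean())
                gen[t] = gen[t] + a * (x - x.mean())

    # top-up noise so realised heritability hits the target
    pheno = {}
    for t in ("SUC", "FRU", "GLC", "SOR"):
        vg = gen[t].var()
        target_env = vg * (1 - h2[t]) / h2[t]
        current_env = (raw[t] - gen[t]).var()
        extra = max(target_env - current_env, 0.0)
        pheno[t] = raw[t] + rng.normal(0.0, np.sqrt(extra), n)

    pheno["TSC"] = pheno["SUC"] + pheno["FRU"] + pheno["GLC"] + pheno["SOR"]
    gen["TSC"] = gen["SUC"] + gen["FRU"] + gen["GLC"] + gen["SOR"]

    # non-sugar polygenic channels
    for t in ("HarT", "FruW", "FruH", "Aci"):
        mu_t, var_t = st[t]
        fam_var = model.family_variance * var_t
        gval = (_polygenic(rng, genotypes, model.n_polygenes,
                           max(h2[t] * var_t - fam_var, 0.0))
                + _family_effects(rng, codes, fam_var))
        for q in model.direct_qtls:
            if t in q.target_traits:
                j = _resolve_marker(genotypes, q)
                qtl_markers[f"{t}:{q.chromosome}"] = j
                a = assign_qtl_effects(q, genotypes, var_t, marker_index=j)
                x = genotypes.dosage[:, j]
                gval = gval + a * (x - x.mean())
        vg = gval.var()
        env = vg * (1 - h2[t]) / h2[t] if vg > 0 else var_t * (1 - h2[t])
        pheno[t] = mu_t + gval + rng.normal(0.0, np.sqrt(env), n)
        gen[t] = mu_t + gval

    scale = st["SSC"][0] / st["TSC"][0]
    pheno["SSC"] = pheno["TSC"] * scale + rng.normal(0.0, model.ssc_noise_sd, n)
    gen["SSC"] = gen["TSC"] * scale

    cols = ["SUC", "FRU", "GLC", "SOR", "TSC", "HarT", "FruW", "FruH", "SSC", "Aci"]
    ph = pd.DataFrame({t: pheno[t] for t in cols}, index=genotypes.ids)
    gv = pd.DataFrame({t: gen[t] for t in cols}, index=genotypes.ids)
    ph.index.name = gv.index.name = "id"
    return SimulatedPhenotypes(ph, gv, qtl_markers)


def encode_harvest_day(calendar_date: datetime.date) -> int:
    """Days after June 30 of the same year (July 1 = day 1)."""
    ref = datetime.date(calendar_date.year, 6, 30)
    delta = (calendar_date - ref).days
    if delta <= 0:
        raise SimError("harvest date must fall after June 30")
    return delta


def simulate_pear_study(config: SimConfig | None = None,
                        model: SugarTraitModel | None = None,
                        seed: int | None = None):
    """One-call default preset: genotypes, families, phenotypes."""
    config = config or pear_default_config()
    if seed is not None:
        config = replace(config, seed=seed)
    model = model or pear_default_trait_model()
    panel = simulate_founders(config)
    g, fam = build_population(config, panel)
    sim = simulate_sugar_phenotypes(model, g, fam, seed=config.seed)
    return g, fam, sim
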