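"""Kinship, linkage disequilibrium, tag-SNP selection, pruning and PCA.

These are the structural statistics feeding both the mixed-model scan
(kinship, principal components) and genomic prediction.  LD is the
composite (dosage-correlation) r-squared: phase is unavailable after
genotype calling, and squared Pearson correlation of dosages is the
standard phase-free surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix


class StructureError(ValueError):
    pass


@dataclass
class KinshipMatrix:
    values: np.ndarray  # symmetric (n, n)
    ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def vanraden_kinship(g: GenotypeMatrix, freqs: np.ndarray | None = None,
                     ridge: float = 1e-8) -> KinshipMatrix:
    """Genomic relationship matrix G = W W' / (2 sum p(1-p)).

    W is the dosage matrix centered at twice the alt-allele frequency.
    Frequencies default to those observed in ``g`` (the full analysed
    set); pass training-set frequencies explicitly when building
    cross-validation blocks.  Monomorphic markers are skipped.  A ridge
    is added on the diagonal so the result is positive semi-definite to
    numerical precision.
    """
    d = g.dosage
    if np.isnan(d).any():
        raise StructureError("kinship requires complete dosages (impute first)")
    p = d.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    poly = (p > 0) & (p < 1) & (d.var(axis=0) > 0)
    if poly.sum() < 2:
        raise StructureError("need >= 2 polymorphic markers for kinship")
    W = d[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    G = (W @ W.T) / denom
    G[np.diag_indices_from(G)] += ridge
    return KinshipMatrix(G, list(g.ids))


def cross_kinship(g_test: GenotypeMatrix, g_train: GenotypeMatrix,
                  freqs: np.ndarray) -> np.ndarray:
    """Test x train block of the VanRaden G, with given (training) freqs."""
    p = np.asarray(freqs, dtype=float)
    poly = (p > 0) & (p < 1)
    Wx = g_test.dosage[:, poly] - 2.0 * p[poly]
    Wt = g_train.dosage[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return (Wx @ Wt.T) / denom


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD).

    Returns nan when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise StructureError("vectors must have equal length >= 3")
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    c = np.mean((x - x.mean()) * (y - y.mean()))
    return float(c * c / (vx * vy))


def _r2_matrix(d: np.ndarray) -> np.ndarray:
    """All-pairs r² between columns; nan rows/cols for monomorphic markers."""
    sd = d.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (d - d.mean(axis=0)) / sd
    r = (z.T @ z) / d.shape[0]
    return r * r


@dataclass
class LdDecayTable:
    table: pd.DataFrame  # columns: bin_lo, bin_hi, mean_r2, n_pairs


def ld_decay(g: GenotypeMatrix, bin_bp: int = 10_000,
             max_bp: int = 2_000_000) -> LdDecayTable:
    """Mean r² of intra-chromosomal marker pairs binned by distance.

    Pairs are formed within each chromosome up to ``max_bp`` apart and
    binned in ``bin_bp`` increments.  Markers on the fictive chromosome
    "0" (unassigned scaffolds) are excluded.  Empty bins carry count 0
    and a missing mean.
    """
    n_bins = int(np.ceil(max_bp / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom, idx in g.markers.groupby("chrom", sort=False).groups.items():
        if str(chrom) == "0":
            continue
        idx = np.asarray(idx)
        pos = g.markers["pos"].to_numpy()[idx]
        d = g.dosage[:, idx]
        r2 = _r2_matrix(d)
        ii, jj = np.triu_indices(len(idx), k=1)
        dist = np.abs(pos[jj] - pos[ii])
        val = r2[ii, jj]
        ok = (dist < max_bp) & ~np.isnan(val)
        b = (dist[ok] // bin_bp).astype(np.int64)
        np.add.at(sums, b, val[ok])
        np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    tab = pd.DataFrame({
        "bin_lo": np.arange(n_bins) * bin_bp,
        "bin_hi": (np.arange(n_bins) + 1) * bin_bp,
        "mean_r2": mean,
        "n_pairs": counts,
    })
    return LdDecayTable(tab)


def greedy_tag_snps(g: GenotypeMatrix, r2_min: float = 0.8
                    ) -> tuple[np.ndarray, dict[int, int]]:
    """Pairwise greedy tagger (Haploview-style).

    Repeatedly picks the marker that covers (r² >= r2_min on the same
    chromosome, including itself) the largest number of not-yet-covered
    markers; ties break by smaller chromosome then smaller position.
    Returns (sorted tag indices, mapping non-tag index -> covering tag).
    """
    d = g.dosage
    if np.isnan(d).any():
        raise StructureError("tagger requires complete dosages")
    m = g.n_markers
    chrom = g.markers["chrom"].to_numpy()
    pos = g.markers["pos"].to_numpy()

    def chrom_key(c: str) -> tuple:
        s = str(c)
        return (0, int(s)) if s.isdigit() else (1, s)

    order = sorted(range(m), key=lambda j: (chrom_key(chrom[j]), pos[j], j))
    rank = np.empty(m, dtype=np.int64)
    for r, j in enumerate(order):
        rank[j] = r

    cover = [np.array([j]) for j in range(m)]
    for _, idx in g.markers.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        r2 = _r2_matrix(d[:, idx])
        hit = r2 >= r2_min
        np.fill_diagonal(hit, True)
        for a, j in enumerate(idx):
            cover[j] = idx[hit[a]]

    covered = np.zeros(m, dtype=bool)
    tags: list[int] = []
    assign: dict[int, int] = {}
    while not covered.all():
        best_j, best_n = -1, -1
        for j in range(m):
            n_new = int((~covered[cover[j]]).sum())
            if n_new > best_n or (n_new == best_n and rank[j] < rank[best_j]):
                best_j, best_n = j, n_new
        tags.append(best_j)
        newly = cover[best_j][~covered[cover[best_j]]]
        for t in newly:
            assign[int(t)] = best_j
        covered[cover[best_j]] = True
    return np.array(sorted(tags)), assign


def ld_prune(g: GenotypeMatrix, window: int = 50, step: int = 10,
             r2_max: float = 0.1) -> np.ndarray:
    """PLINK-style windowed LD pruning (indep-pairwise semantics).

    A window of ``window`` markers advances by ``step`` along each
    chromosome; within a window, while any retained pair exceeds
    ``r2_max`` the later-positioned member is dropped.  Deterministic.
    Returns the retained marker indices (original order).
    """
    d = g.dosage
    if np.isnan(d).any():
        raise StructureError("pruning requires complete dosages")
    keep = np.ones(g.n_markers, dtype=bool)
    for _, idx in g.markers.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        pos = g.markers["pos"].to_numpy()[idx]
        local = idx[np.argsort(pos, kind="stable")]
        start = 0
        while True:
            win = local[start:start + window]
            if len(win) > 1:
                r2w = _r2_matrix(d[:, win])  # window is small; vectorise
                changed = True
                while changed:
                    changed = False
                    active = [a for a, j in enumerate(win) if keep[j]]
                    for ia, a in enumerate(active):
                        for b in active[ia + 1:]:
                            r2 = r2w[a, b]
                            if not np.isnan(r2) and r2 > r2_max:
                                keep[win[b]] = False
                                changed = True
                                break
                        if changed:
                            break
            if start + window >= len(local):
                break
            start += step
    return np.flatnonzero(keep)


@dataclass
class PcaResult:
    scores: np.ndarray        # (n, k)
    proportions: np.ndarray   # fraction of total variance per component
    loadings: np.ndarray      # (m_used, k)
    marker_idx: np.ndarray    # markers entering the PCA (after pruning)


def genotype_pca(g: GenotypeMatrix, n_components: int = 3,
                 prune_first: bool = True, scale: bool = False,
                 window: int = 50, step: int = 10, r2_max: float = 0.1
                 ) -> PcaResult:
    """PCA of (optionally LD-pruned) centered dosages via SVD.

    Columns are centered, not variance-scaled, matching common PLINK
    usage (``scale=True`` opts in).  Proportions are eigenvalue shares of
    the total variance.  Sign convention: the largest-magnitude loading
    of each component is positive.
    """
    idx = ld_prune(g, window, step, r2_max) if prune_first else np.arange(g.n_markers)
    X = g.dosage[:, idx]
    if np.isnan(X).any():
        raise StructureError("PCA requires complete dosages")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    n = X.shape[0]
    if n_components > min(X.shape) or n_components >= n:
        raise StructureError("n_components exceeds matrix rank")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = min(X.shape)
    if n_components > np.sum(s > s[0] * 1e-12):
        raise StructureError("n_components exceeds matrix rank")
    total = float(np.sum(s ** 2))
    scores = U[:, :n_components] * s[:n_components]
    load = Vt[:n_components].T
    for k in range(n_components):
        jmax = int(np.argmax(np.abs(load[:, k])))
        if load[jmax, k] < 0:
            load[:, k] = -load[:, k]
            scores[:, k] = -scores[:, k]
    props = (s[:n_components] ** 2) / total
    return PcaResult(scores, props, load, idx)
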