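"""Post-GWAS effect characterisation.

Genotype-class summaries, the per-SNP percentage of phenotypic variance
explained (PVE), and the marker x family PVE matrix used to see which
breeding populations actually segregate for, and respond to, each QTL.

PVE is the effect-based variance share

    PVE = 100 * Var(x * effect) / Var(y) = 100 * effect^2 * Var(x) / Var(y)

with population variances (divisor n).  A genotype-class-mean R2
alternative is available behind ``method="class_r2"`` for sensitivity
analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geno_io import FamilyStructure, GenotypeMatrix


class EffectError(ValueError):
    pass


def genotype_class_means(y: np.ndarray, x: np.ndarray) -> pd.DataFrame:
    """Count, mean and median of the trait per genotype class (0, 1, 2).

    Individuals with missing phenotype are dropped; an absent class
    carries missing summaries.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = ~np.isnan(y)
    rows = []
    for k in (0.0, 1.0, 2.0):
        sel = ok & (x == k)
        if sel.sum():
            rows.append({"genotype": int(k), "count": int(sel.sum()),
                         "mean": float(np.mean(y[sel])),
                         "median": float(np.median(y[sel]))})
        else:
            rows.append({"genotype": int(k), "count": 0,
                         "mean": np.nan, "median": np.nan})
    return pd.DataFrame(rows).set_index("genotype")


def snp_pve(y: np.ndarray, x: np.ndarray, effect: float,
            method: str = "effect") -> float:
    """Percentage of phenotypic variance explained by one marker."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = ~np.isnan(y)
    y, x = y[ok], x[ok]
    vy = float(np.var(y))
    if vy == 0.0:
        raise EffectError("phenotype has zero variance")
    if method == "effect":
        return 100.0 * float(effect) ** 2 * float(np.var(x)) / vy
    if method == "class_r2":
        resid = 0.0
        for k in np.unique(x):
            sel = x == k
            resid += float(np.sum((y[sel] - y[sel].mean()) ** 2))
        return 100.0 * (1.0 - resid / (len(y) * vy))
    raise EffectError(f"unknown PVE method {method!r}")


def pve_per_family(y: np.ndarray, g: GenotypeMatrix,
                   families: FamilyStructure, marker_idx: np.ndarray,
                   effects: np.ndarray | None = None,
                   min_class_count: int = 2,
                   reestimate: bool = True) -> pd.DataFrame:
    """Marker x family matrix of PVE (%), plus a pooled "ALL" column.

    Within each family the marker effect is re-estimated by OLS on that
    family's individuals (``reestimate=False`` reuses the global
    ``effects``) and the PVE uses the family's own phenotypic variance.
    Cells are missing where the marker shows fewer than two genotype
    classes in the family, or any observed class has fewer than
    ``min_class_count`` members.
    """
    y = np.asarray(y, dtype=float)
    marker_idx = np.asarray(marker_idx)
    if not reestimate and effects is None:
        raise EffectError("effects required when reestimate=False")
    fams = families.families() + [families.collection_label]
    lab = families.labels.reindex(g.ids).to_numpy()
    names = [g.marker_names()[j] for j in marker_idx]
    out = pd.DataFrame(index=names, columns=fams + ["ALL"], dtype=float)

    def cell(sel: np.ndarray, j: int, global_eff: float | None) -> float:
        xs = g.dosage[sel, j]
        ys = y[sel]
        ok = ~np.isnan(ys)
        xs, ys = xs[ok], ys[ok]
        classes, counts = np.unique(xs, return_counts=True)
        if len(classes) < 2 or counts.min() < min_class_count:
            return np.nan
        if np.var(ys) == 0:
            return np.nan
        if reestimate:
            vx = np.var(xs)
            eff = float(np.mean((xs - xs.mean()) * (ys - ys.mean())) / vx)
        else:
            eff = float(global_eff)
        return snp_pve(ys, xs, eff)

    for t, j in enumerate(marker_idx):
        geff = None if effects is None else effects[t]
        for f in fams:
            out.loc[names[t], f] = cell(lab == f, j, geff)
        out.loc[names[t], "ALL"] = cell(np.ones(len(y), dtype=bool), j, geff)
    return out


def pve_long_format(pve: pd.DataFrame) -> pd.DataFrame:
    """Heatmap-ready long table (marker, family, pve)."""
    long = pve.reset_index(names="marker").melt(
        id_vars="marker", var_name="family", value_name="pve")
    return long
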