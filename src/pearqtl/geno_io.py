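"""Genotype / phenotype file handling and marker quality control.

Genotypes are held as alternate-allele dosages (0, 1, 2; ``nan`` = missing)
in a :class:`GenotypeMatrix`.  VCF reading goes through :mod:`cyvcf2`;
multiallelic records are skipped, matching the two-allele restriction used
when calling SNPs in breeding material.  Marker QC applies a minor-allele
frequency floor and a missing-rate ceiling, and missing calls can be filled
with the per-marker modal dosage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Traits evaluated on mature fruit.  Sugars are mg/ml of juice, HarT is
#: days after June 30, FruW grams, FruH pounds (Magness-Taylor), SSC %,
#: Aci is juice pH.
KNOWN_TRAITS = ("SUC", "FRU", "GLC", "SOR", "TSC", "HarT", "FruW", "FruH", "SSC", "Aci")

TRAIT_UNITS = {
    "SUC": "mg/ml", "FRU": "mg/ml", "GLC": "mg/ml", "SOR": "mg/ml",
    "TSC": "mg/ml", "HarT": "days", "FruW": "g", "FruH": "lb",
    "SSC": "%", "Aci": "pH",
}

MISSING_TOKENS = ("NA", "NaN", "nan", "", ".")


class GenoIOError(ValueError):
    """Raised for malformed genotype/phenotype inputs."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with marker metadata.

    dosage: float array, entries in {0, 1, 2} or nan for missing.
    markers: DataFrame with columns chrom (str, "0" = unassigned scaffolds),
        pos (int, 1-based), ref, alt.
    ids: individual identifiers, unique.
    """

    dosage: np.ndarray
    markers: pd.DataFrame
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise GenoIOError("dosage must be 2-D (individuals x markers)")
        if len(self.ids) != self.dosage.shape[0]:
            raise GenoIOError("number of ids does not match dosage rows")
        if len(set(self.ids)) != len(self.ids):
            raise GenoIOError("individual IDs must be unique")
        if len(self.markers) != self.dosage.shape[1]:
            raise GenoIOError("marker table does not match dosage columns")
        if len(self.markers) and (self.markers["pos"] < 1).any():
            raise GenoIOError("marker positions must be >= 1 (1-based)")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def marker_names(self) -> list[str]:
        return [
            f"Chr{c}_{p}" for c, p in zip(self.markers["chrom"], self.markers["pos"])
        ]

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per marker over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosage), axis=0)

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosage[:, idx],
            self.markers.iloc[np.asarray(idx)].reset_index(drop=True),
            list(self.ids),
        )

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosage[idx, :],
            self.markers.copy().reset_index(drop=True),
            [self.ids[i] for i in idx],
        )


@dataclass
class FamilyStructure:
    """Mapping individual -> family label; cultivars carry ``collection``."""

    labels: pd.Series  # index = individual ID, value = family label
    collection_label: str = "collection"

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            raise GenoIOError("duplicate individual IDs in family table")

    def families(self) -> list[str]:
        """F1 family labels (excludes the cultivar collection)."""
        out = [f for f in pd.unique(self.labels) if f != self.collection_label]
        return sorted(out)

    def members(self, family: str) -> list[str]:
        return list(self.labels.index[self.labels == family])

    def codes_for(self, ids: list[str]) -> np.ndarray:
        """Integer family codes aligned to ``ids`` (collection included)."""
        lab = self.labels.reindex(ids)
        if lab.isna().any():
            missing = list(lab.index[lab.isna()])[:5]
            raise GenoIOError(f"individuals without family label: {missing}")
        cats = sorted(pd.unique(lab))
        mapping = {c: i for i, c in enumerate(cats)}
        return np.array([mapping[v] for v in lab], dtype=np.int64)


def read_vcf(path: str, min_qual: float | None = None) -> GenotypeMatrix:
    """Parse a VCF into dosages.

    Biallelic records only; multiallelic ALTs are skipped with a logged
    count.  ``./.`` and ``.`` genotypes become missing.  Phased and
    unphased separators are both accepted (cyvcf2 normalises them).
    ``min_qual`` drops records whose QUAL is present and below it; records
    without QUAL pass (synthetic VCFs carry none).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # malformed header
        raise GenoIOError(f"cannot open VCF {path!r}: {exc}") from exc
    ids = list(vcf.samples)
    rows, chroms, poss, refs, alts = [], [], [], [], []
    n_multi = 0
    saw_gt = False
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        if min_qual is not None and var.QUAL is not None and var.QUAL < min_qual:
            continue
        gts = var.genotype.array()  # (n, ploidy+1): allele0, allele1, phased
        saw_gt = True
        a = gts[:, 0].astype(float)
        b = gts[:, 1].astype(float)
        dose = a + b
        dose[(a < 0) | (b < 0)] = np.nan
        rows.append(dose)
        chroms.append(str(var.CHROM).removeprefix("Chr").removeprefix("chr"))
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    if rows and not saw_gt:
        raise GenoIOError("VCF has no GT field")
    if n_multi:
        logger.info("read_vcf: skipped %d multiallelic records", n_multi)
    dosage = np.array(rows, dtype=float).T if rows else np.empty((len(ids), 0))
    markers = pd.DataFrame(
        {"chrom": chroms, "pos": np.array(poss, dtype=int), "ref": refs, "alt": alts}
    )
    return GenotypeMatrix(dosage, markers, ids)


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCFv4.2 (GT only, unphased)."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(g.markers["chrom"]):
            fh.write(f"##contig=<ID=Chr{c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.ids)
            + "\n"
        )
        names = g.marker_names()
        for j in range(g.n_markers):
            row = g.markers.iloc[j]
            calls = [
                code.get(d, "./.") if not np.isnan(d) else "./."
                for d in g.dosage[:, j]
            ]
            fh.write(
                f"Chr{row['chrom']}\t{row['pos']}\t{names[j]}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def filter_markers(
    g: GenotypeMatrix, maf_min: float = 0.01, max_missing: float = 0.25
) -> tuple[GenotypeMatrix, dict]:
    """Keep markers with MAF >= maf_min and missing rate <= max_missing.

    Removal on missingness is strictly-greater-than ``max_missing`` (a
    marker at exactly the ceiling is retained).  MAF is computed on
    non-missing calls.  Marker order is preserved.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise GenoIOError("maf_min must be in [0, 0.5]")
    if not (0.0 <= max_missing <= 1.0):
        raise GenoIOError("max_missing must be in [0, 1]")
    p = g.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    miss = g.missing_rate()
    keep = (maf >= maf_min) & (miss <= max_missing) & ~np.isnan(maf)
    stats = {"kept": int(keep.sum()), "removed": int((~keep).sum())}
    if stats["kept"] == 0:
        logger.warning("filter_markers removed every marker")
    return g.take_markers(np.flatnonzero(keep)), stats


def impute_mode(g: GenotypeMatrix) -> tuple[GenotypeMatrix, float]:
    """Replace missing calls with the marker's modal dosage class.

    Ties break toward the smaller dosage.  Stands in for haplotype-based
    imputation when phase information is unavailable.  Returns the imputed
    matrix and the fraction of calls that were filled.
    """
    d = g.dosage.copy()
    n_missing = 0
    for j in range(d.shape[1]):
        col = d[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        if miss.all():
            raise GenoIOError(f"marker column {j} is entirely missing")
        counts = np.array([(col == k).sum() for k in (0.0, 1.0, 2.0)])
        col[miss] = float(np.argmax(counts))  # argmax takes the first max: ties -> smaller dosage
        n_missing += int(miss.sum())
    frac = n_missing / d.size if d.size else 0.0
    out = replace(g, dosage=d, markers=g.markers.copy(), ids=list(g.ids))
    return out, frac


def _read_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={0: str}, na_values=list(MISSING_TOKENS),
        keep_default_na=False,
    )
    idcol = df.columns[0]
    if df[idcol].duplicated().any():
        dup = df[idcol][df[idcol].duplicated()].iloc[0]
        raise GenoIOError(f"duplicate individual ID {dup!r}")
    return df.set_index(idcol)


def read_phenotypes(
    path: str,
    genotype_ids: list[str] | None = None,
    allow_unknown_traits: bool = False,
) -> pd.DataFrame:
    """Read a tab-separated phenotype table (first column = individual ID).

    Unknown trait columns are rejected unless ``allow_unknown_traits``.
    Individuals present in ``genotype_ids`` but absent from the file get
    all-missing rows.  Non-numeric cells (other than missing tokens) are
    rejected.
    """
    df = _read_table(path)
    unknown = [c for c in df.columns if c not in KNOWN_TRAITS]
    if unknown and not allow_unknown_traits:
        raise GenoIOError(f"unknown trait column(s): {unknown}")
    for c in df.columns:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise GenoIOError(f"non-numeric value in trait {c!r}: {exc}") from exc
    if genotype_ids is not None:
        df = df.reindex(genotype_ids)
        df.index.name = "id"
    return df


def read_families(path: str, collection_label: str = "collection") -> FamilyStructure:
    """Read a two-column TSV of individual -> family label."""
    df = _read_table(path)
    if df.shape[1] < 1:
        raise GenoIOError("family table needs a label column")
    labels = df.iloc[:, 0].astype(str)
    return FamilyStructure(labels, collection_label=collection_label)


def write_phenotypes(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t", index_label="id", na_rep="NA")


def write_families(fam: FamilyStructure, path: str) -> None:
    fam.labels.rename("family").to_csv(path, sep="\t", index_label="id")
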