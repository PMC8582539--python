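"""Domain types, gene→arm indexing, and readers/writers for the file dialects
used throughout the package.

The central object is a gene-level thresholded copy-number call matrix in the
GISTIC2 ``all_thresholded.by_genes`` dialect: one row per gene, one column per
sample, integer calls in {−2, −1, 0, +1, +2} (deep deletion, shallow deletion,
neutral, gain, amplification).  Gene position is modeled only through the
annotation's chromosome/arm/cytoband columns — no base-pair coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

VALID_CALLS = frozenset({-2, -1, 0, 1, 2})

#: MAF variant classifications treated as synonymous (not protein-altering).
SILENT_CLASSIFICATIONS = frozenset({"Silent"})

CHROMOSOMES = tuple(str(c) for c in range(1, 23)) + ("X", "Y")

T_GROUPS = ("T0-T2/TX", "T3-T4")
N_GROUPS = ("N0-N2a/NX", "N2b-N3")
STAGE_GROUPS = ("I-III", "IV")
SMOKING_LEVELS = ("non-smoker", "light", "heavy", "unknown")

CLINICAL_COLUMNS = [
    "sample",
    "hpv_status",
    "age",
    "sex",
    "site",
    "smoking",
    "pack_years",
    "t_group",
    "n_group",
    "stage_group",
    "adjuvant_rt",
    "distant_metastasis",
    "time_days",
    "event",
]


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


class ValidationError(ValueError):
    """An in-memory object violates a type invariant."""


_CYTOBAND_RE = re.compile(r"^(\d{1,2}|X|Y)([pq])")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene symbol with its chromosome, arm and cytoband."""

    symbol: str
    chromosome: str
    arm: str
    cytoband: str

    def __post_init__(self):
        if self.chromosome not in CHROMOSOMES:
            raise ValidationError(
                f"{self.symbol}: unknown chromosome {self.chromosome!r}"
            )
        if self.arm not in ("p", "q"):
            raise ValidationError(f"{self.symbol}: arm must be 'p' or 'q'")
        m = _CYTOBAND_RE.match(self.cytoband)
        if m is None or m.group(1) != self.chromosome or m.group(2) != self.arm:
            raise ValidationError(
                f"{self.symbol}: cytoband {self.cytoband!r} inconsistent with "
                f"chromosome {self.chromosome}{self.arm}"
            )


def parse_cytoband(cytoband: str) -> tuple[str, str]:
    """Split a cytoband string like ``'3p14.2'`` into (chromosome, arm)."""
    m = _CYTOBAND_RE.match(str(cytoband))
    if m is None:
        raise FormatError(f"unparseable cytoband {cytoband!r}")
    return m.group(1), m.group(2)


class CnaCallMatrix:
    """Genes × samples integer matrix of thresholded copy-number calls.

    Parameters
    ----------
    calls
        DataFrame indexed by gene symbol with sample-ID columns; every entry
        must lie in {−2, −1, 0, +1, +2}.
    annotations
        Optional mapping from gene symbol to :class:`GeneAnnotation`; present
        when the source file carried a cytoband column.
    """

    def __init__(self, calls: pd.DataFrame,
                 annotations: dict[str, GeneAnnotation] | None = None):
        if calls.index.has_duplicates:
            dups = calls.index[calls.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dups[:5]}")
        if calls.columns.has_duplicates:
            raise ValidationError("duplicate sample IDs")
        arr = calls.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.round(arr)):
                raise ValidationError("non-integer copy-number call")
            arr = arr.astype(np.int64)
            calls = pd.DataFrame(arr, index=calls.index, columns=calls.columns)
        bad = (arr < -2) | (arr > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"call {arr[i, j]} out of range at gene {calls.index[i]!r}, "
                f"sample {calls.columns[j]!r}"
            )
        self.calls = calls.astype(np.int64)
        self.annotations = annotations

    @property
    def genes(self) -> list[str]:
        return list(self.calls.index)

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    def sample_calls(self, sample: str, genes=None) -> pd.Series:
        if sample not in self.calls.columns:
            raise KeyError(f"sample {sample!r} not in matrix")
        col = self.calls[sample]
        return col if genes is None else col.loc[list(genes)]

    def __repr__(self):
        return (f"CnaCallMatrix({len(self.genes)} genes × "
                f"{len(self.samples)} samples)")


# ---------------------------------------------------------------------------
# GISTIC thresholded-by-genes dialect
# ---------------------------------------------------------------------------

_GISTIC_GENE_COL = "Gene Symbol"
_GISTIC_LOCUS_COL = "Locus ID"
_GISTIC_BAND_COL = "Cytoband"


def read_cna_matrix(path, dialect: str = "gistic_thresholded") -> CnaCallMatrix:
    """Read a gene-level thresholded copy-number TSV.

    The header names the samples; leading columns give the gene symbol and,
    optionally, a locus ID and cytoband.  Cytobands, when present, are parsed
    into :class:`GeneAnnotation` records.
    """
    if dialect != "gistic_thresholded":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if _GISTIC_GENE_COL not in df.columns:
        raise FormatError(f"missing {_GISTIC_GENE_COL!r} column in {path}")
    meta_cols = [c for c in (_GISTIC_GENE_COL, _GISTIC_LOCUS_COL, _GISTIC_BAND_COL)
                 if c in df.columns]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise FormatError(f"no sample columns in {path}")
    symbols = df[_GISTIC_GENE_COL]
    if symbols.duplicated().any():
        raise FormatError(
            f"duplicate gene symbol {symbols[symbols.duplicated()].iloc[0]!r}")
    try:
        calls = df[sample_cols].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-integer call value in {path}: {exc}") from None
    calls.index = symbols.rename("gene")
    annotations = None
    if _GISTIC_BAND_COL in df.columns:
        annotations = {}
        for sym, band in zip(symbols, df[_GISTIC_BAND_COL]):
            chrom, arm = parse_cytoband(band)
            annotations[sym] = GeneAnnotation(sym, chrom, arm, band)
    try:
        return CnaCallMatrix(calls, annotations)
    except ValidationError as exc:
        raise FormatError(str(exc)) from None


def write_cna_matrix(matrix: CnaCallMatrix, path) -> None:
    out = matrix.calls.copy()
    out.insert(0, _GISTIC_GENE_COL, out.index)
    if matrix.annotations is not None:
        out.insert(1, _GISTIC_BAND_COL,
                   [matrix.annotations[g].cytoband for g in matrix.calls.index])
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MAF (somatic mutation table)
# ---------------------------------------------------------------------------

_MAF_REQUIRED = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


def read_maf(path, silent_classes=SILENT_CLASSIFICATIONS) -> pd.DataFrame:
    """Read a somatic mutation table (MAF dialect).

    Only three columns are required — gene symbol, sample barcode and variant
    classification; all others are ignored.  The returned frame has columns
    ``sample``, ``gene``, ``classification`` and ``synonymous``, the last set
    true exactly for classifications in ``silent_classes``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"MAF {path} missing required column(s) {missing}")
    out = pd.DataFrame({
        "sample": df["Tumor_Sample_Barcode"],
        "gene": df["Hugo_Symbol"],
        "classification": df["Variant_Classification"],
    })
    out["synonymous"] = out["classification"].isin(set(silent_classes))
    return out


def write_maf(snvs: pd.DataFrame, path) -> None:
    pd.DataFrame({
        "Hugo_Symbol": snvs["gene"],
        "Tumor_Sample_Barcode": snvs["sample"],
        "Variant_Classification": snvs["classification"],
    }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

def bin_t_category(raw) -> str | float:
    if pd.isna(raw):
        return np.nan
    r = str(raw).strip().upper()
    if r in ("T0", "T1", "T2", "TIS", "TX") or r.startswith(("T1", "T2")):
        return T_GROUPS[0]
    if r.startswith(("T3", "T4")):
        return T_GROUPS[1]
    raise FormatError(f"unrecognized T category {raw!r}")


def bin_n_category(raw) -> str | float:
    if pd.isna(raw):
        return np.nan
    r = str(raw).strip().upper()
    if r in ("N2B", "N2C", "N3") or r.startswith(("N2B", "N2C", "N3")):
        return N_GROUPS[1]
    if r.startswith(("N0", "N1", "N2", "NX")):
        return N_GROUPS[0]
    raise FormatError(f"unrecognized N category {raw!r}")


def bin_stage(raw) -> str | float:
    if pd.isna(raw):
        return np.nan
    r = str(raw).strip().upper().replace("STAGE", "").strip()
    if r.startswith("IV"):
        return STAGE_GROUPS[1]
    if r in ("I", "II", "III") or r.startswith(("I", "II", "III")):
        return STAGE_GROUPS[0]
    raise FormatError(f"unrecognized stage {raw!r}")


def smoking_from_pack_years(pack_years) -> str:
    """Heavy for >20 pack-years, light for a positive history of ≤20,
    non-smoker for zero."""
    if pd.isna(pack_years):
        return "unknown"
    py = float(pack_years)
    if py < 0:
        raise ValidationError(f"negative pack-years {py}")
    if py > 20:
        return "heavy"
    if py > 0:
        return "light"
    return "non-smoker"


def read_clinical(path) -> pd.DataFrame:
    """Read the per-sample clinical TSV.

    Raw staging columns (``t_category``, ``n_category``, ``stage``), when
    present, are binned into the grouped columns; a missing smoking category
    is filled from pack-years.  Missing values stay missing — analyses drop
    them pairwise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise FormatError(f"clinical table {path} lacks a 'sample' column")
    for num in ("age", "pack_years", "time_days"):
        if num in df.columns:
            df[num] = pd.to_numeric(df[num], errors="coerce")
    if "event" in df.columns:
        df["event"] = pd.to_numeric(df["event"], errors="coerce").astype("Int64")
    if "t_category" in df.columns and "t_group" not in df.columns:
        df["t_group"] = df["t_category"].map(bin_t_category)
    if "n_category" in df.columns and "n_group" not in df.columns:
        df["n_group"] = df["n_category"].map(bin_n_category)
    if "stage" in df.columns and "stage_group" not in df.columns:
        df["stage_group"] = df["stage"].map(bin_stage)
    if "pack_years" in df.columns:
        derived = df["pack_years"].map(smoking_from_pack_years)
        if "smoking" not in df.columns:
            df["smoking"] = derived
        else:
            missing = df["smoking"].isna() | (df["smoking"] == "unknown")
            df.loc[missing, "smoking"] = derived[missing]
            both = ~missing & df["pack_years"].notna()
            clash = both & (
                ((df["smoking"] == "heavy") != (df["pack_years"] > 20))
                & (df["smoking"] != "non-smoker")
            )
            clash &= df["pack_years"] > 0
            if clash.any():
                bad = df.loc[clash, "sample"].iloc[0]
                raise ValidationError(
                    f"sample {bad!r}: smoking category inconsistent with "
                    f"pack-years (heavy iff >20)")
    if "time_days" in df.columns and (df["time_days"].dropna() <= 0).any():
        bad = df.loc[df["time_days"] <= 0, "sample"].iloc[0]
        raise ValidationError(f"sample {bad!r}: non-positive follow-up time")
    return df


def write_clinical(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Expression matrices and DE tables
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Features × samples non-negative abundance matrix (first column =
    feature symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "feature"
    df = df.astype(float)
    if df.index.has_duplicates:
        raise FormatError(f"duplicate feature symbols in {path}")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"negative abundance in {path}")
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="feature", float_format="%.6g")


def read_de_table(path) -> pd.DataFrame:
    """Differential-expression table: gene, shrunken log2 fold change, FDR q."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "log2fc", "q"):
        if col not in df.columns:
            raise FormatError(f"DE table {path} missing column {col!r}")
    if df["gene"].duplicated().any():
        raise FormatError(f"duplicate gene in DE table {path}")
    if ((df["q"] < 0) | (df["q"] > 1)).any():
        raise FormatError(f"q outside [0, 1] in {path}")
    return df


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# Arm index
# ---------------------------------------------------------------------------

def build_arm_index(annotations) -> dict[tuple[str, str], set[str]]:
    """Partition gene symbols into (chromosome, arm) buckets.

    Accepts an iterable of :class:`GeneAnnotation` or a symbol→annotation
    mapping.  Every gene lands in exactly one bucket; bucket sizes sum to the
    annotation count.
    """
    if isinstance(annotations, dict):
        annotations = annotations.values()
    annotations = list(annotations)
    if not annotations:
        raise ValidationError("empty annotation set")
    index: dict[tuple[str, str], set[str]] = {}
    for ann in annotations:
        index.setdefault((ann.chromosome, ann.arm), set()).add(ann.symbol)
    return index
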