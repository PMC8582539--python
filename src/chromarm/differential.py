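"""Cohort-level contrasts by arm status: clinical association tables,
differential SNVs and CNAs, CNA×mRNA integration, and burden contrasts.

All contrasts take a ``groups`` mapping sample → {"lost", "preserved"}
(excluded samples simply absent) and are run within a single HPV stratum.
"""

from __future__ import annotations

import functools
import warnings

import numpy as np
import pandas as pd
import scipy.stats as sps

from . import stats
from .model import CnaCallMatrix, build_arm_index

GROUP_LOST = "lost"
GROUP_PRESERVED = "preserved"

EVENT_CLASSES = {
    "deep_deletion": -2,
    "shallow_deletion": -1,
    "gain": 1,
    "amplification": 2,
}

DELETION_CLASSES = ("deep_deletion", "shallow_deletion")
GAIN_CLASSES = ("gain", "amplification")

#: Clinical variables with their analysis kind (Mann–Whitney for continuous).
DEFAULT_CLINICAL_VARIABLES = {
    "age": "continuous",
    "sex": "categorical",
    "site": "categorical",
    "smoking": "categorical",
    "t_group": "categorical",
    "n_group": "categorical",
    "stage_group": "categorical",
    "adjuvant_rt": "categorical",
    "distant_metastasis": "categorical",
}


@functools.lru_cache(maxsize=1_000_000)
def _cached_fisher_p(a: int, b: int, c: int, d: int) -> float:
    return float(sps.fisher_exact([[a, b], [c, d]])[1])


def _sample_or(a, b, c, d) -> float:
    if b * c == 0:
        return np.inf if a * d > 0 else np.nan
    return a * d / (b * c)


# ---------------------------------------------------------------------------
# Clinical association (Tables 1–2 layout)
# ---------------------------------------------------------------------------

def clinical_association_table(cohort: pd.DataFrame, groups: dict,
                               variables: dict | None = None,
                               test_policy: str = "auto",
                               exact_max_tables: int = 500_000):
    """Compare clinical variables between arm-lost and arm-preserved samples.

    Categorical variables are cross-tabulated against group and tested with
    Fisher's exact test (2×2), Pearson's χ² (larger tables under the default
    policy), or the Freeman–Halton exact test (``test_policy="exact"`` when
    enumeration stays under ``exact_max_tables``).  Continuous variables use
    the Mann–Whitney U test.  Missing values are dropped pairwise per
    variable; a variable with a single observed level is recorded as
    untestable rather than raising.

    Returns (results DataFrame, dict variable → contingency DataFrame with
    count and column-percent columns per group).
    """
    if variables is None:
        variables = {k: v for k, v in DEFAULT_CLINICAL_VARIABLES.items()
                     if k in cohort.columns}
    df = cohort[cohort["sample"].isin(groups)].copy()
    df["_group"] = df["sample"].map(groups)
    rows, tables = [], {}
    for var, kind in variables.items():
        sub = df[[var, "_group"]].copy()
        sub[var] = sub[var].replace("unknown", np.nan)
        sub = sub.dropna()
        if kind == "continuous":
            x = sub.loc[sub["_group"] == GROUP_LOST, var].astype(float)
            y = sub.loc[sub["_group"] == GROUP_PRESERVED, var].astype(float)
            if x.empty or y.empty:
                rows.append((var, kind, "untestable", np.nan,
                             "a group has no observations"))
                continue
            res = stats.mann_whitney_u(x, y)
            rows.append((var, kind, res.method, res.p, None))
            continue
        ct = pd.crosstab(sub[var], sub["_group"])
        for g in (GROUP_LOST, GROUP_PRESERVED):
            if g not in ct.columns:
                ct[g] = 0
        ct = ct[[GROUP_LOST, GROUP_PRESERVED]]
        out = ct.copy()
        for g in ct.columns:
            tot = ct[g].sum()
            out[f"{g}_pct"] = (100 * ct[g] / tot).round(1) if tot else np.nan
        tables[var] = out
        if ct.shape[0] < 2 or (ct.sum(axis=0) == 0).any():
            rows.append((var, kind, "untestable", np.nan,
                         "fewer than two observed levels"))
            continue
        arr = ct.to_numpy()
        if test_policy == "chi2":
            res = stats.chi_square_test(arr)
        elif test_policy == "exact":
            try:
                res = (stats.fisher_exact_2x2(arr) if arr.shape == (2, 2)
                       else stats.exact_rxc(arr, max_tables=exact_max_tables))
            except ValueError:
                res = stats.chi_square_test(arr)
        else:  # auto: exact for 2×2, χ² above
            res = (stats.fisher_exact_2x2(arr) if arr.shape == (2, 2)
                   else stats.chi_square_test(arr))
        rows.append((var, kind, res.method, res.p, res.note))
    results = pd.DataFrame(rows, columns=["variable", "kind", "test", "p", "note"])
    return results, tables


# ---------------------------------------------------------------------------
# Differential SNVs
# ---------------------------------------------------------------------------

def differential_snv(snvs: pd.DataFrame, groups: dict, min_patients: int = 10,
                     exclude_genes=("TTN",), include_synonymous: bool = False
                     ) -> pd.DataFrame:
    """Per-gene Fisher tests of mutated-patient counts by arm status.

    A patient counts once per gene regardless of how many qualifying variants
    they carry.  Synonymous variants and the configured excluded genes (TTN
    by default — a passenger-mutation magnet) are removed first; genes
    mutated in fewer than ``min_patients`` patients in both arms are dropped
    before testing, so the BH family contains only tested genes.
    """
    lost = {s for s, g in groups.items() if g == GROUP_LOST}
    pres = {s for s, g in groups.items() if g == GROUP_PRESERVED}
    if not lost or not pres:
        raise ValueError("both comparison arms must be non-empty")
    rec = snvs[snvs["sample"].isin(lost | pres)]
    if not include_synonymous:
        rec = rec[~rec["synonymous"]]
    rec = rec[~rec["gene"].isin(set(exclude_genes))]
    pairs = rec[["sample", "gene"]].drop_duplicates()
    pairs["_group"] = pairs["sample"].map(groups)
    counts = pairs.pivot_table(index="gene", columns="_group", values="sample",
                               aggfunc="count", fill_value=0)
    for g in (GROUP_LOST, GROUP_PRESERVED):
        if g not in counts.columns:
            counts[g] = 0
    keep = counts.max(axis=1) >= min_patients
    counts = counts[keep]
    if counts.empty:
        warnings.warn("no genes pass the minimum-patient filter", stacklevel=2)
        return pd.DataFrame(columns=["gene", "event_class", "n_lost_mut",
                                     "n_lost", "n_preserved_mut", "n_preserved",
                                     "odds_ratio", "p", "q"])
    n1, n2 = len(lost), len(pres)
    rows = []
    for gene in sorted(counts.index):
        a = int(counts.loc[gene, GROUP_LOST])
        b = int(counts.loc[gene, GROUP_PRESERVED])
        p = _cached_fisher_p(a, b, n1 - a, n2 - b)
        rows.append((gene, "snv", a, n1, b, n2,
                     _sample_or(a, b, n1 - a, n2 - b), p))
    out = pd.DataFrame(rows, columns=["gene", "event_class", "n_lost_mut",
                                      "n_lost", "n_preserved_mut",
                                      "n_preserved", "odds_ratio", "p"])
    out["q"] = stats.bh_adjust(out["p"].to_numpy())
    return out.sort_values("q", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Differential CNAs
# ---------------------------------------------------------------------------

def differential_cna(matrix: CnaCallMatrix, groups: dict,
                     flag_arms=(("3", "p"),)) -> pd.DataFrame:
    """Per-gene, per-event-class Fisher tests of carrier counts by arm status.

    Each of the four event classes (deep deletion −2, shallow deletion −1,
    gain +1, amplification +2) is tested as its own 2×2 carrier/non-carrier
    contrast, with BH correction within each class — classes are separate
    test families.  Genes on the arms listed in ``flag_arms`` are marked in
    an ``on_flagged_arm`` column so genome-wide summaries can exclude the
    arm that defined the groups.
    """
    lost = [s for s in matrix.samples if groups.get(s) == GROUP_LOST]
    pres = [s for s in matrix.samples if groups.get(s) == GROUP_PRESERVED]
    if not lost or not pres:
        raise ValueError("both comparison arms must be non-empty")
    n1, n2 = len(lost), len(pres)
    lost_calls = matrix.calls[lost].to_numpy()
    pres_calls = matrix.calls[pres].to_numpy()
    flagged = np.zeros(len(matrix.genes), dtype=bool)
    if matrix.annotations is not None and flag_arms:
        index = build_arm_index(matrix.annotations)
        flag_set = set()
        for armkey in flag_arms:
            flag_set |= index.get(tuple(armkey), set())
        flagged = np.array([g in flag_set for g in matrix.genes])
    frames = []
    for cls, value in EVENT_CLASSES.items():
        a = (lost_calls == value).sum(axis=1)
        b = (pres_calls == value).sum(axis=1)
        ps = np.array([_cached_fisher_p(int(ai), int(bi),
                                        n1 - int(ai), n2 - int(bi))
                       for ai, bi in zip(a, b)])
        ors = np.array([_sample_or(ai, bi, n1 - ai, n2 - bi)
                        for ai, bi in zip(a, b)])
        frames.append(pd.DataFrame({
            "gene": matrix.genes, "event_class": cls,
            "n_lost_mut": a, "n_lost": n1,
            "n_preserved_mut": b, "n_preserved": n2,
            "odds_ratio": ors, "p": ps, "q": stats.bh_adjust(ps),
            "on_flagged_arm": flagged,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# CNA × mRNA integration
# ---------------------------------------------------------------------------

def integrate_cna_mrna(cna_records: pd.DataFrame, de_table: pd.DataFrame,
                       cna_q: float = 0.1, mrna_q: float = 0.01,
                       min_abs_log2fc: float = 1.0):
    """Filter CNA hits through the differential-expression table.

    Keeps genes with CNA q < ``cna_q``, mRNA q < ``mrna_q``, and at least a
    twofold mRNA change (|log2FC| ≥ ``min_abs_log2fc``).  A gene significant
    as both a deletion-type and a gain-type event is assigned the class with
    the lower CNA q.  The concordant flag marks direction agreement:
    gain-type with positive fold change, deletion-type with negative.

    Returns (IntegrationRecord DataFrame, count of significant CNA genes
    dropped for lack of a DE entry).
    """
    sig = cna_records[cna_records["q"] < cna_q].copy()
    sig["cn_type"] = np.where(sig["event_class"].isin(GAIN_CLASSES),
                              "gain", "deletion")
    # per gene: best (lowest-q) record overall decides the assigned class
    best = (sig.sort_values(["q", "p"], kind="stable")
            .drop_duplicates("gene", keep="first"))
    de = de_table.set_index("gene")
    n_missing = int((~best["gene"].isin(de.index)).sum())
    best = best[best["gene"].isin(de.index)]
    rows = []
    for _, r in best.iterrows():
        d = de.loc[r["gene"]]
        if d["q"] >= mrna_q or abs(d["log2fc"]) < min_abs_log2fc:
            continue
        concordant = ((r["cn_type"] == "gain" and d["log2fc"] > 0)
                      or (r["cn_type"] == "deletion" and d["log2fc"] < 0))
        rows.append((r["gene"], r["cn_type"], r["event_class"], r["q"],
                     d["q"], d["log2fc"], concordant))
    out = pd.DataFrame(rows, columns=["gene", "cn_type", "event_class",
                                      "cna_q", "mrna_q", "log2fc", "concordant"])
    return out.sort_values("cna_q", kind="stable").reset_index(drop=True), n_missing


# ---------------------------------------------------------------------------
# Burden contrast
# ---------------------------------------------------------------------------

def burden_contrast(burdens: pd.DataFrame, groups: dict,
                    column: str = "pga") -> stats.TestResult:
    """Mann–Whitney comparison of a burden metric by arm status."""
    sub = burdens[burdens["sample"].isin(groups)]
    grp = sub["sample"].map(groups)
    x = sub.loc[grp == GROUP_LOST, column].to_numpy()
    y = sub.loc[grp == GROUP_PRESERVED, column].to_numpy()
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    return stats.mann_whitney_u(x, y)
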