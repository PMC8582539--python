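"""Gene-set scoring of expression data and group comparison.

Two scoring schemes:

* hypoxia-style median-split scores — for each signature gene, samples
  strictly above the cohort median get +1, strictly below get −1, at the
  median 0; a sample's score is the sum over signature genes.  Rank-based by
  construction, so invariant to any monotone per-gene transform.
* marker-mean scores — arithmetic mean of (optionally log2(x+1)) marker
  abundances, the convention of marker-based microenvironment estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats


@dataclass
class GeneSignature:
    name: str
    genes: list[str]
    description: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate symbols in signature {self.name!r}")


def read_gmt(path) -> list[GeneSignature]:
    """GMT gene-set format: name, description, then symbols, tab-separated."""
    sigs = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sigs.append(GeneSignature(parts[0], parts[2:], parts[1]))
    return sigs


def write_gmt(signatures: list[GeneSignature], path) -> None:
    with open(path, "w") as fh:
        for s in signatures:
            fh.write("\t".join([s.name, s.description] + list(s.genes)) + "\n")


def _present_genes(expr: pd.DataFrame, signature: GeneSignature) -> list[str]:
    present = [g for g in signature.genes if g in expr.index]
    if not present:
        raise ValueError(f"no genes of signature {signature.name!r} in matrix")
    if len(present) < len(signature.genes):
        warnings.warn(
            f"signature {signature.name!r}: "
            f"{len(signature.genes) - len(present)} gene(s) absent, dropped",
            stacklevel=3)
    return present


def hypoxia_score(expr: pd.DataFrame, signature: GeneSignature) -> pd.Series:
    """Per-sample median-split signature score (integer in [−|S|, +|S|])."""
    if expr.shape[1] < 2:
        raise ValueError("need at least two samples")
    sub = expr.loc[_present_genes(expr, signature)]
    med = sub.median(axis=1)
    score = (sub.gt(med, axis=0).astype(int)
             - sub.lt(med, axis=0).astype(int)).sum(axis=0)
    return score.rename(signature.name)


def marker_score(expr: pd.DataFrame, markers: GeneSignature,
                 log_transform: bool = True) -> pd.Series:
    """Per-sample mean abundance over a marker set."""
    sub = expr.loc[_present_genes(expr, markers)]
    if log_transform:
        sub = np.log2(sub + 1)
    return sub.mean(axis=0).rename(markers.name)


def score_matrix(expr: pd.DataFrame, signatures: list[GeneSignature],
                 kind: str = "hypoxia", log_transform: bool = True
                 ) -> pd.DataFrame:
    """Samples × signatures score matrix."""
    scorer = {"hypoxia": lambda s: hypoxia_score(expr, s),
              "marker": lambda s: marker_score(expr, s, log_transform)}[kind]
    return pd.concat([scorer(s) for s in signatures], axis=1)


def pik3ca_gain_covariate(cna_matrix, samples, gene: str = "PIK3CA") -> np.ndarray:
    """Binary gain covariate: thresholded call ≥ +1 for ``gene``."""
    if gene not in cna_matrix.calls.index:
        raise KeyError(f"{gene!r} not in copy-number matrix")
    calls = cna_matrix.calls.loc[gene]
    return np.array([int(calls[s] >= 1) for s in samples])


def compare_scores_by_group(scores: pd.DataFrame, groups: dict,
                            covariate: np.ndarray | dict | None = None
                            ) -> pd.DataFrame:
    """Box–Cox regression of each signature score on arm status.

    ``covariate``, when given, is a per-sample binary adjustment (e.g.
    PIK3CA gain) included in the linear model.  q-values are BH-adjusted
    across signatures.
    """
    samples = [s for s in scores.index if s in groups]
    if not samples:
        raise ValueError("no scored samples with group assignments")
    labels = np.array([groups[s] for s in samples])
    # code lost = 1 so a positive coefficient means higher in the lost group
    grp = ((labels == "lost").astype(int) if "lost" in labels
           else labels)
    if covariate is not None and isinstance(covariate, dict):
        covariate = np.array([covariate[s] for s in samples], dtype=float)
    rows = []
    for sig in scores.columns:
        y = scores.loc[samples, sig].to_numpy(dtype=float)
        try:
            res = stats.boxcox_regression(y, grp, covariates=covariate)
            rows.append((sig, res.statistic, res.effect, res.ci_low,
                         res.ci_high, res.p, None))
        except ValueError as exc:
            rows.append((sig, np.nan, np.nan, np.nan, np.nan, np.nan, str(exc)))
    out = pd.DataFrame(rows, columns=["signature", "coef", "fold_change",
                                      "ci_low", "ci_high", "p", "note"])
    testable = out["p"].notna()
    q = np.full(len(out), np.nan)
    if testable.any():
        q[testable.to_numpy()] = stats.bh_adjust(out.loc[testable, "p"].to_numpy())
    out["q"] = q
    return out


def validate_feature_mrna_correlation(features: pd.DataFrame, mrna: pd.DataFrame,
                                      pair_map: dict, q_threshold: float = 0.1,
                                      require_positive: bool = False
                                      ) -> pd.DataFrame:
    """Validate features (proteins, miRNAs) against mRNA by rank correlation.

    ``pair_map`` maps a feature symbol to one or more mRNA symbols.  Each
    pair gets a Spearman rho and p; BH across pairs; ``pass`` requires
    q below threshold and, in protein mode (``require_positive``), rho > 0.
    Zero-variance features are recorded as untestable.
    """
    shared = [s for s in features.columns if s in mrna.columns]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    rows = []
    for feat, targets in pair_map.items():
        if isinstance(targets, str):
            targets = [targets]
        for gene in targets:
            if feat not in features.index or gene not in mrna.index:
                continue
            x = features.loc[feat, shared].to_numpy(dtype=float)
            y = mrna.loc[gene, shared].to_numpy(dtype=float)
            try:
                res = stats.spearman_correlation(x, y)
                rows.append((feat, gene, res.effect, res.p, None))
            except ValueError as exc:
                rows.append((feat, gene, np.nan, np.nan, str(exc)))
    out = pd.DataFrame(rows, columns=["feature", "gene", "rho", "p", "note"])
    testable = out["p"].notna()
    q = np.full(len(out), np.nan)
    if testable.any():
        q[testable.to_numpy()] = stats.bh_adjust(out.loc[testable, "p"].to_numpy())
    out["q"] = q
    passed = (out["q"] < q_threshold)
    if require_positive:
        passed &= out["rho"] > 0
    out["pass"] = passed.fillna(False)
    return out
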