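"""Per-sample chromosome-arm deletion metrics and arm-loss classification.

Three operational definitions of arm loss are supported:

* ``threshold`` — classify by the fraction of arm genes with a deletion call
  (≤ −1).  HPV-negative tumors are called *lost* at ≥97% of the arm deleted
  and *preserved* below 1%; HPV-positive tumors use >50% / <1%.  Samples
  between the cutoffs are excluded as intermediate, and samples with a
  homozygous (−2) deletion of more than half the arm are excluded outright —
  whole-arm homozygous loss is a biologically distinct, rare event.
* ``fragile_site`` — lost iff the median thresholded call over a small
  genetically unstable locus (3p14.2 by default) is ≤ −1.
* ``panel_full`` / ``panel_any`` — targeted-panel definitions: >80% of arm
  genes deleted, or any arm gene deleted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .model import CnaCallMatrix, ValidationError

STATUS_LOST = "lost"
STATUS_PRESERVED = "preserved"
STATUS_INTERMEDIATE = "excluded_intermediate"
STATUS_HOMOZYGOUS = "excluded_homozygous"

EXCLUDED_STATUSES = (STATUS_INTERMEDIATE, STATUS_HOMOZYGOUS)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Cutoffs for the threshold definition of arm loss.

    ``high_inclusive`` controls the boundary rule at the high cutoff: the
    HPV-negative policy calls f_del ≥ 0.97 lost, while the HPV-positive
    policy requires f_del strictly > 0.50.
    """

    high: float
    low: float
    homozygous: float = 0.50
    high_inclusive: bool = True

    def __post_init__(self):
        if not (0 <= self.low < self.high <= 1):
            raise ValidationError(
                f"require 0 ≤ low < high ≤ 1, got low={self.low}, high={self.high}")
        if not (0 < self.homozygous <= 1):
            raise ValidationError("homozygous cutoff must be in (0, 1]")


#: Default policies by HPV stratum.
HPV_NEGATIVE_POLICY = ThresholdPolicy(high=0.97, low=0.01, high_inclusive=True)
HPV_POSITIVE_POLICY = ThresholdPolicy(high=0.50, low=0.01, high_inclusive=False)


def policy_for_hpv(hpv_status: str) -> ThresholdPolicy:
    if hpv_status == "negative":
        return HPV_NEGATIVE_POLICY
    if hpv_status == "positive":
        return HPV_POSITIVE_POLICY
    raise ValueError(f"unknown HPV status {hpv_status!r}")


@dataclass
class ArmStatusCall:
    sample: str
    arm: tuple[str, str]
    f_del: float
    f_homo: float
    status: str
    definition: str

    def __post_init__(self):
        if not (0 <= self.f_homo <= self.f_del <= 1):
            if not (0 <= self.f_del <= 1 and 0 <= self.f_homo <= self.f_del):
                raise ValidationError(
                    f"{self.sample}: need 0 ≤ f_homo ≤ f_del ≤ 1 "
                    f"(got f_del={self.f_del}, f_homo={self.f_homo})")


def arm_deletion_fraction(matrix: CnaCallMatrix, arm_genes, sample
                          ) -> tuple[float, float]:
    """Fraction of arm genes with any deletion (call ≤ −1) and with a deep
    deletion (call = −2) in one sample."""
    arm_genes = list(arm_genes)
    if not arm_genes:
        raise ValidationError("empty arm gene set")
    missing = set(arm_genes) - set(matrix.calls.index)
    if missing:
        raise ValidationError(
            f"{len(missing)} arm genes absent from matrix, e.g. "
            f"{sorted(missing)[:3]}")
    calls = matrix.sample_calls(sample, arm_genes).to_numpy()
    f_del = float((calls <= -1).mean())
    f_homo = float((calls == -2).mean())
    return f_del, f_homo


def classify_threshold(f_del: float, f_homo: float, hpv: str | None = None,
                       policy: ThresholdPolicy | None = None,
                       sample: str = "", arm: tuple[str, str] = ("3", "p")
                       ) -> ArmStatusCall:
    """Classify one sample under the threshold definition.

    The homozygous exclusion (f_homo > cutoff) is evaluated first; then lost
    at the high cutoff, preserved below the low cutoff, and intermediate
    (excluded) in between.
    """
    if policy is None:
        if hpv is None:
            raise ValueError("provide hpv status or an explicit policy")
        policy = policy_for_hpv(hpv)
    if f_homo > policy.homozygous:
        status = STATUS_HOMOZYGOUS
    elif (f_del >= policy.high) if policy.high_inclusive else (f_del > policy.high):
        status = STATUS_LOST
    elif f_del < policy.low:
        status = STATUS_PRESERVED
    else:
        status = STATUS_INTERMEDIATE
    return ArmStatusCall(sample, arm, f_del, f_homo, status, "threshold")


def classify_fragile_site(matrix: CnaCallMatrix, locus_genes, sample,
                          arm: tuple[str, str] = ("3", "p")) -> ArmStatusCall:
    """Fragile-site definition: lost iff the median thresholded call over the
    locus genes is ≤ −1.

    With an even gene count and a half/half split the median lands between
    the two classes (e.g. −0.5), which is > −1 and therefore *preserved* —
    the tie resolves conservatively toward no loss.
    """
    locus_genes = [g for g in locus_genes if g in set(matrix.calls.index)]
    if not locus_genes:
        raise ValidationError("no fragile-site locus genes present in matrix")
    calls = matrix.sample_calls(sample, locus_genes).to_numpy()
    med = float(np.median(calls))
    status = STATUS_LOST if med <= -1 else STATUS_PRESERVED
    f_del = float((calls <= -1).mean())
    f_homo = float((calls == -2).mean())
    return ArmStatusCall(sample, arm, f_del, f_homo, status, "fragile_site")


def classify_panel(matrix: CnaCallMatrix, arm_genes, sample, mode: str = "full",
                   arm: tuple[str, str] = ("3", "p")) -> ArmStatusCall:
    """Targeted-panel definitions: ``full`` = >80% of arm genes deleted,
    ``any`` = at least one arm gene deleted."""
    f_del, f_homo = arm_deletion_fraction(matrix, arm_genes, sample)
    if mode == "full":
        status = STATUS_LOST if f_del > 0.80 else STATUS_PRESERVED
    elif mode == "any":
        status = STATUS_LOST if f_del > 0 else STATUS_PRESERVED
    else:
        raise ValueError(f"unknown panel mode {mode!r}")
    return ArmStatusCall(sample, arm, f_del, f_homo, status, f"panel_{mode}")


def classify_cohort(matrix: CnaCallMatrix, arm_genes, hpv_by_sample: dict,
                    definition: str = "threshold", locus_genes=None,
                    policy: ThresholdPolicy | None = None,
                    arm: tuple[str, str] = ("3", "p")) -> list[ArmStatusCall]:
    """Classify every sample of the matrix under one definition."""
    calls = []
    for sample in matrix.samples:
        if definition == "threshold":
            f_del, f_homo = arm_deletion_fraction(matrix, arm_genes, sample)
            calls.append(classify_threshold(
                f_del, f_homo, hpv=hpv_by_sample.get(sample),
                policy=policy, sample=sample, arm=arm))
        elif definition == "fragile_site":
            calls.append(classify_fragile_site(matrix, locus_genes, sample, arm))
        elif definition in ("panel_full", "panel_any"):
            calls.append(classify_panel(matrix, arm_genes, sample,
                                        mode=definition.split("_")[1], arm=arm))
        else:
            raise ValueError(f"unknown definition {definition!r}")
    return calls


def calls_to_frame(calls: list[ArmStatusCall]) -> pd.DataFrame:
    return pd.DataFrame({
        "sample": [c.sample for c in calls],
        "arm": [f"{c.arm[0]}{c.arm[1]}" for c in calls],
        "f_del": [c.f_del for c in calls],
        "f_homo": [c.f_homo for c in calls],
        "status": [c.status for c in calls],
        "definition": [c.definition for c in calls],
    })


def status_map(calls: list[ArmStatusCall]) -> dict[str, str]:
    """sample → status for non-excluded samples only."""
    return {c.sample: c.status for c in calls
            if c.status in (STATUS_LOST, STATUS_PRESERVED)}


def concordance_table(calls_a: list[ArmStatusCall], calls_b: list[ArmStatusCall]):
    """Cross-tabulate two definitions over {lost, preserved}.

    Samples excluded under either definition are dropped pairwise.  Returns
    (2×2 count DataFrame A-rows × B-columns, row-conditional percentages,
    Fisher exact result).
    """
    a = status_map(calls_a)
    b = status_map(calls_b)
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("no samples classified under both definitions")
    levels = [STATUS_LOST, STATUS_PRESERVED]
    counts = pd.DataFrame(0, index=levels, columns=levels)
    for s in shared:
        counts.loc[a[s], b[s]] += 1
    row_tot = counts.sum(axis=1).replace(0, np.nan)
    percents = counts.div(row_tot, axis=0) * 100
    result = stats.fisher_exact_2x2(counts.to_numpy())
    return counts, percents, result
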