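"""Config-driven orchestration of the full analysis on a cohort bundle.

Stage order follows the analysis's dependency structure: classify → clinical
→ burden → differential SNV/CNA → CNA×mRNA integration → signature scores →
survival.  HPV strata are always analyzed separately, never pooled.  Each
stage writes its result TSVs into the output directory; failures are recorded
in the run report and dependent stages are skipped while independent stages
still run.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import traceback
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import arm_status, burden, differential, model, signatures, survival
from .simulate import (SimulationConfig, fragile_site_symbols, simulate_bundle,
                       arm_symbols)

log = logging.getLogger("chromarm")

ALL_STAGES = ("classify", "clinical", "burden", "snv", "cna", "integrate",
              "scores", "survival")

#: stage → stages it needs
_DEPENDS = {
    "clinical": ("classify",),
    "burden": ("classify",),
    "snv": ("classify",),
    "cna": ("classify",),
    "integrate": ("classify", "cna"),
    "scores": ("classify",),
    "survival": ("classify",),
}


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    simulate: SimulationConfig | None = None
    cna_path: str | None = None
    maf_path: str | None = None
    clinical_path: str | None = None
    mrna_path: str | None = None
    de_path: str | None = None
    signatures_path: str | None = None
    stages: tuple = ALL_STAGES
    arm: str = "3p"
    fdr_cna: float = 0.1
    fdr_mrna: float = 0.01
    min_abs_log2fc: float = 1.0
    min_patients: int = 10
    exclude_genes: tuple = ("TTN",)

    def __post_init__(self):
        for thr in (self.fdr_cna, self.fdr_mrna):
            if not 0 < thr < 1:
                raise ValueError(f"FDR threshold {thr} outside (0, 1)")


@dataclass
class RunReport:
    seed: int
    stages: list = field(default_factory=list)
    sample_accounting: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def record(self, stage: str, status: str, outputs=(), detail: str = ""):
        self.stages.append({"stage": stage, "status": status,
                            "outputs": list(outputs), "detail": detail})

    def failed(self, stage: str) -> bool:
        return any(s["stage"] == stage and s["status"] != "ok"
                   for s in self.stages)


def _load_inputs(config: PipelineConfig):
    """Either simulate a bundle or read the configured input files."""
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        bundle = simulate_bundle(sim)
        arm_genes = arm_symbols(bundle.genome, config.arm)
        locus = fragile_site_symbols(bundle.genome)
        return dict(cna=bundle.cna, snvs=bundle.snvs, clinical=bundle.clinical,
                    mrna=bundle.mrna, de=bundle.de_table,
                    signatures=bundle.hypoxia_signatures,
                    arm_genes=arm_genes, locus_genes=locus, bundle=bundle)
    if config.cna_path is None or config.clinical_path is None:
        raise ValueError("need either a simulate block or cna/clinical paths")
    cna = model.read_cna_matrix(config.cna_path)
    clinical = model.read_clinical(config.clinical_path)
    if cna.annotations is None:
        raise ValueError("CNA matrix lacks cytoband annotations; cannot "
                         "resolve arm membership")
    index = model.build_arm_index(cna.annotations)
    chrom, arm = config.arm[:-1], config.arm[-1]
    arm_genes = sorted(index.get((chrom, arm), ()))
    locus = sorted(g for g, a in cna.annotations.items()
                   if a.cytoband == f"{config.arm}14.2")
    snvs = model.read_maf(config.maf_path) if config.maf_path else None
    mrna = model.read_expression(config.mrna_path) if config.mrna_path else None
    de = model.read_de_table(config.de_path) if config.de_path else None
    sigs = (signatures.read_gmt(config.signatures_path)
            if config.signatures_path else [])
    return dict(cna=cna, snvs=snvs, clinical=clinical, mrna=mrna, de=de,
                signatures=sigs, arm_genes=arm_genes, locus_genes=locus,
                bundle=None)


def run_pipeline(config: PipelineConfig) -> RunReport:
    os.makedirs(config.out_dir, exist_ok=True)
    report = RunReport(seed=config.seed)
    report.parameters = {
        "arm": config.arm, "fdr_cna": config.fdr_cna,
        "fdr_mrna": config.fdr_mrna, "min_patients": config.min_patients,
        "exclude_genes": list(config.exclude_genes),
        "threshold_policy_hpv_negative": dataclasses.asdict(
            arm_status.HPV_NEGATIVE_POLICY),
        "threshold_policy_hpv_positive": dataclasses.asdict(
            arm_status.HPV_POSITIVE_POLICY),
    }
    inputs = _load_inputs(config)
    clinical = inputs["clinical"]
    hpv = dict(zip(clinical["sample"], clinical["hpv_status"]))

    def out(name):
        return os.path.join(config.out_dir, name)

    def wants(stage):
        if stage not in config.stages:
            report.record(stage, "skipped", detail="toggled off")
            return False
        missing = [d for d in _DEPENDS.get(stage, ()) if report.failed(d)]
        if missing:
            report.record(stage, "skipped",
                          detail=f"dependency failed: {missing}")
            return False
        return True

    def run_stage(stage, fn):
        if not wants(stage):
            return
        try:
            outputs = fn() or ()
            report.record(stage, "ok", outputs=outputs)
        except Exception as exc:  # recorded, not raised: independent stages continue
            log.exception("stage %s failed", stage)
            report.record(stage, "failed",
                          detail=f"{type(exc).__name__}: {exc}")

    calls: list = []
    groups: dict = {}

    def stage_classify():
        nonlocal calls, groups
        calls = arm_status.classify_cohort(inputs["cna"], inputs["arm_genes"],
                                           hpv, definition="threshold")
        status_df = arm_status.calls_to_frame(calls)
        status_df["hpv_status"] = status_df["sample"].map(hpv)
        burdens = burden.burden_table(inputs["cna"], inputs["snvs"])
        status_df = status_df.merge(burdens, on="sample")
        status_df.to_csv(out("arm_status.tsv"), sep="\t", index=False,
                         float_format="%.6g")
        groups.update(arm_status.status_map(calls))
        for stratum in ("negative", "positive"):
            sub = status_df[status_df["hpv_status"] == stratum]
            report.sample_accounting[stratum] = (
                sub["status"].value_counts().to_dict())
        log.info("threshold policy (HPV-negative): %s",
                 arm_status.HPV_NEGATIVE_POLICY)
        return ["arm_status.tsv"]

    run_stage("classify", stage_classify)

    def stratum_groups(stratum):
        return {s: g for s, g in groups.items() if hpv.get(s) == stratum}

    def per_stratum(stage, fn):
        def run():
            outputs = []
            for stratum in ("negative", "positive"):
                g = stratum_groups(stratum)
                if len(set(g.values())) < 2:
                    log.info("%s: stratum %s lacks both groups, skipped",
                             stage, stratum)
                    continue
                outputs.extend(fn(stratum, g) or ())
            return outputs
        run_stage(stage, run)

    def stage_clinical(stratum, g):
        sub = clinical[clinical["hpv_status"] == stratum]
        results, tables = differential.clinical_association_table(sub, g)
        name = f"clinical_association_hpv_{stratum}.tsv"
        results.to_csv(out(name), sep="\t", index=False, float_format="%.6g")
        return [name]

    per_stratum("clinical", stage_clinical)

    def stage_burden(stratum, g):
        burdens = burden.burden_table(inputs["cna"], inputs["snvs"])
        res = differential.burden_contrast(burdens, g, column="pga")
        name = f"burden_contrast_hpv_{stratum}.tsv"
        pd.DataFrame([{"metric": "pga", "p": res.p,
                       "statistic": res.statistic}]
                     ).to_csv(out(name), sep="\t", index=False)
        return [name]

    per_stratum("burden", stage_burden)

    def stage_snv(stratum, g):
        if inputs["snvs"] is None:
            raise ValueError("no SNV input configured")
        res = differential.differential_snv(
            inputs["snvs"], g, min_patients=config.min_patients,
            exclude_genes=config.exclude_genes)
        name = f"differential_snv_hpv_{stratum}.tsv"
        res.to_csv(out(name), sep="\t", index=False, float_format="%.6g")
        return [name]

    per_stratum("snv", stage_snv)

    cna_results: dict = {}

    def stage_cna(stratum, g):
        res = differential.differential_cna(inputs["cna"], g)
        cna_results[stratum] = res
        name = f"differential_cna_hpv_{stratum}.tsv"
        res.to_csv(out(name), sep="\t", index=False, float_format="%.6g")
        return [name]

    per_stratum("cna", stage_cna)

    def stage_integrate(stratum, g):
        if inputs["de"] is None:
            raise ValueError("no differential-expression input configured")
        if stratum not in cna_results:
            return []
        res = cna_results[stratum]
        res = res[~res["on_flagged_arm"]]
        integ, n_missing = differential.integrate_cna_mrna(
            res, inputs["de"], cna_q=config.fdr_cna, mrna_q=config.fdr_mrna,
            min_abs_log2fc=config.min_abs_log2fc)
        name = f"integration_hpv_{stratum}.tsv"
        integ.to_csv(out(name), sep="\t", index=False, float_format="%.6g")
        if n_missing:
            log.info("integration (%s): %d CNA genes lacked DE entries",
                     stratum, n_missing)
        return [name]

    per_stratum("integrate", stage_integrate)

    def stage_scores(stratum, g):
        if inputs["mrna"] is None or not inputs["signatures"]:
            raise ValueError("scores stage needs mRNA and signature inputs")
        expr = inputs["mrna"][[s for s in inputs["mrna"].columns if s in g]]
        scores = signatures.score_matrix(expr, inputs["signatures"],
                                         kind="hypoxia")
        cov = None
        if "PIK3CA" in inputs["cna"].calls.index:
            cov = dict(zip(scores.index, signatures.pik3ca_gain_covariate(
                inputs["cna"], list(scores.index))))
        res = signatures.compare_scores_by_group(scores, g, covariate=cov)
        name = f"signature_scores_hpv_{stratum}.tsv"
        res.to_csv(out(name), sep="\t", index=False, float_format="%.6g")
        return [name]

    per_stratum("scores", stage_scores)

    def stage_survival(stratum, g):
        sub = clinical[clinical["sample"].isin(g)].copy()
        sub["group"] = sub["sample"].map(g)
        res = survival.logrank_test(sub, group_col="group")
        rows = [{"test": "logrank", "p": res.p, "statistic": res.statistic}]
        sub["lost"] = (sub["group"] == "lost").astype(float)
        try:
            cov_cols = ["lost"]
            if sub["adjuvant_rt"].nunique() == 2:
                sub["rt"] = (sub["adjuvant_rt"] == "yes").astype(float)
                cov_cols.append("rt")
            cox = survival.cox_ph(sub, cov_cols)
            for _, r in cox.iterrows():
                rows.append({"test": f"cox_{r['covariate']}", "p": r["p"],
                             "statistic": r["hr"]})
        except ValueError as exc:
            rows.append({"test": "cox", "p": np.nan, "statistic": np.nan,
                         "note": str(exc)})
        name = f"survival_hpv_{stratum}.tsv"
        pd.DataFrame(rows).to_csv(out(name), sep="\t", index=False)
        km_frames = []
        for label in ("lost", "preserved"):
            km = survival.kaplan_meier(sub[sub["group"] == label])
            km["group"] = label
            km_frames.append(km)
        km_name = f"km_hpv_{stratum}.tsv"
        pd.concat(km_frames).to_csv(out(km_name), sep="\t", index=False,
                                    float_format="%.6g")
        return [name, km_name]

    per_stratum("survival", stage_survival)

    write_report(report, config.out_dir)
    return report


def write_report(report: RunReport, out_dir) -> str:
    """Structured-text run report: parameters, per-stratum sample accounting,
    and per-stage status."""
    path = os.path.join(out_dir, "report.txt")
    lines = [f"chromarm run report (seed={report.seed})", ""]
    lines.append("[parameters]")
    for k, v in report.parameters.items():
        lines.append(f"{k} = {v}")
    lines.append("")
    lines.append("[sample accounting]")
    for stratum, counts in report.sample_accounting.items():
        total = sum(counts.values())
        lines.append(f"hpv_{stratum}: total={total} " +
                     " ".join(f"{k}={v}" for k, v in sorted(counts.items())))
    lines.append("")
    lines.append("[stages]")
    for s in report.stages:
        extra = f" ({s['detail']})" if s["detail"] else ""
        outs = f" -> {', '.join(s['outputs'])}" if s["outputs"] else ""
        lines.append(f"{s['stage']}: {s['status']}{extra}{outs}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
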