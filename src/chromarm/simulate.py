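"""Seeded synthetic tumor cohorts with the statistical structure the
downstream analyses assume.

The generator emulates an HNSCC-like cohort stratified by HPV status:

* per-sample 3p deletion fractions drawn from a three-component Beta mixture
  — a "preserved" mode packed below 1%, a "lost" mode near complete arm loss
  (tight above 97% for HPV-negative, broad above 50% for HPV-positive), and
  a minority intermediate component;
* deletions realized as one contiguous block of the arm's ordered gene list
  (segmental loss), so fragile-site and threshold definitions agree the way
  they do in real tumors; rare whole-arm homozygous (−2) events;
* co-occurring 3q gains (isochromosome-3q-like coupling), status-dependent
  background aberration rates elsewhere (a percent-genome-altered contrast);
* clinical covariates tied to arm status through logistic models (male sex,
  laryngeal site, heavy smoking, advanced N, stage IV, distant metastasis);
* per-gene SNV rates with arm-status multipliers (a TP53-like enriched gene,
  CASP8/HRAS-like depleted genes, a high-rate neutral TTN);
* expression with a planted hypoxia-signature shift, cis dosage effects,
  immune-marker depletion, mRNA-correlated proteins and anticorrelated
  miRNA–target pairs; and
* exponential survival with uniform censoring and a configurable arm-status
  hazard ratio, 1.0 (no effect) by default.

All randomness flows through one ``numpy`` generator seeded from the config;
a fixed seed reproduces the bundle byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arm_status import policy_for_hpv
from .model import CnaCallMatrix, GeneAnnotation

SPECIAL_GENES = {
    # symbol: (arm, role) — placed at deterministic positions
    "FHIT": ("3p", "fragile_site"),
    "PIK3CA": ("3q", "oncogene"),
    "TP53": ("17p", "snv_enriched"),
    "CASP8": ("2q", "snv_depleted"),
    "TTN": ("2q", "snv_neutral"),
    "HRAS": ("11p", "snv_depleted"),
    "HLA-A": ("6p", "snv_depleted"),
    "HLA-B": ("6p", "snv_depleted"),
    "HUWE1": ("Xp", "snv_depleted"),
    "COL22A1": ("8q", "snv_depleted"),
}


@dataclass(frozen=True)
class BetaComponent:
    weight: float
    a: float
    b: float


@dataclass(frozen=True)
class DeletionMixture:
    """Per-stratum mixture over the true 3p deletion fraction."""
    preserved: BetaComponent
    lost: BetaComponent
    intermediate: BetaComponent

    def __post_init__(self):
        total = self.preserved.weight + self.lost.weight + self.intermediate.weight
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {total}, not 1")


@dataclass
class ClinicalModel:
    """Baseline (arm-preserved) probabilities and log-odds effects of arm
    loss for the clinical covariates of one HPV stratum."""
    male_base: float = 0.51
    male_effect: float = 1.1
    larynx_base: float = 0.10
    larynx_effect: float = 1.3
    site_other: tuple = (("oropharynx", 0.01), ("hypopharynx", 0.01),
                         ("oral cavity", 0.88))
    heavy_smoking_base: float = 0.39
    heavy_smoking_effect: float = 1.0
    light_given_not_heavy: float = 0.33
    t_high_base: float = 0.55
    t_high_effect: float = 0.0
    n_high_base: float = 0.19
    n_high_effect: float = 1.0
    stage_iv_base: float = 0.49
    stage_iv_effect: float = 0.57
    rt_base: float = 0.58
    rt_effect: float = 0.34
    metastasis_base: float = 0.005
    metastasis_effect: float = 2.3
    age_mean: float = 63.0
    age_sd: float = 10.0
    age_effect: float = -2.0

    def null(self) -> "ClinicalModel":
        """Copy with every arm-status effect zeroed (for calibration runs)."""
        out = dataclasses.replace(self)
        for f in dataclasses.fields(out):
            if f.name.endswith("_effect"):
                setattr(out, f.name, 0.0)
        return out


HPV_POSITIVE_CLINICAL = ClinicalModel(
    male_base=0.92, male_effect=0.0,
    larynx_base=0.01, larynx_effect=0.5,
    site_other=(("oropharynx", 0.78), ("hypopharynx", 0.02),
                ("oral cavity", 0.19)),
    heavy_smoking_base=0.24, heavy_smoking_effect=1.6,
    light_given_not_heavy=0.46,
    t_high_base=0.24, n_high_base=0.36, n_high_effect=0.0,
    stage_iv_base=0.62, stage_iv_effect=0.0,
    rt_base=0.86, rt_effect=-0.5,
    metastasis_base=0.02, metastasis_effect=0.5,
    age_mean=57.0, age_effect=2.0,
)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_samples: int = 496
    hpv_positive_fraction: float = 0.15
    arm_gene_counts: dict = field(default_factory=lambda: {
        "3p": 642, "3q": 500, "17p": 200, "2q": 400, "11p": 250,
        "6p": 300, "8q": 300, "9p": 250, "Xp": 150,
    })
    fragile_site_size: int = 12
    mixtures: dict = field(default_factory=lambda: {
        "negative": DeletionMixture(
            preserved=BetaComponent(0.20, 1, 300),
            lost=BetaComponent(0.68, 350, 6),
            intermediate=BetaComponent(0.12, 2, 2)),
        "positive": DeletionMixture(
            preserved=BetaComponent(0.55, 1, 300),
            lost=BetaComponent(0.38, 6, 3),
            intermediate=BetaComponent(0.07, 2, 8)),
    })
    homozygous_arm_prob: float = 0.008
    gain_3q_prob_lost: float = 0.85
    gain_3q_prob_preserved: float = 0.15
    amp_within_gain_prob: float = 0.3
    background_rate_lost: float = 0.05
    background_rate_preserved: float = 0.02
    clinical: dict = field(default_factory=lambda: {
        "negative": ClinicalModel(),
        "positive": HPV_POSITIVE_CLINICAL,
    })
    # SNV model
    snv_special: dict = field(default_factory=lambda: {
        "TP53": (0.55, 1.6), "CASP8": (0.22, 0.30), "HRAS": (0.08, 0.25),
        "HLA-A": (0.10, 0.35), "HUWE1": (0.08, 0.30), "HLA-B": (0.08, 0.35),
        "COL22A1": (0.08, 0.30), "TTN": (0.35, 1.0),
    })
    n_background_snv_genes: int = 100
    background_snv_rate_range: tuple = (0.01, 0.08)
    silent_extra_prob: float = 0.25
    # expression model
    gene_base_log2_mean: float = 5.0
    gene_base_log2_sd: float = 1.5
    expr_noise_sd: float = 0.8
    cis_dosage_per_call: float = 1.0  # log2 units per copy-number step
    hypoxia_shift: float = 1.0
    n_hypoxia_signatures: int = 8
    hypoxia_signature_size: int = 15
    tcell_marker_size: int = 10
    tcell_depletion: float = -0.9
    caf_marker_size: int = 10
    caf_enrichment: float = 0.7
    # protein / miRNA
    n_proteins: int = 40
    protein_mrna_slope: float = 0.8
    protein_noise_sd: float = 0.8
    n_mirna: int = 30
    n_mirna_target_pairs: int = 5
    mirna_target_slope: float = 1.0
    mirna_noise_sd: float = 1.7
    mirna_lost_shift: float = 0.8
    n_mirna_differential: int = 2
    # survival
    baseline_hazard_per_day: float = 6.4e-4
    hazard_ratio_lost: float = 1.0
    censoring_max_days: float = 2500.0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be ≥ 2")
        if not 0 <= self.hpv_positive_fraction <= 1:
            raise ValueError("hpv_positive_fraction must be in [0, 1]")
        if any(c <= 0 for c in self.arm_gene_counts.values()):
            raise ValueError("per-arm gene counts must be positive")
        if "3p" not in self.arm_gene_counts or "3q" not in self.arm_gene_counts:
            raise ValueError("genome must designate 3p and 3q arms")


@dataclass
class CohortBundle:
    config: SimulationConfig
    genome: dict            # symbol -> GeneAnnotation, insertion-ordered
    cna: CnaCallMatrix
    snvs: pd.DataFrame
    clinical: pd.DataFrame
    mrna: pd.DataFrame
    protein: pd.DataFrame
    mirna: pd.DataFrame
    de_table: pd.DataFrame
    truth: pd.DataFrame
    hypoxia_signatures: list
    marker_sets: list
    mirna_targets: dict     # miRNA -> target gene symbol
    protein_targets: dict   # protein feature -> gene symbol


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> dict:
    """Construct the synthetic gene annotation set (symbol → annotation).

    Gene order within an arm is positional; the 3p arm carries a centered
    fragile-site block annotated ``3p14.2``.  Named marker genes (TP53-like,
    PIK3CA-like, …) are planted at fixed positions on their arms.
    """
    genome: dict[str, GeneAnnotation] = {}
    special_by_arm: dict[str, list[str]] = {}
    for sym, (arm, _role) in SPECIAL_GENES.items():
        special_by_arm.setdefault(arm, []).append(sym)
    for arm_label, count in config.arm_gene_counts.items():
        chrom, arm = arm_label[:-1], arm_label[-1]
        frag_lo = frag_hi = -1
        if arm_label == "3p":
            if count < config.fragile_site_size:
                raise ValueError("3p arm smaller than its fragile site")
            frag_lo = (count - config.fragile_site_size) // 2
            frag_hi = frag_lo + config.fragile_site_size
        specials = special_by_arm.get(arm_label, [])
        # plant specials mid-arm, inside the fragile block for 3p
        special_pos = {}
        base = frag_lo if arm_label == "3p" else count // 2
        for k, sym in enumerate(specials):
            special_pos[min(base + k, count - 1)] = sym
        for i in range(count):
            band = f"{arm_label}14.2" if frag_lo <= i < frag_hi else f"{arm_label}21"
            sym = special_pos.get(i, f"{arm_label}G{i:04d}")
            genome[sym] = GeneAnnotation(sym, chrom, arm, band)
    return genome


def arm_symbols(genome: dict, arm_label: str) -> list[str]:
    chrom, arm = arm_label[:-1], arm_label[-1]
    return [s for s, a in genome.items()
            if a.chromosome == chrom and a.arm == arm]


def fragile_site_symbols(genome: dict, band: str = "3p14.2") -> list[str]:
    return [s for s, a in genome.items() if a.cytoband == band]


# ---------------------------------------------------------------------------
# CNA + clinical
# ---------------------------------------------------------------------------

def _bernoulli(rng, p, n=None):
    return rng.random(n) < p if n is not None else rng.random() < p


def _logistic_prob(base: float, effect: float, lost: bool) -> float:
    base = min(max(base, 1e-9), 1 - 1e-9)
    logit = np.log(base / (1 - base)) + (effect if lost else 0.0)
    return 1.0 / (1.0 + np.exp(-logit))


def _draw_fraction(rng, mixture: DeletionMixture) -> float:
    comps = [mixture.preserved, mixture.lost, mixture.intermediate]
    weights = np.array([c.weight for c in comps])
    k = rng.choice(3, p=weights / weights.sum())
    c = comps[k]
    return float(rng.beta(c.a, c.b))


def simulate_cna_and_clinical(config: SimulationConfig, genome: dict,
                              rng: np.random.Generator):
    """Draw the copy-number matrix, clinical table and per-sample truth.

    Deletion fractions are realized as one contiguous block of the ordered
    3p gene list; the recorded true fraction is the realized block fraction,
    and the true status applies the stratum's threshold policy to it.
    Background aberrations are placed on arms other than 3p/3q so that the
    planted arm fractions stay exact.
    """
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    genes = list(genome)
    gene_pos = {g: i for i, g in enumerate(genes)}
    p3 = arm_symbols(genome, "3p")
    q3 = arm_symbols(genome, "3q")
    other = [g for g in genes if g not in set(p3) | set(q3)]
    other_idx = np.array([gene_pos[g] for g in other], dtype=np.intp)
    p3_idx = np.array([gene_pos[g] for g in p3], dtype=np.intp)
    q3_idx = np.array([gene_pos[g] for g in q3], dtype=np.intp)
    n3p, n3q = len(p3), len(q3)

    calls = np.zeros((len(genes), n), dtype=np.int64)
    truth_rows = []
    clin_rows = []
    for j, sample in enumerate(samples):
        hpv = "positive" if _bernoulli(rng, config.hpv_positive_fraction) else "negative"
        mixture = config.mixtures[hpv]
        f_drawn = _draw_fraction(rng, mixture)
        homozygous = bool(_bernoulli(rng, config.homozygous_arm_prob))
        if homozygous:
            # homozygous whole-arm events sit in the lost mode
            f_drawn = float(rng.beta(40, 2))
        block = int(round(f_drawn * n3p))
        start = int(rng.integers(0, n3p - block + 1)) if block < n3p else 0
        depth = -2 if homozygous else -1
        calls[p3_idx[start:start + block], j] = depth
        f_del = block / n3p
        f_homo = f_del if homozygous else 0.0
        call = policy_for_hpv(hpv)
        if f_homo > call.homozygous:
            status = "excluded_homozygous"
        elif (f_del >= call.high) if call.high_inclusive else (f_del > call.high):
            status = "lost"
        elif f_del < call.low:
            status = "preserved"
        else:
            status = "excluded_intermediate"
        lost = status == "lost"

        gain_p = config.gain_3q_prob_lost if lost else config.gain_3q_prob_preserved
        gained = bool(_bernoulli(rng, gain_p))
        if gained:
            gfrac = float(rng.beta(20, 3))
            glen = max(1, int(round(gfrac * n3q)))
            gstart = int(rng.integers(0, n3q - glen + 1)) if glen < n3q else 0
            calls[q3_idx[gstart:gstart + glen], j] = 1
            if _bernoulli(rng, config.amp_within_gain_prob):
                alen = max(1, glen // 5)
                astart = gstart + int(rng.integers(0, glen - alen + 1))
                calls[q3_idx[astart:astart + alen], j] = 2

        rate = (config.background_rate_lost if lost
                else config.background_rate_preserved)
        u = rng.random(other_idx.size)
        v = rng.random(other_idx.size)
        altered = u < rate
        # 45% shallow del, 45% gain, 5% each deep del / amplification
        bg = np.where(v < 0.45, -1, np.where(v < 0.90, 1,
                                             np.where(v < 0.95, -2, 2)))
        calls[other_idx[altered], j] = bg[altered]

        cm = config.clinical[hpv]
        sex = "male" if _bernoulli(rng, _logistic_prob(cm.male_base, cm.male_effect, lost)) else "female"
        if _bernoulli(rng, _logistic_prob(cm.larynx_base, cm.larynx_effect, lost)):
            site = "larynx"
        else:
            labels = [s for s, _ in cm.site_other]
            probs = np.array([p for _, p in cm.site_other], dtype=float)
            site = labels[int(rng.choice(len(labels), p=probs / probs.sum()))]
        heavy = _bernoulli(rng, _logistic_prob(cm.heavy_smoking_base,
                                               cm.heavy_smoking_effect, lost))
        if heavy:
            smoking, pack_years = "heavy", 21.0 + float(rng.exponential(20.0))
        elif _bernoulli(rng, cm.light_given_not_heavy):
            smoking, pack_years = "light", float(rng.uniform(1.0, 20.0))
        else:
            smoking, pack_years = "non-smoker", 0.0
        age = float(np.clip(rng.normal(cm.age_mean + (cm.age_effect if lost else 0),
                                       cm.age_sd), 19, 84))
        t_group = "T3-T4" if _bernoulli(rng, _logistic_prob(cm.t_high_base, cm.t_high_effect, lost)) else "T0-T2/TX"
        n_group = "N2b-N3" if _bernoulli(rng, _logistic_prob(cm.n_high_base, cm.n_high_effect, lost)) else "N0-N2a/NX"
        stage_group = "IV" if _bernoulli(rng, _logistic_prob(cm.stage_iv_base, cm.stage_iv_effect, lost)) else "I-III"
        rt = "yes" if _bernoulli(rng, _logistic_prob(cm.rt_base, cm.rt_effect, lost)) else "no"
        met = "yes" if _bernoulli(rng, _logistic_prob(cm.metastasis_base, cm.metastasis_effect, lost)) else "no"

        hazard = config.baseline_hazard_per_day * (
            config.hazard_ratio_lost if lost else 1.0)
        t_event = rng.exponential(1.0 / hazard)
        t_censor = rng.uniform(1.0, config.censoring_max_days)
        event = int(t_event <= t_censor)
        time_days = max(1.0, round(min(t_event, t_censor)))

        truth_rows.append((sample, hpv, f_del, f_homo, status, homozygous,
                           gained, start, block))
        clin_rows.append((sample, hpv, round(age, 1), sex, site, smoking,
                          round(pack_years, 1), t_group, n_group, stage_group,
                          rt, met, time_days, event))

    cna = CnaCallMatrix(pd.DataFrame(calls, index=pd.Index(genes, name="gene"),
                                     columns=samples), dict(genome))
    truth = pd.DataFrame(truth_rows, columns=[
        "sample", "hpv_status", "true_f_del", "true_f_homo", "true_status",
        "homozygous_arm", "gain_3q", "block_start", "block_len"])
    clinical = pd.DataFrame(clin_rows, columns=[
        "sample", "hpv_status", "age", "sex", "site", "smoking", "pack_years",
        "t_group", "n_group", "stage_group", "adjuvant_rt",
        "distant_metastasis", "time_days", "event"])
    return cna, clinical, truth


# ---------------------------------------------------------------------------
# SNVs
# ---------------------------------------------------------------------------

def simulate_snvs(config: SimulationConfig, genome: dict, truth: pd.DataFrame,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene Bernoulli mutation model with arm-status rate multipliers."""
    background = [g for g in genome
                  if g not in SPECIAL_GENES][:config.n_background_snv_genes]
    lo, hi = config.background_snv_rate_range
    bg_rates = rng.uniform(lo, hi, len(background))
    lost_mask = (truth["true_status"] == "lost").to_numpy()
    records = []
    for sample, lost in zip(truth["sample"], lost_mask):
        for gene, (base, mult) in config.snv_special.items():
            p = min(0.95, base * (mult if lost else 1.0))
            if _bernoulli(rng, p):
                records.append((sample, gene, "Missense_Mutation", False))
                if _bernoulli(rng, config.silent_extra_prob):
                    records.append((sample, gene, "Silent", True))
        hitmask = rng.random(len(background)) < bg_rates
        for gene in np.asarray(background)[hitmask]:
            records.append((sample, gene, "Missense_Mutation", False))
            if _bernoulli(rng, config.silent_extra_prob):
                records.append((sample, gene, "Silent", True))
    return pd.DataFrame(records,
                        columns=["sample", "gene", "classification",
                                 "synonymous"])


# ---------------------------------------------------------------------------
# Expression, proteins, miRNAs
# ---------------------------------------------------------------------------

def simulate_omics(config: SimulationConfig, genome: dict, truth: pd.DataFrame,
                   cna: CnaCallMatrix, rng: np.random.Generator):
    """Generate mRNA/protein/miRNA matrices, gene sets, and the DE table.

    mRNA works in log2 space: per-gene baseline + cis dosage effect from the
    copy-number call + planted group shifts (hypoxia up, immune markers down
    in arm-lost tumors) + Gaussian noise.  The DE table is computed from the
    simulated matrix itself by per-gene Welch tests on log2 abundance — its
    q-values are calibrated because the nulls really are null.
    """
    from scipy import stats as sps
    from .signatures import GeneSignature

    samples = list(truth["sample"])
    genes = list(genome)
    lost = (truth["true_status"] == "lost").to_numpy()
    pres = (truth["true_status"] == "preserved").to_numpy()

    # reserve disjoint gene sets on background arms for signatures/markers
    pool = [g for g in genes
            if genome[g].chromosome not in ("3", "X")
            and g not in SPECIAL_GENES]
    if not pool:  # degenerate genome: fall back to the 3q arm
        pool = [g for g in genes if genome[g].arm == "q"] or genes

    def take(k):
        # sets are drawn independently and may overlap (as real published
        # signatures do); each is duplicate-free internally
        k = min(k, len(pool))
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[i] for i in idx]

    hyp_sigs = [GeneSignature(f"hypoxia_{i+1}",
                              take(config.hypoxia_signature_size))
                for i in range(config.n_hypoxia_signatures)]
    tcell = GeneSignature("T_cells", take(config.tcell_marker_size))
    caf = GeneSignature("CAF", take(config.caf_marker_size))
    mirna_target_genes = take(config.n_mirna_target_pairs)
    protein_genes = take(config.n_proteins)

    base = rng.normal(config.gene_base_log2_mean, config.gene_base_log2_sd,
                      len(genes))
    log2 = np.tile(base[:, None], (1, len(samples)))
    log2 += config.cis_dosage_per_call * cna.calls.to_numpy()
    gidx = {g: i for i, g in enumerate(genes)}
    hyp_genes = [g for s in hyp_sigs for g in s.genes]
    log2[np.ix_([gidx[g] for g in hyp_genes], np.where(lost)[0])] += config.hypoxia_shift
    log2[np.ix_([gidx[g] for g in tcell.genes], np.where(lost)[0])] += config.tcell_depletion
    log2[np.ix_([gidx[g] for g in caf.genes], np.where(lost)[0])] += config.caf_enrichment
    log2 += rng.normal(0, config.expr_noise_sd, log2.shape)
    mrna = pd.DataFrame(np.exp2(log2), index=pd.Index(genes, name="feature"),
                        columns=samples)

    # DE table: Welch t-tests on log2 abundance, lost vs preserved
    la = log2[:, lost]
    pa = log2[:, pres]
    if la.shape[1] >= 2 and pa.shape[1] >= 2:
        tt = sps.ttest_ind(la, pa, axis=1, equal_var=False)
        pvals = np.nan_to_num(tt.pvalue, nan=1.0)
        from .stats import bh_adjust
        de = pd.DataFrame({"gene": genes,
                           "log2fc": la.mean(axis=1) - pa.mean(axis=1),
                           "p": pvals, "q": bh_adjust(pvals)})
    else:
        de = pd.DataFrame({"gene": genes, "log2fc": 0.0, "p": 1.0, "q": 1.0})

    # proteins: linear in their gene's log2 mRNA, positive slope
    prot_log2 = (config.protein_mrna_slope
                 * log2[[gidx[g] for g in protein_genes], :]
                 + rng.normal(0, config.protein_noise_sd,
                              (len(protein_genes), len(samples))))
    protein = pd.DataFrame(np.exp2(prot_log2),
                           index=pd.Index(protein_genes, name="feature"),
                           columns=samples)
    protein_targets = {g: g for g in protein_genes}

    # miRNAs: planted anticorrelated targets, two differential in lost group
    mirna_names = [f"hsa-mir-{i+1:03d}" for i in range(config.n_mirna)]
    mir_log2 = rng.normal(6.0, 1.0, (config.n_mirna, len(samples)))
    mirna_targets = {}
    for k, gene in enumerate(mirna_target_genes):
        z = log2[gidx[gene], :]
        mir_log2[k, :] = (8.0 - config.mirna_target_slope * (z - z.mean())
                          + rng.normal(0, config.mirna_noise_sd, len(samples)))
        mirna_targets[mirna_names[k]] = gene
    for k in range(config.n_mirna_differential):
        mir_log2[config.n_mirna - 1 - k, lost] += config.mirna_lost_shift
    mir_log2 += rng.normal(0, 0.2, mir_log2.shape)
    mirna = pd.DataFrame(np.exp2(mir_log2),
                         index=pd.Index(mirna_names, name="feature"),
                         columns=samples)
    marker_sets = [tcell, caf]
    return mrna, protein, mirna, de, hyp_sigs, marker_sets, mirna_targets, protein_targets


# ---------------------------------------------------------------------------
# Bundle orchestration and writing
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimulationConfig) -> CohortBundle:
    """Generate a complete cohort bundle from one seeded generator.

    Draw order: CNA+clinical (per sample), SNVs, then omics.
    """
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config)
    cna, clinical, truth = simulate_cna_and_clinical(config, genome, rng)
    snvs = simulate_snvs(config, genome, truth, rng)
    (mrna, protein, mirna, de, hyp_sigs, marker_sets,
     mirna_targets, protein_targets) = simulate_omics(config, genome, truth,
                                                      cna, rng)
    return CohortBundle(config=config, genome=genome, cna=cna, snvs=snvs,
                        clinical=clinical, mrna=mrna, protein=protein,
                        mirna=mirna, de_table=de, truth=truth,
                        hypoxia_signatures=hyp_sigs, marker_sets=marker_sets,
                        mirna_targets=mirna_targets,
                        protein_targets=protein_targets)


def _config_to_jsonable(config: SimulationConfig) -> dict:
    def conv(x):
        if dataclasses.is_dataclass(x) and not isinstance(x, type):
            return {f.name: conv(getattr(x, f.name)) for f in dataclasses.fields(x)}
        if isinstance(x, dict):
            return {str(k): conv(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [conv(v) for v in x]
        if isinstance(x, (np.integer, np.floating)):
            return x.item()
        return x
    return conv(config)


def write_bundle(bundle: CohortBundle, directory, overwrite: bool = False) -> dict:
    """Write the bundle as standard-format text files plus a manifest.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.  Returns the name → path map.
    """
    import os
    import yaml
    from . import model
    from .signatures import write_gmt

    os.makedirs(directory, exist_ok=True)
    if os.listdir(directory) and not overwrite:
        raise FileExistsError(
            f"{directory} is not empty; pass overwrite=True to replace")
    paths = {}

    def p(name):
        paths[name] = os.path.join(directory, name)
        return paths[name]

    model.write_cna_matrix(bundle.cna, p("cna.tsv"))
    model.write_maf(bundle.snvs, p("snv.maf.tsv"))
    model.write_clinical(bundle.clinical, p("clinical.tsv"))
    model.write_expression(bundle.mrna, p("mrna.tsv"))
    model.write_expression(bundle.protein, p("protein.tsv"))
    model.write_expression(bundle.mirna, p("mirna.tsv"))
    model.write_de_table(bundle.de_table, p("de_mrna.tsv"))
    bundle.truth.to_csv(p("truth.tsv"), sep="\t", index=False,
                        float_format="%.6g")
    write_gmt(bundle.hypoxia_signatures + bundle.marker_sets,
              p("signatures.gmt"))
    pd.DataFrame({"mirna": list(bundle.mirna_targets),
                  "target": list(bundle.mirna_targets.values())}
                 ).to_csv(p("mirna_targets.tsv"), sep="\t", index=False)
    with open(p("manifest.yaml"), "w") as fh:
        yaml.safe_dump({"seed": bundle.config.seed,
                        "config": _config_to_jsonable(bundle.config)}, fh,
                       sort_keys=True)
    return paths
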