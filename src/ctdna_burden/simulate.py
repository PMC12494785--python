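"""Synthetic liquid-biopsy cohorts with a survival change-point.

The generator emulates the statistical structure of a pancreatic-cancer
plasma-sequencing study: a mixed adjuvant/palliative cohort with serial
plasma draws (1-5 per patient, median 3), zero-inflated baseline tumor
fractions, lognormal cfDNA concentrations, per-locus allelic compositions
(including amplified backgrounds), binomial read sampling of allele
frequencies at duplex-consensus depth, and exponential overall survival
whose median switches at a configurable absolute-burden threshold
(mGE/ml).  Clinical workups alternate with plasma draws and carry a
radiology-style disease status correlated with the underlying burden
trajectory.

Every random draw flows from one master seed through independent
per-table streams, so regenerating any table is bit-for-bit reproducible
and adding a table never perturbs the others.

Focused generators for parameter-recovery studies (pure exponential
survival, a continuous per-1000-mGE hazard effect, a confounded binary
group effect, and a hazard change-point cohort) live alongside the full
cohort simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import SCHEMAS, write_table
from .quant import expected_vaf, mge_per_ml

LN2 = math.log(2.0)

#: coding-region genes of the focused plasma panel (22 genes plus KRAS
#: hotspot codons G12/G13/Q61), with representative hg19-style coordinates
PANEL_A_GENES = (
    "KRAS", "TP53", "CDKN2A", "SMAD4", "ARID1A", "PIK3CA", "BRCA1", "BRCA2",
    "ATM", "APC", "TGFBR2", "MLH1", "MSH2", "MSH6", "PALB2", "STK11",
    "CTNNB1", "GNAS", "RNF43", "ERBB2", "BRAF", "FGFR2", "AKT1",
)

GENE_LOCI = {
    "KRAS": ("12", 25398284), "TP53": ("17", 7577120), "CDKN2A": ("9", 21971120),
    "SMAD4": ("18", 48591918), "ARID1A": ("1", 27105930), "PIK3CA": ("3", 178936091),
    "BRCA1": ("17", 41245466), "BRCA2": ("13", 32914437), "ATM": ("11", 108175462),
    "APC": ("5", 112175240), "TGFBR2": ("3", 30713126), "MLH1": ("3", 37067240),
    "MSH2": ("2", 47702181), "MSH6": ("2", 48030639), "PALB2": ("16", 23646627),
    "STK11": ("19", 1221320), "CTNNB1": ("3", 41266113), "GNAS": ("20", 57484420),
    "RNF43": ("17", 56435160), "ERBB2": ("17", 37880220), "BRAF": ("7", 140453136),
    "FGFR2": ("10", 123258036), "AKT1": ("14", 105246551),
}

_BASES = ("A", "C", "G", "T")

TIMEPOINT_LABELS = ("BL", "1M", "2M", "3M", "EOT")

SAMPLE_EXTRA_COLUMNS = ["ca19_9", "truth_frac", "truth_mge"]
PATIENT_EXTRA_COLUMNS = ["truth_high", "truth_baseline_mge", "exclude_from_search"]


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults mirror the emulated study.

    Survival medians are those of the dichotomized palliative cohort (3.7
    months above / 11.9 months below the 350 mGE/ml threshold); baseline
    ctDNA negativity is 26% in palliative-like and 80% in adjuvant-like
    patients; consensus depth reflects UMI-collapsed target coverage around
    1400x.
    """

    n_patients: int = 60
    palliative_fraction: float = 0.75
    seed: int = 0
    true_cutoff: float = 350.0
    median_os_high: float = 3.7
    median_os_low: float = 11.9
    censoring_median_months: float = 60.0
    cfdna_conc_lognormal_params: tuple[float, float] = (3.0, 0.9)  # ln ng/ml
    baseline_frac_beta: tuple[float, float] = (0.8, 8.0)
    negative_fraction_palliative: float = 0.26
    negative_fraction_adjuvant: float = 0.80
    sample_count_probs: tuple[float, ...] = (0.10, 0.20, 0.40, 0.20, 0.10)  # 1..5 draws
    cycle_days: int = 28
    consensus_depth: int = 1400
    panel_genes: tuple[str, ...] = PANEL_A_GENES
    kras_anchor_prob: float = 0.9
    cn_event_rate: float = 0.3
    amplified_rate: float = 0.08
    drift_mu: float = -0.25       # per-cycle drift of log tumor fraction
    drift_sigma: float = 0.5
    conc_within_sigma: float = 0.3
    extra_variant_mean: float = 1.5
    subclonal_range: tuple[float, float] = (0.25, 0.85)
    tissue_rate: float = 0.6
    tissue_detect_prob: float = 0.9
    noncanonical_rate: float = 0.03
    chip_rate: float = 0.02
    not_assessable_rate: float = 0.03
    workup_flip_prob: float = 0.15
    ca199_measure_prob: float = 0.7
    covariate_params: dict = field(default_factory=lambda: {
        "age_mean": 68.0, "age_sd": 9.0,
        "ecog_probs_high": (0.25, 0.45, 0.22, 0.08),
        "ecog_probs_low": (0.45, 0.40, 0.12, 0.03),
        "m1_prob_low": 0.55,
        "regimens": ("gemcitabine", "nabpaclitaxel", "oxaliplatin"),
        "regimen_probs": (0.5, 0.3, 0.2),
        "ca199_ln_mean": 5.3, "ca199_ln_sd": 1.3, "ca199_high_shift": 1.0,
        "cea_ln_mean": 1.2, "cea_ln_sd": 1.0, "cea_high_shift": 0.6,
        "crp_ln_mean": 2.1, "crp_ln_sd": 0.8, "crp_high_shift": 0.8,
        "albumin_mean": 38.0, "albumin_sd": 4.0, "albumin_high_shift": -3.0,
    })

    def validate(self) -> None:
        probs = {
            "palliative_fraction": self.palliative_fraction,
            "negative_fraction_palliative": self.negative_fraction_palliative,
            "negative_fraction_adjuvant": self.negative_fraction_adjuvant,
            "kras_anchor_prob": self.kras_anchor_prob,
            "cn_event_rate": self.cn_event_rate,
            "amplified_rate": self.amplified_rate,
            "tissue_rate": self.tissue_rate,
            "tissue_detect_prob": self.tissue_detect_prob,
            "noncanonical_rate": self.noncanonical_rate,
            "chip_rate": self.chip_rate,
            "not_assessable_rate": self.not_assessable_rate,
            "workup_flip_prob": self.workup_flip_prob,
            "ca199_measure_prob": self.ca199_measure_prob,
        }
        for name, p in probs.items():
            if not (np.isfinite(p) and 0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must be a probability in [0, 1], got {p}")
        for name, v in [("median_os_high", self.median_os_high),
                        ("median_os_low", self.median_os_low),
                        ("censoring_median_months", self.censoring_median_months),
                        ("true_cutoff", self.true_cutoff)]:
            if not (np.isfinite(v) and v > 0):
                raise ConfigurationError(f"{name} must be positive and finite, got {v}")
        if self.n_patients < 0:
            raise ConfigurationError(f"n_patients must be >= 0, got {self.n_patients}")
        if self.consensus_depth < 1:
            raise ConfigurationError(f"consensus_depth must be >= 1, got {self.consensus_depth}")
        if abs(sum(self.sample_count_probs) - 1.0) > 1e-9:
            raise ConfigurationError("sample_count_probs must sum to 1")
        lo, hi = self.subclonal_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError(f"subclonal_range must satisfy 0 < lo <= hi < 1, "
                                     f"got {self.subclonal_range}")
        for name in ("cfdna_conc_lognormal_params", "baseline_frac_beta"):
            a, b = getattr(self, name)
            if not (np.isfinite(a) and np.isfinite(b)):
                raise ConfigurationError(f"{name} must be finite, got {(a, b)}")
        if self.baseline_frac_beta[0] <= 0 or self.baseline_frac_beta[1] <= 0:
            raise ConfigurationError("baseline_frac_beta parameters must be positive")


@dataclass
class CohortDataset:
    """The six canonical tables of one simulated cohort."""

    patients: pd.DataFrame
    samples: pd.DataFrame
    variants: pd.DataFrame
    copy_states: pd.DataFrame
    tissue_variants: pd.DataFrame
    workups: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "patients": self.patients, "samples": self.samples,
            "variants": self.variants, "copy_states": self.copy_states,
            "tissue_variants": self.tissue_variants, "workups": self.workups,
        }

    def to_dir(self, path) -> None:
        for name, df in self.tables().items():
            write_table(df, f"{path}/{name}.tsv")


def _exp_months(rng: np.random.Generator, median: float, size=None):
    return rng.exponential(median / LN2, size=size)


def _draw_copy_state(rng: np.random.Generator, cfg: SimulationConfig,
                     allow_amplified: bool) -> tuple[int, int, bool]:
    u = rng.random()
    if allow_amplified and u < cfg.amplified_rate:
        cn = int(rng.integers(6, 11))
        m = int(rng.integers(2, cn))
        return cn, m, True
    if u < cfg.cn_event_rate:
        states = [(1, 1), (3, 1), (3, 2), (4, 2), (4, 3)]
        cn, m = states[rng.integers(0, len(states))]
        return cn, m, False
    return 2, 1, False


def _mutate(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(0, 4)]
    alt = ref
    while alt == ref:
        alt = _BASES[rng.integers(0, 4)]
    return ref, alt


def _empty_tables() -> CohortDataset:
    def mk(schema, extra):
        return pd.DataFrame(columns=SCHEMAS[schema] + extra)
    return CohortDataset(
        patients=mk("patients", PATIENT_EXTRA_COLUMNS),
        samples=mk("samples", SAMPLE_EXTRA_COLUMNS),
        variants=mk("variants", ["normal_vaf"]),
        copy_states=mk("copy_states", []),
        tissue_variants=mk("tissue_variants", ["timepoint", "tumor_fraction"]),
        workups=mk("workups", []),
    )


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Generate one complete synthetic cohort (see the module docstring)."""
    config.validate()
    if config.n_patients == 0:
        return _empty_tables()
    ss = np.random.SeedSequence(config.seed)
    r_pat, r_samp, r_cn, r_var, r_tis, r_wk = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )
    cv = config.covariate_params
    a_frac, b_frac = config.baseline_frac_beta
    mu_c, sd_c = config.cfdna_conc_lognormal_params

    patients_rows, samples_rows, variant_rows = [], [], []
    copy_rows, tissue_rows, workup_rows = [], [], []

    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        arm = "palliative" if r_pat.random() < config.palliative_fraction else "adjuvant"
        neg_p = (config.negative_fraction_palliative if arm == "palliative"
                 else config.negative_fraction_adjuvant)
        negative = r_pat.random() < neg_p
        frac_bl = 0.0 if negative else float(r_pat.beta(a_frac, b_frac))
        conc_bl = float(np.exp(r_pat.normal(mu_c, sd_c)))
        mge_bl = mge_per_ml(frac_bl, conc_bl)
        truth_high = mge_bl > config.true_cutoff
        median = config.median_os_high if truth_high else config.median_os_low
        t_death = float(_exp_months(r_pat, median))
        t_cens = float(_exp_months(r_pat, config.censoring_median_months))
        os_months = max(min(t_death, t_cens), 0.03)
        death_event = t_death <= t_cens

        age = float(r_pat.normal(cv["age_mean"], cv["age_sd"]))
        ecog_probs = cv["ecog_probs_high"] if truth_high else cv["ecog_probs_low"]
        ecog = int(r_pat.choice(4, p=ecog_probs))
        m_stage = "M1" if (truth_high or r_pat.random() < cv["m1_prob_low"]) else "M0"
        regimen = str(r_pat.choice(cv["regimens"], p=cv["regimen_probs"]))
        shift = 1.0 if truth_high else 0.0
        ca199 = float(np.exp(r_pat.normal(cv["ca199_ln_mean"] + shift * cv["ca199_high_shift"],
                                          cv["ca199_ln_sd"])))
        cea = float(np.exp(r_pat.normal(cv["cea_ln_mean"] + shift * cv["cea_high_shift"],
                                        cv["cea_ln_sd"])))
        crp = float(np.exp(r_pat.normal(cv["crp_ln_mean"] + shift * cv["crp_high_shift"],
                                        cv["crp_ln_sd"])))
        albumin = float(r_pat.normal(cv["albumin_mean"] + shift * cv["albumin_high_shift"],
                                     cv["albumin_sd"]))
        patients_rows.append([pid, arm, os_months, death_event, age, ecog, m_stage,
                              regimen, ca199, cea, crp, albumin,
                              truth_high, mge_bl, False])

        # --- serial plasma draws -------------------------------------------
        n_s = int(r_samp.choice(np.arange(1, 6), p=config.sample_count_probs))
        days = [0]
        for k in range(1, n_s):
            days.append(int(k * config.cycle_days + r_samp.integers(-3, 4)))
        fracs = [frac_bl]
        for k in range(1, n_s):
            if fracs[-1] <= 0:
                fracs.append(0.0)
            else:
                step = float(r_samp.normal(config.drift_mu, config.drift_sigma))
                fracs.append(min(fracs[-1] * math.exp(step), 0.95))
        concs = [conc_bl] + [
            float(conc_bl * math.exp(r_samp.normal(0.0, config.conc_within_sigma)))
            for _ in range(1, n_s)
        ]
        assessable = [bool(r_samp.random() >= config.not_assessable_rate) for _ in range(n_s)]
        truth_mges = [mge_per_ml(f, c) for f, c in zip(fracs, concs)]
        ca199_vals = []
        for k in range(n_s):
            if r_samp.random() < config.ca199_measure_prob:
                scale = (fracs[k] / frac_bl) ** 0.5 if frac_bl > 0 and fracs[k] > 0 else 1.0
                ca199_vals.append(float(ca199 * scale * math.exp(r_samp.normal(0.0, 0.4))))
            else:
                ca199_vals.append(np.nan)
        sample_ids = [f"{pid}_{TIMEPOINT_LABELS[k]}" for k in range(n_s)]
        for k in range(n_s):
            samples_rows.append([pid, sample_ids[k], TIMEPOINT_LABELS[k], days[k],
                                 concs[k], assessable[k], ca199_vals[k],
                                 fracs[k], truth_mges[k]])

        # --- truth variants and copy states --------------------------------
        truth_variants = []  # (gene, chrom, pos, ref, alt, clonality, cn, m, amp)
        ever_positive = any(f > 0 for f in fracs)
        if ever_positive:
            if r_var.random() < config.kras_anchor_prob:
                anchor_gene = "KRAS"
            else:
                others = [g for g in config.panel_genes if g != "KRAS"]
                anchor_gene = str(r_var.choice(others))
            cn_a, m_a, _ = _draw_copy_state(r_cn, config, allow_amplified=False)
            chrom, base = GENE_LOCI.get(anchor_gene, ("1", 1_000_000))
            pos = int(base + r_var.integers(0, 500))
            ref, alt = _mutate(r_var)
            truth_variants.append([anchor_gene, chrom, pos, ref, alt, 1.0, cn_a, m_a, False])
            e_anchor = expected_vaf(0.2, cn_a, m_a)
            n_extra = int(r_var.poisson(config.extra_variant_mean))
            pool = [g for g in config.panel_genes if g != anchor_gene]
            extra_genes = list(r_var.choice(pool, size=min(n_extra, len(pool)), replace=False))
            for gene in extra_genes:
                cn_v, m_v, amp = _draw_copy_state(r_cn, config, allow_amplified=True)
                clon = float(r_var.uniform(*config.subclonal_range))
                if not amp:
                    e_sub = expected_vaf(min(clon * 0.2, 1.0), cn_v, m_v)
                    if e_sub >= e_anchor:
                        clon *= 0.9 * e_anchor / e_sub
                chrom_v, base_v = GENE_LOCI.get(gene, ("1", 2_000_000))
                pos_v = int(base_v + r_var.integers(0, 500))
                ref_v, alt_v = _mutate(r_var)
                truth_variants.append([gene, chrom_v, pos_v, ref_v, alt_v, clon,
                                       cn_v, m_v, amp])
            for gene, chrom_v, pos_v, _r, _a, _c, cn_v, m_v, amp in truth_variants:
                copy_rows.append([pid, chrom_v, pos_v, cn_v, m_v, amp, "observed"])

        # --- plasma calls (binomial read sampling) -------------------------
        detected_in: dict[tuple, set[str]] = {}
        for k in range(n_s):
            f_t = fracs[k]
            if f_t <= 0:
                continue
            for gene, chrom_v, pos_v, ref_v, alt_v, clon, cn_v, m_v, amp in truth_variants:
                p = expected_vaf(min(f_t * clon, 1.0), cn_v, m_v)
                alt_reads = int(r_var.binomial(config.consensus_depth, p))
                if alt_reads == 0:
                    continue
                vaf = alt_reads / config.consensus_depth
                impact = "moderate" if gene == "KRAS" else \
                    str(r_var.choice(["high", "moderate"], p=[0.3, 0.7]))
                canonical = bool(r_var.random() >= config.noncanonical_rate)
                in_normal = bool(r_var.random() < config.chip_rate)
                normal_vaf = float(r_var.uniform(0.0005, 0.01)) if in_normal else np.nan
                variant_rows.append([pid, sample_ids[k], "plasma", TIMEPOINT_LABELS[k],
                                     chrom_v, pos_v, ref_v, alt_v, gene, vaf, alt_reads,
                                     2, impact, canonical, in_normal,
                                     gene == "KRAS", False, normal_vaf])
                detected_in.setdefault((chrom_v, pos_v, ref_v, alt_v), set()).add(sample_ids[k])

        # --- matched tissue ------------------------------------------------
        tissue_keys: set[tuple] = set()
        if ever_positive and r_tis.random() < config.tissue_rate:
            tcf = float(r_tis.uniform(0.2, 0.7))
            tid = f"{pid}_T1"
            for gene, chrom_v, pos_v, ref_v, alt_v, clon, cn_v, m_v, amp in truth_variants:
                if r_tis.random() >= config.tissue_detect_prob:
                    continue
                p = expected_vaf(min(tcf * clon, 1.0), cn_v, m_v)
                alt_reads = int(r_tis.binomial(500, p))
                if alt_reads == 0:
                    continue
                n_callers = int(r_tis.choice([1, 2, 3, 4], p=[0.1, 0.4, 0.3, 0.2]))
                impact = "moderate" if gene == "KRAS" else \
                    str(r_tis.choice(["high", "moderate"], p=[0.3, 0.7]))
                tissue_rows.append([pid, tid, "tissue", chrom_v, pos_v, ref_v, alt_v,
                                    gene, alt_reads / 500, n_callers, impact, False,
                                    "T", tcf])
                tissue_keys.add((chrom_v, pos_v, ref_v, alt_v))

        # cross-sample confirmation flags (tissue or a second plasma sample)
        for row in variant_rows:
            if row[0] != pid:
                continue
            key = (row[4], row[5], row[6], row[7])
            seen = detected_in.get(key, set())
            row[16] = (len(seen) > 1) or (key in tissue_keys)
        for row in tissue_rows:
            if row[0] != pid:
                continue
            key = (row[3], row[4], row[5], row[6])
            row[11] = key in detected_in

        # --- clinical workups between consecutive draws --------------------
        for k in range(n_s - 1):
            wday = int((days[k] + days[k + 1]) / 2 + r_wk.integers(-2, 3))
            progressed = truth_mges[k + 1] > truth_mges[k] + 25.0
            if r_wk.random() < config.workup_flip_prob:
                progressed = not progressed
            status = "progression" if progressed else \
                str(r_wk.choice(["stable", "regression"], p=[0.7, 0.3]))
            workup_rows.append([pid, f"{pid}_W{k + 1}", wday, status])

    empty = _empty_tables()
    def frame(rows, template):
        return pd.DataFrame(rows, columns=template.columns) if rows else template

    return CohortDataset(
        patients=frame(patients_rows, empty.patients),
        samples=frame(samples_rows, empty.samples),
        variants=frame(variant_rows, empty.variants),
        copy_states=frame(copy_rows, empty.copy_states),
        tissue_variants=frame(tissue_rows, empty.tissue_variants),
        workups=frame(workup_rows, empty.workups),
    )


# --------------------------------------------------------------------------
# focused generators for parameter-recovery studies
# --------------------------------------------------------------------------

def _censor(rng: np.random.Generator, t_event: np.ndarray,
            rates: np.ndarray | float, censor_fraction: float):
    """Independent exponential censoring tuned to the target overall fraction."""
    if censor_fraction <= 0:
        return t_event, np.ones_like(t_event, dtype=bool)
    mean_rate = float(np.mean(rates))
    mu = mean_rate * censor_fraction / (1.0 - censor_fraction)
    t_cens = rng.exponential(1.0 / mu, size=len(t_event))
    event = t_event <= t_cens
    return np.minimum(t_event, t_cens), event


def simulate_exponential_survival(n: int, median_months: float,
                                  censor_fraction: float = 0.1,
                                  rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Exponential survival times with independent exponential censoring."""
    rng = rng or np.random.default_rng()
    rate = LN2 / median_months
    t = rng.exponential(1.0 / rate, size=n)
    times, events = _censor(rng, t, rate, censor_fraction)
    return pd.DataFrame({"os_months": times, "death_event": events})


def simulate_continuous_effect_cohort(n: int, hr_per_1000: float = 1.2,
                                      baseline_median: float = 8.0,
                                      mge_lognormal: tuple[float, float] = (math.log(200.0), 1.2),
                                      censor_fraction: float = 0.1,
                                      rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Baseline burden with a loglinear continuous effect on the hazard.

    log h(t | mge) = log h0 + log(hr_per_1000) * mge/1000, exponential
    baseline.
    """
    rng = rng or np.random.default_rng()
    mge = np.exp(rng.normal(*mge_lognormal, size=n))
    beta = math.log(hr_per_1000)
    rates = (LN2 / baseline_median) * np.exp(beta * mge / 1000.0)
    t = rng.exponential(1.0 / rates)
    times, events = _censor(rng, t, rates, censor_fraction)
    return pd.DataFrame({"baseline_mge": mge, "os_months": times, "death_event": events})


def simulate_adjusted_group_cohort(n: int, group_hr: float = 3.5,
                                   group_prob: float = 0.35,
                                   baseline_median: float = 10.0,
                                   censor_fraction: float = 0.1,
                                   rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Binary burden group with correlated ECOG/CRP/albumin confounders.

    The confounders shift with group membership *and* carry small hazard
    effects of their own, so only an adjusted fit recovers the group hazard
    ratio.
    """
    rng = rng or np.random.default_rng()
    g = (rng.random(n) < group_prob).astype(int)
    ecog = np.clip(np.round(rng.normal(0.7 + 0.6 * g, 0.7)), 0, 3).astype(int)
    crp = np.exp(rng.normal(math.log(8.0) + 0.8 * g, 0.7))
    albumin = rng.normal(38.0 - 3.0 * g, 4.0)
    loghaz = (math.log(group_hr) * g + 0.15 * ecog + 0.004 * crp
              - 0.03 * (albumin - 38.0))
    rates = (LN2 / baseline_median) * np.exp(loghaz)
    t = rng.exponential(1.0 / rates)
    times, events = _censor(rng, t, rates, censor_fraction)
    return pd.DataFrame({"group": g, "ecog": ecog, "crp": crp, "albumin": albumin,
                         "os_months": times, "death_event": events})


def simulate_changepoint_cohort(n: int = 200, cutoff: float = 350.0,
                                median_high: float = 3.7, median_low: float = 11.9,
                                mge_lognormal: tuple[float, float] = (math.log(200.0), 1.2),
                                censor_fraction: float = 0.1,
                                rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Baseline burden with a discontinuous hazard at the burden cutoff."""
    rng = rng or np.random.default_rng()
    mge = np.exp(rng.normal(*mge_lognormal, size=n))
    high = mge > cutoff
    medians = np.where(high, median_high, median_low)
    rates = LN2 / medians
    t = rng.exponential(1.0 / rates)
    times, events = _censor(rng, t, rates, censor_fraction)
    return pd.DataFrame({"baseline_mge": mge, "os_months": times,
                         "death_event": events, "truth_high": high})


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
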