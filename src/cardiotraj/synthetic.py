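"""Synthetic derivation- and testing-style cohorts with known ground truth.

The generator emulates a community cohort of older adults followed with up
to three echocardiograms: six latent trajectory groups (labelled by the
colours pink, light_green, red, dark_green, orange, blue) whose baseline
LVEF / E-A means and within-group SDs, prevalences, visit-age schedule and
attendance pattern are set from the published cohort description, plus
cause-specific heart-failure outcomes, a plasma-proteome matrix with
planted group-associated aptamers, and paired exposure/outcome GWAS summary
statistics with a known causal effect.

Every draw is reproducible from the config seed, and every generated object
returns its ground truth so downstream stages have a parameter-recovery
test surface.

Outcome construction
--------------------
Any-HF event times are exponential with group-specific proportional
hazards; an independent exponential death process competes, and the first
event before administrative censoring wins.  Each HF event is then typed
(HFpEF / HFrEF / unknown EF) by a group-specific multinomial split.  Under
this thinning construction the cause-specific hazard of subtype s in group
g is  lambda_any * HR_any(g) * p_s(g), so both the any-HF hazard ratios and
the subtype-specific hazard ratios are exact, configurable quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "GROUPS",
    "CohortConfig",
    "HazardConfig",
    "ProteomeConfig",
    "GwasSimConfig",
    "derivation_config",
    "testing_config",
    "default_group_curves",
    "generate_cohort",
    "generate_proteome",
    "generate_gwas_pair",
    "subtype_split_from_hazard_ratios",
]

GROUPS = ("pink", "light_green", "red", "dark_green", "orange", "blue")
EVENT_CODES = ("none", "hf_pef", "hf_ref", "hf_unknown", "death")

# Baseline (age ~64.5 y) per-group means and within-group SDs
_LVEF_MEAN = np.array([66.3, 79.6, 72.3, 56.8, 82.8, 71.5])
_LVEF_SD = np.array([15.5, 5.9, 8.5, 10.5, 7.1, 8.9])
_EA_MEAN = np.array([1.01, 0.96, 0.69, 0.72, 0.93, 1.19])
_EA_SD = np.array([0.21, 0.28, 0.13, 0.16, 0.29, 0.24])

# Per-decade slopes chosen to match the qualitative group descriptions:
# pink / light_green rising LVEF, falling E/A; red flat LVEF; dark_green
# declining LVEF; orange steeply declining LVEF with rising E/A; blue rising
# E/A despite rising LVEF.
_LVEF_SLOPE = np.array([4.0, 3.0, 0.0, -6.0, -12.0, 3.0])
_EA_SLOPE = np.array([-0.10, -0.08, -0.05, -0.03, 0.15, 0.12])

_BASELINE_AGE = 64.5

_DERIVATION_PREV = np.array([375, 130, 168, 29, 17, 28]) / 747.0
_TESTING_PREV = np.array([2201, 676, 942, 162, 90, 348]) / 4419.0

# Per-group binary covariate prevalences at baseline
_COVARIATE_PREV = {
    "male": (0.33, 0.11, 0.29, 0.69, 0.53, 0.32),
    "obesity": (0.51, 0.51, 0.52, 0.55, 0.41, 0.54),
    "hypertension": (0.68, 0.64, 0.83, 0.76, 0.94, 0.71),
    "diabetes": (0.22, 0.23, 0.31, 0.32, 0.35, 0.32),
    "ckd": (0.04, 0.06, 0.04, 0.03, 0.06, 0.11),
    "chd": (0.06, 0.04, 0.08, 0.17, 0.00, 0.14),
}

# Testing-cohort hazard configuration: any-HF hazard ratios vs. pink and the
# observed pink event split 87 HFpEF / 50 HFrEF / 26 unknown out of 163.
_HR_ANY_TESTING = np.array([1.0, 0.65, 1.18, 3.26, 2.32, 1.64])
_HR_PEF_TESTING = np.array([1.0, 0.57, 0.97, 1.17, 2.33, 1.76])
_HR_REF_TESTING = np.array([1.0, 0.59, 1.67, 8.08, 3.74, 1.34])
_PINK_SPLIT = np.array([87.0, 50.0, 26.0]) / 163.0

_HR_ANY_DERIVATION = np.array([1.0, 0.8, 1.97, 2.78, 4.21, 3.86])


def subtype_split_from_hazard_ratios(hr_any, hr_pef, hr_ref, base_split=_PINK_SPLIT):
    """Group-wise (pef, ref, unknown) splits reproducing target subtype HRs.

    Solves p_s(g) = (HR_s(g)/HR_any(g)) * p_s(reference) for s in {pef, ref};
    unknown takes the remainder.  If the two subtype shares exceed 1 for a
    group (possible because published HRs are empirical) they are scaled down
    proportionally and the unknown share is zero for that group.
    """
    hr_any = np.asarray(hr_any, dtype=float)
    p = np.zeros((len(hr_any), 3))
    p[:, 0] = np.asarray(hr_pef) / hr_any * base_split[0]
    p[:, 1] = np.asarray(hr_ref) / hr_any * base_split[1]
    over = p[:, :2].sum(axis=1)
    scale = np.where(over > 1.0, 1.0 / over, 1.0)
    p[:, :2] *= scale[:, None]
    p[:, 2] = np.clip(1.0 - p[:, :2].sum(axis=1), 0.0, 1.0)
    return p / p.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class HazardConfig:
    """Cause-specific outcome hazards (events per person-year at the pink rate)."""

    hf_rate: float = 0.0107
    hf_log_hr: tuple = tuple(np.log(_HR_ANY_TESTING))
    subtype_probs: tuple = tuple(
        map(tuple, subtype_split_from_hazard_ratios(
            _HR_ANY_TESTING, _HR_PEF_TESTING, _HR_REF_TESTING)))
    death_rate: float = 0.025
    death_log_hr: tuple = (0.0,) * 6

    def validate(self) -> None:
        if self.hf_rate < 0:
            raise ConfigurationError("hazards.hf_rate must be >= 0")
        if self.death_rate < 0:
            raise ConfigurationError("hazards.death_rate must be >= 0")
        sp = np.asarray(self.subtype_probs, dtype=float)
        if sp.shape != (len(self.hf_log_hr), 3) or np.any(sp < 0) or \
                np.any(np.abs(sp.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigurationError("hazards.subtype_probs must be per-group "
                                     "(pef, ref, unknown) probability rows")


def default_group_curves() -> np.ndarray:
    """(6 groups, 2 targets, 2 terms) coefficients on z = (age - 70) / 10.

    Anchored so the curve evaluated at the baseline age (64.5 y) equals the
    published per-group baseline mean exactly.
    """
    z0 = (_BASELINE_AGE - 70.0) / 10.0
    curves = np.zeros((6, 2, 2))
    curves[:, 0, 1] = _LVEF_SLOPE
    curves[:, 0, 0] = _LVEF_MEAN - _LVEF_SLOPE * z0
    curves[:, 1, 1] = _EA_SLOPE
    curves[:, 1, 0] = _EA_MEAN - _EA_SLOPE * z0
    return curves


@dataclass(frozen=True)
class CohortConfig:
    """Everything the cohort generator needs, with published-value defaults."""

    n_participants: int = 747
    group_prevalences: tuple = tuple(_DERIVATION_PREV)
    group_curves: tuple = tuple(map(lambda g: tuple(map(tuple, g)), default_group_curves()))
    residual_sd: tuple = tuple(map(tuple, np.column_stack([_LVEF_SD, _EA_SD])))
    visit_age_means: tuple = (64.7, 74.7, 80.5)
    visit_age_sds: tuple = (5.0, 4.9, 4.6)
    attendance: tuple = (1.0, 731 / 747, 488 / 747)
    covariate_prevalences: dict = field(default_factory=lambda: dict(_COVARIATE_PREV))
    af_prevalence: float = 0.0
    hazards: HazardConfig = field(default_factory=HazardConfig)
    admin_censor_years: float = 12.0
    ea_floor: float = 0.2
    reference_age: float = 70.0
    age_scale: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        prev = np.asarray(self.group_prevalences, dtype=float)
        if np.any(prev < 0):
            raise ConfigurationError("group_prevalences must be >= 0")
        if abs(prev.sum() - 1.0) > 1e-12:
            raise ConfigurationError("group_prevalences must sum to 1 within 1e-12")
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if abs(self.attendance[0] - 1.0) > 0:
            raise ConfigurationError("attendance[0] must be 1 (baseline echo universal)")
        if any(a < 0 or a > 1 for a in self.attendance):
            raise ConfigurationError("attendance entries must lie in [0, 1]")
        sd = np.asarray(self.residual_sd, dtype=float)
        if np.any(sd <= 0):
            raise ConfigurationError("residual_sd entries must be > 0")
        if len(self.visit_age_means) != len(self.attendance):
            raise ConfigurationError("visit_age_means and attendance lengths differ")
        if self.admin_censor_years <= 0:
            raise ConfigurationError("admin_censor_years must be > 0")
        self.hazards.validate()


def derivation_config(n_participants: int = 747, seed: int = 0, **overrides) -> CohortConfig:
    """Derivation-style cohort: 3-visit panel, composite-era follow-up (12 y)."""
    hz = HazardConfig(
        hf_rate=0.005,
        hf_log_hr=tuple(np.log(_HR_ANY_DERIVATION)),
        # composite-era follow-up: subtype split uninformative, same in every group
        subtype_probs=tuple(tuple(_PINK_SPLIT) for _ in _HR_ANY_DERIVATION),
        death_rate=0.012,
    )
    kwargs = dict(n_participants=n_participants, seed=seed)
    kwargs.update(overrides)
    return replace(CohortConfig(hazards=hz), **kwargs)


def testing_config(n_participants: int = 4419, seed: int = 0, **overrides) -> CohortConfig:
    """Testing-style cohort: single echo at ~75 y, cause-specific follow-up."""
    kwargs = dict(
        n_participants=n_participants,
        group_prevalences=tuple(_TESTING_PREV),
        visit_age_means=(75.3,),
        visit_age_sds=(5.1,),
        attendance=(1.0,),
        af_prevalence=0.04,
        admin_censor_years=7.4,
        seed=seed,
    )
    kwargs.update(overrides)
    return replace(CohortConfig(), **kwargs)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _draw_visit_ages(rng, cfg: CohortConfig, n: int) -> np.ndarray:
    """(n, n_visits) ages: shared per-person offset + 1-year visit jitter."""
    means = np.asarray(cfg.visit_age_means, dtype=float)
    sds = np.asarray(cfg.visit_age_sds, dtype=float)
    between = np.sqrt(np.maximum(sds**2 - 1.0, 0.25))
    offset = rng.standard_normal(n)
    jitter = rng.standard_normal((n, len(means)))
    ages = means[None, :] + offset[:, None] * between[None, :] + jitter
    return np.clip(ages, 45.0, 100.0)


def generate_cohort(config: CohortConfig):
    """Generate (visits, covariates, survival, truth) tables.

    Returns
    -------
    visits : DataFrame(participant_id, visit, age_years, lvef_pct, ea_ratio),
        long format - a missed visit is an absent row.
    covariates : DataFrame(participant_id, age_years, male, obesity,
        hypertension, diabetes, ckd, chd, af)
    survival : DataFrame(participant_id, time_years, event) with event in
        {none, hf_pef, hf_ref, hf_unknown, death}
    truth : DataFrame(participant_id, group) - the latent group labels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    n_groups = len(config.group_prevalences)
    curves = np.asarray(config.group_curves, dtype=float)  # (G, 2, P)
    res_sd = np.asarray(config.residual_sd, dtype=float)   # (G, 2)

    groups = rng.choice(n_groups, size=n, p=np.asarray(config.group_prevalences))
    ages = _draw_visit_ages(rng, config, n)
    n_visits = ages.shape[1]
    attend = np.ones((n, n_visits), dtype=bool)
    for v in range(1, n_visits):
        attend[:, v] = rng.random(n) < config.attendance[v]

    z = (ages - config.reference_age) / config.age_scale
    P = curves.shape[2]
    zpow = np.stack([z**p for p in range(P)], axis=-1)         # (n, V, P)
    mean_lvef = np.einsum("nvp,np->nv", zpow, curves[groups, 0, :])
    mean_ea = np.einsum("nvp,np->nv", zpow, curves[groups, 1, :])
    lvef = mean_lvef + rng.standard_normal((n, n_visits)) * res_sd[groups, 0][:, None]
    ea = mean_ea + rng.standard_normal((n, n_visits)) * res_sd[groups, 1][:, None]
    ea = np.maximum(ea, config.ea_floor)

    pid = np.array([f"P{i:06d}" for i in range(n)])
    rows = np.nonzero(attend)
    visits = pd.DataFrame({
        "participant_id": pid[rows[0]],
        "visit": rows[1] + 1,
        "age_years": ages[rows],
        "lvef_pct": lvef[rows],
        "ea_ratio": ea[rows],
    })

    cov = {"participant_id": pid, "age_years": ages[:, 0]}
    for name, prevs in config.covariate_prevalences.items():
        cov[name] = (rng.random(n) < np.asarray(prevs)[groups]).astype(int)
    cov["af"] = (rng.random(n) < config.af_prevalence).astype(int)
    covariates = pd.DataFrame(cov)

    hz = config.hazards
    hr_hf = np.exp(np.asarray(hz.hf_log_hr))[groups]
    hr_death = np.exp(np.asarray(hz.death_log_hr))[groups]
    t_hf = _exponential_or_inf(rng, hz.hf_rate * hr_hf)
    t_death = _exponential_or_inf(rng, hz.death_rate * hr_death)
    subtype_p = np.asarray(hz.subtype_probs, dtype=float)
    subtype_u = rng.random(n)

    t_admin = config.admin_censor_years
    time = np.minimum(np.minimum(t_hf, t_death), t_admin)
    event = np.full(n, "none", dtype=object)
    is_death = (t_death < t_hf) & (t_death < t_admin)
    is_hf = (t_hf <= t_death) & (t_hf < t_admin)
    event[is_death] = "death"
    cum = np.cumsum(subtype_p[groups], axis=1)
    subtype_idx = (subtype_u[:, None] >= cum).sum(axis=1)  # 0 pef, 1 ref, 2 unknown
    hf_labels = np.array(["hf_pef", "hf_ref", "hf_unknown"], dtype=object)
    event[is_hf] = hf_labels[subtype_idx[is_hf]]
    survival = pd.DataFrame({
        "participant_id": pid,
        "time_years": time,
        "event": event,
    })

    truth = pd.DataFrame({"participant_id": pid,
                          "group": np.asarray(GROUPS)[groups]})
    return visits, covariates, survival, truth


def _exponential_or_inf(rng, rates: np.ndarray) -> np.ndarray:
    """Exponential draws honouring zero rates (no event ever).

    Always consumes exactly len(rates) uniforms so the stream layout does not
    depend on the rates.
    """
    u = rng.random(len(rates))
    with np.errstate(divide="ignore"):
        return np.where(rates > 0, -np.log1p(-u) / np.maximum(rates, 1e-300), np.inf)


# --------------------------------------------------------------------------
# proteome generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteomeConfig:
    """Planted-signal aptamer matrix configuration.

    n_signal_per_group maps group label -> number of aptamers whose mean is
    shifted (by effect_size SDs) in that group alone; overlap_spec maps
    tuples of group labels -> number of aptamers shared by exactly those
    groups.  equicorrelation adds a common latent factor across aptamers.
    """

    n_aptamers: int = 4877
    n_signal_per_group: dict = field(default_factory=lambda: {
        "red": 50, "dark_green": 12, "orange": 5, "blue": 25})
    overlap_spec: dict = field(default_factory=lambda: {
        ("red", "blue"): 8, ("red", "dark_green"): 3,
        ("red", "dark_green", "orange", "blue"): 2})
    effect_size: float = 0.5
    equicorrelation: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.n_signal_per_group.values()) + sum(self.overlap_spec.values())
        if self.effect_size != 0.0 and total > self.n_aptamers:
            raise ConfigurationError("n_signal_per_group + overlaps exceed n_aptamers")
        if not np.isfinite(self.effect_size):
            raise ConfigurationError("effect_size must be finite")
        if not 0.0 <= self.equicorrelation < 1.0:
            raise ConfigurationError("equicorrelation must lie in [0, 1)")


def generate_proteome(truth: pd.DataFrame, config: ProteomeConfig):
    """Generate (matrix, annotation, signal_truth) given true group labels.

    Null aptamers are standard normal independent of group; each signal
    aptamer's mean is shifted by effect_size (in SD units) among members of
    its target group(s).
    """
    config.validate()
    if len(truth) == 0:
        raise DataError("truth table is empty")
    rng = np.random.default_rng(config.seed)
    n = len(truth)
    m = config.n_aptamers
    labels = truth["group"].to_numpy()

    matrix = rng.standard_normal((n, m))
    if config.equicorrelation > 0:
        rho = config.equicorrelation
        common = rng.standard_normal(n)
        matrix = np.sqrt(1 - rho) * matrix + np.sqrt(rho) * common[:, None]

    patterns = []
    if config.effect_size != 0.0:
        for g, cnt in config.n_signal_per_group.items():
            patterns.extend([(g,)] * cnt)
        for combo, cnt in config.overlap_spec.items():
            patterns.extend([tuple(combo)] * cnt)
    aptamer_ids = np.array([f"APT{j:05d}" for j in range(m)])
    signal_rows = []
    for j, pattern in enumerate(patterns):
        mask = np.isin(labels, pattern)
        matrix[mask, j] += config.effect_size
        signal_rows.append({"aptamer_id": aptamer_ids[j],
                            "groups": ";".join(pattern),
                            "effect_size": config.effect_size})
    signal_truth = pd.DataFrame(signal_rows,
                                columns=["aptamer_id", "groups", "effect_size"])

    annotation = pd.DataFrame({
        "aptamer_id": aptamer_ids,
        "gene": [f"GENE{j:05d}" for j in range(m)],
        "chrom": [str(j % 22 + 1) for j in range(m)],
        "tss_bp": rng.integers(1_000_000, 200_000_000, size=m),
    })
    matrix_df = pd.DataFrame(matrix, index=truth["participant_id"].to_numpy(),
                             columns=aptamer_ids)
    matrix_df.index.name = "participant_id"
    return matrix_df, annotation, signal_truth


# --------------------------------------------------------------------------
# GWAS pair generation
# --------------------------------------------------------------------------

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class GwasSimConfig:
    """Paired exposure/outcome summary-statistics simulation."""

    n_variants: int = 30
    true_causal_effect: float = 0.3
    instrument_strength: float = 0.15
    se_exposure: float = 0.01
    se_outcome: float = 0.01
    flip_fraction: float = 0.3        # outcome rows coded on the swapped allele
    strand_flip_fraction: float = 0.1  # outcome rows coded on the other strand
    palindromic_fraction: float = 0.0
    cis_fraction: float = 1.0
    gene_chrom: str = "1"
    gene_tss: int = 50_000_000
    cis_window: int = 1_000_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be >= 1")
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ConfigurationError("se scales must be > 0")
        for f in ("flip_fraction", "strand_flip_fraction",
                  "palindromic_fraction", "cis_fraction"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ConfigurationError(f"{f} must lie in [0, 1]")


def generate_gwas_pair(config: GwasSimConfig):
    """Generate (exposure, outcome, true_causal_effect) summary tables.

    Per variant the true exposure effect has magnitude ~ instrument_strength
    and random sign; the true outcome effect is causal_effect * exposure
    effect.  Observed betas add Gaussian noise at the reported SEs.  A
    configurable fraction of outcome rows is re-coded (allele swap and/or
    strand complement) to exercise harmonization, and palindromic variants
    can be injected.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.n_variants
    sign = rng.choice([-1.0, 1.0], size=k)
    beta_exp_true = sign * config.instrument_strength * rng.uniform(0.5, 1.5, size=k)
    beta_exp = beta_exp_true + rng.normal(0.0, config.se_exposure, size=k)
    beta_out_true = config.true_causal_effect * beta_exp_true
    beta_out = beta_out_true + rng.normal(0.0, config.se_outcome, size=k)

    is_palin = rng.random(k) < config.palindromic_fraction
    pal_idx = rng.integers(0, len(_PALINDROMIC), size=k)
    non_idx = rng.integers(0, len(_NONPALINDROMIC), size=k)
    ea = np.where(is_palin,
                  [p[0] for p in np.array(_PALINDROMIC, dtype=object)[pal_idx]],
                  [p[0] for p in np.array(_NONPALINDROMIC, dtype=object)[non_idx]])
    oa = np.where(is_palin,
                  [p[1] for p in np.array(_PALINDROMIC, dtype=object)[pal_idx]],
                  [p[1] for p in np.array(_NONPALINDROMIC, dtype=object)[non_idx]])

    is_cis = rng.random(k) < config.cis_fraction
    pos = np.where(
        is_cis,
        config.gene_tss + rng.integers(-config.cis_window, config.cis_window + 1, size=k),
        config.gene_tss + rng.integers(5_000_000, 50_000_000, size=k),
    )
    chrom = np.where(is_cis, config.gene_chrom, "7")
    eaf = rng.uniform(0.05, 0.95, size=k)
    variant_id = np.array([f"rs{1000 + j}" for j in range(k)])

    def _table(beta, se):
        z = np.where(se > 0, beta / se, 0.0)
        from scipy.stats import norm as _norm
        return pd.DataFrame({
            "variant_id": variant_id, "chrom": chrom, "pos_bp": pos,
            "effect_allele": ea.copy(), "other_allele": oa.copy(),
            "beta": beta, "se": np.full(k, se), "pval": 2 * _norm.sf(np.abs(z)),
            "eaf": eaf.copy(),
        })

    exposure = _table(beta_exp, config.se_exposure)
    outcome = _table(beta_out, config.se_outcome)

    swap = rng.random(k) < config.flip_fraction
    strand = rng.random(k) < config.strand_flip_fraction
    o_ea = outcome["effect_allele"].to_numpy(dtype=object).copy()
    o_oa = outcome["other_allele"].to_numpy(dtype=object).copy()
    o_beta = outcome["beta"].to_numpy().copy()
    o_eaf = outcome["eaf"].to_numpy().copy()
    o_ea[swap], o_oa[swap] = o_oa[swap].copy(), o_ea[swap].copy()
    o_beta[swap] = -o_beta[swap]
    o_eaf[swap] = 1.0 - o_eaf[swap]
    if strand.any():
        comp = np.vectorize(_COMPLEMENT.get)
        o_ea[strand] = comp(o_ea[strand])
        o_oa[strand] = comp(o_oa[strand])
    outcome["effect_allele"] = o_ea
    outcome["other_allele"] = o_oa
    outcome["beta"] = o_beta
    outcome["eaf"] = o_eaf

    return exposure, outcome, config.true_causal_effect
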