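"""Cause-specific Cox modelling of incident heart failure by trajectory.

The event coding follows the published censoring rules: with incident HFpEF
as the endpoint, HFrEF and unknown-EF heart-failure events are censored at
the time of that event (and symmetrically for HFrEF); death censors all HF
endpoints; the derivation cohort uses a composite HF-or-death endpoint.
Cox models use Breslow tie handling (Efron available) with the largest
trajectory group as reference.  Discrimination is summarized with
Harrell's C and nested models compared by paired bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index
from scipy.stats import norm
import statsmodels.api as sm

from .errors import DataError, EstimationError, UsageError

__all__ = [
    "ENDPOINTS",
    "cause_specific_dataset",
    "fit_cox",
    "harrell_c",
    "compare_c",
    "CoxResult",
]

EVENT_LABELS = ("none", "hf_pef", "hf_ref", "hf_unknown", "death")
ENDPOINTS = ("any_hf", "hf_pef", "hf_ref", "hf_or_death")

_EVENT_SETS = {
    "any_hf": {"hf_pef", "hf_ref", "hf_unknown"},
    "hf_pef": {"hf_pef"},
    "hf_ref": {"hf_ref"},
    "hf_or_death": {"hf_pef", "hf_ref", "hf_unknown", "death"},
}


def cause_specific_dataset(records: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """Binary event indicator under the endpoint's censoring rules.

    Every input record appears exactly once in the output with unchanged
    time; competing events become censorings at their event time.
    """
    if endpoint not in _EVENT_SETS:
        raise UsageError(f"unknown endpoint {endpoint!r}; one of {ENDPOINTS}")
    required = {"participant_id", "time_years", "event"}
    missing = required - set(records.columns)
    if missing:
        raise DataError(f"survival table is missing columns: {sorted(missing)}")
    bad = set(records["event"]) - set(EVENT_LABELS)
    if bad:
        raise DataError(f"unknown event codes: {sorted(bad)}")
    if np.any(records["time_years"].to_numpy(dtype=float) <= 0):
        raise DataError("time_years must be > 0")
    out = records[["participant_id", "time_years"]].copy()
    out["event"] = records["event"].isin(_EVENT_SETS[endpoint]).astype(int)
    return out


@dataclass
class CoxResult:
    """Cox fit summary: per-covariate effects plus endpoint bookkeeping."""

    table: pd.DataFrame        # index covariate; coef, se, hr, ci_low, ci_high, p
    n_events: int
    endpoint: str
    model_label: str = ""
    dropped: tuple = ()

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])


def _trajectory_indicators(labels: pd.Series, reference_group) -> pd.DataFrame:
    labels = pd.Series(labels).astype(str).reset_index(drop=True)
    cats = [c for c in pd.unique(labels) if c != str(reference_group)]
    if str(reference_group) not in set(labels):
        raise UsageError(f"reference group {reference_group!r} absent from labels")
    cols = {f"traj[{c}]": (labels == c).astype(float) for c in sorted(cats)}
    return pd.DataFrame(cols)


def fit_cox(
    dataset: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    trajectory: pd.Series | np.ndarray | None = None,
    reference_group=None,
    endpoint: str = "",
    model_label: str = "",
    ties: str = "breslow",
    alpha: float = 0.05,
) -> CoxResult:
    """Cox proportional-hazards fit with trajectory indicators vs. reference.

    dataset must carry time_years and a binary event column (see
    cause_specific_dataset).  covariates (optional) are added as-is;
    constant columns are dropped with a warning entry in `dropped`.
    """
    time = dataset["time_years"].to_numpy(dtype=float)
    event = dataset["event"].to_numpy(dtype=int)
    n_events = int(event.sum())
    if n_events < 1:
        raise EstimationError("no events: cannot fit a Cox model")

    parts = []
    if trajectory is not None:
        if reference_group is None:
            vals, counts = np.unique(np.asarray(trajectory, dtype=str), return_counts=True)
            reference_group = vals[np.argmax(counts)]
        parts.append(_trajectory_indicators(pd.Series(np.asarray(trajectory)),
                                            reference_group))
    if covariates is not None:
        parts.append(covariates.reset_index(drop=True).astype(float))
    if not parts:
        raise UsageError("need trajectory labels and/or covariates to fit on")
    X = pd.concat(parts, axis=1)

    dropped = tuple(c for c in X.columns if X[c].nunique() <= 1)
    if dropped:
        import warnings

        warnings.warn(f"dropping constant covariates: {dropped}", stacklevel=2)
        X = X.drop(columns=list(dropped))
    if X.shape[1] == 0:
        raise EstimationError("all covariates constant; nothing to estimate")

    model = sm.PHReg(time, X.to_numpy(), status=event, ties=ties)
    try:
        fit = model.fit(method="bfgs", maxiter=200, disp=False)
        coef = np.asarray(fit.params, dtype=float)
        # Newton polish on the analytic score/Hessian: BFGS stops early, and
        # Wald CIs need the curvature at the true maximum anyway
        for _ in range(50):
            score = model.score(coef)
            if np.max(np.abs(score)) < 1e-10:
                break
            coef = coef + np.linalg.solve(-model.hessian(coef), score)
        cov = np.linalg.inv(-model.hessian(coef))
        se = np.sqrt(np.diag(cov))
    except Exception as exc:  # pragma: no cover - statsmodels failure path
        raise EstimationError(f"Cox fit failed to converge: {exc}") from exc
    zcrit = norm.ppf(1.0 - alpha / 2.0)
    table = pd.DataFrame({
        "coef": coef,
        "se": se,
        "hr": np.exp(coef),
        "ci_low": np.exp(coef - zcrit * se),
        "ci_high": np.exp(coef + zcrit * se),
        "p": 2.0 * norm.sf(np.abs(coef) / np.where(se > 0, se, np.nan)),
    }, index=X.columns)
    return CoxResult(table=table, n_events=n_events, endpoint=endpoint,
                     model_label=model_label, dropped=dropped)


def harrell_c(risk_scores, dataset: pd.DataFrame) -> float:
    """Harrell's concordance for risk scores (higher score = earlier event).

    Usable pairs are (event, later-or-censored-after); score ties count 0.5.
    """
    risk = np.asarray(risk_scores, dtype=float)
    if not np.all(np.isfinite(risk)):
        raise DataError("risk scores must be finite")
    time = dataset["time_years"].to_numpy(dtype=float)
    event = dataset["event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise EstimationError("no events: no usable pairs for the C-statistic")
    try:
        return float(concordance_index(time, -risk, event))
    except ZeroDivisionError as exc:
        raise EstimationError("no usable pairs for the C-statistic") from exc


def compare_c(model_a_scores, model_b_scores, dataset: pd.DataFrame,
              n_boot: int = 1000, seed: int = 0):
    """Paired-bootstrap comparison of two models' Harrell C on the same records.

    delta = C_b - C_a; the two-sided p-value uses a normal approximation on
    the bootstrap SE of delta.  Deterministic given seed.
    """
    if n_boot < 100:
        raise UsageError("n_boot must be >= 100")
    a = np.asarray(model_a_scores, dtype=float)
    b = np.asarray(model_b_scores, dtype=float)
    if a.shape != b.shape or len(a) != len(dataset):
        raise UsageError("score vectors must align with the dataset records")
    c_a = harrell_c(a, dataset)
    c_b = harrell_c(b, dataset)
    delta = c_b - c_a

    rng = np.random.default_rng(seed)
    time = dataset["time_years"].to_numpy(dtype=float)
    event = dataset["event"].to_numpy(dtype=int)
    n = len(a)
    deltas = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ev = event[idx]
        if ev.sum() == 0:
            continue
        sub = pd.DataFrame({"time_years": time[idx], "event": ev})
        try:
            deltas.append(harrell_c(b[idx], sub) - harrell_c(a[idx], sub))
        except EstimationError:
            continue
    deltas = np.asarray(deltas)
    if len(deltas) < n_boot // 2:
        raise EstimationError("bootstrap failed on most resamples")
    se = float(deltas.std(ddof=1))
    if se == 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        p = float(2.0 * norm.sf(abs(delta) / se))
    return delta, p
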