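"""Bayesian non-parametric mixture of joint LVEF / E-A age trajectories.

The model is a truncated stick-breaking (Dirichlet-process) mixture of
per-group polynomial regressions on standardized age.  Each latent group g
carries, for each target d (LVEF in percent, E/A ratio on the natural
scale), a coefficient vector beta_{g,d} on the age basis and a residual
precision tau_{g,d}; the two targets are conditionally independent given
group membership.  A participant i with observed points {(x_iv, y_ivd)}
contributes the likelihood

    sum_g pi_g  prod_{v,d observed}  Normal(y_ivd | x_iv' beta_{g,d}, 1/tau_{g,d})

where pi follows a truncated stick-breaking construction with concentration
alpha.  Because the group curves, not individual slopes, define the mixture,
membership can be evaluated from any subset of observations - including a
single echocardiogram - by Bayes' rule.

Inference is coordinate-ascent variational Bayes with conjugate
normal-gamma priors on (beta, tau) and Beta posteriors on the sticks; the
evidence lower bound (ELBO) is non-decreasing across iterations of a run,
which the fitter verifies at every step.  Unbalanced panels (one to three
visits, either target missing at a visit) are supported throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import digamma, gammaln, logsumexp
from scipy.stats import norm

from .errors import DataError

__all__ = [
    "AgeBasis",
    "GroupParameters",
    "TrajectoryModel",
    "ObservationSet",
    "MembershipPosterior",
    "build_design",
    "fit_trajectories",
    "posterior_membership",
    "assign_memberships",
    "trajectory_curves",
    "effective_groups",
    "save_model",
    "load_model",
]

TARGETS = ("lvef", "ea")
_TARGET_COLUMNS = {"lvef": "lvef_pct", "ea": "ea_ratio"}
_LOG2PI = float(np.log(2.0 * np.pi))


# --------------------------------------------------------------------------
# age basis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeBasis:
    """Polynomial basis on standardized age z = (age - reference_age) / scale."""

    reference_age: float = 70.0
    scale: float = 10.0
    degree: int = 2

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise DataError("AgeBasis.scale must be > 0")
        if self.degree not in (0, 1, 2):
            raise DataError("AgeBasis.degree must be 0, 1 or 2")

    @property
    def n_terms(self) -> int:
        return self.degree + 1

    def design(self, ages: np.ndarray) -> np.ndarray:
        """Design matrix (n, degree+1) with columns 1, z, z^2, ..."""
        ages = np.asarray(ages, dtype=float)
        if not np.all(np.isfinite(ages)):
            raise DataError("ages must be finite")
        z = (ages - self.reference_age) / self.scale
        return np.vander(z, self.n_terms, increasing=True)


def build_design(age, basis: AgeBasis) -> np.ndarray:
    """Basis vector (1, z, z^2, ...) for a single age."""
    return basis.design(np.atleast_1d(age))[0]


# --------------------------------------------------------------------------
# fitted-model containers
# --------------------------------------------------------------------------

@dataclass
class GroupParameters:
    """Posterior-mean curve coefficients and residual SDs for one group."""

    coefficients: dict  # target -> (degree+1,) ndarray
    residual_sd: dict   # target -> float

    def predict(self, target: str, X: np.ndarray) -> np.ndarray:
        return X @ np.asarray(self.coefficients[target], dtype=float)


@dataclass
class TrajectoryModel:
    """Fitted truncated stick-breaking mixture of joint age trajectories."""

    k_max: int
    weights: np.ndarray            # expected mixing weights, length k_max
    groups: list                   # list[GroupParameters], length k_max
    concentration: float
    basis: AgeBasis
    priors: dict                   # target -> {m0, lam0, a0, b0}
    fit_meta: dict = field(default_factory=dict)
    targets: tuple = TARGETS

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.groups) != self.k_max:
            raise DataError("length(groups) must equal k_max")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-8:
            raise DataError("weights must be a probability vector (sum 1 within 1e-8)")


@dataclass
class ObservationSet:
    """Observations for one participant; either target may be missing at a visit."""

    participant_id: object
    ages: np.ndarray               # (n_visits,)
    values: dict                   # target -> (n_visits,) with NaN = missing

    def __post_init__(self) -> None:
        self.ages = np.atleast_1d(np.asarray(self.ages, dtype=float))
        if self.ages.size < 1:
            raise DataError("ObservationSet needs at least one visit")
        if np.any(self.ages < 30) or np.any(self.ages > 110):
            raise DataError("visit ages must lie within [30, 110] years")
        self.values = {t: np.atleast_1d(np.asarray(v, dtype=float))
                       for t, v in self.values.items()}
        observed = np.zeros(self.ages.size, dtype=bool)
        for v in self.values.values():
            if v.shape != self.ages.shape:
                raise DataError("value arrays must match ages in length")
            observed |= np.isfinite(v)
        if not observed.all():
            raise DataError("every visit needs at least one observed target")


@dataclass
class MembershipPosterior:
    """Posterior probability vector over trajectory groups for one participant."""

    participant_id: object
    probabilities: np.ndarray
    map_group: int                 # argmax index, ties broken toward lower index

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-10:
            raise DataError("membership probabilities must sum to 1 within 1e-10")
        self.probabilities = p


# --------------------------------------------------------------------------
# internal: data marshalling
# --------------------------------------------------------------------------

def _stack_visits(visits: pd.DataFrame, basis: AgeBasis):
    """Split a long visits table into per-target stacked design/response arrays."""
    required = {"participant_id", "age_years"}
    missing = required - set(visits.columns)
    if missing:
        raise DataError(f"visits table is missing columns: {sorted(missing)}")
    if len(visits) == 0:
        raise DataError("visits table is empty")
    pids = pd.unique(visits["participant_id"])
    pid_index = {p: i for i, p in enumerate(pids)}
    idx = visits["participant_id"].map(pid_index).to_numpy()
    ages = visits["age_years"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ages)):
        bad = visits.index[~np.isfinite(ages)].tolist()
        raise DataError(f"non-finite ages at rows {bad[:10]}")
    X_all = basis.design(ages)
    data = {}
    for target in TARGETS:
        col = _TARGET_COLUMNS[target]
        if col not in visits.columns:
            raise DataError(f"visits table is missing column: {col}")
        y = visits[col].to_numpy(dtype=float)
        obs = np.isfinite(y)
        if np.any(np.isinf(y)):
            bad = visits.index[np.isinf(y)].tolist()
            raise DataError(f"non-finite values in {col} at rows {bad[:10]}")
        data[target] = (X_all[obs], y[obs], idx[obs])
    n_obs_per_pid = np.zeros(len(pids), dtype=int)
    for X, y, pidx in data.values():
        np.add.at(n_obs_per_pid, pidx, 1)
    if np.any(n_obs_per_pid == 0):
        raise DataError("every participant needs at least one observed value")
    return pids, data


def _default_priors(data: dict, basis: AgeBasis) -> dict:
    """Empirical normal-gamma hyperparameters: pooled OLS mean, diffuse scale."""
    priors = {}
    for target, (X, y, _) in data.items():
        XtX = X.T @ X + 1e-8 * np.eye(X.shape[1])
        beta = np.linalg.solve(XtX, X.T @ y)
        resid = y - X @ beta
        s2 = max(float(resid @ resid) / max(len(y) - X.shape[1], 1), 1e-8)
        priors[target] = {
            # Var(beta | tau) = (tau * lam0)^-1 ~ 100 * sigma^2 around the pooled fit
            "m0": beta,
            "lam0": np.eye(X.shape[1]) / 100.0,
            "a0": 1.0,
            "b0": s2,
        }
    return priors


# --------------------------------------------------------------------------
# internal: CAVI machinery
# --------------------------------------------------------------------------

class _NormalGammaState:
    """Variational normal-gamma posterior for one (group, target)."""

    __slots__ = ("m", "lam", "a", "b", "chol", "logdet")

    def update(self, prior, X, y, w):
        """Exact conjugate update given responsibilities w over points."""
        lam0, m0, a0, b0 = prior["lam0"], prior["m0"], prior["a0"], prior["b0"]
        Xw = X * w[:, None]
        self.lam = lam0 + X.T @ Xw
        rhs = lam0 @ m0 + Xw.T @ y
        c, low = cho_factor(self.lam, lower=True)
        self.m = cho_solve((c, low), rhs)
        n_eff = float(w.sum())
        self.a = a0 + 0.5 * n_eff
        syy = float(np.dot(w * y, y))
        self.b = b0 + 0.5 * (syy + float(m0 @ lam0 @ m0) - float(self.m @ self.lam @ self.m))
        # b is positive by construction; guard against float cancellation only
        self.b = max(self.b, 1e-12)
        self.chol = np.asarray(c if low else c.T)
        self.logdet = 2.0 * float(np.log(np.diag(self.chol)).sum())

    def point_loglik(self, X, y):
        """E_q[log N(y | x'beta, 1/tau)] per point."""
        e_logtau = digamma(self.a) - np.log(self.b)
        e_tau = self.a / self.b
        mu = X @ self.m
        W = solve_triangular(self.chol, X.T, lower=True)
        quad = np.einsum("ij,ij->j", W, W)
        return 0.5 * (e_logtau - _LOG2PI) - 0.5 * (e_tau * (y - mu) ** 2 + quad)

    def kl(self, prior):
        """KL(q(beta,tau) || p(beta,tau)) between normal-gamma distributions."""
        lam0, m0, a0, b0 = prior["lam0"], prior["m0"], prior["a0"], prior["b0"]
        P = len(self.m)
        e_logtau = digamma(self.a) - np.log(self.b)
        e_tau = self.a / self.b
        sign0, logdet0 = np.linalg.slogdet(lam0)
        dm = self.m - m0
        lam_inv = cho_solve((self.chol, True), np.eye(P))
        quad = e_tau * float(dm @ lam0 @ dm) + float(np.trace(lam0 @ lam_inv))
        lq = (0.5 * P * e_logtau + 0.5 * self.logdet - 0.5 * P * _LOG2PI - 0.5 * P
              + self.a * np.log(self.b) - gammaln(self.a) + (self.a - 1.0) * e_logtau - self.a)
        lp = (0.5 * P * e_logtau + 0.5 * logdet0 - 0.5 * P * _LOG2PI - 0.5 * quad
              + a0 * np.log(b0) - gammaln(a0) + (a0 - 1.0) * e_logtau - b0 * e_tau)
        return lq - lp


def _stick_expectations(gamma1, gamma2):
    """E[log v_k], E[log(1-v_k)] and E[log pi_k] under truncated sticks."""
    K = len(gamma1) + 1
    e_logv = np.zeros(K)
    e_log1mv = np.zeros(K)
    e_logv[:-1] = digamma(gamma1) - digamma(gamma1 + gamma2)
    e_log1mv[:-1] = digamma(gamma2) - digamma(gamma1 + gamma2)
    e_logpi = e_logv + np.concatenate([[0.0], np.cumsum(e_log1mv[:-1])])
    return e_logv, e_log1mv, e_logpi


def _expected_weights(gamma1, gamma2):
    K = len(gamma1) + 1
    ev = np.ones(K)
    ev[:-1] = gamma1 / (gamma1 + gamma2)
    rem = np.concatenate([[1.0], np.cumprod(1.0 - ev[:-1])])
    return ev * rem


def _init_responsibilities(n, K, mode, rng, features=None):
    if mode == "kmeans" and features is not None and n >= 2 * K:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=K, n_init=3,
                    random_state=int(rng.integers(2**31 - 1))).fit(features)
        r = np.full((n, K), 0.5 / (K - 1) if K > 1 else 1.0)
        r[np.arange(n), km.labels_] = 0.5 if K > 1 else 1.0
        if K > 1:
            r /= r.sum(axis=1, keepdims=True)
        return r
    g = rng.gamma(1.0, size=(n, K))
    return g / g.sum(axis=1, keepdims=True)


def _participant_features(pids, data, basis):
    """Per-participant (mean level, crude slope) per target, standardized."""
    n = len(pids)
    feats = np.zeros((n, 2 * len(TARGETS)))
    for j, target in enumerate(TARGETS):
        X, y, pidx = data[target]
        z = X[:, 1] if X.shape[1] > 1 else np.zeros(len(y))
        sums = np.zeros(n)
        cnts = np.zeros(n)
        sz = np.zeros(n)
        szz = np.zeros(n)
        szy = np.zeros(n)
        np.add.at(sums, pidx, y)
        np.add.at(cnts, pidx, 1.0)
        np.add.at(sz, pidx, z)
        np.add.at(szz, pidx, z * z)
        np.add.at(szy, pidx, z * y)
        c = np.maximum(cnts, 1.0)
        mean = sums / c
        var_z = szz / c - (sz / c) ** 2
        cov_zy = szy / c - (sz / c) * mean
        slope = np.where(var_z > 1e-8, cov_zy / np.maximum(var_z, 1e-8), 0.0)
        feats[:, 2 * j] = mean
        feats[:, 2 * j + 1] = slope
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    return (feats - feats.mean(axis=0)) / sd


def _run_cavi(pids, data, basis, k_max, priors, alpha, r, max_iter, tol):
    """One CAVI run from initial responsibilities; returns state + ELBO trace."""
    n, K = r.shape
    states = {t: [_NormalGammaState() for _ in range(K)] for t in TARGETS}
    elbo_trace = []
    elbo_prev = -np.inf
    for iteration in range(max_iter):
        # --- q(beta, tau): exact conjugate update per (group, target)
        S = np.zeros((n, K))
        for target in TARGETS:
            X, y, pidx = data[target]
            w_pts = r[pidx]  # (n_points, K)
            for k in range(K):
                st = states[target][k]
                st.update(priors[target], X, y, w_pts[:, k])
                pll = st.point_loglik(X, y)
                np.add.at(S[:, k], pidx, pll)
        # --- q(v): stick-breaking Beta updates
        Nk = r.sum(axis=0)
        tail = np.concatenate([np.cumsum(Nk[::-1])[::-1][1:], [0.0]])
        gamma1 = 1.0 + Nk[:-1]
        gamma2 = alpha + tail[:-1]
        e_logv, e_log1mv, e_logpi = _stick_expectations(gamma1, gamma2)
        # --- q(z): responsibilities
        logrho = e_logpi[None, :] + S
        log_norm = logsumexp(logrho, axis=1)
        r = np.exp(logrho - log_norm[:, None])
        # --- ELBO
        elbo = float(log_norm.sum())
        elbo += float(((alpha - 1.0) * e_log1mv[:-1]).sum() + (K - 1) * np.log(alpha))
        lq_v = (gammaln(gamma1 + gamma2) - gammaln(gamma1) - gammaln(gamma2)
                + (gamma1 - 1.0) * e_logv[:-1] + (gamma2 - 1.0) * e_log1mv[:-1])
        elbo -= float(lq_v.sum())
        for target in TARGETS:
            for k in range(K):
                elbo -= states[target][k].kl(priors[target])
        elbo_trace.append(elbo)
        if elbo < elbo_prev - 1e-8 * max(1.0, abs(elbo_prev)):
            raise EstimationErrorFromElbo(elbo_prev, elbo, iteration)
        if iteration > 0 and abs(elbo - elbo_prev) < tol * max(1.0, abs(elbo_prev)):
            elbo_prev = elbo
            break
        elbo_prev = elbo
    weights = _expected_weights(gamma1, gamma2)
    return states, weights, r, elbo_trace


class EstimationErrorFromElbo(RuntimeError):
    """ELBO decreased beyond numerical tolerance - a coordinate-update bug."""

    def __init__(self, before, after, iteration):
        super().__init__(
            f"ELBO decreased at iteration {iteration}: {before!r} -> {after!r}")


# --------------------------------------------------------------------------
# public fitting API
# --------------------------------------------------------------------------

def fit_trajectories(
    visits: pd.DataFrame,
    basis: AgeBasis | None = None,
    k_max: int = 20,
    priors: dict | None = None,
    restarts: int = 20,
    seed: int = 0,
    concentration: float = 1.0,
    max_iter: int = 2000,
    tol: float = 1e-8,
    initial_responsibilities: np.ndarray | None = None,
) -> TrajectoryModel:
    """Fit the trajectory mixture by coordinate-ascent variational Bayes.

    Parameters
    ----------
    visits
        Long table with columns participant_id, age_years, lvef_pct, ea_ratio;
        NaN marks a missing target at a visit, absent rows mark missed visits.
    basis
        Standardized-age polynomial basis (default: reference 70 y, scale
        10 y, degree 2).
    k_max
        Stick-breaking truncation level; effective groups are read off the
        fitted weights afterwards.
    priors
        Optional normal-gamma hyperparameters per target
        ({"m0", "lam0", "a0", "b0"}); defaults are set empirically from a
        pooled single-group least-squares fit with diffuse (x100) variance.
    restarts
        Independent initializations; the run with the highest final ELBO is
        returned.  Even restarts seed from k-means on per-participant
        level/slope summaries, odd restarts from random responsibilities.
    seed
        Root seed; the fit is deterministic given (data, seed).
    initial_responsibilities
        Optional (n_participants, k_max) responsibility matrix (rows in order
        of first appearance in `visits`); when given, a single CAVI run
        starts from it and `restarts` is ignored.
    """
    basis = basis or AgeBasis()
    pids, data = _stack_visits(visits, basis)
    n = len(pids)
    if n < 2:
        raise DataError("need at least 2 participants to fit trajectories")
    priors = priors or _default_priors(data, basis)
    for target in TARGETS:
        priors[target]["m0"] = np.asarray(priors[target]["m0"], dtype=float)
        priors[target]["lam0"] = np.asarray(priors[target]["lam0"], dtype=float)
    features = _participant_features(pids, data, basis)

    if initial_responsibilities is not None:
        r0 = np.asarray(initial_responsibilities, dtype=float)
        if r0.shape != (n, k_max):
            raise DataError("initial_responsibilities must be (n_participants, k_max)")
        r0 = r0 / r0.sum(axis=1, keepdims=True)
        states, weights, resp, trace = _run_cavi(
            pids, data, basis, k_max, priors, concentration, r0, max_iter, tol)
        best = {"states": states, "weights": weights, "resp": resp,
                "trace": trace, "elbo": trace[-1], "restart": -1}
        restarts = 0

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(max(restarts, 1))
    best = best if initial_responsibilities is not None else None
    for ridx in range(restarts):
        rng = np.random.default_rng(children[ridx])
        mode = "kmeans" if ridx % 2 == 0 else "random"
        r0 = _init_responsibilities(n, k_max, mode, rng, features)
        states, weights, resp, trace = _run_cavi(
            pids, data, basis, k_max, priors, concentration, r0, max_iter, tol)
        if best is None or trace[-1] > best["elbo"]:
            best = {"states": states, "weights": weights, "resp": resp,
                    "trace": trace, "elbo": trace[-1], "restart": ridx}

    groups = []
    for k in range(k_max):
        coeffs = {}
        sds = {}
        for target in TARGETS:
            st = best["states"][target][k]
            coeffs[target] = np.asarray(st.m, dtype=float)
            sds[target] = float(np.sqrt(st.b / st.a))
        groups.append(GroupParameters(coefficients=coeffs, residual_sd=sds))

    model = TrajectoryModel(
        k_max=k_max,
        weights=best["weights"],
        groups=groups,
        concentration=concentration,
        basis=basis,
        priors={t: {k2: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k2, v in priors[t].items()} for t in TARGETS},
        fit_meta={
            "seed": seed,
            "restarts": restarts,
            "best_restart": best["restart"],
            "elbo": best["elbo"],
            "iterations": len(best["trace"]),
            "elbo_trace": [float(v) for v in best["trace"]],
            "n_participants": n,
            "occupancy": (best["resp"].sum(axis=0) / n).tolist(),
        },
    )
    return model


# --------------------------------------------------------------------------
# membership, curves, effective groups
# --------------------------------------------------------------------------

def _log_membership(model: TrajectoryModel, ages, values: dict) -> np.ndarray:
    """Unnormalized log posterior over groups for one observation set."""
    X = model.basis.design(np.atleast_1d(ages))
    with np.errstate(divide="ignore"):
        logp = np.log(model.weights.astype(float))
    n_observed = 0
    for target in model.targets:
        y = np.atleast_1d(np.asarray(values.get(target, np.nan), dtype=float))
        obs = np.isfinite(y)
        if not obs.any():
            continue
        n_observed += int(obs.sum())
        Xo, yo = X[obs], y[obs]
        for k, g in enumerate(model.groups):
            if not np.isfinite(logp[k]):
                continue
            mu = g.predict(target, Xo)
            logp[k] += float(norm.logpdf(yo, mu, g.residual_sd[target]).sum())
    if n_observed == 0:
        raise DataError("all targets missing: nothing to assign on")
    return logp


def posterior_membership(model: TrajectoryModel, obs: ObservationSet) -> MembershipPosterior:
    """Bayes-rule membership from any subset of observations (one visit suffices).

    probabilities[g] is proportional to weight[g] times the product of Normal
    densities of the observed (visit, target) values at group g's curve;
    missing targets contribute nothing.
    """
    logp = _log_membership(model, obs.ages, obs.values)
    p = np.exp(logp - logsumexp(logp))
    p /= p.sum()
    map_group = int(np.flatnonzero(p == p.max())[0])  # ties -> lowest index
    return MembershipPosterior(obs.participant_id, p, map_group)


def assign_memberships(model: TrajectoryModel, visits: pd.DataFrame) -> pd.DataFrame:
    """Batch membership for a long visits table (one row per participant out).

    Returns a DataFrame with participant_id, map_group and prob_0..prob_{K-1}.
    This is the assignment rule of the fitted model applied in bulk; on the
    training data it reproduces the per-participant responsibilities.
    """
    out = []
    for pid, sub in visits.groupby("participant_id", sort=False):
        values = {t: sub[_TARGET_COLUMNS[t]].to_numpy(dtype=float) for t in model.targets}
        logp = _log_membership(model, sub["age_years"].to_numpy(dtype=float), values)
        p = np.exp(logp - logsumexp(logp))
        p /= p.sum()
        out.append((pid, int(np.flatnonzero(p == p.max())[0]), *p))
    cols = ["participant_id", "map_group"] + [f"prob_{k}" for k in range(model.k_max)]
    return pd.DataFrame(out, columns=cols)


def trajectory_curves(model: TrajectoryModel, age_grid: Sequence[float]) -> pd.DataFrame:
    """Per-group predicted LVEF and E/A on an age grid, in original units."""
    ages = np.asarray(list(age_grid), dtype=float)
    X = model.basis.design(ages)
    rows = []
    for k, g in enumerate(model.groups):
        preds = {t: g.predict(t, X) for t in model.targets}
        for i, a in enumerate(ages):
            rows.append({"group": k, "age_years": a,
                         **{t: preds[t][i] for t in model.targets}})
    return pd.DataFrame(rows)


def effective_groups(model: TrajectoryModel, min_weight: float = 0.01):
    """Groups with expected membership >= min_weight, ranked by weight.

    Returns (internal_indices, mapping) where internal_indices is sorted by
    descending weight and mapping maps internal index -> rank label 1..K.
    """
    keep = np.flatnonzero(model.weights >= min_weight)
    order = keep[np.argsort(-model.weights[keep], kind="stable")]
    mapping = {int(idx): rank + 1 for rank, idx in enumerate(order)}
    return [int(i) for i in order], mapping


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

_SCHEMA_VERSION = 1


def model_to_dict(model: TrajectoryModel) -> dict:
    return {
        "schema_version": _SCHEMA_VERSION,
        "k_max": model.k_max,
        "concentration": model.concentration,
        "targets": list(model.targets),
        "basis": {"reference_age": model.basis.reference_age,
                  "scale": model.basis.scale,
                  "degree": model.basis.degree},
        "weights": model.weights.tolist(),
        "groups": [
            {"coefficients": {t: np.asarray(g.coefficients[t]).tolist()
                              for t in model.targets},
             "residual_sd": {t: g.residual_sd[t] for t in model.targets}}
            for g in model.groups
        ],
        "priors": model.priors,
        "fit_meta": model.fit_meta,
    }


def model_from_dict(doc: dict) -> TrajectoryModel:
    if doc.get("schema_version") != _SCHEMA_VERSION:
        raise DataError(f"unsupported model schema version: {doc.get('schema_version')}")
    basis = AgeBasis(**doc["basis"])
    groups = [
        GroupParameters(
            coefficients={t: np.asarray(c, dtype=float)
                          for t, c in g["coefficients"].items()},
            residual_sd={t: float(v) for t, v in g["residual_sd"].items()},
        )
        for g in doc["groups"]
    ]
    return TrajectoryModel(
        k_max=int(doc["k_max"]),
        weights=np.asarray(doc["weights"], dtype=float),
        groups=groups,
        concentration=float(doc["concentration"]),
        basis=basis,
        priors=doc.get("priors", {}),
        fit_meta=doc.get("fit_meta", {}),
        targets=tuple(doc.get("targets", TARGETS)),
    )


def save_model(model: TrajectoryModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_model(path) -> TrajectoryModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
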