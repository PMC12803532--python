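"""Proteome-wide multinomial association scan of predicted trajectory membership.

Each aptamer is related to predicted trajectory (reference = largest,
low-risk group) with one multinomial logistic model per aptamer including
all effective groups simultaneously, adjusted for age and sex; proteins and
age are standardized (mean 0, SD 1, population convention).
Benjamini-Hochberg q-values are computed within each trajectory contrast
across all scanned aptamers, and shared/unique significant-set accounting
follows an upset-style exact partition.

The multinomial fits use a dedicated Newton solver with analytic gradient
and Hessian so a proteome-wide scan (thousands of small fits) stays cheap;
Wald standard errors come from the inverse observed information.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .errors import DataError, EstimationError, SeparationError

__all__ = [
    "scale_features",
    "multinomial_logit",
    "fit_multinomial",
    "scan_proteins",
    "fdr_adjust",
    "shared_unique_counts",
]

logger = logging.getLogger(__name__)


def scale_features(matrix: pd.DataFrame):
    """Center/scale columns to mean 0, SD 1 (population SD convention).

    Returns (scaled, excluded) where excluded lists constant columns that
    were dropped (logged as a warning).
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) \
        else np.asarray(matrix, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0
    constant = sd == 0
    excluded = []
    if isinstance(matrix, pd.DataFrame):
        excluded = [c for c, bad in zip(matrix.columns, constant) if bad]
    elif constant.any():
        excluded = list(np.flatnonzero(constant))
    if excluded:
        logger.warning("excluding %d constant column(s): %s",
                       len(excluded), excluded[:10])
    keep = ~constant
    scaled = (X[:, keep] - mean[keep]) / sd[keep]
    if isinstance(matrix, pd.DataFrame):
        scaled = pd.DataFrame(scaled, index=matrix.index,
                              columns=[c for c in matrix.columns if c not in set(excluded)])
    return scaled, excluded


def multinomial_logit(X: np.ndarray, y: np.ndarray, n_categories: int,
                      max_iter: int = 100, tol: float = 1e-10):
    """Maximum-likelihood multinomial logit (category 0 = reference).

    Newton-Raphson on the full (p*(K-1)) parameter vector with the analytic
    block Hessian.  Returns (params (p, K-1), cov ((p*(K-1))^2), converged).
    Raises SeparationError when estimates diverge (complete separation).
    """
    n, p = X.shape
    K = n_categories
    if K < 2:
        raise DataError("need at least 2 label categories")
    Y = np.zeros((n, K))
    Y[np.arange(n), y] = 1.0
    B = np.zeros((p, K - 1))
    ll_prev = -np.inf
    for _ in range(max_iter):
        eta = X @ B                               # (n, K-1)
        eta_full = np.concatenate([np.zeros((n, 1)), eta], axis=1)
        eta_full -= eta_full.max(axis=1, keepdims=True)
        expeta = np.exp(eta_full)
        Pfull = expeta / expeta.sum(axis=1, keepdims=True)
        ll = float((Y * (eta_full - np.log(expeta.sum(axis=1, keepdims=True)))).sum())
        Pk = Pfull[:, 1:]                          # (n, K-1)
        grad = X.T @ (Y[:, 1:] - Pk)               # (p, K-1)
        H = np.zeros((p * (K - 1), p * (K - 1)))
        for j in range(K - 1):
            for l in range(j, K - 1):
                w = Pk[:, j] * ((1.0 if j == l else 0.0) - Pk[:, l])
                blk = X.T @ (X * w[:, None])
                H[j * p:(j + 1) * p, l * p:(l + 1) * p] = blk
                if l != j:
                    H[l * p:(l + 1) * p, j * p:(j + 1) * p] = blk
        g = grad.T.reshape(-1)                     # order: contrast-major
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(H.shape[0]), g)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix") from exc
        B = B + step.reshape(K - 1, p).T
        # log-odds beyond ~12 per (standardized) unit are numerically
        # saturated: the MLE does not exist (complete/quasi-complete separation)
        if np.max(np.abs(B)) > 12.0:
            raise SeparationError("multinomial estimates diverged "
                                  "(complete or quasi-complete separation)")
        if abs(ll - ll_prev) < tol * max(1.0, abs(ll)) and np.max(np.abs(g)) < 1e-6:
            cov = np.linalg.inv(H + 1e-10 * np.eye(H.shape[0]))
            return B, cov, True
        ll_prev = ll
    return B, np.linalg.inv(H + 1e-10 * np.eye(H.shape[0])), False


def fit_multinomial(protein, covariates: pd.DataFrame, labels,
                    reference) -> pd.DataFrame:
    """Per-trajectory log-odds of one protein (vs. reference), Wald inference.

    covariates: DataFrame of adjustment columns (age, sex); the protein and
    age are expected already standardized.  Returns a DataFrame indexed by
    non-reference group with columns beta, se, p.
    """
    labels = np.asarray(labels, dtype=str)
    cats = [str(reference)] + sorted(c for c in pd.unique(labels) if c != str(reference))
    if len(cats) < 2:
        raise DataError("need at least 2 label categories present")
    if str(reference) not in set(labels):
        raise DataError(f"reference {reference!r} absent from labels")
    code = {c: i for i, c in enumerate(cats)}
    y = np.array([code[c] for c in labels])
    protein = np.asarray(protein, dtype=float)
    Xcov = covariates.to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y)), protein, Xcov])
    B, cov, converged = multinomial_logit(X, y, len(cats))
    if not converged:
        raise EstimationError("multinomial fit did not converge")
    p_dim = X.shape[1]
    rows = []
    for j, cat in enumerate(cats[1:]):
        beta = B[1, j]
        se = float(np.sqrt(cov[j * p_dim + 1, j * p_dim + 1]))
        rows.append({"group": cat, "beta": beta, "se": se,
                     "p": 2.0 * norm.sf(abs(beta) / se)})
    return pd.DataFrame(rows).set_index("group")


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def scan_proteins(matrix: pd.DataFrame, covariates: pd.DataFrame, labels,
                  reference, q_threshold: float = 0.05,
                  pooled_fdr: bool = False):
    """Proteome-wide scan: one multinomial model per aptamer, BH per contrast.

    matrix: participants x aptamers (raw scale; standardized internally).
    covariates: age (standardized internally) and sex indicator.
    Returns (results, significant) where results has one row per
    (aptamer, contrast) with beta/se/p/q/converged, and significant maps
    each non-reference group to its set of q < q_threshold aptamer ids.
    Non-converged aptamers are excluded from the FDR family (q = NaN).
    """
    scaled, excluded = scale_features(matrix)
    cov = covariates.copy()
    if "age_years" in cov.columns:
        cov["age_years"] = (cov["age_years"] - cov["age_years"].mean()) / cov["age_years"].std(ddof=0)
    labels = np.asarray(labels, dtype=str)
    rows = []
    for aptamer in scaled.columns:
        try:
            est = fit_multinomial(scaled[aptamer].to_numpy(), cov, labels, reference)
            for grp, r in est.iterrows():
                rows.append({"aptamer_id": aptamer, "group": grp,
                             "beta": r["beta"], "se": r["se"], "p": r["p"],
                             "converged": True})
        except (SeparationError, EstimationError) as exc:
            logger.warning("aptamer %s excluded from FDR: %s", aptamer, exc)
            rows.append({"aptamer_id": aptamer, "group": None, "beta": np.nan,
                         "se": np.nan, "p": np.nan, "converged": False})
    results = pd.DataFrame(rows)
    ok = results["converged"] & results["group"].notna()
    results["q"] = np.nan
    if pooled_fdr:
        results.loc[ok, "q"] = fdr_adjust(results.loc[ok, "p"].to_numpy())
    else:
        for grp in results.loc[ok, "group"].unique():
            sel = ok & (results["group"] == grp)
            results.loc[sel, "q"] = fdr_adjust(results.loc[sel, "p"].to_numpy())
    significant = {
        grp: set(results.loc[ok & (results["group"] == grp)
                             & (results["q"] < q_threshold), "aptamer_id"])
        for grp in results.loc[ok, "group"].unique()
    }
    return results, significant


def shared_unique_counts(significant_sets: dict) -> dict:
    """Upset-style exact intersection counts plus per-trajectory unique counts.

    Returns {"patterns": {tuple(sorted groups): count of aptamers significant
    in exactly that set of groups}, "unique": {group: count}}.
    """
    groups = sorted(significant_sets)
    patterns = {}
    for r in range(1, len(groups) + 1):
        for combo in itertools.combinations(groups, r):
            inside = set.intersection(*(significant_sets[g] for g in combo)) if combo else set()
            outside = set().union(*(significant_sets[g] for g in groups
                                    if g not in combo), set())
            exact = inside - outside
            if exact:
                patterns[combo] = len(exact)
    unique = {g: patterns.get((g,), 0) for g in groups}
    return {"patterns": patterns, "unique": unique}
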