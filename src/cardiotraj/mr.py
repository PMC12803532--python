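"""Two-sample Mendelian randomization from GWAS summary statistics.

Instruments are pre-clumped pQTLs for trajectory-associated proteins;
outcomes are cardiac structure/function GWAS.  The module harmonizes
effect-allele coding between the two tables (sign flips for swapped
alleles, strand complements where needed, unconditional drop of palindromic
variants), estimates causal effects with the Wald ratio (single instrument)
or fixed-effect inverse-variance weighting (several instruments, with
Cochran's Q heterogeneity), and labels instruments cis or trans relative to
the encoding gene's transcription start site (1 Mb window, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .errors import DataError, EstimationError, UsageError

__all__ = [
    "VariantEffect",
    "GwasPair",
    "MRResult",
    "harmonize_variants",
    "wald_ratio",
    "ivw",
    "classify_cis_trans",
    "mr_scan",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID = set("ACGT")


@dataclass(frozen=True)
class VariantEffect:
    """One variant's effect estimate in a GWAS summary table."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float = np.nan
    eaf: float = np.nan

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise DataError(f"{self.variant_id}: se must be > 0")
        if self.effect_allele not in _VALID or self.other_allele not in _VALID:
            raise DataError(f"{self.variant_id}: alleles must be A/C/G/T")


@dataclass
class GwasPair:
    """Harmonized per-variant exposure/outcome effects."""

    variants: pd.DataFrame  # variant_id, beta_exposure, se_exposure, beta_outcome, se_outcome
    n_dropped: int = 0
    drop_log: list = field(default_factory=list)


@dataclass
class MRResult:
    estimate: float
    se: float
    p: float
    method: str           # "wald" or "ivw"
    n_variants: int
    q_statistic: float = np.nan
    q_pvalue: float = np.nan
    cis_status: str = ""


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def harmonize_variants(exposure: pd.DataFrame, outcome: pd.DataFrame) -> GwasPair:
    """Align outcome effect-allele coding to the exposure table.

    Inner join on variant_id; swapped outcome alleles flip the outcome beta
    sign; alleles matching only after strand complement are complemented
    first; palindromic (A/T, C/G) variants are dropped unconditionally;
    irreconcilable allele pairs are dropped with a logged reason.
    """
    for name, df in (("exposure", exposure), ("outcome", outcome)):
        missing = {"variant_id", "effect_allele", "other_allele", "beta", "se"} - set(df.columns)
        if missing:
            raise DataError(f"{name} table missing columns: {sorted(missing)}")
    merged = exposure.merge(outcome, on="variant_id", suffixes=("_exp", "_out"))
    if merged["variant_id"].duplicated().any():
        dups = merged.loc[merged["variant_id"].duplicated(), "variant_id"].tolist()
        raise DataError(f"duplicate variant ids after join: {dups[:5]}")
    rows = []
    drop_log = []
    for rec in merged.itertuples(index=False):
        ea_e, oa_e = rec.effect_allele_exp, rec.other_allele_exp
        ea_o, oa_o = rec.effect_allele_out, rec.other_allele_out
        if not {ea_e, oa_e, ea_o, oa_o} <= _VALID:
            drop_log.append((rec.variant_id, "invalid_alleles"))
            continue
        if _is_palindromic(ea_e, oa_e):
            drop_log.append((rec.variant_id, "palindromic"))
            continue
        beta_out = rec.beta_out
        if (ea_o, oa_o) == (ea_e, oa_e):
            pass
        elif (ea_o, oa_o) == (oa_e, ea_e):
            beta_out = -beta_out
        else:
            cea, coa = _COMPLEMENT[ea_o], _COMPLEMENT[oa_o]
            if (cea, coa) == (ea_e, oa_e):
                pass
            elif (cea, coa) == (oa_e, ea_e):
                beta_out = -beta_out
            else:
                drop_log.append((rec.variant_id, "irreconcilable_alleles"))
                continue
        rows.append({
            "variant_id": rec.variant_id,
            "beta_exposure": rec.beta_exp, "se_exposure": rec.se_exp,
            "beta_outcome": beta_out, "se_outcome": rec.se_out,
        })
    variants = pd.DataFrame(rows, columns=["variant_id", "beta_exposure",
                                           "se_exposure", "beta_outcome", "se_outcome"])
    if len(variants) and (np.any(variants["se_exposure"] <= 0)
                          or np.any(variants["se_outcome"] <= 0)):
        raise DataError("all standard errors must be > 0")
    return GwasPair(variants=variants, n_dropped=len(drop_log), drop_log=drop_log)


def wald_ratio(beta_exposure: float, se_exposure: float,
               beta_outcome: float, se_outcome: float) -> MRResult:
    """Single-instrument Wald ratio with first-order delta-method SE."""
    if beta_exposure == 0:
        raise UsageError("wald_ratio undefined for beta_exposure = 0")
    estimate = beta_outcome / beta_exposure
    se = se_outcome / abs(beta_exposure)
    p = 2.0 * norm.sf(abs(estimate) / se) if se > 0 else np.nan
    return MRResult(estimate=estimate, se=se, p=p, method="wald", n_variants=1)


def ivw(pair: GwasPair) -> MRResult:
    """Fixed-effect inverse-variance weighted mean of per-variant Wald ratios.

    Weights are 1/se_ratio^2 with se_ratio = se_outcome/|beta_exposure|;
    Cochran's Q and its chi-square p-value quantify heterogeneity.  A single
    harmonized variant delegates to the Wald ratio.
    """
    v = pair.variants
    if len(v) == 0:
        raise EstimationError("no harmonized variants to estimate from")
    if np.any(v["beta_exposure"] == 0):
        raise UsageError("beta_exposure = 0 present; drop weak instruments first")
    if len(v) == 1:
        r = v.iloc[0]
        return wald_ratio(r["beta_exposure"], r["se_exposure"],
                          r["beta_outcome"], r["se_outcome"])
    ratios = v["beta_outcome"].to_numpy() / v["beta_exposure"].to_numpy()
    se_ratio = v["se_outcome"].to_numpy() / np.abs(v["beta_exposure"].to_numpy())
    w = 1.0 / se_ratio**2
    estimate = float(np.sum(w * ratios) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2.0 * norm.sf(abs(estimate) / se))
    q = float(np.sum(w * (ratios - estimate) ** 2))
    q_p = float(chi2.sf(q, len(v) - 1))
    return MRResult(estimate=estimate, se=se, p=p, method="ivw",
                    n_variants=len(v), q_statistic=q, q_pvalue=q_p)


def classify_cis_trans(chrom: str, pos: int, gene_chrom: str, gene_tss: int,
                       window: int = 1_000_000) -> str:
    """cis iff same chromosome and |pos - tss| <= window (inclusive)."""
    if str(chrom) == str(gene_chrom) and abs(int(pos) - int(gene_tss)) <= window:
        return "cis"
    return "trans"


def mr_scan(proteins: list, outcomes: dict, alpha: float = 0.05,
            alpha_policy: str = "bonferroni", cis_window: int = 1_000_000) -> pd.DataFrame:
    """Harmonize and estimate per protein x outcome; flag significance.

    proteins: list of dicts with keys protein, gene, chrom (gene chromosome),
    tss (gene TSS, bp), exposure (GWAS DataFrame with variant chrom/pos_bp),
    and optionally trajectory_beta (observational direction, for the
    direction-consistency flag).  outcomes: name -> GWAS DataFrame.
    Significance is Bonferroni across all protein x outcome tests by
    default.  A protein with zero surviving instruments is recorded as
    untestable rather than raising.
    """
    if alpha_policy not in ("bonferroni", "none"):
        raise UsageError(f"unknown alpha_policy {alpha_policy!r}")
    rows = []
    for prot in proteins:
        exposure = prot["exposure"]
        for outcome_name, outcome in outcomes.items():
            pair = harmonize_variants(exposure, outcome)
            base = {"protein": prot["protein"], "gene": prot.get("gene", ""),
                    "outcome": outcome_name, "n_dropped": pair.n_dropped}
            if len(pair.variants) == 0:
                rows.append({**base, "method": "untestable", "n_variants": 0,
                             "estimate": np.nan, "se": np.nan, "p": np.nan,
                             "q_statistic": np.nan, "cis_status": "",
                             "direction_consistent": np.nan})
                continue
            res = ivw(pair)
            kept = exposure[exposure["variant_id"].isin(pair.variants["variant_id"])]
            statuses = {
                classify_cis_trans(c, p_, prot.get("chrom", ""), prot.get("tss", -1),
                                   cis_window)
                for c, p_ in zip(kept["chrom"], kept["pos_bp"])
            } if {"chrom", "pos_bp"} <= set(kept.columns) else set()
            cis_status = statuses.pop() if len(statuses) == 1 else ("mixed" if statuses else "")
            direction = np.nan
            if "trajectory_beta" in prot and np.isfinite(res.estimate):
                direction = float(np.sign(res.estimate)
                                  == np.sign(prot["trajectory_beta"]))
            rows.append({**base, "method": res.method, "n_variants": res.n_variants,
                         "estimate": res.estimate, "se": res.se, "p": res.p,
                         "q_statistic": res.q_statistic, "cis_status": cis_status,
                         "direction_consistent": direction})
    table = pd.DataFrame(rows)
    n_tests = int(table["p"].notna().sum())
    if alpha_policy == "bonferroni" and n_tests > 0:
        table["significant"] = table["p"] < alpha / n_tests
    else:
        table["significant"] = table["p"] < alpha
    return table
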