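"""Two-sample Mendelian randomization from QTL exposure to outcome GWAS.

Instruments are cis variants strongly associated with a feature (p < 5e-8,
falling back to 5e-6 when nothing passes), pruned to approximate
independence by greedy LD clumping. The causal effect of the feature on the
outcome is estimated by the Wald ratio for a single instrument or
inverse-variance-weighted (IVW) meta-analysis of per-variant ratios for
several, with MR-Egger regression, Cochran's Q heterogeneity and Steiger
directionality checks as sensitivity analyses.

IVW uses the first-order delta-method weights w_j = beta_exp_j^2 / se_out_j^2
on the ratios b_j = beta_out_j / beta_exp_j; the fixed-effect standard error
1/sqrt(sum w) is inflated by sqrt(Q/(k-1)) when Q/(k-1) > 1 (multiplicative
random effects). MR-Egger regresses outcome on exposure effects with an
intercept (weights 1/se_out^2, exposure effects oriented positive); the
intercept tests directional pleiotropy.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .types import Instrument, LdMatrix, SnpAssoc

logger = logging.getLogger(__name__)

__all__ = [
    "MrResult",
    "MrGateError",
    "select_instruments",
    "clump",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "steiger",
    "run_mr",
    "replicate",
    "MendelianRandomization",
]

P_INSTRUMENT = 5e-8
P_INSTRUMENT_FALLBACK = 5e-6
CLUMP_R2 = 0.001
CLUMP_WINDOW_KB = 10_000

_CI_Z = 1.96


class MrGateError(ValueError):
    """Raised when causal follow-up is requested for an ineligible feature."""


@dataclass
class MrResult:
    """A causal estimate with its sensitivity statistics.

    ``beta`` is on the log-OR scale; ``or_`` = exp(beta) with a 95% Wald
    interval. Heterogeneity (Q), Egger intercept and Steiger fields are None
    when the corresponding analysis does not apply (e.g. Egger needs >= 3
    instruments). ``status`` is "ok", "not-estimable" (no surviving
    instrument) or "no-instrument".
    """

    feature_id: str = ""
    outcome: str = ""
    method: str = ""
    n_snps: int = 0
    beta: Optional[float] = None
    se: Optional[float] = None
    or_: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    pvalue: Optional[float] = None
    q_stat: Optional[float] = None
    q_df: Optional[int] = None
    q_p: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_p: Optional[float] = None
    steiger_correct_direction: Optional[bool] = None
    steiger_p: Optional[float] = None
    status: str = "ok"

    def summary(self) -> str:
        if self.beta is None:
            return f"MR {self.feature_id} -> {self.outcome}: {self.status}"
        lines = [
            f"Mendelian randomization: {self.feature_id or 'exposure'} -> "
            f"{self.outcome or 'outcome'}",
            "-" * 60,
            f"  method          {self.method} ({self.n_snps} SNP(s))",
            f"  beta (se)       {self.beta:+.4f} ({self.se:.4f})",
            f"  OR [95% CI]     {self.or_:.3f} [{self.ci_low:.3f}, {self.ci_high:.3f}]",
            f"  p-value         {self.pvalue:.3g}",
        ]
        if self.q_stat is not None:
            lines.append(f"  Cochran Q       {self.q_stat:.3f} (df={self.q_df}, p={self.q_p:.3g})")
        if self.egger_intercept is not None:
            lines.append(
                f"  Egger intercept {self.egger_intercept:+.4f} (p={self.egger_intercept_p:.3g})"
            )
        if self.steiger_correct_direction is not None:
            lines.append(
                f"  Steiger         direction "
                f"{'exposure->outcome' if self.steiger_correct_direction else 'REVERSED'}"
                f" (p={self.steiger_p:.3g})"
            )
        return "\n".join(lines)


def _finish(res: MrResult, beta: float, se: float) -> MrResult:
    res.beta = float(beta)
    res.se = float(se)
    res.or_ = math.exp(beta)
    res.ci_low = math.exp(beta - _CI_Z * se)
    res.ci_high = math.exp(beta + _CI_Z * se)
    res.pvalue = float(2.0 * stats.norm.sf(abs(beta) / se))
    return res


def select_instruments(
    exposure: Iterable[SnpAssoc],
    p_primary: float = P_INSTRUMENT,
    p_fallback: float = P_INSTRUMENT_FALLBACK,
) -> list[SnpAssoc]:
    """Variants passing the primary threshold, else the relaxed fallback.

    Returns an empty list (logged) when nothing passes either threshold.
    """
    exposure = list(exposure)
    if not exposure:
        raise ValueError("select_instruments: empty exposure statistics")
    primary = [r for r in exposure if r.pvalue is not None and r.pvalue < p_primary]
    if primary:
        return primary
    fallback = [r for r in exposure if r.pvalue is not None and r.pvalue < p_fallback]
    if fallback:
        logger.info("select_instruments: fallback threshold %g engaged", p_fallback)
        return fallback
    logger.info("select_instruments: no instrument passes %g or %g", p_primary, p_fallback)
    return []


def clump(
    snps: Sequence[SnpAssoc],
    ld: LdMatrix,
    r2: float = CLUMP_R2,
    window_kb: float = CLUMP_WINDOW_KB,
) -> list[SnpAssoc]:
    """Greedy LD clumping by ascending p-value.

    Repeatedly keep the most significant remaining variant and discard all
    others on the same chromosome within ``window_kb`` whose squared
    correlation with it exceeds ``r2``.
    """
    remaining = sorted(snps, key=lambda r: (r.pvalue if r.pvalue is not None else 1.0, r.snp_id))
    kept: list[SnpAssoc] = []
    while remaining:
        lead = remaining.pop(0)
        kept.append(lead)
        li = ld.index([lead.snp_id])[0]
        survivors = []
        for other in remaining:
            same_chrom = other.chrom == lead.chrom
            close = abs(other.pos - lead.pos) <= window_kb * 1_000
            if same_chrom and close:
                oi = ld.index([other.snp_id])[0]
                if ld.r[li, oi] ** 2 > r2:
                    continue
            survivors.append(other)
        remaining = survivors
    return kept


def wald_ratio(inst: Instrument, feature_id: str = "", outcome: str = "") -> MrResult:
    """Single-instrument ratio estimate with first-order delta-method SE."""
    if abs(inst.beta_exp) < 1e-12:
        raise ValueError("wald_ratio: exposure effect is (numerically) zero")
    beta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    res = MrResult(feature_id=feature_id, outcome=outcome, method="wald_ratio", n_snps=1)
    res = _finish(res, beta, se)
    res.steiger_correct_direction, res.steiger_p = steiger([inst]) if inst.n_exp and inst.n_out else (None, None)
    return res


def _ivw_core(insts: Sequence[Instrument]) -> tuple[float, float, float, int]:
    b = np.array([i.beta_out / i.beta_exp for i in insts])
    w = np.array([i.beta_exp**2 / i.se_out**2 for i in insts])
    beta = float(np.sum(w * b) / np.sum(w))
    se_fe = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (b - beta) ** 2))
    return beta, se_fe, q, len(insts)


def ivw(
    insts: Sequence[Instrument],
    feature_id: str = "",
    outcome: str = "",
    allow_single: bool = False,
) -> MrResult:
    """Inverse-variance-weighted meta-analysis of per-variant ratios.

    Multiplicative random effects: the fixed-effect SE is inflated by
    sqrt(Q/(k-1)) when the dispersion exceeds 1. With a single instrument
    (``allow_single``) the estimate coincides exactly with the Wald ratio.
    """
    insts = list(insts)
    if len(insts) < (1 if allow_single else 2):
        raise ValueError("ivw: need at least two instruments")
    for i in insts:
        if abs(i.beta_exp) < 1e-12:
            raise ValueError(f"ivw: zero exposure effect at {i.snp_id}")
    beta, se_fe, q, k = _ivw_core(insts)
    se = se_fe
    q_df: Optional[int] = None
    q_p: Optional[float] = None
    if k >= 2:
        q_df = k - 1
        q_p = float(stats.chi2.sf(q, q_df))
        if q / q_df > 1.0:
            se = se_fe * math.sqrt(q / q_df)
    res = MrResult(
        feature_id=feature_id,
        outcome=outcome,
        method="ivw" if k > 1 else "wald_ratio",
        n_snps=k,
        q_stat=q if k >= 2 else None,
        q_df=q_df,
        q_p=q_p,
    )
    res = _finish(res, beta, se)
    if all(i.n_exp and i.n_out for i in insts):
        res.steiger_correct_direction, res.steiger_p = steiger(insts)
    return res


def mr_egger(insts: Sequence[Instrument], feature_id: str = "", outcome: str = "") -> MrResult:
    """Weighted Egger regression: slope = causal estimate, intercept = pleiotropy.

    Exposure effects are oriented positive (each pair flipped jointly), then
    beta_out is regressed on beta_exp with an intercept under weights
    1/se_out^2. The residual dispersion multiplies the coefficient variances
    when it exceeds 1; intercept and slope p-values use t(k-2).
    """
    insts = list(insts)
    k = len(insts)
    if k < 3:
        raise ValueError("mr_egger: need at least three instruments")
    sgn = np.array([1.0 if i.beta_exp >= 0 else -1.0 for i in insts])
    bx = np.array([i.beta_exp for i in insts]) * sgn
    by = np.array([i.beta_out for i in insts]) * sgn
    wt = np.array([1.0 / i.se_out**2 for i in insts])
    if np.ptp(bx) < 1e-12:
        raise ValueError("mr_egger: exposure effects have no spread; slope/intercept not identifiable")

    # weighted normal equations for [intercept, slope]
    X = np.column_stack([np.ones(k), bx])
    xtwx = X.T @ (wt[:, None] * X)
    xtwy = X.T @ (wt * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    df = k - 2
    sigma2 = float(np.sum(wt * resid**2) / df)
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    inter, slope = float(coef[0]), float(coef[1])
    se_inter, se_slope = float(math.sqrt(cov[0, 0])), float(math.sqrt(cov[1, 1]))

    res = MrResult(feature_id=feature_id, outcome=outcome, method="egger", n_snps=k)
    res = _finish(res, slope, se_slope)
    res.pvalue = float(2.0 * stats.t.sf(abs(slope) / se_slope, df))
    res.egger_intercept = inter
    res.egger_intercept_se = se_inter
    res.egger_intercept_p = float(2.0 * stats.t.sf(abs(inter) / se_inter, df))
    return res


def _steiger_r2(z: float, n: float) -> float:
    """Variance explained implied by a marginal z-score at sample size n."""
    return z * z / (z * z + n - 2.0)


def steiger(
    insts: Sequence[Instrument], aggregate: str = "sum"
) -> tuple[bool, float]:
    """Directionality test: do the instruments explain more exposure than outcome?

    Per-instrument variance explained r^2 = z^2/(z^2 + n - 2) is aggregated
    over instruments (summation by default, assuming post-clumping
    independence; ``aggregate="max"`` available). Direction is correct when
    the aggregate exposure r^2 exceeds the outcome r^2; the p-value is a
    two-sample Fisher-z test on the implied correlations.
    """
    insts = list(insts)
    if not insts:
        raise ValueError("steiger: no instruments")
    for i in insts:
        if not (i.n_exp and i.n_out):
            raise ValueError(f"steiger: sample sizes required ({i.snp_id})")
    r2_exp = [_steiger_r2(i.z_exp, i.n_exp) for i in insts]
    r2_out = [_steiger_r2(i.z_out, i.n_out) for i in insts]
    if aggregate == "sum":
        agg_exp, agg_out = sum(r2_exp), sum(r2_out)
    elif aggregate == "max":
        agg_exp, agg_out = max(r2_exp), max(r2_out)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    direction = agg_exp > agg_out

    n_exp = float(np.mean([i.n_exp for i in insts]))
    n_out = float(np.mean([i.n_out for i in insts]))
    r_exp = min(math.sqrt(min(agg_exp, 1.0)), 1.0 - 1e-12)
    r_out = min(math.sqrt(min(agg_out, 1.0)), 1.0 - 1e-12)
    se = math.sqrt(1.0 / max(n_exp - 3.0, 1.0) + 1.0 / max(n_out - 3.0, 1.0))
    zstat = (math.atanh(r_exp) - math.atanh(r_out)) / se
    p = float(2.0 * stats.norm.sf(abs(zstat)))
    return direction, p


def steiger_filter(insts: Sequence[Instrument]) -> list[Instrument]:
    """Drop instruments individually explaining more outcome than exposure."""
    kept = [
        i
        for i in insts
        if not (i.n_exp and i.n_out)
        or _steiger_r2(i.z_exp, i.n_exp) > _steiger_r2(i.z_out, i.n_out)
    ]
    if len(kept) < len(insts):
        logger.info("steiger_filter: dropped %d reverse-direction instrument(s)", len(insts) - len(kept))
    return kept


class MendelianRandomization:
    """Model-style surface: build from harmonized instruments, ``fit()``.

    ``fit()`` routes to the Wald ratio for one instrument and IVW for
    several, attaching Cochran's Q, MR-Egger (when k >= 3) and the Steiger
    direction test; ``fit(method=...)`` forces a specific estimator.
    """

    def __init__(self, instruments: Sequence[Instrument], feature_id: str = "", outcome: str = ""):
        self.instruments = list(instruments)
        self.feature_id = feature_id
        self.outcome = outcome

    def fit(self, method: str = "auto") -> MrResult:
        insts = self.instruments
        if not insts:
            return MrResult(
                feature_id=self.feature_id, outcome=self.outcome, status="not-estimable"
            )
        if method == "wald_ratio" or (method == "auto" and len(insts) == 1):
            return wald_ratio(insts[0], self.feature_id, self.outcome)
        if method == "egger":
            return mr_egger(insts, self.feature_id, self.outcome)
        if method in ("auto", "ivw"):
            res = ivw(insts, self.feature_id, self.outcome)
            if method == "auto" and len(insts) >= 3:
                try:
                    egger = mr_egger(insts, self.feature_id, self.outcome)
                except ValueError as exc:  # unidentifiable design: report IVW alone
                    logger.info("%s: egger skipped (%s)", self.feature_id, exc)
                else:
                    res.egger_intercept = egger.egger_intercept
                    res.egger_intercept_se = egger.egger_intercept_se
                    res.egger_intercept_p = egger.egger_intercept_p
            return res
        raise ValueError(f"unknown method {method!r}")


def run_mr(
    feature,
    exposure: Sequence[SnpAssoc],
    outcome_stats: Sequence[SnpAssoc],
    ld: LdMatrix,
    outcome: str = "",
    p_primary: float = P_INSTRUMENT,
    p_fallback: float = P_INSTRUMENT_FALLBACK,
    clump_r2: float = CLUMP_R2,
    clump_window_kb: float = CLUMP_WINDOW_KB,
    apply_steiger_filter: bool = True,
) -> MrResult:
    """Tier-gated causal analysis for one feature.

    ``feature`` is a :class:`ptmr.tiering.TierRecord`; only Strong/Moderate
    features without a cross-layer direction conflict are analysed. Stages:
    instrument selection -> LD clumping -> allele harmonization -> Steiger
    filtering -> Wald ratio / IVW (+ Egger, Q). A feature with no surviving
    instrument yields status "not-estimable" rather than an exception.
    """
    from .io import harmonize_pairs  # local import: io depends on types only

    if not feature.mr_eligible:
        raise MrGateError(
            f"{feature.feature_id}: tier {feature.tier!r}"
            + (" (direction-inconsistent)" if feature.direction_consistent is False else "")
            + " is not eligible for causal follow-up"
        )
    selected = select_instruments(exposure, p_primary, p_fallback)
    if not selected:
        return MrResult(
            feature_id=feature.feature_id, outcome=outcome, status="no-instrument"
        )
    clumped = clump(selected, ld, clump_r2, clump_window_kb)
    insts = harmonize_pairs(clumped, outcome_stats)
    agg_direction = agg_p = None
    if insts and all(i.n_exp and i.n_out for i in insts):
        agg_direction, agg_p = steiger(insts)
        if apply_steiger_filter:
            insts = steiger_filter(insts)
    if not insts:
        return MrResult(
            feature_id=feature.feature_id, outcome=outcome, status="not-estimable"
        )
    res = MendelianRandomization(insts, feature.feature_id, outcome).fit()
    if agg_direction is not None:
        res.steiger_correct_direction = agg_direction
        res.steiger_p = agg_p
    return res


def replicate(discovery: MrResult, validations: Sequence[MrResult]) -> str:
    """External-cohort replication verdict for one discovery estimate.

    "replicated" — some validation shares the effect sign with p < 0.05;
    "trend" — some validation shares the sign but none is significant;
    "not-replicated" — every validation has the opposite sign (or nothing
    usable).
    """
    if discovery.beta is None:
        raise ValueError("replicate: discovery estimate is missing")
    same_sign = [
        v
        for v in validations
        if v.beta is not None and math.copysign(1, v.beta) == math.copysign(1, discovery.beta)
    ]
    if any(v.pvalue is not None and v.pvalue < 0.05 for v in same_sign):
        return "replicated"
    if same_sign:
        return "trend"
    return "not-replicated"
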