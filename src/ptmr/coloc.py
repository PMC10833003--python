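"""Bayesian colocalization of two association signals in one locus.

Under the single-causal-variant assumption, the evidence that two traits
share a causal variant in a locus of m SNPs is enumerated over five
hypotheses: H0 (no association), H1/H2 (association with one trait only),
H3 (both traits, different variants), H4 (both traits, one shared variant).

Per-SNP evidence enters through the Wakefield approximate Bayes factor
computed from each SNP's effect estimate and standard error with a prior
effect-size standard deviation W^0.5:

    log ABF = 0.5 * [ ln(V/(V+W)) + z^2 * W/(V+W) ],   V = se^2, z = beta/se

Hypothesis weights combine the per-SNP ABFs with per-SNP priors p1, p2
(trait-specific causality) and p12 (shared causality); everything is
accumulated in log space for numerical stability.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.special import logsumexp

from .types import SnpAssoc

__all__ = [
    "ColocPriors",
    "ColocResult",
    "log_abf",
    "colocalize",
    "coloc_evidence_flag",
    "Colocalization",
]


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities and effect-size prior SDs.

    Defaults are the canonical ones: p1 = p2 = 1e-4 (a variant is causal for
    one trait), p12 = 1e-5 (causal for both); prior effect SD 0.15 for a
    quantitative trait (the QTL side) and 0.2 for a binary outcome.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    sd1: float = 0.15
    sd2: float = 0.2

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        if not (self.sd1 > 0 and self.sd2 > 0):
            raise ValueError("prior effect SDs must be positive")


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    feature_id: str
    layer: str
    outcome: str
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_snps: int
    labf1: np.ndarray = field(repr=False, default=None)
    labf2: np.ndarray = field(repr=False, default=None)

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2, self.pph3, self.pph4])

    @property
    def modal_hypothesis(self) -> str:
        return f"H{int(np.argmax(self.posteriors))}"

    def summary(self) -> str:
        lines = [
            f"Colocalization ({self.feature_id or 'locus'} vs {self.outcome or 'trait2'},"
            f" {self.n_snps} SNPs)",
            "-" * 58,
        ]
        labels = (
            "H0 no association",
            "H1 trait-1 only",
            "H2 trait-2 only",
            "H3 distinct variants",
            "H4 shared variant",
        )
        for lab, p in zip(labels, self.posteriors):
            lines.append(f"  PP.{lab:<22s} {p:8.4f}")
        return "\n".join(lines)


def log_abf(beta: float, se: float, prior_sd: float) -> float:
    """Wakefield log approximate Bayes factor for one association estimate."""
    if se <= 0:
        raise ValueError("se must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    v = se * se
    w = prior_sd * prior_sd
    z = beta / se
    return 0.5 * (math.log(v / (v + w)) + z * z * w / (v + w))


def colocalize(
    stats1: Iterable[SnpAssoc],
    stats2: Iterable[SnpAssoc],
    priors: ColocPriors = ColocPriors(),
    feature_id: str = "",
    layer: str = "",
    outcome: str = "",
) -> ColocResult:
    """Posterior hypothesis probabilities for two traits in one locus.

    SNPs are intersected on id (the ABF depends on z^2 only, so allele
    orientation is immaterial here). With hypothesis sums
    L1 = sum_j ABF1_j, L2 = sum_j ABF2_j, L12 = sum_j ABF1_j*ABF2_j:

        S0 = 1, S1 = p1*L1, S2 = p2*L2,
        S3 = p1*p2*(L1*L2 - L12)  (clamped at >= 0),
        S4 = p12*L12,

    all evaluated via log-sum-exp, then normalised. A single shared SNP gives
    pph3 = 0 by construction.
    """
    by_id = {r.snp_id: r for r in stats2}
    shared = [(r, by_id[r.snp_id]) for r in stats1 if r.snp_id in by_id]
    if not shared:
        raise ValueError("colocalize: no shared SNPs between the two traits")

    l1 = np.array([log_abf(a.beta, a.se, priors.sd1) for a, _ in shared])
    l2 = np.array([log_abf(b.beta, b.se, priors.sd2) for _, b in shared])

    L1 = logsumexp(l1)
    L2 = logsumexp(l2)
    L12 = logsumexp(l1 + l2)

    log_s = np.full(5, -np.inf)
    log_s[0] = 0.0
    log_s[1] = math.log(priors.p1) + L1
    log_s[2] = math.log(priors.p2) + L2
    log_s[4] = math.log(priors.p12) + L12
    # S3 = p1 p2 (L1 L2 - L12); the cross-term difference can only be
    # negative through floating error, in which case it is clamped to zero
    diff = L12 - (L1 + L2)
    if diff < 0.0:
        log_s[3] = math.log(priors.p1) + math.log(priors.p2) + L1 + L2 + math.log1p(-math.exp(diff))

    denom = logsumexp(log_s)
    post = np.exp(log_s - denom)
    return ColocResult(
        feature_id=feature_id,
        layer=layer,
        outcome=outcome,
        pph0=float(post[0]),
        pph1=float(post[1]),
        pph2=float(post[2]),
        pph3=float(post[3]),
        pph4=float(post[4]),
        n_snps=len(shared),
        labf1=l1,
        labf2=l2,
    )


def coloc_evidence_flag(res: ColocResult, threshold: float = 0.75) -> bool:
    """True iff the shared-variant posterior strictly exceeds the threshold."""
    return res.pph4 > threshold


class Colocalization:
    """Model-style wrapper: build from two traits' statistics, ``fit()``.

    Example
    -------
    >>> model = Colocalization(qtl_stats, gwas_stats)
    >>> res = model.fit()
    >>> res.pph4 > 0.75
    """

    def __init__(
        self,
        stats1: Iterable[SnpAssoc],
        stats2: Iterable[SnpAssoc],
        priors: ColocPriors = ColocPriors(),
        feature_id: str = "",
        layer: str = "",
        outcome: str = "",
    ):
        self.stats1 = list(stats1)
        self.stats2 = list(stats2)
        self.priors = priors
        self.feature_id = feature_id
        self.layer = layer
        self.outcome = outcome

    def fit(self) -> ColocResult:
        return colocalize(
            self.stats1,
            self.stats2,
            priors=self.priors,
            feature_id=self.feature_id,
            layer=self.layer,
            outcome=self.outcome,
        )
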