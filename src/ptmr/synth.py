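"""Synthetic GWAS/QTL summary statistics with known ground truth.

The generators emulate the statistical structure of the real inputs the
pipeline was designed for — an LD-correlated cis-SNP block around each
feature, sparse cis-QTL weights, marginal GWAS z-scores induced by a
feature-level causal effect plus LD-correlated noise, and binary-trait
sample sizes — without touching individual-level genotypes.

Marginal z-scores follow the standard multivariate-normal summary-statistic
model: for a cis window with LD correlation R and predictor weights w, a
feature-level effect alpha (log-OR per SD of the predicted feature) induces

    z = alpha * sqrt(n) * (R w) / sqrt(w' R w) + eps,   eps ~ MVN(0, R)

so that the downstream feature-level association Z-statistic is N(0, 1)
under alpha = 0. Effects are kept in per-SD units with se = 1/sqrt(n) even
for the binary outcome: every downstream statistic consumes (beta, se, z, n)
identically, and case/control counts are carried only as metadata.

All generators are pure functions of (parameters, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import Instrument, LdMatrix, SnpAssoc, WeightModel, LAYERS

__all__ = [
    "SimTruth",
    "simulate_ld",
    "simulate_feature_gwas",
    "simulate_coloc_pair",
    "simulate_mr_set",
    "simulate_study",
    "StudyTruth",
]

GWAS_P_THRESHOLD = 5e-8

#: default cis-window block size (number of SNPs)
DEFAULT_M = 50
#: default AR(1) LD decay
DEFAULT_RHO = 0.6

# Default sample sizes mirror the scale of large published resources:
# a plasma pQTL discovery cohort of a few thousand, whole-blood eQTL
# meta-analyses in the tens of thousands, a small tissue panel, and a
# case/control GWAS of a couple of hundred thousand.
DEFAULT_N_GWAS = 228_951
DEFAULT_N_CASE = 122_977
DEFAULT_N_CONTROL = 105_974
DEFAULT_N_QTL = {"plasma_pwas": 7_213, "blood_twas": 31_684, "breast_twas": 396}


@dataclass
class SimTruth:
    """Ground truth attached to a single simulated feature or scenario."""

    feature_id: str
    alpha: float
    true_weights: np.ndarray
    causal_snps: tuple[int, ...]
    scenario: Optional[str] = None
    seed: Optional[int] = None


def simulate_ld(m: int, rho: float, seed: int = 0) -> LdMatrix:
    """AR(1) LD panel: r[i, j] = rho^|i - j|.

    Deterministic given (m, rho); the seed argument is accepted for interface
    uniformity with the other generators and ignored.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    idx = np.arange(m)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    return LdMatrix([f"snp{i + 1:04d}" for i in range(m)], r)


def _records_from_z(
    z: np.ndarray,
    ld: LdMatrix,
    n: float,
    chrom: str = "1",
    pos0: int = 100_000,
    ncase: Optional[int] = None,
    ncontrol: Optional[int] = None,
) -> list[SnpAssoc]:
    sqrt_n = np.sqrt(n)
    return [
        SnpAssoc(
            snp_id=sid,
            chrom=chrom,
            pos=pos0 + 1_000 * i,
            effect_allele="A",
            other_allele="G",
            eaf=0.3,
            beta=float(z[i] / sqrt_n),
            se=float(1.0 / sqrt_n),
            n=n,
            ncase=ncase,
            ncontrol=ncontrol,
        )
        for i, sid in enumerate(ld.snp_ids)
    ]


def _mvn_chol(ld: LdMatrix) -> np.ndarray:
    # AR(1) is strictly PD for rho < 1; tiny jitter guards near-singular input
    try:
        return np.linalg.cholesky(ld.r)
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(ld.r + 1e-10 * np.eye(ld.m))


def simulate_feature_gwas(
    ld: LdMatrix,
    w: Sequence[float],
    alpha: float,
    n: float,
    seed: int,
    noise_scale: float = 1.0,
    chrom: str = "1",
    pos0: int = 100_000,
    ncase: Optional[int] = None,
    ncontrol: Optional[int] = None,
) -> list[SnpAssoc]:
    """Marginal GWAS statistics for one cis window under a feature effect.

    ``noise_scale=0`` suppresses the MVN noise and yields the closed-form
    mean z exactly (useful for tests). ``n`` must be at least 50.
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (ld.m,):
        raise ValueError("weight vector not aligned to LD panel")
    if n < 50:
        raise ValueError("n must be >= 50")
    wrw = float(w @ ld.r @ w)
    if wrw <= 0:
        raise ValueError("w'Rw must be positive")
    mu = alpha * np.sqrt(n) * (ld.r @ w) / np.sqrt(wrw)
    rng = np.random.default_rng(seed)
    eps = _mvn_chol(ld) @ rng.standard_normal(ld.m)
    z = mu + noise_scale * eps
    return _records_from_z(z, ld, n, chrom=chrom, pos0=pos0, ncase=ncase, ncontrol=ncontrol)


def _qtl_records(
    ld: LdMatrix,
    causal: Sequence[int],
    z_causal: float,
    n: float,
    rng: np.random.Generator,
    chrom: str = "1",
    pos0: int = 100_000,
) -> list[SnpAssoc]:
    """Marginal QTL z-scores for direct per-SNP effects of size z_causal."""
    mu = np.zeros(ld.m)
    for j in causal:
        mu += z_causal * ld.r[:, j]
    z = mu + _mvn_chol(ld) @ rng.standard_normal(ld.m)
    return _records_from_z(z, ld, n, chrom=chrom, pos0=pos0)


def simulate_coloc_pair(
    scenario: str,
    m: int = DEFAULT_M,
    n1: float = 10_000,
    n2: float = 50_000,
    rho: float = DEFAULT_RHO,
    effect: float = 8.0,
    seed: int = 0,
) -> tuple[list[SnpAssoc], list[SnpAssoc]]:
    """Two traits' summary statistics in one locus under a coloc hypothesis.

    ``effect`` is the causal SNP's expected marginal |z|; the default 8 keeps
    the causal variant comfortably genome-wide significant (|z| >= 6) in
    expectation. Scenarios: H0 both null, H1/H2 one causal trait, H3 two
    distinct causal SNPs at r^2 < 0.2, H4 one shared causal SNP.
    """
    scenario = scenario.upper()
    if scenario not in {"H0", "H1", "H2", "H3", "H4"}:
        raise ValueError(f"unknown scenario {scenario!r}")
    if m < 3:
        raise ValueError("m must be >= 3")
    ld = simulate_ld(m, rho)
    rng = np.random.default_rng(seed)
    L = _mvn_chol(ld)

    j1 = m // 3
    if scenario == "H3":
        # second causal SNP must be in low LD with the first
        r2 = ld.r[j1] ** 2
        candidates = [j for j in range(m) if j != j1 and r2[j] < 0.2]
        if not candidates:
            raise ValueError(
                "no SNP pair with r^2 < 0.2 under this rho; increase m or lower rho"
            )
        j2 = max(candidates, key=lambda j: abs(j - j1))
    else:
        j2 = j1

    def draw(causal: Optional[int], n: float) -> list[SnpAssoc]:
        mu = effect * ld.r[:, causal] if causal is not None else np.zeros(m)
        z = mu + L @ rng.standard_normal(m)
        return _records_from_z(z, ld, n)

    spec_ = {
        "H0": (None, None),
        "H1": (j1, None),
        "H2": (None, j1),
        "H3": (j1, j2),
        "H4": (j1, j1),
    }[scenario]
    return draw(spec_[0], n1), draw(spec_[1], n2)


def simulate_mr_set(
    k: int,
    alpha: float,
    pleiotropy_sd: float = 0.0,
    n_exp: float = 35_000,
    n_out: float = 230_000,
    seed: int = 0,
    beta_sd: float = 0.15,
    p_select: float = GWAS_P_THRESHOLD,
) -> tuple[list[Instrument], SimTruth]:
    """Independent MR instruments with a known causal effect.

    True per-variant exposure effects are N(0, beta_sd^2); observed exposure
    estimates carry sampling noise (se = 1/sqrt(n_exp)) and a variant is kept
    only when its observed p-value passes ``p_select``, mimicking instrument
    selection. Outcome effects are alpha * true_beta plus a direct
    (pleiotropic) effect N(0, pleiotropy_sd^2) plus sampling noise.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    se_exp = 1.0 / np.sqrt(n_exp)
    se_out = 1.0 / np.sqrt(n_out)
    z_thresh = stats.norm.isf(p_select / 2.0)

    true_betas = np.empty(k)
    insts: list[Instrument] = []
    for j in range(k):
        while True:
            b_true = rng.normal(0.0, beta_sd)
            b_hat = b_true + rng.normal(0.0, se_exp)
            if abs(b_hat) / se_exp > z_thresh:
                break
        pleio = rng.normal(0.0, pleiotropy_sd) if pleiotropy_sd > 0 else 0.0
        bo_hat = alpha * b_true + pleio + rng.normal(0.0, se_out)
        true_betas[j] = b_true
        insts.append(
            Instrument(
                snp_id=f"iv{j + 1:03d}",
                beta_exp=b_hat,
                se_exp=se_exp,
                beta_out=bo_hat,
                se_out=se_out,
                n_exp=n_exp,
                n_out=n_out,
            )
        )
    truth = SimTruth(
        feature_id="mr_set",
        alpha=alpha,
        true_weights=true_betas,
        causal_snps=tuple(range(k)),
        seed=seed,
    )
    return insts, truth


# ---------------------------------------------------------------------------
# full multi-layer study scenario


@dataclass
class StudyTruth:
    """Which simulated features truly affect the outcome, and how strongly."""

    causal_features: tuple[str, ...]
    alpha: float
    per_feature: dict[str, SimTruth] = field(default_factory=dict)


def simulate_study(
    seed: int,
    n_features: int = 20,
    n_causal: int = 2,
    m: int = DEFAULT_M,
    rho: float = DEFAULT_RHO,
    alpha: float = 0.025,
    n_gwas: float = DEFAULT_N_GWAS,
    n_qtl: Optional[dict[str, float]] = None,
    layers: Sequence[str] = LAYERS,
    outcome: str = "overall",
):
    """A complete three-layer synthetic study with known causal features.

    Each feature occupies its own cis window (AR(1) LD, one causal cis-SNP —
    the single-pQTL regime that dominates plasma-protein data). Causal
    features carry a feature-level effect ``alpha`` (log-OR per SD) on the
    outcome, transmitted through their cis-SNP; null features' windows hold
    pure LD noise. Per-layer QTL statistics share the causal SNP, so a causal
    feature shows a colocalizing signal in every layer.

    Returns ``(StudyData, StudyTruth)``; ``StudyData`` is defined in
    :mod:`ptmr.pipeline`.
    """
    from .pipeline import StudyData  # late import to avoid a cycle

    n_qtl = dict(DEFAULT_N_QTL if n_qtl is None else n_qtl)
    # expected causal-SNP QTL |z| per layer: cis effects are strong
    qtl_z = {"plasma_pwas": 12.0, "blood_twas": 16.0, "breast_twas": 9.0}

    rng = np.random.default_rng(seed)
    features = [f"FEAT{i + 1:03d}" for i in range(n_features)]
    causal = tuple(features[:n_causal])

    gwas: list[SnpAssoc] = []
    weights: dict[str, list[WeightModel]] = {layer: [] for layer in layers}
    qtl: dict[tuple[str, str], list[SnpAssoc]] = {}
    ld_by_feature: dict[str, LdMatrix] = {}
    per_feature: dict[str, SimTruth] = {}

    base_ld = simulate_ld(m, rho)
    for fi, feat in enumerate(features):
        chrom = str(fi % 22 + 1)
        pos0 = 1_000_000 * (fi + 1)
        snp_ids = [f"{feat}_s{j + 1:03d}" for j in range(m)]
        ld = LdMatrix(snp_ids, base_ld.r)
        ld_by_feature[feat] = ld

        j_causal = int(rng.integers(m))
        w = np.zeros(m)
        w[j_causal] = 1.0
        a = alpha if feat in causal else 0.0
        per_feature[feat] = SimTruth(feat, a, w.copy(), (j_causal,), seed=seed)

        gwas.extend(
            simulate_feature_gwas(
                ld,
                w,
                a,
                n_gwas,
                seed=int(rng.integers(2**31)),
                chrom=chrom,
                pos0=pos0,
                ncase=DEFAULT_N_CASE,
                ncontrol=DEFAULT_N_CONTROL,
            )
        )
        for layer in layers:
            qtl[(feat, layer)] = _qtl_records(
                ld, (j_causal,), qtl_z[layer], n_qtl[layer], rng, chrom=chrom, pos0=pos0
            )
            weights[layer].append(
                WeightModel(
                    feature_id=feat,
                    layer=layer,
                    snp_ids=[snp_ids[j_causal]],
                    weights=np.array([1.0]),
                    ld=ld.subset([snp_ids[j_causal]]),
                )
            )

    data = StudyData(
        gwas={outcome: gwas},
        weights=weights,
        qtl=qtl,
        ld=ld_by_feature,
    )
    return data, StudyTruth(causal_features=causal, alpha=alpha, per_feature=per_feature)
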