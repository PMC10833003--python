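"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import math

import numpy as np
import pytest

from ptmr.types import Instrument, SnpAssoc


def make_snp(
    snp_id: str = "rs1",
    beta: float = 0.1,
    se: float = 0.05,
    chrom: str = "1",
    pos: int = 100_000,
    ea: str = "A",
    oa: str = "G",
    **kw,
) -> SnpAssoc:
    return SnpAssoc(
        snp_id=snp_id,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        beta=beta,
        se=se,
        **kw,
    )


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; never share code with the package)


def coloc_enumeration_oracle(l1, l2, p1=1e-4, p2=1e-4, p12=1e-5):
    """Posterior hypothesis probabilities by exhaustive causal-configuration
    enumeration in linear space: 1 null config, m single-trait configs per
    trait, m(m-1) two-distinct-SNP configs, m shared-SNP configs."""
    a1 = np.exp(np.asarray(l1, dtype=float))
    a2 = np.exp(np.asarray(l2, dtype=float))
    m = len(a1)
    s = np.zeros(5)
    s[0] = 1.0
    for i in range(m):
        s[1] += p1 * a1[i]
        s[2] += p2 * a2[i]
        s[4] += p12 * a1[i] * a2[i]
        for j in range(m):
            if j != i:
                s[3] += p1 * p2 * a1[i] * a2[j]
    return s / s.sum()


def wls_through_origin_oracle(bx, by, se_out):
    """Weighted least squares of by on bx through the origin, weights 1/se_out^2
    after scaling both sides by 1/bx — algebraically the ratio meta-analysis."""
    bx, by, se_out = map(np.asarray, (bx, by, se_out))
    w = 1.0 / se_out**2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se = float(1.0 / math.sqrt(np.sum(w * bx**2)))
    return beta, se


def wls_with_intercept_oracle(bx, by, se_out):
    """Generic weighted regression via statsmodels; returns (intercept, slope)
    point estimates and the weighted residual dispersion."""
    import statsmodels.api as sm

    X = sm.add_constant(np.asarray(bx))
    fit = sm.WLS(np.asarray(by), X, weights=1.0 / np.asarray(se_out) ** 2).fit()
    return float(fit.params[0]), float(fit.params[1]), float(fit.scale)


def make_instruments(bx, by, se_exp=0.01, se_out=0.02, n_exp=None, n_out=None):
    return [
        Instrument(
            snp_id=f"iv{i}",
            beta_exp=float(x),
            se_exp=se_exp,
            beta_out=float(y),
            se_out=se_out,
            n_exp=n_exp,
            n_out=n_out,
        )
        for i, (x, y) in enumerate(zip(bx, by))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240118)
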