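"""Core summary-statistics containers shared across the pipeline.

Everything downstream — the association screen, colocalization, tiering and
Mendelian randomization — consumes per-variant marginal statistics
(beta, se, z, p, n), per-feature cis weight vectors, and an LD correlation
matrix over the cis window. These three containers are the atoms.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["SnpAssoc", "LdMatrix", "WeightModel", "Instrument", "LAYERS"]

#: recognised evidence layers, in the order they are scored
LAYERS = ("plasma_pwas", "blood_twas", "breast_twas")

_VALID_ALLELES = frozenset("ACGT")

# tolerances for internal consistency of stored statistics
_Z_RTOL = 1e-8
_P_ATOL = 1e-6


@dataclass
class SnpAssoc:
    """One variant's marginal association statistics for one trait.

    ``beta`` is the additive effect per copy of ``effect_allele`` (log-odds
    ratio for binary outcomes); ``zscore`` and ``pvalue`` are back-filled
    from (beta, se) when absent. Positions are 1-based; chromosome labels
    are plain strings without a "chr" prefix.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: Optional[float] = None
    pvalue: Optional[float] = None
    zscore: Optional[float] = None
    n: Optional[float] = None
    ncase: Optional[int] = None
    ncontrol: Optional[int] = None

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()
        self._backfill()

    def _backfill(self) -> None:
        if self.zscore is None and self.se:
            self.zscore = self.beta / self.se
        if self.pvalue is None and self.zscore is not None:
            self.pvalue = float(2.0 * stats.norm.sf(abs(self.zscore)))

    def validate(self) -> None:
        """Raise ``ValueError`` when any stored-field invariant is broken."""
        if self.effect_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: bad effect allele {self.effect_allele!r}")
        if self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: bad other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValueError(f"{self.snp_id}: se must be positive, got {self.se}")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.snp_id}: non-finite beta")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.snp_id}: eaf {self.eaf} outside [0,1]")
        if self.zscore is not None:
            expect = self.beta / self.se
            if abs(self.zscore - expect) > _Z_RTOL * max(1.0, abs(expect)):
                raise ValueError(
                    f"{self.snp_id}: zscore {self.zscore} inconsistent with beta/se {expect}"
                )
        if self.pvalue is not None:
            if not (0.0 < self.pvalue <= 1.0):
                raise ValueError(f"{self.snp_id}: pvalue {self.pvalue} outside (0,1]")
            if self.zscore is not None:
                expect_p = float(2.0 * stats.norm.sf(abs(self.zscore)))
                if abs(self.pvalue - expect_p) > _P_ATOL:
                    raise ValueError(
                        f"{self.snp_id}: pvalue {self.pvalue} inconsistent with z ({expect_p})"
                    )

    @property
    def z(self) -> float:
        return self.beta / self.se if self.zscore is None else self.zscore

    def copy(self, **changes) -> "SnpAssoc":
        return replace(self, **changes)


@dataclass
class LdMatrix:
    """Pairwise allelic correlations (r, not r²) over an ordered SNP list."""

    snp_ids: list[str]
    r: np.ndarray

    _SYM_TOL = 1e-10
    _PSD_TOL = 1e-8

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("LD matrix must be square")
        if len(self.snp_ids) != self.r.shape[0]:
            raise ValueError("snp_ids length does not match matrix dimension")

    def validate(self) -> None:
        if not np.allclose(self.r, self.r.T, atol=self._SYM_TOL):
            raise ValueError("LD matrix not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1.0 + 1e-10):
            raise ValueError("LD entries must lie in [-1, 1]")
        if np.linalg.eigvalsh(self.r).min() < -self._PSD_TOL:
            raise ValueError("LD matrix is not positive semi-definite")

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    def index(self, snp_ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([pos[s] for s in snp_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"SNP {exc.args[0]} absent from LD panel") from None

    def subset(self, snp_ids: Sequence[str]) -> "LdMatrix":
        idx = self.index(snp_ids)
        return LdMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])


@dataclass
class WeightModel:
    """A feature's cis-SNP weight vector w plus its LD reference.

    The weighted combination w'x of cis genotypes predicts the feature
    (a plasma protein or a transcript); the association screen turns the
    weights plus GWAS z-scores into a feature-level Z-statistic.
    """

    feature_id: str
    layer: str
    snp_ids: list[str]
    weights: np.ndarray
    ld: LdMatrix

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if len(self.snp_ids) != len(set(self.snp_ids)):
            raise ValueError(f"{self.feature_id}: duplicate SNP ids in weight model")
        if self.weights.shape != (len(self.snp_ids),):
            raise ValueError(f"{self.feature_id}: weights/snp_ids length mismatch")
        if not np.any(self.weights != 0.0):
            raise ValueError(f"{self.feature_id}: all weights are zero")


@dataclass
class Instrument:
    """A harmonized exposure/outcome pair for one instrumental variant.

    Effects on both sides are oriented to the same exposure effect allele;
    harmonization happens upstream (``ptmr.io.align_alleles``).
    """

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    p_exp: Optional[float] = None
    p_out: Optional[float] = None
    n_exp: Optional[float] = None
    n_out: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ValueError(f"{self.snp_id}: standard errors must be positive")

    @property
    def z_exp(self) -> float:
        return self.beta_exp / self.se_exp

    @property
    def z_out(self) -> float:
        return self.beta_out / self.se_out
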