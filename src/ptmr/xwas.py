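"""Feature-level association screen from cis weights and GWAS z-scores.

Given a feature's cis-SNP weight vector w, the GWAS z-scores z at those SNPs
and the LD correlation matrix R of the reference panel, the imputed
feature-trait association statistic is

    Z = w' z / sqrt(w' R w)

which is standard normal when the feature has no effect on the trait. Each
evidence layer (plasma proteome, whole-blood transcriptome, tissue
transcriptome) is screened separately, duplicate measurements of the same
feature (e.g. multiple aptamers per protein) are collapsed to the smallest
unadjusted p-value, and Benjamini-Hochberg FDR is applied across the
collapsed features of the layer.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import SnpAssoc, WeightModel

logger = logging.getLogger(__name__)

__all__ = ["XwasResult", "xwas_z", "bh_adjust", "run_layer"]

_DEGENERATE_TOL = 1e-12


@dataclass
class XwasResult:
    """One feature-outcome association from the weighted-burden statistic."""

    feature_id: str
    layer: str
    outcome: str
    zscore: float
    pvalue: float
    n_snps_used: int
    p_fdr: Optional[float] = None

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_fdr is not None and self.p_fdr < alpha


def xwas_z(w: WeightModel, gwas: Iterable[SnpAssoc], outcome: str = "") -> XwasResult:
    """Feature association Z-statistic Z = w'z / sqrt(w'Rw).

    Weighted SNPs missing from the GWAS are dropped jointly from w and R
    (weights are NOT renormalized on the surviving subset); dropping all of
    them is an error, as is a degenerate predictor variance w'Rw <= 1e-12.
    """
    by_id = {r.snp_id: r for r in gwas}
    keep, z = [], []
    for i, sid in enumerate(w.snp_ids):
        rec = by_id.get(sid)
        if rec is None:
            continue
        keep.append(i)
        z.append(rec.z)
    if not keep:
        raise ValueError(f"{w.feature_id}: no weighted SNP present in the GWAS")
    if len(keep) < len(w.snp_ids):
        logger.info(
            "%s: %d of %d weighted SNPs missing from GWAS",
            w.feature_id,
            len(w.snp_ids) - len(keep),
            len(w.snp_ids),
        )
    idx = np.asarray(keep, dtype=int)
    wv = w.weights[idx]
    sub = w.ld.subset([w.snp_ids[i] for i in keep])
    wrw = float(wv @ sub.r @ wv)
    if wrw <= _DEGENERATE_TOL:
        raise ValueError(f"{w.feature_id}: degenerate predictor variance w'Rw = {wrw:g}")
    zstat = float(wv @ np.asarray(z) / np.sqrt(wrw))
    return XwasResult(
        feature_id=w.feature_id,
        layer=w.layer,
        outcome=outcome,
        zscore=zstat,
        pvalue=float(2.0 * stats.norm.sf(abs(zstat))),
        n_snps_used=len(keep),
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_layer(
    weights: Sequence[WeightModel],
    gwas: Iterable[SnpAssoc],
    outcome: str = "",
) -> list[XwasResult]:
    """Screen one layer: per-feature Z, duplicate collapse, BH across features.

    When several weight models share a feature_id (duplicate aptamers/probes)
    only the one with the smallest unadjusted p is retained before the FDR
    adjustment.
    """
    if not weights:
        raise ValueError("run_layer: no weight models")
    gwas = list(gwas)
    best: dict[str, XwasResult] = {}
    for w in weights:
        try:
            res = xwas_z(w, gwas, outcome=outcome)
        except ValueError as exc:
            logger.warning("run_layer: skipping %s (%s)", w.feature_id, exc)
            continue
        cur = best.get(w.feature_id)
        if cur is None or res.pvalue < cur.pvalue:
            best[w.feature_id] = res
    results = list(best.values())
    if results:
        adj = bh_adjust([r.pvalue for r in results])
        for r, a in zip(results, adj):
            r.p_fdr = float(a)
    return results
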