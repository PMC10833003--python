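"""Evidence-tier scoring of features across association layers.

Each evidence layer (plasma proteome, whole-blood transcriptome, tissue
transcriptome) can contribute up to two points for a feature: one for a
significant BH-adjusted association p-value (< 0.05) and one for strong
colocalization evidence (PPH4 > 0.75, strict). The 0-6 total maps to a tier:

    0 -> None, 1-2 -> Weak, 3-4 -> Moderate, 5-6 -> Strong

A separate cross-layer direction check flags features whose significant
layers disagree in sign with the plasma layer; such features keep their
score and tier but are excluded from causal (MR) follow-up.

The module ships a verbatim transcription of a published 25-protein
breast-cancer evidence table (``data/table2.tsv``) used as a worked example:
applying the scoring rule to its per-layer values reproduces its printed
score and tier columns exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import LAYERS

__all__ = [
    "TierRecord",
    "score_feature",
    "direction_consistency",
    "tier_table",
    "load_table2",
    "score_table",
    "TIER_NAMES",
]

TIER_NAMES = ("None", "Weak", "Moderate", "Strong")

#: mapping from total score to tier label
_TIER_BY_SCORE = {0: "None", 1: "Weak", 2: "Weak", 3: "Moderate", 4: "Moderate", 5: "Strong", 6: "Strong"}


@dataclass
class TierRecord:
    """Per-feature evidence points, total score, tier and direction flag."""

    feature_id: str
    outcome: str
    layer_points: dict = field(default_factory=dict)  # layer -> (assoc, coloc)
    score: int = 0
    tier: str = "None"
    direction_consistent: Optional[bool] = None

    @property
    def mr_eligible(self) -> bool:
        """Tier gate for causal follow-up: Strong/Moderate and not sign-discordant."""
        return self.tier in ("Strong", "Moderate") and self.direction_consistent is not False


def _tier_for(score: int) -> str:
    try:
        return _TIER_BY_SCORE[score]
    except KeyError:
        raise ValueError(f"score {score} outside 0-6") from None


def score_feature(
    feature_id: str,
    assoc: Mapping[str, Tuple[float, float]],
    colocs: Mapping[str, float],
    outcome: str = "",
    alpha: float = 0.05,
    pph4_threshold: float = 0.75,
) -> TierRecord:
    """Score one feature from its per-layer evidence.

    ``assoc`` maps layer -> (BH-adjusted p, association z-score) for layers
    with data; ``colocs`` maps layer -> PPH4. Per layer: +1 if p_fdr < alpha,
    +1 if PPH4 > pph4_threshold (strict). Absent layers contribute nothing.
    The plasma layer must be present; p_fdr values must lie in (0, 1].
    """
    if "plasma_pwas" not in assoc:
        raise ValueError(f"{feature_id}: plasma layer evidence is required")
    points: dict[str, tuple[int, int]] = {}
    total = 0
    for layer in LAYERS:
        if layer not in assoc and layer not in colocs:
            continue
        assoc_pt = 0
        if layer in assoc:
            p_fdr = float(assoc[layer][0])
            if not (0.0 < p_fdr <= 1.0) or math.isnan(p_fdr):
                raise ValueError(f"{feature_id}/{layer}: p_fdr {p_fdr} outside (0,1]")
            assoc_pt = int(p_fdr < alpha)
        coloc_pt = 0
        if layer in colocs and colocs[layer] is not None:
            coloc_pt = int(float(colocs[layer]) > pph4_threshold)
        points[layer] = (assoc_pt, coloc_pt)
        total += assoc_pt + coloc_pt

    zscores = {lay: float(v[1]) for lay, v in assoc.items() if v[1] is not None and not math.isnan(float(v[1]))}
    significant = {lay: float(v[0]) < alpha for lay, v in assoc.items()}
    return TierRecord(
        feature_id=feature_id,
        outcome=outcome,
        layer_points=points,
        score=total,
        tier=_tier_for(total),
        direction_consistent=direction_consistency(zscores, significant),
    )


def direction_consistency(
    zscores: Mapping[str, float],
    significant: Optional[Mapping[str, bool]] = None,
) -> Optional[bool]:
    """Do all significant layers agree in sign with the plasma layer?

    Returns None (not assessable) when only one layer is present. Layers
    marked non-significant are ignored — an insignificant z carries no
    directional evidence. When ``significant`` is omitted every present
    layer is treated as significant.
    """
    if "plasma_pwas" not in zscores:
        raise ValueError("plasma-layer z-score is required")
    if len(zscores) < 2:
        return None
    ref = np.sign(zscores["plasma_pwas"])
    for layer, z in zscores.items():
        if layer == "plasma_pwas":
            continue
        if significant is not None and not significant.get(layer, True):
            continue
        if np.sign(z) != ref:
            return False
    return True


def tier_table(records: Sequence[TierRecord]) -> dict[str, int]:
    """Counts of features per tier; values sum to ``len(records)``."""
    counts = {name: 0 for name in TIER_NAMES}
    for r in records:
        counts[r.tier] += 1
    return counts


# ---------------------------------------------------------------------------
# packaged worked-example table

_LAYER_PREFIX = {"plasma_pwas": "plasma", "blood_twas": "blood", "breast_twas": "breast"}


def load_table2() -> pd.DataFrame:
    """The packaged 25-protein evidence table (one row per protein).

    Adjusted p-values are printed to four decimals in the source table, so an
    exactly-zero entry is a display-rounded tiny value; the loader maps such
    zeros to the smallest positive float (any value below 5e-5 scores
    identically).
    """
    with resources.files("ptmr.data").joinpath("table2.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    for col in ("plasma_p_fdr", "blood_p_fdr", "breast_p_fdr"):
        df[col] = df[col].where(df[col] != 0.0, np.finfo(float).tiny)
    return df


def score_table(
    df: pd.DataFrame,
    outcome: str = "overall",
    alpha: float = 0.05,
    pph4_threshold: float = 0.75,
) -> list[TierRecord]:
    """Apply the scoring rule to a per-feature evidence table.

    Expects the ``load_table2`` column layout: per layer a z-score, adjusted
    p and PPH4 column with prefixes plasma/blood/breast; missing cells mark
    absent layers.
    """
    records = []
    for row in df.itertuples(index=False):
        assoc: dict[str, tuple[float, float]] = {}
        colocs: dict[str, float] = {}
        for layer, pre in _LAYER_PREFIX.items():
            p = getattr(row, f"{pre}_p_fdr")
            if p is None or (isinstance(p, float) and math.isnan(p)):
                continue
            assoc[layer] = (float(p), float(getattr(row, f"{pre}_z")))
            pph4 = getattr(row, f"{pre}_pph4")
            if pph4 is not None and not math.isnan(float(pph4)):
                colocs[layer] = float(pph4)
        records.append(
            score_feature(
                str(row.gene),
                assoc,
                colocs,
                outcome=outcome,
                alpha=alpha,
                pph4_threshold=pph4_threshold,
            )
        )
    return records
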