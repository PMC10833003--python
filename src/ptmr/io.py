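"""Readers/writers for the tab-separated dialects used across the pipeline,
plus allele harmonization between summary-statistics sources.

All tabular artifacts are TSV with a header row. Summary-statistics files may
come in arbitrary column dialects; a dialect is a mapping from canonical field
names (``snp_id``, ``chrom``, ``pos``, ``effect_allele``, ``other_allele``,
``eaf``, ``beta``, ``se``, ``pvalue``, ``zscore``, ``n``, ``ncase``,
``ncontrol``) to the column names actually present. Rows violating the
per-record invariants are dropped and counted in the module log rather than
aborting the read — real summary files are dirty.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import Instrument, LdMatrix, SnpAssoc, WeightModel

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_DIALECT",
    "read_sumstats",
    "write_sumstats",
    "write_report",
    "read_records",
    "read_ld",
    "write_ld",
    "read_weights",
    "write_weights",
    "align_alleles",
    "harmonize_pairs",
]

#: identity dialect: canonical field name -> column name
DEFAULT_DIALECT: dict[str, str] = {
    f.name: f.name for f in dataclasses.fields(SnpAssoc)
}

_MANDATORY = ("snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: allele-frequency window inside which a palindromic (A/T or C/G) variant's
#: strand cannot be resolved from frequency
PALINDROMIC_EAF_WINDOW = (0.42, 0.58)


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def read_sumstats(path, dialect: Optional[Mapping[str, str]] = None) -> list[SnpAssoc]:
    """Read a summary-statistics TSV into validated :class:`SnpAssoc` records.

    Missing ``zscore``/``pvalue`` are back-filled from (beta, se); rows whose
    stored fields contradict each other beyond tolerance, or that violate any
    record invariant, are dropped with a logged count. Raises ``ValueError``
    when a mandatory column is absent or no valid row remains.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    df = pd.read_csv(path, sep="\t", dtype={dialect["chrom"]: str, dialect["snp_id"]: str})
    for field in _MANDATORY:
        if dialect[field] not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {dialect[field]!r}")

    records: list[SnpAssoc] = []
    dropped = 0
    for row in df.itertuples(index=False):
        row = row._asdict()
        try:
            rec = SnpAssoc(
                snp_id=str(row[dialect["snp_id"]]),
                chrom=str(row[dialect["chrom"]]),
                pos=int(row[dialect["pos"]]),
                effect_allele=row[dialect["effect_allele"]],
                other_allele=row[dialect["other_allele"]],
                beta=float(row[dialect["beta"]]),
                se=float(row[dialect["se"]]),
                eaf=_opt(row.get(dialect.get("eaf", "eaf"))),
                pvalue=_opt(row.get(dialect.get("pvalue", "pvalue"))),
                zscore=_opt(row.get(dialect.get("zscore", "zscore"))),
                n=_opt(row.get(dialect.get("n", "n"))),
            )
            rec.validate()
        except (ValueError, TypeError) as exc:
            logger.info("dropping row %s: %s", row.get(dialect["snp_id"], "?"), exc)
            dropped += 1
            continue
        records.append(rec)
    if dropped:
        logger.warning("read_sumstats(%s): dropped %d invalid row(s)", path, dropped)
    if not records:
        raise ValueError(f"{path}: no valid summary-statistic rows")
    return records


def write_sumstats(records: Sequence[SnpAssoc], path) -> None:
    write_report(records, path)


def write_report(records: Sequence, path) -> None:
    """Write any list of result dataclasses as a TSV with stable column order.

    Floats are written at full precision so write-then-read round-trips
    reproduce values to 1e-12. Empty input is an error.
    """
    records = list(records)
    if not records:
        raise ValueError("write_report: empty record list")
    rows = [_as_flat_dict(r) for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _as_flat_dict(rec) -> dict:
    if dataclasses.is_dataclass(rec):
        out = {}
        for f in dataclasses.fields(rec):
            v = getattr(rec, f.name)
            if isinstance(v, (np.ndarray, LdMatrix)):
                continue  # matrix payloads have their own sidecar format
            if isinstance(v, dict):
                for k, sub in v.items():
                    if isinstance(sub, (tuple, list)):
                        for i, s in enumerate(sub):
                            out[f"{k}_{i}"] = s
                    else:
                        out[str(k)] = sub
            else:
                out[f.name] = v
        return out
    if isinstance(rec, Mapping):
        return dict(rec)
    raise TypeError(f"cannot serialise record of type {type(rec)!r}")


def read_records(path, cls) -> list:
    """Read a :func:`write_report` TSV back into dataclass instances of ``cls``.

    Only columns matching ``cls`` field names are used; NaN becomes None.
    """
    df = pd.read_csv(path, sep="\t")
    names = {f.name for f in dataclasses.fields(cls)}
    str_fields = {
        f.name for f in dataclasses.fields(cls) if f.type in ("str", str)
    }
    out = []
    for row in df.to_dict(orient="records"):
        kw = {}
        for k, v in row.items():
            if k not in names:
                continue
            if isinstance(v, float) and np.isnan(v):
                v = None
            elif k in str_fields:
                v = str(v)
            kw[k] = v
        out.append(cls(**kw))
    return out


def write_ld(ld: LdMatrix, path) -> None:
    """Square TSV; header and index column carry the SNP ids."""
    pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep="\t", index_label="snp_id"
    )


def read_ld(path) -> LdMatrix:
    df = pd.read_csv(path, sep="\t", index_col="snp_id")
    ld = LdMatrix(list(df.columns), df.to_numpy(dtype=float))
    ld.validate()
    return ld


def write_weights(models: Sequence[WeightModel], path) -> None:
    """Long-format TSV: one row per (feature, layer, SNP, weight)."""
    rows = [
        {"feature_id": m.feature_id, "layer": m.layer, "snp_id": s, "weight": w}
        for m in models
        for s, w in zip(m.snp_ids, m.weights)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_weights(path, ld: LdMatrix) -> list[WeightModel]:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "feature_id": str})
    models = []
    for (feat, layer), grp in df.groupby(["feature_id", "layer"], sort=False):
        models.append(
            WeightModel(
                feature_id=str(feat),
                layer=str(layer),
                snp_ids=[str(s) for s in grp["snp_id"]],
                weights=grp["weight"].to_numpy(dtype=float),
                ld=ld.subset([str(s) for s in grp["snp_id"]]),
            )
        )
    return models


# ---------------------------------------------------------------------------
# allele harmonization


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def _flip(b: SnpAssoc, ea: str, oa: str) -> SnpAssoc:
    return b.copy(
        effect_allele=ea,
        other_allele=oa,
        beta=-b.beta,
        zscore=None if b.zscore is None else -b.zscore,
        eaf=None if b.eaf is None else 1.0 - b.eaf,
    )


def align_alleles(a: SnpAssoc, b: SnpAssoc) -> tuple[SnpAssoc, str]:
    """Orient ``b``'s effect to ``a``'s effect allele.

    Returns ``(b_harmonized, status)`` with status one of ``ok`` (already
    aligned), ``flipped`` (b's alleles were swapped: beta sign and eaf
    flipped), ``complemented`` / ``complemented_flipped`` (opposite strand
    resolved via base complements), ``palindromic`` (A/T or C/G variant whose
    orientation cannot be resolved — allele frequency missing or within
    ``PALINDROMIC_EAF_WINDOW``), or ``incompatible`` (allele sets
    irreconcilable even after complementing). The last two are flags, not
    errors; callers drop such variants.
    """
    if a.snp_id != b.snp_id:
        raise ValueError(f"align_alleles: mismatched snp ids {a.snp_id}/{b.snp_id}")
    ea, oa = a.effect_allele, a.other_allele

    if _is_palindromic(ea, oa):
        if {b.effect_allele, b.other_allele} != {ea, oa}:
            return b, "incompatible"
        lo, hi = PALINDROMIC_EAF_WINDOW
        if a.eaf is None or b.eaf is None or lo <= a.eaf <= hi or lo <= b.eaf <= hi:
            return b, "palindromic"
        # resolve orientation by frequency: the effect alleles correspond when
        # both frequencies sit on the same side of 0.5
        same_side = (a.eaf - 0.5) * (b.eaf - 0.5) > 0
        matches = b.effect_allele == ea
        if same_side == matches:
            return (b if matches else b.copy(effect_allele=ea, other_allele=oa)), "ok"
        return _flip(b, ea, oa), "flipped"

    if (b.effect_allele, b.other_allele) == (ea, oa):
        return b, "ok"
    if (b.effect_allele, b.other_allele) == (oa, ea):
        return _flip(b, ea, oa), "flipped"
    cea = _COMPLEMENT.get(b.effect_allele)
    coa = _COMPLEMENT.get(b.other_allele)
    if (cea, coa) == (ea, oa):
        return b.copy(effect_allele=ea, other_allele=oa), "complemented"
    if (cea, coa) == (oa, ea):
        return _flip(b.copy(effect_allele=coa, other_allele=cea), ea, oa), "complemented_flipped"
    return b, "incompatible"


def harmonize_pairs(
    exposure: Iterable[SnpAssoc], outcome: Iterable[SnpAssoc]
) -> list[Instrument]:
    """Intersect two summary-statistics sets on snp_id and harmonize alleles.

    Variants flagged palindromic/incompatible are dropped (logged).
    """
    out_by_id = {r.snp_id: r for r in outcome}
    insts: list[Instrument] = []
    dropped = 0
    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            continue
        out_h, status = align_alleles(exp, out)
        if status in ("palindromic", "incompatible"):
            dropped += 1
            logger.info("harmonize: dropping %s (%s)", exp.snp_id, status)
            continue
        insts.append(
            Instrument(
                snp_id=exp.snp_id,
                beta_exp=exp.beta,
                se_exp=exp.se,
                p_exp=exp.pvalue,
                n_exp=exp.n,
                beta_out=out_h.beta,
                se_out=out_h.se,
                p_out=out_h.pvalue,
                n_out=out_h.n,
            )
        )
    if dropped:
        logger.warning("harmonize_pairs: dropped %d non-harmonizable variant(s)", dropped)
    return insts
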