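"""End-to-end orchestration of the two-phase discovery-confirmatory analysis.

Phase one (association): per outcome and evidence layer, the weighted-burden
screen with BH-FDR, then Bayesian colocalization of every significant
feature's QTL signal with the outcome GWAS, then evidence-tier scoring.
Phase two (causation): tier-gated two-sample MR with sensitivity columns and
optional external-cohort replication. Each outcome runs independently; a
hard failure in one outcome is logged and the others continue.

Inputs can be supplied as an in-memory :class:`StudyData` (the synthetic
generator's output) or as TSV paths listed in a YAML run configuration.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as ptio
from .coloc import ColocPriors, ColocResult, colocalize
from .mr import MrResult, run_mr, replicate
from .tiering import TierRecord, score_feature, tier_table
from .types import LAYERS, LdMatrix, SnpAssoc, WeightModel
from .xwas import XwasResult, run_layer

logger = logging.getLogger(__name__)

__all__ = ["StudyData", "Thresholds", "RunConfig", "validate_config", "run_study", "run_all", "ReportBundle"]


@dataclass
class StudyData:
    """All inputs for one study, keyed by outcome, layer and feature."""

    gwas: dict[str, list[SnpAssoc]]                     # outcome -> GWAS records
    weights: dict[str, list[WeightModel]]               # layer -> weight models
    qtl: dict[tuple[str, str], list[SnpAssoc]]          # (feature, layer) -> QTL records
    ld: dict[str, LdMatrix]                             # feature -> cis LD panel
    validation_qtl: dict[str, dict[str, list[SnpAssoc]]] = field(default_factory=dict)
    # cohort name -> feature -> QTL records (plasma layer, external replication)


@dataclass
class Thresholds:
    alpha_fdr: float = 0.05
    pph4: float = 0.75
    p_instr: float = 5e-8
    p_fallback: float = 5e-6
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0

    def validate(self) -> None:
        for name, lo, hi in (
            ("alpha_fdr", 0.0, 1.0),
            ("pph4", 0.0, 1.0),
            ("p_instr", 0.0, 1.0),
            ("p_fallback", 0.0, 1.0),
            ("clump_r2", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo < v < hi):
                raise ValueError(f"threshold {name}={v} outside ({lo}, {hi})")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be positive")


@dataclass
class RunConfig:
    """Typed, validated run configuration (YAML-backed)."""

    outcomes: dict[str, str]
    layers: dict[str, dict[str, str]]   # layer -> {"weights": path, "qtl": path}
    ld: str
    output_dir: str = "ptmr_out"
    thresholds: Thresholds = field(default_factory=Thresholds)
    coloc: ColocPriors = field(default_factory=ColocPriors)
    seed: int = 0
    validations: dict[str, str] = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        doc = {
            "outcomes": dict(self.outcomes),
            "layers": {k: dict(v) for k, v in self.layers.items()},
            "ld": self.ld,
            "output_dir": self.output_dir,
            "thresholds": dataclasses.asdict(self.thresholds),
            "coloc": dataclasses.asdict(self.coloc),
            "seed": self.seed,
            "validations": dict(self.validations),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


_KNOWN_KEYS = {"outcomes", "layers", "ld", "output_dir", "thresholds", "coloc", "seed", "validations"}


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Defaults are injected for absent threshold/prior keys; unknown top-level
    keys are warned about; missing referenced paths are a hard error listing
    the offending entry.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: configuration must be a YAML mapping")
    for key in doc:
        if key not in _KNOWN_KEYS:
            logger.warning("config %s: unknown key %r ignored", path, key)
    if "outcomes" not in doc or not doc["outcomes"]:
        raise ValueError(f"{path}: at least one outcome GWAS path is required")
    if "ld" not in doc:
        raise ValueError(f"{path}: an LD panel path is required")
    cfg = RunConfig(
        outcomes={str(k): str(v) for k, v in doc["outcomes"].items()},
        layers={
            str(k): {sk: str(sv) for sk, sv in v.items()}
            for k, v in doc.get("layers", {}).items()
        },
        ld=str(doc["ld"]),
        output_dir=str(doc.get("output_dir", "ptmr_out")),
        thresholds=Thresholds(**doc.get("thresholds", {})),
        coloc=ColocPriors(**doc.get("coloc", {})),
        seed=int(doc.get("seed", 0)),
        validations={str(k): str(v) for k, v in doc.get("validations", {}).items()},
    )
    cfg.thresholds.validate()
    base = Path(path).parent
    missing = []
    for name, p in cfg.outcomes.items():
        if not (base / p).exists() and not Path(p).exists():
            missing.append(f"outcome {name}: {p}")
    for layer, paths in cfg.layers.items():
        for kind, p in paths.items():
            if not (base / p).exists() and not Path(p).exists():
                missing.append(f"layer {layer} {kind}: {p}")
    if not (base / cfg.ld).exists() and not Path(cfg.ld).exists():
        missing.append(f"ld: {cfg.ld}")
    if missing:
        raise ValueError(f"{path}: missing input path(s): " + "; ".join(missing))
    return cfg


@dataclass
class OutcomeReport:
    """Per-outcome result tables plus drop accounting."""

    outcome: str
    xwas: list[XwasResult]
    colocs: list[ColocResult]
    tiers: list[TierRecord]
    mr: list[MrResult]
    replication: dict[str, str] = field(default_factory=dict)
    counts: dict = field(default_factory=dict)


@dataclass
class ReportBundle:
    outcomes: dict[str, OutcomeReport] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def summary(self) -> dict:
        out = {}
        for name, rep in self.outcomes.items():
            out[name] = {
                "tier_counts": tier_table(rep.tiers),
                "n_features_screened": len(rep.xwas),
                "n_significant_plasma": rep.counts.get("significant_plasma", 0),
                "n_coloc": len(rep.colocs),
                "n_mr": len(rep.mr),
                "n_mr_gated_out": rep.counts.get("mr_gated_out", 0),
                "replication": rep.replication,
            }
        if self.errors:
            out["errors"] = dict(self.errors)
        return out


def _analyse_outcome(
    outcome: str,
    data: StudyData,
    thresholds: Thresholds,
    priors: ColocPriors,
) -> OutcomeReport:
    gwas = data.gwas[outcome]
    gwas_by_id = {r.snp_id: r for r in gwas}

    # --- association screen, per layer ---------------------------------
    layer_results: dict[str, dict[str, XwasResult]] = {}
    all_xwas: list[XwasResult] = []
    for layer in LAYERS:
        models = data.weights.get(layer, [])
        if not models:
            continue
        results = run_layer(models, gwas, outcome=outcome)
        layer_results[layer] = {r.feature_id: r for r in results}
        all_xwas.extend(results)

    plasma = layer_results.get("plasma_pwas", {})
    significant_plasma = [
        f for f, r in plasma.items() if r.significant(thresholds.alpha_fdr)
    ]

    # --- colocalization for significant features, per layer ------------
    colocs: list[ColocResult] = []
    pph4: dict[tuple[str, str], float] = {}
    for layer, results in layer_results.items():
        for feat, res in results.items():
            if not res.significant(thresholds.alpha_fdr):
                continue
            qtl = data.qtl.get((feat, layer))
            if not qtl:
                continue
            locus_gwas = [gwas_by_id[s.snp_id] for s in qtl if s.snp_id in gwas_by_id]
            if not locus_gwas:
                continue
            cres = colocalize(
                qtl, locus_gwas, priors=priors, feature_id=feat, layer=layer, outcome=outcome
            )
            colocs.append(cres)
            pph4[(feat, layer)] = cres.pph4

    # --- tier scoring for plasma-significant features -------------------
    tiers: list[TierRecord] = []
    for feat in significant_plasma:
        assoc = {
            layer: (results[feat].p_fdr, results[feat].zscore)
            for layer, results in layer_results.items()
            if feat in results and results[feat].p_fdr is not None
        }
        cmap = {layer: pph4[(feat, layer)] for layer in LAYERS if (feat, layer) in pph4}
        tiers.append(
            score_feature(
                feat,
                assoc,
                cmap,
                outcome=outcome,
                alpha=thresholds.alpha_fdr,
                pph4_threshold=thresholds.pph4,
            )
        )

    # --- tier-gated MR ---------------------------------------------------
    mr_results: list[MrResult] = []
    gated_out = 0
    replication: dict[str, str] = {}
    for rec in sorted(tiers, key=lambda t: t.feature_id):
        if not rec.mr_eligible:
            gated_out += 1
            continue
        exposure = data.qtl.get((rec.feature_id, "plasma_pwas"))
        ld = data.ld.get(rec.feature_id)
        if exposure is None or ld is None:
            logger.warning("%s/%s: no exposure QTL or LD panel for MR", outcome, rec.feature_id)
            continue
        outcome_stats = [gwas_by_id[s.snp_id] for s in exposure if s.snp_id in gwas_by_id]
        res = run_mr(
            rec,
            exposure,
            outcome_stats,
            ld,
            outcome=outcome,
            p_primary=thresholds.p_instr,
            p_fallback=thresholds.p_fallback,
            clump_r2=thresholds.clump_r2,
            clump_window_kb=thresholds.clump_window_kb,
        )
        mr_results.append(res)
        if res.beta is not None and data.validation_qtl:
            vals = []
            for cohort, qtl_map in data.validation_qtl.items():
                vexp = qtl_map.get(rec.feature_id)
                if not vexp:
                    continue
                vout = [gwas_by_id[s.snp_id] for s in vexp if s.snp_id in gwas_by_id]
                vres = run_mr(
                    rec, vexp, vout, ld, outcome=outcome,
                    p_primary=thresholds.p_instr, p_fallback=thresholds.p_fallback,
                    clump_r2=thresholds.clump_r2, clump_window_kb=thresholds.clump_window_kb,
                )
                if vres.beta is not None:
                    vals.append(vres)
            if vals:
                replication[rec.feature_id] = replicate(res, vals)

    return OutcomeReport(
        outcome=outcome,
        xwas=all_xwas,
        colocs=colocs,
        tiers=tiers,
        mr=mr_results,
        replication=replication,
        counts={
            "significant_plasma": len(significant_plasma),
            "mr_gated_out": gated_out,
        },
    )


def run_study(
    data: StudyData,
    thresholds: Optional[Thresholds] = None,
    priors: Optional[ColocPriors] = None,
) -> ReportBundle:
    """Run both phases over every outcome of an in-memory study.

    A hard error in one outcome is recorded in ``bundle.errors`` and the
    remaining outcomes still run.
    """
    thresholds = thresholds or Thresholds()
    priors = priors or ColocPriors()
    bundle = ReportBundle()
    for outcome in data.gwas:
        try:
            bundle.outcomes[outcome] = _analyse_outcome(outcome, data, thresholds, priors)
        except Exception as exc:  # noqa: BLE001 - per-outcome isolation is the contract
            logger.error("outcome %s aborted: %s", outcome, exc)
            bundle.errors[outcome] = str(exc)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir) -> None:
    """Write tiers.tsv / mr.tsv / xwas.tsv / coloc.tsv + summary.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tiers, mrs, xw, cl = [], [], [], []
    for rep in bundle.outcomes.values():
        tiers.extend(rep.tiers)
        mrs.extend(rep.mr)
        xw.extend(rep.xwas)
        cl.extend(rep.colocs)
    if tiers:
        ptio.write_report(tiers, out / "tiers.tsv")
    if mrs:
        ptio.write_report(mrs, out / "mr.tsv")
    if xw:
        ptio.write_report(xw, out / "xwas.tsv")
    if cl:
        ptio.write_report(cl, out / "coloc.tsv")
    (out / "summary.json").write_text(json.dumps(bundle.summary(), indent=2, sort_keys=True))


def _load_layer_qtl(path) -> dict[str, list[SnpAssoc]]:
    """QTL TSV with a leading feature_id column -> per-feature records."""
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "snp_id": str, "chrom": str})
    out: dict[str, list[SnpAssoc]] = {}
    for feat, grp in df.groupby("feature_id", sort=False):
        recs = []
        for row in grp.to_dict(orient="records"):
            row.pop("feature_id")
            kw = {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in row.items()}
            rec = SnpAssoc(**kw)
            rec.validate()
            recs.append(rec)
        out[str(feat)] = recs
    return out


def load_study(cfg: RunConfig, base: Optional[Path] = None) -> StudyData:
    """Materialise a :class:`StudyData` from the paths in a run config."""
    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.exists() or base is None else base / p

    panel = ptio.read_ld(_resolve(cfg.ld))
    gwas = {name: ptio.read_sumstats(_resolve(p)) for name, p in cfg.outcomes.items()}
    weights: dict[str, list[WeightModel]] = {}
    qtl: dict[tuple[str, str], list[SnpAssoc]] = {}
    ld_by_feature: dict[str, LdMatrix] = {}
    for layer, paths in cfg.layers.items():
        models = ptio.read_weights(_resolve(paths["weights"]), panel)
        weights[layer] = models
        if "qtl" in paths:
            for feat, recs in _load_layer_qtl(_resolve(paths["qtl"])).items():
                qtl[(feat, layer)] = recs
                ld_by_feature.setdefault(feat, panel.subset([r.snp_id for r in recs]))
    validation: dict[str, dict[str, list[SnpAssoc]]] = {}
    for cohort, path in cfg.validations.items():
        validation[cohort] = _load_layer_qtl(_resolve(path))
    return StudyData(gwas=gwas, weights=weights, qtl=qtl, ld=ld_by_feature, validation_qtl=validation)


def run_all(config: RunConfig, config_dir: Optional[Path] = None) -> ReportBundle:
    """File-based entry point: load inputs, run both phases, write reports."""
    data = load_study(config, base=config_dir)
    bundle = run_study(data, thresholds=config.thresholds, priors=config.coloc)
    write_bundle(bundle, config.output_dir)
    return bundle
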