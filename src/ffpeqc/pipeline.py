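"""End-to-end QC pipeline: normalize -> metrics -> flag -> propagate,
with optional replicate statistics, threshold derivation and predictor
fitting, all driven by a single typed configuration."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as qio
from . import models as qpredict
from . import replicates as qreplicates
from .normalize import counts_to_tpm, tmm_log2cpm
from .qc import QCThresholds, compute_qc_metrics, flag_samples, propagate_batch_failure

logger = logging.getLogger("ffpeqc")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    counts: str = ""
    annotation: str = ""
    metadata: str = ""
    out_dir: str = "ffpeqc_out"
    cor_min: float = 0.75
    reads_min: int = 25_000_000
    tpm4_min: int = 11_400
    correlation_layer: str = "logCPM"  # or "TPM"
    loess_span: float = 0.75
    saturation_fraction: float = 0.85
    lfc_grid: tuple = (0.5, 1.0, 1.5, 2.0)
    cv_folds: int = 10
    cv_repeats: int = 3
    model: str = "cart"
    positive_class: str = "PASS"
    seed: int = 0
    run_replicate_stats: bool = True
    run_predictor: bool = True
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = {k: v for k, v in raw.items() if k not in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extra.update(unknown)
        return cfg

    def thresholds(self) -> QCThresholds:
        return QCThresholds(self.cor_min, self.reads_min, self.tpm4_min)

    def semantic_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # output location is not semantic
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Writes qc_metrics.tsv, qc_summary.json and (when enabled) fpr.tsv
    and model.json under ``config.out_dir``. On stage failure, removes
    partial outputs and raises :class:`PipelineError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "read inputs"
        counts = qio.read_counts(config.counts)
        annot = qio.read_gene_annotation(config.annotation)
        meta = qio.read_metadata(config.metadata)
        shared = counts.gene_ids.intersection(annot.index)
        dropped = counts.n_genes - len(shared)
        if dropped:
            logger.warning("dropping %d genes absent from annotation", dropped)
            counts = type(counts)(counts.values.loc[shared], "counts")

        stage = "normalize"
        tpm = counts_to_tpm(counts, annot["length_bp"])
        logcpm = tmm_log2cpm(counts)

        stage = "qc metrics"
        corr_layer = logcpm if config.correlation_layer == "logCPM" else tpm
        metrics = compute_qc_metrics(counts, tpm, corr_layer)

        stage = "flag"
        flagged = flag_samples(metrics, config.thresholds())
        if {"batch_id", "is_technical_control"}.issubset(meta.columns):
            stage = "batch propagation"
            flagged = propagate_batch_failure(flagged, meta)

        stage = "write qc outputs"
        qc_path = out_dir / "qc_metrics.tsv"
        out = flagged.copy()
        out["fail_reasons"] = out["fail_reasons"].map(lambda r: ";".join(r))
        out.to_csv(qc_path, sep="\t")
        written.append(qc_path)
        summary = {
            "n_samples": int(len(flagged)),
            "n_pass": int((flagged["status"] == "PASS").sum()),
            "n_fail": int((flagged["status"] == "FAIL").sum()),
            "fail_reason_counts": dict(
                pd.Series(
                    [r for reasons in flagged["fail_reasons"] for r in reasons]
                ).value_counts()
                if any(flagged["fail_reasons"])
                else {}
            ),
            "thresholds": asdict(config.thresholds()),
            "seed": config.seed,
            "config_hash": config.semantic_hash(),
        }
        summary_path = out_dir / "qc_summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, default=int) + "\n")
        written.append(summary_path)

        results = {"qc_metrics": flagged, "summary": summary}

        if config.run_replicate_stats and "replicate_group" in meta.columns:
            stage = "replicate stats"
            groups = {
                g: list(ids)
                for g, ids in meta.groupby("replicate_group").groups.items()
                if len(ids) >= 2 and all(s in logcpm.sample_ids for s in ids)
            }
            if groups:
                fpr_table = qreplicates.replicate_fpr_table(
                    logcpm, groups, config.lfc_grid, tpm=tpm
                )
                fpr_path = out_dir / "fpr.tsv"
                fpr_table.to_csv(fpr_path, sep="\t", index=False)
                written.append(fpr_path)
                results["fpr"] = fpr_table

        if config.run_predictor and {"rna_qubit", "library_qubit"}.issubset(meta.columns):
            stage = "predictor"
            feats = meta.loc[flagged.index, ["rna_qubit", "library_qubit"]]
            labels = flagged["status"]
            if labels.nunique() == 2 and len(labels) >= 10:
                model, train_ids, test_ids = qpredict.evaluate_split(
                    feats,
                    labels,
                    model_kind=config.model,
                    seed=config.seed,
                    positive_class=config.positive_class,
                    cv=(config.cv_folds, config.cv_repeats),
                )
                model_path = out_dir / "model.json"
                model_path.write_text(
                    json.dumps(serialize_model(model, config), indent=2) + "\n"
                )
                written.append(model_path)
                results["model"] = model
            else:
                logger.warning("skipping predictor: need both classes and >= 10 samples")
        return results
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def serialize_model(model, config: RunConfig) -> dict:
    """JSON-serializable form of a fitted model (tree or logistic)."""
    base = {"seed": config.seed, "config_hash": config.semantic_hash()}
    if isinstance(model, qpredict.DecisionModel):

        def node_dict(node):
            d = {
                "prediction": node.prediction,
                "pass_fraction": round(node.pass_fraction, 6),
                "sample_fraction": round(node.sample_fraction, 6),
            }
            if not node.is_leaf:
                d |= {
                    "feature": node.feature,
                    "threshold": node.threshold,
                    "left": node_dict(node.left),
                    "right": node_dict(node.right),
                }
            return d

        return base | {
            "kind": "cart",
            "cp": model.cp,
            "f_score": model.f_score,
            "feature_importance": (
                model.feature_importance.round(6).to_dict()
                if model.feature_importance is not None
                else None
            ),
            "cv_table": (
                model.cv_table.round(6).to_dict(orient="list")
                if model.cv_table is not None
                else None
            ),
            "tree": node_dict(model.root),
        }
    return base | {
        "kind": "logistic",
        "beta0": model.beta0,
        "beta1": model.beta1.to_dict(),
        "converged": model.converged,
        "f_score": model.f_score,
    }
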