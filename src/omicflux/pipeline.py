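"""End-to-end orchestration with a config file and a reproducible manifest.

Stage order: synth (optional) -> normalize -> fluxes -> diff (flux and
reaction-expression layers) -> enrich -> classify -> shap.  Every stage
writes plain-text artifacts into the output directory; the manifest records
seeds, configuration, and SHA-256 digests of all outputs so reruns can be
checked for bit-identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .eflux import DEFAULT_VMAX, MediumSpec, fluxome_for_cohort
from .enrich import (
    DEFAULT_ENRICH_ALPHA,
    collapse_split_ids,
    enrich_terms,
    enrichment_heat_table,
    enrichment_rows_to_frame,
    subsystem_term_map,
)
from .ensemble import (
    DEFAULT_SHAP_THRESHOLD,
    DEFAULT_TRAIN_FRACTION,
    SMALL_RF_GRID,
    DEFAULT_RF_GRID,
    EnsembleModel,
    evaluate,
    fit_layer,
    shap_rank,
    split_train_test,
)
from .expression import DEFAULT_REFERENCE_GENE, ExpressionMatrix, normalize_reference_minmax
from .gsmm import make_irreversible, read_model, write_model
from .stats import build_groups, differential_analysis, reaction_expression
from .synthetic import SyntheticDesign, make_cohort, make_toy_model

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "PipelineError"]

DEFAULT_DIFF_ALPHA = 0.05


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class RunConfig:
    """Validated pipeline configuration with the published defaults."""

    # inputs: either a synthetic design or explicit paths
    design: Optional[SyntheticDesign] = None
    model_path: Optional[str] = None
    tx_path: Optional[str] = None
    gx_path: Optional[str] = None
    px_path: Optional[str] = None
    metadata_path: Optional[str] = None
    # constants
    reference_gene: str = DEFAULT_REFERENCE_GENE
    vmax: float = DEFAULT_VMAX
    medium_uptake: Optional[list[str]] = None
    uptake_limit: float = 1000.0
    scheme: str = "custom"
    diff_alpha: float = DEFAULT_DIFF_ALPHA
    enrich_alpha: float = DEFAULT_ENRICH_ALPHA
    train_fraction: float = DEFAULT_TRAIN_FRACTION
    shap_threshold: float = DEFAULT_SHAP_THRESHOLD
    task: str = "C/N"
    grid: str = "small"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("diff_alpha", self.diff_alpha),
            ("enrich_alpha", self.enrich_alpha),
            ("train_fraction", self.train_fraction),
            ("shap_threshold", self.shap_threshold),
        ):
            if not 0 < value <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {value}")
        if self.design is None:
            required = {
                "model_path": self.model_path,
                "tx_path": self.tx_path,
                "metadata_path": self.metadata_path,
            }
            missing = [k for k, v in required.items() if v is None]
            if missing:
                raise ValueError(
                    f"without a synthetic design, config must provide {missing}"
                )
            for key in (
                "model_path",
                "tx_path",
                "gx_path",
                "px_path",
                "metadata_path",
            ):
                value = getattr(self, key)
                if value is not None and not Path(value).exists():
                    raise FileNotFoundError(f"{key}: {value}")
        if self.grid not in ("small", "default"):
            raise ValueError(f"grid must be 'small' or 'default', got {self.grid!r}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "design" in doc and doc["design"] is not None:
            doc["design"] = SyntheticDesign.from_dict(doc["design"])
        return cls(**doc)

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "model_path",
                "tx_path",
                "gx_path",
                "px_path",
                "metadata_path",
                "reference_gene",
                "vmax",
                "medium_uptake",
                "uptake_limit",
                "scheme",
                "diff_alpha",
                "enrich_alpha",
                "train_fraction",
                "shap_threshold",
                "task",
                "grid",
                "seed",
            )
        }
        out["design"] = self.design.to_dict() if self.design else None
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(doc: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _safe_name(comparison: str) -> str:
    return comparison.replace("/", "_").replace(" ", "_")


def task_labels(metadata: pd.DataFrame, task: str) -> dict[str, str]:
    """Sample -> label mapping for a classification task.

    ``C/N`` uses the condition column on all samples; ``S1/N`` keeps normal
    samples and first-stage cancers; ``subtype`` compares cancer subtypes.
    """
    meta = metadata.set_index("sample_id")
    if task == "C/N":
        return meta["condition"].astype(str).to_dict()
    if task == "S1/N":
        keep = (meta["condition"] == "N") | (meta.get("stage") == "S1")
        return meta.loc[keep, "condition"].astype(str).to_dict()
    if task == "subtype":
        keep = meta["condition"] == "C"
        return meta.loc[keep, "subtype"].astype(str).to_dict()
    raise ValueError(f"unknown task {task!r}")


def run_all(config: RunConfig, out_dir: Union[str, Path]) -> dict:
    """Execute every pipeline stage; returns (and writes) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
    }
    outputs: dict[str, Path] = {}

    def record(stage: str, paths: dict[str, Path]) -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "status": "completed",
                "outputs": {str(p.relative_to(out)): _sha256(p) for p in paths.values()},
            }
        )
        outputs.update(paths)

    # ---- synth / load -----------------------------------------------------
    try:
        if config.design is not None:
            design = config.design
            model = make_toy_model(design)
            cohort = make_cohort(design, model)
            tx, gx, px, metadata = cohort.tx, cohort.gx, cohort.px, cohort.metadata
            medium = design.medium()
            reference = design.reference_gene
            paths = {
                "model": out / "model.json",
                "tx": out / "tx.tsv",
                "gx": out / "gx.tsv",
                "px": out / "px.tsv",
                "metadata": out / "metadata.tsv",
                "design": out / "design.json",
            }
            write_model(model, paths["model"])
            tx.to_tsv(paths["tx"])
            gx.to_tsv(paths["gx"])
            px.to_tsv(paths["px"])
            metadata.to_csv(paths["metadata"], sep="\t", index=False, lineterminator="\n")
            _write_json(design.to_dict(), paths["design"])
            record("synth", paths)
        else:
            model = read_model(config.model_path)
            tx = ExpressionMatrix.from_tsv(config.tx_path, layer="TX")
            gx = (
                ExpressionMatrix.from_tsv(config.gx_path, layer="GX")
                if config.gx_path
                else None
            )
            px = (
                ExpressionMatrix.from_tsv(config.px_path, layer="PX")
                if config.px_path
                else None
            )
            metadata = pd.read_csv(
                config.metadata_path, sep="\t", dtype=str, keep_default_na=False
            )
            allowed = config.medium_uptake or [
                r.id for r in model.reactions if r.is_exchange
            ]
            medium = MediumSpec(
                allowed_uptake=frozenset(allowed), uptake_limit=config.uptake_limit
            )
            reference = config.reference_gene
            record("load", {})
    except Exception as exc:  # noqa: BLE001 — stage boundary
        raise PipelineError("synth", str(exc)) from exc

    # ---- normalize --------------------------------------------------------
    try:
        tx_norm = normalize_reference_minmax(tx, reference)
        path = out / "tx_norm.tsv"
        tx_norm.to_tsv(path)
        record("normalize", {"tx_norm": path})
    except Exception as exc:
        raise PipelineError("normalize", str(exc)) from exc

    # ---- fluxes -----------------------------------------------------------
    try:
        split, _mapping = make_irreversible(model)
        flux = fluxome_for_cohort(split, tx_norm, vmax=config.vmax, medium=medium)
        jx = flux.as_expression()
        paths = {"jx": out / "jx.tsv", "flux_meta": out / "flux_run.json"}
        flux.to_tsv(paths["jx"])
        _write_json(flux.metadata(), paths["flux_meta"])
        record("fluxes", paths)
    except Exception as exc:
        raise PipelineError("fluxes", str(exc)) from exc

    # ---- differential -----------------------------------------------------
    try:
        groups = build_groups(metadata, scheme=config.scheme)
        rx = reaction_expression(split, tx_norm)
        diff_dir = out / "diff"
        diff_dir.mkdir(exist_ok=True)
        diff_paths: dict[str, Path] = {}
        diff_results: dict[tuple[str, str], object] = {}
        for layer_matrix in (jx, rx):
            for result in differential_analysis(
                layer_matrix, groups, alpha=config.diff_alpha
            ):
                key = f"{_safe_name(result.group.name)}_{result.data_layer}"
                path = diff_dir / f"{key}.tsv"
                result.to_tsv(path)
                diff_paths[key] = path
                diff_results[(result.group.name, result.data_layer)] = result
        record("diff", diff_paths)
    except Exception as exc:
        raise PipelineError("diff", str(exc)) from exc

    # ---- enrichment -------------------------------------------------------
    try:
        term_map = subsystem_term_map(split, collapse_split=True)
        enrich_dir = out / "enrich"
        enrich_dir.mkdir(exist_ok=True)
        enrich_paths: dict[str, Path] = {}
        rows_by_layer: dict[str, dict[str, list]] = {}
        for (group_name, layer), result in diff_results.items():
            significant = collapse_split_ids(
                result.significant(config.diff_alpha), split
            )
            significant &= term_map.universe
            rows = enrich_terms(significant, term_map, alpha=config.enrich_alpha)
            key = f"{_safe_name(group_name)}_{layer}"
            path = enrich_dir / f"{key}.tsv"
            enrichment_rows_to_frame(rows).to_csv(
                path, sep="\t", index=False, lineterminator="\n"
            )
            enrich_paths[key] = path
            rows_by_layer.setdefault(layer, {})[group_name] = rows
        for layer, by_comparison in rows_by_layer.items():
            long, wide = enrichment_heat_table(by_comparison)
            path = enrich_dir / f"heat_{layer}.tsv"
            wide.to_csv(path, sep="\t", lineterminator="\n")
            enrich_paths[f"heat_{layer}"] = path
        record("enrich", enrich_paths)
    except Exception as exc:
        raise PipelineError("enrich", str(exc)) from exc

    # ---- classify ---------------------------------------------------------
    try:
        labels = task_labels(metadata, config.task)
        layer_data = {"TX": tx_norm, "JX": jx}
        if gx is not None:
            layer_data["GX"] = gx
        if px is not None:
            layer_data["PX"] = px
        common = set(labels)
        for mat in layer_data.values():
            common &= set(mat.sample_ids)
        samples = sorted(common)
        y = {s: labels[s] for s in samples}
        train, test = split_train_test(
            samples,
            [y[s] for s in samples],
            train_fraction=config.train_fraction,
            seed=config.seed,
        )
        grid = SMALL_RF_GRID if config.grid == "small" else DEFAULT_RF_GRID
        layer_models = []
        cls_dir = out / "classify"
        cls_dir.mkdir(exist_ok=True)
        cls_paths: dict[str, Path] = {}
        metrics: dict[str, dict] = {}
        for name in sorted(layer_data):
            lm = fit_layer(
                layer_data[name], y, train, grid=grid, seed=config.seed
            )
            layer_models.append(lm)
            probs = lm.predict_proba(layer_data[name], test)
            report = evaluate(probs, y)
            metrics[name] = report.to_dict()
            for cls, roc in report.roc.items():
                path = cls_dir / f"roc_{name}_{_safe_name(cls)}.tsv"
                roc.to_csv(path, sep="\t", index=False, lineterminator="\n")
                cls_paths[f"roc_{name}_{cls}"] = path
        ensemble = EnsembleModel(layer_models=layer_models)
        pooled = ensemble.predict_proba(layer_data, test)
        report = evaluate(pooled, y)
        metrics["ensemble"] = report.to_dict()
        metrics["split"] = {"train": sorted(train), "test": sorted(test)}
        path = cls_dir / "metrics.json"
        _write_json(metrics, path)
        cls_paths["metrics"] = path
        record("classify", cls_paths)
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc

    # ---- shap -------------------------------------------------------------
    try:
        shap_dir = out / "shap"
        shap_dir.mkdir(exist_ok=True)
        shap_paths: dict[str, Path] = {}
        for lm in layer_models:
            ranking = shap_rank(
                lm, layer_data[lm.layer], test, threshold=config.shap_threshold
            )
            path = shap_dir / f"shap_{lm.layer}.tsv"
            ranking.to_tsv(path)
            shap_paths[lm.layer] = path
        record("shap", shap_paths)
    except Exception as exc:
        raise PipelineError("shap", str(exc)) from exc

    _write_json(manifest, out / "manifest.json")
    return manifest
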