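"""End-to-end orchestration: config, staged execution, reproducible run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import (
    aggregate_gene_support,
    attribute_pixels,
    select_background,
    top_k_pixels,
    write_attributions,
)
from .classify import CNNConfig, build_cnn, compute_class_weights, save_checkpoint, train_cnn
from .evaluate import crossvalidate, write_metrics
from .image import fit_feature_map, normalize_norm2, transform_to_images
from .io import (
    LabeledDataset,
    filter_autosomal,
    filter_high_expression,
    filter_protein_coding,
    read_annotation,
    read_expression_matrix,
    read_labels,
)

__all__ = ["RunConfig", "run_pipeline", "apply_filters"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a run needs; every paper-mode constant is a default here."""

    expression_path: str = ""
    annotation_path: str = ""
    labels_path: str = ""
    orientation: str = "genes_in_rows"
    out_dir: str = "run"
    # filters
    autosomal: bool = True
    high_expression: bool = True
    min_count: float = 10.0
    min_samples: int = 10
    protein_coding: bool = False
    missing_policy: str = "error"
    # feature map
    grid_size: int = 380
    embed_method: str = "tsne"
    perplexity: float = 30.0
    map_scope: str = "train"
    # classifier
    cnn: dict = field(default_factory=dict)  # CNNConfig overrides
    # evaluation
    cv_k: int = 12
    stratified: bool = True
    # attribution
    background_n: int = 200
    top_k: int = 10
    min_support: int | None = None
    attribution_mode: str = "signed"
    attribution_steps: int = 32
    attribution_max_background: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def cnn_config(self) -> CNNConfig:
        base = {"input_size": self.grid_size, "seed": self.seed}
        base.update(self.cnn)
        if "conv_depths" in base:
            base["conv_depths"] = tuple(base["conv_depths"])
        return CNNConfig(**base)

    def validate_paths(self) -> None:
        for name in ("expression_path", "annotation_path", "labels_path"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name} missing or not found: {p!r}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def apply_filters(m, ann, cfg: RunConfig):
    """Run the configured gene filters in the canonical order."""
    if cfg.autosomal:
        m = filter_autosomal(m, ann, missing=cfg.missing_policy)
    if cfg.protein_coding:
        m = filter_protein_coding(m, ann, missing=cfg.missing_policy)
    if cfg.high_expression:
        m = filter_high_expression(m, cfg.min_count, cfg.min_samples)
    return m


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute read -> filter -> normalize -> map -> images -> CV -> attribute -> report.

    Artifacts land in ``cfg.out_dir`` together with ``manifest.json`` (config,
    seeds, library versions, input digests). A stage failure aborts with the
    stage name; artifacts of completed stages are preserved.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "validate"
    try:
        cfg.validate_paths()

        stage = "read"
        m = read_expression_matrix(cfg.expression_path, cfg.orientation)
        ann = read_annotation(cfg.annotation_path)
        labels = read_labels(cfg.labels_path)

        stage = "filter"
        m = apply_filters(m, ann, cfg)
        dataset = LabeledDataset(m, labels)
        log.info("after filtering: %d genes x %d samples", m.n_genes, m.n_samples)

        stage = "normalize+map"
        norm, params = normalize_norm2(m)
        fm = fit_feature_map(
            norm, cfg.grid_size, method=cfg.embed_method, seed=cfg.seed,
            perplexity=cfg.perplexity, normalization_params=params,
        )
        fm.save(out / "feature_map.json")

        stage = "images"
        images = transform_to_images(norm, fm)

        stage = "crossvalidate"
        cv = crossvalidate(
            dataset, grid_size=cfg.grid_size, embed_method=cfg.embed_method,
            perplexity=cfg.perplexity, cnn=cfg.cnn_config(), map_scope=cfg.map_scope,
            k=cfg.cv_k, stratified=cfg.stratified, seed=cfg.seed,
        )
        write_metrics(cv, out)

        stage = "train"
        ccfg = cfg.cnn_config()
        weights = compute_class_weights(dataset.y)
        clf = train_cnn(build_cnn(ccfg), images, dataset.y, ccfg, weights)
        save_checkpoint(clf, out / "model", extra={"data_hash": _sha256(cfg.expression_path)})

        stage = "attribute"
        background = select_background(images, min(cfg.background_n, images.n_samples), seed=cfg.seed)
        att = attribute_pixels(
            clf, images, background, n_steps=cfg.attribution_steps,
            max_background=cfg.attribution_max_background, seed=cfg.seed,
        )
        write_attributions(att, out / "attributions")

        stage = "aggregate"
        top = top_k_pixels(att, k=cfg.top_k, mode=cfg.attribution_mode)
        report = aggregate_gene_support(top, fm, min_support=cfg.min_support, k=cfg.top_k)
        report.ranked.to_csv(out / "gene_support.tsv", sep="\t", index=False)
        report.support.rename("support").to_frame().to_csv(
            out / "gene_support_full.tsv", sep="\t", index_label="gene_id"
        )

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config": dataclasses.asdict(cfg),
            "class_weights": weights,
            "inputs": {
                p: _sha256(getattr(cfg, p))
                for p in ("expression_path", "annotation_path", "labels_path")
            },
            "versions": _library_versions(),
            "platform": platform.platform(),
            "n_genes_after_filter": m.n_genes,
            "n_samples": m.n_samples,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    return out


def _library_versions() -> dict[str, str]:
    import scipy
    import shapely
    import sklearn

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "shapely": shapely.__version__,
    }
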