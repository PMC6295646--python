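"""End-to-end orchestration: signals -> PLI graphs -> embeddings -> images -> CV.

Each stage persists its intermediate artifact as plain text so any
stage can be skipped by supplying its input artifact directly; a run
logs the full configuration snapshot, the master seed and every derived
per-stage seed, which is sufficient to reproduce any artifact.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from ._rng import derive_seed
from .classifier import CNNConfig, CVResult, LabeledImageSet, cross_validate
from .connectivity import ConnectivityGraph, Recording, band_filter, connectivity_matrix, instantaneous_phase
from .embedding import SkipGramConfig, WalkConfig, node2vec
from .imaging import graph_to_image

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage settings plus the master seed.

    Per-stage seeds (walks, skip-gram, CNN, fold partitioning) are
    derived from ``seed`` by name, so stages are individually
    reproducible; per-subject embedding seeds additionally fold in the
    subject index.
    """

    band_low_hz: float | None = None
    band_high_hz: float | None = None
    epoch_samples: int | None = None
    walk: WalkConfig = field(default_factory=WalkConfig)
    skipgram: SkipGramConfig = field(default_factory=SkipGramConfig)
    d_pca: int = 4
    resolution: int = 10
    cnn: CNNConfig = field(default_factory=CNNConfig)
    cv_folds: int = 4
    cv_iterations: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_pca >= self.skipgram.dim:
            raise ValueError("d_pca must be smaller than the embedding dimension")
        expected = (self.resolution, self.resolution, self.d_pca // 2)
        if tuple(self.cnn.input_shape) != expected:
            raise ValueError(
                f"cnn.input_shape {self.cnn.input_shape} inconsistent with "
                f"resolution/d_pca (expected {expected})"
            )

    def with_seed(self) -> "PipelineConfig":
        """Propagate per-stage seeds derived from the master seed."""
        return dataclasses.replace(
            self,
            walk=dataclasses.replace(self.walk, seed=derive_seed(self.seed, "walks")),
            skipgram=dataclasses.replace(self.skipgram, seed=derive_seed(self.seed, "skipgram")),
            cnn=dataclasses.replace(self.cnn, seed=derive_seed(self.seed, "cnn")),
        )

    def snapshot(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj
        return plain(dataclasses.asdict(self))


def _graph_from_recording(rec: Recording, cfg: PipelineConfig) -> ConnectivityGraph:
    if cfg.band_low_hz is not None and cfg.band_high_hz is not None:
        rec = band_filter(rec, cfg.band_low_hz, cfg.band_high_hz)
    phases = instantaneous_phase(rec)
    return connectivity_matrix(phases, epoch_samples=cfg.epoch_samples)


def run_pipeline(
    config: PipelineConfig,
    labels,
    subject_ids: list[str],
    out_dir,
    recordings: list[Recording] | None = None,
    graphs: list[ConnectivityGraph] | None = None,
    images: LabeledImageSet | None = None,
) -> CVResult:
    """Run the stages needed to get from the supplied inputs to a CVResult.

    Exactly one of ``recordings``, ``graphs`` or ``images`` must be
    given; earlier stages are skipped when a later artifact is supplied.
    All intermediates plus a JSON summary are written under ``out_dir``.
    """
    supplied = [x is not None for x in (recordings, graphs, images)]
    if sum(supplied) != 1:
        raise ValueError("supply exactly one of recordings, graphs or images")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(labels, dtype=int)
    cfg = config.with_seed()
    logger.info("pipeline config: %s", cfg.snapshot())
    io.write_config(out / "config.yaml", config.snapshot())

    if recordings is not None:
        if len(recordings) != labels.size:
            raise ValueError("connectivity stage: one recording per label required")
        graphs = []
        for sid, rec in zip(subject_ids, recordings):
            g = _graph_from_recording(rec, cfg)
            io.write_adjacency(out / f"adjacency_{sid}.tsv", g)
            graphs.append(g)
        logger.info("connectivity stage: %d graphs", len(graphs))

    if images is None:
        if len(graphs) != labels.size:
            raise ValueError("embedding stage: one graph per label required")
        tensors = []
        for i, (sid, g) in enumerate(zip(subject_ids, graphs)):
            walk_cfg = dataclasses.replace(
                cfg.walk, seed=derive_seed(cfg.walk.seed, f"subject-{i}"))
            sg_cfg = dataclasses.replace(
                cfg.skipgram, seed=derive_seed(cfg.skipgram.seed, f"subject-{i}"))
            emb = node2vec(g, walk_cfg, sg_cfg)
            io.write_embedding(out / f"embedding_{sid}.tsv", emb)
            img = graph_to_image(emb, d_pca=cfg.d_pca, r=cfg.resolution)
            io.write_image(out / f"image_{sid}.tsv", img)
            tensors.append(img.channels)
        images = LabeledImageSet(np.stack(tensors), labels, list(subject_ids))
        io.write_manifest(out / "manifest.tsv", subject_ids, labels,
                          [f"image_{sid}.tsv" for sid in subject_ids])
        logger.info("imaging stage: %d images", len(images))

    result = cross_validate(images, cfg.cv_folds, cfg.cv_iterations, cfg.cnn,
                            seed=derive_seed(cfg.seed, "cv"))
    io.write_results(out / "cv_results.json", {
        "master_seed": config.seed,
        "derived_seeds": {
            "walks": cfg.walk.seed, "skipgram": cfg.skipgram.seed,
            "cnn": cfg.cnn.seed, "cv": derive_seed(cfg.seed, "cv"),
        },
        "fold_accuracies": result.fold_accuracies,
        "mean_accuracy": result.mean_accuracy,
        "stopped_epochs": [h.stopped_epoch for h in result.histories],
    })
    logger.info("cross-validation mean accuracy: %.3f", result.mean_accuracy)
    return result
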