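"""End-to-end PAD pipeline: segment -> features -> fuse/classify -> evaluate.

``fit_pad`` trains a complete detector from segmented iris ROIs; a
:class:`PadModel` then scores new ROIs in [0, 1] (higher = attack).
``run_pipeline`` wires the whole flow from a labelled image set and
returns a JSON-serializable report with per-split APCER/BPCER/ACER, the
DET curve, and the size-weighted ACER across test splits.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.transform import resize

from irispad import cnn, evaluation, fusion, mlbp
from irispad.errors import IrisPadError, ValidationError
from irispad.io_manifest import DatasetRecord
from irispad.segmentation import SegConfig, segment

log = logging.getLogger("irispad")


@dataclass
class PipelineConfig:
    """Everything needed for a reproducible end-to-end run."""

    mode: str = "feature"  # feature | score
    seg: SegConfig = field(default_factory=SegConfig)
    mlbp_config: mlbp.MLBPConfig = field(default_factory=lambda: mlbp.DEFAULT_MLBP)
    cnn_spec: str = "reduced"  # reduced | full
    # 96 px keeps the ~2-px printing raster above the resampling limit
    # (224-px ROIs are themselves upsampled from ~60-90 px native crops)
    cnn_input_size: int = 96
    train_config: cnn.TrainConfig = field(default_factory=cnn.TrainConfig)
    kernel_hybrid: fusion.KernelSpec = field(
        default_factory=lambda: fusion.KernelSpec("rbf")
    )
    kernel_cnn: fusion.KernelSpec = field(
        default_factory=lambda: fusion.KernelSpec("rbf")
    )
    kernel_mlbp: fusion.KernelSpec = field(
        default_factory=lambda: fusion.KernelSpec("rbf")
    )
    svm_c: float = 1.0
    pca_k: int = 512
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("feature", "score"):
            raise ValidationError("mode must be 'feature' or 'score'")
        if self.cnn_spec not in ("reduced", "full"):
            raise ValidationError("cnn_spec must be 'reduced' or 'full'")


def build_network_spec(config: PipelineConfig) -> cnn.NetworkSpec:
    if config.cnn_spec == "full":
        return cnn.build_vgg19_spec()
    return cnn.build_reduced_spec(input_size=config.cnn_input_size)


def compute_rois(
    images: Sequence[np.ndarray], seg_config: SegConfig
) -> np.ndarray:
    """Segment every image and stack the 224x224x3 iris ROIs."""
    rois = []
    for i, img in enumerate(images):
        try:
            rois.append(segment(img, seg_config).roi)
        except IrisPadError as exc:
            raise type(exc)(f"image #{i}: {exc}") from exc
    return np.stack(rois)


def _cnn_inputs(rois: np.ndarray, size: int) -> np.ndarray:
    if rois.shape[1] == size:
        return rois
    out = np.empty((len(rois), size, size, 3))
    for i, roi in enumerate(rois):
        out[i] = resize(
            roi, (size, size, 3), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    return out


def _mlbp_matrix(rois: np.ndarray, config: mlbp.MLBPConfig) -> np.ndarray:
    return np.stack([mlbp.mlbp_features(roi, config).values for roi in rois])


def _fit_subsystem(
    train_x: np.ndarray,
    labels: np.ndarray,
    kernel_spec: fusion.KernelSpec,
    pca_k: int,
    C: float,
):
    stats = fusion.fit_norm(train_x)
    xn = fusion.z_normalize(train_x, stats)
    k = fusion.default_pca_k(len(xn), xn.shape[1], pca_k)
    pca = fusion.fit_pca(xn, k)
    xp = fusion.project(xn, pca)
    svm = fusion.train_svm(xp, labels, kernel_spec, C=C)
    fusion.calibrate(svm, xp, labels)
    return stats, pca, svm


def _apply_subsystem(x: np.ndarray, stats, pca, svm) -> np.ndarray:
    return fusion.score(svm, fusion.project(fusion.z_normalize(x, stats), pca))


@dataclass
class PadModel:
    """A trained PAD detector (either fusion mode)."""

    config: PipelineConfig
    cnn_model: cnn.CnnModel
    stats_cnn: fusion.NormStats
    stats_mlbp: fusion.NormStats
    # feature mode
    pca_hybrid: fusion.PcaModel | None = None
    svm_hybrid: fusion.SvmModel | None = None
    # score mode
    pca_cnn: fusion.PcaModel | None = None
    svm_cnn: fusion.SvmModel | None = None
    pca_mlbp: fusion.PcaModel | None = None
    svm_mlbp: fusion.SvmModel | None = None
    weights: fusion.FusionWeights | None = None

    def _features(self, rois: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x_cnn = self.cnn_model.extract_features_batch(
            _cnn_inputs(rois, self.config.cnn_input_size)
        )
        x_mlbp = _mlbp_matrix(rois, self.config.mlbp_config)
        return x_cnn, x_mlbp

    def score_rois(self, rois: np.ndarray) -> np.ndarray:
        """PAD scores in [0, 1] for a stack of 224x224x3 ROIs."""
        x_cnn, x_mlbp = self._features(rois)
        if self.config.mode == "feature":
            hybrid = np.hstack(
                [
                    fusion.z_normalize(x_cnn, self.stats_cnn),
                    fusion.z_normalize(x_mlbp, self.stats_mlbp),
                ]
            )
            return fusion.score(
                self.svm_hybrid, fusion.project(hybrid, self.pca_hybrid)
            )
        s1 = _apply_subsystem(x_cnn, self.stats_cnn, self.pca_cnn, self.svm_cnn)
        s2 = _apply_subsystem(x_mlbp, self.stats_mlbp, self.pca_mlbp, self.svm_mlbp)
        return fusion.fuse(s1, s2, self.weights)

    def predict(self, roi: np.ndarray) -> dict:
        s = float(self.score_rois(np.asarray(roi)[None])[0])
        label = "attack" if s >= self.config.threshold else "bona_fide"
        return {"score": s, "label": label}


def fit_pad(
    rois_train: np.ndarray, labels_train: np.ndarray, config: PipelineConfig
) -> PadModel:
    """Train the CNN backbone and the configured fusion pipeline."""
    labels_train = np.asarray(labels_train, dtype=np.int64)
    spec = build_network_spec(config)
    tc = config.train_config
    if tc.seed != config.seed:
        tc = cnn.TrainConfig(
            momentum=tc.momentum, batch_size=tc.batch_size,
            initial_lr=tc.initial_lr, lr_drop_factor=tc.lr_drop_factor,
            lr_drop_period=tc.lr_drop_period, n_epochs=tc.n_epochs,
            seed=config.seed,
        )
    t0 = time.perf_counter()
    model = cnn.train(
        spec, _cnn_inputs(rois_train, config.cnn_input_size), labels_train, tc
    )
    log.info("CNN training: %.1fs", time.perf_counter() - t0)

    x_cnn = model.extract_features_batch(
        _cnn_inputs(rois_train, config.cnn_input_size)
    )
    x_mlbp = _mlbp_matrix(rois_train, config.mlbp_config)
    stats_cnn = fusion.fit_norm(x_cnn)
    stats_mlbp = fusion.fit_norm(x_mlbp)

    pad = PadModel(
        config=config, cnn_model=model, stats_cnn=stats_cnn, stats_mlbp=stats_mlbp
    )
    if config.mode == "feature":
        hybrid = np.hstack(
            [
                fusion.z_normalize(x_cnn, stats_cnn),
                fusion.z_normalize(x_mlbp, stats_mlbp),
            ]
        )
        k = fusion.default_pca_k(len(hybrid), hybrid.shape[1], config.pca_k)
        pad.pca_hybrid = fusion.fit_pca(hybrid, k)
        xp = fusion.project(hybrid, pad.pca_hybrid)
        pad.svm_hybrid = fusion.train_svm(
            xp, labels_train, config.kernel_hybrid, C=config.svm_c
        )
        fusion.calibrate(pad.svm_hybrid, xp, labels_train)
    else:
        xn1 = fusion.z_normalize(x_cnn, stats_cnn)
        k1 = fusion.default_pca_k(len(xn1), xn1.shape[1], config.pca_k)
        pad.pca_cnn = fusion.fit_pca(xn1, k1)
        xp1 = fusion.project(xn1, pad.pca_cnn)
        pad.svm_cnn = fusion.train_svm(
            xp1, labels_train, config.kernel_cnn, C=config.svm_c
        )
        fusion.calibrate(pad.svm_cnn, xp1, labels_train)

        xn2 = fusion.z_normalize(x_mlbp, stats_mlbp)
        k2 = fusion.default_pca_k(len(xn2), xn2.shape[1], config.pca_k)
        pad.pca_mlbp = fusion.fit_pca(xn2, k2)
        xp2 = fusion.project(xn2, pad.pca_mlbp)
        pad.svm_mlbp = fusion.train_svm(
            xp2, labels_train, config.kernel_mlbp, C=config.svm_c
        )
        fusion.calibrate(pad.svm_mlbp, xp2, labels_train)

        s1 = fusion.score(pad.svm_cnn, xp1)
        s2 = fusion.score(pad.svm_mlbp, xp2)
        pad.weights = fusion.select_weights(s1, s2, labels_train)
    return pad


def run_pipeline(
    config: PipelineConfig,
    images: Sequence[np.ndarray],
    records: Sequence[DatasetRecord],
) -> dict:
    """Full run on an in-memory dataset; returns the evaluation report."""
    if len(images) != len(records):
        raise ValidationError("images and records length mismatch")
    t0 = time.perf_counter()
    rois = compute_rois(images, config.seg)
    log.info("segmentation of %d images: %.1fs", len(images), time.perf_counter() - t0)

    labels = np.array([1 if r.label == "attack" else 0 for r in records])
    splits = np.array([r.split for r in records])
    train_mask = splits == "train"
    if train_mask.sum() < 2 or len(np.unique(labels[train_mask])) < 2:
        raise ValidationError("train split must contain both classes")

    pad = fit_pad(rois[train_mask], labels[train_mask], config)

    report: dict = {
        "mode": config.mode,
        "threshold": config.threshold,
        "n_train": int(train_mask.sum()),
        "splits": {},
    }
    if config.mode == "score":
        report["fusion_weights"] = {"w1": pad.weights.w1, "w2": pad.weights.w2}

    weighted: list[tuple[evaluation.EvalResult, int]] = []
    for split in ("test_known", "test_unknown"):
        mask = splits == split
        if not mask.any():
            continue
        scores = pad.score_rois(rois[mask])
        scored = evaluation.ScoredSet(scores=scores, labels=labels[mask])
        result = evaluation.evaluate(scored, config.threshold)
        weighted.append((result, int(mask.sum())))
        report["splits"][split] = {
            "n": int(mask.sum()),
            "apcer": result.apcer,
            "bpcer": result.bpcer,
            "acer": result.acer,
            "det": [[a, b] for a, b in result.det],
        }
    if weighted:
        report["weighted_acer"] = evaluation.weighted_acer(weighted)
    return report
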