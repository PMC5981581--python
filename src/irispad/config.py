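"""YAML configuration for the end-to-end pipeline.

Round-trip safe: ``load_config(dump_config(cfg)) == cfg``.  Arc angles
are stored in radians, matching the in-memory representation exactly.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from irispad import cnn, fusion, mlbp
from irispad.errors import ValidationError
from irispad.pipeline import PipelineConfig
from irispad.segmentation import SegConfig


def _kernel_to_dict(k: fusion.KernelSpec) -> dict:
    return {"kind": k.kind, "gamma": k.gamma, "coef": k.coef, "degree": k.degree}


def _kernel_from_dict(d: dict) -> fusion.KernelSpec:
    return fusion.KernelSpec(
        kind=d.get("kind", "rbf"),
        gamma=d.get("gamma"),
        coef=d.get("coef", 1.0),
        degree=d.get("degree", 3),
    )


def config_to_dict(config: PipelineConfig) -> dict:
    seg = config.seg
    return {
        "mode": config.mode,
        "seed": config.seed,
        "threshold": config.threshold,
        "pca_k": config.pca_k,
        "svm_c": config.svm_c,
        "segmentation": {
            "s_range": list(seg.s_range) if seg.s_range else None,
            "s_step": seg.s_step,
            "pupil_stride": seg.pupil_stride,
            "ced_center_stride": seg.ced_center_stride,
            "n_samples": seg.n_samples,
            "smooth_sigma": seg.smooth_sigma,
            "pupil_r_range": list(seg.pupil_r_range) if seg.pupil_r_range else None,
            "iris_r_range": list(seg.iris_r_range) if seg.iris_r_range else None,
            "iris_r_factor": seg.iris_r_factor,
            "iris_arcs": [[a, b] for a, b in seg.iris_arcs],
            "roi_size": seg.roi_size,
        },
        "mlbp": {"levels": [{"R": l.R, "P": l.P} for l in config.mlbp_config.levels]},
        "cnn": {
            "spec": config.cnn_spec,
            "input_size": config.cnn_input_size,
            "train": asdict(config.train_config),
        },
        "kernels": {
            "hybrid": _kernel_to_dict(config.kernel_hybrid),
            "cnn": _kernel_to_dict(config.kernel_cnn),
            "mlbp": _kernel_to_dict(config.kernel_mlbp),
        },
    }


def config_from_dict(d: dict) -> PipelineConfig:
    seg_d = d.get("segmentation", {})
    arcs = seg_d.get("iris_arcs")
    seg_kwargs = dict(
        s_range=tuple(seg_d["s_range"]) if seg_d.get("s_range") else None,
        s_step=seg_d.get("s_step", 4),
        pupil_stride=seg_d.get("pupil_stride", 2),
        ced_center_stride=seg_d.get("ced_center_stride", 2),
        n_samples=seg_d.get("n_samples", 256),
        smooth_sigma=seg_d.get("smooth_sigma", 1.0),
        pupil_r_range=tuple(seg_d["pupil_r_range"]) if seg_d.get("pupil_r_range") else None,
        iris_r_range=tuple(seg_d["iris_r_range"]) if seg_d.get("iris_r_range") else None,
        iris_r_factor=seg_d.get("iris_r_factor", 1.1),
        roi_size=seg_d.get("roi_size", 224),
    )
    if arcs is not None:
        seg_kwargs["iris_arcs"] = tuple((float(a), float(b)) for a, b in arcs)
    mlbp_d = d.get("mlbp", {})
    if "levels" in mlbp_d:
        mlbp_config = mlbp.MLBPConfig(
            levels=tuple(mlbp.LBPConfig(l["R"], l["P"]) for l in mlbp_d["levels"])
        )
    else:
        mlbp_config = mlbp.DEFAULT_MLBP
    cnn_d = d.get("cnn", {})
    train_d = cnn_d.get("train", {})
    kernels = d.get("kernels", {})
    return PipelineConfig(
        mode=d.get("mode", "feature"),
        seg=SegConfig(**seg_kwargs),
        mlbp_config=mlbp_config,
        cnn_spec=cnn_d.get("spec", "reduced"),
        cnn_input_size=cnn_d.get("input_size", 96),
        train_config=cnn.TrainConfig(**train_d) if train_d else cnn.TrainConfig(),
        kernel_hybrid=_kernel_from_dict(kernels.get("hybrid", {})),
        kernel_cnn=_kernel_from_dict(kernels.get("cnn", {})),
        kernel_mlbp=_kernel_from_dict(kernels.get("mlbp", {})),
        svm_c=d.get("svm_c", 1.0),
        pca_k=d.get("pca_k", 512),
        threshold=d.get("threshold", 0.5),
        seed=d.get("seed", 0),
    )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"config {path} is not a mapping")
    return config_from_dict(data)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
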