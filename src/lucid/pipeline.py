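"""End-to-end most-informative-frame selection.

``run_pipeline`` decodes a video (TIFF stack or frame directory), scores every
frame on the three axes — eardrum view S_edv, eardrum coverage S_edc (via
BC-AdvCAM segmentation) and clarity S_blf — fuses them into the informative
score S_I by weighted ranks, and exports the top-k frames.  A frame whose FOV
cannot be detected shows no otoscope content at all, so it is treated as
non-diagnostic: it is retained with all three raw scores set to 0 (rather
than dropped) so rank denominators stay consistent across the axes, and —
because any frame with a valid FOV has strictly positive view score — it can
never win selection over a valid frame.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.transform import resize

from . import cam as cam_mod
from . import clarity as clarity_mod
from .cam import ClimbingConfig
from .frame_io import read_frames, to_grayscale, write_frame_png
from .nn import ConvNetClassifier, TrainConfig
from .scoring import FusionWeights, informative_score, select_top_k
from .view import eardrum_view_score, predict_view, train_view_classifier

logger = logging.getLogger("lucid")

__all__ = ["PipelineConfig", "run_pipeline", "train_demo_models"]


@dataclass
class PipelineConfig:
    """All pipeline knobs; see module docs for the scoring model itself."""

    stride: int = 1
    top_k: int = 4
    seed: int = 0
    # clarity
    sigma_smooth: float = 2.0
    delta_r: int = 5
    radius_range: tuple[float, float] | None = None
    epsilon: float = clarity_mod.EPSILON
    # CAM / coverage
    cam: ClimbingConfig = field(default_factory=ClimbingConfig)
    # fusion
    weights: FusionWeights = field(default_factory=FusionWeights)
    # checkpoints (stems; .npz/.json pairs written by ConvNetClassifier.save)
    view_checkpoint: str | None = None
    binary_checkpoint: str | None = None

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if isinstance(self.cam, dict):
            self.cam = ClimbingConfig(**self.cam)
        if isinstance(self.weights, dict):
            self.weights = FusionWeights(**self.weights)
        if isinstance(self.radius_range, list):
            self.radius_range = tuple(self.radius_range)
        self.cam.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def train_demo_models(seed: int = 0, n_images: int = 300,
                      epochs: int = 25) -> tuple[ConvNetClassifier, ConvNetClassifier]:
    """Train the 3-class view model and the binary CAM model on synthetic data.

    This is the self-contained path used when no clinical checkpoints exist:
    both small CNNs are trained on generator output in a couple of minutes on
    a single CPU.  Deterministic for a fixed seed.
    """
    from .synthetic import generate_shapes_dataset, generate_view_dataset

    images3, labels3 = generate_view_dataset(n_images, seed=seed)
    view_model = train_view_classifier(
        images3, labels3, TrainConfig(seed=seed, epochs=epochs, restarts=3), n_classes=3
    )
    images2, labels2, _ = generate_shapes_dataset(n_images, seed=seed + 1)
    binary_model = train_view_classifier(
        images2, labels2, TrainConfig(seed=seed, epochs=max(epochs, 30), restarts=3), n_classes=2
    )
    return view_model, binary_model


def _coverage_for_frame(binary_model: ConvNetClassifier, image: np.ndarray,
                        cfg: PipelineConfig) -> float:
    amap = cam_mod.bc_advcam(binary_model, image, cfg.cam)
    values = resize(amap.values, image.shape[:2], order=1, preserve_range=True)
    mask = cam_mod.threshold_mask(values, cfg.cam.mask_threshold)
    return cam_mod.coverage_score(mask).s_edc


def run_pipeline(
    input_path: str | Path,
    config: PipelineConfig | None = None,
    view_model: ConvNetClassifier | None = None,
    binary_model: ConvNetClassifier | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Score every frame and select the top-k most informative ones.

    Models are resolved in order: explicit argument, checkpoint path in the
    config, else both are trained on synthetic data (demo mode).  Returns the
    per-frame score table (one row per scored frame, ``selected`` column
    marking the top-k).  When ``out_dir`` is given, writes ``scores.csv``,
    the selected frames as PNGs and a JSON run manifest.
    """
    cfg = config or PipelineConfig()
    t0 = time.time()
    if view_model is None:
        if cfg.view_checkpoint:
            view_model = ConvNetClassifier.load(cfg.view_checkpoint)
        else:
            logger.info("no view checkpoint: training demo models on synthetic data")
    if binary_model is None and cfg.binary_checkpoint:
        binary_model = ConvNetClassifier.load(cfg.binary_checkpoint)
    if view_model is None or binary_model is None:
        vm, bm = train_demo_models(seed=cfg.seed)
        view_model = view_model or vm
        binary_model = binary_model or bm
    t_models = time.time() - t0

    rows = []
    timings = {"clarity": 0.0, "view": 0.0, "coverage": 0.0}
    n_fov_failures = 0
    for frame in read_frames(input_path, stride=cfg.stride):
        gray = to_grayscale(frame)
        t = time.time()
        clarity = clarity_mod.assess_clarity(
            gray, seed=cfg.seed, sigma_smooth=cfg.sigma_smooth,
            delta_r=cfg.delta_r, radius_range=cfg.radius_range, epsilon=cfg.epsilon,
        )
        fov_ok = clarity.fov is not None
        if not fov_ok:
            n_fov_failures += 1
            logger.warning(
                "frame %d: no FOV detected, treated as non-diagnostic "
                "(all scores 0)", frame.frame_index,
            )
        timings["clarity"] += time.time() - t
        t = time.time()
        s_edv = (
            eardrum_view_score(predict_view(view_model, frame)).s_edv if fov_ok else 0.0
        )
        timings["view"] += time.time() - t
        t = time.time()
        s_edc = _coverage_for_frame(binary_model, frame.image, cfg) if fov_ok else 0.0
        timings["coverage"] += time.time() - t
        rows.append(
            {
                "frame_index": frame.frame_index,
                "s_edv": s_edv,
                "s_edc": s_edc,
                "s_blf": clarity.s_blf,
                "s_bl": clarity.s_bl,
                "s_f": clarity.s_f,
                "sigma_max": clarity.sigma_max,
                "contrast": clarity.contrast,
                "fov_x": clarity.fov.center[0] if clarity.fov else np.nan,
                "fov_y": clarity.fov.center[1] if clarity.fov else np.nan,
                "fov_r": clarity.fov.radius if clarity.fov else np.nan,
                "focus_x": clarity.focus_point[0],
                "focus_y": clarity.focus_point[1],
            }
        )
    if not rows:
        raise ValueError(f"no frames decoded from {input_path}")

    table = informative_score(pd.DataFrame(rows), cfg.weights)
    k = min(cfg.top_k, len(table))
    selected = select_top_k(table, k)
    table["selected"] = table["frame_index"].isin(selected)
    table = table.sort_values("frame_index").reset_index(drop=True)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "scores.csv", index=False)
        stem = Path(input_path).stem
        by_index = {f.frame_index: f for f in read_frames(input_path, stride=cfg.stride)
                    if f.frame_index in set(selected)}
        for rank, idx in enumerate(selected, start=1):
            write_frame_png(by_index[idx], out_dir / f"{stem}_rank{rank}_frame{idx}.png")
        manifest = {
            "input": str(input_path),
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "n_frames": len(table),
            "n_fov_failures": n_fov_failures,
            "selected": selected,
            "timings_s": {**{k_: round(v, 3) for k_, v in timings.items()},
                          "model_setup": round(t_models, 3)},
        }
        (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return table
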