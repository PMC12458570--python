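"""Eardrum view classification and the eardrum view score S_edv.

A 3-class classifier assigns each frame probabilities of showing no eardrum,
a partial eardrum, or the full eardrum.  The view score is the expectation of
per-class "eardrum area scores" (none=0, partial=0.5, full=1) under those
probabilities:

    S_edv = P_full * 1 + P_partial * 0.5 + P_non * 0

so S_edv lies in [0, 1] and grows with view completeness.  Class order is
fixed as (none, partial, full) in all arrays and serialized outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .frame_io import Frame
from .nn import ConvNetClassifier, TrainConfig, train_classifier

__all__ = [
    "CLASS_ORDER",
    "ViewProbabilities",
    "ViewScore",
    "train_view_classifier",
    "predict_view",
    "eardrum_view_score",
]

CLASS_ORDER = ("none", "partial", "full")
_AREA_SCORES = {"none": 0.0, "partial": 0.5, "full": 1.0}


@dataclass(frozen=True)
class ViewProbabilities:
    p_non: float
    p_partial: float
    p_full: float

    def __post_init__(self) -> None:
        probs = (self.p_non, self.p_partial, self.p_full)
        if any(p < -1e-9 or p > 1 + 1e-9 for p in probs):
            raise ValueError(f"probabilities must lie in [0, 1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-6:
            raise ValueError(f"probabilities must sum to 1: {probs}")


@dataclass(frozen=True)
class ViewScore:
    s_edv: float
    probs: ViewProbabilities


def train_view_classifier(
    images: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig | None = None,
    n_classes: int = 3,
) -> ConvNetClassifier:
    """Train the view classifier (or the 2-class CAM model with n_classes=2).

    ``labels`` follow :data:`CLASS_ORDER` for the 3-class head and
    (0=background/absent, 1=eardrum present) for the binary head.  Images are
    resized to ``config.image_size`` if needed.  Training is the usual
    resize / cross-entropy / Adam / best-on-validation recipe and is
    deterministic for a fixed seed.
    """
    cfg = config or TrainConfig()
    images = np.asarray(images, dtype=np.float64)
    if images.shape[1] != cfg.image_size or images.shape[2] != cfg.image_size:
        images = np.stack(
            [resize(im, (cfg.image_size, cfg.image_size, 3), anti_aliasing=True,
                    preserve_range=True) for im in images]
        )
    return train_classifier(images, labels, n_classes=n_classes, config=cfg)


def _prepare(model: ConvNetClassifier, image: np.ndarray) -> np.ndarray:
    s = model.image_size
    if image.shape[0] != s or image.shape[1] != s:
        image = resize(image, (s, s, 3), anti_aliasing=True, preserve_range=True)
    return np.clip(image, 0.0, 1.0)


def predict_view(model: ConvNetClassifier, frame: Frame | np.ndarray) -> ViewProbabilities:
    """Softmax class probabilities for one frame, in (none, partial, full) order."""
    if model.n_classes != 3:
        raise ValueError(f"view classifier needs a 3-class head, got {model.n_classes}")
    image = frame.image if isinstance(frame, Frame) else np.asarray(frame)
    probs = model.predict_proba(_prepare(model, image)[None])[0]
    return ViewProbabilities(p_non=float(probs[0]), p_partial=float(probs[1]),
                             p_full=float(probs[2]))


def eardrum_view_score(probs: ViewProbabilities) -> ViewScore:
    """Expected eardrum area score under the class probabilities."""
    s = (
        probs.p_full * _AREA_SCORES["full"]
        + probs.p_partial * _AREA_SCORES["partial"]
        + probs.p_non * _AREA_SCORES["none"]
    )
    return ViewScore(s_edv=float(s), probs=probs)
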