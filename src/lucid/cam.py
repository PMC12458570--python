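"""Weakly supervised eardrum segmentation: Grad-CAM, adversarial climbing
(AdvCAM) and its binary-class refinement (BC-AdvCAM), plus the coverage score.

Grad-CAM localizes the classifier's evidence for a class but tends to cover
only the most discriminative part of the object.  Adversarial climbing
iteratively perturbs the *input* along the gradient that raises the target
logit while suppressing the other logits and penalizing growth in regions the
map already activates:

    x_t = x_{t-1} + eps * grad_x L
    L   = y_c - sum_{k != c} y_k - lambda_restrict * || M (.) (CAM(x_t) - CAM(x_0)) ||_1
    M   = 1[ CAM(x_{t-1}) > tau ]

which progressively recruits less-discriminative object regions into the map.
For a binary eardrum/background task the foreground map is further refined by
subtracting a weighted background map:

    BC-AdvCAM(x) = AdvCAM_1(x) - lambda_bc * AdvCAM_0(x)

with negatives clamped to zero.  The eardrum coverage score S_edc is the
fraction of frame pixels inside the thresholded map.

Numerical conventions (the source formulation leaves them open): maps are
min-max normalized to [0, 1] before thresholding and before the BC
subtraction; the climbing trajectory is aggregated by summing per-iteration
raw maps and normalizing once; inside the restriction term the Grad-CAM
channel weights and the normalization constant are held fixed (stop-gradient),
so its gradient flows through the feature maps only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .nn import ConvNetClassifier

__all__ = [
    "ActivationMap",
    "ClimbingConfig",
    "CoverageScore",
    "grad_cam",
    "adversarial_climb",
    "bc_advcam",
    "threshold_mask",
    "coverage_score",
]


@dataclass(frozen=True)
class ActivationMap:
    """Nonnegative relevance map aligned to the image grid.

    ``logit_start``/``logit_end`` record the target logit before and after
    adversarial climbing (None for plain Grad-CAM), as a climb diagnostic.
    """

    values: np.ndarray  # (H, W), in [0, 1] after finalization
    class_id: int
    logit_start: float | None = None
    logit_end: float | None = None


@dataclass(frozen=True)
class ClimbingConfig:
    """Adversarial climbing hyperparameters.

    step_size (eps) is in input-intensity units per iteration; iterations is
    the climb length T; restrict_weight (lambda) scales the anti-saturation
    penalty; mask_threshold (tau) is the high-activation cut as a fraction of
    the map maximum; bc_lambda weights the background map in the BC
    subtraction.  Defaults: T=30 climb steps, lambda_restrict=7, tau=0.5,
    bc_lambda=1.0 (following common climbing practice); eps=0.02 on [0,1]
    input, sized to this package's small CNN so that thirty raw-gradient
    steps reliably raise the target logit.
    """

    step_size: float = 0.02
    iterations: int = 30
    restrict_weight: float = 7.0
    mask_threshold: float = 0.5
    bc_lambda: float = 1.0

    def validate(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if not (0.0 < self.mask_threshold < 1.0):
            raise ValueError("mask_threshold must lie in (0, 1)")
        if self.restrict_weight < 0 or self.bc_lambda < 0:
            raise ValueError("restrict_weight and bc_lambda must be >= 0")


@dataclass(frozen=True)
class CoverageScore:
    s_edc: float
    mask: np.ndarray


def _normalize(values: np.ndarray) -> np.ndarray:
    top = values.max()
    return values / top if top > 0 else values


def _raw_cam(model: ConvNetClassifier, class_id: int) -> np.ndarray:
    """ReLU'd gradient-weighted feature combination at feature resolution.

    Assumes ``model.forward`` has been called; uses the cached feature maps.
    """
    grads = model.feature_gradients(class_id)  # (1, C, fh, fw)
    weights = grads.mean(axis=(2, 3))  # Grad-CAM channel weights
    cam = np.einsum("c,chw->hw", weights[0], model.features[0])
    return np.maximum(cam, 0.0)


def _finalize(raw: np.ndarray, shape: tuple[int, int], class_id: int) -> ActivationMap:
    up = resize(raw, shape, order=1, anti_aliasing=False, preserve_range=True)
    return ActivationMap(_normalize(np.maximum(up, 0.0)), class_id)


def _check_input(image: np.ndarray, model: ConvNetClassifier) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) image, got {image.shape}")
    if image.shape[0] != model.image_size or image.shape[1] != model.image_size:
        image = resize(image, (model.image_size,) * 2 + (3,), anti_aliasing=True,
                       preserve_range=True)
    return image


def grad_cam(model: ConvNetClassifier, image: np.ndarray, class_id: int) -> ActivationMap:
    """Grad-CAM map for ``class_id``, upsampled to the image grid and
    min-max normalized to [0, 1] (an all-zero map stays all-zero)."""
    image = _check_input(image, model)
    if not (0 <= class_id < model.n_classes):
        raise ValueError(f"class_id {class_id} out of range")
    model.forward(image.transpose(2, 0, 1)[None])
    return _finalize(_raw_cam(model, class_id), image.shape[:2], class_id)


def adversarial_climb(
    model: ConvNetClassifier,
    image: np.ndarray,
    class_id: int,
    config: ClimbingConfig | None = None,
) -> ActivationMap:
    """AdvCAM: climb the target logit for T iterations and aggregate the maps.

    With ``config.iterations == 0`` this reduces exactly to :func:`grad_cam`.
    Raises ``FloatingPointError`` if the climb produces non-finite gradients
    (a degenerate classifier).
    """
    cfg = config or ClimbingConfig()
    cfg.validate()
    image = _check_input(image, model)
    if not (0 <= class_id < model.n_classes):
        raise ValueError(f"class_id {class_id} out of range")

    x = image.transpose(2, 0, 1)[None].copy()
    dlogits = np.full((1, model.n_classes), -1.0)
    dlogits[0, class_id] = 1.0  # ascend y_c, suppress the other logits

    logits0 = model.forward(x)
    logit_start = float(logits0[0, class_id])
    logit_end = logit_start
    cam0_raw = _raw_cam(model, class_id)
    cam0_n = _normalize(cam0_raw)
    agg = cam0_raw.copy()
    cam_prev_n = cam0_n

    for _t in range(cfg.iterations):
        # gradient of L at the current point x_{t-1} (forward already cached)
        mask = cam_prev_n > cfg.mask_threshold
        # restriction term: lambda * || M (.) (CAMn(x) - CAMn(x_0)) ||_1 with
        # channel weights and normalization constant held fixed
        grads = model.feature_gradients(class_id)
        weights = grads.mean(axis=(2, 3))[0]
        pre = np.einsum("c,chw->hw", weights, model.features[0])
        top = max(pre.max(), 0.0)
        dfeat_extra = None
        if cfg.restrict_weight > 0 and top > 0:
            diff = _normalize(np.maximum(pre, 0.0)) - cam0_n
            dcam = cfg.restrict_weight * mask * np.sign(diff)
            dpre = dcam * (pre > 0) / top
            dfeat_extra = -np.einsum("c,hw->chw", weights, dpre)[None]
        dx = model.backward(dlogits, dfeatures_extra=dfeat_extra)
        if not np.isfinite(dx).all():
            raise FloatingPointError("non-finite climbing gradient")
        x = x + cfg.step_size * dx

        logits = model.forward(x)
        logit_end = float(logits[0, class_id])
        cam_raw = _raw_cam(model, class_id)
        agg += cam_raw
        cam_prev_n = _normalize(cam_raw)

    final = _finalize(agg, image.shape[:2], class_id)
    return ActivationMap(final.values, class_id, logit_start, logit_end)


def bc_advcam(
    model: ConvNetClassifier,
    image: np.ndarray,
    config: ClimbingConfig | None = None,
) -> ActivationMap:
    """Binary-class AdvCAM: foreground minus weighted background map.

    Requires a 2-class head (0=background, 1=eardrum).  Both per-class AdvCAM
    maps are computed with the same config; the difference is clamped at zero
    and min-max normalized.  With ``bc_lambda == 0`` the result equals the
    foreground AdvCAM exactly.
    """
    cfg = config or ClimbingConfig()
    if model.n_classes != 2:
        raise ValueError(f"BC-AdvCAM needs a binary head, got {model.n_classes} classes")
    fg = adversarial_climb(model, image, class_id=1, config=cfg)
    if cfg.bc_lambda == 0:
        return ActivationMap(fg.values, class_id=1)
    bg = adversarial_climb(model, image, class_id=0, config=cfg)
    diff = np.maximum(fg.values - cfg.bc_lambda * bg.values, 0.0)
    return ActivationMap(_normalize(diff), class_id=1)


def threshold_mask(amap: ActivationMap | np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Binary mask of pixels above ``tau`` times the map maximum.

    An all-zero map yields an all-zero mask.
    """
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie in (0, 1)")
    values = amap.values if isinstance(amap, ActivationMap) else np.asarray(amap)
    top = values.max()
    if top <= 0:
        return np.zeros_like(values, dtype=bool)
    return values > tau * top


def coverage_score(mask: np.ndarray) -> CoverageScore:
    """Eardrum coverage S_edc = eardrum pixels / total frame pixels."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("mask must be non-empty")
    mask = mask.astype(bool)
    return CoverageScore(s_edc=float(mask.sum()) / mask.size, mask=mask)
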