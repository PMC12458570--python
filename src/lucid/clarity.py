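"""Image clarity assessment for otoscope frames.

Otoscope imagery defeats classic frequency-domain blur detectors: most of the
frame is a dark surround, variance is low, and energy sits in low frequencies.
Three otoscope-specific measures are combined instead:

* **Blur score S_bl** — sharp frames show a long-tailed, signed edge-energy
  distribution while blurry frames concentrate it near zero.  A 2-component
  Gaussian mixture is fitted to the pooled signed Sobel responses inside the
  field of view; the wider component's standard deviation sigma_max captures
  the tail, and S_bl = sigma_max / (C_p + eps) where C_p is the RMS contrast
  inside the FOV.  Larger S_bl means a clearer frame.
* **FOV detection** — candidate circles from a Hough transform are scored by
  the absolute difference between mean interior lightness and mean lightness
  of a width-delta_r exterior annulus; the circle with the largest lightness
  change is the otoscope field of view.
* **Focus score S_F** — the focus point is the argmax of the squared
  Laplacian-of-Gaussian response; S_F = r_FOV minus the distance from the
  focus point to the FOV center (clamped at zero), so centrally focused
  frames score highest.

The final blur score is the product S_blf = S_bl * S_F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks
from sklearn.mixture import GaussianMixture

__all__ = [
    "EdgeEnergySample",
    "GmmFit",
    "FovCircle",
    "ClarityResult",
    "FovNotFoundError",
    "edge_energy",
    "fit_edge_gmm",
    "blur_score",
    "fov_contrast",
    "detect_fov",
    "detect_focus_point",
    "focus_score",
    "final_blur_score",
    "assess_clarity",
]

EPSILON = 1e-6  # division guard in S_bl


class FovNotFoundError(RuntimeError):
    """No circular field of view detected; the frame gets S_blf = 0."""


@dataclass(frozen=True)
class EdgeEnergySample:
    values: np.ndarray  # 1-D signed edge responses
    source_pixel_count: int


@dataclass(frozen=True)
class GmmFit:
    means: tuple[float, float]
    sigmas: tuple[float, float]
    weights: tuple[float, float]
    sigma_max: float
    degenerate: bool = False


@dataclass(frozen=True)
class FovCircle:
    center: tuple[float, float]  # (x, y)
    radius: float
    lightness_change: float


@dataclass(frozen=True)
class ClarityResult:
    s_bl: float
    s_f: float
    s_blf: float
    sigma_max: float
    contrast: float
    focus_point: tuple[int, int]
    fov: FovCircle | None


# Signed 3x3 Sobel kernels; responses keep their sign (edge direction).
_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_SOBEL_Y = _SOBEL_X.T


def _fov_interior(shape: tuple[int, int], fov: FovCircle, shrink: float = 1.0) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = fov.center
    return (xx - cx) ** 2 + (yy - cy) ** 2 < (fov.radius - shrink) ** 2


def edge_energy(gray: np.ndarray, fov: FovCircle) -> EdgeEnergySample:
    """Pooled signed Sobel responses (both orientations) strictly inside the FOV.

    The FOV restriction keeps the dark surround and the rim step edge from
    dominating the distribution; the interior is shrunk by one pixel plus the
    kernel reach so every response is computed from in-FOV pixels only.
    """
    gray = np.asarray(gray, dtype=np.float64)
    inside = _fov_interior(gray.shape, fov, shrink=2.0)
    if inside.sum() < 9:
        raise ValueError("FOV interior smaller than the 3x3 edge kernel support")
    gx = ndimage.convolve(gray, _SOBEL_X, mode="nearest")
    gy = ndimage.convolve(gray, _SOBEL_Y, mode="nearest")
    values = np.concatenate([gx[inside], gy[inside]])
    return EdgeEnergySample(values=values, source_pixel_count=int(inside.sum()))


def fit_edge_gmm(sample: EdgeEnergySample, seed: int = 0) -> GmmFit:
    """EM fit of a 2-component 1-D Gaussian mixture to the edge responses.

    Returns the wider component's standard deviation as ``sigma_max``
    regardless of its mixture weight.  An all-identical sample cannot support
    a mixture; it returns sigma_max = 0 with the ``degenerate`` flag set.
    """
    values = np.asarray(sample.values, dtype=np.float64)
    if values.size < 50:
        raise ValueError(f"need >= 50 edge samples, got {values.size}")
    if np.ptp(values) == 0:
        return GmmFit((float(values[0]),) * 2, (0.0, 0.0), (0.5, 0.5),
                      sigma_max=0.0, degenerate=True)
    # Edge-energy distributions are near-zero-mean scale mixtures; a k-means
    # init splits them left/right and EM then stalls in that local optimum.
    # Initialize both components at the sample center with variances from the
    # inner and outer halves of the absolute deviations instead.
    center = float(np.median(values))
    dev = np.abs(values - center)
    cut = np.median(dev)
    inner, outer = values[dev <= cut], values[dev > cut]
    var_floor = max(values.var() * 1e-6, 1e-18)
    var_inner = max(inner.var(), var_floor)
    var_outer = max(outer.var(), var_inner * (1 + 1e-6))
    gmm = GaussianMixture(
        n_components=2, covariance_type="full", max_iter=200, tol=1e-6,
        random_state=seed, reg_covar=1e-12,
        weights_init=np.array([0.5, 0.5]),
        means_init=np.array([[center], [center]]),
        precisions_init=np.array([[[1.0 / var_inner]], [[1.0 / var_outer]]]),
    )
    gmm.fit(values[:, None])
    sigmas = np.sqrt(gmm.covariances_.reshape(2))
    return GmmFit(
        means=tuple(float(m) for m in gmm.means_.reshape(2)),
        sigmas=(float(sigmas[0]), float(sigmas[1])),
        weights=(float(gmm.weights_[0]), float(gmm.weights_[1])),
        sigma_max=float(sigmas.max()),
    )


def blur_score(fit: GmmFit, contrast: float, epsilon: float = EPSILON) -> float:
    """S_bl = sigma_max / (C_p + epsilon); larger means clearer."""
    if contrast < 0:
        raise ValueError("contrast must be >= 0")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    return fit.sigma_max / (contrast + epsilon)


def fov_contrast(gray: np.ndarray, fov: FovCircle) -> float:
    """RMS contrast (intensity standard deviation) inside the FOV."""
    inside = _fov_interior(np.asarray(gray).shape, fov)
    if not inside.any():
        return 0.0
    return float(np.std(np.asarray(gray, dtype=np.float64)[inside]))


def detect_fov(
    gray: np.ndarray,
    radius_range: tuple[float, float] | None = None,
    delta_r: int = 5,
    n_candidates: int = 8,
    radius_step: int = 1,
) -> FovCircle:
    """Find the otoscope FOV circle by Hough transform + lightness change.

    Candidate circles come from a Hough circle transform on Canny edges
    (quantile thresholds, so detection is invariant to global intensity
    scaling).  Each candidate k is scored by
    delta_L_k = |mean interior lightness - mean exterior-annulus lightness|,
    the annulus having width ``delta_r`` and being clipped to image bounds;
    the candidate with the largest delta_L wins.

    ``radius_range`` defaults to (0.25, 0.60) * min(H, W).
    Raises :class:`FovNotFoundError` when no circular structure is found.
    """
    gray = np.asarray(gray, dtype=np.float64)
    h, w = gray.shape
    if radius_range is None:
        radius_range = (0.25 * min(h, w), 0.60 * min(h, w))
    radii = np.arange(int(radius_range[0]), int(radius_range[1]) + 1, radius_step)
    if len(radii) == 0:
        raise ValueError("empty radius range")

    scale = gray.max()
    norm = gray / scale if scale > 0 else gray
    edges = canny(norm, sigma=2.0, use_quantiles=True,
                  low_threshold=0.90, high_threshold=0.98)
    if not edges.any():
        raise FovNotFoundError("no edges: image has no circular structure")
    accum = hough_circle(edges, radii)
    _, cxs, cys, rads = hough_circle_peaks(
        accum, radii, total_num_peaks=n_candidates, normalize=True
    )
    if len(cxs) == 0:
        raise FovNotFoundError("Hough transform produced no circle candidates")

    yy, xx = np.mgrid[0:h, 0:w]

    def delta_l(cx: float, cy: float, r: float) -> float:
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        interior = d2 <= r**2
        annulus = (d2 > r**2) & (d2 <= (r + delta_r) ** 2)
        if not interior.any() or not annulus.any():
            return -np.inf
        return abs(float(gray[interior].mean()) - float(gray[annulus].mean()))

    best: FovCircle | None = None
    for cx, cy, r in zip(cxs, cys, rads):
        dl = delta_l(cx, cy, r)
        if np.isfinite(dl) and (best is None or dl > best.lightness_change):
            best = FovCircle((float(cx), float(cy)), float(r), dl)
    if best is None:
        raise FovNotFoundError("no candidate circle had a valid exterior annulus")

    # Refine the winning candidate's center over its integer neighborhood
    # with the same lightness-change objective (the accumulator peak can sit
    # 1-2 px off on blurred frames).  The radius is kept from the Hough
    # accumulator: it is localized by the edge-gradient maximum, which stays
    # on the rim under blur, whereas the annulus-contrast objective drifts
    # outward on soft rims.
    cx0, cy0 = best.center
    r0 = best.radius
    for cx in np.arange(cx0 - 2, cx0 + 2.5, 1.0):
        for cy in np.arange(cy0 - 2, cy0 + 2.5, 1.0):
            dl = delta_l(cx, cy, r0)
            if np.isfinite(dl) and dl > best.lightness_change:
                best = FovCircle((float(cx), float(cy)), r0, dl)
    return best


def detect_focus_point(gray: np.ndarray, sigma_smooth: float = 2.0) -> tuple[int, int]:
    """Argmax of the squared Laplacian-of-Gaussian sharpness map S(x, y).

    Returns (x, y) = (column, row).  Ties are broken by smallest row then
    column (so a flat image returns (0, 0)).
    """
    gray = np.asarray(gray, dtype=np.float64)
    smoothed = ndimage.gaussian_filter(gray, sigma_smooth)
    sharpness = ndimage.laplace(smoothed) ** 2
    flat_idx = int(np.argmax(sharpness))  # row-major -> smallest row, then column
    row, col = np.unravel_index(flat_idx, sharpness.shape)
    return (int(col), int(row))


def focus_score(fov: FovCircle, focus_point: tuple[float, float]) -> float:
    """S_F = r_FOV - distance(focus point, FOV center), clamped below at 0."""
    dist = float(np.hypot(focus_point[0] - fov.center[0], focus_point[1] - fov.center[1]))
    return max(fov.radius - dist, 0.0)


def final_blur_score(s_bl: float, s_f: float) -> float:
    """S_blf = S_bl * S_F; zero iff either factor is zero."""
    if s_bl < 0 or s_f < 0:
        raise ValueError("scores must be non-negative")
    return s_bl * s_f


def assess_clarity(
    gray: np.ndarray,
    seed: int = 0,
    sigma_smooth: float = 2.0,
    delta_r: int = 5,
    radius_range: tuple[float, float] | None = None,
    epsilon: float = EPSILON,
) -> ClarityResult:
    """Full clarity assessment of one grayscale frame.

    A frame without a detectable FOV receives S_blf = 0 (its blur and focus
    scores are reported as 0 with ``fov=None``).
    """
    try:
        fov = detect_fov(gray, radius_range=radius_range, delta_r=delta_r)
    except FovNotFoundError:
        focus = detect_focus_point(gray, sigma_smooth)
        return ClarityResult(0.0, 0.0, 0.0, 0.0, 0.0, focus, None)
    sample = edge_energy(gray, fov)
    fit = fit_edge_gmm(sample, seed=seed)
    contrast = fov_contrast(gray, fov)
    s_bl = blur_score(fit, contrast, epsilon)
    focus = detect_focus_point(gray, sigma_smooth)
    s_f = focus_score(fov, focus)
    return ClarityResult(
        s_bl=s_bl, s_f=s_f, s_blf=final_blur_score(s_bl, s_f),
        sigma_max=fit.sigma_max, contrast=contrast, focus_point=focus, fov=fov,
    )
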