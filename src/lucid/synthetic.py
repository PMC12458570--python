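"""Synthetic otoscope-like frames and videos with known ground truth.

Real otoscopy frames show a bright circular field of view (FOV, the illuminated
ear canal) on a dark surround, with the eardrum appearing as a lighter, pearly
disk inside it.  This module renders a geometric emulation of that regime —
textured FOV interior, optional textured "eardrum" disk, controllable Gaussian
blur and an optional blur-exempt sharp patch marking the focus location — so
that every pipeline stage (view classification, CAM segmentation, FOV/focus
detection, blur scoring, rank fusion) can be tested against exact ground truth.

Conventions: 0-based (x, y) = (column, row) coordinates, origin top-left;
images are float RGB in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SyntheticFrameSpec",
    "SyntheticFrame",
    "generate_frame",
    "generate_video",
    "generate_shapes_dataset",
    "generate_view_dataset",
    "random_frame_spec",
    "designed_video_specs",
]

VISIBILITIES = ("full", "partial", "none")

# mean colors (R, G, B): warm canal wall vs lighter pearly-gray eardrum
_FOV_COLOR = np.array([0.62, 0.42, 0.30])
_EARDRUM_COLOR = np.array([0.82, 0.74, 0.66])
_SHARP_PATCH_RADIUS = 12  # px; blur-exempt focus patch


@dataclass(frozen=True)
class SyntheticFrameSpec:
    """Full parametric description of one synthetic frame.

    ``focus_offset`` is the sharp patch's displacement from the FOV center;
    ``None`` disables the patch (used for pure blur-monotonicity frames).
    """

    image_size: tuple[int, int] = (240, 240)  # (height, width)
    fov_center: tuple[float, float] = (120.0, 120.0)  # (x, y)
    fov_radius: float = 90.0
    eardrum_center: tuple[float, float] = (120.0, 120.0)
    eardrum_radius: float = 45.0
    visibility: str = "full"
    blur_sigma: float = 0.0
    focus_offset: tuple[float, float] | None = (0.0, 0.0)
    texture_seed: int = 0
    noise_std: float = 0.01

    def validate(self) -> None:
        h, w = self.image_size
        cx, cy = self.fov_center
        r = self.fov_radius
        if r <= 0:
            raise ValueError("fov_radius must be positive")
        if not (cx - r >= 0 and cx + r <= w - 1 and cy - r >= 0 and cy + r <= h - 1):
            raise ValueError(
                f"FOV circle (center=({cx},{cy}), r={r}) does not fit in a {w}x{h} image"
            )
        if self.visibility not in VISIBILITIES:
            raise ValueError(f"visibility must be one of {VISIBILITIES}")
        if self.blur_sigma < 0 or self.noise_std < 0:
            raise ValueError("blur_sigma and noise_std must be non-negative")
        if self.visibility == "full":
            ex, ey = self.eardrum_center
            d = np.hypot(ex - cx, ey - cy)
            if d + self.eardrum_radius > r:
                raise ValueError("visibility='full' requires the eardrum disk inside the FOV")
        if self.visibility == "partial":
            ex, ey = self.eardrum_center
            d = np.hypot(ex - cx, ey - cy)
            if d + self.eardrum_radius <= r:
                raise ValueError("visibility='partial' requires the disk clipped by the FOV rim")
            if d - self.eardrum_radius >= r:
                raise ValueError("visibility='partial' requires part of the disk inside the FOV")


@dataclass(frozen=True)
class SyntheticFrame:
    image: np.ndarray  # (H, W, 3) in [0, 1]
    spec: SyntheticFrameSpec
    eardrum_mask: np.ndarray  # bool (H, W); ground-truth segmentation
    fov_mask: np.ndarray  # bool (H, W)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = center
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def _bandlimited_texture(shape: tuple[int, int], rng: np.random.Generator,
                         smooth: float = 1.0, amplitude: float = 0.22) -> np.ndarray:
    """Zero-mean smoothed uniform noise; keeps high frequencies so blur has signal."""
    noise = rng.uniform(-1.0, 1.0, size=shape)
    tex = ndimage.gaussian_filter(noise, smooth)
    tex /= max(np.abs(tex).max(), 1e-12)
    return amplitude * tex


def generate_frame(spec: SyntheticFrameSpec) -> SyntheticFrame:
    """Render one frame deterministically from its spec.

    Composition order: dark surround -> textured FOV interior -> textured
    eardrum disk (clipped to the FOV) -> sharp focus patch -> Gaussian blur of
    everything except the patch -> sensor noise -> clip to [0, 1].
    """
    spec.validate()
    h, w = spec.image_size
    rng = np.random.default_rng(spec.texture_seed)

    fov_mask = _disk_mask((h, w), spec.fov_center, spec.fov_radius)
    if spec.visibility == "none":
        eardrum_mask = np.zeros((h, w), dtype=bool)
    else:
        disk = _disk_mask((h, w), spec.eardrum_center, spec.eardrum_radius)
        eardrum_mask = disk & fov_mask

    img = np.full((h, w, 3), 0.03)  # dark surround
    img += rng.normal(0.0, 0.01, size=(h, w, 3))

    fov_tex = _bandlimited_texture((h, w), rng)
    img[fov_mask] = _FOV_COLOR[None, :] + fov_tex[fov_mask, None]
    if eardrum_mask.any():
        drum_tex = _bandlimited_texture((h, w), rng, smooth=1.2, amplitude=0.16)
        img[eardrum_mask] = _EARDRUM_COLOR[None, :] + drum_tex[eardrum_mask, None]

    patch_mask = None
    if spec.focus_offset is not None:
        fx = spec.fov_center[0] + spec.focus_offset[0]
        fy = spec.fov_center[1] + spec.focus_offset[1]
        patch_mask = _disk_mask((h, w), (fx, fy), _SHARP_PATCH_RADIUS) & fov_mask
        yy, xx = np.mgrid[0:h, 0:w]
        # 5-px blocks: coarse enough that Gaussian pre-smoothing in the focus
        # detector does not cancel adjacent cells, so the patch has a
        # well-defined sharpness argmax
        checker = (((xx // 5) + (yy // 5)) % 2).astype(float)
        img[patch_mask] = 0.25 + 0.6 * checker[patch_mask, None]

    if spec.blur_sigma > 0:
        blurred = np.stack(
            [ndimage.gaussian_filter(img[..., c], spec.blur_sigma) for c in range(3)], axis=-1
        )
        if patch_mask is not None:
            blurred[patch_mask] = img[patch_mask]  # focus patch exempt from blur
        img = blurred

    if spec.noise_std > 0:
        img = img + rng.normal(0.0, spec.noise_std, size=img.shape)

    return SyntheticFrame(np.clip(img, 0.0, 1.0), spec, eardrum_mask, fov_mask)


def _is_designed_best(spec: SyntheticFrameSpec) -> bool:
    return (
        spec.visibility == "full"
        and spec.blur_sigma == 0
        and spec.focus_offset == (0.0, 0.0)
    )


def generate_video(specs: list[SyntheticFrameSpec], path: str | Path) -> pd.DataFrame:
    """Render frames and write them as a video plus a ground-truth sidecar CSV.

    A path ending in ``.tif``/``.tiff`` becomes a lossless multi-page TIFF
    stack (the container used for exact round-trip tests); any other path is
    treated as a directory of PNG frames.  The sidecar
    ``<stem>_ground_truth.csv`` records per-frame visibility, coverage,
    blur_sigma, focus location and a ``designed_best`` flag.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    sizes = {s.image_size for s in specs}
    if len(sizes) > 1:
        raise ValueError(f"all specs must share image_size; got {sizes}")

    frames = [generate_frame(s) for s in specs]
    path = Path(path)
    arr = np.stack([(f.image * 255).round().astype(np.uint8) for f in frames])
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, arr, photometric="rgb")
        sidecar = path.with_name(path.stem + "_ground_truth.csv")
    else:
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(arr):
            iio.imwrite(path / f"frame_{i:05d}.png", frame)
        sidecar = path / "ground_truth.csv"

    h, w = specs[0].image_size
    rows = []
    for i, (s, f) in enumerate(zip(specs, frames)):
        focus = (
            (s.fov_center[0] + s.focus_offset[0], s.fov_center[1] + s.focus_offset[1])
            if s.focus_offset is not None
            else (np.nan, np.nan)
        )
        rows.append(
            {
                "frame_index": i,
                "visibility": s.visibility,
                "coverage": float(f.eardrum_mask.sum()) / (h * w),
                "blur_sigma": s.blur_sigma,
                "focus_x": focus[0],
                "focus_y": focus[1],
                "fov_x": s.fov_center[0],
                "fov_y": s.fov_center[1],
                "fov_r": s.fov_radius,
                "designed_best": _is_designed_best(s),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(sidecar, index=False)
    return table


def random_frame_spec(
    rng: np.random.Generator,
    image_size: tuple[int, int] = (240, 240),
    visibility: str | None = None,
    blur_sigma: float | None = None,
    with_focus_patch: bool = True,
) -> SyntheticFrameSpec:
    """Draw a valid random spec; partial visibility places 25-75% of the disk
    outside the FOV by construction."""
    h, w = image_size
    if visibility is None:
        visibility = rng.choice(VISIBILITIES)
    r_fov = rng.uniform(0.30, 0.40) * min(h, w)
    margin = r_fov + 2
    cx = rng.uniform(margin, w - 1 - margin)
    cy = rng.uniform(margin, h - 1 - margin)
    r_e = rng.uniform(0.35, 0.55) * r_fov
    if visibility == "full":
        d = rng.uniform(0.0, max(r_fov - r_e - 2, 0.0))
    elif visibility == "partial":
        # center distance in (r_fov - r_e, r_fov + r_e) clips the disk;
        # the middle of that band keeps ~25-75% of the area outside
        d = r_fov + r_e * rng.uniform(-0.4, 0.4)
    else:
        d = 0.0
    theta = rng.uniform(0, 2 * np.pi)
    e_center = (cx + d * np.cos(theta), cy + d * np.sin(theta))
    if with_focus_patch:
        rho = rng.uniform(0.0, 0.5 * r_fov)
        phi = rng.uniform(0, 2 * np.pi)
        focus = (rho * np.cos(phi), rho * np.sin(phi))
    else:
        focus = None
    blur = float(rng.choice([0.0, 1.0, 2.0, 4.0])) if blur_sigma is None else blur_sigma
    return SyntheticFrameSpec(
        image_size=image_size,
        fov_center=(cx, cy),
        fov_radius=r_fov,
        eardrum_center=e_center,
        eardrum_radius=r_e,
        visibility=visibility,
        blur_sigma=blur,
        focus_offset=focus,
        texture_seed=int(rng.integers(0, 2**31 - 1)),
        noise_std=0.01,
    )


def designed_video_specs(seed: int, image_size: tuple[int, int] = (160, 160),
                         n_frames: int = 10) -> list[SyntheticFrameSpec]:
    """A short clip with exactly one designed best frame among degraded ones.

    The best frame has a fully visible, large, centered eardrum, zero blur and
    a centered focus patch; every other frame is measurably degraded on at
    least one axis (absent/partial view, strong blur, off-center focus,
    reduced eardrum coverage) and no better on the rest.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    center = ((w - 1) / 2, (h - 1) / 2)
    r_fov = 0.36 * min(h, w)
    base = SyntheticFrameSpec(
        image_size=image_size,
        fov_center=center,
        fov_radius=r_fov,
        eardrum_center=center,
        eardrum_radius=0.55 * r_fov,
        visibility="full",
        blur_sigma=0.0,
        focus_offset=(0.0, 0.0),
        texture_seed=int(rng.integers(0, 2**31 - 1)),
    )
    specs = [base]
    degradations = ["none_view", "partial", "blur", "off_focus", "small", "blur", "partial",
                    "none_view", "off_focus"]
    for kind in degradations[: n_frames - 1]:
        seed_t = int(rng.integers(0, 2**31 - 1))
        if kind == "none_view":
            specs.append(replace(base, visibility="none", blur_sigma=3.0,
                                 focus_offset=None, texture_seed=seed_t))
        elif kind == "partial":
            d = r_fov  # half the disk outside
            specs.append(replace(base, visibility="partial", blur_sigma=1.5,
                                 eardrum_center=(center[0] + d, center[1]),
                                 focus_offset=(0.3 * r_fov, 0.0), texture_seed=seed_t))
        elif kind == "blur":
            specs.append(replace(base, blur_sigma=4.0, focus_offset=None,
                                 eardrum_radius=0.4 * r_fov, texture_seed=seed_t))
        elif kind == "off_focus":
            specs.append(replace(base, blur_sigma=2.0, eardrum_radius=0.4 * r_fov,
                                 focus_offset=(0.85 * r_fov, 0.0), texture_seed=seed_t))
        elif kind == "small":
            specs.append(replace(base, eardrum_radius=0.2 * r_fov, blur_sigma=1.0,
                                 focus_offset=(0.5 * r_fov, 0.2 * r_fov),
                                 texture_seed=seed_t))
    order = rng.permutation(len(specs))
    return [specs[i] for i in order]


def generate_view_dataset(
    n: int, seed: int, image_size: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced 3-class (none / partial / full) image set for the view model.

    Labels follow the fixed class order 0=none, 1=partial, 2=full.
    """
    if n < 3:
        raise ValueError("n must be >= 3 (one image per class)")
    rng = np.random.default_rng(seed)
    images = np.empty((n, image_size, image_size, 3))
    labels = np.array([i % 3 for i in range(n)])
    names = {0: "none", 1: "partial", 2: "full"}
    for i in range(n):
        # half the images carry a focus patch, matching the frames the
        # pipeline scores, so the patch never marks a frame as atypical
        spec = random_frame_spec(
            rng, image_size=(image_size, image_size), visibility=names[labels[i]],
            blur_sigma=float(rng.uniform(0.0, 1.5)),
            with_focus_patch=bool(rng.integers(0, 2)),
        )
        images[i] = generate_frame(spec).image
    return images, labels


def generate_shapes_dataset(
    n: int, seed: int, image_size: int = 64
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class-balanced eardrum-present/absent image set with ground-truth masks.

    Returns ``(images, labels, masks)`` with images (n, s, s, 3) in [0, 1],
    labels in {0: absent, 1: present} balanced within +/-1, and boolean masks
    (all-zero for absent images).  Used to train and evaluate the binary CAM
    model; every present image has a nonempty mask by construction.

    "Present" mixes fully visible and rim-clipped (partial) eardrums — the
    binary task merges the partial and full view classes.  The partial
    examples matter for localization: a model that must flag a small clipped
    drum cannot lean on whole-image color statistics, so its evidence (and
    hence its class activation map) stays on the drum pixels.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    images = np.empty((n, image_size, image_size, 3))
    masks = np.zeros((n, image_size, image_size), dtype=bool)
    labels = np.array([i % 2 for i in range(n)])  # alternating -> balanced +/-1
    for i in range(n):
        if labels[i] == 1:
            visibility = "full" if rng.uniform() < 0.5 else "partial"
        else:
            visibility = "none"
        spec = random_frame_spec(
            rng, image_size=(image_size, image_size), visibility=visibility,
            blur_sigma=float(rng.uniform(0.0, 1.0)), with_focus_patch=False,
        )
        frame = generate_frame(spec)
        images[i] = frame.image
        masks[i] = frame.eardrum_mask
    return images, labels, masks
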