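"""Seeded generator of paired synthetic TEE-like images and LAA-like masks.

The generator emulates the statistical structure of a clinical
transesophageal-echo LAA dataset without any clinical data: a sector-shaped
B-mode field of view with multiplicative speckle, a hypoechoic lobed cavity
with a narrow neck as the segmentation target, per-patient anatomical
correlation (all images of a patient jitter around one base shape), and a
per-patient thrombus flag rendered as an echogenic blob inside the cavity.

Every output is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data import DatasetManifest, SampleRecord, save_image_png, save_manifest, save_mask_png


@dataclass
class ShapeParams:
    """Geometry of one LAA-like cavity.

    The body is an ellipse with semi-axes ``body_axes`` (pixels) at
    ``orientation`` (radians); ``n_lobes - 1`` accessory lobes overlap the
    distal body boundary; a narrow neck channel of width
    ``neck_width_frac * (2 * minor axis)`` extends from the proximal pole;
    ``curvature`` bends the whole shape into the finger-like hook.
    """

    n_lobes: int = 2
    neck_width_frac: float = 0.3
    body_axes: tuple[float, float] = (22.0, 13.0)
    orientation: float = 0.4
    center: tuple[float, float] = (64.0, 64.0)
    curvature: float = 0.2

    def validate(self) -> None:
        a, b = self.body_axes
        if not np.all(np.isfinite([a, b, self.orientation, self.curvature,
                                   *self.center, self.neck_width_frac])):
            raise ValueError("ShapeParams fields must be finite")
        if a <= 0 or b <= 0:
            raise ValueError("body_axes must be positive (degenerate shape)")
        if not 1 <= int(self.n_lobes) <= 4:
            raise ValueError("n_lobes must be in 1..4")
        if not 0.0 < self.neck_width_frac < 1.0:
            raise ValueError("neck_width_frac must be in (0, 1)")


@dataclass
class SpeckleParams:
    """Appearance of the rendered B-mode frame.

    Speckle is multiplicative, per pixel, Gamma distributed with unit mean
    and standard deviation ``speckle_scale``; ``psf_sigma`` is the Gaussian
    point-spread blur in pixels.  The cavity must be hypoechoic:
    ``cavity_level < tissue_level``.
    """

    speckle_scale: float = 0.3
    psf_sigma: float = 1.0
    tissue_level: float = 0.6
    cavity_level: float = 0.15
    sector_angle: float = np.deg2rad(75.0)
    thrombus: bool = False
    thrombus_level: float = 0.85

    def validate(self) -> None:
        for name in ("tissue_level", "cavity_level", "thrombus_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cavity_level >= self.tissue_level:
            raise ValueError("cavity_level must be below tissue_level (hypoechoic cavity)")
        if self.speckle_scale < 0 or self.psf_sigma < 0:
            raise ValueError("speckle_scale and psf_sigma must be non-negative")
        if not 0 < self.sector_angle < np.pi:
            raise ValueError("sector_angle must be in (0, pi)")


def _body_frame(size: tuple[int, int], shape: ShapeParams):
    """Rotated, curvature-warped coordinates (u along the major axis)."""
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = shape.center
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(shape.orientation), np.sin(shape.orientation)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    a = shape.body_axes[0]
    v = v - shape.curvature * (u * u) / a   # bend into a hook
    return u, v


def generate_laa_mask(shape: ShapeParams, size: tuple[int, int],
                      rng: np.random.Generator) -> np.ndarray:
    """Rasterize one LAA-like binary mask.

    The rng drives a small low-frequency boundary wobble and the placement
    of accessory lobes; identical (shape, size, seed) give identical masks.
    """
    shape.validate()
    h, w = size
    if h < 32 or w < 32:
        raise ValueError("size must be at least 32x32")
    a, b = shape.body_axes
    u, v = _body_frame(size, shape)

    # low-frequency radial wobble of the boundary (<= ~6%)
    phase = np.arctan2(v / b, u / a)
    amps = rng.uniform(-0.03, 0.03, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    wobble = 1.0
    for k in range(3):
        wobble = wobble + amps[k] * np.cos((k + 2) * phase + phases[k])

    r2 = (u / a) ** 2 + (v / b) ** 2
    mask = r2 <= wobble

    # accessory lobes: smaller ellipses centred on the distal body boundary
    for _ in range(int(shape.n_lobes) - 1):
        psi = rng.uniform(-0.45 * np.pi, 0.45 * np.pi)
        u0 = 0.9 * a * np.cos(psi)
        v0 = 0.9 * b * np.sin(psi)
        la = a * rng.uniform(0.35, 0.5)
        lb = b * rng.uniform(0.35, 0.5)
        mask |= ((u - u0) / la) ** 2 + ((v - v0) / lb) ** 2 <= 1.0

    # narrow neck channel from the proximal pole
    neck_half = shape.neck_width_frac * b
    neck_len = 0.8 * a
    mask |= (u >= -(a + neck_len)) & (u <= -0.2 * a) & (np.abs(v) <= neck_half)

    mask = mask.astype(np.uint8)
    # image-border clipping can in principle split the shape; keep the
    # largest component so the target stays a single connected structure
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = (labels == (1 + int(np.argmax(sizes)))).astype(np.uint8)
    return mask


def sector_mask(size: tuple[int, int], sector_angle: float) -> np.ndarray:
    """Ultrasound wedge: apex above the top edge, opening downward."""
    h, w = size
    apex_y, apex_x = -0.08 * h, w / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dy, dx = yy - apex_y, xx - apex_x
    r = np.hypot(dy, dx)
    theta = np.arctan2(dx, dy)          # angle from the downward axis
    radius = 1.15 * h
    return (np.abs(theta) <= sector_angle / 2.0) & (r <= radius)


def render_tee_image(mask: np.ndarray, sp: SpeckleParams,
                     rng: np.random.Generator) -> np.ndarray:
    """Render a grayscale B-mode-like frame for a given cavity mask."""
    sp.validate()
    m = np.asarray(mask)
    if not np.all(np.isin(np.unique(m), (0, 1))):
        raise ValueError("mask must be binary")
    size = m.shape
    sector = sector_mask(size, sp.sector_angle)
    if not np.any((m == 1) & sector):
        raise ValueError("mask lies entirely outside the imaging sector (unusable geometry)")

    img = np.full(size, sp.tissue_level, dtype=np.float64)
    img[m == 1] = sp.cavity_level

    if sp.thrombus:
        img = _place_thrombus(img, m, sp, rng)

    if sp.speckle_scale > 0:
        s2 = sp.speckle_scale ** 2
        noise = rng.gamma(shape=1.0 / s2, scale=s2, size=size)
        img = img * noise
    if sp.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, sp.psf_sigma)

    img = np.clip(img, 0.0, 1.0)
    img[~sector] = 0.0
    return img


def _place_thrombus(img: np.ndarray, mask: np.ndarray, sp: SpeckleParams,
                    rng: np.random.Generator) -> np.ndarray:
    """Drop a bright elliptical blob strictly inside the cavity."""
    erode_r = max(2, int(np.ceil(2 * sp.psf_sigma)) + 1)
    interior = mask.astype(bool)
    for radius in range(erode_r, 0, -1):
        er = ndimage.binary_erosion(mask, iterations=radius)
        if er.any():
            interior = er
            break
    ys, xs = np.nonzero(interior)
    idx = rng.integers(len(ys))
    cy, cx = float(ys[idx]), float(xs[idx])
    area = float(mask.sum())
    rb = max(2.0 * sp.psf_sigma + 1.0, 0.25 * np.sqrt(area / np.pi))
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]].astype(float)
    blob = ((yy - cy) ** 2 + (xx - cx) ** 2 <= rb * rb) & (mask == 1)
    out = img.copy()
    out[blob] = sp.thrombus_level
    return out


# ---------------------------------------------------------------------------
# dataset-level generation


def _sample_base_shape(rng: np.random.Generator, size: tuple[int, int]) -> ShapeParams:
    h, w = size
    scale = min(h, w)
    a = scale * rng.uniform(0.14, 0.22)
    b = a * rng.uniform(0.45, 0.68)
    return ShapeParams(
        n_lobes=int(rng.integers(1, 5)),
        neck_width_frac=float(rng.uniform(0.15, 0.4)),
        body_axes=(float(a), float(b)),
        orientation=float(rng.uniform(-0.4 * np.pi, 0.4 * np.pi)),
        center=(h * 0.5 + float(rng.uniform(-0.08, 0.08)) * h,
                w * 0.5 + float(rng.uniform(-0.08, 0.08)) * w),
        curvature=float(rng.uniform(-0.3, 0.3)),
    )


def _jitter_shape(base: ShapeParams, rng: np.random.Generator,
                  size: tuple[int, int]) -> ShapeParams:
    """Per-image jitter <= ~10% per field around the patient base shape."""
    h, w = size
    a, b = base.body_axes
    return replace(
        base,
        body_axes=(a * float(rng.uniform(0.9, 1.1)), b * float(rng.uniform(0.9, 1.1))),
        neck_width_frac=float(np.clip(base.neck_width_frac * rng.uniform(0.9, 1.1),
                                      0.05, 0.95)),
        orientation=base.orientation + float(rng.uniform(-0.1, 0.1)),
        curvature=base.curvature + float(rng.uniform(-0.03, 0.03)),
        center=(base.center[0] + float(rng.uniform(-0.03, 0.03)) * h,
                base.center[1] + float(rng.uniform(-0.03, 0.03)) * w),
    )


def generate_dataset(n_patients: int, images_per_patient: int,
                     thrombus_fraction: float, size: tuple[int, int],
                     seed: int, out_dir: str | Path) -> DatasetManifest:
    """Write a full synthetic dataset (PNG pairs + manifest.csv).

    All images of one patient share one base :class:`ShapeParams` with small
    per-image jitter, so within-patient masks are more alike than
    cross-patient ones; the thrombus flag is constant per patient.
    """
    if n_patients < 3:
        raise ValueError("need at least 3 patients for a patient-level 4:1:1 split")
    if not 0.0 <= thrombus_fraction <= 1.0:
        raise ValueError("thrombus_fraction must lie in [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_thromb = int(round(thrombus_fraction * n_patients))
    flags = np.zeros(n_patients, dtype=bool)
    flags[rng.permutation(n_patients)[:n_thromb]] = True

    records: list[SampleRecord] = []
    for p in range(n_patients):
        pid = f"P{p:02d}"
        base = _sample_base_shape(rng, size)
        sp_base = SpeckleParams(thrombus=bool(flags[p]))
        for i in range(images_per_patient):
            shape = _jitter_shape(base, rng, size)
            sp = replace(
                sp_base,
                tissue_level=float(np.clip(sp_base.tissue_level + rng.uniform(-0.03, 0.03),
                                           0, 1)),
                cavity_level=float(np.clip(sp_base.cavity_level + rng.uniform(-0.03, 0.03),
                                           0, 1)),
            )
            mask = generate_laa_mask(shape, size, rng)
            image = render_tee_image(mask, sp, rng)
            img_rel = f"{pid}_{i:03d}.png"
            msk_rel = f"{pid}_{i:03d}_mask.png"
            save_image_png(image, out_dir / img_rel)
            save_mask_png(mask, out_dir / msk_rel)
            records.append(SampleRecord(img_rel, msk_rel, pid, bool(flags[p])))

    manifest = DatasetManifest(records, tuple(size), seed, out_dir)
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest
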