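"""Deterministic synthetic fundus phantoms with grade-dependent lesions.

A phantom is a dark field containing a bright, warm-coloured circular
fundus disc crossed by wavy vessel curves, plus three lesion families whose
counts and sizes grow with the ICDR grade:

* microaneurysm-like small dark-red dots,
* exudate-like bright yellow blobs,
* haemorrhage-like larger dark-red blotches.

Grade 0 renders a clean retina (no lesions); the default ladder places
0 / 3 / 8 / 16 / 28 lesions at grades 0-4 with sizes scaling up by 15% per
grade.  These are frozen, desk-scale stand-ins for real fundus photographs:
they give the downstream pipeline a learnable grade signal and exact ground
truth, not photorealism.  All randomness flows from explicit seeds.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from scipy import ndimage

from .data_io import Manifest, ManifestRecord, write_manifest

__all__ = ["PhantomConfig", "render_phantom", "generate_dataset"]

#: total lesions per grade (micro + exudate + haemorrhage), frozen defaults
MICRO_COUNTS = (0, 2, 4, 8, 14)
EXUDATE_COUNTS = (0, 1, 3, 5, 8)
HAEMORRHAGE_COUNTS = (0, 0, 1, 3, 6)


@dataclass
class PhantomConfig:
    image_side: int = 224
    disc_radius_frac: float = 0.45
    disc_color: tuple[float, float, float] = (0.72, 0.38, 0.14)
    background: tuple[float, float, float] = (0.04, 0.02, 0.02)
    n_vessels: int = 6
    vessel_width_frac: float = 0.012
    vessel_waviness: float = 0.25
    micro_counts: tuple[int, ...] = MICRO_COUNTS
    exudate_counts: tuple[int, ...] = EXUDATE_COUNTS
    haemorrhage_counts: tuple[int, ...] = HAEMORRHAGE_COUNTS
    micro_radius_frac: tuple[float, float] = (0.010, 0.018)
    exudate_radius_frac: tuple[float, float] = (0.020, 0.035)
    haemorrhage_radius_frac: tuple[float, float] = (0.035, 0.060)
    size_growth_per_grade: float = 0.15
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("micro_counts", "exudate_counts", "haemorrhage_counts"):
            counts = getattr(self, name)
            if len(counts) != 5:
                raise ValueError(f"{name} must list counts for grades 0..4")
            if counts[0] != 0:
                raise ValueError("grade 0 must have zero lesions")
            if any(b < a for a, b in zip(counts, counts[1:])):
                raise ValueError(f"{name} must be non-decreasing in grade")
        max_scale = 1 + self.size_growth_per_grade * 4
        biggest = max(self.micro_radius_frac[1], self.exudate_radius_frac[1],
                      self.haemorrhage_radius_frac[1]) * max_scale
        if biggest >= self.disc_radius_frac:
            raise ValueError(
                f"largest lesion radius {biggest:.3f} (fraction of side) exceeds "
                f"disc radius {self.disc_radius_frac}"
            )


def _disc_mask(side: int, radius: float, soft: float = 1.5) -> np.ndarray:
    c = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    dist = np.hypot(yy - c, xx - c)
    return np.clip((radius - dist) / soft + 0.5, 0.0, 1.0)


def _vessel_mask(side: int, radius: float, cfg: PhantomConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Distance-based soft mask of wavy curves radiating from the disc centre."""
    hit = np.zeros((side, side), dtype=bool)
    c = (side - 1) / 2.0
    s = np.linspace(0.02, 0.92, 4 * side)
    for _ in range(cfg.n_vessels):
        theta0 = rng.uniform(0, 2 * np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        freq = rng.uniform(2.0, 4.0)
        theta = theta0 + cfg.vessel_waviness * np.sin(freq * np.pi * s + phase)
        r = s * radius
        py = np.clip(np.round(c + r * np.sin(theta)).astype(int), 0, side - 1)
        px = np.clip(np.round(c + r * np.cos(theta)).astype(int), 0, side - 1)
        hit[py, px] = True
    dist = ndimage.distance_transform_edt(~hit)
    width = max(cfg.vessel_width_frac * side, 0.6)
    return np.exp(-(dist / width) ** 2)


def _splat(canvas: np.ndarray, cy: float, cx: float, radius: float,
           color: np.ndarray, strength: float) -> None:
    """Add a Gaussian-profiled elliptical blob of the given colour in place."""
    side = canvas.shape[0]
    r_int = int(np.ceil(3 * radius))
    y0, y1 = max(0, int(cy) - r_int), min(side, int(cy) + r_int + 1)
    x0, x1 = max(0, int(cx) - r_int), min(side, int(cx) + r_int + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    profile = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (radius ** 2)))
    canvas[y0:y1, x0:x1] += strength * profile[:, :, None] * color[None, None, :]


def render_phantom(grade: int, cfg: PhantomConfig | None = None,
                   seed: int | None = None) -> tuple[np.ndarray, list[dict]]:
    """Render one phantom; returns (H x W x 3 image in [0, 1], lesion list).

    The lesion list carries exact ground truth: type, centre (row, col) and
    radius in pixels of every rendered lesion.
    """
    cfg = cfg or PhantomConfig()
    if grade not in range(5):
        raise ValueError(f"grade must be 0..4, got {grade}")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    side = cfg.image_side
    radius = cfg.disc_radius_frac * side
    c = (side - 1) / 2.0

    img = np.empty((side, side, 3), dtype=np.float64)
    img[:] = cfg.background
    disc = _disc_mask(side, radius)
    # radial shading: slightly darker toward the rim, as in real fundus photos
    yy, xx = np.mgrid[0:side, 0:side]
    shade = 1.0 - 0.35 * np.clip(np.hypot(yy - c, xx - c) / radius, 0, 1) ** 2
    disc_rgb = np.array(cfg.disc_color)[None, None, :] * (disc * shade)[:, :, None]
    img = img * (1 - disc[:, :, None]) + disc_rgb

    vessels = _vessel_mask(side, radius, cfg, rng)
    vessel_color = np.array([0.45, 0.08, 0.05])
    v = (vessels * disc)[:, :, None]
    img = img * (1 - 0.8 * v) + vessel_color[None, None, :] * 0.8 * v

    scale = 1 + cfg.size_growth_per_grade * grade
    lesions: list[dict] = []

    def _sample_center(r_px: float) -> tuple[float, float]:
        rr = (radius - r_px - 1) * np.sqrt(rng.uniform())
        ang = rng.uniform(0, 2 * np.pi)
        return c + rr * np.sin(ang), c + rr * np.cos(ang)

    families = (
        ("microaneurysm", cfg.micro_counts[grade], cfg.micro_radius_frac,
         np.array([0.55, 0.30, 0.10]), -0.9),
        ("exudate", cfg.exudate_counts[grade], cfg.exudate_radius_frac,
         np.array([0.35, 0.45, 0.05]), +1.0),
        ("haemorrhage", cfg.haemorrhage_counts[grade], cfg.haemorrhage_radius_frac,
         np.array([0.50, 0.33, 0.11]), -0.85),
    )
    for kind, count, (rlo, rhi), color, strength in families:
        for _ in range(count):
            r_px = rng.uniform(rlo, rhi) * side * scale
            cy, cx = _sample_center(r_px)
            _splat(img, cy, cx, r_px, color, strength)
            lesions.append(dict(type=kind, row=float(cy), col=float(cx),
                                radius=float(r_px)))

    img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0), lesions


def derive_seed(master_seed: int, grade: int, index: int | str) -> int:
    """Stable per-image seed below 2**31 derived from (master, grade, index)."""
    digest = hashlib.sha256(f"{master_seed}:{grade}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31 - 1)


def generate_dataset(n_per_class: int, cfg: PhantomConfig | None = None,
                     out_dir=None) -> tuple[Manifest, dict[str, np.ndarray]]:
    """Render a balanced 5-grade dataset; optionally write PNGs + manifest CSV.

    Returns the manifest and an id -> image dict.  When ``out_dir`` is given
    the images are written as 8-bit PNGs and the manifest as
    ``manifest.csv`` in the EyePACS CSV dialect.
    """
    cfg = cfg or PhantomConfig()
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    records, images = [], {}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for grade in range(5):
        for index in range(n_per_class):
            image_id = f"phantom_g{grade}_{index:04d}"
            img, _ = render_phantom(grade, cfg, seed=derive_seed(cfg.seed, grade, index))
            images[image_id] = img
            path = str(out_path / f"{image_id}.png") if out_path is not None else f"{image_id}.png"
            if out_path is not None:
                iio.imwrite(path, (np.round(img * 255)).astype(np.uint8))
            records.append(ManifestRecord(image_id, path, grade))
    manifest = Manifest(records)
    if out_path is not None:
        write_manifest(manifest, out_path / "manifest.csv")
    return manifest, images
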