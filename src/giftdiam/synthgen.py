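"""Synthetic benchmark images with known ground-truth line width.

Two classes mirror the standard validation sets for fiber-measurement
software: *ordered* images contain straight, parallel, regularly spaced
lines of one constant width at an arbitrary orientation; *disordered*
images contain randomly placed smooth curves of one constant width, which
visually resemble electrospun nonwovens. Both are hard binary images
(values 0 and 255, no anti-aliasing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .errors import InvalidParameterError

DEFAULT_WIDTHS = (3, 5, 7, 10, 15, 20, 25, 50, 75, 100)
DEFAULT_IMAGE_SIZE = (640, 640)


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Ground-truth description of one generated benchmark image."""

    kind: str  # "ordered" | "disordered"
    width_px: int
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE
    angle_deg: float | None = None  # ordered only
    spacing_px: int | None = None  # ordered only
    n_curves: int | None = None  # disordered only
    seed: int = 0

    @property
    def ground_truth_width(self) -> int:
        return self.width_px

    def to_dict(self) -> dict:
        return asdict(self)


def generate_ordered(spec: SyntheticImageSpec) -> np.ndarray:
    """Parallel white bands of exact perpendicular width on black.

    Band membership is periodic in the coordinate u = r*cos(a) + c*sin(a)
    measured along the band normal, so the perpendicular width is exactly
    ``width_px`` and at 90 deg the image is the transpose of the 0 deg one.
    """
    if spec.spacing_px is None or spec.angle_deg is None:
        raise InvalidParameterError("ordered spec requires spacing_px and angle_deg")
    if spec.spacing_px <= spec.width_px:
        raise InvalidParameterError(
            f"spacing_px ({spec.spacing_px}) must exceed width_px ({spec.width_px})"
        )
    h, w = spec.image_size
    a = np.deg2rad(spec.angle_deg)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    u = rr * np.cos(a) + cc * np.sin(a)
    band = np.mod(u, spec.spacing_px) < spec.width_px
    return np.where(band, 255, 0).astype(np.uint8)


# target fraction of the frame covered by strokes (before overlap)
_TARGET_COVERAGE = 0.28
_MAX_CURVES = 400


def _draw_curve(rng, image_size, width_px: int, max_tries: int = 60) -> np.ndarray:
    """Densely sampled random open cubic-spline curve for a given stroke width.

    Control points are drawn uniformly over a slightly extended frame and
    ordered along a random sweep direction so the curve progresses across
    the frame. A candidate is redrawn when its curvature radius anywhere
    drops below the stroke width (the turn would fill in and locally exceed
    the target width) or when two non-adjacent parts of the curve come
    closer than width + 3 px (the strokes would merge into a thicker blob).
    After ``max_tries`` the best candidate seen is used.
    """
    h, w = image_size
    min_radius = float(width_px)
    min_selfdist = width_px + 3.0
    best, best_score = None, -np.inf
    for _ in range(max_tries):
        n_ctrl = int(rng.integers(4, 7))
        pts = np.column_stack(
            [
                rng.uniform(-0.1 * h, 1.1 * h, n_ctrl),
                rng.uniform(-0.1 * w, 1.1 * w, n_ctrl),
            ]
        )
        phi = rng.uniform(0.0, np.pi)
        pts = pts[np.argsort(pts @ np.array([np.cos(phi), np.sin(phi)]))]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        t = np.concatenate([[0.0], np.cumsum(seg)])
        if t[-1] <= 0:
            continue
        t /= t[-1]
        csp = CubicSpline(t, pts, axis=0)
        u = np.linspace(0.0, 1.0, 384)
        p = csp(u)
        p1 = csp(u, 1)
        p2 = csp(u, 2)
        speed = np.linalg.norm(p1, axis=1)
        cross = np.abs(p1[:, 0] * p2[:, 1] - p1[:, 1] * p2[:, 0])
        with np.errstate(divide="ignore", invalid="ignore"):
            radius = np.where(cross > 0, speed**3 / cross, np.inf)
        r_min = float(np.nanmin(radius))
        # self-proximity of non-adjacent curve sections
        arc_pos = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(p, axis=0), axis=1))]
        )
        dist = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=2)
        arc_sep = np.abs(arc_pos[:, None] - arc_pos[None, :])
        nonlocal_pairs = arc_sep >= 2.0 * width_px
        d_min = float(dist[nonlocal_pairs].min()) if nonlocal_pairs.any() else np.inf
        score = min(r_min / min_radius, d_min / min_selfdist)
        if score > best_score:
            best_score, best = score, csp
        if r_min >= min_radius and d_min >= min_selfdist:
            break
    csp = best
    # oversample relative to arc length so the rasterized line is connected
    coarse = csp(np.linspace(0.0, 1.0, 256))
    arc = float(np.sum(np.linalg.norm(np.diff(coarse, axis=0), axis=1)))
    return csp(np.linspace(0.0, 1.0, max(256, int(3 * arc))))


def generate_disordered(spec: SyntheticImageSpec) -> np.ndarray:
    """Randomly placed smooth curves stroked to a constant width.

    Each curve is a cubic spline through control points drawn uniformly
    over a slightly extended frame; all curve centerlines are rasterized
    and then thickened to ``width_px`` by thresholding the Euclidean
    distance transform at (width-1)/2, which keeps the stroke width within
    one pixel of the target. When ``n_curves`` is not given, curves are
    added until the estimated stroke coverage (centerline pixels x width)
    reaches ~28% of the frame. Reproducible from ``spec.seed``.
    """
    if spec.width_px < 1:
        raise InvalidParameterError(f"width_px must be >= 1, got {spec.width_px}")
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    centerline = np.zeros((h, w), dtype=bool)
    n_drawn = 0
    while True:
        if spec.n_curves is not None:
            if n_drawn >= spec.n_curves:
                break
        elif n_drawn >= 1 and (
            centerline.sum() * spec.width_px >= _TARGET_COVERAGE * h * w
            or n_drawn >= _MAX_CURVES
        ):
            break
        n_drawn += 1
        dense = _draw_curve(rng, (h, w), width_px=spec.width_px)
        rr = np.rint(dense[:, 0]).astype(int)
        cc = np.rint(dense[:, 1]).astype(int)
        inside = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        centerline[rr[inside], cc[inside]] = True
    if not centerline.any():
        # degenerate draw: fall back to one horizontal centerline
        centerline[h // 2, :] = True
    dist = ndimage.distance_transform_edt(~centerline)
    img = dist <= (spec.width_px - 1) / 2.0
    return np.where(img, 255, 0).astype(np.uint8)


def generate_image(spec: SyntheticImageSpec) -> np.ndarray:
    if spec.kind == "ordered":
        return generate_ordered(spec)
    if spec.kind == "disordered":
        return generate_disordered(spec)
    raise InvalidParameterError(f"unknown synthetic image kind: {spec.kind!r}")


def generate_benchmark_set(
    widths=DEFAULT_WIDTHS,
    kinds=("ordered", "disordered"),
    n_per_cell: int = 3,
    base_seed: int = 0,
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
) -> list[tuple[np.ndarray, SyntheticImageSpec]]:
    """Generate ``n_per_cell`` images per (kind, width) cell.

    Per-image seeds are derived from ``base_seed`` with a SeedSequence, so
    two calls with the same arguments return identical sets. Ordered images
    get a per-image random orientation (the benchmark convention of
    "variable angles") and spacing of three line widths.
    """
    if not widths:
        raise InvalidParameterError("widths must be non-empty")
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(len(kinds) * len(widths) * n_per_cell)
    out: list[tuple[np.ndarray, SyntheticImageSpec]] = []
    i = 0
    for kind in kinds:
        for width in widths:
            for _ in range(n_per_cell):
                seed = int(children[i].generate_state(1)[0] % (2**31))
                i += 1
                if kind == "ordered":
                    angle = float(np.random.default_rng(seed).uniform(0.0, 180.0))
                    spec = SyntheticImageSpec(
                        kind="ordered",
                        width_px=int(width),
                        image_size=image_size,
                        angle_deg=round(angle, 2),
                        spacing_px=3 * int(width),
                        seed=seed,
                    )
                else:
                    spec = SyntheticImageSpec(
                        kind="disordered",
                        width_px=int(width),
                        image_size=image_size,
                        seed=seed,
                    )
                out.append((generate_image(spec), spec))
    return out


def write_benchmark_set(directory, **kwargs) -> Path:
    """Write a benchmark set as PNGs plus a JSON manifest of ground truths."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for img, spec in generate_benchmark_set(**kwargs):
        name = f"{spec.kind}_w{spec.width_px:03d}_s{spec.seed}.png"
        iio.imwrite(directory / name, img)
        rec = spec.to_dict()
        rec["file"] = name
        manifest.append(rec)
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path
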