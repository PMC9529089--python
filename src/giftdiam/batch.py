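"""Batch processing: one parameter set applied to a folder of micrographs.

Mirrors the intended user workflow: point the tool at an input folder and
an output folder, and every image is processed identically, with per-image
raw data (distances, histogram, plot) and a summary table written out.
Failed images are recorded in the summary, never silently dropped.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diameter import ImageResult, analyze_image
from .errors import InvalidParameterError
from .params import GiftParameters

logger = logging.getLogger("giftdiam")

IMAGE_EXTENSIONS = (".tif", ".tiff", ".png", ".jpg", ".jpeg")


@dataclass
class RunConfig:
    """Configuration of one batch run."""

    input_path: Path
    output_dir: Path
    params: GiftParameters = field(default_factory=GiftParameters)
    save_intermediates: bool = False
    extensions: tuple[str, ...] = IMAGE_EXTENSIONS


def read_image(path) -> np.ndarray:
    import imageio.v3 as iio

    return iio.imread(Path(path))


def run_single(image_path, params: GiftParameters | None = None) -> ImageResult:
    """Analyze one image file (thin file-I/O wrapper over analyze_image)."""
    path = Path(image_path)
    if not path.is_file():
        raise FileNotFoundError(f"image not found: {path}")
    return analyze_image(read_image(path), params, source_id=path.stem)


def _write_image_outputs(result: ImageResult, out_dir: Path) -> None:
    stem = result.source_id
    pd.DataFrame({"distance": result.sample.distances}).to_csv(
        out_dir / f"{stem}_distances.csv", index=False
    )
    pd.DataFrame(
        {
            "bin_center": result.histogram.bin_centers,
            "count": result.histogram.counts,
        }
    ).to_csv(out_dir / f"{stem}_histogram.csv", index=False)
    from .plotting import plot_histogram_fit

    plot_histogram_fit(
        result.histogram, result.fit, out_dir / f"{stem}_fit.png", title=stem
    )


def _write_intermediates(image: np.ndarray, params: GiftParameters, out_dir: Path,
                         stem: str) -> None:
    import imageio.v3 as iio

    from .diameter import prepare_stack
    from .imageproc import (
        crop_top,
        line_opening,
        percent_threshold,
        quantize_gradient,
        sobel_magnitude,
        to_gray8,
    )

    inter = out_dir / f"{stem}_intermediates"
    inter.mkdir(exist_ok=True)
    gray = to_gray8(image)
    if params.crop_height_px is not None:
        gray = crop_top(gray, params.crop_height_px)
    grad = quantize_gradient(sobel_magnitude(gray))
    iio.imwrite(inter / "gradient.png", grad)
    mask = percent_threshold(grad, params.threshold_percent)
    iio.imwrite(inter / "edge_mask.png", (mask * 255).astype(np.uint8))
    stack = prepare_stack(image, params)
    for angle, copy in zip(stack.angles_deg, stack.copies):
        opened = line_opening(copy, params.line_length_px)
        iio.imwrite(
            inter / f"opened_{angle:g}deg.png", (opened * 255).astype(np.uint8)
        )


def run_batch(config: RunConfig) -> pd.DataFrame:
    """Process a file or a folder of images with one parameter set.

    Returns the summary table (one row per image, failures flagged in the
    ``error`` column) and writes per-image outputs, the summary CSV, the
    effective configuration and a log into the output folder.
    """
    input_path = Path(config.input_path)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if input_path.is_file():
        files = [input_path]
    elif input_path.is_dir():
        files = sorted(
            p for p in input_path.iterdir()
            if p.suffix.lower() in config.extensions
        )
        if not files:
            raise InvalidParameterError(
                f"no images with extensions {config.extensions} in {input_path}"
            )
    else:
        raise FileNotFoundError(f"input not found: {input_path}")

    effective = {
        "input": str(input_path),
        "output": str(out_dir),
        "save_intermediates": config.save_intermediates,
        "parameters": config.params.to_dict(),
    }
    (out_dir / "config.json").write_text(json.dumps(effective, indent=1))

    rows = []
    for path in files:
        t0 = time.perf_counter()
        row = {
            "image": path.name,
            "n_distances": 0,
            "mean_diameter": np.nan,
            "sd_diameter": np.nan,
            "converged": False,
            "clipped_to_zero": False,
            "units": config.params.units,
            "error": None,
        }
        try:
            result = analyze_image(read_image(path), config.params, source_id=path.stem)
            row.update(
                n_distances=result.n_distances,
                mean_diameter=result.mean_diameter,
                sd_diameter=result.sd_diameter,
                converged=result.fit.converged,
                clipped_to_zero=result.fit.clipped_to_zero,
            )
            _write_image_outputs(result, out_dir)
            if config.save_intermediates:
                _write_intermediates(read_image(path), config.params, out_dir, path.stem)
        except Exception as exc:  # unreadable file or any stage failure:
            # record the failure row and continue with the rest of the batch
            row["error"] = f"{type(exc).__name__}: {exc}"
            logger.warning("failed to process %s: %s", path.name, exc)
        row["seconds"] = round(time.perf_counter() - t0, 3)
        logger.info("%s: %s in %.2fs", path.name, row["mean_diameter"], row["seconds"])
        rows.append(row)

    summary = pd.DataFrame(rows)
    summary.to_csv(out_dir / "summary.csv", index=False)
    return summary
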