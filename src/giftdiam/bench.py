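"""Percent-error benchmarking against ground truth and parameter sweeps.

The benchmark convention: analyze each synthetic image of known line width
D_real, take the measured mean diameter D_calc, and score

    %error = |D_real - D_calc| / D_real * 100

with group averages reported separately for thin (3-7 px) and thick
(10-100 px) lines. The parameter sweep re-analyzes one image over a full
factorial grid of (line length, threshold percent, rotation angle) to
quantify sensitivity to user input.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .diameter import analyze_image, build_histogram, fit_gaussian
from .errors import GiftError, InvalidParameterError
from .imageproc import measure_stack
from .params import GiftParameters
from .synthgen import SyntheticImageSpec

# standard group boundaries: thin and thick line ranges (px, inclusive)
DEFAULT_GROUPS = ((3, 7), (10, 100))

# Benchmark analysis defaults: binary synthetic images are analyzed at a 1%
# threshold; distances are integer px, so 1 px bins are the natural binning.
BENCH_PARAMS = GiftParameters(
    line_length_px=8, threshold_percent=1.0, angle_step_deg=45.0,
    bin_size=1.0, scale_px_per_um=1.0,
)


def percent_error(d_real: float, d_calc: float) -> float:
    """|D_real - D_calc| / D_real * 100 (symmetric in over/underestimation)."""
    if d_real <= 0:
        raise InvalidParameterError(f"d_real must be > 0, got {d_real}")
    return abs(d_real - d_calc) / d_real * 100.0


@dataclass(frozen=True)
class ErrorRecord:
    """Per-image benchmark outcome."""

    image_id: str
    kind: str
    d_real_px: float
    d_calc_px: float

    @property
    def percent_error(self) -> float:
        return percent_error(self.d_real_px, self.d_calc_px)


@dataclass(frozen=True)
class ErrorSummary:
    """Aggregate error over one (kind, width-range) group."""

    kind: str
    width_range: tuple[float, float]
    mean_error: float
    sd_error: float
    median_error: float
    n_images: int


def summarize_records(records: list[ErrorRecord], groups=DEFAULT_GROUPS
                      ) -> list[ErrorSummary]:
    """Group error records by kind and width range; mean +/- sd and median."""
    out: list[ErrorSummary] = []
    kinds = sorted({r.kind for r in records})
    for kind in kinds:
        for lo, hi in groups:
            errs = np.array(
                [r.percent_error for r in records
                 if r.kind == kind and lo <= r.d_real_px <= hi]
            )
            if errs.size == 0:
                continue
            out.append(
                ErrorSummary(
                    kind=kind,
                    width_range=(lo, hi),
                    mean_error=float(errs.mean()),
                    sd_error=float(errs.std(ddof=1)) if errs.size > 1 else 0.0,
                    median_error=float(np.median(errs)),
                    n_images=int(errs.size),
                )
            )
    return out


def run_benchmark(
    items: list[tuple[np.ndarray, SyntheticImageSpec]],
    params: GiftParameters = BENCH_PARAMS,
    groups=DEFAULT_GROUPS,
    exclude_ids: tuple[str, ...] = (),
) -> tuple[list[ErrorRecord], list[ErrorSummary]]:
    """Analyze every (image, spec) pair and summarize percent errors.

    ``exclude_ids`` drops images by id before summarizing (the published
    benchmark convention excludes one pathological disordered image with
    extreme line overlap); exclusions are explicit, never silent.
    """
    records: list[ErrorRecord] = []
    for image, spec in items:
        image_id = f"{spec.kind}_w{spec.width_px}_s{spec.seed}"
        if image_id in exclude_ids:
            continue
        if spec.ground_truth_width is None or spec.ground_truth_width <= 0:
            raise InvalidParameterError(f"{image_id}: missing ground-truth width")
        result = analyze_image(image, params, source_id=image_id)
        records.append(
            ErrorRecord(
                image_id=image_id,
                kind=spec.kind,
                d_real_px=float(spec.ground_truth_width),
                d_calc_px=float(result.mean_diameter),
            )
        )
    return records, summarize_records(records, groups)


def records_to_frame(records: list[ErrorRecord]) -> pd.DataFrame:
    rows = [
        {**dataclasses.asdict(r), "percent_error": r.percent_error} for r in records
    ]
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: list[ErrorSummary]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries])


# ---------------------------------------------------------------------------
# parameter sweep

SWEEP_LINE_LENGTHS = tuple(range(4, 13))  # 4-12 px
SWEEP_THRESHOLDS = tuple(range(2, 9))  # 2-8 %
SWEEP_ANGLES = (90.0, 45.0, 6.0)


@dataclass
class SweepResult:
    """Full-factorial sensitivity grid for one image.

    ``table`` has one row per (line_length_px, threshold_percent,
    angle_step_deg) cell with the measured mean diameter (negative fits
    recorded as 0) and a flag/message for cells that failed.
    """

    table: pd.DataFrame

    @property
    def diameters(self) -> np.ndarray:
        ok = self.table["mean_diameter"].to_numpy(dtype=float)
        return ok[np.isfinite(ok)]

    def spread(self) -> float:
        """Max minus min mean diameter over all successful cells."""
        d = self.diameters
        if d.size == 0:
            raise GiftError("sweep produced no successful cells")
        return float(d.max() - d.min())


def parameter_sweep(
    image: np.ndarray,
    base_params: GiftParameters = BENCH_PARAMS,
    line_lengths=SWEEP_LINE_LENGTHS,
    thresholds=SWEEP_THRESHOLDS,
    angle_steps=SWEEP_ANGLES,
) -> SweepResult:
    """Analyze one image over the full (line length x threshold x angle) grid.

    Per-cell failures are recorded in the output table, not raised. The
    rotation stack depends only on (threshold, angle), so it is computed
    once per such pair and shared across line lengths; each cell is
    numerically identical to a standalone ``analyze_image`` call.
    """
    if not (line_lengths and thresholds and angle_steps):
        raise InvalidParameterError("sweep grid must be non-empty")
    from .diameter import prepare_stack

    rows = []
    for thr in thresholds:
        for angle in angle_steps:
            cell_params = replace(
                base_params, threshold_percent=float(thr), angle_step_deg=float(angle)
            )
            try:
                stack = prepare_stack(image, cell_params)
            except GiftError as exc:
                stack, stack_err = None, str(exc)
            else:
                stack_err = None
            for ll in line_lengths:
                row = {
                    "line_length_px": int(ll),
                    "threshold_percent": float(thr),
                    "angle_step_deg": float(angle),
                    "mean_diameter": np.nan,
                    "sd_diameter": np.nan,
                    "n_distances": 0,
                    "converged": False,
                    "error": stack_err,
                }
                if stack is not None:
                    try:
                        sample = measure_stack(
                            stack, int(ll), cell_params.scale_px_per_um
                        )
                        if sample.n == 0:
                            raise GiftError("no distances measured")
                        hist = build_histogram(
                            sample, cell_params.bin_size, units=cell_params.units
                        )
                        fit = fit_gaussian(hist)
                        row.update(
                            mean_diameter=max(fit.mean, 0.0),
                            sd_diameter=fit.sd,
                            n_distances=sample.n,
                            converged=fit.converged,
                            error=None,
                        )
                    except GiftError as exc:
                        row["error"] = str(exc)
                rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        ["line_length_px", "threshold_percent", "angle_step_deg"], ignore_index=True
    )
    return SweepResult(table=table)


# ---------------------------------------------------------------------------
# external benchmark sets (downloaded published images + manifest)


def load_external_benchmark(directory) -> list[tuple[np.ndarray, SyntheticImageSpec]]:
    """Load a benchmark image set from disk with its JSON manifest.

    The manifest is a list of records with at least ``file``, ``kind`` and
    ``width_px`` fields (the format written by
    :func:`giftdiam.synthgen.write_benchmark_set`); this is how an externally
    published validation set is fed to :func:`run_benchmark` once downloaded.
    """
    import imageio.v3 as iio

    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.is_file():
        raise FileNotFoundError(
            f"no benchmark manifest at {manifest_path}; expected a JSON list of "
            "records with 'file', 'kind' and 'width_px' fields"
        )
    items = []
    for rec in json.loads(manifest_path.read_text()):
        img = iio.imread(directory / rec["file"])
        spec = SyntheticImageSpec(
            kind=rec["kind"],
            width_px=int(rec["width_px"]),
            image_size=tuple(img.shape[:2]),
            angle_deg=rec.get("angle_deg"),
            spacing_px=rec.get("spacing_px"),
            n_curves=rec.get("n_curves"),
            seed=int(rec.get("seed", 0)),
        )
        items.append((img, spec))
    return items
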