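"""Diameter estimation: histogram binning and Gaussian peak fitting.

Vertical edge-to-edge distances across one fiber recur at the fiber's
diameter, while distances between different fibers are randomly
distributed. Binning all measured distances therefore produces a histogram
with a dominant peak at the mean fiber diameter riding on a roughly flat
background; a four-parameter Gaussian (amplitude, center, width, constant
offset) is least-squares fitted to the counts and its center is reported as
the mean diameter, its sigma as the diameter standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import InsufficientDataError, InvalidParameterError
from .imageproc import (
    DistanceSample,
    crop_top,
    make_rotation_stack,
    measure_stack,
    percent_threshold,
    quantize_gradient,
    sobel_magnitude,
    to_gray8,
)
from .params import GiftParameters


@dataclass
class DiameterHistogram:
    """Binned gap distances: uniform bins [0, b), [b, 2b), ... .

    The last bin's right edge is closed so the maximum distance is counted.
    ``units`` is "um" when a physical scale was applied, otherwise "px".
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    units: str = "px"

    @property
    def bin_size(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def build_histogram(
    sample: DistanceSample | np.ndarray, bin_size: float, units: str = "px"
) -> DiameterHistogram:
    """Bin a distance sample into uniform bins of width ``bin_size`` from 0.

    Every distance is counted exactly once; bins are half-open [kb, (k+1)b)
    and extend one bin past the maximum distance so the closed right edge of
    the final numpy bin can never double-count. An empty sample yields a
    zero-bin histogram.
    """
    if bin_size <= 0:
        raise InvalidParameterError(f"bin_size must be > 0, got {bin_size}")
    d = sample.distances if isinstance(sample, DistanceSample) else np.asarray(sample, dtype=float)
    if d.size == 0:
        return DiameterHistogram(
            bin_edges=np.array([0.0, bin_size]), counts=np.zeros(1, dtype=np.int64),
            units=units,
        )
    n_bins = int(np.floor(d.max() / bin_size)) + 1
    edges = np.arange(n_bins + 1, dtype=np.float64) * bin_size
    counts, _ = np.histogram(d, bins=edges)
    return DiameterHistogram(bin_edges=edges, counts=counts.astype(np.int64), units=units)


@dataclass
class GaussianFit:
    """Fitted peak of the distance histogram.

    ``mean`` is the peak center (the mean fiber diameter, clipped to 0 when
    the fitted center is negative — ``clipped_to_zero`` records this);
    ``sd`` is the Gaussian sigma, reported as the fiber-diameter standard
    deviation; ``offset`` absorbs the random inter-fiber background floor.
    """

    mean: float
    sd: float
    amplitude: float
    offset: float
    converged: bool
    clipped_to_zero: bool = False
    raw_mean: float = field(default=float("nan"))


def _gauss(x, offset, amplitude, mean, sd):
    return offset + amplitude * np.exp(-((x - mean) ** 2) / (2.0 * sd**2))


def fit_gaussian(hist: DiameterHistogram) -> GaussianFit:
    """Least-squares fit of offset + Gaussian to the histogram counts.

    The fit is over the full histogram range against bin centers, with
    counts weighted equally. Initial guesses: center of the tallest bin,
    the tallest count, half the full-width-at-half-maximum (fallback two bin
    widths), and the median count as offset. A fitted negative center is
    reported as mean 0 with ``clipped_to_zero`` set.
    """
    counts = np.asarray(hist.counts, dtype=np.float64)
    x = hist.bin_centers
    if np.count_nonzero(counts) < 4:
        raise InsufficientDataError(
            "Gaussian fit needs at least 4 non-empty histogram bins, "
            f"got {int(np.count_nonzero(counts))}"
        )
    i_peak = int(np.argmax(counts))
    amp0 = float(counts[i_peak])
    mean0 = float(x[i_peak])
    offset0 = float(np.median(counts))
    half = offset0 + 0.5 * (amp0 - offset0)
    above = counts > half
    # contiguous above-half region around the peak -> FWHM estimate
    lo = i_peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i_peak
    while hi < counts.size - 1 and above[hi + 1]:
        hi += 1
    fwhm = (hi - lo + 1) * hist.bin_size
    sd0 = 0.5 * fwhm if fwhm > 0 else 2.0 * hist.bin_size
    sd0 = max(sd0, hist.bin_size / 4.0)

    try:
        popt, _ = curve_fit(
            _gauss,
            x,
            counts,
            p0=[offset0, amp0, mean0, sd0],
            bounds=([-np.inf, 0.0, -np.inf, 1e-12], np.inf),
            maxfev=20000,
        )
        converged = bool(np.all(np.isfinite(popt)))
    except (RuntimeError, ValueError):
        return GaussianFit(
            mean=mean0, sd=sd0, amplitude=amp0, offset=offset0,
            converged=False, raw_mean=mean0,
        )
    offset, amplitude, mean, sd = (float(v) for v in popt)
    clipped = mean < 0
    return GaussianFit(
        mean=0.0 if clipped else mean,
        sd=abs(sd),
        amplitude=amplitude,
        offset=offset,
        converged=converged,
        clipped_to_zero=clipped,
        raw_mean=mean,
    )


@dataclass
class ImageResult:
    """Complete analysis output for one image."""

    source_id: str
    params: GiftParameters
    sample: DistanceSample
    histogram: DiameterHistogram
    fit: GaussianFit

    @property
    def n_distances(self) -> int:
        return self.sample.n

    @property
    def mean_diameter(self) -> float:
        return self.fit.mean

    @property
    def sd_diameter(self) -> float:
        return self.fit.sd


def prepare_stack(image: np.ndarray, params: GiftParameters):
    """Stages of the pipeline up to the rotation stack (threshold/angle only)."""
    gray = to_gray8(image)
    if params.crop_height_px is not None:
        gray = crop_top(gray, params.crop_height_px)
    grad = quantize_gradient(sobel_magnitude(gray))
    mask = percent_threshold(grad, params.threshold_percent)
    return make_rotation_stack(mask, params.angle_step_deg)


def analyze_image(
    image: np.ndarray, params: GiftParameters | None = None, source_id: str = "image"
) -> ImageResult:
    """Run the full pipeline on one raster and estimate the fiber diameter.

    Deterministic: identical input and parameters produce identical output.
    Raises :class:`InsufficientDataError` when no gap distances survive
    (e.g. a featureless image) or too few bins are populated for the fit.
    """
    if params is None:
        params = GiftParameters()
    stack = prepare_stack(image, params)
    sample = measure_stack(stack, params.line_length_px, params.scale_px_per_um)
    if sample.n == 0:
        raise InsufficientDataError(
            f"{source_id}: no edge-to-edge distances were measured "
            "(gap_distances stage produced an empty sample)"
        )
    hist = build_histogram(sample, params.bin_size, units=params.units)
    fit = fit_gaussian(hist)
    return ImageResult(
        source_id=source_id, params=params, sample=sample, histogram=hist, fit=fit
    )
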