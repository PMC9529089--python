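# Methods

## The measurement principle

`giftdiam` measures the mean fiber diameter of nonwoven fibrous materials
(electrospun mats imaged by SEM are the canonical case) without segmenting
individual fibers. The idea: detect all edges in the image, then measure the
vertical pixel distance between consecutive edges in every image column.
Distances measured *across* a fiber recur at that fiber's diameter in every
column the fiber crosses, while distances *between* different fibers are
randomly distributed. Pooled over the whole image, the distance histogram
shows a dominant peak at the mean fiber diameter on top of a roughly flat
random background; a Gaussian fit to the histogram reads off the peak
position (mean diameter) and width (diameter standard deviation).

Because a column only samples a fiber's width correctly where the fiber's
edges are near-horizontal, the edge image is rotated in steps of θ degrees
(180/θ copies at 0, θ, 2θ, …) and all copies are measured, so fibers of
every orientation present near-horizontal edges in some copy.

## Pipeline stages

1. **8-bit conversion** (`to_gray8`): multi-channel images are converted
   with Rec. 601 luminance weights; deeper integer or float images are
   min–max rescaled to [0, 255] (a constant image maps to 0). Optional
   top-crop removes scale bars and banners.
2. **Sobel gradient** (`sobel_magnitude`): magnitude of the standard 3×3
   Sobel pair, borders replicated so the frame produces no artificial
   gradient ring.
3. **Gradient quantization** (`quantize_gradient`): magnitudes are rounded
   and saturated at 255, mirroring 8-bit edge images. This matters for tie
   structure: on a binary image all true edge pixels saturate into one tie
   class, so a small threshold percent keeps all of them rather than an
   arbitrary strongest sub-class (staircase corners).
4. **Percent thresholding** (`percent_threshold`): the cutoff is the k-th
   largest magnitude with k = round(p%·N); every pixel ≥ the cutoff is an
   edge (the whole tie class is included, making the mask
   order-independent), and zero-magnitude pixels are never edges. On
   all-distinct inputs exactly k pixels are marked.
5. **Rotation stack** (`make_rotation_stack`): the binary mask is rotated
   with bilinear interpolation and re-binarized at 0.5 on an expanded
   canvas; padding is non-edge and tracked in a per-copy validity mask.
   Multiples of 90° map the grid onto itself and are exact.
6. **Line opening** (`line_opening`): morphological opening with a 1-row
   horizontal line of L pixels. For this structuring element the opening
   equals keeping exactly the horizontal runs of ≥ L edge pixels, which is
   how it is computed (run-length filtering; exact, idempotent,
   anti-extensive).
7. **Column maxima** (`column_maxima`): each maximal vertical run of edge
   pixels in a column yields one position, the run's center row (half
   rounds toward the top). Runs vertically adjacent to rotation padding are
   discarded; since the rotated valid region is convex, each column's valid
   pixels are one interval and surviving gaps never cross padding.
8. **Gap distances** (`gap_distances` / `measure_stack`): consecutive
   differences of the positions in each column, pooled over all rotated
   copies and divided by the px/μm scale. Two measurement guards are
   applied in the pooled measurement (see below).
9. **Histogram and fit** (`build_histogram`, `fit_gaussian`): uniform bins
   [0, b), [b, 2b), …; least-squares fit of
   `count(x) = offset + A·exp(−(x−μ)²/2σ²)` against bin centers over the
   full histogram range. μ is the mean diameter (clipped to 0 and flagged
   if fitted negative), σ the diameter SD, and the constant offset absorbs
   the random inter-fiber background floor.

## Measurement guards

Two rules in `measure_stack` remove known artifacts of binarized edge
geometry; both are stated in pixel units and applied before scaling:

- **Resolution floor** (`MIN_RESOLVABLE_GAP_PX = 3`). Sobel edges of a hard
  step are two pixels thick, so two distinct parallel edges closer than
  3 px cannot be resolved as separate column maxima. Observed gaps of
  1–2 px are re-binarization jitter of a single edge line after rotation
  and are discarded. The smallest measurable diameter is therefore 3 px,
  which is also the smallest width in standard validation sets.
- **Pair persistence** (`MIN_PAIR_PERSISTENCE_COLS = 3`). A genuine fiber
  diameter recurs in many adjacent columns, i.e. the same pair of opened-
  mask connected components produces the gap again and again. Short
  fragments of oblique staircase edges that slip through a short opening
  line produce small spurious gaps that co-occur in only one or two
  columns. Gaps whose component pair is seen in fewer than 3 columns are
  discarded. Without this rule, a 4 px opening line on thick-line images
  lets the staircase spike (3–5 px gaps) overwhelm the true diameter peak.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `line_length_px` | 8 | horizontal opening line length; longer lines demand straighter, more horizontal edge segments |
| `threshold_percent` | 5.0 | percent of pixels kept as edges (adaptive per image); 1.0 for binary synthetic images |
| `angle_step_deg` | 45 | rotation step; 180/θ copies analyzed (90→2, 45→4, 6→30) |
| `bin_size` | 0.1 | histogram bin width in output units (μm if scaled, else px) |
| `scale_px_per_um` | 1.0 | pixels per μm; 1.0 reports px |
| `crop_height_px` | none | keep only the top N rows |

For px-scale benchmark images the natural bin size is 1 px (gap distances
are integers; `bench.BENCH_PARAMS` uses 8 px / 1% / 45° / 1 px bins). Bin
centers then sit at half-integers, which contributes a structural +0.5 px
bias to the fitted mean — about 5% at width 10 px and negligible for thick
lines.

## Synthetic benchmark generator

Two image classes with known ground-truth line width, both hard binary
(0/255, no anti-aliasing):

- **Ordered**: parallel straight bands of exact perpendicular width w at an
  arbitrary orientation, spaced 3w center-to-center by default. Band
  membership is periodic in the coordinate along the band normal, so width
  is exact and the 90° image is the transpose of the 0° one.
- **Disordered**: random open cubic-spline curves (control points uniform
  over a slightly extended frame, ordered along a random sweep direction),
  stroked to width w by thresholding the distance transform of the
  rasterized centerline at (w−1)/2 — accurate to ±1 px. Candidate curves
  are redrawn when their curvature radius drops below w (the turn would
  fill in) or when non-adjacent sections approach within w+3 px (strokes
  would merge). Curves are added until centerline-pixels × width reach
  ~28% of the frame, giving realistic mat-like coverage at every width.

The default benchmark set is 3 images per width in
{3, 5, 7, 10, 15, 20, 25, 50, 75, 100} px for each class, at 640×640 —
deliberately smaller than the published 1024² validation images to keep
desk-scale runs fast; the parameter-sweep experiment uses 1024² because a
100 px-wide stroke in a smaller frame leaves too few true-diameter columns
at the 90° rotation setting.

What the generator does *not* emulate: grayscale texture, noise, blur,
depth layering and contrast variation of real SEM micrographs. Passing
benchmarks on it validates the geometry-measurement chain, not robustness
to imaging conditions (that is what the percent-threshold design addresses,
and only real micrographs can test).

## Benchmarking and sensitivity

`bench.percent_error` scores |D_real − D_calc|/D_real·100 per image;
group summaries (mean ± sd and median) are reported separately for thin
(3–7 px) and thick (10–100 px) lines, the standard grouping for this
validation set. `bench.parameter_sweep` re-analyzes one image over the full
factorial grid line length 4–12 px × threshold 2–8% × rotation {90°, 45°,
6°}, recording negative diameters as 0 and per-cell failures as flagged
rows. The rotation stack is shared across line-length cells of the same
(threshold, angle) pair — each cell remains numerically identical to a
standalone `analyze_image` call.

## Numerical choices and degenerate inputs

- Gaussian fit initial guesses: tallest bin center (μ), tallest count (A),
  half the FWHM estimate with a 2-bin fallback (σ), median count (offset);
  bounds A ≥ 0, σ > 0; non-convergence is reported via a flag, never an
  exception.
- A featureless (zero-gradient) image yields no edges and raises an
  insufficient-data error naming the stage, as does a histogram with fewer
  than 4 populated bins (4 free parameters).
- Ties at the threshold cutoff, run centers (half rounds toward the top),
  and the tallest-bin argmax (first maximum wins) are all resolved
  deterministically; the whole pipeline is deterministic — identical input
  and parameters give bit-identical results.

## Known limitations

- Single-peak assumption: bimodal fiber populations are averaged or
  one-sided; the raw distance export is the escape hatch.
- At width 3 px the measured diameter is biased high by roughly 1–1.5 px
  (bin-center offset plus edge-thickness jitter), so thin-group errors on
  the internal generator are larger than for widths ≥ 5 px, which recover
  within ~7% (widths ≥ 10 px within ~5%).
- Highly ordered, regularly spaced structures make the background spacing
  itself recur; the fit can lock onto the background peak. Reducing the
  rotation step to 6° mitigates this, as the benchmark results show
  (ordered-set mean error drops several-fold at 6°).
- Orientation analysis, pore metrics and multimodal fitting are out of
  scope; the per-image raw distance and histogram CSVs are the supported
  extension point.
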