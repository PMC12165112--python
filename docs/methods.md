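# Methods

This note documents the models, algorithms and numerical choices behind
`evquant`, and what its synthetic-data generators do and do not emulate.

## Image model and quantification

A TIRF field is modeled as a pixel grid (default 512 × 512 px at
0.15625 µm/px, i.e. an 80 µm × 80 µm field; any geometry with consistent
metadata is accepted). Each surface-captured vesicle contributes an
isotropic Gaussian spot of integrated amplitude *A* (arbitrary fluorescence
units) with PSF width σ ≈ 1.3 px, on a uniform background, with Poisson
shot noise on the expected count and additive Gaussian read noise.

Quantification proceeds per field:

1. **Denoise.** Undecimated B3-spline à-trous ("starlet") wavelet transform,
   3 levels by default. The pixel noise sd is estimated as
   MAD(finest detail)/0.6745 divided by the finest level's exact filter
   norm; detail coefficients below `threshold_k = 3` level-wise noise sd
   (level norms computed exactly from the equivalent filters) are zeroed
   before reconstruction. A constant field passes through unchanged.
2. **Detect** on the *denoised* image: pixels exceeding the starlet coarse
   plane (the local background estimate) by `detect_k = 3` × noise sd plus
   an optional absolute floor `min_contrast` are segmented into
   8-connected components. The coarse plane for detection uses
   `bg_levels = 5` (two scales coarser than the denoising depth) so a
   spot's own mass inflates its local background estimate as little as
   possible; at 3 levels the residual bump under a spot measurably biases
   the recovered intensity (≈ −7% on sparse noiseless fields vs ≈ −0.5% at
   5 levels).
3. **Measure** on the *raw* image — detection and photometry are
   deliberately decoupled so wavelet shrinkage never biases TFI. For each
   mask: `net = (mean_in − mean_surround) × area`, with the surround taken
   from an annulus (1 px gap, 2 px width) around the mask, excluding pixels
   of any other spot and pixels outside the image. Spots whose annulus is
   entirely excluded are dropped and counted in the log. Subtracting the
   *mean* surround makes every net intensity — and therefore TFI — exactly
   invariant to a uniform background offset.
4. **Filter.** Spot area must lie in [2, 50] px (at 0.15625 µm/px) and net
   intensity must be positive; non-positive nets are discarded so TFI
   cannot go negative. All thresholds are configuration, since none are
   physically forced; the defaults are standard for fluorescence spot
   detection.

Well TFI is the sum of retained net intensities over all fields (100 per
well in the emulated protocol); sample TFI is the arithmetic mean of its
replicate wells (two in the protocol), with a QC flag when the between-well
CV exceeds 0.5.

**Quantification fidelity.** For a Gaussian spot, an aperture at the
3σ contour captures 1 − e^(−4.5) = 98.9% of *A*; the missing mass under a
threshold contour at height *t* is 2πσ²·t regardless of *A*. The oracle
tests therefore compare recovered TFI against 0.989 × injected amplitude
(tolerance 5%), with spot brightness placed so the detection contour sits
near 3σ. Oracle and detection-performance tests run on 256 × 256 px fields
at 0.3125 µm/px (the same 80 µm field at half sampling) with ~10
spots/field, which keeps a 20-well × 100-field run under a minute; the
defaults are unchanged.

## Calibration

The spike-in response is modeled log–log linearly with Langmuir capture
saturation: expected TFI(C) = baseline + 10^b · (C·K/(C+K))^m, where K is
the half-saturation concentration (K = ∞ disables saturation, the
diagnostic-linear-range regime). The fit is OLS of log10(replicate-mean
TFI) on log10(C) over concentrations at or above the LOD, optionally
restricted further to exclude a saturated top point. Fitting replicate
means (3 replicates in the emulated protocol) rather than pooled replicates
is the default; the blank mean is subtracted before the log transform by
default because spiked series sit on a healthy-donor matrix background, and
non-positive adjusted responses are dropped with a warning.

LOD rule: lowest tested concentration whose replicate-mean TFI exceeds
blank mean + 3 × blank sd (sample sd, ddof = 1); a sentinel (`inf`) is
returned when no tested concentration qualifies. This is the standard
blank-based rule; it operates on the tested grid, so the LOD is never
interpolated between concentrations.

TFI → EV-equivalents inverts the fitted line and flags results outside the
fitted concentration range as extrapolated.

## Cutoffs, subtype calls and classifiers

* Quartiles use linear interpolation (type 7, NumPy default); other NumPy
  conventions are selectable. Tukey fences sit at Q1 − 1.5·IQR and
  Q3 + 1.5·IQR; the whisker cutoff is the largest control value inside the
  fences (equal to the control maximum when nothing exceeds the upper
  fence).
* The 100%-specificity cutoff is the control maximum. Positivity is a
  strict inequality (`value > cutoff`) everywhere, so a value equal to the
  cutoff is negative and specificity on the deriving controls is exactly
  100% by construction — a property, not an empirical result.
* Subtype calls: ratios r = TFI/cutoff per transcription factor; positive
  set {m : r_m > 1}; primary label is the largest-ratio positive subtype
  with deterministic tie-break A > N > P (a sample above several cutoffs
  keeps its full positive set in the output); SCLC-I when the positive set
  is empty. Every sample receives exactly one primary label.
* The dual DLL3 call concatenates H/L letters (Exo-mRNA first) and is
  positive unless L/L.
* Combined scores: default `max_log_ratio` = max over markers of
  log2(TFI/cutoff) — threshold-free, monotone in each marker, positive as
  soon as any marker exceeds its cutoff, i.e. the same any-marker-high
  logic as the dual rule. A maximum-likelihood logistic model on log10
  TFIs is available for comparison; when the classes are separated (or the
  MLE fails to converge) it falls back to `max_log_ratio` with a logged
  warning rather than reporting divergent coefficients.

### Statistics

AUC is computed by the tie-corrected rank formula U/(n₁·n₀) (ties count
1/2), which equals the trapezoidal area under the empirical ROC curve; the
curve itself is enumerated over distinct score thresholds. The Mann–Whitney
test enumerates all C(n, n₁) label assignments when the pooled size is at
most 12 (≤ 924 arrangements, exact under ties) and otherwise uses the
tie-corrected normal approximation without continuity correction. The
two-sided p is the probability of a U at least as far from n₁·n₀/2 as
observed.

## Synthetic cohorts: what they emulate and what they do not

Per-sample log10 TFI across markers is multivariate normal — log-normal
TFI, chosen because TFI is a sum of many positive spot intensities spanning
decades — with group/marker means, per-marker sd 0.25, and a mild shared
inter-marker correlation of 0.2. SCLC samples draw a latent subtype with
prevalences 0.539 / 0.197 / 0.211 / 0.053 (A/N/P/I) and receive additive
log10 shifts: +0.8 on the defining transcription factor and +0.5 on DLL3
Exo-mRNA for subtypes A and N (reflecting the cell-line observation that
DLL3 mRNA is elevated in both); group sizes default to 45 HRS / 33 LS /
43 ES. DLL3 group shifts (+0.4 log10 mRNA in both stages; +0.05 LS /
+0.25 ES protein) reproduce the qualitative ordering of the clinical
readouts — mRNA separating both stages, protein mainly extensive stage,
the dual rule beating either marker alone. These defaults are calibrated to
qualitative behavior only; no claim is made that simulated AUCs or cutoff
values match any clinical dataset numerically, and passing tests demonstrate
correctness of the *computations*, not clinical performance. Real data
features not emulated: between-site batch effects, heavy-tailed outliers,
non-lognormal zero-inflation in low-expressing controls, and correlation
between subtype and disease stage.

Field simulation likewise omits optical vignetting, EMCCD gain-register
noise, stage drift and overlapping-spot crowding; the oracle tests operate
in the non-overlapping regime (minimum spot separation enforced by
rejection sampling) because the photometric contract is only well-defined
there.

**Seed discipline.** Every generator is a pure function of (config, seed).
The master seed feeds named `SeedSequence` substreams (spot counts,
positions, amplitudes, noise, spike replicates, cohort rows), and per-field
seeds in a well are derived from a scrambled offset of the master seed, so
extending a well leaves earlier fields bit-identical.

## Degenerate inputs and numerical conventions

* Noiseless images give a noise sd estimate of exactly 0; detection then
  relies on the `min_contrast` floor (oracle tests set it explicitly).
* Constant fields: no detail coefficients, no detections, TFI 0.
* All-tied samples in the normal-approximation Mann–Whitney return p = 1.
* The intensity-weighted centroid falls back to the geometric centroid for
  zero-intensity masks.
* CSV/JSON outputs are written with stable ordering, so identical inputs
  and configuration produce byte-identical artifacts.

## Known limitations

* The LOD is grid-restricted (see above) and carries no confidence
  interval; calibration uncertainty beyond OLS is out of scope.
* No drift/flat-field correction, channel colocalization or
  photobleaching-step counting in the image pipeline.
* No YAP1/SCLC-Y calling (the assayed panel measures ASCL1, NEUROD1 and
  POU2F3 only) and no survival analysis.
* Exact Mann–Whitney enumeration is limited to pooled n ≤ 12; beyond that
  the normal approximation is used even in the presence of heavy ties.
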