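# Methods

## Scan protocol model

The interleaved volumetric protocol is modelled by five constants:
`n_groups` (8), `locations_per_group` (16), `n_repeats` (32),
`a_lines_per_bscan` (512) and `a_line_rate` (50,000 A-lines/s), plus the
per-B-scan wall-clock slot `bscan_period_ms` (12.8 ms).  The slot is a
device constant that absorbs galvo flyback and settling; it is not
derivable from the A-line rate alone (the active sweep is 10.24 ms), and
12.8 ms is the value jointly forced by the previous sequential protocol
(350 frames in 4.48 s) and the interleaved revisit interval
(204.8 ms = 16 × 12.8 ms).  No dead time is modelled between groups: the
published totals (6.5536 s per group, 52.4288 s per volume) are
consistent with none.  Acquisition time is assigned at frame start and no
intra-B-scan time structure is modelled.

The acquisition stream is ordered group-major, then repeat, then
location within the group; `address_of` / `demultiplex` realize the
bijection onto the (location, repeat) lattice.  Consecutive repeats of a
location are separated by exactly Δt, which is what gives the dynamics
estimators their delay grid τ_i = i·Δt and a Nyquist frequency of
1/(2Δt) = 2.44 Hz.  Fast dynamics (tens of ms) are out of reach of this
protocol by construction; only the late-delay decay analysis is
implemented.

## LIV

LIV is the per-voxel *population* (1/N) variance of the N-point dB
series.  Under i.i.d. fluctuation of variance σ² its expectation is
σ²(N−1)/N (4.84375 dB² for σ² = 5, N = 32).  Under temporally
correlated fluctuation the expectation is lower, because the sample mean
absorbs part of the slow component:
E[LIV] = σ²[(N−1)/N − (2/N²)Σ_{k=1}^{N−1}(N−k)ρ_k].  For an AR(1)
shell with σ² = 8 dB² and τ_c = 400 ms at Δt = 204.8 ms this gives
≈ 7.26 dB² rather than 7.94 dB² — visible in the phantom suites and
worth remembering when comparing LIV across decorrelation times.
Computation is NumPy's two-pass variance in double precision, which is
stable against large constant dB offsets.

## Kernel-pooled autocorrelation and OCDSl

For lag i, the autocorrelation at a voxel is estimated from the pooled
sample of all kernel pixels × all N−i overlapping time pairs; the
per-lag means and the two per-lag variances are taken over that same
pooled sample, and the covariance is normalized by the geometric mean of
the variances.  This makes ρ(τ₀) exactly 1 and keeps |ρ| ≤ 1 up to
rounding.  Consequences of pooled (rather than per-pixel) means:

* Static *inter-pixel* structure inside the kernel (e.g. a backscatter
  step) contributes to the pooled variance and compresses the apparent
  decay.  At a spheroid–medium boundary with a ~25 dB step, a single
  medium pixel inside the 2×4 kernel pins ρ near 1 and drives OCDSl
  toward 0; a thin (~kernel-reach) boundary layer of the shell is
  therefore systematically scored non-viable by OCDSl (not by LIV, which
  uses no kernel).  This shrinks like kernel-footprint/radius and is ~5 %
  of the shell for a 600 µm phantom at the instrument pitches.
* The finite record (N = 32) gives ρ̂ a negative, lag-increasing bias for
  slowly decorrelating series (mean estimated over a window comparable
  to τ_c).  The bias shrinks roughly as 1/(k·l) with kernel size; at
  2×4 and τ_c = 1000 ms it is ≈ −0.02 to −0.04 over lags 1–6 and
  *steepens* the measured decay, inflating OCDSl by ≈ 2×10⁻⁵ ms⁻¹.

Kernel conventions: k spans depth (axial), l spans the fast axis
(lateral); no pooling across the slow axis, whose neighbours are not
time-synchronized.  The window is centered on the output voxel (even
sizes put the extra pixel on the high side) and truncated at image
borders, so the output keeps full spatial extent and the spheroid rim is
not discarded.  Zero-variance (constant) kernels get ρ = 0 at lags ≥ 1,
ρ = 1 at lag 0, a `degenerate` flag, and hence OCDSl = 0 — background
never produces NaNs in renders.

Numerics: the record is centered by a single per-location scalar mean
before moment accumulation.  A global shift leaves the statistic exactly
invariant (per-voxel centering would not, because the pooled means span
kernel pixels) and removes the catastrophic cancellation that raw dB
offsets of tens of dB would otherwise cause in the raw-moment sums.  The
`fft` path computes the O(N²) lagged cross-products with `scipy.fft`
(zero-padded autocorrelation); the `direct` path sums them in the time
domain.  Both share the pooling and normalization code and agree to
≤1e−9 relative; the test suite additionally checks both against a
literal triple-loop transcription of the pooled estimator.

OCDSl is the negated OLS slope (with intercept) of ρ over the window
[204.8, 1228.8] ms — lags 1..6 at the default Δt.  The intercept is
free: the window excludes lag 0, and anchoring the fit at ρ(0) = 1 would
bias the slope whenever a noise floor makes the true amplitude r < 1.
Decaying correlation yields positive OCDSl; rising correlation yields
negative values and is not clipped.  No clipping of ρ to [0, 1] is
applied before fitting.

**Response shape.** The window slope is *not* globally monotone in the
decorrelation rate: for exp(−τ/τ_c) the true OLS slope over lags 1..6
peaks near τ_c ≈ 600 ms (per unit amplitude: 4.4×10⁻⁴ at τ_c = 300 ms,
5.2×10⁻⁴ at 400 ms, 5.6×10⁻⁴ at 600 ms, 5.1×10⁻⁴ at 1000 ms,
2.1×10⁻⁴ at 4000 ms), because very fast decorrelation completes before
the first sampled delay.  OCDSl is best read as a band-pass measure of
slow dynamics: monotone in 1/τ_c only on the slow side of the peak
(τ_c ≳ 600 ms at this window), which is where the property suite asserts
it.  Together with the finite-record bias above, this means a
τ_c = 400 ms process and a τ_c = 1000 ms process produce nearly
indistinguishable mean OCDSl at N = 32.

An auxiliary `fit_exponential_decay` performs a weighted log-linear fit
of ρ over lags ≥ 1 (weights ρ², the delta-method inverse variance of
log ρ; lags with ρ ≤ 0.05 excluded).  The intercept absorbs the noise
amplitude r, so the recovered τ_c is insensitive to white measurement
noise; the recovery suite requires the shell median to be within 25 %
for τ_c ∈ [300, 3000] ms at N = 32, kernel 2×4.

## Synthetic phantom

Each voxel's series is I_dB(tᵢ) = mean + s(tᵢ) + εᵢ with s a stationary
zero-mean Gaussian AR(1) process (variance σ_d², AR coefficient
φ = exp(−Δt/τ_c) — the unique discrete Gaussian process with exactly
exponential ACF on the Δt grid) and ε i.i.d. N(0, σ_n²).  Expected
estimator values are then closed-form: E[ρ(τᵢ)] ≈ r·exp(−τᵢ/τ_c) with
r = σ_d²/(σ_d²+σ_n²), and E[LIV] as above.  Voxels are spatially
independent, so kernel pooling only reduces estimator variance — which
the oracles exploit.

Default study conditions (units: dB, dB², ms):

| compartment | mean | σ_d² | τ_c | σ_n² | rationale |
|---|---|---|---|---|---|
| shell  | 30 | 8.0  | 400  | 0.2 | viable rim: safely above both cutoffs (E[LIV] ≈ 7.3 dB², E[OCDSl] ≈ 5×10⁻⁴ ms⁻¹) |
| core   | 25 | 0.5  | 6000 | 0.3 | necrotic core: safely below both cutoffs |
| medium | 5  | 0.05 | 200  | 0.3 | low-backscatter, essentially static culture medium |

Geometry defaults follow the modelled instrument: pitches 1.95 µm
(fast), 7.24 µm (depth), 7.8125 µm (slow, 1 mm / 128 locations);
spheroid radius 250 µm (a ~500 µm-diameter spheroid), core radius
150 µm.  The viability-decline series replaces the shell stage-by-stage
with (σ_d², τ_c) = (8, 400) → (4, 1400) → (2, 3000) → (1, 7000):
fluctuation magnitude shrinks and decorrelation slows as viability is
lost, so mean LIV, mean OCDSl and both viable ratios fall strictly
stage over stage.

What the phantom does **not** emulate: physical speckle statistics (dB
fluctuations of real speckle are non-Gaussian), lateral speckle
correlation, confocal/sensitivity roll-off along depth, sample drift or
rotation between groups, and medium turbidity.  Passing phantom tests
therefore demonstrates correctness of the estimators and the
quantification arithmetic under the stated statistical model — not
instrument-level fidelity on biological tissue.

## Quantification

Segmentation is `(mean intensity > threshold) ∧ ROI`, with the ROI
either the full grid, a 3D box, or per-slice polygons (rasterized with
`skimage.draw.polygon2mask`); an optional largest-connected-component
cleanup uses 26-connectivity.  The threshold can be absolute or relative
to a background estimate (median of a user-designated background box
plus an offset, default 10 dB) for reproducible batch operation.  An
empty mask is returned with a warning in its provenance; summaries
refuse it.

Viability comparisons are strict (`>`): a voxel exactly at the cutoff
(3 dB² LIV, 2×10⁻⁴ ms⁻¹ OCDSl) counts as non-viable — immaterial for
continuous data, fixed by convention.  Volumes are voxel counts times
the voxel volume (product of the three pitches).

## Rendering

Hue = linear map of clipped dynamics onto [0°, 120°] (red → green),
saturation = 1, value = linear map of clipped intensity onto [0, 1],
converted with `matplotlib.colors.hsv_to_rgb`.  Display spans (LIV
[0, 10] dB², OCDSl [0, 6×10⁻⁴] ms⁻¹, 40 dB intensity span) are
configurable presentation choices that reproduce the red-core /
green-rim reading of the tomograms; no perceptual-uniformity claim is
made.  3D visualization is limited to orthogonal slice extraction
(fast / slow / en-face) with physical extents from the pitches.

## Problem sizes in the test and acceptance suites

The suites are sized to exercise every statistical claim with
comfortable error bars while staying fast: the i.i.d. LIV-bias check
uses 102,400 voxels (SE ≈ 0.004 dB²); the white-noise ACF check uses
512-repeat records on a kernel-strided (hence independent) 400-voxel
subgrid; the 3:1 viability phantom is a 600 µm spheroid at instrument
pitches, grid 80×88×318 (≈ 590 k spheroid voxels); the decline series
uses a coarser 400 µm phantom (grid 40×64×256) per stage.  All random
draws are seeded; every simulation is byte-reproducible from its spec.

## Known limitations

* OCDSe-style early-delay analysis is impossible at Δt = 204.8 ms and is
  deliberately out of scope.
* The kernel-pooled estimator is biased at sharp intensity boundaries
  and for τ_c comparable to the record length (details above); both
  effects are properties of the estimator, not implementation artifacts,
  and both are quantified by the phantom suites.
* No registration across time points: floating or rotating samples are
  analysed as acquired.
* Input is scalar dB intensity; polarization processing and
  interferogram reconstruction are upstream of this package.
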