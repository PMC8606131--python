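# dynoct

Volumetric **dynamics OCT** analysis: label-free tissue-viability imaging
from repeated OCT B-scans, for people who evaluate 3D cell cultures
(tumor spheroids, organoids) with a scanning OCT/OCM system.

Sub-cellular motion makes the OCT speckle of viable tissue fluctuate in
time; necrotic tissue is comparatively static.  `dynoct` implements the
full analysis stack that turns a time series of co-located B-scans into
quantitative viability maps:

* **Interleaved scan protocol** — the en-face plane is split into groups
  of adjacent B-scan locations; each group is raster-scanned repeatedly
  before moving on.  A location is revisited every
  Δt = locations_per_group × B-scan period (204.8 ms at the defaults),
  so a whole volume of 8 × 16 locations × 32 repeats completes in
  52.4 s while each voxel still carries a 6.55 s dynamics record.
  The module handles scheduling, timing arithmetic and demultiplexing of
  acquisition-ordered frame streams.
* **LIV** (logarithmic intensity variance, dB²) — the population variance
  of the dB-scale signal at each voxel,
  LIV(x,z) = (1/N) Σᵢ [I_dB(x,z,tᵢ) − ⟨I_dB(x,z)⟩ₜ]².
* **OCDSl** (late OCT correlation decay speed, ms⁻¹) — the negated OLS
  slope of the temporal autocorrelation ρ_A(τ) over τ ∈ [204.8, 1228.8] ms.
  With only N = 32 repeats, ρ_A is estimated with a small spatial kernel
  (2 axial × 4 lateral pixels): covariance and per-lag variances are
  pooled over all kernel pixels and overlapping time pairs.  Both a
  direct and an FFT-based implementation are provided (equal to ≤1e−9).
* **Quantification** — intensity-based spheroid segmentation, spheroid
  volume by voxel counting, masked mean LIV/OCDSl, and viable cell
  ratios against fixed cutoffs (3 dB² for LIV, 2×10⁻⁴ ms⁻¹ for OCDSl):
  viable cell ratio = viable volume / entire spheroid volume.
* **Rendering** — HSV composites (hue = dynamics, red → green;
  value = OCT intensity; saturation = 1) and fast/slow/en-face slice
  extraction.
* **Synthetic phantoms** — spherical spheroid phantoms (viable shell,
  necrotic core, low-backscatter medium) whose per-voxel dB series are
  Gaussian AR(1) processes with exactly exponential autocorrelation, so
  every estimator has a closed-form expectation.  The entire pipeline is
  testable end-to-end without instrument data.

## Worked example

Simulate a 400 µm-diameter phantom whose shell:core voxel ratio is 3:1,
then run the full analysis:

```python
import json
from dynoct import (PhantomSpec, compute_acf, compute_liv, compute_ocds,
                    quantify, segment_spheroid, simulate_stack)

spec = PhantomSpec(shape=(40, 64, 256), x_pitch_um=2.0, y_pitch_um=12.0,
                   z_pitch_um=7.0, spheroid_radius_um=200.0,
                   core_radius_um=200.0 * 0.25 ** (1 / 3), rng_seed=0)
stack, labels = simulate_stack(spec)          # (location, repeat, depth, fast)
liv  = compute_liv(stack)                      # dB² volume
ocds = compute_ocds(compute_acf(stack))        # ms⁻¹ volume, 2×4 kernel
mask = segment_spheroid(liv.mean_intensity_db, threshold_db=15.0,
                        voxel_volume_um3=liv.voxel_volume_um3)
print(json.dumps(quantify(mask, liv=liv, ocds=ocds).to_dict(), indent=2))
```

prints

```json
{
  "n_voxels": 199392,
  "volume_um3": 33497856.0,
  "mean_liv_db2": 5.546425152898909,
  "mean_ocds_ms_inv": 0.00037791808545334165,
  "viable_ratio_liv": 0.7425523591718826,
  "viable_ratio_ocds": 0.7135943267533301,
  "liv_cutoff_db2": 3.0,
  "ocds_cutoff_ms_inv": 0.0002
}
```

The segmentation recovers every spheroid voxel (199,392 = shell + core
count), and both viable ratios land near the constructed 0.75: the shell
(75 % of the spheroid) sits above both cutoffs, the core below.  The
ratios sit slightly under 0.75 because estimator noise pushes a small
fraction of shell voxels below cutoff, and because the pooling kernel
straddling the spheroid–medium intensity step suppresses OCDSl in a thin
boundary layer (see `docs/methods.md`).

The same workflow is available from the shell:

```sh
dynoct schedule                      # protocol timing summary
dynoct simulate --out stack.tif --truth labels.tif
dynoct liv  --stack stack.tif --out liv.tif
dynoct ocds --stack stack.tif --out ocds.tif --kernel 2x4 --fit 204.8:1228.8
dynoct quantify --liv liv.tif --ocds ocds.tif --threshold-db 15 --out report.json
dynoct render --volume liv.tif --plane enface --index 32 --out enface.png
dynoct pipeline --config run.json --outdir out/   # all stages from one config
```

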