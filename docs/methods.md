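# Methods

## The acquisition model

`cofi` models coded-exposure snapshot compressive imaging (SCI) of a
fast fluorescence scene.  During one camera exposure a spatial light
modulator cycles through `T` binary patterns `C_i` on a schedule of
start times and exposure windows; the detector integrates

    Y = sum_i  x_i ⊙ C_i  + n,

where `x_i` is the scene intensity integrated over window `i` and `⊙` is
the element-wise product.  Stacking the frames, `y = Φx + n` with a
sensing matrix `Φ` made of diagonal blocks, so `ΦΦᵀ = diag(R)` with
`R = Σ_i C_i²` (= `Σ_i C_i` for binary codes).  That diagonal structure
gives the data subproblem of the reconstruction a closed form and is
verified by the adjoint/diagonality property tests.

Masks are i.i.d. Bernoulli with fill fraction 0.5 (maximum code
variance; no inter-code structure is required by the solver).  The
camera model is shot noise plus additive read noise,
`Poisson(gain·Y)/gain + N(0, σ_read)`, clipped at zero; defaults are
gain 1 and σ_read 3 counts.  Read noise is paid once per snapshot, which
is the root of the multiplexing advantage over frame-by-frame short
exposures; the property test checks the SNR ordering over 20 paired
seeds in the read-noise-dominated regime (per-frame signal ≤ 50 counts,
σ_read ≥ 3).

Schedules may be nonuniform.  Two presets ship for two-snapshot
lifetime imaging: snapshot 1 places 10 codes at 300-µs intervals then 10
at 600-µs intervals (150-µs exposures, compression ratio 20); snapshot 2
places 10 codes at 1-ms intervals (500-µs exposures, compression ratio
10).  The reference time of a code is its mid-exposure time: the
midpoint rule is exact for signals linear in time and its relative error
for an exponential decay is bounded by `(exposure/τ)²/24`, which is
≤ 1.1×10⁻⁴ at the preset exposure/lifetime ratios (checked by test).
Scene sampling over a window uses the mean of K = 3 sub-renderings at
the midpoints of equal subdivisions; frames are mean intensities (not
absolute integrals) so that frames from unequal exposures share one
scale, which the merged lifetime fit requires.

## Reconstruction

The inverse problem `min_x ½‖y − Φx‖² + λR(x)` is solved by
plug-and-play ADMM: with auxiliary `θ` and scaled dual `u`,

    x ← z + Φᵀ[(y − Φz) ⊘ (R + ρ)],  z = θ − u/ρ
    θ ← D_σ(x + u/ρ)                  (denoiser cascade, then x ≥ 0)
    u ← u + ρ(x − θ)

The x-update is the exact minimiser of the quadratic subproblem (dense
normal-equations oracle equivalence to 10⁻¹⁰ is tested on random
instances).  On the sign convention: the source equations for this
scheme circulate with inconsistent signs between the augmented
Lagrangian and its subproblems; we use the standard scaled-dual form
above.  The alternative convention (`z = θ + u/ρ` with the same dual
ascent) was implemented and measured first: it degrades reconstructions
by an order of magnitude on the microsphere phantom because the dual
feedback then amplifies rather than cancels the denoiser bias.

Initialisation is the mask-normalised backprojection
`x⁰ = Φᵀy ⊘ max(R, 1)` (scale-correct, parameter-free), `θ⁰ = x⁰`,
`u⁰ = 0`.  The solver runs a non-increasing noise-level ladder σ =
{0.10, 0.05, 0.02} × the dynamic range of `x⁰`; λ is absorbed into the
per-stage TV weight (`weight = strength_scale · σ`).  The returned
reconstruction is θ, the prior-consistent iterate.  All solver math is
double precision; files are written as 32-bit float TIFF.

The denoiser cascade is a list of stages mirroring a
TV → frame-denoiser → frame-denoiser → video-denoiser layout, so trained
models can be registered as plugins (callable `(array, σ) → array`; a
registration check requires constants to be preserved to 10⁻⁶
relative).  No learned denoiser ships with the package.  The default
stage is total variation, implemented as Chambolle's dual projection
with a fixed 30 inner iterations and step 0.25 — fixed counts keep runs
bit-reproducible; the implementation agrees with an independent
long-run Chambolle solver to < 5×10⁻³ on random images.

Three solver presets are used by the benchmarks:

- **frame-wise TV** (strength 2σ, 90 iterations): no temporal coupling,
  so per-frame amplitudes and a lone object's position stay unbiased —
  used for the lifetime and microsphere scenes;
- **spatiotemporal TV** (3-D, strength 0.5σ, 60 iterations): temporal
  coupling averages away code-dependent per-frame ghosting — used for
  the thin, low-flux bar target where that ghosting dominates the
  centroid error;
- **cascade** (3-D TV at 0.5σ, then frame-wise TV at 1σ, 60
  iterations): suppresses ghosting and then re-sharpens each frame —
  the best compromise measured for multi-object tracking scenes.

An optional pixel-super-resolution stage upsamples frames by 2× or 4×
separable cubic interpolation on the pixel-centre grid with per-frame
mean flux preserved (or by a registered plugin with the same contract);
the output pixel pitch is divided by the factor.

## Phantoms

All phantoms live on a physical grid: positions in µm from the top-left
pixel centre (x along columns, y along rows), time in ms from exposure
start.  The default grid is 128×160 pixels at 15-µm pitch (a
1.92 × 2.40 mm field of view).  Shapes are rasterised on a grid finer by
the supersampling factor (default 4) and mean-binned, which conserves
flux exactly and gives sub-pixel-accurate centroid ground truth (the
rendered 10.14-µm disk's centroid matches its preset position to
< pitch/4, tested at 8× supersampling).  Intensities are expected
photoelectron counts: default object peak 500 counts over a background
of 5, so the camera noise model applies directly.

- **Moving shaped objects**: circles/ellipses on arbitrary
  time-to-position functions; intensities add where objects overlap.
- **Bar target**: three groups of three parallel bars (width = half the
  centre-to-centre spacing, 50% duty cycle) with spacings 45.6, 60.8 and
  76 µm at 45° to the horizontal, translating rigidly at
  (−10, +10) µm/ms — a diagonal drift of ~0.28 px per 300-µs frame.
  The preset per-bar centroids are returned as the ground-truth table.
- **Decay phantom**: three disk regions (two "ears" and a "head") with
  mono-exponential lifetimes 3.2, 4.5 and 7.2 ms, amplitude 500 counts.
  Overlapping regions sum their decays (emulating sample cross-talk); a
  flag forbids overlap for clean tests.
- **Microsphere flow**: a uniform-brightness 10.14-µm disk moving at
  1.02 µm/ms along the channel.  This scene uses a 0.3-µm sample-plane
  pitch — the 15-µm detector pitch divided by the 50× objective used for
  micron-scale flow imaging — so the sphere spans ~34 px and its travel
  over the 20-ms snapshot (~65 px) exceeds its diameter.

What the phantoms deliberately omit: optical point-spread and tissue
scattering, SLM switching transients, camera nonlinearity, and optical
throughput losses.  Passing tests therefore demonstrate the
computational pipeline's correctness and its noise behaviour, not
system-level image quality on real tissue.

## Lifetime estimation

The two snapshots are reconstructed independently (their codes and
schedules are independent) and merged on a common clock: snapshot 2's
mid-exposure times are offset by snapshot 1's span plus a configurable
readout gap (default 0 ms).  The merged 30-point series is fitted per
pixel or per region with `I(t) = baseline + A·exp(−t/τ)` by bounded
least squares (τ ∈ [0.1, 100] ms), initialised from a log-linear
regression on baseline-subtracted values.  Noiseless fits recover τ to
< 0.1% across τ ∈ [1, 10] ms on the preset schedules.  The per-pixel map
fits only pixels whose peak intensity reaches a threshold — by default
5× the robust (MAD) σ of a user-specified background region above its
median; elsewhere the map holds NaN with `validity_mask = False`.  A
deliberately mono-exponential model is used even where regions overlap;
mixed pixels legitimately yield intermediate τ (the least-squares
optimum of a two-component mixture lies strictly between the component
lifetimes, verified against a dense-grid oracle).

## Metrics

- **Centroid**: intensity-weighted mean position over an ROI after
  background subtraction (ROI minimum by default), in µm.
- **Tracking**: greedy per-object windows with mean-shift refinement —
  the window is recentred on the measured centroid and the measurement
  repeated (3–5 passes).  The refinement matters: a window fixed at the
  previous position imprints a lag bias on a moving object of order the
  reconstruction's trailing smear; with refinement the recovered
  microsphere speed moved from ~25% low to within ~1% of truth.
- **Velocity**: per-axis ordinary least squares versus time; speed is
  the norm of the slope vector; exact linear tracks return the exact
  slope.
- **Positional error**: per frame and axis, the mean over line pairs of
  (measured − preset); the summary is the maximum absolute mean over
  frames and axes.
- **SNR**: the ratio of mean intensity in a signal ROI to that in a
  disjoint background ROI, with no background subtraction.
- **Resolvability**: the mean cross-profile of a bar group perpendicular
  to its orientation; modulation contrast `(peak − trough)/(peak +
  trough)` with a group resolvable when contrast ≥ 0.1 (config-exposed;
  reported alongside the contrast so conclusions do not hinge on it) and
  the expected number of peaks is found; a spacing `d` µm converts to
  `1000/d` lp/mm.
- **SBTP**: effective resolved pixels × frame rate.  The effective pixel
  count is an explicit input — it is not derivable from the field of
  view and the resolvable frequency alone.

## Benchmark outcomes and known limitations

At the studied conditions (compression ratio 20, Bernoulli-0.5 masks,
gain 1, read σ 3):

- Lifetime recovery through the full two-snapshot pipeline is within
  ~1.5% per region, stable across seeds.
- Microsphere speed recovery is within ~1.5%, stable across seeds.
- The bar-target maximum mean positional error lands at 3–6.5 µm
  depending on the mask/noise seed (4.5 µm at the canonical seed 0).
  This sits above the ~3.8-µm level reported for trained
  reconstruction cascades.  The residual is dominated by endpoint-frame
  temporal shrinkage and code-dependent ghosting, both artefacts of
  untrained priors at this compression ratio; frame-wise TV,
  anisotropic temporal weights, accelerated measurement feedback,
  mirrored temporal padding, TV+wavelet cascades and 2–5× longer
  ladders were all measured and none robustly improves on the
  spatiotemporal-TV preset.  Closing the gap is exactly the role of the
  learned denoiser/super-resolver plugins, which are out of scope here.

Degenerate inputs are handled explicitly: zero-mass ROIs raise an
undefined-centroid error, constant decay series return a non-converged
fit rather than raising, lost tracking objects truncate the track with
a warning, overlapping exposure windows and non-binary masks are
rejected at construction, and non-finite solver iterates raise with the
iteration index.
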