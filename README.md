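# cofi — snapshot compressive fluorescence imaging

`cofi` is a Python toolkit for **coded-exposure snapshot compressive
imaging (SCI)** of fast fluorescence dynamics: the acquisition scheme in
which a spatial light modulator imprints `T` binary random patterns on a
scene during a single camera exposure, and the `T`-frame video is
recovered computationally from that one compressed measurement.  The
scheme multiplies the effective frame rate of slow, sensitive NIR
cameras by an order of magnitude while incurring the detector's read
noise only once (the multiplexing advantage).

The package is aimed at people building or evaluating such systems: it
provides the full computational chain — synthetic dynamic phantoms on a
physical µm/ms grid, the forward model with a shot+read camera noise
model, plug-and-play ADMM reconstruction with a total-variation
denoiser cascade (and a plugin contract for trained denoisers /
super-resolvers), phosphorescence-lifetime mapping from flexibly coded
snapshots, and the standard evaluation metrics (centroid tracking,
velocity fits, positional error, mean-ratio SNR, line-pair
resolvability, space–bandwidth–time product).

## Model

Acquisition: `y = Φx + n`, where `x` stacks the `T` scene frames,
`Φ` applies per-frame binary masks `C_i` and sums
(`Y = Σ_i x_i ⊙ C_i`), and `n` is Poisson shot noise plus Gaussian read
noise.  Because `ΦΦᵀ = diag(Σ_i C_i²)`, the data subproblem of

    min_x  ½‖y − Φx‖² + λR(x)

has a closed form inside ADMM, and the prior step is any denoiser
(plug-and-play):

    x ← z + Φᵀ[(y − Φz) ⊘ (R + ρ)],   z = θ − u/ρ
    θ ← D_σ(x + u/ρ),                 u ← u + ρ(x − θ)

Lifetimes: two snapshots with nonuniform schedules (dense 300/600-µs
sampling of the fast decay, then 1-ms sampling of the tail) are
reconstructed independently, merged at mid-exposure times, and fitted
per pixel/region with `I(t) = baseline + A·e^{−t/τ}`.

See `docs/methods.md` for assumptions, parameter defaults and known
limitations.

## Worked example

Run the microsphere-flow benchmark (a 10.14-µm fluorescent sphere moving
at 1.02 µm/ms, encoded 20 frames → 1 snapshot at 1-ms code intervals,
reconstructed, tracked, and speed-fitted):

```
$ cofi run --preset microfluidics_fig4 --seed 0 --out runs/micro
{
 "snr_recon": 328.9422124700396,
 "snr_short_exposure": 211.70558099794982,
 "speed_um_per_ms": 1.0121067769776564,
 "truth_speed_um_per_ms": 1.02
}
```

Reading the numbers: the linear fit to the tracked centroid recovers the
simulated flow speed to within ~1% (1.0121 vs 1.02 µm/ms), and the
reconstructed frame's signal-to-background ratio exceeds that of a
single short exposure with the same per-frame signal and read noise —
the multiplexing advantage in the read-noise-limited regime.  The output
directory contains the phantom, masks, snapshot, reconstruction,
tracks and a `run.json` that is byte-identical across repeated runs.

The same pattern runs the other benchmarks: `tracking_fig1` (two moving
shaped emitters), `resolution_fig2` (a translating three-group line-pair
target with 45.6/60.8/76-µm spacings), and `lifetime_fig3` (a
three-region decay phantom with 3.2/4.5/7.2-ms lifetimes acquired in two
flexibly coded snapshots).

Library use mirrors the CLI:

```python
from cofi import (SceneSpec, make_mask_stack, make_schedule,
                  sample_scene_on_schedule, forward_encode,
                  add_sensor_noise, run_pnp_admm)
from cofi.phantoms import render_microsphere_flow

spec = SceneSpec(grid=(128, 160), pixel_pitch_um=0.3, background_level=1.0)
sched = make_schedule("uniform", (20, 1.0, 0.5))
scene = sample_scene_on_schedule(
    lambda ts: render_microsphere_flow(spec, 10.14, 1.02, ts,
                                       start_position_um=(12.0, 19.2))[0],
    sched)
masks = make_mask_stack(scene.grid, 20, 0.5, seed=0)
snap = add_sensor_noise(forward_encode(scene, masks), 1.0, 3.0, seed=0)
recon, state = run_pnp_admm(snap, masks)
```

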