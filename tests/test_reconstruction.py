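import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cofi.encoding import (
    SensingOperator,
    forward_encode,
    make_all_on_masks,
    make_mask_stack,
)
from cofi.errors import PluginError, ValidationError
from cofi.reconstruction import (
    DenoiserSpec,
    SolverConfig,
    apply_psr,
    identity_denoiser,
    run_pnp_admm,
    theta_update,
    tv_denoise,
    u_update,
    x_update,
)


# ---------------------------------------------------------------------------
# x-update against a dense linear-algebra oracle
# ---------------------------------------------------------------------------


def dense_x_update(op, y, z, rho):
    """Oracle: solve (Phi^T Phi + rho I) x = Phi^T y + rho z directly."""
    phi = op.dense_matrix()
    n = phi.shape[1]
    A = phi.T @ phi + rho * np.eye(n)
    b = phi.T @ y.ravel() + rho * z.ravel()
    return np.linalg.solve(A, b).reshape(z.shape)


def test_x_update_consistent_z_is_fixed_point(rng, tiny_masks):
    op = SensingOperator(tiny_masks)
    z = rng.random((4, 6, 6))
    y = op.forward(z)
    x = x_update(z, np.zeros_like(z), y, op, rho=1.0)
    np.testing.assert_allclose(x, z, atol=1e-12)


def test_x_update_single_pixel_arithmetic():
    """1 pixel, T=2, masks all-on, y=3, z=(1,1): correction 1/3 per frame."""
    masks = make_all_on_masks((1, 1), 2)
    op = SensingOperator(masks)
    z = np.ones((2, 1, 1))
    y = np.array([[3.0]])
    x = x_update(z, np.zeros_like(z), y, op, rho=1.0)
    np.testing.assert_allclose(x, 4.0 / 3.0)
    np.testing.assert_allclose(x, dense_x_update(op, y, z, 1.0))


@settings(max_examples=15, deadline=None)
@given(st.integers(0, 10_000))
def test_x_update_matches_dense_solve(seed):
    rng = np.random.default_rng(seed)
    T = int(rng.integers(1, 6))
    h, w = int(rng.integers(2, 9)), int(rng.integers(2, 9))
    op = SensingOperator(make_mask_stack((h, w), T, 0.5, seed=seed + 7))
    theta = rng.standard_normal((T, h, w))
    u = rng.standard_normal((T, h, w))
    y = rng.random((h, w)) * 5
    rho = float(rng.uniform(0.1, 5.0))
    x = x_update(theta, u, y, op, rho)
    oracle = dense_x_update(op, y, theta - u / rho, rho)
    assert np.max(np.abs(x - oracle)) / max(np.max(np.abs(oracle)), 1) < 1e-10


def test_x_update_rejects_bad_rho(rng, tiny_masks):
    op = SensingOperator(tiny_masks)
    z = rng.random((4, 6, 6))
    with pytest.raises(ValidationError):
        x_update(z, np.zeros_like(z), op.forward(z), op, rho=0.0)


# ---------------------------------------------------------------------------
# theta / u updates
# ---------------------------------------------------------------------------


def test_theta_update_identity_cascade(rng):
    x = rng.random((3, 5, 5))
    u = rng.random((3, 5, 5))
    out = theta_update(x, u, 2.0, [identity_denoiser()], sigma=0.1)
    np.testing.assert_allclose(out, x + u / 2.0)


def test_theta_update_constant_cube_unchanged():
    x = np.full((2, 6, 6), 4.2)
    u = np.zeros_like(x)
    cascade = [DenoiserSpec(kind="tv2d", strength_scale=1.0),
               DenoiserSpec(kind="tv3d", strength_scale=1.0)]
    out = theta_update(x, u, 1.0, cascade, sigma=0.3)
    np.testing.assert_allclose(out, x, rtol=1e-6)


def test_plugin_shape_violation_identified():
    bad = DenoiserSpec.__new__(DenoiserSpec)  # bypass registration check
    bad.kind, bad.fn, bad.scope, bad.name = "plugin", lambda a, s: a[:1], "video", "bad"
    bad.strength_scale, bad.tv_iters, bad.tv_step = 1.0, 30, 0.25
    with pytest.raises(PluginError, match="bad"):
        theta_update(np.zeros((3, 4, 4)), np.zeros((3, 4, 4)), 1.0, [bad], 0.1)


def test_plugin_registration_rejects_nonconstant_preserving():
    with pytest.raises(PluginError):
        DenoiserSpec(kind="plugin", fn=lambda a, s: a * 0.5, scope="video")


def test_u_update_recurrence(rng):
    x = rng.random((2, 4, 4))
    theta = x - 1.0  # x - theta = 1 everywhere
    u = np.zeros_like(x)
    for k in range(1, 4):
        u = u_update(u, x, theta, rho=2.0)
        np.testing.assert_allclose(u, 2.0 * k)
    np.testing.assert_allclose(u_update(u, x, x, 2.0), u)


# ---------------------------------------------------------------------------
# TV denoiser
# ---------------------------------------------------------------------------


def test_tv_strength_zero_identity(rng):
    img = rng.random((12, 12))
    np.testing.assert_array_equal(tv_denoise(img, 0.0), img)


def test_tv_constant_unchanged():
    img = np.full((10, 10), 2.5)
    np.testing.assert_allclose(tv_denoise(img, 1.0), img, atol=1e-9)


def test_tv_improves_noisy_step_edge(rng):
    clean = np.zeros((16, 64))
    clean[:, 32:] = 1.0
    noisy = clean + rng.normal(0, 0.1, clean.shape)
    den = tv_denoise(noisy, 0.15)
    assert np.sum((den - clean) ** 2) < np.sum((noisy - clean) ** 2)


def test_tv_matches_skimage_chambolle(rng):
    """Independent oracle: skimage's Chambolle solver, long run."""
    from skimage.restoration import denoise_tv_chambolle
    img = rng.random((24, 24))
    ours = tv_denoise(img, 0.08, n_iter=400)
    ref = denoise_tv_chambolle(img, weight=0.08, max_num_iter=1000, eps=1e-10)
    assert np.max(np.abs(ours - ref)) < 5e-3


# ---------------------------------------------------------------------------
# full solver
# ---------------------------------------------------------------------------


def test_cr1_identity_reconstruction(rng):
    """T=1 with an all-ones mask is invertible: recon equals the snapshot."""
    frame = rng.random((12, 12)) * 100
    masks = make_all_on_masks((12, 12), 1)
    snap = forward_encode(frame[np.newaxis], masks)
    cfg = SolverConfig(sigma_schedule=((0.0, 30),),
                       denoiser_cascade=(identity_denoiser(),))
    recon, state = run_pnp_admm(snap, masks, cfg)
    assert np.max(np.abs(recon[0] - frame)) / frame.max() < 1e-6


def test_solver_deterministic(rng):
    scene = rng.random((4, 10, 10)) * 50
    masks = make_mask_stack((10, 10), 4, 0.5, seed=5)
    snap = forward_encode(scene, masks)
    cfg = SolverConfig(sigma_schedule=((0.05, 10), (0.02, 10)))
    a, _ = run_pnp_admm(snap, masks, cfg)
    b, _ = run_pnp_admm(snap, masks, cfg)
    np.testing.assert_array_equal(a, b)


def test_data_residual_decreases_from_init(rng):
    scene = rng.random((4, 12, 12)) * 50
    masks = make_mask_stack((12, 12), 4, 0.5, seed=8)
    op = SensingOperator(masks)
    snap = forward_encode(scene, masks)
    x0 = op.adjoint(snap.image / np.maximum(op.R, 1.0))
    init_resid = float(np.linalg.norm(snap.image - op.forward(x0)))
    _, state = run_pnp_admm(snap, masks, SolverConfig(
        sigma_schedule=((0.05, 5),)))
    assert state.residual_history[0][0] <= init_resid + 1e-9
    assert len(state.residual_history) == state.k


def test_identity_cascade_terminates_finite(rng):
    scene = rng.random((3, 8, 8)) * 10
    masks = make_mask_stack((8, 8), 3, 0.5, seed=2)
    snap = forward_encode(scene, masks)
    cfg = SolverConfig(sigma_schedule=((0.05, 25),),
                       denoiser_cascade=(identity_denoiser(),))
    recon, state = run_pnp_admm(snap, masks, cfg)
    assert np.all(np.isfinite(recon))
    assert state.k <= 25


def test_moving_disk_centroid_recovery_noiseless():
    """Noiseless CR-20 disk phantom: per-frame centroid error < 1 pixel."""
    from cofi.encoding import sample_scene_on_schedule, make_schedule
    from cofi.phantoms import SceneSpec, render_microsphere_flow
    from cofi.metrics import track_nearest_neighbor

    spec = SceneSpec(grid=(64, 80), pixel_pitch_um=1.0,
                     supersampling_factor=4, background_level=1.0)
    sched = make_schedule("uniform", (20, 1.0, 0.5))
    render = lambda ts: render_microsphere_flow(
        spec, 16.0, 1.0, ts, start_position_um=(20.0, 32.0),
        intensity=500.0)[0]
    scene = sample_scene_on_schedule(render, sched)
    _, truth = render_microsphere_flow(spec, 16.0, 1.0, sched.midpoints_ms,
                                       start_position_um=(20.0, 32.0))
    masks = make_mask_stack(scene.grid, 20, 0.5, seed=6)
    snap = forward_encode(scene, masks)
    cfg = SolverConfig(
        sigma_schedule=((0.10, 20), (0.05, 20), (0.02, 20)),
        denoiser_cascade=(DenoiserSpec(kind="tv2d", strength_scale=2.0),))
    recon, _ = run_pnp_admm(snap, masks, cfg)
    tracks = track_nearest_neighbor(
        recon, sched.midpoints_ms,
        {"s": (float(truth["x_um"].iloc[0]), float(truth["y_um"].iloc[0]))},
        window_radius_um=10.0, pixel_pitch_um=1.0, refine_iters=5)
    tr = tracks[0]
    assert tr.time_ms.size == 20
    err = np.hypot(tr.x_um - truth["x_um"].to_numpy(),
                   tr.y_um - truth["y_um"].to_numpy())
    assert err.mean() < 1.0  # 1 pixel at 1-um pitch


def test_two_object_trajectories_recovered_subpixel():
    """Noiseless CR-20 two-object scene: mean centroid error < 1 pixel."""
    from cofi.encoding import sample_scene_on_schedule, make_schedule
    from cofi.phantoms import ObjectTrajectory, SceneSpec, \
        render_moving_objects
    from cofi.metrics import track_nearest_neighbor

    spec = SceneSpec()  # 128 x 160 at 15-um pitch
    sched = make_schedule("uniform", (20, 0.3, 0.15))
    # objects traverse more than their own footprint over the snapshot,
    # the regime where frame separation from one snapshot is well posed
    objs = [
        ObjectTrajectory(shape="circle", diameter_um=150.0, intensity=500.0,
                         position_function=lambda t: (600 + 60 * t,
                                                      700 + 25 * t),
                         object_id="circle"),
        ObjectTrajectory(shape="ellipse", semi_axes_um=(75.0, 45.0),
                         orientation_deg=30.0, intensity=500.0,
                         position_function=lambda t: (1700 - 45 * t,
                                                      1000 + 40 * t),
                         object_id="ellipse"),
    ]
    scene = sample_scene_on_schedule(
        lambda ts: render_moving_objects(spec, objs, ts), sched)
    masks = make_mask_stack(scene.grid, 20, 0.5, seed=17)
    snap = forward_encode(scene, masks)
    cfg = SolverConfig(
        sigma_schedule=((0.10, 20), (0.05, 20), (0.02, 20)),
        denoiser_cascade=(DenoiserSpec(kind="tv3d", strength_scale=0.5),
                          DenoiserSpec(kind="tv2d", strength_scale=1.0)))
    recon, _ = run_pnp_admm(snap, masks, cfg)
    times = sched.midpoints_ms
    for obj, window in ((objs[0], 100.0), (objs[1], 100.0)):
        truth = np.array([obj.position(t) for t in times])
        tracks = track_nearest_neighbor(
            recon, times, {obj.object_id: tuple(truth[0])},
            window_radius_um=window, pixel_pitch_um=15.0, refine_iters=5)
        tr = tracks[0]
        assert tr.time_ms.size == 20
        err = np.hypot(tr.x_um - truth[:, 0], tr.y_um - truth[:, 1])
        assert err.mean() < 15.0, f"{obj.object_id}: {err.mean():.1f} um"


# ---------------------------------------------------------------------------
# PSR
# ---------------------------------------------------------------------------


def test_psr_factor1_identity(rng):
    cube = rng.random((2, 8, 8))
    np.testing.assert_array_equal(apply_psr(cube, 1), cube)


def test_psr_constant_preserved():
    cube = np.full((2, 8, 8), 3.3)
    out = apply_psr(cube, 2)
    assert out.shape == (2, 16, 16)
    np.testing.assert_allclose(out, 3.3, rtol=1e-9)


def test_psr_preserves_mean_flux(rng):
    cube = rng.random((3, 10, 10)) * 20
    out = apply_psr(cube, 4)
    for f_in, f_out in zip(cube, out):
        assert np.isclose(f_in.mean(), f_out.mean())


def test_psr_increases_bar_contrast():
    """Cubic upsampling must not reduce line-pair modulation contrast."""
    from cofi.phantoms import SceneSpec, render_bar_target
    from cofi.metrics import resolvability

    spec = SceneSpec(grid=(64, 64), pixel_pitch_um=15.0,
                     supersampling_factor=4, background_level=0.0)
    d = 60.8
    cube, truth = render_bar_target(spec, [d], 0.0, (0.0, 0.0), [0.0],
                                    group_centers_um=[(480.0, 480.0)])
    frame = cube.frames[0]
    center = (480.0, 480.0)
    base = resolvability(frame, center, 0.0, d, 3, 15.0)
    up = apply_psr(frame, 2)
    fine = resolvability(up, center, 0.0, d, 3, 7.5)
    assert fine.contrast >= base.contrast - 1e-6


def test_psr_rejects_bad_factor(rng):
    with pytest.raises(ValidationError):
        apply_psr(rng.random((2, 4, 4)), 3)


def test_psr_plugin_contract(rng):
    cube = rng.random((2, 6, 6))
    out = apply_psr(cube, 2, plugin=lambda f, k: np.kron(f, np.ones((k, k))))
    assert out.shape == (2, 12, 12)
    with pytest.raises(PluginError):
        apply_psr(cube, 2, plugin=lambda f, k: f)
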