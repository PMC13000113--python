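import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cofi.errors import (
    InsufficientDataError,
    UndefinedCentroidError,
    UndefinedSnrError,
    ValidationError,
)
from cofi.metrics import (
    Track,
    centroid,
    fit_velocity,
    oriented_rect_mask,
    positional_error,
    resolvability,
    sbtp,
    snr,
    spacing_to_lp_per_mm,
    track_nearest_neighbor,
)


# ---------------------------------------------------------------------------
# centroid
# ---------------------------------------------------------------------------


def _gaussian_blob(h, w, cy, cx, sigma=2.0):
    y, x = np.mgrid[:h, :w]
    return np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma ** 2))


def test_centroid_symmetric_blob_center():
    img = _gaussian_blob(21, 21, 10, 10)
    x, y = centroid(img, None, "none", pixel_pitch_um=15.0)
    assert np.isclose(x, 150.0) and np.isclose(y, 150.0)


def test_centroid_two_point_masses():
    img = np.zeros((5, 11))
    img[2, 0] = 10.0
    img[2, 10] = 10.0
    x, _ = centroid(img, None, "none", pixel_pitch_um=3.0)
    assert np.isclose(x, 15.0)  # midpoint of 0 and 30 um


def test_centroid_translation_and_scale_equivariance(rng):
    img = np.zeros((32, 32))
    img[8:14, 10:17] = rng.random((6, 7)) + 0.5
    x0, y0 = centroid(img, None, "none")
    shifted = np.roll(np.roll(img, 3, axis=0), -2, axis=1)
    x1, y1 = centroid(shifted, None, "none")
    assert np.isclose(x1, x0 - 2) and np.isclose(y1, y0 + 3)
    x2, y2 = centroid(img * 7.3, None, "none")
    assert np.isclose(x2, x0) and np.isclose(y2, y0)


def test_centroid_zero_mass_raises():
    img = np.full((8, 8), 3.0)
    with pytest.raises(UndefinedCentroidError):
        centroid(img, None, "min")  # min subtraction removes all mass


def test_oriented_rect_mask_axis_aligned():
    mask = oriented_rect_mask((10, 10), 1.0, (4.0, 4.0), 0.0, 2.0, 1.0)
    rows, cols = np.nonzero(mask)
    assert cols.min() == 2 and cols.max() == 6
    assert rows.min() == 3 and rows.max() == 5


# ---------------------------------------------------------------------------
# tracking and velocity
# ---------------------------------------------------------------------------


def _moving_blob_cube(n=12, h=40, w=60, x0=10.0, y0=20.0, vx=2.0, vy=0.5):
    frames = np.stack([_gaussian_blob(h, w, y0 + vy * k, x0 + vx * k)
                       for k in range(n)])
    return frames, np.arange(n, dtype=float)


def test_single_object_track_matches_centroids():
    cube, times = _moving_blob_cube()
    tracks = track_nearest_neighbor(cube, times, {"b": (10.0, 20.0)},
                                    window_radius_um=8.0, refine_iters=5)
    tr = tracks[0]
    assert tr.time_ms.size == 12
    expected_x = 10.0 + 2.0 * np.arange(12)
    np.testing.assert_allclose(tr.x_um, expected_x, atol=0.05)


def test_two_crossing_objects_identities_preserved():
    n, h, w = 10, 40, 60
    frames = np.zeros((n, h, w))
    for k in range(n):
        frames[k] += _gaussian_blob(h, w, 10, 10 + 3 * k)   # moves right
        frames[k] += _gaussian_blob(h, w, 30, 40 - 3 * k)   # moves left
    tracks = track_nearest_neighbor(frames, np.arange(n, dtype=float),
                                    {"right": (10.0, 10.0),
                                     "left": (40.0, 30.0)},
                                    window_radius_um=6.0)
    by_id = {t.object_id: t for t in tracks}
    assert by_id["right"].y_um.mean() < 15
    assert by_id["left"].y_um.mean() > 25
    assert np.all(np.diff(by_id["right"].x_um) > 0)
    assert np.all(np.diff(by_id["left"].x_um) < 0)


def test_empty_cube_truncates_with_warning():
    cube = np.zeros((5, 16, 16))
    with pytest.warns(UserWarning, match="lost"):
        tracks = track_nearest_neighbor(cube, np.arange(5.0),
                                        {"o": (8.0, 8.0)}, 4.0)
    assert tracks[0].time_ms.size == 0


def test_velocity_exact_linear_track():
    t = np.arange(20, dtype=float)
    speed = 1.02
    tr = Track("s", t, 100 + speed * t * 0.6, 50 + speed * t * 0.8,
               np.ones(20))
    fit = fit_velocity(tr)
    assert np.isclose(fit.speed_um_per_ms, speed, rtol=1e-12)
    assert np.isclose(fit.r_squared, 1.0)


def test_velocity_stationary_track():
    t = np.arange(10, dtype=float)
    fit = fit_velocity(Track("s", t, np.full(10, 5.0), np.full(10, 7.0),
                             np.ones(10)))
    assert fit.speed_um_per_ms == 0.0


def test_velocity_jitter_within_ols_sampling_band():
    """Slope estimate stays within 3 standard errors of the truth."""
    rng = np.random.default_rng(77)
    t = np.arange(20, dtype=float)
    vx, vy = 0.9, -0.4
    for _ in range(10):
        tr = Track("s", t,
                   10 + vx * t + rng.normal(0, 0.5, 20),
                   40 + vy * t + rng.normal(0, 0.5, 20), np.ones(20))
        fit = fit_velocity(tr)
        assert abs(fit.slope_x - vx) < 3 * fit.stderr_x + 1e-12
        assert abs(fit.slope_y - vy) < 3 * fit.stderr_y + 1e-12


def test_velocity_needs_three_points():
    with pytest.raises(InsufficientDataError):
        fit_velocity(Track("s", np.arange(2.0), np.arange(2.0),
                           np.arange(2.0), np.ones(2)))


# ---------------------------------------------------------------------------
# positional error
# ---------------------------------------------------------------------------


def _truth_table(ids, n, positions):
    rows = []
    for oid in ids:
        for k in range(n):
            x, y = positions(oid, k)
            rows.append((k, float(k), oid, x, y))
    return pd.DataFrame(rows, columns=["frame_index", "time_ms", "object_id",
                                       "x_um", "y_um"])


def test_positional_error_zero_for_exact_match():
    truth = _truth_table(["a", "b"], 5, lambda o, k: (10.0 * k, 5.0 * k))
    tracks = [Track(o, np.arange(5.0), 10.0 * np.arange(5),
                    5.0 * np.arange(5), np.ones(5)) for o in ("a", "b")]
    table, mx = positional_error(tracks, truth)
    assert mx == 0.0
    assert np.allclose(table["mean_error_um"], 0.0)


def test_positional_error_constant_offset():
    truth = _truth_table(["a", "b"], 4, lambda o, k: (3.0 * k, 1.0))
    tracks = [Track(o, np.arange(4.0), 3.0 * np.arange(4) + 2.0,
                    np.ones(4), np.ones(4)) for o in ("a", "b")]
    table, mx = positional_error(tracks, truth)
    x_err = table[table["axis"] == "x"]["mean_error_um"]
    assert np.allclose(x_err, 2.0)
    assert np.isclose(mx, 2.0)


def test_positional_error_unmatched_ids_listed():
    truth = _truth_table(["a"], 3, lambda o, k: (0.0, 0.0))
    tracks = [Track("z", np.arange(3.0), np.zeros(3), np.zeros(3),
                    np.ones(3))]
    with pytest.raises(ValidationError, match="a.*z|z.*a"):
        positional_error(tracks, truth)


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------


def test_snr_simple_ratio():
    img = np.zeros((10, 10))
    img[:5] = 100.0
    img[5:] = 10.0
    rep = snr(img, (0, 0, 10, 5), (0, 5, 10, 10))
    assert np.isclose(rep.snr, 10.0)
    assert np.isclose(rep.signal_mean, 100.0)


def test_snr_identical_statistics_near_one(rng):
    img = rng.normal(50, 1, (20, 40))
    rep = snr(img, (0, 0, 20, 20), (20, 0, 40, 20))
    assert abs(rep.snr - 1.0) < 0.05


def test_snr_invariant_to_scaling_monotone_in_signal(rng):
    img = rng.random((16, 16)) + 1.0
    sig, bg = (0, 0, 8, 8), (8, 8, 16, 16)
    r1 = snr(img, sig, bg)
    r2 = snr(img * 9.0, sig, bg)
    assert np.isclose(r1.snr, r2.snr)
    brighter = img.copy()
    brighter[:8, :8] += 1.0
    assert snr(brighter, sig, bg).snr > r1.snr


def test_snr_rejects_overlapping_rois():
    img = np.ones((8, 8))
    with pytest.raises(ValidationError):
        snr(img, (0, 0, 5, 5), (4, 4, 8, 8))


def test_snr_nonpositive_background_undefined():
    img = np.zeros((8, 8))
    img[:4] = 5.0
    with pytest.raises(UndefinedSnrError):
        snr(img, (0, 0, 8, 4), (0, 4, 8, 8))


# ---------------------------------------------------------------------------
# resolvability and SBTP
# ---------------------------------------------------------------------------


def _bar_frame(spacing_um=60.8, pitch=15.0, orientation=0.0):
    from cofi.phantoms import SceneSpec, render_bar_target
    spec = SceneSpec(grid=(64, 64), pixel_pitch_um=pitch,
                     supersampling_factor=4, background_level=0.0)
    cube, _ = render_bar_target(spec, [spacing_um], orientation, (0, 0),
                                [0.0], group_centers_um=[(480.0, 480.0)])
    return cube.frames[0]


def test_ideal_square_wave_resolvable():
    frame = _bar_frame(76.0)
    rep = resolvability(frame, (480.0, 480.0), 0.0, 76.0, 3, 15.0)
    assert rep.resolvable
    assert rep.contrast > 0.8
    assert rep.n_peaks_found == 3


def test_flat_profile_not_resolvable():
    frame = np.full((64, 64), 7.0)
    rep = resolvability(frame, (480.0, 480.0), 0.0, 60.8, 3, 15.0)
    assert not rep.resolvable
    assert rep.contrast == 0.0


def test_smallest_resolvable_spacing_converts_to_lp_mm():
    assert np.isclose(spacing_to_lp_per_mm(60.8), 16.447368421052632)
    rep = resolvability(_bar_frame(60.8), (480.0, 480.0), 0.0, 60.8, 3, 15.0)
    assert np.isclose(rep.lp_per_mm, 1000.0 / 60.8)


def test_sbtp_product_and_linearity():
    assert sbtp(1, 1) == 1
    assert np.isclose(sbtp(127_878, 3_300), 4.22e8, rtol=2e-3)
    assert np.isclose(sbtp(1000, 2 * 50), 2 * sbtp(1000, 50))
    with pytest.raises(ValidationError):
        sbtp(0, 10)


# ---------------------------------------------------------------------------
# multiplexing advantage
# ---------------------------------------------------------------------------


def test_multiplexing_advantage_read_noise_regime():
    """Coded 20-frame integration beats one short exposure in >= 18/20 seeds.

    Low per-frame signal (<= 50 counts) with read noise sigma >= 3 is the
    detector-noise-limited regime where summing the coded frames into one
    exposure incurs the read penalty once instead of per frame.
    """
    from cofi.encoding import (add_sensor_noise, forward_encode,
                               make_all_on_masks, make_mask_stack)
    rng_shape = (32, 32)
    frame = np.full(rng_shape, 1.0)
    # per-frame signal 10 counts: shot sigma ~3.2 < read sigma 5
    frame[12:20, 12:20] = 10.0
    scene = np.stack([frame] * 20)
    sig_roi, bg_roi = (12, 12, 20, 20), (0, 0, 8, 8)
    wins = 0
    for seed in range(20):
        masks = make_mask_stack(rng_shape, 20, 0.5, seed=100 + seed)
        snap = add_sensor_noise(forward_encode(scene, masks), 1.0, 5.0,
                                seed=200 + seed)
        # normalise the coded sum per pixel by the number of open codes
        coded_estimate = snap.image / np.maximum(masks.codes.sum(0), 1)
        short = add_sensor_noise(
            forward_encode(scene[:1], make_all_on_masks(rng_shape, 1)),
            1.0, 5.0, seed=300 + seed)
        snr_coded = snr(coded_estimate, sig_roi, bg_roi).snr
        snr_short = snr(short.image, sig_roi, bg_roi).snr
        wins += snr_coded > snr_short
    assert wins >= 18
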