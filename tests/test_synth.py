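import itertools

import numpy as np
import pytest

from diffuserlf import (
    DiffuserSim,
    LightField,
    generate_bar_target,
    generate_point_pattern,
    make_point_lightfield,
    refocus,
    rescale_pattern,
    shift_pattern,
    simulate_multipoint_scene,
    small_geometry,
)


def _tile_correlations(pattern, sim):
    """Pairwise Pearson correlation matrix of the pattern's tiles."""
    r_up, _, c_left, _ = sim.support_bounds
    th, tw = sim.tile_shape
    tiles = []
    for i in range(sim.config.n_u):
        for j in range(sim.config.n_v):
            tiles.append(pattern.intensity[r_up + i * th:r_up + (i + 1) * th,
                                           c_left + j * tw:c_left + (j + 1) * tw].ravel())
    return np.corrcoef(np.stack(tiles))


def test_pattern_deterministic_and_confined():
    cfg = small_geometry(n_s=8, n_t=8, n_u=4, n_v=4, sensor=128)
    sim = DiffuserSim(config=cfg, seed=11, support_px=(64, 64))
    a = generate_point_pattern(sim)
    b = generate_point_pattern(sim)
    assert np.array_equal(a.intensity, b.intensity)
    r_up, r_down, c_left, c_right = a.meta["support"]
    outside = a.intensity.copy()
    outside[r_up:r_down + 1, c_left:c_right + 1] = 0.0
    assert outside.max() == 0.0
    inside = a.intensity[r_up:r_down + 1, c_left:c_right + 1]
    assert inside.min() > 0.0  # contrast < 1 keeps support strictly positive


def test_degenerate_single_angular_sample():
    cfg = small_geometry(n_s=4, n_t=4, n_u=1, n_v=1, sensor=64)
    sim = DiffuserSim(config=cfg, seed=0, support_px=(16, 16))
    pat = generate_point_pattern(sim)
    r_up, r_down, c_left, c_right = pat.meta["support"]
    crop = pat.intensity[r_up:r_down + 1, c_left:c_right + 1]
    assert np.array_equal(crop, sim.tiles()[0, 0])


def test_tile_too_small_rejected():
    cfg = small_geometry(n_s=4, n_t=4, n_u=8, n_v=8, sensor=64)
    with pytest.raises(ValueError):
        DiffuserSim(config=cfg, seed=0, support_px=(16, 16))


@pytest.mark.parametrize("seed", range(20))
def test_sub_images_pairwise_distinguishable(seed):
    """Off-diagonal tile correlations stay below 0.5 across a seed sweep.

    The transmission model rests on the sub-images being different from
    each other; this enforces, rather than hopes for, that property.
    """
    cfg = small_geometry(n_s=4, n_t=4, n_u=4, n_v=4, sensor=224)
    sim = DiffuserSim(config=cfg, seed=seed, support_px=(192, 192))
    corr = _tile_correlations(generate_point_pattern(sim), sim)
    off = corr[~np.eye(16, dtype=bool)]
    assert np.abs(off).max() < 0.5


def test_shift_identity_inverse_and_conservation(tiny_pattern):
    same = shift_pattern(tiny_pattern, 0, 0)
    assert np.array_equal(same.intensity, tiny_pattern.intensity)
    back = shift_pattern(shift_pattern(tiny_pattern, 5, -3), -5, 3)
    assert np.array_equal(back.intensity, tiny_pattern.intensity)
    moved = shift_pattern(tiny_pattern, 7, 9)
    assert moved.intensity.sum() == pytest.approx(tiny_pattern.intensity.sum())


def test_shift_off_sensor_is_an_error(tiny_pattern):
    with pytest.raises(ValueError, match="off the"):
        shift_pattern(tiny_pattern, 10_000, 0)


def test_rescale_identity_roundtrip_and_centroid():
    cfg = small_geometry(n_s=4, n_t=4, n_u=2, n_v=2, sensor=256)
    sim = DiffuserSim(config=cfg, seed=6, support_px=(64, 64))
    pattern = generate_point_pattern(sim)
    same = rescale_pattern(pattern, 1.0)
    assert np.allclose(same.intensity, pattern.intensity, atol=1e-12)

    up = rescale_pattern(pattern, 2.0)
    back = rescale_pattern(up, 0.5)
    ref = pattern.intensity
    resid = np.linalg.norm(back.intensity - ref) / np.linalg.norm(ref)
    assert resid < 0.3  # bilinear round-trip bound, frozen from a pilot run

    def centroid(img):
        r_up, r_down, c_left, c_right = img.meta["support"]
        return ((r_up + r_down) / 2.0, (c_left + c_right) / 2.0)

    c0 = centroid(pattern)
    c1 = centroid(up)
    assert abs(c0[0] - c1[0]) <= 1.0 and abs(c0[1] - c1[1]) <= 1.0


def test_rescale_beyond_sensor_is_an_error(tiny_pattern):
    with pytest.raises(ValueError, match="exceeds the sensor"):
        rescale_pattern(tiny_pattern, 50.0)


def test_multipoint_scene_cases(tiny_pattern):
    single = simulate_multipoint_scene(tiny_pattern, [(0, 0)], [1.0])
    assert np.array_equal(single.intensity, tiny_pattern.intensity)

    zero = simulate_multipoint_scene(tiny_pattern, [(1, 1), (2, 2)], [0.0, 0.0])
    assert zero.intensity.max() == 0.0

    two = simulate_multipoint_scene(tiny_pattern, [(3, -2), (-4, 5)], [1.0, 2.0])
    expected = (shift_pattern(tiny_pattern, 3, -2).intensity
                + 2.0 * shift_pattern(tiny_pattern, -4, 5).intensity)
    assert np.allclose(two.intensity, expected)


def test_multipoint_scene_linear_in_weights(tiny_pattern, rng):
    shifts = [(2, 1), (-3, 4), (0, -5)]
    w1 = rng.random(3)
    w2 = rng.random(3)
    a = simulate_multipoint_scene(tiny_pattern, shifts, list(w1)).intensity
    b = simulate_multipoint_scene(tiny_pattern, shifts, list(w2)).intensity
    ab = simulate_multipoint_scene(tiny_pattern, shifts, list(w1 + w2)).intensity
    assert np.allclose(ab, a + b)


def test_bar_target_empty_and_radiance():
    cfg = small_geometry(n_s=48, n_t=48, n_u=2, n_v=2, sensor=64)
    empty = generate_bar_target(cfg, [])
    assert empty.radiance.max() == 0.0

    lf = generate_bar_target(cfg, [(3, 3)], sample_pitch_um=25.0)
    w = int(round(49.606 / 25.0))  # 2 samples per bar
    height = min(cfg.n_s - 4, 5 * w)
    assert lf.radiance.sum() == pytest.approx(3 * w * height * cfg.n_angular)


def test_bar_target_three_peaks_at_true_slope():
    from diffuserlf import usaf_linewidth_um

    cfg = small_geometry(n_s=48, n_t=48, n_u=3, n_v=3, sensor=64)
    pitch = 50.0
    lf = generate_bar_target(cfg, [(1, 5)], beta=1.0, sample_pitch_um=pitch)
    w = int(round(usaf_linewidth_um(1, 5) / pitch))
    sl = refocus(lf, 1.0)
    row = sl[cfg.n_s // 2, :]
    peaks = [t for t in range(1, cfg.n_t - 1)
             if row[t] >= row[t - 1] and row[t] >= row[t + 1] and row[t] > 0.5 * row.max()]
    # group contiguous plateau indices into bar centres
    groups = []
    for t in peaks:
        if groups and t - groups[-1][-1] == 1:
            groups[-1].append(t)
        else:
            groups.append([t])
    centres = [np.mean(g) for g in groups]
    assert len(centres) == 3
    assert np.allclose(np.diff(centres), 2 * w, atol=0.6)


def test_bar_width_below_sampling_rejected():
    cfg = small_geometry(n_s=32, n_t=32, n_u=2, n_v=2, sensor=64)
    with pytest.raises(ValueError, match="below one spatial sample"):
        generate_bar_target(cfg, [(7, 6)], sample_pitch_um=100.0)


def test_point_lightfield_rejects_off_grid_beta():
    cfg = small_geometry(n_s=16, n_t=16, n_u=4, n_v=4, sensor=64)
    with pytest.raises(ValueError, match="non-integer"):
        make_point_lightfield(cfg, [(8, 8, 1.0, 1.0)])  # offsets +-0.5 -> 0.5
    lf = make_point_lightfield(cfg, [(8, 8, 2.0, 1.0)])
    assert lf.radiance.sum() == pytest.approx(cfg.n_angular)
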