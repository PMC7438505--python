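import numpy as np
import pytest
import scipy.linalg

from diffuserlf import (
    DiffuserSim,
    LightField,
    ReconSettings,
    SensorImage,
    apply_forward,
    build_transmission_matrix,
    calibrate,
    estimate_lipschitz,
    estimate_step,
    finite_difference,
    finite_difference_adjoint,
    generate_point_pattern,
    prox_fd_nonneg,
    prox_l1_nonneg,
    reconstruct,
    small_geometry,
)
from diffuserlf.core import EncodingKernel


# ---------------------------------------------------------------------------
# proximal operators


def test_prox_l1_nonneg_closed_form():
    assert np.allclose(prox_l1_nonneg(np.array([3.0, -2.0, 0.5]), 1.0), [2.0, 0.0, 0.0])
    x = np.array([-1.0, 0.3, 2.0])
    assert np.allclose(prox_l1_nonneg(x, 0.0), np.maximum(x, 0.0))
    with pytest.raises(ValueError):
        prox_l1_nonneg(x, -0.1)


@pytest.mark.parametrize("x", [-2.0, -0.3, 0.0, 0.4, 1.0, 3.7])
@pytest.mark.parametrize("tau", [0.0, 0.5, 2.0])
def test_prox_l1_nonneg_minimizes_scalar_objective(x, tau):
    """Grid-search oracle: the prox is the constrained scalar minimizer."""
    zs = np.linspace(0.0, 10.0, 20001)
    obj = 0.5 * (zs - x) ** 2 + tau * zs
    oracle = zs[np.argmin(obj)]
    assert prox_l1_nonneg(np.array([x]), tau)[0] == pytest.approx(oracle, abs=1e-3)


def test_finite_difference_closed_forms():
    const = np.ones((4, 3, 2, 2))
    assert finite_difference(const).max() == 0.0
    ramp = np.arange(4.0)[:, None, None, None] * np.ones((1, 1, 1, 1))
    d = finite_difference(ramp)
    assert np.allclose(d[0].ravel(), [1.0, 1.0, 1.0, 0.0])


def test_finite_difference_adjoint_identity(rng):
    x = rng.standard_normal((5, 4, 2, 3))
    p = rng.standard_normal((2, 5, 4, 2, 3))
    lhs = np.sum(finite_difference(x) * p)
    rhs = np.sum(x * finite_difference_adjoint(p))
    assert abs(lhs - rhs) <= 1e-10 * max(abs(lhs), abs(rhs))


def test_prox_fd_nonneg_against_numeric_oracle(rng):
    """Dual FGP matches a direct bounded minimization on a tiny problem."""
    from scipy.optimize import minimize

    x = rng.standard_normal((4, 3, 1, 1)) * 2.0
    weight = 0.7

    def objective(zflat):
        z = zflat.reshape(x.shape)
        return (0.5 * np.sum((z - x) ** 2)
                + weight * np.abs(finite_difference(z)).sum())

    res = minimize(objective, np.maximum(x, 0).ravel(), method="L-BFGS-B",
                   bounds=[(0, None)] * x.size, options={"maxiter": 2000,
                                                         "ftol": 1e-14})
    ours = prox_fd_nonneg(x, weight, n_inner=400)
    assert objective(ours.ravel()) <= res.fun * (1 + 1e-6) + 1e-9
    assert ours.min() >= 0.0
    # weight 0 degenerates to plain projection
    assert np.allclose(prox_fd_nonneg(x, 0.0), np.maximum(x, 0.0))


# ---------------------------------------------------------------------------
# step-size estimation


def _one_pixel_kernel(value: float) -> EncodingKernel:
    cfg = small_geometry(n_s=4, n_t=4, n_u=1, n_v=1, sensor=32)
    sub = np.zeros((1, 1, 4, 4))
    sub[0, 0, 1, 1] = value
    return EncodingKernel(sub, (14, 17), (14, 17), cfg)


def test_lipschitz_rank_one_case():
    c = 3.0
    kernel = _one_pixel_kernel(c)
    L = estimate_lipschitz(kernel, kernel.config)
    assert L == pytest.approx(c**2, rel=1e-8)


def test_lipschitz_matches_svd_oracle(tiny_kernel, tiny_config):
    T = build_transmission_matrix(tiny_kernel, tiny_config)
    sigma_max = scipy.linalg.svdvals(T.toarray())[0]
    L = estimate_lipschitz(tiny_kernel, tiny_config)
    assert L == pytest.approx(sigma_max**2, rel=1e-2)
    assert estimate_step(tiny_kernel, tiny_config) == pytest.approx(1.0 / L)


def test_lipschitz_quadratic_homogeneity(tiny_kernel, tiny_config):
    scaled = EncodingKernel(2.0 * tiny_kernel.sub_images, tiny_kernel.support_rows,
                            tiny_kernel.support_cols, tiny_kernel.config)
    L1 = estimate_lipschitz(tiny_kernel, tiny_config)
    L2 = estimate_lipschitz(scaled, tiny_config)
    assert L2 == pytest.approx(4.0 * L1, rel=1e-6)


# ---------------------------------------------------------------------------
# the solver


def test_zero_image_gives_zero_lightfield(tiny_kernel, tiny_config):
    img = SensorImage(np.zeros(tiny_config.sensor_shape))
    for tau in (None, 0.0, 1.0):
        lf, trace = reconstruct(img, tiny_kernel, tiny_config,
                                ReconSettings(tau=tau, max_iter=5))
        assert lf.radiance.max() == 0.0
        assert trace[-1] == 0.0


def test_nonfinite_image_rejected(tiny_kernel, tiny_config):
    bad = np.zeros(tiny_config.sensor_shape)
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        reconstruct(SensorImage(bad), tiny_kernel, tiny_config)


def test_single_point_support_recovery(tiny_kernel, tiny_config):
    """A noiseless on-axis point concentrates energy at the true (s, t)."""
    delta = np.zeros(tiny_config.lightfield_shape)
    s0 = tiny_config.n_s // 2
    t0 = tiny_config.n_t // 2
    delta[s0, t0, :, :] = 1.0
    img = apply_forward(LightField(delta, tiny_config), tiny_kernel)
    lf, trace = reconstruct(img, tiny_kernel, tiny_config,
                            ReconSettings(max_iter=300))
    for u in range(tiny_config.n_u):
        for v in range(tiny_config.n_v):
            sl = lf.radiance[:, :, u, v]
            assert np.unravel_index(np.argmax(sl), sl.shape) == (s0, t0)
    assert trace[-1] <= trace[0]
    assert lf.radiance.min() >= 0.0


def _projected_gradient_oracle(T, d, tau, n_iter=50_000):
    """Independent long-run reference: dense projected gradient on Eq-form."""
    Td = T.T @ d
    G = T.T @ T
    L = scipy.linalg.eigvalsh(G)[-1]
    x = np.zeros(T.shape[1])
    step = 1.0 / L
    for _ in range(n_iter):
        x = np.maximum(x - step * (G @ x - Td + tau), 0.0)
    return 0.5 * np.sum((T @ x - d) ** 2) + tau * x.sum()


def test_objective_within_one_percent_of_longrun_oracle(rng):
    cfg = small_geometry(n_s=6, n_t=6, n_u=2, n_v=2, sensor=48)
    sim = DiffuserSim(config=cfg, seed=9, support_px=(16, 16))
    kernel = calibrate(generate_point_pattern(sim), cfg)
    truth = np.zeros(cfg.lightfield_shape)
    truth[2, 3, :, :] = 1.0
    truth[4, 1, :, :] = 0.5
    img = apply_forward(LightField(truth, cfg), kernel)
    tau = 0.05
    lf, trace = reconstruct(img, kernel, cfg,
                            ReconSettings(tau=tau, max_iter=2000, tol=0.0))
    T = build_transmission_matrix(kernel, cfg).toarray()
    ref = _projected_gradient_oracle(T, img.intensity.ravel(), tau)
    assert trace[-1] <= ref * 1.01 + 1e-12


def test_fd_regularizer_monotone_and_near_reference():
    cfg = small_geometry(n_s=6, n_t=6, n_u=2, n_v=2, sensor=48)
    sim = DiffuserSim(config=cfg, seed=9, support_px=(16, 16))
    kernel = calibrate(generate_point_pattern(sim), cfg)
    truth = np.zeros(cfg.lightfield_shape)
    truth[1:4, 2:5, :, :] = 1.0  # a small area patch
    img = apply_forward(LightField(truth, cfg), kernel)
    settings = ReconSettings(tau=0.05, psi="finite_difference", max_iter=400,
                             tol=0.0)
    lf, trace = reconstruct(img, kernel, cfg, settings)
    assert trace[-1] <= trace[0]
    assert np.all(np.diff(trace) <= 1e-12)  # monotone variant
    assert lf.radiance.min() >= 0.0
    long = ReconSettings(tau=0.05, psi="finite_difference", max_iter=4000, tol=0.0)
    _, trace_long = reconstruct(img, kernel, cfg, long)
    assert trace[-1] <= trace_long[-1] * 1.01


def test_more_rays_than_pixels_supported():
    """columns(T) > rows(T): the under-determined regime runs fine."""
    cfg = small_geometry(n_s=20, n_t=20, n_u=2, n_v=2, sensor=32)
    sim = DiffuserSim(config=cfg, seed=4, support_px=(8, 8))
    kernel = calibrate(generate_point_pattern(sim), cfg)
    assert cfg.n_rays > cfg.sensor_rows * cfg.sensor_cols
    delta = np.zeros(cfg.lightfield_shape)
    delta[10, 10, :, :] = 1.0
    img = apply_forward(LightField(delta, cfg), kernel)
    lf, _ = reconstruct(img, kernel, cfg, ReconSettings(max_iter=50))
    assert lf.radiance.shape == cfg.lightfield_shape


def test_deterministic_given_settings(tiny_kernel, tiny_config, rng):
    lfarr = rng.random(tiny_config.lightfield_shape)
    img = apply_forward(LightField(lfarr, tiny_config), tiny_kernel)
    a, ta = reconstruct(img, tiny_kernel, tiny_config, ReconSettings(max_iter=30))
    b, tb = reconstruct(img, tiny_kernel, tiny_config, ReconSettings(max_iter=30))
    assert np.array_equal(a.radiance, b.radiance)
    assert np.array_equal(ta, tb)
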