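"""Decoupling reconstruction: sparse non-negative inversion of d = T l.

The inverse problem is underdetermined (T has more columns than rows), so
the light field is recovered as

    argmin_{l >= 0}  1/2 ||d - T l||_2^2  +  tau ||Psi l||_1

with Psi either the identity (point-like scenes) or a first-order
finite-difference operator (area objects).  The solver is a monotone FISTA:
accelerated proximal gradient whose accepted iterate never increases the
objective, with the non-negativity constraint folded into the proximal
step.  Initialization is all-zeros and the iteration is fully
deterministic.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import EncodingKernel, LightField, ReconSettings, SamplingConfig, SensorImage
from .forward import adjoint_array, forward_array

log = logging.getLogger(__name__)

__all__ = [
    "reconstruct",
    "prox_l1_nonneg",
    "prox_fd_nonneg",
    "finite_difference",
    "finite_difference_adjoint",
    "estimate_lipschitz",
    "estimate_step",
]


def prox_l1_nonneg(x: np.ndarray, threshold: float) -> np.ndarray:
    """Proximal map of tau||.||_1 + indicator(. >= 0): one-sided soft threshold.

    For the non-negative orthant the minimizer of
    ``1/2||z - x||^2 + threshold*||z||_1`` over z >= 0 is
    ``max(x - threshold, 0)`` elementwise.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return np.maximum(np.asarray(x, dtype=np.float64) - threshold, 0.0)


def finite_difference(arr: np.ndarray) -> np.ndarray:
    """First-order forward differences along s and t, per angular sample.

    Returns an array of shape ``(2,) + arr.shape``: channel 0 holds
    ``l[s+1]-l[s]`` (zero at the far boundary), channel 1 the analogue
    along t.
    """
    arr = np.asarray(arr, dtype=np.float64)
    out = np.zeros((2,) + arr.shape)
    out[0, :-1] = arr[1:] - arr[:-1]
    out[1, :, :-1] = arr[:, 1:] - arr[:, :-1]
    return out


def finite_difference_adjoint(p: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`finite_difference` (a negative divergence)."""
    p = np.asarray(p, dtype=np.float64)
    out = np.zeros(p.shape[1:])
    out[:-1] -= p[0, :-1]
    out[1:] += p[0, :-1]
    out[:, :-1] -= p[1, :, :-1]
    out[:, 1:] += p[1, :, :-1]
    return out


def prox_fd_nonneg(x: np.ndarray, weight: float, n_inner: int = 30) -> np.ndarray:
    """Prox of ``weight*||D .||_1`` plus non-negativity (anisotropic TV).

    Solved in the dual by fast gradient projection: the dual variable p is
    box-constrained to [-weight, weight] per difference, the primal iterate
    is ``max(x - D' p, 0)``, and p ascends along D of the primal with step
    1/8 (the operator-norm bound of the 2-D difference operator), with
    Nesterov acceleration over ``n_inner`` inner iterations.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    x = np.asarray(x, dtype=np.float64)
    if weight == 0:
        return np.maximum(x, 0.0)
    p = np.zeros((2,) + x.shape)
    q = p.copy()
    t = 1.0
    z = np.maximum(x, 0.0)
    for _ in range(n_inner):
        z = np.maximum(x - finite_difference_adjoint(q), 0.0)
        p_next = np.clip(q + 0.125 * finite_difference(z), -weight, weight)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        q = p_next + ((t - 1.0) / t_next) * (p_next - p)
        p, t = p_next, t_next
    return np.maximum(x - finite_difference_adjoint(p), 0.0)


def estimate_lipschitz(
    kernel: EncodingKernel,
    config: SamplingConfig,
    stride: int = 1,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> float:
    """Largest eigenvalue L = ||T||^2 of T'T by power iteration.

    Deterministic (fixed starting vector).  Raises if the iteration has not
    stabilized within ``max_iter`` sweeps.
    """
    rng = np.random.default_rng(12345)
    x = np.abs(rng.standard_normal(config.lightfield_shape)) + 0.1
    x /= np.linalg.norm(x)
    lam_prev = 0.0
    for _ in range(max_iter):
        y = adjoint_array(forward_array(x, kernel, config, stride),
                          kernel, config, stride)
        lam = float(np.linalg.norm(y))
        if lam == 0.0:
            raise ValueError("kernel maps every light field to zero")
        x = y / lam
        if abs(lam - lam_prev) <= tol * lam:
            return lam
        lam_prev = lam
    raise RuntimeError("power iteration did not converge")


def estimate_step(
    kernel: EncodingKernel, config: SamplingConfig | None = None, stride: int = 1
) -> float:
    """Gradient step 1/L for the data term, L from power iteration."""
    if config is None:
        config = kernel.config
    return 1.0 / estimate_lipschitz(kernel, config, stride)


def _objective(
    x: np.ndarray,
    d: np.ndarray,
    kernel: EncodingKernel,
    config: SamplingConfig,
    stride: int,
    tau: float,
    psi: str,
) -> float:
    resid = forward_array(x, kernel, config, stride) - d
    if psi == "identity":
        reg = float(np.abs(x).sum())
    else:
        reg = float(np.abs(finite_difference(x)).sum())
    return 0.5 * float(np.sum(resid * resid)) + tau * reg


def reconstruct(
    img: SensorImage,
    kernel: EncodingKernel,
    config: SamplingConfig | None = None,
    settings: ReconSettings | None = None,
    stride: int = 1,
) -> tuple[LightField, np.ndarray]:
    """Recover a light field from a sensor image (monotone FISTA).

    Returns the reconstructed light field and the per-iteration objective
    trace.  The result is non-negative at every iterate; the run is
    deterministic for fixed settings.
    """
    if settings is None:
        settings = ReconSettings()
    if config is None:
        config = kernel.config
    d = img.intensity
    if not np.all(np.isfinite(d)):
        raise ValueError("sensor image contains non-finite values")
    if d.shape != kernel.config.sensor_shape:
        raise ValueError("image shape disagrees with kernel sensor geometry")

    atd = adjoint_array(d, kernel, config, stride)
    tau = settings.tau
    if tau is None:
        tau = 1e-3 * float(np.abs(atd).max())
    step = settings.step
    if step == "auto":
        step = estimate_step(kernel, config, stride)

    x = np.zeros(config.lightfield_shape)
    y = x.copy()
    t = 1.0
    fx = _objective(x, d, kernel, config, stride, tau, settings.psi)
    trace = [fx]
    for _ in range(settings.max_iter):
        grad = adjoint_array(forward_array(y, kernel, config, stride),
                             kernel, config, stride) - atd
        if settings.psi == "identity":
            z = prox_l1_nonneg(y - step * grad, step * tau)
        else:
            z = prox_fd_nonneg(y - step * grad, step * tau)
        fz = _objective(z, d, kernel, config, stride, tau, settings.psi)
        accepted = fz <= fx
        if accepted:
            x_next, f_next = z, fz
        else:  # monotone safeguard: keep the best iterate
            x_next, f_next = x, fx
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = x_next + (t / t_next) * (z - x_next) + ((t - 1.0) / t_next) * (x_next - x)
        prev_fx = fx
        x, fx, t = x_next, f_next, t_next
        trace.append(fx)
        log.debug("iter %d objective %.6g%s", len(trace) - 1, fx,
                  "" if accepted else " (step rejected)")
        # convergence is judged on accepted steps only: a rejected momentum
        # step repeats the previous objective without implying stationarity
        if accepted and prev_fx > 0:
            if abs(prev_fx - fx) <= settings.tol * abs(prev_fx):
                break
    return LightField(np.maximum(x, 0.0), config), np.asarray(trace)
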