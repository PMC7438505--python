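"""Light-field post-processing: refocusing, focal stacks, FWHM, depth maps.

Digital refocusing is shift-and-add synthesis on the two-plane light
field: the slice at refocus slope ``beta`` averages the angular samples
after shearing each by ``beta`` times its angular offset from the grid
centre.  ``beta = 0`` reproduces the in-focus image at the spatial
sampling plane; sweeping beta yields a focal stack whose per-pixel focus
maximum gives depth.  Slopes are dimensionless (spatial samples per
angular index); :func:`beta_to_depth` converts to metric depth for a given
plane separation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import DepthMap, FocalStack, LightField

__all__ = [
    "refocus",
    "focal_stack",
    "fwhm",
    "depth_map",
    "beta_to_depth",
]


def refocus(lf: LightField, beta: float) -> np.ndarray:
    """Shift-and-add refocused slice at slope beta.

    ``slice(s, t) = (1/n) * sum_{u,v} l(s + beta*(u - u_bar),
    t + beta*(v - v_bar), u, v)`` with bilinear interpolation, zero beyond
    the grid (physical field of view, no wraparound).
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    cfg = lf.config
    u_bar = (cfg.n_u - 1) / 2.0
    v_bar = (cfg.n_v - 1) / 2.0
    out = np.zeros((cfg.n_s, cfg.n_t))
    for i in range(cfg.n_u):
        for j in range(cfg.n_v):
            ds = beta * (i - u_bar)
            dt = beta * (j - v_bar)
            # output[s] = l[s + ds] -> content moves by -ds
            out += ndimage.shift(lf.radiance[:, :, i, j], (-ds, -dt),
                                 order=1, mode="constant", cval=0.0)
    return out / cfg.n_angular


def focal_stack(lf: LightField, betas: np.ndarray) -> FocalStack:
    """Stack of refocused slices over a sorted slope sweep."""
    betas = np.asarray(betas, dtype=np.float64)
    if betas.size == 0:
        raise ValueError("empty beta sweep")
    if not np.all(np.isfinite(betas)):
        raise ValueError("betas must be finite")
    if np.any(np.diff(betas) < 0):
        raise ValueError("betas must be sorted ascending")
    slices = np.stack([refocus(lf, float(b)) for b in betas])
    return FocalStack(slices, betas)


def fwhm(profile: np.ndarray) -> float:
    """Full width at half maximum of a 1-D profile, in sample units.

    Linear interpolation between the outermost crossings of half the peak
    value.  Used as the computationally resolved size of a reconstructed
    point.  Note the unit is spatial samples, not micrometres: the physical
    size additionally depends on the sample pitch.
    """
    profile = np.asarray(profile, dtype=np.float64)
    if profile.ndim != 1:
        raise ValueError("profile must be 1-D")
    peak = profile.max()
    if peak <= 0:
        raise ValueError("profile has no positive maximum")
    half = peak / 2.0
    above = np.flatnonzero(profile >= half)
    first, last = int(above[0]), int(above[-1])
    if first == 0:
        left = 0.0
    else:
        lo, hi = profile[first - 1], profile[first]
        left = first - 1 + (half - lo) / (hi - lo)
    n = profile.size
    if last == n - 1:
        right = float(n - 1)
    else:
        hi, lo = profile[last], profile[last + 1]
        right = last + (hi - half) / (hi - lo)
    return right - left


def depth_map(stack: FocalStack, window: int = 9) -> DepthMap:
    """Depth from focus: per-pixel argmax slope of a local focus metric.

    The metric is the local variance of the Laplacian over an odd square
    window (default 9).  Ties break toward the smallest beta, so the output
    is deterministic.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if stack.slices.shape[0] < 2:
        raise ValueError("depth is undefined for a single-slice stack")
    scores = np.empty_like(stack.slices)
    for k, sl in enumerate(stack.slices):
        lap = ndimage.laplace(sl, mode="nearest")
        mean = ndimage.uniform_filter(lap, window, mode="nearest")
        mean_sq = ndimage.uniform_filter(lap * lap, window, mode="nearest")
        scores[k] = np.maximum(mean_sq - mean * mean, 0.0)
    # argmax returns the first maximum; betas ascend, so ties pick smallest
    best = np.argmax(scores, axis=0)
    return DepthMap(
        best_beta=stack.betas[best],
        focus_score=np.take_along_axis(scores, best[None], axis=0)[0],
    )


def beta_to_depth(beta: float, plane_separation_mm: float,
                  pitch_ratio: float = 1.0) -> float:
    """Metric depth of the plane refocused at slope beta.

    Under the two-plane geometry a point at distance z from the angular
    (diffuser) plane refocuses at ``beta = (1 - z0/z) * pitch_ratio`` where
    z0 is the spatial-plane separation and ``pitch_ratio`` the
    angular-to-spatial sample pitch ratio; inverting gives
    ``z = z0 / (1 - beta/pitch_ratio)``.  beta = 0 returns the spatial
    sampling plane itself.
    """
    denom = 1.0 - beta / pitch_ratio
    if denom <= 0:
        raise ValueError("beta out of the geometric range for this pitch ratio")
    return plane_separation_mm / denom
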