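"""SVD conditioning analysis of transmission submatrices.

For an object made of a few points, the relevant operator is the
submatrix ``T_sub = (H_i, H_j, ...)`` stacking the per-point blocks, each
a shifted copy of the encoding kernel.  Its singular-value spectrum
quantifies how ill-posed the decoupling inversion is: closely packed
points (an area object) yield nearly collinear columns and a large
condition number, while well-separated points keep the spectrum flat.
The sweep utilities reproduce those trends on simulated kernels at
reduced scale; trends, not absolute condition numbers, are the contract.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp

from .calibration import kernel_for_point
from .core import EncodingKernel, SamplingConfig, TransmissionMatrix
from .forward import _MAX_MATRIX_ENTRIES, single_point_image, spatial_shift

__all__ = [
    "build_submatrix",
    "singular_spectrum",
    "condition_number",
    "scene_points",
    "sampling_sweep",
]


def build_submatrix(
    kernel: EncodingKernel,
    point_spatial_indices: list[tuple[int, int]],
    config: SamplingConfig | None = None,
    stride: int = 1,
) -> TransmissionMatrix:
    """T_sub = (H_i, H_j, ...): horizontal concatenation of per-point blocks.

    Each block holds the n columns of one object point, built by shifting
    the encoding kernel to that point's pixel offset.
    """
    if config is None:
        config = kernel.config
    rows = config.sensor_rows * config.sensor_cols
    n = kernel.n
    cols = n * len(point_spatial_indices)
    if rows * cols > _MAX_MATRIX_ENTRIES:
        raise ValueError("requested submatrix exceeds the materialization guard")
    blocks = []
    column_index = []
    for s, t in point_spatial_indices:
        if not (0 <= s < config.n_s and 0 <= t < config.n_t):
            raise ValueError(f"point ({s}, {t}) is off the spatial sampling grid")
        dr, dc = spatial_shift(s, t, config, stride)
        shifted = kernel_for_point(kernel, dr, dc)
        cols_block = np.empty((rows, n))
        for k in range(n):
            g = np.zeros(n)
            g[k] = 1.0
            cols_block[:, k] = single_point_image(shifted, g).intensity.ravel()
            u, v = divmod(k, config.n_v)
            column_index.append((s, t, u, v))
        blocks.append(sp.csc_matrix(cols_block))
    return TransmissionMatrix(sp.hstack(blocks, format="csc"), column_index)


def singular_spectrum(tmat: TransmissionMatrix | np.ndarray) -> np.ndarray:
    """Singular values normalized by the largest, descending."""
    arr = tmat.toarray() if isinstance(tmat, TransmissionMatrix) else np.asarray(tmat)
    if arr.size == 0:
        raise ValueError("empty matrix")
    sv = scipy.linalg.svdvals(arr)
    if sv[0] == 0:
        raise ValueError("all-zero matrix has no normalized spectrum")
    return sv / sv[0]


def condition_number(tmat: TransmissionMatrix | np.ndarray) -> float:
    """Ratio of largest to smallest singular value (inf if rank deficient)."""
    arr = tmat.toarray() if isinstance(tmat, TransmissionMatrix) else np.asarray(tmat)
    sv = scipy.linalg.svdvals(arr)
    smin = sv[min(arr.shape) - 1]
    if smin == 0:
        return float("inf")
    return float(sv[0] / smin)


def scene_points(
    config: SamplingConfig, n_points: int, interval: int, axis: int = 0
) -> list[tuple[int, int]]:
    """Collinear object points spaced by ``interval`` sample gaps.

    ``interval = 0`` gives grid-adjacent points (the area-object surrogate);
    large intervals give well-separated distributed points.  Points are
    centred on the grid along the chosen axis.
    """
    step = interval + 1
    span = (n_points - 1) * step
    limit = config.n_s if axis == 0 else config.n_t
    if span >= limit:
        raise ValueError(
            f"{n_points} points spaced by {interval} intervals exceed the grid"
        )
    start = (limit - 1 - span) // 2
    fixed = (config.n_t if axis == 0 else config.n_s) // 2
    if axis == 0:
        return [(start + k * step, fixed) for k in range(n_points)]
    return [(fixed, start + k * step) for k in range(n_points)]


def _decay_rate(spectrum: np.ndarray) -> float:
    """Mean per-index drop of log10 singular values (larger = faster decay)."""
    pos = spectrum[spectrum > 0]
    if pos.size < 2:
        return float("inf")
    return float(-(np.log10(pos[-1]) - np.log10(pos[0])) / (pos.size - 1))


def sampling_sweep(
    kernel_factory,
    spatial_samplings: list[int],
    angular_samplings: list[int],
    scenes: dict[str, tuple[int, int]],
    fov_px: int | None = None,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Condition-number sweep over spatio-angular samplings and scenes.

    ``kernel_factory(n_u)`` must return an ``(EncodingKernel, SamplingConfig)``
    pair for that angular sampling; ``scenes`` maps a scene name to
    ``(n_points, interval)``.  Spatial sampling is swept at fixed field of
    view: an ``n_s``-sample grid covers ``fov_px`` pixels with stride
    ``fov_px // n_s`` (finer sampling = smaller stride, as in refining the
    reconstruction grid over the same optics).

    Returns the per-configuration table and booleans for the two expected
    trends: the area-scene condition number grows monotonically with
    spatial sampling, and at fixed spatial sampling the condition number
    varies across angular samplings by less than a factor of 5.
    """
    rows = []
    for n_u in angular_samplings:
        kernel, config = kernel_factory(n_u)
        for n_s in spatial_samplings:
            fov = fov_px if fov_px is not None else max(spatial_samplings)
            if fov % n_s:
                raise ValueError("each n_s must divide the field of view")
            stride = fov // n_s
            cfg = SamplingConfig(
                n_s=n_s, n_t=n_s, n_u=config.n_u, n_v=config.n_v,
                sensor_rows=config.sensor_rows, sensor_cols=config.sensor_cols,
                pixel_pitch_um=config.pixel_pitch_um,
                plane_separation_mm=config.plane_separation_mm,
            )
            for scene, (n_points, interval) in scenes.items():
                pts = scene_points(cfg, n_points, interval)
                tsub = build_submatrix(kernel, pts, cfg, stride=stride)
                spec = singular_spectrum(tsub)
                rows.append({
                    "scene": scene,
                    "n_s": n_s,
                    "n_u": cfg.n_u,
                    "stride_px": stride,
                    "condition_number": condition_number(tsub),
                    "decay_rate": _decay_rate(spec),
                })
    table = pd.DataFrame(rows)
    trends = {}
    if "area" in scenes:
        ok = True
        for n_u in angular_samplings:
            cn = (table[(table.scene == "area") & (table.n_u == n_u)]
                  .sort_values("n_s").condition_number.to_numpy())
            ok &= bool(np.all(np.diff(cn) > 0))
        trends["area_cn_increases_with_spatial_sampling"] = ok
    if len(angular_samplings) > 1:
        ok = True
        for scene in scenes:
            for n_s in spatial_samplings:
                cn = table[(table.scene == scene) & (table.n_s == n_s)
                           ].condition_number.to_numpy()
                finite = cn[np.isfinite(cn)]
                if finite.size != cn.size or finite.min() <= 0:
                    ok = False
                else:
                    ok &= bool(finite.max() / finite.min() < 5.0)
        trends["cn_weak_in_angular_sampling"] = ok
    return table, trends
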