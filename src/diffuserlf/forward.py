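"""Forward transmission model: light field -> sensor image.

Two equivalent routes are provided.  The explicit sparse transmission
matrix T materializes every column (one per ray) and exists as a
brute-force oracle for small instances; the production route exploits
lateral shift invariance to evaluate d = T l as a sum of n 2-D
convolutions (one per angular sample) and scales to full sensor sizes.
Both truncate contributions that fall off the sensor identically, so they
agree to machine precision.

Spatial sample (s, t) maps to the integer pixel shift
``((s - n_s//2) * stride, (t - n_t//2) * stride)`` of the calibrated
support, with a default stride of one pixel.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from scipy import signal

from .core import (
    EncodingKernel,
    LightField,
    SamplingConfig,
    SensorImage,
    TransmissionMatrix,
    ray_index,
)

__all__ = [
    "spatial_shift",
    "single_point_image",
    "build_transmission_matrix",
    "apply_forward",
    "apply_adjoint",
    "forward_array",
    "adjoint_array",
]

_MAX_MATRIX_ENTRIES = 2**28  # rows * cols guard for the explicit oracle


def spatial_shift(s: int, t: int, config: SamplingConfig, stride: int = 1) -> tuple[int, int]:
    """Pixel shift of the pattern for spatial sample (s, t)."""
    return ((s - config.n_s // 2) * stride, (t - config.n_t // 2) * stride)


def _place_tile(canvas: np.ndarray, tile: np.ndarray, r0: int, c0: int,
                weight: float = 1.0) -> None:
    """Add weight*tile at (r0, c0), truncating at the sensor border."""
    rows, cols = canvas.shape
    th, tw = tile.shape
    rs, re = max(r0, 0), min(r0 + th, rows)
    cs, ce = max(c0, 0), min(c0 + tw, cols)
    if rs >= re or cs >= ce:
        return
    canvas[rs:re, cs:ce] += weight * tile[rs - r0:re - r0, cs - c0:ce - c0]


def single_point_image(kernel: EncodingKernel, g: np.ndarray) -> SensorImage:
    """Pattern of one point source: f = H g, a weighted sum of placed tiles.

    ``g`` holds the n per-ray radiances in row-major (u, v) order.
    """
    g = np.asarray(g, dtype=np.float64).reshape(-1)
    if g.size != kernel.n:
        raise ValueError(f"g has length {g.size}, expected n = {kernel.n}")
    canvas = np.zeros(kernel.config.sensor_shape)
    n_v = kernel.config.n_v
    for i, j, tile in kernel.iter_tiles():
        w = g[i * n_v + j]
        if w != 0.0:
            r0, c0 = kernel.tile_origin(i, j)
            _place_tile(canvas, tile, r0, c0, w)
    return SensorImage(canvas)


def build_transmission_matrix(
    kernel: EncodingKernel,
    config: SamplingConfig | None = None,
    stride: int = 1,
) -> TransmissionMatrix:
    """Materialize T = (H_1, ..., H_k) column by column (oracle; small only).

    Column (s, t, u, v) is the flattened image of sub-image (u, v) placed at
    the support translated by the pixel shift of (s, t).  A spatial sample
    whose shifted support lies entirely off the sensor yields a zero column
    and a recorded warning; partial overlap is truncated at the border,
    exactly as in :func:`apply_forward`.
    """
    if config is None:
        config = kernel.config
    rows = config.sensor_rows * config.sensor_cols
    cols = config.n_rays
    if rows * cols > _MAX_MATRIX_ENTRIES:
        raise ValueError(
            f"explicit T would have {rows}x{cols} entries; "
            "use apply_forward for large instances"
        )
    th, tw = kernel.tile_shape
    data, row_idx, col_ptr = [], [], [0]
    canvas = np.zeros(config.sensor_shape)
    index = ray_index(config)
    for s, t, u, v in index:
        dr, dc = spatial_shift(s, t, config, stride)
        r0 = kernel.support_rows[0] + u * th + dr
        c0 = kernel.support_cols[0] + v * tw + dc
        shifted_support_off = (
            kernel.support_rows[1] + dr < 0
            or kernel.support_rows[0] + dr >= config.sensor_rows
            or kernel.support_cols[1] + dc < 0
            or kernel.support_cols[0] + dc >= config.sensor_cols
        )
        if shifted_support_off:
            warnings.warn(
                f"spatial sample ({s},{t}) shifts the support entirely off "
                "the sensor; its columns are zero",
                stacklevel=2,
            )
        canvas.fill(0.0)
        _place_tile(canvas, kernel.sub_images[u, v], r0, c0)
        nz = np.flatnonzero(canvas.ravel())
        data.append(canvas.ravel()[nz])
        row_idx.append(nz)
        col_ptr.append(col_ptr[-1] + nz.size)
    mat = sp.csc_matrix(
        (np.concatenate(data) if data else np.empty(0),
         np.concatenate(row_idx) if row_idx else np.empty(0, dtype=int),
         np.asarray(col_ptr)),
        shape=(rows, cols),
    )
    return TransmissionMatrix(mat, index)


def forward_array(
    radiance: np.ndarray, kernel: EncodingKernel, config: SamplingConfig,
    stride: int = 1,
) -> np.ndarray:
    """Linear forward map on a raw (possibly signed) 4-D radiance array.

    The workhorse behind :func:`apply_forward`; solvers use it directly on
    signed iterates (gradients, residual algebra) where the physical
    non-negativity validation of the public types would get in the way.
    """
    radiance = np.asarray(radiance, dtype=np.float64)
    if radiance.shape != config.lightfield_shape:
        raise ValueError("radiance shape disagrees with config")
    if (config.n_u, config.n_v) != (kernel.config.n_u, kernel.config.n_v):
        raise ValueError("light field and kernel disagree on angular sampling")
    th, tw = kernel.tile_shape
    canvas = np.zeros(kernel.config.sensor_shape)
    gh = (config.n_s - 1) * stride + 1
    gw = (config.n_t - 1) * stride + 1
    weights = np.zeros((gh, gw))
    for i in range(config.n_u):
        for j in range(config.n_v):
            sl = radiance[:, :, i, j]
            if not sl.any():
                continue
            weights.fill(0.0)
            weights[::stride, ::stride] = sl
            conv = signal.fftconvolve(weights, kernel.sub_images[i, j], mode="full")
            r0 = (kernel.support_rows[0] + i * th
                  - (config.n_s // 2) * stride)
            c0 = (kernel.support_cols[0] + j * tw
                  - (config.n_t // 2) * stride)
            _place_tile(canvas, conv, r0, c0)
    return canvas


def apply_forward(
    lf: LightField, kernel: EncodingKernel, stride: int = 1
) -> SensorImage:
    """Efficient forward model d = T l via per-angle 2-D convolution.

    For each angular sample the spatial slice l(., ., u, v), lifted to the
    pixel grid at the sampling stride, is convolved with sub-image (u, v)
    and accumulated at the tile's placement offset; contributions beyond the
    sensor border are truncated.
    """
    canvas = forward_array(lf.radiance, kernel, lf.config, stride)
    return SensorImage(np.clip(canvas, 0.0, None))


def adjoint_array(
    image: np.ndarray, kernel: EncodingKernel, config: SamplingConfig,
    stride: int = 1,
) -> np.ndarray:
    """Exact adjoint T' d of :func:`forward_array` on a raw 2-D array."""
    image = np.asarray(image, dtype=np.float64)
    th, tw = kernel.tile_shape
    rows, cols = image.shape
    out = np.zeros(config.lightfield_shape)
    for i in range(config.n_u):
        for j in range(config.n_v):
            tile = kernel.sub_images[i, j]
            corr = signal.fftconvolve(image, tile[::-1, ::-1], mode="full")
            r0 = (kernel.support_rows[0] + i * th
                  - (config.n_s // 2) * stride)
            c0 = (kernel.support_cols[0] + j * tw
                  - (config.n_t // 2) * stride)
            # l[s,t] = corr[r0 + s*stride + th - 1, c0 + t*stride + tw - 1]
            r_idx = r0 + np.arange(config.n_s) * stride + th - 1
            c_idx = c0 + np.arange(config.n_t) * stride + tw - 1
            rv = (r_idx >= 0) & (r_idx < rows + th - 1)
            cv = (c_idx >= 0) & (c_idx < cols + tw - 1)
            if rv.any() and cv.any():
                out[np.ix_(np.flatnonzero(rv), np.flatnonzero(cv))
                    + (i, j)] = corr[np.ix_(r_idx[rv], c_idx[cv])]
    return out


def apply_adjoint(
    img: SensorImage, kernel: EncodingKernel, config: SamplingConfig, stride: int = 1
) -> np.ndarray:
    """Adjoint applied to a sensor image; see :func:`adjoint_array`.

    Returns a raw 4-D array (not a LightField) because adjoint images of
    general data need not be non-negative.
    """
    return adjoint_array(img.intensity, kernel, config, stride)
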