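"""Domain types, geometry and sampling conventions.

The imaging model lives on a two-plane parameterization of the light field:
rays are indexed by where they cross the *spatial sampling plane* (s, t) and
the *angular sampling plane* (u, v), the latter coinciding with the diffuser.
A thin diffuser maps every ray to a distinct pseudorandom sub-image on the
sensor, so a single 2-D exposure is a linear code of the 4-D radiance
function l(s, t, u, v).

Conventions used throughout the package:

* index order is ``(s, t, u, v)``, row-major, 0-based; ``s``/``t`` are
  aligned with sensor rows/columns,
* angular samples sit on a regular ``n_u x n_v`` grid over the square
  aperture, enumerated row-major,
* vectorization (``flatten_lightfield``) is plain C-order ravel of that
  4-D array, and the transmission-matrix column order matches it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import scipy.sparse as sp

__all__ = [
    "SamplingConfig",
    "LightField",
    "SensorImage",
    "EncodingKernel",
    "TransmissionMatrix",
    "FocalStack",
    "DepthMap",
    "ReconSettings",
    "flatten_lightfield",
    "unflatten_lightfield",
    "usaf_linewidth_um",
    "truncate_decimal",
    "lightfield_sample_count",
    "sensor_megapixels",
]


@dataclass(frozen=True)
class SamplingConfig:
    """Spatio-angular sampling geometry of the imaging system.

    Parameters
    ----------
    n_s, n_t
        Number of spatial samples (rows/columns of the spatial sampling
        plane grid).
    n_u, n_v
        Number of angular samples; ``n = n_u * n_v`` is the number of
        sub-beams, i.e. per-point sub-images.
    sensor_rows, sensor_cols
        Sensor pixel counts.
    pixel_pitch_um
        Sensor pixel size in micrometres.
    plane_separation_mm
        Distance between the spatial sampling plane and the angular
        (diffuser) plane in millimetres.
    """

    n_s: int
    n_t: int
    n_u: int
    n_v: int
    sensor_rows: int
    sensor_cols: int
    pixel_pitch_um: float = 6.5
    plane_separation_mm: float = 10.0

    def __post_init__(self) -> None:
        for name in ("n_s", "n_t", "n_u", "n_v", "sensor_rows", "sensor_cols"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.plane_separation_mm <= 0:
            raise ValueError("plane_separation_mm must be positive")

    @property
    def n_angular(self) -> int:
        """Number of sub-beams n = n_u * n_v."""
        return self.n_u * self.n_v

    @property
    def lightfield_shape(self) -> tuple[int, int, int, int]:
        return (self.n_s, self.n_t, self.n_u, self.n_v)

    @property
    def n_rays(self) -> int:
        return self.n_s * self.n_t * self.n_u * self.n_v

    @property
    def sensor_shape(self) -> tuple[int, int]:
        return (self.sensor_rows, self.sensor_cols)


def lightfield_sample_count(config: SamplingConfig) -> int:
    """Total number of light-field samples (rays) decoupled from one image."""
    return config.n_rays


def sensor_megapixels(config: SamplingConfig) -> float:
    """Sensor pixel count in megapixels."""
    return config.sensor_rows * config.sensor_cols / 1e6


@dataclass
class LightField:
    """4-D radiance l(s, t, u, v) on the two-plane parameterization."""

    radiance: np.ndarray
    config: SamplingConfig

    def __post_init__(self) -> None:
        self.radiance = np.asarray(self.radiance, dtype=np.float64)
        if self.radiance.shape != self.config.lightfield_shape:
            raise ValueError(
                f"radiance shape {self.radiance.shape} does not match config "
                f"{self.config.lightfield_shape}"
            )
        if np.any(self.radiance < 0):
            raise ValueError("radiance must be non-negative everywhere")

    @classmethod
    def zeros(cls, config: SamplingConfig) -> "LightField":
        return cls(np.zeros(config.lightfield_shape), config)

    def copy(self) -> "LightField":
        return LightField(self.radiance.copy(), self.config)


@dataclass
class SensorImage:
    """2-D non-negative detected intensity (the measurement vector d)."""

    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be 2-D")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def copy(self) -> "SensorImage":
        return SensorImage(self.intensity.copy(), dict(self.meta))


@dataclass
class EncodingKernel:
    """Per-angle sub-images of the on-axis point source.

    ``sub_images[i, j]`` is the sub-image of the sub-beam with angular index
    ``(u=i, v=j)``; the n tiles partition the pattern support
    ``[r_up, r_down] x [c_left, c_right]`` (inclusive bounds) without
    overlap, tile (i, j) sitting at rows ``r_up + i*th`` and columns
    ``c_left + j*tw``.
    """

    sub_images: np.ndarray  # (n_u, n_v, tile_h, tile_w)
    support_rows: tuple[int, int]  # (r_up, r_down) inclusive
    support_cols: tuple[int, int]  # (c_left, c_right) inclusive
    config: SamplingConfig

    def __post_init__(self) -> None:
        self.sub_images = np.asarray(self.sub_images, dtype=np.float64)
        if self.sub_images.ndim != 4:
            raise ValueError("sub_images must be a (n_u, n_v, h, w) stack")
        n_u, n_v, th, tw = self.sub_images.shape
        if (n_u, n_v) != (self.config.n_u, self.config.n_v):
            raise ValueError("sub_images angular shape disagrees with config")
        if np.any(self.sub_images < 0):
            raise ValueError("sub-images must be non-negative")
        r_up, r_down = self.support_rows
        c_left, c_right = self.support_cols
        if r_down - r_up + 1 != n_u * th or c_right - c_left + 1 != n_v * tw:
            raise ValueError("support extent does not match the tile partition")

    @property
    def tile_shape(self) -> tuple[int, int]:
        return self.sub_images.shape[2:]

    @property
    def n(self) -> int:
        return self.sub_images.shape[0] * self.sub_images.shape[1]

    def tile_origin(self, i: int, j: int) -> tuple[int, int]:
        """Sensor (row, col) of the top-left pixel of tile (i, j)."""
        th, tw = self.tile_shape
        return (self.support_rows[0] + i * th, self.support_cols[0] + j * tw)

    def iter_tiles(self) -> Iterator[tuple[int, int, np.ndarray]]:
        for i in range(self.sub_images.shape[0]):
            for j in range(self.sub_images.shape[1]):
                yield i, j, self.sub_images[i, j]


@dataclass
class TransmissionMatrix:
    """Explicit sparse transmission matrix T (small instances; oracle use).

    Rows index sensor pixels (C-order), columns index rays.  For the full
    matrix, column order matches :func:`flatten_lightfield`; for submatrices
    ``column_index[k]`` records the (s, t, u, v) tuple of column k.
    """

    matrix: sp.spmatrix
    column_index: list[tuple[int, int, int, int]]

    def __post_init__(self) -> None:
        self.matrix = sp.csc_matrix(self.matrix)
        if self.matrix.shape[1] != len(self.column_index):
            raise ValueError("column_index length must equal column count")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("transmission-matrix entries must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


@dataclass
class FocalStack:
    """Refocused slices over a sweep of the refocus slope beta."""

    slices: np.ndarray  # (n_beta, n_s, n_t)
    betas: np.ndarray

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=np.float64)
        self.betas = np.asarray(self.betas, dtype=np.float64)
        if self.slices.ndim != 3 or len(self.betas) != self.slices.shape[0]:
            raise ValueError("slices must be (n_beta, n_s, n_t) matching betas")


@dataclass
class DepthMap:
    """Per-pixel argmax refocus slope and its focus-metric score."""

    best_beta: np.ndarray
    focus_score: np.ndarray

    def __post_init__(self) -> None:
        if self.best_beta.shape != self.focus_score.shape:
            raise ValueError("best_beta and focus_score must share a shape")


@dataclass
class ReconSettings:
    """Solver settings for the sparse non-negative inversion.

    tau
        Sparsity weight; ``None`` selects a data-scaled default
        ``1e-3 * max |T' d|``.
    psi
        Sparsifying transform: ``"identity"`` or ``"finite_difference"``.
    step
        Gradient step; ``"auto"`` uses 1/L with L from power iteration on
        the normal operator.
    """

    tau: float | None = None
    psi: str = "identity"
    max_iter: int = 200
    step: float | str = "auto"
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau is not None and self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.psi not in ("identity", "finite_difference"):
            raise ValueError("psi must be 'identity' or 'finite_difference'")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if isinstance(self.step, str):
            if self.step != "auto":
                raise ValueError("step must be a positive number or 'auto'")
        elif self.step <= 0:
            raise ValueError("step must be positive")


# ---------------------------------------------------------------------------
# vectorization


def flatten_lightfield(lf: LightField) -> np.ndarray:
    """Vectorize a light field in C-order over (s, t, u, v).

    The ordering matches the column order of the full transmission matrix,
    so ``T @ flatten_lightfield(lf)`` is the flattened sensor image.
    """
    return lf.radiance.reshape(-1).copy()


def unflatten_lightfield(vec: np.ndarray, config: SamplingConfig) -> LightField:
    """Inverse of :func:`flatten_lightfield`."""
    vec = np.asarray(vec, dtype=np.float64)
    if vec.size != config.n_rays:
        raise ValueError(
            f"vector length {vec.size} does not match config ray count {config.n_rays}"
        )
    return LightField(vec.reshape(config.lightfield_shape), config)


def ray_index(config: SamplingConfig) -> list[tuple[int, int, int, int]]:
    """Column -> (s, t, u, v) mapping matching :func:`flatten_lightfield`."""
    shape = config.lightfield_shape
    return [
        tuple(int(x) for x in np.unravel_index(k, shape))
        for k in range(config.n_rays)
    ]


# ---------------------------------------------------------------------------
# USAF-1951 resolution arithmetic


def usaf_linewidth_um(group: int, element: int) -> float:
    """Line width in µm of a USAF-1951 target element.

    The target encodes spatial frequency ``2**(group + (element-1)/6)`` line
    pairs per millimetre, i.e. a line width of ``500 / 2**(group +
    (element-1)/6)`` micrometres.
    """
    if not 1 <= element <= 6:
        raise ValueError("element must be in 1..6")
    return 500.0 / 2.0 ** (group + (element - 1) / 6.0)


def truncate_decimal(x: float, decimals: int = 1) -> float:
    """Truncate (not round) toward zero at the given number of decimals."""
    scale = 10.0**decimals
    return math.trunc(x * scale) / scale
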