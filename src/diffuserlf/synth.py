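"""Synthetic diffuser data: point-source patterns, scenes and targets.

A thin holographic diffuser with an aperture placed against it maps an
on-axis point source to a high-contrast pseudorandom pattern confined to a
rectangular support on the sensor.  Dividing the emitted beam into
``n_u x n_v`` thin sub-beams partitions that support into non-overlapping
sub-images, one per sub-beam, which are statistically independent of each
other because each sub-beam samples a different patch of the random
surface.  The generator reproduces exactly that structure: independent
smoothed-noise tiles on a rectangular support, zero outside.

Sub-images are modelled as smoothed clipped Gaussian noise rather than by
physical wave propagation; the transmission model only requires
distinguishable, non-overlapping, shift-invariant sub-images, and caustic
rendering is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import LightField, SamplingConfig, SensorImage, usaf_linewidth_um

__all__ = [
    "DiffuserSim",
    "small_geometry",
    "full_geometry",
    "generate_point_pattern",
    "shift_pattern",
    "rescale_pattern",
    "simulate_multipoint_scene",
    "generate_bar_target",
    "make_point_lightfield",
]


def full_geometry(n_s: int = 512, n_t: int = 512, n_u: int = 6, n_v: int = 6) -> SamplingConfig:
    """Hardware-scale defaults: 2048x2048 sensor, 6.5 µm pitch, 10 mm gap."""
    return SamplingConfig(
        n_s=n_s, n_t=n_t, n_u=n_u, n_v=n_v,
        sensor_rows=2048, sensor_cols=2048,
        pixel_pitch_um=6.5, plane_separation_mm=10.0,
    )


def small_geometry(
    n_s: int = 32,
    n_t: int = 32,
    n_u: int = 4,
    n_v: int = 4,
    sensor: int = 256,
) -> SamplingConfig:
    """Reduced geometry for fast simulation and testing."""
    return SamplingConfig(
        n_s=n_s, n_t=n_t, n_u=n_u, n_v=n_v,
        sensor_rows=sensor, sensor_cols=sensor,
        pixel_pitch_um=6.5, plane_separation_mm=10.0,
    )


@dataclass
class DiffuserSim:
    """Simulator of the diffuser's point-source response.

    Parameters
    ----------
    seed
        RNG seed; every generator below is deterministic given it.
    correlation_px
        Gaussian smoothing scale of the pseudorandom texture, in pixels
        (the speckle-grain analogue).
    contrast
        Target normalized contrast of each sub-image, in (0, 1]; tiles are
        rescaled so their minimum is ``(1 - contrast)`` of their mean.
    config
        Sampling geometry.
    support_px
        (height, width) of the pattern support in pixels; must be divisible
        by (n_u, n_v).  Default: the largest multiple of ``2 * n_u`` tile
        rows that keeps the support at about half the sensor.
    """

    config: SamplingConfig
    seed: int = 0
    correlation_px: float = 2.0
    contrast: float = 0.9
    support_px: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.correlation_px < 1:
            raise ValueError("correlation_px must be >= 1")
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must be in (0, 1]")
        if self.support_px is None:
            th = max(4, self.config.sensor_rows // (2 * self.config.n_u))
            tw = max(4, self.config.sensor_cols // (2 * self.config.n_v))
            self.support_px = (th * self.config.n_u, tw * self.config.n_v)
        sh, sw = self.support_px
        if sh % self.config.n_u or sw % self.config.n_v:
            raise ValueError("support_px must be divisible by (n_u, n_v)")
        if sh > self.config.sensor_rows or sw > self.config.sensor_cols:
            raise ValueError("support larger than sensor")
        if sh // self.config.n_u < 4 or sw // self.config.n_v < 4:
            raise ValueError("sub-image tile smaller than 4x4 pixels")

    @property
    def tile_shape(self) -> tuple[int, int]:
        return (self.support_px[0] // self.config.n_u,
                self.support_px[1] // self.config.n_v)

    @property
    def support_bounds(self) -> tuple[int, int, int, int]:
        """Centered support as inclusive (r_up, r_down, c_left, c_right)."""
        sh, sw = self.support_px
        r_up = (self.config.sensor_rows - sh) // 2
        c_left = (self.config.sensor_cols - sw) // 2
        return (r_up, r_up + sh - 1, c_left, c_left + sw - 1)

    def tiles(self) -> np.ndarray:
        """Ground-truth sub-image stack, shape (n_u, n_v, th, tw)."""
        rng = np.random.default_rng(self.seed)
        th, tw = self.tile_shape
        out = np.empty((self.config.n_u, self.config.n_v, th, tw))
        for i in range(self.config.n_u):
            for j in range(self.config.n_v):
                out[i, j] = self._texture(rng, th, tw)
        return out

    def _texture(self, rng: np.random.Generator, h: int, w: int) -> np.ndarray:
        noise = rng.standard_normal((h, w))
        tex = ndimage.gaussian_filter(noise, self.correlation_px, mode="reflect")
        tex = np.clip(tex, 0.0, None)
        mean = tex.mean()
        if mean <= 0:  # pathological draw; fall back to a flat tile
            return np.ones((h, w))
        # min >= (1 - contrast) * mean keeps every support pixel positive
        return 1.0 + self.contrast * (tex / mean - 1.0)


def generate_point_pattern(sim: DiffuserSim) -> SensorImage:
    """Pattern of the on-axis point source: tiled pseudorandom sub-images.

    The support is an axis-aligned rectangle centered on the sensor,
    partitioned into ``n_u x n_v`` independent smoothed-noise tiles; the
    intensity outside the support is exactly zero.  The ground-truth support
    is recorded in ``meta["support"]``.
    """
    r_up, r_down, c_left, c_right = sim.support_bounds
    img = np.zeros(sim.config.sensor_shape)
    th, tw = sim.tile_shape
    tiles = sim.tiles()
    for i in range(sim.config.n_u):
        for j in range(sim.config.n_v):
            r0 = r_up + i * th
            c0 = c_left + j * tw
            img[r0:r0 + th, c0:c0 + tw] = tiles[i, j]
    return SensorImage(img, meta={
        "support": (r_up, r_down, c_left, c_right),
        "seed": sim.seed,
        "kind": "point_pattern",
    })


def _support_of(img: SensorImage) -> tuple[int, int, int, int]:
    if "support" in img.meta:
        return tuple(int(x) for x in img.meta["support"])
    nz = np.nonzero(img.intensity)
    if nz[0].size == 0:
        raise ValueError("image is identically zero; no support")
    return (int(nz[0].min()), int(nz[0].max()), int(nz[1].min()), int(nz[1].max()))


def shift_pattern(img: SensorImage, dr: int, dc: int) -> SensorImage:
    """Translate a pattern by integer pixels, zero fill, intensity conserved.

    Mirrors the lateral shift invariance of the diffuser response: a lateral
    move of the point source translates its pattern rigidly.  Raises if the
    shifted support would leave the sensor (a silent crop would destroy
    encoded rays).
    """
    dr, dc = int(dr), int(dc)
    r_up, r_down, c_left, c_right = _support_of(img)
    rows, cols = img.intensity.shape
    if not (0 <= r_up + dr and r_down + dr < rows and 0 <= c_left + dc and c_right + dc < cols):
        raise ValueError(
            f"shift ({dr}, {dc}) pushes support {(r_up, r_down, c_left, c_right)} "
            f"off the {rows}x{cols} sensor"
        )
    out = np.zeros_like(img.intensity)
    src = img.intensity[r_up:r_down + 1, c_left:c_right + 1]
    out[r_up + dr:r_down + 1 + dr, c_left + dc:c_right + 1 + dc] = src
    meta = dict(img.meta)
    meta["support"] = (r_up + dr, r_down + dr, c_left + dc, c_right + dc)
    return SensorImage(out, meta)


def rescale_pattern(img: SensorImage, scale: float) -> SensorImage:
    """Magnify/demagnify a pattern about its support centre.

    Emulates the pattern of a point source at a different axial depth via
    the scaling property of imaging through a thin scatterer.  Bilinear
    interpolation; the result is re-embedded at the same support centre and
    the support metadata is rescaled consistently.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    r_up, r_down, c_left, c_right = _support_of(img)
    rows, cols = img.intensity.shape
    h, w = r_down - r_up + 1, c_right - c_left + 1
    new_h = max(1, int(round(h * scale)))
    new_w = max(1, int(round(w * scale)))
    cr = (r_up + r_down) / 2.0
    cc = (c_left + c_right) / 2.0
    new_r_up = int(round(cr - (new_h - 1) / 2.0))
    new_c_left = int(round(cc - (new_w - 1) / 2.0))
    if new_r_up < 0 or new_r_up + new_h > rows or new_c_left < 0 or new_c_left + new_w > cols:
        raise ValueError(f"scaled support ({new_h}x{new_w}) exceeds the sensor")
    crop = img.intensity[r_up:r_down + 1, c_left:c_right + 1]
    zoomed = ndimage.zoom(crop, (new_h / h, new_w / w), order=1,
                          mode="grid-constant", cval=0.0, grid_mode=True)
    zoomed = np.clip(zoomed, 0.0, None)
    out = np.zeros_like(img.intensity)
    out[new_r_up:new_r_up + new_h, new_c_left:new_c_left + new_w] = zoomed
    meta = dict(img.meta)
    meta["support"] = (new_r_up, new_r_up + new_h - 1,
                       new_c_left, new_c_left + new_w - 1)
    meta["scale"] = scale * float(img.meta.get("scale", 1.0))
    return SensorImage(out, meta)


def simulate_multipoint_scene(
    base: SensorImage,
    shifts: list[tuple[int, int]],
    weights: list[float],
) -> SensorImage:
    """Sensor image of several point sources: weighted sum of shifted patterns.

    Each object point in the spatial sampling plane contributes a rigidly
    shifted copy of the base pattern; an incoherent sensor adds intensities,
    so the scene image is their weighted superposition (linear in weights).
    The ground-truth shifts/weights are carried in ``meta`` for recovery
    tests.
    """
    if len(shifts) != len(weights):
        raise ValueError("shifts and weights must have equal length")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    acc = np.zeros_like(base.intensity)
    for (dr, dc), w in zip(shifts, weights):
        if w == 0:
            continue
        acc += w * shift_pattern(base, dr, dc).intensity
    return SensorImage(acc, meta={
        "kind": "multipoint_scene",
        "shifts": [tuple(int(x) for x in s) for s in shifts],
        "weights": [float(w) for w in weights],
    })


def generate_bar_target(
    config: SamplingConfig,
    group_element_list: list[tuple[int, int]],
    beta: float = 0.0,
    sample_pitch_um: float | None = None,
    level: float = 1.0,
) -> LightField:
    """Light field of a USAF-style three-bar area target.

    Each (group, element) pair renders a vertical three-bar triple whose bar
    width in spatial samples is the USAF line width divided by the spatial
    sample pitch.  The target is an ideal Lambertian emitter: radiance is
    constant across angular indices, and a non-zero ``beta`` places it at
    that refocus slope by shearing each angular slice accordingly.
    """
    if sample_pitch_um is None:
        sample_pitch_um = config.pixel_pitch_um
    plane = np.zeros((config.n_s, config.n_t))
    col = 2
    for group, element in group_element_list:
        w = int(round(usaf_linewidth_um(group, element) / sample_pitch_um))
        if w < 1:
            raise ValueError(
                f"bar width for G{group}/E{element} is below one spatial sample"
            )
        height = min(config.n_s - 4, 5 * w)
        r0 = (config.n_s - height) // 2
        for b in range(3):
            c0 = col + 2 * b * w
            if c0 + w > config.n_t:
                raise ValueError("bar triple does not fit the spatial grid")
            plane[r0:r0 + height, c0:c0 + w] = level
        col += 6 * w + max(2, w)
    lf = np.zeros(config.lightfield_shape)
    u_bar = (config.n_u - 1) / 2.0
    v_bar = (config.n_v - 1) / 2.0
    for i in range(config.n_u):
        for j in range(config.n_v):
            if beta == 0.0:
                lf[:, :, i, j] = plane
            else:
                # l(s,t,u,v) = plane(s - beta*(u-u_bar), t - beta*(v-v_bar))
                lf[:, :, i, j] = np.clip(
                    ndimage.shift(plane, (beta * (i - u_bar), beta * (j - v_bar)),
                                  order=1, mode="constant", cval=0.0),
                    0.0, None)
    return LightField(lf, config)


def make_point_lightfield(
    config: SamplingConfig,
    points: list[tuple[int, int, float, float]],
) -> LightField:
    """Ground-truth light field of ideal point emitters.

    ``points`` is a list of ``(s, t, beta, weight)``.  A point in the
    spatial sampling plane (beta = 0) is a delta at (s, t) across all
    angular samples; a point at refocus slope beta has its per-angle spatial
    position sheared, ``s(u) = s + beta*(u - u_bar)``, which must land on
    the grid (choose beta so the per-angle offsets are integers).
    """
    lf = np.zeros(config.lightfield_shape)
    u_bar = (config.n_u - 1) / 2.0
    v_bar = (config.n_v - 1) / 2.0
    for s, t, beta, weight in points:
        if weight < 0:
            raise ValueError("point weight must be non-negative")
        for i in range(config.n_u):
            for j in range(config.n_v):
                ds = beta * (i - u_bar)
                dt = beta * (j - v_bar)
                if abs(ds - round(ds)) > 1e-9 or abs(dt - round(dt)) > 1e-9:
                    raise ValueError(
                        f"beta={beta} gives non-integer per-angle offsets; "
                        "choose beta so beta*(u - u_bar) is integral"
                    )
                si, ti = s + int(round(ds)), t + int(round(dt))
                if not (0 <= si < config.n_s and 0 <= ti < config.n_t):
                    raise ValueError(
                        f"point ({s},{t}) at beta={beta} leaves the spatial grid"
                    )
                lf[si, ti, i, j] += weight
    return LightField(lf, config)
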