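"""Encoding-kernel calibration from a single point-source pattern.

Because the diffuser response is laterally shift invariant, a single
captured pattern of the on-axis point source determines the whole
transmission matrix: the pattern's support is located, evenly segmented
into ``n_u x n_v`` non-overlapping sub-images (one per sub-beam), and every
other point's block of the matrix is the same kernel with its support
translated.
"""

from __future__ import annotations

import numpy as np

from .core import EncodingKernel, SamplingConfig, SensorImage

__all__ = ["find_support", "segment_pattern", "kernel_for_point", "calibrate"]


def find_support(
    img: SensorImage, threshold_frac: float = 0.01
) -> tuple[int, int, int, int]:
    """Tightest rectangle containing all pixels >= threshold_frac * max.

    The aperture confines the pattern to a rectangular region; intensity
    outside is negligible, so a small fraction of the peak (default 1%)
    separates support from background.  Returns inclusive bounds
    ``(r_up, r_down, c_left, c_right)``.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    peak = img.intensity.max()
    if peak <= 0:
        raise ValueError("cannot find the support of an all-zero image")
    mask = img.intensity >= threshold_frac * peak
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return (int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1]))


def segment_pattern(
    img: SensorImage,
    config: SamplingConfig,
    support: tuple[int, int, int, int],
    pad: bool = True,
) -> EncodingKernel:
    """Evenly segment a pattern's support into the n_u x n_v sub-images.

    Tile (i, j) of the partition is bound to angular sample (u=i, v=j) by
    its row-major geometric position inside the support.  If the support
    extent is not divisible by the angular counts, it is symmetrically
    zero-padded up to the next multiple (trimming would discard encoded
    rays); set ``pad=False`` to make indivisibility an error instead.
    """
    r_up, r_down, c_left, c_right = (int(x) for x in support)
    if r_up > r_down or c_left > c_right:
        raise ValueError("invalid support rectangle")
    h = r_down - r_up + 1
    w = c_right - c_left + 1
    pad_r = (-h) % config.n_u
    pad_c = (-w) % config.n_v
    if (pad_r or pad_c) and not pad:
        raise ValueError(
            f"support {h}x{w} not divisible by angular sampling "
            f"{config.n_u}x{config.n_v} and padding is disabled"
        )
    # grow symmetrically, nudged back inside the sensor if a border is hit
    r_up2 = r_up - pad_r // 2
    r_down2 = r_down + (pad_r - pad_r // 2)
    c_left2 = c_left - pad_c // 2
    c_right2 = c_right + (pad_c - pad_c // 2)
    rows, cols = img.intensity.shape
    if r_up2 < 0:
        r_down2 -= r_up2
        r_up2 = 0
    if r_down2 >= rows:
        r_up2 -= r_down2 - (rows - 1)
        r_down2 = rows - 1
    if c_left2 < 0:
        c_right2 -= c_left2
        c_left2 = 0
    if c_right2 >= cols:
        c_left2 -= c_right2 - (cols - 1)
        c_right2 = cols - 1
    if r_up2 < 0 or c_left2 < 0:
        raise ValueError("padded support does not fit on the sensor")
    th = (r_down2 - r_up2 + 1) // config.n_u
    tw = (c_right2 - c_left2 + 1) // config.n_v
    if th < 1 or tw < 1:
        raise ValueError("support too small for the requested angular sampling")
    crop = img.intensity[r_up2:r_down2 + 1, c_left2:c_right2 + 1]
    sub = crop.reshape(config.n_u, th, config.n_v, tw).transpose(0, 2, 1, 3).copy()
    return EncodingKernel(
        sub_images=sub,
        support_rows=(r_up2, r_down2),
        support_cols=(c_left2, c_right2),
        config=config,
    )


def kernel_for_point(kernel: EncodingKernel, dr: int, dc: int) -> EncodingKernel:
    """Kernel of a laterally shifted point: same sub-images, moved support.

    Shift invariance means the block H_i of an off-axis point is the on-axis
    kernel with its support row/column range translated by the point's pixel
    shift (r_shift); column shifts are handled identically to row shifts.
    """
    dr, dc = int(dr), int(dc)
    r_up, r_down = kernel.support_rows
    c_left, c_right = kernel.support_cols
    rows, cols = kernel.config.sensor_shape
    if not (0 <= r_up + dr and r_down + dr < rows
            and 0 <= c_left + dc and c_right + dc < cols):
        raise ValueError(
            f"shift ({dr}, {dc}) moves the kernel support off the sensor"
        )
    return EncodingKernel(
        sub_images=kernel.sub_images.copy(),
        support_rows=(r_up + dr, r_down + dr),
        support_cols=(c_left + dc, c_right + dc),
        config=kernel.config,
    )


def calibrate(
    img: SensorImage,
    config: SamplingConfig,
    threshold_frac: float = 0.01,
    pad: bool = True,
) -> EncodingKernel:
    """find_support + segment_pattern in one call."""
    return segment_pattern(img, config, find_support(img, threshold_frac), pad=pad)
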