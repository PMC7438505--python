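"""File formats: TIFF/PNG sensor images, HDF5 light fields and kernels."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
from PIL import Image

from .core import EncodingKernel, LightField, SamplingConfig, SensorImage

__all__ = [
    "read_image",
    "write_image",
    "save_lightfield",
    "load_lightfield",
    "save_kernel",
    "load_kernel",
]

FORMAT_VERSION = "1"

_CONFIG_FIELDS = (
    "n_s", "n_t", "n_u", "n_v", "sensor_rows", "sensor_cols",
    "pixel_pitch_um", "plane_separation_mm",
)


def read_image(path: str | Path, allow_rgb: bool = False) -> SensorImage:
    """Read a grayscale TIFF or PNG sensor image.

    Values are promoted to float64 and never rescaled.  Colour input is
    rejected unless ``allow_rgb=True``, in which case channels are
    averaged; non-finite pixels are rejected with their locations.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        with Image.open(path) as im:
            if im.mode in ("I;16", "I;16B"):
                im = im.convert("I")
            arr = np.asarray(im)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if not allow_rgb:
            raise ValueError(
                f"{path} is a colour image; pass allow_rgb=True to average "
                "channels to grayscale"
            )
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    arr = arr.astype(np.float64)
    bad = ~np.isfinite(arr)
    if bad.any():
        locs = np.argwhere(bad)[:5].tolist()
        raise ValueError(
            f"{path} contains {bad.sum()} non-finite pixels, first at {locs}"
        )
    if arr.min() < 0:
        raise ValueError(f"{path} contains negative intensities")
    return SensorImage(arr, meta={"source": str(path)})


def write_image(img: SensorImage, path: str | Path, dtype: str = "auto") -> None:
    """Write a sensor image to TIFF (16-bit integer or float32) or PNG.

    ``dtype='auto'`` keeps integer-valued data in uint16 when it fits
    (lossless round trip) and falls back to float32 TIFF otherwise.
    """
    path = Path(path)
    arr = img.intensity
    if dtype == "auto":
        integral = np.all(arr == np.round(arr)) and arr.max() <= np.iinfo(np.uint16).max
        dtype = "uint16" if integral else "float32"
    out = arr.astype(dtype)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    elif suffix == ".png":
        if dtype not in ("uint8", "uint16"):
            raise ValueError("PNG output requires integer data (uint8/uint16)")
        Image.fromarray(out).save(path)  # uint16 -> I;16, uint8 -> L
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def _write_config(group: h5py.Group, config: SamplingConfig) -> None:
    for f in _CONFIG_FIELDS:
        group.attrs[f] = getattr(config, f)


def _read_config(group: h5py.Group) -> SamplingConfig:
    kwargs = {}
    for f in _CONFIG_FIELDS:
        if f not in group.attrs:
            raise ValueError(f"missing config attribute '{f}'")
        val = group.attrs[f]
        kwargs[f] = float(val) if f.endswith(("_um", "_mm")) else int(val)
    return SamplingConfig(**kwargs)


def _check_version(f: h5py.File, kind: str) -> None:
    version = f.attrs.get("format_version")
    if version is None:
        raise ValueError(f"{kind} file has no format_version attribute")
    if str(version) != FORMAT_VERSION:
        raise ValueError(
            f"{kind} format version {version!r} unsupported "
            f"(expected {FORMAT_VERSION!r})"
        )


def save_lightfield(lf: LightField, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["kind"] = "lightfield"
        dset = f.create_dataset("radiance", data=lf.radiance)
        _write_config(dset, lf.config)


def load_lightfield(path: str | Path) -> LightField:
    with h5py.File(path, "r") as f:
        _check_version(f, "light-field")
        dset = f["radiance"]
        return LightField(dset[()], _read_config(dset))


def save_kernel(kernel: EncodingKernel, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["kind"] = "encoding_kernel"
        dset = f.create_dataset("sub_images", data=kernel.sub_images)
        dset.attrs["support_rows"] = kernel.support_rows
        dset.attrs["support_cols"] = kernel.support_cols
        _write_config(dset, kernel.config)


def load_kernel(path: str | Path) -> EncodingKernel:
    with h5py.File(path, "r") as f:
        _check_version(f, "kernel")
        dset = f["sub_images"]
        return EncodingKernel(
            sub_images=dset[()],
            support_rows=tuple(int(x) for x in dset.attrs["support_rows"]),
            support_cols=tuple(int(x) for x in dset.attrs["support_cols"]),
            config=_read_config(dset),
        )


def write_scene_sidecar(path: str | Path, shifts, weights) -> None:
    """JSON ground-truth sidecar for a simulated multi-point scene."""
    payload = {
        "shifts": [[int(r), int(c)] for r, c in shifts],
        "weights": [float(w) for w in weights],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_scene_sidecar(path: str | Path) -> tuple[list[tuple[int, int]], list[float]]:
    payload = json.loads(Path(path).read_text())
    return ([tuple(s) for s in payload["shifts"]], payload["weights"])
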