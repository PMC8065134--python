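"""Readers and writers for height maps, pattern images and state arrays."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .geometry import HeightField

__all__ = [
    "write_height_map",
    "read_height_map",
    "write_pattern",
    "save_state_arrays",
    "load_state_arrays",
]


def _quantise(z: np.ndarray) -> tuple[np.ndarray, float, float]:
    offset = float(z.min())
    span = float(z.max() - z.min())
    scale = span / 65535.0 if span > 0 else 1.0
    pix = np.round((z - offset) / scale).astype(np.uint16)
    return pix, scale, offset


def write_height_map(path: str | Path, hf: HeightField) -> Path:
    """Write a height field as 16-bit grey-scale image(s) plus a JSON sidecar.

    ``path`` may end in .tif/.tiff/.png (two files, ``*_top`` and
    ``*_bottom``, are produced) or .csv (plain arrays, lossless).  The
    sidecar records the pixel-to-height affine map, the grid spacing and
    the periodicity flags.
    """
    path = Path(path)
    meta: dict = {
        "spacing": hf.spacing,
        "periodic_xy": list(hf.periodic_xy),
        "format": path.suffix.lower().lstrip("."),
    }
    if path.suffix.lower() == ".csv":
        top = path.with_name(path.stem + "_top.csv")
        bot = path.with_name(path.stem + "_bottom.csv")
        np.savetxt(top, hf.z_top, delimiter=",")
        np.savetxt(bot, hf.z_bottom, delimiter=",")
        meta["surfaces"] = {"top": top.name, "bottom": bot.name}
    elif path.suffix.lower() in (".tif", ".tiff", ".png"):
        meta["surfaces"] = {}
        for name, z in (("top", hf.z_top), ("bottom", hf.z_bottom)):
            pix, scale, offset = _quantise(z)
            f = path.with_name(f"{path.stem}_{name}{path.suffix}")
            if path.suffix.lower() == ".png":
                Image.fromarray(pix, mode="I;16").save(f)
            else:
                tifffile.imwrite(f, pix)
            meta["surfaces"][name] = {"file": f.name, "scale": scale, "offset": offset}
    else:
        raise ValueError(f"unsupported height-map format {path.suffix!r}")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_height_map(path: str | Path) -> HeightField:
    """Read a height field written by :func:`write_height_map`.

    ``path`` is the JSON sidecar (or any of the surface files, whose
    sidecar is looked up next to it).
    """
    path = Path(path)
    sidecar = path if path.suffix == ".json" else path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar}: height maps need the JSON file recording "
            "the pixel-to-height scaling, spacing and periodicity"
        )
    meta = json.loads(sidecar.read_text())
    surfaces = {}
    for name, entry in meta["surfaces"].items():
        if meta["format"] == "csv":
            surfaces[name] = np.loadtxt(sidecar.parent / entry, delimiter=",")
        else:
            f = sidecar.parent / entry["file"]
            if f.suffix.lower() == ".png":
                img = Image.open(f)
                arr = np.asarray(img)
            else:
                arr = tifffile.imread(f)
            if arr.dtype.itemsize < 2:
                raise ValueError(
                    f"{f.name} is {arr.dtype}; height maps require at least "
                    "16-bit grey-scale images"
                )
            surfaces[name] = arr.astype(float) * entry["scale"] + entry["offset"]
    return HeightField(
        z_top=surfaces["top"],
        z_bottom=surfaces["bottom"],
        spacing=float(meta["spacing"]),
        periodic_xy=tuple(bool(b) for b in meta["periodic_xy"]),
    )


def write_pattern(path: str | Path, g_image: np.ndarray) -> Path:
    """Write a green-intensity image as an 8-bit green-on-black PNG."""
    path = Path(path)
    g = np.clip(np.nan_to_num(np.asarray(g_image, dtype=float), nan=0.5), 0.0, 1.0)
    rgb = np.zeros(g.shape + (3,), dtype=np.uint8)
    rgb[..., 1] = np.round(g * 255).astype(np.uint8)
    Image.fromarray(rgb).save(path)
    return path


def save_state_arrays(path: str | Path, **arrays: np.ndarray) -> Path:
    """Raw component grids in a portable compressed array container."""
    path = Path(path)
    np.savez_compressed(path, **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_state_arrays(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}
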