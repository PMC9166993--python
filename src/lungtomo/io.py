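"""File I/O helpers: images, sinograms, phantom specs, metric tables."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .geometry import ProjectionGeometry, Sinogram
from .phantom import ImageGrid, PhantomSpec

__all__ = ["save_image", "load_image", "save_sinogram", "load_sinogram",
           "save_phantom_spec", "load_phantom_spec"]


def save_image(image: ImageGrid, path: str | Path, raw: bool = True) -> None:
    """Write a 16-bit grayscale PNG/TIFF plus a lossless ``.npy`` dump.

    The PNG is scaled from the declared value range to the full uint16
    range; the ``.npy`` side-car keeps the exact float values.
    """
    path = Path(path)
    lo, hi = image.value_range
    span = hi - lo if hi > lo else 1.0
    scaled = np.clip((image.values - lo) / span, 0.0, 1.0)
    iio.imwrite(path, (scaled * 65535).astype(np.uint16))
    if raw:
        np.save(path.with_suffix(".npy"), image.values)
        meta = {"pixel_size": image.pixel_size, "value_range": list(image.value_range)}
        path.with_suffix(".json").write_text(json.dumps(meta, sort_keys=True))


def load_image(path: str | Path) -> ImageGrid:
    """Load an image from a ``.npy`` raw dump (with optional ``.json`` meta)."""
    path = Path(path)
    values = np.load(path.with_suffix(".npy") if path.suffix != ".npy" else path)
    meta_path = path.with_suffix(".json")
    pixel_size, value_range = 1.0, (0.0, 1.0)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        pixel_size = float(meta.get("pixel_size", 1.0))
        value_range = tuple(meta.get("value_range", (0.0, 1.0)))
    return ImageGrid(values, pixel_size=pixel_size, value_range=value_range)


def save_sinogram(sino: Sinogram, path: str | Path) -> None:
    """Write sinogram values + geometry to an ``.npz`` archive."""
    geo = sino.geometry
    np.savez(Path(path), values=sino.values, angles=np.asarray(geo.angles),
             detector_count=geo.detector_count,
             detector_spacing=geo.detector_spacing,
             beam_model=np.str_(geo.beam_model))


def load_sinogram(path: str | Path) -> Sinogram:
    with np.load(Path(path)) as z:
        geo = ProjectionGeometry(
            angles=tuple(z["angles"].tolist()),
            detector_count=int(z["detector_count"]),
            detector_spacing=float(z["detector_spacing"]),
            beam_model=str(z["beam_model"]))
        return Sinogram(z["values"], geo)


def save_phantom_spec(spec: PhantomSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=True))


def load_phantom_spec(path: str | Path) -> PhantomSpec:
    return PhantomSpec.from_dict(yaml.safe_load(Path(path).read_text()))
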