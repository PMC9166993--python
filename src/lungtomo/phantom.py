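"""Phantom generation: analytic test objects and lung-slice-like attenuation maps.

Images are square attenuation maps on a grid centred on the coordinate
origin, x to the right, y up, pixel centres at half-integer offsets.  Pixel
membership in a primitive is decided by pixel-centre inclusion (no
anti-aliasing), so counting oracles are exact.

The lung phantom emulates the HRCT appearance of bronchiolitis obliterans:
low-attenuation lung fields with patchy "mosaic perfusion" regions of even
lower density, ring-shaped thickened airway walls, and thin bright vessel
lines inside a soft-tissue thorax ellipse.  All randomness comes from one
NumPy ``default_rng`` (PCG64) stream seeded explicitly, so a given
``(grid_size, seed)`` pair always yields a bit-identical image.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Ellipse",
    "Annulus",
    "Polyline",
    "BlobPatch",
    "PhantomSpec",
    "ImageGrid",
    "LungPhantom",
    "render_phantom",
    "make_lung_phantom",
    "disk_spec",
]


# ---------------------------------------------------------------------------
# primitives


@dataclass(frozen=True)
class Ellipse:
    """Filled ellipse: centre (x, y), semi-axes (a, b), rotation in degrees CCW."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0
    value: float = 1.0

    def validate(self) -> None:
        if self.semi_axes[0] <= 0 or self.semi_axes[1] <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    def mask(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        dx, dy = x - self.center[0], y - self.center[1]
        th = np.deg2rad(self.rotation)
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@dataclass(frozen=True)
class Annulus:
    """Ring between inner and outer radius (airway wall cross-section)."""

    center: tuple[float, float]
    inner_radius: float
    outer_radius: float
    value: float = 1.0

    def validate(self) -> None:
        if self.inner_radius < 0 or self.outer_radius <= 0:
            raise ValueError("annulus radii must be positive")
        if self.inner_radius >= self.outer_radius:
            raise ValueError("annulus inner radius must be < outer radius")

    def mask(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        r2 = (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2
        return (r2 >= self.inner_radius**2) & (r2 <= self.outer_radius**2)


@dataclass(frozen=True)
class Polyline:
    """Thick polyline (vessel-like line); width is the full stroke width."""

    points: tuple[tuple[float, float], ...]
    width: float = 1.0
    value: float = 1.0

    def validate(self) -> None:
        if len(self.points) < 2:
            raise ValueError("polyline needs at least two points")
        if self.width <= 0:
            raise ValueError("polyline width must be positive")

    def mask(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        half = self.width / 2.0
        out = np.zeros(x.shape, dtype=bool)
        pts = np.asarray(self.points, dtype=float)
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            ex, ey = x1 - x0, y1 - y0
            L2 = ex * ex + ey * ey
            if L2 == 0.0:
                d2 = (x - x0) ** 2 + (y - y0) ** 2
            else:
                t = np.clip(((x - x0) * ex + (y - y0) * ey) / L2, 0.0, 1.0)
                d2 = (x - x0 - t * ex) ** 2 + (y - y0 - t * ey) ** 2
            out |= d2 <= half * half
        return out


@dataclass(frozen=True)
class BlobPatch:
    """Disk-shaped patch (mosaic-perfusion region)."""

    center: tuple[float, float]
    radius: float
    value: float = 1.0

    def validate(self) -> None:
        if self.radius <= 0:
            raise ValueError("patch radius must be positive")

    def mask(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2 <= self.radius**2


Primitive = Ellipse | Annulus | Polyline | BlobPatch


# ---------------------------------------------------------------------------
# spec + image containers


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a phantom: grid + ordered primitive list.

    ``value_mode="replace"`` paints each primitive over what is below it (in
    list order); ``"additive"`` accumulates primitive values.
    """

    grid_size: int
    pixel_size: float = 1.0
    elements: tuple[Primitive, ...] = ()
    value_mode: str = "replace"
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.value_mode not in ("replace", "additive"):
            raise ValueError(f"unknown value_mode {self.value_mode!r}")

    def to_dict(self) -> dict:
        def plain(v):  # numpy scalars -> YAML/JSON-safe python numbers
            if isinstance(v, (tuple, list)):
                return [plain(u) for u in v]
            return float(v) if isinstance(v, (float, np.floating)) else v

        elems = []
        for e in self.elements:
            d = {k: plain(v) for k, v in dataclasses.asdict(e).items()}
            d["kind"] = type(e).__name__.lower()
            elems.append(d)
        return {
            "grid_size": self.grid_size,
            "pixel_size": self.pixel_size,
            "value_mode": self.value_mode,
            "background": self.background,
            "elements": elems,
        }

    @staticmethod
    def from_dict(d: dict) -> "PhantomSpec":
        kinds = {
            "ellipse": Ellipse,
            "annulus": Annulus,
            "polyline": Polyline,
            "blobpatch": BlobPatch,
        }
        elems = []
        for e in d.get("elements", []):
            e = dict(e)
            cls = kinds[e.pop("kind")]
            for k in ("center", "semi_axes"):
                if k in e:
                    e[k] = tuple(e[k])
            if "points" in e:
                e["points"] = tuple(tuple(p) for p in e["points"])
            elems.append(cls(**e))
        return PhantomSpec(
            grid_size=int(d["grid_size"]),
            pixel_size=float(d.get("pixel_size", 1.0)),
            elements=tuple(elems),
            value_mode=d.get("value_mode", "replace"),
            background=float(d.get("background", 0.0)),
        )


@dataclass
class ImageGrid:
    """Square 2D attenuation map.

    ``values[i, j]`` is the attenuation of the pixel in row ``i`` (top row is
    ``i = 0``, largest y) and column ``j`` (leftmost is smallest x).  The
    flattened image vector used by the projector and the solvers is the
    row-major ravel of ``values``.
    """

    values: np.ndarray
    pixel_size: float = 1.0
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"image must be square 2D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def grid_size(self) -> int:
        return self.values.shape[0]

    @property
    def vector(self) -> np.ndarray:
        return self.values.ravel()

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of pixel centres, shape (n, n) each."""
        n, d = self.grid_size, self.pixel_size
        c = (np.arange(n) - (n - 1) / 2.0) * d
        x = np.broadcast_to(c, (n, n))
        y = np.broadcast_to(-c[:, None], (n, n))
        return x, y

    def copy(self) -> "ImageGrid":
        return ImageGrid(self.values.copy(), self.pixel_size, self.value_range)

    @staticmethod
    def from_vector(
        vec: np.ndarray, grid_size: int, pixel_size: float = 1.0,
        value_range: tuple[float, float] = (0.0, 1.0),
    ) -> "ImageGrid":
        return ImageGrid(
            np.asarray(vec, dtype=float).reshape(grid_size, grid_size),
            pixel_size, value_range,
        )


# ---------------------------------------------------------------------------
# rendering


def render_phantom(spec: PhantomSpec) -> ImageGrid:
    """Rasterise a PhantomSpec by pixel-centre inclusion.

    Primitives are applied in list order.  Deterministic: the same spec
    always yields the same array.
    """
    for k, e in enumerate(spec.elements):
        try:
            e.validate()
        except ValueError as err:
            raise ValueError(f"element {k} ({type(e).__name__}): {err}") from err

    n, d = spec.grid_size, spec.pixel_size
    img = np.full((n, n), float(spec.background))
    c = (np.arange(n) - (n - 1) / 2.0) * d
    x = np.broadcast_to(c, (n, n))
    y = np.broadcast_to(-c[:, None], (n, n))
    for e in spec.elements:
        m = e.mask(x, y)
        if spec.value_mode == "replace":
            img[m] = e.value
        else:
            img[m] += e.value
    lo = float(min(img.min(), 0.0))
    hi = float(max(img.max(), 1.0))
    return ImageGrid(img, pixel_size=d, value_range=(lo, hi))


def disk_spec(grid_size: int, radius: float, value: float = 1.0,
              pixel_size: float = 1.0) -> PhantomSpec:
    """Centred uniform disk — the standard analytic test object."""
    return PhantomSpec(
        grid_size=grid_size,
        pixel_size=pixel_size,
        elements=(BlobPatch(center=(0.0, 0.0), radius=radius, value=value),),
    )


# ---------------------------------------------------------------------------
# lung phantom

# relative attenuation values on a [0, 1] scale (air = 0, dense tissue ~ 0.5)
_THORAX_VALUE = 0.50
_LUNG_VALUE = 0.10
_MOSAIC_VALUE = 0.04
_LUMEN_VALUE = 0.03
_WALL_VALUE = 0.35
_VESSEL_VALUE = 0.35


@dataclass
class LungPhantom:
    """Rendered lung phantom plus the spec and placement manifest behind it."""

    image: ImageGrid
    spec: PhantomSpec
    manifest: pd.DataFrame  # columns: element, cx, cy, size1, size2, value


def _sample_in_ellipse(rng: np.random.Generator, ell: Ellipse,
                       margin: float) -> tuple[float, float]:
    """Uniform point in the ellipse shrunk by ``margin`` (0..1)."""
    while True:
        u, v = rng.uniform(-1, 1, size=2)
        if u * u + v * v <= margin * margin:
            return (ell.center[0] + u * ell.semi_axes[0],
                    ell.center[1] + v * ell.semi_axes[1])


def make_lung_phantom(grid_size: int, seed: int,
                      pixel_size: float | None = None) -> LungPhantom:
    """Build a thorax-slice phantom with BO-like imaging signs.

    The slice contains: a soft-tissue thorax ellipse; two low-attenuation
    lung fields; seeded mosaic-perfusion patches (attenuation below the
    surrounding lung); airway cross-sections as air lumens ringed by
    thickened walls (>= 1 px); and thin vessel lines fanning out from the
    hila.  ``pixel_size`` defaults to ``4.0 / grid_size`` so that a ray
    through the mediastinum accumulates optical depth of about 2, a
    physically sensible regime for the Beer–Lambert dose model.
    """
    if grid_size < 64:
        raise ValueError("grid_size must be >= 64 to place all structure classes")
    if pixel_size is None:
        pixel_size = 4.0 / grid_size
    rng = np.random.default_rng(seed)
    W = grid_size * pixel_size  # physical image width
    px = pixel_size

    elements: list[Primitive] = []
    rows: list[dict] = []

    def add(elem: Primitive, cls: str, cx: float, cy: float,
            s1: float, s2: float, val: float) -> None:
        elements.append(elem)
        rows.append(dict(element=cls, cx=cx, cy=cy, size1=s1, size2=s2, value=val))

    thorax = Ellipse((0.0, 0.0), (0.47 * W, 0.36 * W), 0.0, _THORAX_VALUE)
    add(thorax, "thorax", 0.0, 0.0, 0.47 * W, 0.36 * W, _THORAX_VALUE)

    lungs = [
        Ellipse((-0.21 * W, 0.01 * W), (0.16 * W, 0.27 * W), 8.0, _LUNG_VALUE),
        Ellipse((+0.21 * W, 0.01 * W), (0.16 * W, 0.27 * W), -8.0, _LUNG_VALUE),
    ]
    for lung in lungs:
        add(lung, "lung_field", *lung.center, *lung.semi_axes, _LUNG_VALUE)

    # mosaic-perfusion patches: lower attenuation than the lung around them
    for lung in lungs:
        for _ in range(int(rng.integers(3, 6))):
            r = rng.uniform(0.030, 0.060) * W
            margin = 1.0 - r / min(lung.semi_axes) - 0.05
            cx, cy = _sample_in_ellipse(rng, lung, max(margin, 0.1))
            add(BlobPatch((cx, cy), r, _MOSAIC_VALUE), "mosaic_patch",
                cx, cy, r, r, _MOSAIC_VALUE)

    # vessels: thin bright lines from the hilum toward the periphery
    for lung, sgn in zip(lungs, (-1.0, +1.0)):
        hx = lung.center[0] - sgn * 0.55 * lung.semi_axes[0]
        hy = lung.center[1]
        for _ in range(int(rng.integers(2, 5))):
            tip = _sample_in_ellipse(rng, lung, 0.85)
            mid = (0.5 * (hx + tip[0]) + rng.uniform(-0.02, 0.02) * W,
                   0.5 * (hy + tip[1]) + rng.uniform(-0.02, 0.02) * W)
            wdt = max(px, rng.uniform(0.010, 0.018) * W)
            line = Polyline(((hx, hy), mid, tip), wdt, _VESSEL_VALUE)
            add(line, "vessel_line", 0.5 * (hx + tip[0]), 0.5 * (hy + tip[1]),
                wdt, float(np.hypot(tip[0] - hx, tip[1] - hy)), _VESSEL_VALUE)

    # airways: air lumen + thickened wall ring (wall >= 1 px)
    for lung in lungs:
        for _ in range(int(rng.integers(1, 3))):
            r_out = rng.uniform(0.028, 0.045) * W
            wall = max(px, 0.35 * r_out)
            r_in = max(r_out - wall, 0.25 * r_out)
            margin = 1.0 - r_out / min(lung.semi_axes) - 0.05
            cx, cy = _sample_in_ellipse(rng, lung, max(margin, 0.1))
            add(BlobPatch((cx, cy), r_in, _LUMEN_VALUE), "airway_lumen",
                cx, cy, r_in, r_in, _LUMEN_VALUE)
            add(Annulus((cx, cy), r_in, r_out, _WALL_VALUE), "airway_annulus",
                cx, cy, r_in, r_out, _WALL_VALUE)

    spec = PhantomSpec(grid_size=grid_size, pixel_size=pixel_size,
                       elements=tuple(elements))
    image = render_phantom(spec)
    manifest = pd.DataFrame(rows)
    return LungPhantom(image=image, spec=spec, manifest=manifest)
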