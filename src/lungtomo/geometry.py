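"""Parallel-beam projection geometry: system matrix and forward projection.

Conventions (fixed once, recorded in ``SystemMatrix.meta``):

* image centred at the origin, x right, y up, pixel centres at
  half-integer offsets; pixels flattened row-major from the top-left;
* the view angle ``theta`` is measured counterclockwise from the +x axis
  and parametrises the detector coordinate ``s = x cos(theta) + y
  sin(theta)``; a ray (or strip) is the level set of ``s``;
* rays are indexed angle-major, then detector bin; the detector array is
  centred on the origin.

Two beam models are supported.  In ``"strip"`` mode a ray is a band of
width equal to the detector spacing and the weight of pixel j in ray i is
the intersection area divided by the pixel area (a dimensionless number in
[0, 1]).  In ``"line"`` mode the ray has zero width and the weight is the
chord length of the line through the pixel.  Both are evaluated with the
exact piecewise-quadratic overlap of a square with a half-plane, so the
weights agree with brute-force polygon clipping to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .phantom import ImageGrid

__all__ = ["ProjectionGeometry", "SystemMatrix", "Sinogram",
           "build_system_matrix", "forward_project"]


@dataclass(frozen=True)
class ProjectionGeometry:
    """View angles (degrees, in [0, 360), strictly increasing) + detector layout."""

    angles: tuple[float, ...]
    detector_count: int
    detector_spacing: float = 1.0
    beam_model: str = "strip"

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "angles", tuple(a.tolist()))
        if a.size == 0:
            raise ValueError("angles must be nonempty")
        if np.any(a < 0) or np.any(a >= 360):
            raise ValueError("angles must lie in [0, 360)")
        if np.any(np.diff(a) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.detector_count < 1:
            raise ValueError("detector_count must be >= 1")
        if self.detector_spacing <= 0:
            raise ValueError("detector_spacing must be positive")
        if self.beam_model not in ("strip", "line"):
            raise ValueError(f"unknown beam_model {self.beam_model!r}")

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    @property
    def n_rays(self) -> int:
        return self.n_angles * self.detector_count

    def detector_positions(self) -> np.ndarray:
        """Centre coordinate s_k of each detector bin (centred array)."""
        d, w = self.detector_count, self.detector_spacing
        return (np.arange(d) - (d - 1) / 2.0) * w

    @staticmethod
    def uniform(start: float, stop: float, step: float, detector_count: int,
                detector_spacing: float = 1.0, beam_model: str = "strip",
                ) -> "ProjectionGeometry":
        angles = tuple(np.arange(start, stop, step, dtype=float).tolist())
        return ProjectionGeometry(angles, detector_count, detector_spacing,
                                  beam_model)


@dataclass
class SystemMatrix:
    """Sparse ray-by-pixel weight matrix R (rows angle-major, cols row-major)."""

    entries: sp.csr_matrix
    geometry: ProjectionGeometry
    grid_size: int
    pixel_size: float
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    @property
    def row_norms_sq(self) -> np.ndarray:
        """||a_i||^2 per ray, cached (needed by the Kaczmarz update)."""
        if "row_norms_sq" not in self.meta:
            self.meta["row_norms_sq"] = np.asarray(
                self.entries.multiply(self.entries).sum(axis=1)).ravel()
        return self.meta["row_norms_sq"]


@dataclass
class Sinogram:
    """Projection measurements, shape (n_angles, detector_count)."""

    values: np.ndarray
    geometry: ProjectionGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expect = (self.geometry.n_angles, self.geometry.detector_count)
        if self.values.shape != expect:
            raise ValueError(
                f"sinogram shape {self.values.shape} != geometry shape {expect}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")

    @property
    def vector(self) -> np.ndarray:
        return self.values.ravel()


# ---------------------------------------------------------------------------
# square/half-plane overlap profile
#
# Project the pixel square onto the detector axis.  With a = |cos t|*delta,
# b = |sin t|*delta, amax = max(a,b), bmin = min(a,b), the chord length of
# the line s = const through the square, as a function of the offset
# u = s - (c - h) from the leading edge (c = projected centre,
# h = (amax+bmin)/2), is the trapezoid
#     L(u) = k*u            on (0, bmin],     k = delta^2/(amax*bmin)
#          = delta^2/amax   on (bmin, amax]
#          = k*(amax+bmin-u) on (amax, amax+bmin)
# and the cumulative area A(u) = integral of L is used for strip weights.


def _overlap_params(theta_rad: float, delta: float) -> tuple[float, float]:
    a = abs(np.cos(theta_rad)) * delta
    b = abs(np.sin(theta_rad)) * delta
    return (max(a, b), min(a, b))


def _cum_area(u: np.ndarray, amax: float, bmin: float, delta: float) -> np.ndarray:
    """Area of the pixel square on the side s <= (leading edge + u)."""
    full = delta * delta
    H = full / amax
    u = np.clip(u, 0.0, amax + bmin)
    if bmin < 1e-12 * delta:  # axis-aligned view: rectangular profile
        return H * np.clip(u, 0.0, amax)
    k = H / bmin
    out = np.where(
        u <= bmin,
        0.5 * k * u * u,
        np.where(
            u <= amax,
            0.5 * k * bmin * bmin + H * (u - bmin),
            full - 0.5 * k * (amax + bmin - u) ** 2,
        ),
    )
    return out


def _chord(u: np.ndarray, amax: float, bmin: float, delta: float) -> np.ndarray:
    """Chord length of the line at offset u from the leading edge."""
    full = delta * delta
    H = full / amax
    inside = (u > 0) & (u < amax + bmin)
    if bmin < 1e-12 * delta:
        # axis-aligned view: half-open [0, amax) so a line on a shared pixel
        # edge is claimed by exactly one pixel, not zero or two
        return np.where((u >= 0) & (u < amax), H, 0.0)
    k = H / bmin
    out = np.where(
        u <= bmin, k * u,
        np.where(u <= amax, H, k * (amax + bmin - u)),
    )
    return np.where(inside, out, 0.0)


def build_system_matrix(grid: ImageGrid | int, geometry: ProjectionGeometry,
                        pixel_size: float | None = None) -> SystemMatrix:
    """Build the sparse projection matrix R for a grid and a geometry.

    ``grid`` may be an :class:`ImageGrid` (its size and pixel size are used)
    or a bare grid size, in which case ``pixel_size`` applies (default 1).
    """
    if isinstance(grid, ImageGrid):
        n, delta = grid.grid_size, grid.pixel_size
    else:
        n, delta = int(grid), float(pixel_size if pixel_size is not None else 1.0)
        if n < 2:
            raise ValueError("grid size must be >= 2")
        if delta <= 0:
            raise ValueError("pixel_size must be positive")

    D = geometry.detector_count
    w = geometry.detector_spacing
    strip = geometry.beam_model == "strip"
    # pixel centres, flattened row-major (top-left first)
    c1 = (np.arange(n) - (n - 1) / 2.0) * delta
    X = np.broadcast_to(c1, (n, n)).ravel()
    Y = np.broadcast_to(-c1[:, None], (n, n)).ravel()
    cols_all: list[np.ndarray] = []
    rows_all: list[np.ndarray] = []
    vals_all: list[np.ndarray] = []
    pix_idx = np.arange(n * n)
    s_first = -(D - 1) / 2.0 * w  # centre of bin 0
    edge0 = s_first - w / 2.0     # left edge of bin 0

    for vi, ang in enumerate(geometry.angles):
        t = np.deg2rad(ang)
        amax, bmin = _overlap_params(t, delta)
        h = 0.5 * (amax + bmin)
        c = X * np.cos(t) + Y * np.sin(t)      # projected pixel centres
        start = c - h                          # leading edge of each pixel
        if strip:
            k_lo = np.floor((start - edge0) / w).astype(np.int64)
            span = int(np.ceil(2 * h / w)) + 1
            for off in range(span + 1):
                k = k_lo + off
                ok = (k >= 0) & (k < D)
                if not np.any(ok):
                    continue
                uL = edge0 + k[ok] * w - start[ok]
                wgt = (_cum_area(uL + w, amax, bmin, delta)
                       - _cum_area(uL, amax, bmin, delta)) / (delta * delta)
                nz = wgt > 0
                if not np.any(nz):
                    continue
                cols_all.append(pix_idx[ok][nz])
                rows_all.append(vi * D + k[ok][nz])
                vals_all.append(wgt[nz])
        else:
            k_lo = np.ceil((start - s_first) / w).astype(np.int64)
            span = int(np.floor(2 * h / w)) + 1
            for off in range(span + 1):
                k = k_lo + off
                ok = (k >= 0) & (k < D)
                if not np.any(ok):
                    continue
                u = s_first + k[ok] * w - start[ok]
                wgt = _chord(u, amax, bmin, delta)
                nz = wgt > 0
                if not np.any(nz):
                    continue
                cols_all.append(pix_idx[ok][nz])
                rows_all.append(vi * D + k[ok][nz])
                vals_all.append(wgt[nz])

    if rows_all:
        rows = np.concatenate(rows_all)
        cols = np.concatenate(cols_all)
        vals = np.concatenate(vals_all)
    else:  # every ray misses the grid
        rows = cols = np.empty(0, dtype=np.int64)
        vals = np.empty(0)
    R = sp.coo_matrix((vals, (rows, cols)),
                      shape=(geometry.n_rays, n * n)).tocsr()
    R.sum_duplicates()
    meta = {
        "ray_order": "angle-major",
        "pixel_order": "row-major-from-top-left",
        "angle_convention": "ccw-from-+x; s = x cos(theta) + y sin(theta)",
    }
    return SystemMatrix(entries=R, geometry=geometry, grid_size=n,
                        pixel_size=delta, meta=meta)


def forward_project(image: ImageGrid, matrix: SystemMatrix) -> Sinogram:
    """Discrete Radon transform: sinogram_i = sum_j r_ij x_j (linear in x)."""
    if image.grid_size != matrix.grid_size:
        raise ValueError(
            f"image grid {image.values.shape} does not match the "
            f"{matrix.grid_size}x{matrix.grid_size} grid the matrix was built for")
    p = matrix.entries @ image.vector
    geo = matrix.geometry
    return Sinogram(p.reshape(geo.n_angles, geo.detector_count), geo)
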