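"""Counting probes: 3D unbiased brick (optical disector), double disector,
2D unbiased counting frame, and point grids.

The disector rule: a particle is counted by a brick iff it intersects the
closed brick box and touches none of the brick's exclusion surfaces — the
look-up face, plus the 2D frame's forbidden line of the brick footprint
swept through every plane from the look-up level onward (through the brick
and beyond the reference plane).  With this surface set, translated copies
of the brick tile space so that every particle is counted by exactly one
copy (the mosaic property), which is what makes the number estimate
unbiased regardless of particle size or shape.  Sweeping the full 2D
forbidden line — rather than only the two side faces and their vertical
extensions — is what resolves particles that straddle a lateral corner of
the footprint without entering the diagonal neighbour; it is also how an
optical disector is operated in practice (unbiased frame applied on every
optical section, look-up section excluded).

The 2D unbiased counting frame is the planar analogue: a rectangle whose
forbidden line is the left edge, the bottom edge, the upward extension of
the left edge line and the downward extension of the line through the
bottom-right corner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Sequence, Union

import numpy as np

from .geometry import (
    Box3,
    PlanarSurface,
    Profile,
    Spheroid,
    spheroids_to_arrays,
)

__all__ = [
    "DisectorBrick",
    "CountingFrame2D",
    "PointGrid",
    "DisectorTally",
    "brick_count",
    "double_disector_count",
    "frame_count",
    "point_grid_hits",
    "brick_count_stack",
]

_INF = float("inf")


# ---------------------------------------------------------------------------
# vectorised spheroid kernels
# ---------------------------------------------------------------------------

def _vec_intersects_box(C: np.ndarray, A: np.ndarray, box: Box3) -> np.ndarray:
    lo = (box.lo[None, :] - C) / A
    hi = (box.hi[None, :] - C) / A
    nearest = np.clip(0.0, lo, hi)
    return np.einsum("ij,ij->i", nearest, nearest) <= 1.0


def _vec_slice(
    C: np.ndarray, A: np.ndarray, axis: int, coord: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[int, int]]:
    """Slice all spheroids with plane axis=coord.

    Returns (exists, c2 (n,2), a2 (n,2), in_plane_axes).  Entries where
    ``exists`` is False carry garbage and must be masked by the caller.
    """
    t = (coord - C[:, axis]) / A[:, axis]
    exists = np.abs(t) <= 1.0
    scale = np.sqrt(np.clip(1.0 - t * t, 0.0, None))
    in_plane = tuple(i for i in range(3) if i != axis)
    c2 = C[:, in_plane]
    a2 = A[:, in_plane] * scale[:, None]
    return exists, c2, a2, in_plane  # type: ignore[return-value]


def _vec_ellipse_rect(
    c2: np.ndarray, a2: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Closed ellipse vs closed rect, vectorised; exact incl. degenerate axes."""
    bbox = np.ones(len(c2), dtype=bool)
    d2 = np.zeros(len(c2))
    for i in range(2):
        bbox &= (c2[:, i] - a2[:, i] <= hi[i]) & (lo[i] <= c2[:, i] + a2[:, i])
        with np.errstate(divide="ignore", invalid="ignore"):
            tlo = (lo[i] - c2[:, i]) / a2[:, i]
            thi = (hi[i] - c2[:, i]) / a2[:, i]
            t = np.clip(0.0, tlo, thi)
        t = np.where(a2[:, i] > 0.0, t, 0.0)  # degenerate axis: bbox test decides
        d2 += t * t
    return bbox & (d2 <= 1.0)


# ---------------------------------------------------------------------------
# 3D brick
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DisectorBrick:
    """The 3D unbiased counting brick.

    ``look_up`` names the exclusion face along z: ``'bottom'`` (the classic
    orientation: browse down through the stack toward the look-up plane) or
    ``'top'`` (the reversed direction of a double disector).
    """

    box: Box3
    look_up: Literal["bottom", "top"] = "bottom"

    @property
    def frame_area(self) -> float:
        w, d, _ = self.box.extents
        return w * d

    @property
    def height(self) -> float:
        return self.box.extents[2]

    @property
    def lookup_z(self) -> float:
        return float(self.box.lo[2] if self.look_up == "bottom" else self.box.hi[2])

    @property
    def reference_z(self) -> float:
        return float(self.box.hi[2] if self.look_up == "bottom" else self.box.lo[2])

    def exclusion_surfaces(self) -> list[PlanarSurface]:
        """Look-up face plus the swept forbidden line of the footprint frame.

        The sweep runs from the look-up plane toward and beyond the
        reference plane: z ∈ [z0, ∞) when looking up from the bottom,
        z ∈ (−∞, z1] when the look-up face is on top.
        """
        x0, y0, _ = self.box.origin
        x1, y1 = float(self.box.hi[0]), float(self.box.hi[1])
        z0, z1 = float(self.box.lo[2]), float(self.box.hi[2])
        z_sweep = (z0, _INF) if self.look_up == "bottom" else (-_INF, z1)
        return [
            # look-up face (full footprint rectangle)
            PlanarSurface("rect", axis=2, coord=self.lookup_z, bounds={0: (x0, x1), 1: (y0, y1)}),
            # left edge line of the footprint frame, with its upward extension
            PlanarSurface("rect", axis=0, coord=x0, bounds={1: (y0, _INF), 2: z_sweep}),
            # bottom edge of the footprint frame
            PlanarSurface("rect", axis=1, coord=y0, bounds={0: (x0, x1), 2: z_sweep}),
            # downward extension of the line through the bottom-right corner
            PlanarSurface("rect", axis=0, coord=x1, bounds={1: (-_INF, y0), 2: z_sweep}),
        ]


def brick_count(particles: Iterable[Spheroid], brick: DisectorBrick) -> set[int]:
    """Ids of particles sampled by the brick.

    Counted iff the particle intersects the closed box and touches no
    exclusion surface.  Exact and deterministic for axis-aligned spheroids.
    """
    ids, C, A = spheroids_to_arrays(particles)
    if len(ids) == 0:
        return set()
    box = brick.box
    x0, y0, _ = box.origin
    x1, y1 = float(box.hi[0]), float(box.hi[1])
    z0, z1 = float(box.lo[2]), float(box.hi[2])
    z_sw_lo, z_sw_hi = (z0, _INF) if brick.look_up == "bottom" else (-_INF, z1)

    keep = _vec_intersects_box(C, A, box)

    # look-up face (full footprint rectangle)
    ex, c2, a2, _ = _vec_slice(C, A, 2, brick.lookup_z)
    forb = ex & _vec_ellipse_rect(c2, a2, np.array([x0, y0]), np.array([x1, y1]))

    # swept forbidden line of the footprint frame (in-plane axes (y, z) / (x, z))
    ex, c2, a2, _ = _vec_slice(C, A, 0, x0)  # left edge + upward extension
    forb |= ex & _vec_ellipse_rect(c2, a2, np.array([y0, z_sw_lo]), np.array([_INF, z_sw_hi]))
    ex, c2, a2, _ = _vec_slice(C, A, 1, y0)  # bottom edge
    forb |= ex & _vec_ellipse_rect(c2, a2, np.array([x0, z_sw_lo]), np.array([x1, z_sw_hi]))
    ex, c2, a2, _ = _vec_slice(C, A, 0, x1)  # downward extension at the right edge
    forb |= ex & _vec_ellipse_rect(c2, a2, np.array([-_INF, z_sw_lo]), np.array([y0, z_sw_hi]))

    counted = keep & ~forb
    return set(int(i) for i in ids[counted])


@dataclass(frozen=True)
class DisectorTally:
    """Raw result of a (double) disector probe placement."""

    Q: int
    a: float  # frame area, µm²
    h: float  # reported probe height, µm (2 × slab height for a double disector)
    ids_down: frozenset[int]
    ids_up: frozenset[int]

    @property
    def volume(self) -> float:
        return self.a * self.h


def double_disector_count(particles: Sequence[Spheroid], slab: Box3) -> DisectorTally:
    """Apply the brick in both z-directions on the same slab.

    Q sums the two directions; the reported probe height is twice the slab
    height, which keeps E[Q]/(a·2h) equal to the numerical density even
    though a particle interior to the slab may be counted by both
    directions.
    """
    down = brick_count(particles, DisectorBrick(slab, look_up="bottom"))
    up = brick_count(particles, DisectorBrick(slab, look_up="top"))
    w, d, h = slab.extents
    return DisectorTally(
        Q=len(down) + len(up),
        a=w * d,
        h=2.0 * h,
        ids_down=frozenset(down),
        ids_up=frozenset(up),
    )


# ---------------------------------------------------------------------------
# 2D unbiased counting frame
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountingFrame2D:
    """Rectangle with a forbidden line (Gundersen frame).

    Forbidden: left edge, bottom edge, the upward extension of the left-edge
    line above the top-left corner, and the downward extension of the
    vertical line through the bottom-right corner.  The convention is fixed
    by the tiling property: contiguous frames count every profile exactly
    once.
    """

    x0: float
    y0: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame width and height must be positive")

    @property
    def x1(self) -> float:
        return self.x0 + self.width

    @property
    def y1(self) -> float:
        return self.y0 + self.height

    @property
    def area(self) -> float:
        return self.width * self.height


def _profiles_to_arrays(profiles: Iterable[Profile]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    prof = list(profiles)
    if not prof:
        return (np.empty(0, dtype=np.int64), np.empty((0, 2)), np.empty((0, 2)))
    ids = np.array([p.particle_id for p in prof], dtype=np.int64)
    c = np.array([p.center for p in prof], dtype=float)
    a = np.array([p.semi_axes for p in prof], dtype=float)
    return ids, c, a


def _ellipse_meets_vseg(
    c: np.ndarray, a: np.ndarray, x: float, ylo: float, yhi: float
) -> np.ndarray:
    """Vectorised: closed ellipse vs the segment {x} × [ylo, yhi]."""
    dx = np.abs(x - c[:, 0])
    on_plane = dx <= a[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = dx / a[:, 0]
    t = np.where(a[:, 0] > 0.0, t, 0.0)
    hw = a[:, 1] * np.sqrt(np.clip(1.0 - t * t, 0.0, None))
    return on_plane & (c[:, 1] - hw <= yhi) & (ylo <= c[:, 1] + hw)


def _ellipse_meets_hseg(
    c: np.ndarray, a: np.ndarray, y: float, xlo: float, xhi: float
) -> np.ndarray:
    return _ellipse_meets_vseg(c[:, ::-1], a[:, ::-1], y, xlo, xhi)


def frame_count(profiles: Iterable[Profile], frame: CountingFrame2D) -> set[int]:
    """Particle ids of profiles sampled by the unbiased frame."""
    ids, c, a = _profiles_to_arrays(profiles)
    if len(ids) == 0:
        return set()
    lo = np.array([frame.x0, frame.y0])
    hi = np.array([frame.x1, frame.y1])
    inside = _vec_ellipse_rect(c, a, lo, hi)
    forb = _ellipse_meets_vseg(c, a, frame.x0, frame.y0, _INF)  # left edge + up extension
    forb |= _ellipse_meets_hseg(c, a, frame.y0, frame.x0, frame.x1)  # bottom edge
    forb |= _ellipse_meets_vseg(c, a, frame.x1, -_INF, frame.y0)  # down extension at x1
    counted = inside & ~forb
    return set(int(i) for i in ids[counted])


# ---------------------------------------------------------------------------
# point grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PointGrid:
    """Regular test-point grid with spacing (sx, sy) and offset (ox, oy).

    The grid point (i, j) sits at (ox + i·sx, oy + j·sy).  Area per point is
    sx·sy; within a frame of area a containing p points, a/p estimates the
    same quantity.
    """

    spacing: tuple[float, float]
    offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not all(s > 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")

    @property
    def area_per_point(self) -> float:
        return self.spacing[0] * self.spacing[1]

    def points_in_frame(self, frame: CountingFrame2D) -> np.ndarray:
        """(p, 2) array of grid points inside the closed frame rectangle."""
        sx, sy = self.spacing
        ox, oy = self.offset
        i0 = int(np.ceil((frame.x0 - ox) / sx - 1e-12))
        i1 = int(np.floor((frame.x1 - ox) / sx + 1e-12))
        j0 = int(np.ceil((frame.y0 - oy) / sy - 1e-12))
        j1 = int(np.floor((frame.y1 - oy) / sy + 1e-12))
        if i1 < i0 or j1 < j0:
            return np.empty((0, 2))
        xs = ox + sx * np.arange(i0, i1 + 1)
        ys = oy + sy * np.arange(j0, j1 + 1)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])


RegionLike = Union[Callable[[np.ndarray], np.ndarray], np.ndarray]


def point_grid_hits(
    region: RegionLike,
    grid: PointGrid,
    frame: CountingFrame2D,
    *,
    mask_origin: tuple[float, float] = (0.0, 0.0),
    pixel_size: float = 1.0,
) -> int:
    """Number of grid points inside the frame that hit the region.

    ``region`` is either a predicate mapping an (n, 2) array of points to a
    boolean array, or a 2D mask (row-major, indexed [iy, ix]) with
    ``mask_origin``/``pixel_size`` giving its placement; a point hits the
    mask when it lands on a nonzero pixel.
    """
    pts = grid.points_in_frame(frame)
    if len(pts) == 0:
        return 0
    if callable(region):
        hits = np.asarray(region(pts), dtype=bool)
    else:
        mask = np.asarray(region)
        ix = np.floor((pts[:, 0] - mask_origin[0]) / pixel_size).astype(int)
        iy = np.floor((pts[:, 1] - mask_origin[1]) / pixel_size).astype(int)
        ok = (ix >= 0) & (ix < mask.shape[1]) & (iy >= 0) & (iy < mask.shape[0])
        hits = np.zeros(len(pts), dtype=bool)
        hits[ok] = mask[iy[ok], ix[ok]] != 0
    return int(np.count_nonzero(hits))


# ---------------------------------------------------------------------------
# stack-based disector (labelled z-stack)
# ---------------------------------------------------------------------------

def _labels_in_region(page: np.ndarray, region: np.ndarray) -> set[int]:
    vals = np.unique(page[region])
    return set(int(v) for v in vals if v != 0)


def brick_count_stack(
    stack,
    frame: CountingFrame2D,
    k_ref: int,
    k_lookup: int,
) -> set[int]:
    """Optical-disector counting on a labelled z-stack.

    Pages are ordered top-down (page 0 = shallowest, largest z), so the
    reference page index ``k_ref`` is smaller than the look-up page index
    ``k_lookup``.  A label is counted iff it appears inside the frame on
    some page in ``k_ref..k_lookup`` and is excluded when it (i) appears in
    the look-up page inside the frame footprint, (ii) touches the frame's
    forbidden line on any page of the probe, or (iii) touches the forbidden
    line on any page above the reference plane (the discrete image of the
    exclusion half-planes).

    Pixel-level contact uses half-pixel-wide closed bands around the
    forbidden line; at fine resolution this matches the geometric rule for
    configurations in general position.
    """
    n_pages = stack.pages.shape[0]
    if not (0 <= k_ref < k_lookup < n_pages):
        raise ValueError(
            f"probe pages [{k_ref}..{k_lookup}] must lie within the stack (0..{n_pages - 1})"
        )
    px = float(stack.pixel_size)
    half = px / 2.0
    H, W = stack.pages.shape[1:]
    xs = stack.origin[0] + (np.arange(W) + 0.5) * px
    ys = stack.origin[1] + (np.arange(H) + 0.5) * px
    X, Y = np.meshgrid(xs, ys)  # [iy, ix]

    in_rect = (X >= frame.x0) & (X <= frame.x1) & (Y >= frame.y0) & (Y <= frame.y1)
    forb = (np.abs(X - frame.x0) <= half) & (Y >= frame.y0 - half)
    forb |= (np.abs(Y - frame.y0) <= half) & (X >= frame.x0 - half) & (X <= frame.x1 + half)
    forb |= (np.abs(X - frame.x1) <= half) & (Y <= frame.y0 + half)

    present: set[int] = set()
    excluded: set[int] = set()
    for k in range(k_ref, k_lookup + 1):
        page = stack.pages[k]
        present |= _labels_in_region(page, in_rect)
        excluded |= _labels_in_region(page, forb)
    excluded |= _labels_in_region(stack.pages[k_lookup], in_rect)
    for k in range(0, k_ref):  # pages above the reference plane
        excluded |= _labels_in_region(stack.pages[k], forb)
    return present - excluded
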