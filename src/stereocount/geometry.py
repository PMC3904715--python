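"""Exact geometry for axis-aligned spheroids and axis-aligned probes.

Everything downstream (disector bricks, counting frames, synthetic tissue)
reduces to a handful of primitives implemented here: z-extents, plane
sections (elliptical profiles), spheroid-vs-box intersection, spheroid
contact with bounded planar surfaces, and exact spheroid-in-spheroid /
spheroid-vs-spheroid tests.

Conventions
-----------
* All lengths are in micrometres (µm).
* Spheroids are axis-aligned ellipsoids; rotation is deliberately not
  supported, which keeps every probe test exact.
* Closed-set contact convention: touching counts as intersecting.  All
  tie-breaking between "counted" and "excluded" then lives in the probe
  rules, never in the geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Spheroid",
    "Box3",
    "PlanarSurface",
    "Profile",
    "z_extent",
    "plane_profile",
    "plane_ellipse",
    "intersects_box",
    "touches_surface",
    "spheroid_contains_spheroid",
    "spheroids_overlap",
    "ellipse_meets_rect",
    "ellipse_meets_band",
    "spheroids_to_arrays",
    "spheroid_to_dict",
    "spheroid_from_dict",
]

Role = Literal["particle", "cell_body"]

_AXIS_NAMES = {0: "x", 1: "y", 2: "z"}


@dataclass(frozen=True)
class Spheroid:
    """An axis-aligned ellipsoid: a particle (chloroplast) or a cell body.

    The z semi-axis ``rz`` carries the biology: the particle's caliper
    height along the optical axis is ``2*rz`` (≈4 µm for a chloroplast,
    40–60 µm for a mesophyll cell).
    """

    id: int
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    role: Role = "particle"
    parent_id: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.center) != 3 or len(self.semi_axes) != 3:
            raise ValueError("center and semi_axes must be 3-vectors")
        if not all(a > 0 for a in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(self, "semi_axes", tuple(float(a) for a in self.semi_axes))

    @property
    def caliper_z(self) -> float:
        """Caliper (height) along z: 2·rz."""
        return 2.0 * self.semi_axes[2]

    @property
    def volume(self) -> float:
        rx, ry, rz = self.semi_axes
        return 4.0 / 3.0 * np.pi * rx * ry * rz


@dataclass(frozen=True)
class Box3:
    """Closed axis-aligned box [x0,x0+w] × [y0,y0+d] × [z0,z0+h]."""

    origin: tuple[float, float, float]
    extents: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(e > 0 for e in self.extents):
            raise ValueError(f"box extents must be positive, got {self.extents}")
        object.__setattr__(self, "origin", tuple(float(c) for c in self.origin))
        object.__setattr__(self, "extents", tuple(float(e) for e in self.extents))

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    @property
    def hi(self) -> np.ndarray:
        return self.lo + np.asarray(self.extents, dtype=float)

    @property
    def volume(self) -> float:
        w, d, h = self.extents
        return w * d * h

    def contains_point(self, p: Sequence[float]) -> bool:
        p = np.asarray(p, dtype=float)
        return bool(np.all(p >= self.lo) and np.all(p <= self.hi))


@dataclass(frozen=True)
class PlanarSurface:
    """A closed planar set used as a probe face: a rectangle inside an
    axis-aligned plane, or a half-plane of it.

    ``axis``/``coord`` fix the plane (normal axis index and its coordinate).
    For ``kind='rect'``, ``bounds`` maps each in-plane axis index to a closed
    interval; bounds may be infinite, so quarter-planes and strips are
    expressible.  For ``kind='half_plane'``, ``edge_axis``/``edge_coord``/
    ``side`` select the closed half-plane ``side*(u - edge_coord) >= 0``
    along the in-plane axis ``edge_axis`` (the other in-plane axis is
    unbounded).
    """

    kind: Literal["rect", "half_plane"]
    axis: int
    coord: float
    bounds: Optional[dict[int, tuple[float, float]]] = None
    edge_axis: Optional[int] = None
    edge_coord: Optional[float] = None
    side: int = +1

    def __post_init__(self) -> None:
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")
        if self.kind == "rect":
            if self.bounds is None or set(self.bounds) != {a for a in range(3) if a != self.axis}:
                raise ValueError("rect surface needs bounds for both in-plane axes")
        elif self.kind == "half_plane":
            if self.edge_axis is None or self.edge_axis == self.axis or self.edge_axis not in (0, 1, 2):
                raise ValueError("half_plane needs an in-plane edge_axis")
            if self.side not in (-1, +1):
                raise ValueError("side must be -1 or +1")
        else:
            raise ValueError(f"unknown surface kind {self.kind!r}")

    def __repr__(self) -> str:  # compact, for logs
        plane = f"{_AXIS_NAMES[self.axis]}={self.coord:g}"
        if self.kind == "rect":
            b = ", ".join(
                f"{_AXIS_NAMES[a]}∈[{lo:g},{hi:g}]" for a, (lo, hi) in sorted(self.bounds.items())
            )
            return f"PlanarSurface(rect {plane}; {b})"
        op = "≥" if self.side > 0 else "≤"
        return f"PlanarSurface(half {plane}; {_AXIS_NAMES[self.edge_axis]}{op}{self.edge_coord:g})"


@dataclass(frozen=True)
class Profile:
    """The 2D ellipse cut from a spheroid by a section plane z=const."""

    particle_id: int
    z: float
    center: tuple[float, float]
    semi_axes: tuple[float, float]

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.semi_axes):
            raise ValueError("profile semi-axes must be non-negative")


# ---------------------------------------------------------------------------
# basic operations
# ---------------------------------------------------------------------------

def z_extent(s: Spheroid) -> tuple[float, float]:
    """(z_min, z_max) of the spheroid: center_z ∓ rz."""
    cz = s.center[2]
    rz = s.semi_axes[2]
    return (cz - rz, cz + rz)


def plane_ellipse(
    s: Spheroid, axis: int, coord: float
) -> Optional[tuple[np.ndarray, np.ndarray, tuple[int, int]]]:
    """Slice a spheroid with the plane ``axis=coord``.

    Returns ``(center2, semi2, in_plane_axes)`` in the coordinates of the two
    in-plane axes (ascending order), or None when the plane misses the
    spheroid.  A tangent plane returns a degenerate (zero semi-axis) ellipse —
    the closed-set convention keeps it.
    """
    c = np.asarray(s.center)
    a = np.asarray(s.semi_axes)
    t = (coord - c[axis]) / a[axis]
    if abs(t) > 1.0:
        return None
    scale = float(np.sqrt(max(0.0, 1.0 - t * t)))
    in_plane = tuple(i for i in range(3) if i != axis)
    return c[list(in_plane)], a[list(in_plane)] * scale, in_plane  # type: ignore[return-value]


def plane_profile(s: Spheroid, z: float) -> Optional[Profile]:
    """Elliptical profile of a spheroid cut at height z, or None."""
    sl = plane_ellipse(s, 2, z)
    if sl is None:
        return None
    c2, a2, _ = sl
    return Profile(
        particle_id=s.id,
        z=float(z),
        center=(float(c2[0]), float(c2[1])),
        semi_axes=(float(a2[0]), float(a2[1])),
    )


def intersects_box(s: Spheroid, b: Box3) -> bool:
    """Exact closed spheroid ∩ closed box test.

    Scaling each axis by the spheroid's semi-axes maps the spheroid to the
    unit ball and keeps the box axis-aligned, so the test reduces to the
    distance from the scaled center to the scaled box.
    """
    c = np.asarray(s.center)
    a = np.asarray(s.semi_axes)
    lo = (b.lo - c) / a
    hi = (b.hi - c) / a
    nearest = np.clip(0.0, lo, hi)  # closest point of scaled box to origin
    return float(nearest @ nearest) <= 1.0


def _interval_overlap(lo1: float, hi1: float, lo2: float, hi2: float) -> bool:
    return lo1 <= hi2 and lo2 <= hi1


def ellipse_meets_rect(
    center: np.ndarray, semi: np.ndarray, rect: dict[int, tuple[float, float]], axes: tuple[int, int]
) -> bool:
    """Closed axis-aligned ellipse vs closed rectangle in a plane.

    Degenerate semi-axes (tangent slices) are handled as segments/points.
    """
    c = np.asarray(center, dtype=float)
    a = np.asarray(semi, dtype=float)
    lo = np.array([rect[axes[0]][0], rect[axes[1]][0]])
    hi = np.array([rect[axes[0]][1], rect[axes[1]][1]])
    # quick bounding-box reject keeps degenerate cases exact
    for i in range(2):
        if not _interval_overlap(c[i] - a[i], c[i] + a[i], lo[i], hi[i]):
            return False
    d2 = 0.0
    for i in range(2):
        if a[i] > 0.0:
            t = np.clip(0.0, (lo[i] - c[i]) / a[i], (hi[i] - c[i]) / a[i])
            d2 += t * t
        # a[i] == 0: bounding-box check above already forced c[i] within rect slab
    return d2 <= 1.0


def ellipse_meets_band(
    center: np.ndarray, semi: np.ndarray, comp: int, edge: float, side: int
) -> bool:
    """Closed ellipse vs closed half-plane ``side*(u_comp - edge) >= 0``."""
    reach = center[comp] + side * semi[comp]
    return bool(side * (reach - edge) >= 0.0)


def touches_surface(s: Spheroid, surf: PlanarSurface) -> bool:
    """True iff the closed spheroid meets the closed planar surface.

    The plane-slice of the spheroid is an ellipse (possibly degenerate);
    contact reduces to 2D ellipse-vs-rectangle or ellipse-vs-half-plane.
    """
    sl = plane_ellipse(s, surf.axis, surf.coord)
    if sl is None:
        return False
    c2, a2, in_plane = sl
    if surf.kind == "rect":
        return ellipse_meets_rect(c2, a2, surf.bounds, in_plane)
    comp = in_plane.index(surf.edge_axis)
    return ellipse_meets_band(c2, a2, comp, surf.edge_coord, surf.side)


# ---------------------------------------------------------------------------
# spheroid-vs-spheroid tests (secular-equation solvers)
# ---------------------------------------------------------------------------

def _max_norm_on_ellipsoid(c: np.ndarray, b: np.ndarray) -> float:
    """max ‖c + b∘v‖ over ‖v‖ ≤ 1 for diagonal semi-axes b > 0.

    Lagrange stationarity gives v_i = b_i c_i / (µ − b_i²) with the secular
    equation Σ v_i² = 1 solved on (max b_i², ∞).  When c has no component
    along the largest axis the maximiser may pin µ at that eigenvalue with a
    free component there (the hard case of the trust-region subproblem).
    """
    c = np.abs(np.asarray(c, dtype=float))
    b = np.asarray(b, dtype=float)
    if np.all(c == 0.0):
        return float(np.max(b))
    b2 = b * b

    def g(mu: float) -> float:
        return float(np.sum((b * c) ** 2 / (mu - b2) ** 2))

    b2max = float(np.max(b2))
    if np.any((b2 == b2max) & (c == 0.0)):
        # hard case candidate: µ = b2max, remaining norm goes to the free axis
        active = ~((b2 == b2max) & (c == 0.0))
        s = float(np.sum((b[active] * c[active]) ** 2 / (b2max - b2[active]) ** 2))
        if s <= 1.0:
            v = np.zeros_like(c)
            v[active] = b[active] * c[active] / (b2max - b2[active])
            val2 = float(np.sum((c[active] + b[active] * v[active]) ** 2)) + b2max * (1.0 - s)
            return float(np.sqrt(val2))
    # generic case: root of g(µ)=1 on (b2max, ∞)
    lo = b2max * (1.0 + 1e-12) + 1e-300
    hi = (b2max**0.5 + float(np.linalg.norm(b * c)) + 1.0) ** 2
    while g(hi) > 1.0:
        hi *= 4.0
    # guard: g may be < 1 already at lo only in the hard case handled above
    glo = g(lo)
    if glo <= 1.0:
        mu = lo
    else:
        mu = brentq(lambda m: g(m) - 1.0, lo, hi, xtol=1e-14, rtol=1e-14)
    v = b * c / (mu - b2)
    nv = np.linalg.norm(v)
    if nv > 0:
        v = v / nv  # normalise against round-off
    return float(np.linalg.norm(c + b * v))


def spheroid_contains_spheroid(inner: Spheroid, outer: Spheroid) -> bool:
    """Exact closed containment of one axis-aligned spheroid in another.

    Scale by the outer semi-axes (outer → unit ball); the inner spheroid
    stays axis-aligned and containment becomes max-norm ≤ 1.
    """
    R = np.asarray(outer.semi_axes)
    c = (np.asarray(inner.center) - np.asarray(outer.center)) / R
    b = np.asarray(inner.semi_axes) / R
    # cheap sufficient test first (covers the vast majority of calls)
    if float(np.linalg.norm(c)) + float(np.max(b)) <= 1.0:
        return True
    return _max_norm_on_ellipsoid(c, b) <= 1.0 + 1e-12


def spheroids_overlap(s1: Spheroid, s2: Spheroid) -> bool:
    """Exact closed overlap test for two axis-aligned spheroids.

    Minimises the quadratic of ``s2`` over ``s1`` (a diagonal trust-region
    subproblem): overlap iff the minimum is ≤ 1.
    """
    c = np.asarray(s1.center) - np.asarray(s2.center)
    a = np.asarray(s1.semi_axes)
    w = 1.0 / np.asarray(s2.semi_axes)
    # fast paths: s1's center inside s2, or bounding spheres disjoint
    if float(np.sum((c * w) ** 2)) <= 1.0:
        return True
    if float(np.linalg.norm(c)) > float(np.max(a)) + float(np.max(s2.semi_axes)):
        return False
    w2a = (w * w) * a

    def u_of(lam: float) -> np.ndarray:
        return -w2a * c / (w * w * a * a + lam)

    u0 = u_of(0.0)
    if float(u0 @ u0) <= 1.0:
        q = float(np.sum((w * (c + a * u0)) ** 2))
        return q <= 1.0
    hi = float(np.linalg.norm(w2a * c))  # ‖u(hi)‖ ≤ ‖w2a·c‖/hi = 1
    lam = brentq(
        lambda L: float(np.sum(u_of(L) ** 2)) - 1.0, 0.0, max(hi, 1e-300),
        xtol=1e-14, rtol=1e-14,
    )
    u = u_of(lam)
    nu = np.linalg.norm(u)
    if nu > 0:
        u = u / nu
    q = float(np.sum((w * (c + a * u)) ** 2))
    return q <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# array bridging and serialization
# ---------------------------------------------------------------------------

def spheroids_to_arrays(
    spheroids: Iterable[Spheroid],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ids, centers (n,3), semi_axes (n,3)) for vectorised probe kernels."""
    sph = list(spheroids)
    if not sph:
        return (
            np.empty(0, dtype=np.int64),
            np.empty((0, 3), dtype=float),
            np.empty((0, 3), dtype=float),
        )
    ids = np.array([s.id for s in sph], dtype=np.int64)
    centers = np.array([s.center for s in sph], dtype=float)
    axes = np.array([s.semi_axes for s in sph], dtype=float)
    return ids, centers, axes


def spheroid_to_dict(s: Spheroid) -> dict:
    return {
        "id": s.id,
        "parent_id": s.parent_id,
        "center": list(s.center),
        "semi_axes": list(s.semi_axes),
        "role": s.role,
    }


def spheroid_from_dict(d: dict) -> Spheroid:
    return Spheroid(
        id=int(d["id"]),
        center=tuple(d["center"]),
        semi_axes=tuple(d["semi_axes"]),
        role=d.get("role", "particle"),
        parent_id=d.get("parent_id"),
    )
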