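"""Synthetic geometric models standing in for confocal acquisitions of
conifer-needle mesophyll.

The generator emulates the study system: spheroidal chloroplasts of mean
z-caliper ≈ 4 µm packed (~210 per cell) inside mesophyll cell bodies of
z-caliper 40–60 µm, cells occupying ≈ 72% of the tissue volume, sections
sampled in a systematic uniform random (SUR) way, and optical sections
0.5 µm (chloroplast stacks) or 2 µm (cell stacks) apart.  Models are exact
geometry; voxelised labelled z-stacks can be rendered from them as a
stand-in for segmented confocal stacks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np

from .geometry import (
    Box3,
    Profile,
    Spheroid,
    plane_profile,
    spheroid_contains_spheroid,
    spheroid_from_dict,
    spheroid_to_dict,
    spheroids_overlap,
    spheroids_to_arrays,
)

__all__ = [
    "ModelCellSpec",
    "TissueSpec",
    "StackSpec",
    "CellModel",
    "TissueModel",
    "LabelStack",
    "PlacementError",
    "load_model",
    "generate_model_cell",
    "generate_tissue",
    "sur_positions",
    "section_profiles",
    "section_profile_counts",
    "cell_volume_fraction",
    "render_label_stack",
]


class PlacementError(RuntimeError):
    """Raised when rejection placement cannot satisfy the spec."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelCellSpec:
    """A single simplified mesophyll cell filled with chloroplasts.

    Defaults follow the study system: 210 chloroplasts of semi-axes
    (2.5, 2.5, 2.0) µm (z-caliper 4 µm) inside a cell body of z-caliper
    49 µm — within the 40–60 µm range typical of needle mesophyll.
    """

    n_chloroplasts: int = 210
    cell_semi_axes: tuple[float, float, float] = (15.0, 15.0, 24.5)
    chl_semi_axes_mean: tuple[float, float, float] = (2.5, 2.5, 2.0)
    chl_semi_axes_cv: float = 0.1
    placement: Literal["uniform", "peripheral_shell"] = "uniform"
    shell_thickness: float = 5.0  # used only by peripheral_shell placement
    allow_overlap: bool = True
    caliper_validity: Optional[tuple[float, float]] = (40.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chloroplasts < 0:
            raise ValueError("n_chloroplasts must be >= 0")
        if not all(a > 0 for a in self.cell_semi_axes):
            raise ValueError("cell semi-axes must be positive")
        if self.caliper_validity is not None:
            lo, hi = self.caliper_validity
            cal = 2.0 * self.cell_semi_axes[2]
            if not (lo <= cal <= hi):
                raise ValueError(
                    f"cell z-caliper {cal:g} µm outside declared validity range "
                    f"[{lo:g}, {hi:g}]; pass caliper_validity=None to override"
                )


@dataclass(frozen=True)
class TissueSpec:
    """A block of mesophyll: non-overlapping cell bodies, each hosting its
    own chloroplast population.

    Exactly one of ``n_cells``, ``cells_per_volume`` or the
    ``mesophyll_fraction`` target determines how many cells are placed
    (precedence in that order).  ``arrangement='random'`` dart-throws cells
    (practical up to ~0.3 volume fraction); ``'lattice'`` staggers them on a
    jittered close-packing lattice and reaches dense tissue-like fractions
    (~0.72 in the bulk); ``'auto'`` (default) picks the placement able to
    reach the implied density.
    """

    domain: Box3 = field(default_factory=lambda: Box3((0, 0, 0), (400, 160, 120)))
    cell_caliper_mean: float = 40.0
    cell_caliper_sd: float = 0.0
    cell_lateral_mean: float = 15.0
    cell_lateral_sd: float = 0.0
    n_cells: Optional[int] = None
    cells_per_volume: Optional[float] = None
    mesophyll_fraction: Optional[float] = 0.72
    chloroplasts_per_cell_mean: float = 210.0
    chloroplasts_per_cell_sd: float = 20.0
    chl_semi_axes_mean: tuple[float, float, float] = (2.5, 2.5, 2.0)
    chl_semi_axes_cv: float = 0.1
    arrangement: Literal["auto", "random", "lattice"] = "auto"
    lattice_jitter: float = 0.0  # µm, uniform jitter of lattice sites
    max_attempts_per_cell: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_caliper_mean <= 0 or self.cell_lateral_mean <= 0:
            raise ValueError("cell size means must be positive")
        if self.chloroplasts_per_cell_mean < 0:
            raise ValueError("chloroplasts_per_cell_mean must be >= 0")


@dataclass(frozen=True)
class StackSpec:
    """Voxelisation request for a labelled z-stack.

    ``origin`` gives (x, y) of the frame corner and the z of the *topmost*
    optical plane; page k lies at z = origin_z − k·dz (page 0 is the
    shallowest plane, matching the browsing order of an optical disector).
    """

    origin: tuple[float, float, float]
    frame: tuple[float, float]  # (w, d) µm
    n_sections: int
    dz: float
    pixel_size: float
    channel: Literal["cells", "chloroplasts", "both"] = "chloroplasts"

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if self.dz <= 0 or self.pixel_size <= 0:
            raise ValueError("dz and pixel_size must be positive")
        if not all(f > 0 for f in self.frame):
            raise ValueError("frame extents must be positive")

    def page_z(self, k: int) -> float:
        return self.origin[2] - k * self.dz


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

@dataclass
class CellModel:
    """Ground truth for a single model cell: the cell body plus particles."""

    cell: Spheroid
    particles: list[Spheroid]
    spec: ModelCellSpec

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    def to_dict(self) -> dict:
        return {
            "kind": "cell_model",
            "particles": [spheroid_to_dict(p) for p in [self.cell] + self.particles],
            "domain": None,
            "spec": asdict(self.spec),
        }

    def to_json(self, path: Optional[str] = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "CellModel":
        sph = [spheroid_from_dict(p) for p in d["particles"]]
        cells = [s for s in sph if s.role == "cell_body"]
        parts = [s for s in sph if s.role == "particle"]
        spec = ModelCellSpec(**{**d["spec"], "cell_semi_axes": tuple(d["spec"]["cell_semi_axes"]),
                                "chl_semi_axes_mean": tuple(d["spec"]["chl_semi_axes_mean"]),
                                "caliper_validity": tuple(d["spec"]["caliper_validity"])
                                if d["spec"]["caliper_validity"] else None})
        return cls(cell=cells[0], particles=parts, spec=spec)


@dataclass
class TissueModel:
    """Ground truth for a tissue block: domain, cell bodies, particles."""

    domain: Box3
    cells: list[Spheroid]
    particles: list[Spheroid]
    spec: Optional[TissueSpec] = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def particles_per_cell(self) -> dict[int, int]:
        out: dict[int, int] = {c.id: 0 for c in self.cells}
        for p in self.particles:
            out[p.parent_id] += 1
        return out

    @property
    def mean_particles_per_cell(self) -> float:
        if not self.cells:
            return float("nan")
        return len(self.particles) / len(self.cells)

    @property
    def mesophyll_fraction_realized(self) -> float:
        return sum(c.volume for c in self.cells) / self.domain.volume

    def to_dict(self) -> dict:
        return {
            "kind": "tissue_model",
            "particles": [spheroid_to_dict(s) for s in self.cells + self.particles],
            "domain": {"origin": list(self.domain.origin), "extents": list(self.domain.extents)},
            "metadata": self.metadata,
        }

    def to_json(self, path: Optional[str] = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "TissueModel":
        sph = [spheroid_from_dict(p) for p in d["particles"]]
        dom = d["domain"]
        return cls(
            domain=Box3(tuple(dom["origin"]), tuple(dom["extents"])),
            cells=[s for s in sph if s.role == "cell_body"],
            particles=[s for s in sph if s.role == "particle"],
            spec=None,
            metadata=d.get("metadata", {}),
        )


def load_model(path: str):
    """Load a CellModel or TissueModel from its JSON document."""
    d = json.loads(Path(path).read_text())
    if d.get("kind") == "tissue_model":
        return TissueModel.from_dict(d)
    return CellModel.from_dict(d)


# ---------------------------------------------------------------------------
# model-cell generation
# ---------------------------------------------------------------------------

def _draw_semi_axes(
    rng: np.random.Generator, mean: Sequence[float], cv: float, n: int
) -> np.ndarray:
    """Per-axis truncated-normal sizes; mean caliper is preserved."""
    mean = np.asarray(mean, dtype=float)
    if cv <= 0:
        return np.tile(mean, (n, 1))
    f = rng.normal(1.0, cv, size=(n, 3))
    f = np.clip(f, 0.2, None)
    return mean[None, :] * f


def _sample_in_unit_ball(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.uniform(0.0, 1.0, size=(n, 1)) ** (1.0 / 3.0)
    return v * r


_MAX_PLACEMENT_ROUNDS = 200


def generate_model_cell(spec: ModelCellSpec) -> CellModel:
    """Place ``n_chloroplasts`` spheroids wholly inside the cell body.

    Placement is rejection sampling of particle centers (uniform in the
    cell, or in a peripheral shell) with exact closed-containment checks;
    deterministic given the spec's seed.  Raises :class:`PlacementError`
    after a bounded number of rejection rounds when the cell is too small.
    """
    rng = np.random.default_rng(spec.seed)
    R = np.asarray(spec.cell_semi_axes, dtype=float)
    cell = Spheroid(id=0, center=(0.0, 0.0, 0.0), semi_axes=tuple(R), role="cell_body")
    axes = _draw_semi_axes(rng, spec.chl_semi_axes_mean, spec.chl_semi_axes_cv, spec.n_chloroplasts)

    particles: list[Spheroid] = []
    rounds = 0
    i = 0
    while i < spec.n_chloroplasts:
        if rounds >= _MAX_PLACEMENT_ROUNDS:
            raise PlacementError(
                f"could not place particle {i + 1}/{spec.n_chloroplasts} inside the "
                f"cell after {_MAX_PLACEMENT_ROUNDS} rejection rounds; the cell is "
                "too small for the requested particles"
            )
        rounds += 1
        batch = max(64, 2 * (spec.n_chloroplasts - i))
        centers = _sample_in_unit_ball(rng, batch) * R[None, :]
        if spec.placement == "peripheral_shell":
            # keep candidates whose scaled radius lies in the outer shell
            rr = np.linalg.norm(centers / R[None, :], axis=1)
            inner = np.clip(1.0 - spec.shell_thickness / float(np.min(R)), 0.0, 1.0)
            centers = centers[rr >= inner]
        for c in centers:
            if i >= spec.n_chloroplasts:
                break
            cand = Spheroid(
                id=i + 1,
                center=(float(c[0]), float(c[1]), float(c[2])),
                semi_axes=tuple(float(a) for a in axes[i]),
                role="particle",
                parent_id=0,
            )
            if not spheroid_contains_spheroid(cand, cell):
                continue
            if not spec.allow_overlap and any(spheroids_overlap(cand, q) for q in particles):
                continue
            particles.append(cand)
            i += 1
            rounds = 0
    return CellModel(cell=cell, particles=particles, spec=spec)


# ---------------------------------------------------------------------------
# tissue generation
# ---------------------------------------------------------------------------

def _target_n_cells(spec: TissueSpec, mean_cell_volume: float) -> int:
    if spec.n_cells is not None:
        return int(spec.n_cells)
    if spec.cells_per_volume is not None:
        return int(round(spec.cells_per_volume * spec.domain.volume))
    if spec.mesophyll_fraction is not None:
        return int(round(spec.mesophyll_fraction * spec.domain.volume / mean_cell_volume))
    raise ValueError("TissueSpec needs n_cells, cells_per_volume or mesophyll_fraction")


def _cell_axes(rng: np.random.Generator, spec: TissueSpec, n: int) -> np.ndarray:
    rz = 0.5 * np.clip(rng.normal(spec.cell_caliper_mean, spec.cell_caliper_sd, n)
                       if spec.cell_caliper_sd > 0 else np.full(n, spec.cell_caliper_mean),
                       1e-3, None)
    rl = np.clip(rng.normal(spec.cell_lateral_mean, spec.cell_lateral_sd, n)
                 if spec.cell_lateral_sd > 0 else np.full(n, spec.cell_lateral_mean),
                 1e-3, None)
    return np.column_stack([rl, rl, rz])


def _place_cells_random(rng: np.random.Generator, spec: TissueSpec, n_target: int) -> list[Spheroid]:
    lo, hi = spec.domain.lo, spec.domain.hi
    cells: list[Spheroid] = []
    axes = _cell_axes(rng, spec, n_target)
    for i in range(n_target):
        a = axes[i]
        clo, chi = lo + a, hi - a
        if np.any(chi < clo):
            raise PlacementError("domain too small for a single cell")
        placed = False
        for _ in range(spec.max_attempts_per_cell):
            c = rng.uniform(clo, chi)
            cand = Spheroid(id=i + 1, center=tuple(c), semi_axes=tuple(a), role="cell_body")
            if all(not spheroids_overlap(cand, q) for q in cells):
                cells.append(cand)
                placed = True
                break
        if not placed:
            achieved = sum(c.volume for c in cells) / spec.domain.volume
            raise PlacementError(
                f"dart-throwing placed only {len(cells)}/{n_target} cells "
                f"(achieved packing fraction {achieved:.3f}); the density target is "
                "unreachable by random placement — lower it or use arrangement='lattice'"
            )
    return cells


def _place_cells_lattice(rng: np.random.Generator, spec: TissueSpec, n_target: int) -> list[Spheroid]:
    """Jittered FCC-like stagger, scaled per-axis to the (mean) cell shape.

    An affine image of a sphere close-packing keeps its packing fraction, so
    dense tissue-like fractions (up to ~0.74 in the bulk) are reachable for
    spheroids; the spacing is chosen from the requested number of cells.
    """
    a = _cell_axes(rng, spec, 1)[0]  # lattice uses the mean shape
    lo, hi = spec.domain.lo, spec.domain.hi
    ext = hi - lo
    v_cell = 4.0 / 3.0 * np.pi * np.prod(a)
    by_count = spec.n_cells is not None or spec.cells_per_volume is not None
    if by_count:
        frac = n_target * v_cell / spec.domain.volume
    else:
        frac = float(spec.mesophyll_fraction)
    # FCC packing fraction π/(3√2) at touching: scale sphere radius accordingly
    fcc = np.pi / np.sqrt(18.0)
    if frac >= fcc:
        raise PlacementError(
            f"requested packing fraction {frac:.3f} exceeds the close-packing "
            f"limit {fcc:.3f}"
        )
    r_rel = (frac / fcc) ** (1.0 / 3.0)
    # FCC conventional cubic cell, side 2√2·r for touching spheres of radius r
    side = 2.0 * np.sqrt(2.0) * (1.0 / r_rel)  # in units of the scaled radius
    basis = np.array(
        [[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]], dtype=float
    )
    # per-axis lattice pitch in µm (scaled by the cell's per-axis radii)
    pitch = side * a
    n_rep = np.maximum(1, np.ceil(ext / pitch).astype(int))
    sites = []
    for ix in range(n_rep[0] + 1):
        for iy in range(n_rep[1] + 1):
            for iz in range(n_rep[2] + 1):
                sites.append((np.array([ix, iy, iz], dtype=float)[None, :] + basis) * pitch[None, :])
    sites_arr = np.vstack(sites) + lo[None, :]
    if spec.lattice_jitter > 0:
        sites_arr = sites_arr + rng.uniform(
            -spec.lattice_jitter, spec.lattice_jitter, size=sites_arr.shape
        )
    inside = np.all(sites_arr - a[None, :] >= lo[None, :], axis=1) & np.all(
        sites_arr + a[None, :] <= hi[None, :], axis=1
    )
    sites_arr = sites_arr[inside]
    rng.shuffle(sites_arr, axis=0)
    if by_count:
        if len(sites_arr) < n_target:
            achieved = len(sites_arr) * v_cell / spec.domain.volume
            raise PlacementError(
                f"lattice fits only {len(sites_arr)} of {n_target} cells "
                f"(achieved packing fraction {achieved:.3f})"
            )
        sites_arr = sites_arr[:n_target]
    # fraction target: keep every interior site — the pitch realises the
    # target in the bulk; the unfillable boundary layer is reported honestly
    return [
        Spheroid(id=i + 1, center=tuple(c), semi_axes=tuple(a), role="cell_body")
        for i, c in enumerate(sites_arr)
    ]


def _place_particles_in_cell(
    rng: np.random.Generator, cell: Spheroid, n: int,
    mean_axes: Sequence[float], cv: float, id_start: int,
) -> list[Spheroid]:
    """Vectorised rejection placement of n particles wholly inside a cell."""
    R = np.asarray(cell.semi_axes)
    c0 = np.asarray(cell.center)
    axes = _draw_semi_axes(rng, mean_axes, cv, n)
    out: list[Spheroid] = []
    i = 0
    rounds = 0
    while i < n:
        if rounds >= _MAX_PLACEMENT_ROUNDS:
            raise PlacementError(
                f"cell {cell.id}: cannot fit particle {i + 1}/{n}"
            )
        rounds += 1
        batch = max(32, 2 * (n - i))
        centers = c0[None, :] + _sample_in_unit_ball(rng, batch) * R[None, :]
        for c in centers:
            if i >= n:
                break
            cand = Spheroid(
                id=id_start + i, center=tuple(float(v) for v in c),
                semi_axes=tuple(float(v) for v in axes[i]),
                role="particle", parent_id=cell.id,
            )
            if spheroid_contains_spheroid(cand, cell):
                out.append(cand)
                i += 1
                rounds = 0
    return out


def generate_tissue(spec: TissueSpec) -> TissueModel:
    """Generate a tissue block: cells, then chloroplasts inside each cell."""
    rng = np.random.default_rng(spec.seed)
    mean_axes = _cell_axes(np.random.default_rng(spec.seed), spec, 1)[0]
    v_mean = 4.0 / 3.0 * np.pi * float(np.prod(mean_axes))
    n_target = _target_n_cells(spec, v_mean)
    arrangement = spec.arrangement
    if arrangement == "auto":
        # dart-throwing saturates well below random-sequential-adsorption
        # packing; fall back to the staggered lattice for dense tissue
        implied = n_target * v_mean / spec.domain.volume
        arrangement = "random" if implied <= 0.25 else "lattice"
    if arrangement == "lattice":
        cells = _place_cells_lattice(rng, spec, n_target)
    else:
        cells = _place_cells_random(rng, spec, n_target)

    particles: list[Spheroid] = []
    next_id = len(cells) + 1
    if spec.chloroplasts_per_cell_mean > 0:
        if spec.chloroplasts_per_cell_sd > 0:
            counts = np.clip(
                np.round(rng.normal(spec.chloroplasts_per_cell_mean,
                                    spec.chloroplasts_per_cell_sd, len(cells))),
                0, None,
            ).astype(int)
        else:
            counts = np.full(len(cells), int(round(spec.chloroplasts_per_cell_mean)))
        for cell, cnt in zip(cells, counts):
            placed = _place_particles_in_cell(
                rng, cell, int(cnt), spec.chl_semi_axes_mean, spec.chl_semi_axes_cv, next_id
            )
            particles.extend(placed)
            next_id += int(cnt)

    model = TissueModel(
        domain=spec.domain, cells=cells, particles=particles, spec=spec,
        metadata={
            "seed": spec.seed,
            "n_cells": len(cells),
            "n_particles": len(particles),
            "mesophyll_fraction_target": spec.mesophyll_fraction,
            "mesophyll_fraction_realized": sum(c.volume for c in cells) / spec.domain.volume,
            "mean_particles_per_cell": (len(particles) / len(cells)) if cells else None,
        },
    )
    return model


# ---------------------------------------------------------------------------
# SUR sampling and sectioning
# ---------------------------------------------------------------------------

def sur_positions(
    length: float,
    period: float,
    rng: Optional[np.random.Generator] = None,
    *,
    offset: Optional[float] = None,
    dialect: Literal["grid6", "continuous"] = "grid6",
) -> np.ndarray:
    """Systematic uniform random positions along [0, length].

    ``dialect='grid6'`` draws the first position as (k+1)·period/6 with k a
    uniform integer in 0..5 (the random-number-table protocol used for
    needle cross-sections, where period 3 mm puts the first section at
    0.5–3 mm from the tip); ``'continuous'`` draws it uniformly in
    (0, period].  An explicit ``offset`` overrides the draw.
    """
    if not (0 < period <= length):
        raise ValueError(f"period must satisfy 0 < period <= length, got {period} vs {length}")
    if offset is None:
        if rng is None:
            raise ValueError("provide either an rng or an explicit offset")
        if dialect == "grid6":
            k = int(rng.integers(0, 6))
            offset = (k + 1) * period / 6.0
        elif dialect == "continuous":
            offset = float(period - rng.uniform(0.0, period))  # uniform in (0, period]
        else:
            raise ValueError(f"unknown SUR dialect {dialect!r}")
    if not (0 < offset <= period):
        raise ValueError("offset must lie in (0, period]")
    n = int(np.floor((length - offset) / period)) + 1
    return offset + period * np.arange(n)


def section_profile_counts(model, zs) -> np.ndarray:
    """Profile counts for many section planes at once.

    Counts, for each z in ``zs``, the particles whose z-extent contains z —
    by definition the number of profiles :func:`section_profiles` would
    return, without building them.
    """
    spheroids = model.particles if hasattr(model, "particles") else model
    zs = np.atleast_1d(np.asarray(zs, dtype=float))
    if not spheroids:
        return np.zeros(len(zs), dtype=int)
    _, C, A = spheroids_to_arrays(spheroids)
    hit = np.abs(zs[:, None] - C[None, :, 2]) <= A[None, :, 2]
    return hit.sum(axis=1)


def cell_volume_fraction(model, region: Optional[Box3] = None, spacing: float = 4.0) -> float:
    """Volume fraction occupied by cell bodies, by point counting on a
    regular 3D grid (vectorised); ``region`` defaults to the model domain."""
    region = region or model.domain
    lo, hi = region.lo, region.hi
    axes_pts = [np.arange(lo[i] + spacing / 2.0, hi[i], spacing) for i in range(3)]
    inside = np.zeros(tuple(len(ax) for ax in axes_pts), dtype=bool)
    for c in model.cells:
        cc = np.asarray(c.center)
        aa = np.asarray(c.semi_axes)
        sl, t = [], []
        for i in range(3):
            i0 = int(np.searchsorted(axes_pts[i], cc[i] - aa[i]))
            i1 = int(np.searchsorted(axes_pts[i], cc[i] + aa[i], side="right"))
            sl.append(slice(i0, i1))
            t.append((axes_pts[i][i0:i1] - cc[i]) / aa[i])
        if any(len(ti) == 0 for ti in t):
            continue
        q = (
            t[0][:, None, None] ** 2
            + t[1][None, :, None] ** 2
            + t[2][None, None, :] ** 2
        )
        inside[sl[0], sl[1], sl[2]] |= q <= 1.0
    return float(inside.mean())


def section_profiles(model, z: float) -> list[Profile]:
    """All particle profiles cut by the plane at height z.

    ``model`` may be a CellModel/TissueModel (its ``particles`` are
    sectioned) or a plain sequence of spheroids.
    """
    spheroids = model.particles if hasattr(model, "particles") else model
    profiles = []
    for p in spheroids:
        prof = plane_profile(p, z)
        if prof is not None:
            profiles.append(prof)
    return profiles


# ---------------------------------------------------------------------------
# voxelised label stacks
# ---------------------------------------------------------------------------

@dataclass
class LabelStack:
    """A labelled optical z-stack: pages[k] is the section at
    z = origin_z − k·dz (page 0 on top), 16-bit labels, pixel centers at
    origin + (index + 0.5)·pixel_size."""

    pages: np.ndarray  # (n_sections, H, W) uint16
    origin: tuple[float, float, float]  # (x, y, z_top)
    pixel_size: float
    dz: float
    channel: str = "chloroplasts"

    def page_z(self, k: int) -> float:
        return self.origin[2] - k * self.dz

    @property
    def n_sections(self) -> int:
        return int(self.pages.shape[0])

    def metadata(self) -> dict:
        return {
            "pixel_size_um": self.pixel_size,
            "dz_um": self.dz,
            "origin_um": list(self.origin),
            "channel": self.channel,
            "n_sections": self.n_sections,
            "shape": list(self.pages.shape),
        }

    def write_tiff(self, path: str) -> None:
        """Multi-page TIFF with voxel metadata in the image description,
        plus a sidecar JSON next to it."""
        import tifffile

        tifffile.imwrite(
            path,
            self.pages,
            photometric="minisblack",
            description=json.dumps(self.metadata()),
            resolution=(1.0 / self.pixel_size, 1.0 / self.pixel_size),
        )
        Path(str(path) + ".json").write_text(json.dumps(self.metadata(), indent=1))

    @classmethod
    def read_tiff(cls, path: str) -> "LabelStack":
        import tifffile

        with tifffile.TiffFile(path) as tf:
            pages = tf.asarray()
            desc = tf.pages[0].description
        meta = json.loads(desc) if desc else json.loads(Path(str(path) + ".json").read_text())
        if pages.ndim == 2:
            pages = pages[None, :, :]
        return cls(
            pages=pages.astype(np.uint16),
            origin=tuple(meta["origin_um"]),
            pixel_size=float(meta["pixel_size_um"]),
            dz=float(meta["dz_um"]),
            channel=meta.get("channel", "chloroplasts"),
        )


def render_label_stack(model, spec: StackSpec) -> LabelStack:
    """Voxelise a model into a labelled stack.

    A pixel gets a particle's id when the pixel center lies inside the
    particle's profile at the page's z; where profiles overlap, the highest
    id wins.  Pages whose plane misses the model entirely stay blank.
    """
    import warnings

    if spec.channel == "cells":
        spheroids = list(getattr(model, "cells", [])) or [model.cell]
    elif spec.channel == "chloroplasts":
        spheroids = list(model.particles)
    else:
        spheroids = list(getattr(model, "cells", []) or ([model.cell] if hasattr(model, "cell") else []))
        spheroids += list(model.particles)

    w, d = spec.frame
    W = int(round(w / spec.pixel_size))
    H = int(round(d / spec.pixel_size))
    pages = np.zeros((spec.n_sections, H, W), dtype=np.uint16)
    x0, y0, _ = spec.origin
    px = spec.pixel_size
    xs = x0 + (np.arange(W) + 0.5) * px
    ys = y0 + (np.arange(H) + 0.5) * px

    if spheroids:
        _, C, A = spheroids_to_arrays(spheroids)
        bx0, bx1 = float(np.min(C[:, 0] - A[:, 0])), float(np.max(C[:, 0] + A[:, 0]))
        by0, by1 = float(np.min(C[:, 1] - A[:, 1])), float(np.max(C[:, 1] + A[:, 1]))
        if bx1 < xs[0] or bx0 > xs[-1] or by1 < ys[0] or by0 > ys[-1]:
            warnings.warn("stack frame lies outside the model; rendering blank pages")

    order = np.argsort([s.id for s in spheroids])  # ascending ids: later paint wins
    for k in range(spec.n_sections):
        z = spec.page_z(k)
        page = pages[k]
        for idx in order:
            s = spheroids[idx]
            prof = plane_profile(s, z)
            if prof is None:
                continue
            (cx, cy), (ax, ay) = prof.center, prof.semi_axes
            j0 = max(0, int(np.floor((cx - ax - x0) / px - 0.5)))
            j1 = min(W - 1, int(np.ceil((cx + ax - x0) / px)))
            i0 = max(0, int(np.floor((cy - ay - y0) / px - 0.5)))
            i1 = min(H - 1, int(np.ceil((cy + ay - y0) / px)))
            if j1 < j0 or i1 < i0:
                continue
            gx = xs[j0 : j1 + 1]
            gy = ys[i0 : i1 + 1]
            with np.errstate(divide="ignore", invalid="ignore"):
                tx = np.where(ax > 0, (gx - cx) / ax, np.where(gx == cx, 0.0, np.inf))
                ty = np.where(ay > 0, (gy - cy) / ay, np.where(gy == cy, 0.0, np.inf))
            inside = tx[None, :] ** 2 + ty[:, None] ** 2 <= 1.0
            sub = page[i0 : i1 + 1, j0 : j1 + 1]
            sub[inside] = np.uint16(s.id)
    return LabelStack(
        pages=pages, origin=spec.origin, pixel_size=spec.pixel_size,
        dz=spec.dz, channel=spec.channel,
    )
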