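"""Stereological estimators: numerical and areal densities from probe
tallies, per-cell ratios, Cavalieri volume, and the profile-counting bias.

Densities are ratios of pooled sums, not means of per-probe ratios: with
ΣQ particles counted over probes of frame area a (p grid points each,
height h) and ΣP reference-space grid hits,

    N_V = ΣQ·p / (ΣP·a·h)        (number per volume)
    N_A = ΣQ·p / (ΣP·a)          (profiles per area)

For thin section planes N_A = N_V · h̄, with h̄ the mean particle caliper
along the sectioning axis (DeHoff's relation) — which is exactly why a
per-cell count formed from profile densities is biased by the factor
h̄_particle / h̄_cell (≈ 4/40 = 0.1 for chloroplasts in mesophyll cells:
a ten-fold underestimate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CountTally",
    "EstimateReport",
    "nv_estimate",
    "na_estimate",
    "per_cell_ratio",
    "cavalieri_volume",
    "bias_ratio",
    "expected_profiles_per_section",
]


@dataclass(frozen=True)
class CountTally:
    """Pooled raw tallies from a set of probes.

    ``h`` is the probe height in µm (for a double disector, twice the slab
    height); leave it None for 2D (frame) tallies.
    """

    sum_Q: int
    sum_P: int
    p: int
    a: float
    h: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sum_Q < 0 or self.sum_P < 0:
            raise ValueError("tallies must be non-negative")
        if self.p < 1:
            raise ValueError("p (points per frame) must be >= 1")
        if self.a <= 0:
            raise ValueError("frame area must be positive")
        if self.h is not None and self.h <= 0:
            raise ValueError("probe height must be positive when given")


class ZeroReferenceError(ZeroDivisionError):
    """ΣP = 0: the reference space was never hit, densities are undefined."""


def nv_estimate(t: CountTally) -> float:
    """Numerical density (µm⁻³) from a disector tally: ΣQ·p / (ΣP·a·h)."""
    if t.h is None:
        raise ValueError("nv_estimate needs a probe height h")
    if t.sum_P == 0:
        raise ZeroReferenceError(
            "sum of reference points is zero; cannot divide by zero reference volume"
        )
    return t.sum_Q * t.p / (t.sum_P * t.a * t.h)


def na_estimate(t: CountTally) -> float:
    """Areal profile density (µm⁻²) from a frame tally: ΣQ·p / (ΣP·a)."""
    if t.sum_P == 0:
        raise ZeroReferenceError(
            "sum of reference points is zero; cannot divide by zero reference area"
        )
    return t.sum_Q * t.p / (t.sum_P * t.a)


def per_cell_ratio(numerator_density: float, denominator_density: float) -> float:
    """Particles per cell as a ratio of two densities over the same space."""
    if denominator_density <= 0:
        raise ZeroDivisionError("denominator density must be positive")
    return numerator_density / denominator_density


def cavalieri_volume(
    areas: Sequence[float],
    period: float,
    mode: str = "mean_times_length",
    length: Optional[float] = None,
) -> float:
    """Volume from systematically spaced section areas.

    ``mode='sum'`` is the textbook Cavalieri estimator T·ΣAᵢ.
    ``mode='mean_times_length'`` multiplies the mean section area by the
    specimen length L (the needle-protocol variant; default).  The two
    agree exactly when L = n·T.
    """
    areas = np.asarray(list(areas), dtype=float)
    if areas.size == 0:
        raise ValueError("need at least one section area")
    if period <= 0:
        raise ValueError("section period must be positive")
    if mode == "sum":
        return float(period * areas.sum())
    if mode == "mean_times_length":
        if length is None:
            length = period * areas.size
        return float(areas.mean() * length)
    raise ValueError(f"unknown Cavalieri mode {mode!r}")


def bias_ratio(h_particle: float, h_cell: float) -> float:
    """Factor by which 2D profile counting underestimates particles per cell.

    The per-cell ratio of areal densities converges to N·h̄_particle/h̄_cell,
    so the 2D estimate is the true count multiplied by this fraction
    (0.1 for 4 µm chloroplasts in 40 µm cells — a ten-fold underestimate).
    """
    if h_particle <= 0 or h_cell <= 0:
        raise ValueError("caliper heights must be positive")
    return h_particle / h_cell


def expected_profiles_per_section(n: int, h_particle: float, extent: float) -> float:
    """Expected profile count for a uniform random plane through a region of
    z-extent ``extent`` containing n particles of caliper ``h_particle``."""
    if not (extent >= h_particle > 0):
        raise ValueError("need extent >= h_particle > 0")
    return n * h_particle / extent


@dataclass
class EstimateReport:
    """Derived density/ratio estimates with their provenance."""

    Nv_cell: Optional[float] = None  # cells / µm³
    Nv_chl: Optional[float] = None  # chloroplasts / µm³
    Na_cell: Optional[float] = None  # cell profiles / µm²
    Na_chl: Optional[float] = None  # chloroplast profiles / µm²
    n_per_cell_3d: Optional[float] = None
    n_per_cell_2d: Optional[float] = None
    volume: Optional[float] = None  # µm³
    per_section: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("Nv_cell", "Nv_chl", "Na_cell", "Na_chl"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_per_cell_3d is not None and self.Nv_cell and self.Nv_chl:
            expected = self.Nv_chl / self.Nv_cell
            if not np.isclose(self.n_per_cell_3d, expected, rtol=1e-9):
                raise ValueError("n_per_cell_3d must equal Nv_chl / Nv_cell")

    def to_dict(self) -> dict:
        return {
            "Nv_cell_per_um3": self.Nv_cell,
            "Nv_chl_per_um3": self.Nv_chl,
            "Na_cell_per_um2": self.Na_cell,
            "Na_chl_per_um2": self.Na_chl,
            "n_per_cell_3d": self.n_per_cell_3d,
            "n_per_cell_2d": self.n_per_cell_2d,
            "volume_um3": self.volume,
            "per_section": self.per_section,
            "metadata": self.metadata,
        }
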