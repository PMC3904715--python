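"""Experiment orchestration: the model-cell sectioning experiment and the
paired 3D-vs-2D tissue comparison.

Both experiments are fully seeded and emit JSON-serialisable reports; the
tissue comparison also produces a per-probe tally table.  The model-cell
experiment cuts systematic (SUR) sections through a single model cell and
compares the mean profile count per section with the true particle number;
the tissue comparison runs double disectors and middle-section frame counts
at SUR positions through a synthetic tissue block and forms both per-cell
estimates from pooled tallies, the way the needle protocol pools per
cross-section.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    CountTally,
    expected_profiles_per_section,
    na_estimate,
    nv_estimate,
    per_cell_ratio,
)
from .geometry import Box3
from .probes import CountingFrame2D, PointGrid, double_disector_count, frame_count, point_grid_hits
from .synthetic import (
    ModelCellSpec,
    TissueSpec,
    generate_model_cell,
    generate_tissue,
    section_profile_counts,
    section_profiles,
    sur_positions,
)

__all__ = [
    "ModelCellExperimentConfig",
    "TissueComparisonConfig",
    "run_model_cell_experiment",
    "run_tissue_comparison",
    "paired_t",
]


# ---------------------------------------------------------------------------
# paired t-test
# ---------------------------------------------------------------------------

class ZeroVarianceError(ValueError):
    """Differences have zero variance; the paired t statistic is undefined."""


def paired_t(x, y) -> dict:
    """Paired two-sided t-test: returns {'t', 'df', 'p_two_sided'}."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        raise ZeroVarianceError("paired differences have zero variance")
    res = stats.ttest_rel(x, y)
    return {"t": float(res.statistic), "df": int(x.size - 1), "p_two_sided": float(res.pvalue)}


# ---------------------------------------------------------------------------
# model-cell experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelCellExperimentConfig:
    model: ModelCellSpec = field(default_factory=ModelCellSpec)
    n_sections: int = 111
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")


def run_model_cell_experiment(cfg: ModelCellExperimentConfig) -> dict:
    """Cut systematic sections through a model cell and count profiles.

    Sections are SUR over the cell's z-extent (a random phase then a fixed
    period), an assumption recorded in the report.  The underestimation
    factor is the true particle number divided by the mean profile count.
    """
    rng = np.random.default_rng(cfg.seed)
    # the experiment seed drives everything: re-seed the model spec with it
    model = generate_model_cell(replace(cfg.model, seed=cfg.seed))
    z0, z1 = model.cell.center[2] - model.cell.semi_axes[2], model.cell.center[2] + model.cell.semi_axes[2]
    extent = z1 - z0
    period = extent / cfg.n_sections
    planes = z0 + sur_positions(extent, period, rng, dialect="continuous")
    counts = section_profile_counts(model, planes)

    mean = float(counts.mean())
    se = float(counts.std(ddof=1) / np.sqrt(cfg.n_sections)) if cfg.n_sections > 1 else None
    true_n = model.n_particles
    mean_caliper = (
        float(np.mean([2.0 * p.semi_axes[2] for p in model.particles])) if model.particles else 0.0
    )
    return {
        "experiment": "model_cell",
        "seed": cfg.seed,
        "model_seed": cfg.model.seed,
        "n_sections": cfg.n_sections,
        "section_period_um": period,
        "per_section_counts": counts.tolist(),
        "mean_profiles_per_section": mean,
        "se_profiles_per_section": se,
        "true_n": true_n,
        "underestimation_factor": (true_n / mean) if mean > 0 else None,
        "analytic_expectation": expected_profiles_per_section(
            true_n, mean_caliper, extent
        ) if true_n > 0 else 0.0,
        "mean_particle_caliper_um": mean_caliper,
        "cell_z_extent_um": extent,
        "assumptions": ["sections are systematic uniform random through the cell z-extent"],
    }


# ---------------------------------------------------------------------------
# tissue comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueComparisonConfig:
    """Probe layout for the paired 3D/2D comparison.

    Probes sit at SUR positions along x; at each position a double disector
    for cells (slab height ``h_cell``) and one for chloroplasts (slab height
    ``h_chl``) share a frame footprint centered in y, with a point grid for
    the reference space and an unbiased 2D frame on the middle section.
    """

    tissue: TissueSpec = field(
        default_factory=lambda: TissueSpec(
            domain=Box3((0, 0, 0), (480, 200, 240)),
            n_cells=250,
            mesophyll_fraction=None,
            max_attempts_per_cell=400,
        )
    )
    frame_size: tuple[float, float] = (120.0, 120.0)  # (w, d) µm
    h_cell: float = 10.0  # slab height for cell counting (double → 20 µm)
    h_chl: float = 5.5  # slab height for chloroplast counting (double → 11 µm)
    n_positions: int = 16
    grid_points: tuple[int, int] = (3, 3)  # test points per frame (p = 9)
    wall_buffer: float = 15.0  # µm kept between sampling bands and domain walls
    seed: int = 0


def _position_layout(
    cfg: TissueComparisonConfig, rng: np.random.Generator
) -> tuple[list[tuple[float, float]], float]:
    """SUR probe positions: systematic along x, paired with an independently
    phased (and shuffled) systematic series of slab-center depths z.

    Varying the depth across positions keeps the probes from resampling the
    same thin layer of cells.  Confined hard-core placement concentrates
    cell centers in a layer right at the domain walls, so every band of
    cell centers a probe can sample — the disector bands and the
    middle-section profile band — is kept ``wall_buffer`` µm inside the
    region where the center density is flat.  Returns the (x, z) pairs and
    the frame's y origin.
    """
    dom = cfg.tissue.domain
    fw, fd = cfg.frame_size
    b = cfg.wall_buffer
    rl = cfg.tissue.cell_lateral_mean + 2.0 * cfg.tissue.cell_lateral_sd
    rz = cfg.tissue.cell_caliper_mean / 2.0 + 2.0 * cfg.tissue.cell_caliper_sd

    x_lo = dom.lo[0] + b
    x_hi = dom.hi[0] - fw - 2.0 * rl - b  # keep the (x0+rl, x0+fw+rl] band inside
    span = x_hi - x_lo
    if span <= 0:
        raise ValueError("domain too small in x for the frame and wall buffer")
    xs = x_lo + np.asarray(
        sur_positions(span, span / cfg.n_positions, rng, dialect="continuous")
    )

    y_lo, y_hi = dom.lo[1] + b, dom.hi[1] - fd - 2.0 * rl - b
    if y_hi < y_lo:
        raise ValueError("domain too small in y for the frame and wall buffer")
    y0 = 0.5 * (y_lo + y_hi)

    z_lo = dom.lo[2] + 2.0 * rz + cfg.h_cell / 2.0 + b
    z_hi = dom.hi[2] - 2.0 * rz - cfg.h_cell / 2.0 - b
    z_span = z_hi - z_lo
    if z_span <= 0:
        raise ValueError("domain too shallow for the cell caliper, slab and buffer")
    zs = z_lo + np.asarray(
        sur_positions(z_span, z_span / cfg.n_positions, rng, dialect="continuous")
    )
    zs = rng.permutation(zs)
    n = min(len(xs), len(zs))
    return [(float(xs[i]), float(zs[i])) for i in range(n)], float(y0)


def run_tissue_comparison(cfg: TissueComparisonConfig) -> dict:
    """Generate tissue and estimate chloroplasts per cell by both routes.

    3D: double disectors for cells and chloroplasts, reference volume from
    point counts; per-cell count as the ratio of pooled numerical
    densities.  2D: unbiased-frame profile counts on each probe's middle
    section; per-cell count as the ratio of pooled areal densities.  The
    ratio of the two estimates measures the profile-counting bias.
    """
    rng = np.random.default_rng(cfg.seed)
    model = generate_tissue(replace(cfg.tissue, seed=cfg.seed))
    dom = model.domain
    fw, fd = cfg.frame_size
    positions, y0 = _position_layout(cfg, rng)

    px_n, py_n = cfg.grid_points
    p = px_n * py_n

    rows = []
    flagged = []
    sum_Q_cell = sum_Q_chl = sum_F_cell = sum_F_chl = 0
    sum_P_cell = sum_P_chl = sum_P_2d = 0
    for i, (x, z_mid) in enumerate(positions):
        frame = CountingFrame2D(x, y0, fw, fd)
        grid = PointGrid(
            spacing=(fw / px_n, fd / py_n),
            offset=(x + fw / (2 * px_n), y0 + fd / (2 * py_n)),
        )
        in_tissue = lambda pts: (
            (pts[:, 0] >= dom.lo[0]) & (pts[:, 0] <= dom.hi[0])
            & (pts[:, 1] >= dom.lo[1]) & (pts[:, 1] <= dom.hi[1])
        )
        P = point_grid_hits(in_tissue, grid, frame)

        slab_cell = Box3((x, y0, z_mid - cfg.h_cell / 2.0), (fw, fd, cfg.h_cell))
        slab_chl = Box3((x, y0, z_mid - cfg.h_chl / 2.0), (fw, fd, cfg.h_chl))
        t_cell = double_disector_count(model.cells, slab_cell)
        t_chl = double_disector_count(model.particles, slab_chl)

        profs_cell = section_profiles(model.cells, z_mid)
        profs_chl = section_profiles(model.particles, z_mid)
        F_cell = len(frame_count(profs_cell, frame))
        F_chl = len(frame_count(profs_chl, frame))

        sum_Q_cell += t_cell.Q
        sum_Q_chl += t_chl.Q
        sum_F_cell += F_cell
        sum_F_chl += F_chl
        sum_P_cell += P
        sum_P_chl += P
        sum_P_2d += P

        row = {
            "probe_id": i, "x_um": x, "z_um": z_mid, "Q_cell": t_cell.Q, "Q_chl": t_chl.Q,
            "F_cell": F_cell, "F_chl": F_chl, "P": P, "p": p,
            "a_um2": fw * fd, "h_cell_um": t_cell.h, "h_chl_um": t_chl.h,
        }
        if t_cell.Q == 0 or F_cell == 0:
            flagged.append({**row, "reason": "zero cell tally at this position"})
            row["paired_ok"] = False
        else:
            row["n3d"] = per_cell_ratio(
                nv_estimate(CountTally(t_chl.Q, P, p, fw * fd, t_chl.h)),
                nv_estimate(CountTally(t_cell.Q, P, p, fw * fd, t_cell.h)),
            )
            row["n2d"] = per_cell_ratio(
                na_estimate(CountTally(F_chl, P, p, fw * fd)),
                na_estimate(CountTally(F_cell, P, p, fw * fd)),
            )
            row["paired_ok"] = True
        rows.append(row)

    a = fw * fd
    Nv_cell = nv_estimate(CountTally(sum_Q_cell, sum_P_cell, p, a, 2 * cfg.h_cell))
    Nv_chl = nv_estimate(CountTally(sum_Q_chl, sum_P_chl, p, a, 2 * cfg.h_chl))
    Na_cell = na_estimate(CountTally(sum_F_cell, sum_P_2d, p, a))
    Na_chl = na_estimate(CountTally(sum_F_chl, sum_P_2d, p, a))
    n3d = per_cell_ratio(Nv_chl, Nv_cell)
    n2d = per_cell_ratio(Na_chl, Na_cell)

    paired = [(r["n3d"], r["n2d"]) for r in rows if r.get("paired_ok")]
    ttest: Optional[dict]
    try:
        ttest = paired_t([v[0] for v in paired], [v[1] for v in paired]) if len(paired) >= 2 else None
    except ZeroVarianceError as exc:
        ttest = {"error": str(exc)}

    return {
        "experiment": "tissue_compare",
        "seed": cfg.seed,
        "n_positions": len(positions),
        "positions_um": positions,
        "tallies": rows,
        "flagged_positions": flagged,
        "Nv_cell_per_um3": Nv_cell,
        "Nv_chl_per_um3": Nv_chl,
        "Na_cell_per_um2": Na_cell,
        "Na_chl_per_um2": Na_chl,
        "n_per_cell_3d": n3d,
        "n_per_cell_2d": n2d,
        "ratio_3d_to_2d": n3d / n2d,
        "true_mean_particles_per_cell": model.mean_particles_per_cell,
        "mesophyll_fraction_realized": model.mesophyll_fraction_realized,
        "paired_t": ttest,
        "assumptions": [
            "probe positions are systematic uniform random along x, paired with a "
            "shuffled systematic series of slab depths z",
            "densities pooled as ratios of sums across positions",
        ],
    }


def write_report(report: dict, out_dir: str) -> None:
    """report.json, tallies.csv and a short summary.md under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    if "tallies" in report:
        pd.DataFrame(report["tallies"]).to_csv(out / "tallies.csv", index=False)
    lines = [f"# {report['experiment']} report", ""]
    for key in (
        "seed", "mean_profiles_per_section", "true_n", "underestimation_factor",
        "n_per_cell_3d", "n_per_cell_2d", "ratio_3d_to_2d",
        "true_mean_particles_per_cell",
    ):
        if key in report and report[key] is not None:
            lines.append(f"- {key}: {report[key]}")
    (out / "summary.md").write_text("\n".join(lines) + "\n")
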