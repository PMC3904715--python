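"""Synthetic models: model cell, tissue, SUR sampling, sections, stacks."""

import numpy as np
import pytest
from scipy import ndimage

from stereocount.geometry import Box3, spheroid_contains_spheroid
from stereocount.synthetic import (
    CellModel,
    ModelCellSpec,
    PlacementError,
    StackSpec,
    TissueSpec,
    cell_volume_fraction,
    generate_model_cell,
    generate_tissue,
    render_label_stack,
    section_profile_counts,
    section_profiles,
    sur_positions,
)


class TestModelCell:
    def test_default_has_210_contained_particles(self):
        m = generate_model_cell(ModelCellSpec(seed=3))
        assert m.n_particles == 210
        assert all(p.parent_id == m.cell.id for p in m.particles)
        assert all(spheroid_contains_spheroid(p, m.cell) for p in m.particles)
        assert m.cell.caliper_z == pytest.approx(49.0)

    def test_empty_model(self):
        m = generate_model_cell(ModelCellSpec(n_chloroplasts=0, seed=0))
        assert m.particles == []

    def test_seed_determinism_byte_identical(self):
        a = generate_model_cell(ModelCellSpec(seed=11)).to_json()
        b = generate_model_cell(ModelCellSpec(seed=11)).to_json()
        assert a == b
        c = generate_model_cell(ModelCellSpec(seed=12)).to_json()
        assert a != c

    def test_round_trip(self):
        m = generate_model_cell(ModelCellSpec(n_chloroplasts=20, seed=5))
        m2 = CellModel.from_dict(__import__("json").loads(m.to_json()))
        assert m2.n_particles == 20
        assert m2.particles == m.particles

    def test_too_small_cell_raises(self):
        spec = ModelCellSpec(
            n_chloroplasts=50,
            cell_semi_axes=(3.0, 3.0, 22.0),
            chl_semi_axes_mean=(2.6, 2.6, 2.0),
            allow_overlap=False,
            caliper_validity=None,
            seed=0,
        )
        with pytest.raises(PlacementError):
            generate_model_cell(spec)

    def test_caliper_validity_enforced(self):
        with pytest.raises(ValueError, match="validity"):
            ModelCellSpec(cell_semi_axes=(15, 15, 35.0))

    def test_non_overlap_mode(self):
        m = generate_model_cell(
            ModelCellSpec(n_chloroplasts=30, allow_overlap=False, seed=4)
        )
        from stereocount.geometry import spheroids_overlap

        for i, p in enumerate(m.particles):
            for q in m.particles[i + 1:]:
                assert not spheroids_overlap(p, q)

    def test_peripheral_shell_placement(self):
        m = generate_model_cell(
            ModelCellSpec(n_chloroplasts=60, placement="peripheral_shell",
                          shell_thickness=4.0, seed=6)
        )
        R = np.asarray(m.spec.cell_semi_axes)
        rr = [np.linalg.norm(np.asarray(p.center) / R) for p in m.particles]
        assert min(rr) >= 1.0 - 4.0 / float(R.min()) - 1e-9


class TestSurPositions:
    def test_enumerated_positions(self):
        pos = sur_positions(30_000, 3_000, offset=2_000)
        assert list(pos) == [2_000 + 3_000 * i for i in range(10)]

    def test_grid6_offsets_land_on_sixths(self):
        rng = np.random.default_rng(0)
        offsets = {float(sur_positions(3_000, 3_000, rng)[0]) for _ in range(200)}
        assert offsets <= {500.0 * (k + 1) for k in range(6)}
        assert 500.0 in offsets  # k=0: first section half a period from the start

    def test_period_equals_length_single_position(self):
        assert len(sur_positions(100.0, 100.0, offset=50.0)) == 1

    def test_invalid_period_raises(self):
        with pytest.raises(ValueError):
            sur_positions(10.0, 0.0, offset=1.0)
        with pytest.raises(ValueError):
            sur_positions(10.0, 20.0, offset=1.0)

    def test_grid6_uniformity(self):
        rng = np.random.default_rng(42)
        draws = np.array([sur_positions(600.0, 600.0, rng)[0] for _ in range(6_000)])
        freqs = np.array([(draws == 100.0 * (k + 1)).mean() for k in range(6)])
        sigma = np.sqrt((1 / 6) * (5 / 6) / 6_000)
        assert np.all(np.abs(freqs - 1 / 6) < 3 * sigma)

    def test_continuous_dialect_in_range(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            pos = sur_positions(100.0, 10.0, rng, dialect="continuous")
            assert 0 < pos[0] <= 10.0
            assert pos[-1] <= 100.0


class TestSections:
    def test_profile_count_equals_straddlers(self):
        m = generate_model_cell(ModelCellSpec(seed=8))
        z = m.cell.center[2]
        profs = section_profiles(m, z)
        straddle = [
            p for p in m.particles
            if p.center[2] - p.semi_axes[2] <= z <= p.center[2] + p.semi_axes[2]
        ]
        assert {p.particle_id for p in profs} == {p.id for p in straddle}
        assert section_profile_counts(m, [z])[0] == len(straddle)

    def test_plane_outside_cell_empty(self):
        m = generate_model_cell(ModelCellSpec(seed=8))
        assert section_profiles(m, 100.0) == []

    def test_mean_profiles_over_fine_grid_matches_caliper_identity(self):
        """Averaged over an exhaustive z-grid through the cell, profiles per
        section approach n * (mean caliper) / (cell height)."""
        m = generate_model_cell(ModelCellSpec(seed=9))
        rz = m.cell.semi_axes[2]
        zs = np.linspace(m.cell.center[2] - rz, m.cell.center[2] + rz, 4_001)
        mean_count = section_profile_counts(m, zs).mean()
        total_caliper = sum(2 * p.semi_axes[2] for p in m.particles)
        assert mean_count == pytest.approx(total_caliper / (2 * rz), rel=2e-3)


class TestTissue:
    def test_counts_and_parentage(self):
        spec = TissueSpec(
            domain=Box3((0, 0, 0), (200, 200, 120)),
            n_cells=5, mesophyll_fraction=None,
            chloroplasts_per_cell_mean=30, chloroplasts_per_cell_sd=0,
            seed=1,
        )
        m = generate_tissue(spec)
        assert m.n_cells == 5
        assert len(m.particles) == 150
        cell_ids = {c.id for c in m.cells}
        assert all(p.parent_id in cell_ids for p in m.particles)
        by_cell = {c.id: c for c in m.cells}
        assert all(
            spheroid_contains_spheroid(p, by_cell[p.parent_id]) for p in m.particles
        )

    def test_cells_inside_domain_and_disjoint(self):
        spec = TissueSpec(
            domain=Box3((0, 0, 0), (250, 250, 150)),
            n_cells=20, mesophyll_fraction=None, chloroplasts_per_cell_mean=0, seed=2,
        )
        m = generate_tissue(spec)
        from stereocount.geometry import spheroids_overlap

        for c in m.cells:
            lo = np.asarray(c.center) - np.asarray(c.semi_axes)
            hi = np.asarray(c.center) + np.asarray(c.semi_axes)
            assert np.all(lo >= m.domain.lo - 1e-9) and np.all(hi <= m.domain.hi + 1e-9)
        for i, c in enumerate(m.cells):
            for d in m.cells[i + 1:]:
                assert not spheroids_overlap(c, d)

    def test_single_cell_reduces_to_model_cell(self):
        spec = TissueSpec(
            domain=Box3((0, 0, 0), (200, 200, 200)),
            n_cells=1, mesophyll_fraction=None,
            chloroplasts_per_cell_mean=50, chloroplasts_per_cell_sd=0, seed=3,
        )
        m = generate_tissue(spec)
        assert m.n_cells == 1
        assert len(m.particles) == 50
        assert m.mean_particles_per_cell == 50

    def test_unreachable_density_raises_with_fraction(self):
        spec = TissueSpec(
            domain=Box3((0, 0, 0), (120, 120, 120)),
            mesophyll_fraction=0.72, chloroplasts_per_cell_mean=0,
            arrangement="random", max_attempts_per_cell=50, seed=4,
        )
        with pytest.raises(PlacementError, match="packing fraction"):
            generate_tissue(spec)

    def test_lattice_reaches_dense_mesophyll_fraction(self):
        """Staggered-lattice placement realises the 72% mesophyll target in
        the bulk of the block (point-counted away from the boundary layer
        that whole-cell placement cannot fill)."""
        spec = TissueSpec(
            domain=Box3((0, 0, 0), (400, 400, 400)),
            mesophyll_fraction=0.72, chloroplasts_per_cell_mean=0,
            arrangement="lattice", seed=5,
        )
        m = generate_tissue(spec)
        assert m.metadata["mesophyll_fraction_realized"] > 0.5
        core = Box3((40, 40, 45), (320, 320, 310))
        frac = cell_volume_fraction(m, core, spacing=4.0)
        assert frac == pytest.approx(0.72, abs=0.05)

    def test_tissue_json_round_trip(self, tmp_path):
        spec = TissueSpec(
            domain=Box3((0, 0, 0), (200, 200, 120)),
            n_cells=4, mesophyll_fraction=None,
            chloroplasts_per_cell_mean=10, chloroplasts_per_cell_sd=0, seed=9,
        )
        m = generate_tissue(spec)
        path = tmp_path / "tissue.json"
        m.to_json(str(path))
        from stereocount.synthetic import load_model

        back = load_model(str(path))
        assert back.cells == m.cells
        assert back.particles == m.particles
        assert back.domain == m.domain

    def test_realized_fraction_reported(self):
        spec = TissueSpec(
            domain=Box3((0, 0, 0), (200, 200, 120)),
            n_cells=8, mesophyll_fraction=None, chloroplasts_per_cell_mean=0, seed=6,
        )
        m = generate_tissue(spec)
        vol = sum(c.volume for c in m.cells)
        assert m.metadata["mesophyll_fraction_realized"] == pytest.approx(
            vol / m.domain.volume
        )


class TestLabelStack:
    def test_sphere_voxel_count_matches_volume(self):
        from stereocount.geometry import Spheroid

        model = CellModel(
            cell=Spheroid(id=0, center=(6, 6, 0), semi_axes=(6, 6, 6), role="cell_body"),
            particles=[Spheroid(id=1, center=(6, 6, 0), semi_axes=(5, 5, 5), parent_id=0)],
            spec=ModelCellSpec(n_chloroplasts=1, caliper_validity=None,
                               cell_semi_axes=(6, 6, 6)),
        )
        spec = StackSpec(origin=(0, 0, 5.0), frame=(12, 12), n_sections=41,
                         dz=0.25, pixel_size=0.25)
        stack = render_label_stack(model, spec)
        voxels = int(np.count_nonzero(stack.pages))
        expected = 4 / 3 * np.pi * 5**3 / 0.25**3
        assert voxels == pytest.approx(expected, rel=0.02)

    def test_empty_model_blank_pages(self):
        model = CellModel(
            cell=__import__("stereocount.geometry", fromlist=["Spheroid"]).Spheroid(
                id=0, center=(0, 0, 0), semi_axes=(5, 5, 5), role="cell_body"),
            particles=[],
            spec=ModelCellSpec(n_chloroplasts=0, caliper_validity=None,
                               cell_semi_axes=(5, 5, 5)),
        )
        spec = StackSpec(origin=(-5, -5, 4.0), frame=(10, 10), n_sections=5,
                         dz=2.0, pixel_size=0.5)
        stack = render_label_stack(model, spec)
        assert not stack.pages.any()

    def test_page_profiles_recover_section_ids(self):
        """Connected components of a rendered page carry exactly the ids of
        the geometric section profiles (non-overlapping particles)."""
        from stereocount.geometry import Spheroid

        rng = np.random.default_rng(7)
        particles = []
        for i in range(12):
            c = rng.uniform(8, 52, size=2)
            cz = rng.uniform(-3, 3)
            if any(np.hypot(c[0] - p.center[0], c[1] - p.center[1]) < 9 for p in particles):
                continue
            particles.append(
                Spheroid(id=i + 1, center=(c[0], c[1], cz), semi_axes=(3, 3, 3))
            )
        model = CellModel(
            cell=Spheroid(id=0, center=(30, 30, 0), semi_axes=(40, 40, 10), role="cell_body"),
            particles=particles,
            spec=ModelCellSpec(n_chloroplasts=0, caliper_validity=None,
                               cell_semi_axes=(40, 40, 10)),
        )
        spec = StackSpec(origin=(0, 0, 0.0), frame=(60, 60), n_sections=1,
                         dz=0.5, pixel_size=0.25)
        stack = render_label_stack(model, spec)
        page = stack.pages[0]
        n_components, _ = ndimage.label(page > 0)[1], None
        geometric = {p.particle_id for p in section_profiles(model, 0.0)
                     if min(p.semi_axes) >= 0.5}  # ≥ 2 px across
        assert set(np.unique(page)) - {0} == geometric
        assert n_components == len(geometric)

    def test_tiff_round_trip(self, tmp_path):
        m = generate_model_cell(ModelCellSpec(n_chloroplasts=15, seed=10))
        spec = StackSpec(origin=(-15, -15, 10.0), frame=(30, 30), n_sections=9,
                         dz=2.0, pixel_size=0.5)
        stack = render_label_stack(m, spec)
        path = tmp_path / "stack.tif"
        stack.write_tiff(str(path))
        from stereocount.synthetic import LabelStack

        back = LabelStack.read_tiff(str(path))
        assert np.array_equal(back.pages, stack.pages)
        assert back.dz == stack.dz and back.pixel_size == stack.pixel_size
        assert back.origin == stack.origin

    def test_frame_outside_model_warns(self):
        m = generate_model_cell(ModelCellSpec(n_chloroplasts=5, seed=0))
        spec = StackSpec(origin=(500, 500, 0), frame=(10, 10), n_sections=3,
                         dz=1.0, pixel_size=0.5)
        with pytest.warns(UserWarning, match="outside"):
            stack = render_label_stack(m, spec)
        assert not stack.pages.any()
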