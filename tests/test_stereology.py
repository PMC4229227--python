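"""Optical fractionator: grid placement, counting-frame edge rules,
density arithmetic and the coefficient of error."""

import numpy as np
import pytest

from wmiquant import stereology as st
from wmiquant import synthetic as syn


SQUARE_MM = [(0.0, 0.0), (1000.0, 0.0), (1000.0, 1000.0), (0.0, 1000.0)]


def make_field(xyz, pyknotic=None, extent=(200.0, 200.0, 40.0)):
    xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
    if pyknotic is None:
        pyknotic = np.zeros(len(xyz), dtype=bool)
    n = len(xyz)
    vol = extent[0] * extent[1] * extent[2] * 1e-9
    return syn.CellField3D(slab_extent=extent, xyz=xyz,
                           pyknotic=np.asarray(pyknotic, bool),
                           true_density=n / vol,
                           true_pyknotic_fraction=float(np.mean(pyknotic)) if n else 0.0,
                           seed=0)


class TestSamplingDesign:
    def test_defaults_are_published_geometry(self):
        d = st.SamplingDesign()
        assert (d.grid_dx_um, d.grid_dy_um) == (296.6, 277.2)
        assert (d.frame_w_um, d.frame_h_um) == (85.0, 85.0)
        assert d.guard_um == 3.0 and d.dissector_h_um == 25.0
        assert d.thickness_every == 5
        assert d.box_volume_um3 == pytest.approx(85 * 85 * 25)

    def test_frame_must_fit_grid_cell(self):
        with pytest.raises(ValueError):
            st.SamplingDesign(grid_dx_um=50.0)


class TestPlaceGrid:
    def test_mean_site_count_matches_area_ratio(self):
        # 1 mm^2 / (296.6 x 277.2 um) = 12.16 expected sites
        design = st.SamplingDesign()
        counts = [len(st.place_grid(SQUARE_MM, design, seed=s))
                  for s in range(1000)]
        assert 11.9 <= np.mean(counts) <= 12.5

    def test_zero_area_roi_rejected(self):
        with pytest.raises(ValueError):
            st.place_grid([(0, 0), (0, 0), (0, 0)], st.SamplingDesign())

    def test_degenerate_tiling_covers_roi_exactly(self):
        design = st.SamplingDesign(grid_dx_um=85.0, grid_dy_um=85.0)
        roi = [(0, 0), (850, 0), (850, 850), (0, 850)]
        sites = st.place_grid(roi, design, offset=(0.0, 0.0))
        assert len(sites) == 11 * 11  # boundary points included (covers)

    def test_tiny_roi_warns_when_empty(self):
        design = st.SamplingDesign()
        roi = [(10, 10), (20, 10), (20, 20), (10, 20)]
        with pytest.warns(UserWarning):
            sites = st.place_grid(roi, design, offset=(150.0, 150.0))
        assert sites == []

    def test_deterministic_per_seed(self):
        d = st.SamplingDesign()
        assert st.place_grid(SQUARE_MM, d, seed=4) == st.place_grid(SQUARE_MM, d, seed=4)


class TestCountFrame:
    design = st.SamplingDesign()

    def test_empty_field(self):
        field = make_field(np.empty((0, 3)))
        sc = st.count_frame(field, (10.0, 10.0), self.design)
        assert (sc.q_intact, sc.q_pyknotic) == (0, 0)

    def test_cell_at_frame_center_counted(self):
        field = make_field([[52.5, 52.5, 10.0]])
        sc = st.count_frame(field, (10.0, 10.0), self.design)
        assert sc.q_intact == 1

    def test_forbidden_and_inclusion_edges(self):
        x0, y0 = 10.0, 10.0
        w = self.design.frame_w_um
        cells = [
            [x0, 40.0, 10.0],          # on left (forbidden) edge
            [x0 + w, 40.0, 10.0],      # on right (inclusion) edge
            [40.0, y0, 10.0],          # on bottom (forbidden) edge
            [40.0, y0 + w, 10.0],      # on top (inclusion) edge
        ]
        field = make_field(cells)
        sc = st.count_frame(field, (x0, y0), self.design)
        assert sc.q_total == 2

    def test_guard_zone_and_dissector_depth(self):
        x, y = 40.0, 40.0
        cells = [
            [x, y, 2.9],    # inside guard zone -> excluded
            [x, y, 3.0],    # top of counting box -> included
            [x, y, 27.9],   # just above box floor -> included
            [x, y, 28.0],   # box floor (half-open) -> excluded
        ]
        field = make_field(cells)
        sc = st.count_frame(field, (10.0, 10.0), self.design)
        assert sc.q_total == 2

    def test_pyknotic_tallied_separately(self):
        field = make_field([[40, 40, 10], [50, 50, 10], [60, 60, 10]],
                           pyknotic=[True, False, True])
        sc = st.count_frame(field, (10.0, 10.0), self.design)
        assert (sc.q_intact, sc.q_pyknotic) == (1, 2)

    def test_thin_slab_rejected(self):
        field = make_field([[10, 10, 5]], extent=(200.0, 200.0, 20.0))
        with pytest.raises(ValueError):
            st.count_frame(field, (0.0, 0.0), self.design)

    def test_no_cell_countable_in_two_adjacent_frames(self, rng):
        # tiling design: frames share edges; the edge rules must assign
        # every cell to exactly one frame
        design = st.SamplingDesign(grid_dx_um=50.0, grid_dy_um=50.0,
                                   frame_w_um=50.0, frame_h_um=50.0,
                                   guard_um=0.0, dissector_h_um=40.0)
        extent = (200.0, 200.0, 40.0)
        xyz = rng.uniform(0, 1, (300, 3)) * np.asarray(extent)
        # drop measure-zero coordinates at exactly 0 (excluded by design)
        field = make_field(xyz, extent=extent)
        total = 0
        for x0 in np.arange(0.0, 200.0, 50.0):
            for y0 in np.arange(0.0, 200.0, 50.0):
                total += st.count_frame(field, (x0, y0), design).q_total
        assert total == 300  # exhaustive tiling == brute-force count

    def test_expected_count_invariant_under_translation(self):
        # systematic sampling is unbiased for any grid offset
        design = st.SamplingDesign()
        field = syn.generate_cell_field((1200.0, 1200.0, 40.0), 25000.0, 0.0,
                                        seed=12)
        roi = [(0, 0), (1115, 0), (1115, 1115), (0, 1115)]
        rng = np.random.default_rng(5)
        means = []
        for _ in range(150):
            sites = st.place_grid(roi, design,
                                  offset=tuple(rng.uniform(0, 300, 2)))
            counts = st.count_sites(field, sites, design)
            means.append(np.mean([c.q_total for c in counts]))
        expected = field.true_density * design.box_volume_um3 * 1e-9
        sem = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - expected) < 3 * sem + 0.05


class TestDensityAndCE:
    design = st.SamplingDesign()

    def _sites(self, qs, pyk=None):
        pyk = pyk or [0] * len(qs)
        return [st.SiteCount(i, (0.0, 0.0), q, p)
                for i, (q, p) in enumerate(zip(qs, pyk))]

    def test_zero_counts(self):
        est = st.estimate_density(self._sites([0] * 10), self.design)
        assert est.density_per_mm3 == 0.0
        assert est.pyknotic_pct is None
        assert est.ce is None

    def test_unit_arithmetic(self):
        # 36 cells over 10 sites x (85 x 85 x 25 um^3) = 19,931 / mm^3
        est = st.estimate_density(self._sites([4, 4, 4, 4, 4, 4, 4, 4, 2, 2]),
                                  self.design)
        assert est.sum_q == 36
        assert est.density_per_mm3 == pytest.approx(
            36 / (10 * 85 * 85 * 25) * 1e9)
        assert est.density_per_mm3 == pytest.approx(19930.8, abs=0.5)

    def test_pyknotic_percentage(self):
        est = st.estimate_density(self._sites([3, 3], [1, 1]), self.design)
        assert est.pyknotic_pct == pytest.approx(100 * 2 / 8)

    def test_no_sites_rejected(self):
        with pytest.raises(ValueError):
            st.estimate_density([], self.design)

    def test_ce_zero_for_equal_counts(self):
        assert st.schaffer_ce([5, 5, 5, 5]) == 0.0

    def test_ce_worked_example(self):
        # counts {1,2,3,4}: mean 2.5, SD 1.291 -> CE = (1.291/2)/2.5
        assert st.schaffer_ce([1, 2, 3, 4]) == pytest.approx(0.258, abs=5e-4)

    def test_ce_undefined_for_all_zero(self):
        assert st.schaffer_ce([0, 0, 0]) is None

    def test_ce_needs_two_sites(self):
        with pytest.raises(ValueError):
            st.schaffer_ce([3])

    def test_ce_shrinks_with_between_site_variance(self):
        assert st.schaffer_ce([2, 3, 2, 3]) < st.schaffer_ce([0, 5, 1, 4])


class TestPlanarDensities:
    def test_field_density_zero(self):
        assert st.field_density([0] * 10, 250000.0) == 0.0

    def test_field_density_published_control_level(self):
        # 293 cells over ten 0.25 mm^2 fields -> 117.2 cells/mm^2
        assert st.field_density([29, 29, 29, 29, 29, 30, 30, 30, 29, 29],
                                250000.0) == pytest.approx(117.2)

    def test_field_density_identity(self):
        assert st.field_density([1], 1e6) == pytest.approx(1.0)

    def test_exhaustive_density_zero_and_published_level(self):
        assert st.exhaustive_density(0, 1e8) == 0.0
        # 162 cells in 100 mm^2 -> 1.62 cells/mm^2
        assert st.exhaustive_density(162, 100 * 1e6) == pytest.approx(1.62)

    def test_exhaustive_density_linear_in_count(self):
        assert st.exhaustive_density(50, 1e7) * 2 == pytest.approx(
            st.exhaustive_density(100, 1e7))

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            st.exhaustive_density(10, 0.0)
        with pytest.raises(ValueError):
            st.field_density([1], 0.0)


class TestIO:
    def test_site_counts_roundtrip(self, tmp_path):
        field = syn.generate_cell_field((600, 600, 40), 20000, 0.05, seed=2)
        design = st.SamplingDesign()
        sites = st.place_grid([(0, 0), (500, 0), (500, 500), (0, 500)],
                              design, seed=3)
        counts = st.count_sites(field, sites, design)
        path = tmp_path / "sites.csv"
        st.write_site_counts_csv(counts, path)
        back = st.read_site_counts_csv(path)
        assert back == counts

    def test_thickness_recorded_every_fifth_site(self):
        field = syn.generate_cell_field((2000, 2000, 40), 20000, 0.0, seed=4)
        design = st.SamplingDesign()
        sites = st.place_grid([(0, 0), (1900, 0), (1900, 1900), (0, 1900)],
                              design, seed=5)
        counts = st.count_sites(field, sites, design)
        for c in counts:
            if c.site_index % design.thickness_every == 0:
                assert c.thickness_um == pytest.approx(40.0)
                assert c.thickness_um >= design.min_thickness_um
            else:
                assert c.thickness_um is None

    def test_design_yaml_roundtrip(self, tmp_path):
        d = st.SamplingDesign(guard_um=2.0)
        st.write_design_yaml(d, tmp_path / "d.yaml")
        assert st.read_design_yaml(tmp_path / "d.yaml") == d
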