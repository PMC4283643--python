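"""ROI assignment, injection zeroing, proportions, groups, placement."""

import numpy as np
import pandas as pd
import pytest

import cortexflat as cf
from cortexflat.roi import (
    DEFAULT_CORTICAL_GROUPING,
    DEFAULT_THALAMIC_GROUPING,
    read_manual_counts,
)


def _square(name, x0, y0, size=10.0, section="s"):
    v = np.array(
        [[x0, y0], [x0 + size, y0], [x0 + size, y0 + size], [x0, y0 + size]]
    )
    return cf.ROIPolygon(name=name, section_id=section, vertices=v)


def _cells(points, **extra):
    df = pd.DataFrame(points, columns=["x", "y"])
    for k, v in extra.items():
        df[k] = v
    return df


def _point_in_polygon_evenodd(px, py, verts):
    """Independent even-odd ray-casting oracle (boundary treated as inside
    via a tiny symmetric tolerance)."""
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # on-edge check
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if abs(cross) < 1e-9 and min(x1, x2) - 1e-9 <= px <= max(x1, x2) + 1e-9 \
                and min(y1, y2) - 1e-9 <= py <= max(y1, y2) + 1e-9:
            return True
        if (y1 > py) != (y2 > py):
            xin = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xin:
                inside = not inside
    return inside


class TestPolygons:
    def test_too_few_vertices(self):
        with pytest.raises(ValueError):
            cf.ROIPolygon("A", "s", np.array([[0, 0], [1, 1]]))

    def test_self_intersecting_named_in_error(self):
        bowtie = np.array([[0.0, 0.0], [10.0, 10.0], [10.0, 0.0], [0.0, 10.0]])
        with pytest.raises(ValueError, match="Bow"):
            cf.ROIPolygon("Bowtie", "s", bowtie)


class TestAssignment:
    def test_inside_and_outside(self):
        rois = [_square("A", 0, 0), _square("B", 20, 0)]
        counts, unassigned, assigned = cf.assign_cells_to_rois(
            _cells([(5.0, 5.0), (50.0, 50.0)]), rois
        )
        assert counts["A"] == 1 and counts["B"] == 0
        assert unassigned == 1
        assert assigned.iloc[0] == "A" and assigned.iloc[1] is None

    def test_boundary_counts_as_inside(self):
        counts, _, _ = cf.assign_cells_to_rois(
            _cells([(0.0, 5.0)]), [_square("A", 0, 0)]
        )
        assert counts["A"] == 1

    def test_overlap_resolved_by_name_order(self):
        rois = [_square("Zeta", 0, 0, 20), _square("Alpha", 5, 5, 20)]
        counts, _, assigned = cf.assign_cells_to_rois(_cells([(10.0, 10.0)]), rois)
        assert assigned.iloc[0] == "Alpha"
        assert counts["Alpha"] == 1 and counts["Zeta"] == 0

    def test_contralateral_cells_never_counted(self):
        cells = _cells([(5.0, 5.0), (6.0, 6.0)], contralateral=[False, True])
        counts, unassigned, _ = cf.assign_cells_to_rois(cells, [_square("A", 0, 0)])
        assert counts["A"] == 1
        assert unassigned == 0

    def test_blind_to_tracer_intensities(self):
        rng = np.random.default_rng(0)
        cells = _cells(
            rng.uniform(0, 30, (50, 2)),
            tracer_red_integrated=rng.uniform(0, 5e5, 50),
        )
        rois = [_square("A", 0, 0, 15), _square("B", 15, 0, 15)]
        counts1, _, a1 = cf.assign_cells_to_rois(cells, rois)
        permuted = cells.copy()
        permuted["tracer_red_integrated"] = rng.permutation(
            permuted["tracer_red_integrated"].to_numpy()
        )
        counts2, _, a2 = cf.assign_cells_to_rois(permuted, rois)
        pd.testing.assert_series_equal(counts1, counts2)
        pd.testing.assert_series_equal(a1, a2)

    def test_against_raycasting_oracle(self):
        """500 random cells vs an independent even-odd point-in-polygon."""
        rng = np.random.default_rng(12)
        tri = cf.ROIPolygon(
            "Tri", "s", np.array([[10.0, 5.0], [60.0, 20.0], [25.0, 70.0]])
        )
        pent = cf.ROIPolygon(
            "Pent",
            "s",
            np.array(
                [[70.0, 10.0], [95.0, 25.0], [90.0, 55.0], [72.0, 60.0], [60.0, 30.0]]
            ),
        )
        pts = rng.uniform(0, 100, (500, 2))
        counts, unassigned, _ = cf.assign_cells_to_rois(
            _cells([tuple(p) for p in pts]), [tri, pent]
        )
        oracle = {"Tri": 0, "Pent": 0}
        n_out = 0
        for px, py in pts:
            in_tri = _point_in_polygon_evenodd(px, py, tri.vertices)
            in_pent = _point_in_polygon_evenodd(px, py, pent.vertices)
            if in_pent:
                oracle["Pent"] += 1  # 'Pent' sorts before 'Tri'
            elif in_tri:
                oracle["Tri"] += 1
            else:
                n_out += 1
        assert counts["Tri"] == oracle["Tri"]
        assert counts["Pent"] == oracle["Pent"]
        assert unassigned == n_out


class TestZeroing:
    def _table(self):
        return cf.CountTable(
            "rat1", raw=pd.Series({"MPtA": 40.0, "RSD": 10.0, "S1": 5.0})
        )

    def _inj(self, rois):
        return cf.InjectionSite(
            center=(0.0, 0.0), section_id="s", extent_um=100.0, covered_rois=rois
        )

    def test_single_roi_zeroed(self):
        out = cf.zero_injection_rois(self._table(), self._inj(("MPtA",)))
        assert out.zeroed["MPtA"] == 0
        assert out.zeroed["RSD"] == 10.0 and out.zeroed["S1"] == 5.0

    def test_straddling_injection_zeroes_both(self):
        out = cf.zero_injection_rois(self._table(), self._inj(("MPtA", "RSD")))
        assert out.zeroed["MPtA"] == 0 and out.zeroed["RSD"] == 0

    def test_idempotent(self):
        inj = self._inj(("MPtA",))
        once = cf.zero_injection_rois(self._table(), inj)
        twice = cf.zero_injection_rois(
            cf.CountTable("rat1", raw=once.zeroed), inj
        )
        pd.testing.assert_series_equal(once.zeroed, twice.zeroed)

    def test_unknown_roi_rejected(self):
        with pytest.raises(KeyError):
            cf.zero_injection_rois(self._table(), self._inj(("V1",)))

    def test_injection_covers_at_most_two(self):
        with pytest.raises(ValueError):
            self._inj(("A", "B", "C"))


class TestProportions:
    def test_basic(self):
        p = cf.counts_to_proportions(pd.Series([2.0, 3.0, 5.0]))
        np.testing.assert_allclose(p, [0.2, 0.3, 0.5])

    def test_single_nonzero(self):
        p = cf.counts_to_proportions(pd.Series({"A": 0.0, "B": 7.0}))
        assert p["A"] == 0.0 and p["B"] == 1.0

    def test_inverse_roundtrip(self):
        counts = pd.Series([4.0, 9.0, 1.0, 6.0])
        p = cf.counts_to_proportions(counts)
        np.testing.assert_allclose(p * counts.sum(), counts, atol=1e-9)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_is_explicit_error(self):
        with pytest.raises(ValueError):
            cf.counts_to_proportions(pd.Series([0.0, 0.0]))


class TestGroups:
    def test_member_sum(self):
        p = pd.Series({"RSD": 0.3, "RSG": 0.2, "S1": 0.5})
        g = cf.aggregate_groups(p, {"RSD": "medial", "RSG": "medial", "S1": "somatic"})
        assert g["medial"] == pytest.approx(0.5)
        assert g["somatic"] == pytest.approx(0.5)

    def test_partition_sums_to_one(self):
        rng = np.random.default_rng(5)
        rois = list(DEFAULT_CORTICAL_GROUPING)
        p = pd.Series(rng.dirichlet(np.ones(len(rois))), index=rois)
        g = cf.aggregate_groups(p, DEFAULT_CORTICAL_GROUPING)
        assert g.sum() == pytest.approx(1.0, abs=1e-9)
        assert set(g.index) == {"medial", "lateral", "somatic", "claustrum_entorhinal"}

    def test_thalamic_grouping_has_seven_levels(self):
        rois = list(DEFAULT_THALAMIC_GROUPING)
        p = pd.Series(np.ones(len(rois)) / len(rois), index=rois)
        g = cf.aggregate_groups(p, DEFAULT_THALAMIC_GROUPING)
        assert len(g) == 7  # motor, sensory, 3x associative, intralaminar, midline

    def test_unmapped_roi_listed(self):
        with pytest.raises(KeyError, match="Nowhere"):
            cf.aggregate_groups(pd.Series({"Nowhere": 1.0}), {})


class TestInjectionMetrics:
    def test_distance_and_classes(self, straight_line):
        inj = cf.InjectionSite(
            center=(50.0, 10.0),
            section_id="s",
            extent_um=100.0,
            covered_rois=("MPtA",),
            ap_estimate_mm=-4.0,
        )
        out = cf.injection_metrics(
            inj, straight_line, ml_boundary_um=40.0, rc_boundary_mm=-4.25
        )
        assert out.ml_distance_um == pytest.approx(50.0)
        assert out.ml_class == "lateral"
        assert out.rc_class == "rostral"

    def test_boundary_tie_is_medial(self, straight_line):
        inj = cf.InjectionSite(
            center=(40.0, 0.0), section_id="s", extent_um=10.0, covered_rois=("A",)
        )
        out = cf.injection_metrics(inj, straight_line, ml_boundary_um=40.0)
        assert out.ml_class == "medial"

    def test_planted_injection_distance_recovered(self, small_section):
        """Generator truth: the planted centre's arc distance matches the
        measured one within one pixel."""
        b = small_section
        inj = cf.InjectionSite(
            center=b.truth[0].true_center,
            section_id=b.section_id,
            extent_um=50.0,
            covered_rois=(b.truth[0].true_roi,),
        )
        out = cf.injection_metrics(inj, b.reference_line, ml_boundary_um=0.0)
        assert out.ml_distance_um == pytest.approx(
            b.truth[0].true_arc_um, abs=1.0 * b.reference_line.pixel_size + 1e-6
        )

    def test_missing_border_rejected(self):
        inj = cf.InjectionSite(
            center=(0.0, 0.0), section_id="s", extent_um=10.0, covered_rois=("A",)
        )
        with pytest.raises(ValueError):
            cf.injection_metrics(inj, None, ml_boundary_um=0.0)


class TestAnterograde:
    def _inj(self, rois=("PC",)):
        return cf.InjectionSite(
            center=(0.0, 0.0), section_id="s", extent_um=10.0, covered_rois=rois
        )

    def test_basic_proportions(self):
        p = cf.anterograde_proportions(
            pd.Series({"A": 100.0, "B": 300.0}), self._inj()
        )
        np.testing.assert_allclose(p, [0.25, 0.75])
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_injected_roi_out_of_denominator(self):
        p = cf.anterograde_proportions(
            pd.Series({"PC": 1000.0, "A": 100.0, "B": 300.0}), self._inj()
        )
        assert p["PC"] == 0.0
        np.testing.assert_allclose(p[["A", "B"]], [0.25, 0.75])

    def test_all_zero_after_zeroing_rejected(self):
        with pytest.raises(ValueError):
            cf.anterograde_proportions(pd.Series({"PC": 1000.0}), self._inj())


def test_manual_thalamic_counts_path(tmp_path):
    csv = tmp_path / "thal.csv"
    pd.DataFrame(
        {
            "roi": ["LD", "AV", "AV", "MD"],
            "count": [10, 4, 6, 5],
            "animal_id": ["r1"] * 4,
        }
    ).to_csv(csv, index=False)
    table = read_manual_counts(csv, animal_id="r1")
    assert table.raw["AV"] == 10
    props = cf.counts_to_proportions(table.raw)
    groups = cf.aggregate_groups(
        props, {"LD": "lateral_associative", "AV": "anterior_associative", "MD": "mediodorsal_associative"}
    )
    assert groups.sum() == pytest.approx(1.0)
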