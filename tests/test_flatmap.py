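"""Reference-line smoothing, arc projection, landmark frames, assembly."""

import numpy as np
import pandas as pd
import pytest

import cortexflat as cf
from cortexflat.flatmap import (
    ArcProjector,
    RunlineSmoother,
    resample_polyline,
)


def _wiggly_line(pixel_size=1.0, anchor=10):
    t = np.linspace(0, 4 * np.pi, 400)
    verts = np.column_stack([t * 30, 40 * np.sin(t)])
    return cf.ReferenceLine(verts, cingulum_anchor=anchor, pixel_size=pixel_size)


class TestReferenceLine:
    def test_validation(self):
        with pytest.raises(ValueError):
            cf.ReferenceLine(np.array([[0.0, 0.0]]), cingulum_anchor=0)
        with pytest.raises(ValueError):
            cf.ReferenceLine(
                np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]), cingulum_anchor=0
            )
        with pytest.raises(ValueError):
            cf.ReferenceLine(np.array([[0.0, 0.0], [1.0, 0.0]]), cingulum_anchor=5)
        with pytest.raises(ValueError):
            cf.ReferenceLine(np.array([[0.0, 0.0], [1.0, 0.0]]), cingulum_anchor=None)

    def test_json_roundtrip(self, straight_line):
        back = cf.ReferenceLine.from_dict(straight_line.to_dict())
        assert np.array_equal(back.vertices, straight_line.vertices)
        assert back.cingulum_anchor == straight_line.cingulum_anchor


class TestProjection:
    def test_forced_geometry(self, straight_line):
        arc, dist = cf.project_cell([30.0, 7.0], straight_line)
        assert arc == pytest.approx(30.0)
        assert dist == pytest.approx(7.0)

    def test_clamped_beyond_lateral_end(self, straight_line):
        arc, dist = cf.project_cell([120.0, 5.0], straight_line)
        assert arc == pytest.approx(100.0)
        assert dist == pytest.approx(np.hypot(20.0, 5.0))

    def test_negative_arc_medial_of_anchor(self):
        verts = np.column_stack([np.arange(0.0, 101.0), np.zeros(101)])
        line = cf.ReferenceLine(verts, cingulum_anchor=40, pixel_size=0.5)
        arc, _ = cf.project_cell([10.0, 3.0], line)
        assert arc == pytest.approx((10 - 40) * 0.5)

    def test_dense_resampling_oracle(self):
        """1000 random points agree with a brute-force nearest point on the
        line resampled at 0.01 px, within 0.05 px of arc length."""
        from scipy.spatial import cKDTree

        line = _wiggly_line()
        rng = np.random.default_rng(42)
        pts = np.column_stack(
            [rng.uniform(0, 370, 1000), rng.uniform(-60, 60, 1000)]
        )
        res = ArcProjector().fit(line).transform(pts)

        dense = resample_polyline(line.vertices, 0.01)
        arcs = np.concatenate(
            [[0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))]
        )
        anchor_arc = line.arc_lengths[line.cingulum_anchor]
        d, j = cKDTree(dense).query(pts)
        assert np.abs(res[:, 0] - (arcs[j] - anchor_arc)).max() < 0.05
        assert np.abs(res[:, 1] - d).max() < 0.05

    def test_rigid_transform_invariance(self):
        """Arc positions are unchanged by section rotation + translation."""
        line = _wiggly_line()
        rng = np.random.default_rng(1)
        pts = np.column_stack(
            [rng.uniform(0, 370, 200), rng.uniform(-60, 60, 200)]
        )
        base = ArcProjector().fit(line).transform(pts)
        th = np.deg2rad(30.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shift = np.array([55.0, -12.0])
        moved = cf.ReferenceLine(
            line.vertices @ R.T + shift,
            cingulum_anchor=line.cingulum_anchor,
            pixel_size=line.pixel_size,
        )
        res = ArcProjector().fit(moved).transform(pts @ R.T + shift)
        assert np.abs(res - base).max() < 1e-6

    def test_tie_breaks_toward_smaller_arc(self):
        # V-shaped line: apex equidistant points resolve to the first segment
        verts = np.array([[0.0, 0.0], [10.0, 10.0], [20.0, 0.0]])
        line = cf.ReferenceLine(verts, cingulum_anchor=0, pixel_size=1.0)
        arc, _ = cf.project_cell([10.0, 0.0], line)
        assert arc <= np.sqrt(200.0) / 2 + 1e-9


class TestSmoothing:
    def test_collinear_identity(self):
        col = np.column_stack([np.arange(50.0), 2 * np.arange(50.0)])
        line = cf.ReferenceLine(col, cingulum_anchor=0, pixel_size=1.0)
        sm = cf.smooth_reference_line(line)
        # a line fit of points on a line returns the line
        proj = ArcProjector().fit(line).transform(sm.vertices)
        assert np.abs(proj[:, 1]).max() < 1e-9
        assert abs(sm.total_length - line.total_length) < 1e-9

    def test_window_one_is_identity(self, straight_line):
        sm = RunlineSmoother(window=1, resample_spacing=None).transform(
            straight_line
        )
        assert np.allclose(sm.vertices, straight_line.vertices)

    def test_window_clamped_with_warning(self):
        verts = np.array([[0.0, 0.0], [1.0, 0.5], [2.0, 0.0]])
        line = cf.ReferenceLine(verts, cingulum_anchor=0, pixel_size=1.0)
        with pytest.warns(UserWarning, match="clamp"):
            RunlineSmoother(window=99, resample_spacing=None).transform(line)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            cf.SmoothingParams(window=4)
        with pytest.raises(ValueError):
            cf.SmoothingParams(step=0)

    def test_noise_reduction_over_seeds(self):
        """Smoothing a noisy boundary moves it closer to the noiseless curve
        and never lengthens it (20 seeds)."""
        t = np.linspace(0, 300, 301)
        clean = np.column_stack([t, 30 * np.sin(t / 40)])
        clean_line = cf.ReferenceLine(clean, cingulum_anchor=0, pixel_size=1.0)
        proj = ArcProjector().fit(clean_line)
        improved = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = clean + rng.normal(0, 1, clean.shape)
            line = cf.ReferenceLine(noisy, cingulum_anchor=0, pixel_size=1.0)
            sm = cf.smooth_reference_line(line)
            rms_raw = np.sqrt(np.mean(proj.transform(noisy)[:, 1] ** 2))
            rms_sm = np.sqrt(np.mean(proj.transform(sm.vertices)[:, 1] ** 2))
            assert sm.total_length <= line.total_length
            improved += rms_sm < rms_raw
        assert improved == 20

    def test_anchor_reattached_near_original_position(self):
        line = _wiggly_line(anchor=100)
        sm = cf.smooth_reference_line(line)
        orig = line.vertices[line.cingulum_anchor]
        new = sm.vertices[sm.cingulum_anchor]
        assert np.linalg.norm(orig - new) < 5.0


class TestLandmarks:
    def test_anchor_is_origin(self, straight_line):
        frame = cf.align_to_landmarks(straight_line)
        assert frame["cingulum"] == 0.0

    def test_rhinal_arc_position(self):
        verts = np.column_stack([np.arange(0.0, 10.0), np.zeros(10)])
        line = cf.ReferenceLine(
            verts, cingulum_anchor=0, rhinal_sulcus=3, pixel_size=0.23
        )
        frame = cf.align_to_landmarks(line)
        assert frame["rhinal_sulcus"] == pytest.approx(3 * 0.23)

    def test_rigid_transform_leaves_frame_unchanged(self):
        line = _wiggly_line(anchor=50)
        line = cf.ReferenceLine(
            line.vertices,
            cingulum_anchor=50,
            rhinal_sulcus=390,
            extra_marks={"V1_border": 200},
            pixel_size=0.23,
        )
        th = np.deg2rad(77.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = cf.ReferenceLine(
            line.vertices @ R.T + [3.0, -8.0],
            cingulum_anchor=50,
            rhinal_sulcus=390,
            extra_marks={"V1_border": 200},
            pixel_size=0.23,
        )
        a, b = cf.align_to_landmarks(line), cf.align_to_landmarks(moved)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-6)


class TestAssembly:
    def _sections(self, n):
        line = _wiggly_line()
        out = []
        for i in range(n):
            cells = pd.DataFrame(
                {
                    "x": [50.0 + i, 150.0],
                    "y": [5.0, -8.0],
                    "cell_id": [0, 1],
                    "tracer_role": ["tracer_red"] * 2,
                }
            )
            out.append((f"sec{i:03d}", 0.1 * i, line, cells))
        return out

    def test_rows_ordered_by_ap(self):
        secs = self._sections(4)
        flat = cf.assemble_flatmap(list(reversed(secs)))
        assert [r.section_id for r in flat.rows] == [s[0] for s in secs]

    def test_duplicate_ids_rejected(self):
        secs = self._sections(2)
        secs[1] = (secs[0][0], *secs[1][1:])
        with pytest.raises(ValueError):
            cf.assemble_flatmap(secs)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cf.assemble_flatmap([])

    def test_cells_match_projection_oracle(self):
        secs = self._sections(3)
        flat = cf.assemble_flatmap(secs)
        for row, (sid, ap, line, cells) in zip(flat.rows, secs):
            for cell, (_, src) in zip(row.cells, cells.iterrows()):
                arc, nd = cf.project_cell([src["x"], src["y"]], line)
                assert cell.arc_um == pytest.approx(arc)
                assert cell.normal_um == pytest.approx(nd)

    def test_brain_of_24_cut_sections_gives_4_rows(self, small_params):
        bundles, _ = cf.generate_brain(small_params, 24)
        secs = []
        for b in bundles:
            if not b.mapped:
                continue
            cells = pd.DataFrame(
                {
                    "x": [c.true_center[0] for c in b.truth if c.true_positive],
                    "y": [c.true_center[1] for c in b.truth if c.true_positive],
                    "cell_id": [c.cell_id for c in b.truth if c.true_positive],
                    "tracer_role": "tracer_red",
                }
            )
            secs.append((b.section_id, b.ap_position, b.reference_line, cells))
        flat = cf.assemble_flatmap(secs)
        assert len(flat.rows) == 4
        assert flat.to_frame().shape[0] == sum(
            sum(c.true_positive for c in b.truth) for b in bundles if b.mapped
        )

    def test_injection_marked_and_render(self, tmp_path):
        secs = self._sections(2)

        class _Inj:
            section_id = "sec001"
            center = (100.0, 10.0)

        flat = cf.assemble_flatmap(secs, injection=_Inj())
        assert flat.injection_mark is not None
        assert flat.injection_mark[0] == "sec001"
        from cortexflat.flatmap import render_flatmap

        out = tmp_path / "fm.png"
        render_flatmap(flat, str(out))
        assert out.stat().st_size > 0
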