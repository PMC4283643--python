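"""Cortical flat-map geometry.

Sections are "unrolled" by projecting every tracer-positive neuron onto a
reference polyline drawn through the layer IV/V boundary.  The polyline is
smoothed with a moving-window line regression (the classical ``runline``
filter), anchored at the lateral cingulum border (arc position 0) with the
rhinal sulcus as a lateral landmark, and each section becomes one row of a
2D map keyed by its anterior-posterior position.

Coordinates are 0-based pixel indices (x rightward, y downward); arc
positions are reported in micrometres, signed negative medial of the
cingulum anchor and positive lateral (toward the rhinal sulcus).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "ReferenceLine",
    "SmoothingParams",
    "FlatCell",
    "FlatMapRow",
    "FlatMap",
    "RunlineSmoother",
    "ArcProjector",
    "resample_polyline",
    "smooth_reference_line",
    "project_cell",
    "align_to_landmarks",
    "assemble_flatmap",
    "render_flatmap",
]


# ---------------------------------------------------------------------------
# data types


@dataclass
class ReferenceLine:
    """Ordered polyline through the layer IV/V boundary of one section.

    Parameters
    ----------
    vertices : (N, 2) array of float
        Ordered vertex coordinates ``(x, y)`` in pixels, running medial to
        lateral.
    cingulum_anchor : int
        Index of the vertex at the lateral border of the cingulate cortex;
        defines arc position 0.
    rhinal_sulcus : int, optional
        Index of the vertex marking the rhinal sulcus (lateral landmark).
    extra_marks : dict of str to int
        Additional named landmark vertices (e.g. V1 borders).
    pixel_size : float
        Micrometres per pixel (0.23 for 40x whole-slide acquisition).
    """

    vertices: np.ndarray
    cingulum_anchor: int
    rhinal_sulcus: int | None = None
    extra_marks: dict[str, int] = field(default_factory=dict)
    pixel_size: float = 0.23

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("reference line needs at least 2 (x, y) vertices")
        if np.any(np.all(np.diff(v, axis=0) == 0.0, axis=1)):
            raise ValueError("consecutive vertices must be distinct")
        if self.cingulum_anchor is None:
            raise ValueError("cingulum anchor is required (arc origin)")
        object.__setattr__(self, "vertices", v)
        n = len(v)
        for name, idx in self._landmark_items():
            if not (0 <= idx < n):
                raise ValueError(f"landmark {name!r} index {idx} out of range")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def _landmark_items(self) -> list[tuple[str, int]]:
        items = [("cingulum", self.cingulum_anchor)]
        if self.rhinal_sulcus is not None:
            items.append(("rhinal_sulcus", self.rhinal_sulcus))
        items.extend(self.extra_marks.items())
        return items

    @property
    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length (pixels) at each vertex."""
        return _cumulative_arc(self.vertices)

    @property
    def total_length(self) -> float:
        """Total polyline length in pixels."""
        return float(self.arc_lengths[-1])

    def to_dict(self) -> dict:
        return {
            "vertices": self.vertices.tolist(),
            "cingulum_anchor": int(self.cingulum_anchor),
            "rhinal_sulcus": None
            if self.rhinal_sulcus is None
            else int(self.rhinal_sulcus),
            "extra_marks": {k: int(v) for k, v in self.extra_marks.items()},
            "pixel_size": float(self.pixel_size),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceLine":
        return cls(
            vertices=np.asarray(d["vertices"], dtype=float),
            cingulum_anchor=int(d["cingulum_anchor"]),
            rhinal_sulcus=None
            if d.get("rhinal_sulcus") is None
            else int(d["rhinal_sulcus"]),
            extra_marks={k: int(v) for k, v in d.get("extra_marks", {}).items()},
            pixel_size=float(d.get("pixel_size", 0.23)),
        )


@dataclass(frozen=True)
class SmoothingParams:
    """Runline parameters: window and step are in resampled pixels."""

    window: int = 5
    step: int = 1

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass(frozen=True)
class FlatCell:
    """One tracer-positive neuron placed on the flat map."""

    section_id: str
    cell_id: int
    arc_um: float
    normal_um: float
    tracer_role: str
    in_injection_roi: bool = False


@dataclass
class FlatMapRow:
    section_id: str
    ap_position: float
    landmarks: dict[str, float]
    cells: list[FlatCell]


@dataclass
class FlatMap:
    """Whole-brain flat map: one row per mapped section, rostral to caudal."""

    rows: list[FlatMapRow]
    injection_mark: tuple[str, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            for c in row.cells:
                recs.append(
                    {
                        "section_id": row.section_id,
                        "ap_position": row.ap_position,
                        "arc_um": c.arc_um,
                        "normal_um": c.normal_um,
                        "tracer_role": c.tracer_role,
                        "cell_id": c.cell_id,
                        "in_injection_roi": c.in_injection_roi,
                    }
                )
        cols = [
            "section_id",
            "ap_position",
            "arc_um",
            "normal_um",
            "tracer_role",
            "cell_id",
            "in_injection_roi",
        ]
        return pd.DataFrame(recs, columns=cols)


# ---------------------------------------------------------------------------
# polyline helpers


def _cumulative_arc(vertices: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(vertices: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Resample a polyline to (approximately) uniform arc spacing.

    The first and last vertices are preserved exactly; interior samples are
    linear interpolations along the original segments.
    """
    vertices = np.asarray(vertices, dtype=float)
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    arc = _cumulative_arc(vertices)
    total = arc[-1]
    if total == 0:
        raise ValueError("degenerate zero-length polyline")
    n = max(int(np.round(total / spacing)), 1)
    samples = np.linspace(0.0, total, n + 1)
    x = np.interp(samples, arc, vertices[:, 0])
    y = np.interp(samples, arc, vertices[:, 1])
    return np.column_stack([x, y])


def _nearest_vertex_by_arc(arc_positions: np.ndarray, target_arc: float) -> int:
    return int(np.argmin(np.abs(arc_positions - target_arc)))


# ---------------------------------------------------------------------------
# runline smoothing


class RunlineSmoother(BaseEstimator):
    """Moving-window line-regression smoother for reference polylines.

    The line is first resampled to uniform ``resample_spacing`` arc spacing
    (so the window has a fixed metric footprint: 5 px = 1.15 um at
    0.23 um/px), then each output vertex is the centre-point evaluation of
    an ordinary least-squares line fitted to the ``window`` vertices centred
    on it.  Windows shrink one-sidedly at the endpoints.  Landmarks are
    re-attached to the nearest smoothed vertex by arc position.

    Parameters
    ----------
    window : int
        Window size in (resampled) pixels; odd, >= 1.  ``window=1`` is the
        identity transform.
    step : int
        Evaluation stride in pixels.
    resample_spacing : float or None
        Uniform arc spacing before smoothing; ``None`` skips resampling.
    """

    def __init__(
        self,
        window: int = 5,
        step: int = 1,
        resample_spacing: float | None = 1.0,
    ) -> None:
        self.window = window
        self.step = step
        self.resample_spacing = resample_spacing

    def transform(self, line: ReferenceLine) -> ReferenceLine:
        params = SmoothingParams(window=self.window, step=self.step)
        old_arc = line.arc_lengths
        landmark_arcs = {name: old_arc[idx] for name, idx in line._landmark_items()}

        if self.resample_spacing is not None:
            verts = resample_polyline(line.vertices, self.resample_spacing)
        else:
            verts = line.vertices.copy()
        n = len(verts)

        window = params.window
        if window > n:
            warnings.warn(
                f"smoothing window {window} exceeds vertex count {n}; clamping",
                stacklevel=2,
            )
            window = n if n % 2 == 1 else n - 1
            window = max(window, 1)

        half = window // 2
        centers = np.arange(0, n, params.step)
        if centers[-1] != n - 1:
            centers = np.append(centers, n - 1)
        out = np.empty((len(centers), 2))
        idx_all = np.arange(n)
        for k, i in enumerate(centers):
            lo = max(0, i - half)
            hi = min(n, i + half + 1)
            t = idx_all[lo:hi].astype(float)
            if hi - lo < 2:
                out[k] = verts[i]
                continue
            tc = t - t.mean()
            denom = np.dot(tc, tc)
            seg = verts[lo:hi]
            mean = seg.mean(axis=0)
            slope = (tc[:, None] * (seg - mean)).sum(axis=0) / denom
            out[k] = mean + slope * (i - t.mean())

        # drop accidental duplicate consecutive vertices introduced by heavy
        # smoothing of tight folds
        keep = np.concatenate([[True], np.any(np.diff(out, axis=0) != 0.0, axis=1)])
        out = out[keep]

        new_arc = _cumulative_arc(out)
        scale = new_arc[-1] / old_arc[-1] if old_arc[-1] > 0 else 1.0

        def reattach(arc_value: float) -> int:
            return _nearest_vertex_by_arc(new_arc, arc_value * scale)

        return ReferenceLine(
            vertices=out,
            cingulum_anchor=reattach(landmark_arcs["cingulum"]),
            rhinal_sulcus=None
            if line.rhinal_sulcus is None
            else reattach(landmark_arcs["rhinal_sulcus"]),
            extra_marks={
                k: reattach(landmark_arcs[k]) for k in line.extra_marks
            },
            pixel_size=line.pixel_size,
        )


def smooth_reference_line(
    line: ReferenceLine, params: SmoothingParams | None = None
) -> ReferenceLine:
    """Smooth a reference line with the runline moving-window regression."""
    params = params or SmoothingParams()
    return RunlineSmoother(window=params.window, step=params.step).transform(line)


# ---------------------------------------------------------------------------
# arc-length projection


class ArcProjector(BaseEstimator):
    """Project points onto a reference line, returning signed arc positions.

    ``fit`` precomputes segment geometry; ``transform`` maps an ``(M, 2)``
    array of pixel coordinates to an ``(M, 2)`` array of
    ``(arc_um, normal_um)``: the signed arc length from the cingulum anchor
    to the nearest point on the polyline (orthogonal projection clamped to
    segment ends, ties broken toward the smaller arc position) and the
    Euclidean distance to that point.  Projections beyond the line ends are
    clamped, never extrapolated.
    """

    def fit(self, line: ReferenceLine) -> "ArcProjector":
        verts = line.vertices
        arc = _cumulative_arc(verts)
        if arc[-1] == 0:
            raise ValueError("degenerate zero-length reference line")
        d = np.diff(verts, axis=0)
        seg_len = np.linalg.norm(d, axis=1)
        ok = seg_len > 0
        self.line_ = line
        self.seg_start_ = verts[:-1][ok]
        self.seg_vec_ = d[ok]
        self.seg_len_ = seg_len[ok]
        self.seg_arc0_ = arc[:-1][ok]
        self.anchor_arc_ = float(arc[line.cingulum_anchor])
        return self

    def transform(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        A = self.seg_start_
        D = self.seg_vec_
        L = self.seg_len_
        # per-point, per-segment clamped projection parameter
        t = np.einsum("mij,ij->mi", pts[:, None, :] - A[None, :, :], D) / (L * L)
        t = np.clip(t, 0.0, 1.0)
        proj = A[None, :, :] + t[:, :, None] * D[None, :, :]
        diff = pts[:, None, :] - proj
        dist2 = np.einsum("mij,mij->mi", diff, diff)
        j = np.argmin(dist2, axis=1)  # first minimum = smaller arc on ties
        m = np.arange(len(pts))
        arc_px = self.seg_arc0_[j] + t[m, j] * L[j] - self.anchor_arc_
        dist_px = np.sqrt(dist2[m, j])
        um = self.line_.pixel_size
        return np.column_stack([arc_px * um, dist_px * um])


def project_cell(
    point: np.ndarray, line: ReferenceLine
) -> tuple[float, float]:
    """Project one point; returns ``(arc_um, normal_um)``."""
    out = ArcProjector().fit(line).transform(np.asarray(point, dtype=float))
    return float(out[0, 0]), float(out[0, 1])


def align_to_landmarks(line: ReferenceLine) -> dict[str, float]:
    """Arc coordinate frame of a section: landmark name -> arc position (um).

    The cingulum anchor defines arc 0; the rhinal sulcus and any extra marks
    are reported in the same frame.  The frame depends only on arc lengths,
    so rigid transforms of the section leave it unchanged.
    """
    if line.cingulum_anchor is None:
        raise ValueError("cingulum anchor is required to align a section")
    arc = line.arc_lengths
    anchor = arc[line.cingulum_anchor]
    frame = {
        name: float((arc[idx] - anchor) * line.pixel_size)
        for name, idx in line._landmark_items()
    }
    return frame


# ---------------------------------------------------------------------------
# assembly


def assemble_flatmap(
    sections: list[tuple[str, float, ReferenceLine, pd.DataFrame]],
    injection=None,
) -> FlatMap:
    """Assemble per-section projections into a whole-brain flat map.

    Parameters
    ----------
    sections : list of (section_id, ap_position, line, cells)
        ``cells`` is a DataFrame with columns ``x``, ``y``, ``cell_id``,
        ``tracer_role`` and optionally ``in_injection_roi``.  Cells flagged
        ``in_injection_roi`` are kept out of quantification but rendered
        distinctly.
    injection : object, optional
        Anything with ``section_id`` and ``center`` attributes; its centre
        is projected and marked on its own section's row.
    """
    if not sections:
        raise ValueError("at least one mapped section is required")
    ids = [s[0] for s in sections]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate section ids in flat-map assembly")

    rows = []
    injection_mark = None
    for section_id, ap, line, cells in sections:
        projector = ArcProjector().fit(line)
        landmarks = align_to_landmarks(line)
        flat_cells: list[FlatCell] = []
        if len(cells):
            arcs = projector.transform(cells[["x", "y"]].to_numpy(dtype=float))
            inj_flags = (
                cells["in_injection_roi"].to_numpy(dtype=bool)
                if "in_injection_roi" in cells
                else np.zeros(len(cells), dtype=bool)
            )
            for (_, cell), (a, nd), flag in zip(cells.iterrows(), arcs, inj_flags):
                flat_cells.append(
                    FlatCell(
                        section_id=section_id,
                        cell_id=int(cell["cell_id"]),
                        arc_um=float(a),
                        normal_um=float(nd),
                        tracer_role=str(cell.get("tracer_role", "tracer_red")),
                        in_injection_roi=bool(flag),
                    )
                )
        rows.append(FlatMapRow(section_id, float(ap), landmarks, flat_cells))
        if injection is not None and getattr(injection, "section_id", None) == section_id:
            arc_um, _ = project_cell(np.asarray(injection.center, float), line)
            injection_mark = (section_id, arc_um)

    rows.sort(key=lambda r: r.ap_position)
    return FlatMap(rows=rows, injection_mark=injection_mark)


def render_flatmap(flat_map: FlatMap, path: str) -> None:
    """Render a flat map (one row per section) to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 6))
    for row in flat_map.rows:
        y = row.ap_position
        quant = [c for c in row.cells if not c.in_injection_roi]
        excl = [c for c in row.cells if c.in_injection_roi]
        if quant:
            ax.scatter(
                [c.arc_um for c in quant], [y] * len(quant),
                s=4, c="green", linewidths=0, label=None,
            )
        if excl:
            ax.scatter(
                [c.arc_um for c in excl], [y] * len(excl),
                s=10, c="darkblue", alpha=0.5, linewidths=0,
            )
        ax.scatter([row.landmarks.get("cingulum", 0.0)], [y], s=24, c="blue")
        if "rhinal_sulcus" in row.landmarks:
            ax.scatter([row.landmarks["rhinal_sulcus"]], [y], s=24, c="red")
    if flat_map.injection_mark is not None:
        sec, arc = flat_map.injection_mark
        y = next(r.ap_position for r in flat_map.rows if r.section_id == sec)
        ax.scatter([arc], [y], s=160, c="orange", alpha=0.6, zorder=0)
    ax.set_xlabel("arc position from cingulum border (µm)")
    ax.set_ylabel("A-P position (mm)")
    ax.set_title("Cortical flat map of tracer-positive neurons")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
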