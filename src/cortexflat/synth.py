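"""Synthetic section images with known ground truth.

Emulates NeuN-stained coronal sections of a rat brain carrying a
retrograde tracer injection: a curved cortical ribbon holds Gaussian-
profile somata, a subset of which also carry tracer-channel signal; the
layer IV/V boundary is the reference polyline with a cingulum-border
anchor and rhinal-sulcus landmark, and the ribbon is partitioned into
named ROI polygons by arc-length breakpoints.  Every quantity a downstream
stage recovers (cell centres, per-channel integrated intensities, ROI
membership, arc positions, the injection site) is recorded as ground
truth, making the whole pipeline testable without real data.

Channel order is fixed as (neun, tracer_red, tracer_yellow); rasters are
8-bit per channel (0-255) and, matching 40x whole-slide acquisition, the
default pixel size is 0.23 um.  Somata are painted as isotropic Gaussians
clipped at the cell radius, additive with saturation at 255; the NeuN
profile is wider (sigma = r/1.8) than the tracer profile (sigma = r/3) so
a soma's segmented footprint captures essentially all of its tracer mass.
Intensity ranges default to values that straddle the tracer-positive
classification rule (integrated > 250,000 and max pixel > 150) with a
comfortable margin on both sides; see docs/methods.md for the reasoning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flatmap import ReferenceLine, _cumulative_arc, resample_polyline
from .roi import InjectionSite, ROIPolygon

__all__ = [
    "SynthParams",
    "GroundTruthCell",
    "SectionBundle",
    "PlacementError",
    "generate_section",
    "generate_brain",
    "generate_count_fixture",
    "generate_cohort_proportions",
    "truth_to_frame",
]

CHANNEL_ROLES = {"neun": 0, "tracer_red": 1, "tracer_yellow": 2}

_DEFAULT_CONTROL_POINTS = (
    (400.0, 300.0),
    (1500.0, 400.0),
    (2600.0, 800.0),
    (3400.0, 1500.0),
    (3700.0, 2300.0),
)

_DEFAULT_ROI_NAMES = ("Cg1", "RSG", "RSD", "MPtA", "LPtA", "V2MM", "V2ML", "S1")


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place all requested cells."""


@dataclass(frozen=True)
class SynthParams:
    """Conditions for one synthetic section (and, via series, a brain)."""

    image_width: int = 4000
    image_height: int = 2600
    pixel_size: float = 0.23  # um per pixel at 40x
    n_cells: int = 80
    n_tracer_positive: int = 60
    cell_radius_range: tuple[float, float] = (45.0, 54.0)  # px
    min_separation: float = 120.0  # px, > 2 x max radius
    neun_intensity_range: tuple[float, float] = (150.0, 230.0)
    tracer_intensity_range_positive: tuple[float, float] = (215.0, 250.0)
    tracer_intensity_range_negative: tuple[float, float] = (20.0, 60.0)
    background_noise_sd: float = 5.0
    ribbon_control_points: tuple[tuple[float, float], ...] = _DEFAULT_CONTROL_POINTS
    ribbon_halfwidth: float = 300.0  # px
    anchor_arc_um: float = 80.0  # cingulum anchor, arc from medial end
    rhinal_arc_um: float | None = None  # default: near the lateral end
    roi_arc_breakpoints: tuple[float, ...] | None = None  # um, relative to anchor
    roi_names: tuple[str, ...] = _DEFAULT_ROI_NAMES
    injection_center: tuple[float, float] | None = None  # default: mid-MPtA
    injection_extent_um: float = 70.0
    tracer_role: str = "tracer_red"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracer_positive > self.n_cells:
            raise ValueError("n_tracer_positive must be <= n_cells")
        if self.n_cells < 0 or self.n_tracer_positive < 0:
            raise ValueError("cell counts must be non-negative")
        lo, hi = self.cell_radius_range
        if not (0 < lo <= hi):
            raise ValueError("invalid cell_radius_range")
        if self.n_cells > 1 and self.min_separation <= 2 * hi:
            raise ValueError("min_separation must exceed 2 x max cell radius")
        for rng in (
            self.neun_intensity_range,
            self.tracer_intensity_range_positive,
            self.tracer_intensity_range_negative,
        ):
            if not (0 <= rng[0] <= rng[1] <= 255):
                raise ValueError("intensity ranges must lie within 0-255")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")
        if len(self.ribbon_control_points) < 2:
            raise ValueError("need >= 2 ribbon control points")


@dataclass(frozen=True)
class GroundTruthCell:
    cell_id: int
    true_center: tuple[float, float]  # (x, y) px
    true_positive: bool
    true_integrated: dict[str, float]  # channel role -> painted sum
    true_max: dict[str, float]
    true_roi: str | None
    true_arc_um: float  # relative to cingulum anchor
    radius: float


@dataclass
class SectionBundle:
    """One synthetic section: raster, geometry, ROIs and ground truth."""

    image: np.ndarray | None  # (H, W, 3) uint8, channels (neun, red, yellow)
    reference_line: ReferenceLine
    rois: list[ROIPolygon]
    truth: list[GroundTruthCell]
    section_order_index: int
    ap_position: float  # mm-from-bregma analogue
    section_id: str = "sec000"
    mapped: bool = True
    channel_roles: dict[str, int] = field(default_factory=lambda: dict(CHANNEL_ROLES))
    injection: InjectionSite | None = None


# ---------------------------------------------------------------------------
# ribbon geometry


def _ribbon_curve(params: SynthParams) -> tuple[np.ndarray, np.ndarray]:
    """Smooth ribbon centreline resampled at ~2 px; returns (vertices, arcs)."""
    from scipy.interpolate import splev, splprep

    cp = np.asarray(params.ribbon_control_points, dtype=float)
    if len(cp) >= 4:
        tck, _ = splprep([cp[:, 0], cp[:, 1]], s=0.0, k=3)
        u = np.linspace(0.0, 1.0, 4096)
        dense = np.column_stack(splev(u, tck))
    else:
        dense = cp
    verts = resample_polyline(dense, spacing=2.0)
    return verts, _cumulative_arc(verts)


def _curve_interpolators(verts: np.ndarray, arcs: np.ndarray):
    """Position and unit-normal lookups by arc length (px)."""

    def position(s: np.ndarray) -> np.ndarray:
        x = np.interp(s, arcs, verts[:, 0])
        y = np.interp(s, arcs, verts[:, 1])
        return np.column_stack([x, y])

    tang = np.gradient(verts, arcs, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])

    def normal_at(s: np.ndarray) -> np.ndarray:
        nx = np.interp(s, arcs, normal[:, 0])
        ny = np.interp(s, arcs, normal[:, 1])
        n = np.column_stack([nx, ny])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    return position, normal_at


def _default_breakpoints(params: SynthParams, total_um: float, anchor_um: float):
    """Partition the full ribbon evenly into len(roi_names) ROIs."""
    n = len(params.roi_names)
    edges = np.linspace(-anchor_um, total_um - anchor_um, n + 1)
    return tuple(edges)


def _build_rois(
    params: SynthParams,
    section_id: str,
    position,
    normal_at,
    breakpoints_um: np.ndarray,
    anchor_arc_px: float,
) -> list[ROIPolygon]:
    rois = []
    w = params.ribbon_halfwidth
    for name, lo_um, hi_um in zip(
        params.roi_names, breakpoints_um[:-1], breakpoints_um[1:]
    ):
        lo = anchor_arc_px + lo_um / params.pixel_size
        hi = anchor_arc_px + hi_um / params.pixel_size
        s = np.linspace(lo, hi, max(int((hi - lo) / 10), 4))
        p = position(s)
        n = normal_at(s)
        ring = np.vstack([p + w * n, (p - w * n)[::-1]])
        rois.append(
            ROIPolygon(name=name, section_id=section_id, vertices=ring)
        )
    return rois


# ---------------------------------------------------------------------------
# painting


def _paint_cell(
    img: np.ndarray,
    center: tuple[float, float],
    radius: float,
    amplitudes: dict[int, tuple[float, float]],
) -> tuple[dict[int, float], dict[int, float]]:
    """Add per-channel radial profiles at ``center``; returns painted sums/maxima.

    ``amplitudes`` maps channel index -> (peak, sigma).  Profiles are
    isotropic Gaussians evaluated on the pixel grid and clipped at
    ``radius``; sums are the brute-force totals of the painted footprint
    before noise or saturation.
    """
    h, w = img.shape[:2]
    cx, cy = center
    x0, x1 = int(np.floor(cx - radius)), int(np.ceil(cx + radius)) + 1
    y0, y1 = int(np.floor(cy - radius)), int(np.ceil(cy + radius)) + 1
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    footprint = d2 <= radius**2
    sums: dict[int, float] = {}
    maxima: dict[int, float] = {}
    for ch, (peak, sigma) in amplitudes.items():
        prof = peak * np.exp(-d2 / (2.0 * sigma**2))
        prof[~footprint] = 0.0
        img[y0:y1, x0:x1, ch] += prof
        sums[ch] = float(prof.sum())
        maxima[ch] = float(prof.max()) if prof.size else 0.0
    return sums, maxima


def _place_cells(
    params: SynthParams,
    rng: np.random.Generator,
    arcs_px: tuple[float, float],
    position,
    normal_at,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rejection-sample cell centres on the ribbon; returns (centers, s, radii)."""
    n = params.n_cells
    radii = rng.uniform(*params.cell_radius_range, size=n)
    centers = np.empty((n, 2))
    arc_samples = np.empty(n)
    lo, hi = arcs_px
    for i in range(n):
        r = radii[i]
        placed = False
        for _ in range(1000):
            s = rng.uniform(lo + r, hi - r)
            vmax = params.ribbon_halfwidth - r - 5.0
            v = rng.uniform(-vmax, vmax)
            c = position(np.array([s]))[0] + v * normal_at(np.array([s]))[0]
            if not (
                r <= c[0] < params.image_width - r
                and r <= c[1] < params.image_height - r
            ):
                continue
            if i and np.min(np.linalg.norm(centers[:i] - c, axis=1)) < params.min_separation:
                continue
            centers[i], arc_samples[i] = c, s
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {i + 1}/{n} at min_separation="
                f"{params.min_separation} after 1000 retries"
            )
    return centers, arc_samples, radii


# ---------------------------------------------------------------------------
# public generators


def generate_section(
    params: SynthParams,
    section_order_index: int = 0,
    ap_position: float = 0.0,
    rng: np.random.Generator | None = None,
    section_id: str | None = None,
    render: bool = True,
    with_injection: bool = False,
) -> SectionBundle:
    """Generate one synthetic section with full ground truth.

    Deterministic for a fixed seed: ``rng`` defaults to
    ``np.random.default_rng(params.seed)``.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    section_id = section_id or f"sec{section_order_index:03d}"

    verts, arcs = _ribbon_curve(params)
    position, normal_at = _curve_interpolators(verts, arcs)
    total_px = arcs[-1]
    anchor_arc_px = params.anchor_arc_um / params.pixel_size
    anchor_idx = int(np.argmin(np.abs(arcs - anchor_arc_px)))
    rhinal_um = (
        params.rhinal_arc_um
        if params.rhinal_arc_um is not None
        else (total_px - anchor_arc_px - 20.0) * params.pixel_size
    )
    rhinal_idx = int(
        np.argmin(np.abs(arcs - (anchor_arc_px + rhinal_um / params.pixel_size)))
    )
    line = ReferenceLine(
        vertices=verts,
        cingulum_anchor=anchor_idx,
        rhinal_sulcus=rhinal_idx,
        pixel_size=params.pixel_size,
    )

    if params.roi_arc_breakpoints is not None:
        breakpoints = np.asarray(params.roi_arc_breakpoints, dtype=float)
        if len(breakpoints) != len(params.roi_names) + 1:
            raise ValueError("need len(roi_names)+1 arc breakpoints")
    else:
        breakpoints = np.asarray(
            _default_breakpoints(params, total_px * params.pixel_size, params.anchor_arc_um)
        )
    rois = _build_rois(params, section_id, position, normal_at, breakpoints, anchor_arc_px)

    injection = None
    inj_center = params.injection_center
    if inj_center is None:
        # centre of the 4th ROI (defaults: MPtA) on the ribbon centreline
        k = min(3, len(params.roi_names) - 1)
        mid_um = 0.5 * (breakpoints[k] + breakpoints[k + 1])
        inj_center = tuple(
            position(np.array([anchor_arc_px + mid_um / params.pixel_size]))[0]
        )
    if with_injection:
        # which ROI holds the centre, by arc position
        from .flatmap import project_cell

        arc_um, _ = project_cell(np.asarray(inj_center), line)
        k = int(np.clip(np.searchsorted(breakpoints, arc_um) - 1, 0, len(params.roi_names) - 1))
        injection = InjectionSite(
            center=tuple(map(float, inj_center)),
            section_id=section_id,
            extent_um=params.injection_extent_um,
            covered_rois=(params.roi_names[k],),
            ap_estimate_mm=ap_position,
        )

    image: np.ndarray | None = None
    truth: list[GroundTruthCell] = []
    role_to_ch = CHANNEL_ROLES
    tracer_ch = role_to_ch[params.tracer_role]

    canvas = (
        np.zeros((params.image_height, params.image_width, 3), dtype=float)
        if render
        else None
    )

    if params.n_cells > 0:
        centers, arc_samples, radii = _place_cells(
            params, rng, (arcs[0], arcs[-1]), position, normal_at
        )
        neun_amp = rng.uniform(*params.neun_intensity_range, size=params.n_cells)
        pos_flags = np.zeros(params.n_cells, dtype=bool)
        pos_flags[: params.n_tracer_positive] = True
        tracer_amp = np.where(
            pos_flags,
            rng.uniform(*params.tracer_intensity_range_positive, size=params.n_cells),
            rng.uniform(*params.tracer_intensity_range_negative, size=params.n_cells),
        )
        for i in range(params.n_cells):
            r = radii[i]
            amps = {
                role_to_ch["neun"]: (neun_amp[i], r / 1.8),
                tracer_ch: (tracer_amp[i], r / 3.0),
            }
            if canvas is not None:
                sums, maxima = _paint_cell(canvas, centers[i], r, amps)
            else:
                sums, maxima = _analytic_sums(centers[i], r, amps)
            integ = {role: 0.0 for role in role_to_ch}
            mx = {role: 0.0 for role in role_to_ch}
            for role, ch in role_to_ch.items():
                if ch in sums:
                    integ[role], mx[role] = sums[ch], maxima[ch]
            arc_um = (arc_samples[i] - anchor_arc_px) * params.pixel_size
            k = int(np.clip(np.searchsorted(breakpoints, arc_um) - 1, 0, len(params.roi_names) - 1))
            truth.append(
                GroundTruthCell(
                    cell_id=i,
                    true_center=(float(centers[i, 0]), float(centers[i, 1])),
                    true_positive=bool(pos_flags[i]),
                    true_integrated=integ,
                    true_max=mx,
                    true_roi=params.roi_names[k],
                    true_arc_um=float(arc_um),
                    radius=float(r),
                )
            )

    if canvas is not None:
        if injection is not None:
            # overexposed deposit in the tracer channel at the centre
            _paint_cell(
                canvas,
                injection.center,
                params.injection_extent_um / params.pixel_size / 2.0,
                {tracer_ch: (180.0, params.injection_extent_um / params.pixel_size / 4.0)},
            )
        if params.background_noise_sd > 0:
            canvas += rng.normal(0.0, params.background_noise_sd, canvas.shape)
        image = np.clip(np.round(canvas), 0, 255).astype(np.uint8)

    return SectionBundle(
        image=image,
        reference_line=line,
        rois=rois,
        truth=truth,
        section_order_index=section_order_index,
        ap_position=ap_position,
        section_id=section_id,
        injection=injection,
    )


def _analytic_sums(center, radius, amplitudes):
    """Painted sums/maxima without a canvas (render=False path)."""
    cx, cy = center
    x0, x1 = int(np.floor(cx - radius)), int(np.ceil(cx + radius)) + 1
    y0, y1 = int(np.floor(cy - radius)), int(np.ceil(cy + radius)) + 1
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    footprint = d2 <= radius**2
    sums, maxima = {}, {}
    for ch, (peak, sigma) in amplitudes.items():
        prof = peak * np.exp(-d2 / (2.0 * sigma**2))
        prof[~footprint] = 0.0
        sums[ch] = float(prof.sum())
        maxima[ch] = float(prof.max()) if prof.size else 0.0
    return sums, maxima


def generate_brain(
    params: SynthParams,
    n_cut_sections: int,
    render_unmapped: bool = False,
) -> tuple[list[SectionBundle], dict]:
    """Generate the NeuN series of a synthetic brain with 1-in-6 mapping.

    Sections are cut at a 50 um analogue spacing and collected in 3
    parallel series; the NeuN series is every 3rd cut section, and a flat
    map is made for every other NeuN section, i.e. exactly 1/6 of the cut
    sections are mapped.  ``ap_position`` increases monotonically with the
    cut index (0.05 mm per section).

    Returns the NeuN-series bundles and a sampling mask dict with keys
    ``n_cut_sections``, ``neun_series`` and ``mapped`` (cut indices).
    """
    if n_cut_sections < 6:
        raise ValueError("need at least 6 cut sections for 3 series x 1/2 mapping")
    if n_cut_sections % 6 != 0:
        raise ValueError("n_cut_sections must be divisible by 6 for exact 1/6 sampling")

    neun_idx = list(range(0, n_cut_sections, 3))
    mapped_idx = set(neun_idx[::2])
    injection_cut = sorted(mapped_idx)[len(mapped_idx) // 2]

    bundles = []
    for cut in neun_idx:
        mapped = cut in mapped_idx
        rng = np.random.default_rng([int(params.seed) % (2**31), cut])
        bundle = generate_section(
            params,
            section_order_index=cut,
            ap_position=0.05 * cut,
            rng=rng,
            section_id=f"sec{cut:03d}",
            render=mapped or render_unmapped,
            with_injection=(cut == injection_cut),
        )
        bundle.mapped = mapped
        bundles.append(bundle)

    mask = {
        "n_cut_sections": int(n_cut_sections),
        "neun_series": neun_idx,
        "mapped": sorted(mapped_idx),
        "mapped_fraction": len(mapped_idx) / n_cut_sections,
    }
    return bundles, mask


def generate_count_fixture(
    true_counts,
    offset: float,
    noise_sd: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired (manual, automated) ROI counts with a planted undercount.

    Manual counts equal the true counts; automated counts are
    ``max(0, true - offset + noise)``, so a manual-on-automated regression
    recovers the planted offset as an x-intercept of ``-offset``.
    """
    true_counts = np.asarray(true_counts, dtype=float)
    if np.any(true_counts < 0):
        raise ValueError("true counts must be non-negative")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=true_counts.shape) if noise_sd > 0 else 0.0
    automated = np.maximum(0.0, true_counts - offset + noise)
    return pd.DataFrame({"manual": true_counts, "automated": automated})


def generate_cohort_proportions(
    base_proportions: pd.Series,
    n_subjects_per_group: dict[str, int],
    group_effects: dict[str, pd.Series] | None = None,
    concentration: float = 300.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-animal ROI proportion profiles for group comparisons.

    Each animal's profile is a Dirichlet draw around its group's mean
    profile (``base_proportions`` times an optional per-group multiplier,
    renormalised); ``concentration`` sets the between-animal variability.
    Returns a DataFrame with one row per animal, ROI columns and a
    ``group`` column.
    """
    rng = np.random.default_rng(seed)
    base = base_proportions / base_proportions.sum()
    rows, groups, names = [], [], []
    for g, n in n_subjects_per_group.items():
        mean = base.copy()
        if group_effects and g in group_effects:
            mean = mean * group_effects[g].reindex(mean.index).fillna(1.0)
            mean = mean / mean.sum()
        alpha = np.maximum(mean.to_numpy() * concentration, 1e-3)
        for i in range(n):
            rows.append(rng.dirichlet(alpha))
            groups.append(g)
            names.append(f"{g}_{i}")
    df = pd.DataFrame(rows, columns=base.index, index=names)
    df["group"] = groups
    return df


def truth_to_frame(bundle: SectionBundle) -> pd.DataFrame:
    """Flatten a section's ground truth into a tidy table."""
    recs = []
    for c in bundle.truth:
        rec = {
            "section_id": bundle.section_id,
            "cell_id": c.cell_id,
            "x": c.true_center[0],
            "y": c.true_center[1],
            "true_positive": c.true_positive,
            "true_roi": c.true_roi,
            "true_arc_um": c.true_arc_um,
            "radius": c.radius,
        }
        for role, v in c.true_integrated.items():
            rec[f"true_{role}_integrated"] = v
        for role, v in c.true_max.items():
            rec[f"true_{role}_max"] = v
        recs.append(rec)
    return pd.DataFrame(recs)
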