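"""ROI counting, injection-site bookkeeping, and group aggregation.

Tracer-positive cells are assigned to hand-drawn (here: generated) region
polygons, the ROI(s) covering the injection centre are zeroed on every
section, counts are normalised to proportions over the included regions,
and proportions are aggregated into cortical networks (medial / lateral /
somatic / claustrum-entorhinal) or thalamic nuclear groups.  Thalamic
counts may instead enter from a manual-counts table, since thalamic somata
are hard to segment automatically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import shapely

from .flatmap import ArcProjector, ReferenceLine

logger = logging.getLogger(__name__)

__all__ = [
    "ROIPolygon",
    "InjectionSite",
    "CountTable",
    "DEFAULT_CORTICAL_GROUPING",
    "DEFAULT_THALAMIC_GROUPING",
    "assign_cells_to_rois",
    "zero_injection_rois",
    "counts_to_proportions",
    "aggregate_groups",
    "injection_metrics",
    "anterograde_proportions",
    "load_grouping",
    "read_manual_counts",
]


@dataclass
class ROIPolygon:
    """Closed region-of-interest polygon on one section."""

    name: str
    section_id: str
    vertices: np.ndarray  # (M, 2) pixel coordinates
    compartment: str = "cortical"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError(f"ROI {self.name!r} needs >= 3 (x, y) vertices")
        object.__setattr__(self, "vertices", v)
        if self.compartment not in ("cortical", "thalamic"):
            raise ValueError("compartment must be 'cortical' or 'thalamic'")
        poly = shapely.Polygon(v)
        if not poly.is_valid:
            raise ValueError(f"ROI {self.name!r} polygon is self-intersecting")

    @property
    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "section_id": self.section_id,
            "vertices": self.vertices.tolist(),
            "compartment": self.compartment,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ROIPolygon":
        return cls(
            name=d["name"],
            section_id=d["section_id"],
            vertices=np.asarray(d["vertices"], dtype=float),
            compartment=d.get("compartment", "cortical"),
        )


@dataclass
class InjectionSite:
    """Tracer deposit location and its derived placement metrics."""

    center: tuple[float, float]
    section_id: str
    extent_um: float
    covered_rois: tuple[str, ...]
    ml_distance_um: float | None = None
    ap_estimate_mm: float | None = None
    ml_class: str | None = None
    rc_class: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= len(self.covered_rois) <= 2):
            raise ValueError("an injection covers 1 or 2 ROIs")
        if self.extent_um <= 0:
            raise ValueError("injection extent must be positive")

    def to_dict(self) -> dict:
        return {
            "center": list(map(float, self.center)),
            "section_id": self.section_id,
            "extent_um": float(self.extent_um),
            "covered_rois": list(self.covered_rois),
            "ml_distance_um": self.ml_distance_um,
            "ap_estimate_mm": self.ap_estimate_mm,
            "ml_class": self.ml_class,
            "rc_class": self.rc_class,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InjectionSite":
        return cls(
            center=tuple(d["center"]),
            section_id=d["section_id"],
            extent_um=float(d["extent_um"]),
            covered_rois=tuple(d["covered_rois"]),
            ml_distance_um=d.get("ml_distance_um"),
            ap_estimate_mm=d.get("ap_estimate_mm"),
            ml_class=d.get("ml_class"),
            rc_class=d.get("rc_class"),
        )


@dataclass
class CountTable:
    """Per-animal, per-ROI counts at successive processing stages."""

    animal_id: str
    raw: pd.Series
    adjusted: pd.Series | None = None
    zeroed: pd.Series | None = None
    proportions: pd.Series | None = None
    group_label: str | None = None

    @property
    def current(self) -> pd.Series:
        """Most processed count column available."""
        for s in (self.zeroed, self.adjusted, self.raw):
            if s is not None:
                return s
        raise ValueError("empty count table")


# Default network / nuclear-group memberships (overridable via config files).
# Cortical networks follow the medial / lateral / somatic /
# claustrum-entorhinal scheme used for whole-cortex input maps; thalamic
# nuclei are grouped into motor, sensory, three associative subgroups,
# intralaminar and midline.
DEFAULT_CORTICAL_GROUPING: dict[str, str] = {
    "Cg1": "medial", "Cg2": "medial", "mPFC": "medial", "oFC": "medial",
    "RSD": "medial", "RSG": "medial", "MPtA": "medial", "LPtA": "medial",
    "V2MM": "medial", "V2ML": "medial", "V2M/PtA": "medial", "V1": "medial",
    "AUD": "lateral", "AuD": "lateral", "TE": "lateral", "V2L": "lateral",
    "PRh": "lateral", "Ect": "lateral",
    "M1": "somatic", "M2": "somatic", "S1": "somatic", "S1FL": "somatic",
    "S1HL": "somatic", "S2": "somatic",
    "Cl": "claustrum_entorhinal", "LEC": "claustrum_entorhinal",
    "MEC": "claustrum_entorhinal",
}

DEFAULT_THALAMIC_GROUPING: dict[str, str] = {
    "VA": "motor", "VL": "motor", "VM": "motor",
    "VPL": "sensory", "Po": "sensory", "DLG": "sensory",
    "AD": "anterior_associative", "AM": "anterior_associative",
    "AV": "anterior_associative",
    "LD": "lateral_associative", "LPLR": "lateral_associative",
    "LPMR": "lateral_associative",
    "MD": "mediodorsal_associative", "IMD": "mediodorsal_associative",
    "Sub": "mediodorsal_associative",
    "CM": "intralaminar", "PC": "intralaminar", "PF": "intralaminar",
    "Rh": "intralaminar",
    "PV": "midline", "PT": "midline", "Re": "midline",
}


def assign_cells_to_rois(
    cells: pd.DataFrame, rois: list[ROIPolygon]
) -> tuple[pd.Series, int, pd.Series]:
    """Count cells per ROI; boundary points count as inside.

    Cells carrying a truthy ``contralateral`` column are excluded entirely
    (only the hemisphere ipsilateral to the injection is quantified).  If
    polygons overlap, a cell is assigned to the first match in name-sorted
    order and a warning is logged.

    Returns ``(counts, n_unassigned, assignment)`` where ``assignment`` maps
    each (included) cell's index to an ROI name or ``None``.
    """
    order = sorted(rois, key=lambda r: r.name)
    names = [r.name for r in order]
    if len(set(names)) != len(names):
        raise ValueError("duplicate ROI names")

    if "contralateral" in cells.columns:
        cells = cells.loc[~cells["contralateral"].astype(bool)]

    counts = pd.Series(0, index=names, dtype=int)
    assignment = pd.Series([None] * len(cells), index=cells.index, dtype=object)
    if len(cells) == 0:
        return counts, 0, assignment

    pts = shapely.points(cells[["x", "y"]].to_numpy(dtype=float))
    inside = np.column_stack(
        [shapely.covers(r.polygon, pts) for r in order]
    )  # (n_cells, n_rois)
    multi = inside.sum(axis=1)
    if np.any(multi > 1):
        logger.warning(
            "%d cells fall in overlapping ROIs; using name-sorted first match",
            int(np.sum(multi > 1)),
        )
    any_hit = multi > 0
    first = np.argmax(inside, axis=1)
    for i, (idx, hit) in enumerate(zip(cells.index, any_hit)):
        if hit:
            name = names[first[i]]
            assignment.loc[idx] = name
            counts[name] += 1
    return counts, int(np.sum(~any_hit)), assignment


def zero_injection_rois(table: CountTable, injection: InjectionSite) -> CountTable:
    """Zero the ROI(s) containing the injection centre (idempotent)."""
    base = table.adjusted if table.adjusted is not None else table.raw
    for roi in injection.covered_rois:
        if roi not in base.index:
            raise KeyError(f"injection ROI {roi!r} not present in count table")
    zeroed = base.copy()
    zeroed[list(injection.covered_rois)] = 0
    return replace(table, zeroed=zeroed)


def counts_to_proportions(
    counts: pd.Series, included_rois: list[str] | None = None
) -> pd.Series:
    """Normalise counts over included ROIs so they sum to 1."""
    if included_rois is not None:
        counts = counts.loc[list(included_rois)]
    total = float(counts.sum())
    if total <= 0:
        raise ValueError("all counts are zero; proportions undefined")
    return counts / total


def aggregate_groups(
    proportions: pd.Series, grouping: dict[str, str]
) -> pd.Series:
    """Sum member proportions into network / nuclear-group totals."""
    unmapped = [r for r in proportions.index if r not in grouping]
    if unmapped:
        raise KeyError(f"ROIs missing from grouping map: {unmapped}")
    out: dict[str, float] = {}
    for roi, value in proportions.items():
        g = grouping[roi]
        out[g] = out.get(g, 0.0) + float(value)
    return pd.Series(out)


def injection_metrics(
    injection: InjectionSite,
    cingulate_border: ReferenceLine,
    ml_boundary_um: float,
    rc_boundary_mm: float | None = None,
) -> InjectionSite:
    """Complete an injection record with placement distance and classes.

    ``ml_distance_um`` is the arc distance along the reference frame from
    the medial border of the cingulate cortex (the cingulum anchor) to the
    injection centre.  Centres exactly on the medial/lateral boundary
    classify as medial; centres exactly on the rostral/caudal boundary
    classify as rostral (tie rules, logged).
    """
    if cingulate_border is None:
        raise ValueError("cingulate border polyline is required")
    arc_um, _ = (
        ArcProjector()
        .fit(cingulate_border)
        .transform(np.asarray(injection.center, dtype=float))[0]
    )
    ml_class = "medial" if arc_um <= ml_boundary_um else "lateral"
    if arc_um == ml_boundary_um:
        logger.info("injection exactly on M/L boundary; classified medial")
    rc_class = injection.rc_class
    if rc_boundary_mm is not None and injection.ap_estimate_mm is not None:
        rc_class = "rostral" if injection.ap_estimate_mm >= rc_boundary_mm else "caudal"
        if injection.ap_estimate_mm == rc_boundary_mm:
            logger.info("injection exactly on R/C boundary; classified rostral")
    return replace(
        injection,
        ml_distance_um=float(arc_um),
        ml_class=ml_class,
        rc_class=rc_class,
    )


def anterograde_proportions(
    intensity_per_roi: pd.Series, injection: InjectionSite
) -> pd.Series:
    """Proportion of total integrated terminal intensity per ROI.

    The injected ROI(s) are zeroed before normalisation, so they contribute
    neither to the numerator nor to the denominator.
    """
    if (intensity_per_roi < 0).any():
        raise ValueError("intensities must be non-negative")
    zeroed = intensity_per_roi.astype(float).copy()
    for roi in injection.covered_rois:
        if roi in zeroed.index:
            zeroed[roi] = 0.0
    total = float(zeroed.sum())
    if total <= 0:
        raise ValueError("no terminal intensity outside the injected region")
    return zeroed / total


def load_grouping(path: str) -> dict[str, str]:
    """Load an ROI -> group map from a JSON or YAML file."""
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            data = json.load(fh)
    if not isinstance(data, dict):
        raise ValueError("grouping file must map ROI names to group names")
    return {str(k): str(v) for k, v in data.items()}


def read_manual_counts(path: str, animal_id: str | None = None) -> CountTable:
    """Read a manual-counts CSV (columns: roi, count[, animal_id]).

    This is the data path for thalamic regions, where somata are counted by
    hand rather than segmented.
    """
    df = pd.read_csv(path)
    if animal_id is not None and "animal_id" in df.columns:
        df = df.loc[df["animal_id"] == animal_id]
    if not {"roi", "count"}.issubset(df.columns):
        raise ValueError("manual counts CSV needs 'roi' and 'count' columns")
    counts = df.groupby("roi")["count"].sum().astype(float)
    return CountTable(animal_id=animal_id or "manual", raw=counts)
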