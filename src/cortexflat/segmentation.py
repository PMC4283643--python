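"""NeuN-channel neuron detection and per-cell feature extraction.

The detector is deliberately simple and fully specified: Gaussian
smoothing, Otsu (or absolute) thresholding of the NeuN channel, a
distance-transform watershed to split touching somata, and a minimum-area
filter.  For every labelled soma it measures the intensity-weighted
centroid and, per channel, the integrated intensity (sum of pixel values
within the segmented boundary) plus the maximum and minimum pixel — the
features the tracer classifier consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed
from skimage.feature import peak_local_max
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "SectionImage",
    "SegmentedCell",
    "NeuronSegmenter",
    "tile_image",
    "segment_neurons",
    "extract_features",
    "detect_cells",
    "cells_to_frame",
]

FEATURE_CHANNELS = ("neun", "tracer_red", "tracer_yellow")


@dataclass
class SectionImage:
    """8-bit multichannel section raster with channel-role metadata."""

    data: np.ndarray  # (H, W, C)
    pixel_size: float = 0.23
    channel_roles: dict[str, int] = field(
        default_factory=lambda: {"neun": 0, "tracer_red": 1, "tracer_yellow": 2}
    )
    section_id: str = "sec000"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.ndim != 3:
            raise ValueError("section image must be H x W x C")
        if arr.dtype != np.uint8:
            if np.issubdtype(arr.dtype, np.integer):
                info = np.iinfo(arr.dtype)
                factor = 255.0 / info.max
                logger.info(
                    "rescaling %s raster to 8-bit (factor %.6g)", arr.dtype, factor
                )
                arr = np.clip(np.round(arr * factor), 0, 255).astype(np.uint8)
            else:
                raise ValueError("section images must be integer rasters (8-bit)")
        if "neun" not in self.channel_roles:
            raise ValueError("channel_roles must include 'neun'")
        if not any(r.startswith("tracer") for r in self.channel_roles):
            raise ValueError("channel_roles must include at least one tracer role")
        for role, ch in self.channel_roles.items():
            if not (0 <= ch < arr.shape[2]):
                raise ValueError(f"channel index for {role!r} out of range")
        self.data = arr

    def channel(self, role: str) -> np.ndarray:
        return self.data[:, :, self.channel_roles[role]]


@dataclass(frozen=True)
class SegmentedCell:
    """One detected neuron with its intrinsic features."""

    cell_id: int
    section_id: str
    centroid_xy: tuple[float, float]
    area: int
    integrated_intensity: dict[str, float]
    max_intensity: dict[str, float]
    min_intensity: dict[str, float]


def tile_image(
    image: np.ndarray, tile_size: int, overlap: int = 0
) -> list[tuple[np.ndarray, tuple[int, int]]]:
    """Split a raster into overlapping tiles with back-mappable offsets.

    Returns ``(tile, (x_offset, y_offset))`` pairs covering every pixel;
    tiles at the right/bottom edge are clamped to the image bounds.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    if overlap < 0 or tile_size <= 2 * overlap:
        raise ValueError("require 0 <= overlap < tile_size / 2")
    h, w = image.shape[:2]
    stride = tile_size - overlap
    ys = list(range(0, max(h - overlap, 1), stride))
    xs = list(range(0, max(w - overlap, 1), stride))
    tiles = []
    for y in ys:
        y1 = min(y + tile_size, h)
        for x in xs:
            x1 = min(x + tile_size, w)
            tiles.append((image[y:y1, x:x1], (x, y)))
    return tiles


class NeuronSegmenter(BaseEstimator):
    """Watershed-based NeuN soma detector.

    Parameters
    ----------
    sigma : float
        Gaussian pre-smoothing of the NeuN channel, in pixels.
    threshold : float or None
        Absolute foreground threshold on the smoothed NeuN channel; when
        ``None``, Otsu's threshold is used.  Sparse fluorescence images
        violate Otsu's bimodality assumption, so pipelines on dim, sparse
        sections usually set a low absolute value.
    min_area : int
        Minimum object area in pixels; smaller components are discarded.
    min_distance : int
        Minimum separation of watershed seed peaks in the distance
        transform, in pixels.
    """

    def __init__(
        self,
        sigma: float = 1.0,
        threshold: float | None = None,
        min_area: int = 20,
        min_distance: int = 7,
    ) -> None:
        self.sigma = sigma
        self.threshold = threshold
        self.min_area = min_area
        self.min_distance = min_distance

    def segment(self, image: SectionImage) -> np.ndarray:
        """Label map of detected somata (0 = background)."""
        neun = image.channel("neun").astype(float)
        smoothed = ndi.gaussian_filter(neun, self.sigma) if self.sigma > 0 else neun
        if self.threshold is not None:
            thr = float(self.threshold)
        else:
            if smoothed.max() == smoothed.min():
                thr = smoothed.max()  # flat image: nothing segmentable below
            else:
                thr = float(threshold_otsu(smoothed))
        mask = smoothed > thr
        if mask.all():
            warnings.warn(
                "entire section above threshold (saturated?); returning a "
                "single unreliable region",
                stacklevel=2,
            )
            return np.ones(mask.shape, dtype=np.int32)
        if not mask.any():
            return np.zeros(mask.shape, dtype=np.int32)

        distance = ndi.distance_transform_edt(mask)
        coords = peak_local_max(
            distance,
            min_distance=self.min_distance,
            labels=mask,
            exclude_border=False,
        )
        if len(coords) == 0:
            labels, _ = ndi.label(mask)
        else:
            markers = np.zeros(mask.shape, dtype=np.int32)
            markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
            labels = watershed(-distance, markers, mask=mask)

        # min-area filter with sequential relabelling
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        keep = ids[counts >= self.min_area]
        lut = np.zeros(labels.max() + 1, dtype=np.int32)
        lut[keep] = np.arange(1, len(keep) + 1)
        return lut[labels]


def segment_neurons(image: SectionImage, **kwargs) -> np.ndarray:
    """Functional wrapper around :class:`NeuronSegmenter`."""
    return NeuronSegmenter(**kwargs).segment(image)


def extract_features(
    image: SectionImage, labels: np.ndarray, cell_id_offset: int = 0
) -> list[SegmentedCell]:
    """Per-label features over every channel of the section raster.

    Centroids are intensity-weighted by the NeuN channel and reported in
    pixel-centre convention (x = column, y = row).
    """
    if labels.shape != image.data.shape[:2]:
        raise ValueError("label map shape does not match the image raster")
    n = int(labels.max())
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    areas = ndi.sum_labels(np.ones_like(labels), labels, idx).astype(int)
    neun = image.channel("neun").astype(float)
    # intensity-weighted centroids; fall back to geometric centroid for
    # (pathological) all-zero footprints
    com = ndi.center_of_mass(np.where(neun > 0, neun, 0) + 1e-12, labels, idx)
    feats: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for role in image.channel_roles:
        chan = image.channel(role).astype(float)
        feats[role] = (
            ndi.sum_labels(chan, labels, idx),
            ndi.maximum(chan, labels, idx),
            ndi.minimum(chan, labels, idx),
        )
    cells = []
    for k, lab in enumerate(idx):
        integrated = {r: float(feats[r][0][k]) for r in feats}
        vmax = {r: float(feats[r][1][k]) for r in feats}
        vmin = {r: float(feats[r][2][k]) for r in feats}
        cy, cx = com[k]
        cells.append(
            SegmentedCell(
                cell_id=cell_id_offset + k,
                section_id=image.section_id,
                centroid_xy=(float(cx), float(cy)),
                area=int(areas[k]),
                integrated_intensity=integrated,
                max_intensity=vmax,
                min_intensity=vmin,
            )
        )
    return cells


def cells_to_frame(cells: list[SegmentedCell]) -> pd.DataFrame:
    """Tidy feature table: one row per cell, per-channel feature columns."""
    recs = []
    for c in cells:
        rec = {
            "section_id": c.section_id,
            "cell_id": c.cell_id,
            "x": c.centroid_xy[0],
            "y": c.centroid_xy[1],
            "area": c.area,
        }
        for role, v in c.integrated_intensity.items():
            rec[f"{role}_integrated"] = v
        for role, v in c.max_intensity.items():
            rec[f"{role}_max"] = v
        for role, v in c.min_intensity.items():
            rec[f"{role}_min"] = v
        recs.append(rec)
    return pd.DataFrame(recs)


def detect_cells(
    image: SectionImage,
    segmenter: NeuronSegmenter | None = None,
    tile_size: int | None = None,
    overlap: int = 64,
    dedup_radius: float = 15.0,
) -> pd.DataFrame:
    """Segment a whole section, optionally tile-wise, into a feature table.

    With tiling, duplicate detections in overlap bands are resolved by
    keeping the candidate whose centroid lies farthest from its own tile
    border (the complete soma rather than a cut fragment).
    """
    segmenter = segmenter or NeuronSegmenter()
    if tile_size is None:
        labels = segmenter.segment(image)
        cells = extract_features(image, labels)
        return cells_to_frame(cells)

    records = []
    for tile, (ox, oy) in tile_image(image.data, tile_size, overlap):
        sub = SectionImage(
            data=tile,
            pixel_size=image.pixel_size,
            channel_roles=dict(image.channel_roles),
            section_id=image.section_id,
        )
        labels = segmenter.segment(sub)
        for c in extract_features(sub, labels):
            x, y = c.centroid_xy
            th, tw = tile.shape[:2]
            border_dist = min(x, y, tw - 1 - x, th - 1 - y)
            records.append((c, ox, oy, border_dist))
    if not records:
        return cells_to_frame([])

    pts = np.array(
        [(c.centroid_xy[0] + ox, c.centroid_xy[1] + oy) for c, ox, oy, _ in records]
    )
    border = np.array([bd for *_, bd in records])
    # union-find duplicate clusters within dedup_radius
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    pairs = tree.query_pairs(dedup_radius)
    parent = list(range(len(records)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    best: dict[int, int] = {}
    for i in range(len(records)):
        r = find(i)
        if r not in best or border[i] > border[best[r]]:
            best[r] = i

    kept = sorted(best.values(), key=lambda i: (pts[i, 1], pts[i, 0]))
    cells = []
    for new_id, i in enumerate(kept):
        c, ox, oy, _ = records[i]
        cells.append(
            SegmentedCell(
                cell_id=new_id,
                section_id=c.section_id,
                centroid_xy=(c.centroid_xy[0] + ox, c.centroid_xy[1] + oy),
                area=c.area,
                integrated_intensity=c.integrated_intensity,
                max_intensity=c.max_intensity,
                min_intensity=c.min_intensity,
            )
        )
    return cells_to_frame(cells)
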