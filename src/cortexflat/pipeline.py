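"""Pipeline orchestration: simulate -> segment -> classify -> calibrate ->
flatmap -> quantify -> stats, driven by one YAML config.

Each stage reads the previous stage's artifacts from the output directory,
writes its own atomically, and records parameters, seed and output
checksums in ``manifest.json`` so a rerun with an identical config is
verifiable and an interrupted run can resume from the last completed
stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import flatmap as fm
from . import roi as roi_mod
from . import segmentation as seg
from . import stats as st
from . import synth
from . import tracer

logger = logging.getLogger(__name__)

STAGE_ORDER = [
    "simulate",
    "segment",
    "classify",
    "calibrate",
    "flatmap",
    "quantify",
    "stats",
]

_STAGE_REQUIRES = {
    "simulate": [],
    "segment": ["geometry.json"],
    "classify": ["cells.csv"],
    "calibrate": ["cells_classified.csv", "truth.csv"],
    "flatmap": ["cells_classified.csv", "geometry.json"],
    "quantify": ["cells_classified.csv", "geometry.json", "calibration.json"],
    "stats": ["proportions.csv"],
}

_STAGE_OUTPUTS = {
    "simulate": ["geometry.json", "truth.csv"],
    "segment": ["cells.csv"],
    "classify": ["cells_classified.csv"],
    "calibrate": ["count_pairs.csv", "calibration.json"],
    "flatmap": ["flatmap.csv", "flatmap.png"],
    "quantify": ["counts.csv", "proportions.csv", "groups.csv"],
    "stats": ["cohort.csv", "anova.csv", "posthoc.csv"],
}

_PRODUCER = {
    out: stage for stage, outs in _STAGE_OUTPUTS.items() for out in outs
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    log_level: str = "INFO"
    stages: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "PipelineConfig":
        if not isinstance(raw, dict):
            raise PipelineError("config: top level must be a mapping")
        known = set(STAGE_ORDER) | {"out_dir", "seed", "log_level"}
        for key in raw:
            if key not in known:
                raise PipelineError(f"config: unknown field {key!r}")
        out_dir = Path(raw.get("out_dir", "cortexflat_out"))
        if base_dir is not None and not out_dir.is_absolute():
            out_dir = base_dir / out_dir
        stages = {}
        for name in STAGE_ORDER:
            block = raw.get(name, {}) or {}
            if not isinstance(block, dict):
                raise PipelineError(f"config: {name} block must be a mapping")
            stages[name] = block
        return cls(
            out_dir=out_dir,
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
            stages=stages,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


class Pipeline:
    """Stage runner with a manifest for resumability and provenance."""

    def __init__(self, config: PipelineConfig) -> None:
        self.config = config
        self.out_dir = Path(config.out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        logging.basicConfig(level=config.log_level)

    # -- manifest ----------------------------------------------------------

    @property
    def manifest_path(self) -> Path:
        return self.out_dir / "manifest.json"

    def _load_manifest(self) -> dict:
        if self.manifest_path.exists():
            return json.loads(self.manifest_path.read_text())
        return {}

    def _record(self, stage: str, outputs: list[Path]) -> None:
        manifest = self._load_manifest()
        entry = {
            "params": self.config.stages.get(stage, {}),
            "seed": self.config.seed,
            "outputs": {},
        }
        for p in outputs:
            rel = str(p.relative_to(self.out_dir))
            entry["outputs"][rel] = _sha256(p) if p.suffix != ".png" else None
        manifest[stage] = entry
        _atomic_write_text(self.manifest_path, json.dumps(manifest, indent=2))

    def _check_upstream(self, stage: str) -> None:
        for req in _STAGE_REQUIRES[stage]:
            if not (self.out_dir / req).exists():
                producer = _PRODUCER.get(req, "an upstream stage")
                raise PipelineError(
                    f"stage {stage!r} needs {req!r}; run stage {producer!r} first"
                )

    def stage_complete(self, stage: str) -> bool:
        manifest = self._load_manifest()
        if stage not in manifest:
            return False
        return all(
            (self.out_dir / rel).exists()
            for rel in manifest[stage]["outputs"]
        )

    # -- public API --------------------------------------------------------

    def run_stage(self, name: str) -> list[Path]:
        if name not in STAGE_ORDER:
            raise PipelineError(f"unknown stage {name!r}")
        self._check_upstream(name)
        outputs = getattr(self, f"_run_{name}")()
        self._record(name, outputs)
        logger.info("stage %s complete (%d artifacts)", name, len(outputs))
        return outputs

    def run_all(self, force: bool = False) -> None:
        for name in STAGE_ORDER:
            if not force and self.stage_complete(name):
                logger.info("stage %s up to date; skipping", name)
                continue
            self.run_stage(name)

    # -- stages ------------------------------------------------------------

    def _synth_params(self) -> synth.SynthParams:
        block = dict(self.config.stages.get("simulate", {}))
        block.pop("n_cut_sections", None)
        overrides = block.pop("params", {}) or {}
        for key in ("cell_radius_range", "ribbon_control_points",
                    "tracer_intensity_range_positive",
                    "tracer_intensity_range_negative",
                    "neun_intensity_range", "roi_names",
                    "roi_arc_breakpoints", "injection_center"):
            if key in overrides and overrides[key] is not None:
                val = overrides[key]
                overrides[key] = tuple(
                    tuple(v) if isinstance(v, (list, tuple)) else v for v in val
                )
        return synth.SynthParams(seed=self.config.seed, **overrides)

    def _run_simulate(self) -> list[Path]:
        import tifffile

        block = self.config.stages.get("simulate", {})
        n_cut = int(block.get("n_cut_sections", 12))
        params = self._synth_params()
        bundles, mask = synth.generate_brain(params, n_cut)

        sec_dir = self.out_dir / "sections"
        sec_dir.mkdir(exist_ok=True)
        geometry = {"sampling": mask, "sections": [], "pixel_size": params.pixel_size}
        truth_frames = []
        outputs = []
        for b in bundles:
            entry = {
                "section_id": b.section_id,
                "ap_position": b.ap_position,
                "section_order_index": b.section_order_index,
                "mapped": b.mapped,
                "reference_line": b.reference_line.to_dict(),
                "rois": [r.to_dict() for r in b.rois],
                "injection": None if b.injection is None else b.injection.to_dict(),
            }
            geometry["sections"].append(entry)
            if b.mapped and b.image is not None:
                tif = sec_dir / f"{b.section_id}.tif"
                tifffile.imwrite(tif, b.image, photometric="rgb")
                outputs.append(tif)
            truth_frames.append(synth.truth_to_frame(b))
        geo_path = self.out_dir / "geometry.json"
        _atomic_write_text(geo_path, json.dumps(geometry))
        truth = pd.concat([t for t in truth_frames if len(t)], ignore_index=True)
        truth_path = self.out_dir / "truth.csv"
        truth.to_csv(truth_path, index=False)
        return [geo_path, truth_path, *outputs]

    def _load_geometry(self) -> dict:
        return json.loads((self.out_dir / "geometry.json").read_text())

    def _run_segment(self) -> list[Path]:
        import tifffile

        block = self.config.stages.get("segment", {})
        segmenter = seg.NeuronSegmenter(
            sigma=float(block.get("sigma", 1.0)),
            threshold=block.get("threshold"),
            min_area=int(block.get("min_area", 20)),
            min_distance=int(block.get("min_distance", 7)),
        )
        tile_size = block.get("tile_size")
        geometry = self._load_geometry()
        frames = []
        for entry in geometry["sections"]:
            if not entry["mapped"]:
                continue
            tif = self.out_dir / "sections" / f"{entry['section_id']}.tif"
            image = seg.SectionImage(
                data=tifffile.imread(tif),
                pixel_size=geometry["pixel_size"],
                section_id=entry["section_id"],
            )
            frames.append(
                seg.detect_cells(
                    image,
                    segmenter=segmenter,
                    tile_size=None if tile_size is None else int(tile_size),
                    overlap=int(block.get("overlap", 160)),
                    dedup_radius=float(block.get("dedup_radius", 60.0)),
                )
            )
        cells = pd.concat(frames, ignore_index=True)
        path = self.out_dir / "cells.csv"
        cells.to_csv(path, index=False)
        return [path]

    def _classifier(self) -> tracer.TracerClassifier:
        block = self.config.stages.get("classify", {})
        return tracer.TracerClassifier(
            integrated_threshold=float(
                block.get("integrated_threshold", tracer.DEFAULT_INTEGRATED_THRESHOLD)
            ),
            max_pixel_threshold=float(
                block.get("max_pixel_threshold", tracer.DEFAULT_MAX_PIXEL_THRESHOLD)
            ),
            tracer_channel=str(block.get("tracer_channel", "tracer_red")),
        ).fit()

    def _run_classify(self) -> list[Path]:
        cells = pd.read_csv(self.out_dir / "cells.csv")
        clf = self._classifier()
        cells["tracer_positive"] = clf.predict(cells)
        cells["tracer_role"] = clf.tracer_channel
        path = self.out_dir / "cells_classified.csv"
        cells.to_csv(path, index=False)
        return [path]

    def _section_counts(
        self, cells: pd.DataFrame, geometry: dict, positives_only: bool = True
    ) -> pd.DataFrame:
        """Per-(section, ROI) automated counts."""
        rows = []
        for entry in geometry["sections"]:
            if not entry["mapped"]:
                continue
            sid = entry["section_id"]
            rois = [roi_mod.ROIPolygon.from_dict(d) for d in entry["rois"]]
            sub = cells.loc[cells["section_id"] == sid]
            if positives_only:
                sub = sub.loc[sub["tracer_positive"]]
            counts, _, _ = roi_mod.assign_cells_to_rois(sub, rois)
            for name, c in counts.items():
                rows.append({"section_id": sid, "roi": name, "count": int(c)})
        return pd.DataFrame(rows)

    def _run_calibrate(self) -> list[Path]:
        geometry = self._load_geometry()
        cells = pd.read_csv(self.out_dir / "cells_classified.csv")
        truth = pd.read_csv(self.out_dir / "truth.csv")
        auto = self._section_counts(cells, geometry)
        manual = (
            truth.loc[truth["true_positive"]]
            .groupby(["section_id", "true_roi"])
            .size()
            .rename("manual")
            .reset_index()
            .rename(columns={"true_roi": "roi"})
        )
        pairs = auto.merge(manual, on=["section_id", "roi"], how="left").fillna(
            {"manual": 0}
        )
        pairs = pairs.rename(columns={"count": "automated"})
        path_pairs = self.out_dir / "count_pairs.csv"
        pairs.to_csv(path_pairs, index=False)
        model = tracer.fit_calibration(
            pairs[["manual", "automated"]]
        )
        path_model = self.out_dir / "calibration.json"
        model.to_json(path_model)
        return [path_pairs, path_model]

    def _run_flatmap(self) -> list[Path]:
        block = self.config.stages.get("flatmap", {})
        smoother = fm.RunlineSmoother(
            window=int(block.get("window", 5)), step=int(block.get("step", 1))
        )
        geometry = self._load_geometry()
        cells = pd.read_csv(self.out_dir / "cells_classified.csv")
        injection = None
        sections = []
        for entry in geometry["sections"]:
            if not entry["mapped"]:
                continue
            sid = entry["section_id"]
            line = smoother.transform(
                fm.ReferenceLine.from_dict(entry["reference_line"])
            )
            rois = [roi_mod.ROIPolygon.from_dict(d) for d in entry["rois"]]
            sub = cells.loc[
                (cells["section_id"] == sid) & cells["tracer_positive"]
            ].copy()
            if entry["injection"] is not None:
                injection = roi_mod.InjectionSite.from_dict(entry["injection"])
            inj_rois = (
                set(injection.covered_rois) if injection is not None else set()
            )
            if len(sub):
                _, _, assigned = roi_mod.assign_cells_to_rois(sub, rois)
                sub["in_injection_roi"] = [
                    (a in inj_rois) for a in assigned.to_numpy()
                ]
            sections.append((sid, entry["ap_position"], line, sub))
        flat = fm.assemble_flatmap(sections, injection=injection)
        path_csv = self.out_dir / "flatmap.csv"
        flat.to_frame().to_csv(path_csv, index=False)
        path_png = self.out_dir / "flatmap.png"
        fm.render_flatmap(flat, str(path_png))
        return [path_csv, path_png]

    def _run_quantify(self) -> list[Path]:
        block = self.config.stages.get("quantify", {})
        geometry = self._load_geometry()
        cells = pd.read_csv(self.out_dir / "cells_classified.csv")
        model = tracer.CalibrationModel.from_json(self.out_dir / "calibration.json")
        per_section = self._section_counts(cells, geometry)
        raw = per_section.groupby("roi")["count"].sum().astype(float)

        injection = None
        for entry in geometry["sections"]:
            if entry["injection"] is not None:
                injection = roi_mod.InjectionSite.from_dict(entry["injection"])
        table = roi_mod.CountTable(animal_id=str(block.get("animal_id", "synth01")), raw=raw)
        adjusted = tracer.apply_calibration(raw, model)
        table.adjusted = adjusted
        if injection is not None:
            table = roi_mod.zero_injection_rois(table, injection)
        else:
            table.zeroed = adjusted
        table.proportions = roi_mod.counts_to_proportions(table.zeroed)

        grouping_path = block.get("grouping")
        grouping = (
            roi_mod.load_grouping(grouping_path)
            if grouping_path
            else roi_mod.DEFAULT_CORTICAL_GROUPING
        )
        groups = roi_mod.aggregate_groups(table.proportions, grouping)

        counts_df = pd.DataFrame(
            {
                "raw": table.raw,
                "adjusted": table.adjusted,
                "zeroed": table.zeroed,
            }
        )
        counts_df.index.name = "roi"
        path_counts = self.out_dir / "counts.csv"
        counts_df.to_csv(path_counts)
        path_props = self.out_dir / "proportions.csv"
        table.proportions.rename("proportion").to_frame().rename_axis("roi").to_csv(
            path_props
        )
        path_groups = self.out_dir / "groups.csv"
        groups.rename("proportion").to_frame().rename_axis("network").to_csv(
            path_groups
        )
        outputs = [path_counts, path_props, path_groups]

        manual_csv = block.get("manual_thalamus")
        if manual_csv:
            thal = roi_mod.read_manual_counts(manual_csv)
            thal_props = roi_mod.counts_to_proportions(thal.raw)
            thal_groups = roi_mod.aggregate_groups(
                thal_props, roi_mod.DEFAULT_THALAMIC_GROUPING
            )
            p = self.out_dir / "thalamus_groups.csv"
            thal_groups.rename("proportion").to_frame().rename_axis("group").to_csv(p)
            outputs.append(p)
        return outputs

    def _run_stats(self) -> list[Path]:
        block = self.config.stages.get("stats", {})
        input_csv = block.get("input")
        if input_csv:
            cohort = pd.read_csv(input_csv, index_col=0)
        else:
            props = pd.read_csv(self.out_dir / "proportions.csv", index_col="roi")[
                "proportion"
            ]
            n_per_group = dict(
                block.get("n_subjects_per_group", {"medial": 5, "lateral": 4})
            )
            effects_cfg = block.get("group_effects") or {
                "lateral": {"S1": 2.5, "RSD": 0.5}
            }
            effects = {
                g: pd.Series(mult, dtype=float) for g, mult in effects_cfg.items()
            }
            cohort = synth.generate_cohort_proportions(
                props,
                n_per_group,
                group_effects=effects,
                concentration=float(block.get("concentration", 300.0)),
                seed=self.config.seed,
            )
        path_cohort = self.out_dir / "cohort.csv"
        cohort.to_csv(path_cohort)

        groups = cohort.pop("group").to_numpy()
        alpha = float(block.get("alpha", 0.05))
        results = []
        one = st.one_way_rm_anova(st.RMDesign(cohort, alpha=alpha))
        results.append(("one_way", one))
        two = st.two_way_rm_anova(st.RMDesign(cohort, groups=groups, alpha=alpha))
        results.extend((f"two_way_{k}", v) for k, v in two.items())
        anova_df = pd.DataFrame(
            [
                {
                    "analysis": name,
                    "effect": r.effect,
                    "F": r.F,
                    "df_num": r.df_num,
                    "df_den": r.df_den,
                    "p": r.p,
                }
                for name, r in results
            ]
        )
        path_anova = self.out_dir / "anova.csv"
        anova_df.to_csv(path_anova, index=False)

        top = cohort.mean().idxmax()
        pairs = [(top, other) for other in cohort.columns if other != top]
        post = st.bonferroni_posthoc(st.RMDesign(cohort, alpha=alpha), pairs)
        path_post = self.out_dir / "posthoc.csv"
        post.to_csv(path_post, index=False)
        return [path_cohort, path_anova, path_post]


def run_stage(name: str, config: PipelineConfig) -> list[Path]:
    """Run one named stage of the pipeline."""
    return Pipeline(config).run_stage(name)


def run_all(config: PipelineConfig, force: bool = False) -> None:
    """Run every stage in dependency order, resuming from the manifest."""
    Pipeline(config).run_all(force=force)


def demo_config(out_dir: str, seed: int = 1) -> PipelineConfig:
    """Small, fast end-to-end demonstration configuration."""
    return PipelineConfig.from_dict(
        {
            "out_dir": out_dir,
            "seed": seed,
            "simulate": {
                "n_cut_sections": 12,
                "params": {
                    "image_width": 2200,
                    "image_height": 1500,
                    "n_cells": 25,
                    "n_tracer_positive": 18,
                    "ribbon_control_points": [
                        [220, 180],
                        [850, 240],
                        [1450, 480],
                        [1900, 900],
                        [2050, 1330],
                    ],
                    "ribbon_halfwidth": 190,
                },
            },
            "segment": {"threshold": 30, "min_area": 500},
            "stats": {"n_subjects_per_group": {"medial": 5, "lateral": 4}},
        }
    )
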