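"""Benchmark measurements of the pipeline against planted ground truth.

Each function sets up a known-truth scenario with the synthetic-data
generator (or an analytically forced design), runs the relevant pipeline
stage, and measures agreement.  Where an independent oracle is called for
(dense-resampling nearest point, loop-based sums of squares) it is
computed here by a route separate from the implementation it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synth
from .flatmap import ArcProjector, ReferenceLine, resample_polyline
from .roi import CountTable, counts_to_proportions, zero_injection_rois
from .segmentation import NeuronSegmenter, SectionImage, detect_cells
from .stats import RMDesign, one_way_rm_anova, two_way_rm_anova
from .synth import SynthParams
from .tracer import TracerClassifier, fit_calibration

__all__ = [
    "two_way_design_df",
    "sampling_fraction",
    "classifier_fidelity",
    "projection_oracle_agreement",
    "calibration_recovery",
    "endtoend_proportion_recovery",
    "anova_oracle_agreement",
    "anova_type1_error",
]


def two_way_design_df(seed: int = 0, n_regions: int = 21) -> dict:
    """Interaction degrees of freedom of the medial/lateral split-plot
    design: ``n_regions`` ROIs x 9 animals (5 medial, 4 lateral)."""
    rng = np.random.default_rng(seed)
    base = pd.Series(
        rng.dirichlet(np.ones(n_regions) * 2.0),
        index=[f"ROI{j:02d}" for j in range(n_regions)],
    )
    cohort = synth.generate_cohort_proportions(
        base,
        {"medial": 5, "lateral": 4},
        group_effects={"lateral": pd.Series({"ROI00": 2.0, "ROI01": 0.5})},
        seed=seed,
    )
    groups = cohort.pop("group").to_numpy()
    res = two_way_rm_anova(RMDesign(cohort, groups=groups))
    inter = res["interaction"]
    return {
        "df_num": inter.df_num,
        "df_den": inter.df_den,
        "F": inter.F,
        "n_subjects": len(cohort),
    }


def sampling_fraction(n_cut_sections: int = 24, seed: int = 0) -> dict:
    """Fraction of cut sections that receive a flat map (3 parallel series,
    every other NeuN section mapped)."""
    params = SynthParams(
        n_cells=0, n_tracer_positive=0, seed=seed,
        image_width=1200, image_height=900,
        ribbon_control_points=(
            (120.0, 100.0), (450.0, 140.0), (800.0, 300.0),
            (1050.0, 520.0), (1130.0, 800.0),
        ),
        ribbon_halfwidth=170.0,
    )
    bundles, mask = synth.generate_brain(params, n_cut_sections)
    n_mapped = sum(b.mapped for b in bundles)
    return {
        "mapped_fraction": n_mapped / n_cut_sections,
        "n_mapped": n_mapped,
        "n_cut_sections": n_cut_sections,
    }


def classifier_fidelity(seed: int = 0, n_cells: int = 400) -> dict:
    """Recall/precision of the threshold rule on a feature table whose
    positive and negative populations straddle both thresholds with a
    >= 10% margin (including negatives failing only one criterion)."""
    rng = np.random.default_rng(seed)
    n_pos = n_cells // 2
    n_neg = n_cells - n_pos
    pos = pd.DataFrame(
        {
            "tracer_red_integrated": rng.uniform(275_000, 600_000, n_pos),
            "tracer_red_max": rng.uniform(165, 255, n_pos),
        }
    )
    kinds = rng.integers(0, 3, n_neg)
    neg = pd.DataFrame(
        {
            "tracer_red_integrated": np.where(
                kinds == 1,
                rng.uniform(275_000, 600_000, n_neg),  # bright but dim peak
                rng.uniform(0, 225_000, n_neg),
            ),
            "tracer_red_max": np.where(
                kinds == 2,
                rng.uniform(165, 255, n_neg),  # hot pixel but low total
                rng.uniform(0, 135, n_neg),
            ),
        }
    )
    cells = pd.concat([pos, neg], ignore_index=True)
    truth = np.arange(n_cells) < n_pos
    flags = TracerClassifier().fit().predict(cells)
    tp = int(np.sum(flags & truth))
    fp = int(np.sum(flags & ~truth))
    fn = int(np.sum(~flags & truth))
    return {
        "recall": tp / (tp + fn) if tp + fn else np.nan,
        "precision": tp / (tp + fp) if tp + fp else np.nan,
        "n_cells": n_cells,
    }


def projection_oracle_agreement(seed: int = 0, n_points: int = 1000) -> dict:
    """Arc projection vs a dense-resampling brute-force nearest point
    (0.01 px sampling), plus rigid-transform invariance."""
    from scipy.spatial import cKDTree

    t = np.linspace(0, 4 * np.pi, 400)
    verts = np.column_stack([t * 30, 40 * np.sin(t)])
    line = ReferenceLine(verts, cingulum_anchor=10, pixel_size=1.0)
    rng = np.random.default_rng(seed)
    pts = np.column_stack(
        [rng.uniform(0, 370, n_points), rng.uniform(-60, 60, n_points)]
    )
    res = ArcProjector().fit(line).transform(pts)

    dense = resample_polyline(verts, 0.01)
    arcs = np.concatenate(
        [[0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))]
    )
    anchor_arc = line.arc_lengths[line.cingulum_anchor]
    d, j = cKDTree(dense).query(pts)
    arc_err = np.abs(res[:, 0] - (arcs[j] - anchor_arc)).max()

    th = np.deg2rad(33.0)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    shift = np.array([41.0, -17.0])
    moved = ReferenceLine(verts @ R.T + shift, cingulum_anchor=10, pixel_size=1.0)
    res_moved = ArcProjector().fit(moved).transform(pts @ R.T + shift)
    rigid_dev = np.abs(res_moved - res).max()
    return {
        "max_arc_error_px": float(arc_err),
        "max_rigid_deviation_um": float(rigid_dev),
        "n_points": n_points,
    }


def calibration_recovery(
    seed: int = 0,
    offsets: tuple[float, ...] = (1.0, 3.0, 5.0),
    n_pairs: int = 50,
    noise_sd: float = 1.0,
    n_seeds: int = 100,
) -> dict:
    """Planted-undercount recovery: fraction of seeds with the fitted
    x-intercept within +/- 0.5 of ``-offset``, and the noiseless exact
    check.  True counts span sparse and dense ROIs (10-30 and 250-400)."""
    rng = np.random.default_rng(seed)
    true = np.concatenate(
        [
            rng.integers(10, 31, n_pairs // 2),
            rng.integers(250, 401, n_pairs - n_pairs // 2),
        ]
    ).astype(float)
    out: dict = {"n_pairs": n_pairs, "n_seeds": n_seeds}
    base = int(rng.integers(0, 2**20))
    for k in offsets:
        hits = 0
        xs = []
        for s in range(n_seeds):
            fix = synth.generate_count_fixture(
                true, offset=k, noise_sd=noise_sd, seed=base + s
            )
            model = fit_calibration(fix)
            xs.append(model.x_intercept)
            hits += abs(model.x_intercept + k) <= 0.5
        out[f"offset_{int(k)}"] = {
            "hit_rate": hits / n_seeds,
            "mean_x_intercept": float(np.mean(xs)),
        }
    noiseless = fit_calibration(
        synth.generate_count_fixture(true, offset=3.0, noise_sd=0.0)
    )
    out["noiseless_abs_error"] = abs(noiseless.x_intercept + 3.0)
    return out


def endtoend_proportion_recovery(seed: int = 0, n_cut_sections: int = 60) -> dict:
    """Full image pipeline on a synthetic brain: generate, segment,
    classify, assign to ROIs, zero the injection, normalise — then compare
    recovered per-ROI proportions with the planted ones (L-infinity)."""
    from scipy.spatial import cKDTree

    params = SynthParams(seed=seed)
    bundles, _ = synth.generate_brain(params, n_cut_sections)
    segmenter = NeuronSegmenter(threshold=30.0, min_area=500)
    clf = TracerClassifier().fit()
    from .roi import assign_cells_to_rois

    injection = None
    auto_counts: dict[str, int] = {}
    true_counts: dict[str, int] = {}
    n_true_pos = 0
    n_recalled = 0
    for b in bundles:
        if not b.mapped:
            continue
        if b.injection is not None:
            injection = b.injection
        image = SectionImage(b.image, section_id=b.section_id)
        cells = detect_cells(image, segmenter)
        flags = clf.predict(cells)
        positives = cells.loc[flags]
        truth_pos = [c for c in b.truth if c.true_positive]
        n_true_pos += len(truth_pos)
        if len(positives) and truth_pos:
            d, _ = cKDTree(positives[["x", "y"]].to_numpy()).query(
                np.array([c.true_center for c in truth_pos])
            )
            n_recalled += int((d < 3.0).sum())
        counts, _, _ = assign_cells_to_rois(positives, b.rois)
        for name, c in counts.items():
            auto_counts[name] = auto_counts.get(name, 0) + int(c)
        for c in truth_pos:
            true_counts[c.true_roi] = true_counts.get(c.true_roi, 0) + 1

    names = sorted(auto_counts)
    auto = pd.Series({n: float(auto_counts[n]) for n in names})
    true = pd.Series({n: float(true_counts.get(n, 0)) for n in names})
    rec_table = zero_injection_rois(CountTable("auto", raw=auto), injection)
    tru_table = zero_injection_rois(CountTable("true", raw=true), injection)
    recovered = counts_to_proportions(rec_table.zeroed)
    planted = counts_to_proportions(tru_table.zeroed)
    return {
        "detection_recall": n_recalled / n_true_pos,
        "n_true_positive_cells": n_true_pos,
        "proportion_linf_error": float((recovered - planted).abs().max()),
        "proportion_sum": float(recovered.sum()),
        "injection_rois": list(injection.covered_rois),
        "recovered": recovered,
        "planted": planted,
    }


def anova_oracle_agreement(seed: int = 0, n_matrices: int = 20) -> dict:
    """One-way RM-ANOVA F vs an independent loop-based sums-of-squares
    computation on random 5 x 4 matrices."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        x = rng.normal(size=(5, 4))
        res = one_way_rm_anova(RMDesign(x))
        n, k = x.shape
        gm = x.mean()
        ss_region = sum(n * (x[:, j].mean() - gm) ** 2 for j in range(k))
        ss_subject = sum(k * (x[i, :].mean() - gm) ** 2 for i in range(n))
        ss_total = sum(
            (x[i, j] - gm) ** 2 for i in range(n) for j in range(k)
        )
        ss_error = ss_total - ss_region - ss_subject
        F = (ss_region / (k - 1)) / (ss_error / ((k - 1) * (n - 1)))
        worst = max(worst, abs(res.F - F))
    return {"max_abs_F_difference": worst, "n_matrices": n_matrices}


def anova_type1_error(seed: int = 0, n_reps: int = 2000, alpha: float = 0.05) -> dict:
    """Monte-Carlo type-I error of the one-way RM F-test under an iid
    normal null (sphericity holds, so the nominal level should be hit)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        x = rng.normal(size=(8, 5))
        rejections += one_way_rm_anova(RMDesign(x)).p < alpha
    rate = rejections / n_reps
    half_width = 1.96 * np.sqrt(alpha * (1 - alpha) / n_reps)
    return {
        "rejection_rate": rate,
        "nominal_alpha": alpha,
        "binomial_halfwidth": half_width,
        "n_reps": n_reps,
    }
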