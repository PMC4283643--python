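"""Repeated-measures ANOVA and Bonferroni post-hoc machinery.

Regional proportion profiles are compared with a one-way within-subject
ANOVA (region as the repeated factor) or, when animals fall into
injection-placement groups (medial vs lateral, rostral vs caudal), a
two-way split-plot ANOVA with group as the between-subject factor.
Classical uncorrected degrees of freedom are reported by default
(Greenhouse-Geisser is available behind a flag); post-hoc paired
comparisons use Bonferroni adjustment with an explicit family size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RMDesign",
    "AnovaResult",
    "one_way_rm_anova",
    "two_way_rm_anova",
    "bonferroni_posthoc",
]


@dataclass
class RMDesign:
    """Complete subjects x within-levels design, optionally grouped.

    ``data`` is an ``(n_subjects, k_levels)`` array or DataFrame (columns
    are the within-subject levels, e.g. ROIs); ``groups`` holds one
    between-subject label per row.  Missing cells are rejected.
    """

    data: np.ndarray | pd.DataFrame
    groups: np.ndarray | None = None
    alpha: float = 0.05
    level_names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if isinstance(self.data, pd.DataFrame):
            self.level_names = [str(c) for c in self.data.columns]
            values = self.data.to_numpy(dtype=float)
        else:
            values = np.asarray(self.data, dtype=float)
            self.level_names = [f"level{j}" for j in range(values.shape[1])]
        if values.ndim != 2:
            raise ValueError("design data must be 2-D (subjects x levels)")
        if not np.all(np.isfinite(values)):
            raise ValueError("design contains missing or non-finite cells")
        n, k = values.shape
        if k < 2:
            raise ValueError("need at least 2 within-subject levels")
        if n < 2:
            raise ValueError("need at least 2 subjects")
        self._values = values
        if self.groups is not None:
            g = np.asarray(self.groups)
            if len(g) != n:
                raise ValueError("one group label per subject required")
            labels, counts = np.unique(g, return_counts=True)
            if len(labels) < 2:
                raise ValueError("need at least 2 between-subject groups")
            if np.any(counts < 2):
                small = labels[counts < 2].tolist()
                raise ValueError(f"groups with < 2 subjects: {small}")
            self.groups = g
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @property
    def values(self) -> np.ndarray:
        return self._values


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    ss: dict[str, float]

    def __str__(self) -> str:  # convenient for reports
        return f"{self.effect}: F({self.df_num}, {self.df_den}) = {self.F:.3f}, p = {self.p:.4g}"


def _gg_epsilon(values: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from the sample covariance."""
    k = values.shape[1]
    S = np.cov(values, rowvar=False)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(row_means**2) + k**2 * mean_all**2)
    return float(num / den) if den > 0 else 1.0


def one_way_rm_anova(design: RMDesign, gg_correction: bool = False) -> AnovaResult:
    """Classical one-way within-subject ANOVA.

    Decomposes total variation into region (within-level), subject and
    residual sums of squares; ``F = MS_region / MS_error`` with
    ``df = (k-1, (k-1)(n-1))``.
    """
    if design.groups is not None:
        raise ValueError("one-way design must not carry a between factor")
    x = design.values
    n, k = x.shape
    gm = x.mean()
    level_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_region = n * float(np.sum((level_means - gm) ** 2))
    ss_subject = k * float(np.sum((subj_means - gm) ** 2))
    ss_total = float(np.sum((x - gm) ** 2))
    ss_error = ss_total - ss_region - ss_subject
    df_num, df_den = k - 1, (k - 1) * (n - 1)
    ms_region = ss_region / df_num
    ms_error = ss_error / df_den
    F = ms_region / ms_error if ms_error > 0 else 0.0
    if gg_correction:
        eps = _gg_epsilon(x)
        p = float(sps.f.sf(F, eps * df_num, eps * df_den))
    else:
        p = float(sps.f.sf(F, df_num, df_den))
    return AnovaResult(
        effect="region",
        F=float(F),
        df_num=df_num,
        df_den=df_den,
        p=p,
        ss={
            "region": ss_region,
            "subject": ss_subject,
            "error": ss_error,
            "total": ss_total,
        },
    )


def two_way_rm_anova(design: RMDesign) -> dict[str, AnovaResult]:
    """Split-plot (mixed) ANOVA: between-subject group x within regions.

    Returns the ``group`` and ``region`` main effects and the
    ``interaction``, with classical uncorrected degrees of freedom;
    the interaction df is ``((g-1)(k-1), (N-g)(k-1))``.
    """
    if design.groups is None:
        raise ValueError("two-way design requires between-subject group labels")
    x = design.values
    N, k = x.shape
    groups = np.asarray(design.groups)
    labels = np.unique(groups)
    g = len(labels)

    gm = x.mean()
    ss_total = float(np.sum((x - gm) ** 2))

    subj_means = x.mean(axis=1)
    level_means = x.mean(axis=0)

    ss_between = 0.0
    ss_subj_within = 0.0
    ss_cells = 0.0
    for lab in labels:
        sel = groups == lab
        n_g = int(sel.sum())
        gmean = x[sel].mean()
        ss_between += k * n_g * (gmean - gm) ** 2
        ss_subj_within += k * float(np.sum((subj_means[sel] - gmean) ** 2))
        cell_means = x[sel].mean(axis=0)
        ss_cells += n_g * float(np.sum((cell_means - gm) ** 2))
    ss_region = N * float(np.sum((level_means - gm) ** 2))
    ss_interaction = ss_cells - ss_between - ss_region
    ss_error_within = ss_total - ss_cells - ss_subj_within

    df_group, df_group_err = g - 1, N - g
    df_region, df_within_err = k - 1, (N - g) * (k - 1)
    df_inter = (g - 1) * (k - 1)

    def result(effect, ss_num, df_num, ss_den, df_den):
        ms_num = ss_num / df_num
        ms_den = ss_den / df_den
        F = ms_num / ms_den if ms_den > 0 else 0.0
        return AnovaResult(
            effect=effect,
            F=float(max(F, 0.0)),
            df_num=df_num,
            df_den=df_den,
            p=float(sps.f.sf(max(F, 0.0), df_num, df_den)),
            ss={
                "effect": float(ss_num),
                "error": float(ss_den),
                "total": ss_total,
            },
        )

    return {
        "group": result("group", ss_between, df_group, ss_subj_within, df_group_err),
        "region": result("region", ss_region, df_region, ss_error_within, df_within_err),
        "interaction": result(
            "group x region", ss_interaction, df_inter, ss_error_within, df_within_err
        ),
    }


def bonferroni_posthoc(
    design: RMDesign,
    pairs: list[tuple[str, str]],
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Paired-t comparisons between within-levels, Bonferroni adjusted.

    ``n_comparisons`` sets the family size explicitly (defaults to
    ``len(pairs)``); adjusted p is ``min(1, raw_p * family)``.
    """
    if not pairs:
        raise ValueError("empty comparison list")
    names = design.level_names
    m = n_comparisons if n_comparisons is not None else len(pairs)
    x = design.values
    rows = []
    for a, b in pairs:
        if a not in names or b not in names:
            raise KeyError(f"unknown level in pair ({a!r}, {b!r})")
        ia, ib = names.index(a), names.index(b)
        t, p = sps.ttest_rel(x[:, ia], x[:, ib])
        p_adj = min(1.0, float(p) * m)
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": p_adj,
                "significant": p_adj < design.alpha,
            }
        )
    return pd.DataFrame(rows)
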