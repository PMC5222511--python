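"""Repeated-measures statistics over the frame-averaging metric tables.

Each metric (SNR, endpoints, segment length, density, ICD) is tabulated as
subjects x frame-counts (1..10) per peripapillary region.  A one-way
within-subjects ANOVA with the Greenhouse-Geisser sphericity correction
tests for any frame-count effect; a Bonferroni-corrected paired t-test over
the nine sequential comparisons (1v2, 2v3, ..., 9v10) localises it; the
"optimal" number of averaged frames is the smallest n after which no
sequential gain is significant.  Percent differences between the reference
and averaged means summarise effect sizes, and length density converts to
an area-coverage percentage by assuming a uniform 9 um capillary diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MetricMatrix",
    "RMAnovaResult",
    "PosthocResult",
    "NormativeFlag",
    "metric_matrix",
    "percent_difference",
    "rm_anova_gg",
    "sequential_posthoc",
    "optimal_frames",
    "area_coverage_from_length_density",
    "normative_comparison",
    "table1_percent_differences",
    "table2_optimal_frames",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = (
    "snr",
    "n_endpoints",
    "mean_segment_length_um",
    "density_mm_inv",
    "icd_um",
)


@dataclass
class MetricMatrix:
    """Subjects x frame-count table for one metric in one region.

    Subjects with any missing or excluded cell are dropped listwise, so
    every retained subject contributes a complete within-subject profile.
    """

    metric: str
    region: str
    values: pd.DataFrame  # index: subject, columns: n_frames (sorted)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_levels(self) -> int:
        return self.values.shape[1]


def metric_matrix(df: pd.DataFrame, metric: str, region: str) -> MetricMatrix:
    """Pivot a tidy metrics table into a complete subjects x levels matrix."""
    sub = df[(df["region"] == region)]
    if "excluded" in sub.columns:
        sub = sub.copy()
        sub.loc[sub["excluded"].astype(bool), metric] = np.nan
    wide = sub.pivot_table(index="subject", columns="n_frames", values=metric, aggfunc="mean")
    wide = wide.reindex(sorted(wide.columns), axis=1).dropna(axis=0, how="any")
    return MetricMatrix(metric=metric, region=region, values=wide)


def percent_difference(ref_mean: float, avg_mean: float) -> float:
    """Signed percent change from a reference mean to an averaged mean."""
    if ref_mean == 0:
        raise ValueError("reference mean is zero; percent difference undefined")
    return 100.0 * (avg_mean - ref_mean) / ref_mean


@dataclass(frozen=True)
class RMAnovaResult:
    F: float
    df_num: float
    df_den: float
    epsilon_gg: float
    p_gg: float
    p_uncorrected: float = np.nan


def rm_anova_gg(data: MetricMatrix | pd.DataFrame | np.ndarray) -> RMAnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    Decomposes total variability into subject, condition and error sums of
    squares; epsilon comes from the double-centred sample covariance of the
    within-subject conditions and scales both degrees of freedom before the
    F test.  With two levels epsilon is exactly 1 (sphericity is trivial).
    """
    y = np.asarray(data.values if isinstance(data, MetricMatrix) else data, dtype=float)
    if isinstance(data, pd.DataFrame):
        y = data.to_numpy(dtype=float)
    if y.ndim != 2:
        raise ValueError("need a subjects x levels matrix")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 subjects and >= 2 levels")
    if not np.isfinite(y).all():
        raise ValueError("matrix contains missing values; drop incomplete subjects first")

    grand = y.mean()
    col_means = y.mean(axis=0)
    row_means = y.mean(axis=1)
    ss_cond = n * float(((col_means - grand) ** 2).sum())
    ss_subj = k * float(((row_means - grand) ** 2).sum())
    ss_tot = float(((y - grand) ** 2).sum())
    ss_err = ss_tot - ss_cond - ss_subj

    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err if df_err > 0 else np.nan

    if ss_cond <= 1e-300 * max(ss_tot, 1.0):
        return RMAnovaResult(0.0, float(df_cond), float(df_err), 1.0, 1.0, 1.0)
    f_stat = ms_cond / ms_err if ms_err > 0 else np.inf

    if k == 2:
        eps = 1.0
    else:
        s = np.cov(y, rowvar=False, ddof=1)
        sd = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
        denom = (k - 1) * float((sd**2).sum())
        eps = float(np.trace(sd) ** 2 / denom) if denom > 0 else 1.0
        eps = min(max(eps, 1.0 / (k - 1)), 1.0)

    p_unc = float(sps.f.sf(f_stat, df_cond, df_err)) if np.isfinite(f_stat) else 0.0
    p_gg = float(sps.f.sf(f_stat, df_cond * eps, df_err * eps)) if np.isfinite(f_stat) else 0.0
    return RMAnovaResult(
        F=float(f_stat),
        df_num=df_cond * eps,
        df_den=df_err * eps,
        epsilon_gg=eps,
        p_gg=p_gg,
        p_uncorrected=p_unc,
    )


@dataclass
class PosthocResult:
    """Bonferroni-corrected paired comparisons of sequential frame counts."""

    pairs: list[tuple[int, int]]
    p_raw: np.ndarray
    p_adj: np.ndarray
    alpha: float = 0.05
    flagged_degenerate: list[tuple[int, int]] = field(default_factory=list)

    @property
    def significant(self) -> np.ndarray:
        return self.p_adj < self.alpha


def sequential_posthoc(
    data: MetricMatrix | pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
    all_pairs: bool = False,
) -> PosthocResult:
    """Paired two-sided t-tests on sequential frame-count pairs with a
    Bonferroni correction (m = number of pairs; 9 for ten levels).

    ``all_pairs=True`` switches to every pairwise comparison (m = k(k-1)/2).
    A pair with zero within-pair variance gets p 0 or 1 by whether the
    means differ, and is flagged.
    """
    if isinstance(data, MetricMatrix):
        y = data.values.to_numpy(dtype=float)
        levels = [int(c) for c in data.values.columns]
    elif isinstance(data, pd.DataFrame):
        y = data.to_numpy(dtype=float)
        levels = [int(c) for c in data.columns]
    else:
        y = np.asarray(data, dtype=float)
        levels = list(range(1, y.shape[1] + 1))
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("post hoc needs >= 2 subjects and >= 2 levels")

    if all_pairs:
        idx_pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    else:
        idx_pairs = [(i, i + 1) for i in range(k - 1)]
    pairs = [(levels[i], levels[j]) for i, j in idx_pairs]
    m = len(pairs)
    p_raw = np.empty(m)
    degenerate = []
    for idx, (i, j) in enumerate(idx_pairs):
        diff = y[:, j] - y[:, i]
        if np.allclose(diff.std(ddof=1), 0.0):
            p_raw[idx] = 0.0 if abs(diff.mean()) > 0 else 1.0
            degenerate.append(pairs[idx])
        else:
            p_raw[idx] = sps.ttest_rel(y[:, j], y[:, i]).pvalue
    p_adj = np.minimum(p_raw * m, 1.0)
    return PosthocResult(pairs, p_raw, p_adj, alpha, degenerate)


def optimal_frames(posthoc: PosthocResult, alpha: float | None = None) -> int:
    """Smallest n such that every sequential comparison from (n, n+1)
    onward is non-significant.

    If nothing is significant the answer is the first level (averaging
    never helps significantly); if the last comparison is significant the
    answer is the last level.
    """
    alpha = posthoc.alpha if alpha is None else alpha
    sig = posthoc.p_adj < alpha
    last_sig = -1
    for i, s in enumerate(sig):
        if s:
            last_sig = i
    if last_sig < 0:
        return posthoc.pairs[0][0]
    return posthoc.pairs[last_sig][1]


def area_coverage_from_length_density(
    density_mm_inv: float, diameter_um: float = 9.0
) -> float:
    """Convert vessel length density (mm^-1) to an area-coverage percentage
    assuming a uniform capillary diameter (9 um histologically)."""
    if density_mm_inv < 0:
        raise ValueError("density must be non-negative")
    return 100.0 * density_mm_inv * (diameter_um / 1000.0)


@dataclass
class NormativeFlag:
    region: str
    value: float
    quantile: float
    below_lower_whisker: bool
    below_minimum: bool


def normative_comparison(
    control_densities: dict[str, np.ndarray] | pd.DataFrame,
    case_density: dict[str, float],
    min_controls: int = 5,
) -> list[NormativeFlag]:
    """Place one eye's per-region density within a healthy-control sample.

    Returns each case value's empirical quantile among controls plus flags
    relative to the control box plot (below Q1 - 1.5 IQR, below minimum).
    """
    if isinstance(control_densities, pd.DataFrame):
        controls = {
            str(r): g.dropna().to_numpy(dtype=float)
            for r, g in control_densities.groupby("region")["density_mm_inv"]
        }
    else:
        controls = {r: np.asarray(v, dtype=float) for r, v in control_densities.items()}
    out = []
    for region, value in case_density.items():
        if region not in controls:
            raise KeyError(f"region {region!r} absent from control data")
        sample = controls[region]
        if len(sample) < min_controls:
            raise ValueError(f"need >= {min_controls} controls in region {region!r}")
        q1, q3 = np.percentile(sample, [25, 75])
        fence = q1 - 1.5 * (q3 - q1)
        inside = sample[sample >= fence]
        # box-plot convention: the whisker ends at the lowest datum inside
        # the Q1 - 1.5 IQR fence
        whisker_end = inside.min() if inside.size else sample.min()
        quantile = float(np.mean(sample <= value))
        out.append(
            NormativeFlag(
                region=region,
                value=float(value),
                quantile=quantile,
                below_lower_whisker=bool(value < whisker_end),
                below_minimum=bool(value < sample.min()),
            )
        )
    return out


def table1_percent_differences(
    df: pd.DataFrame,
    metrics: tuple[str, ...] = METRIC_COLUMNS,
    n_ref: int = 1,
    n_avg: tuple[int, ...] = (5, 10),
    mode: str = "ratio_of_means",
) -> pd.DataFrame:
    """Percent difference from the reference to averaged images, per metric
    and region.

    ``mode='ratio_of_means'`` (default) takes the percent difference of
    across-subject means; ``'mean_of_ratios'`` averages per-subject percent
    differences instead.
    """
    if mode not in ("ratio_of_means", "mean_of_ratios"):
        raise ValueError("mode must be 'ratio_of_means' or 'mean_of_ratios'")
    rows = []
    for metric in metrics:
        for region in sorted(df["region"].unique()):
            mat = metric_matrix(df, metric, region)
            if mat.n_subjects == 0 or n_ref not in mat.values.columns:
                continue
            for n in n_avg:
                if n not in mat.values.columns:
                    continue
                ref_col = mat.values[n_ref]
                avg_col = mat.values[n]
                if mode == "ratio_of_means":
                    pct = percent_difference(float(ref_col.mean()), float(avg_col.mean()))
                else:
                    per_subject = 100.0 * (avg_col - ref_col) / ref_col
                    pct = float(per_subject.mean())
                rows.append(
                    {"metric": metric, "region": region, "n_frames": n, "percent_difference": pct}
                )
    return pd.DataFrame(rows)


def table2_optimal_frames(
    df: pd.DataFrame,
    metrics: tuple[str, ...] = METRIC_COLUMNS,
    alpha: float = 0.05,
    all_pairs: bool = False,
) -> pd.DataFrame:
    """Optimal number of averaged frames per metric and region, with the
    supporting RM-ANOVA results."""
    rows = []
    for metric in metrics:
        for region in sorted(df["region"].unique()):
            mat = metric_matrix(df, metric, region)
            if mat.n_subjects < 2 or mat.n_levels < 2:
                continue
            anova = rm_anova_gg(mat)
            post = sequential_posthoc(mat, alpha=alpha, all_pairs=all_pairs)
            rows.append(
                {
                    "metric": metric,
                    "region": region,
                    "n_subjects": mat.n_subjects,
                    "F": anova.F,
                    "epsilon_gg": anova.epsilon_gg,
                    "p_gg": anova.p_gg,
                    "optimal_frames": optimal_frames(post, alpha),
                }
            )
    return pd.DataFrame(rows)
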