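"""Summary-statistics group tests, behavioral ANOVA, and DTI comparisons.

Covers the cohort-matching table (two-sample t and Cohen's d from
printed means/SDs), the 2x2 group-by-format ANOVA on in-scanner
behaviour, and per-tract group comparisons of diffusion metrics
(FA/MD/AD/RD) with BH-FDR across tracts within each metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import DataError, NumericalError
from .rois import bh_adjust

DTI_METRICS = ("FA", "MD", "AD", "RD")


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DataError(f"n must be >= 2, got {self.n}")
        if self.sd <= 0:
            raise DataError(f"sd must be > 0, got {self.sd}")

    @classmethod
    def from_values(cls, values: np.ndarray) -> "GroupSummary":
        v = np.asarray(values, float)
        return cls(mean=float(v.mean()), sd=float(v.std(ddof=1)), n=v.size)


#: Cohort-matching summaries (dyscalculia vs. control, n = 24 each):
#: standardized math tests (French Kit, Tempo Test Arithmetic, WAIS
#: Arithmetic), reading z-score, WAIS IQ subtests, and motor-speed task.
MATCHING_VARIABLES: dict[str, tuple[GroupSummary, GroupSummary]] = {
    "Age (years)": (GroupSummary(21.96, 2.16, 24), GroupSummary(21.67, 2.20, 24)),
    "French Kit": (GroupSummary(35.00, 7.97, 24), GroupSummary(54.50, 15.86, 24)),
    "Tempo Test Arithmetic": (GroupSummary(113.0, 17.46, 24), GroupSummary(148.75, 21.92, 24)),
    "Arithmetic (WAIS)": (GroupSummary(7.50, 2.06, 24), GroupSummary(10.79, 2.21, 24)),
    "Z-score Reading": (GroupSummary(-0.20, 1.12, 24), GroupSummary(0.20, 0.62, 24)),
    "Matrix reasoning (WAIS)": (GroupSummary(9.08, 2.90, 24), GroupSummary(10.23, 3.01, 24)),
    "Vocabulary (WAIS)": (GroupSummary(10.79, 2.99, 24), GroupSummary(12.08, 2.26, 24)),
    "Motor accuracy (%)": (GroupSummary(96.88, 10.82, 24), GroupSummary(98.75, 2.21, 24)),
    "Motor reaction time (s)": (GroupSummary(0.40, 0.08, 24), GroupSummary(0.36, 0.06, 24)),
}


def pooled_sd(a: GroupSummary, b: GroupSummary) -> float:
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    return float(np.sqrt(sp2))


def two_sample_t_summary(a: GroupSummary, b: GroupSummary) -> tuple[float, int, float]:
    """Pooled-variance two-sided t-test from summary statistics.

    Returns (t, df, p) with df = n_a + n_b - 2. Sign convention: positive
    t means group a's mean exceeds group b's.
    """
    sp = pooled_sd(a, b)
    t = (a.mean - b.mean) / (sp * np.sqrt(1 / a.n + 1 / b.n))
    df = a.n + b.n - 2
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def cohens_d_summary(a: GroupSummary, b: GroupSummary) -> float:
    """d = (mean_a - mean_b) / pooled SD (the equal-n simplification
    sqrt((sd_a^2 + sd_b^2)/2) when n_a = n_b)."""
    if a.n == b.n:
        sp = np.sqrt((a.sd**2 + b.sd**2) / 2)
    else:
        sp = pooled_sd(a, b)
    if sp == 0:
        raise NumericalError("zero pooled SD")
    return float((a.mean - b.mean) / sp)


def matching_table(
    measures: dict[str, tuple[GroupSummary, GroupSummary]] | None = None,
) -> pd.DataFrame:
    """t, df, p, and Cohen's d for each cohort-matching measure."""
    measures = MATCHING_VARIABLES if measures is None else measures
    rows = []
    for name, (a, b) in measures.items():
        t, df, p = two_sample_t_summary(a, b)
        rows.append(
            dict(measure=name, mean_dyscalculia=a.mean, sd_dyscalculia=a.sd,
                 mean_control=b.mean, sd_control=b.sd, t=t, abs_t=abs(t),
                 df=df, p=p, cohens_d=cohens_d_summary(a, b))
        )
    return pd.DataFrame(rows)


def anova_2x2(data: pd.DataFrame) -> pd.DataFrame:
    """Two-way between-observations ANOVA: score ~ group * format.

    ``data`` needs columns group, format, score with >= 2 observations per
    cell. With 48 subjects x 2 formats this yields the (1, 92) df layout;
    the two formats of one subject are treated as independent rows.
    """
    for col in ("group", "format", "score"):
        if col not in data:
            raise DataError(f"missing column {col!r}")
    counts = data.groupby(["group", "format"]).size()
    if len(counts) < 4 or (counts < 2).any():
        raise DataError("every group x format cell needs >= 2 observations")
    model = smf.ols("score ~ C(group) * C(format)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    # degenerate all-equal data: every SS is round-off; F is 0/0 -> define 0
    scale = float((data.score**2).mean()) or 1.0
    resid_ms = table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"]
    if resid_ms <= 1e-12 * scale:
        for effect in table.index[:-1]:
            if table.loc[effect, "sum_sq"] <= 1e-12 * scale:
                table.loc[effect, "F"] = 0.0
                table.loc[effect, "PR(>F)"] = 1.0
    out = table.rename(
        index={
            "C(group)": "group",
            "C(format)": "format",
            "C(group):C(format)": "group x format",
            "Residual": "residual",
        }
    )
    out.index.name = "effect"
    return out


def dti_group_compare(
    table: pd.DataFrame,
    groups: tuple[str, str] = ("dyscalculia", "control"),
    metrics: tuple[str, ...] = DTI_METRICS,
) -> pd.DataFrame:
    """Two-sample t per tract and metric, BH-FDR across tracts per metric.

    ``table``: one row per subject x tract with columns subject, group,
    tract and the metric columns. Subjects with a missing value for a
    tract are excluded from that tract's test (count reported).
    """
    ga, gb = groups
    rows = []
    for tract, sub in table.groupby("tract"):
        for metric in metrics:
            if metric not in sub:
                raise DataError(f"missing metric column {metric!r}")
            a = sub.loc[sub.group == ga, metric].to_numpy(float)
            b = sub.loc[sub.group == gb, metric].to_numpy(float)
            n_missing = int(np.isnan(a).sum() + np.isnan(b).sum())
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            if a.size < 2 or b.size < 2:
                raise DataError(f"tract {tract!r}: both groups must be present")
            t, p = stats.ttest_ind(a, b)
            rows.append(
                dict(tract=tract, metric=metric, t=float(t), p=float(p),
                     n_a=a.size, n_b=b.size, n_excluded=n_missing)
            )
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    for metric in metrics:
        sel = out.metric == metric
        out.loc[sel, "p_fdr"] = bh_adjust(out.loc[sel, "p"].to_numpy())
    return out
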