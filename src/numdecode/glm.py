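"""First-level GLM: per-run condition-vs-baseline t-patterns.

Per run, each voxel's time course is modelled as a linear combination of
8 HRF-convolved condition boxcars, a fixation (baseline) regressor, the
6 motion parameters, and an intercept. Ordinary least squares gives the
betas; the decoding substrate is the t-statistic of the
condition-minus-fixation contrast, t = c'b / sqrt(s2 * c'(X'X)^-1 c),
with df = volumes - rank(X). No prewhitening is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .design import RunSchedule
from .errors import DataError
from .hrf import convolved_regressor

MOTION_LABELS = ("tx", "ty", "tz", "rx", "ry", "rz")
FIXATION_LABEL = "fixation"
INTERCEPT_LABEL = "intercept"


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_volumes, n_regressors)
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != self.matrix.shape[1]:
            raise DataError("label count != regressor count")
        if len(set(self.labels)) != len(self.labels):
            raise DataError("regressor labels not unique")

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]


def build_design_matrix(
    schedule: RunSchedule, motion: np.ndarray, tr: float | None = None
) -> DesignMatrix:
    """Condition + fixation + motion + intercept design at TR sampling."""
    tr = schedule.design.tr if tr is None else tr
    n_vols = int(round(schedule.total_duration / tr))
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise DataError(f"motion table must be (n_volumes, 6), got {motion.shape}")
    if motion.shape[0] != n_vols:
        raise DataError(
            f"schedule implies {n_vols} volumes but motion table has "
            f"{motion.shape[0]} rows"
        )
    conditions = [
        c for c in schedule.design.conditions
        if any(b.condition == c for b in schedule.experimental_blocks)
    ]
    cols = [
        convolved_regressor(schedule, condition=c, tr=tr, n_volumes=n_vols)
        for c in conditions
    ]
    cols.append(convolved_regressor(schedule, kind="fixation", tr=tr, n_volumes=n_vols))
    labels = list(conditions) + [FIXATION_LABEL]
    matrix = np.column_stack(cols + [motion, np.ones((n_vols, 1))])
    labels += list(MOTION_LABELS) + [INTERCEPT_LABEL]
    return DesignMatrix(matrix=matrix, labels=tuple(labels))


@dataclass
class GLMFit:
    betas: np.ndarray  # (n_voxels, n_regressors)
    residual_variance: np.ndarray  # (n_voxels,)
    df: int
    design: DesignMatrix
    data_scale: np.ndarray | None = None  # per-voxel mean square of the data


def fit_glm(timecourses: np.ndarray, design: DesignMatrix) -> GLMFit:
    """OLS fit of every voxel's time course against the design.

    Rank-deficient designs produce a warning and the minimum-norm solution.
    """
    y = np.atleast_2d(np.asarray(timecourses, dtype=float))  # (V, T)
    x = design.matrix
    if y.shape[1] != x.shape[0]:
        raise DataError(
            f"time axis mismatch: data has {y.shape[1]} volumes, design has "
            f"{x.shape[0]} rows"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        warnings.warn(
            f"design matrix rank {rank} < {x.shape[1]} columns; using the "
            "minimum-norm (pseudo-inverse) solution",
            stacklevel=2,
        )
    betas = (np.linalg.pinv(x) @ y.T).T  # (V, K)
    resid = y - betas @ x.T
    df = y.shape[1] - rank
    sigma2 = (
        (resid**2).sum(axis=1) / df if df > 0 else np.full(y.shape[0], np.nan)
    )
    return GLMFit(betas=betas, residual_variance=sigma2, df=df, design=design,
                  data_scale=(y**2).mean(axis=1))


@dataclass
class ConditionTPatterns:
    """Per run x condition voxel t-statistics (the decoding substrate)."""

    t: dict[str, np.ndarray]  # condition -> (n_voxels,) for one run
    df: int
    zero_variance: np.ndarray  # (n_voxels,) bool flags


def t_contrast(
    fit: GLMFit, contrast: dict[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """t-map of a named-regressor contrast; zero-variance voxels -> t = 0,
    flagged in the returned boolean mask rather than left infinite."""
    for name in contrast:
        if name not in fit.design.labels:
            raise DataError(f"unknown regressor in contrast: {name!r}")
    c = np.array([contrast.get(lab, 0.0) for lab in fit.design.labels])
    x = fit.design.matrix
    xtx_inv = np.linalg.pinv(x.T @ x)
    cvar = float(c @ xtx_inv @ c)
    effect = fit.betas @ c
    scale = fit.data_scale if fit.data_scale is not None else np.ones_like(
        fit.residual_variance
    )
    # "zero" residual variance judged relative to the data's magnitude, so
    # exact fits are flagged despite float round-off
    zero = ~(fit.residual_variance > 1e-12 * scale)
    se2 = fit.residual_variance * cvar
    valid = se2 > 0
    t = np.zeros_like(effect)
    np.divide(effect, np.sqrt(se2, where=valid, out=np.ones_like(se2)),
              out=t, where=valid)
    return t, zero


def condition_t_patterns(fit: GLMFit, conditions: list[str] | None = None) -> ConditionTPatterns:
    """Condition-minus-fixation t-pattern per condition for one run's fit."""
    if conditions is None:
        conditions = [
            lab for lab in fit.design.labels
            if lab not in (FIXATION_LABEL, INTERCEPT_LABEL) + MOTION_LABELS
        ]
    t: dict[str, np.ndarray] = {}
    zero = np.zeros(fit.betas.shape[0], dtype=bool)
    for cond in conditions:
        tmap, z = t_contrast(fit, {cond: 1.0, FIXATION_LABEL: -1.0})
        t[cond] = tmap
        zero |= z
    return ConditionTPatterns(t=t, df=fit.df, zero_variance=zero)


def estimate_t_patterns(
    timecourses: np.ndarray,
    schedule: RunSchedule,
    motion: np.ndarray,
    tr: float | None = None,
) -> ConditionTPatterns:
    """Convenience: design -> OLS -> condition-vs-fixation t in one call."""
    design = build_design_matrix(schedule, motion, tr)
    return condition_t_patterns(fit_glm(timecourses, design))
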