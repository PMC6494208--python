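"""Seed-based functional connectivity.

Seed time courses go through the six preprocessing steps of the study,
in order: (1) 0.01-0.2 Hz band-pass, (2) regression of motion
parameters and their first derivatives, (3) regression of
white-matter/ventricle signals and their first derivatives,
(4) regression of the task-vs-baseline regressor, (5) scrubbing of
high-motion volumes, (6) spatial smoothing (volumetric mode only, not
applicable to ROI-averaged series). Pearson correlations between each
seed pair are Fisher r-to-z transformed; within-group edges are tested
against zero (BH-FDR at 0.001 across edges) and between groups with
two-sample t-tests (BH-FDR at 0.05 across edges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .design import RunSchedule
from .errors import ConfigurationError, DataError
from .hrf import convolved_regressor
from .rois import bh_adjust
from .simulate import TimeCourseSet


@dataclass(frozen=True)
class PreprocSpec:
    band: tuple[float, float] = (0.01, 0.2)
    fd_threshold_mm: float = 0.5
    scrub_back: int = 1
    scrub_forward: int = 2
    head_radius_mm: float = 50.0
    filter_order: int = 4


def bandpass(
    ts: np.ndarray, band: tuple[float, float] = (0.01, 0.2), tr: float = 3.0
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the time axis."""
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    nyq = 0.5 / tr
    lo, hi = band
    if not 0 < lo < hi:
        raise ConfigurationError(f"invalid band {band}")
    if lo >= nyq:
        raise ConfigurationError(
            f"band {band} lies entirely above Nyquist {nyq:.4g} Hz at TR={tr}s"
        )
    if hi >= nyq:
        # the nominal 0.01-0.2 Hz band exceeds Nyquist at TR = 3 s
        # (0.167 Hz); clip the upper edge, making the filter effectively
        # high-pass at the lower cut
        warnings.warn(
            f"band upper edge {hi} Hz >= Nyquist {nyq:.4g} Hz at TR={tr}s; "
            f"clipping to {0.99 * nyq:.4g} Hz",
            stacklevel=2,
        )
        hi = 0.99 * nyq
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=1.0 / tr, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                             (sos[:, 5] == 0).sum()))
    if ts.shape[1] <= padlen:
        raise DataError(
            f"series length {ts.shape[1]} too short for zero-phase filtering "
            f"(needs > {padlen} samples)"
        )
    return signal.sosfiltfilt(sos, ts - ts.mean(axis=1, keepdims=True), axis=1)


def first_derivatives(columns: np.ndarray) -> np.ndarray:
    """Backward differences with a zero first row."""
    cols = np.atleast_2d(np.asarray(columns, float))
    d = np.diff(cols, axis=0, prepend=cols[:1])
    return d


def nuisance_regress(ts: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Residualise each region's series against the confound columns.

    An intercept is always included; rank-deficient confound matrices
    produce a warning and use the pseudo-inverse.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    c = np.atleast_2d(np.asarray(confounds, dtype=float))
    if c.shape[0] != ts.shape[1]:
        raise DataError(
            f"confound rows {c.shape[0]} != time-course length {ts.shape[1]}"
        )
    x = np.column_stack([c, np.ones(c.shape[0])])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        warnings.warn("rank-deficient confounds; using pseudo-inverse", stacklevel=2)
    beta = np.linalg.pinv(x) @ ts.T
    return ts - (x @ beta).T


def framewise_displacement(motion: np.ndarray, head_radius_mm: float = 50.0) -> np.ndarray:
    """FD per volume: sum of absolute backward differences of the 6 motion
    parameters, rotations (radians) converted to arc length on a
    ``head_radius_mm`` sphere. First volume has FD 0."""
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise DataError(f"motion table must be (n_volumes, 6), got {m.shape}")
    d = np.abs(np.diff(m, axis=0, prepend=m[:1]))
    d[:, 3:] *= head_radius_mm
    return d.sum(axis=1)


def scrub(
    ts: np.ndarray,
    motion: np.ndarray,
    fd_threshold: float = 0.5,
    n_back: int = 1,
    n_forward: int = 2,
    head_radius_mm: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Censor volumes with FD above threshold plus their neighbours.

    Returns (censored series, kept boolean index). Warns when fewer than
    half the volumes survive.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    n = ts.shape[1]
    if np.asarray(motion).shape[0] != n:
        raise DataError("motion table not aligned to time axis")
    fd = framewise_displacement(motion, head_radius_mm)
    bad = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(fd > fd_threshold):
        bad[max(0, i - n_back): min(n, i + n_forward + 1)] = True
    kept = ~bad
    if kept.sum() < n / 2:
        warnings.warn(
            f"scrubbing retained only {int(kept.sum())}/{n} volumes", stacklevel=2
        )
    return ts[:, kept], kept


def connectivity_matrix(ts: np.ndarray) -> np.ndarray:
    """Pearson correlations between every pair of region series."""
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    if ts.shape[1] < 3:
        raise DataError(f"need >= 3 retained volumes, got {ts.shape[1]}")
    sd = ts.std(axis=1)
    zero = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts)
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance region(s): entries undefined",
            stacklevel=2,
        )
        r[zero, :] = np.nan
        r[:, zero] = np.nan
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r: np.ndarray, clamp_eps: float = 1e-7) -> np.ndarray:
    """Fisher r-to-z: z = atanh(r), diagonal set to NaN (excluded from
    tests); |r| = 1 is clamped to 1 - clamp_eps with a warning."""
    r = np.array(r, dtype=float, copy=True)
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1):
        warnings.warn(
            f"|r| >= 1 off-diagonal; clamping to 1 - {clamp_eps}", stacklevel=2
        )
        r[off & (np.abs(r) >= 1)] = np.sign(r[off & (np.abs(r) >= 1)]) * (1 - clamp_eps)
    z = np.arctanh(r, where=off, out=np.zeros_like(r))
    np.fill_diagonal(z, np.nan)
    return z


def preprocess_subject(
    data: np.ndarray,
    motion: np.ndarray,
    tissue: np.ndarray | None,
    schedule: RunSchedule,
    tr: float,
    spec: PreprocSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Steps (1)-(5) for one subject's seed series; returns (series, kept)."""
    spec = spec or PreprocSpec()
    ts = bandpass(data, spec.band, tr)
    conf = [motion, first_derivatives(motion)]
    if tissue is not None:
        conf += [tissue, first_derivatives(tissue)]
    n_vols = ts.shape[1]
    task_run = convolved_regressor(schedule, kind="experimental", tr=tr)
    reps = int(np.ceil(n_vols / task_run.size))
    conf.append(np.tile(task_run, reps)[:n_vols, None])
    ts = nuisance_regress(ts, np.column_stack(conf))
    return scrub(
        ts, motion, spec.fd_threshold_mm, spec.scrub_back, spec.scrub_forward,
        spec.head_radius_mm,
    )


def cohort_z_matrices(
    tcs: TimeCourseSet, spec: PreprocSpec | None = None
) -> pd.DataFrame:
    """Full pipeline per subject: preprocess -> Pearson -> Fisher z.

    Returns long-format rows (subject, group, seed_a, seed_b, r, z,
    retained) over the upper-triangle edges.
    """
    spec = spec or PreprocSpec()
    regions = tcs.regions
    rows = []
    for s in tcs.subjects:
        ts, kept = preprocess_subject(
            s.data, s.motion, s.tissue, tcs.schedule, tcs.tr, spec
        )
        r = connectivity_matrix(ts)
        z = fisher_z(r)
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                rows.append(
                    dict(
                        subject=s.subject_id, group=s.group,
                        seed_a=regions[i], seed_b=regions[j],
                        r=r[i, j], z=z[i, j], retained=int(kept.sum()),
                    )
                )
    return pd.DataFrame(rows)


def group_connectivity_tests(
    z_edges: pd.DataFrame,
    groups: tuple[str, str] = ("dyscalculia", "control"),
    alpha_within: float = 0.001,
    alpha_between: float = 0.05,
) -> pd.DataFrame:
    """Edge-wise random-effects and group-difference tests on Fisher z.

    Per edge: one-sample t vs 0 within each group (BH-FDR across edges at
    ``alpha_within``) and a two-sample t between groups (BH-FDR across
    edges at ``alpha_between``), with the direction of any difference.
    Edges with undefined (NaN) values are excluded with a count.
    """
    ga, gb = groups
    rows = []
    n_dropped = 0
    for (a_name, b_name), edge in z_edges.groupby(["seed_a", "seed_b"]):
        za = edge.loc[edge.group == ga, "z"].to_numpy(float)
        zb = edge.loc[edge.group == gb, "z"].to_numpy(float)
        dropped = np.isnan(za).sum() + np.isnan(zb).sum()
        n_dropped += int(dropped)
        za, zb = za[~np.isnan(za)], zb[~np.isnan(zb)]
        if za.size < 2 or zb.size < 2:
            raise DataError(
                f"edge {a_name}-{b_name}: fewer than 2 subjects per group"
            )
        t_a, p_a = stats.ttest_1samp(za, 0.0)
        t_b, p_b = stats.ttest_1samp(zb, 0.0)
        t_ab, p_ab = stats.ttest_ind(za, zb)
        rows.append(
            dict(
                seed_a=a_name, seed_b=b_name,
                mean_z_a=za.mean(), mean_z_b=zb.mean(),
                t_within_a=float(t_a), p_within_a=float(p_a),
                t_within_b=float(t_b), p_within_b=float(p_b),
                t_between=float(t_ab), p_between=float(p_ab),
                direction=f"{ga}<{gb}" if za.mean() < zb.mean() else f"{ga}>{gb}",
                n_excluded_values=int(dropped),
            )
        )
    out = pd.DataFrame(rows)
    out["p_fdr_within_a"] = bh_adjust(out["p_within_a"].to_numpy())
    out["p_fdr_within_b"] = bh_adjust(out["p_within_b"].to_numpy())
    out["p_fdr_between"] = bh_adjust(out["p_between"].to_numpy())
    out["sig_within_a"] = out["p_fdr_within_a"] < alpha_within
    out["sig_within_b"] = out["p_fdr_within_b"] < alpha_within
    out["sig_between"] = out["p_fdr_between"] < alpha_between
    if n_dropped:
        out.attrs["n_excluded_values"] = n_dropped
    return out
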