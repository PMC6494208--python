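"""Synthetic cohorts: voxel patterns, ROI time courses, and toy volumes.

Everything downstream of image preprocessing can be exercised on data
from this module. The generator emulates the structure of the study
cohort — two groups (dyscalculia vs. control) of 24 adults, 8-12 runs of
a 280-s block design, 8 conditions (numerosities 2/4/6/8 in symbolic and
non-symbolic format) — with three knobs that encode the effects of
interest:

* ``separation``: distance between condition prototypes in voxel-pattern
  space, per (group, format, region). The default cohort gives the
  dyscalculia group a *reduced non-symbolic* separation with equal
  symbolic separation, the qualitative effect structure the decoding
  pipeline is meant to detect.
* ``noise_sd``: iid Gaussian observation noise on each run's pattern.
* ``connectivity_target``: per-group seed-by-seed correlation matrices
  for the BOLD time-course generator; the default cohort weakens the
  visual-to-visual-association couplings (PVC-IOC, PVC-FG) in the
  dyscalculia group.

Condition prototypes sit on a scaled orthonormal frame (a regular
simplex up to translation), so every same-format prototype pair is
exactly ``separation * sqrt(2)`` apart and pairwise distances scale
linearly in the separation parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .design import CONDITIONS, ExperimentDesign, RunSchedule, condition_format, generate_run_schedule
from .errors import ConfigurationError, DataError, NumericalError
from .hrf import convolved_regressor

GROUPS: tuple[str, str] = ("dyscalculia", "control")

#: Level-III regions retained as connectivity seeds in the default cohort.
DEFAULT_REGIONS: tuple[str, ...] = (
    "FG", "IFG", "SFG", "IOC", "PVC", "IPL", "SPL", "IPS",
)


def uniform_separation(
    value_by_group_format: Mapping[tuple[str, str], float],
    regions: Sequence[str] = DEFAULT_REGIONS,
) -> dict[tuple[str, str, str], float]:
    """Expand a (group, format) -> separation map to every region."""
    return {
        (g, f, r): v
        for (g, f), v in value_by_group_format.items()
        for r in regions
    }


def default_separation() -> dict[tuple[str, str, str], float]:
    """Study-structured effect map: equal symbolic, reduced non-symbolic
    pattern separation in the dyscalculia group."""
    return uniform_separation(
        {
            ("control", "symbolic"): 0.8,
            ("dyscalculia", "symbolic"): 0.8,
            ("control", "nonsymbolic"): 1.0,
            ("dyscalculia", "nonsymbolic"): 0.5,
        }
    )


def _connectivity_matrix(
    regions: Sequence[str], base_r: float, edges: Mapping[tuple[str, str], float]
) -> np.ndarray:
    n = len(regions)
    idx = {r: i for i, r in enumerate(regions)}
    m = np.full((n, n), base_r)
    np.fill_diagonal(m, 1.0)
    for (a, b), r in edges.items():
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = r
    return m


def default_connectivity_target(
    regions: Sequence[str] = DEFAULT_REGIONS,
) -> dict[str, np.ndarray]:
    """Per-group seed correlation targets: weakened PVC-IOC / PVC-FG
    coupling in the dyscalculia group against a mild common background."""
    return {
        "control": _connectivity_matrix(
            regions, 0.2, {("PVC", "IOC"): 0.6, ("PVC", "FG"): 0.6}
        ),
        "dyscalculia": _connectivity_matrix(
            regions, 0.2, {("PVC", "IOC"): 0.3, ("PVC", "FG"): 0.3}
        ),
    }


@dataclass
class SyntheticCohortSpec:
    """Parameters of one synthetic two-group cohort (defaults = study scale)."""

    n_per_group: int = 24
    n_runs: int = 10
    voxels_per_roi: dict[str, int] = field(
        default_factory=lambda: {r: 30 for r in DEFAULT_REGIONS}
    )
    separation: dict[tuple[str, str, str], float] = field(
        default_factory=default_separation
    )
    noise_sd: float = 1.0
    connectivity_target: dict[str, np.ndarray] = field(
        default_factory=default_connectivity_target
    )
    task_amplitude: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.n_runs < 1:
            raise ConfigurationError("n_per_group and n_runs must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        for region, v in self.voxels_per_roi.items():
            if v < 2:
                raise ConfigurationError(
                    f"voxels_per_roi[{region!r}] = {v} < 2: patterns with "
                    "fewer than 2 voxels cannot be standardized"
                )
        for s in self.separation.values():
            if s < 0:
                raise ConfigurationError("separation values must be >= 0")
        for group, m in self.connectivity_target.items():
            m = np.asarray(m, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ConfigurationError(
                    f"connectivity_target[{group!r}] is not square"
                )
            if not np.allclose(m, m.T):
                raise ConfigurationError(
                    f"connectivity_target[{group!r}] is not symmetric"
                )
            if not np.allclose(np.diag(m), 1.0):
                raise ConfigurationError(
                    f"connectivity_target[{group!r}] diagonal is not 1"
                )

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.voxels_per_roi)

    def sep(self, group: str, fmt: str, region: str) -> float:
        return self.separation.get((group, fmt, region), 0.0)


@dataclass
class SubjectPatterns:
    subject_id: str
    group: str
    #: region -> array of shape (n_runs, n_conditions, n_voxels)
    patterns: dict[str, np.ndarray]


@dataclass
class PatternDataset:
    """Per subject x run x condition voxel patterns, grouped by region."""

    subjects: list[SubjectPatterns]
    regions: tuple[str, ...]
    conditions: tuple[str, ...] = CONDITIONS

    def by_group(self, group: str) -> list[SubjectPatterns]:
        return [s for s in self.subjects if s.group == group]

    def validate(self) -> None:
        for s in self.subjects:
            if set(s.patterns) != set(self.regions):
                raise DataError(f"{s.subject_id}: region set mismatch")
            for region, arr in s.patterns.items():
                if arr.shape[1] != len(self.conditions):
                    raise DataError(
                        f"{s.subject_id}/{region}: expected "
                        f"{len(self.conditions)} conditions, got {arr.shape[1]}"
                    )
                if not np.isfinite(arr).all():
                    raise DataError(f"{s.subject_id}/{region}: non-finite values")


def _prototype_frame(
    n_voxels: int, n_conditions: int, rng: np.random.Generator
) -> np.ndarray:
    """Random orthonormal frame: one unit direction per condition."""
    if n_voxels < n_conditions:
        raise ConfigurationError(
            f"need >= {n_conditions} voxels for {n_conditions} orthonormal "
            f"condition prototypes, got {n_voxels}"
        )
    q, _ = np.linalg.qr(rng.normal(size=(n_voxels, n_conditions)))
    return q  # (V, C), columns orthonormal


def generate_condition_patterns(spec: SyntheticCohortSpec) -> PatternDataset:
    """Sample a cohort of per-run condition patterns.

    Per subject and region the condition prototypes are
    ``separation(group, format, region) * q_c`` with ``q_c`` an orthonormal
    frame; each run observes prototype + N(0, noise_sd) iid noise.
    Deterministic under ``spec.seed``.
    """
    conditions = CONDITIONS
    ss = np.random.SeedSequence(spec.seed)
    subjects: list[SubjectPatterns] = []
    child_seeds = ss.spawn(2 * spec.n_per_group)
    i = 0
    for group in GROUPS:
        for k in range(spec.n_per_group):
            rng = np.random.default_rng(child_seeds[i])
            i += 1
            patterns: dict[str, np.ndarray] = {}
            for region, n_vox in spec.voxels_per_roi.items():
                frame = _prototype_frame(n_vox, len(conditions), rng)
                protos = np.stack(
                    [
                        spec.sep(group, condition_format(c), region) * frame[:, ci]
                        for ci, c in enumerate(conditions)
                    ]
                )  # (C, V)
                noise = rng.normal(
                    scale=spec.noise_sd,
                    size=(spec.n_runs, len(conditions), n_vox),
                )
                patterns[region] = protos[None, :, :] + noise
            subjects.append(
                SubjectPatterns(f"{group[:3]}{k:02d}", group, patterns)
            )
    return PatternDataset(subjects=subjects, regions=spec.regions)


@dataclass
class SubjectTimeCourses:
    subject_id: str
    group: str
    data: np.ndarray  # (n_regions, n_volumes)
    motion: np.ndarray  # (n_volumes, 6)
    tissue: np.ndarray  # (n_volumes, 2) white-matter / ventricle signals


@dataclass
class TimeCourseSet:
    """Per-subject seed-region BOLD-like series at TR spacing."""

    subjects: list[SubjectTimeCourses]
    regions: tuple[str, ...]
    tr: float
    schedule: RunSchedule

    def validate(self) -> None:
        for s in self.subjects:
            if s.data.shape[0] != len(self.regions):
                raise DataError(f"{s.subject_id}: region axis mismatch")
            if s.motion.shape != (s.data.shape[1], 6):
                raise DataError(
                    f"{s.subject_id}: motion table length {s.motion.shape[0]} "
                    f"!= time-course length {s.data.shape[1]}"
                )


def _cholesky_psd(m: np.ndarray, group: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(m)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            f"connectivity_target[{group!r}] is not positive semi-definite"
        ) from exc


def generate_roi_time_courses(
    spec: SyntheticCohortSpec,
    schedule: RunSchedule | None = None,
    n_volumes: int | None = None,
) -> TimeCourseSet:
    """Sample seed-region time courses with the target correlation structure.

    Per subject: correlated Gaussian noise (Cholesky factor of the group's
    target matrix) plus a shared task component (experimental-block boxcar
    convolved with the canonical HRF, scaled by ``task_amplitude``) and a
    random-walk motion table, sampled at TR spacing over all runs.
    """
    schedule = schedule or generate_run_schedule(ExperimentDesign(), seed=spec.seed)
    tr = schedule.design.tr
    vols_per_run = int(round(schedule.total_duration / tr))
    n_vols = n_volumes if n_volumes is not None else spec.n_runs * vols_per_run
    regions = spec.regions
    n_reg = len(regions)

    task_run = convolved_regressor(schedule, kind="experimental", tr=tr)
    reps = int(np.ceil(n_vols / task_run.size))
    task = np.tile(task_run, reps)[:n_vols]

    chol = {
        g: _cholesky_psd(np.asarray(m, dtype=float), g)
        for g, m in spec.connectivity_target.items()
    }
    for group in GROUPS:
        if group not in chol:
            raise ConfigurationError(f"connectivity_target missing group {group!r}")
        if chol[group].shape[0] != n_reg:
            raise ConfigurationError(
                f"connectivity_target[{group!r}] is "
                f"{chol[group].shape[0]}x{chol[group].shape[0]} but the spec "
                f"names {n_reg} regions"
            )

    ss = np.random.SeedSequence(spec.seed + 1_000_003)
    child_seeds = ss.spawn(2 * spec.n_per_group)
    subjects: list[SubjectTimeCourses] = []
    i = 0
    for group in GROUPS:
        for k in range(spec.n_per_group):
            rng = np.random.default_rng(child_seeds[i])
            i += 1
            noise = chol[group] @ rng.normal(size=(n_reg, n_vols))
            data = noise + spec.task_amplitude * task[None, :]
            motion = np.cumsum(
                rng.normal(scale=[0.02] * 3 + [0.0004] * 3, size=(n_vols, 6)),
                axis=0,
            )
            tissue = rng.normal(size=(n_vols, 2))
            subjects.append(
                SubjectTimeCourses(f"{group[:3]}{k:02d}", group, data, motion, tissue)
            )
    return TimeCourseSet(subjects=subjects, regions=regions, tr=tr, schedule=schedule)


@dataclass(frozen=True)
class ClusterSpec:
    """A spherical informative cluster inside a toy volume."""

    center: tuple[int, int, int]
    radius: int
    amplitude: float = 1.0


@dataclass
class VolumetricPatterns:
    """Per-run condition patterns on a small 3-D grid, with a brain mask."""

    data: np.ndarray  # (n_runs, n_conditions, X, Y, Z)
    mask: np.ndarray  # (X, Y, Z) bool
    conditions: tuple[str, ...]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[2:]


def generate_toy_volume(
    grid_shape: tuple[int, int, int],
    clusters: Sequence[ClusterSpec] = (),
    *,
    n_runs: int = 8,
    conditions: Sequence[str] = CONDITIONS,
    noise_sd: float = 1.0,
    mask: np.ndarray | None = None,
    seed: int = 0,
) -> VolumetricPatterns:
    """Toy searchlight fixture: condition information only inside clusters.

    In-cluster voxels carry fixed per-condition offsets (amplitude-scaled
    Gaussian prototypes, constant across runs); all other voxels are pure
    noise. Cluster spheres must lie fully inside the grid.
    """
    if any(s > 30 for s in grid_shape):
        raise ConfigurationError(f"grid {grid_shape} exceeds 30^3 desk scale")
    rng = np.random.default_rng(seed)
    conditions = tuple(conditions)
    shape = tuple(grid_shape)
    mask = np.ones(shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    if mask.shape != shape:
        raise DataError(f"mask shape {mask.shape} != grid shape {shape}")

    protos = np.zeros((len(conditions),) + shape)
    xx, yy, zz = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    for cl in clusters:
        cx, cy, cz = cl.center
        for c, r in zip(cl.center, shape):
            if c - cl.radius < 0 or c + cl.radius >= r:
                raise ConfigurationError(
                    f"cluster at {cl.center} radius {cl.radius} extends "
                    f"outside grid {shape}"
                )
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2 <= cl.radius**2
        protos[:, inside] = cl.amplitude * rng.normal(
            size=(len(conditions), int(inside.sum()))
        )

    noise = rng.normal(scale=noise_sd, size=(n_runs, len(conditions)) + shape)
    data = protos[None] + noise
    return VolumetricPatterns(data=data, mask=mask, conditions=conditions)
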