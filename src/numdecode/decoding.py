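"""ROI-based pairwise decoding of numerical magnitude.

Per subject and ROI, every pair of the 8 conditions is decoded with a
C-SVC (C = 1, linear kernel by default) under repeated random
subsampling: runs are split 70/30 into training and test 100 times, the
test runs' patterns are averaged to one pattern per condition, and the
pair's cell of the 8x8 accuracy matrix is the mean accuracy over
repeats. Patterns are standardized per condition (subtract the mean
across voxels, divide by the SD across voxels) before classification.
The two headline summaries are the mean within-format accuracies over
the 6 symbolic and 6 non-symbolic pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .design import CONDITIONS, condition_format
from .errors import ConfigurationError, DataError, NumericalError
from .simulate import PatternDataset


@dataclass(frozen=True)
class CVSpec:
    """Repeated random subsampling over runs."""

    train_fraction: float = 0.70
    n_repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")


@dataclass(frozen=True)
class ClassifierSpec:
    """C-SVC parameters, fixed across all ROIs/subjects/repeats of a run."""

    kernel: str = "linear"  # "linear" | "rbf"
    C: float = 1.0
    gamma: float = 1.0  # used by the rbf kernel only

    def make(self) -> SVC:
        if self.kernel == "linear":
            return SVC(kernel="linear", C=self.C)
        if self.kernel == "rbf":
            return SVC(kernel="rbf", C=self.C, gamma=self.gamma)
        raise ConfigurationError(f"unknown kernel {self.kernel!r}")


def standardize_pattern(pattern: np.ndarray, context: str = "pattern") -> np.ndarray:
    """Standardize one voxel vector to mean 0, population SD 1."""
    v = np.asarray(pattern, dtype=float)
    if v.size < 2:
        raise DataError(f"{context}: need >= 2 voxels, got {v.size}")
    sd = v.std()  # population SD
    if sd == 0:
        raise NumericalError(
            f"{context}: constant pattern (zero SD) carries no decodable shape"
        )
    return (v - v.mean()) / sd


def train_binary_classifier(
    train_patterns: np.ndarray, labels: np.ndarray, spec: ClassifierSpec
) -> SVC:
    """Fit the C-SVC on training patterns; both classes must be present."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise DataError("training set contains a single class")
    return spec.make().fit(np.asarray(train_patterns, float), labels)


def within_format_pairs(
    fmt: str, conditions: tuple[str, ...] = CONDITIONS
) -> list[tuple[int, int]]:
    """Index pairs of same-format conditions (6 per format for 4 numerosities)."""
    idx = [i for i, c in enumerate(conditions) if condition_format(c) == fmt]
    return list(itertools.combinations(idx, 2))


def _split_runs(
    n_runs: int, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n_train = int(round(train_fraction * n_runs))
    n_train = min(max(n_train, 1), n_runs - 1)
    perm = rng.permutation(n_runs)
    return perm[:n_train], perm[n_train:]


def pairwise_decoding_matrix(
    patterns: np.ndarray,
    cv: CVSpec,
    spec: ClassifierSpec | None = None,
    pairs: list[tuple[int, int]] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Pairwise condition decoding for one subject x ROI.

    ``patterns``: (n_runs, n_conditions, n_voxels) t-patterns. Returns the
    symmetric (n_conditions x n_conditions) accuracy matrix with NaN on
    the diagonal (and in cells outside ``pairs`` when a subset is given).
    """
    spec = spec or ClassifierSpec()
    x = np.asarray(patterns, dtype=float)
    if x.ndim != 3:
        raise DataError(f"expected (runs, conditions, voxels), got {x.shape}")
    n_runs, n_cond, _ = x.shape
    if n_runs < 4:
        raise DataError(
            f"need >= 4 runs for a 70/30 run split with >= 1 test run, got {n_runs}"
        )
    rng = rng if rng is not None else np.random.default_rng(cv.seed)

    z = np.empty_like(x)
    for r in range(n_runs):
        for c in range(n_cond):
            z[r, c] = standardize_pattern(x[r, c], context=f"run {r}, condition {c}")

    if pairs is None:
        pairs = list(itertools.combinations(range(n_cond), 2))

    hits = np.zeros((n_cond, n_cond))
    for _ in range(cv.n_repeats):
        train_runs, test_runs = _split_runs(n_runs, cv.train_fraction, rng)
        test_mean = z[test_runs].mean(axis=0)  # (C, V) one pattern per condition
        for i, j in pairs:
            xtr = np.concatenate([z[train_runs, i], z[train_runs, j]])
            ytr = np.array([0] * train_runs.size + [1] * train_runs.size)
            clf = spec.make().fit(xtr, ytr)
            pred = clf.predict(test_mean[[i, j]])
            acc = float((pred == np.array([0, 1])).mean())
            hits[i, j] += acc
            hits[j, i] += acc

    matrix = np.full((n_cond, n_cond), np.nan)
    for i, j in pairs:
        matrix[i, j] = matrix[j, i] = hits[i, j] / cv.n_repeats
    return matrix


def within_format_accuracy(
    matrix: np.ndarray, fmt: str, conditions: tuple[str, ...] = CONDITIONS
) -> float:
    """Mean of the format's 6 within-format pairwise cells."""
    pairs = within_format_pairs(fmt, conditions)
    return float(np.mean([matrix[i, j] for i, j in pairs]))


def decode_dataset(
    dataset: PatternDataset,
    cv: CVSpec,
    spec: ClassifierSpec | None = None,
    regions: list[str] | None = None,
    formats: tuple[str, ...] = ("symbolic", "nonsymbolic"),
    within_format_only: bool = False,
) -> pd.DataFrame:
    """Within-format accuracies for every subject x region of a cohort.

    Returns long-format rows (subject, group, region, format, accuracy).
    ``within_format_only`` restricts decoding to the 12 same-format pairs,
    a cheaper run when cross-format cells are not needed.
    """
    spec = spec or ClassifierSpec()
    regions = list(regions or dataset.regions)
    pairs = None
    if within_format_only:
        pairs = [p for f in formats for p in within_format_pairs(f, dataset.conditions)]
    ss = np.random.SeedSequence(cv.seed)
    rows = []
    for subject, child in zip(dataset.subjects, ss.spawn(len(dataset.subjects))):
        rng = np.random.default_rng(child)
        for region in regions:
            matrix = pairwise_decoding_matrix(
                subject.patterns[region], cv, spec, pairs=pairs, rng=rng
            )
            for fmt in formats:
                rows.append(
                    dict(
                        subject=subject.subject_id,
                        group=subject.group,
                        region=region,
                        format=fmt,
                        accuracy=within_format_accuracy(
                            matrix, fmt, dataset.conditions
                        ),
                    )
                )
    return pd.DataFrame(rows)


def group_compare_accuracy(
    group_a: np.ndarray, group_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided two-sample (pooled-variance) t-test on accuracies."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise DataError("need >= 2 accuracies per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise NumericalError("zero variance in both groups: p undefined")
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def chance_test(accuracies: np.ndarray, chance: float = 0.5) -> tuple[float, float]:
    """One-sample two-sided t-test of a group's accuracies against chance."""
    t, p = stats.ttest_1samp(np.asarray(accuracies, float), chance)
    return float(t), float(p)
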