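"""Whole-brain subject classification: LPOCV and Monte-Carlo permutation.

Subjects (dyscalculia vs. control, equal-sized groups) are classified
from contrast-map feature vectors with a C-SVC. Cross-validation is
leave-one-pair-out: subjects are randomly paired across groups; each
fold trains on everyone except one pair and tests on that pair, so every
subject is held out exactly once per repeat and the training set never
becomes class-imbalanced. Because the pairing is random, the procedure
is repeated (1000 times in the full analysis) and accuracies averaged.
Significance comes from a Monte-Carlo permutation test: training labels
are permuted, the identical LPOCV is re-run, and
p = #{null >= observed} / n_permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoding import ClassifierSpec
from .errors import DataError


def _check_features(features: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise DataError(f"features {x.shape} do not match {y.size} labels")
    classes = np.unique(y)
    if classes.size != 2:
        raise DataError(f"need exactly 2 groups, got {classes.size}")
    n0 = int((y == classes[0]).sum())
    n1 = int((y == classes[1]).sum())
    if n0 != n1:
        raise DataError(
            f"groups must be equal-sized for leave-one-pair-out CV "
            f"({n0} vs {n1}): unequal groups would re-introduce the class "
            "imbalance the pairing is designed to avoid"
        )
    return x, y


def lpocv_folds(
    labels: np.ndarray, rng: np.random.Generator
) -> list[np.ndarray]:
    """One random cross-group pairing: list of held-out index pairs.

    Every subject appears in exactly one pair, each pair holding one
    subject from each group.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    idx0 = np.flatnonzero(y == classes[0])
    idx1 = np.flatnonzero(y == classes[1])
    rng.shuffle(idx0)
    rng.shuffle(idx1)
    return [np.array([a, b]) for a, b in zip(idx0, idx1)]


def _lpocv_once(
    x: np.ndarray,
    y_train_source: np.ndarray,
    y_true: np.ndarray,
    spec: ClassifierSpec,
    rng: np.random.Generator,
) -> float:
    """One LPOCV repeat. Training uses ``y_train_source`` (possibly permuted
    labels); scoring is always against the true labels ``y_true``."""
    correct = 0
    n = y_true.size
    for pair in lpocv_folds(y_true, rng):
        train = np.setdiff1d(np.arange(n), pair)
        clf = spec.make().fit(x[train], y_train_source[train])
        pred = clf.predict(x[pair])
        correct += int((pred == y_true[pair]).sum())
    return correct / n


def lpocv_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec | None = None,
    n_repeats: int = 1000,
    seed: int = 0,
    return_repeats: bool = False,
):
    """Mean leave-one-pair-out accuracy over ``n_repeats`` random pairings."""
    spec = spec or ClassifierSpec()
    x, y = _check_features(features, labels)
    rng = np.random.default_rng(seed)
    accs = np.array(
        [_lpocv_once(x, y, y, spec, rng) for _ in range(n_repeats)]
    )
    if return_repeats:
        return float(accs.mean()), accs
    return float(accs.mean())


def permutation_p(observed: float, null: np.ndarray, plus_one: bool = False) -> float:
    """p = #{null >= observed} / N (optionally the (b+1)/(N+1) variant)."""
    null = np.asarray(null, float)
    b = int((null >= observed).sum())
    if plus_one:
        return (b + 1) / (null.size + 1)
    return b / null.size


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p: float
    n_permutations: int


def permutation_test(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec | None = None,
    n_permutations: int = 1000,
    lpocv_repeats: int = 20,
    observed_repeats: int | None = None,
    seed: int = 0,
    plus_one: bool = False,
) -> PermutationResult:
    """Monte-Carlo permutation test of the LPOCV accuracy.

    Each iteration draws one global label permutation — a coherent
    relabelling of the cohort, applied to training sets and to the scoring
    of held-out pairs alike — and records the accuracy of an otherwise
    identical LPOCV (``lpocv_repeats`` pairings averaged). Permuting the
    labels incoherently (training only, scoring against the true labels)
    is not an exchangeable null and is measurably anti-conservative at
    small n. The observed accuracy uses ``observed_repeats`` pairings
    (defaults to ``lpocv_repeats`` so observed and null estimates are
    equally noisy).
    ``plus_one`` switches to the (b+1)/(N+1) small-sample correction; the
    default keeps the plain b/N estimator, under which p = 0 is possible.
    """
    spec = spec or ClassifierSpec()
    x, y = _check_features(features, labels)
    rng = np.random.default_rng(seed)
    observed_repeats = lpocv_repeats if observed_repeats is None else observed_repeats
    observed = float(
        np.mean([_lpocv_once(x, y, y, spec, rng) for _ in range(observed_repeats)])
    )
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        y_perm = y[rng.permutation(y.size)]
        null[k] = np.mean(
            [_lpocv_once(x, y_perm, y_perm, spec, rng) for _ in range(lpocv_repeats)]
        )
    return PermutationResult(
        observed=observed,
        null=null,
        p=permutation_p(observed, null, plus_one=plus_one),
        n_permutations=n_permutations,
    )
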