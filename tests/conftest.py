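"""Shared fixtures. Heavy simulation products are session-scoped so the
calibration suites and the acceptance tests reuse one computation."""

from __future__ import annotations

import numpy as np
import pytest

import numdecode as nd
from numdecode.decoding import CVSpec
from numdecode.simulate import SyntheticCohortSpec, uniform_separation


@pytest.fixture(scope="session")
def default_schedule():
    return nd.generate_run_schedule(nd.ExperimentDesign(), seed=0)


def small_cohort_spec(
    *,
    n_per_group: int,
    n_runs: int = 8,
    regions: tuple[str, ...] = ("IPS",),
    voxels: int = 16,
    sym: tuple[float, float] = (0.8, 0.8),
    nonsym: tuple[float, float] = (0.8, 0.8),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> SyntheticCohortSpec:
    """Desk-scale cohort helper; (dyscalculia, control) separation tuples."""
    sep = uniform_separation(
        {
            ("dyscalculia", "symbolic"): sym[0],
            ("control", "symbolic"): sym[1],
            ("dyscalculia", "nonsymbolic"): nonsym[0],
            ("control", "nonsymbolic"): nonsym[1],
        },
        regions,
    )
    n_reg = len(regions)
    eye = np.eye(n_reg)
    return SyntheticCohortSpec(
        n_per_group=n_per_group,
        n_runs=n_runs,
        voxels_per_roi={r: voxels for r in regions},
        separation=sep,
        noise_sd=noise_sd,
        connectivity_target={"dyscalculia": eye.copy(), "control": eye.copy()},
        seed=seed,
    )


@pytest.fixture(scope="session")
def null_cohort_accuracies():
    """Within-format decoding accuracies of a label-exchangeable cohort
    (zero separation everywhere): 25+25 subjects x 1 ROI, reduced repeats.

    Used for the chance-calibration checks; returns the long-format
    accuracy table from the full decode path.
    """
    spec = small_cohort_spec(
        n_per_group=25, n_runs=8, sym=(0.0, 0.0), nonsym=(0.0, 0.0), seed=11
    )
    dataset = nd.generate_condition_patterns(spec)
    return nd.decoding.decode_dataset(
        dataset, CVSpec(n_repeats=10, seed=5), within_format_only=False
    )


@pytest.fixture(scope="session")
def null_permutation_pvalues():
    """Permutation-test p-values under exchangeable labels.

    400 simulated datasets (4+4 subjects, 10 noise features), each tested
    with a reduced-permutation run (39 permutations, 3 LPOCV pairings per
    permutation). Returns (p-values, null-distribution means).
    """
    from numdecode.subjects import permutation_test

    rng = np.random.default_rng(2024)
    labels = np.array(["a"] * 4 + ["b"] * 4)
    pvals = np.empty(400)
    null_means = np.empty(400)
    for i in range(400):
        x = rng.normal(size=(8, 10))
        res = permutation_test(
            x, labels, n_permutations=39, lpocv_repeats=3,
            seed=int(rng.integers(2**31)),
        )
        pvals[i] = res.p
        null_means[i] = res.null.mean()
    return pvals, null_means


@pytest.fixture(scope="session")
def headline_recovery_counts():
    """Gated-test outcomes over 50 cohorts simulated with the effect
    structure of interest: reduced non-symbolic separation in the
    dyscalculia group, equal symbolic separation.

    Returns (n_cohorts, n_joint) where a cohort counts as a joint success
    when the gated hierarchy's root is significant for non-symbolic AND
    not significant for symbolic accuracy at alpha 0.05.
    """
    from numdecode.pipeline import _flat_hierarchy, _gated_values

    n_cohorts = 50
    regions = ("IPS", "PVC")
    hier = _flat_hierarchy(regions)
    n_joint = 0
    for k in range(n_cohorts):
        spec = small_cohort_spec(
            n_per_group=12, n_runs=8, regions=regions, voxels=16,
            sym=(0.8, 0.8), nonsym=(0.4, 1.2), seed=10_000 + k,
        )
        dataset = nd.generate_condition_patterns(spec)
        acc = nd.decoding.decode_dataset(
            dataset, CVSpec(n_repeats=6, seed=20_000 + k), within_format_only=True
        )
        results = {
            fmt: nd.gated_level_test(hier, _gated_values(acc, fmt, regions), alpha=0.05)
            for fmt in ("nonsymbolic", "symbolic")
        }
        root_ns = results["nonsymbolic"].set_index("node").loc["All Regions"]
        root_s = results["symbolic"].set_index("node").loc["All Regions"]
        n_joint += int(
            root_ns.status == "significant" and root_s.status != "significant"
        )
    return n_cohorts, n_joint
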