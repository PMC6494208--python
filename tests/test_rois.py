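"""ROI definition, exclusion bookkeeping, and gated hierarchical FDR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from numdecode.errors import DataError
from numdecode.rois import (
    ROOT_NAME,
    ROIHierarchy,
    ROINode,
    bh_adjust,
    connectivity_seeds,
    default_hierarchy,
    define_roi,
    exclude_undefinable,
    gated_level_test,
    univariate_roi_stat,
)


def bh_stepup_oracle(pvals):
    """Brute-force BH step-up: find the largest k with p_(k) <= k/m * q by
    direct enumeration, then form adjusted p-values by the defining minimum."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    # adjusted p_(i) = min_{j >= i} ( m * p_(j) / j )
    for rank_i in range(m):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_i, m)
        ]
        adj[order[rank_i]] = min(1.0, min(candidates))
    return adj


class TestDefineROI:
    def test_all_subthreshold_localizer_gives_empty_roi(self):
        mask = np.ones((4, 4, 4), bool)
        tmap = np.zeros((4, 4, 4))  # p = 0.5 everywhere, far above 0.001
        roi = define_roi(mask, tmap, p_threshold=0.001, df=90)
        assert not roi.any()

    def test_exact_count_of_suprathreshold_voxels(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        df = 60
        t_crit = stats.t.isf(0.001, df)
        tmap = np.full((5, 5, 5), 0.0)
        hot = [(1, 1, 1), (2, 2, 2), (3, 3, 3), (0, 0, 0)]  # last is off-mask
        for v in hot:
            tmap[v] = t_crit + 1.0
        roi = define_roi(mask, tmap, p_threshold=0.001, df=df)
        assert roi.sum() == 3  # the off-mask voxel must not count
        assert all(roi[v] for v in hot[:3])

    def test_default_threshold_is_uncorrected_p_001(self):
        import inspect

        sig = inspect.signature(define_roi)
        assert sig.parameters["p_threshold"].default == 0.001

    def test_grid_mismatch_reports_both_shapes(self):
        with pytest.raises(DataError, match=r"\(4, 4, 4\).*\(5, 5, 5\)"):
            define_roi(np.ones((4, 4, 4), bool), np.zeros((5, 5, 5)))


def _hierarchy_with_definability(n_subjects, undefined_counts):
    """Default tree with synthetic single-voxel masks; ``undefined_counts``
    maps node name -> number of subjects lacking the node."""
    hier = default_hierarchy()
    subjects = [f"s{i:02d}" for i in range(n_subjects)]
    for node in hier.nodes.values():
        n_undef = undefined_counts.get(node.name, 0)
        for i, s in enumerate(subjects):
            mask = np.zeros(3, bool)
            if i >= n_undef:
                mask[0] = True
            node.voxels[s] = mask
    return hier, subjects


class TestExclusion:
    def test_node_undefined_in_five_subjects_is_excluded(self):
        hier, subjects = _hierarchy_with_definability(48, {"angular gyrus": 5})
        pruned = exclude_undefinable(hier, subjects, min_undefined=5)
        assert "angular gyrus" in pruned.excluded
        assert "angular gyrus" not in pruned.nodes

    def test_node_defined_everywhere_is_retained(self):
        hier, subjects = _hierarchy_with_definability(48, {})
        pruned = exclude_undefinable(hier, subjects)
        assert not pruned.excluded

    def test_undefined_in_four_subjects_is_retained(self):
        hier, subjects = _hierarchy_with_definability(48, {"IPL": 4})
        pruned = exclude_undefinable(hier, subjects)
        assert "IPL" in pruned.nodes

    def test_study_exclusions_leave_8_connectivity_seeds(self):
        """11 level-III regions minus the 3 that cannot be defined in >= 5
        subjects = 8 seeds."""
        undefined = {
            "supramarginal gyrus": 7,
            "superior occipital gyrus": 6,
            "angular gyrus": 5,
        }
        hier, subjects = _hierarchy_with_definability(48, undefined)
        assert len(hier.level_nodes(3)) == 11
        pruned = exclude_undefinable(hier, subjects, min_undefined=5)
        seeds = connectivity_seeds(pruned)
        assert len(seeds) == 8
        assert set(seeds) == {"FG", "IFG", "SFG", "IOC", "PVC", "IPL", "SPL", "IPS"}


class TestHierarchyStructure:
    def test_default_tree_has_four_levels_and_single_root(self):
        hier = default_hierarchy()
        assert hier.root.name == ROOT_NAME
        assert len(hier.level_nodes(2)) == 4
        assert len(hier.level_nodes(3)) == 11
        assert len(hier.level_nodes(4)) == 4

    def test_nesting_violation_detected(self):
        hier = default_hierarchy()
        parent_mask = np.zeros(8, bool)
        parent_mask[:2] = True
        child_mask = np.zeros(8, bool)
        child_mask[5] = True  # outside parent
        hier.nodes["parietal cortex"].voxels["s0"] = parent_mask
        hier.nodes["IPS"].voxels["s0"] = child_mask
        with pytest.raises(DataError, match="nested"):
            hier.check_nesting()

    def test_nested_synthetic_hierarchy_passes_check(self):
        hier = default_hierarchy()
        rng = np.random.default_rng(1)
        n_vox = 64
        root_mask = rng.random(n_vox) < 0.9
        for node in hier.nodes.values():
            if node.parent is None:
                node.voxels["s0"] = root_mask
        for level in (2, 3, 4):
            for node in hier.level_nodes(level):
                parent_mask = hier.nodes[node.parent].voxels["s0"]
                node.voxels["s0"] = parent_mask & (rng.random(n_vox) < 0.7)
        hier.check_nesting()

    def test_two_roots_rejected(self):
        with pytest.raises(DataError, match="root"):
            ROIHierarchy(nodes={
                "a": ROINode("a", 1, None), "b": ROINode("b", 1, None)
            })


class TestUnivariateStat:
    def test_constant_map_returns_the_constant(self):
        mask = np.ones((3, 3), bool)
        assert univariate_roi_stat(np.full((3, 3), 2.5), mask) == 2.5

    def test_three_voxel_roi_mean(self):
        mask = np.array([True, True, True, False])
        values = np.array([1.0, 2.0, 6.0, 100.0])
        assert univariate_roi_stat(values, mask) == pytest.approx(3.0)

    def test_agrees_with_voxel_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            values = rng.normal(size=(6, 6))
            mask = rng.random((6, 6)) < 0.4
            if not mask.any():
                continue
            oracle = np.mean([values[i, j] for i in range(6) for j in range(6)
                              if mask[i, j]])
            assert univariate_roi_stat(values, mask) == pytest.approx(oracle)

    def test_empty_roi_raises(self):
        with pytest.raises(DataError, match="empty"):
            univariate_roi_stat(np.zeros(4), np.zeros(4, bool))


class TestBH:
    def test_hand_example_all_adjusted_to_004(self):
        adj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(3)
        p = rng.random(8)
        assert (bh_adjust(p) >= p - 1e-12).all()

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8))
    def test_matches_stepup_oracle_on_all_short_inputs(self, pvals):
        np.testing.assert_allclose(
            bh_adjust(np.array(pvals)), bh_stepup_oracle(pvals), atol=1e-12
        )


def _two_level_values(root, children):
    values = {ROOT_NAME: root}
    values.update(children)
    return values


def _simple_hierarchy(child_names):
    nodes = {ROOT_NAME: ROINode(ROOT_NAME, 1, None)}
    for name in child_names:
        nodes[name] = ROINode(name, 2, ROOT_NAME)
    return ROIHierarchy(nodes=nodes)


class TestGatedLevelTest:
    def test_root_null_closes_all_gates(self):
        hier = _simple_hierarchy(["a", "b"])
        same = (np.arange(10.0), np.arange(10.0))
        shifted = (np.arange(10.0), np.arange(10.0) + 50)
        res = gated_level_test(hier, _two_level_values(same, {"a": shifted, "b": shifted}))
        res = res.set_index("node")
        assert res.loc[ROOT_NAME, "status"] == "not significant"
        assert res.loc["a", "status"] == "not tested"
        assert res.loc["b", "status"] == "not tested"

    def test_significant_root_opens_child_testing_with_level_fdr(self):
        rng = np.random.default_rng(4)
        hier = _simple_hierarchy(["a", "b", "c"])
        ga = rng.normal(size=12)
        gb = rng.normal(loc=5.0, size=12)
        null = (rng.normal(size=12), rng.normal(size=12))
        res = gated_level_test(
            hier,
            _two_level_values((ga, gb), {"a": (ga, gb), "b": (ga, gb), "c": null}),
        ).set_index("node")
        assert res.loc[ROOT_NAME, "status"] == "significant"
        assert res.loc["a", "status"] == "significant"
        assert res.loc["c", "status"] == "not significant"
        # level-2 FDR computed over the 3 tested nodes together
        raw = res.loc[["a", "b", "c"], "p"].to_numpy()
        np.testing.assert_allclose(
            res.loc[["a", "b", "c"], "p_fdr"].to_numpy(), bh_stepup_oracle(raw)
        )

    def test_uses_two_sided_two_sample_t(self):
        hier = _simple_hierarchy([])
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=10), rng.normal(size=10)
        res = gated_level_test(hier, {ROOT_NAME: (a, b)}).set_index("node")
        t_ref, p_ref = stats.ttest_ind(a, b)
        assert res.loc[ROOT_NAME, "t"] == pytest.approx(t_ref)
        assert res.loc[ROOT_NAME, "p"] == pytest.approx(p_ref)

    def test_gating_is_per_parent(self):
        """Children of a significant parent are testable even when a sibling
        parent at the same level is not significant."""
        rng = np.random.default_rng(6)
        nodes = {
            ROOT_NAME: ROINode(ROOT_NAME, 1, None),
            "p1": ROINode("p1", 2, ROOT_NAME),
            "p2": ROINode("p2", 2, ROOT_NAME),
            "c1": ROINode("c1", 3, "p1"),
            "c2": ROINode("c2", 3, "p2"),
        }
        hier = ROIHierarchy(nodes=nodes)
        strong = (rng.normal(size=12), rng.normal(loc=8.0, size=12))
        null = (rng.normal(size=12), rng.normal(size=12))
        values = {ROOT_NAME: strong, "p1": strong, "p2": null,
                  "c1": strong, "c2": strong}
        res = gated_level_test(hier, values).set_index("node")
        assert res.loc["p1", "status"] == "significant"
        assert res.loc["p2", "status"] == "not significant"
        assert res.loc["c1", "status"] == "significant"
        assert res.loc["c2", "status"] == "not tested"

    def test_excluded_nodes_never_tested(self):
        hier = _simple_hierarchy(["a"])
        hier.excluded["dropped"] = "undefinable in 6 of 10 subjects"
        rng = np.random.default_rng(7)
        strong = (rng.normal(size=10), rng.normal(loc=9.0, size=10))
        res = gated_level_test(hier, _two_level_values(strong, {"a": strong}))
        res = res.set_index("node")
        assert res.loc["dropped", "status"] == "excluded"

    def test_small_group_skipped_with_reason(self):
        hier = _simple_hierarchy(["a"])
        rng = np.random.default_rng(8)
        strong = (rng.normal(size=10), rng.normal(loc=9.0, size=10))
        tiny = (np.array([1.0]), rng.normal(size=10))
        res = gated_level_test(hier, _two_level_values(strong, {"a": tiny}))
        res = res.set_index("node")
        assert res.loc["a", "status"] == "skipped"
        assert "fewer than 2" in res.loc["a", "reason"]

    def test_no_node_with_untested_ancestor_is_tested(self):
        """Gate soundness audited over random 3-level hierarchies."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            nodes = {ROOT_NAME: ROINode(ROOT_NAME, 1, None)}
            for i in range(3):
                nodes[f"l2_{i}"] = ROINode(f"l2_{i}", 2, ROOT_NAME)
                for j in range(2):
                    nodes[f"l3_{i}{j}"] = ROINode(f"l3_{i}{j}", 3, f"l2_{i}")
            hier = ROIHierarchy(nodes=nodes)
            values = {
                name: (rng.normal(size=8), rng.normal(loc=rng.choice([0, 3]), size=8))
                for name in nodes
            }
            res = gated_level_test(hier, values).set_index("node")
            for name, node in nodes.items():
                if node.parent is None:
                    continue
                parent_status = res.loc[node.parent, "status"]
                if parent_status != "significant":
                    assert res.loc[name, "status"] in ("not tested",)

    def test_type_i_rate_of_full_null_pipeline_within_monte_carlo_band(self):
        """200 null cohorts (zero separation): proportion of hierarchies
        declaring any significant node stays within alpha + 2 MC SEs.

        Node values come from the univariate route (ROI-mean pattern
        values), exercising generator -> ROI stat -> gated test end to end.
        """
        import numdecode as nd
        from conftest import small_cohort_spec

        alpha = 0.05
        n_sim = 200
        regions = ("IPS", "PVC")
        hier = _simple_hierarchy(list(regions))
        n_any = 0
        for k in range(n_sim):
            spec = small_cohort_spec(
                n_per_group=8, n_runs=4, regions=regions, voxels=8,
                sym=(0.0, 0.0), nonsym=(0.0, 0.0), seed=40_000 + k,
            )
            ds = nd.generate_condition_patterns(spec)
            values = {}
            per_region = {
                r: {
                    g: np.array([
                        s.patterns[r].mean() for s in ds.by_group(g)
                    ])
                    for g in ("dyscalculia", "control")
                }
                for r in regions
            }
            values[ROOT_NAME] = tuple(
                np.mean([per_region[r][g] for r in regions], axis=0)
                for g in ("dyscalculia", "control")
            )
            for r in regions:
                values[r] = (per_region[r]["dyscalculia"], per_region[r]["control"])
            res = gated_level_test(hier, values, alpha=alpha)
            n_any += int((res.status == "significant").any())
        rate = n_any / n_sim
        mc_se = np.sqrt(alpha * (1 - alpha) / n_sim)
        assert rate <= alpha + 2 * mc_se
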