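"""ROI definition, 4-level hierarchy, and gated level-wise FDR group tests.

ROIs are defined per subject as the intersection of an anatomical mask
with localizer activity exceeding an uncorrected one-sided p < 0.001.
They are organised in a 4-level tree — (I) All Regions, (II) lobes,
(III) regions, (IV) IPS subparts — and group differences are tested
top-down: a level's nodes are Benjamini-Hochberg corrected together, and
a node's children are tested only if the node itself survives. Nodes
undefinable in at least 5 subjects are excluded outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError

ROOT_NAME = "All Regions"

#: (name, level, parent) for the study's 20-node tree.
DEFAULT_TREE: tuple[tuple[str, int, str | None], ...] = (
    (ROOT_NAME, 1, None),
    ("frontal cortex", 2, ROOT_NAME),
    ("parietal cortex", 2, ROOT_NAME),
    ("temporal cortex", 2, ROOT_NAME),
    ("occipital cortex", 2, ROOT_NAME),
    ("IFG", 3, "frontal cortex"),
    ("SFG", 3, "frontal cortex"),
    ("supramarginal gyrus", 3, "parietal cortex"),
    ("angular gyrus", 3, "parietal cortex"),
    ("IPL", 3, "parietal cortex"),
    ("SPL", 3, "parietal cortex"),
    ("IPS", 3, "parietal cortex"),
    ("FG", 3, "temporal cortex"),
    ("IOC", 3, "occipital cortex"),
    ("superior occipital gyrus", 3, "occipital cortex"),
    ("PVC", 3, "occipital cortex"),
    ("IPS_LA", 4, "IPS"),
    ("IPS_RA", 4, "IPS"),
    ("IPS_LP", 4, "IPS"),
    ("IPS_RP", 4, "IPS"),
)

STATUS_SIG = "significant"
STATUS_NS = "not significant"
STATUS_NOT_TESTED = "not tested"
STATUS_EXCLUDED = "excluded"
STATUS_SKIPPED = "skipped"


@dataclass
class ROINode:
    name: str
    level: int
    parent: str | None
    #: subject id -> boolean voxel mask (or None when only bookkeeping is needed)
    voxels: dict[str, np.ndarray] = field(default_factory=dict)

    def definable(self, subject: str) -> bool:
        mask = self.voxels.get(subject)
        return mask is not None and bool(np.any(mask))


@dataclass
class ROIHierarchy:
    nodes: dict[str, ROINode]
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise DataError(f"hierarchy must have exactly one root, found {len(roots)}")
        for node in self.nodes.values():
            if node.parent is not None and node.parent not in self.nodes:
                raise DataError(f"{node.name}: unknown parent {node.parent!r}")

    @property
    def root(self) -> ROINode:
        return next(n for n in self.nodes.values() if n.parent is None)

    def children(self, name: str) -> list[ROINode]:
        return [n for n in self.nodes.values() if n.parent == name]

    def level_nodes(self, level: int) -> list[ROINode]:
        return [n for n in self.nodes.values() if n.level == level]

    @property
    def max_level(self) -> int:
        return max(n.level for n in self.nodes.values())

    def check_nesting(self) -> None:
        """Assert child voxel sets are subsets of their parent's, per subject."""
        for node in self.nodes.values():
            if node.parent is None:
                continue
            parent = self.nodes[node.parent]
            for subject, mask in node.voxels.items():
                pmask = parent.voxels.get(subject)
                if mask is None or pmask is None:
                    continue
                if np.any(mask & ~pmask):
                    raise DataError(
                        f"{node.name} voxels not nested in {node.parent} "
                        f"for subject {subject}"
                    )


def default_hierarchy() -> ROIHierarchy:
    """The 4-level tree (root, 4 lobes, 11 regions, 4 IPS subparts)."""
    return ROIHierarchy(
        nodes={name: ROINode(name, level, parent) for name, level, parent in DEFAULT_TREE}
    )


def define_roi(
    anatomical_mask: np.ndarray,
    localizer_map: np.ndarray,
    p_threshold: float = 0.001,
    df: int = 90,
) -> np.ndarray:
    """Subject ROI: anatomical mask ∩ supra-threshold localizer voxels.

    The localizer map holds t-statistics of task-minus-fixation; voxels
    with one-sided p < ``p_threshold`` (uncorrected) are retained. An empty
    result is allowed and marks the ROI undefinable for that subject.
    """
    anatomical_mask = np.asarray(anatomical_mask, dtype=bool)
    localizer_map = np.asarray(localizer_map, dtype=float)
    if anatomical_mask.shape != localizer_map.shape:
        raise DataError(
            f"grid mismatch: mask {anatomical_mask.shape} vs "
            f"localizer map {localizer_map.shape}"
        )
    p = stats.t.sf(localizer_map, df)
    return anatomical_mask & (p < p_threshold)


def exclude_undefinable(
    hierarchy: ROIHierarchy,
    subjects: list[str],
    min_undefined: int = 5,
) -> ROIHierarchy:
    """Exclude nodes undefinable in at least ``min_undefined`` subjects.

    Subjects lacking a *retained* ROI are simply skipped for that ROI's
    tests (handled downstream); the node itself stays.
    """
    nodes = dict(hierarchy.nodes)
    excluded = dict(hierarchy.excluded)
    for name, node in list(nodes.items()):
        n_undef = sum(not node.definable(s) for s in subjects)
        if n_undef >= min_undefined:
            excluded[name] = (
                f"undefinable in {n_undef} of {len(subjects)} subjects "
                f"(>= {min_undefined})"
            )
            del nodes[name]
    return ROIHierarchy(nodes=nodes, excluded=excluded)


def connectivity_seeds(hierarchy: ROIHierarchy, level: int = 3) -> list[str]:
    """Retained level-III regions, the seeds of the connectivity analysis."""
    return sorted(n.name for n in hierarchy.level_nodes(level))


def univariate_roi_stat(value_map: np.ndarray, roi_mask: np.ndarray) -> float:
    """Mean contrast value over the ROI's voxels (one subject)."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    value_map = np.asarray(value_map, dtype=float)
    if value_map.shape != roi_mask.shape:
        raise DataError(
            f"grid mismatch: values {value_map.shape} vs mask {roi_mask.shape}"
        )
    if not roi_mask.any():
        raise DataError("empty ROI")
    return float(value_map[roi_mask].mean())


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def gated_level_test(
    hierarchy: ROIHierarchy,
    values: dict[str, tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Top-down gated group tests over the hierarchy.

    ``values`` maps node name -> (group A per-subject values, group B
    values). The root is tested first with a two-sided two-sample t-test;
    within each deeper level all *tested* nodes are BH-FDR corrected
    together, and a node is tested only if its own parent's adjusted
    p < alpha. Nodes on the hierarchy's excluded list never enter testing;
    nodes with fewer than 2 subjects in a group are skipped with a reason.
    """
    rows: dict[str, dict] = {}
    significant: set[str] = set()

    for name, reason in hierarchy.excluded.items():
        rows[name] = dict(node=name, level=np.nan, t=np.nan, p=np.nan,
                          p_fdr=np.nan, status=STATUS_EXCLUDED, reason=reason)

    for level in range(1, hierarchy.max_level + 1):
        testable: list[ROINode] = []
        for node in hierarchy.level_nodes(level):
            if node.parent is not None and node.parent not in significant:
                rows[node.name] = dict(
                    node=node.name, level=level, t=np.nan, p=np.nan,
                    p_fdr=np.nan, status=STATUS_NOT_TESTED,
                    reason="gate closed: parent not significant",
                )
                continue
            if node.name not in values:
                rows[node.name] = dict(
                    node=node.name, level=level, t=np.nan, p=np.nan,
                    p_fdr=np.nan, status=STATUS_SKIPPED,
                    reason="no values supplied",
                )
                continue
            a, b = values[node.name]
            a = np.asarray(a, float)
            b = np.asarray(b, float)
            if a.size < 2 or b.size < 2:
                rows[node.name] = dict(
                    node=node.name, level=level, t=np.nan, p=np.nan,
                    p_fdr=np.nan, status=STATUS_SKIPPED,
                    reason=f"fewer than 2 subjects per group ({a.size}/{b.size})",
                )
                continue
            testable.append(node)
        if not testable:
            continue
        stats_p = []
        for node in testable:
            a, b = values[node.name]
            t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
            stats_p.append((float(t), float(p)))
        p_adj = bh_adjust(np.array([p for _, p in stats_p]))
        for node, (t, p), padj in zip(testable, stats_p, p_adj):
            sig = padj < alpha
            if sig:
                significant.add(node.name)
            rows[node.name] = dict(
                node=node.name, level=level, t=t, p=p, p_fdr=float(padj),
                status=STATUS_SIG if sig else STATUS_NS, reason="",
            )

    out = pd.DataFrame(list(rows.values()))
    return out.sort_values(["level", "node"], na_position="last").reset_index(drop=True)
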