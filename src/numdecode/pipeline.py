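"""End-to-end orchestration: simulate -> decode -> classify -> connect.

``run_pipeline`` executes the enabled stages in dependency order on a
synthetic cohort, writing TSV/JSON outputs, a config snapshot, and a log
into the output directory. All randomness derives from the single
config seed, so a rerun with the same config reproduces every table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import PreprocSpec, cohort_z_matrices, group_connectivity_tests
from .decoding import CVSpec, ClassifierSpec, decode_dataset
from .design import FORMATS, ExperimentDesign, generate_run_schedule
from .errors import ConfigurationError
from .group_stats import matching_table
from .rois import ROIHierarchy, ROINode, ROOT_NAME, gated_level_test
from .simulate import (
    GROUPS,
    PatternDataset,
    SyntheticCohortSpec,
    generate_condition_patterns,
    generate_roi_time_courses,
)

log = logging.getLogger("numdecode")

STAGES = ("simulate", "decode", "classify", "connectivity", "table1")


@dataclass
class RunConfig:
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    cohort: SyntheticCohortSpec = field(default_factory=SyntheticCohortSpec)
    cv: CVSpec = field(default_factory=CVSpec)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    preproc: PreprocSpec = field(default_factory=PreprocSpec)
    alpha: float = 0.05
    n_permutations: int = 200
    lpocv_repeats: int = 5

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ConfigurationError(f"unknown stage {s!r}")

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))

        d = dataclasses.asdict(self)
        d["cohort"]["separation"] = [
            list(k) + [v] for k, v in self.cohort.separation.items()
        ]
        d["cohort"]["connectivity_target"] = {
            g: np.asarray(m).tolist()
            for g, m in self.cohort.connectivity_target.items()
        }
        return json.dumps(d, indent=2, default=default)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        cohort = d.get("cohort", {})
        if "separation" in cohort:
            cohort["separation"] = {
                (g, f, r): v for g, f, r, v in cohort["separation"]
            }
        if "connectivity_target" in cohort:
            cohort["connectivity_target"] = {
                g: np.asarray(m) for g, m in cohort["connectivity_target"].items()
            }
        if "voxels_per_roi" in cohort:
            cohort["voxels_per_roi"] = dict(cohort["voxels_per_roi"])
        kwargs = dict(d)
        kwargs["cohort"] = SyntheticCohortSpec(**cohort)
        kwargs["cv"] = CVSpec(**d.get("cv", {}))
        kwargs["classifier"] = ClassifierSpec(**d.get("classifier", {}))
        kwargs["preproc"] = PreprocSpec(
            **{k: tuple(v) if k == "band" else v for k, v in d.get("preproc", {}).items()}
        )
        kwargs["stages"] = tuple(d.get("stages", STAGES))
        return cls(**kwargs)


def _flat_hierarchy(regions: tuple[str, ...]) -> ROIHierarchy:
    """Root + one level of region nodes, for gated tests on synthetic ROIs."""
    nodes = {ROOT_NAME: ROINode(ROOT_NAME, 1, None)}
    for r in regions:
        nodes[r] = ROINode(r, 2, ROOT_NAME)
    return ROIHierarchy(nodes=nodes)


def _gated_values(acc: pd.DataFrame, fmt: str, regions) -> dict:
    sub = acc[acc.format == fmt]
    values = {}
    by_subject = sub.groupby(["group", "subject"]).accuracy.mean().reset_index()
    values[ROOT_NAME] = tuple(
        by_subject.loc[by_subject.group == g, "accuracy"].to_numpy() for g in GROUPS
    )
    for region in regions:
        rsub = sub[sub.region == region]
        values[region] = tuple(
            rsub.loc[rsub.group == g, "accuracy"].to_numpy() for g in GROUPS
        )
    return values


def _subject_features(dataset: PatternDataset, fmt: str) -> tuple[np.ndarray, np.ndarray]:
    """Per subject: run-averaged patterns of one format, all regions stacked
    (the synthetic analogue of a format-minus-fixation contrast map)."""
    fmt_idx = [i for i, c in enumerate(dataset.conditions) if c.startswith(fmt)]
    feats, labels = [], []
    for s in dataset.subjects:
        vec = np.concatenate(
            [s.patterns[r][:, fmt_idx].mean(axis=(0, 1)) for r in dataset.regions]
        )
        feats.append(vec)
        labels.append(s.group)
    return np.array(feats), np.array(labels)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the enabled stages, write outputs, return the report dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    (out / "config.json").write_text(config.to_json())
    report: dict = {"seed": config.seed, "version": __version__}

    cohort = dataclasses.replace(config.cohort, seed=config.seed)
    schedule = generate_run_schedule(ExperimentDesign(), seed=config.seed)
    dataset = None

    if "simulate" in config.stages:
        log.info("simulate: %d+%d subjects, %d runs", cohort.n_per_group,
                 cohort.n_per_group, cohort.n_runs)
        schedule.write_tsv(out / "run_schedule.tsv")
        dataset = generate_condition_patterns(cohort)
        report["simulate"] = {
            "n_subjects": len(dataset.subjects),
            "n_runs": cohort.n_runs,
            "run_duration_s": schedule.total_duration,
            "regions": list(dataset.regions),
        }

    def need_dataset() -> PatternDataset:
        nonlocal dataset
        if dataset is None:
            raise ConfigurationError(
                "stage requires simulated patterns: enable the 'simulate' stage"
            )
        return dataset

    if "decode" in config.stages:
        ds = need_dataset()
        cv = dataclasses.replace(config.cv, seed=config.seed)
        log.info("decode: %d repeats x 70/30 run splits", cv.n_repeats)
        acc = decode_dataset(ds, cv, config.classifier, within_format_only=True)
        acc.to_csv(out / "decoding_accuracy.tsv", sep="\t", index=False)
        hier = _flat_hierarchy(ds.regions)
        report["decode"] = {}
        for fmt in FORMATS:
            gated = gated_level_test(
                hier, _gated_values(acc, fmt, ds.regions), alpha=config.alpha
            )
            gated.to_csv(out / f"gated_{fmt}.tsv", sep="\t", index=False)
            root = gated[gated.node == ROOT_NAME].iloc[0]
            report["decode"][fmt] = {
                "root_t": None if np.isnan(root.t) else float(root.t),
                "root_p_fdr": None if np.isnan(root.p_fdr) else float(root.p_fdr),
                "root_status": root.status,
                "mean_accuracy": float(acc.loc[acc.format == fmt, "accuracy"].mean()),
            }

    if "classify" in config.stages:
        ds = need_dataset()
        from .subjects import permutation_test  # deferred: optional stage

        report["classify"] = {}
        for fmt in FORMATS:
            x, y = _subject_features(ds, fmt)
            res = permutation_test(
                x, y, config.classifier,
                n_permutations=config.n_permutations,
                lpocv_repeats=config.lpocv_repeats,
                seed=config.seed,
            )
            report["classify"][fmt] = {
                "observed_accuracy": res.observed,
                "p": res.p,
                "null_mean": float(res.null.mean()),
            }
        (out / "subject_classification.json").write_text(
            json.dumps(report["classify"], indent=2)
        )

    if "connectivity" in config.stages:
        tcs = generate_roi_time_courses(cohort, schedule)
        edges = cohort_z_matrices(tcs, config.preproc)
        edges.to_csv(out / "connectivity_edges.tsv", sep="\t", index=False)
        tests = group_connectivity_tests(edges)
        tests.to_csv(out / "connectivity_tests.tsv", sep="\t", index=False)
        report["connectivity"] = {
            "n_edges": len(tests),
            "n_sig_between": int(tests.sig_between.sum()),
            "sig_between_edges": [
                f"{r.seed_a}-{r.seed_b}"
                for r in tests[tests.sig_between].itertuples()
            ],
        }

    if "table1" in config.stages:
        t1 = matching_table()
        t1.to_csv(out / "matching_table.tsv", sep="\t", index=False)
        report["table1"] = {
            row.measure: {"t": round(row.abs_t, 2), "d": round(row.cohens_d, 2)}
            for row in t1.itertuples()
        }

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
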