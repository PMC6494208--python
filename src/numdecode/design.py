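"""Experimental design and run-schedule generation.

The study protocol is a short-block number-comparison design: each run
interleaves 48 experimental blocks (8 conditions = 4 numerosities x 2
formats, 6 blocks each, 4-6 s long) with 7 fixation blocks (8-s boundary
fixations plus 5 short interleaved ones), for a total run length of 280 s
sampled at TR = 3 s.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

NUMEROSITIES: tuple[int, ...] = (2, 4, 6, 8)
FORMATS: tuple[str, str] = ("symbolic", "nonsymbolic")

#: Canonical 8-condition labels, symbolic first, ascending numerosity.
CONDITIONS: tuple[str, ...] = tuple(
    f"{fmt}{n}" for fmt in FORMATS for n in NUMEROSITIES
)


def condition_format(label: str) -> str:
    """Format ('symbolic' | 'nonsymbolic') of a canonical condition label."""
    for fmt in FORMATS:
        if label.startswith(fmt):
            return fmt
    raise ValueError(f"not a canonical condition label: {label!r}")


def condition_labels(n_conditions: int) -> tuple[str, ...]:
    """Canonical labels when n == 8, generic 'c0'..'c{n-1}' otherwise."""
    if n_conditions == len(CONDITIONS):
        return CONDITIONS
    return tuple(f"c{i}" for i in range(n_conditions))


@dataclass(frozen=True)
class ExperimentDesign:
    """Block/trial timing parameters of one experimental run.

    Defaults reproduce the study protocol: 8 conditions x 6 blocks of
    4/5/6 s (balanced so each condition totals 30 s), 8-s boundary
    fixations, 5 interleaved fixation blocks, 280-s runs at TR = 3 s.
    """

    n_conditions: int = 8
    blocks_per_condition: int = 6
    block_durations: tuple[float, ...] = (4.0, 5.0, 6.0)
    trial_duration: float = 1.0
    stim_on: float = 0.2
    boundary_fixation: float = 8.0
    n_interleaved_fixation: int = 5
    tr: float = 3.0
    run_length_s: float = 280.0

    def __post_init__(self) -> None:
        if self.n_conditions < 0 or self.blocks_per_condition < 0:
            raise ConfigurationError("counts must be non-negative")
        if not self.block_durations:
            raise ConfigurationError("block_durations must be non-empty")
        for d in self.block_durations:
            if d <= 0 or (d / self.trial_duration) % 1 != 0:
                raise ConfigurationError(
                    f"block duration {d} s is not a whole number of "
                    f"{self.trial_duration}-s trials"
                )

    @property
    def conditions(self) -> tuple[str, ...]:
        return condition_labels(self.n_conditions)

    @property
    def n_experimental_blocks(self) -> int:
        return self.n_conditions * self.blocks_per_condition

    @property
    def n_volumes(self) -> int:
        return int(round(self.run_length_s / self.tr))


@dataclass(frozen=True)
class Block:
    kind: str  # "experimental" | "fixation"
    condition: str | None
    onset: float
    duration: float


@dataclass(frozen=True)
class RunSchedule:
    """Ordered, contiguous block sequence of one run."""

    blocks: tuple[Block, ...]
    design: ExperimentDesign = field(default_factory=ExperimentDesign)

    def __post_init__(self) -> None:
        t = 0.0
        for b in self.blocks:
            if abs(b.onset - t) > 1e-9:
                raise ConfigurationError(
                    f"blocks not contiguous at onset {b.onset} (expected {t})"
                )
            t += b.duration

    @property
    def total_duration(self) -> float:
        return float(sum(b.duration for b in self.blocks))

    @property
    def experimental_blocks(self) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.kind == "experimental")

    @property
    def fixation_blocks(self) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.kind == "fixation")

    def condition_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for b in self.experimental_blocks:
            counts[b.condition] = counts.get(b.condition, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": [b.kind for b in self.blocks],
                "condition": [b.condition or "" for b in self.blocks],
                "onset_s": [b.onset for b in self.blocks],
                "duration_s": [b.duration for b in self.blocks],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, design: ExperimentDesign | None = None
    ) -> "RunSchedule":
        blocks = tuple(
            Block(
                kind=row.kind,
                condition=(row.condition or None)
                if isinstance(row.condition, str)
                else None,
                onset=float(row.onset_s),
                duration=float(row.duration_s),
            )
            for row in frame.itertuples()
        )
        return cls(blocks=blocks, design=design or ExperimentDesign())

    @classmethod
    def read_tsv(cls, path, design: ExperimentDesign | None = None) -> "RunSchedule":
        frame = pd.read_csv(path, sep="\t", keep_default_na=False)
        return cls.from_frame(frame, design)


def _balanced_condition_durations(
    design: ExperimentDesign, rng: np.random.Generator
) -> dict[str, list[float]]:
    """Per-condition block-duration multisets, balanced over the duration set.

    Each condition receives every allowed duration equally often, so all
    conditions carry identical total stimulation time (30 s under the
    default design).
    """
    n_dur = len(design.block_durations)
    if design.blocks_per_condition % n_dur != 0:
        raise ConfigurationError(
            f"blocks_per_condition={design.blocks_per_condition} cannot be "
            f"balanced over {n_dur} block durations {design.block_durations}"
        )
    reps = design.blocks_per_condition // n_dur
    base = [d for d in design.block_durations for _ in range(reps)]
    out: dict[str, list[float]] = {}
    for cond in design.conditions:
        durs = list(base)
        rng.shuffle(durs)
        out[cond] = durs
    return out


def _interleaved_fixation_durations(
    design: ExperimentDesign, rng: np.random.Generator
) -> list[float]:
    """Fixation-block durations chosen so the run hits its target length.

    The durations come from the same {4,5,6}-s set as experimental blocks;
    the multiset is the lexicographically smallest one whose sum closes the
    gap to ``run_length_s``, presented in seeded random order (24 s -> e.g.
    4+4+5+5+6 under the default design).
    """
    n = design.n_interleaved_fixation
    if n == 0:
        return []
    target = (
        design.run_length_s
        - 2 * design.boundary_fixation
        - design.n_conditions
        * (design.blocks_per_condition // len(design.block_durations))
        * sum(design.block_durations)
    )
    for combo in itertools.combinations_with_replacement(
        sorted(design.block_durations), n
    ):
        if abs(sum(combo) - target) < 1e-9:
            durs = list(combo)
            rng.shuffle(durs)
            return durs
    raise ConfigurationError(
        f"no multiset of {n} durations from {design.block_durations} "
        f"sums to {target} s (run_length_s={design.run_length_s})"
    )


def generate_run_schedule(
    design: ExperimentDesign | None = None, seed: int = 0
) -> RunSchedule:
    """Generate one seeded run schedule satisfying the design's invariants.

    The run opens and closes with a boundary fixation; experimental blocks
    are globally shuffled with exactly ``blocks_per_condition`` per
    condition; one interleaved fixation follows every 8th experimental
    block (more generally every ``n_exp / (n_interleaved + 1)``-th).
    """
    design = design or ExperimentDesign()
    rng = np.random.default_rng(seed)

    if design.blocks_per_condition == 0 or design.n_conditions == 0:
        blocks = (
            Block("fixation", None, 0.0, design.boundary_fixation),
            Block("fixation", None, design.boundary_fixation, design.boundary_fixation),
        )
        return RunSchedule(blocks=blocks, design=design)

    per_cond = _balanced_condition_durations(design, rng)
    exp_blocks: list[tuple[str, float]] = [
        (cond, dur) for cond, durs in per_cond.items() for dur in durs
    ]
    order = rng.permutation(len(exp_blocks))
    exp_blocks = [exp_blocks[i] for i in order]

    fix_durs = _interleaved_fixation_durations(design, rng)
    n_exp = len(exp_blocks)
    n_fix = len(fix_durs)
    if n_fix:
        if n_exp % (n_fix + 1) != 0:
            raise ConfigurationError(
                f"{n_exp} experimental blocks cannot be split evenly around "
                f"{n_fix} interleaved fixations"
            )
        interval = n_exp // (n_fix + 1)
    else:
        interval = n_exp + 1

    blocks: list[Block] = []
    t = 0.0

    def push(kind: str, cond: str | None, dur: float) -> None:
        nonlocal t
        blocks.append(Block(kind, cond, t, dur))
        t += dur

    push("fixation", None, design.boundary_fixation)
    for i, (cond, dur) in enumerate(exp_blocks, start=1):
        push("experimental", cond, dur)
        if n_fix and i % interval == 0 and i < n_exp:
            push("fixation", None, fix_durs[(i // interval) - 1])
    push("fixation", None, design.boundary_fixation)

    return RunSchedule(blocks=tuple(blocks), design=design)
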