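"""Factorial experimental design: paired Gabors under repetition/expectation contingencies.

The task presents two Gabors per trial (600 ms stimulus onset asynchrony).
Within a *repeating* block 80% of trials repeat the first Gabor's orientation
and 20% alternate; an *alternating* block reverses the contingency.  Crossing
trial type (repeat/alternate) with block type yields the 2x2 factorial

    expected_repeat      repeat trial in a repeating block
    unexpected_repeat    repeat trial in an alternating block
    expected_alternate   alternate trial in an alternating block
    unexpected_alternate alternate trial in a repeating block

so repetition and expectation can be analysed as orthogonal factors.
Orientations are drawn from a 9-value grid (0..160 deg in 20 deg steps) and
the second-Gabor orientation is exactly balanced over the grid within every
condition cell.  10% of trials in a session carry a coloured target (a task
flag only; the simulated signal is unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import ORIENTATION_GRID, rng_for

BLOCK_TYPES = ("repeating", "alternating")
TRIAL_TYPES = ("repeat", "alternate")
CONDITIONS = (
    "expected_repeat",
    "unexpected_repeat",
    "expected_alternate",
    "unexpected_alternate",
)

#: fixed column order of the design table (CSV contract)
DESIGN_COLUMNS = [
    "session_id",
    "block_id",
    "block_type",
    "trial_type",
    "condition",
    "orientation_first",
    "orientation_second",
    "is_target",
    "onset_second_s",
]

#: stimulus onset asynchrony between the two Gabors in a pair (seconds)
SOA_S = 0.6


class DesignConfigurationError(ValueError):
    """A requested design violates a divisibility/balance constraint."""


@dataclass(frozen=True)
class TrialRecord:
    """One trial of the paired-Gabor task."""

    session_id: int
    block_id: int
    block_type: str
    trial_type: str
    condition: str
    orientation_first: int
    orientation_second: int
    is_target: bool
    onset_second_s: float = SOA_S

    def __post_init__(self):
        if self.block_type not in BLOCK_TYPES:
            raise ValueError(f"unknown block_type {self.block_type!r}")
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial_type {self.trial_type!r}")
        if (self.trial_type == "repeat") != (
            self.orientation_first == self.orientation_second
        ):
            raise ValueError("trial_type must match orientation repetition")
        if condition_of(self.block_type, self.trial_type) != self.condition:
            raise ValueError("condition inconsistent with block/trial type")
        for ori in (self.orientation_first, self.orientation_second):
            if ori not in ORIENTATION_GRID:
                raise ValueError(f"orientation {ori} not on the 9-value grid")


def condition_of(block_type: str, trial_type: str) -> str:
    """Derive the factorial condition label from block and trial type.

    A trial is *expected* iff its type matches the block's majority
    contingency (repeat trials in repeating blocks, alternate trials in
    alternating blocks).
    """
    expected = (trial_type == "repeat") == (block_type == "repeating")
    return f"{'expected' if expected else 'unexpected'}_{trial_type}"


def expectation_of(condition) -> np.ndarray:
    """Map condition labels to the expectation factor (expected/unexpected)."""
    return np.asarray(
        ["expected" if str(c).startswith("expected") else "unexpected" for c in np.atleast_1d(condition)]
    )


@dataclass
class ExperimentDesign:
    """An ordered session of trials plus its block structure.

    The canonical representation is a :class:`pandas.DataFrame` with the
    columns in :data:`DESIGN_COLUMNS`; ``trials`` materialises it as
    :class:`TrialRecord` objects on demand.
    """

    table: pd.DataFrame
    n_blocks: int
    trials_per_block: int

    def __post_init__(self):
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns {missing}")
        self.table = self.table[DESIGN_COLUMNS].reset_index(drop=True)
        if len(self.table) != self.n_blocks * self.trials_per_block:
            raise ValueError("table length does not match n_blocks * trials_per_block")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def trials(self) -> list[TrialRecord]:
        return [TrialRecord(**rec) for rec in self.table.to_dict("records")]

    def labels(self, grouping: str) -> np.ndarray:
        """Per-trial labels for a grouping factor.

        ``grouping`` is a design column name or one of the derived factors
        ``"expectation"`` (expected/unexpected) or ``"repetition"``
        (alias of ``trial_type``).
        """
        if grouping == "expectation":
            return expectation_of(self.table["condition"].to_numpy())
        if grouping == "repetition":
            return self.table["trial_type"].to_numpy()
        if grouping not in self.table.columns:
            raise KeyError(f"unknown grouping column {grouping!r}")
        return self.table[grouping].to_numpy()

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path) -> "ExperimentDesign":
        table = pd.read_csv(path)
        table["is_target"] = table["is_target"].astype(bool)
        n_blocks = int(table["block_id"].nunique())
        tpb = int(len(table) // n_blocks)
        return cls(table=table, n_blocks=n_blocks, trials_per_block=tpb)


def _balanced_orientations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly n/9 trials of each grid orientation in shuffled order."""
    reps = n // len(ORIENTATION_GRID)
    out = np.repeat(ORIENTATION_GRID, reps)
    rng.shuffle(out)
    return out


class _AlternateDeck:
    """Counterbalanced first-Gabor draws for alternate trials.

    For each second-Gabor orientation, first orientations cycle through a
    shuffled deck of the 8 non-matching grid values and are only reshuffled
    once the deck is exhausted -- a without-replacement scheme that keeps the
    first/second orientation pairing as even as the trial counts allow.
    """

    def __init__(self, rng: np.random.Generator):
        self._rng = rng
        self._decks: dict[int, list[int]] = {}

    def draw(self, second: int) -> int:
        deck = self._decks.get(second)
        if not deck:
            deck = [o for o in ORIENTATION_GRID if o != second]
            self._rng.shuffle(deck)
            self._decks[second] = deck
        return int(deck.pop())


def generate_session_design(
    n_blocks: int = 20,
    trials_per_block: int = 135,
    start_block_type: str = "repeating",
    seed: int = 0,
    session_id: int = 0,
    majority_fraction: float = 0.8,
    target_fraction: float = 0.1,
) -> ExperimentDesign:
    """Generate one session of the factorial paired-Gabor design.

    Contingencies are enforced exactly per block (e.g. 108 repeats + 27
    alternates in a repeating block of 135), second-Gabor orientations are
    exactly balanced over the 9-value grid within each block-type x
    trial-type cell, block types alternate starting from
    ``start_block_type``, and exactly ``target_fraction`` of the session's
    trials carry a colour target, placed uniformly at random.

    Raises :class:`DesignConfigurationError` when the requested counts
    cannot be met exactly.
    """
    if start_block_type not in BLOCK_TYPES:
        raise DesignConfigurationError(f"unknown start_block_type {start_block_type!r}")
    n_major = majority_fraction * trials_per_block
    if abs(n_major - round(n_major)) > 1e-9:
        raise DesignConfigurationError(
            f"trials_per_block={trials_per_block} not divisible for an exact "
            f"{majority_fraction:.0%}/{1 - majority_fraction:.0%} split"
        )
    n_major = int(round(n_major))
    n_minor = trials_per_block - n_major
    k = len(ORIENTATION_GRID)
    if n_major % k or n_minor % k:
        raise DesignConfigurationError(
            f"per-block trial-type counts ({n_major}/{n_minor}) must be divisible "
            f"by the {k} grid orientations for exact balance "
            f"(trials_per_block divisible by 45 with an 80/20 split)"
        )
    if n_blocks % 2:
        raise DesignConfigurationError(
            f"n_blocks={n_blocks} must be even to balance the two block types"
        )
    n_trials = n_blocks * trials_per_block
    n_targets = target_fraction * n_trials
    if abs(n_targets - round(n_targets)) > 1e-9:
        raise DesignConfigurationError(
            f"session size {n_trials} not divisible for an exact "
            f"{target_fraction:.0%} target rate"
        )
    n_targets = int(round(n_targets))

    rng = rng_for(seed, session_id)
    deck = _AlternateDeck(rng)
    first_type = start_block_type
    other_type = BLOCK_TYPES[1 - BLOCK_TYPES.index(first_type)]

    rows = []
    for block_id in range(n_blocks):
        block_type = first_type if block_id % 2 == 0 else other_type
        majority = "repeat" if block_type == "repeating" else "alternate"
        minority = "alternate" if majority == "repeat" else "repeat"
        types = np.array([majority] * n_major + [minority] * n_minor, dtype=object)
        seconds = np.empty(trials_per_block, dtype=int)
        seconds[:n_major] = _balanced_orientations(n_major, rng)
        seconds[n_major:] = _balanced_orientations(n_minor, rng)
        order = rng.permutation(trials_per_block)
        types, seconds = types[order], seconds[order]
        for trial_type, second in zip(types, seconds):
            first = int(second) if trial_type == "repeat" else deck.draw(int(second))
            rows.append(
                {
                    "session_id": session_id,
                    "block_id": block_id,
                    "block_type": block_type,
                    "trial_type": trial_type,
                    "condition": condition_of(block_type, trial_type),
                    "orientation_first": first,
                    "orientation_second": int(second),
                    "is_target": False,
                    "onset_second_s": SOA_S,
                }
            )
    table = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    target_idx = rng.choice(n_trials, size=n_targets, replace=False)
    table.loc[np.sort(target_idx), "is_target"] = True
    return ExperimentDesign(table=table, n_blocks=n_blocks, trials_per_block=trials_per_block)
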