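"""Matching-to-sample task environment.

A trial presents one sample stimulus and a set of comparison stimuli;
the agent picks a comparison via its softmax rule and, in training
modes, receives differential feedback on the chosen edge.  Trials are
organized into shuffled blocks (every trained pair presented a fixed
number of times per block) and a phase repeats blocks until the block
accuracy reaches the mastery criterion.

The comparison set for a trial is all stimuli sharing the correct
comparison's role letter across classes (4-alternative MTS in the
replicated design), which is how comparison-only foils enter the
agent's clip space without ever being directly trained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from equivnet.clip_network import (
    AgentParams,
    ClipSpace,
    ConfigurationError,
    parse_label,
    select_comparison,
)

__all__ = [
    "MasteryState",
    "PhaseOutcome",
    "PhaseSpec",
    "TrialRecord",
    "build_block",
    "build_comparison_pool",
    "class_success_rates",
    "run_block",
    "run_entailment_tests",
    "run_phase_to_mastery",
    "trial_log_frame",
]

TrainedPair = tuple[str, str]

#: callback invoked after every trial: (record, correct_comparison_label)
TrialHook = Callable[["TrialRecord", str], None]


@dataclass(frozen=True)
class PhaseSpec:
    """One training (or testing) phase of an MTS experiment.

    ``trained_pairs`` are (sample, correct comparison) label pairs; a
    block presents each pair ``presentations_per_pair`` times in random
    order, so the block size is ``len(trained_pairs) *
    presentations_per_pair``.
    """

    name: str
    trained_pairs: tuple[TrainedPair, ...]
    presentations_per_pair: int
    mode: str = "train"  # train | mixed_train | test

    def __post_init__(self) -> None:
        if self.mode not in ("train", "mixed_train", "test"):
            raise ConfigurationError(f"unknown phase mode {self.mode!r}")
        if self.presentations_per_pair < 1:
            raise ConfigurationError("presentations_per_pair must be >= 1")

    @property
    def trials_per_block(self) -> int:
        return len(self.trained_pairs) * self.presentations_per_pair

    @property
    def classes_active(self) -> frozenset[int]:
        return frozenset(parse_label(s)[1] for s, _ in self.trained_pairs)

    @property
    def is_test(self) -> bool:
        return self.mode == "test"


@dataclass(frozen=True)
class TrialRecord:
    """One MTS trial as experienced by the agent."""

    step: int
    phase: str
    block: int
    sample: str
    comparisons: tuple[str, ...]
    chosen: str
    correct: bool
    class_id: int


@dataclass
class MasteryState:
    """Running tally for block-level mastery gating."""

    criterion: float
    block_correct: int = 0
    block_total: int = 0
    blocks_used: int = 0

    def block_accuracy(self) -> float:
        return self.block_correct / self.block_total if self.block_total else 0.0

    def mastered(self) -> bool:
        return self.block_total > 0 and self.block_accuracy() >= self.criterion


@dataclass
class PhaseOutcome:
    """Result of running one phase to mastery."""

    phase: str
    blocks_used: int
    final_accuracy: float
    converged: bool
    trials_per_block: int
    records: list[TrialRecord] = field(default_factory=list)


def build_comparison_pool(all_labels: Iterable[str]) -> dict[str, list[str]]:
    """Group the stimulus universe by role letter (sorted within letter)."""
    pool: dict[str, list[str]] = {}
    for label in all_labels:
        letter, _ = parse_label(label)
        pool.setdefault(letter, []).append(label)
    for letter in pool:
        pool[letter] = sorted(pool[letter])
    return pool


def build_block(
    phase: PhaseSpec,
    comparison_pool: Mapping[str, Sequence[str]],
    rng: np.random.Generator,
) -> list[tuple[str, str, tuple[str, ...]]]:
    """A shuffled block of (sample, correct, comparisons) trials.

    Each trained pair appears ``presentations_per_pair`` times; the
    comparison set is every stimulus in the pool sharing the correct
    comparison's letter, so untrained comparison-only stimuli appear as
    foils.
    """
    trials: list[tuple[str, str, tuple[str, ...]]] = []
    for sample, correct in phase.trained_pairs:
        letter, _ = parse_label(correct)
        if letter not in comparison_pool:
            raise ConfigurationError(
                f"phase {phase.name!r} pair ({sample}, {correct}) references letter "
                f"{letter!r} with no stimuli in the comparison pool"
            )
        comps = tuple(comparison_pool[letter])
        if correct not in comps:
            raise ConfigurationError(
                f"correct comparison {correct!r} missing from the pool for letter {letter!r}"
            )
        trials.extend([(sample, correct, comps)] * phase.presentations_per_pair)
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def run_block(
    space: ClipSpace,
    phase: PhaseSpec,
    params: AgentParams,
    rng: np.random.Generator,
    comparison_pool: Mapping[str, Sequence[str]],
    block_index: int = 0,
    on_trial: TrialHook | None = None,
) -> tuple[list[TrialRecord], float]:
    """Run one block; returns the trial records and the block accuracy.

    Clips are created on first sighting.  Testing blocks use ``beta_t``
    and deliver no feedback, leaving every h-value untouched.
    """
    records: list[TrialRecord] = []
    beta = params.beta_t if phase.is_test else params.beta_h
    n_correct = 0
    for sample, correct_label, comps in build_block(phase, comparison_pool, rng):
        space.step += 1
        space.ensure_clip(sample)
        for c in comps:
            space.ensure_clip(c)
        chosen = select_comparison(space, sample, comps, beta, rng, h0=params.h0)
        correct = chosen == correct_label
        if not phase.is_test:
            space.apply_feedback(sample, chosen, correct, params)
        if correct:
            n_correct += 1
        rec = TrialRecord(
            step=space.step,
            phase=phase.name,
            block=block_index,
            sample=sample,
            comparisons=comps,
            chosen=chosen,
            correct=correct,
            class_id=parse_label(sample)[1],
        )
        records.append(rec)
        if on_trial is not None:
            on_trial(rec, correct_label)
    return records, n_correct / len(records)


def run_phase_to_mastery(
    space: ClipSpace,
    phase: PhaseSpec,
    params: AgentParams,
    rng: np.random.Generator,
    comparison_pool: Mapping[str, Sequence[str]],
    criterion: float = 0.9,
    max_blocks: int = 50,
    on_trial: TrialHook | None = None,
    keep_records: bool = True,
) -> PhaseOutcome:
    """Repeat blocks until block accuracy >= criterion (or max_blocks).

    ``blocks_used`` is the phase's time statistic; hitting ``max_blocks``
    without mastery sets ``converged=False`` instead of raising.
    """
    if not 0.0 < criterion <= 1.0:
        raise ConfigurationError(f"mastery criterion must be in (0, 1], got {criterion}")
    state = MasteryState(criterion=criterion)
    all_records: list[TrialRecord] = []
    while state.blocks_used < max_blocks:
        records, accuracy = run_block(
            space, phase, params, rng, comparison_pool,
            block_index=state.blocks_used + 1, on_trial=on_trial,
        )
        state.block_correct = sum(r.correct for r in records)
        state.block_total = len(records)
        state.blocks_used += 1
        if keep_records:
            all_records.extend(records)
        if phase.is_test or state.mastered():
            break
    return PhaseOutcome(
        phase=phase.name,
        blocks_used=state.blocks_used,
        final_accuracy=state.block_accuracy(),
        converged=phase.is_test or state.mastered(),
        trials_per_block=phase.trials_per_block,
        records=all_records,
    )


def class_success_rates(records: Iterable[TrialRecord]) -> dict[int, float]:
    """Per-class success rate (correct/total) over the sample's class.

    Classes with no trials are absent from the map.
    """
    correct: dict[int, int] = {}
    total: dict[int, int] = {}
    for rec in records:
        total[rec.class_id] = total.get(rec.class_id, 0) + 1
        correct[rec.class_id] = correct.get(rec.class_id, 0) + int(rec.correct)
    return {cid: correct[cid] / total[cid] for cid in total}


def run_entailment_tests(
    space: ClipSpace,
    params: AgentParams,
    tests: Sequence[tuple[str, Sequence[int]]],
    comparison_pool: Mapping[str, Sequence[str]],
    rng: np.random.Generator,
    presentations: int = 4,
    on_trial: TrialHook | None = None,
) -> dict[str, float]:
    """Probe derived relations without feedback, using beta_t.

    ``tests`` lists (tag, class_ids) where a tag like ``"A-C"`` means:
    for each listed class c, present sample ``Ac`` with every C-letter
    stimulus as comparison and score ``Cc`` as correct.  Returns
    per-tag accuracy over ``presentations`` repeats per class.
    """
    out: dict[str, float] = {}
    for tag, class_ids in tests:
        try:
            sample_letter, target_letter = tag.split("-")
        except ValueError:
            raise ConfigurationError(f"malformed entailment tag {tag!r}; expected 'X-Y'")
        n_correct = 0
        n_total = 0
        for cid in class_ids:
            sample = f"{sample_letter}{cid}"
            correct_label = f"{target_letter}{cid}"
            comps = tuple(comparison_pool[target_letter])
            for _ in range(presentations):
                space.step += 1
                space.ensure_clip(sample)
                for c in comps:
                    space.ensure_clip(c)
                chosen = select_comparison(
                    space, sample, comps, params.beta_t, rng, h0=params.h0
                )
                ok = chosen == correct_label
                n_correct += int(ok)
                n_total += 1
                rec = TrialRecord(
                    step=space.step,
                    phase=f"test_{tag}",
                    block=0,
                    sample=sample,
                    comparisons=comps,
                    chosen=chosen,
                    correct=ok,
                    class_id=cid,
                )
                if on_trial is not None:
                    on_trial(rec, correct_label)
        out[tag] = n_correct / n_total
    return out


def trial_log_frame(records: Iterable[TrialRecord]):
    """Trial log as a pandas DataFrame (comparisons '|'-joined for CSV)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "step": r.step,
            "phase": r.phase,
            "block": r.block,
            "sample": r.sample,
            "comparisons": "|".join(r.comparisons),
            "chosen": r.chosen,
            "correct": r.correct,
            "class_id": r.class_id,
        }
        for r in records
    )
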