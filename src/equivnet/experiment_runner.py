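"""Orchestration of full experiments: single agents, cohorts, conditions.

An experiment runs a sequence of training phases, each gated by a
block-accuracy mastery criterion, with the network-enhancement
consolidation applied either after every mastered phase
(``during_training``), once before the derived-relation tests
(``end_of_training``), or not at all (``none``).  A cohort runs
``n_agents`` statistically independent agents (seeds ``base_seed + i``)
and aggregates blocks-to-mastery, final block accuracies, test
accuracies and the density-volume correlation matrix.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from equivnet.clip_network import AgentParams, ClipSpace
from equivnet.mts_environment import (
    PhaseOutcome,
    PhaseSpec,
    TrialRecord,
    build_comparison_pool,
    run_entailment_tests,
    run_phase_to_mastery,
)
from equivnet.network_enhancement import NeParams, NeTrace, apply_ne
from equivnet.rdt_metrics import (
    DEFAULT_EDGE_THRESHOLD,
    MassCorrelations,
    RdtSeries,
    RdtTracker,
    mass_correlations,
)

__all__ = [
    "AgentResult",
    "CohortResult",
    "ConditionComparison",
    "ExperimentConfig",
    "compare_conditions",
    "run_agent",
    "run_cohort",
]

SCHEDULES = ("none", "end_of_training", "during_training")


@dataclass
class ExperimentConfig:
    """Complete description of one experiment.

    ``classes`` maps class id to its declared member labels;
    ``comparison_only`` lists stimuli that appear as foils but are never
    directly trained (and are not counted as class members by the RDT
    tracker).  ``entailment_tests`` lists (tag, class ids) probes run
    after training, e.g. ("A-C", [1, 2, 3, 4]).
    """

    classes: dict[int, list[str]]
    phases: list[PhaseSpec]
    agent: AgentParams = field(default_factory=AgentParams)
    ne: NeParams = field(default_factory=NeParams)
    comparison_only: list[str] = field(default_factory=list)
    entailment_tests: list[tuple[str, list[int]]] = field(default_factory=list)
    mastery_criterion: float = 0.9
    max_blocks: int = 50
    n_agents: int = 15
    base_seed: int = 0
    rdt_sampling_stride: int = 1
    entailment_presentations: int = 4
    checkpoint_step: int = 500

    @property
    def all_stimuli(self) -> list[str]:
        seen: list[str] = []
        for members in self.classes.values():
            seen.extend(members)
        seen.extend(self.comparison_only)
        return seen

    def comparison_pool(self) -> dict[str, list[str]]:
        return build_comparison_pool(self.all_stimuli)

    def with_schedule(self, schedule: str) -> "ExperimentConfig":
        """A copy of the config with a different consolidation schedule."""
        return dataclasses.replace(
            self, ne=dataclasses.replace(self.ne, schedule=schedule)
        )


@dataclass
class AgentResult:
    """Everything one simulated agent produced."""

    seed: int
    phase_stats: list[PhaseOutcome]
    test_accuracies: dict[str, float]
    series: RdtSeries
    space: ClipSpace
    ne_traces: list[NeTrace]
    checkpoint: dict[str, int | None]
    records: list[TrialRecord] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return all(p.converged for p in self.phase_stats)


@dataclass
class CohortResult:
    """Aggregates over ``n_agents`` independent runs of one condition."""

    schedule: str
    agents: list[AgentResult]
    per_phase: pd.DataFrame  # phase, trials_per_block, mean_blocks_to_mastery, mean_final_accuracy
    test_accuracies: dict[str, float]
    correlations: MassCorrelations
    warnings: list[str] = field(default_factory=list)


@dataclass
class ConditionComparison:
    """Side-by-side results of the two consolidation schedules."""

    cohorts: dict[str, CohortResult]
    table: pd.DataFrame  # Table-1-style schema
    checkpoint: pd.DataFrame  # relation counts at the checkpoint step


def run_agent(
    config: ExperimentConfig,
    seed: int,
    keep_records: bool = False,
) -> AgentResult:
    """Run one agent through every phase plus the derived-relation tests.

    Fully deterministic given the seed: block shuffling and choice
    sampling share a single seeded generator, and the consolidation
    step consumes no randomness.
    """
    rng = np.random.default_rng(seed)
    space = ClipSpace()
    tracker = RdtTracker(
        space,
        config.classes,
        beta_h=config.agent.beta_h,
        edge_threshold=config.agent.h0 + 1e-9,
        stride=config.rdt_sampling_stride,
    )
    pool = config.comparison_pool()
    checkpoint: dict[str, int | None] = {
        "step": config.checkpoint_step,
        "relations": None,
        "relations_above_threshold": None,
    }
    threshold = config.agent.h0 + 1e-9

    def make_hook(is_training: bool):
        def hook(rec: TrialRecord, correct_label: str) -> None:
            tracker.on_trial(rec, correct_label, is_training=is_training)
            if checkpoint["relations"] is None and rec.step >= config.checkpoint_step:
                checkpoint["relations"] = len(space.relations)
                checkpoint["relations_above_threshold"] = sum(
                    1
                    for (s, t) in space.relations
                    if space.get_h(s, t) > threshold
                )

        return hook

    phase_stats: list[PhaseOutcome] = []
    records: list[TrialRecord] = []
    ne_traces: list[NeTrace] = []
    for phase in config.phases:
        outcome = run_phase_to_mastery(
            space,
            phase,
            config.agent,
            rng,
            pool,
            criterion=config.mastery_criterion,
            max_blocks=config.max_blocks,
            on_trial=make_hook(is_training=not phase.is_test),
            keep_records=keep_records,
        )
        if keep_records:
            records.extend(outcome.records)
        outcome.records = outcome.records if keep_records else []
        phase_stats.append(outcome)
        tracker.mark_phase_boundary()
        if config.ne.schedule == "during_training" and not phase.is_test:
            ne_traces.append(apply_ne(space, config.ne))
            tracker.snapshot()
    if config.ne.schedule == "end_of_training":
        ne_traces.append(apply_ne(space, config.ne))
        tracker.snapshot()
    test_accuracies = run_entailment_tests(
        space,
        config.agent,
        config.entailment_tests,
        pool,
        rng,
        presentations=config.entailment_presentations,
        on_trial=make_hook(is_training=False),
    )
    return AgentResult(
        seed=seed,
        phase_stats=phase_stats,
        test_accuracies=test_accuracies,
        series=tracker.series(),
        space=space,
        ne_traces=ne_traces,
        checkpoint=checkpoint,
        records=records,
    )


def run_cohort(
    config: ExperimentConfig,
    schedule: str | None = None,
    keep_records: bool = False,
) -> CohortResult:
    """Run ``config.n_agents`` independent agents and aggregate.

    Agent i uses seed ``base_seed + i`` regardless of ``n_agents``, so
    any single agent can be reproduced in isolation.
    """
    if schedule is not None:
        config = config.with_schedule(schedule)
    agents = [
        run_agent(config, config.base_seed + i, keep_records=keep_records)
        for i in range(config.n_agents)
    ]
    warnings = [
        f"agent seed {a.seed}: phase {p.phase} did not reach mastery in "
        f"{config.max_blocks} blocks"
        for a in agents
        for p in a.phase_stats
        if not p.converged
    ]
    rows = []
    for pi, phase in enumerate(config.phases):
        rows.append(
            {
                "phase": phase.name,
                "trials_per_block": phase.trials_per_block,
                "mean_blocks_to_mastery": float(
                    np.mean([a.phase_stats[pi].blocks_used for a in agents])
                ),
                "mean_final_accuracy": float(
                    np.mean([a.phase_stats[pi].final_accuracy for a in agents])
                ),
            }
        )
    test_accuracies = {
        tag: float(np.mean([a.test_accuracies[tag] for a in agents]))
        for tag, _ in config.entailment_tests
    }
    correlations = mass_correlations([a.series for a in agents])
    return CohortResult(
        schedule=config.ne.schedule,
        agents=agents,
        per_phase=pd.DataFrame(rows),
        test_accuracies=test_accuracies,
        correlations=correlations,
        warnings=warnings,
    )


def compare_conditions(
    config: ExperimentConfig,
    schedules: Sequence[str] = ("end_of_training", "during_training"),
    keep_records: bool = False,
) -> ConditionComparison:
    """Run the consolidation schedules on identical seed sets.

    Both conditions share trial sequences exactly until the first
    consolidation fires.  The summary table lists, per phase, the
    trials per block and each condition's mean blocks-to-mastery and
    mean final accuracy; the checkpoint frame compares stored-relation
    counts at the configured checkpoint step.
    """
    cohorts = {
        s: run_cohort(config, schedule=s, keep_records=keep_records) for s in schedules
    }
    table_rows = []
    for pi, phase in enumerate(config.phases):
        row: dict[str, object] = {
            "phase": phase.name,
            "n_trials": phase.trials_per_block,
        }
        for s in schedules:
            per = cohorts[s].per_phase
            row[f"time_{s}"] = float(per["mean_blocks_to_mastery"].iloc[pi])
            row[f"mastery_{s}"] = float(per["mean_final_accuracy"].iloc[pi])
        table_rows.append(row)
    checkpoint_rows = []
    for s in schedules:
        counts = [
            a.checkpoint["relations"]
            for a in cohorts[s].agents
            if a.checkpoint["relations"] is not None
        ]
        checkpoint_rows.append(
            {
                "schedule": s,
                "checkpoint_step": config.checkpoint_step,
                "mean_relations": float(np.mean(counts)) if counts else float("nan"),
                "n_agents": len(counts),
            }
        )
    return ConditionComparison(
        cohorts=cohorts,
        table=pd.DataFrame(table_rows),
        checkpoint=pd.DataFrame(checkpoint_rows),
    )
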