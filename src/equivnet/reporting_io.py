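"""Config validation, fixtures, result serialization and static figures."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from equivnet.clip_network import AgentParams, ClipSpace, parse_label
from equivnet.experiment_runner import ConditionComparison, ExperimentConfig
from equivnet.mts_environment import PhaseSpec
from equivnet.network_enhancement import NeParams

__all__ = [
    "ConfigError",
    "config_to_dict",
    "export_graph_figure",
    "export_heatmap_matrix",
    "make_fixture",
    "save_comparison",
    "validate_config",
    "write_manifest",
]

FIXTURE_KINDS = ("two_class_linear", "cotter_stewart", "one_to_many", "many_to_one")


class ConfigError(ValueError):
    """A configuration violation, reported with its JSON path."""


_TOP_KEYS = {
    "classes", "comparison_only", "phases", "entailment_tests", "agent", "ne",
    "mastery_criterion", "max_blocks", "n_agents", "base_seed",
    "rdt_sampling_stride", "entailment_presentations", "checkpoint_step",
}
_AGENT_KEYS = {f.name for f in dataclasses.fields(AgentParams)}
_NE_KEYS = {f.name for f in dataclasses.fields(NeParams)}
_PHASE_KEYS = {"name", "trained_pairs", "presentations_per_pair", "mode"}


def _reject_unknown(section: Mapping, allowed: set[str], path: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")


def _build_section(cls, raw: Mapping | None, allowed: set[str], path: str):
    if raw is None:
        return cls()
    _reject_unknown(raw, allowed, path)
    defaults = cls()
    for name in sorted(allowed - set(raw)):
        warnings.warn(
            f"{path}.{name} missing; default {getattr(defaults, name)!r} applied",
            stacklevel=3,
        )
    try:
        return cls(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def validate_config(raw: Mapping) -> ExperimentConfig:
    """Schema-check a raw JSON config, fill defaults, reject unknown keys.

    Every violation is reported with the JSON path that caused it.
    """
    _reject_unknown(raw, _TOP_KEYS, "$")
    if "classes" not in raw or not raw["classes"]:
        raise ConfigError("$.classes: at least one class is required")
    classes: dict[int, list[str]] = {}
    for key, members in raw["classes"].items():
        try:
            cid = int(key)
        except (TypeError, ValueError):
            raise ConfigError(f"$.classes.{key}: class id must be an integer") from None
        if cid < 1:
            raise ConfigError(f"$.classes.{key}: class id must be >= 1")
        for m in members:
            _, label_cid = parse_label(m)
            if label_cid != cid:
                raise ConfigError(
                    f"$.classes.{key}: member {m!r} parses to class {label_cid}, not {cid}"
                )
        classes[cid] = list(members)
    comparison_only = list(raw.get("comparison_only", []))
    for m in comparison_only:
        parse_label(m)
    declared = {m for members in classes.values() for m in members} | set(comparison_only)

    if "phases" not in raw or not raw["phases"]:
        raise ConfigError("$.phases: at least one phase is required")
    phases: list[PhaseSpec] = []
    for i, p in enumerate(raw["phases"]):
        _reject_unknown(p, _PHASE_KEYS, f"$.phases[{i}]")
        pairs = tuple(tuple(pair) for pair in p.get("trained_pairs", ()))
        for s, t in pairs:
            for label in (s, t):
                if label not in declared:
                    raise ConfigError(
                        f"$.phases[{i}].trained_pairs: {label!r} is not a declared stimulus"
                    )
        try:
            phases.append(
                PhaseSpec(
                    name=p.get("name", f"phase{i + 1}"),
                    trained_pairs=pairs,
                    presentations_per_pair=int(p["presentations_per_pair"]),
                    mode=p.get("mode", "train"),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"$.phases[{i}]: {exc}") from exc

    entailment: list[tuple[str, list[int]]] = []
    for i, t in enumerate(raw.get("entailment_tests", [])):
        _reject_unknown(t, {"tag", "classes"}, f"$.entailment_tests[{i}]")
        tag = t["tag"]
        if "-" not in tag:
            raise ConfigError(f"$.entailment_tests[{i}].tag: expected 'X-Y', got {tag!r}")
        cids = [int(c) for c in t["classes"]]
        for c in cids:
            if c not in classes:
                raise ConfigError(
                    f"$.entailment_tests[{i}].classes: unknown class {c}"
                )
        entailment.append((tag, cids))

    agent = _build_section(AgentParams, raw.get("agent"), _AGENT_KEYS, "$.agent")
    ne = _build_section(NeParams, raw.get("ne"), _NE_KEYS, "$.ne")

    mastery = float(raw.get("mastery_criterion", 0.9))
    if not 0.0 < mastery <= 1.0:
        raise ConfigError(f"$.mastery_criterion: must be in (0, 1], got {mastery}")
    n_agents = int(raw.get("n_agents", 15))
    if n_agents < 1:
        raise ConfigError(f"$.n_agents: must be >= 1, got {n_agents}")

    return ExperimentConfig(
        classes=classes,
        phases=phases,
        agent=agent,
        ne=ne,
        comparison_only=comparison_only,
        entailment_tests=entailment,
        mastery_criterion=mastery,
        max_blocks=int(raw.get("max_blocks", 50)),
        n_agents=n_agents,
        base_seed=int(raw.get("base_seed", 0)),
        rdt_sampling_stride=int(raw.get("rdt_sampling_stride", 1)),
        entailment_presentations=int(raw.get("entailment_presentations", 4)),
        checkpoint_step=int(raw.get("checkpoint_step", 500)),
    )


def config_to_dict(config: ExperimentConfig) -> dict:
    """JSON-serializable form of a config; round-trips through validate_config."""
    return {
        "classes": {str(c): list(m) for c, m in config.classes.items()},
        "comparison_only": list(config.comparison_only),
        "phases": [
            {
                "name": p.name,
                "trained_pairs": [list(pair) for pair in p.trained_pairs],
                "presentations_per_pair": p.presentations_per_pair,
                "mode": p.mode,
            }
            for p in config.phases
        ],
        "entailment_tests": [
            {"tag": tag, "classes": list(cids)} for tag, cids in config.entailment_tests
        ],
        "agent": dataclasses.asdict(config.agent),
        "ne": dataclasses.asdict(config.ne),
        "mastery_criterion": config.mastery_criterion,
        "max_blocks": config.max_blocks,
        "n_agents": config.n_agents,
        "base_seed": config.base_seed,
        "rdt_sampling_stride": config.rdt_sampling_stride,
        "entailment_presentations": config.entailment_presentations,
        "checkpoint_step": config.checkpoint_step,
    }


# ---------------------------------------------------------------------------
# fixtures


def make_fixture(kind: str) -> ExperimentConfig:
    """Deterministic ready-made experiment configurations.

    ``cotter_stewart``    the replicated 4-class design: classes 1-2 with
                          five members (A-E), classes 3-4 with three
                          (A-C), four comparison-only foils, five phases
                          with 48/48/24/24/72 trials per block.
    ``two_class_linear``  two 3-member classes trained A-B then B-C.
    ``one_to_many``       one sample trained to several comparisons.
    ``many_to_one``       the same pairs with orientation reversed.
    """
    if kind == "cotter_stewart":
        classes = {
            1: ["A1", "B1", "C1", "D1", "E1"],
            2: ["A2", "B2", "C2", "D2", "E2"],
            3: ["A3", "B3", "C3"],
            4: ["A4", "B4", "C4"],
        }
        ab = tuple((f"A{c}", f"B{c}") for c in range(1, 5))
        bc = tuple((f"B{c}", f"C{c}") for c in range(1, 5))
        cd = tuple((f"C{c}", f"D{c}") for c in (1, 2))
        de = tuple((f"D{c}", f"E{c}") for c in (1, 2))
        phases = [
            PhaseSpec("phase1_AB", ab, 12),
            PhaseSpec("phase2_BC", bc, 12),
            PhaseSpec("phase3_CD", cd, 12),
            PhaseSpec("phase4_DE", de, 12),
            PhaseSpec("phase5_mixed", ab + bc + cd + de, 6, mode="mixed_train"),
        ]
        all_classes = [1, 2, 3, 4]
        long_classes = [1, 2]
        return ExperimentConfig(
            classes=classes,
            phases=phases,
            comparison_only=["D3", "D4", "E3", "E4"],
            entailment_tests=[
                ("A-C", all_classes),
                ("C-A", all_classes),
                ("C-B", all_classes),
                ("B-A", all_classes),
                ("D-C", long_classes),
                ("E-D", long_classes),
                ("A-E", long_classes),
                ("E-A", long_classes),
            ],
        )
    if kind == "two_class_linear":
        classes = {1: ["A1", "B1", "C1"], 2: ["A2", "B2", "C2"]}
        phases = [
            PhaseSpec("phase1_AB", (("A1", "B1"), ("A2", "B2")), 12),
            PhaseSpec("phase2_BC", (("B1", "C1"), ("B2", "C2")), 12),
        ]
        return ExperimentConfig(
            classes=classes,
            phases=phases,
            entailment_tests=[("A-C", [1, 2]), ("C-A", [1, 2]), ("B-A", [1, 2])],
            n_agents=3,
            checkpoint_step=100,
        )
    if kind in ("one_to_many", "many_to_one"):
        classes = {1: ["A1", "B1", "C1"], 2: ["A2", "B2", "C2"]}
        if kind == "one_to_many":
            p1 = (("A1", "B1"), ("A2", "B2"))
            p2 = (("A1", "C1"), ("A2", "C2"))
        else:
            p1 = (("B1", "A1"), ("B2", "A2"))
            p2 = (("C1", "A1"), ("C2", "A2"))
        phases = [PhaseSpec("phase1", p1, 12), PhaseSpec("phase2", p2, 12)]
        return ExperimentConfig(
            classes=classes,
            phases=phases,
            entailment_tests=[("B-C", [1, 2]), ("C-B", [1, 2])],
            n_agents=3,
            checkpoint_step=100,
        )
    raise ConfigError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")


# ---------------------------------------------------------------------------
# exports


def class_grouped_order(space: ClipSpace) -> list[str]:
    """Stimulus labels grouped by class, alphabetical within class."""
    return sorted(space.labels, key=lambda l: (space.clips[l].class_id, l))


def export_heatmap_matrix(
    space: ClipSpace,
    csv_path,
    image_path=None,
    order: Sequence[str] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Min-max normalized h matrix, class-grouped, as CSV (6 decimals).

    Rows are percept/sample stimuli, columns action/comparison stimuli.
    An empty space yields an empty matrix with headers.  Optionally
    renders a heatmap image.
    """
    labels = list(order) if order is not None else class_grouped_order(space)
    _, W = space.weight_matrix(labels)
    if W.size:
        lo, hi = W.min(), W.max()
        norm = (W - lo) / (hi - lo) if hi > lo else np.zeros_like(W)
    else:
        norm = W
    frame = pd.DataFrame(np.round(norm, 6), index=labels, columns=labels)
    frame.to_csv(csv_path, float_format="%.6f")
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import seaborn as sns

        fig, ax = plt.subplots(figsize=(8, 7))
        sns.heatmap(frame, cmap="gist_heat_r", ax=ax, square=True)
        ax.set_xlabel("action / comparison")
        ax.set_ylabel("percept / sample")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return labels, norm


def export_graph_figure(
    space: ClipSpace,
    image_path=None,
    graphml_path=None,
    min_opacity: float = 0.33,
) -> None:
    """Column-per-class network figure plus GraphML export.

    Edge opacity is the network-normalized weight floored at
    ``min_opacity`` so weak edges never vanish; thickness scales the
    same way.
    """
    if graphml_path is not None:
        space.to_graphml(graphml_path)
    if image_path is None:
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    class_ids = sorted({c.class_id for c in space.clips.values()})
    col = {cid: i for i, cid in enumerate(class_ids)}
    letters = sorted({c.role_letter for c in space.clips.values()})
    row = {letter: i for i, letter in enumerate(letters)}
    pos = {
        l: (col[c.class_id], -row[c.role_letter]) for l, c in space.clips.items()
    }
    edges = [(s, t, h) for s, t, h, _, _ in space.edge_list() if h > 0]
    hmax = max((h for _, _, h in edges), default=1.0)
    fig, ax = plt.subplots(figsize=(8, 6))
    ax.set_facecolor("0.85")
    for s, t, h in edges:
        w = h / hmax if hmax else 0.0
        alpha = max(w, min_opacity)
        (x0, y0), (x1, y1) = pos[s], pos[t]
        ax.annotate(
            "",
            xy=(x1, y1),
            xytext=(x0, y0),
            arrowprops=dict(
                arrowstyle="-|>", alpha=alpha, lw=0.5 + 2.5 * w, color="black"
            ),
        )
    for l, (x, y) in pos.items():
        ax.scatter([x], [y], s=600, color="white", edgecolor="black", zorder=3)
        ax.annotate(l, (x, y), ha="center", va="center", zorder=4)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(image_path, dpi=150)
    plt.close(fig)


def config_hash(config: ExperimentConfig) -> str:
    canonical = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_manifest(outdir, config: ExperimentConfig, files: Sequence[str]) -> Path:
    """Record everything needed to reproduce a run: config hash, seeds, files."""
    from equivnet import __version__

    outdir = Path(outdir)
    manifest = {
        "config_hash": config_hash(config),
        "seeds": [config.base_seed + i for i in range(config.n_agents)],
        "software_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": sorted(files),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def save_comparison(
    outdir, comparison: ConditionComparison, config: ExperimentConfig
) -> list[str]:
    """Write the standard result files for a two-condition run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def _write(name: str, frame: pd.DataFrame) -> None:
        frame.to_csv(outdir / name, index=False)
        files.append(name)

    _write("phase_summary.csv", comparison.table)
    _write("checkpoint_relations.csv", comparison.checkpoint)
    for schedule, cohort in comparison.cohorts.items():
        corr = cohort.correlations.summary.copy()
        corr["per_agent_r"] = [
            "|".join(
                f"{r:.6f}" if np.isfinite(r) else "nan"
                for _, _, r in cohort.correlations.per_series[(row.density_measure, row.volume_measure)]
            )
            for row in corr.itertuples()
        ]
        _write(f"correlations_{schedule}.csv", corr)
        _write(
            f"ne_trace_{schedule}.csv",
            pd.DataFrame(
                {
                    "agent_seed": a.seed,
                    "application": i + 1,
                    "step": t.step,
                    "iterations": t.iterations,
                    "final_delta": t.final_delta,
                    "edges_before": t.edges_before,
                    "edges_after": t.edges_after,
                }
                for a in cohort.agents
                for i, t in enumerate(a.ne_traces)
            ),
        )
        _write(
            f"test_accuracies_{schedule}.csv",
            pd.DataFrame(
                [{"tag": k, "mean_accuracy": v} for k, v in cohort.test_accuracies.items()]
            ),
        )
        long = pd.concat(
            [
                a.series.to_long().assign(agent_seed=a.seed)
                for a in cohort.agents
            ],
            ignore_index=True,
        )
        _write(f"rdt_series_{schedule}.csv", long)
    (outdir / "config.json").write_text(json.dumps(config_to_dict(config), indent=2))
    files.append("config.json")
    write_manifest(outdir, config, files + ["manifest.json"])
    return files
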