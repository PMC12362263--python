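"""The agent's episodic-compositional memory: a clip network.

A projective-simulation agent stores every stimulus it has perceived as a
*clip*, a node in a weighted directed graph.  The edge weights (h-values)
drive action selection through a softmax rule and are updated by
differential reinforcement with damping toward a resting value of 1:

    h(t+1) = h(t) - gamma * (h(t) - 1) + lambda

where ``lambda`` is the reward delivered on the reinforced edge
(+1 on a correct match, -1 on an incorrect one by default) and ``gamma``
is a slow global forgetting rate.  h-values are unbounded: negative
weights are allowed and simply make an option very unlikely under the
softmax.

The matrix view of the clip space (rows = percept/sample clips, columns
= action/comparison clips, absent edges = 0) is the input to the
network-enhancement consolidation step and to all density/volume
metrics.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AgentParams",
    "ClipSpace",
    "ConfigurationError",
    "Relation",
    "RelationKind",
    "StateError",
    "StimulusClip",
    "parse_label",
    "select_comparison",
    "transition_probabilities",
    "update_h",
]

_LABEL_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


class ConfigurationError(ValueError):
    """Raised for malformed labels or invalid parameter settings."""


class StateError(KeyError):
    """Raised when an operation references a clip that does not exist."""


def parse_label(label: str) -> tuple[str, int]:
    """Split a stimulus label into (role letter, class id), e.g. "B3" -> ("B", 3)."""
    m = _LABEL_RE.match(label or "")
    if m is None:
        raise ConfigurationError(
            f"malformed stimulus label {label!r}: expected letter(s) followed by a class number"
        )
    return m.group(1), int(m.group(2))


class RelationKind(str, Enum):
    """Provenance of an edge in the clip space."""

    BASELINE = "baseline"            # directly reinforced sample -> correct comparison
    SYMMETRY_TRAINED = "symmetry_trained"  # mirror of a reinforced edge
    DERIVED = "derived"              # created by consolidation or manual editing
    INCORRECT = "incorrect"          # sample -> wrongly chosen comparison


@dataclass(frozen=True)
class StimulusClip:
    """A remembered stimulus: one node of the clip network."""

    label: str
    class_id: int
    role_letter: str
    first_seen_step: int = 0


@dataclass
class Relation:
    """Metadata for one directed edge; the h-value itself lives in the weight matrix."""

    source: str
    target: str
    kind: RelationKind
    created_step: int


@dataclass
class AgentParams:
    """Learning parameters of the projective-simulation agent.

    gamma            damping / forgetting rate in [0, 1]
    beta_h           softmax temperature during training (small => slow learning)
    beta_t           softmax temperature during testing
    h0               initial edge weight; also the score of a never-seen edge
                     at choice time, so novel comparisons are picked at chance
    reward_correct   lambda applied to the chosen edge on a correct match
    reward_incorrect lambda applied on an incorrect match
    mirror_updates   whether the reverse edge receives the same reward
                     (the mechanism by which symmetry arises during training)
    global_damping   whether every stored edge is damped toward 1 once per trial
    """

    gamma: float = 0.001
    beta_h: float = 0.1
    beta_t: float = 4.0
    h0: float = 1.0
    reward_correct: float = 1.0
    reward_incorrect: float = -1.0
    mirror_updates: bool = True
    global_damping: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ConfigurationError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.beta_h < 0 or self.beta_t < 0:
            raise ConfigurationError("softmax temperatures beta_h/beta_t must be >= 0")


def update_h(h: float, gamma: float, lam: float) -> float:
    """One reinforcement update: h - gamma*(h - 1) + lam.

    For lam = 0 this is pure damping toward the resting value 1, which is
    the fixed point of the update.
    """
    return h - gamma * (h - 1.0) + lam


class ClipSpace:
    """Weighted directed graph over stimulus clips.

    Clips are created on first sighting and never removed.  Edges carry
    an h-value (stored in a dense matrix for fast vectorized damping and
    metric computation) plus a :class:`Relation` record with provenance.
    """

    def __init__(self) -> None:
        self.clips: dict[str, StimulusClip] = {}
        self.relations: dict[tuple[str, str], Relation] = {}
        self.step: int = 0
        self.audit: list[tuple[int, str, str, float | None, float]] = []
        self._index: dict[str, int] = {}
        self._labels: list[str] = []
        self._W = np.zeros((0, 0))
        self._mask = np.zeros((0, 0), dtype=bool)

    # -- clip management ------------------------------------------------

    @property
    def labels(self) -> list[str]:
        """Clip labels in insertion order (the matrix row/column order)."""
        return list(self._labels)

    def ensure_clip(self, label: str, step: int | None = None) -> StimulusClip:
        """Create a clip for ``label`` if absent; idempotent on repeats."""
        if label in self.clips:
            return self.clips[label]
        letter, class_id = parse_label(label)
        clip = StimulusClip(
            label=label,
            class_id=class_id,
            role_letter=letter,
            first_seen_step=self.step if step is None else step,
        )
        self.clips[label] = clip
        self._index[label] = len(self._labels)
        self._labels.append(label)
        n = len(self._labels)
        W = np.zeros((n, n))
        M = np.zeros((n, n), dtype=bool)
        W[: n - 1, : n - 1] = self._W
        M[: n - 1, : n - 1] = self._mask
        self._W, self._mask = W, M
        return clip

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise StateError(f"unknown clip {label!r}") from None

    # -- edge access ----------------------------------------------------

    def has_edge(self, source: str, target: str) -> bool:
        return (source, target) in self.relations

    def get_h(self, source: str, target: str, default: float = 0.0) -> float:
        """h-value of an edge, or ``default`` if the edge does not exist."""
        if (source, target) not in self.relations:
            return default
        return float(self._W[self._index[source], self._index[target]])

    def set_h(
        self,
        source: str,
        target: str,
        value: float,
        kind: RelationKind = RelationKind.DERIVED,
        step: int | None = None,
    ) -> None:
        """Write an h-value, creating the relation (with ``kind``) if absent."""
        i, j = self.index(source), self.index(target)
        if (source, target) not in self.relations:
            self.relations[(source, target)] = Relation(
                source=source,
                target=target,
                kind=kind,
                created_step=self.step if step is None else step,
            )
            self._mask[i, j] = True
        self._W[i, j] = value

    def edit_relation(self, source: str, target: str, new_h: float) -> None:
        """Programmatic relation editor: set an edge weight, with audit trail.

        Creates the edge (kind ``derived``) when absent.
        """
        if not np.isfinite(new_h):
            raise ConfigurationError(f"edge weight must be finite, got {new_h!r}")
        old = self.get_h(source, target) if self.has_edge(source, target) else None
        self.set_h(source, target, float(new_h), kind=RelationKind.DERIVED)
        self.audit.append((self.step, source, target, old, float(new_h)))

    # -- learning -------------------------------------------------------

    def apply_feedback(
        self, sample: str, chosen: str, correct: bool, params: AgentParams
    ) -> None:
        """Differential reinforcement of one MTS choice.

        The edge sample->chosen receives lambda = ``reward_correct`` or
        ``reward_incorrect``; with ``mirror_updates`` the reverse edge
        receives the same lambda.  All stored edges are damped toward 1
        by gamma once per call when ``global_damping`` is set (the
        reinforced edges receive damping plus lambda, i.e. the full
        update rule).
        """
        if sample not in self.clips:
            raise StateError(f"unknown clip {sample!r}")
        if chosen not in self.clips:
            raise StateError(f"unknown clip {chosen!r}")
        lam = params.reward_correct if correct else params.reward_incorrect
        fwd_kind = RelationKind.BASELINE if correct else RelationKind.INCORRECT
        if not self.has_edge(sample, chosen):
            self.set_h(sample, chosen, params.h0, kind=fwd_kind)
        targets = [(sample, chosen)]
        if params.mirror_updates and sample != chosen:
            if not self.has_edge(chosen, sample):
                self.set_h(chosen, sample, params.h0, kind=RelationKind.SYMMETRY_TRAINED)
            targets.append((chosen, sample))
        if params.global_damping and params.gamma:
            self._W[self._mask] -= params.gamma * (self._W[self._mask] - 1.0)
        else:
            for s, t in targets:
                i, j = self._index[s], self._index[t]
                self._W[i, j] = self._W[i, j] - params.gamma * (self._W[i, j] - 1.0)
        for s, t in targets:
            self._W[self._index[s], self._index[t]] += lam

    # -- matrix / export views -------------------------------------------

    def weight_matrix(
        self, order: Sequence[str] | None = None
    ) -> tuple[list[str], np.ndarray]:
        """Dense h-value matrix (rows = sample/percept, cols = comparison/action).

        Absent edges read 0.  ``order`` selects and orders the labels;
        default is insertion order.
        """
        labels = list(order) if order is not None else list(self._labels)
        idx = [self.index(l) for l in labels]
        W = self._W[np.ix_(idx, idx)].copy()
        M = self._mask[np.ix_(idx, idx)]
        W[~M] = 0.0
        return labels, W

    def edge_mask(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Boolean existence mask aligned with :meth:`weight_matrix`."""
        labels = list(order) if order is not None else list(self._labels)
        idx = [self.index(l) for l in labels]
        return self._mask[np.ix_(idx, idx)].copy()

    def edge_list(self) -> list[tuple[str, str, float, str, int]]:
        """(source, target, h, kind, created_step) rows, insertion-ordered by label."""
        rows = []
        for (s, t), rel in self.relations.items():
            rows.append((s, t, self.get_h(s, t), rel.kind.value, rel.created_step))
        rows.sort(key=lambda r: (self._index[r[0]], self._index[r[1]]))
        return rows

    def to_edge_list_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["source", "target", "h", "kind", "created_step"])
            for row in self.edge_list():
                w.writerow([row[0], row[1], repr(row[2]), row[3], row[4]])

    def to_networkx(self):
        """Export as a networkx.DiGraph with node/edge attributes."""
        import networkx as nx

        g = nx.DiGraph()
        for label, clip in self.clips.items():
            g.add_node(
                label,
                class_id=clip.class_id,
                role_letter=clip.role_letter,
                first_seen_step=clip.first_seen_step,
            )
        for s, t, h, kind, created in self.edge_list():
            g.add_edge(s, t, h=h, kind=kind, created_step=created)
        return g

    def to_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def from_networkx(cls, g) -> "ClipSpace":
        space = cls()
        for label, data in g.nodes(data=True):
            space.ensure_clip(label, step=int(data.get("first_seen_step", 0)))
        for s, t, data in g.edges(data=True):
            space.set_h(
                s,
                t,
                float(data["h"]),
                kind=RelationKind(data.get("kind", "derived")),
                step=int(data.get("created_step", 0)),
            )
        return space

    @classmethod
    def from_graphml(cls, path) -> "ClipSpace":
        import networkx as nx

        return cls.from_networkx(nx.read_graphml(path))

    def copy(self) -> "ClipSpace":
        out = ClipSpace()
        out.clips = dict(self.clips)
        out.relations = {k: Relation(*vars(v).values()) for k, v in self.relations.items()}
        out.step = self.step
        out.audit = list(self.audit)
        out._index = dict(self._index)
        out._labels = list(self._labels)
        out._W = self._W.copy()
        out._mask = self._mask.copy()
        return out


def transition_probabilities(
    space: ClipSpace,
    sample: str,
    comparisons: Sequence[str],
    beta: float,
    h0: float = 1.0,
) -> np.ndarray:
    """Softmax choice distribution over the comparison set.

    p_i = exp(beta * h_i) / sum_k exp(beta * h_k), with h read from the
    clip space and missing edges scored at the resting weight ``h0`` so
    that novel comparisons are choosable at chance.  Computed with
    max-subtraction for overflow safety.
    """
    if len(comparisons) == 0:
        raise ConfigurationError("comparison set must be non-empty")
    h = np.array([space.get_h(sample, c, default=h0) for c in comparisons])
    z = beta * h
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def select_comparison(
    space: ClipSpace,
    sample: str,
    comparisons: Sequence[str],
    beta: float,
    rng: np.random.Generator,
    h0: float = 1.0,
) -> str:
    """Sample one comparison according to :func:`transition_probabilities`."""
    p = transition_probabilities(space, sample, comparisons, beta, h0=h0)
    return comparisons[int(rng.choice(len(comparisons), p=p))]
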