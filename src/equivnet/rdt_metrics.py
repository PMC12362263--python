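"""Relational Density Theory instrumentation.

RDT treats a relational network as having *volume* (how many stimuli /
relations, how far apart), *density* (how strong the relations are) and
*mass*, their product, which predicts resistance to change.  This
module computes four volume measures and three density measures per
stimulus class, per trial:

volume
    true nodal distance      shortest-path separation over the current
                             clip space (derived edges included), summed
                             over member pairs
    empirical nodal distance separation counted only through directly
                             trained relations (training-structure fact,
                             independent of h-values)
    class size               number of member stimuli observed so far
    number of relations      directed intra-class edges above threshold

density
    mean transition probability  average softmax probability of
                                 intra-class edges (the agent's own
                                 choice rule turned into a measure)
    class accuracy               cumulative proportion of correct trials
                                 whose sample belongs to the class
    mean h-value                 average intra-class edge weight

Pearson correlations between each density and volume series quantify
which pairing best captures the inverse density-volume relationship.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from equivnet.clip_network import ClipSpace
from equivnet.mts_environment import TrialRecord

__all__ = [
    "DENSITY_MEASURES",
    "DEFAULT_EDGE_THRESHOLD",
    "VOLUME_MEASURES",
    "MassCorrelations",
    "RdtSeries",
    "RdtSnapshot",
    "RdtTracker",
    "class_accuracy",
    "class_size",
    "empirical_nodal_distance",
    "mass_correlations",
    "mean_h",
    "mean_transition_probability",
    "num_relations",
    "pairwise_hops",
    "relational_mass",
    "true_nodal_distance",
]

#: an edge "exists" once reinforced above the resting weight h0 = 1
DEFAULT_EDGE_THRESHOLD = 1.0 + 1e-9

DENSITY_MEASURES = ("mean_transition_probability", "class_accuracy", "mean_h")
VOLUME_MEASURES = (
    "true_nodal_distance",
    "empirical_nodal_distance",
    "class_size",
    "num_relations",
)


def _present_members(
    space: ClipSpace, class_id: int, members: Sequence[str] | None
) -> list[str]:
    if members is None:
        return [l for l, c in space.clips.items() if c.class_id == class_id]
    return [m for m in members if m in space.clips]


def pairwise_hops(
    space: ClipSpace,
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
    directed: bool = False,
) -> tuple[list[str], np.ndarray]:
    """Unweighted shortest-path (hop) matrix over all clips.

    Only edges with h above ``edge_threshold`` participate; by default
    edges are treated as undirected (equivalence relations are
    bidirectional).  Unreachable pairs are +inf.
    """
    labels, W = space.weight_matrix()
    mask = space.edge_mask()
    adj = ((W > edge_threshold) & mask).astype(float)
    if not directed:
        adj = np.maximum(adj, adj.T)
    if adj.shape[0] == 0:
        return labels, np.zeros((0, 0))
    dist = shortest_path(adj, method="D", directed=True, unweighted=True)
    return labels, dist


def true_nodal_distance(
    space: ClipSpace,
    class_id: int,
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
    members: Sequence[str] | None = None,
    directed: bool = False,
    hops: tuple[list[str], np.ndarray] | None = None,
) -> float:
    """Sum over member pairs of intermediate-node counts on shortest paths.

    Paths run through the *whole* current clip space, so derived and
    even inter-class edges can link a pair.  A directly linked pair
    contributes 0; a disconnected pair contributes a finite penalty of
    (number of present members - 1), which produces the characteristic
    spike when a member first appears as an untrained comparison.
    Singleton classes score 0.
    """
    present = _present_members(space, class_id, members)
    m = len(present)
    if m < 2:
        return 0.0
    if hops is None:
        hops = pairwise_hops(space, edge_threshold, directed=directed)
    labels, dist = hops
    idx = {l: i for i, l in enumerate(labels)}
    penalty = float(m - 1)
    total = 0.0
    for a in range(m):
        for b in range(a + 1, m):
            d = dist[idx[present[a]], idx[present[b]]]
            total += penalty if np.isinf(d) else max(d - 1.0, 0.0)
    return total


def empirical_nodal_distance(
    space: ClipSpace,
    class_id: int,
    trained_pairs: Iterable[tuple[str, str]],
    members: Sequence[str] | None = None,
) -> float:
    """Nodal distance through directly trained relations only.

    The graph contains only the directly reinforced pairs (undirected);
    for every member pair *not* directly trained, the intermediate
    stimuli on the shortest path are counted (each such stimulus
    necessarily carries at least two trained relations).  Disconnected
    untrained pairs contribute the same finite penalty as
    :func:`true_nodal_distance`.  The measure depends only on the
    training structure, never on h-values.
    """
    present = _present_members(space, class_id, members)
    m = len(present)
    if m < 2:
        return 0.0
    adj: dict[str, set[str]] = {}
    trained: set[frozenset[str]] = set()
    for s, t in trained_pairs:
        trained.add(frozenset((s, t)))
        adj.setdefault(s, set()).add(t)
        adj.setdefault(t, set()).add(s)
    penalty = float(m - 1)
    total = 0.0
    for a in range(m):
        for b in range(a + 1, m):
            u, v = present[a], present[b]
            if frozenset((u, v)) in trained:
                continue
            d = _bfs_hops(adj, u, v)
            total += penalty if d is None else max(d - 1.0, 0.0)
    return total


def _bfs_hops(adj: Mapping[str, set[str]], start: str, goal: str) -> int | None:
    if start not in adj or goal not in adj:
        return None
    seen = {start}
    frontier = [start]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for node in frontier:
            for nb in adj.get(node, ()):
                if nb == goal:
                    return d
                if nb not in seen:
                    seen.add(nb)
                    nxt.append(nb)
        frontier = nxt
    return None


def class_size(
    space: ClipSpace, class_id: int, members: Sequence[str] | None = None
) -> int:
    """Number of member stimuli currently present in the clip space."""
    return len(_present_members(space, class_id, members))


def _intra_class_edges(
    space: ClipSpace, present: Sequence[str]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    labels, W = space.weight_matrix()
    mask = space.edge_mask()
    member_idx = np.array([labels.index(m) for m in present], dtype=int)
    intra = np.zeros_like(mask)
    intra[np.ix_(member_idx, member_idx)] = True
    np.fill_diagonal(intra, False)
    return labels, W, mask & intra


def num_relations(
    space: ClipSpace,
    class_id: int,
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
    members: Sequence[str] | None = None,
) -> int:
    """Count of directed intra-class edges with h above threshold."""
    present = _present_members(space, class_id, members)
    if len(present) < 2:
        return 0
    _, W, intra = _intra_class_edges(space, present)
    return int(np.count_nonzero(intra & (W > edge_threshold)))


def mean_h(
    space: ClipSpace,
    class_id: int,
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
    members: Sequence[str] | None = None,
) -> float:
    """Arithmetic mean h over intra-class edges above threshold (NaN if none)."""
    present = _present_members(space, class_id, members)
    if len(present) < 2:
        return float("nan")
    _, W, intra = _intra_class_edges(space, present)
    sel = intra & (W > edge_threshold)
    if not sel.any():
        return float("nan")
    return float(W[sel].mean())


def mean_transition_probability(
    space: ClipSpace,
    class_id: int,
    beta_h: float,
    members: Sequence[str] | None = None,
) -> float:
    """Average softmax transition probability between intra-class stimuli.

    Every ordered pair (i, j) of distinct present members is scored
    with the agent's own choice rule applied to the class: exp(beta_h
    * h_ij) normalized over the transitions from i to every class
    member, the self transition included (h read from the weight
    matrix, absent edges 0).  Untrained pairs pull the average down,
    so the measure sits roughly at 1/(number of stimuli) once h-values
    saturate and is inversely related to the volume measures; weak
    derived and reflexive edges added by consolidation lower it
    further.  A class with a single present member scores exactly 1.0
    -- the whole distribution sits on the one self-referential
    transition, producing the early-trial spike.  An empty class is
    NaN.
    """
    present = _present_members(space, class_id, members)
    if not present:
        return float("nan")
    if len(present) == 1:
        return 1.0
    labels, W = space.weight_matrix()
    idx = {l: i for i, l in enumerate(labels)}
    member_idx = np.array([idx[m] for m in present])
    H = W[np.ix_(member_idx, member_idx)]
    Z = beta_h * H
    Z -= Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    P = E / E.sum(axis=1, keepdims=True)
    m = len(present)
    off_diag = ~np.eye(m, dtype=bool)
    return float(P[off_diag].mean())


def class_accuracy(records: Iterable[TrialRecord], class_id: int) -> float:
    """Cumulative proportion correct over trials whose sample is in the class."""
    n = c = 0
    for rec in records:
        if rec.class_id == class_id:
            n += 1
            c += int(rec.correct)
    return c / n if n else float("nan")


def relational_mass(density: float, volume: float) -> float:
    """Relational mass Rm = Rp x Rv; NaN inputs propagate."""
    return float(density) * float(volume)


# ---------------------------------------------------------------------------
# per-trial time series


@dataclass(frozen=True)
class RdtSnapshot:
    """All measures for one class at one step."""

    step: int
    class_id: int
    true_nodal_distance: float
    empirical_nodal_distance: float
    class_size: int
    num_relations: int
    mean_transition_probability: float
    class_accuracy: float
    mean_h: float


@dataclass
class RdtSeries:
    """Per-class measure time series plus phase-transition markers."""

    frame: pd.DataFrame
    phase_boundaries: list[int] = field(default_factory=list)

    def for_class(self, class_id: int) -> pd.DataFrame:
        return self.frame[self.frame["class_id"] == class_id].reset_index(drop=True)

    def to_long(self) -> pd.DataFrame:
        """(step, class_id, measure_name, value) long format for CSV export."""
        return self.frame.melt(
            id_vars=["step", "class_id"], var_name="measure_name", value_name="value"
        )


class RdtTracker:
    """Hookable per-trial recorder of every density/volume measure.

    Attach :meth:`on_trial` to the environment's trial hook; a snapshot
    of all measures for every class is taken every ``stride`` trials.
    ``class_members`` fixes class membership to the experiment's
    declared members, so comparison-only foils do not inflate class
    size (their clips still participate in true-nodal-distance paths).
    """

    def __init__(
        self,
        space: ClipSpace,
        class_members: Mapping[int, Sequence[str]],
        beta_h: float,
        edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
        stride: int = 1,
    ) -> None:
        self.space = space
        self.class_members = {c: list(m) for c, m in class_members.items()}
        self.beta_h = beta_h
        self.edge_threshold = edge_threshold
        self.stride = max(int(stride), 1)
        self.trained_pairs: set[tuple[str, str]] = set()
        self.phase_boundaries: list[int] = []
        self._rows: list[RdtSnapshot] = []
        self._n_trials = 0
        self._acc_total: dict[int, int] = {}
        self._acc_correct: dict[int, int] = {}
        self._emp_cache: tuple[int, int, dict[int, float]] | None = None

    def on_trial(
        self, rec: TrialRecord, correct_label: str, is_training: bool = True
    ) -> None:
        if is_training:
            self.trained_pairs.add((rec.sample, correct_label))
        self._acc_total[rec.class_id] = self._acc_total.get(rec.class_id, 0) + 1
        self._acc_correct[rec.class_id] = (
            self._acc_correct.get(rec.class_id, 0) + int(rec.correct)
        )
        self._n_trials += 1
        if self._n_trials % self.stride == 0:
            self.snapshot(rec.step)

    def mark_phase_boundary(self) -> None:
        self.phase_boundaries.append(self.space.step)

    def _empirical_all(self) -> dict[int, float]:
        key = (len(self.trained_pairs), len(self.space.clips))
        if self._emp_cache is not None and self._emp_cache[:2] == key:
            return self._emp_cache[2]
        values = {
            cid: empirical_nodal_distance(
                self.space, cid, self.trained_pairs, members=members
            )
            for cid, members in self.class_members.items()
        }
        self._emp_cache = (*key, values)
        return values

    def snapshot(self, step: int | None = None) -> None:
        step = self.space.step if step is None else step
        hops = pairwise_hops(self.space, self.edge_threshold)
        emp = self._empirical_all()
        for cid, members in self.class_members.items():
            present = [m for m in members if m in self.space.clips]
            if not present:
                continue
            total = self._acc_total.get(cid, 0)
            acc = (
                self._acc_correct.get(cid, 0) / total if total else float("nan")
            )
            self._rows.append(
                RdtSnapshot(
                    step=step,
                    class_id=cid,
                    true_nodal_distance=true_nodal_distance(
                        self.space, cid, self.edge_threshold,
                        members=present, hops=hops,
                    ),
                    empirical_nodal_distance=emp[cid],
                    class_size=len(present),
                    num_relations=num_relations(
                        self.space, cid, self.edge_threshold, members=present
                    ),
                    mean_transition_probability=mean_transition_probability(
                        self.space, cid, self.beta_h, members=present
                    ),
                    class_accuracy=acc,
                    mean_h=mean_h(
                        self.space, cid, self.edge_threshold, members=present
                    ),
                )
            )

    def series(self) -> RdtSeries:
        frame = pd.DataFrame([vars(r) for r in self._rows])
        return RdtSeries(frame=frame, phase_boundaries=list(self.phase_boundaries))


# ---------------------------------------------------------------------------
# correlations across the cohort


@dataclass
class MassCorrelations:
    """Pearson r between every density and volume series.

    ``per_series`` holds one r per (agent, class); ``summary`` averages
    them per (density, volume) combination.  Zero-variance or too-short
    series are missing (NaN), never 0.
    """

    summary: pd.DataFrame
    per_series: dict[tuple[str, str], list[tuple[int, int, float]]]

    def mean_r(self, density_measure: str, volume_measure: str) -> float:
        sel = self.summary[
            (self.summary["density_measure"] == density_measure)
            & (self.summary["volume_measure"] == volume_measure)
        ]
        return float(sel["mean_r"].iloc[0])


def _pearson(x: np.ndarray, y: np.ndarray, min_points: int = 3) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < min_points or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def mass_correlations(
    series_collection: Sequence[RdtSeries],
    density_measures: Sequence[str] = DENSITY_MEASURES,
    volume_measures: Sequence[str] = VOLUME_MEASURES,
    min_points: int = 3,
    pooled: bool = False,
) -> MassCorrelations:
    """Correlate each density series with each volume series.

    Default aggregation is one Pearson r per class per agent, then the
    mean over all of them; ``pooled=True`` instead concatenates all
    step series into a single correlation per combination.
    """
    per_series: dict[tuple[str, str], list[tuple[int, int, float]]] = {
        (d, v): [] for d in density_measures for v in volume_measures
    }
    pooled_xy: dict[tuple[str, str], tuple[list, list]] = {
        (d, v): ([], []) for d in density_measures for v in volume_measures
    }
    for agent_idx, series in enumerate(series_collection):
        frame = series.frame
        for cid in sorted(frame["class_id"].unique()):
            sub = frame[frame["class_id"] == cid]
            for d in density_measures:
                for v in volume_measures:
                    x = sub[d].to_numpy(dtype=float)
                    y = sub[v].to_numpy(dtype=float)
                    if pooled:
                        pooled_xy[(d, v)][0].extend(x)
                        pooled_xy[(d, v)][1].extend(y)
                    else:
                        per_series[(d, v)].append(
                            (agent_idx, int(cid), _pearson(x, y, min_points))
                        )
    rows = []
    for d in density_measures:
        for v in volume_measures:
            if pooled:
                r = _pearson(
                    np.array(pooled_xy[(d, v)][0]),
                    np.array(pooled_xy[(d, v)][1]),
                    min_points,
                )
                rows.append(
                    {"density_measure": d, "volume_measure": v, "mean_r": r, "n_series": 1}
                )
            else:
                rs = np.array([r for _, _, r in per_series[(d, v)]], dtype=float)
                valid = rs[np.isfinite(rs)]
                rows.append(
                    {
                        "density_measure": d,
                        "volume_measure": v,
                        "mean_r": float(valid.mean()) if len(valid) else float("nan"),
                        "n_series": int(len(valid)),
                    }
                )
    return MassCorrelations(summary=pd.DataFrame(rows), per_series=per_series)
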