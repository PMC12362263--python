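"""Network Enhancement: diffusion-based consolidation of the clip space.

Derived (symmetry / transitivity / equivalence) relations are not
produced by the reinforcement rule itself.  Instead the agent's whole
weight matrix is de-noised by a diffusion process that strengthens
within-class connectivity:

1. K-nearest-neighbour localization builds a row-stochastic transition
   matrix over N_i, the top-K neighbours of i by weight, with a
   self-loop carrying a configurable share of each row's transition
   mass.  The self-loop is essential: without it the kernel of a
   linearly trained class is bipartite, the diffusion (which
   accumulates only odd kernel powers) can never place weight on
   even-hop pairs, and neither transitive (A->C) nor reflexive
   relations could ever form.
2. (symmetric variant only) a localized kernel
   T_ij = sum_k P_ik P_jk / sum_v P_vk,
   which is symmetric and emphasizes affinity within about three hops.
3. The diffusion  W_{t+1} = alpha * kernel @ W_t @ kernel + (1-alpha) * kernel
   is iterated to convergence.  The directed variant (DNE) uses P as
   the kernel, the symmetric variant (SNE) uses T.

Because the kernels are row-stochastic, the linear map
W -> alpha * kernel @ W @ kernel is a contraction in the induced
infinity norm for alpha < 1, so the iteration always converges.

The consolidation can run once at the end of training (the classical
schedule) or after every mastered phase (the during-training schedule),
which is the experimental contrast this package exists to study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from equivnet.clip_network import ClipSpace, ConfigurationError, RelationKind

__all__ = [
    "NeParams",
    "NeTrace",
    "NumericalError",
    "apply_ne",
    "diffuse",
    "knn_transition_matrix",
    "local_network",
]


class NumericalError(RuntimeError):
    """Raised when the diffusion iteration diverges."""


@dataclass
class NeParams:
    """Settings of the network-enhancement step.

    k_neighbors      K of the K-NN localization (the replicated study uses 1)
    alpha            diffusion retention weight, strictly inside (0, 1)
    self_retention   share of each row's transition mass kept on the node
                     itself (0 disables the self-loop)
    symmetrize_knn   localize over the symmetrized K-NN graph (i keeps j
                     as a neighbour if either selected the other), the
                     construction used by the original enhancement
                     method; without it, nodes that nothing points to
                     are unreachable by the diffusion
    variant          "DNE" (directed kernel P) or "SNE" (symmetric kernel T)
    schedule         "end_of_training", "during_training", or "none"
    baseline_mode    "preserve": directly experienced edges (baseline,
                     mirror, incorrect) enter the diffusion input but keep
                     their stored h-values on write-back, so consolidation
                     only ever adds derived relations; "exclude_input":
                     baseline edges are additionally zeroed out of the
                     input matrix
    """

    k_neighbors: int = 1
    alpha: float = 0.7
    variant: str = "DNE"
    schedule: str = "end_of_training"
    max_iterations: int = 100
    tolerance: float = 1e-8
    baseline_mode: str = "preserve"
    self_retention: float = 0.5
    symmetrize_knn: bool = True

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ConfigurationError(f"k_neighbors must be >= 1, got {self.k_neighbors}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must be strictly inside (0, 1), got {self.alpha}")
        if not 0.0 <= self.self_retention < 1.0:
            raise ConfigurationError(
                f"self_retention must be in [0, 1), got {self.self_retention}"
            )
        if self.variant not in ("DNE", "SNE"):
            raise ConfigurationError(f"variant must be 'DNE' or 'SNE', got {self.variant!r}")
        if self.schedule not in ("end_of_training", "during_training", "none"):
            raise ConfigurationError(f"unknown schedule {self.schedule!r}")
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be > 0")
        if self.baseline_mode not in ("preserve", "exclude_input"):
            raise ConfigurationError(f"unknown baseline_mode {self.baseline_mode!r}")


@dataclass
class NeTrace:
    """Diagnostics for one consolidation application."""

    step: int
    iterations: int
    final_delta: float
    edges_before: int
    edges_after: int


def knn_transition_matrix(
    W: np.ndarray,
    K: int,
    self_retention: float = 0.5,
    symmetrize: bool = True,
) -> np.ndarray:
    """Row-stochastic K-NN transition matrix with self-loop regularization.

    For each node i, N_i is the top-K neighbours by weight (ties
    broken by label order for determinism).  With ``symmetrize`` the
    localized weights are (L + L^T) / 2 where L is W restricted to the
    K-NN selections, so i and j remain mutually reachable whenever
    either selected the other.  Each neighbourhood row is normalized
    to carry ``1 - self_retention`` of the row's transition mass, and
    the node keeps ``self_retention`` on itself; the self-loop makes
    the kernel aperiodic, which is what allows the diffusion to reach
    even-hop (transitive) and reflexive positions.  Rows whose
    neighbourhood carries no weight become uniform over all nodes,
    keeping P well-defined for isolated clips.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if K < 1:
        raise ConfigurationError(f"K must be >= 1, got {K}")
    if K > n - 1:
        raise ConfigurationError(f"K={K} exceeds the {n - 1} available neighbours")
    if np.any(W < 0):
        raise ConfigurationError("weights must be nonnegative; clamp before localization")
    L = np.zeros((n, n))
    for i in range(n):
        candidates = [j for j in range(n) if j != i]
        # stable sort on (-weight, index): ties resolved by label order
        candidates.sort(key=lambda j: (-W[i, j], j))
        neigh = candidates[:K]
        L[i, neigh] = W[i, neigh]
    if symmetrize:
        L = (L + L.T) / 2.0
    P = np.zeros((n, n))
    for i in range(n):
        total = L[i].sum()
        if total > 0:
            P[i] = (1.0 - self_retention) * L[i] / total
            P[i, i] += self_retention
        else:
            P[i, :] = 1.0 / n
    return P


def local_network(P: np.ndarray) -> np.ndarray:
    """Symmetric localized kernel T_ij = sum_k P_ik P_jk / sum_v P_vk.

    Columns of P that sum to zero are skipped (0/0 -> 0).
    """
    P = np.asarray(P, dtype=float)
    col = P.sum(axis=0)
    inv = np.where(col > 0, 1.0 / np.where(col > 0, col, 1.0), 0.0)
    return (P * inv) @ P.T


def diffuse(
    W0: np.ndarray,
    kernel: np.ndarray,
    alpha: float,
    max_iterations: int = 100,
    tolerance: float = 1e-8,
) -> tuple[np.ndarray, int, float]:
    """Iterate W_{t+1} = alpha * kernel @ W_t @ kernel + (1 - alpha) * kernel.

    Returns (converged matrix, iterations used, final max |delta|).
    Divergence (norm growth over 10 consecutive iterations) raises
    :class:`NumericalError`; with a row-stochastic kernel and alpha in
    (0, 1) this cannot happen.
    """
    W = np.asarray(W0, dtype=float).copy()
    kernel = np.asarray(kernel, dtype=float)
    growth_streak = 0
    prev_norm = np.abs(W).max() if W.size else 0.0
    delta = np.inf
    for it in range(1, max_iterations + 1):
        W_next = alpha * (kernel @ W @ kernel) + (1.0 - alpha) * kernel
        delta = float(np.abs(W_next - W).max()) if W.size else 0.0
        W = W_next
        norm = float(np.abs(W).max()) if W.size else 0.0
        growth_streak = growth_streak + 1 if norm > prev_norm else 0
        prev_norm = norm
        if growth_streak >= 10 and norm > 1e6:
            raise NumericalError(
                f"diffusion diverging: max |W| = {norm:.3g} after {it} iterations"
            )
        if delta < tolerance:
            return W, it, delta
    return W, max_iterations, delta


def apply_ne(space: ClipSpace, params: NeParams) -> NeTrace:
    """Consolidate the clip space in place; returns diagnostics.

    The h-values are clamped to 0 on entry (diffusion assumes
    nonnegative affinities), diffused with the configured kernel, and
    the output is min-max rescaled to [0, max input h] (zeros
    preserved) so the training softmax temperature keeps its meaning.
    Consolidation introduces derived relations without touching direct
    experience: every directly experienced edge (baseline, mirror, and
    incorrect kinds) keeps its stored h-value, while derived positions
    are overwritten and previously absent edges are created with kind
    ``derived`` (including reflexive ones, which can arise only here).
    """
    labels = space.labels
    n = len(labels)
    if n == 0:
        raise ConfigurationError("cannot consolidate an empty clip space")
    edges_before = len(space.relations)
    _, W = space.weight_matrix(labels)
    W_in = np.maximum(W, 0.0)
    preserved = [
        (s, t)
        for (s, t), rel in space.relations.items()
        if rel.kind is not RelationKind.DERIVED
    ]
    if params.baseline_mode == "exclude_input":
        for (s, t), rel in space.relations.items():
            if rel.kind is RelationKind.BASELINE:
                W_in[space.index(s), space.index(t)] = 0.0
    h_max = W_in.max()
    if h_max <= 0:
        return NeTrace(space.step, 0, 0.0, edges_before, edges_before)
    K = min(params.k_neighbors, n - 1)
    P = knn_transition_matrix(
        W_in, K,
        self_retention=params.self_retention,
        symmetrize=params.symmetrize_knn,
    )
    kernel = local_network(P) if params.variant == "SNE" else P
    W_out, iterations, delta = diffuse(
        W_in, kernel, params.alpha, params.max_iterations, params.tolerance
    )
    out_max = W_out.max()
    if out_max > 0:
        W_out = W_out * (h_max / out_max)
    preserved_set = set(preserved)
    for i, s in enumerate(labels):
        for j, t in enumerate(labels):
            if (s, t) in preserved_set:
                continue  # directly experienced relations are never overwritten
            if space.has_edge(s, t):
                space.set_h(s, t, float(W_out[i, j]))
            elif W_out[i, j] > 0:
                space.set_h(s, t, float(W_out[i, j]), kind=RelationKind.DERIVED)
    return NeTrace(
        step=space.step,
        iterations=iterations,
        final_delta=delta,
        edges_before=edges_before,
        edges_after=len(space.relations),
    )
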