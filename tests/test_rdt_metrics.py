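"""Density, volume and mass measures, with brute-force path oracles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from equivnet.clip_network import ClipSpace, RelationKind
from equivnet.mts_environment import TrialRecord
from equivnet.network_enhancement import NeParams, apply_ne
from equivnet.rdt_metrics import (
    RdtSeries,
    class_accuracy,
    class_size,
    empirical_nodal_distance,
    mass_correlations,
    mean_h,
    mean_transition_probability,
    num_relations,
    relational_mass,
    true_nodal_distance,
)
from tests.conftest import build_linear_space

LINEAR = ("A1", "B1", "C1", "D1", "E1")


def oracle_true_nodal_distance(space, members, threshold):
    """Independent check via networkx shortest paths."""
    g = nx.Graph()
    g.add_nodes_from(space.labels)
    for s, t, h, _, _ in space.edge_list():
        if h > threshold:
            g.add_edge(s, t)
    total = 0.0
    present = [m for m in members if m in space.clips]
    for a, b in itertools.combinations(present, 2):
        try:
            total += max(nx.shortest_path_length(g, a, b) - 1, 0)
        except nx.NetworkXNoPath:
            total += len(present) - 1
    return total


class TestTrueNodalDistance:
    def test_adjacent_pair_is_zero(self):
        space = build_linear_space(("A1", "B1"))
        assert true_nodal_distance(space, 1) == 0.0

    def test_linear_five_member_class_totals_ten(self, linear_space):
        # pairwise intermediate counts 0+1+2+3+0+1+2+0+1+0
        assert true_nodal_distance(linear_space, 1) == 10.0
        assert true_nodal_distance(linear_space, 1) == oracle_true_nodal_distance(
            linear_space, LINEAR, 1.0 + 1e-9
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_networkx_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        space = ClipSpace()
        labels = [f"{letter}1" for letter in "ABCDEF"]
        for l in labels:
            space.ensure_clip(l)
        for s, t in itertools.permutations(labels, 2):
            if rng.random() < 0.25:
                space.set_h(s, t, float(rng.uniform(0, 5)))
        thr = 1.0 + 1e-9
        assert true_nodal_distance(space, 1, thr) == oracle_true_nodal_distance(
            space, labels, thr
        )

    def test_fully_connected_class_is_zero(self, linear_space):
        for a, b in itertools.permutations(LINEAR, 2):
            linear_space.set_h(a, b, 30.0)
        assert true_nodal_distance(linear_space, 1) == 0.0

    def test_disconnected_member_pays_finite_penalty(self):
        space = build_linear_space(("A1", "B1", "C1"))
        space.ensure_clip("D1")  # sighted, never trained
        # pairs with D1 pay (members - 1) = 3 each; (A1,C1) contributes 1
        assert true_nodal_distance(space, 1) == 3 * 3 + 1

    def test_singleton_class_is_zero(self):
        space = ClipSpace()
        space.ensure_clip("A3")
        assert true_nodal_distance(space, 3) == 0.0

    def test_paths_may_cross_other_classes(self):
        space = ClipSpace()
        for l in ("A1", "B1", "A2"):
            space.ensure_clip(l)
        space.set_h("A1", "A2", 5.0)  # inter-class link
        space.set_h("A2", "B1", 5.0)
        assert true_nodal_distance(space, 1, members=["A1", "B1"]) == 1.0


class TestEmpiricalNodalDistance:
    def test_one_node_between_untrained_endpoints(self):
        space = build_linear_space(("A1", "B1", "C1"))
        pairs = {("A1", "B1"), ("B1", "C1")}
        assert empirical_nodal_distance(space, 1, pairs) == 1.0

    def test_directly_trained_pair_contributes_nothing(self):
        space = build_linear_space(("A1", "B1"))
        assert empirical_nodal_distance(space, 1, {("A1", "B1")}) == 0.0

    def test_linear_five_member_class_totals_ten(self, linear_space):
        # six untrained pairs with 1+2+3+1+2+1 intermediates
        pairs = set(zip(LINEAR[:-1], LINEAR[1:]))
        assert empirical_nodal_distance(linear_space, 1, pairs) == 10.0

    def test_depends_only_on_training_structure(self, linear_space):
        pairs = set(zip(LINEAR[:-1], LINEAR[1:]))
        before = empirical_nodal_distance(linear_space, 1, pairs)
        for s, t, h, _, _ in linear_space.edge_list():
            linear_space.set_h(s, t, h * 17.5 - 3.0)  # perturb every h
        linear_space.set_h("A1", "E1", 99.0)  # derived shortcut must not count
        assert empirical_nodal_distance(linear_space, 1, pairs) == before

    def test_untrained_member_pays_penalty(self):
        space = build_linear_space(("A1", "B1"))
        space.ensure_clip("C1")
        assert empirical_nodal_distance(space, 1, {("A1", "B1")}) == 2 * 2


class TestClassSizeAndRelations:
    def test_size_counts_only_sighted_members(self):
        space = ClipSpace()
        space.ensure_clip("A1")
        space.ensure_clip("B1")
        members = ["A1", "B1", "C1", "D1", "E1"]
        assert class_size(space, 1, members=members) == 2

    def test_declared_membership_excludes_comparison_only_foils(self):
        space = ClipSpace()
        for l in ("A3", "B3", "C3", "D3"):
            space.ensure_clip(l)
        assert class_size(space, 3, members=["A3", "B3", "C3"]) == 3
        assert class_size(space, 3) == 4  # label-based fallback counts D3

    def test_untrained_class_has_no_relations(self):
        space = ClipSpace()
        space.ensure_clip("A1")
        space.ensure_clip("B1")
        assert num_relations(space, 1) == 0

    def test_trained_pair_with_mirror_counts_two(self):
        space = build_linear_space(("A1", "B1"), h=4.0)
        assert num_relations(space, 1) == 2

    def test_num_relations_non_decreasing_across_consolidation(self, linear_space):
        before = num_relations(linear_space, 1)
        apply_ne(linear_space, NeParams())
        assert num_relations(linear_space, 1) >= before


class TestDensityMeasures:
    def test_single_member_class_spikes_to_one(self):
        space = ClipSpace()
        space.ensure_clip("A1")
        assert mean_transition_probability(space, 1, 0.1) == 1.0

    def test_saturated_pair_approaches_one(self):
        space = build_linear_space(("A1", "B1"), h=100.0)
        mtp = mean_transition_probability(space, 1, beta_h=0.1)
        assert mtp == pytest.approx(1.0, abs=1e-4)

    def test_zero_temperature_gives_reciprocal_class_size(self):
        space = build_linear_space(LINEAR)
        assert mean_transition_probability(space, 1, beta_h=0.0) == pytest.approx(0.2)

    def test_declines_as_untrained_members_join(self):
        space = build_linear_space(("A1", "B1"), h=40.0)
        small = mean_transition_probability(space, 1, 0.1)
        space = build_linear_space(LINEAR, h=40.0)
        large = mean_transition_probability(space, 1, 0.1)
        assert large < small

    @pytest.mark.parametrize("seed", [0, 1])
    def test_always_a_probability(self, seed):
        rng = np.random.default_rng(seed)
        space = ClipSpace()
        labels = [f"{letter}1" for letter in "ABCDE"]
        for l in labels:
            space.ensure_clip(l)
        for s, t in itertools.permutations(labels, 2):
            if rng.random() < 0.5:
                space.set_h(s, t, float(rng.normal(0, 20)))
        mtp = mean_transition_probability(space, 1, 0.1)
        assert 0.0 < mtp <= 1.0

    def test_mean_h_over_thresholded_edges(self):
        space = build_linear_space(("A1", "B1"), h=2.0, mirrors=False)
        space.set_h("B1", "A1", 4.0)
        space.set_h("A1", "A1", 50.0)  # reflexive edges are not intra-pair edges
        assert mean_h(space, 1) == pytest.approx(3.0)

    def test_mean_h_missing_without_edges(self):
        space = ClipSpace()
        space.ensure_clip("A1")
        space.ensure_clip("B1")
        assert np.isnan(mean_h(space, 1))

    def test_class_accuracy_counts_sample_class_trials(self):
        records = [
            TrialRecord(i, "p", 1, "A1", ("B1",), "B1", ok, 1)
            for i, ok in enumerate([True, True, True, False])
        ] + [TrialRecord(9, "p", 1, "A2", ("B2",), "B2", True, 2)]
        assert class_accuracy(records, 1) == 0.75
        assert np.isnan(class_accuracy(records, 3))


class TestRelationalMass:
    def test_product_and_zero_volume(self):
        assert relational_mass(0.25, 10.0) == 2.5
        assert relational_mass(0.7, 0.0) == 0.0

    def test_bilinearity_in_density(self):
        assert relational_mass(3 * 0.2, 7.0) == pytest.approx(3 * relational_mass(0.2, 7.0))

    def test_missing_input_propagates(self):
        assert np.isnan(relational_mass(float("nan"), 4.0))


def _series_from(step, class_id, density, volume):
    frame = pd.DataFrame(
        {
            "step": step,
            "class_id": class_id,
            "true_nodal_distance": volume,
            "empirical_nodal_distance": volume,
            "class_size": volume,
            "num_relations": volume,
            "mean_transition_probability": density,
            "class_accuracy": density,
            "mean_h": density,
        }
    )
    return RdtSeries(frame=frame)


class TestMassCorrelations:
    def test_perfect_anticorrelation(self):
        v = np.arange(10.0)
        series = _series_from(np.arange(10), 1, -v, v)
        out = mass_correlations([series])
        assert out.mean_r("mean_transition_probability", "class_size") == pytest.approx(-1.0)

    def test_constant_density_is_missing_not_zero(self):
        series = _series_from(np.arange(10), 1, np.ones(10), np.arange(10.0))
        out = mass_correlations([series])
        assert np.isnan(out.mean_r("mean_transition_probability", "class_size"))
        rs = [r for _, _, r in out.per_series[("mean_transition_probability", "class_size")]]
        assert all(np.isnan(r) for r in rs)

    def test_hand_computed_pearson_value(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        out = mass_correlations([_series_from(np.arange(5), 1, x, y)])
        assert out.mean_r("mean_h", "num_relations") == pytest.approx(0.8)

    def test_aggregates_across_classes_and_agents(self):
        v = np.arange(8.0)
        s1 = _series_from(np.arange(8), 1, -v, v)
        f2 = _series_from(np.arange(8), 2, -v, v).frame
        s1.frame = pd.concat([s1.frame, f2], ignore_index=True)
        s2 = _series_from(np.arange(8), 1, v, v)  # second agent, r = +1
        out = mass_correlations([s1, s2])
        assert out.mean_r("mean_transition_probability", "class_size") == pytest.approx(
            (-1.0 - 1.0 + 1.0) / 3
        )

    def test_all_twelve_combinations_reported(self):
        v = np.arange(6.0)
        out = mass_correlations([_series_from(np.arange(6), 1, -v, v)])
        assert len(out.summary) == 12
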