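"""Description length, move proposals, inference, and refinement."""

import numpy as np
import pytest
from sklearn.metrics import v_measure_score

from mosbm import (
    MoveContext,
    MultipartiteNetwork,
    add_feature_links,
    build_network,
    description_length,
    fit_blockmodel,
    generate_layers,
    generate_regulatory_links,
    merge_split_refine,
    move_probability,
    PlantedModel,
)
from mosbm.sbm import _BlockState, _graph_from_network

from conftest import random_tiny_network, set_partitions


def enumerate_min_sigma(net):
    """Exhaustive minimum flat Σ over all type-pure partitions."""
    kind_groups = {}
    for idx, k in enumerate(net.node_kinds):
        kind_groups.setdefault(k, []).append(idx)
    best = np.inf
    import itertools

    for combo in itertools.product(
        *[list(set_partitions(g)) for g in kind_groups.values()]
    ):
        assignment = {}
        label = 0
        for part in combo:
            for block in part:
                for n in block:
                    assignment[net.node_ids[n]] = label
                label += 1
        best = min(best, description_length(net, assignment))
    return best


class TestMoveProbability:
    def test_direct_substitution(self):
        assert move_probability(MoveContext(e_ts=3, e_t=10, B=2, epsilon=1)) == pytest.approx(
            1 / 3
        )

    def test_sums_to_one_over_candidates(self):
        rng = np.random.default_rng(0)
        e_ts = rng.integers(0, 20, size=7)
        e_t = int(e_ts.sum())
        probs = [
            move_probability(MoveContext(int(e), e_t, 7, epsilon=0.37)) for e in e_ts
        ]
        assert sum(probs) == pytest.approx(1.0)

    def test_large_epsilon_limit_is_uniform(self):
        p = move_probability(MoveContext(e_ts=5, e_t=100, B=4, epsilon=1e12))
        assert p == pytest.approx(1 / 4, rel=1e-6)

    def test_epsilon_must_be_positive(self):
        with pytest.raises(ValueError):
            move_probability(MoveContext(1, 2, 3, epsilon=0))


class TestDescriptionLength:
    def test_positive(self, toy_bipartite):
        labels = {n: (0 if n.startswith("s") else 1) for n in toy_bipartite.node_ids}
        assert description_length(toy_bipartite, labels) > 0

    def test_planted_beats_single_block_per_kind(self, toy_bipartite):
        planted = {"s0": 0, "s1": 0, "s2": 1, "s3": 1, "g0": 2, "g1": 2, "g2": 3, "g3": 3}
        merged = {n: (0 if n.startswith("s") else 1) for n in toy_bipartite.node_ids}
        assert description_length(toy_bipartite, planted) < description_length(
            toy_bipartite, merged
        )

    def test_mixed_kind_block_rejected(self, toy_bipartite):
        bad = dict.fromkeys(toy_bipartite.node_ids, 0)
        with pytest.raises(ValueError, match="type-pure"):
            description_length(toy_bipartite, bad)

    def test_uncovered_node_rejected(self, toy_bipartite):
        partial = {n: 0 for n in toy_bipartite.node_ids[:-1]}
        with pytest.raises(ValueError, match="cover"):
            description_length(toy_bipartite, partial)

    def test_incremental_updates_match_scratch(self):
        rng = np.random.default_rng(3)
        net = random_tiny_network(rng)
        graph = _graph_from_network(net)
        state = _BlockState(graph, np.arange(net.V))
        for _ in range(150):
            i = int(rng.integers(net.V))
            cands = state.candidates_of_kind(int(graph.kind[i]))
            s = int(cands[rng.integers(cands.size)])
            d = state.deltas_move(i, np.array([s]))[0]
            state.apply_move(i, s, float(d))
            assert state.sigma == pytest.approx(state.sigma_scratch(), rel=1e-9)

    def test_label_equivariance(self, toy_bipartite):
        """Renaming blocks leaves Σ unchanged."""
        a = {"s0": 0, "s1": 0, "s2": 1, "s3": 1, "g0": 2, "g1": 2, "g2": 3, "g3": 3}
        b = {k: {0: 9, 1: 4, 2: 7, 3: 5}[v] for k, v in a.items()}
        assert description_length(toy_bipartite, a) == pytest.approx(
            description_length(toy_bipartite, b)
        )


class TestFit:
    def test_disconnected_islands_recovered(self, toy_bipartite):
        h = fit_blockmodel(toy_bipartite, n_init=5, seed=0)
        clusters = h.sample_clusters(0)
        assert clusters["s0"] == clusters["s1"]
        assert clusters["s2"] == clusters["s3"]
        assert clusters["s0"] != clusters["s2"]

    def test_matches_exhaustive_minimum_on_tiny_networks(self):
        rng = np.random.default_rng(42)
        for trial in range(6):
            net = random_tiny_network(rng)
            h = fit_blockmodel(net, n_init=10, seed=trial)
            flat = description_length(net, h.assignments[0])
            assert flat == pytest.approx(enumerate_min_sigma(net), abs=1e-8)

    def test_fixed_seed_is_reproducible(self, toy_bipartite):
        h1 = fit_blockmodel(toy_bipartite, n_init=3, seed=5)
        h2 = fit_blockmodel(toy_bipartite, n_init=3, seed=5)
        assert h1.sigma == h2.sigma
        assert all((a == b).all() for a, b in zip(h1.assignments, h2.assignments))

    def test_node_relabeling_permutes_assignment(self, toy_bipartite):
        """Swapping two sample nodes' identities swaps their blocks."""
        perm = [1, 0, 2, 3, 4, 5, 6, 7]
        ids = [toy_bipartite.node_ids[p] for p in perm]
        inv = np.argsort(perm)
        edges = toy_bipartite.edges.copy()
        edges[:, 0] = inv[edges[:, 0]]
        edges[:, 1] = inv[edges[:, 1]]
        permuted = MultipartiteNetwork(
            ids, [toy_bipartite.node_kinds[p] for p in perm], edges, ["genes"]
        )
        h1 = fit_blockmodel(toy_bipartite, n_init=3, seed=1)
        h2 = fit_blockmodel(permuted, n_init=3, seed=1)
        c1, c2 = h1.sample_clusters(0), h2.sample_clusters(0)
        assert v_measure_score(c1[sorted(c1.index)], c2[sorted(c2.index)]) == 1.0

    def test_empty_network_errors(self):
        with pytest.raises(ValueError):
            net = MultipartiteNetwork(["s0", "g0"], ["sample", "genes"],
                                      np.empty((0, 3), dtype=int), ["genes"])
            fit_blockmodel(net)

    def test_type_purity_at_every_level(self, small_fit):
        for level in range(small_fit.n_levels):
            labels = small_fit.assignments[level]
            kinds = np.asarray(small_fit.node_kinds, dtype=object)
            for block in np.unique(labels):
                assert len(set(kinds[labels == block])) == 1

    def test_coarser_levels_are_exact_merges(self, small_fit):
        for fine, coarse in zip(small_fit.assignments[:-1], small_fit.assignments[1:]):
            mapping = {}
            for f, c in zip(fine, coarse):
                assert mapping.setdefault(f, c) == c


class TestPlantedRecovery:
    def test_strong_signal_recovers_clusters(self):
        model = PlantedModel(
            n_samples=30,
            cluster_sizes=(15, 15),
            branches={"genes": (6, 6), "mirna": (5, 5)},
            hazard_multipliers=(1.0, 1.0),
        )
        layers, truth = generate_layers(model, seed=2)
        h = fit_blockmodel(build_network(layers), n_init=5, seed=2)
        nmi = v_measure_score(truth["cluster_labels"], h.sample_clusters(0))
        assert nmi >= 0.9


class TestEstimatorWrapper:
    def test_fit_sets_fitted_attributes(self, small_network):
        from mosbm import MultipartiteBlockModel

        est = MultipartiteBlockModel(n_init=2, random_state=4)
        assert est.get_params()["n_init"] == 2
        est.fit(small_network)
        assert est.sigma_ == est.hierarchy_.sigma > 0
        assert est.labels_.shape == (len(small_network.sample_nodes),)
        assert est.n_levels_ >= 1

    def test_fit_accepts_layer_list(self, small_data):
        from mosbm import MultipartiteBlockModel

        layers, _ = small_data
        labels = MultipartiteBlockModel(n_init=2, random_state=4).fit_predict(layers)
        assert labels.shape == (layers[0].n_samples,)

    def test_set_params_rejects_unknown(self):
        from mosbm import MultipartiteBlockModel

        with pytest.raises(ValueError):
            MultipartiteBlockModel().set_params(bogus=1)


class TestMergeSplitRefine:
    def test_zero_sweeps_is_identity(self, small_network, small_fit):
        out = merge_split_refine(small_network, small_fit, n_sweeps=0, seed=0)
        assert out is small_fit

    def test_never_worsens_sigma(self, small_network, small_fit):
        out = merge_split_refine(small_network, small_fit, n_sweeps=3, seed=0)
        assert out.sigma <= small_fit.sigma + 1e-9

    def test_oversplit_state_remerges(self, toy_bipartite):
        from mosbm.sbm import BlockHierarchy

        # deliberately split each planted block into singletons
        labels = np.arange(toy_bipartite.V)
        start = description_length(toy_bipartite, labels)
        oversplit = BlockHierarchy(
            list(toy_bipartite.node_ids),
            list(toy_bipartite.node_kinds),
            [labels],
            [list(toy_bipartite.node_kinds)],
            start,
            [start],
            None,
            0,
            1,
        )
        refined = merge_split_refine(toy_bipartite, oversplit, n_sweeps=5, seed=0)
        assert refined.sigma < start
        clusters = refined.sample_clusters(0)
        assert clusters["s0"] == clusters["s1"] != clusters["s2"]


class TestFeatureLinks:
    def test_empty_links_identity(self, small_network):
        out = add_feature_links(small_network, [])
        assert out.E == small_network.E
        assert (out.edges == small_network.edges).all()

    def test_single_link_adds_one_edge(self, small_network):
        links = [("genes_000", "genes", "mirna_000", "mirna")]
        out = add_feature_links(small_network, links)
        assert out.E == small_network.E + 1

    def test_unknown_feature_and_same_branch_errors(self, small_network):
        with pytest.raises(KeyError, match="nope"):
            add_feature_links(small_network, [("nope", "genes", "mirna_000", "mirna")])
        with pytest.raises(ValueError, match="same-branch"):
            add_feature_links(
                small_network, [("genes_000", "genes", "genes_001", "genes")]
            )

    def test_consistent_links_do_not_hurt_recovery(self):
        """Regulatory links mirroring the planting: paired seeded comparison."""
        model = PlantedModel(seed=3)
        layers, truth = generate_layers(model, seed=3)
        net = build_network(layers)
        h = fit_blockmodel(net, n_init=3, seed=3)
        base = merge_split_refine(net, h, n_sweeps=3, seed=3)
        nmi_base = v_measure_score(truth["cluster_labels"], base.sample_clusters(0))
        links = generate_regulatory_links(model, n_links=120, fraction_consistent=1.0, seed=3)
        linked = add_feature_links(net, links)
        refined = merge_split_refine(linked, h, n_sweeps=3, seed=3)
        nmi_links = v_measure_score(truth["cluster_labels"], refined.sample_clusters(0))
        assert nmi_links >= nmi_base - 1e-12
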