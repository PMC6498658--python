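import networkx as nx
import numpy as np
import pytest

from discoursenet.coalitions import (
    Partition,
    cluster_k2_ensemble,
    girvan_newman,
    label_coalitions,
    modularity,
)
from discoursenet.errors import ConsistencyError, ParameterError
from discoursenet.network import ActorNetwork
from discoursenet.statements import StatementSet
from discoursenet.transform import build_stances

from conftest import (
    block_network,
    make_statement,
    modularity_double_sum,
)


def random_network(rng, n=10, p=0.4):
    W = (rng.random((n, n)) < p).astype(float)
    W = np.triu(W, 1)
    W = W + W.T
    return ActorNetwork(nodes=[f"n{i}" for i in range(n)], weights=W, stage="thresholded")


class TestModularity:
    def test_single_cluster_is_zero(self, two_cliques):
        p = {a: 0 for a in two_cliques.nodes}
        assert modularity(two_cliques, p) == pytest.approx(0.0, abs=1e-15)

    def test_two_equal_disconnected_cliques_half(self, two_cliques):
        p = {a: (0 if a.startswith("b0") else 1) for a in two_cliques.nodes}
        assert modularity(two_cliques, p) == pytest.approx(0.5, abs=1e-15)

    def test_equals_direct_double_sum(self, rng):
        for trial in range(5):
            net = random_network(rng)
            labels = rng.integers(0, 2, size=net.n)
            assignment = {a: int(l) for a, l in zip(net.nodes, labels) if (net.weights[net.index(a)] > 0).any()}
            got = modularity(net, assignment)
            expected = modularity_double_sum(net.weights, [assignment.get(a, -1 - i) for i, a in enumerate(net.nodes)])
            assert got == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_networkx_on_weighted_graph(self, rng):
        mask = random_network(rng, n=12, p=0.5).weights
        W = mask * (0.4 + 0.6 * rng.random((12, 12)))
        W = (W + W.T) / 2
        net = ActorNetwork(nodes=[f"n{i}" for i in range(12)], weights=W, stage="thresholded")
        assignment = {a: i % 2 for i, a in enumerate(net.nodes) if a in net.non_isolates()}
        comms = [
            {a for a, c in assignment.items() if c == cid} for cid in sorted(set(assignment.values()))
        ]
        G = net.to_networkx().subgraph(assignment)
        expected = nx.community.modularity(G, comms, weight="weight")
        assert modularity(net, assignment) == pytest.approx(expected, abs=1e-12)

    def test_partition_actor_missing_from_network_raises(self, two_cliques):
        with pytest.raises(ConsistencyError):
            modularity(two_cliques, {"ghost": 0, **{a: 0 for a in two_cliques.nodes}})

    def test_bounds_on_random_partitions(self, rng):
        for _ in range(20):
            net = random_network(rng, n=8, p=0.5)
            if not net.non_isolates():
                continue
            assignment = {a: int(rng.integers(3)) for a in net.non_isolates()}
            q = modularity(net, assignment)
            assert -0.5 - 1e-12 <= q <= 1.0


class TestGirvanNewman:
    def test_two_cliques_with_bridge(self):
        net = block_network([4, 4], bridges=[((0, 0), (1, 0))])
        p = girvan_newman(net)
        assert p.sizes() == [4, 4]
        groups = p.clusters()
        assert {frozenset(m) for m in groups.values()} == {
            frozenset(f"b0n{i}" for i in range(4)),
            frozenset(f"b1n{i}" for i in range(4)),
        }

    def test_never_merges_components(self, rng):
        net = block_network([5, 3, 4])
        p = girvan_newman(net)
        for cid, members in p.clusters().items():
            blocks = {m.split("n")[0] for m in members}
            assert len(blocks) == 1

    def test_agrees_with_networkx_first_split(self):
        net = block_network([4, 5], bridges=[((0, 1), (1, 2))])
        p = girvan_newman(net, stop=2)
        G = net.to_networkx(binary=True)
        G.remove_nodes_from(net.isolates())
        nx_split = next(nx.community.girvan_newman(G))
        ours = {frozenset(m) for m in p.clusters().values()}
        assert ours == {frozenset(c) for c in nx_split}

    def test_max_modularity_cut_matches_exhaustive_bipartition(self):
        # bridged cliques: the GN max-Q cut is the two-clique split, which is
        # also the exhaustive max-modularity bipartition of the 9-node graph
        net = block_network([4, 5], bridges=[((0, 0), (1, 0))])
        p = girvan_newman(net)
        assert p.k == 2
        from conftest import exhaustive_max_bipartition_q

        assert p.modularity == pytest.approx(exhaustive_max_bipartition_q(net.weights), abs=1e-12)

    def test_empty_edge_set_all_isolates(self):
        net = ActorNetwork(nodes=list("abc"), weights=np.zeros((3, 3)), stage="thresholded")
        with pytest.warns(UserWarning):
            p = girvan_newman(net)
        assert p.assignment == {} and sorted(p.isolates) == ["a", "b", "c"]

    def test_isolates_reported_separately(self):
        net = block_network([3, 3])
        W = np.zeros((7, 7))
        W[:6, :6] = net.weights
        net7 = ActorNetwork(nodes=net.nodes + ["loner"], weights=W, stage="thresholded")
        p = girvan_newman(net7)
        assert p.isolates == ["loner"]
        assert "loner" not in p.assignment

    def test_invalid_stop_rejected(self, two_cliques):
        with pytest.raises(ParameterError):
            girvan_newman(two_cliques, stop=0)
        with pytest.raises(ParameterError):
            girvan_newman(two_cliques, stop="elbow")


class TestK2Ensemble:
    def test_disconnected_triangles_every_method_finds_split(self):
        net = block_network([3, 3])
        parts = cluster_k2_ensemble(net, seed=0)
        assert len(parts) >= 8  # GN-k2 may skip on some graphs; most must run
        expected = {frozenset({"b0n0", "b0n1", "b0n2"}), frozenset({"b1n0", "b1n1", "b1n2"})}
        for p in parts:
            assert {frozenset(m) for m in p.clusters().values()} == expected
            assert p.modularity == pytest.approx(0.5, abs=1e-12)

    def test_complete_graph_no_partition_beats_null(self):
        net = block_network([6])  # K6
        parts = cluster_k2_ensemble(net, seed=0)
        assert parts and all(p.modularity <= 1e-12 for p in parts)

    def test_planted_bipartition_recovered(self, rng):
        # 12 nodes, two planted blocks, within-p 1.0 minus a little noise
        W = np.zeros((12, 12))
        labels = [0] * 6 + [1] * 6
        for i in range(12):
            for j in range(i + 1, 12):
                p = 0.95 if labels[i] == labels[j] else 0.05
                if rng.random() < p:
                    W[i, j] = W[j, i] = 1.0
        net = ActorNetwork(nodes=[f"n{i}" for i in range(12)], weights=W, stage="thresholded")
        parts = cluster_k2_ensemble(net, seed=1)
        best = max(parts, key=lambda p: p.modularity)
        from sklearn.metrics import adjusted_rand_score

        found = [best.assignment[a] for a in net.nodes if a in best.assignment]
        true = [labels[i] for i, a in enumerate(net.nodes) if a in best.assignment]
        assert adjusted_rand_score(true, found) == 1.0

    def test_all_partitions_have_k2_and_provenance(self, rng):
        net = random_network(rng, n=9, p=0.5)
        parts = cluster_k2_ensemble(net, seed=42)
        for p in parts:
            assert p.k == 2
            assert set(p.assignment.values()) == {0, 1}
            assert p.method
            assert p.modularity is not None

    def test_seed_determinism(self, rng):
        net = random_network(rng, n=14, p=0.3)
        a = cluster_k2_ensemble(net, seed=7)
        b = cluster_k2_ensemble(net, seed=7)
        assert [(p.method, p.assignment) for p in a] == [(p.method, p.assignment) for p in b]

    def test_max_q_monotone_in_method_count(self, rng):
        from discoursenet.coalitions import DEFAULT_K2_METHODS

        net = random_network(rng, n=12, p=0.35)
        prev = -np.inf
        for k in (3, 6, 11):
            parts = cluster_k2_ensemble(net, methods=DEFAULT_K2_METHODS[:k], seed=5)
            best = max(p.modularity for p in parts)
            assert best >= prev - 1e-15
            prev = best

    def test_too_few_non_isolates_rejected(self):
        net = ActorNetwork(nodes=["a"], weights=np.zeros((1, 1)), stage="thresholded")
        with pytest.raises(ParameterError):
            cluster_k2_ensemble(net, seed=0)


class TestLabelCoalitions:
    def _profile(self):
        stmts = [
            make_statement("P1", "tax effective", True),
            make_statement("P2", "tax effective", True),
            make_statement("S1", "tax effective", False),
            make_statement("S2", "tax effective", False),
        ]
        return build_stances(StatementSet(statements=stmts))

    def test_unanimous_agreement_supportive(self):
        p = Partition(assignment={"P1": 0, "P2": 0, "S1": 1, "S2": 1}, k=2, method="manual")
        labels = label_coalitions(p, self._profile(), ["tax effective"])
        assert labels == {0: "supportive", 1: "sceptical"}

    def test_no_mention_labelled_other_with_warning(self):
        p = Partition(assignment={"P1": 0, "P2": 0, "S1": 1, "S2": 1, "Z": 2}, k=3, method="manual")
        profile = build_stances(
            StatementSet(
                statements=[
                    make_statement("P1", "tax effective", True),
                    make_statement("P2", "tax effective", True),
                    make_statement("S1", "tax effective", False),
                    make_statement("S2", "tax effective", False),
                    make_statement("Z", "unrelated", True),
                ]
            )
        )
        with pytest.warns(UserWarning):
            labels = label_coalitions(p, profile, ["tax effective"])
        assert labels[2] == "other"

    def test_mixed_cluster_matches_mean_sign(self, rng):
        stmts = []
        votes = {}
        for i in range(6):
            agree = bool(rng.integers(2))
            votes[f"M{i}"] = 1 if agree else -1
            stmts.append(make_statement(f"M{i}", "core", agree))
        profile = build_stances(StatementSet(statements=stmts))
        p = Partition(assignment={f"M{i}": 0 for i in range(6)}, k=1, method="manual")
        labels = label_coalitions(p, profile, ["core"])
        mean = np.mean(list(votes.values()))
        expected = "supportive" if mean > 0 else "sceptical" if mean < 0 else "other"
        assert labels[0] == expected

    def test_empty_pro_concepts_rejected(self):
        p = Partition(assignment={"P1": 0}, k=1, method="manual")
        with pytest.raises(ParameterError):
            label_coalitions(p, self._profile(), [])
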