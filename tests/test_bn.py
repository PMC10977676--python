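"""BDeu scoring, DAG enumeration and the simulated-annealing search."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from rearnet.blocklist import EdgeBlocklist
from rearnet.bn import (
    SAConfig,
    Scorer,
    bde_local_score,
    enumerate_dags,
    exhaustive_search,
    is_acyclic,
    learn_subset_networks,
    network_score,
    sa_search,
)
from rearnet.discretize import DiscreteDataset
from rearnet.errors import EnumerationLimitError, ValidationError

from conftest import binary_dataset


def naive_bde_oracle(child, parents, data, ess):
    """Independent log-gamma oracle: explicit loops over pandas crosstabs."""
    df = data.data
    arity = data.arity
    r = arity[child]
    parent_states = [range(arity[p]) for p in parents]
    import itertools

    q = int(np.prod([arity[p] for p in parents])) if parents else 1
    a_jk = ess / (q * r)
    a_j = ess / q
    total = 0.0
    configs = itertools.product(*parent_states) if parents else [()]
    for cfg in configs:
        rows = df
        for p, s in zip(parents, cfg):
            rows = rows[rows[p] == s]
        n_j = len(rows)
        total += gammaln(a_j) - gammaln(a_j + n_j)
        for k in range(r):
            n_jk = (rows[child] == k).sum()
            total += gammaln(a_jk + n_jk) - gammaln(a_jk)
    return total


class TestBDeScore:
    def test_no_parent_binary_worked_example(self):
        # binary child, counts (2,2), ess=1 -> ln(3/128)
        ds = binary_dataset({"A": [0, 0, 1, 1]})
        score = bde_local_score("A", [], ds, ess=1.0)
        assert score == pytest.approx(math.log(3 / 128), abs=1e-9)

    def test_empty_data_scores_zero(self):
        ds = DiscreteDataset(
            pd.DataFrame({"A": pd.Series([], dtype=np.int64)}),
            {"A": {0: "0", 1: "1"}},
        )
        assert bde_local_score("A", [], ds) == 0.0

    def test_matches_naive_oracle_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            arities = rng.integers(2, 4, size=3)
            n = int(rng.integers(5, 60))
            cols = {
                name: rng.integers(0, a, n)
                for name, a in zip("ABC", arities)
            }
            df = pd.DataFrame(cols)
            maps = {
                k: {int(s): str(s) for s in range(arities[i])}
                for i, k in enumerate("ABC")
            }
            ds = DiscreteDataset(df, maps)
            ess = float(rng.uniform(0.5, 10))
            ours = bde_local_score("A", ["B", "C"], ds, ess=ess)
            oracle = naive_bde_oracle("A", ["B", "C"], ds, ess)
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_child_in_parents_rejected(self, chain_dataset):
        with pytest.raises(ValidationError):
            bde_local_score("A", ["A"], chain_dataset)

    def test_nonpositive_ess_rejected(self, chain_dataset):
        with pytest.raises(ValidationError):
            bde_local_score("A", [], chain_dataset, ess=0.0)

    def test_decomposability_total_equals_sum(self, chain_dataset):
        net = exhaustive_search(chain_dataset)
        assert network_score(net, chain_dataset) == pytest.approx(
            net.score, abs=1e-9
        )

    def test_edge_deletion_touches_only_child(self, chain_dataset):
        before = {
            n: bde_local_score(n, {"A": [], "B": ["A"], "C": ["B"]}[n],
                               chain_dataset)
            for n in "ABC"
        }
        after = {
            n: bde_local_score(n, {"A": [], "B": ["A"], "C": []}[n],
                               chain_dataset)
            for n in "ABC"
        }
        assert before["A"] == after["A"] and before["B"] == after["B"]
        assert before["C"] != after["C"]

    def test_markov_equivalent_dags_score_identically(self, chain_dataset):
        ds = chain_dataset
        chain = [("A", []), ("B", ["A"]), ("C", ["B"])]
        fork = [("A", ["B"]), ("B", []), ("C", ["B"])]
        rev = [("A", ["B"]), ("B", ["C"]), ("C", [])]
        scores = [
            sum(bde_local_score(c, p, ds) for c, p in dag)
            for dag in (chain, fork, rev)
        ]
        assert max(scores) - min(scores) < 1e-9

    def test_collider_scores_differently_on_vstructure_data(
        self, collider_dataset
    ):
        ds = collider_dataset
        collider = [("A", []), ("B", []), ("C", ["A", "B"])]
        chain = [("A", []), ("B", ["A"]), ("C", ["B"])]
        s_col = sum(bde_local_score(c, p, ds) for c, p in collider)
        s_chain = sum(bde_local_score(c, p, ds) for c, p in chain)
        assert s_col - s_chain > 1.0  # v-structure wins decisively

    def test_duplicating_rows_widens_true_vs_empty_gap(self, chain_dataset):
        ds = chain_dataset
        doubled = DiscreteDataset(
            pd.concat([ds.data, ds.data], ignore_index=True),
            ds.category_maps,
        )

        def gap(d):
            true = sum(
                bde_local_score(c, p, d)
                for c, p in [("A", []), ("B", ["A"]), ("C", ["B"])]
            )
            empty = sum(bde_local_score(c, [], d) for c in "ABC")
            return true - empty

        assert gap(doubled) > gap(ds)


class TestAcyclicity:
    @pytest.mark.parametrize(
        "edges,expected",
        [
            ([("A", "B"), ("B", "C")], True),
            ([("A", "B"), ("B", "A")], False),
            ([], True),
        ],
    )
    def test_examples(self, edges, expected):
        assert is_acyclic(edges, ["A", "B", "C"]) is expected


class TestEnumeration:
    def test_three_node_dag_count(self):
        assert sum(1 for _ in enumerate_dags(3)) == 25

    def test_four_node_dag_count(self):
        # labelled-DAG sequence: a(4) = 543
        assert sum(1 for _ in enumerate_dags(4)) == 543

    def test_limit_enforced(self):
        with pytest.raises(EnumerationLimitError):
            list(enumerate_dags(7))

    def test_single_variable_network(self):
        ds = binary_dataset({"A": [0, 1, 0, 1]})
        net = exhaustive_search(ds)
        assert net.edges == set()
        assert net.score == pytest.approx(
            bde_local_score("A", [], ds), abs=1e-12
        )

    def test_independent_pair_prefers_empty_graph(self):
        rng = np.random.default_rng(12)
        ds = binary_dataset(
            {"A": rng.integers(0, 2, 500), "B": rng.integers(0, 2, 500)}
        )
        net = exhaustive_search(ds)
        assert net.edges == set()


class TestSimulatedAnnealing:
    SA = SAConfig(
        max_iterations=4000, moves_per_temperature=50,
        cooling_factor=0.85, restarts=2, seed=0,
    )

    def test_recovers_exhaustive_maximum_on_chain(self, chain_dataset):
        oracle = exhaustive_search(chain_dataset)
        net = sa_search(chain_dataset, None, self.SA)
        assert net.score == pytest.approx(oracle.score, abs=1e-6)

    def test_all_edges_blocked_returns_empty_graph(self, chain_dataset):
        bl = EdgeBlocklist()
        for u in "ABC":
            for v in "ABC":
                if u != v:
                    bl.add(u, v, "confounded")
        net = sa_search(chain_dataset, bl, self.SA)
        assert net.edges == set()

    def test_independent_data_keeps_empty_graph_competitive(self):
        rng = np.random.default_rng(13)
        wins = 0
        for seed in range(5):
            ds = binary_dataset(
                {k: rng.integers(0, 2, 800) for k in ("A", "B", "C")}
            )
            empty = sum(bde_local_score(c, [], ds) for c in "ABC")
            single_best = max(
                bde_local_score(v, [u], ds)
                + sum(bde_local_score(w, [], ds) for w in "ABC" if w != v)
                for u in "ABC"
                for v in "ABC"
                if u != v
            )
            wins += empty >= single_best
        assert wins >= 4

    def test_blocked_edges_never_learned(self, chain_dataset):
        bl = EdgeBlocklist()
        bl.add("A", "B", "contingency", 0.9)
        bl.add("B", "A", "contingency", 0.9)
        net = sa_search(chain_dataset, bl, self.SA)
        assert ("A", "B") not in net.edges and ("B", "A") not in net.edges

    def test_max_parents_respected(self, collider_dataset):
        cfg = SAConfig(
            max_iterations=3000, moves_per_temperature=50,
            cooling_factor=0.85, max_parents=1, seed=1,
        )
        net = sa_search(collider_dataset, None, cfg)
        assert all(len(net.parents(n)) <= 1 for n in net.nodes)

    def test_deterministic_given_seed(self, chain_dataset):
        a = sa_search(chain_dataset, None, self.SA)
        b = sa_search(chain_dataset, None, self.SA)
        assert a.score == b.score and a.edges == b.edges

    def test_reported_score_matches_recompute(self, chain_dataset):
        net = sa_search(chain_dataset, None, self.SA)
        assert network_score(net, chain_dataset) == pytest.approx(
            net.score, abs=1e-9
        )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            SAConfig(cooling_factor=1.0)
        with pytest.raises(ValidationError):
            SAConfig(max_iterations=None, time_budget=None)
        with pytest.raises(ValidationError):
            SAConfig(equivalent_sample_size=0.0)


class TestSubsetNetworks:
    def test_one_network_per_subset_and_determinism(self, chain_dataset):
        cfg = SAConfig(
            max_iterations=1500, moves_per_temperature=50,
            cooling_factor=0.85, seed=21,
        )
        datasets = [chain_dataset] * 3
        nets1 = learn_subset_networks(datasets, None, cfg)
        nets2 = learn_subset_networks(datasets, None, cfg)
        assert len(nets1) == 3
        assert [n.score for n in nets1] == [n.score for n in nets2]
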