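import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from envconn import (COMMUNITIES, NetworkPartition, community_edge_counts,
                     density_sweep, load_partition, threshold_proportional)
from envconn.graph import UNASSIGNED


def _sym(rng, n):
    m = rng.standard_normal((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, np.nan)
    return m


def _partition_frame(mapping):
    rows = []
    for label, comm in mapping.items():
        net, hemi = comm.rsplit("_", 1)
        rows.append((label, net, hemi))
    return pd.DataFrame(rows, columns=["roi_label", "network", "hemisphere"])


class TestThresholdProportional:
    def test_top_k_by_sort_oracle(self, rng):
        m = _sym(rng, 5)
        adj = threshold_proportional(m, 0.2)
        iu = np.triu_indices(5, 1)
        order = np.argsort(m[iu])[::-1]
        expected = set(zip(iu[0][order[:2]], iu[1][order[:2]]))
        got = set(zip(*np.nonzero(np.triu(adj.values, 1))))
        assert got == expected
        assert adj.n_edges == 2

    def test_full_density_complete_graph(self, rng):
        adj = threshold_proportional(_sym(rng, 5), 1.0)
        assert adj.n_edges == 10

    def test_reference_cortex_edge_count(self, rng):
        """446 ROIs at 15% density retain floor(0.15 * C(446,2)) = 14885 edges."""
        adj = threshold_proportional(_sym(rng, 446), 0.15)
        assert adj.n_edges == 14885

    @pytest.mark.parametrize("density", [0.0, -0.1, 1.5])
    def test_invalid_density(self, rng, density):
        with pytest.raises(ValueError):
            threshold_proportional(_sym(rng, 4), density)

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            threshold_proportional(np.full((4, 4), np.nan), 0.5)

    def test_tie_break_deterministic_and_exact(self):
        """Ties resolve by (value desc, i asc, j asc); count stays exact."""
        m = np.ones((5, 5))
        np.fill_diagonal(m, np.nan)
        adj = threshold_proportional(m, 0.35)  # floor(3.5) = 3 of 10 edges
        got = list(zip(*np.nonzero(np.triu(adj.values, 1))))
        assert got == [(0, 1), (0, 2), (0, 3)]

    @given(st.integers(5, 25), st.floats(0.05, 1.0), st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_edge_count_exact_property(self, n, density, seed):
        m = _sym(np.random.default_rng(seed), n)
        adj = threshold_proportional(m, density)
        assert adj.n_edges == math.floor(density * n * (n - 1) / 2)


def _toy_partition(labels, sizes=(2, 2, 2), comms=("FPN_L", "LM_L", "SAL_R")):
    mapping, i = {}, 0
    for size, comm in zip(sizes, comms):
        for _ in range(size):
            mapping[labels[i]] = comm
            i += 1
    for rest in labels[i:]:
        mapping[rest] = UNASSIGNED
    return NetworkPartition(mapping)


class TestLoadPartition:
    def test_toy_table(self):
        labels = [f"r{i}" for i in range(6)]
        part = _toy_partition(labels)
        table = _partition_frame({l: part.community(l) for l in labels})
        loaded = load_partition(table, labels)
        sizes = pd.Series([loaded.community(l) for l in labels]).value_counts()
        assert sizes.to_dict() == {"FPN_L": 2, "LM_L": 2, "SAL_R": 2}

    def test_missing_label_becomes_unassigned(self):
        table = _partition_frame({"r0": "FPN_L"})
        part = load_partition(table, ["r0", "r_extra"])
        assert part.community("r_extra") == UNASSIGNED

    def test_duplicate_label_rejected(self):
        table = pd.concat([_partition_frame({"r0": "FPN_L"})] * 2)
        with pytest.raises(ValueError, match="r0"):
            load_partition(table, ["r0"])

    def test_unknown_network_rejected(self):
        table = pd.DataFrame(
            [("r0", "NOPE", "L")], columns=["roi_label", "network", "hemisphere"]
        )
        with pytest.raises(ValueError, match="NOPE"):
            load_partition(table, ["r0"])


class TestCommunityEdgeCounts:
    def test_complete_graph_closed_form(self):
        """Communities of sizes 3 and 2 in K5: intra C(3,2)=3 and C(2,2)=1, inter 3*2=6."""
        labels = [f"r{i}" for i in range(5)]
        part = _toy_partition(labels, sizes=(3, 2), comms=("FPN_L", "LM_L"))
        adj = ~np.eye(5, dtype=bool)
        counts = community_edge_counts(adj, part, labels)
        assert counts.intra["FPN_L"] == 3
        assert counts.intra["LM_L"] == 1
        assert counts.inter[("FPN_L", "LM_L")] == 6
        assert counts.unassigned_touching == 0

    def test_empty_graph_all_zero(self):
        labels = [f"r{i}" for i in range(5)]
        part = _toy_partition(labels, sizes=(3, 2), comms=("FPN_L", "LM_L"))
        counts = community_edge_counts(np.zeros((5, 5), bool), part, labels)
        assert counts.total_edges == 0
        assert counts.as_series().sum() == 0

    def test_unassigned_edges_bucketed(self):
        labels = ["r0", "r1", "r2"]
        part = _toy_partition(labels, sizes=(2,), comms=("FPN_L",))
        adj = ~np.eye(3, dtype=bool)
        counts = community_edge_counts(adj, part, labels)
        assert counts.intra["FPN_L"] == 1
        assert counts.unassigned_touching == 2

    def test_conservation_over_random_graphs(self):
        """Intra + inter + unassigned always equals the total edge count."""
        rng = np.random.default_rng(0)
        labels = [f"r{i}" for i in range(20)]
        mapping = {l: COMMUNITIES[i % 14] for i, l in enumerate(labels[:16])}
        mapping.update({l: UNASSIGNED for l in labels[16:]})
        part = NetworkPartition(mapping)
        for _ in range(200):
            adj = np.triu(rng.random((20, 20)) < 0.3, 1)
            adj = adj | adj.T
            counts = community_edge_counts(adj, part, labels)
            total = (counts.as_series().sum() + counts.unassigned_touching)
            assert total == counts.total_edges == int(adj.sum()) // 2

    def test_matches_networkx_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(3)
        labels = [f"r{i}" for i in range(15)]
        part = NetworkPartition({l: COMMUNITIES[i % 5] for i, l in enumerate(labels)})
        adj = np.triu(rng.random((15, 15)) < 0.4, 1)
        adj = adj | adj.T
        counts = community_edge_counts(adj, part, labels)
        g = nx.from_numpy_array(adj)
        intra = {c: 0 for c in COMMUNITIES}
        inter = {}
        for u, v in g.edges():
            cu, cv = part.community(labels[u]), part.community(labels[v])
            if cu == cv:
                intra[cu] += 1
            else:
                key = tuple(sorted((cu, cv), key=COMMUNITIES.index))
                inter[key] = inter.get(key, 0) + 1
        assert counts.intra == intra
        assert {k: v for k, v in counts.inter.items() if v} == inter

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        labels = [f"r{i}" for i in range(12)]
        part = NetworkPartition({l: COMMUNITIES[i % 4] for i, l in enumerate(labels)})
        adj = np.triu(rng.random((12, 12)) < 0.4, 1)
        adj = adj | adj.T
        perm = rng.permutation(12)
        counts = community_edge_counts(adj, part, labels)
        counts_p = community_edge_counts(
            adj[np.ix_(perm, perm)], part, [labels[i] for i in perm]
        )
        assert counts.as_series().equals(counts_p.as_series())


class TestDensitySweep:
    def _setup(self, seed=1, n=10):
        rng = np.random.default_rng(seed)
        m = _sym(rng, n)
        labels = [f"r{i}" for i in range(n)]
        part = NetworkPartition({l: COMMUNITIES[i % 3] for i, l in enumerate(labels)})
        return m, part, labels

    def test_counts_nondecreasing_in_density(self):
        m, part, labels = self._setup()
        sweep = density_sweep(m, part, labels)
        wide = sweep.pivot_table(index="measure", columns="density", values="count")
        assert (wide.diff(axis=1).iloc[:, 1:] >= 0).all().all()

    def test_consistent_with_single_threshold_call(self):
        m, part, labels = self._setup()
        sweep = density_sweep(m, part, labels, densities=(0.15,))
        single = community_edge_counts(threshold_proportional(m, 0.15), part, labels)
        got = sweep.set_index("measure")["count"]
        for measure, count in single.as_series().items():
            assert got[measure] == count

    def test_matches_brute_force_enumeration(self):
        """Hand enumeration of the top-k pairs reproduces the sweep counts."""
        m, part, labels = self._setup(seed=7)
        n = len(labels)
        pairs = sorted(
            ((m[i, j], i, j) for i, j in itertools.combinations(range(n), 2)),
            key=lambda t: (-t[0], t[1], t[2]),
        )
        for density in (0.1, 0.3):
            k = math.floor(density * n * (n - 1) / 2)
            brute = {}
            for _, i, j in pairs[:k]:
                ci, cj = part.community(labels[i]), part.community(labels[j])
                if ci == cj:
                    key = f"intra:{ci}"
                else:
                    a, b = sorted((ci, cj), key=COMMUNITIES.index)
                    key = f"inter:{a}|{b}"
                brute[key] = brute.get(key, 0) + 1
            sweep = density_sweep(m, part, labels, densities=(density,))
            got = sweep.set_index("measure")["count"]
            for key, count in brute.items():
                assert got[key] == count
            assert got.drop("unassigned_touching").sum() == k
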