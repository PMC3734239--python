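import numpy as np
import pytest

from vtod.datatypes import GeneLocation, PipelineConfig, PPIGraph
from vtod.ggr import Relationship, RelationshipNetwork
from vtod.merging import (
    Module,
    interconnectivity,
    merge_premodules,
    merging_value,
    module_overlap_stats,
    select_delta,
    shuffle_relationships,
    significance_curve,
)
from vtod.seeds import build_seed_set
from vtod.voting import PreModule


def _net(pairs, genes):
    seed = build_seed_set(set(genes), set(), set(genes), set())
    net = RelationshipNetwork(seed)
    for a, b, w in pairs:
        lo, hi = min(a, b), max(a, b)
        net.relationships[(lo, hi)] = Relationship(lo, hi, w, "GE-GE")
    return net


class TestInterconnectivity:
    def test_half_of_smaller_set_connected(self):
        edges = [("a", "p"), ("b", "q")]
        ppi = PPIGraph.from_edges(edges + [("x", "y")])
        ic = interconnectivity(
            frozenset("abcd"), frozenset({"p", "q", "x", "y", "z"}), ppi
        )
        assert ic == pytest.approx(0.5)

    def test_fully_interconnected_cliques(self):
        edges = [(a, b) for a in "ab" for b in "pq"]
        ppi = PPIGraph.from_edges(edges)
        assert interconnectivity(frozenset("ab"), frozenset("pq"), ppi) == 1.0

    def test_no_cross_edges(self):
        ppi = PPIGraph.from_edges([("a", "b"), ("p", "q")])
        assert interconnectivity(frozenset("ab"), frozenset("pq"), ppi) == 0.0


class TestMergingValue:
    def test_ic_plus_mean_cross_relationship(self):
        genes = list("abpq")
        edges = [(a, b) for a in "ab" for b in "pq"]
        ppi = PPIGraph.from_edges(edges)
        net = _net([(a, b, 0.5) for a in "ab" for b in "pq"], genes)
        mv = merging_value(frozenset("ab"), frozenset("pq"), net, ppi)
        assert mv == pytest.approx(1.5)  # IC 1.0 + mean(0.5 x 4)

    def test_empty_cross_gives_zero(self):
        ppi = PPIGraph.from_edges([("a", "b"), ("p", "q")])
        net = _net([], list("abpq"))
        assert merging_value(frozenset("ab"), frozenset("pq"), net, ppi) == 0.0

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(77)
        genes = [f"g{i}" for i in range(10)]
        for _ in range(25):
            pairs = []
            for i in range(10):
                for j in range(i + 1, 10):
                    if rng.random() < 0.4:
                        pairs.append((genes[i], genes[j], float(rng.uniform(0, 1))))
            edges = [
                (genes[i], genes[j])
                for i in range(10)
                for j in range(i + 1, 10)
                if rng.random() < 0.3
            ]
            ppi = PPIGraph.from_edges(edges) if edges else PPIGraph.from_edges([("g0", "g1")])
            net = _net(pairs, genes)
            mi = frozenset(rng.choice(genes, size=4, replace=False))
            mj = frozenset(rng.choice(genes, size=5, replace=False))
            a = merging_value(mi, mj, net, ppi)
            b = merging_value(mj, mi, net, ppi)
            assert a == pytest.approx(b)
            assert 0.0 <= a <= 2.0


class TestShuffle:
    def _network(self):
        genes = [f"g{i}" for i in range(12)]
        rng = np.random.default_rng(5)
        pairs = []
        for i in range(12):
            for j in range(i + 1, 12):
                if rng.random() < 0.35:
                    pairs.append((genes[i], genes[j], float(rng.uniform(0.2, 1))))
        return _net(pairs, genes)

    def test_weight_multiset_and_count_conserved(self):
        net = self._network()
        sh = shuffle_relationships(net, np.random.default_rng(1))
        assert len(sh) == len(net)
        w0 = sorted(r.weight for r in net.relationships.values())
        w1 = sorted(r.weight for r in sh.relationships.values())
        assert w0 == pytest.approx(w1)

    def test_reproducible(self):
        net = self._network()
        a = shuffle_relationships(net, np.random.default_rng(3))
        b = shuffle_relationships(net, np.random.default_rng(3))
        assert sorted(a.relationships) == sorted(b.relationships)

    def test_pairs_actually_move(self):
        net = self._network()
        sh = shuffle_relationships(net, np.random.default_rng(2))
        assert set(sh.relationships) != set(net.relationships)


class TestMergeLoop:
    def _toy(self):
        # two tightly related pre-modules plus one weak outsider
        genes = list("abcdefxyz")
        pairs = [(a, b, 0.9) for a in "abc" for b in "def"]
        net = _net(pairs, genes)
        ppi = PPIGraph.from_edges([(a, b) for a in "abc" for b in "def"] + [("x", "y")])
        pre = [
            PreModule("a", frozenset("abc"), frozenset("bc")),
            PreModule("d", frozenset("def"), frozenset("ef")),
            PreModule("x", frozenset("xyz"), frozenset("yz")),
        ]
        return pre, net, ppi

    def test_single_merge_above_delta(self):
        pre, net, ppi = self._toy()
        mods, steps = merge_premodules(pre, net, ppi, delta=1.0)
        assert len(mods) == 2
        assert len(steps) == 1
        assert steps[0][3] == pytest.approx(1.9)  # IC 1 + mean rel 0.9
        merged = next(m for m in mods if len(m.members) == 6)
        assert merged.lineage == ("a", "d")

    def test_delta_above_two_blocks_all_merging(self):
        pre, net, ppi = self._toy()
        mods, steps = merge_premodules(pre, net, ppi, delta=2.5)
        assert len(mods) == 3 and steps == []

    def test_delta_zero_merges_to_single_module(self):
        pre, net, ppi = self._toy()
        mods, steps = merge_premodules(pre, net, ppi, delta=0.0)
        assert len(mods) == 1
        assert mods[0].members == frozenset("abcdefxyz")
        assert len(steps) == 2

    def test_coverage_never_shrinks(self):
        pre, net, ppi = self._toy()
        mods, _ = merge_premodules(pre, net, ppi, delta=0.0)
        assert set().union(*[m.members for m in mods]) == set("abcdefxyz")


class TestOverlapStats:
    def test_disjoint_identical_and_half(self):
        mk = lambda s: Module(frozenset(s), (min(s),))
        mean, ratios = module_overlap_stats([mk("abcd"), mk("wxyz")])
        assert mean == 0.0
        mean, _ = module_overlap_stats([mk("abcd"), mk("abcd")])
        assert mean == 1.0
        mean, ratios = module_overlap_stats([mk("abcd"), mk("cdef")])
        assert mean == pytest.approx(0.5)
        assert ratios[(0, 1)] == pytest.approx(2 / 4)


class TestDeltaCalibration:
    def _setup(self):
        rng = np.random.default_rng(21)
        genes = [f"g{i:02d}" for i in range(24)]
        # strong block on the first 8 genes, aligned with a PPI clique
        pairs = []
        for i in range(24):
            for j in range(i + 1, 24):
                if i < 8 and j < 8:
                    pairs.append((genes[i], genes[j], float(rng.uniform(0.8, 1.0))))
                elif rng.random() < 0.15:
                    pairs.append((genes[i], genes[j], float(rng.uniform(0.1, 0.4))))
        net = _net(pairs, genes)
        edges = [(genes[i], genes[j]) for i in range(8) for j in range(i + 1, 8)]
        edges += [
            (genes[i], genes[j])
            for i in range(24)
            for j in range(i + 1, 24)
            if rng.random() < 0.06
        ]
        ppi = PPIGraph.from_edges(edges)
        pre = [
            PreModule(genes[0], frozenset(genes[0:4]), frozenset(genes[1:4])),
            PreModule(genes[4], frozenset(genes[4:8]), frozenset(genes[5:8])),
            PreModule(genes[9], frozenset(genes[9:12]), frozenset(genes[10:12])),
        ]
        locs = {g: GeneLocation(g, "chr1", "1q11", None) for g in genes}
        cfg = PipelineConfig(global_top_percent=10.0, rng_seed=0)
        return pre, net, ppi, locs, cfg

    def test_delta_reproducible_and_traced(self):
        pre, net, ppi, locs, cfg = self._setup()
        d1, t1 = select_delta(pre, net, ppi, 30, 0.05, np.random.default_rng(6),
                              config=cfg, locations=locs)
        d2, t2 = select_delta(pre, net, ppi, 30, 0.05, np.random.default_rng(6),
                              config=cfg, locations=locs)
        assert d1 == d2
        assert t1.random_first_step_max == t2.random_first_step_max
        assert len(t1.random_first_step_max) == 30
        if d1 is not None:
            assert all(step[3] >= d1 for step in t1.steps)

    def test_significance_curve_length(self):
        pre, net, ppi, locs, cfg = self._setup()
        curve = significance_curve(pre, net, ppi, 10, np.random.default_rng(2),
                                   config=cfg, locations=locs)
        assert len(curve) == len(pre) - 1
        for obs, rmean, p in curve:
            assert 0 <= obs <= 2 and 0 <= rmean <= 2 and 0 < p <= 1
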