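"""Pre-module merging and its randomization-calibrated stopping threshold.

The merging value between two (pre-)modules adds a topological term — the
inter-connectivity IC, the fraction of the smaller module's genes with at
least one PPI partner in the other module — and a data-driven term, the mean
relationship value over all cross pairs (absent relationships count as 0).
Both terms lie in [0, 1], both enter with equal weight, so MV lies in [0, 2].

The stopping threshold delta is calibrated against a null in which the
relationship network's gene pairs are re-drawn uniformly (same weights, same
count, same seed genes) while the PPI graph is untouched: for each of
n_random shuffles the whole pipeline (votes -> pre-modules -> first merge) is
re-run and the first-step maximum MV recorded. Observed merging proceeds
while the current maximum MV is empirically significant against that
distribution; delta is the smallest observed maximum still significant. When
not even the first observed step is significant, delta is undefined and no
module survives the calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from ._utils import pair_count, unrank_pairs
from .datatypes import GeneLocation, PPIGraph, PipelineConfig
from .ggr import Relationship, RelationshipNetwork
from .voting import PreModule, _representatives_from_matrix, form_premodules, vote_matrix_from

log = logging.getLogger(__name__)


@dataclass
class Module:
    members: frozenset
    lineage: tuple[str, ...]  # representatives of the merged pre-modules
    final: bool = False

    def __post_init__(self):
        if len(self.members) < 3:
            raise ValueError("a module needs at least 3 genes")


@dataclass
class MergeTrace:
    steps: list[tuple[int, tuple[str, ...], tuple[str, ...], float, float]] = field(
        default_factory=list
    )  # (step, lineage_i, lineage_j, mv, empirical_p)
    random_first_step_max: list[float] = field(default_factory=list)
    delta: Optional[float] = None


# ---------------------------------------------------------------- MV


def interconnectivity(m_i: frozenset, m_j: frozenset, ppi: PPIGraph,
                      mode: str = "smaller") -> float:
    """Fraction of the smaller module's genes with >= 1 PPI partner in the
    other module. Equal sizes take the maximum of both directions so the
    value stays symmetric; mode="symmetric_max" always does."""

    def _ic(small: frozenset, other: frozenset) -> float:
        hits = 0
        for g in small:
            if g in ppi and any(nb in other and nb != g for nb in ppi.graph.adj[g]):
                hits += 1
        return hits / len(small)

    if not m_i or not m_j:
        raise ValueError("modules must be non-empty")
    if mode == "symmetric_max" or len(m_i) == len(m_j):
        return max(_ic(m_i, m_j), _ic(m_j, m_i))
    small, other = (m_i, m_j) if len(m_i) < len(m_j) else (m_j, m_i)
    return _ic(small, other)


def merging_value(
    m_i: frozenset, m_j: frozenset, rel: RelationshipNetwork, ppi: PPIGraph,
    ic_mode: str = "smaller",
) -> float:
    """MV = IC + mean over cross pairs (a in M_i, b in M_j, a != b) of
    Rel(a, b); absent relationships contribute 0."""
    ic = interconnectivity(m_i, m_j, ppi, mode=ic_mode)
    total = 0.0
    n = 0
    for a in m_i:
        for b in m_j:
            if a != b:
                total += rel.weight(a, b)
                n += 1
    dd = total / n if n else 0.0
    return ic + dd


# ------------------------------------------------- array engine (fast path)


class _MergeEngine:
    """Array-backed MV computation over a fixed gene order, used by the merge
    loop and the shuffle calibration (identical semantics to the public ops)."""

    def __init__(self, genes: list[str], adj: np.ndarray, rel_matrix: np.ndarray,
                 ic_mode: str = "smaller"):
        self.genes = genes
        self.index = {g: i for i, g in enumerate(genes)}
        self.adj = adj
        self.rel = rel_matrix
        self.ic_mode = ic_mode

    def mask(self, members: frozenset) -> np.ndarray:
        m = np.zeros(len(self.genes), dtype=bool)
        for g in members:
            m[self.index[g]] = True
        return m

    def mv(self, mi: np.ndarray, mj: np.ndarray) -> float:
        ni, nj = int(mi.sum()), int(mj.sum())

        def ic_dir(small: np.ndarray, other: np.ndarray) -> float:
            # a gene's edge to itself never exists (no self-loops), so edges
            # into `other` need no self exclusion
            return float((self.adj[small][:, other].any(axis=1)).sum() / small.sum())

        if self.ic_mode == "symmetric_max" or ni == nj:
            ic = max(ic_dir(mi, mj), ic_dir(mj, mi))
        elif ni < nj:
            ic = ic_dir(mi, mj)
        else:
            ic = ic_dir(mj, mi)
        cross = self.rel[mi][:, mj]
        n_cross = ni * nj - int((mi & mj).sum())
        dd = float(cross.sum() / n_cross) if n_cross else 0.0
        # diagonal of rel is 0, so shared genes contribute nothing to the sum
        return ic + dd


def _max_pair(engine: _MergeEngine, mods: list[Module]):
    """Maximum-MV module pair; ties break by lexicographic lineage."""
    best = None
    masks = [engine.mask(m.members) for m in mods]
    for i in range(len(mods)):
        for j in range(i + 1, len(mods)):
            mv = engine.mv(masks[i], masks[j])
            li, lj = sorted((mods[i].lineage, mods[j].lineage))
            key = (-mv, li, lj)
            if best is None or key < best[0]:
                best = (key, i, j, mv)
    if best is None:
        return None
    _, i, j, mv = best
    return i, j, mv


def merge_premodules(
    premodules: Sequence[PreModule],
    rel: RelationshipNetwork,
    ppi: PPIGraph,
    delta: float,
    ic_mode: str = "smaller",
) -> tuple[list[Module], list[tuple[int, tuple, tuple, float]]]:
    """Greedy merging: repeatedly merge the maximum-MV pair (set union) while
    the maximum MV >= delta. Returns the final modules and the per-step
    (step, lineage_i, lineage_j, mv) series."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    genes = sorted({g for pm in premodules for g in pm.members})
    engine = _MergeEngine(
        genes, ppi.adjacency_for(genes), rel.weight_matrix(genes), ic_mode
    )
    mods = [
        Module(pm.members, (pm.representative,)) for pm in premodules
    ]
    steps = []
    step = 0
    while len(mods) >= 2:
        found = _max_pair(engine, mods)
        if found is None:
            break
        i, j, mv = found
        if mv < delta:
            break
        step += 1
        a, b = mods[i], mods[j]
        steps.append((step, a.lineage, b.lineage, mv))
        merged = Module(a.members | b.members, tuple(sorted(a.lineage + b.lineage)))
        mods = [m for k, m in enumerate(mods) if k not in (i, j)] + [merged]
    for m in mods:
        m.final = True
    return mods, steps


# ---------------------------------------------------------------- null model


def _shuffled_weight_matrix(
    weights: np.ndarray, n_genes: int, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric matrix with the same weight multiset on a uniformly re-drawn
    set of gene pairs."""
    n_pairs = pair_count(n_genes)
    m = len(weights)
    if m > n_pairs:
        raise ValueError("more relationships than available pairs")
    idx = rng.choice(n_pairs, size=m, replace=False)
    i, j = unrank_pairs(idx, n_genes)
    w = np.zeros((n_genes, n_genes))
    w[i, j] = weights
    w[j, i] = weights
    return w


def shuffle_relationships(
    rel: RelationshipNetwork, rng: np.random.Generator
) -> RelationshipNetwork:
    """Reassign the relationship weights/kinds to uniformly re-drawn gene
    pairs over the same seed genes; the PPI graph is untouched."""
    genes = sorted(rel.seed_genes.genes)
    items = [rel.relationships[k] for k in sorted(rel.relationships)]
    if len(items) < 2:
        raise ValueError("need at least 2 relationships to shuffle")
    idx = rng.choice(pair_count(len(genes)), size=len(items), replace=False)
    ii, jj = unrank_pairs(idx, len(genes))
    out = RelationshipNetwork(rel.seed_genes, thresholds={})
    for old, a, b in zip(items, ii, jj):
        lo, hi = genes[int(a)], genes[int(b)]
        path = None
        if old.kind == "indirect":
            path = (lo, *old.path[1:-1], hi)
        out.relationships[(lo, hi)] = Relationship(
            lo, hi, old.weight, old.kind, path=path, path_p=old.path_p
        )
    return out


def _premodules_from_rel_matrix(
    genes: list[str],
    rel_matrix: np.ndarray,
    nc: np.ndarray,
    spl: np.ndarray,
    locations: Mapping[str, GeneLocation],
    config: PipelineConfig,
) -> list[PreModule]:
    v = vote_matrix_from(rel_matrix, nc, spl, config.vote_spl_limit)
    rep_map = _representatives_from_matrix(
        genes, v, config.local_rank_limit, config.global_top_percent,
        config.local_rank_mode,
    )
    return form_premodules(rep_map, locations)


def _first_step_max(
    engine_genes: list[str],
    adj: np.ndarray,
    rel_matrix: np.ndarray,
    premodules: Sequence[PreModule],
    ic_mode: str,
) -> float:
    if len(premodules) < 2:
        return 0.0
    engine = _MergeEngine(engine_genes, adj, rel_matrix, ic_mode)
    mods = [Module(pm.members, (pm.representative,)) for pm in premodules]
    found = _max_pair(engine, mods)
    return found[2] if found else 0.0


def select_delta(
    premodules: Sequence[PreModule],
    rel: RelationshipNetwork,
    ppi: PPIGraph,
    n_random: int,
    merge_alpha: float,
    rng: np.random.Generator,
    *,
    config: PipelineConfig,
    locations: Mapping[str, GeneLocation],
) -> tuple[Optional[float], MergeTrace]:
    """Calibrate the merge-stopping threshold delta.

    Each of `n_random` relationship shuffles re-runs votes -> pre-modules ->
    first merge and records the first-step maximum MV; a run with fewer than
    2 pre-modules contributes 0. Observed merging proceeds while the current
    maximum MV has empirical p <= merge_alpha ((+1)/(n+1) convention); delta
    is the smallest observed maximum still significant, or None when not even
    the first step is significant.
    """
    if len(premodules) < 2:
        raise ValueError("need at least 2 pre-modules")
    genes = sorted(rel.seed_genes.genes)
    spl = ppi.spl_matrix(genes, cutoff=config.vote_spl_limit)
    nc = np.array([ppi.normalized_connectivity(g) for g in genes])
    adj = ppi.adjacency_for(genes)
    weights = np.array([rel.relationships[k].weight for k in sorted(rel.relationships)])

    random_max = []
    for _ in range(n_random):
        w = _shuffled_weight_matrix(weights, len(genes), rng)
        pre_r = _premodules_from_rel_matrix(genes, w, nc, spl, locations, config)
        random_max.append(_first_step_max(genes, adj, w, pre_r, config.ic_mode))
    random_max = np.array(random_max)

    # observed merge sequence, tested step by step
    rel_matrix = rel.weight_matrix(genes)
    engine = _MergeEngine(genes, adj, rel_matrix, config.ic_mode)
    mods = [Module(pm.members, (pm.representative,)) for pm in premodules]
    trace = MergeTrace(random_first_step_max=[float(x) for x in random_max])
    delta: Optional[float] = None
    step = 0
    while len(mods) >= 2:
        found = _max_pair(engine, mods)
        if found is None:
            break
        i, j, mv = found
        p = (int((random_max >= mv).sum()) + 1) / (n_random + 1)
        if p > merge_alpha:
            break
        step += 1
        delta = mv if delta is None else min(delta, mv)
        a, b = mods[i], mods[j]
        trace.steps.append((step, a.lineage, b.lineage, mv, p))
        merged = Module(a.members | b.members, tuple(sorted(a.lineage + b.lineage)))
        mods = [m for k, m in enumerate(mods) if k not in (i, j)] + [merged]
    trace.delta = delta
    return delta, trace


def significance_curve(
    premodules: Sequence[PreModule],
    rel: RelationshipNetwork,
    ppi: PPIGraph,
    n_random: int,
    rng: np.random.Generator,
    *,
    config: PipelineConfig,
    locations: Mapping[str, GeneLocation],
) -> list[tuple[float, float, float]]:
    """Merge both the observed pre-modules and every shuffled replicate to
    exhaustion; per step return (observed max MV, random mean, empirical p).

    Random runs shorter than the observed sequence are padded with 0 (no
    merge left means no merging value to beat).
    """
    if len(premodules) < 2:
        raise ValueError("need at least 2 pre-modules")
    genes = sorted(rel.seed_genes.genes)
    spl = ppi.spl_matrix(genes, cutoff=config.vote_spl_limit)
    nc = np.array([ppi.normalized_connectivity(g) for g in genes])
    adj = ppi.adjacency_for(genes)
    weights = np.array([rel.relationships[k].weight for k in sorted(rel.relationships)])

    def run_to_exhaustion(rel_matrix, pre) -> list[float]:
        engine = _MergeEngine(genes, adj, rel_matrix, config.ic_mode)
        mods = [Module(pm.members, (pm.representative,)) for pm in pre]
        out = []
        while len(mods) >= 2:
            found = _max_pair(engine, mods)
            if found is None:
                break
            i, j, mv = found
            out.append(mv)
            a, b = mods[i], mods[j]
            merged = Module(a.members | b.members, tuple(sorted(a.lineage + b.lineage)))
            mods = [m for k, m in enumerate(mods) if k not in (i, j)] + [merged]
        return out

    observed = run_to_exhaustion(rel.weight_matrix(genes), premodules)
    rand_series = []
    for _ in range(n_random):
        w = _shuffled_weight_matrix(weights, len(genes), rng)
        pre_r = _premodules_from_rel_matrix(genes, w, nc, spl, locations, config)
        rand_series.append(run_to_exhaustion(w, pre_r) if len(pre_r) >= 2 else [])
    out = []
    for s, obs in enumerate(observed):
        vals = np.array([rs[s] if s < len(rs) else 0.0 for rs in rand_series])
        p = (int((vals >= obs).sum()) + 1) / (n_random + 1)
        out.append((float(obs), float(vals.mean()), p))
    return out


def module_overlap_stats(modules: Sequence[Module]) -> tuple[float, dict]:
    """Per ordered module pair, |intersection| / |module|; mean reported."""
    if len(modules) < 2:
        raise ValueError("need at least 2 modules")
    ratios = {}
    for i, a in enumerate(modules):
        for j, b in enumerate(modules):
            if i != j:
                ratios[(i, j)] = len(a.members & b.members) / len(a.members)
    return float(np.mean(list(ratios.values()))), ratios
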