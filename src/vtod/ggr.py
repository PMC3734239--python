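"""The gene-gene relationship network GGR = (S, R).

Direct relationships: for every unordered seed pair the absolute Pearson
correlations of all available channel pairs (GE-GE, CNA-GE in both
orientations, CNA-CNA) are computed; CNA-CNA is suppressed for genes sharing
a focal aberrant region or a cytoband (their copy-number correlation is
positional). The maximum available value (MaxRel) enters R when it reaches
its own channel's top-quantile threshold.

Indirect relationships: for pairs not in R that are joined by a short PPI
path through data-bearing genes, the path with the highest mean normalized
connectivity is scored by the geometric mean of MaxRel along its consecutive
pairs; significance is an empirical p against node-label permutations of the
PPI graph (topology conserved, labels detached).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional

import networkx as nx
import numpy as np

from ._utils import geometric_mean, pair_count, top_fraction_threshold
from .datatypes import GeneLocation, OmicsDataset, PPIGraph, PipelineConfig, co_located
from .seeds import SeedGeneSet

log = logging.getLogger(__name__)

DIRECT_KINDS = ("GE-GE", "CNA-GE", "CNA-CNA")


@dataclass(frozen=True)
class Relationship:
    gene_a: str
    gene_b: str
    weight: float
    kind: str
    path: Optional[tuple[str, ...]] = None
    path_p: Optional[float] = None

    def __post_init__(self):
        if self.gene_a >= self.gene_b:
            raise ValueError("genes must be stored with gene_a < gene_b")
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"weight {self.weight} outside [0, 1]")
        if (self.kind == "indirect") != (self.path is not None):
            raise ValueError("kind=indirect iff a path is present")


class RelationshipNetwork:
    """Keyed store of relationships among seed genes plus per-kind thresholds."""

    def __init__(self, seed_genes: SeedGeneSet, thresholds: Optional[dict] = None):
        self.seed_genes = seed_genes
        self.thresholds: dict[str, float] = dict(thresholds or {})
        self.relationships: dict[tuple[str, str], Relationship] = {}
        # Figure-S5-style profiling: one pair can exceed several per-type
        # thresholds even though its stored kind is the argmax only.
        self.per_type_pairs: dict[str, set[tuple[str, str]]] = {k: set() for k in DIRECT_KINDS}

    @staticmethod
    def key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a < b else (b, a)

    def add(self, rel: Relationship) -> None:
        if rel.gene_a not in self.seed_genes or rel.gene_b not in self.seed_genes:
            raise ValueError("relationship endpoint outside the seed set")
        k = (rel.gene_a, rel.gene_b)
        if k in self.relationships:
            raise ValueError(f"pair {k} already stored")
        if rel.kind in self.thresholds and rel.weight < self.thresholds[rel.kind]:
            raise ValueError("direct weight below its kind threshold")
        self.relationships[k] = rel

    def __len__(self) -> int:
        return len(self.relationships)

    def __contains__(self, pair) -> bool:
        return self.key(*pair) in self.relationships

    def get(self, a: str, b: str) -> Optional[Relationship]:
        return self.relationships.get(self.key(a, b))

    def weight(self, a: str, b: str) -> float:
        rel = self.get(a, b)
        return rel.weight if rel is not None else 0.0

    def weight_matrix(self, genes: list[str]) -> np.ndarray:
        """Dense symmetric weight matrix over the given gene order (0 = none)."""
        idx = {g: i for i, g in enumerate(genes)}
        w = np.zeros((len(genes), len(genes)))
        for (a, b), rel in self.relationships.items():
            ia, ib = idx.get(a), idx.get(b)
            if ia is not None and ib is not None:
                w[ia, ib] = w[ib, ia] = rel.weight
        return w


# ---------------------------------------------------------------- correlations


def abs_pcc(x, y) -> Optional[float]:
    """|Pearson r|; None when either vector is constant (undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if x.std() == 0.0 or y.std() == 0.0:
        return None
    r = np.corrcoef(x, y)[0, 1]
    return float(min(1.0, abs(r)))


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    """Rows scaled to zero mean, unit norm; constant rows become all-NaN."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = centered / norms
    z[(norms == 0).ravel()] = np.nan
    return z


def channel_matrices(
    genes: list[str], data: OmicsDataset
) -> dict[str, np.ndarray]:
    """Per-channel |PCC| matrices over `genes` (NaN where unavailable).

    CNA-CNA applies the co-location exclusion. CNA-GE holds the larger of the
    two orientations (CNA of one gene vs GE of the other).
    """
    n = len(genes)
    out = {k: np.full((n, n), np.nan) for k in DIRECT_KINDS}

    ge_rows = np.array([g in data.expr for g in genes])
    if ge_rows.any():
        zg = _standardize_rows(
            np.stack([data.expr.row(g) for g in np.array(genes)[ge_rows]])
        )
        c = np.abs(zg @ zg.T)
        np.clip(c, 0.0, 1.0, out=c)
        ii = np.where(ge_rows)[0]
        out["GE-GE"][np.ix_(ii, ii)] = c

    cna_rows = np.array([data.has_cna(g) for g in genes])
    if data.cna is not None and cna_rows.any():
        zc = _standardize_rows(
            np.stack([data.cna.row(g) for g in np.array(genes)[cna_rows]])
        )
        jj = np.where(cna_rows)[0]
        c = np.abs(zc @ zc.T)
        np.clip(c, 0.0, 1.0, out=c)
        out["CNA-CNA"][np.ix_(jj, jj)] = c
        # positional exclusion
        locs = [data.location(g) for g in genes]
        for ai, a in enumerate(genes):
            for bi in range(ai + 1, n):
                if co_located(locs[ai], locs[bi]):
                    out["CNA-CNA"][ai, bi] = out["CNA-CNA"][bi, ai] = np.nan
        if ge_rows.any():
            ii = np.where(ge_rows)[0]
            zg = _standardize_rows(
                np.stack([data.expr.row(g) for g in np.array(genes)[ge_rows]])
            )
            cross = np.abs(zc @ zg.T)  # cna rows x ge rows
            np.clip(cross, 0.0, 1.0, out=cross)
            m = out["CNA-GE"]
            m[np.ix_(jj, ii)] = cross
            # both orientations: keep the larger
            out["CNA-GE"] = np.fmax(m, m.T)

    for k in DIRECT_KINDS:
        np.fill_diagonal(out[k], np.nan)
    return out


def maxrel_matrix(
    genes: list[str], data: OmicsDataset
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Combined MaxRel matrix, argmax kind codes, and per-channel matrices.

    Kind codes index DIRECT_KINDS; -1 marks pairs with no available channel.
    Exact ties between channels resolve in DIRECT_KINDS order.
    """
    ch = channel_matrices(genes, data)
    stack = np.stack([ch[k] for k in DIRECT_KINDS])
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs are expected
        m = np.nanmax(stack, axis=0)
    kind = np.full(m.shape, -1, dtype=int)
    valid = ~np.isnan(m)
    # first channel attaining the max (DIRECT_KINDS order)
    for ci in range(len(DIRECT_KINDS) - 1, -1, -1):
        hit = valid & (stack[ci] == m)
        kind[hit] = ci
    return m, kind, ch


def max_rel(
    gene_i: str, gene_j: str, data: OmicsDataset
) -> Optional[tuple[float, str]]:
    """MaxRel for one pair: the largest available channel value and its kind."""
    if gene_i == gene_j:
        raise ValueError("MaxRel is defined for distinct genes")
    m, kind, _ = maxrel_matrix([gene_i, gene_j], data)
    if np.isnan(m[0, 1]):
        return None
    return float(m[0, 1]), DIRECT_KINDS[kind[0, 1]]


# ---------------------------------------------------------------- direct pass


def direct_thresholds(
    candidates_by_kind: Mapping[str, Iterable[float]], top_fraction: float
) -> dict[str, float]:
    """Per-kind (1 - top_fraction) quantile so that ~top_fraction of each
    kind's candidate values are >= the threshold. Empty kinds are disabled."""
    out = {}
    for kind, vals in candidates_by_kind.items():
        vals = np.asarray(list(vals), dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            log.warning("no candidate values for kind %s; kind disabled", kind)
            continue
        out[kind] = top_fraction_threshold(vals, top_fraction)
    return out


def build_direct(
    seed: SeedGeneSet,
    data: OmicsDataset,
    top_fraction: float = 0.10,
) -> RelationshipNetwork:
    """Enumerate all unordered seed pairs and store those whose MaxRel reaches
    its own kind's top-quantile threshold."""
    genes = sorted(seed.genes)
    if not genes:
        raise ValueError("empty seed set")
    m, kindcode, ch = maxrel_matrix(genes, data)
    iu, ju = np.triu_indices(len(genes), k=1)
    candidates = {
        kind: ch[kind][iu, ju][~np.isnan(ch[kind][iu, ju])] for kind in DIRECT_KINDS
    }
    thresholds = direct_thresholds(candidates, top_fraction) if top_fraction > 0 else {}
    net = RelationshipNetwork(seed, thresholds)
    if top_fraction <= 0:
        return net

    for kind in DIRECT_KINDS:
        if kind not in thresholds:
            continue
        vals = ch[kind][iu, ju]
        hit = ~np.isnan(vals) & (vals >= thresholds[kind])
        net.per_type_pairs[kind] = {
            (genes[int(a)], genes[int(b)]) for a, b in zip(iu[hit], ju[hit])
        }

    vals = m[iu, ju]
    kinds = kindcode[iu, ju]
    for a, b, v, kc in zip(iu, ju, vals, kinds):
        if np.isnan(v) or kc < 0:
            continue
        kind = DIRECT_KINDS[kc]
        if kind in thresholds and v >= thresholds[kind]:
            net.add(Relationship(genes[int(a)], genes[int(b)], float(v), kind))
    total = pair_count(len(genes))
    log.info(
        "direct pass: %d of %d seed pairs stored (%.2f%%)",
        len(net), total, 100.0 * len(net) / total if total else 0.0,
    )
    return net


# ---------------------------------------------------------------- indirect pass


def normalized_connectivity(gene: str, ppi: PPIGraph) -> float:
    """degree / global max degree, in [0, 1]; 0 for genes absent from the PPI."""
    return ppi.normalized_connectivity(gene)


def path_connectivity_score(path: Iterable[str], ppi: PPIGraph) -> float:
    """Mean normalized connectivity over all genes on a path."""
    path = list(path)
    return float(np.mean([normalized_connectivity(g, ppi) for g in path]))


def best_path(
    gene_i: str,
    gene_j: str,
    ppi: PPIGraph,
    data_genes: set[str],
    L: int = 2,
) -> Optional[list[str]]:
    """The simple PPI path (2..L edges, >= 1 intermediate) between two genes
    whose intermediates all carry data, maximizing mean normalized
    connectivity; ties break lexicographically. None when no such path."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if gene_i not in ppi or gene_j not in ppi:
        return None
    best: Optional[tuple[float, tuple[str, ...]]] = None
    for path in nx.all_simple_paths(ppi.graph, gene_i, gene_j, cutoff=L):
        if len(path) < 3:
            continue  # a bare edge has no intermediate chain to score
        if any(g not in data_genes for g in path[1:-1]):
            continue
        score = path_connectivity_score(path, ppi)
        cand = (score, tuple(path))
        if best is None or score > best[0] or (score == best[0] and cand[1] < best[1]):
            best = cand
    return list(best[1]) if best else None


def indirect_significance(
    path: list[str],
    maxrel_lookup: Callable[[str, str], Optional[float]],
    ppi: PPIGraph,
    data_genes: set[str],
    n_random: int,
    rng: np.random.Generator,
    L: Optional[int] = None,
) -> tuple[float, float]:
    """Observed geometric-mean statistic of a path and its empirical p.

    The null re-runs the path search between the path's endpoints in each of
    `n_random` node-label permutations of the PPI graph (topology conserved)
    and scores the resulting best path with the observed MaxRel values of its
    labels; p uses the (+1)/(n+1) pseudo-count convention. Replicates with no
    admissible path contribute a null statistic of 0.
    """
    if len(path) < 3:
        raise ValueError("path must contain at least one intermediate gene")
    vals = [maxrel_lookup(a, b) for a, b in zip(path[:-1], path[1:])]
    if any(v is None for v in vals):
        raise ValueError("path rejected: a consecutive pair has no MaxRel")
    observed = geometric_mean(vals)
    if L is None:
        L = len(path) - 1
    gi, gj = path[0], path[-1]
    nodes = list(ppi.nodes)
    n_ge = 0
    for _ in range(n_random):
        perm = rng.permutation(len(nodes))
        mapping = {nodes[k]: nodes[perm[k]] for k in range(len(nodes))}
        g_perm = PPIGraph(nx.relabel_nodes(ppi.graph, mapping, copy=True))
        p_rand = best_path(gi, gj, g_perm, data_genes, L)
        stat = 0.0
        if p_rand is not None:
            vals_r = [maxrel_lookup(a, b) for a, b in zip(p_rand[:-1], p_rand[1:])]
            if all(v is not None for v in vals_r):
                stat = geometric_mean(vals_r)
        if stat >= observed:
            n_ge += 1
    p = (n_ge + 1) / (n_random + 1)
    return observed, p


def _indirect_pass_l2(
    net: RelationshipNetwork,
    data: OmicsDataset,
    ppi: PPIGraph,
    config: PipelineConfig,
    rng: np.random.Generator,
) -> int:
    """Vectorised indirect search for the default path length limit L = 2,
    where every admissible path is endpoint-intermediate-endpoint and the
    best path maximizes the intermediate's normalized connectivity."""
    seed_genes = sorted(net.seed_genes.genes)
    if config.strict_seed_paths:
        data_genes = set(seed_genes)
    else:
        data_genes = {g for g in ppi.nodes if data.has_ge(g) or data.has_cna(g)}
    labels = sorted(set(seed_genes) | data_genes)
    labels = [g for g in labels if g in ppi]
    if not labels:
        return 0
    li = {g: k for k, g in enumerate(labels)}
    m_lab = len(labels)

    mrel, _, _ = maxrel_matrix(labels, data)  # NaN where unavailable

    full_nodes = list(ppi.nodes)
    n_full = len(full_nodes)
    a_full = nx.to_scipy_sparse_array(ppi.graph, nodelist=full_nodes, dtype=bool, format="csr")
    fpos = {g: k for k, g in enumerate(full_nodes)}
    full_idx = np.array([fpos[g] for g in labels], dtype=int)
    deg_full = np.array([ppi.degree[g] for g in full_nodes], dtype=float)
    maxdeg = ppi.max_degree or 1

    allowed = np.array([g in data_genes for g in labels])

    # candidate pairs: seed pairs absent from R, both endpoints in the PPI
    cand = []
    for ai, a in enumerate(seed_genes):
        if a not in li:
            continue
        for b in seed_genes[ai + 1:]:
            if b in li and (a, b) not in net:
                cand.append((li[a], li[b]))
    if not cand:
        return 0
    I = np.array([c[0] for c in cand])
    J = np.array([c[1] for c in cand])
    n_pairs = len(cand)

    def best_stats(sub_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """For each candidate pair, the statistic of the best 2-edge path in
        the permuted network whose labels sit at positions sub_idx."""
        a_sub = a_full[sub_idx][:, sub_idx].toarray()
        np.fill_diagonal(a_sub, False)
        nc = deg_full[sub_idx] / maxdeg
        order = sorted(range(m_lab), key=lambda k: (-nc[k], labels[k]))
        order = np.array(order)
        a_ord = a_sub[:, order] & allowed[order][None, :]
        common = a_ord[I] & a_ord[J]
        kpos = np.argmax(common, axis=1)
        has = common[np.arange(n_pairs), kpos]
        k = order[kpos]
        with np.errstate(invalid="ignore"):
            stat = np.sqrt(mrel[I, k] * mrel[k, J])
        stat = np.where(has & ~np.isnan(stat), stat, np.where(has, np.nan, 0.0))
        # has & nan -> path exists but chain undefined: statistic undefined
        return stat, k

    obs_stat, obs_k = best_stats(full_idx)
    valid = ~np.isnan(obs_stat) & (obs_stat > 0.0)

    n_ge = np.zeros(n_pairs)
    for _ in range(config.n_random_ppi):
        perm = rng.permutation(n_full)
        stat_r, _ = best_stats(perm[full_idx])
        stat_r = np.nan_to_num(stat_r, nan=0.0)
        n_ge += stat_r >= obs_stat
    pvals = (n_ge + 1) / (config.n_random_ppi + 1)

    n_added = 0
    for t in np.where(valid & (pvals <= config.path_alpha))[0]:
        a, b = labels[I[t]], labels[J[t]]
        mid = labels[int(obs_k[t])]
        weight = float(obs_stat[t])
        if config.indirect_weight == "maxrel":
            w_alt = mrel[I[t], J[t]]
            weight = float(w_alt) if not np.isnan(w_alt) else weight
        lo, hi = (a, b) if a < b else (b, a)
        path = (a, mid, b) if a < b else (b, mid, a)
        net.relationships[(lo, hi)] = Relationship(
            lo, hi, min(weight, 1.0), "indirect", path=path, path_p=float(pvals[t])
        )
        n_added += 1
    return n_added


def build_ggr(
    seed: SeedGeneSet,
    data: OmicsDataset,
    ppi: PPIGraph,
    config: PipelineConfig,
    rng: Optional[np.random.Generator] = None,
) -> RelationshipNetwork:
    """Direct pass then indirect pass over the remaining pairs."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    net = build_direct(seed, data, config.top_fraction_direct)
    n_direct = len(net)
    total = pair_count(len(seed.genes))
    remainder = total - n_direct

    if config.path_length_limit == 2:
        n_indirect = _indirect_pass_l2(net, data, ppi, config, rng)
    else:
        n_indirect = _indirect_pass_generic(net, data, ppi, config, rng)
    log.info(
        "GGR: %d direct (%.2f%% of %d pairs), %d indirect (%.2f%% of remainder)",
        n_direct,
        100.0 * n_direct / total if total else 0.0,
        total,
        n_indirect,
        100.0 * n_indirect / remainder if remainder else 0.0,
    )
    return net


def _indirect_pass_generic(
    net: RelationshipNetwork,
    data: OmicsDataset,
    ppi: PPIGraph,
    config: PipelineConfig,
    rng: np.random.Generator,
) -> int:
    """Reference-path for L != 2: explicit simple-path enumeration per pair."""
    seed_genes = sorted(net.seed_genes.genes)
    if config.strict_seed_paths:
        data_genes = set(seed_genes)
    else:
        data_genes = {g for g in ppi.nodes if data.has_ge(g) or data.has_cna(g)}
    labels = sorted({g for g in set(seed_genes) | data_genes if g in ppi})
    mrel, _, _ = maxrel_matrix(labels, data)
    li = {g: k for k, g in enumerate(labels)}

    def lookup(a: str, b: str) -> Optional[float]:
        v = mrel[li[a], li[b]]
        return None if np.isnan(v) else float(v)

    n_added = 0
    for ai, a in enumerate(seed_genes):
        for b in seed_genes[ai + 1:]:
            if (a, b) in net or a not in ppi or b not in ppi:
                continue
            path = best_path(a, b, ppi, data_genes, config.path_length_limit)
            if path is None:
                continue
            try:
                obs, p = indirect_significance(
                    path, lookup, ppi, data_genes, config.n_random_ppi, rng,
                    L=config.path_length_limit,
                )
            except ValueError:
                continue
            if p <= config.path_alpha and obs > 0:
                lo, hi = (a, b) if a < b else (b, a)
                weight = obs
                if config.indirect_weight == "maxrel" and lookup(a, b) is not None:
                    weight = lookup(a, b)
                net.relationships[(lo, hi)] = Relationship(
                    lo, hi, min(weight, 1.0), "indirect",
                    path=tuple(path if a < b else reversed(path)), path_p=p,
                )
                n_added += 1
    return n_added
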