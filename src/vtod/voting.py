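"""Pairwise votes, representative selection, and pre-module formation.

The vote from gene i to gene j combines the pair's data-driven relationship
value with j's normalized PPI connectivity damped by the shortest-path
length:

    vote(i -> j) = Rel(i, j) + NC(j) / SPL(i, j)   when 1 <= SPL <= Lmax
    vote(i -> j) = Rel(i, j)                        otherwise

Both terms lie in [0, 1], so every vote lies in [0, 2]. Votes are asymmetric
(the topological term uses the receiver's connectivity): hub genes are
preferentially chosen as representatives, but only by genes close to them in
the PPI graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .datatypes import GeneLocation, PPIGraph
from .ggr import RelationshipNetwork

log = logging.getLogger(__name__)


@dataclass
class VoteStore:
    """All ordered-pair votes over a fixed gene order, with the SPL matrix."""

    genes: list[str]
    matrix: np.ndarray  # votes, diag 0
    spl: np.ndarray  # shortest PPI path lengths (inf when absent/beyond cutoff)

    def __post_init__(self):
        self._index = {g: i for i, g in enumerate(self.genes)}

    def vote(self, gene_i: str, gene_j: str) -> float:
        return float(self.matrix[self._index[gene_i], self._index[gene_j]])

    @property
    def votes(self) -> dict[tuple[str, str], float]:
        out = {}
        for i, gi in enumerate(self.genes):
            for j, gj in enumerate(self.genes):
                if i != j:
                    out[(gi, gj)] = float(self.matrix[i, j])
        return out


@dataclass
class PreModule:
    representative: str
    members: frozenset
    voters: frozenset

    def __post_init__(self):
        if self.representative not in self.members:
            raise ValueError("representative must be a member")
        if self.members != self.voters | {self.representative}:
            raise ValueError("members must equal voters plus the representative")


def vote_matrix_from(
    rel_matrix: np.ndarray, nc: np.ndarray, spl: np.ndarray, Lmax: int
) -> np.ndarray:
    """Array form of the vote: Rel + NC(receiver)/SPL within the SPL cutoff."""
    with np.errstate(divide="ignore"):
        topo = np.where((spl >= 1) & (spl <= Lmax), nc[None, :] / spl, 0.0)
    v = rel_matrix + topo
    np.fill_diagonal(v, 0.0)
    return v


def compute_votes(
    rel: RelationshipNetwork, ppi: PPIGraph, Lmax: int = 2,
    genes: Optional[list[str]] = None,
) -> VoteStore:
    if genes is None:
        genes = sorted(rel.seed_genes.genes)
    spl = ppi.spl_matrix(genes, cutoff=Lmax)
    nc = np.array([ppi.normalized_connectivity(g) for g in genes])
    v = vote_matrix_from(rel.weight_matrix(genes), nc, spl, Lmax)
    return VoteStore(genes, v, spl)


def vote_value(
    gene_i: str, gene_j: str, rel: RelationshipNetwork, ppi: PPIGraph, Lmax: int = 2
) -> float:
    """Scalar vote from i to j (Rel = 0 when the pair is not in the network)."""
    if gene_i == gene_j:
        raise ValueError("vote is defined for distinct genes")
    v = rel.weight(gene_i, gene_j)
    if gene_i in ppi and gene_j in ppi:
        import networkx as nx

        try:
            spl = nx.shortest_path_length(ppi.graph, gene_i, gene_j)
        except nx.NetworkXNoPath:
            spl = np.inf
        if 1 <= spl <= Lmax:
            v += ppi.normalized_connectivity(gene_j) / spl
    return float(v)


def _representatives_from_matrix(
    genes: list[str], v: np.ndarray, P: int, q_percent: float,
    local_rank_mode: str = "top_p",
) -> dict[str, set[str]]:
    n = len(genes)
    if n < 2:
        return {}
    if not v.any():
        log.warning("all votes are zero; no representatives selected")
        return {}
    # global cutoff: value of the floor(q * N / 100)-th largest vote over all
    # ordered pairs; ties at the cutoff are admitted (>=). floor, not ceil,
    # so that a vanishing q admits nobody
    n_ordered = n * (n - 1)
    k_global = int(np.floor(q_percent / 100.0 * n_ordered))
    if k_global < 1:
        log.warning("global vote budget is zero at q=%g%%", q_percent)
        return {}
    offdiag = v[~np.eye(n, dtype=bool)]
    global_cutoff = np.partition(offdiag, offdiag.size - k_global)[offdiag.size - k_global]

    out: dict[str, set[str]] = {}
    for i in range(n):
        row = v[i].copy()
        row[i] = -np.inf
        if local_rank_mode == "cumulative":
            # alternative reading: candidates within the top-P cumulative vote
            # mass, in descending vote order
            order = np.argsort(-row)
            csum = np.cumsum(np.where(np.isfinite(row[order]), row[order], 0.0))
            local_ok = np.zeros(n, dtype=bool)
            local_ok[order[csum <= P]] = True
            if n > 1:  # the top vote always qualifies
                local_ok[order[0]] = True
        else:
            kth = np.partition(row, n - 1 - (min(P, n - 1) - 1))[n - 1 - (min(P, n - 1) - 1)]
            local_ok = row >= kth
        sel = local_ok & (row >= global_cutoff) & (row > 0)
        if sel.any():
            out[genes[i]] = {genes[j] for j in np.where(sel)[0]}
    return out


def select_representatives(
    votes: VoteStore, P: int = 1, q_percent: float = 0.1,
    local_rank_mode: str = "top_p",
) -> dict[str, set[str]]:
    """Representative set R_i per gene i.

    j is in R_i iff vote(i -> j) is (i) among the top-P votes cast by i and
    (ii) within the top q% of all ordered-pair votes. Zero votes never select
    a representative.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    if not (0.0 < q_percent <= 100.0):
        raise ValueError("q_percent must be in (0, 100]")
    return _representatives_from_matrix(
        votes.genes, votes.matrix, P, q_percent, local_rank_mode
    )


def form_premodules(
    rep_map: Mapping[str, set[str]],
    locations: Mapping[str, GeneLocation],
) -> list[PreModule]:
    """One pre-module per representative (itself plus its voters), then:
    (a) drop any pre-module whose member set is a subset of another's,
    (b) drop two-gene pre-modules,
    (c) drop pre-modules whose non-representative members all share one
        focal aberrant region (a positional artifact, not a pathway).
    """
    voters_of: dict[str, set[str]] = {}
    for voter, reps in rep_map.items():
        for r in reps:
            voters_of.setdefault(r, set()).add(voter)
    pre = [
        PreModule(r, frozenset(vs | {r}), frozenset(vs - {r}))
        for r, vs in sorted(voters_of.items())
    ]
    # (a) subset removal; identical member sets keep the lexicographically
    # smallest representative
    keep = []
    for pm in pre:
        redundant = False
        for other in pre:
            if other is pm:
                continue
            if pm.members < other.members:
                redundant = True
                break
            if pm.members == other.members and other.representative < pm.representative:
                redundant = True
                break
        if not redundant:
            keep.append(pm)
    # (b) two-gene pre-modules
    keep = [pm for pm in keep if len(pm.members) > 2]
    # (c) single-focal-region pre-modules
    out = []
    for pm in keep:
        others = pm.members - {pm.representative}
        fids = {
            locations[g].focal_region_id if g in locations else None for g in others
        }
        if len(fids) == 1 and None not in fids:
            continue
        out.append(pm)
    return out
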