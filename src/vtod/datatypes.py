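"""Domain containers for the module-detection pipeline.

Matrices are held fully in memory (seed-gene spaces are a few thousand genes
at most), gene order is preserved from the input files, and every container
validates its own invariants at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np


def _check_unique(items, what: str) -> None:
    seen = set()
    for it in items:
        if it in seen:
            raise ValueError(f"duplicate {what}: {it!r}")
        seen.add(it)


class ExpressionMatrix:
    """Log-scale expression, genes x samples, with symbol/sample indices."""

    def __init__(self, genes: list[str], samples: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        _check_unique(genes, "gene symbol")
        _check_unique(samples, "sample identifier")
        if values.shape != (len(genes), len(samples)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        self.genes = list(genes)
        self.samples = list(samples)
        self.values = values
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def row(self, gene: str) -> np.ndarray:
        return self.values[self._index[gene]]

    def subset(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self._index]
        idx = [self._index[g] for g in genes]
        return ExpressionMatrix(genes, self.samples, self.values[idx])

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


class CNAMatrix(ExpressionMatrix):
    """Gene-level copy-number values; imputed cells are tracked in a mask.

    After loading no missing values remain and sex-chromosome genes are
    expected to have been excluded upstream.
    """

    def __init__(self, genes, samples, values, imputed_mask: Optional[np.ndarray] = None):
        super().__init__(genes, samples, values)
        if imputed_mask is None:
            imputed_mask = np.zeros(self.values.shape, dtype=bool)
        imputed_mask = np.asarray(imputed_mask, dtype=bool)
        if imputed_mask.shape != self.values.shape:
            raise ValueError("imputed_mask shape mismatch")
        if np.isnan(self.values).any():
            raise ValueError("CNA matrix still contains missing values after load")
        self.imputed_mask = imputed_mask

    def subset(self, genes: Iterable[str]) -> "CNAMatrix":
        genes = [g for g in genes if g in self._index]
        idx = [self._index[g] for g in genes]
        return CNAMatrix(genes, self.samples, self.values[idx], self.imputed_mask[idx])


@dataclass(frozen=True)
class GeneLocation:
    """Chromosomal placement of one gene: cytoband and optional focal region."""

    gene: str
    chromosome: str
    cytoband: Optional[str] = None
    focal_region_id: Optional[str] = None

    def __post_init__(self):
        if self.cytoband is not None:
            prefix = self.chromosome.removeprefix("chr")
            if not self.cytoband.startswith(prefix):
                raise ValueError(
                    f"cytoband {self.cytoband!r} does not begin with the "
                    f"chromosome band prefix {prefix!r}"
                )


def co_located(a: Optional[GeneLocation], b: Optional[GeneLocation]) -> bool:
    """True when two genes share a focal aberrant region or a cytoband.

    Such pairs are excluded from CNA-CNA pairing: proximal genes are amplified
    or deleted together, so their copy-number correlation is positional, not
    functional.
    """
    if a is None or b is None:
        return False
    if (
        a.focal_region_id is not None
        and b.focal_region_id is not None
        and a.focal_region_id == b.focal_region_id
    ):
        return True
    if (
        a.cytoband is not None
        and b.cytoband is not None
        and a.chromosome == b.chromosome
        and a.cytoband == b.cytoband
    ):
        return True
    return False


class PPIGraph:
    """Undirected protein-interaction graph (no self-loops, no multi-edges)."""

    def __init__(self, graph: nx.Graph):
        if any(u == v for u, v in graph.edges):
            raise ValueError("PPI graph contains self-loops")
        self.graph = graph
        self.degree = dict(graph.degree())
        self.max_degree = max(self.degree.values()) if self.degree else 0
        self._nodes = list(graph.nodes)
        self._node_index = {n: i for i, n in enumerate(self._nodes)}

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "PPIGraph":
        g = nx.Graph()
        g.add_edges_from((u, v) for u, v in edges if u != v)
        return cls(g)

    @property
    def nodes(self) -> list[str]:
        return self._nodes

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self._node_index

    def normalized_connectivity(self, gene: str) -> float:
        """degree(gene) / max_degree; 0 for genes absent from the graph."""
        if gene not in self._node_index or self.max_degree == 0:
            return 0.0
        return self.degree[gene] / self.max_degree

    def adjacency_for(self, genes: list[str]) -> np.ndarray:
        """Dense boolean adjacency among the given gene labels.

        Genes absent from the graph get all-False rows/columns.
        """
        n = len(genes)
        a = np.zeros((n, n), dtype=bool)
        pos = {g: i for i, g in enumerate(genes)}
        for i, g in enumerate(genes):
            if g not in self._node_index:
                continue
            for nb in self.graph.adj[g]:
                j = pos.get(nb)
                if j is not None:
                    a[i, j] = True
        return a

    def spl_matrix(self, genes: list[str], cutoff: int) -> np.ndarray:
        """Pairwise shortest-path lengths up to `cutoff`; inf beyond/absent."""
        n = len(genes)
        spl = np.full((n, n), np.inf)
        pos = {g: i for i, g in enumerate(genes)}
        for i, g in enumerate(genes):
            if g not in self._node_index:
                continue
            lengths = nx.single_source_shortest_path_length(self.graph, g, cutoff=cutoff)
            for nb, d in lengths.items():
                j = pos.get(nb)
                if j is not None and d >= 1:
                    spl[i, j] = d
        return spl


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. one GMT file) with a free-text source note."""

    name: str
    sets: dict[str, set[str]]
    source: str = ""

    def __post_init__(self):
        for sname, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {sname!r} is empty")

    def universe(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return out

    def filtered(self, min_size: int, max_size: int) -> "GeneSetCollection":
        """Boundary-inclusive size filter (min_size <= |set| <= max_size)."""
        kept = {
            n: s for n, s in self.sets.items() if min_size <= len(s) <= max_size
        }
        return GeneSetCollection(self.name, kept, self.source)


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline.

    Defaults follow the published analysis: Bonferroni alpha 0.05 for DE
    selection, per-type top-10% correlation thresholds, path length limit 2
    with 50 randomized networks at alpha 0.05 for indirect relationships,
    local rank 1 and global top-0.1% for representatives, and 100 relationship
    shuffles at alpha 0.05 for the merge threshold delta.
    """

    de_alpha: float = 0.05
    top_fraction_direct: float = 0.10
    path_length_limit: int = 2
    n_random_ppi: int = 50
    path_alpha: float = 0.05
    vote_spl_limit: int = 2
    local_rank_limit: int = 1
    global_top_percent: float = 0.1
    n_random_merge: int = 100
    merge_alpha: float = 0.05
    expr_change_top_fraction: float = 0.10
    go_min_size: int = 5
    go_max_size: int = 250
    enrichment_fdr: float = 0.05
    rng_seed: int = 0
    # behaviour switches for genuinely under-specified details
    indirect_weight: str = "geometric_mean"  # or "maxrel"
    local_rank_mode: str = "top_p"  # or "cumulative"
    strict_seed_paths: bool = False
    ic_mode: str = "smaller"  # or "symmetric_max"

    def __post_init__(self):
        for name in ("top_fraction_direct", "expr_change_top_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not (0.0 < self.global_top_percent <= 100.0):
            raise ValueError("global_top_percent must be in (0, 100]")
        if self.path_length_limit < 1 or self.vote_spl_limit < 1:
            raise ValueError("path length limits must be >= 1")
        if self.local_rank_limit < 1:
            raise ValueError("local_rank_limit must be >= 1")
        for name in ("de_alpha", "path_alpha", "merge_alpha", "enrichment_fdr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")


@dataclass
class OmicsDataset:
    """Aligned tumor expression / control expression / CNA matrices plus
    gene locations — the raw material for pairwise relationships."""

    expr: ExpressionMatrix
    controls: ExpressionMatrix
    cna: Optional[CNAMatrix] = None
    locations: Mapping[str, GeneLocation] = field(default_factory=dict)

    def has_ge(self, gene: str) -> bool:
        return gene in self.expr

    def has_cna(self, gene: str) -> bool:
        return self.cna is not None and gene in self.cna

    def location(self, gene: str) -> Optional[GeneLocation]:
        return self.locations.get(gene)
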