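"""Hypergeometric over-representation of modules with BH-FDR correction,
construction of the cancer-related pathway subset, and per-module
relationship-type profiles.

FDR is corrected within each (module x collection) family by default: the
corrected q depends on the number of comparisons, so a module can be enriched
for a pathway under the cancer-related subset but not under the full
collection, and vice versa.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetCollection
from .ggr import DIRECT_KINDS, RelationshipNetwork
from ._utils import pair_count

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    module_id: str
    collection: str
    set_name: str
    overlap_count: int
    module_size: int
    set_size: int
    universe_size: int
    p: float
    q: float
    overlap_genes: frozenset

    def __post_init__(self):
        if self.overlap_count > min(self.module_size, self.set_size):
            raise ValueError("overlap larger than either set")
        if self.q < self.p - 1e-12:
            raise ValueError("q must be >= p")


@dataclass
class ModuleProfile:
    module_id: str
    size: int
    n_ge_ge: int
    n_cna_ge: int
    n_cna_cna: int
    cgc_p: float = 1.0

    @property
    def n_relationship_types(self) -> int:
        return sum(1 for n in (self.n_ge_ge, self.n_cna_ge, self.n_cna_cna) if n > 0)

    def fraction(self, kind: str) -> float:
        n = {"GE-GE": self.n_ge_ge, "CNA-GE": self.n_cna_ge, "CNA-CNA": self.n_cna_cna}[kind]
        total = pair_count(self.size)
        return n / total if total else 0.0


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    k: overlap, K: gene-set size, n: module size, N: universe size.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(K, n, N) < 0:
        raise ValueError(f"impossible configuration k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fdr_correct(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def cancer_related_subset(
    collection: GeneSetCollection,
    cancer_genes: set[str],
    fdr: float = 0.05,
    universe: Optional[set[str]] = None,
) -> GeneSetCollection:
    """Sets significantly enriched with cancer genes (hypergeometric + BH FDR
    across the collection's sets) define the cancer-related subset."""
    if not collection.sets or not cancer_genes:
        raise ValueError("collection and cancer gene list must be non-empty")
    if universe is None:
        universe = collection.universe() | cancer_genes
    names = sorted(collection.sets)
    cg = cancer_genes & universe
    ps = []
    for name in names:
        s = collection.sets[name] & universe
        k = len(s & cg)
        ps.append(hypergeom_p(k, len(cg), len(s), len(universe)) if s else 1.0)
    qs = fdr_correct(ps)
    kept = {n: collection.sets[n] for n, q in zip(names, qs) if q <= fdr}
    return GeneSetCollection(
        f"{collection.name}_cancer_related", kept, source=collection.source
    )


def enrich_modules(
    modules: Sequence,
    collections: Iterable[GeneSetCollection],
    universe: set[str],
    fdr: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric test of every (module, set) pair with k >= 1, FDR
    corrected within each (module x collection) family."""
    results: list[EnrichmentResult] = []
    for mid, mod in enumerate(modules, start=1):
        members = set(mod.members) & universe
        for coll in collections:
            fam: list[tuple[str, int, int, frozenset, float]] = []
            for sname in sorted(coll.sets):
                s = coll.sets[sname] & universe
                if not s:
                    continue
                overlap = members & s
                if not overlap:
                    continue
                p = hypergeom_p(len(overlap), len(s), len(members), len(universe))
                fam.append((sname, len(overlap), len(s), frozenset(overlap), p))
            qs = fdr_correct([f[4] for f in fam])
            for (sname, k, ssize, ogenes, p), q in zip(fam, qs):
                results.append(
                    EnrichmentResult(
                        module_id=f"M{mid}",
                        collection=coll.name,
                        set_name=sname,
                        overlap_count=k,
                        module_size=len(members),
                        set_size=ssize,
                        universe_size=len(universe),
                        p=p,
                        q=float(q),
                        overlap_genes=ogenes,
                    )
                )
    return results


def module_enrichment_summary(
    results: Sequence[EnrichmentResult], modules: Sequence, fdr: float = 0.05
) -> dict:
    """Per-module enrichment flags per collection and the count of distinct
    enriched sets across all modules."""
    flags: dict[str, dict[str, bool]] = {f"M{i}": {} for i in range(1, len(modules) + 1)}
    distinct: set[tuple[str, str]] = set()
    for r in results:
        if r.q <= fdr:
            flags[r.module_id][r.collection] = True
            distinct.add((r.collection, r.set_name))
    return {
        "per_module": flags,
        "n_distinct_enriched_sets": len(distinct),
        "n_enriched_modules": {
            coll: sum(1 for m in flags.values() if m.get(coll))
            for coll in {r.collection for r in results}
        },
    }


def profile_modules(
    modules: Sequence,
    rel: RelationshipNetwork,
    cancer_genes: Optional[set[str]] = None,
    universe: Optional[set[str]] = None,
) -> tuple[list[ModuleProfile], dict[str, Optional[float]]]:
    """Per-module counts of each direct-relationship type among member pairs
    (one pair can exceed several per-type thresholds), CGC enrichment p, and
    the Pearson correlations of the number of relationship types with
    -log10(CGC p) and with module size."""
    profiles = []
    for mid, mod in enumerate(modules, start=1):
        members = set(mod.members)
        counts = {}
        for kind in DIRECT_KINDS:
            counts[kind] = sum(
                1 for (a, b) in rel.per_type_pairs.get(kind, ())
                if a in members and b in members
            )
        cgc_p = 1.0
        if cancer_genes:
            uni = universe if universe is not None else set(rel.seed_genes.genes) | cancer_genes
            mem_u = members & uni
            cg = cancer_genes & uni
            if mem_u and cg:
                cgc_p = hypergeom_p(len(mem_u & cg), len(cg), len(mem_u), len(uni))
        profiles.append(
            ModuleProfile(
                module_id=f"M{mid}",
                size=len(members),
                n_ge_ge=counts["GE-GE"],
                n_cna_ge=counts["CNA-GE"],
                n_cna_cna=counts["CNA-CNA"],
                cgc_p=cgc_p,
            )
        )
    corrs: dict[str, Optional[float]] = {"cgc": None, "size": None}
    if len(profiles) >= 3:
        ntypes = np.array([p.n_relationship_types for p in profiles], dtype=float)
        neglog = np.array([-math.log10(max(p.cgc_p, 1e-300)) for p in profiles])
        sizes = np.array([p.size for p in profiles], dtype=float)
        if ntypes.std() > 0 and neglog.std() > 0:
            corrs["cgc"] = float(np.corrcoef(ntypes, neglog)[0, 1])
        if ntypes.std() > 0 and sizes.std() > 0:
            corrs["size"] = float(np.corrcoef(ntypes, sizes)[0, 1])
    return profiles, corrs
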