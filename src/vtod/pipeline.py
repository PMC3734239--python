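"""End-to-end orchestration: load -> seeds -> GGR -> votes -> pre-modules ->
delta calibration -> merging -> enrichment, with a run manifest.

Randomized stages draw from independent child generators derived from the
single configured seed, so re-running any stage alone is stable. The
expensive GGR build is cached in the output directory keyed by input digests
plus the relevant config subset.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from numpy.random import SeedSequence, default_rng

from . import io as vio
from ._utils import pair_count
from .datatypes import GeneSetCollection, OmicsDataset, PipelineConfig
from .enrichment import (
    cancer_related_subset,
    enrich_modules,
    module_enrichment_summary,
    profile_modules,
)
from .ggr import RelationshipNetwork, Relationship, build_ggr
from .merging import Module, MergeTrace, merge_premodules, module_overlap_stats, select_delta
from .seeds import build_seed_set, select_de_genes
from .voting import compute_votes, form_premodules, select_representatives

log = logging.getLogger(__name__)


@dataclass
class InputPaths:
    expression: Path
    controls: Path
    cna: Path
    ppi: Path
    cytoband: Path
    focal: Path
    gene_coords: Path
    sa_genes: Path
    gene_sets: Sequence[Path] = ()
    cancer_genes: Sequence[Path] = ()

    @classmethod
    def from_dir(cls, d, **overrides) -> "InputPaths":
        d = Path(d)
        kw = dict(
            expression=d / "expression.tsv",
            controls=d / "controls.tsv",
            cna=d / "cna.tsv",
            ppi=d / "ppi.tsv",
            cytoband=d / "cytoband.txt",
            focal=d / "focal_regions.bed",
            gene_coords=d / "gene_coords.tsv",
            sa_genes=d / "sa_genes.txt",
            gene_sets=(d / "gene_sets.gmt",) if (d / "gene_sets.gmt").exists() else (),
            cancer_genes=(d / "cancer_genes.txt",) if (d / "cancer_genes.txt").exists() else (),
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class RunResult:
    seed_genes: list[str]
    network: RelationshipNetwork
    premodules: list
    delta: Optional[float]
    trace: MergeTrace
    modules: list[Module]
    manifest: dict
    enrichment: list = field(default_factory=list)
    profiles: list = field(default_factory=list)
    profile_correlations: dict = field(default_factory=dict)


def _digest(*paths) -> str:
    h = hashlib.sha256()
    for p in paths:
        h.update(Path(p).read_bytes())
    return h.hexdigest()[:16]


def _cache_ggr(net: RelationshipNetwork, path: Path) -> None:
    rows = []
    for (a, b), r in sorted(net.relationships.items()):
        rows.append([a, b, r.weight, r.kind, list(r.path) if r.path else None, r.path_p])
    payload = {
        "thresholds": net.thresholds,
        "relationships": rows,
        "per_type_pairs": {k: sorted(map(list, v)) for k, v in net.per_type_pairs.items()},
    }
    path.write_text(json.dumps(payload))


def _load_cached_ggr(path: Path, seed_set) -> RelationshipNetwork:
    payload = json.loads(path.read_text())
    net = RelationshipNetwork(seed_set, payload["thresholds"])
    for a, b, w, kind, p, pp in payload["relationships"]:
        net.relationships[(a, b)] = Relationship(
            a, b, w, kind, path=tuple(p) if p else None, path_p=pp
        )
    net.per_type_pairs = {
        k: {tuple(x) for x in v} for k, v in payload["per_type_pairs"].items()
    }
    return net


def run(config: PipelineConfig, inputs: InputPaths, out_dir) -> RunResult:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_ggr, rng_delta = (
        default_rng(s) for s in SeedSequence(config.rng_seed).spawn(2)
    )

    # ---- load ----
    expr = vio.read_matrix(inputs.expression, "expression")
    controls = vio.read_matrix(inputs.controls, "expression")
    cna = vio.read_matrix(inputs.cna, "cna") if Path(inputs.cna).exists() else None
    ppi = vio.read_ppi(inputs.ppi)
    coords = vio.read_gene_coords(inputs.gene_coords)
    locations = vio.read_locations(inputs.cytoband, inputs.focal, coords)
    sa = vio.read_gene_list(inputs.sa_genes) if Path(inputs.sa_genes).exists() else set()

    # ---- seeds ----
    de_results = select_de_genes(expr, controls, config.de_alpha)
    de = {r.gene for r in de_results if r.is_de}
    seed = build_seed_set(
        de, sa, set(expr.genes), set(cna.genes) if cna else set()
    )
    data = OmicsDataset(expr=expr, controls=controls, cna=cna, locations=locations)

    # ---- GGR (cached on input digests + relevant config) ----
    key_cfg = (
        config.top_fraction_direct, config.path_length_limit, config.n_random_ppi,
        config.path_alpha, config.de_alpha, config.rng_seed,
        config.indirect_weight, config.strict_seed_paths,
    )
    cache_key = _digest(inputs.expression, inputs.controls, inputs.cna, inputs.ppi)
    cache_key = hashlib.sha256((cache_key + repr(key_cfg)).encode()).hexdigest()[:16]
    cache_path = out / f"ggr_cache_{cache_key}.json"
    if cache_path.exists():
        net = _load_cached_ggr(cache_path, seed)
        log.info("loaded cached GGR (%d relationships)", len(net))
    else:
        net = build_ggr(seed, data, ppi, config, rng_ggr)
        _cache_ggr(net, cache_path)

    # ---- votes -> representatives -> pre-modules ----
    votes = compute_votes(net, ppi, config.vote_spl_limit)
    rep_map = select_representatives(
        votes, config.local_rank_limit, config.global_top_percent,
        config.local_rank_mode,
    )
    premodules = form_premodules(rep_map, locations)

    # ---- delta calibration and merging ----
    if len(premodules) >= 2:
        delta, trace = select_delta(
            premodules, net, ppi, config.n_random_merge, config.merge_alpha,
            rng_delta, config=config, locations=locations,
        )
    else:
        delta, trace = None, MergeTrace()
    if delta is None:
        # no merge step clears the null: the pre-modules fail the calibration
        modules: list[Module] = []
    else:
        modules, _ = merge_premodules(premodules, net, ppi, delta, config.ic_mode)

    # ---- evaluation ----
    cancer_genes: set[str] = set()
    for p in inputs.cancer_genes:
        cancer_genes |= vio.read_gene_list(p)
    collections = [
        vio.read_gmt(p, config.go_min_size, config.go_max_size)
        for p in inputs.gene_sets
    ]
    universe = set(seed.genes)
    for coll in collections:
        universe |= coll.universe()
    enr = enrich_modules(modules, collections, universe, config.enrichment_fdr) if modules else []
    summary = module_enrichment_summary(enr, modules, config.enrichment_fdr) if modules else {}
    profiles, corrs = profile_modules(modules, net, cancer_genes or None, universe) if modules else ([], {})
    if collections and cancer_genes:
        for coll in collections:
            subset = cancer_related_subset(coll, cancer_genes, config.enrichment_fdr)
            if subset.sets:
                vio.write_gmt(subset, out / f"{coll.name}_cancer_related.gmt")

    # ---- outputs + manifest ----
    n_seed = len(seed.genes)
    total_pairs = pair_count(n_seed)
    n_direct = sum(1 for r in net.relationships.values() if r.kind != "indirect")
    n_indirect = len(net) - n_direct
    remainder = total_pairs - n_direct
    manifest = {
        "config": {k: v for k, v in vars(config).items()},
        "input_digest": cache_key,
        "n_seed_genes": n_seed,
        "n_de_genes": len(de),
        "n_sa_genes": len(sa & set(seed.genes)),
        "n_seed_pairs": total_pairs,
        "n_direct": n_direct,
        "direct_fraction": round(n_direct / total_pairs, 6) if total_pairs else 0.0,
        "n_indirect": n_indirect,
        "indirect_fraction": round(n_indirect / remainder, 6) if remainder else 0.0,
        "thresholds": net.thresholds,
        "n_premodules": len(premodules),
        "delta": delta,
        "n_modules": len(modules),
        "mean_overlap_ratio": (
            module_overlap_stats(modules)[0] if len(modules) >= 2 else None
        ),
        "rng_seed": config.rng_seed,
    }
    vio.write_relationships_tsv(net, out / "relationships.tsv")
    vio.write_gmt(
        {f"PM{i + 1}": set(pm.members) for i, pm in enumerate(premodules)},
        out / "premodules.gmt",
    )
    vio.write_gmt(
        {f"M{i + 1}": set(m.members) for i, m in enumerate(modules)},
        out / "modules.gmt",
    )
    vio.write_modules_tsv(modules, out / "modules.tsv")
    if enr:
        vio.write_enrichment_tsv(enr, out / "enrichment.tsv")
    with open(out / "merge_trace.tsv", "w") as fh:
        fh.write("step\tpair\tmv\tp\n")
        for step, li, lj, mv, p in trace.steps:
            fh.write(f"{step}\t{'+'.join(li)}|{'+'.join(lj)}\t{mv:.6g}\t{p:.6g}\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return RunResult(
        seed_genes=list(seed.genes),
        network=net,
        premodules=premodules,
        delta=delta,
        trace=trace,
        modules=modules,
        manifest=manifest,
        enrichment=enr,
        profiles=profiles,
        profile_correlations=corrs,
    )
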