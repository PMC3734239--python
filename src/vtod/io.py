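"""Readers and writers for every external format the pipeline touches.

TSV matrices (header = samples, first column = gene symbol), SIF or
two-column TSV protein-interaction edge lists, GMT gene sets, the UCSC
cytoBand.txt dialect, BED-like focal regions, and plain one-symbol-per-line
gene lists. Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .datatypes import (
    CNAMatrix,
    ExpressionMatrix,
    GeneLocation,
    GeneSetCollection,
    PPIGraph,
)

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """A structural problem in an input file."""


# ---------------------------------------------------------------- matrices


def read_matrix(path, kind: str = "expression"):
    """Load a genes-x-samples TSV.

    kind="cna": empty cells are imputed with the row mean across all samples
    and flagged in ``imputed_mask``; a row with every value missing is a
    format error (its mean is undefined).
    kind="expression": missing cells are a format error.
    """
    if kind not in ("expression", "cna"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = [str(g) for g in df.index]
    dup = pd.Index(genes)[pd.Index(genes).duplicated()]
    if len(dup):
        raise FormatError(f"duplicate gene symbol in {path}: {dup[0]!r}")
    samples = [str(s) for s in df.columns]
    values = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    missing = np.isnan(values)
    if kind == "expression":
        if missing.any():
            g, s = np.argwhere(missing)[0]
            raise FormatError(
                f"missing expression value for gene {genes[g]!r}, sample {samples[s]!r}"
            )
        return ExpressionMatrix(genes, samples, values)
    all_missing = missing.all(axis=1)
    if all_missing.any():
        bad = genes[int(np.argmax(all_missing))]
        raise FormatError(f"CNA row {bad!r} has all values missing; mean undefined")
    row_means = np.nanmean(values, axis=1)
    values = np.where(missing, row_means[:, None], values)
    if missing.any():
        log.info("imputed %d missing CNA cells with row means", int(missing.sum()))
    return CNAMatrix(genes, samples, values, imputed_mask=missing)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.genes, columns=matrix.samples)
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


# ---------------------------------------------------------------- PPI


def read_ppi(path) -> PPIGraph:
    """Load an undirected PPI graph from SIF ("A rel B") or 2-column TSV.

    Edges are deduplicated (A-B == B-A) and self-loops dropped with a logged
    count.
    """
    edges: set[tuple[str, str]] = set()
    n_self = 0
    n_lines = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) == 2:
                a, b = fields
            elif len(fields) >= 3:
                a, b = fields[0], fields[2]  # SIF: source relation target
            else:
                raise FormatError(f"{path}:{ln}: cannot parse edge line {line!r}")
            if not a or not b:
                raise FormatError(f"{path}:{ln}: empty node name")
            n_lines += 1
            if a == b:
                n_self += 1
                continue
            edges.add((min(a, b), max(a, b)))
    if n_lines == 0:
        raise FormatError(f"{path}: no edges found")
    if n_self:
        log.info("dropped %d self-loop(s) while reading %s", n_self, path)
    return PPIGraph.from_edges(sorted(edges))


def write_ppi(ppi: PPIGraph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted((min(u, v), max(u, v)) for u, v in ppi.graph.edges):
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------- gene sets


def read_gmt(path, min_size: int = 1, max_size: int = 10**9,
             name: Optional[str] = None) -> GeneSetCollection:
    """Standard GMT (set name, description, member genes...).

    Sets with size outside [min_size, max_size] (boundary-inclusive) are
    excluded and the exclusion count is logged.
    """
    sets: dict[str, set[str]] = {}
    n_excluded = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: GMT line has fewer than 3 fields")
            sname = fields[0]
            if sname in sets:
                raise FormatError(f"{path}:{ln}: duplicate set name {sname!r}")
            genes = {g for g in fields[2:] if g}
            if not (min_size <= len(genes) <= max_size):
                n_excluded += 1
                continue
            sets[sname] = genes
    if n_excluded:
        log.info("excluded %d gene set(s) outside [%d, %d] from %s",
                 n_excluded, min_size, max_size, path)
    if not sets:
        log.warning("no gene sets retained from %s", path)
    return GeneSetCollection(name or Path(str(path)).stem, sets, source=str(path))


def write_gmt(collection_or_sets, path, description: str = "na") -> None:
    sets = (
        collection_or_sets.sets
        if isinstance(collection_or_sets, GeneSetCollection)
        else collection_or_sets
    )
    with open(path, "w") as fh:
        for sname in sets:
            genes = sorted(sets[sname])
            fh.write("\t".join([sname, description, *genes]) + "\n")


def read_gene_list(path) -> set[str]:
    """One symbol per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line.split("\t")[0])
    return out


# ---------------------------------------------------------------- locations


def read_gene_coords(path) -> dict[str, tuple[str, int, int]]:
    """Gene coordinate TSV: gene, chromosome, start, end (0-based half-open)."""
    coords = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{ln}: expected gene, chrom, start, end")
            gene, chrom, start, end = fields[0], fields[1], int(fields[2]), int(fields[3])
            coords[gene] = (chrom, start, end)
    return coords


def _read_intervals(path, n_fields: int, label: str):
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < n_fields:
                raise FormatError(f"{path}:{ln}: {label} line needs >= {n_fields} fields")
            rows.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
    return rows


def read_locations(
    cytoband_path,
    focal_path,
    gene_coords: Mapping[str, tuple[str, int, int]],
) -> dict[str, GeneLocation]:
    """Assign each gene a cytoband (band containing its start coordinate) and,
    when its interval overlaps a focal aberrant region by >= 1 bp, the focal
    region id. A gene overlapping several focal regions gets the one with the
    larger overlap; exact ties break lexicographically on region id.
    """
    bands = _read_intervals(cytoband_path, 4, "cytoband")
    focals = _read_intervals(focal_path, 4, "focal region") if focal_path else []
    bands_by_chrom: dict[str, list] = {}
    for chrom, s, e, band in bands:
        bands_by_chrom.setdefault(chrom, []).append((s, e, band))
    focals_by_chrom: dict[str, list] = {}
    for chrom, s, e, rid in focals:
        focals_by_chrom.setdefault(chrom, []).append((s, e, rid))

    out: dict[str, GeneLocation] = {}
    for gene, (chrom, gstart, gend) in gene_coords.items():
        cytoband = None
        chrom_bands = bands_by_chrom.get(chrom)
        if chrom_bands is None:
            log.info("gene %s on chromosome %s absent from cytoband file", gene, chrom)
        else:
            for s, e, band in chrom_bands:
                if s <= gstart < e:
                    cytoband = chrom.removeprefix("chr") + band
                    break
        focal_id = None
        best = 0
        for s, e, rid in focals_by_chrom.get(chrom, []):
            overlap = min(gend, e) - max(gstart, s)
            if overlap >= 1 and (
                overlap > best or (overlap == best and (focal_id is None or rid < focal_id))
            ):
                best, focal_id = overlap, rid
        out[gene] = GeneLocation(gene, chrom, cytoband, focal_id)
    return out


# ---------------------------------------------------------------- tables


def write_modules_tsv(modules, path) -> None:
    """Long-format module table: module_id, gene, is_representative."""
    rows = []
    for mid, mod in enumerate(modules, start=1):
        reps = set(getattr(mod, "lineage", []) or [])
        for gene in sorted(mod.members):
            rows.append((f"M{mid}", gene, int(gene in reps)))
    pd.DataFrame(rows, columns=["module_id", "gene", "is_representative"]).to_csv(
        path, sep="\t", index=False
    )


def write_relationships_tsv(network, path) -> None:
    rows = []
    for (a, b), rel in sorted(network.relationships.items()):
        rows.append(
            (
                a,
                b,
                rel.weight,
                rel.kind,
                "|".join(rel.path) if rel.path else "",
                "" if rel.path_p is None else rel.path_p,
            )
        )
    pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "weight", "kind", "path", "path_p"]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_enrichment_tsv(results, path) -> None:
    rows = [
        (
            r.module_id,
            r.collection,
            r.set_name,
            r.overlap_count,
            r.module_size,
            r.set_size,
            r.universe_size,
            r.p,
            r.q,
            "|".join(sorted(r.overlap_genes)),
        )
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=[
            "module_id",
            "collection",
            "set_name",
            "overlap",
            "module_size",
            "set_size",
            "universe_size",
            "p",
            "q",
            "overlap_genes",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
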