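"""Fully synthetic GE / CNA / PPI / gene-set inputs with planted overlapping
modules, in exactly the formats the readers consume.

The generator emulates the statistical structure the pipeline exploits:

* tumor expression follows a latent-factor model — genes of one module share
  a per-sample factor, x = shift + sqrt(rho) * factor + sqrt(1 - rho) * noise,
  so `ge_latent_loading` rho IS the expected within-module |PCC|; controls
  are pure noise, and the mean shift makes planted genes differentially
  expressed;
* a fraction of each module's genes additionally share a per-module
  copy-number aberration profile (amplitude `cna_effect` over unit noise);
  these genes are the "significantly altered" list and each sits on its own
  synthetic cytoband, so the positional CNA-CNA exclusion cannot erase the
  planted signal;
* the PPI graph is a planted-partition graph (edge probability p_in within
  modules, p_out elsewhere);
* gene sets are the planted modules plus random decoys, and the cancer-gene
  list is the union of the first two planted modules;
* background genes are not inert: one tranche is differentially expressed
  without being co-expressed, and another consists of focal-region passengers
  sharing a per-region aberration profile (their CNA-CNA correlation is
  positional and gets excluded, exactly like passenger genes in real focal
  aberration calls). Seed genes therefore outnumber module genes, as in real
  tumor cohorts, and the per-kind top-quantile thresholds operate on a
  mostly-null candidate distribution.

What this deliberately does not model: microarray noise structure, genome-
scale gene counts, broad arm-level aberrations, or CNA-to-expression dosage
coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio

BAND_BP = 1_000_000
GENES_PER_CHROM = 50


@dataclass
class SynthConfig:
    n_modules: int = 5
    module_size_range: tuple[int, int] = (20, 20)
    n_background_genes: int = 120
    n_tumor: int = 60
    n_control: int = 10
    ge_latent_loading: float = 0.8  # mean within-module |PCC|
    loading_spread: float = 0.15  # per-gene loading jitter (eigengene spectrum)
    cna_effect: float = 1.5
    frac_cna_genes: float = 0.5
    ppi_p_in: float = 0.5
    ppi_p_out: float = 0.01
    overlap_genes: int = 2  # shared between consecutive modules
    de_shift: float = 3.0  # tumor-mean shift of DE genes, in noise SDs
    n_focal_background: int = 20  # focal-region passenger genes (SA, no module)
    frac_background_de: float = 0.75  # of remaining background: DE, not co-expressed
    n_hub_proteins: int = 3  # dataless sticky hubs: heavy-tailed PPI degrees
    hub_attachment: float = 0.6
    hub_member_attachment: float = 0.8  # module hub reaches this share of members
    n_decoy_sets: int = 20
    rng_seed: int = 0

    def __post_init__(self):
        lo, hi = self.module_size_range
        if not (3 <= lo <= hi):
            raise ValueError("module sizes must be >= 3 and ordered")
        if not (0.0 <= self.ge_latent_loading < 1.0):
            raise ValueError("ge_latent_loading must be in [0, 1)")
        if self.overlap_genes >= lo:
            raise ValueError("overlap cannot be the whole module")

    def nulled(self) -> "SynthConfig":
        """Same layout with every effect parameter zeroed."""
        return SynthConfig(
            n_modules=self.n_modules,
            module_size_range=self.module_size_range,
            n_background_genes=self.n_background_genes,
            n_tumor=self.n_tumor,
            n_control=self.n_control,
            ge_latent_loading=0.0,
            loading_spread=0.0,
            cna_effect=0.0,
            frac_cna_genes=self.frac_cna_genes,
            ppi_p_in=self.ppi_p_out,  # no planted PPI structure either
            ppi_p_out=self.ppi_p_out,
            overlap_genes=self.overlap_genes,
            de_shift=0.0,
            n_focal_background=self.n_focal_background,
            frac_background_de=self.frac_background_de,
            n_hub_proteins=self.n_hub_proteins,
            hub_attachment=self.hub_attachment,
            hub_member_attachment=self.hub_member_attachment,
            n_decoy_sets=self.n_decoy_sets,
            rng_seed=self.rng_seed,
        )


@dataclass
class GroundTruth:
    modules: list[set]
    sa_genes: set
    module_genes: set
    background_genes: set
    gene_flags: dict = field(default_factory=dict)  # gene -> {"ge", "cna"}

    def write(self, path) -> None:
        rows = []
        for mi, mod in enumerate(self.modules):
            for g in sorted(mod):
                rows.append((f"PLANTED_{mi}", g, int(g in self.sa_genes)))
        pd.DataFrame(rows, columns=["module", "gene", "has_cna_signal"]).to_csv(
            path, sep="\t", index=False
        )


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _layout(config: SynthConfig, rng: np.random.Generator):
    """Assign genes to modules (with overlap between consecutive modules)."""
    lo, hi = config.module_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_modules)
    modules: list[list[int]] = []
    cursor = 0
    for m, size in enumerate(sizes):
        members = []
        if m > 0 and config.overlap_genes > 0:
            members.extend(modules[m - 1][-config.overlap_genes:])
        fresh = int(size) - len(members)
        members.extend(range(cursor, cursor + fresh))
        cursor += fresh
        modules.append(members)
    n_module_genes = cursor
    n_total = n_module_genes + config.n_background_genes
    return modules, n_module_genes, n_total


def generate(config: SynthConfig, out_dir) -> tuple[dict, GroundTruth]:
    """Write a complete synthetic input bundle; returns paths and truth.

    Deterministic: the same config (including rng_seed) produces
    byte-identical files.
    """
    rng = np.random.default_rng(config.rng_seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    modules_idx, n_module_genes, n_total = _layout(config, rng)
    genes = _gene_names(n_total)
    if n_total > GENES_PER_CHROM * 200:
        raise ValueError("module sizes exceed the synthetic gene budget")
    module_sets = [set(genes[i] for i in m) for m in modules_idx]
    module_genes = set().union(*module_sets) if module_sets else set()
    background = set(genes[n_module_genes:])

    tumor = [f"T{i:03d}" for i in range(config.n_tumor)]
    control = [f"N{i:03d}" for i in range(config.n_control)]

    # background roles: focal passengers / DE-without-co-expression / inert
    bg_idx = list(range(n_module_genes, n_total))
    n_focal_bg = min(config.n_focal_background, len(bg_idx))
    focal_bg_idx = bg_idx[:n_focal_bg]
    rest = bg_idx[n_focal_bg:]
    bg_de_idx = rest[: int(round(config.frac_background_de * len(rest)))]

    # ---- expression: latent factor per module, per-gene loading spectrum ----
    rho = config.ge_latent_loading
    factors = rng.standard_normal((config.n_modules, config.n_tumor))
    expr = rng.standard_normal((n_total, config.n_tumor))
    # per-gene loading jitter emulates the eigengene (kME) spectrum of real
    # co-expression modules: high-loading genes become everyone's best
    # correlate, which is what concentrates votes on representatives
    loadings = np.clip(
        rho + config.loading_spread * rng.uniform(-1.0, 1.0, size=n_total),
        0.0, 0.97,
    )
    gene_modules: dict[int, list[int]] = {}
    for mi, members in enumerate(modules_idx):
        for gi in members:
            gene_modules.setdefault(gi, []).append(mi)
    for gi, mis in gene_modules.items():
        shared = factors[mis].sum(axis=0) / np.sqrt(len(mis))
        l = loadings[gi]
        expr[gi] = np.sqrt(1.0 - l) * expr[gi] + np.sqrt(l) * shared + config.de_shift
    for gi in bg_de_idx:
        expr[gi] += config.de_shift
    controls = rng.standard_normal((n_total, config.n_control))

    # ---- CNA: shared per-module aberration profile on a gene subset ----
    sa_genes: set[str] = set()
    cna = rng.standard_normal((n_total, config.n_tumor))
    profiles = rng.standard_normal((config.n_modules, config.n_tumor))
    for mi, members in enumerate(modules_idx):
        n_cna = int(round(config.frac_cna_genes * len(members)))
        carriers = members[:n_cna]  # deterministic: first genes of the module
        for gi in carriers:
            cna[gi] += config.cna_effect * profiles[mi]
            sa_genes.add(genes[gi])

    # ---- locations: one gene per synthetic cytoband ----
    coord_rows, band_rows = [], []
    for gi, g in enumerate(genes):
        chrom = f"chr{gi // GENES_PER_CHROM + 1}"
        band_i = gi % GENES_PER_CHROM
        start = band_i * BAND_BP
        coord_rows.append((g, chrom, start + 1000, start + 3000))
        band_rows.append((chrom, start, start + BAND_BP, f"q{band_i + 1}", "gpos50"))

    # focal aberrant regions: chromosome-contiguous runs of passenger genes
    # sharing one aberration profile (their mutual CNA-CNA is positional and
    # will be excluded, like real focal-call passengers)
    focal_rows = []
    regions: list[list[int]] = []
    cur: list[int] = []
    for gi in focal_bg_idx:
        if cur and (gi // GENES_PER_CHROM != cur[-1] // GENES_PER_CHROM or len(cur) >= 10):
            regions.append(cur)
            cur = []
        cur.append(gi)
    if cur:
        regions.append(cur)
    for ri, reg in enumerate(regions):
        prof = rng.standard_normal(config.n_tumor)
        for gi in reg:
            cna[gi] += config.cna_effect * prof
            sa_genes.add(genes[gi])
        chrom = coord_rows[reg[0]][1]
        starts = [coord_rows[gi][2] for gi in reg]
        ends = [coord_rows[gi][3] for gi in reg]
        focal_rows.append((chrom, min(starts) - 100, max(ends) + 100, f"FR{ri + 1}"))

    # ---- PPI: planted partition ----
    same_module = np.zeros((n_total, n_total), dtype=bool)
    for members in modules_idx:
        m = np.array(members)
        same_module[np.ix_(m, m)] = True
    iu, ju = np.triu_indices(n_total, k=1)
    p_edge = np.where(same_module[iu, ju], config.ppi_p_in, config.ppi_p_out)
    draw = rng.random(len(iu)) < p_edge
    edge_set = {(int(a), int(b)) for a, b in zip(iu[draw], ju[draw])}
    # each module's top-loading gene is its PPI hub (scaffold pattern): the
    # method assumes representatives are hubs in both data and topology; the
    # hub reaches most (not all) members, so modules split into a couple of
    # pre-modules and merging stays active, as observed for real cohorts
    for members in modules_idx:
        hub = max(members, key=lambda gi: (loadings[gi], -gi))
        for gi in members:
            if gi != hub and rng.random() < config.hub_member_attachment:
                edge_set.add((min(hub, gi), max(hub, gi)))
    edges = [(genes[a], genes[b]) for a, b in sorted(edge_set)]
    # dataless sticky hub proteins give the graph the heavy-tailed degree
    # distribution of real interactomes: max_degree >> a typical gene degree,
    # so normalized connectivity is small for ordinary genes
    for h in range(config.n_hub_proteins):
        hub = f"HUB{h:02d}"
        attached = rng.random(n_total) < config.hub_attachment
        edges.extend((hub, genes[gi]) for gi in np.where(attached)[0])

    # ---- gene sets: planted modules + decoys; cancer genes from modules 0,1
    sets = {f"PLANTED_{mi}": s for mi, s in enumerate(module_sets)}
    for d in range(config.n_decoy_sets):
        size = int(rng.integers(10, 25))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"DECOY_{d:02d}"] = set(members.tolist())
    cancer_genes = sorted(set().union(*module_sets[:2])) if len(module_sets) >= 2 else []

    # ---- write everything ----
    paths = {
        "expression": out / "expression.tsv",
        "controls": out / "controls.tsv",
        "cna": out / "cna.tsv",
        "ppi": out / "ppi.tsv",
        "cytoband": out / "cytoband.txt",
        "focal": out / "focal_regions.bed",
        "gene_coords": out / "gene_coords.tsv",
        "sa_genes": out / "sa_genes.txt",
        "gene_sets": out / "gene_sets.gmt",
        "cancer_genes": out / "cancer_genes.txt",
        "ground_truth": out / "ground_truth.tsv",
    }
    fmt = "%.8g"
    pd.DataFrame(expr, index=genes, columns=tumor).to_csv(
        paths["expression"], sep="\t", index_label="gene", float_format=fmt
    )
    pd.DataFrame(controls, index=genes, columns=control).to_csv(
        paths["controls"], sep="\t", index_label="gene", float_format=fmt
    )
    cna_df = pd.DataFrame(cna, index=genes, columns=tumor).round(8)
    # a few missing background cells exercise the load-time imputation
    if background:
        bg0 = sorted(background)[0]
        cna_df.loc[bg0, tumor[0]] = np.nan
    cna_df.to_csv(paths["cna"], sep="\t", index_label="gene", float_format=fmt)
    with open(paths["ppi"], "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")
    with open(paths["cytoband"], "w") as fh:
        for row in band_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(paths["focal"], "w") as fh:
        for row in focal_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(paths["gene_coords"], "w") as fh:
        for row in coord_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(paths["sa_genes"], "w") as fh:
        for g in sorted(sa_genes):
            fh.write(g + "\n")
    vio.write_gmt(sets, paths["gene_sets"])
    with open(paths["cancer_genes"], "w") as fh:
        for g in cancer_genes:
            fh.write(g + "\n")

    truth = GroundTruth(
        modules=module_sets,
        sa_genes=sa_genes,
        module_genes=module_genes,
        background_genes=background,
        gene_flags={g: {"ge"} | ({"cna"} if g in sa_genes else set()) for g in genes},
    )
    truth.write(paths["ground_truth"])
    return paths, truth


def null_dataset(config: SynthConfig, out_dir) -> tuple[dict, GroundTruth]:
    """Matched dataset with every effect parameter zeroed (calibration runs)."""
    return generate(config.nulled(), out_dir)
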