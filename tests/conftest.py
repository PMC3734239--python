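import numpy as np
import pytest

from vtod.datatypes import ExpressionMatrix, OmicsDataset, PipelineConfig, PPIGraph
from vtod.pipeline import InputPaths
from vtod.seeds import select_de_genes
from vtod.synthgen import SynthConfig, generate, null_dataset
from vtod import io as vio


def best_match_jaccard(planted, modules) -> float:
    """Mean over planted modules of the best Jaccard against found modules."""
    scores = []
    for pm in planted:
        best = 0.0
        for m in modules:
            mem = m.members if hasattr(m, "members") else m
            j = len(pm & set(mem)) / len(pm | set(mem))
            best = max(best, j)
        scores.append(best)
    return float(np.mean(scores))


def desk_scale_q(data_dir) -> float:
    """Global vote budget scaled to the seed-set size: ~5 eligible votes per
    seed gene, the ratio of the published operating point (top 0.1% of 23.2M
    ordered votes over 4,821 seed genes)."""
    d = InputPaths.from_dir(data_dir)
    expr = vio.read_matrix(d.expression, "expression")
    controls = vio.read_matrix(d.controls, "expression")
    sa = vio.read_gene_list(d.sa_genes)
    de = {r.gene for r in select_de_genes(expr, controls, 0.05) if r.is_de}
    n = len(de | sa)
    return min(100.0, 100.0 * 5.0 / max(1, n - 1))


@pytest.fixture(scope="session")
def strong_bundle(tmp_path_factory):
    """One strong-signal synthetic dataset shared across fast tests."""
    d = tmp_path_factory.mktemp("strong")
    paths, truth = generate(SynthConfig(rng_seed=0), d)
    return d, paths, truth


@pytest.fixture(scope="session")
def null_bundle(tmp_path_factory):
    d = tmp_path_factory.mktemp("null")
    paths, truth = null_dataset(SynthConfig(rng_seed=0), d)
    return d, paths, truth


@pytest.fixture()
def toy_omics():
    """Six samples, hand-designed correlation structure.

    A and B are strongly anti-correlated in expression (|PCC| = 1), C is an
    independent pattern. A and B also carry CNA; they sit on different
    cytobands, while B and C share one.
    """
    from vtod.datatypes import CNAMatrix, GeneLocation

    samples = [f"S{i}" for i in range(6)]
    expr = ExpressionMatrix(
        ["A", "B", "C"],
        samples,
        np.array([
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
            [1.0, -1.0, 1.0, -1.0, 1.0, -1.0],
        ]),
    )
    controls = ExpressionMatrix(
        ["A", "B", "C"], ["N0", "N1"], np.zeros((3, 2))
    )
    cna = CNAMatrix(
        ["A", "B"],
        samples,
        np.array([
            [0.1, 0.9, 0.2, 0.8, 0.3, 0.7],
            [0.1, 0.9, 0.2, 0.8, 0.3, 0.6],
        ]),
    )
    locations = {
        "A": GeneLocation("A", "chr1", "1q11", None),
        "B": GeneLocation("B", "chr1", "1q22", "FR1"),
        "C": GeneLocation("C", "chr1", "1q22", "FR1"),
    }
    return OmicsDataset(expr=expr, controls=controls, cna=cna, locations=locations)


@pytest.fixture()
def star_ppi():
    """Star on 5 nodes: hub H with leaves L1..L4."""
    return PPIGraph.from_edges([("H", f"L{i}") for i in range(1, 5)])
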