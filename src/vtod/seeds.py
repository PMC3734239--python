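"""Seed-gene selection.

Differentially expressed (DE) genes are found with a two-tailed pooled
(equal-variance) t-test against unmatched controls, Bonferroni-corrected
across all tested genes. Significantly copy-number-altered (SA) genes are
consumed as a list (they come from published focal-aberration calls, not from
re-running an aberration caller). The seed set is S = DE ∪ SA; a gene can
carry expression data, copy-number data, or both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import stats

from .datatypes import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class SeedGeneSet:
    genes: list[str]
    has_ge: dict[str, bool]
    has_cna: dict[str, bool]
    origin: dict[str, frozenset]

    def __post_init__(self):
        for g in self.genes:
            if not (self.has_ge.get(g) or self.has_cna.get(g)):
                raise ValueError(f"seed gene {g} has neither GE nor CNA data")
            if not self.origin.get(g):
                raise ValueError(f"seed gene {g} has empty origin")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.has_ge


@dataclass(frozen=True)
class DEResult:
    gene: str
    t_stat: float
    p_raw: float
    p_bonferroni: float
    is_de: bool


def pooled_t_test(tumor_values, control_values) -> tuple[float, float]:
    """Two-tailed pooled (equal-variance) two-sample t-test.

    Degenerate case of zero pooled variance: identical means give (0, 1);
    different means give (inf-signed t, 0) with a warning.
    """
    x = np.asarray(tumor_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least 2 observations")
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        log.warning("zero pooled variance with unequal means; p = 0")
        return float(np.sign(diff) * np.inf), 0.0
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def select_de_genes(
    expr: ExpressionMatrix, controls: ExpressionMatrix, alpha: float = 0.05
) -> list[DEResult]:
    """Per-gene pooled t-test with Bonferroni factor = number of genes tested."""
    if set(expr.genes) != set(controls.genes):
        diff = sorted(set(expr.genes) ^ set(controls.genes))
        raise ValueError(f"tumor/control gene universes differ: {diff}")
    x = expr.values
    y = np.stack([controls.row(g) for g in expr.genes])
    n1, n2 = x.shape[1], y.shape[1]
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(axis=1, ddof=1) + (n2 - 1) * y.var(axis=1, ddof=1)) / df
    diff_means = x.mean(axis=1) - y.mean(axis=1)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff_means / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate rows: zero pooled variance
    zero_var = sp2 == 0.0
    t = np.where(zero_var & (diff_means == 0), 0.0, t)
    p = np.where(zero_var, np.where(diff_means == 0, 1.0, 0.0), p)
    m = len(expr.genes)
    p_bonf = np.minimum(1.0, p * m)
    return [
        DEResult(g, float(t[i]), float(p[i]), float(p_bonf[i]), bool(p_bonf[i] <= alpha and alpha > 0))
        for i, g in enumerate(expr.genes)
    ]


def build_seed_set(
    de_genes: Iterable[str],
    sa_genes: Iterable[str],
    ge_universe: Iterable[str],
    cna_universe: Iterable[str],
) -> SeedGeneSet:
    """S = DE ∪ SA with per-gene data-availability flags and origin labels."""
    de, sa = set(de_genes), set(sa_genes)
    ge_u, cna_u = set(ge_universe), set(cna_universe)
    if not de <= ge_u:
        raise ValueError(f"DE genes outside the GE universe: {sorted(de - ge_u)}")
    if not sa <= cna_u:
        raise ValueError(f"SA genes outside the CNA universe: {sorted(sa - cna_u)}")
    union = sorted(de | sa)
    if not union:
        raise ValueError("empty seed set: no DE and no SA genes")
    origin = {
        g: frozenset(
            (["DE"] if g in de else []) + (["SA"] if g in sa else [])
        )
        for g in union
    }
    return SeedGeneSet(
        genes=union,
        has_ge={g: g in ge_u for g in union},
        has_cna={g: g in cna_u for g in union},
        origin=origin,
    )


def expression_change_fraction(
    expr: ExpressionMatrix,
    controls: ExpressionMatrix,
    top_fraction: float = 0.10,
    threshold: Optional[float] = None,
) -> Mapping[str, float]:
    """Fraction of tumor samples in which each gene is over/under-expressed.

    A sample counts when |e(g, t) - mean_control(g)| reaches the global
    threshold, which by default is the (1 - top_fraction) quantile of the
    scores pooled over all genes and samples. The published per-cancer
    thresholds (0.4 for GBM, 0.365 for OVC) can be injected via `threshold`.
    """
    from ._utils import top_fraction_threshold

    if threshold is None and not (0.0 < top_fraction < 1.0):
        raise ValueError(f"top_fraction must be in (0, 1), got {top_fraction}")
    if not controls.genes:
        raise ValueError("control matrix is empty")
    control_means = np.array([controls.row(g).mean() for g in expr.genes])
    scores = np.abs(expr.values - control_means[:, None])
    if threshold is None:
        threshold = top_fraction_threshold(scores.ravel(), top_fraction)
    frac = (scores >= threshold).mean(axis=1)
    return {g: float(frac[i]) for i, g in enumerate(expr.genes)}
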