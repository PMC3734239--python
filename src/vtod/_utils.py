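"""Small shared numerics: pair counting, top-quantile thresholds, pair unranking."""

from __future__ import annotations

import numpy as np
from numpy.random import Generator, default_rng
from numpy.random import SeedSequence


def pair_count(n: int) -> int:
    """Number of unordered pairs among n items, C(n, 2)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n - 1) // 2


def top_fraction_threshold(values, top_fraction: float) -> float:
    """Value of the k-th largest entry with k = ceil(top_fraction * n).

    Downstream admission uses >=, so ties at the cutoff are admitted and at
    least a fraction `top_fraction` of the values pass.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("cannot take a quantile of an empty value set")
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    k = max(1, int(np.ceil(top_fraction * v.size)))
    return float(np.partition(v, v.size - k)[v.size - k])


def spawn_rngs(seed: int, n: int) -> list[Generator]:
    """Independent child generators derived from one seed (stage-stable reruns)."""
    return [default_rng(s) for s in SeedSequence(seed).spawn(n)]


def unrank_pairs(idx, n: int):
    """Map linear indices in [0, C(n,2)) to unordered pairs (i, j), i < j.

    Ordering is i-major: (0,1), (0,2), ..., (0,n-1), (1,2), ...
    Vectorised; used to sample relationship pairs uniformly without
    materialising all C(n, 2) pairs.
    """
    idx = np.asarray(idx, dtype=np.int64)
    # solve i from the triangular offsets: off(i) = i*n - i*(i+1)/2
    b = 2 * n - 1
    i = np.floor((b - np.sqrt(b * b - 8.0 * idx)) / 2.0).astype(np.int64)
    off = i * n - i * (i + 1) // 2
    # guard floating point at offsets' boundaries
    too_big = off > idx
    i[too_big] -= 1
    off = i * n - i * (i + 1) // 2
    j = idx - off + i + 1
    return i, j


def geometric_mean(values) -> float:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("geometric mean of an empty sequence")
    if np.any(v < 0):
        raise ValueError("geometric mean requires non-negative values")
    if np.any(v == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(v))))
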