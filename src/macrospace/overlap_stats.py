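"""Gene-set overlap statistics.

Hypergeometric enrichment of the overlap between two gene sets drawn from a
common universe, computed in log-space so p-values far below float
underflow (the scale of 1e-69 seen in expression-overlap comparisons)
remain meaningful, plus Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetOverlap", "overlap_test", "bh_adjust"]


@dataclass(frozen=True)
class GeneSetOverlap:
    n_a: int
    n_b: int
    n_universe: int
    k: int  # observed overlap
    fraction_of_a: float  # k / |A|
    fold_enrichment: float  # (k / |A|) / (|B| / universe)
    p_value: float  # may underflow to 0.0; log10_p stays exact
    log10_p: float
    tail: str  # 'enrichment' or 'depletion'


def overlap_test(set_a, set_b, universe, tail: str = "enrichment") -> GeneSetOverlap:
    """Hypergeometric test of the overlap between two gene sets.

    With ``X ~ Hypergeometric(universe, |A|, |B|)`` and observed overlap
    ``k = |A ∩ B|``, the enrichment tail is ``P(X >= k)`` (inclusive) and
    the depletion tail ``P(X <= k)``.  Computed in log-space; ``log10_p``
    is reliable even when ``p_value`` underflows.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("gene sets must be contained in the universe")
    if tail not in ("enrichment", "depletion"):
        raise ValueError("tail must be 'enrichment' or 'depletion'")
    k = len(a & b)
    dist = scipy.stats.hypergeom(len(u), len(a), len(b))
    if tail == "enrichment":
        logp = dist.logsf(k - 1)  # P(X >= k)
    else:
        logp = dist.logcdf(k)  # P(X <= k)
    logp = float(min(logp, 0.0))
    frac = k / len(a) if a else float("nan")
    fold = (
        (k * len(u)) / (len(a) * len(b)) if a and b else float("nan")
    )
    return GeneSetOverlap(
        n_a=len(a),
        n_b=len(b),
        n_universe=len(u),
        k=k,
        fraction_of_a=frac,
        fold_enrichment=fold,
        p_value=float(math.exp(logp)),
        log10_p=logp / math.log(10.0),
        tail=tail,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
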