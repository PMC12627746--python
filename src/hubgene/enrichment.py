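"""Gene-set overlap enrichment and per-cell geneset scoring.

Enrichment of a query gene list (e.g. hub+ genes) in a target set is measured
as the ratio of the proportion of query genes in the set to the proportion of
background genes in the set, with significance from the hypergeometric tail
P(X >= x) — the probability of drawing x or more target-set genes in a random
sample of the query's size from the background. Cell-level analysis scores
each cell by its total log-normalised expression of a geneset and correlates
the score with pseudotime within a cell population (Spearman).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "enrichment_ratio",
    "hypergeom_p",
    "geneset_overlap_test",
    "cell_geneset_score",
    "score_pseudotime_correlation",
]


@dataclass
class EnrichmentResult:
    """Overlap statistics: x of n query genes hit a target set of K in background M."""

    x: int
    n: int
    K: int
    M: int
    enrichment: float
    p: float

    def as_row(self) -> dict:
        return {"x": self.x, "n": self.n, "K": self.K, "M": self.M,
                "enrichment": self.enrichment, "p": self.p}


def enrichment_ratio(x: int, n: int, K: int, M: int) -> float:
    """(x/n) / (K/M): fold enrichment of the query over the background rate."""
    _check_counts(x, n, K, M)
    if K == 0 or n == 0:
        raise ValueError("enrichment undefined for empty target or query set")
    return (x / n) / (K / M)


def hypergeom_p(x: int, n: int, K: int, M: int, strict: bool = False) -> float:
    """Upper-tail hypergeometric probability of the overlap.

    ``P(X >= x)`` for X ~ Hypergeometric(M, K, n) (``P(X > x)`` when
    ``strict``). ``x = 0`` gives p = 1 by convention.
    """
    _check_counts(x, n, K, M)
    thr = x if strict else x - 1
    if thr < 0:
        return 1.0
    return float(stats.hypergeom.sf(thr, M, K, n))


def _check_counts(x, n, K, M):
    for name, v in (("x", x), ("n", n), ("K", K), ("M", M)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    if n > M or K > M:
        raise ValueError("set sizes cannot exceed the background size")
    if x > min(n, K):
        raise ValueError(f"infeasible overlap x={x} for n={n}, K={K}")


def geneset_overlap_test(query, target, background) -> EnrichmentResult:
    """Hypergeometric overlap test of two gene sets within a background universe.

    Genes outside the background are dropped from query and target before
    counting (x = |query∩target∩background|, n = |query∩background|,
    K = |target∩background|, M = |background|).
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    q = set(query) & background
    t = set(target) & background
    x, n, K, M = len(q & t), len(q), len(t), len(background)
    ratio = 0.0 if (n == 0 or K == 0) else enrichment_ratio(x, n, K, M)
    p = 1.0 if (n == 0 or K == 0) else hypergeom_p(x, n, K, M)
    return EnrichmentResult(x=x, n=n, K=K, M=M, enrichment=ratio, p=p)


def cell_geneset_score(cells, geneset) -> pd.DataFrame:
    """Per-cell total log-normalised expression of a geneset.

    ``cells`` is an AnnData with log-normalised values in X and
    ``population`` / ``pseudotime`` columns in obs. Returns a DataFrame with
    score, population and pseudotime per cell.
    """
    present = [g for g in dict.fromkeys(geneset) if g in cells.var_names]
    if not present:
        raise ValueError("geneset has no genes in the expression table")
    X = cells[:, present].X
    X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    return pd.DataFrame(
        {
            "score": X.sum(axis=1).astype(float),
            "population": cells.obs["population"].to_numpy(),
            "pseudotime": cells.obs["pseudotime"].to_numpy(),
        },
        index=cells.obs_names,
    )


def score_pseudotime_correlation(scores: pd.DataFrame, population) -> tuple[float, int]:
    """Spearman correlation of geneset score with pseudotime within a population.

    Returns ``(rho, n_cells)``; rho is NaN when scores are constant.
    """
    sub = scores[scores["population"] == population]
    n = len(sub)
    if n < 3:
        raise ValueError(f"fewer than 3 cells in population {population!r}")
    if sub["score"].nunique() < 2 or sub["pseudotime"].nunique() < 2:
        return float("nan"), n
    rho = stats.spearmanr(sub["score"], sub["pseudotime"]).statistic
    return float(rho), n
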