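"""Rank-rank hypergeometric overlap (RRHO).

For two ranked gene lists over the same universe of size ``N``, every pair
of rank thresholds ``(i, j)`` on a step grid is scored by the upper-tail
hypergeometric probability of observing at least the actual overlap
``k = |top_i ∩ top_j|``. The map of ``−log10 p`` values locates the most
significant overlap; tail probabilities are accumulated in log space so
maps survive universes of tens of thousands of genes without underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from rrhosig.ranking import RankedList

LOG10 = np.log(10.0)


# ---------------------------------------------------------------------------
# hypergeometric upper tail in log space
# ---------------------------------------------------------------------------

def _log_binom_table(n: int) -> np.ndarray:
    """gammaln(x+1) for x = 0..n, so log C(a,b) = t[a]-t[b]-t[a-b]."""
    return gammaln(np.arange(n + 1) + 1.0)


def log_hypergeom_tail(k: int, i: int, j: int, N: int, _table: np.ndarray | None = None) -> float:
    """Natural-log upper tail P(X >= k), X ~ Hypergeometric(N, i, j).

    ``i`` marked genes in a universe of ``N``; ``j`` draws. Symmetric in
    ``(i, j)``. Summation runs in log space over the feasible support.
    """
    if not (0 <= i <= N and 0 <= j <= N):
        raise ValueError(f"need 0 <= i, j <= N, got i={i}, j={j}, N={N}")
    lo, hi = max(0, i + j - N), min(i, j)
    if not lo <= k <= hi:
        raise ValueError(f"k={k} outside feasible range [{lo}, {hi}] for (i={i}, j={j}, N={N})")
    if k <= lo:
        return 0.0
    t = _table if _table is not None else _log_binom_table(N)
    x = np.arange(k, hi + 1)
    # log pmf(x) = log C(i,x) + log C(N-i, j-x) - log C(N,j)
    log_pmf = (
        t[i] - t[x] - t[i - x]
        + t[N - i] - t[j - x] - t[N - i - j + x]
        - (t[N] - t[j] - t[N - j])
    )
    return float(min(logsumexp(log_pmf), 0.0))


def hypergeom_tail(k: int, i: int, j: int, N: int) -> float:
    """Upper-tail probability P(X >= k); exact 1.0 when k is forced."""
    return float(np.exp(log_hypergeom_tail(k, i, j, N)))


def neglog10_hypergeom_tail(k: int, i: int, j: int, N: int) -> float:
    """−log10 P(X >= k), the map's cell value."""
    return -log_hypergeom_tail(k, i, j, N) / LOG10


# ---------------------------------------------------------------------------
# the map
# ---------------------------------------------------------------------------

@dataclass
class RRHOMap:
    """Grid of −log10 hypergeometric tail p-values over rank-threshold pairs.

    Rows index ``thresholds_1`` (first list), columns ``thresholds_2``.
    ``quadrant_boundaries`` holds the count of positive-score genes in each
    list, separating the FO-leaning prefix from the PO-leaning suffix.
    """

    thresholds_1: np.ndarray
    thresholds_2: np.ndarray
    neglog_p: np.ndarray
    overlap_counts: np.ndarray
    universe_size: int
    step: int
    quadrant_boundaries: tuple[int, int]

    def __post_init__(self) -> None:
        expect = (len(self.thresholds_1), len(self.thresholds_2))
        if self.neglog_p.shape != expect or self.overlap_counts.shape != expect:
            raise ValueError("matrix dimensions must match threshold grids")

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.neglog_p, index=self.thresholds_1, columns=self.thresholds_2
        ).to_csv(path, sep="\t", index_label="rank1")

    def to_png(self, path, title: str = "") -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4.2))
        im = ax.imshow(
            self.neglog_p,
            origin="lower",
            aspect="auto",
            extent=(
                self.thresholds_2[0], self.thresholds_2[-1],
                self.thresholds_1[0], self.thresholds_1[-1],
            ),
            cmap="jet",
        )
        fig.colorbar(im, ax=ax, label=r"$-\log_{10}$ p")
        ax.set_xlabel("rank threshold, list 2")
        ax.set_ylabel("rank threshold, list 1")
        if title:
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


@dataclass
class OverlapResult:
    """The map maximum and the genes overlapping there."""

    i_star: int
    j_star: int
    neglog_p_max: float
    genes: list[str]
    quadrant: str

    def to_dict(self) -> dict:
        return {
            "i_star": self.i_star,
            "j_star": self.j_star,
            "neglog_p_max": self.neglog_p_max,
            "n_genes": len(self.genes),
            "genes": self.genes,
            "quadrant": self.quadrant,
        }


def _threshold_grid(N: int, step: int) -> np.ndarray:
    """step, 2·step, …, N — always includes N, never 0."""
    grid = np.arange(step, N + 1, step)
    if grid.size == 0 or grid[-1] != N:
        grid = np.append(grid, N)
    return grid


def default_step(N: int) -> int:
    """~100×100 grid by default."""
    return max(1, N // 100)


def _check_universes(rl1: RankedList, rl2: RankedList) -> None:
    s1, s2 = set(rl1.genes), set(rl2.genes)
    if s1 != s2:
        odd = sorted((s1 ^ s2))[:10]
        raise ValueError(f"ranked lists have different gene universes; e.g. {odd}")


def overlap_count_matrix(rl1: RankedList, rl2: RankedList, grid1, grid2) -> np.ndarray:
    """k[i, j] = |top_{grid1[i]}(rl1) ∩ top_{grid2[j]}(rl2)|.

    O(N + cells): bin each gene's (rank1, rank2) pair into the grid once,
    then take 2-D cumulative sums.
    """
    pos2 = {g: r for r, g in enumerate(rl2.genes, start=1)}
    r1 = np.arange(1, len(rl1) + 1)
    r2 = np.array([pos2[g] for g in rl1.genes])
    # half-integer edges so a rank equal to a threshold lands in that bin
    edges1 = np.concatenate([[0.5], np.asarray(grid1) + 0.5])
    edges2 = np.concatenate([[0.5], np.asarray(grid2) + 0.5])
    hist, _, _ = np.histogram2d(r1, r2, bins=(edges1, edges2))
    return np.cumsum(np.cumsum(hist, axis=0), axis=1).astype(int)


def rrho_map(rl1: RankedList, rl2: RankedList, step: int | None = None) -> RRHOMap:
    """Build the full −log10 tail-p map over the step grid.

    Cells are evaluated in log space; only the over-enrichment (upper)
    tail is computed.
    """
    _check_universes(rl1, rl2)
    N = len(rl1)
    if step is None:
        step = default_step(N)
    if step < 1:
        raise ValueError("step must be >= 1")

    grid1 = _threshold_grid(N, step)
    grid2 = _threshold_grid(N, step)
    counts = overlap_count_matrix(rl1, rl2, grid1, grid2)

    table = _log_binom_table(N)
    neglog = np.empty_like(counts, dtype=float)
    for a, i in enumerate(grid1):
        for b, j in enumerate(grid2):
            neglog[a, b] = -log_hypergeom_tail(int(counts[a, b]), int(i), int(j), N, table) / LOG10

    return RRHOMap(
        thresholds_1=grid1,
        thresholds_2=grid2,
        neglog_p=neglog,
        overlap_counts=counts,
        universe_size=N,
        step=step,
        quadrant_boundaries=(rl1.n_positive, rl2.n_positive),
    )


def by_correct_map(rmap: RRHOMap) -> RRHOMap:
    """Benjamini–Yekutieli-correct all map cells (optional display mode).

    Adjusted in log space on the −log10 scale so deeply significant cells
    do not underflow; adjusted values are floored at 0 (p capped at 1).
    """
    neglog = rmap.neglog_p
    m = neglog.size
    flat = neglog.ravel()
    # ascending p = descending neglog
    order = np.argsort(-flat, kind="stable")
    ranks = np.empty(m, dtype=float)
    ranks[order] = np.arange(1, m + 1)
    harmonic = float(np.sum(1.0 / np.arange(1, m + 1)))
    adj = flat - (np.log(m) + np.log(harmonic) - np.log(ranks)) / LOG10
    # step-up monotonicity: adjusted p non-decreasing in raw p, i.e. the
    # adjusted neglog (in ascending-p order) is the suffix maximum
    adj_sorted = np.maximum.accumulate(adj[order][::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.maximum(adj_sorted, 0.0)
    return RRHOMap(
        thresholds_1=rmap.thresholds_1,
        thresholds_2=rmap.thresholds_2,
        neglog_p=out.reshape(neglog.shape),
        overlap_counts=rmap.overlap_counts,
        universe_size=rmap.universe_size,
        step=rmap.step,
        quadrant_boundaries=rmap.quadrant_boundaries,
    )


QUADRANTS = ("FO-FO", "PO-PO", "FO-PO", "PO-FO")


def find_quadrant_max(rmap: RRHOMap, quadrant: str = "FO-FO") -> tuple[int, int, float]:
    """Locate the map maximum within one quadrant.

    The map must be oriented so the requested quadrant occupies the
    top-left prefix region (``quadrant_max`` handles reorientation by
    reversing lists). Ties break on the smallest ``i`` then smallest
    ``j``.
    """
    if quadrant not in QUADRANTS:
        raise ValueError(f"unknown quadrant {quadrant!r}")
    b1, b2 = rmap.quadrant_boundaries
    rows = np.flatnonzero(rmap.thresholds_1 <= b1)
    cols = np.flatnonzero(rmap.thresholds_2 <= b2)
    if rows.size == 0 or cols.size == 0:
        raise ValueError(
            f"quadrant {quadrant} is empty: boundaries {rmap.quadrant_boundaries} "
            f"below the first grid step {rmap.step}"
        )
    sub = rmap.neglog_p[np.ix_(rows, cols)]
    best = np.max(sub)
    where = np.argwhere(sub >= best - 0.0)
    # ties: smallest threshold_1, then smallest threshold_2
    a, b = min(map(tuple, where))
    return int(rmap.thresholds_1[rows[a]]), int(rmap.thresholds_2[cols[b]]), float(best)


def overlap_genes(
    rl1: RankedList, rl2: RankedList, i_star: int, j_star: int, quadrant: str = "FO-FO"
) -> list[str]:
    """Genes common to the two threshold prefixes, in rank-sum order.

    For PO quadrants the corresponding list is reversed first, so the
    "prefix" is the PO-most suffix of the original order.
    """
    if quadrant not in QUADRANTS:
        raise ValueError(f"unknown quadrant {quadrant!r}")
    a = rl1.reversed() if quadrant.startswith("PO") else rl1
    b = rl2.reversed() if quadrant.endswith("PO") else rl2
    if not (0 <= i_star <= len(a) and 0 <= j_star <= len(b)):
        raise ValueError("thresholds out of bounds")
    top1 = {g: r for r, g in enumerate(a.genes[:i_star], start=1)}
    top2 = {g: r for r, g in enumerate(b.genes[:j_star], start=1)}
    common = set(top1) & set(top2)
    return sorted(common, key=lambda g: (top1[g] + top2[g], g))


def quadrant_max(
    rl1: RankedList, rl2: RankedList, step: int | None = None, quadrant: str = "FO-FO"
) -> tuple[RRHOMap, OverlapResult]:
    """One-stop: orient lists for the quadrant, map, locate max, list genes.

    PO sides are handled by reversing the corresponding list (scores
    negated), after which the quadrant always sits in the prefix region.
    """
    if quadrant not in QUADRANTS:
        raise ValueError(f"unknown quadrant {quadrant!r}")
    a = rl1.reversed() if quadrant.startswith("PO") else rl1
    b = rl2.reversed() if quadrant.endswith("PO") else rl2
    rmap = rrho_map(a, b, step=step)
    i_star, j_star, best = find_quadrant_max(rmap, quadrant)
    genes = overlap_genes(rl1, rl2, i_star, j_star, quadrant)
    return rmap, OverlapResult(
        i_star=i_star, j_star=j_star, neglog_p_max=best, genes=genes, quadrant=quadrant
    )
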