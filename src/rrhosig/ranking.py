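"""Signed differential ranking and the fold-change/p cutoff baseline.

The ranking score for a gene is ``sign(mean_FO − mean_PO) × (−log10 p)``
where ``p`` is the two-sided equal-variance two-sample t-test p-value.
Rank 1 is the most FO-overexpressed gene; the bottom of the list is the
most PO-overexpressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from rrhosig.dataset import ExpressionDataset, class_matrices


@dataclass
class RankedList:
    """Genes ordered by signed differential score (descending).

    ``scores[i]`` belongs to ``genes[i]``; scores are non-increasing with
    rank. Infinite scores are sentinels for zero within-class variance
    with unequal means and sort outermost.
    """

    genes: list[str]
    scores: np.ndarray
    dataset_id: str = ""
    n_fo: int = 0
    n_po: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        if len(self.scores) > 1 and np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing with rank")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def n_positive(self) -> int:
        """Number of genes with a strictly positive (FO-leaning) score."""
        return int(np.sum(self.scores > 0))

    def restrict(self, genes) -> "RankedList":
        """Subset to ``genes`` preserving rank order (re-rank on a sub-universe)."""
        keep = set(genes)
        idx = [i for i, g in enumerate(self.genes) if g in keep]
        return RankedList(
            genes=[self.genes[i] for i in idx],
            scores=self.scores[idx],
            dataset_id=self.dataset_id,
            n_fo=self.n_fo,
            n_po=self.n_po,
        )

    def reversed(self) -> "RankedList":
        """Reverse order and negate scores (PO-first view of the same data)."""
        return RankedList(
            genes=self.genes[::-1],
            scores=-self.scores[::-1],
            dataset_id=self.dataset_id,
            n_fo=self.n_fo,
            n_po=self.n_po,
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame({"gene": self.genes, "score": self.scores}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, dataset_id: str = "") -> "RankedList":
        df = pd.read_csv(path, sep="\t")
        return cls(genes=df["gene"].astype(str).tolist(), scores=df["score"].to_numpy(),
                   dataset_id=dataset_id)


def _t_and_p(fo: np.ndarray, po: np.ndarray, welch: bool = False):
    """Row-wise two-sample t statistic and two-sided p (vectorized)."""
    with warnings.catch_warnings():
        # constant rows trigger a precision warning; they are handled
        # explicitly by the zero-variance sentinel logic downstream
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(fo, po, axis=1, equal_var=not welch)
    return np.asarray(res.statistic), np.asarray(res.pvalue)


def t_statistics(ds: ExpressionDataset, welch: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe (t, p) between FO and PO groups."""
    fo, po = class_matrices(ds)
    if fo.shape[1] < 2 or po.shape[1] < 2:
        raise ValueError("need at least 2 samples per class")
    return _t_and_p(fo, po, welch=welch)


def differential_score(fo_values, po_values, welch: bool = False) -> float:
    """Signed score for one gene: sign(mean_FO − mean_PO) × (−log10 p).

    Zero mean difference gives 0. Zero pooled variance with unequal means
    gives a ±inf sentinel (ranked outermost downstream).
    """
    fo = np.asarray(fo_values, dtype=float)
    po = np.asarray(po_values, dtype=float)
    if fo.size < 2 or po.size < 2:
        raise ValueError("need at least 2 samples per group")
    if not (np.isfinite(fo).all() and np.isfinite(po).all()):
        raise ValueError("non-finite expression values")
    diff = fo.mean() - po.mean()
    if diff == 0:
        return 0.0
    if fo.var(ddof=1) == 0 and po.var(ddof=1) == 0:
        return float(np.sign(diff) * np.inf)
    _, p = _t_and_p(fo[None, :], po[None, :], welch=welch)
    return float(np.sign(diff) * (-np.log10(p[0])))


def rank_genes(ds: ExpressionDataset, welch: bool = False) -> RankedList:
    """Rank a gene-level dataset by signed −log10 t-test p, descending.

    Ties break by |t| descending, then gene symbol ascending — fully
    deterministic.
    """
    fo, po = class_matrices(ds)
    if fo.shape[1] < 2 or po.shape[1] < 2:
        raise ValueError("need at least 2 samples per class")
    t, p = _t_and_p(fo, po, welch=welch)
    diff = fo.mean(axis=1) - po.mean(axis=1)
    sign = np.sign(diff)

    with np.errstate(divide="ignore"):
        score = sign * (-np.log10(p))
    degenerate = ~np.isfinite(t)  # zero pooled variance rows
    score[degenerate & (sign != 0)] = np.inf * sign[degenerate & (sign != 0)]
    score[sign == 0] = 0.0
    abs_t = np.where(np.isfinite(t), np.abs(t), np.inf)
    abs_t[sign == 0] = 0.0

    order = sorted(
        range(len(score)),
        key=lambda i: (-score[i], -abs_t[i], ds.values.index[i]),
    )
    return RankedList(
        genes=[ds.values.index[i] for i in order],
        scores=score[order],
        dataset_id=ds.platform_id,
        n_fo=fo.shape[1],
        n_po=po.shape[1],
    )


def cutoff_overlap(
    ds1: ExpressionDataset,
    ds2: ExpressionDataset,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    welch: bool = False,
) -> dict[str, set[str]]:
    """Direction-consistent intersection of naive fold-change/p cutoffs.

    Values are log2 intensities, so fold change per gene is the group-mean
    difference thresholded at ``log2(fc_threshold)``. Returns the genes
    passing in both datasets with consistent direction, keyed by
    ``"up"`` (FO-higher) and ``"down"``.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")

    def sig_sets(ds: ExpressionDataset) -> tuple[set[str], set[str]]:
        fo, po = class_matrices(ds)
        t, p = _t_and_p(fo, po, welch=welch)
        diff = fo.mean(axis=1) - po.mean(axis=1)
        log_fc = np.log2(fc_threshold) if np.isfinite(fc_threshold) else np.inf
        hit = (np.abs(diff) > log_fc) & (p < p_threshold)
        genes = np.asarray(ds.values.index)
        return set(genes[hit & (diff > 0)]), set(genes[hit & (diff < 0)])

    up1, down1 = sig_sets(ds1)
    up2, down2 = sig_sets(ds2)
    return {"up": up1 & up2, "down": down1 & down2}
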