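"""Weighted gene voting (WGV) with leave-one-out evaluation.

Each signature gene votes ``W × (S − midpoint)`` where
``W = (mean_FO − mean_PO) / (sd_FO + sd_PO)`` is the signal-to-noise
weight and ``midpoint = (mean_FO + mean_PO) / 2``; the sign of the summed
votes predicts the class. In leave-one-out (LOO) mode the class means and
standard deviations are recomputed without the sample being scored.

Evaluation aggregates LOO predictions into confusion counts, a
rank-based (Mann–Whitney) AUC of the vote sums, and — when survival
annotations are present — a two-group log-rank comparison of the
predicted classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank

from rrhosig.dataset import FO, PO, ExpressionDataset
from rrhosig.signature import Signature

log = logging.getLogger(__name__)


@dataclass
class WGVStatistics:
    """Per-gene class statistics and derived weights, indexed by gene."""

    mean_fo: pd.Series
    mean_po: pd.Series
    sd_fo: pd.Series
    sd_po: pd.Series
    strict_formula: bool = False  # use (mean_FO − mean_PO)/2 as the vote pivot

    @property
    def weight(self) -> pd.Series:
        return (self.mean_fo - self.mean_po) / (self.sd_fo + self.sd_po)

    @property
    def midpoint(self) -> pd.Series:
        if self.strict_formula:
            return (self.mean_fo - self.mean_po) / 2.0
        return (self.mean_fo + self.mean_po) / 2.0

    @property
    def usable(self) -> pd.Series:
        """Genes with positive stdev sum (others cannot vote)."""
        return (self.sd_fo + self.sd_po) > 0


def fit_wgv(
    values: pd.DataFrame,
    classes: pd.Series,
    strict_formula: bool = False,
) -> WGVStatistics:
    """Class means/SDs per gene. ``values``: gene × sample; SD uses n−1."""
    fo_cols = classes.index[classes.values == FO]
    po_cols = classes.index[classes.values == PO]
    if len(fo_cols) < 2 or len(po_cols) < 2:
        raise ValueError("need at least 2 samples per class to fit WGV statistics")
    fo = values[fo_cols]
    po = values[po_cols]
    return WGVStatistics(
        mean_fo=fo.mean(axis=1),
        mean_po=po.mean(axis=1),
        sd_fo=fo.std(axis=1, ddof=1),
        sd_po=po.std(axis=1, ddof=1),
        strict_formula=strict_formula,
    )


def gene_vote(stats: WGVStatistics, gene: str, s_value: float) -> float:
    """One gene's vote for one sample: W × (S − midpoint)."""
    if not stats.usable[gene]:
        raise ValueError(f"gene {gene!r} has zero stdev sum; cannot vote")
    return float(stats.weight[gene] * (s_value - stats.midpoint[gene]))


@dataclass
class VoteResult:
    """One sample's summed vote, prediction, and truth."""

    sample: str
    vote_sum: float
    predicted_class: str
    true_class: str
    gene_votes: pd.Series | None = None


def _signature_rows(ds: ExpressionDataset, sig: Signature) -> pd.DataFrame:
    present = [g for g in sig.genes if g in ds.values.index]
    n_missing = len(sig.genes) - len(present)
    if n_missing:
        log.info("%d signature genes missing from %s; dropped", n_missing, ds.platform_id)
    if not present:
        raise ValueError("no signature gene present in the dataset")
    return ds.values.loc[present]


def classify_sample_loo(
    ds: ExpressionDataset,
    sig: Signature,
    sample_id: str,
    strict_formula: bool = False,
    keep_gene_votes: bool = False,
) -> VoteResult:
    """Score one sample with class statistics fitted on everyone else."""
    if sample_id not in ds.samples:
        raise KeyError(sample_id)
    values = _signature_rows(ds, sig)
    rest = ds.samples.drop(sample_id)
    classes = ds.sample_classes[rest]
    if (classes == FO).sum() < 2 or (classes == PO).sum() < 2:
        raise ValueError("a class would be emptied (or reduced below 2) by holdout")
    stats = fit_wgv(values[rest], classes, strict_formula=strict_formula)
    usable = stats.usable
    if not usable.any():
        raise ValueError("no usable signature genes (all zero within-class stdev sum)")
    n_skipped = int((~usable).sum())
    if n_skipped:
        log.info("skipped %d zero-variance genes for sample %s", n_skipped, sample_id)
    s = values.loc[usable, sample_id]
    votes = stats.weight[usable] * (s - stats.midpoint[usable])
    vote_sum = float(votes.sum())
    return VoteResult(
        sample=sample_id,
        vote_sum=vote_sum,
        predicted_class=FO if vote_sum > 0 else PO,
        true_class=str(ds.sample_classes[sample_id]),
        gene_votes=votes if keep_gene_votes else None,
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationSummary:
    """Confusion counts and derived metrics, FO = positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None = None
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    votes: pd.DataFrame | None = None

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if (self.tn + self.fn) else float("nan")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else float("nan")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "ppv": self.ppv, "npv": self.npv,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "auc": self.auc,
            "logrank_chi2": self.logrank_chi2, "logrank_p": self.logrank_p,
        }


def confusion_from_counts(tp: int, fp: int, tn: int, fn: int) -> EvaluationSummary:
    """Metrics straight from a confusion matrix (no classifier run)."""
    for name, v in {"tp": tp, "fp": fp, "tn": tn, "fn": fn}.items():
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    return EvaluationSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def rank_auc(scores, labels) -> float | None:
    """Mann–Whitney AUC of ``scores`` for the FO class; ties mid-ranked.

    None when either true class is empty.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == FO]
    neg = scores[labels == PO]
    if len(pos) == 0 or len(neg) == 0:
        return None
    ranks = pd.Series(scores).rank(method="average").to_numpy()
    r_pos = ranks[labels == FO].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def logrank_test(group1, group2) -> tuple[float, float]:
    """Two-group log-rank test.

    Each group is a sequence of ``(time, event)`` pairs; returns
    ``(chi_square, p)`` with p from a 1-df chi-square.
    """
    g1 = np.asarray(list(group1), dtype=float)
    g2 = np.asarray(list(group2), dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups need at least one subject")
    events = np.concatenate([g1[:, 1], g2[:, 1]])
    if events.sum() == 0:
        raise ValueError("no events in either group")
    res = _lifelines_logrank(
        durations_A=g1[:, 0], durations_B=g2[:, 0],
        event_observed_A=g1[:, 1], event_observed_B=g2[:, 1],
    )
    return float(res.test_statistic), float(res.p_value)


def evaluate_cohort(
    ds: ExpressionDataset,
    sig: Signature,
    strict_formula: bool = False,
) -> EvaluationSummary:
    """LOO-classify every sample and summarize.

    Fills confusion counts (FO positive), derived metrics, rank AUC on
    the vote sums, and — when the dataset has survival annotations and
    both predicted classes are non-empty with at least one event — the
    log-rank comparison of predicted classes.
    """
    results = [
        classify_sample_loo(ds, sig, s, strict_formula=strict_formula)
        for s in ds.samples
    ]
    votes = pd.DataFrame(
        {
            "sample": [r.sample for r in results],
            "vote_sum": [r.vote_sum for r in results],
            "predicted": [r.predicted_class for r in results],
            "true": [r.true_class for r in results],
        }
    )
    pred = votes["predicted"].to_numpy()
    true = votes["true"].to_numpy()
    summary = EvaluationSummary(
        tp=int(((pred == FO) & (true == FO)).sum()),
        fp=int(((pred == FO) & (true == PO)).sum()),
        tn=int(((pred == PO) & (true == PO)).sum()),
        fn=int(((pred == PO) & (true == FO)).sum()),
        auc=rank_auc(votes["vote_sum"].to_numpy(), true),
        votes=votes,
    )

    if ds.survival is not None and (pred == FO).any() and (pred == PO).any():
        surv = ds.survival.loc[votes["sample"]]
        g_fo = list(zip(surv["time"][pred == FO], surv["event"][pred == FO]))
        g_po = list(zip(surv["time"][pred == PO], surv["event"][pred == PO]))
        try:
            chi2, p = logrank_test(g_fo, g_po)
            summary.logrank_chi2, summary.logrank_p = chi2, p
        except ValueError:
            log.info("log-rank skipped: no events")
    return summary


def km_curves(ds: ExpressionDataset, votes: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier survival curve per predicted class, as a tidy table."""
    from lifelines import KaplanMeierFitter

    frames = []
    surv = ds.survival.loc[votes["sample"]]
    for label in (FO, PO):
        mask = (votes["predicted"] == label).to_numpy()
        if not mask.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(surv["time"][mask], surv["event"][mask], label=label)
        df = kmf.survival_function_.reset_index()
        df.columns = ["time", "survival"]
        df["predicted"] = label
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
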