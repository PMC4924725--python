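"""Probe collapse, universe intersection, and the lymph-contamination filter."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rrhosig.dataset import FO, PO, ExpressionDataset

log = logging.getLogger(__name__)


@dataclass
class LymphClassifierRanges:
    """Per-gene upper bounds of expression in the PO group.

    ``upper_bound`` is indexed by classifier gene (or probe) symbol;
    an FO sample exceeding its bound on ``min_votes`` or more classifiers
    is flagged as lymph-node contaminated.
    """

    upper_bound: pd.Series
    min_votes: int = 3

    def __post_init__(self) -> None:
        if self.min_votes > len(self.upper_bound):
            raise ValueError("min_votes exceeds the number of classifier genes")

    @property
    def classifier_genes(self) -> list[str]:
        return list(self.upper_bound.index)


def collapse_probes(ds: ExpressionDataset, stat_per_probe: pd.Series) -> ExpressionDataset:
    """Collapse to one row per gene, keeping the probe with the largest |score|.

    Ties break on the lexicographically smallest probe id. Probes lacking
    a gene mapping are dropped (logged). The returned dataset is indexed
    by gene symbol.
    """
    stat_per_probe = pd.Series(stat_per_probe)
    missing = ds.probes.difference(stat_per_probe.index)
    if len(missing):
        raise ValueError(f"stat_per_probe missing probes: {list(missing[:5])}")

    tbl = pd.DataFrame(
        {
            "probe": ds.probes,
            "gene": ds.probe_to_gene.values,
            "absstat": stat_per_probe.reindex(ds.probes).abs().values,
        }
    )
    unmapped = tbl["gene"].isna() | (tbl["gene"] == "")
    if unmapped.any():
        log.info("dropping %d probes without gene mapping", int(unmapped.sum()))
        tbl = tbl[~unmapped]

    # argmax |score| per gene; ties -> smallest probe id
    tbl = tbl.sort_values(["gene", "absstat", "probe"], ascending=[True, False, True])
    winners = tbl.drop_duplicates("gene", keep="first")

    values = ds.values.loc[winners["probe"].values]
    values.index = winners["gene"].values
    return ExpressionDataset(
        values=values,
        probe_to_gene=pd.Series(winners["gene"].values, index=winners["gene"].values),
        sample_classes=ds.sample_classes.copy(),
        survival=None if ds.survival is None else ds.survival.copy(),
        platform_id=ds.platform_id,
    )


def collapse_probes_by_t(ds: ExpressionDataset) -> ExpressionDataset:
    """Collapse using each probe's |t| between FO and PO as the score."""
    from rrhosig.ranking import t_statistics

    t, _ = t_statistics(ds)
    return collapse_probes(ds, pd.Series(t, index=ds.probes))


def intersect_universe(ds_list: list[ExpressionDataset]) -> list[ExpressionDataset]:
    """Restrict gene-level datasets to their common gene set, same order."""
    if not ds_list:
        raise ValueError("need at least one dataset")
    common = ds_list[0].values.index
    for ds in ds_list[1:]:
        common = common.intersection(ds.values.index)
    if len(common) == 0:
        sizes = [len(ds.values.index) for ds in ds_list]
        raise ValueError(f"empty gene intersection across datasets (sizes {sizes})")
    common = common.sort_values()
    return [ds.subset_probes(common) for ds in ds_list]


def fit_lymph_ranges(
    ds: ExpressionDataset, classifier_genes, min_votes: int = 3
) -> LymphClassifierRanges:
    """Upper bound per classifier = maximum expression over PO samples."""
    classifier_genes = list(classifier_genes)
    for g in classifier_genes:
        if g not in ds.values.index:
            raise ValueError(f"classifier gene {g!r} absent from dataset")
    po = ds.class_samples(PO)
    if len(po) == 0:
        raise ValueError("no PO samples to fit classifier ranges on")
    upper = ds.values.loc[classifier_genes, po].max(axis=1)
    return LymphClassifierRanges(upper_bound=upper, min_votes=min_votes)


def filter_fo_samples(
    ds: ExpressionDataset, ranges: LymphClassifierRanges
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Drop FO samples exceeding the PO range on >= min_votes classifiers.

    Returns the filtered dataset and a report table (sample, votes,
    offending genes). PO samples are never excluded; exceed means strictly
    greater than the fitted upper bound.
    """
    genes = ranges.classifier_genes
    vals = ds.values.loc[genes]
    over = vals.gt(ranges.upper_bound, axis=0)  # classifier × sample
    votes = over.sum(axis=0)
    is_fo = ds.sample_classes == FO
    excluded_mask = is_fo & (votes >= ranges.min_votes)
    excluded = ds.samples[excluded_mask.values]

    rows = []
    for s in excluded:
        offending = [g for g in genes if over.at[g, s]]
        rows.append({"sample": s, "votes": int(votes[s]), "genes": ";".join(offending)})
    report = pd.DataFrame(rows, columns=["sample", "votes", "genes"])
    kept = ds.subset_samples(ds.samples.difference(excluded, sort=False))
    if len(excluded):
        log.info("lymph filter excluded %d FO samples", len(excluded))
    return kept, report
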