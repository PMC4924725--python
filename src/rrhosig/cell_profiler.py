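"""Cell-type profiling: count signature probes with high enrichment scores.

The enrichment table is a dense probe/gene × cell-type score matrix (TSV,
first column the probe or gene symbol). A signature entry contributes one
count to a cell type for every matching table row whose score exceeds the
threshold (strictly), mirroring per-probe counting.
"""

from __future__ import annotations

import logging

import pandas as pd

from rrhosig.signature import Signature

log = logging.getLogger(__name__)

DEFAULT_ES_THRESHOLD = 700.0


def read_enrichment_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    return table.set_index(table.columns[0]).astype(float)


def write_enrichment_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="probe")


def count_high_es(
    sig: Signature, table: pd.DataFrame, threshold: float = DEFAULT_ES_THRESHOLD
) -> pd.Series:
    """Per cell type: number of signature probes scoring strictly > threshold.

    Signature genes absent from the table are skipped (logged); if none
    remain the call is rejected.
    """
    if not table.notna().all().all():
        raise ValueError("enrichment table contains non-finite scores")
    present = [g for g in sig.genes if g in table.index]
    n_missing = len(sig.genes) - len(present)
    if not present:
        raise ValueError("no signature gene found in the enrichment table")
    if n_missing:
        log.info("%d signature genes absent from enrichment table", n_missing)
    sub = table.loc[present]
    return (sub > threshold).sum(axis=0).astype(int)


def top_cell_types(counts: pd.Series, k: int = 10) -> pd.DataFrame:
    """Top-k cell types by high-score probe count, ties alphabetical."""
    if k <= 0:
        raise ValueError("k must be positive")
    if len(counts) == 0:
        raise ValueError("empty counts")
    df = pd.DataFrame({"cell_type": counts.index, "count": counts.values})
    df = df.sort_values(["count", "cell_type"], ascending=[False, True], kind="stable")
    df = df.head(k).reset_index(drop=True)
    df["rank"] = df.index + 1
    return df[["cell_type", "count", "rank"]]
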