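"""Expression dataset container and its TSV dialect.

The on-disk format is a plain TSV with the first column holding the probe
id, the second the gene symbol, and the remaining columns one sample each.
Sample annotations travel in a companion TSV with columns
``sample``, ``class`` and, optionally, ``time`` and ``event``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FO = "FO"
PO = "PO"
CLASS_LABELS = (FO, PO)


@dataclass
class ExpressionDataset:
    """Probe × sample expression matrix with class and survival annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Continuous (log-intensity scale) expression, indexed by probe id,
        one column per sample.
    probe_to_gene : pandas.Series
        Maps each probe id to exactly one gene symbol. Genes may own
        several probes.
    sample_classes : pandas.Series
        Per-sample label, either ``"FO"`` or ``"PO"``, indexed by sample id.
    survival : pandas.DataFrame or None
        Optional per-sample ``time`` (months, > 0) and ``event`` (0/1),
        indexed by sample id; must cover all samples when present.
    platform_id : str
        Free-text identifier of the originating platform/study.
    """

    values: pd.DataFrame
    probe_to_gene: pd.Series
    sample_classes: pd.Series
    survival: pd.DataFrame | None = None
    platform_id: str = ""

    def __post_init__(self) -> None:
        self.probe_to_gene = self.probe_to_gene.reindex(self.values.index)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated probe ids: {dups[:5]}")
        if self.probe_to_gene.isna().any():
            missing = self.probe_to_gene.index[self.probe_to_gene.isna()].tolist()
            raise ValueError(f"probes without gene mapping: {missing[:5]}")
        self.sample_classes = self.sample_classes.reindex(self.values.columns)
        if self.sample_classes.isna().any():
            raise ValueError("every sample needs a class label")
        bad = set(self.sample_classes.unique()) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        if self.survival is not None:
            self.survival = self.survival.reindex(self.values.columns)
            if self.survival[["time", "event"]].isna().any().any():
                raise ValueError("survival annotations must cover all samples")

    # -- basic accessors -------------------------------------------------

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def genes(self) -> pd.Index:
        return pd.Index(pd.unique(self.probe_to_gene.values))

    def class_samples(self, label: str) -> pd.Index:
        return self.samples[self.sample_classes.values == label]

    @property
    def n_fo(self) -> int:
        return int((self.sample_classes == FO).sum())

    @property
    def n_po(self) -> int:
        return int((self.sample_classes == PO).sum())

    def subset_samples(self, samples) -> "ExpressionDataset":
        samples = pd.Index(samples)
        return ExpressionDataset(
            values=self.values[samples],
            probe_to_gene=self.probe_to_gene.copy(),
            sample_classes=self.sample_classes[samples],
            survival=None if self.survival is None else self.survival.loc[samples],
            platform_id=self.platform_id,
        )

    def subset_probes(self, probes) -> "ExpressionDataset":
        probes = pd.Index(probes)
        return ExpressionDataset(
            values=self.values.loc[probes],
            probe_to_gene=self.probe_to_gene[probes],
            sample_classes=self.sample_classes.copy(),
            survival=None if self.survival is None else self.survival.copy(),
            platform_id=self.platform_id,
        )

    # -- I/O -------------------------------------------------------------

    def to_tsv(self, expr_path, annot_path) -> None:
        """Write the expression matrix and the sample annotation table."""
        out = pd.DataFrame({"probe": self.values.index, "gene": self.probe_to_gene.values})
        out = pd.concat([out.set_index(self.values.index), self.values], axis=1)
        out.to_csv(expr_path, sep="\t", index=False)

        annot = pd.DataFrame({"sample": self.samples, "class": self.sample_classes.values})
        if self.survival is not None:
            annot["time"] = self.survival["time"].values
            annot["event"] = self.survival["event"].values.astype(int)
        annot.to_csv(annot_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, expr_path, annot_path, platform_id: str = "") -> "ExpressionDataset":
        expr = pd.read_csv(expr_path, sep="\t")
        expr = expr.set_index(expr.columns[0])
        gene_col = expr.columns[0]
        probe_to_gene = expr[gene_col].astype(str)
        values = expr.drop(columns=[gene_col]).astype(float)

        annot = pd.read_csv(annot_path, sep="\t").set_index("sample")
        survival = None
        if {"time", "event"}.issubset(annot.columns) and annot["time"].notna().all():
            survival = annot[["time", "event"]].astype(float)
        name = platform_id or Path(str(expr_path)).stem
        return cls(
            values=values,
            probe_to_gene=probe_to_gene,
            sample_classes=annot["class"].astype(str),
            survival=survival,
            platform_id=name,
        )


def class_matrices(ds: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
    """Return (FO matrix, PO matrix) as probe × sample arrays."""
    fo = ds.values[ds.class_samples(FO)].to_numpy()
    po = ds.values[ds.class_samples(PO)].to_numpy()
    return fo, po
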