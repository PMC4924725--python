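"""Pairwise RRHO orchestration and intersection into a conserved signature."""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rrhosig.ranking import RankedList
from rrhosig.rrho import OverlapResult, RRHOMap, quadrant_max


@dataclass
class PairwiseOverlap:
    """One pair's RRHO outcome."""

    pair: tuple[str, str]
    result: OverlapResult
    rmap: RRHOMap
    universe_size: int


@dataclass
class Signature:
    """Ordered gene set common to every pairwise quadrant overlap.

    ``provenance[g]`` lists the pairs whose overlap set contained ``g``
    (all pairs, by the intersection invariant). ``genes`` is ordered by
    total rank across the input lists, ties alphabetical.
    """

    genes: list[str]
    provenance: dict[str, list[str]]
    pairwise: list[PairwiseOverlap]
    quadrant: str = "FO-FO"

    def __len__(self) -> int:
        return len(self.genes)

    def to_text(self, path) -> None:
        Path(path).write_text("".join(g + "\n" for g in self.genes))

    def to_json(self, path) -> None:
        payload = {
            "quadrant": self.quadrant,
            "n_genes": len(self.genes),
            "genes": self.genes,
            "provenance": self.provenance,
            "pairwise": [
                {
                    "pair": list(p.pair),
                    "universe_size": p.universe_size,
                    **p.result.to_dict(),
                }
                for p in self.pairwise
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_gene_list(cls, genes) -> "Signature":
        """Minimal signature wrapping an externally provided gene list."""
        genes = [str(g).strip() for g in genes if str(g).strip()]
        return cls(genes=genes, provenance={g: [] for g in genes}, pairwise=[])


def _pair_label(rl1: RankedList, rl2: RankedList, i1: int, i2: int) -> tuple[str, str]:
    a = rl1.dataset_id or f"list{i1}"
    b = rl2.dataset_id or f"list{i2}"
    return (a, b)


def build_signature(
    ranked_lists: list[RankedList],
    step: int | None = None,
    quadrant: str = "FO-FO",
) -> Signature:
    """Intersect every pair's maximal quadrant-overlap gene set.

    Each unordered pair is re-ranked on its own common gene universe
    before mapping, so platforms with unequal universes are compared on
    exactly the genes they share.
    """
    if len(ranked_lists) < 2:
        raise ValueError("need at least two ranked lists")

    pairwise: list[PairwiseOverlap] = []
    for (i1, rl1), (i2, rl2) in itertools.combinations(enumerate(ranked_lists), 2):
        common = set(rl1.genes) & set(rl2.genes)
        a, b = rl1.restrict(common), rl2.restrict(common)
        try:
            rmap, result = quadrant_max(a, b, step=step, quadrant=quadrant)
        except ValueError as exc:
            raise ValueError(
                f"pair {_pair_label(rl1, rl2, i1, i2)}: {exc}"
            ) from exc
        pairwise.append(
            PairwiseOverlap(
                pair=_pair_label(rl1, rl2, i1, i2),
                result=result,
                rmap=rmap,
                universe_size=len(common),
            )
        )

    gene_sets = [set(p.result.genes) for p in pairwise]
    core = set.intersection(*gene_sets)

    # order: total rank across all input lists, ties alphabetical
    positions = [{g: r for r, g in enumerate(rl.genes)} for rl in ranked_lists]
    def total_rank(g: str) -> int:
        return sum(pos.get(g, len(pos)) for pos in positions)

    ordered = sorted(core, key=lambda g: (total_rank(g), g))
    labels = ["|".join(p.pair) for p in pairwise]
    provenance = {
        g: [lab for lab, s in zip(labels, gene_sets) if g in s] for g in ordered
    }
    return Signature(genes=ordered, provenance=provenance, pairwise=pairwise, quadrant=quadrant)


def signature_report(sig: Signature) -> pd.DataFrame:
    """Per-pair overlap sizes and map maxima, plus the final intersection row."""
    rows = [
        {
            "pair": "|".join(p.pair),
            "universe_size": p.universe_size,
            "i_star": p.result.i_star,
            "j_star": p.result.j_star,
            "neglog_p_max": p.result.neglog_p_max,
            "n_overlap": len(p.result.genes),
        }
        for p in sig.pairwise
    ]
    rows.append(
        {
            "pair": "intersection",
            "universe_size": np.nan,
            "i_star": np.nan,
            "j_star": np.nan,
            "neglog_p_max": np.nan,
            "n_overlap": len(sig.genes),
        }
    )
    return pd.DataFrame(rows)
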