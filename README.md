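# rrhosig

Cross-study discovery of a favorable-outcome gene signature from two-class
expression cohorts, and outcome classification with that signature.

The pipeline:

1. **simulate** — generate multi-platform two-class (FO/PO) expression
   datasets with overlapping gene universes, a planted FO-overexpressed
   gene set, lymph-node-contaminated samples, survival times, and a
   cell-type enrichment-score fixture (`rrhosig.simulate`).
2. **preprocess** — collapse probes to genes (argmax |t| per gene),
   restrict to the common gene universe, and drop FO samples whose
   expression exceeds the poor-outcome range on ≥3 of 6 lymph-node
   classifier genes (`rrhosig.preprocess`).
3. **rank** — order genes by `sign(mean_FO − mean_PO) × (−log10 p)` from a
   two-sample Student's t-test (`rrhosig.ranking`).
4. **rrho** — rank-rank hypergeometric overlap: a −log10 tail-p map over
   all rank-threshold pairs, computed in log space so universes of tens of
   thousands of genes never underflow; per-quadrant maxima and
   overlapping-gene extraction (`rrhosig.rrho`).
5. **signature** — run RRHO on every cohort pair and intersect the
   favorable-quadrant overlap sets into a conserved signature
   (`rrhosig.signature`).
6. **profile** — rank cell/tissue types by the number of signature probes
   with enrichment score >700 (`rrhosig.cell_profiler`).
7. **classify** — weighted gene voting with signal-to-noise weights and
   leave-one-out class statistics; confusion metrics, rank AUC, and
   Kaplan-Meier/log-rank evaluation of predicted classes
   (`rrhosig.classifier`).

## CLI

Each stage runs standalone on TSV files; `run-all` chains everything on a
simulated study:

```bash
# simulate a 3-platform study with planted truth
rrhosig simulate --seed 7 --out out/sim

# rank one platform, compare two ranked lists
rrhosig rank out/sim/P0_expr.tsv out/sim/P0_annot.tsv --out out/P0_ranked.tsv
rrhosig rank out/sim/P1_expr.tsv out/sim/P1_annot.tsv --out out/P1_ranked.tsv
rrhosig rrho out/P0_ranked.tsv out/P1_ranked.tsv --out-prefix out/P0_P1

# full pipeline: simulate → filter → rank → RRHO → signature → profile → WGV
rrhosig run-all --seed 7 --out out/run

# classify an independent cohort with an existing signature
rrhosig classify cohort_expr.tsv cohort_annot.tsv out/run/signature.txt \
    --out-prefix out/validation
```

Expression TSVs have columns `probe`, `gene`, then one column per sample;
annotations have `sample`, `class` (`FO`/`PO`) and optional `time`/`event`.

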