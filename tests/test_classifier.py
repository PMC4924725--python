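import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sp_stats

from rrhosig.classifier import (
    EvaluationSummary,
    classify_sample_loo,
    confusion_from_counts,
    evaluate_cohort,
    fit_wgv,
    gene_vote,
    km_curves,
    logrank_test,
    rank_auc,
)
from rrhosig.dataset import FO, PO
from rrhosig.preprocess import collapse_probes_by_t
from rrhosig.signature import Signature
from rrhosig.simulate import SimulationConfig, generate_study

from conftest import make_dataset


def simple_stats(mean_fo=2.0, mean_po=0.0, sd=0.5, strict=False):
    from rrhosig.classifier import WGVStatistics

    idx = ["g"]
    return WGVStatistics(
        mean_fo=pd.Series([mean_fo], index=idx),
        mean_po=pd.Series([mean_po], index=idx),
        sd_fo=pd.Series([sd], index=idx),
        sd_po=pd.Series([sd], index=idx),
        strict_formula=strict,
    )


class TestGeneVote:
    def test_worked_arithmetic(self):
        # W = 2/(0.5+0.5) = 2; midpoint 1; S=1.5 -> vote 1.0
        assert gene_vote(simple_stats(), "g", 1.5) == pytest.approx(1.0)

    def test_midpoint_gives_zero(self):
        assert gene_vote(simple_stats(), "g", 1.0) == pytest.approx(0.0)

    def test_label_swap_negates(self):
        swapped = simple_stats(mean_fo=0.0, mean_po=2.0)
        assert gene_vote(simple_stats(), "g", 1.7) == pytest.approx(
            -gene_vote(swapped, "g", 1.7)
        )

    def test_zero_stdev_rejected(self):
        with pytest.raises(ValueError, match="stdev"):
            gene_vote(simple_stats(sd=0.0), "g", 1.0)

    def test_strict_formula_pivot(self):
        # strict mode pivots on (mean_FO - mean_PO)/2 = 1 (same value here),
        # differs when means are not symmetric about their midpoint
        s = simple_stats(mean_fo=3.0, mean_po=1.0, strict=True)
        assert gene_vote(s, "g", 1.0) == pytest.approx(2.0 * (1.0 - 1.0))
        s2 = simple_stats(mean_fo=3.0, mean_po=1.0, strict=False)
        assert gene_vote(s2, "g", 1.0) == pytest.approx(2.0 * (1.0 - 2.0))


def separable_cohort(n_per_class=6, n_genes=8, seed=0, effect=5.0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(0, 1, size=(n_genes, 2 * n_per_class))
    vals[:, :n_per_class] += effect
    survival = np.column_stack([
        np.concatenate([rng.exponential(60, n_per_class),
                        rng.exponential(10, n_per_class)]),
        np.ones(2 * n_per_class),
    ])
    return make_dataset(vals, classes=[FO] * n_per_class + [PO] * n_per_class,
                        survival=survival)


class TestClassifySampleLOO:
    def test_separable_cohort_all_correct(self):
        ds = separable_cohort()
        sig = Signature.from_gene_list(ds.values.index)
        for s in ds.samples:
            r = classify_sample_loo(ds, sig, s)
            assert r.predicted_class == r.true_class

    def test_duplicated_column_matches_twin_non_loo(self):
        ds = separable_cohort(n_per_class=4)
        vals = ds.values.copy()
        vals["s_twin"] = vals["s0"]
        classes = ds.sample_classes.copy()
        classes["s_twin"] = classes["s0"]
        ds2 = make_dataset(vals.to_numpy(), genes=vals.index,
                           classes=list(classes.values))
        ds2.values.columns = vals.columns
        ds2 = type(ds2)(
            values=pd.DataFrame(vals.to_numpy(), index=vals.index,
                                columns=vals.columns),
            probe_to_gene=pd.Series(vals.index, index=vals.index),
            sample_classes=classes,
        )
        sig = Signature.from_gene_list(vals.index)
        # LOO on the twin: statistics still contain s0, identical values
        r_twin = classify_sample_loo(ds2, sig, "s_twin")
        stats_all = fit_wgv(ds2.values.drop(columns=["s_twin"]),
                            ds2.sample_classes.drop("s_twin"))
        votes = stats_all.weight * (ds2.values["s0"] - stats_all.midpoint)
        assert r_twin.vote_sum == pytest.approx(float(votes.sum()), rel=1e-10)

    def test_loo_integrity(self):
        # corrupting the held-out sample's values changes only S, not the stats
        ds = separable_cohort(seed=2)
        sig = Signature.from_gene_list(ds.values.index)
        target = "s0"
        base = classify_sample_loo(ds, sig, target)
        corrupted = ds.values.copy()
        corrupted[target] += 100.0
        ds2 = type(ds)(
            values=corrupted,
            probe_to_gene=ds.probe_to_gene,
            sample_classes=ds.sample_classes,
        )
        # stats fitted without the target are unchanged, so the vote shift
        # is exactly 100 × Σ weights — the held-out sample cannot influence
        # its own class statistics
        stats_wo = fit_wgv(ds.values.drop(columns=[target]),
                           ds.sample_classes.drop(target))
        shifted = classify_sample_loo(ds2, sig, target)
        expected_shift = 100.0 * float(stats_wo.weight[stats_wo.usable].sum())
        assert shifted.vote_sum - base.vote_sum == pytest.approx(
            expected_shift, rel=1e-10
        )

    def test_all_zero_variance_rejected(self):
        vals = np.tile([[1.0], [2.0]], (1, 8))
        vals[:, 4:] -= 1.0
        ds = make_dataset(vals, classes=[FO] * 4 + [PO] * 4)
        sig = Signature.from_gene_list(ds.values.index)
        with pytest.raises(ValueError, match="usable"):
            classify_sample_loo(ds, sig, "s0")

    def test_class_emptied_rejected(self):
        ds = separable_cohort(n_per_class=2)
        sig = Signature.from_gene_list(ds.values.index)
        with pytest.raises(ValueError, match="holdout"):
            classify_sample_loo(ds, sig, "s0")

    def test_missing_signature_genes_dropped(self):
        ds = separable_cohort()
        sig = Signature.from_gene_list(list(ds.values.index) + ["missing1"])
        r = classify_sample_loo(ds, sig, "s0")
        assert r.predicted_class == FO


class TestConfusionMetrics:
    def test_paper_set_d_counts(self):
        s = confusion_from_counts(tp=6, fp=1, tn=6, fn=1)
        assert round(s.ppv, 3) == 0.857
        assert round(s.npv, 3) == 0.857
        assert round(s.sensitivity, 3) == 0.857
        assert round(s.specificity, 3) == 0.857

    def test_paper_set_e_counts(self):
        s = confusion_from_counts(tp=26, fp=8, tn=20, fn=16)
        assert round(s.ppv, 3) == 0.765
        assert round(s.npv, 3) == 0.556
        assert round(s.specificity, 3) == 0.714
        assert round(s.sensitivity, 3) == 0.619

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            confusion_from_counts(tp=-1, fp=0, tn=0, fn=0)

    @given(
        tp=st.integers(0, 500), fp=st.integers(0, 500),
        tn=st.integers(0, 500), fn=st.integers(0, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_identities_hold(self, tp, fp, tn, fn):
        s = confusion_from_counts(tp=tp, fp=fp, tn=tn, fn=fn)
        if tp + fp:
            assert s.ppv == tp / (tp + fp) and 0 <= s.ppv <= 1
        if tn + fn:
            assert s.npv == tn / (tn + fn) and 0 <= s.npv <= 1
        if tp + fn:
            assert s.sensitivity == tp / (tp + fn)
        if tn + fp:
            assert s.specificity == tn / (tn + fp)


def brute_force_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == FO]
    neg = [s for s, l in zip(scores, labels) if l == PO]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        scores = [3.0, 2.0, 1.0, -1.0, -2.0]
        labels = [FO, FO, FO, PO, PO]
        assert rank_auc(scores, labels) == 1.0

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 50))
            scores = rng.integers(-3, 4, size=n).astype(float)  # many ties
            labels = rng.choice([FO, PO], size=n)
            if (labels == FO).any() and (labels == PO).any():
                assert rank_auc(scores, labels) == pytest.approx(
                    brute_force_auc(scores, labels), abs=1e-12
                )

    def test_empty_class_returns_none(self):
        assert rank_auc([1.0, 2.0], [FO, FO]) is None

    def test_label_swap_maps_to_complement(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=20)
        labels = np.array([FO, PO] * 10)
        swapped = np.where(labels == FO, PO, FO)
        a = rank_auc(scores, labels)
        # fixed scores, swapped labels: AUC -> 1 - AUC
        assert rank_auc(scores, swapped) == pytest.approx(1 - a, abs=1e-12)
        # negated scores and swapped labels (a global class relabel): invariant
        assert rank_auc(-scores, swapped) == pytest.approx(a, abs=1e-12)


def oracle_logrank(group1, group2):
    """Direct O−E enumeration over distinct event times."""
    data = [(t, e, 0) for t, e in group1] + [(t, e, 1) for t, e in group2]
    event_times = sorted({t for t, e, _ in data if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = [(tt, ee, g) for tt, ee, g in data if tt >= t]
        n = len(at_risk)
        n1 = sum(1 for _, _, g in at_risk if g == 0)
        d = sum(1 for tt, ee, _ in at_risk if tt == t and ee == 1)
        d1 = sum(1 for tt, ee, g in at_risk if tt == t and ee == 1 and g == 0)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, float(sp_stats.chi2.sf(chi2, df=1))


class TestLogrank:
    def test_identical_groups_null(self):
        g = [(1.0, 1), (2.0, 1), (3.0, 0)]
        chi2, p = logrank_test(g, list(g))
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_matches_enumeration_oracle_separated(self):
        g1 = [(1.0, 1), (2.0, 1), (3.0, 1)]
        g2 = [(4.0, 1), (5.0, 1), (6.0, 1)]
        chi2, p = logrank_test(g1, g2)
        exp_chi2, exp_p = oracle_logrank(g1, g2)
        assert chi2 == pytest.approx(exp_chi2, abs=1e-10)
        assert p == pytest.approx(exp_p, abs=1e-10)

    def test_matches_oracle_with_censoring_and_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            g1 = [(float(rng.integers(1, 8)), int(rng.random() < 0.8))
                  for _ in range(8)]
            g2 = [(float(rng.integers(1, 8)), int(rng.random() < 0.8))
                  for _ in range(8)]
            if not any(e for _, e in g1 + g2):
                continue
            chi2, _ = logrank_test(g1, g2)
            exp_chi2, _ = oracle_logrank(g1, g2)
            assert chi2 == pytest.approx(exp_chi2, abs=1e-8)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            logrank_test([(1.0, 0)], [(2.0, 0)])

    def test_planted_survival_power_smoke(self):
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(n_platforms=1, genes_per_platform=20,
                                   shared_gene_fraction=1.0, n_signature_genes=2,
                                   n_fo=35, n_po=35, seed=seed,
                                   survival_scale_fo=60.0, survival_scale_po=12.0)
            (ds,), _ = generate_study(cfg)
            fo = ds.class_samples(FO)
            po = ds.class_samples(PO)
            g1 = list(zip(ds.survival.loc[fo, "time"], ds.survival.loc[fo, "event"]))
            g2 = list(zip(ds.survival.loc[po, "time"], ds.survival.loc[po, "event"]))
            _, p = logrank_test(g1, g2)
            hits += p < 0.05
        assert hits >= 18


class TestEvaluateCohort:
    def test_separable_cohort_perfect(self):
        ds = separable_cohort(n_per_class=6, seed=3)
        sig = Signature.from_gene_list(ds.values.index)
        s = evaluate_cohort(ds, sig)
        assert (s.tp, s.tn, s.fp, s.fn) == (6, 6, 0, 0)
        assert s.auc == 1.0
        assert s.accuracy == 1.0
        assert s.logrank_p is not None

    def test_global_label_swap_antisymmetry(self):
        ds = separable_cohort(n_per_class=5, seed=4, effect=1.0)
        flipped_classes = [PO if c == FO else FO for c in ds.sample_classes]
        ds2 = make_dataset(ds.values.to_numpy(), genes=ds.values.index,
                           classes=flipped_classes)
        sig = Signature.from_gene_list(ds.values.index)
        a = evaluate_cohort(ds, sig)
        b = evaluate_cohort(ds2, sig)
        np.testing.assert_allclose(
            a.votes["vote_sum"].to_numpy(),
            -b.votes["vote_sum"].to_numpy(), atol=1e-10,
        )
        assert (a.tp, a.fp, a.tn, a.fn) == (b.tn, b.fn, b.tp, b.fp)
        # votes negate AND the positive class flips, so the pipeline AUC is
        # invariant; the 1−AUC mapping holds at fixed scores (see TestAUC)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)

    def test_auc_equals_brute_force(self):
        ds = separable_cohort(n_per_class=8, seed=6, effect=0.5)
        sig = Signature.from_gene_list(ds.values.index)
        s = evaluate_cohort(ds, sig)
        assert s.auc == pytest.approx(
            brute_force_auc(s.votes["vote_sum"], s.votes["true"]), abs=1e-12
        )

    def test_km_curves_start_at_one(self):
        ds = separable_cohort(n_per_class=6, seed=7)
        sig = Signature.from_gene_list(ds.values.index)
        s = evaluate_cohort(ds, sig)
        km = km_curves(ds, s.votes)
        for _, grp in km.groupby("predicted"):
            assert grp.sort_values("time")["survival"].iloc[0] == 1.0
            assert (grp["survival"].diff().dropna() <= 1e-12).all()
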