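import numpy as np
import pandas as pd
import pytest

from fdot.reader_stats import (
    DiagnosticTable,
    binary_auc,
    cohen_kappa,
    diagnostic_metrics,
    fleiss_kappa,
    load_ratings_csv,
    paired_tests,
    ratings_from_calls,
    save_ratings_csv,
    simulate_ratings,
)

# 13 cancers / 14 non-cancers: the six reading sessions of the two-reader
# clinical study, counts reconstructed from the printed percentages
STUDY_TABLES = {
    ("reader1", "dbt"): DiagnosticTable(tp=12, fp=5, fn=1, tn=9),
    ("reader1", "dot"): DiagnosticTable(tp=8, fp=2, fn=5, tn=12),
    ("reader1", "fusion"): DiagnosticTable(tp=13, fp=1, fn=0, tn=13),
    ("reader2", "dbt"): DiagnosticTable(tp=12, fp=3, fn=1, tn=11),
    ("reader2", "dot"): DiagnosticTable(tp=8, fp=3, fn=5, tn=11),
    ("reader2", "fusion"): DiagnosticTable(tp=13, fp=2, fn=0, tn=12),
}

PRINTED = {  # (sens, spec, ppv, npv, auc)
    ("reader1", "dbt"): (92.3, 64.3, 70.6, 90.0, 0.783),
    ("reader1", "dot"): (61.5, 85.7, 80.0, 70.6, 0.736),
    ("reader1", "fusion"): (100.0, 92.9, 92.9, 100.0, 0.964),
    ("reader2", "dbt"): (92.3, 78.6, 80.0, 91.7, 0.854),
    ("reader2", "dot"): (61.5, 78.6, 72.7, 68.8, 0.701),
    ("reader2", "fusion"): (100.0, 85.7, 86.7, 100.0, 0.929),
}


def study_ratings() -> pd.DataFrame:
    """Per-subject calls consistent with every printed table: marginals from
    the 2x2 counts, reader overlaps fixed by the printed McNemar p-values
    and agreement statistics."""
    truth = np.array([True] * 13 + [False] * 14)

    def calls(cancer_pos, control_pos):
        v = np.zeros(27, dtype=bool)
        v[list(cancer_pos)] = True
        v[[13 + i for i in control_pos]] = True
        return v

    # cancers indexed 0..12, controls 0..13.  Reader 1 misses cancer 12 on
    # DBT but catches it on DOT (and vice versa for reader 2 with cancer
    # 11): that reproduces the printed McNemar p = 0.219 for the DBT-vs-DOT
    # sensitivity comparison (5 vs 1 discordant cancers) for both readers.
    return ratings_from_calls(
        truth,
        {
            ("reader1", "dbt"): calls(range(12), [0, 1, 2, 3, 4]),
            ("reader2", "dbt"): calls(list(range(11)) + [12], [0, 1, 2]),
            ("reader1", "dot"): calls(list(range(7)) + [12], [0, 1]),
            ("reader2", "dot"): calls(list(range(7)) + [11], [0, 1, 2]),
            # fusion: all cancers; false positives overlap on control 0
            ("reader1", "fusion"): calls(range(13), [0]),
            ("reader2", "fusion"): calls(range(13), [0, 1]),
        },
    )


class TestDiagnosticMetrics:
    @pytest.mark.parametrize("key", sorted(STUDY_TABLES))
    def test_reproduces_printed_study_values(self, key):
        t = STUDY_TABLES[key]
        m = diagnostic_metrics(t)
        sens, spec, ppv, npv, auc = PRINTED[key]
        assert round(m["sensitivity"]["value"], 1) == sens
        assert round(m["specificity"]["value"], 1) == spec
        assert round(m["ppv"]["value"], 1) == ppv
        assert round(m["npv"]["value"], 1) == npv
        assert round(binary_auc(t)["auc"], 3) == auc

    def test_wilson_intervals_match_printed_style(self):
        m = diagnostic_metrics(STUDY_TABLES[("reader1", "dbt")])
        assert round(m["sensitivity"]["ci_low"], 1) == 66.7
        assert round(m["sensitivity"]["ci_high"], 1) == 98.6
        assert round(m["specificity"]["ci_low"], 1) == 38.8
        assert round(m["specificity"]["ci_high"], 1) == 83.7

    def test_clopper_pearson_available_and_wider(self):
        t = STUDY_TABLES[("reader1", "dbt")]
        wilson = diagnostic_metrics(t)["sensitivity"]
        exact = diagnostic_metrics(t, ci_method="beta")["sensitivity"]
        assert exact["ci_low"] < wilson["ci_low"]

    def test_empty_stratum_reported_undefined(self):
        m = diagnostic_metrics(DiagnosticTable(tp=0, fp=3, fn=0, tn=7))
        assert m["sensitivity"] is None
        assert m["specificity"] is not None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            DiagnosticTable(tp=-1, fp=0, fn=0, tn=0)


class TestBinaryAuc:
    def test_delong_interval_matches_printed_dbt_row(self):
        a = binary_auc(STUDY_TABLES[("reader1", "dbt")])
        assert round(a["auc"], 3) == 0.783
        assert round(a["ci_low"], 3) == 0.632
        assert round(a["ci_high"], 3) == 0.933

    def test_perfect_reader(self):
        a = binary_auc(DiagnosticTable(tp=13, fp=0, fn=0, tn=14))
        assert a["auc"] == 1.0

    def test_equals_half_sens_plus_spec_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            tp, fn = rng.integers(1, 20, 2)
            fp, tn = rng.integers(1, 20, 2)
            t = DiagnosticTable(int(tp), int(fp), int(fn), int(tn))
            sens = tp / (tp + fn)
            spec = tn / (tn + fp)
            assert binary_auc(t)["auc"] == pytest.approx(
                (sens + spec) / 2.0, abs=1e-12
            )

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError, match="strata"):
            binary_auc(DiagnosticTable(tp=0, fp=3, fn=0, tn=7))

    def test_random_calls_have_null_auc_half(self):
        rng = np.random.default_rng(42)
        aucs = []
        for _ in range(1000):
            truth = np.arange(30) < 14
            call = rng.random(30) < 0.5
            t = DiagnosticTable(
                tp=int((call & truth).sum()), fp=int((call & ~truth).sum()),
                fn=int((~call & truth).sum()), tn=int((~call & ~truth).sum()),
            )
            if t.n_diseased and t.n_healthy:
                aucs.append(binary_auc(t)["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.02


class TestAgreement:
    def test_perfect_two_rater_agreement(self):
        truth = np.arange(10) < 5
        calls = truth.copy()
        r = ratings_from_calls(
            truth, {("r1", "m"): calls, ("r2", "m"): calls}
        )
        assert fleiss_kappa(r, "m", n_boot=10).kappa == pytest.approx(1.0)

    def test_fusion_configuration_gives_printed_kappa(self):
        r = study_ratings()
        fk = fleiss_kappa(r, "fusion", n_boot=100, seed=0)
        assert round(fk.kappa, 3) == 0.926
        assert round(cohen_kappa(r, "fusion"), 3) == 0.926

    def test_study_two_rater_kappas_match_printed_cohen_form(self):
        """The printed agreement values for all three modalities are the
        two-rater (product-marginal) kappas; the pooled-marginal Fleiss
        form differs from them only in the third decimal."""
        r = study_ratings()
        assert round(cohen_kappa(r, "dbt"), 3) == 0.695
        assert round(cohen_kappa(r, "dot"), 3) == 0.767
        assert round(cohen_kappa(r, "fusion"), 3) == 0.926
        assert abs(fleiss_kappa(r, "dbt", n_boot=10).kappa - 0.695) < 0.003
        assert abs(fleiss_kappa(r, "dot", n_boot=10).kappa - 0.767) < 0.002

    def test_independent_raters_have_near_zero_kappa(self):
        rng = np.random.default_rng(7)
        truth = rng.random(1000) < 0.5
        r = ratings_from_calls(
            truth,
            {
                ("r1", "m"): rng.random(1000) < 0.4,
                ("r2", "m"): rng.random(1000) < 0.4,
            },
        )
        assert abs(fleiss_kappa(r, "m", n_boot=10).kappa) < 0.05

    def test_two_rater_fleiss_equals_pooled_marginal_closed_form(self):
        rng = np.random.default_rng(11)
        for trial in range(100):
            n = rng.integers(8, 40)
            truth = rng.random(n) < 0.5
            a = rng.random(n) < rng.uniform(0.2, 0.8)
            b = rng.random(n) < rng.uniform(0.2, 0.8)
            if (a.sum() + b.sum()) in (0, 2 * n):
                continue  # degenerate: single category
            r = ratings_from_calls(truth, {("r1", "m"): a, ("r2", "m"): b})
            po = float((a == b).mean())
            p = (a.sum() + b.sum()) / (2.0 * n)
            pe = p**2 + (1 - p) ** 2
            expected = (po - pe) / (1 - pe)
            got = fleiss_kappa(r, "m", n_boot=2).kappa
            assert got == pytest.approx(expected, abs=1e-10)

    def test_degenerate_single_category_reported_nan(self):
        truth = np.arange(6) < 3
        calls = np.ones(6, dtype=bool)
        r = ratings_from_calls(truth, {("r1", "m"): calls, ("r2", "m"): calls})
        assert np.isnan(fleiss_kappa(r, "m", n_boot=5).kappa)

    def test_bootstrap_reproducible_bit_exact(self):
        r = study_ratings()
        a = fleiss_kappa(r, "dbt", n_boot=500, seed=123)
        b = fleiss_kappa(r, "dbt", n_boot=500, seed=123)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        c = fleiss_kappa(r, "dbt", n_boot=500, seed=124)
        assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)

    def test_bootstrap_interval_covers_known_agreement(self):
        """Two raters flip a latent truth independently with probability
        eps: true kappa = (1-2 eps)^2.  The 95% bootstrap CI should cover
        it in at least ~90% of replicates at n = 60."""
        eps = 0.15
        true_kappa = (1.0 - 2.0 * eps) ** 2
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            z = rng.random(60) < 0.5
            a = z ^ (rng.random(60) < eps)
            b = z ^ (rng.random(60) < eps)
            r = ratings_from_calls(
                z, {("r1", "m"): a, ("r2", "m"): b}
            )
            fk = fleiss_kappa(r, "m", n_boot=300,
                              seed=int(rng.integers(1 << 31)))
            if fk.ci_low <= true_kappa <= fk.ci_high:
                hits += 1
        assert hits / n_rep >= 0.90


class TestPairedTests:
    def test_identical_calls_give_p_one(self):
        r = study_ratings()
        dup = r[r.modality == "dbt"].copy()
        dup["modality"] = "dbt2"
        both = pd.concat([r[r.modality == "dbt"], dup])
        out = paired_tests(both, "dbt", "dbt2", "reader1")
        assert out["mcnemar_p"] == 1.0
        assert out["delong"]["auc_difference"] == 0.0
        assert out["delong"]["p"] == 1.0

    def test_five_vs_zero_discordant_closed_form(self):
        r = study_ratings()
        out = paired_tests(r, "dot", "fusion", "reader1")
        # reader 1 finds 5 extra cancers on fusion, loses none
        assert out["mcnemar_p_diseased"] == pytest.approx(2 * 0.5**5)

    def test_printed_sensitivity_mcnemar_pvalues(self):
        r = study_ratings()
        dbt_dot = paired_tests(r, "dbt", "dot", "reader1")
        assert round(dbt_dot["mcnemar_p_diseased"], 3) == 0.219
        dbt_fus = paired_tests(r, "dbt", "fusion", "reader1")
        assert dbt_fus["mcnemar_p_diseased"] == 1.0

    def test_mcnemar_matches_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        from fdot.reader_stats import _mcnemar_exact

        rng = np.random.default_rng(3)
        for _ in range(50):
            b, c = (int(v) for v in rng.integers(0, 12, 2))
            table = [[5, b], [c, 5]]
            expected = sm_mcnemar(table, exact=True).pvalue
            assert _mcnemar_exact(b, c) == pytest.approx(expected, abs=1e-12)

    def test_delong_detects_a_large_paired_difference(self):
        truth = np.arange(60) < 30
        good = truth.copy()
        bad = truth.copy()
        bad[:12] = ~bad[:12]  # misses 12 of 30 cancers
        r = ratings_from_calls(
            truth,
            {("r1", "good"): good, ("r1", "bad"): bad},
        )
        out = paired_tests(r, "good", "bad", "r1")
        assert out["delong"]["auc_difference"] == pytest.approx(0.2)
        assert out["delong"]["p"] < 0.01


class TestSimulatorAndIO:
    def test_simulated_marginals_match_requested_accuracy(self):
        r = simulate_ratings(
            4000, 4000, sensitivity=0.9, specificity=0.7,
            n_readers=2, seed=0,
        )
        t = DiagnosticTable.from_ratings(r, "reader1", "sim")
        assert t.tp / t.n_diseased == pytest.approx(0.9, abs=0.02)
        assert t.tn / t.n_healthy == pytest.approx(0.7, abs=0.02)

    def test_subject_effect_raises_agreement(self):
        low = simulate_ratings(300, 300, 0.8, 0.8, subject_effect=0.2, seed=1)
        high = simulate_ratings(300, 300, 0.8, 0.8, subject_effect=3.0, seed=1)
        k_low = fleiss_kappa(low, "sim", n_boot=5).kappa
        k_high = fleiss_kappa(high, "sim", n_boot=5).kappa
        assert k_high > k_low + 0.2

    def test_csv_roundtrip(self, tmp_path):
        r = study_ratings()
        path = tmp_path / "ratings.csv"
        save_ratings_csv(path, r)
        back = load_ratings_csv(path)
        pd.testing.assert_frame_equal(back, r)
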