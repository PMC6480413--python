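"""Stratified CV, Dirichlet test resampling, Wilcoxon signed-rank."""

import numpy as np
import pytest
from scipy import stats

from vanbc import (
    MultinomialVANB,
    OneVsRestVANB,
    PairedSeries,
    VADataset,
    dirichlet_resample_test,
    generate,
    make_separable_spec,
    run_cv,
    stratified_kfold,
    wilcoxon_signed_rank,
)

from conftest import random_dataset


class TestStratifiedKFold:
    def test_partition_is_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(1)
        ds = random_dataset(rng, n=45, s=5, m=3)
        plan = stratified_kfold(ds, k=5, seed=0)
        all_idx = np.concatenate([plan.test_indices(f) for f in range(5)])
        assert sorted(all_idx.tolist()) == list(range(ds.n_records))

    def test_exact_stratification_when_divisible(self):
        # 100 records; one cause has exactly 30 -> 3 per fold with k=10
        y = np.array(["A"] * 30 + ["B"] * 70, dtype=object)
        X = np.random.default_rng(0).integers(0, 2, (100, 4))
        ds = VADataset([str(i) for i in range(100)], list("wxyz"), X, y)
        plan = stratified_kfold(ds, k=10, seed=3)
        for f in range(10):
            fold_y = ds.y[plan.test_indices(f)]
            assert (fold_y == "A").sum() == 3
            assert (fold_y == "B").sum() == 7

    def test_within_cause_fold_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(5)
        ds = random_dataset(rng, n=47, s=4, m=3)
        plan = stratified_kfold(ds, k=4, seed=1)
        for c in ds.causes:
            sizes = [
                int((ds.y[plan.test_indices(f)] == c).sum()) for f in range(4)
            ]
            assert max(sizes) - min(sizes) <= 1

    def test_seed_controls_shuffle(self):
        rng = np.random.default_rng(6)
        ds = random_dataset(rng, n=60, s=4, m=3)
        a = stratified_kfold(ds, k=5, seed=7).assignments
        b = stratified_kfold(ds, k=5, seed=7).assignments
        c = stratified_kfold(ds, k=5, seed=8).assignments
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_k_larger_than_n_rejected(self):
        rng = np.random.default_rng(2)
        ds = random_dataset(rng, n=6, s=3, m=2)
        with pytest.raises(ValueError, match="exceeds"):
            stratified_kfold(ds, k=7)


class TestRunCV:
    def test_separable_data_perfect_at_rank_one(self, separable_dataset):
        res = run_cv(
            separable_dataset,
            {"OAA-NBC": OneVsRestVANB(), "NBC": MultinomialVANB()},
            k=10, max_rank=5, seed=0,
        )
        for r in res.values():
            assert r.mean_metric_at("sensitivity", 1) == 1.0
            assert r.mean_metric_at("csmf_accuracy", 1) == 1.0
            assert r.mean_metric_at("pccc", 1) == 1.0

    def test_two_fold_toy_hand_checkable(self):
        # 4 balanced records, k=2: each member trains on one record per
        # cause; separable signatures make every fold perfect.
        ds = VADataset(
            ["1", "2", "3", "4"], ["sA", "sB"],
            np.array([[1, 0], [0, 1], [1, 0], [0, 1]]),
            np.array(["A", "B", "A", "B"], dtype=object),
        )
        res = run_cv(ds, {"NBC": MultinomialVANB()}, k=2, max_rank=2, seed=0)
        r = res["NBC"]
        assert len(r.fold_results) == 2
        for fold in r.fold_results:
            assert fold.metric_at("sensitivity", 1) == 1.0
        assert r.mean_metric_at("sensitivity", 2) == 1.0

    def test_rank_m_sensitivity_one_in_every_fold(self):
        rng = np.random.default_rng(9)
        ds = random_dataset(rng, n=60, s=6, m=3)
        res = run_cv(ds, {"NBC": MultinomialVANB()}, k=3, seed=4)
        for fold in res["NBC"].fold_results:
            assert fold.metric_at("sensitivity", 3) == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        ds = random_dataset(rng, n=50, s=5, m=3)
        a = run_cv(ds, {"OAA-NBC": OneVsRestVANB()}, k=5, seed=2)["OAA-NBC"]
        b = run_cv(ds, {"OAA-NBC": OneVsRestVANB()}, k=5, seed=2)["OAA-NBC"]
        assert a.mean_per_rank.equals(b.mean_per_rank)

    def test_training_fold_missing_cause_errors(self):
        # cause "C" has a single record: with k=2 one training part lacks it
        y = np.array(["A"] * 5 + ["B"] * 5 + ["C"], dtype=object)
        X = np.random.default_rng(1).integers(0, 2, (11, 4))
        ds = VADataset([str(i) for i in range(11)], list("abcd"), X, y)
        with pytest.raises(ValueError, match="lacks cause"):
            run_cv(ds, {"NBC": MultinomialVANB()}, k=2, seed=0)

    def test_long_report_contains_fold_and_mean_rows(self):
        rng = np.random.default_rng(11)
        ds = random_dataset(rng, n=30, s=4, m=3)
        res = run_cv(ds, {"NBC": MultinomialVANB()}, k=3, max_rank=2, seed=0)
        df = res["NBC"].to_long_frame()
        assert set(df["fold"]) == {"0", "1", "2", "mean"}
        assert set(df["metric"]) == {"sensitivity", "pccc", "csmf_accuracy"}


class TestDirichletResample:
    @pytest.fixture
    def test_set(self):
        rng = np.random.default_rng(20)
        return random_dataset(rng, n=90, s=6, m=3)

    def test_output_size_and_membership(self, test_set):
        rs = dirichlet_resample_test(test_set, seed=0)
        assert rs.n_records == test_set.n_records
        # records are copies of input records (same cause for same symptoms)
        originals = {
            (tuple(row), y) for row, y in zip(test_set.X.tolist(), test_set.y)
        }
        for row, y in zip(rs.X.tolist(), rs.y):
            assert (tuple(row), y) in originals

    def test_concentrated_weights_converge_to_observed_csmf(self, test_set):
        """Dirichlet with a huge concentration on the observed mix
        reproduces that mix up to multinomial noise."""
        target = test_set.csmf()
        c = 1e6 * target
        reps = [
            dirichlet_resample_test(test_set, concentration=c, seed=s).csmf()
            for s in range(30)
        ]
        # CLT band: multinomial sd per cause ~ sqrt(p(1-p)/N)/sqrt(reps)
        sd = np.sqrt(target * (1 - target) / test_set.n_records / len(reps))
        np.testing.assert_allclose(np.mean(reps, axis=0), target, atol=6 * np.max(sd) + 0.01)

    def test_symmetric_weights_vary_widely(self, test_set):
        fracs = np.array([
            [np.mean(rs.y == c) for c in test_set.causes]
            for rs in (dirichlet_resample_test(test_set, seed=s) for s in range(100))
        ])
        assert (fracs.std(axis=0) > 0.05).all()

    def test_separable_predictions_survive_resampling(self):
        ds = generate(make_separable_spec(M=5, N=200, seed=3))
        model = OneVsRestVANB(classes=ds.causes).fit(ds.X, ds.y)
        rs = dirichlet_resample_test(ds, seed=1)
        preds = model.predict_ranked(rs.X)
        assert all(p.ordered_causes[0] == t for p, t in zip(preds, rs.y))

    def test_invalid_concentration_rejected(self, test_set):
        with pytest.raises(ValueError, match="concentration"):
            dirichlet_resample_test(test_set, concentration=[1.0, -1.0, 1.0])


class TestWilcoxon:
    def test_exact_all_positive_small_n(self):
        s = PairedSeries(tuple(range(5)), np.arange(1.0, 6.0), np.zeros(5))
        res = wilcoxon_signed_rank(s, mode="exact")
        assert res.p_value == pytest.approx(2 / 2**5)
        assert res.statistic == 15.0

    @pytest.mark.parametrize("m", [4, 8, 12, 16])
    def test_exact_all_positive_is_two_over_two_to_m(self, m):
        s = PairedSeries(tuple(range(m)), np.arange(1.0, m + 1.0), np.zeros(m))
        assert wilcoxon_signed_rank(s, mode="exact").p_value == pytest.approx(2 / 2**m)

    def test_normal_approx_reproduces_published_p_at_35(self):
        s = PairedSeries(tuple(range(35)), np.arange(1.0, 36.0), np.zeros(35))
        res = wilcoxon_signed_rank(s, mode="normal_approx")
        assert res.z == pytest.approx(5.1594, abs=1e-4)
        assert res.p_value == pytest.approx(2.47e-7, abs=1e-9)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            d = rng.normal(0.3, 1.0, size=18)
            d = d[d != 0]
            s = PairedSeries(tuple(range(len(d))), d, np.zeros(len(d)))
            ours = wilcoxon_signed_rank(s, mode="normal_approx")
            ref = stats.wilcoxon(d, mode="approx", correction=False)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_exact_and_normal_agree_at_m15(self):
        """Sanity band for the normal approximation: within 10%
        relative error of exact enumeration wherever the exact p is
        moderate (>= 0.05). In the far tail the relative error of any
        central-limit approximation grows without bound, so tail draws
        are outside the band's domain of validity."""
        rng = np.random.default_rng(55)
        moderate = 0
        for _ in range(15):
            d = rng.normal(0.0, 1.0, size=15)
            s = PairedSeries(tuple(range(15)), d, np.zeros(15))
            pe = wilcoxon_signed_rank(s, mode="exact").p_value
            pn = wilcoxon_signed_rank(s, mode="normal_approx").p_value
            if pe >= 0.05:
                moderate += 1
                assert pn == pytest.approx(pe, rel=0.10)
        assert moderate >= 10  # null series mostly land in the moderate regime

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.5, 1.0, size=12)
        b = np.zeros(12)
        f = wilcoxon_signed_rank(PairedSeries(tuple(range(12)), a, b), "normal_approx")
        r = wilcoxon_signed_rank(PairedSeries(tuple(range(12)), b, a), "normal_approx")
        assert f.z == pytest.approx(-r.z)
        assert f.p_value == pytest.approx(r.p_value)

    def test_zero_differences_dropped_then_all_zero_errors(self):
        s = PairedSeries(("x", "y"), np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="all paired differences are zero"):
            wilcoxon_signed_rank(s)

    def test_exact_limited_to_twenty(self):
        s = PairedSeries(tuple(range(21)), np.arange(1.0, 22.0), np.zeros(21))
        with pytest.raises(ValueError, match="m <= 20"):
            wilcoxon_signed_rank(s, mode="exact")
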