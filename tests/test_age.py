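"""Metagenomic-age protocol: splits, calibration, relative age, delay."""

import numpy as np
import pandas as pd
import pytest

from metage.age import (
    MetagenomicAge,
    balance_subsample,
    relative_ages,
    run_replicate_protocol,
    split_train_test,
    test_delay,
    train_age_regressor,
)
from metage.containers import FeatureTable

from conftest import toy_metadata


def balanced_metadata(n_per_tp, timepoints, cohort="A"):
    ids, ages = [], []
    for t in timepoints:
        for i in range(n_per_tp):
            ids.append(f"{cohort}_t{t:g}_{i}")
            ages.append(float(t))
    return toy_metadata(ids, ages, [cohort] * len(ids))


class TestSplitArithmetic:
    @pytest.mark.parametrize(
        "n_per,tps,train_pt,test_pt,n_train,n_test",
        [
            (23, (2, 4, 6, 9, 12), 16, 7, 80, 35),
            (29, (3, 4, 5, 6, 8, 10, 12, 14), 20, 9, 160, 72),
            (10, (2, 4, 6, 9, 12), 7, 3, 35, 15),
        ],
    )
    def test_seventy_thirty_floor_split(
        self, n_per, tps, train_pt, test_pt, n_train, n_test
    ):
        meta = balanced_metadata(n_per, tps)
        balanced, plan = balance_subsample(meta, "A", seed=0)
        assert len(balanced) == n_per * len(tps)
        assert plan.train_per_timepoint == train_pt
        assert plan.test_per_timepoint == test_pt
        assert plan.n_train == n_train and plan.n_test == n_test
        train, test = split_train_test(balanced, meta, plan, seed=1)
        assert len(train) == n_train and len(test) == n_test
        assert set(train).isdisjoint(test)
        assert set(train) | set(test) == set(balanced)
        ages = meta.ages_for(train)
        for t in tps:
            assert (ages == t).sum() == train_pt

    def test_undersized_timepoint_named_in_error(self):
        meta = balanced_metadata(8, (2, 4, 6))
        with pytest.raises(ValueError, match="time point 2"):
            balance_subsample(meta, "A", seed=0, n_per_timepoint=9)

    def test_subsample_is_deterministic_and_seed_sensitive(self):
        meta = balanced_metadata(20, (2, 4, 6, 9, 12))
        b1, _ = balance_subsample(meta, "A", seed=3, n_per_timepoint=10)
        b2, _ = balance_subsample(meta, "A", seed=3, n_per_timepoint=10)
        b3, _ = balance_subsample(meta, "A", seed=4, n_per_timepoint=10)
        assert b1 == b2 and b1 != b3


class TestRegressorContract:
    def test_needs_two_distinct_ages(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="distinct ages"):
            train_age_regressor(X, np.full(10, 4.0), n_trees=5)

    def test_constant_features_warn_but_train(self):
        rng = np.random.default_rng(0)
        X = np.ones((20, 4))
        ages = rng.choice([2.0, 12.0], 20)
        with pytest.warns(UserWarning):
            model = train_age_regressor(X, ages, n_trees=10)
        pred = model.predict(np.ones((5, 4)))
        assert np.all((pred >= 2.0) & (pred <= 12.0))


class FakeReplicate:
    """Hand-built replicate with known prediction and calibration."""

    def __init__(self, index, offset):
        self.index = index
        self.cohort = "A"
        self.offset = offset
        self.feature_ids = ["F0"]

    def predict(self, table, sample_ids):
        return table.data.loc["F0", sample_ids].to_numpy() + self.offset

    def spline(self, ages):
        return np.asarray(ages, dtype=float)  # identity calibration


class TestRelativeAges:
    def test_definition_and_count(self):
        ids = [f"s{i}" for i in range(6)]
        ages = [2.0, 2.0, 4.0, 4.0, 6.0, 6.0]
        meta = toy_metadata(ids, ages, ["B"] * 6)
        table = FeatureTable(
            pd.DataFrame([ages], index=["F0"], columns=ids), level="module"
        )
        reps = [FakeReplicate(1, 0.0), FakeReplicate(2, -1.5)]
        est = relative_ages(reps, table, meta, ids)
        assert len(est) == len(ids) * len(reps)
        # relative age = prediction - spline(true age), exactly
        r1 = est[est["replicate"] == 1]["relative_age"]
        np.testing.assert_allclose(r1, 0.0, atol=1e-12)
        r2 = est[est["replicate"] == 2]["relative_age"]
        np.testing.assert_allclose(r2, -1.5, atol=1e-12)

    def test_delay_test_on_constant_shift(self):
        ids = [f"s{i}" for i in range(10)]
        meta = toy_metadata(ids, [6.0] * 10, ["B"] * 10)
        table = FeatureTable(
            pd.DataFrame([[6.0] * 10], index=["F0"], columns=ids), level="module"
        )
        est = relative_ages([FakeReplicate(1, -1.0)], table, meta, ids)
        out = test_delay(est, 6.0)
        assert out.iloc[0]["p_value"] == pytest.approx(2 / 1024)
        assert bool(out.iloc[0]["significant_delay"])

    def test_delay_test_needs_five_estimates(self):
        ids = [f"s{i}" for i in range(3)]
        meta = toy_metadata(ids, [6.0] * 3, ["B"] * 3)
        table = FeatureTable(
            pd.DataFrame([[6.0] * 3], index=["F0"], columns=ids), level="module"
        )
        est = relative_ages([FakeReplicate(1, -1.0)], table, meta, ids)
        with pytest.raises(ValueError, match="at least 5"):
            test_delay(est, 6.0)


class TestFullModel:
    def test_feature_mismatch_error(self, module_dataset):
        mods, meta, _ = module_dataset
        model = MetagenomicAge(mods, meta, n_replicates=1, n_trees=20)
        res = model.fit(seed=0)
        rep = res.replicates["A"][0]
        bad = FeatureTable(
            mods.data.iloc[:3].copy(), level="module", normalized=True
        )
        with pytest.raises(KeyError, match="missing"):
            rep.predict(bad, mods.sample_ids[:2])

    def test_spline_calibrated_on_own_test_set(self, module_dataset):
        mods, meta, _ = module_dataset
        res = MetagenomicAge(mods, meta, n_replicates=2, n_trees=50).fit(seed=1)
        for rep in res.replicates["A"]:
            test_pred = rep.predict(mods, rep.test_ids)
            test_ages = meta.ages_for(rep.test_ids)
            # residuals about the spline average ~0 on its own test set
            resid = test_pred - rep.spline(test_ages)
            assert abs(resid.mean()) < 0.5

    def test_identical_cohorts_center_relative_age_at_zero(self):
        rng = np.random.default_rng(11)
        tps = [2.0, 4.0, 6.0, 9.0, 12.0]
        ids_a, ids_b, ages = [], [], []
        for t in tps:
            for i in range(10):
                ids_a.append(f"A_t{t:g}_{i}")
                ids_b.append(f"B_t{t:g}_{i}")
                ages.append(t)
        vals = rng.lognormal(0, 0.2, size=(20, 50))
        trend = np.outer(np.linspace(0.2, 1.5, 20), np.array(ages) / 12)
        half = vals + trend
        data = np.hstack([half, half])  # cohort B copies cohort A
        table = FeatureTable(
            pd.DataFrame(data, index=[f"F{i}" for i in range(20)],
                         columns=ids_a + ids_b),
            level="module",
        )
        meta = toy_metadata(ids_a + ids_b, ages + ages, ["A"] * 50 + ["B"] * 50)
        res = MetagenomicAge(table, meta, n_replicates=4, n_trees=100).fit(seed=2)
        pooled = pd.concat(res.relative_age_estimates.values())
        assert abs(pooled["relative_age"].median()) < 0.4

    def test_fit_is_deterministic(self, module_dataset):
        mods, meta, _ = module_dataset
        m = MetagenomicAge(mods, meta, n_replicates=2, n_trees=30)
        r1 = m.fit(seed=5)
        r2 = m.fit(seed=5)
        pd.testing.assert_frame_equal(r1.performance, r2.performance)
        pd.testing.assert_frame_equal(r1.delay_tests, r2.delay_tests)
        r3 = m.fit(seed=6)
        assert not r1.performance["r"].equals(r3.performance["r"])

    def test_delayed_cohort_recovers_negative_relative_age(self):
        from metage.profiling import aggregate_support, normalize_single_copy
        from metage.simulate import (
            SyntheticConfig,
            generate_hierarchy,
            generate_profiles,
            universal_ko_ids,
        )

        cfg = SyntheticConfig(seed=3)  # study-scale: 25 subjects, delay 2 mo
        table, meta, truth = generate_profiles(cfg)
        hier = generate_hierarchy(cfg)
        norm = normalize_single_copy(table, universal_ko_ids(cfg))
        mods, _ = aggregate_support(norm, hier, "module")
        assert truth.delay_months == 2.0
        res = MetagenomicAge(mods, meta, n_replicates=5, n_trees=150).fit(seed=3)
        final = max(meta.timepoints)
        assert res.median_relative_age("B", final) < 0
        # mirror property: the reference cohort sits above the delayed one
        assert res.median_relative_age("A", final) > res.median_relative_age(
            "B", final
        )
        d_b, _ = res.delay_fraction("B", final)
        assert d_b >= 0.6
        text = res.summary()
        assert "relative metagenomic age" in text.lower()

    def test_three_feature_sets_protocol(self, small_config, small_dataset):
        from metage.profiling import aggregate_support, normalize_single_copy
        from metage.simulate import generate_hierarchy, universal_ko_ids

        table, meta, _ = small_dataset
        hier = generate_hierarchy(small_config)
        norm = normalize_single_copy(table, universal_ko_ids(small_config))
        tables = {
            lv: aggregate_support(norm, hier, lv)[0] for lv in ("module", "pathway")
        }
        bundles = run_replicate_protocol(
            tables, meta, feature_sets=("module", "pathway", "both"),
            seed=4, n_replicates=2, n_trees=30,
        )
        assert set(bundles) == {"module", "pathway", "both"}
        n_both = bundles["both"].replicates["A"][0].regressor.n_features_in_
        assert n_both == len(tables["module"].feature_ids) + len(
            tables["pathway"].feature_ids
        )
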