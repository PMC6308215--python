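import math
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from ppbqsar.curation import CompoundRecord
from ppbqsar.descriptor_model import (
    DescriptorMatrix,
    VSURFSelector,
    compute_descriptors,
    cross_validate_q2,
    fit_rf,
    prefilter,
    regression_metrics,
    vsurf_select,
)


def rec(smiles, i=0):
    return CompoundRecord(id=f"r{i}", smiles_raw=smiles, smiles_std=smiles, fu=0.5)


class TestComputeDescriptors:
    def test_charge_and_aromatic_counts(self):
        X = compute_descriptors([rec("C", 0), rec("CC(=O)[O-]", 1), rec("c1ccccc1", 2)])
        assert X.data.loc["r0", "rdkit:total_charge"] == 0
        assert X.data.loc["r1", "rdkit:total_charge"] == -1
        assert X.data.loc["r2", "rdkit:aromatic_carbons"] == 6

    def test_empty_input(self):
        X = compute_descriptors([])
        assert X.data.empty

    def test_no_missing_values(self, small_dataset):
        X = compute_descriptors(small_dataset)
        assert not X.data.isna().any().any()
        assert len(X.data) + len(X.dropped_ids) == len(small_dataset)


class TestPrefilter:
    def test_constant_column_removed(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        out = prefilter(DescriptorMatrix(df))
        assert out.columns == ["a"]

    def test_duplicate_column(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        out = prefilter(DescriptorMatrix(df))
        assert out.columns == ["a"]

    def test_correlated_pair_drops_later(self, rng):
        c1 = rng.normal(size=200)
        df = pd.DataFrame(
            {"c1": c1, "c2": rng.normal(size=200), "c3": c1 + 1e-3 * rng.normal(size=200)}
        )
        # oracle: pairwise correlations
        assert abs(np.corrcoef(df["c1"], df["c3"])[0, 1]) > 0.95
        out = prefilter(DescriptorMatrix(df))
        assert out.columns == ["c1", "c2"]

    def test_row_order_invariant(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 6)), columns=list("abcdef"))
        out1 = prefilter(DescriptorMatrix(df))
        out2 = prefilter(DescriptorMatrix(df.iloc[::-1]))
        assert out1.columns == out2.columns


class TestRegressionMetrics:
    def test_perfect(self):
        r2, e = regression_metrics([0, 1, 2], [0, 1, 2])
        assert r2 == 1.0 and e == 0.0

    def test_hand_example(self):
        r2, e = regression_metrics([0, 1, 2], [0, 1, 4])
        assert r2 == pytest.approx(-1.0, abs=1e-12)
        assert e == pytest.approx(math.sqrt(4 / 3), abs=1e-12)

    def test_null_model(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        r2, _ = regression_metrics(obs, np.full(4, obs.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_obs_warns(self):
        with pytest.warns(UserWarning):
            r2, e = regression_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 0.0])
        assert math.isnan(r2) and e > 0

    def test_brute_force_oracle(self, rng):
        for _ in range(50):
            obs = rng.normal(size=20)
            pred = rng.normal(size=20)
            r2, e = regression_metrics(obs, pred)
            ybar = sum(obs) / len(obs)
            num = sum((o - p) ** 2 for o, p in zip(obs, pred))
            den = sum((o - ybar) ** 2 for o in obs)
            assert r2 == pytest.approx(1 - num / den, abs=1e-10)
            assert e == pytest.approx(math.sqrt(num / len(obs)), abs=1e-10)


class TestFitRf:
    def test_constant_target(self, rng):
        X = rng.normal(size=(30, 4))
        rf = fit_rf(X, np.full(30, 2.5), seed=0, n_estimators=20)
        assert np.allclose(rf.predict(X), 2.5)

    def test_learns_identity(self, rng):
        X = rng.normal(size=(200, 3))
        y = X[:, 0]
        rf = fit_rf(X, y, seed=0, n_estimators=200)
        r2, _ = regression_metrics(y, rf.predict(X))
        assert r2 > 0.95

    def test_deterministic(self, rng):
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        p1 = fit_rf(X, y, seed=7, n_estimators=30).predict(X)
        p2 = fit_rf(X, y, seed=7, n_estimators=30).predict(X)
        assert np.array_equal(p1, p2)

    def test_sqrt_candidates(self, rng):
        rf = fit_rf(rng.normal(size=(30, 9)), rng.normal(size=30), seed=0, n_estimators=5)
        assert rf.max_features == "sqrt"

    def test_too_small(self, rng):
        with pytest.raises(ValueError):
            fit_rf(rng.normal(size=(3, 2)), np.zeros(3))


class TestCrossValidateQ2:
    def test_predictable(self, rng):
        X = rng.normal(size=(200, 2))
        y = X[:, 0]
        q2, _ = cross_validate_q2(X, y, k=5, seed=0)
        assert q2 > 0.9

    def test_noise(self, rng):
        X = rng.normal(size=(60, 5))
        y = rng.normal(size=60)
        q2, _ = cross_validate_q2(X, y, k=5, seed=0)
        assert q2 <= 0.1

    def test_loo_runs(self, rng):
        X = rng.normal(size=(12, 2))
        q2, oof = cross_validate_q2(X, X[:, 0], k=12, seed=0)
        assert oof.shape == (12,)

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError):
            cross_validate_q2(rng.normal(size=(4, 2)), np.zeros(4), k=5)

    def test_q2_not_above_training_r2_on_average(self, rng):
        # out-of-fold prediction cannot beat resubstitution in expectation
        diffs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(40, 3))
            y = X[:, 0] + 0.5 * r.normal(size=40)
            rf = fit_rf(X, y, seed=seed, n_estimators=50)
            r2, _ = regression_metrics(y, rf.predict(X))
            factory = lambda s: RandomForestRegressor(  # noqa: E731
                n_estimators=50, max_features="sqrt", random_state=s, n_jobs=1
            )
            q2, _ = cross_validate_q2(X, y, k=5, seed=seed, model_factory=factory)
            diffs.append(r2 - q2)
        assert np.mean(diffs) > 0


class TestVSURF:
    def test_planted_signal(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(
            rng.normal(size=(300, 21)), columns=["x1"] + [f"n{i}" for i in range(20)]
        )
        y = 3 * X["x1"].to_numpy() + rng.normal(size=300)
        sel = VSURFSelector(n_estimators=100, n_forests=3, random_state=1).fit(X, y)
        assert "x1" in sel.selected_
        assert sel.selected_[0] == "x1"

    def test_null_small_selection(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(120, 10)), columns=[f"n{i}" for i in range(10)])
        y = rng.normal(size=120)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = VSURFSelector(n_estimators=80, n_forests=3, random_state=0).fit(X, y)
        assert len(sel.selected_) <= 2

    def test_single_column(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"only": rng.normal(size=50)})
        y = X["only"].to_numpy() + 0.1 * rng.normal(size=50)
        assert vsurf_select(X, y, params={"n_estimators": 50, "n_forests": 2}, seed=0) == ["only"]

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(80, 6)), columns=list("abcdef"))
        y = X["a"].to_numpy() + rng.normal(size=80)
        kw = dict(n_estimators=50, n_forests=2, random_state=5)
        assert VSURFSelector(**kw).fit(X, y).selected_ == VSURFSelector(**kw).fit(X, y).selected_

    def test_too_few_rows(self):
        X = pd.DataFrame({"a": range(10)})
        with pytest.raises(ValueError):
            VSURFSelector().fit(X, np.arange(10.0))
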