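"""Pseudobulk aging clock: binning, ridge fit vs closed form, acceleration."""

import numpy as np
import pandas as pd
import pytest

from scicomb.clock import (ClockModel, age_acceleration, fit_clock,
                           make_pseudobulk)
from scicomb.fixtures import make_clock_cells


@pytest.fixture(scope="module")
def noiseless():
    return make_clock_cells(noise="none", seed=3)


@pytest.fixture(scope="module")
def noisy():
    return make_clock_cells(noise="nb", seed=4)


class TestPseudobulk:
    def test_thirty_cells_make_two_bins(self):
        expr = pd.DataFrame(np.ones((30, 3)), index=[f"c{i}" for i in range(30)])
        meta = pd.DataFrame({"animal": "a1", "cell_type": "T"}, index=expr.index)
        animals = pd.DataFrame({"age_months": [3.0]}, index=["a1"])
        pb = make_pseudobulk(expr, meta, animals, k=15, seed=0)
        assert len(pb) == 2
        assert pb["n_cells"].sum() == 30

    def test_identical_cells_average_to_profile(self):
        expr = pd.DataFrame(np.full((20, 2), 7.0), index=[f"c{i}" for i in range(20)])
        meta = pd.DataFrame({"animal": "a1", "cell_type": "T"}, index=expr.index)
        animals = pd.DataFrame({"age_months": [6.0]}, index=["a1"])
        pb = make_pseudobulk(expr, meta, animals, k=15, seed=0)
        assert (pb[[0, 1]].to_numpy() == 7.0).all()
        assert (pb["ln_age"] == np.log(6.0)).all()

    def test_small_groups_dropped_and_binning_deterministic(self, noisy):
        expr, cmeta, ameta, _ = noisy
        pb1 = make_pseudobulk(expr, cmeta, ameta, k=15, seed=0)
        pb2 = make_pseudobulk(expr, cmeta, ameta, k=15, seed=0)
        pd.testing.assert_frame_equal(pb1, pb2)
        tiny = cmeta.iloc[:5]
        with pytest.raises(ValueError, match="k/2"):
            make_pseudobulk(expr.loc[tiny.index], tiny, ameta, k=15, seed=0)


def ridge_closed_form(X, y, alpha):
    """(X'X + alpha I)^-1 X'y on centered data — the normal-equations oracle."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(X.shape[1]), Xc.T @ yc)
    intercept = y.mean() - X.mean(axis=0) @ beta
    return beta, intercept


class TestFitClock:
    def test_ridge_matches_closed_form_oracle(self, noisy, config):
        expr, cmeta, ameta, _ = noisy
        pb = make_pseudobulk(expr, cmeta, ameta, k=15, seed=0)
        alpha = 2.5
        models = fit_clock(pb, config, seed=0, penalty=alpha)
        m, _ = models["T0"]
        tr_animals = set(m.train_animals)
        tr = pb["animal"].isin(tr_animals).to_numpy()
        X = (pb[m.features].to_numpy() - m.feature_mean) / m.feature_std
        beta, b0 = ridge_closed_form(X[tr], pb["ln_age"].to_numpy()[tr], alpha)
        np.testing.assert_allclose(m.coefficients, beta, atol=1e-8)
        assert m.intercept == pytest.approx(b0, abs=1e-8)

    def test_noiseless_linear_fixture_predicted_exactly(self, noiseless, config):
        expr, cmeta, ameta, _ = noiseless
        pb = make_pseudobulk(expr, cmeta, ameta, k=15, seed=0)
        m, hold = fit_clock(pb, config, seed=0, penalty=0.0)["T0"]
        assert len(hold) > 0
        np.testing.assert_allclose(hold["predicted_ln_age"], hold["ln_age"], atol=1e-6)

    def test_noisy_fixture_holdout_r2(self, noisy, config):
        expr, cmeta, ameta, _ = noisy
        pb = make_pseudobulk(expr, cmeta, ameta, k=15, seed=0)
        m, hold = fit_clock(pb, config, seed=0)["T0"]
        resid = hold["predicted_ln_age"] - hold["ln_age"]
        r2 = 1 - (resid**2).sum() / ((hold["ln_age"] - hold["ln_age"].mean()) ** 2).sum()
        assert r2 > 0.9

    def test_no_animal_in_both_splits(self, noisy, config):
        expr, cmeta, ameta, _ = noisy
        pb = make_pseudobulk(expr, cmeta, ameta, k=15, seed=0)
        m, hold = fit_clock(pb, config, seed=0)["T0"]
        assert not (set(hold["animal"]) & set(m.train_animals))

    def test_age_independent_expression_predicts_training_mean(self, config):
        rng = np.random.default_rng(9)
        pb = pd.DataFrame(rng.normal(size=(60, 20)))
        pb["animal"] = np.repeat([f"a{i}" for i in range(12)], 5)
        pb["cell_type"] = "T"
        pb["n_cells"] = 15
        ages = {f"a{i}": [3.0, 6.0, 21.0][i % 3] for i in range(12)}
        pb["ln_age"] = np.log(pb["animal"].map(ages).astype(float))
        m, hold = fit_clock(pb, config, seed=0)["T"]
        spread = np.abs(hold["predicted_ln_age"] - pb["ln_age"].mean())
        assert spread.mean() < 0.5

    def test_too_few_ages_skipped(self, config):
        pb = pd.DataFrame({"g": [1.0, 2, 3, 4]})
        pb["animal"] = ["a", "a", "b", "b"]
        pb["cell_type"] = "T"
        pb["n_cells"] = 15
        pb["ln_age"] = np.log([3.0, 3.0, 6.0, 6.0])
        with pytest.raises(ValueError, match="3 distinct ages"):
            fit_clock(pb, config, seed=0)


class TestAcceleration:
    def test_older_profiles_labeled_young_show_positive_delta(self, noisy, config):
        expr, cmeta, ameta, _ = noisy
        pb = make_pseudobulk(expr, cmeta, ameta, k=15, seed=0)
        m, _ = fit_clock(pb, config, seed=0)["T0"]
        # 6-month transcriptomes from the same gene-age law, labeled 3 months
        expr6, cmeta6, ameta6, _ = make_clock_cells(
            ages_months=(6.0,), n_animals_per_age=2, noise="nb", seed=4
        )
        pb6 = make_pseudobulk(expr6, cmeta6, ameta6, k=15, seed=0)
        acc = age_acceleration(m, pb6[m.features], np.full(len(pb6), np.log(3.0)))
        assert acc.mean() > 0.3

    def test_in_distribution_delta_near_zero(self, noisy, config):
        expr, cmeta, ameta, _ = noisy
        pb = make_pseudobulk(expr, cmeta, ameta, k=15, seed=0)
        m, hold = fit_clock(pb, config, seed=0)["T0"]
        hold_profiles = pb.loc[pb["animal"].isin(hold["animal"]), m.features]
        lnages = pb.loc[hold_profiles.index, "ln_age"]
        acc = age_acceleration(m, hold_profiles, lnages)
        assert abs(acc.mean()) < 0.2

    def test_gene_order_permutation_invariant(self, noisy, config):
        expr, cmeta, ameta, _ = noisy
        pb = make_pseudobulk(expr, cmeta, ameta, k=15, seed=0)
        m, _ = fit_clock(pb, config, seed=0)["T0"]
        prof = pb[m.features].iloc[:5]
        a1 = age_acceleration(m, prof, np.log([3.0] * 5))
        a2 = age_acceleration(m, prof[list(reversed(m.features))], np.log([3.0] * 5))
        pd.testing.assert_series_equal(a1, a2)

    def test_model_json_round_trip(self, noisy, config, tmp_path):
        expr, cmeta, ameta, _ = noisy
        pb = make_pseudobulk(expr, cmeta, ameta, k=15, seed=0)
        m, _ = fit_clock(pb, config, seed=0)["T0"]
        m.to_json(tmp_path / "clock.json")
        back = ClockModel.from_json(tmp_path / "clock.json")
        prof = pb[m.features].iloc[:3]
        np.testing.assert_allclose(back.predict(prof), m.predict(prof))
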