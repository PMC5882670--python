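"""Recruitment, incomer proportions, movement, anomaly flags."""

import warnings

import numpy as np
import pandas as pd
import pytest

import vitalrates as vr
from vitalrates.recruitment import (
    fit_recruitment,
    fit_size_at_age0,
    flag_anomalous_cohorts,
    incomer_proportion,
    lagged_density_correlation,
    movement_analysis,
)


class TestIncomerProportion:
    def test_zero_without_immigration(self):
        cfg = vr.SimConfig(
            occasions=vr.biannual_occasions("2004-09-15", 9),
            recruitment_mean=80, immigration_rate=0.0, seed=5,
        )
        enc, _ = vr.simulate_population(cfg)
        inc = incomer_proportion(enc)
        assert (inc["proportion"].dropna() == 0).all()

    def test_all_incomers_without_recruitment(self):
        cfg = vr.SimConfig(
            occasions=vr.biannual_occasions("2004-09-15", 7),
            recruitment_mean=0.0, immigration_rate=30.0, n_pre_cohorts=0,
            immigrant_age_classes=(2, 3), seed=6,
            true_growth=vr.GrowthParams(
                log_k=np.log(0.3), log_linf=np.log(330.0), t0=-0.2,
            ),
        )
        enc, _ = vr.simulate_population(cfg)
        inc = incomer_proportion(enc)
        props = inc["proportion"].dropna()
        assert len(props) and (props == 1).all()

    def test_matches_standing_mixture(self, default_sim):
        """Estimated proportions track the generator's late-incomer share."""
        _, enc, truth = default_sim
        inc = incomer_proportion(enc)
        est = inc["proportion"].dropna().iloc[3:]
        fish = truth.fish
        dates = vr.SimConfig(seed=0).dates
        shares = []
        for k, d in enumerate(dates):
            if d.month != 9 or k < 6:
                continue
            present = (fish["entry_occasion"] <= k) & (fish["death_occasion"] > k)
            older = present & (d.year - fish["cohort"] >= 1) & (fish["cohort"] >= 2004)
            shares.append((fish.loc[older, "origin"] == "late").mean())
        se = est.std() / np.sqrt(len(est))
        assert abs(est.mean() - np.mean(shares)) < max(3 * se, 0.04)

    def test_tagging_threshold_only_affects_carry_forward(self):
        """The intact-fin component of the numerator is threshold-free.

        Raising the threshold so nothing gets tagged removes only the
        tag-carried reclassification of previously clipped incomers: the
        untagged variant is a lower bound that coincides at the first
        classifiable occasion."""
        props = {}
        for thr in (115.0, 400.0):
            cfg = vr.SimConfig(
                occasions=vr.biannual_occasions("2004-09-15", 9),
                tagging_threshold=thr, seed=42,
            )
            enc, _ = vr.simulate_population(cfg)
            props[thr] = incomer_proportion(enc)["proportion"].dropna().to_numpy()
        assert props[115.0][0] == pytest.approx(props[400.0][0], abs=1e-12)
        assert (props[400.0] <= props[115.0] + 1e-12).all()


class TestLaggedCorrelation:
    def test_exact_copy_gives_unit_correlation(self):
        years = np.arange(2004, 2012)
        d0 = np.array([5.0, 8, 2, 9, 4, 7, 3, 6])
        series = pd.DataFrame({"year": years, "d0": d0, "dgt0": np.r_[0.0, d0[:-1]]})
        res = lagged_density_correlation(series, lags=(1,))
        assert res["r"].iloc[0] == pytest.approx(1.0)

    def test_arithmetic_oracle(self):
        series = pd.DataFrame(
            {
                "year": [2004, 2005, 2006, 2007, 2008, 2009],
                "d0": [3.0, 1.0, 4.0, 1.0, 5.0, 9.0],
                "dgt0": [2.0, 6.0, 5.0, 3.0, 5.0, 8.0],
            }
        )
        res = lagged_density_correlation(series, lags=(1,))
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        y = np.array([6.0, 5.0, 3.0, 5.0, 8.0])
        r_hand = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert res["r"].iloc[0] == pytest.approx(r_hand, abs=1e-12)

    def test_insufficient_overlap_errors(self):
        series = pd.DataFrame({"year": [2004, 2005, 2006], "d0": [1, 2, 3], "dgt0": [1, 2, 3]})
        with pytest.raises(ValueError, match="4"):
            lagged_density_correlation(series, lags=(1,))

    def test_independent_series_mostly_insignificant(self):
        rng = np.random.default_rng(15)
        n_sig = 0
        for _ in range(30):
            series = pd.DataFrame(
                {
                    "year": np.arange(2004, 2016),
                    "d0": rng.normal(4000, 500, 12),
                    "dgt0": rng.normal(5000, 600, 12),
                }
            )
            res = lagged_density_correlation(series, lags=(1,))
            n_sig += int(res["p"].iloc[0] < 0.05)
        assert n_sig <= 3  # ~ nominal 5% false-positive rate


class TestRecruitmentModels:
    def test_strong_density_signal_wins(self):
        rng = np.random.default_rng(7)
        ds = rng.uniform(2000, 6000, 12)
        series = pd.DataFrame(
            {
                "year": np.arange(2004, 2016),
                "r": 0.5 * ds + rng.normal(0, 50, 12),
                "ds_lag1": ds,
                "gdd_spring": rng.normal(400, 40, 12),
            }
        )
        table, _ = fit_recruitment(series)
        assert "Ds(t-1)" in table.iloc[0]["model"]

    def test_null_competitive_without_signal(self):
        """Pure-noise recruitment: the no-predictor model is ranked first or
        has equal explanatory power (delta-AIC < 2) in >= 60% of replicates."""
        rng = np.random.default_rng(17)
        hits = 0
        n_rep = 30
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(n_rep):
                series = pd.DataFrame(
                    {
                        "year": np.arange(2004, 2014),
                        "r": 3000 + rng.normal(0, 300, 10),
                        "ds_lag1": 3000 + rng.normal(0, 400, 10),
                        "gdd_spring": 400 + rng.normal(0, 40, 10),
                    }
                )
                table, _ = fit_recruitment(series)
                if table[table["model"] == "R ~ 1"]["delta_aic"].iloc[0] < 2:
                    hits += 1
        assert hits / n_rep >= 0.6

    def test_too_few_years_errors(self):
        series = pd.DataFrame(
            {"year": [2004, 2005], "r": [1.0, 2.0], "ds_lag1": [1, 2], "gdd_spring": [1, 2]}
        )
        with pytest.raises(ValueError):
            fit_recruitment(series)


class TestSizeAtAge0:
    def _series(self, noise=0.0, slope=-0.4, seed=0, n=9):
        rng = np.random.default_rng(seed)
        d = rng.uniform(3000, 8000, n)
        gdd = rng.normal(1100, 60, n)
        logl = 5.0 + slope * np.log(d) + rng.normal(0, noise, n)
        return pd.DataFrame(
            {
                "year": np.arange(2004, 2004 + n),
                "l0_mean": np.exp(logl),
                "dgt0": d,
                "gdd_aug": gdd,
            }
        )

    def test_noiseless_log_linear_recovery(self):
        """Exact log-linear density relation is recovered perfectly: every
        top-ranked model contains the density term, and the density-only
        model has R^2 = 1 with the generating negative slope."""
        table, fits = fit_size_at_age0(self._series())
        assert "logD" in table.iloc[0]["model"]
        assert not table.iloc[0]["model"].endswith("~ 1")
        best = fits["logL0 ~ logD"]
        assert best.rsquared == pytest.approx(1.0)
        assert best.params[1] == pytest.approx(-0.4, abs=1e-8)

    def test_ols_matches_normal_equations(self):
        s = self._series(noise=0.1, seed=2)
        _, fits = fit_size_at_age0(s)
        res = fits["logL0 ~ logD"]
        X = np.column_stack([np.ones(len(s)), np.log(s["dgt0"])])
        y = np.log(s["l0_mean"])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(res.params, beta, atol=1e-8)

    def test_weak_signal_yields_equivalence_flags(self):
        s = self._series(noise=0.25, slope=-0.02, seed=4)
        table, _ = fit_size_at_age0(s)
        assert table["equivalent"].sum() >= 2

    def test_nonpositive_values_rejected(self):
        s = self._series()
        s.loc[0, "l0_mean"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_size_at_age0(s)


class TestMovement:
    def test_no_movement_degenerate(self):
        cfg = vr.SimConfig(
            occasions=vr.biannual_occasions("2004-09-15", 9),
            movement_prob=0.0, seed=9,
        )
        enc, _ = vr.simulate_population(cfg)
        mv = movement_analysis(enc)
        assert mv.prop_multi_sector == 0.0
        assert "degenerate" in mv.glm_status

    def test_slope_positive_with_movement(self, default_sim):
        _, enc, _ = default_sim
        mv = movement_analysis(enc)
        assert mv.glm_status == "ok"
        assert mv.glm_slope > 0
        assert 0 < mv.prop_multi_sector < 1

    def test_glm_matches_irls_oracle(self):
        """Logistic GLM coefficients equal a textbook IRLS iteration."""
        enc_rows = []
        rng = np.random.default_rng(13)
        # 20 fish with known years-sampled and multi-sector status
        years_sampled = rng.integers(1, 7, 20)
        multi = (rng.random(20) < 1 / (1 + np.exp(-(-1.0 + 0.5 * years_sampled)))).astype(int)
        for i in range(20):
            for y in range(years_sampled[i]):
                enc_rows.append(
                    {
                        "tag_id": f"T{i:03d}",
                        "date": f"{2004 + y}-09-15",
                        "occasion_index": 2 * y,
                        "pass": 1,
                        "length_mm": 150.0,
                        "sector": (1 + (i % 2) * y % 4 + 1) if multi[i] and y > 0 else 1,
                        "fin_clipped": 1,
                        "age_years": 2 + y,
                    }
                )
        enc = pd.DataFrame(enc_rows)
        mv = movement_analysis(enc)
        per = mv.per_fish
        X = np.column_stack([np.ones(len(per)), per["n_years"].to_numpy(float)])
        y = per["multi_sector"].to_numpy(float)
        beta = np.zeros(2)
        for _ in range(50):  # IRLS
            eta = X @ beta
            mu = 1 / (1 + np.exp(-eta))
            W = mu * (1 - mu)
            z = eta + (y - mu) / np.clip(W, 1e-10, None)
            beta_new = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
            if np.abs(beta_new - beta).max() < 1e-12:
                beta = beta_new
                break
            beta = beta_new
        assert mv.glm_intercept == pytest.approx(beta[0], abs=1e-6)
        assert mv.glm_slope == pytest.approx(beta[1], abs=1e-6)


class TestAnomalyFlags:
    def _panel(self, rng, inflated=(), n_cohorts=6, n_fish=20):
        truth = vr.GrowthParams(
            log_k=np.log(0.3), log_linf=np.log(330.0), t0=-0.2,
            sigma_u=0.1, sigma_v=0.1, sigma_eps=3.0,
            linf_group={2004 + c: (np.log(1.25) if c in inflated else 0.0)
                        for c in range(n_cohorts)},
        )
        rows = []
        for c in range(n_cohorts):
            for i in range(n_fish):
                u, v = rng.standard_normal(2)
                ages = np.array([1.25, 2.25, 3.25])
                L = vr.vbgf_length(truth, ages, u=u, v=v, group=2004 + c)
                L = L + rng.normal(0, 3.0, 3)
                for a, l in zip(ages, L):
                    rows.append(
                        {"fish_id": f"c{c}f{i}", "age": a, "length_mm": l,
                         "cohort": 2004 + c}
                    )
        return pd.DataFrame(rows)

    def test_planted_anomalies_flagged(self):
        rng = np.random.default_rng(31)
        data = self._panel(rng, inflated=(1, 4))
        fit = vr.fit_growth(data, ("cohort",), ("cohort",))
        tab = flag_anomalous_cohorts(fit, reference_age=3.0)
        flagged = set(tab.loc[tab["flagged"], "cohort"])
        assert {2005, 2008} <= flagged

    def test_reference_age_below_t0_errors(self):
        rng = np.random.default_rng(32)
        data = self._panel(rng)
        fit = vr.fit_growth(data, ("cohort",), ("cohort",))
        with pytest.raises(ValueError, match="t0"):
            flag_anomalous_cohorts(fit, reference_age=-1.0)

    def test_too_few_cohorts_errors(self):
        rng = np.random.default_rng(33)
        data = self._panel(rng, n_cohorts=1)
        fit = vr.fit_growth(data, ("cohort",), ("cohort",), compute_se=False)
        with pytest.raises(ValueError, match="cohort"):
            flag_anomalous_cohorts(fit, reference_age=3.0)
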