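"""CJS survival: history construction, likelihood, enumeration oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import vitalrates as vr
from vitalrates.cjs import (
    CJSModelSpec,
    CaptureHistoryMatrix,
    _Collapsed,
    _Design,
    _loglik_grad,
    build_capture_histories,
    cjs_loglik,
    compare_origin_survival,
    fit_cjs,
    rank_cjs_models,
)


def _chm(Y, tau=None, cohorts=None, origins=None, start_year=2004):
    Y = np.asarray(Y)
    n, K = Y.shape
    dates = [pd.Timestamp(f"{start_year + k}-09-15") for k in range(K)]
    return CaptureHistoryMatrix(
        Y=Y,
        tag_ids=np.array([f"t{i}" for i in range(n)]),
        dates=dates,
        cohort=np.asarray(cohorts if cohorts is not None else [start_year - 1] * n),
        origin=np.asarray(origins if origins is not None else ["early"] * n, dtype=object),
        tau=np.asarray(tau if tau is not None else [1.0] * (K - 1)),
        season=np.array(["Winter"] * (K - 1), dtype=object),
    )


def brute_force_history_prob(hist, phi_int, p):
    """Probability of a post-release capture history by summing over every
    death interval (independent of the chi recursion)."""
    K = len(hist)
    f = hist.index(1)
    total = 0.0
    # death after interval d (fish alive at occasions f..d), d = f..K-1;
    # d = K-1 means survived to the end
    for d in range(f, K):
        pr = 1.0
        ok = True
        for t in range(f, K - 1):
            if t < d:  # survived interval t
                pr *= phi_int[t]
                pr *= p[t] if hist[t + 1] else (1 - p[t])
            else:  # died in interval t
                pr *= 1 - phi_int[t]
                if any(hist[t + 1 :]):
                    ok = False
                break
        if ok:
            total += pr
    return total


class TestLikelihood:
    def test_two_occasion_both_seen(self):
        ch = _chm([[1, 1]])
        theta = np.array([logit(0.5), logit(0.8)])
        assert np.exp(cjs_loglik(CJSModelSpec("1", "1"), ch, theta)) == pytest.approx(0.4)

    def test_three_occasion_gap(self):
        ch = _chm([[1, 0, 1]])
        theta = np.array([logit(0.5), logit(0.8)])
        # 0.5 * 0.2 * 0.5 * 0.8
        assert np.exp(cjs_loglik(CJSModelSpec("1", "1"), ch, theta)) == pytest.approx(0.04)

    def test_wrong_theta_length_rejected(self):
        ch = _chm([[1, 1]])
        with pytest.raises(ValueError, match="length"):
            cjs_loglik(CJSModelSpec("1", "1"), ch, np.zeros(5))

    def test_matches_brute_force_enumeration(self):
        """chi-recursion likelihood equals the death-time enumeration for
        every capture history with K <= 5."""
        phi_int = [0.6, 0.5, 0.7, 0.4]
        p = [0.8, 0.7, 0.6, 0.9]
        K = 5
        spec = CJSModelSpec("time", "time")
        for f in range(K - 1):
            for cont in itertools.product([0, 1], repeat=K - f - 1):
                hist = [0] * f + [1] + list(cont)
                ch = _chm([hist])
                design = _Design(ch, spec)
                # map interval-specific values through the design by solving
                # for theta: time factor gives one parameter per interval
                th_phi = np.r_[logit(phi_int[0]), logit(phi_int[1:]) - logit(phi_int[0])]
                th_p = np.r_[logit(p[0]), logit(p[1:]) - logit(p[0])]
                theta = np.r_[th_phi, th_p]
                ll = cjs_loglik(spec, ch, theta)
                expected = brute_force_history_prob(hist, phi_int, p)
                assert np.exp(ll) == pytest.approx(expected, rel=1e-10)

    def test_probabilities_sum_to_one_over_continuations(self):
        """Total CJS probability over all 2^(K-f-1) continuations is 1."""
        phi_int = [0.55, 0.35, 0.8, 0.45]
        p = [0.9, 0.5, 0.7, 0.85]
        for f in range(4):
            tot = sum(
                brute_force_history_prob([0] * f + [1] + list(cont), phi_int, p)
                for cont in itertools.product([0, 1], repeat=4 - f)
            )
            assert tot == pytest.approx(1.0)

    def test_annualization_identity(self):
        """phi_interval == phi_annual at tau = 1; powered otherwise."""
        phi_a = 0.6
        ch1 = _chm([[1, 1]], tau=[1.0])
        ch2 = _chm([[1, 1]], tau=[0.25])
        theta = np.array([logit(phi_a), logit(0.8)])
        ll1 = cjs_loglik(CJSModelSpec("1", "1"), ch1, theta)
        ll2 = cjs_loglik(CJSModelSpec("1", "1"), ch2, theta)
        assert np.exp(ll1) == pytest.approx(phi_a * 0.8)
        assert np.exp(ll2) == pytest.approx(phi_a**0.25 * 0.8)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        Y = (rng.random((30, 4)) < 0.5).astype(int)
        Y[Y.sum(1) == 0, 1] = 1
        ch = _chm(Y)
        perm = rng.permutation(30)
        ch_perm = _chm(Y[perm])
        spec = CJSModelSpec("1", "time")
        theta = rng.normal(0, 0.5, 4)
        assert cjs_loglik(spec, ch, theta) == pytest.approx(
            cjs_loglik(spec, ch_perm, theta)
        )

    def test_analytic_gradient_matches_numeric(self):
        rng = np.random.default_rng(4)
        Y = (rng.random((50, 6)) < 0.4).astype(int)
        Y[Y.sum(1) == 0, 0] = 1
        ch = _chm(Y, tau=[0.75, 0.25, 0.75, 0.25, 0.75],
                  cohorts=rng.choice([2002, 2003], 50))
        spec = CJSModelSpec("cohort+season+age", "time")
        design = _Design(ch, spec)
        col = _Collapsed(ch, design)
        npar = design.phi_X.shape[2] + design.p_X.shape[2]
        theta = rng.normal(0, 0.3, npar)
        _, g = _loglik_grad(theta, col)
        num = np.zeros(npar)
        for i in range(npar):
            e = np.zeros(npar)
            e[i] = 1e-6
            lp, _ = _loglik_grad(theta + e, col, want_grad=False)
            lm, _ = _loglik_grad(theta - e, col, want_grad=False)
            num[i] = (lp - lm) / 2e-6
        assert np.abs(g - num).max() < 1e-6


class TestBuildHistories:
    def test_detection_pattern(self):
        enc = pd.DataFrame(
            {
                "tag_id": ["A", "A", "B"],
                "date": ["2007-09-15", "2009-09-15", "2006-09-15"],
                "occasion_index": [3, 5, 2],
                "pass": [1, 2, 1],
                "length_mm": [150.0, 190.0, 140.0],
                "sector": [1, 1, 2],
                "fin_clipped": [1, 1, 1],
                "age_years": [2, 4, 3],
            }
        )
        dates = [f"200{4+k}-09-15" for k in range(6)]
        ch = build_capture_histories(enc, occasion_dates=dates)
        rowA = ch.Y[list(ch.tag_ids).index("A")]
        assert list(rowA) == [0, 0, 0, 1, 0, 1]
        assert ch.first[list(ch.tag_ids).index("A")] == 3

    def test_untagged_fish_absent(self, small_sim):
        _, enc, truth = small_sim
        ch = build_capture_histories(enc)
        tagged_truth = set(truth.fish.loc[truth.fish["tag_id"] != "", "tag_id"])
        captured_tags = set(enc.loc[enc["tag_id"] != "", "tag_id"])
        assert set(ch.tag_ids) == captured_tags <= tagged_truth

    def test_row_count_conserved(self, default_sim):
        _, enc, truth = default_sim
        ch = build_capture_histories(enc)
        assert ch.n == enc.loc[enc["tag_id"] != "", "tag_id"].nunique()

    def test_every_row_has_detection(self, small_sim):
        _, enc, _ = small_sim
        ch = build_capture_histories(enc)
        assert (ch.Y.sum(axis=1) >= 1).all()

    def test_interval_lengths_from_dates(self, small_sim):
        _, enc, _ = small_sim
        ch = build_capture_histories(enc)
        assert ((ch.tau > 0.2) & (ch.tau < 0.8)).all()
        assert ch.season[0] == "Winter"  # study starts in September


class TestFit:
    def test_complete_data_limit(self):
        """p ~ 1 and everyone observed until death: phi_hat equals the
        empirical survival fraction."""
        rng = np.random.default_rng(6)
        n, K = 400, 6
        phi = 0.7
        alive = np.ones((n, K), dtype=bool)
        for k in range(1, K):
            alive[:, k] = alive[:, k - 1] & (rng.random(n) < phi)
        Y = alive.astype(int)
        ch = _chm(Y)
        fit = fit_cjs(CJSModelSpec("1", "1"), ch, compute_se=False)
        phi_hat = expit(fit.theta[0])
        emp = alive[:, 1:].sum() / alive[:, :-1].sum()
        assert phi_hat == pytest.approx(emp, abs=1e-3)

    def test_optimizer_loglik_consistent(self, small_sim):
        _, enc, _ = small_sim
        ch = build_capture_histories(enc)
        spec = CJSModelSpec("season", "time")
        fit = fit_cjs(spec, ch, compute_se=False)
        assert cjs_loglik(spec, ch, fit.theta) == pytest.approx(fit.loglik)

    def test_npar_counting(self, small_sim):
        """phi(Cohort+Time) p(Time) has (C-1)+(K-2)+1 + (K-1) parameters."""
        _, enc, _ = small_sim
        ch = build_capture_histories(enc)
        C = len(np.unique(ch.cohort))
        K = ch.K
        design = _Design(ch, CJSModelSpec("cohort+time", "time"))
        assert design.phi_X.shape[2] == (C - 1) + (K - 2) + 1
        assert design.p_X.shape[2] == K - 1

    def test_single_model_ranking(self, small_sim):
        _, enc, _ = small_sim
        ch = build_capture_histories(enc)
        table, _ = rank_cjs_models(ch, [CJSModelSpec("1", "1")])
        assert table["delta_aic"].iloc[0] == 0.0

    def test_missing_temperature_refuses_tbar(self, small_sim):
        _, enc, _ = small_sim
        ch = build_capture_histories(enc)  # no temperature attached
        with pytest.raises(ValueError, match="temperature"):
            fit_cjs(CJSModelSpec("tbar", "1"), ch, compute_se=False)


class TestOriginComparison:
    def test_deterministic(self, cjs_sim):
        _, enc, truth = cjs_sim
        origin = truth.fish.set_index("tag_id")["origin"].drop("").to_dict()
        ch = build_capture_histories(enc, origin=origin)
        a = compare_origin_survival(ch)
        b = compare_origin_survival(ch)
        pd.testing.assert_frame_equal(a, b)

    def test_equal_survival_overlapping_cis(self, cjs_sim):
        """Generator gives both origins identical survival: CIs overlap."""
        _, enc, truth = cjs_sim
        origin = truth.fish.set_index("tag_id")["origin"].drop("").to_dict()
        ch = build_capture_histories(enc, origin=origin)
        res = compare_origin_survival(ch).set_index("origin")
        assert res.loc["early", "lo"] <= res.loc["late", "hi"]
        assert res.loc["late", "lo"] <= res.loc["early", "hi"]

    def test_single_origin_errors(self):
        ch = _chm([[1, 1], [1, 0]], origins=["early", "early"])
        with pytest.raises(ValueError, match="origin"):
            compare_origin_survival(ch)
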