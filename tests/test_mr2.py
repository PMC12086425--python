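"""Two-sample MR estimators, diagnostics and sensitivity analyses."""

import numpy as np
import pytest

import crosstrait as ct
from crosstrait.mr2 import EmptyInstrumentError
from crosstrait.sumstats import InstrumentSet

from conftest import instrument_set


def _manual_iv(bx, by, se_y, se_x=None):
    import pandas as pd
    n = len(bx)
    se_x = se_x if se_x is not None else [0.01] * n
    df = pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(n)], "chr": 1,
            "pos": np.arange(n) + 1, "ea": "A", "oa": "G",
            "eaf_x": 0.5, "eaf_y": 0.5,
            "beta_x": bx, "se_x": se_x, "beta_y": by, "se_y": se_y,
            "n_x": 50_000, "n_y": 50_000,
            "palindromic": False, "flipped": False,
        }
    )
    return InstrumentSet(df=df)


class TestIvw:
    def test_single_iv_equals_wald_ratio(self):
        iv = _manual_iv([0.2], [0.05], [0.01])
        fit = ct.ivw(iv)
        assert fit.beta == pytest.approx(0.05 / 0.2)

    def test_exact_proportionality_gives_zero_q(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        iv = _manual_iv(bx, 0.5 * bx, [0.01] * 4)
        fit = ct.ivw(iv)
        assert fit.beta == pytest.approx(0.5)
        assert fit.diagnostics["Q"] == pytest.approx(0.0, abs=1e-20)

    def test_recovers_truth_within_two_se(self):
        d = ct.simulate_instrument_betas(beta_causal=0.1, seed=1)
        fit = ct.ivw(instrument_set(d))
        assert abs(fit.beta - 0.1) < 2 * fit.se

    def test_empty_instruments_rejected(self):
        import pandas as pd
        iv = InstrumentSet(df=pd.DataFrame(
            columns=["snp", "beta_x", "se_x", "beta_y", "se_y"]))
        with pytest.raises(EmptyInstrumentError):
            ct.ivw(iv)

    def test_type_one_error_and_coverage(self):
        # fully vectorized instrument-level simulation, truths 0 and 0.1
        rng = np.random.default_rng(99)
        n_rep, n_iv = 1000, 143
        rejections = 0
        covered = 0
        bx_true = np.abs(rng.normal(0, np.sqrt(0.059 / n_iv),
                                    (n_rep, n_iv)))
        se = 1.0 / np.sqrt(50_000)
        for truth in (0.0, 0.1):
            bx = bx_true + rng.normal(0, se, (n_rep, n_iv))
            by = truth * bx_true + rng.normal(0, se, (n_rep, n_iv))
            w = 1.0 / se**2
            denom = np.sum(w * bx * bx, axis=1)
            beta = np.sum(w * bx * by, axis=1) / denom
            se_fix = np.sqrt(1.0 / denom)
            resid = by - beta[:, None] * bx
            Q = np.sum(w * resid**2, axis=1)
            infl = np.sqrt(np.maximum(1.0, Q / (n_iv - 1)))
            se_mr = se_fix * infl
            if truth == 0.0:
                rejections = np.mean(np.abs(beta) / se_mr > 1.959963985)
            else:
                covered = np.mean(np.abs(beta - truth) < 1.959963985 * se_mr)
        assert 0.03 <= rejections <= 0.07
        assert 0.93 <= covered <= 0.97


class TestEgger:
    def test_null_intercept_coverage(self):
        hits = 0
        reps = 200
        for s in range(reps):
            d = ct.simulate_instrument_betas(n_iv=50, beta_causal=0.1,
                                             seed=1000 + s)
            fit = ct.egger(instrument_set(d))
            a = fit.diagnostics["egger_intercept"]
            sa = fit.diagnostics["egger_intercept_se"]
            if abs(a) < 1.959963985 * sa:
                hits += 1
        assert hits / reps > 0.90

    def test_directional_pleiotropy_recovered(self):
        # every IV carries the same pleiotropic shift: IVW is biased, the
        # Egger slope is not and the intercept finds the shift
        betas, intercepts, int_ses, ivw_betas = [], [], [], []
        for s in range(20):
            d = ct.simulate_instrument_betas(
                n_iv=100, beta_causal=0.1, pleiotropy_mean=0.02,
                n_x=500_000, n_y=500_000, seed=2000 + s)
            iv = instrument_set(d)
            fit = ct.egger(iv)
            betas.append(fit.beta)
            intercepts.append(fit.diagnostics["egger_intercept"])
            int_ses.append(fit.diagnostics["egger_intercept_se"])
            ivw_betas.append(ct.ivw(iv).beta)
        assert np.mean(intercepts) == pytest.approx(
            0.02, abs=2 * np.mean(int_ses) / np.sqrt(20))
        assert abs(np.mean(betas) - 0.1) < abs(np.mean(ivw_betas) - 0.1)

    def test_requires_three_instruments(self):
        iv = _manual_iv([0.1, 0.2], [0.01, 0.02], [0.01, 0.01])
        with pytest.raises(ValueError):
            ct.egger(iv)

    def test_degenerate_design_rejected(self):
        iv = _manual_iv([0.2, 0.2, 0.2], [0.01, 0.02, 0.03], [0.01] * 3)
        with pytest.raises(np.linalg.LinAlgError):
            ct.egger(iv)


class TestWeightedMedian:
    def test_equal_ratios_recovered_regardless_of_weights(self):
        bx = np.array([0.1, 0.2, 0.4])
        iv = _manual_iv(bx, 0.3 * bx, [0.01, 0.02, 0.005])
        fit = ct.weighted_median(iv, n_boot=50, seed=0)
        assert fit.beta == pytest.approx(0.3)

    def test_three_ratio_hand_interpolation(self):
        # ratios (0.1, 0.2, 0.9) with equal weights: cumulative midpoints
        # (1/6, 3/6, 5/6) cross one half exactly at the middle ratio
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.01, 0.02, 0.09])
        iv = _manual_iv(bx, by, [0.01] * 3)
        fit = ct.weighted_median(iv, n_boot=50, seed=0)
        assert fit.beta == pytest.approx(0.2)

    def test_robust_to_under_half_invalid(self):
        # 40% wildly invalid IVs: the median stays near truth, IVW does not
        rng = np.random.default_rng(3)
        n = 50
        bx = np.abs(rng.normal(0.02, 0.005, n))
        by = 0.1 * bx
        by[:20] = 2.0 * bx[:20]  # invalid with ratio 2.0
        iv = _manual_iv(bx, by + rng.normal(0, 5e-4, n), [5e-4] * n)
        wm = ct.weighted_median(iv, n_boot=200, seed=1)
        fit_ivw = ct.ivw(iv)
        assert abs(wm.beta - 0.1) < 2 * wm.se
        assert abs(fit_ivw.beta - 0.1) > 2 * fit_ivw.se

    def test_zero_exposure_effect_excluded(self):
        bx = np.array([0.0, 0.1, 0.2, 0.3])
        iv = _manual_iv(bx, 0.5 * bx, [0.01] * 4)
        fit = ct.weighted_median(iv, n_boot=50, seed=0)
        assert fit.n_iv == 3


class TestMrPresso:
    def test_null_global_p_calibrated(self):
        ps = []
        for s in range(60):
            d = ct.simulate_instrument_betas(n_iv=30, beta_causal=0.1,
                                             seed=3000 + s)
            fit = ct.mr_presso(instrument_set(d), n_sim=400, seed=s)
            ps.append(fit.diagnostics["global_rss_p"])
        frac = np.mean(np.array(ps) < 0.05)
        assert frac <= 0.15  # binomial noise around 5% at 60 reps

    def test_planted_outlier_flagged_and_bias_reduced(self):
        d = ct.simulate_instrument_betas(
            n_iv=51, beta_causal=0.1, outlier_idx="strongest",
            outlier_ratio=10.0, seed=4)
        outlier_snp = f"s{int(np.argmax(d['beta_x_true']))}"
        fit = ct.mr_presso(instrument_set(d), seed=5)
        assert outlier_snp in fit.diagnostics["outlier_ids"]
        bias_corrected = abs(fit.beta - 0.1)
        bias_raw = abs(fit.diagnostics["uncorrected_beta"] - 0.1)
        assert bias_corrected < bias_raw

    def test_deterministic_given_seed(self, make_instruments):
        d = ct.simulate_instrument_betas(n_iv=20, beta_causal=0.0, seed=8)
        a = ct.mr_presso(make_instruments(d), n_sim=300, seed=11)
        b = ct.mr_presso(make_instruments(d), n_sim=300, seed=11)
        assert a.beta == b.beta
        assert a.diagnostics["global_rss_p"] == b.diagnostics["global_rss_p"]

    def test_config_errors(self, make_instruments):
        d = ct.simulate_instrument_betas(n_iv=20, seed=0)
        with pytest.raises(ValueError):
            ct.mr_presso(make_instruments(d), n_sim=50)


class TestLeaveOneOut:
    def test_homogeneous_ivs_stable(self):
        bx = np.linspace(0.1, 0.4, 6)
        iv = _manual_iv(bx, 0.5 * bx, [0.01] * 6)
        fits = ct.leave_one_out(iv)
        assert all(f.beta == pytest.approx(0.5) for f in fits)
        assert not any(f.diagnostics["influential"] for f in fits)

    def test_single_influential_iv_flagged(self):
        bx = np.array([0.1, 0.12, 0.14, 0.16, 0.5])
        by = 0.2 * bx
        by[-1] = 0.5 * 2.0  # one IV with a wildly different ratio
        iv = _manual_iv(bx, by, [0.02] * 5)
        fits = ct.leave_one_out(iv)
        flagged = [f.diagnostics["omitted"] for f in fits
                   if f.diagnostics["influential"]]
        assert flagged == ["s4"]

    def test_two_ivs_give_two_wald_ratios(self):
        iv = _manual_iv([0.1, 0.2], [0.02, 0.01], [0.01, 0.01])
        fits = ct.leave_one_out(iv)
        assert fits[0].beta == pytest.approx(0.01 / 0.2)
        assert fits[1].beta == pytest.approx(0.02 / 0.1)


class TestSteiger:
    def test_exposure_dominant_snv_retained(self):
        iv = _manual_iv([0.1], [0.001], [0.001], se_x=[0.01])
        # z_x = 10, z_y = 1 at equal n
        filtered, report = ct.steiger_filter(iv, n_x=50_000, n_y=50_000)
        assert filtered.n_iv == 1
        assert report == []

    def test_outcome_dominant_snv_removed(self):
        iv = _manual_iv([0.01], [0.1], [0.01], se_x=[0.01])
        filtered, report = ct.steiger_filter(iv, n_x=50_000, n_y=50_000)
        assert filtered.n_iv == 0
        assert report[0]["reason"] == "discordant"

    def test_filter_reduces_bias_with_reverse_causal_snvs(self):
        # 10% of the SNVs actually act on the outcome (reverse direction):
        # strong outcome effect, tiny exposure effect; averaged over seeds
        # the filtered IVW sits closer to truth than the unfiltered one
        bias_raw, bias_filt = [], []
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            n = 50
            d = ct.simulate_instrument_betas(n_iv=n, beta_causal=0.1,
                                             n_x=500_000, n_y=500_000,
                                             seed=100 + s)
            bx, by = d["beta_x"].copy(), d["beta_y"].copy()
            rev = rng.choice(n, 5, replace=False)
            by[rev] = 0.3
            bx[rev] = 0.002
            iv = _manual_iv(bx, by, d["se_y"], se_x=d["se_x"])
            raw = ct.ivw(iv)
            filtered, report = ct.steiger_filter(iv)
            assert len(report) >= 5  # the reverse SNVs are caught
            fit = ct.ivw(filtered)
            bias_raw.append(abs(raw.beta - 0.1))
            bias_filt.append(abs(fit.beta - 0.1))
        assert np.mean(bias_filt) < np.mean(bias_raw)


class TestMvmr:
    def test_zero_second_exposure_matches_univariate(self):
        d = ct.simulate_instrument_betas(n_iv=30, beta_causal=0.1, seed=12)
        iv = instrument_set(d)
        uni = ct.ivw(iv, model="fixed")
        B = np.column_stack([d["beta_x"], np.zeros(30)])
        fits = ct.mvmr_ivw(B, d["beta_y"], d["se_y"],
                           exposure_names=["x", "z"])
        assert fits[0].beta == pytest.approx(uni.beta)

    def test_separates_direct_from_mediated(self):
        # direct effect 0.1 plus a mediated path x -> m -> y with effect 0.3
        rng = np.random.default_rng(13)
        n = 100
        bx = np.abs(rng.normal(0, 0.03, n))
        bm = np.abs(rng.normal(0, 0.03, n))
        se_y = np.full(n, 1e-3)
        by = 0.1 * bx + 0.3 * bm + rng.normal(0, se_y)
        fits = ct.mvmr_ivw(np.column_stack([bx, bm]), by, se_y,
                           exposure_names=["exposure", "mediator"])
        assert fits[0].beta == pytest.approx(0.1, abs=2 * fits[0].se)
        assert fits[1].beta == pytest.approx(0.3, abs=2 * fits[1].se)

    def test_duplicate_exposures_rejected(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        with pytest.raises(np.linalg.LinAlgError):
            ct.mvmr_ivw(np.column_stack([bx, bx]), 0.1 * bx,
                        np.full(5, 0.01))


class TestConfounderExclusion:
    def test_blocklist_semantics(self, make_instruments):
        d = ct.simulate_instrument_betas(n_iv=10, seed=14)
        iv = make_instruments(d)
        assert ct.exclude_confounder_ivs(iv, []).n_iv == 10
        assert ct.exclude_confounder_ivs(iv, ["s0", "s3", "s7"]).n_iv == 7
        emptied = ct.exclude_confounder_ivs(iv, [f"s{i}" for i in range(10)])
        with pytest.raises(EmptyInstrumentError):
            ct.ivw(emptied)


class TestEstimatorInvariants:
    def test_single_iv_all_estimators_agree(self):
        iv = _manual_iv([0.25], [0.05], [0.01])
        assert ct.ivw(iv).beta == pytest.approx(0.2)

    def test_sign_flip_equivariance(self):
        d = ct.simulate_instrument_betas(n_iv=20, beta_causal=0.1, seed=15)
        iv = instrument_set(d)
        flipped = instrument_set(
            {**d, "beta_x": -d["beta_x"], "beta_y": -d["beta_y"]})
        assert ct.ivw(flipped).beta == pytest.approx(ct.ivw(iv).beta)
        assert ct.weighted_median(flipped, n_boot=50, seed=0).beta == \
            pytest.approx(ct.weighted_median(iv, n_boot=50, seed=0).beta)
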