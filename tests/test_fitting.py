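"""Least-squares fitting, goodness-of-fit statistics, and model comparison."""

from types import SimpleNamespace

import numpy as np
import pytest

from lungntcp.curves import normalize_curve
from lungntcp.fitting import (
    ComparisonReport,
    NTCPModel,
    _one_way_anova,
    compare_models,
    cross_model_anova,
    fit_model,
    fit_significance_anova,
    goodness_stats,
    rank_models,
)
from lungntcp.models import MODEL_IDS, NTCPParams, evaluate
from lungntcp.phantom import generate_binned_curve

EDGES = tuple(float(x) for x in range(0, 66, 6))
MIDS = np.arange(3.0, 60.0, 6.0)
TRUE = NTCPParams(35.29, 1.35)


class TestRecovery:
    @pytest.mark.parametrize("model", MODEL_IDS)
    def test_noiseless_parameter_recovery(self, model):
        curve = generate_binned_curve(model, TRUE, EDGES)
        res = NTCPModel(curve.bin_dose, curve.response, model=model).fit()
        assert abs(res.d50 - TRUE.d50) / TRUE.d50 < 1e-3
        assert abs(res.gamma50 - TRUE.gamma50) / TRUE.gamma50 < 1e-3
        assert res.converged

    def test_noisy_recovery_d50_tighter_than_gamma50(self):
        d50s, g50s = [], []
        for rep in range(30):
            curve = generate_binned_curve(
                "lyman", TRUE, EDGES, noise_sd=0.05, seed=1000 + rep
            )
            res = NTCPModel(curve.bin_dose, curve.response, model="lyman").fit()
            d50s.append(res.d50)
            g50s.append(res.gamma50)
        d50s, g50s = np.asarray(d50s), np.asarray(g50s)
        assert np.median(np.abs(d50s - TRUE.d50)) < 2.0
        rel_spread = lambda x: (np.quantile(x, 0.75) - np.quantile(x, 0.25)) / np.median(x)
        assert rel_spread(g50s) > rel_spread(d50s)

    @pytest.mark.parametrize("model", MODEL_IDS)
    def test_multistart_basin_agreement(self, model):
        curve = generate_binned_curve(model, TRUE, EDGES)
        res = NTCPModel(curve.bin_dose, curve.response, model=model).fit()
        assert res.n_starts_agreeing / res.n_starts >= 0.8

    def test_bin_order_permutation_invariant(self):
        curve = generate_binned_curve("logit", TRUE, EDGES, noise_sd=0.03, seed=5)
        res1 = NTCPModel(curve.bin_dose, curve.response, model="logit").fit()
        perm = np.random.default_rng(0).permutation(len(MIDS))
        res2 = NTCPModel(
            curve.bin_dose[perm], curve.response[perm], model="logit"
        ).fit()
        assert res2.d50 == pytest.approx(res1.d50, abs=1e-8)
        assert res2.gamma50 == pytest.approx(res1.gamma50, abs=1e-8)

    def test_flat_curve_hits_bound_and_is_flagged(self):
        res = NTCPModel(MIDS, np.full(10, 0.5), model="lyman").fit()
        assert res.converged
        assert res.at_bounds

    def test_from_curve_requires_normalized(self):
        curve = generate_binned_curve("lyman", TRUE, EDGES)
        with pytest.raises(ValueError, match="normalized"):
            NTCPModel.from_curve(curve, "lyman")
        res = fit_model("lyman", normalize_curve(curve))
        assert res.converged

    def test_unnormalized_scale_rejected(self):
        with pytest.raises(ValueError, match="unnormalized"):
            NTCPModel(MIDS, np.linspace(5, 200, 10))

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="3"):
            NTCPModel(MIDS[:2], [0.1, 0.9])


class TestGoodnessStats:
    def test_information_criterion_identity(self):
        rng = np.random.default_rng(0)
        for n in (5, 8, 10, 15):
            r = rng.normal(0, 0.1, n)
            ssr, _, aic, bic = goodness_stats(r, n, k=2, sst=1.0)
            assert bic - aic == pytest.approx(2 * np.log(n) - 4, abs=1e-12)

    def test_printed_aic_bic_offset_n10(self):
        # at k=2, n=10 the offset is 2*ln(10) - 4 ~= 0.605; AIC and BIC
        # were rounded independently, so agreement holds to one printed ULP
        offset = 2 * np.log(10) - 4
        for aic, bic in [(-22.65, -22.04), (-29.16, -28.56), (-26.54, -25.93)]:
            assert abs((aic + offset) - bic) <= 0.01

    def test_ssr_floor_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            ssr, _, aic, _ = goodness_stats(np.zeros(10), 10, k=2, sst=1.0)
        assert ssr == 1e-12
        assert aic == pytest.approx(10 * np.log(1e-13) + 4)

    def test_perfect_fit_adj_r2_near_one(self):
        _, adj, _, _ = goodness_stats(np.full(10, 1e-9), 10, k=2, sst=1.0)
        assert adj == pytest.approx(1.0, abs=1e-6)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            goodness_stats([0.1, 0.1, 0.1], 3, k=2)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            goodness_stats(np.ones(10), 10, k=2, sst=0.0)


class TestSignificance:
    def test_noiseless_sigmoid_is_highly_significant(self):
        curve = generate_binned_curve("lyman", TRUE, EDGES)
        res = NTCPModel(curve.bin_dose, curve.response, model="lyman").fit()
        f, p = fit_significance_anova(res)
        assert p < 1e-6

    def test_equal_ssr_gives_f_zero_p_one(self):
        from lungntcp.fitting import _fit_f_test

        f, p, _ = _fit_f_test(sst=0.5, ssr_fit=0.5, n=10)
        assert f == 0.0 and p == 1.0


class TestCrossModelAnova:
    def _stub_fits(self, d50s, g50s):
        return [
            SimpleNamespace(d50=d, gamma50=g) for d, g in zip(d50s, g50s)
        ]

    def test_identical_groups_give_f0_p1(self):
        fits = {m: self._stub_fits([30, 35, 40], [1, 2, 3]) for m in MODEL_IDS}
        f_d, p_d, f_g, p_g = cross_model_anova(fits)
        assert (f_d, p_d, f_g, p_g) == (0.0, 1.0, 0.0, 1.0)

    def test_matches_hand_computed_oracle(self):
        # groups {1,2,3},{4,5,6},{1,2,3},{4,5,6}: SSB = 27 (df 3),
        # SSW = 8 (df 8) -> F = 9; tail probability frozen from R pf(9,3,8)
        fits = {
            "logit": self._stub_fits([1, 2, 3], [1, 2, 3]),
            "lyman": self._stub_fits([4, 5, 6], [4, 5, 6]),
            "poisson": self._stub_fits([1, 2, 3], [1, 2, 3]),
            "weibull": self._stub_fits([4, 5, 6], [4, 5, 6]),
        }
        f_d, p_d, f_g, p_g = cross_model_anova(fits)
        assert f_d == pytest.approx(9.0, rel=1e-12)
        assert p_d == pytest.approx(0.00607052885246, rel=1e-9)
        assert (f_g, p_g) == (f_d, p_d)

    def test_two_group_oracle(self):
        # {1,2,3} vs {4,5,6}: SSB = 13.5, SSW = 4 (df 1, 4) -> F = 13.5
        f, p = _one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert f == pytest.approx(13.5, rel=1e-12)
        assert p == pytest.approx(0.0213116411288, rel=1e-9)  # R pf(13.5,1,4)

    def test_unbalanced_rejected(self):
        fits = {m: self._stub_fits([1, 2], [1, 2]) for m in MODEL_IDS}
        fits["lyman"] = self._stub_fits([1], [1])
        with pytest.raises(ValueError, match="balanced"):
            cross_model_anova(fits)


class TestComparison:
    def _stub_report(self, ssrs):
        fits = {}
        for mid, ssr in ssrs.items():
            fits[mid] = SimpleNamespace(
                ssr=ssr, aic=10 + ssr, bic=11 + ssr, adj_r2=1 - ssr,
                to_dict=lambda s=ssr, m=mid: {"model": m, "ssr": s},
            )
        return ComparisonReport(fits=fits)

    def test_ranking_orders_and_consensus(self):
        report = self._stub_report({"lyman": 0.07, "logit": 0.14, "weibull": 0.08,
                                    "poisson": 0.09})
        assert report.rank("ssr") == ["lyman", "weibull", "poisson", "logit"]
        assert report.consensus_best == "lyman"
        table = rank_models(report)
        assert table.loc["lyman", "ssr"] == 1
        assert table.attrs["consensus_best"] == "lyman"

    def test_ties_break_lexicographically(self):
        report = self._stub_report({"weibull": 0.1, "lyman": 0.1, "logit": 0.2,
                                    "poisson": 0.3})
        assert report.rank("ssr")[:2] == ["lyman", "weibull"]

    def test_rank_needs_two_models(self):
        report = self._stub_report({"lyman": 0.1})
        with pytest.raises(ValueError):
            rank_models(report)

    def test_compare_models_end_to_end(self):
        curve = normalize_curve(
            generate_binned_curve("lyman", TRUE, EDGES, noise_sd=0.02, seed=3)
        )
        report = compare_models(curve)
        assert set(report.fits) == set(MODEL_IDS)
        df = report.to_frame()
        assert len(df) == 4
        for res in report.fits.values():
            assert res.bic - res.aic == pytest.approx(
                2 * np.log(res.n_bins_used) - 4, abs=1e-12
            )
        text = report.summary()
        assert "best by" in text

    def test_results_summary_and_confint(self):
        curve = generate_binned_curve("lyman", TRUE, EDGES, noise_sd=0.02, seed=4)
        res = NTCPModel(curve.bin_dose, curve.response, model="lyman").fit()
        text = res.summary()
        assert "lyman" in text and "D50" in text
        ci = res.conf_int()
        assert ci[0, 0] < res.d50 < ci[0, 1]
        assert ci[1, 0] < res.gamma50 < ci[1, 1]
        d = res.to_dict()
        assert {"model", "d50", "gamma50", "ssr", "adj_r2", "aic", "bic"} <= set(d)

    def test_plot_smoke(self):
        import matplotlib

        matplotlib.use("Agg")
        curve = generate_binned_curve("weibull", TRUE, EDGES)
        res = NTCPModel(curve.bin_dose, curve.response, model="weibull").fit()
        ax = res.plot()
        assert ax.get_xlabel() == "dose (Gy)"
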