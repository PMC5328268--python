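import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from itvoverlap.errors import (
    DegenerateDesignError,
    InsufficientDataError,
    UndefinedTestError,
)
from itvoverlap.inference import (
    compare_methods,
    fit_itv_model,
    regress_summary,
    signed_rank_z,
)


def make_meta(n_forests, richness=None, n_types=2, rng=None):
    rng = rng or np.random.default_rng(0)
    richness = richness if richness is not None else np.arange(1, n_forests + 1) * 10
    return pd.DataFrame(
        {
            "forest_id": [f"F{i:02d}" for i in range(n_forests)],
            "forest_type": [f"type_{i % n_types}" for i in range(n_forests)],
            "mat_c": 5 + 0.05 * np.asarray(richness) + rng.normal(0, 1, n_forests),
            "ap_mm": 800 + 5 * np.asarray(richness) + rng.normal(0, 100, n_forests),
            "species_richness": richness,
        }
    )


def simulate_itv_stats(meta, sr_slope, type_sd, resid_sd, n_species_per_forest, rng):
    """Log-CV generated directly from the mixed model's own equation."""
    type_effects = {
        t: rng.normal(0, type_sd) for t in meta["forest_type"].unique()
    }
    rows = []
    for _, m in meta.iterrows():
        for s in range(n_species_per_forest):
            log_cv = (
                3.0
                + sr_slope * m["species_richness"]
                + type_effects[m["forest_type"]]
                + rng.normal(0, resid_sd)
            )
            rows.append(
                {
                    "forest_id": m["forest_id"],
                    "species_id": f"sp{s}",
                    "trait": "leaf_size",
                    "cv_r": float(np.exp(log_cv)),
                }
            )
    return pd.DataFrame(rows)


class TestFitItvModel:
    def test_recovers_generative_slope(self, rng):
        meta = make_meta(20, n_types=4, rng=rng)
        stats = simulate_itv_stats(meta, sr_slope=-0.005, type_sd=0.2,
                                   resid_sd=0.3, n_species_per_forest=15, rng=rng)
        fit = fit_itv_model(stats, meta)
        assert fit.n_obs == 300
        assert fit.sr_slope == pytest.approx(-0.005, abs=0.003)

    def test_r2_ordering_invariant(self, rng):
        meta = make_meta(16, n_types=4, rng=rng)
        stats = simulate_itv_stats(meta, sr_slope=0.002, type_sd=0.4,
                                   resid_sd=0.3, n_species_per_forest=12, rng=rng)
        fit = fit_itv_model(stats, meta)
        assert 0.0 <= fit.r2_marginal <= fit.r2_conditional <= 1.0
        assert fit.random_intercept_variance > 0

    def test_singular_random_effect_falls_back_to_fixed_effects(self):
        rng = np.random.default_rng(0)  # lands the REML fit on the zero boundary
        meta = make_meta(16, n_types=4, rng=rng)
        stats = simulate_itv_stats(meta, sr_slope=0.0, type_sd=0.0,
                                   resid_sd=0.3, n_species_per_forest=20, rng=rng)
        with pytest.warns(UserWarning, match="singular"):
            fit = fit_itv_model(stats, meta)
        assert fit.fixed_effects_only
        assert fit.r2_conditional == fit.r2_marginal

    def test_needs_two_forest_types(self, rng):
        meta = make_meta(10, n_types=1, rng=rng)
        stats = simulate_itv_stats(meta, 0.0, 0.0, 0.3, 5, rng)
        with pytest.raises(InsufficientDataError):
            fit_itv_model(stats, meta)

    def test_gaussian_family_uses_identity_scale(self, rng):
        meta = make_meta(12, n_types=3, rng=rng)
        stats = simulate_itv_stats(meta, 0.0, 0.3, 0.3, 10, rng)
        fit_log = fit_itv_model(stats, meta, family_config="log_gaussian")
        fit_id = fit_itv_model(stats, meta, family_config="gaussian")
        # log-scale intercept is ~3 (log CV); identity-scale is ~exp(3)
        i_log = fit_log.coefficients.set_index("term").loc["intercept", "estimate"]
        i_id = fit_id.coefficients.set_index("term").loc["intercept", "estimate"]
        assert 2.0 < i_log < 4.5
        assert i_id > 10.0


class TestRegressSummary:
    def mk_summaries(self, forests, values):
        return pd.DataFrame(
            {
                "forest_id": forests,
                "trait": "leaf_size",
                "method": "kernel",
                "median_overlap": values,
            }
        )

    def test_perfect_fit_on_sqrt_scale(self):
        # (SR, median) pairs whose sqrt-responses are exactly linear in SR
        meta = make_meta(4, richness=[1, 10, 100, 200])
        sr = np.array([1.0, 10.0, 100.0, 200.0])
        y_sqrt = 0.2 + 0.003 * sr
        s = self.mk_summaries(meta["forest_id"], y_sqrt**2)
        fit = regress_summary(s, meta, response="median_overlap")
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(0.003, abs=1e-12)

    def test_constant_response_gives_r2_zero(self):
        meta = make_meta(5)
        s = self.mk_summaries(meta["forest_id"], [0.16] * 5)
        fit = regress_summary(s, meta, response="median_overlap")
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_four_point_closed_form_ols(self):
        """Hand-checkable least squares on sqrt-transformed responses."""
        meta = make_meta(4, richness=[1, 10, 100, 200])
        s = self.mk_summaries(meta["forest_id"], [0.04, 0.16, 0.36, 0.64])
        fit = regress_summary(s, meta, response="median_overlap")
        x = np.array([1.0, 10.0, 100.0, 200.0])
        y = np.array([0.2, 0.4, 0.6, 0.8])
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        ss_res = ((y - intercept - slope * x) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)

    def test_r2_invariant_to_affine_predictor_rescale(self):
        rng = np.random.default_rng(5)
        meta = make_meta(10, rng=rng)
        vals = rng.uniform(0.05, 0.6, 10)
        s = self.mk_summaries(meta["forest_id"], vals)
        fit1 = regress_summary(s, meta, response="median_overlap")
        meta2 = meta.copy()
        meta2["species_richness"] = meta2["species_richness"] * 3.5 + 40
        fit2 = regress_summary(s, meta2, response="median_overlap")
        assert fit2.r2 == pytest.approx(fit1.r2, abs=1e-10)
        assert fit2.p_value == pytest.approx(fit1.p_value, abs=1e-10)

    def test_zero_richness_variance_rejected(self):
        meta = make_meta(4, richness=[50, 50, 50, 50])
        s = self.mk_summaries(meta["forest_id"], [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(DegenerateDesignError):
            regress_summary(s, meta, response="median_overlap")

    def test_type_i_error_is_calibrated_under_global_null(self):
        """With no richness effect anywhere, the slope test at alpha=0.05
        rejects at close to its nominal rate."""
        rng = np.random.default_rng(99)
        meta = make_meta(21, richness=np.sort(rng.integers(1, 285, 21)))
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            s = self.mk_summaries(meta["forest_id"], rng.uniform(0.05, 0.6, 21))
            fit = regress_summary(s, meta, response="median_overlap")
            rejections += fit.p_value < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


def exact_signed_rank_p(diffs):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    mu = n * (n + 1) / 4
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2**n


class TestCompareMethods:
    def series(self, values, prefix="F"):
        return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])

    def test_mirrored_pairs_give_z_near_zero(self):
        # exactly representable differences so mirrored pairs tie exactly
        d = [0.25, -0.25, 0.5, -0.5, 0.125, -0.125, 1.0, -1.0]
        a = self.series([0.5 + x for x in d])
        b = self.series([0.5] * len(d))
        comp = compare_methods(a, b)
        assert abs(comp.z) < 1e-9
        assert comp.p_value == pytest.approx(1.0)

    def test_all_same_sign_reaches_maximal_z(self):
        n = 21
        diffs = np.linspace(0.01, 0.2, n)
        z, p, n_nz = signed_rank_z(diffs)
        w_max = n * (n + 1) / 2
        mu = n * (n + 1) / 4
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        assert z == pytest.approx((w_max - mu) / sd)
        assert z == pytest.approx(4.015, abs=0.001)

    def test_normal_approximation_tracks_exact_distribution(self, rng):
        """For n <= 12 the approximate p stays close to the enumerated
        exact p across random paired samples."""
        for _ in range(10):
            d = rng.normal(0.05, 0.1, 10)
            z, p, _ = signed_rank_z(d)
            p_exact = exact_signed_rank_p(d)
            assert p == pytest.approx(p_exact, abs=0.06)

    def test_matches_scipy_approx_zstatistic(self, rng):
        d = rng.normal(0.1, 0.2, 15)
        z, p, _ = signed_rank_z(d)
        res = scipy.stats.wilcoxon(d, method="approx", correction=False)
        assert abs(z) == pytest.approx(abs(res.zstatistic), abs=1e-10)
        assert p == pytest.approx(res.pvalue, abs=1e-10)

    def test_antisymmetry(self, rng):
        a = self.series(rng.uniform(0.1, 0.9, 12))
        b = self.series(rng.uniform(0.1, 0.9, 12))
        ab = compare_methods(a, b)
        ba = compare_methods(b, a)
        assert ab.z == pytest.approx(-ba.z, abs=1e-12)
        assert ab.p_value == pytest.approx(ba.p_value, abs=1e-12)

    def test_zero_differences_dropped_and_all_zero_rejected(self):
        a = self.series([0.5] * 8)
        with pytest.raises(UndefinedTestError):
            compare_methods(a, a.copy())

    def test_alignment_on_forest_ids(self):
        a = pd.Series([0.1, 0.2, 0.9], index=["F1", "F2", "F3"])
        b = pd.Series([0.3, 0.15, 0.25, 0.4, 0.1, 0.6, 0.7],
                      index=["F2", "F1", "F3", "F4", "F5", "F6", "F7"])
        with pytest.raises(InsufficientDataError):
            compare_methods(a, b)  # only 3 shared forests
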