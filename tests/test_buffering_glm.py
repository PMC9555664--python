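import numpy as np
import pandas as pd
import pytest

from eggsync import buffering_glm as bg
from eggsync import sync_markov as smk
from eggsync.errors import InsufficientDataError


def _frame(rng=None, n_years=18, sp_effect=1.5, w_slope=-0.4, sync_effect=-0.5,
           sigma=0.5, start=2002, closure=2010):
    """One simulated modelling frame (two species x n_years rows)."""
    rng = rng or np.random.default_rng(0)
    years = np.arange(start, start + n_years)
    wnao = rng.normal(0, 1, n_years)
    sync = ((years >= closure) & (years <= closure + 6)).astype(int)
    rows = []
    for sp, b in (("gull", sp_effect), ("shearwater", 0.0)):
        resp = b + w_slope * wnao + sync_effect * sync + rng.normal(0, sigma, n_years)
        for y, w, s, r in zip(years, wnao, sync, resp):
            rows.append({"species": sp, "year": int(y), "response": r, "sync": int(s),
                         "wnao": w, "phase": int(y >= closure)})
    return pd.DataFrame(rows)


class TestAicc:
    @pytest.mark.parametrize(
        "loglik, k, n, expected",
        [
            (-57.72, 7, 36, 133.44),
            (-60.89, 5, 36, 133.78),
            (-58.14, 6, 36, 131.17740),
            (0, 1, 100, 2 + 4 / 98),
        ],
    )
    def test_published_and_closed_form_values(self, loglik, k, n, expected):
        assert bg.aicc(loglik, k, n) == pytest.approx(expected, abs=5e-3)

    def test_undefined_correction(self):
        with pytest.raises(ValueError):
            bg.aicc(-10, 5, 6)

    def test_reduces_to_aic_for_large_n(self):
        aic = -2 * (-50.0) + 2 * 5
        assert bg.aicc(-50.0, 5, 10**7) == pytest.approx(aic, abs=1e-4)


class TestFit:
    def test_noise_free_fit_recovers_slope_with_tight_ci(self):
        df = _frame(sigma=0.0, sync_effect=0.0)
        fit = bg.fit_gaussian_glm(df, bg.ModelSpec(frozenset({"Sp", "W_NAO"})))
        j = fit.terms.index("W_NAO")
        assert fit.coefficients[j] == pytest.approx(-0.4, abs=1e-10)
        assert fit.ci[j, 1] - fit.ci[j, 0] < 1e-8

    def test_intercept_only_ml_closed_form(self):
        df = pd.DataFrame(
            {"species": ["gull"] * 9, "year": range(2002, 2011),
             "response": [1.0, 2, 3] * 3, "sync": 0, "wnao": 0.0, "phase": 0}
        )
        fit = bg.fit_gaussian_glm(df, bg.ModelSpec(frozenset()))
        assert fit.coefficients[0] == pytest.approx(2.0)
        # ML loglik at sigma^2 = RSS/n = 2/3
        n, s2 = 9, 2 / 3
        ll = -0.5 * n * (np.log(2 * np.pi * s2) + 1)
        assert fit.loglik == pytest.approx(ll, abs=1e-10)

    def test_parameter_count_matches_published_convention(self):
        df = _frame()
        spec = bg.ModelSpec(frozenset({"Sp", "Sync", "W_NAO", "Sp:Sync"}))
        assert bg.fit_gaussian_glm(df, spec).k == 6

    def test_coefficients_match_normal_equations(self):
        df = _frame(rng=np.random.default_rng(5))
        spec = bg.ModelSpec(frozenset({"Sp", "Sync", "W_NAO", "Sp:W_NAO"}))
        fit = bg.fit_gaussian_glm(df, spec)
        X, _ = bg._design_matrix(df, spec)
        y = df["response"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-8)

    def test_rank_deficiency_reported(self):
        df = _frame()
        df["wnao"] = 1.0  # collinear with the intercept
        with pytest.raises(np.linalg.LinAlgError):
            bg.fit_gaussian_glm(df, bg.ModelSpec(frozenset({"W_NAO"})))

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError):
            bg.ModelSpec(frozenset({"Sp:Sync"}))


class TestSelectionAndAveraging:
    def test_candidate_set_is_hierarchical(self):
        specs = bg.candidate_specs()
        assert len(specs) == 18
        names = {s.name for s in specs}
        assert "Sp + Sync + W_NAO + Sp:Sync" in names
        assert "1" in names

    def test_single_candidate(self):
        df = _frame()
        table = bg.model_selection(df, [bg.ModelSpec(frozenset({"W_NAO"}))])
        assert table.delta[0] == 0.0
        assert table.weight[0] == pytest.approx(1.0)

    def test_equal_aicc_gives_equal_weights(self):
        df = _frame()
        f = bg.fit_gaussian_glm(df, bg.ModelSpec(frozenset({"W_NAO"})))
        import dataclasses

        table = bg.ModelTable(fits=[f, f], delta=np.zeros(2), weight=np.array([0.5, 0.5]))
        assert table.weight.sum() == pytest.approx(1.0)

    def test_weights_invariant_to_aicc_offset(self):
        df = _frame()
        table = bg.model_selection(df)
        a = np.array([f.aicc for f in table.fits])
        d = a - a.min()
        w = np.exp(-d / 2) / np.exp(-d / 2).sum()
        w_shift = np.exp(-(d + 100) / 2 + 50) / np.exp(-(d + 100) / 2 + 50).sum()
        np.testing.assert_allclose(w, w_shift)
        np.testing.assert_allclose(table.weight, w)
        assert table.delta[0] == 0.0

    def test_true_model_preferred_over_supersets(self):
        """Data from the small model: its delta <= the full model's, usually."""
        wins = 0
        for seed in range(40):
            df = _frame(rng=np.random.default_rng(seed), sync_effect=0.0)
            small = bg.fit_gaussian_glm(df, bg.ModelSpec(frozenset({"Sp", "W_NAO"})))
            big = bg.fit_gaussian_glm(
                df, bg.ModelSpec(frozenset({"Sp", "Sync", "W_NAO", "Sp:Sync", "Sp:W_NAO"}))
            )
            wins += small.aicc <= big.aicc
        assert wins > 20

    def test_averaging_single_model_is_identity(self):
        df = _frame()
        table = bg.model_selection(df, [bg.ModelSpec(frozenset({"Sp", "W_NAO"}))])
        avg = bg.model_average(table)
        fit = table.fits[0]
        for t, est in zip(avg["term"], avg["estimate"]):
            assert est == pytest.approx(fit.coefficients[fit.terms.index(t)])

    def test_zero_substitution_halves_a_coefficient(self):
        """Two equal-weight models, one lacking the term -> average c/2."""
        df = _frame()
        with_w = bg.fit_gaussian_glm(df, bg.ModelSpec(frozenset({"Sp", "W_NAO"})))
        without = bg.fit_gaussian_glm(df, bg.ModelSpec(frozenset({"Sp"})))
        table = bg.ModelTable(
            fits=[with_w, without], delta=np.zeros(2), weight=np.array([0.5, 0.5])
        )
        avg = bg.model_average(table)
        c = with_w.coefficients[with_w.terms.index("W_NAO")]
        got = float(avg.loc[avg.term == "W_NAO", "estimate"].iloc[0])
        assert got == pytest.approx(c / 2)

    def test_threshold_excludes_distant_models(self):
        df = _frame(rng=np.random.default_rng(3))
        table = bg.model_selection(df)
        avg_terms = set(bg.model_average(table, threshold=4.0)["term"])
        kept = [f for f, d in zip(table.fits, table.delta) if d <= 4.0]
        expected = {t for f in kept for t in f.terms}
        assert avg_terms == expected


class TestSignificance:
    @pytest.mark.parametrize(
        "ci, expected",
        [((0.16, 2.75), True), ((-0.1, 0.1), False), ((0.0, 0.5), False), ((-2.0, -0.5), True)],
    )
    def test_ci_zero_overlap_convention(self, ci, expected):
        assert bg.is_significant(sum(ci) / 2, ci) is expected

    def test_invalid_ci(self):
        with pytest.raises(ValueError):
            bg.is_significant(0.0, (1.0, -1.0))


class TestCodeSynchrony:
    def test_identical_series_all_ones_inside_axis(self, aligned_series_pair):
        a, _ = aligned_series_pair
        res = smk.run_synchrony(a, a, n_sims=200, seed=0)
        coded = bg.code_synchrony(res, a.years)
        assert coded[0] == 0 and coded[-1] == 0  # outside the phi axis
        assert coded[1:-1].sum() == len(res.times)

    def test_desynchronized_all_zero(self):
        x = np.array([1.0, 3, 1, 4, 1, 5, 1, 6, 1, 7])
        res = smk.run_synchrony(x, -x, n_sims=200, seed=0)
        assert bg.code_synchrony(res, np.arange(len(x))).sum() == 0

    def test_mixed_fixture_counts_agreeing_years(self):
        # agree on the shared sawtooth except where b is flattened
        a = np.array([1.0, 5, 1, 5, 1, 5, 1, 5, 1, 5, 1])
        b = np.array([1.0, 5, 1, 5, 1, 5, 1, 5, 3, 2, 4])
        res = smk.run_synchrony(a, b, n_sims=200, seed=0)
        agree = int(np.sum(res.state_a == res.state_b))
        coded = bg.code_synchrony(res, np.arange(len(a)))
        assert coded.sum() == agree
        assert agree == 7


class TestPhaseSlopes:
    def test_recovers_phase_dependent_slopes(self):
        rng = np.random.default_rng(12)
        years = np.arange(2002, 2020)
        wnao = rng.normal(0, 1, len(years))
        rows = []
        for sp in ("gull", "shearwater"):
            for y, w in zip(years, wnao):
                phase = int(y >= 2010)
                slope = -0.4 if (sp == "shearwater" or phase) else 0.0
                rows.append({"species": sp, "year": int(y), "sync": 0, "wnao": w,
                             "phase": phase,
                             "response": slope * w + rng.normal(0, 0.1)})
        out = bg.phase_slopes(pd.DataFrame(rows))
        gull_pre = out[(out.species == "gull") & (out.phase == "before")].iloc[0]
        gull_post = out[(out.species == "gull") & (out.phase == "after")].iloc[0]
        assert abs(gull_pre.estimate) < 3 * gull_pre.se + 0.1
        assert gull_post.estimate == pytest.approx(-0.4, abs=3 * gull_post.se)
        contrast = out[out.phase == "after-before"].iloc[0]
        assert contrast.estimate == pytest.approx(-0.4, abs=3 * contrast.se)

    def test_equal_slopes_give_null_contrast(self):
        df = _frame(rng=np.random.default_rng(4), sync_effect=0.0)
        out = bg.phase_slopes(df)
        contrast = out[out.phase == "after-before"].iloc[0]
        assert abs(contrast.estimate) < 3 * contrast.se

    def test_single_phase_data_error(self):
        df = _frame()
        with pytest.raises(InsufficientDataError):
            bg.phase_slopes(df[df.phase == 1])
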