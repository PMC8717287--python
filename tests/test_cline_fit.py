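import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mimicline.cline_fit import (
    ClineError,
    ClineModel,
    ClineFitResult,
    MCMCSettings,
    ModelClass,
    aicc,
    cline_value,
    compare_clines,
    fit_cline,
    log_likelihood,
    select_model,
)
from mimicline.synthetic_data import simulate_cline_observations


def _model(c=600.0, w=150.0, **kw):
    return ClineModel(ModelClass.II_FREE_NONE, c=c, w=w, **kw)


class TestClineValue:
    def test_half_at_center(self):
        assert cline_value(_model(), 600.0) == pytest.approx(0.5)

    def test_half_width_closed_form(self):
        # p(c + w/2) = (1 + tanh(1)) / 2
        expected = (1 + math.tanh(1.0)) / 2
        assert cline_value(_model(), 675.0) == pytest.approx(expected, abs=1e-12)
        assert cline_value(_model(), 675.0) == pytest.approx(0.88080, abs=1e-5)

    @settings(derandomize=True, max_examples=50)
    @given(d=st.floats(min_value=0, max_value=500))
    def test_odd_symmetry_about_center(self, d):
        m = _model(pmin=0.1, pmax=0.9)
        assert cline_value(m, 600 + d) + cline_value(m, 600 - d) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_invalid_width_rejected(self):
        with pytest.raises(ClineError):
            ClineModel(ModelClass.I_FIXED_NONE, c=0.0, w=0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        c=st.floats(min_value=200, max_value=800),
        w=st.floats(min_value=10, max_value=400),
        dl=st.floats(min_value=0, max_value=300),
        tl=st.floats(min_value=0, max_value=1),
        dr=st.floats(min_value=0, max_value=300),
        tr=st.floats(min_value=0, max_value=1),
        pmin=st.floats(min_value=0, max_value=0.4),
        pmax=st.floats(min_value=0.6, max_value=1),
    )
    def test_monotone_including_tails(self, c, w, dl, tl, dr, tr, pmin, pmax):
        m = ClineModel(
            ModelClass.III_FREE_BOTH, c=c, w=w, pmin=pmin, pmax=pmax,
            deltaL=dl, tauL=tl, deltaR=dr, tauR=tr,
        )
        x = np.linspace(-500, 1500, 800)
        p = cline_value(m, x)
        assert np.all(np.diff(p) >= -1e-10)

    def test_tail_value_continuity(self):
        m = ClineModel(
            ModelClass.III_FREE_BOTH, c=600, w=150, deltaL=80, tauL=0.5,
            deltaR=120, tauR=0.3,
        )
        for xj in (600 - 80, 600 + 120):
            below = cline_value(m, xj - 1e-9)
            above = cline_value(m, xj + 1e-9)
            assert abs(above - below) < 1e-7

    def test_tau_one_slope_continuity(self):
        # with tau = 1 the tail's initial slope equals the sigmoid slope
        m = ClineModel(
            ModelClass.III_FREE_BOTH, c=600, w=150, deltaL=80, tauL=1.0,
            deltaR=80, tauR=1.0,
        )
        h = 1e-5
        for xj in (520.0, 680.0):
            slope_in = (cline_value(m, xj) - cline_value(m, xj - h)) / h
            slope_out = (cline_value(m, xj + h) - cline_value(m, xj)) / h
            assert slope_in == pytest.approx(slope_out, rel=1e-3)


class TestLogLikelihood:
    def test_single_point_at_center(self):
        m = _model()
        assert log_likelihood(m, [600.0], [1.0]) == pytest.approx(math.log(0.5))

    def test_step_limit_approaches_zero(self):
        x = np.array([100.0, 200.0, 900.0, 1000.0])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        lls = [
            log_likelihood(_model(c=550, w=w), x, y) for w in (100.0, 10.0, 1.0)
        ]
        assert lls == sorted(lls)  # sharper cline fits separated data better
        assert lls[-1] > -1e-6

    def test_gaussian_exact_fit_closed_form(self):
        m = _model()
        x = np.linspace(0, 1200, 50)
        y = np.asarray(cline_value(m, x))
        sigma = 0.07
        expected = 50 * math.log(1.0 / (sigma * math.sqrt(2 * math.pi)))
        assert log_likelihood(m, x, y, "gaussian", sigma=sigma) == pytest.approx(expected)

    def test_bernoulli_equals_pooled_binomial(self):
        # individuals at the same x pool into a binomial likelihood term
        m = _model()
        x = np.array([500.0] * 10)
        y = np.array([1.0] * 3 + [0.0] * 7)
        p = float(cline_value(m, 500.0))
        assert log_likelihood(m, x, y) == pytest.approx(
            3 * math.log(p) + 7 * math.log(1 - p)
        )

    def test_empty_data_rejected(self):
        with pytest.raises(ClineError):
            log_likelihood(_model(), [], [])


class TestAicc:
    def test_closed_form(self):
        assert aicc(-100.0, 2, 125) == pytest.approx(204 + 12 / 122)

    def test_zero_parameters(self):
        assert aicc(-50.0, 0, 100) == pytest.approx(100.0)

    def test_approaches_aic_for_large_n(self):
        assert aicc(-100.0, 3, 10**7) == pytest.approx(206.0, abs=1e-4)

    def test_small_n_rejected(self):
        with pytest.raises(ClineError):
            aicc(-10.0, 4, 5)


class TestFitCline:
    def test_recovers_simulated_center(self):
        x, y = simulate_cline_observations(607.0, 157.6, 500, seed=11)
        fit = fit_cline(x, y, "I", mcmc=MCMCSettings(iterations=15_000, seed=5))
        assert abs(fit.posterior_median("c") - 607.0) < 30.0
        lo, hi = fit.center_credible_interval
        assert lo < hi

    def test_deterministic_given_seed(self):
        x, y = simulate_cline_observations(607.0, 157.6, 200, seed=3)
        settings_ = MCMCSettings(iterations=2000, seed=9)
        f1 = fit_cline(x, y, "I", mcmc=settings_)
        f2 = fit_cline(x, y, "I", mcmc=settings_)
        assert f1.model.c == f2.model.c
        assert np.array_equal(f1.posterior_samples, f2.posterior_samples)

    def test_no_signal_center_unidentified(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 1000, 200))
        y = np.zeros(200)
        y[:5] = 1.0  # barely any signal, scattered at the south end by sort
        rng.shuffle(y)
        fit = fit_cline(x, y, "II", mcmc=MCMCSettings(iterations=5000, seed=1))
        lo, hi = fit.center_credible_interval
        assert hi - lo > 300.0  # interval spans a large part of the prior range

    def test_aicc_identity_holds(self):
        x, y = simulate_cline_observations(607.0, 157.6, 200, seed=3)
        fit = fit_cline(x, y, "II", mcmc=MCMCSettings(iterations=3000, seed=2))
        assert fit.aicc == pytest.approx(aicc(fit.logL_max, fit.k, fit.n))
        assert fit.width_inv_max_slope == pytest.approx(
            fit.model.w / (fit.model.pmax - fit.model.pmin)
        )

    def test_non_spanning_data_rejected(self):
        with pytest.raises(ClineError):
            fit_cline([5.0] * 20, [0.0, 1.0] * 10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ClineError):
            fit_cline([1, 2, 3], [0, 1, 0])


class TestModelSelection:
    def _fits(self):
        x, y = simulate_cline_observations(607.0, 157.6, 300, seed=21)
        settings_ = lambda s: MCMCSettings(iterations=6000, seed=s)
        return [
            fit_cline(x, y, mc, mcmc=settings_(7))
            for mc in ("I", "II", "III")
        ]

    def test_tail_free_truth_not_won_by_model_iii(self):
        fits = self._fits()
        best, table = select_model(fits)
        aiccs = {row["model_class"]: row["aicc"] for row in table}
        # data simulated without tails: the 8-parameter model never wins
        # by a meaningful margin over the parsimonious ones
        assert min(aiccs["I"], aiccs["II"]) <= aiccs["III"] + 2.0

    def test_single_fit_returned_unchanged(self):
        fits = self._fits()[:1]
        best, table = select_model(fits)
        assert best is fits[0]
        assert table[0]["delta_aicc"] == 0.0

    def test_tie_broken_toward_fewer_parameters(self):
        fits = self._fits()[:2]
        fits[0].aicc = fits[1].aicc = 100.0
        best, _ = select_model(fits)
        assert best.k == min(f.k for f in fits)

    def test_mixed_data_rejected(self):
        f1 = self._fits()[0]
        x, y = simulate_cline_observations(500.0, 100.0, 300, seed=99)
        f2 = fit_cline(x, y, "I", mcmc=MCMCSettings(iterations=2000, seed=1))
        with pytest.raises(ClineError):
            select_model([f1, f2])


class TestCompareClines:
    def test_self_comparison_zero_shift(self):
        x, y = simulate_cline_observations(607.0, 157.6, 200, seed=3)
        fit = fit_cline(x, y, "I", mcmc=MCMCSettings(iterations=3000, seed=2))
        cmp = compare_clines(fit, fit)
        assert cmp["center_shift_km"] == 0.0
        assert cmp["width_diff_km"] == 0.0

    def test_width_difference_sign(self):
        # width estimates are noisy at n=1000, so average the difference
        # over independent simulation pairs before checking the sign
        diffs = []
        for rep in range(3):
            xa, ya = simulate_cline_observations(661.6, 134.3, 1000, seed=51 + rep)
            xb, yb = simulate_cline_observations(607.0, 157.6, 1000, seed=81 + rep)
            fa = fit_cline(xa, ya, "I", mcmc=MCMCSettings(iterations=8000, seed=4 + rep))
            fb = fit_cline(xb, yb, "I", mcmc=MCMCSettings(iterations=8000, seed=5 + rep))
            cmp = compare_clines(fa, fb)
            diffs.append(cmp["width_diff_km"])
            assert cmp["shift_posterior"].shape[0] > 100
        # the color-type cline (truth width 134.3) is narrower than the
        # mtDNA-type cline (truth width 157.6)
        assert np.mean(diffs) < 0
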