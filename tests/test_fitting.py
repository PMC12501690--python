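import numpy as np
import pandas as pd
import pytest

from ivimseg.fitting import (
    InsufficientDataError,
    compute_f_tilde,
    default_bt_series,
    estimate_D_opAS,
    fit_AS,
    fit_batch,
    fit_curve,
    fit_monoexp,
    fit_opAS,
    fit_OS,
    fit_S,
)
from ivimseg.model import IVIMParams, SignalCurve, ivim_signal
from ivimseg.simulate import ConfigError


def sse_grid_oracle(curve, D, f_grid, dstar_grid):
    """Brute-force 2D grid search over (f, D*) with D and S0 fixed.

    Independent of the production optimizer: evaluates the forward model on
    a dense grid and returns the SSE-minimizing pair.
    """
    b, s, S0 = curve.bvalues, curve.signal, curve.S0
    best = (np.inf, None, None)
    for f in f_grid:
        model = S0 * (
            f * np.exp(-b[None, :] * (D + dstar_grid[:, None]))
            + (1 - f) * np.exp(-b[None, :] * D)
        )
        sse = ((model - s[None, :]) ** 2).sum(axis=1)
        i = int(np.argmin(sse))
        if sse[i] < best[0]:
            best = (sse[i], f, dstar_grid[i])
    return best[1], best[2]


class TestMonoExp:
    def test_exact_on_pure_monoexponential(self, bvalues):
        s = np.exp(-bvalues * 1e-3)
        curve = SignalCurve(bvalues, s)
        for b_t in (0.0, 100.0, 200.0):
            fit = fit_monoexp(curve, b_t)
            assert fit.D_tilde == pytest.approx(1e-3, rel=1e-10)
            assert fit.S_int == pytest.approx(1.0, rel=1e-10)

    def test_high_dstar_tail_is_clean(self, noiseless_curve):
        # residual perfusion at b=200 is e^{-200*0.061} ~ 5e-6 of the signal
        curve, _ = noiseless_curve(D=1e-3, Dstar=60e-3, f=0.1)
        assert fit_monoexp(curve, 200.0).D_tilde == pytest.approx(1e-3, rel=0.005)

    def test_low_dstar_contaminates_tail(self, noiseless_curve):
        curve, _ = noiseless_curve(D=1e-3, Dstar=4e-3, f=0.3)
        assert fit_monoexp(curve, 100.0).D_tilde > 1e-3

    def test_insufficient_points(self, noiseless_curve):
        curve, _ = noiseless_curve()
        with pytest.raises(InsufficientDataError):
            fit_monoexp(curve, 480.0)

    def test_nonpositive_signals_excluded(self, bvalues):
        s = np.exp(-bvalues * 1e-3)
        s[-2:] = 0.0
        curve = SignalCurve(bvalues, s)
        fit = fit_monoexp(curve, 200.0)  # 4 usable points remain
        assert fit.D_tilde == pytest.approx(1e-3, rel=1e-8)
        with pytest.raises(InsufficientDataError):
            fit_monoexp(curve, 350.0)


class TestFTilde:
    def test_algebraic_identity_noiseless(self, noiseless_curve):
        for f, ds in [(0.1, 10e-3), (0.02, 2e-3), (0.5, 60e-3)]:
            curve, p = noiseless_curve(D=1e-3, Dstar=ds, f=f)
            ft = compute_f_tilde(curve, 1e-3)
            expected = f * (1 - np.exp(-curve.bvalues * ds))
            np.testing.assert_allclose(ft.f_tilde, expected, rtol=1e-10, atol=1e-15)

    def test_spot_value(self, noiseless_curve):
        # f (1 - e^{-b D*}) = 0.1 (1 - e^{-1}) at b = 100, D* = 10e-3
        curve, _ = noiseless_curve(D=1e-3, Dstar=10e-3, f=0.1)
        ft = compute_f_tilde(curve, 1e-3)
        j = list(curve.bvalues).index(100.0)
        assert ft.f_tilde[j] == pytest.approx(0.063212, abs=1e-6)

    def test_zero_at_origin_and_for_no_perfusion(self, noiseless_curve):
        curve, _ = noiseless_curve(f=0.0)
        ft = compute_f_tilde(curve, 1e-3)
        assert ft.f_tilde[0] == 0.0
        np.testing.assert_allclose(ft.f_tilde, 0.0, atol=1e-12)


class TestFitS:
    def test_noiseless_recovery_matches_grid_oracle(self, noiseless_curve):
        curve, p = noiseless_curve(D=1e-3, Dstar=60e-3, f=0.2)
        res = fit_S(curve, 200.0)
        assert res.params.f == pytest.approx(0.2, rel=0.01)
        assert res.params.Dstar == pytest.approx(60e-3, rel=0.02)
        f_o, ds_o = sse_grid_oracle(
            curve,
            res.params.D,
            np.linspace(0.15, 0.25, 201),
            np.linspace(40e-3, 80e-3, 401),
        )
        assert res.params.f == pytest.approx(f_o, abs=5e-4)
        assert res.params.Dstar == pytest.approx(ds_o, abs=2e-4)

    def test_no_perfusion_gives_f_at_lower_bound(self, noiseless_curve):
        curve, _ = noiseless_curve(f=0.0)
        assert fit_S(curve, 100.0).params.f <= 1e-3

    def test_low_dstar_underestimates_f(self, noiseless_curve):
        curve, _ = noiseless_curve(D=1e-3, Dstar=4e-3, f=0.1)
        assert fit_S(curve, 100.0).params.f < 0.1


class TestFitOS:
    def test_f_from_intercept_arithmetic(self, noiseless_curve):
        curve, _ = noiseless_curve(D=1e-3, Dstar=60e-3, f=0.1)
        res = fit_OS(curve, 200.0)
        mono = res.intermediates["mono"]
        assert res.params.f == pytest.approx(1 - mono.S_int / curve.S0)

    def test_intercept_above_S0_clips_f_to_zero(self, bvalues):
        # a rising-intercept curve: signal above the b=0 value at low b
        s = 1.05 * np.exp(-bvalues * 1e-3)
        s[0] = 1.0
        curve = SignalCurve(bvalues, s)
        res = fit_OS(curve, 100.0)
        assert res.params.f == 0.0
        assert res.estimates["f"] < 0  # raw estimate keeps the sign
        assert res.params.Dstar == pytest.approx(1.0 / bvalues[-1])  # lower bound
        assert res.converged and "clip" in res.message

    def test_noiseless_recovery_matches_1d_oracle(self, noiseless_curve):
        curve, _ = noiseless_curve(D=1e-3, Dstar=60e-3, f=0.2)
        res = fit_OS(curve, 200.0)
        assert res.params.f == pytest.approx(0.2, rel=0.01)
        assert res.params.Dstar == pytest.approx(60e-3, rel=0.02)
        ds_grid = np.linspace(40e-3, 80e-3, 2001)
        b, s = curve.bvalues, curve.signal
        model = res.params.f * np.exp(-b[None, :] * (res.params.D + ds_grid[:, None])) + (
            1 - res.params.f
        ) * np.exp(-b[None, :] * res.params.D)
        sse = ((model - s[None, :]) ** 2).sum(axis=1)
        assert res.params.Dstar == pytest.approx(ds_grid[np.argmin(sse)], abs=5e-5)


class TestFitAS:
    def test_noiseless_recovery_with_clean_tail(self, noiseless_curve):
        curve, _ = noiseless_curve(D=1e-3, Dstar=60e-3, f=0.2)
        res = fit_AS(curve, 200.0)
        assert res.params.f == pytest.approx(0.2, rel=0.01)
        assert res.params.Dstar == pytest.approx(60e-3, rel=0.02)
        assert abs(res.intermediates["epsilon"]) <= 1e-4

    def test_zero_f_tilde_curve(self, noiseless_curve):
        curve, _ = noiseless_curve(f=0.0)
        res = fit_AS(curve, 200.0)
        assert abs(res.estimates["f"]) <= 1e-6
        assert abs(res.intermediates["epsilon"]) <= 1e-6

    def test_constant_f_tilde_is_degenerate(self, bvalues):
        # S(b) = (1 - c) e^{-bD} for b > 0 makes f~ a step of height c,
        # which the model can only approach with D* at its upper bound
        c = 0.1
        s = (1 - c) * np.exp(-bvalues * 1e-3)
        s[0] = 1.0
        curve = SignalCurve(bvalues, s)
        res = fit_AS(curve, 100.0)
        assert (not res.converged) or res.params.Dstar > 0.4


class TestOpAS:
    def test_no_perfusion_trend_is_flat(self, noiseless_curve):
        curve, _ = noiseless_curve(D=1e-3, f=0.0)
        est = estimate_D_opAS(curve)
        assert est.fD_product == pytest.approx(0.0, abs=2e-6)
        assert est.D == pytest.approx(1e-3, rel=1e-3)
        assert est.ADC == pytest.approx(1e-3, rel=1e-3)

    def test_adc_is_zero_threshold_decay_rate(self, noiseless_curve):
        # the trend-fit ADC is the b_t = 0 mono-exponential decay constant of
        # the whole curve; it lies between D and the b -> 0 tangent D + f D*
        curve, p = noiseless_curve(D=1e-3, Dstar=30e-3, f=0.1)
        est = estimate_D_opAS(curve)
        assert est.ADC == pytest.approx(fit_monoexp(curve, 0.0).D_tilde, rel=0.02)
        assert p.D < est.ADC < p.D + p.f * p.Dstar

    def test_noiseless_end_to_end(self, noiseless_curve):
        curve, _ = noiseless_curve(D=1e-3, Dstar=60e-3, f=0.2)
        res = fit_opAS(curve)
        assert res.params.D == pytest.approx(1e-3, rel=0.02)
        assert res.params.Dstar == pytest.approx(60e-3, rel=0.02)
        assert res.params.f == pytest.approx(0.2, rel=0.02)

    def test_no_perfusion_end_to_end(self, noiseless_curve):
        curve, _ = noiseless_curve(f=0.0)
        res = fit_opAS(curve)
        assert res.params.D == pytest.approx(1e-3, rel=1e-3)
        assert res.params.f <= 1e-3

    def test_beats_thresholded_methods_at_low_dstar(self, noiseless_curve):
        curve, _ = noiseless_curve(D=1e-3, Dstar=4e-3, f=0.1)
        op = fit_opAS(curve)
        s = fit_S(curve, 100.0)
        a = fit_AS(curve, 100.0)
        for param, truth in (("Dstar", 4e-3), ("f", 0.1)):
            err_op = abs(getattr(op.params, param) - truth) / truth
            err_s = abs(getattr(s.params, param) - truth) / truth
            err_a = abs(getattr(a.params, param) - truth) / truth
            assert err_op < err_s
            assert err_op < err_a

    def test_bt_series_default(self, bvalues):
        series = default_bt_series(bvalues)
        assert series[0] == 0.0 and series[-1] == 350.0
        assert series.size == 15

    def test_too_few_thresholds(self, noiseless_curve):
        curve, _ = noiseless_curve()
        with pytest.raises(InsufficientDataError):
            estimate_D_opAS(curve, bt_series=[0.0, 100.0, 200.0])

    def test_monotone_threshold_effect_at_low_dstar(self, noiseless_curve):
        # contamination of the tail fit shrinks as the threshold grows
        for ds in (2e-3, 4e-3, 6e-3):
            curve, _ = noiseless_curve(D=1e-3, Dstar=ds, f=0.3)
            errs = [
                abs(fit_monoexp(curve, bt).D_tilde - 1e-3)
                for bt in default_bt_series(curve.bvalues)
            ]
            assert np.all(np.diff(errs) <= 1e-12)


class TestDispatchAndBatch:
    def test_dispatch_equivalences(self, noiseless_curve):
        curve, _ = noiseless_curve()
        assert fit_curve(curve, "S", 100.0).params == fit_S(curve, 100.0).params
        assert fit_curve(curve, "opAS").params == fit_opAS(curve).params
        # opAS is threshold-free: a caller-supplied b_t changes nothing
        assert fit_curve(curve, "opAS", 100.0).params == fit_curve(curve, "opAS", 200.0).params

    def test_unknown_method_and_missing_bt(self, noiseless_curve):
        curve, _ = noiseless_curve()
        with pytest.raises(ConfigError):
            fit_curve(curve, "bayes")
        with pytest.raises(ConfigError):
            fit_curve(curve, "S")

    def test_batch_fitting_roundtrip(self, bvalues):
        frames = []
        for cid, f in [(1, 0.1), (2, 0.3)]:
            s = ivim_signal(IVIMParams(1e-3, 30e-3, f), bvalues)
            frames.append(pd.DataFrame({"id": cid, "b": bvalues, "signal": s}))
        out = fit_batch(pd.concat(frames), "opAS")
        assert list(out.columns) == [
            "id", "method", "D", "Dstar", "f", "flux", "f0", "epsilon", "ADC", "converged",
        ]
        assert out["f"].to_numpy() == pytest.approx([0.1, 0.3], rel=0.05)
        assert out["converged"].all()

    def test_batch_degenerate_curve_flagged(self, bvalues):
        good = pd.DataFrame(
            {"id": 1, "b": bvalues, "signal": ivim_signal(IVIMParams(1e-3, 30e-3, 0.1), bvalues)}
        )
        bad = pd.DataFrame({"id": 2, "b": bvalues, "signal": np.zeros_like(bvalues)})
        out = fit_batch(pd.concat([good, bad]), "S", b_t=100.0)
        assert out.loc[out["id"] == 1, "converged"].item()
        assert not out.loc[out["id"] == 2, "converged"].item()
        assert np.isnan(out.loc[out["id"] == 2, "D"].item())
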