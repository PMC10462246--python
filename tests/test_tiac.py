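import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from predose import (
    BladderParams,
    FitError,
    FitResult,
    Radionuclide,
    TIACResult,
    TimeActivitySeries,
    ValidationError,
    fit_exponentials,
    plan_empirical,
    tiac_bladder,
    tiac_from_fit,
    tiac_physical_decay,
    tiac_rest_of_body,
    tiac_trapezoid,
)

from oracles import bladder_tiac_simulated


def _nuclide(lambda_p: float) -> Radionuclide:
    return Radionuclide(name="n", half_life_h=np.log(2) / lambda_p)


def _tac(times, values, region="Liver", sd=None):
    return TimeActivitySeries(region=region, times_h=times, values=values, sd=sd)


def _fit_result(c, lb, lam_p, n_points=8):
    c, lb = np.asarray(c, float), np.asarray(lb, float)
    return FitResult(
        region="Totalbody",
        amplitudes=c,
        lambda_bio=lb,
        lambda_p=lam_p,
        wrss=0.0,
        dof=n_points - 2 * c.size,
        score=None,
        success=True,
        constrained=True,
    )


class TestTrapezoid:
    def test_three_term_hand_value(self):
        result = tiac_trapezoid(_tac([1.0, 2.0], [0.8, 0.4]), _nuclide(0.1))
        # head 0.8, trapezoid 0.6, tail 4.0
        assert result.tiac_h == pytest.approx(5.4, rel=1e-12)
        assert result.notes["head_h"] == pytest.approx(0.8)
        assert result.notes["tail_h"] == pytest.approx(4.0)

    def test_zero_activity_gives_zero(self):
        result = tiac_trapezoid(_tac([1.0, 2.0, 5.0], [0.0, 0.0, 0.0]), _nuclide(0.2))
        assert result.tiac_h == 0.0

    def test_single_point_directs_to_other_methods(self):
        with pytest.raises(ValidationError, match="at least 2"):
            tiac_trapezoid(_tac([1.0], [0.5]), _nuclide(0.1))

    def test_converges_to_analytic_value_at_second_order(self):
        # mono-exponential sampled ever denser on a fixed window; the head
        # and tail terms are matched analytically so only the chord error
        # of the measured interval remains, which shrinks as O(dt^2)
        lam_b, lam_p, c = 0.1, 0.05, 0.9
        lam = lam_b + lam_p
        nuclide = _nuclide(lam_p)
        t1, tn = 1.0, 25.0
        errors = []
        for n_iv in (8, 16, 32, 64):
            t = np.linspace(t1, tn, n_iv + 1)
            a = c * np.exp(-lam * t)
            expected = (
                t1 * a[0] + (a[0] - a[-1]) / lam + a[-1] / lam_p
            )
            errors.append(abs(tiac_trapezoid(_tac(t, a), nuclide).tiac_h - expected))
        orders = np.log2(np.array(errors[:-1]) / np.array(errors[1:]))
        assert np.all(orders > 1.8) and np.all(orders < 2.2)


class TestExponentialFit:
    def test_noiseless_biexponential_parameter_recovery(self):
        lam_p = 0.05
        nuclide = _nuclide(lam_p)
        t = plan_empirical(8, np.log(2) / 0.15).times_h
        a = 0.6 * np.exp(-0.15 * t) + 0.4 * np.exp(-0.06 * t)
        fit = fit_exponentials(_tac(t, a), nuclide, n_components=2)
        np.testing.assert_allclose(np.sort(fit.amplitudes), [0.4, 0.6], rtol=1e-6)
        np.testing.assert_allclose(np.sort(fit.lambda_bio), [0.01, 0.1], rtol=1e-6)

    def test_noiseless_monoexponential_is_exact(self):
        nuclide = _nuclide(0.05)
        t = plan_empirical(6, 4.0).times_h
        a = 0.5 * np.exp(-0.2 * t)
        fit = fit_exponentials(_tac(t, a), nuclide, n_components=1)
        assert fit.wrss < 1e-20
        assert fit.success

    def test_dof_guard_biexponential_needs_five_points(self):
        nuclide = _nuclide(0.05)
        t = np.array([1.0, 2.0, 4.0, 8.0])
        a = np.exp(-0.1 * t)
        with pytest.raises(ValidationError, match="degree"):
            fit_exponentials(_tac(t, a), nuclide, n_components=2)

    def test_auto_selection_picks_the_generating_model(self):
        nuclide = _nuclide(0.05)
        t = plan_empirical(9, np.log(2) / 0.15).times_h
        bi = 0.6 * np.exp(-0.15 * t) + 0.4 * np.exp(-0.06 * t)
        mono = 0.8 * np.exp(-0.2 * t)
        assert fit_exponentials(_tac(t, bi), nuclide).n_components == 2
        assert fit_exponentials(_tac(t, mono), nuclide).n_components == 1

    def test_weighted_fit_uses_inverse_variance(self):
        # an outlier with a huge SD should barely influence the fit
        nuclide = _nuclide(0.05)
        t = plan_empirical(6, 4.0).times_h
        a = 0.5 * np.exp(-0.2 * t)
        noisy = a.copy()
        noisy[3] *= 3.0
        sd = np.full_like(a, 1e-4)
        sd[3] = 10.0
        fit = fit_exponentials(_tac(t, noisy, sd=sd), nuclide, n_components=1)
        assert fit.amplitudes[0] == pytest.approx(0.5, rel=1e-3)
        # data decay at 0.2/h total; lambda_p = 0.05 is fixed inside the model
        assert fit.lambda_bio[0] == pytest.approx(0.15, rel=1e-3)

    def test_positivity_constraint_optional(self):
        nuclide = _nuclide(0.05)
        t = plan_empirical(8, 4.0).times_h
        # uptake-then-clearance: difference of exponentials, one negative amplitude
        a = 0.8 * np.exp(-0.15 * t) - 0.5 * np.exp(-0.9 * t)
        fit = fit_exponentials(_tac(t, np.clip(a, 0, None)), nuclide,
                               n_components=2, constrain_positive=False)
        assert fit.amplitudes.min() < 0


class TestTiacFromFit:
    def test_closed_form_hand_value(self):
        fit = _fit_result([0.6, 0.4], [0.1, 0.01], lam_p=0.05)
        result = tiac_from_fit(fit)
        assert result.tiac_h == pytest.approx(0.6 / 0.15 + 0.4 / 0.06, rel=1e-12)
        assert result.tiac_h == pytest.approx(10.667, rel=1e-4)

    def test_no_biological_elimination_gives_mean_lifetime(self):
        lam_p = np.log(2) / 6.0
        result = tiac_from_fit(_fit_result([1.0], [0.0], lam_p=lam_p))
        assert result.tiac_h == pytest.approx(1.0 / lam_p, rel=1e-12)
        assert result.tiac_h == pytest.approx(8.6562, rel=1e-4)

    def test_zero_amplitudes_give_zero(self):
        result = tiac_from_fit(_fit_result([0.0, 0.0], [0.1, 0.01], lam_p=0.05))
        assert result.tiac_h == 0.0

    def test_unconverged_fit_rejected(self):
        fit = FitResult(
            region="x", amplitudes=np.array([1.0]), lambda_bio=np.array([0.1]),
            lambda_p=0.05, wrss=1.0, dof=2, score=None, success=False, constrained=True,
        )
        with pytest.raises(FitError, match="converge"):
            tiac_from_fit(fit)


class TestBladder:
    def test_closed_form_matches_simulation_oracle(self):
        rng = np.random.default_rng(20260201)
        for _ in range(25):
            lam_b = rng.uniform(0.01, 1.0)
            lam_p = rng.uniform(0.01, 1.0)
            fu = rng.uniform(0.0, 1.0)
            tv = rng.uniform(0.5, 12.0)
            fit = _fit_result([1.0], [lam_b], lam_p=lam_p)
            closed = tiac_bladder(fit, BladderParams((fu,), tv)).tiac_h
            simulated = bladder_tiac_simulated([fu], [lam_b], lam_p, tv)
            assert closed == pytest.approx(simulated, rel=1e-4, abs=1e-12)

    def test_multi_component_routing(self):
        fit = _fit_result([0.7, 0.3], [0.3, 0.02], lam_p=0.08, n_points=10)
        params = BladderParams((0.5, 0.2), 3.0)
        closed = tiac_bladder(fit, params).tiac_h
        simulated = bladder_tiac_simulated([0.5, 0.2], [0.3, 0.02], 0.08, 3.0)
        assert closed == pytest.approx(simulated, rel=1e-4)

    def test_infinite_voiding_interval_limit(self):
        fit = _fit_result([1.0], [0.2], lam_p=0.1)
        result = tiac_bladder(fit, BladderParams((1.0,), 1e6))
        assert result.tiac_h == pytest.approx(1 / 0.1 - 1 / 0.3, rel=1e-9)
        assert result.tiac_h == pytest.approx(6.6667, rel=1e-4)

    def test_continuous_voiding_limit_is_zero(self):
        fit = _fit_result([1.0], [0.2], lam_p=0.1)
        assert tiac_bladder(fit, BladderParams((1.0,), 1e-9)).tiac_h == pytest.approx(
            0.0, abs=1e-9
        )

    def test_no_urinary_excretion_gives_zero(self):
        fit = _fit_result([1.0], [0.2], lam_p=0.1)
        assert tiac_bladder(fit, BladderParams((0.0,), 3.0)).tiac_h == 0.0

    def test_invalid_parameters_rejected(self):
        fit = _fit_result([1.0], [0.0], lam_p=0.1)
        with pytest.raises(ValidationError):
            BladderParams((1.0,), 0.0)  # non-positive voiding interval
        with pytest.raises(ValidationError, match="no\\s+biological"):
            tiac_bladder(fit, BladderParams((0.5,), 3.0))  # fu on a lambda_b = 0 term
        with pytest.raises(ValidationError):
            BladderParams((0.7, 0.7), 3.0)  # fractions exceed 1


class TestRestOfBody:
    def test_subtraction_hand_value(self):
        total = TIACResult(region="Totalbody", tiac_h=12.0, method="exponential")
        sources = [
            TIACResult(region="Liver", tiac_h=5.0, method="exponential"),
            TIACResult(region="Kidneys", tiac_h=4.0, method="exponential"),
        ]
        result = tiac_rest_of_body(total, sources)
        assert result.tiac_h == pytest.approx(3.0, rel=1e-12)
        assert result.region == "Restofbody"

    def test_no_sources_is_identity(self):
        total = TIACResult(region="Totalbody", tiac_h=12.0, method="exponential")
        assert tiac_rest_of_body(total, []).tiac_h == 12.0

    def test_oversubscribed_sources_rejected_with_breakdown(self):
        total = TIACResult(region="Totalbody", tiac_h=12.0, method="exponential")
        sources = [
            TIACResult(region="Liver", tiac_h=9.0, method="exponential"),
            TIACResult(region="Kidneys", tiac_h=4.0, method="exponential"),
        ]
        with pytest.raises(ValidationError, match="Liver=9"):
            tiac_rest_of_body(total, sources)
        with pytest.warns(UserWarning, match="clamped"):
            clamped = tiac_rest_of_body(total, sources, clamp_negative=True)
        assert clamped.tiac_h == 0.0

    def test_non_total_body_input_rejected(self):
        liver = TIACResult(region="Liver", tiac_h=5.0, method="exponential")
        with pytest.raises(ValidationError, match="total-body"):
            tiac_rest_of_body(liver, [])


class TestInvariants:
    @given(
        k=st.floats(0.01, 50.0),
        lam_p=st.floats(0.01, 1.0),
        lam_b=st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance_of_both_methods(self, k, lam_p, lam_b):
        t = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        a = 0.5 * np.exp(-(lam_b + lam_p) * t)
        nuclide = _nuclide(lam_p)
        base = tiac_trapezoid(_tac(t, a), nuclide).tiac_h
        scaled = tiac_trapezoid(_tac(t, k * a), nuclide).tiac_h
        assert scaled == pytest.approx(k * base, rel=1e-9)
        fit = _fit_result([0.5], [lam_b], lam_p=lam_p)
        fit_scaled = _fit_result([0.5 * k], [lam_b], lam_p=lam_p)
        assert tiac_from_fit(fit_scaled).tiac_h == pytest.approx(
            k * tiac_from_fit(fit).tiac_h, rel=1e-12
        )

    @given(
        data=st.lists(
            st.tuples(st.floats(0.0, 0.5), st.floats(0.0, 2.0)), min_size=1, max_size=3
        ),
        lam_p=st.floats(0.01, 2.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_tiac_bounded_by_mean_lifetime(self, data, lam_p):
        # amplitudes below 1 in total: the TIAC can never exceed complete
        # local decay of the whole administered activity
        c = np.array([d[0] for d in data])
        lb = np.array([d[1] for d in data])
        if c.sum() > 1.0:
            c = c / (c.sum() + 1e-9)
        fit = _fit_result(c, lb, lam_p=lam_p, n_points=10)
        assert tiac_from_fit(fit).tiac_h <= 1.0 / lam_p + 1e-9

    @given(
        fu=st.floats(0.0, 1.0),
        lam_b=st.floats(0.01, 1.0),
        lam_p=st.floats(0.01, 1.0),
        tv=st.floats(0.1, 24.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_bladder_tiac_bounded_by_mean_lifetime(self, fu, lam_b, lam_p, tv):
        fit = _fit_result([1.0], [lam_b], lam_p=lam_p)
        result = tiac_bladder(fit, BladderParams((fu,), tv))
        assert 0.0 <= result.tiac_h <= 1.0 / lam_p + 1e-9

    def test_fit_and_trapezoid_agree_on_dense_noiseless_data(self):
        lam_p = 0.08
        nuclide = _nuclide(lam_p)
        t = np.linspace(0.25, 60.0, 200)
        a = 0.7 * np.exp(-(0.15 + lam_p) * t) + 0.3 * np.exp(-(0.01 + lam_p) * t)
        trap = tiac_trapezoid(_tac(t, a), nuclide).tiac_h
        fit = fit_exponentials(_tac(t, a), nuclide, n_components=2)
        analytic = tiac_from_fit(fit).tiac_h
        assert trap == pytest.approx(analytic, rel=0.01)

    def test_physical_decay_only_helper(self):
        nuclide = _nuclide(0.1)
        assert tiac_physical_decay(nuclide).tiac_h == pytest.approx(10.0, rel=1e-12)
        assert tiac_physical_decay(nuclide, fraction=0.5).tiac_h == pytest.approx(5.0)
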