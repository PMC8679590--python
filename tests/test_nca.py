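import math

import numpy as np
import pytest

from radplan.curves import TimeActivityCurve
from radplan.errors import (
    CannotFitTerminalError,
    DegenerateCurveError,
    InconsistentTiacsError,
    InsufficientDataError,
    InvalidInputError,
)
from radplan.nca import (
    LN2,
    HumanizationParams,
    RedMarrowParams,
    apply_y90_decay,
    humanize_fia,
    nca,
    red_marrow_tiac,
    remainder_tiac,
    tiac_from_curve,
)

STUDY_TIMES = np.array([0.17, 0.5, 1, 3, 6, 24, 48, 72, 96, 144, 168, 216], dtype=float)


def _mono(c0=1.0, lam=0.01, times=None, unit="pid_per_ml"):
    t = np.asarray(times if times is not None else np.linspace(0, 5 / lam, 200))
    return TimeActivityCurve("s", "blood", unit, t, c0 * np.exp(-lam * t))


class TestNCA:
    def test_monoexponential_closed_form(self):
        c0, lam = 2.0, 0.02
        res = nca(_mono(c0, lam))
        assert res.auc_inf == pytest.approx(c0 / lam, rel=5e-3)
        assert res.t_half == pytest.approx(LN2 / lam, rel=5e-3)
        assert res.mrt == pytest.approx(1 / lam, rel=5e-3)
        assert res.cmax == pytest.approx(c0)
        assert res.tmax == 0.0

    def test_printed_clearance(self):
        # CL = 100 %ID / AUC; printed AUC 5971.67 -> 0.02 at 2 decimals
        cl = 100.0 / 5971.67
        assert round(cl, 2) == 0.02

    def test_biexponential_analytic_auc(self):
        a, alpha, b, beta = 0.05, 1.0, 0.30, 0.005
        t = np.unique(np.concatenate([np.linspace(0, 5, 30),
                                      np.linspace(5, 5 * LN2 / beta, 80)]))
        curve = TimeActivityCurve("s", "blood", "pid_per_ml", t,
                                  a * np.exp(-alpha * t) + b * np.exp(-beta * t))
        res = nca(curve)
        assert res.auc_inf == pytest.approx(a / alpha + b / beta, rel=0.02)
        assert res.t_half == pytest.approx(LN2 / beta, rel=0.02)

    def test_noisy_biexponential_half_life_recovery(self):
        """5% lognormal noise, 20 seeds: median |T1/2 error| < 10%."""
        a, alpha, b, beta = 0.05, 1.0, 0.30, 0.004
        t = STUDY_TIMES
        clean = a * np.exp(-alpha * t) + b * np.exp(-beta * t)
        sigma = math.sqrt(math.log(1 + 0.05**2))
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = clean * rng.lognormal(0, sigma, t.shape)
            res = nca(TimeActivityCurve("s", "blood", "pid_per_ml", t, noisy))
            errs.append(abs(res.t_half - LN2 / beta) / (LN2 / beta))
        assert np.median(errs) < 0.10

    def test_vss_identity(self):
        res = nca(_mono())
        assert res.vss == pytest.approx(res.cl * res.mrt, rel=1e-12)
        assert res.t_half == pytest.approx(LN2 / res.lambda_z, rel=1e-12)

    def test_insufficient_points(self):
        c = TimeActivityCurve("s", "b", "pid_per_ml", [0, 1], [1.0, 0.5])
        with pytest.raises(InsufficientDataError):
            nca(c)

    def test_cannot_fit_rising_tail(self):
        c = TimeActivityCurve("s", "b", "pid_per_ml",
                              np.arange(6.0), np.array([5, 1, 1.2, 1.5, 2.0, 3.0]))
        with pytest.raises(CannotFitTerminalError):
            nca(c)

    def test_extrapolation_warning(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        c = TimeActivityCurve("s", "b", "pid_per_ml", t, np.exp(-0.01 * t))
        with pytest.warns(UserWarning, match="extrapolated"):
            nca(c)

    def test_linuplogdown_rule(self):
        res = nca(_mono(), rule="linuplogdown")
        # log-down is exact on a pure exponential regardless of spacing
        assert res.auc_inf == pytest.approx(1.0 / 0.01, rel=1e-9)


class TestDecay:
    def _fia(self, values, times):
        return TimeActivityCurve("s", "blood", "fia_per_ml",
                                 np.asarray(times, float), np.asarray(values, float))

    def test_t0_unchanged(self):
        c = apply_y90_decay(self._fia([0.8, 0.8], [0, 64]))
        assert c.values[0] == pytest.approx(0.8)

    def test_one_half_life(self):
        c = apply_y90_decay(self._fia([0.8, 0.8], [0, 64]))
        assert c.values[1] == pytest.approx(0.4)

    def test_two_half_lives(self):
        c = apply_y90_decay(self._fia([1.0, 1.0], [0, 128]))
        assert c.values[1] == pytest.approx(0.25)

    def test_unit_guard(self):
        c = TimeActivityCurve("s", "b", "pid", [0.0, 1.0], [1.0, 1.0])
        with pytest.raises(InvalidInputError):
            apply_y90_decay(c)


class TestHumanize:
    def _curve(self, values, times=None):
        t = times if times is not None else np.arange(len(values), dtype=float)
        return TimeActivityCurve("s", "blood", "fia_per_ml", t, np.asarray(values))

    def test_peak_contract(self):
        p = HumanizationParams(monkey_body_mass_g=3200)
        c = humanize_fia(self._curve([1e-3, 5e-3, 2e-3]), p)
        assert np.max(c.values) == pytest.approx(1 / 5300, rel=1e-12)

    def test_peak_contract_any_magnitude(self):
        p = HumanizationParams(monkey_body_mass_g=2500)
        for scale in (1e-6, 1.0, 1e3):
            c = humanize_fia(self._curve(np.array([0.2, 1.0, 0.5]) * scale), p)
            assert np.max(c.values) == pytest.approx(1 / 5300, rel=1e-12)

    def test_identity_mass_chain(self):
        """monkey mass = reference mass: humanized equals the input."""
        p = HumanizationParams(monkey_body_mass_g=73_700)
        vals = np.array([1e-3, 5e-3, 2e-3])
        c = humanize_fia(self._curve(vals), p)
        np.testing.assert_allclose(c.values, vals / (5e-3 * 5300), rtol=1e-12)

    def test_three_sample_spreadsheet_chain(self):
        """Full hand-computed chain: decay -> humanize -> scale."""
        mass, times = 3000.0, np.array([0.0, 24.0, 96.0])
        fia = np.array([4e-3, 3e-3, 2e-3])
        decayed = fia * 0.5 ** (times / 64.0)
        humanized = decayed * mass / 73_700.0
        expected = humanized / (humanized.max() * 5300.0)
        got = humanize_fia(
            apply_y90_decay(self._curve(fia, times)),
            HumanizationParams(monkey_body_mass_g=mass),
        )
        np.testing.assert_allclose(got.values, expected, rtol=1e-12)

    def test_zero_peak(self):
        with pytest.raises(DegenerateCurveError):
            humanize_fia(self._curve([0.0, 0.0]), HumanizationParams(monkey_body_mass_g=3000))


class TestTiac:
    def test_pure_physical_decay_closed_form(self):
        t = np.array([0, 3, 6, 24, 48, 72, 96, 144, 168], dtype=float)
        c = TimeActivityCurve("s", "wb", "fia", t, np.exp(-LN2 * t / 64))
        assert tiac_from_curve(c) == pytest.approx(64 / LN2, rel=0.01)

    def test_zero_curve(self):
        c = TimeActivityCurve("s", "wb", "fia", np.array([0.0, 1, 2]), np.zeros(3))
        assert tiac_from_curve(c) == 0.0

    def test_synthetic_organ_analytic(self, monkey_curves):
        curves, truth = monkey_curves
        for organ in ("heart", "liver", "spleen", "lungs"):
            fia = apply_y90_decay(curves[organ].to_fia())
            assert tiac_from_curve(fia) == pytest.approx(
                truth["tiac_decayed_h"][organ], rel=0.05
            )

    def test_physical_bound_for_normalized_curves(self):
        """Any decay-imposed curve with values <= 1 integrates below 64/ln2."""
        rng = np.random.default_rng(7)
        t = np.array([0, 3, 6, 24, 48, 96, 168], dtype=float)
        for _ in range(20):
            bio = np.clip(rng.uniform(0.2, 1.0) * np.exp(-rng.uniform(0.001, 0.01) * t), 0, 1)
            c = apply_y90_decay(TimeActivityCurve("s", "x", "fia", t, bio))
            assert tiac_from_curve(c) <= 64 / LN2 + 1e-9


class TestRedMarrow:
    def test_zero(self):
        assert red_marrow_tiac(0.0) == 0.0

    def test_printed_constants(self):
        # 1120 x 0.19 / 0.53 = 401.51
        assert red_marrow_tiac(1e-3) == pytest.approx(0.40151, rel=1e-4)

    def test_linearity(self):
        assert red_marrow_tiac(2e-3) == pytest.approx(2 * red_marrow_tiac(1e-3), rel=1e-12)

    def test_hct_guard(self):
        with pytest.raises(InvalidInputError):
            RedMarrowParams(hct=1.0)


class TestRemainder:
    def test_simple_subtraction(self):
        tiacs = {"whole_body": 50.0, "heart_contents": 5.0, "liver": 7.0,
                 "lungs": 4.0, "spleen": 4.0, "red_marrow": 3.0}
        # red marrow is blood-derived and NOT subtracted
        assert remainder_tiac(tiacs) == pytest.approx(30.0)

    def test_negative_remainder_raises(self):
        with pytest.raises(InconsistentTiacsError):
            remainder_tiac({"whole_body": 10.0, "liver": 11.0})

    def test_missing_whole_body(self):
        with pytest.raises(InvalidInputError):
            remainder_tiac({"liver": 1.0})

    def test_synthetic_end_to_end(self, monkey_curves):
        curves, truth = monkey_curves
        tiacs = {}
        for label, c in curves.items():
            key = "heart_contents" if label == "heart" else label
            tiacs[key] = tiac_from_curve(apply_y90_decay(c.to_fia()))
        assert remainder_tiac(tiacs) == pytest.approx(truth["remainder_tiac_h"], rel=0.05)
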