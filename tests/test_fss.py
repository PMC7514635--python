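"""Finite-size-scaling estimators on synthetic trajectories."""

import math

import numpy as np
import pandas as pd
import pytest

from trailzeros import (
    ZeroTrajectory,
    alpha_from_phi,
    extrapolate_critical,
    extrapolate_phi_eff,
    fit_phi_loglog,
    phi_eff_pair,
    replicate_errors,
)
from trailzeros.fss import PhiEstimate


def make_traj(ns, im, re=None, replicate=0, variable="tau"):
    re = re if re is not None else np.full(len(ns), 3.0)
    frame = pd.DataFrame(
        {"N": ns, "re": re, "im": im, "replicate": replicate}
    )
    return ZeroTrajectory(frame, variable=variable)


def power_law_traj(phi=0.83, amp=7.0, ns=None, tau=3.0, b=2.0, c=-5.0,
                   noise=0.0, rng=None, replicate=0):
    ns = np.asarray(ns if ns is not None else range(50, 501, 2))
    im = amp * ns ** (-phi)
    if noise:
        im = im * (1 + noise * rng.standard_normal(len(ns)))
    re = tau + b * im + c * im**2
    if noise:
        re = re + noise * tau * rng.standard_normal(len(ns)) * 0.5
    return make_traj(ns, im, re, replicate=replicate)


class TestRatioEstimator:
    def test_exact_on_pure_power_law(self):
        traj = power_law_traj(phi=0.83)
        for pair in ((100, 98), (300, 296), (500, 400)):
            est = phi_eff_pair(traj, *pair)
            assert est.value == pytest.approx(0.83, abs=1e-12)

    def test_correction_term_drifts_toward_phi(self):
        # Im = A N^-phi (1 + b/N): phi_eff(N, N-2) approaches phi from one side
        ns = np.arange(20, 1001, 2)
        phi, b = 0.8, 1.0
        im = 7.0 * ns ** (-phi) * (1 + b / ns)
        traj = make_traj(ns, im)
        errs = [abs(phi_eff_pair(traj, n, n - 2).value - phi)
                for n in (50, 100, 400, 1000)]
        assert all(e2 < e1 for e1, e2 in zip(errs, errs[1:]))

    def test_parity_mismatch_rejected(self):
        traj = power_law_traj(ns=np.arange(90, 110))
        with pytest.raises(ValueError):
            phi_eff_pair(traj, 100, 99)
        with pytest.raises(KeyError):
            phi_eff_pair(traj, 100, 88)

    def test_extrapolation_recovers_exponent(self):
        traj = power_law_traj(phi=0.6)
        est = extrapolate_phi_eff(traj, gaps=(2, 4))
        assert est.value == pytest.approx(0.6, abs=1e-9)


class TestLogLogFit:
    def test_exact_power_law_to_machine_precision(self):
        traj = power_law_traj(phi=0.5, amp=2.0, ns=np.arange(50, 501, 2))
        est = fit_phi_loglog(traj)
        assert est.value == pytest.approx(0.5, abs=1e-12)
        assert est.drift == pytest.approx(0.0, abs=1e-12)

    def test_noisy_fit_recovers_exponent(self):
        rng = np.random.default_rng(0)
        traj = power_law_traj(phi=0.7, ns=np.arange(100, 300, 2),
                              noise=0.01, rng=rng)
        est = fit_phi_loglog(traj)
        assert est.value == pytest.approx(0.7, abs=0.02)

    def test_too_few_points_rejected(self):
        traj = power_law_traj(ns=np.array([100, 102]))
        with pytest.raises(ValueError):
            fit_phi_loglog(traj)

    def test_amplitude_invariance(self):
        ns = np.arange(60, 201, 2)
        t1 = power_law_traj(phi=0.83, amp=1.0, ns=ns)
        t2 = power_law_traj(phi=0.83, amp=13.0, ns=ns)
        assert fit_phi_loglog(t1).value == pytest.approx(
            fit_phi_loglog(t2).value, abs=1e-12
        )

    def test_estimators_agree_on_noiseless_data(self):
        traj = power_law_traj(phi=0.43)
        a = fit_phi_loglog(traj).value
        b = phi_eff_pair(traj, 500, 496).value
        assert a == pytest.approx(b, abs=1e-10)


class TestCriticalExtrapolation:
    def test_exact_on_polynomial_data(self):
        ns = np.arange(30, 201, 2)
        im = 5.0 * ns ** (-0.8)
        re = 3.0 + 2.0 * im - 5.0 * im**2
        traj = make_traj(ns, im, re)
        for deg in (2, 3, 4):
            est = extrapolate_critical(traj, degree=deg)
            assert est.value == pytest.approx(3.0, abs=1e-9)
            assert est.max_residual < 1e-9

    def test_underdetermined_fit_rejected(self):
        traj = power_law_traj(ns=np.array([100, 102, 104, 106]))
        with pytest.raises(ValueError):
            extrapolate_critical(traj, degree=4)
        with pytest.raises(ValueError):
            extrapolate_critical(traj, degree=0)

    def test_parameter_recovery_under_noise(self):
        # the acceptance-level property at reduced seed count: noisy
        # trajectories recover (phi, tau*) within two standard errors
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            traj = power_law_traj(phi=0.83, tau=3.0, ns=np.arange(50, 501, 2),
                                  noise=0.015, rng=rng)
            crit = extrapolate_critical(traj, degree=2)
            phi = fit_phi_loglog(traj)
            ok_tau = abs(crit.value - 3.0) <= 2 * crit.stderr
            ok_phi = abs(phi.value - 0.83) <= 2 * phi.stderr
            hits += ok_tau and ok_phi
        assert hits >= 17


class TestAlphaIdentity:
    @pytest.mark.parametrize(
        "phi, alpha", [(0.5, 0.0), (3.0 / 7.0, -1.0 / 3.0), (0.83, 2 - 1 / 0.83)]
    )
    def test_values(self, phi, alpha):
        est = PhiEstimate(value=phi, stderr=0.01, method="loglog_fit")
        val, err = alpha_from_phi(est)
        assert val == pytest.approx(alpha, abs=1e-12)
        assert err == pytest.approx(0.01 / phi**2, abs=1e-12)


class TestReplicateErrors:
    def test_identical_replicates_have_zero_spread(self):
        report = replicate_errors([0.83, 0.83, 0.83])
        assert report["replicate_spread"] == 0.0
        assert not report["degraded"]

    def test_offset_replicates_have_analytic_spread(self):
        # two trajectories whose Im differ by a constant factor give log-log
        # slopes that differ by exactly zero; offsetting the exponent instead
        # shifts the slope one for one
        ns = np.arange(100, 301, 2)
        fits = []
        for phi in (0.80, 0.86):
            traj = power_law_traj(phi=phi, ns=ns)
            fits.append(fit_phi_loglog(traj).value)
        report = replicate_errors(fits)
        assert report["replicate_spread"] == pytest.approx(0.03, abs=1e-9)

    def test_window_spread_is_half_range(self):
        report = replicate_errors([1.0], [0.9, 1.0, 1.1])
        assert report["window_spread"] == pytest.approx(0.1)
        assert report["degraded"]

    def test_requires_at_least_one_replicate(self):
        with pytest.raises(ValueError):
            replicate_errors([])


class TestTrajectoryContainer:
    def test_invariants_enforced(self):
        bad = pd.DataFrame({"N": [4, 4], "re": [1, 1], "im": [1, 1],
                            "replicate": [0, 0]})
        with pytest.raises(ValueError):
            ZeroTrajectory(bad, "tau")
        neg = pd.DataFrame({"N": [4, 6], "re": [1, 1], "im": [1, -1],
                            "replicate": [0, 0]})
        with pytest.raises(ValueError):
            ZeroTrajectory(neg, "tau")

    def test_pooling_averages_replicates(self):
        ns = np.arange(50, 101, 2)
        t1 = power_law_traj(ns=ns, amp=7.0, replicate=0)
        t2 = power_law_traj(ns=ns, amp=9.0, replicate=1)
        pooled = ZeroTrajectory.concat([t1, t2]).pooled()
        expect = 8.0 * 50.0 ** (-0.83)
        assert pooled[pooled["N"] == 50]["im"].iloc[0] == pytest.approx(expect)
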