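"""Label swap, divergence summaries, moment estimators, calibration."""

import numpy as np
import pytest

from refugia.msci import (CalibrationConfig, bias_experiment, calibrate_Ne,
                          calibrate_time, divergence_summary, empirical_rate,
                          fit_poisson_shifted_exponential,
                          fit_shifted_exponential, label_swap, msc_moment_fit,
                          round_half_up)
from refugia.registry import ParameterError
from refugia.simulate import MSciParams, PopConfig
from tests.conftest import PEAK1_TAUS, PEAK1_THETA, make_locus_set

CAL = CalibrationConfig()


# ------------------------------------------------------------ calibration

@pytest.mark.parametrize("tau,expect_My,nd", [
    (0.00386, 4.83, 2),   # inner ingroup node
    (0.00614, 7.68, 2),   # root ingroup node
    (0.00142, 1.78, 2),   # introgression time A = B
    (0.0, 0.0, 2),
])
def test_calibrate_time_printed_values(tau, expect_My, nd):
    assert round_half_up(calibrate_time(tau, CAL), nd) == expect_My


def test_calibrate_time_ka_value():
    ka = calibrate_time(0.00017, CAL) * 1000
    assert round_half_up(ka, 0) == 213


def test_calibrate_ne_values():
    assert calibrate_Ne(0.00134, CAL) == pytest.approx(209_375)
    u_gen = CAL.mu_per_My * 1e-6 * CAL.gen_time_yr
    assert calibrate_Ne(4 * u_gen, CAL) == pytest.approx(1.0)
    assert calibrate_Ne(0.0, CAL) == 0.0


def test_empirical_rate_and_roundtrip():
    assert empirical_rate(0.016, 20) == pytest.approx(0.0008)
    assert empirical_rate(0.0107, 20) == pytest.approx(0.000535)
    rng = np.random.default_rng(0)
    for tau in rng.uniform(1e-4, 0.05, 10):
        mu = empirical_rate(tau, CAL.calib_T_My)
        assert calibrate_time(tau, CalibrationConfig(mu_per_My=mu)) == \
            pytest.approx(CAL.calib_T_My)
    with pytest.raises(ParameterError):
        empirical_rate(0.0, 20)


def test_round_half_up_convention():
    assert round_half_up(2.5, 0) == 3
    assert round_half_up(4.825, 2) == 4.83
    assert round_half_up(212.5, 0) == 213
    assert round_half_up(1.775, 2) == 1.78


# ------------------------------------------------------------- label swap

def peak1():
    return MSciParams(theta=PEAK1_THETA, **PEAK1_TAUS,
                      phi_A=0.868, phi_B=0.090, phi_C=0.065, phi_D=0.935)


def test_label_swap_reported_relations():
    sw = label_swap(peak1(), "AB")
    assert sw.phi_A == pytest.approx(0.132)
    assert sw.phi_B == pytest.approx(0.910)
    assert sw.theta["A"] == pytest.approx(0.00295)
    assert sw.theta["B"] == pytest.approx(0.00255)
    assert sw.theta["C"] == peak1().theta["C"]
    assert sw.tau_AB == peak1().tau_AB


def params_close(a, b):
    da, db = a.to_dict(), b.to_dict()
    ta, tb = da.pop("theta"), db.pop("theta")
    return (all(da[k] == pytest.approx(db[k], abs=1e-12) for k in da)
            and all(ta[k] == pytest.approx(tb[k], abs=1e-12) for k in ta))


def test_label_swap_involution_and_fixed_point():
    p = peak1()
    for pair in ("AB", "CD"):
        assert params_close(label_swap(label_swap(p, pair), pair), p)
    sym = MSciParams(theta={**PEAK1_THETA, "A": 2e-3, "B": 2e-3},
                     **PEAK1_TAUS, phi_A=0.5, phi_B=0.5,
                     phi_C=0.065, phi_D=0.935)
    assert params_close(label_swap(sym, "AB"), sym)


def test_label_swap_unknown_pair_rejected():
    with pytest.raises(ParameterError):
        label_swap(peak1(), "AD")


# ----------------------------------------------------- divergence summary

def two_locus_set():
    """Hand-built: 1 DST + 2 STH samples, locus length 1000.

    Locus 0 cross distances {0.010, 0.025}; locus 1 {0.018, 0.018}.
    """
    labels = {"d1": "DST", "s1": "STH", "s2": "STH"}
    g0 = np.zeros((25, 3), dtype=np.int8)
    g0[:10, 1] = 1            # d1 vs s1: 10 diffs
    g0[:25, 2] = 1            # d1 vs s2: 25 diffs
    g1 = np.zeros((18, 3), dtype=np.int8)
    g1[:, 1] = 1
    g1[:, 2] = 1              # both cross pairs: 18 diffs
    return make_locus_set([g0, g1], [np.arange(25), np.arange(18)],
                          labels, locus_len=1000)


def test_divergence_summary_hand_minimum():
    ds = divergence_summary(two_locus_set(), ("DST", "STH"))
    assert ds.d_min_between == pytest.approx(0.010)
    assert ds.d_mean_between == pytest.approx(np.mean([0.010, 0.025, 0.018, 0.018]))
    assert ds.d_locus_between[0] == pytest.approx(0.0175)
    assert ds.d_mean_within["STH"] == pytest.approx(np.mean([0.015, 0.0]))


def test_divergence_identical_sequences_zero():
    labels = {"d1": "DST", "s1": "STH"}
    ls = make_locus_set([np.zeros((0, 2), dtype=np.int8)],
                        [np.zeros(0, dtype=int)], labels, 500)
    ds = divergence_summary(ls, ("DST", "STH"))
    assert ds.d_min_between == 0.0


def test_divergence_empty_side_rejected():
    with pytest.raises(ValueError):
        divergence_summary(two_locus_set(), ("DST", "PLN"))


# -------------------------------------------------------------- estimators

def test_shifted_exponential_consistency():
    rng = np.random.default_rng(3)
    d = 2 * 0.005 + rng.exponential(0.003, 2000)
    tau, theta = fit_shifted_exponential(d)
    assert tau == pytest.approx(0.005, rel=0.02)
    assert theta == pytest.approx(0.003, rel=0.10)


def test_shifted_exponential_degenerate_all_equal():
    tau, theta = fit_shifted_exponential(np.full(50, 0.012))
    assert tau == pytest.approx(0.006)
    assert theta == 0.0


def test_poisson_shifted_exponential_recovers_location():
    rng = np.random.default_rng(4)
    L, tau, theta = 2000, 0.004, 0.002
    lam = L * (2 * tau + rng.exponential(theta, 1500))
    K = rng.poisson(lam).astype(float)
    tau_hat, theta_hat = fit_poisson_shifted_exponential(K, L)
    assert tau_hat == pytest.approx(tau, rel=0.10)
    assert theta_hat == pytest.approx(theta, rel=0.25)
    # the raw minimum sits far below the floor at this noise level
    assert K.min() / L / 2 < 0.9 * tau


def test_msc_moment_fit_validation():
    labels = {"d1": "DST", "s1": "STH", "p1": "PLN"}
    ls = make_locus_set([np.zeros((0, 3), dtype=np.int8)],
                        [np.zeros(0, dtype=int)], labels, 100)
    with pytest.raises(ValueError):
        msc_moment_fit(ls)


def test_bias_experiment_validation():
    p0 = MSciParams(theta=PEAK1_THETA, **PEAK1_TAUS,
                    phi_A=0, phi_B=0, phi_C=0, phi_D=0)
    cfg = PopConfig(n_loci=10, seed=0)
    with pytest.raises(ParameterError):
        bias_experiment(p0, cfg, n_replicates=6, seed=0)
    with pytest.raises(ValueError):
        bias_experiment(label_swap(p0, "AB"), cfg, n_replicates=2, seed=0)
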