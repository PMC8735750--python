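"""Akaike ranking, confidence sets, bootstrap and adjusted LRTs."""

import numpy as np
import pandas as pd
import pytest

from refugia.likelihood import SFSDemography, expected_sfs
from refugia.selection import (akaike_table, bootstrap_spectra,
                               confidence_set, lrt_godambe)
from refugia.sfs import build_jsfs

NONADMIXED = [
    ("refugia_adj_2", 514.28), ("refugia_asymmig_adjacent", 517.90),
    ("refugia_barrier", 518.48), ("split_nomig", 519.38),
    ("refugia_adj_1", 529.54), ("refugia_adj_3", 553.04),
    ("split_asymmig_adjacent", 559.26), ("split_sym_mig_all", 600.70),
    ("split_symmig_adjacent", 624.66), ("refugia_symmig_all", 629.98),
]
ADMIXED = [
    ("refugia_barrier", 738.38), ("refugia_adj_2", 750.78),
    ("refugia_adj_1", 778.82), ("refugia_adj_3", 779.32),
    ("split_asymmig_adjacent", 799.04), ("split_nomig", 840.36),
    ("split_sym_mig_all", 870.88), ("refugia_asymmig_adjacent", 884.50),
    ("split_symmig_adjacent", 992.34), ("refugia_symmig_all", 1226.80),
]


def test_nonadmixed_panel_headline_weights():
    t = akaike_table(NONADMIXED)
    assert t["refugia_adj_2"].wAIC == pytest.approx(0.7328, abs=5e-4)
    assert t["refugia_barrier"].wAIC == pytest.approx(0.09, abs=5e-3)
    assert t["refugia_asymmig_adjacent"].relL == pytest.approx(0.16, abs=5e-3)
    assert t.table["wAIC"].sum() == pytest.approx(1.0, abs=1e-12)
    assert t.table.iloc[0]["dAIC"] == 0.0 and t.table.iloc[0]["relL"] == 1.0


def test_admixed_panel_supports_barrier():
    t = akaike_table(ADMIXED)
    assert t["refugia_barrier"].wAIC == pytest.approx(0.9980, abs=5e-4)
    assert confidence_set(t, 0.95) == ["refugia_barrier"]


def test_nonadmixed_confidence_set_contains_barrier():
    t = akaike_table(NONADMIXED)
    assert "refugia_barrier" in confidence_set(t, 0.95)


def test_equal_aics_split_weight():
    t = akaike_table([("a", 100.0), ("b", 100.0)])
    assert np.allclose(t.table["wAIC"], [0.5, 0.5])


def test_weights_invariant_under_constant_shift():
    t1 = akaike_table(NONADMIXED)
    t2 = akaike_table([(n, a + 123.4) for n, a in NONADMIXED])
    merged = t1.table.merge(t2.table, on="Model")
    assert np.allclose(merged["wAIC_x"], merged["wAIC_y"])


def test_confidence_set_monotone_in_level():
    t = akaike_table(NONADMIXED)
    s90 = set(confidence_set(t, 0.90))
    s99 = set(confidence_set(t, 0.99))
    assert s90 <= s99
    assert confidence_set(akaike_table([("only", 10.0)]), 0.95) == ["only"]
    with pytest.raises(ValueError):
        confidence_set(t, 1.5)


def test_nonfinite_aic_rejected():
    with pytest.raises(ValueError):
        akaike_table([("a", np.nan)])
    with pytest.raises(ValueError):
        akaike_table([])


# ------------------------------------------------------------- bootstrap

def geno_frame(n_loci, rng, samples):
    rows = []
    for l in range(n_loci):
        for s in range(rng.integers(1, 4)):
            rows.append([f"L{l}", s, *rng.integers(0, 2, len(samples))])
    return pd.DataFrame(rows, columns=["locus", "pos", *samples])


SAMPLES = [f"s{i}" for i in range(6)]
POPMAP = {f"s{i}": p for i, p in zip(range(6),
                                     ["DST"] * 2 + ["STH"] * 2 + ["PLN"] * 2)}


def test_bootstrap_mass_and_identical_loci_degenerate():
    rng = np.random.default_rng(0)
    gt = geno_frame(30, rng, SAMPLES)
    orig = build_jsfs(gt, POPMAP)
    boots = bootstrap_spectra(gt, POPMAP, B=20, seed=1)
    masses = [b.total_mass() for b in boots]
    assert np.mean(masses) == pytest.approx(orig.total_mass(), rel=0.3)
    # degenerate: every locus identical -> any resample equals the original
    one = gt[gt["locus"] == "L0"]
    same = pd.concat([one.assign(locus=f"L{i}") for i in range(10)],
                     ignore_index=True)
    b = bootstrap_spectra(same, POPMAP, B=1, seed=5)[0]
    assert np.allclose(b.counts, build_jsfs(same, POPMAP).counts)


def test_bootstrap_mean_converges_to_original():
    rng = np.random.default_rng(2)
    gt = geno_frame(40, rng, SAMPLES)
    orig = build_jsfs(gt, POPMAP)
    boots = bootstrap_spectra(gt, POPMAP, B=200, seed=3)
    stack = np.stack([b.counts for b in boots])
    mean = stack.mean(axis=0)
    se = stack.std(axis=0) / np.sqrt(len(boots))
    diff = np.abs(mean - orig.counts)
    assert np.all(diff <= 3 * se + 1e-9)


def test_bootstrap_validation_errors():
    rng = np.random.default_rng(4)
    gt = geno_frame(10, rng, SAMPLES)
    with pytest.raises(ValueError):
        bootstrap_spectra(gt, POPMAP, B=0, seed=0)
    with pytest.raises(ValueError):
        bootstrap_spectra(gt[gt["locus"] == "L0"], POPMAP, B=2, seed=0)


# ------------------------------------------------------------------ LRT

@pytest.fixture(scope="module")
def lrt_setup():
    params = dict(nu1=1, nuA=1, nu2=1, nu3=1, m1=0.0, m2=0.5, T1=0.5, T2=0.2)
    exp = expected_sfs("refugia_adj_2", params, sizes=(4, 4, 4),
                       n_reps=500, seed=13)
    obs = exp.copy()
    obs.counts *= 2000
    sd_nested = SFSDemography(obs, "refugia_adj_2", n_reps=500,
                              surface_seed=13, fixed={"m1": 0.0})
    fit_nested = sd_nested.fit(start=params, schedule=(), polish=False, seed=0)
    fit_full = fit_nested  # identical fits: the degenerate D = 0 case
    rng = np.random.default_rng(7)
    boots = []
    for _ in range(8):
        b = obs.copy()
        b.counts = rng.poisson(np.maximum(b.counts, 0)).astype(float)
        boots.append(b)
    return fit_full, fit_nested, boots


def test_lrt_identical_fits_give_p_one(lrt_setup):
    fit_full, fit_nested, boots = lrt_setup
    res = lrt_godambe(fit_full, fit_nested, boots, nested_map={"m1": 0.0})
    assert res.D == pytest.approx(0.0, abs=1e-9)
    assert res.p_value == 1.0
    assert res.df == 1


def test_lrt_negative_statistic_gives_p_one(lrt_setup):
    fit_full, fit_nested, boots = lrt_setup
    worse = fit_full
    better = type(fit_nested)(
        model=fit_nested.model, model_name=fit_nested.model_name,
        params=fit_nested.params, lnL=fit_nested.lnL + 50.0,
        k=fit_nested.k, theta_hat=fit_nested.theta_hat, seed=0)
    res = lrt_godambe(worse, better, boots, nested_map={"m1": 0.0})
    assert res.D < 0
    assert res.D_adj <= 0
    assert res.p_value == 1.0


def test_lrt_unregistered_pair_rejected(lrt_setup):
    fit_full, fit_nested, boots = lrt_setup
    with pytest.raises(ValueError):
        lrt_godambe(fit_full, fit_nested, boots, nested_map={})
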