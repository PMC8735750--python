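"""Coalescent data simulators: closed-form means, determinism, hybrids."""


import numpy as np
import pytest

from refugia.registry import ParameterError, get_model
from refugia.simulate import (HybridSpec, MSciParams, PopConfig,
                              coal_time_to_subs, simulate_msc, simulate_msci,
                              subs_to_coal_time)
from tests.conftest import PEAK1_TAUS, PEAK1_THETA


def pairwise_mean(ls, idx_a, idx_b=None):
    """Mean per-site pairwise difference, within (b=None) or between."""
    vals = []
    for g in ls.genotypes:
        if idx_b is None:
            ga = g[:, idx_a]
            n = len(idx_a)
            pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
            diffs = [np.sum(ga[:, i] != ga[:, j]) for i, j in pairs]
        else:
            diffs = [np.sum(g[:, i] != g[:, j]) for i in idx_a for j in idx_b]
        vals.append(np.mean(diffs) / ls.locus_len)
    return float(np.mean(vals))


@pytest.fixture(scope="module")
def msc_locus_set():
    model = get_model("split_nomig").instantiate(
        dict(nu1=1, nuA=1, nu2=1, nu3=1, T1=0.5, T2=0.2))
    cfg = PopConfig(n_samples=4, n_loci=2000, locus_len=100,
                    mut_scale=0.01, seed=3)
    return model, cfg, simulate_msc(model, cfg)


def test_within_population_diversity_matches_theta(msc_locus_set):
    model, cfg, ls = msc_locus_set
    dst = ls.sample_index(ls.samples_of("DST"))
    # constant relative size 1 everywhere: diversity = mut_scale exactly
    assert pairwise_mean(ls, dst) == pytest.approx(cfg.mut_scale, rel=0.05)


def test_between_population_divergence_matches_2tau_plus_theta(msc_locus_set):
    model, cfg, ls = msc_locus_set
    dst = ls.sample_index(ls.samples_of("DST"))
    sth = ls.sample_index(ls.samples_of("STH"))
    tau = coal_time_to_subs(0.7, cfg.mut_scale)  # T1 + T2 to the root
    expect = 2 * tau + cfg.mut_scale  # ancestral nu = 1
    assert pairwise_mean(ls, dst, sth) == pytest.approx(expect, rel=0.05)


def test_simulate_msc_bit_identical_reruns(msc_locus_set):
    model, cfg, ls = msc_locus_set
    again = simulate_msc(model, cfg)
    assert ls.samples == again.samples
    assert all(np.array_equal(a, b)
               for a, b in zip(ls.genotypes, again.genotypes))
    assert all(np.array_equal(a, b)
               for a, b in zip(ls.positions, again.positions))


def test_unit_conversions_roundtrip():
    assert subs_to_coal_time(coal_time_to_subs(0.7, 0.01), 0.01) == pytest.approx(0.7)
    assert coal_time_to_subs(1.0, 0.004) == pytest.approx(0.002)


def test_msci_peak1_divergence_within_bounds(peak1_params, small_config):
    ls = simulate_msci(peak1_params, small_config)
    dst = ls.sample_index(ls.samples_of("DST"))
    sth = ls.sample_index(ls.samples_of("STH"))
    d = pairwise_mean(ls, dst, sth)
    assert 2 * peak1_params.tau_CD < d < (2 * peak1_params.tau_R
                                          + max(PEAK1_THETA.values()))


def test_msci_determinism(peak1_params, small_config):
    a = simulate_msci(peak1_params, small_config)
    b = simulate_msci(peak1_params, small_config)
    assert all(np.array_equal(x, y) for x, y in zip(a.genotypes, b.genotypes))


def test_hybrid_parent_fraction_matches_mixing_prob(nogeneflow_params):
    """Half the hybrid's loci should coalesce first with the STH donors."""
    cfg = PopConfig(n_samples={"DST": 2, "STH": 2, "PLN": 2, "OG": 1},
                    n_loci=1000, locus_len=2000, seed=21)
    hyb = HybridSpec(host_pop="DST", parent_pops=("STH", "DST"),
                     mixing_prob=0.5)
    ls = simulate_msci(nogeneflow_params, cfg, hybrid=hyb)
    h = ls.sample_index(["DST_hyb"])[0]
    sth = ls.sample_index(ls.samples_of("STH"))[:2]
    dst = ls.sample_index([s for s in ls.samples_of("DST")
                           if not s.endswith("hyb")])
    n_sth = 0
    for g in ls.genotypes:
        d_sth = min(np.sum(g[:, h] != g[:, j]) for j in sth)
        d_dst = min(np.sum(g[:, h] != g[:, j]) for j in dst)
        if d_sth < d_dst:
            n_sth += 1
    # ties (equal distances) dilute the count; binomial band around 0.5
    assert 0.38 < n_sth / ls.n_loci < 0.62


def test_hybrid_unknown_population_rejected(nogeneflow_params, small_config):
    bad = HybridSpec(host_pop="DST", parent_pops=("DST", "XXX"))
    with pytest.raises(ParameterError):
        simulate_msci(nogeneflow_params, small_config, hybrid=bad)


def test_msci_invariants_enforced():
    with pytest.raises(ParameterError):
        MSciParams(theta=PEAK1_THETA, **{**PEAK1_TAUS, "tau_CD": 5e-3},
                   phi_A=0, phi_B=0, phi_C=0, phi_D=0)
    with pytest.raises(ParameterError):
        MSciParams(theta=PEAK1_THETA, **PEAK1_TAUS,
                   phi_A=1.2, phi_B=0, phi_C=0, phi_D=0)
    with pytest.raises(ParameterError):
        PopConfig(n_loci=0)


def test_locus_set_roundtrip_files(tmp_path, nogeneflow_params):
    cfg = PopConfig(n_samples={"DST": 2, "STH": 2, "PLN": 2, "OG": 1},
                    n_loci=5, locus_len=50, seed=2)
    ls = simulate_msci(nogeneflow_params, cfg)
    ls.write_fasta(tmp_path / "loci.fasta")
    ls.write_tsv(tmp_path / "geno.tsv")
    ls.write_truth_json(tmp_path / "truth.json")
    from refugia.io import read_fasta_alignment, read_genotype_tsv

    recs = read_fasta_alignment(tmp_path / "loci.fasta")
    assert len(recs) == 5 * 7
    assert all(len(s) == 50 for _, s in recs)
    gt = read_genotype_tsv(tmp_path / "geno.tsv")
    assert list(gt.columns[:2]) == ["locus", "pos"]
    total_snps = sum(g.shape[0] for g in ls.genotypes)
    assert len(gt) == total_snps
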