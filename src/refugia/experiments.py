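"""Validation experiments exercising the whole pipeline end to end.

These drivers define the study-style experiments at fixed, documented
problem sizes: neutral-law checks of the branch-length engine, the
distributional equivalence of the introgression simulator at phi = 0
with the plain multispecies-coalescent simulator, label-swap
indistinguishability, parameter recovery for the no-migration split
model, and the null calibration of the Godambe-adjusted LRT.  Both the
test suite and the acceptance script call them.
"""

from __future__ import annotations

import dataclasses
import numpy as np
from scipy.stats import ks_2samp

from ._engine import EpochPlan, branch_sfs_counts
from .likelihood import SFSDemography
from .msci import divergence_summary
from .registry import get_model
from .selection import bootstrap_spectra, lrt_godambe
from .sfs import build_jsfs
from .simulate import (MSciParams, PopConfig, simulate_msc, simulate_msci,
                       subs_to_coal_time)

__all__ = [
    "neutral_law_max_rel_err", "phi0_equivalence_rejections",
    "labelswap_equivalence_rejections", "split_nomig_recovery",
    "nesting_inequality", "null_lrt_rejection_rate",
]

#: ingroup branch sizes used for the phi = 0 equivalence experiment:
#: constant along each tip lineage so the introgression topology with
#:  phi = 0 reduces exactly to a three-population species tree.
_EQUIV_THETA = {"DST": 1.3e-3, "STH": 3.0e-3, "PLN": 1.0e-3,
                "ANC_EAST": 2.0e-3, "ANC_ROOT": 2.5e-3, "OG": 1.2e-3}
_EQUIV_TAUS = dict(tau_T=3.9e-3, tau_S=6.1e-3, tau_R=9.8e-3)


def _seed_from(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def neutral_law_max_rel_err(n_reps: int = 10_000, seed: int = 1,
                            n_hap: int = 4) -> float:
    """Max relative error of the single-population branch spectrum
    against the neutral 1/i law."""
    P = 5
    plan = EpochPlan(boundaries=[], nu=[[1.0] * P],
                     mig=[np.zeros((P, P))], relabel=[list(range(P))])
    counts = branch_sfs_counts(plan, (0, 0, 0), (n_hap, 0, 0), n_reps, seed)
    xi = counts[1:n_hap, 0, 0]
    expect = 1.0 / np.arange(1, n_hap)
    rel = (xi / xi.sum()) / (expect / expect.sum()) - 1.0
    return float(np.max(np.abs(rel)))


def _equiv_msci_params(phi: float = 0.0) -> MSciParams:
    th = {"OG": _EQUIV_THETA["OG"], "DST": _EQUIV_THETA["DST"],
          "STH": _EQUIV_THETA["STH"], "PLN": _EQUIV_THETA["PLN"],
          "A": _EQUIV_THETA["DST"],           # DST lineage continues
          "B": _EQUIV_THETA["STH"], "C": _EQUIV_THETA["STH"],
          "D": _EQUIV_THETA["PLN"],
          "T": _EQUIV_THETA["ANC_EAST"],
          "S": _EQUIV_THETA["ANC_ROOT"], "R": _EQUIV_THETA["ANC_ROOT"]}
    return MSciParams(theta=th, tau_AB=1.4e-3, tau_CD=0.2e-3, **_EQUIV_TAUS,
                      phi_A=phi, phi_B=phi, phi_C=phi, phi_D=phi)


def _equiv_msc_model():
    """split_nomig instance matching :func:`_equiv_msci_params` at phi=0
    (mut_scale = the root-branch theta)."""
    ref = _EQUIV_THETA["ANC_ROOT"]
    return get_model("split_nomig").instantiate(dict(
        nu1=_EQUIV_THETA["DST"] / ref, nuA=_EQUIV_THETA["ANC_EAST"] / ref,
        nu2=_EQUIV_THETA["STH"] / ref, nu3=_EQUIV_THETA["PLN"] / ref,
        T1=subs_to_coal_time(_EQUIV_TAUS["tau_S"] - _EQUIV_TAUS["tau_T"], ref),
        T2=subs_to_coal_time(_EQUIV_TAUS["tau_T"], ref))), ref


def _contrast_distances(ls):
    root = divergence_summary(ls, ("DST", ("STH", "PLN"))).d_locus_between
    inner = divergence_summary(ls, ("STH", "PLN")).d_locus_between
    return root, inner


def phi0_equivalence_rejections(n_seeds: int = 20, n_loci: int = 1000,
                                seed: int = 0, alpha: float = 0.01) -> int:
    """Count seeds where per-locus divergence distributions from the
    phi = 0 introgression simulator and the matched species-tree MSC
    simulator differ by a two-sample KS test (Bonferroni over the two
    population contrasts)."""
    params = _equiv_msci_params(0.0)
    model, ref = _equiv_msc_model()
    rejections = 0
    for s in range(n_seeds):
        cfg_i = PopConfig(pop_names=("DST", "STH", "PLN"), n_samples=3,
                          n_loci=n_loci, locus_len=500,
                          seed=_seed_from(seed, 101, s))
        cfg_m = PopConfig(n_samples=3, n_loci=n_loci, locus_len=500,
                          mut_scale=ref, seed=_seed_from(seed, 102, s))
        a_root, a_inner = _contrast_distances(simulate_msci(params, cfg_i))
        b_root, b_inner = _contrast_distances(simulate_msc(model, cfg_m))
        p1 = ks_2samp(a_root, b_root).pvalue
        p2 = ks_2samp(a_inner, b_inner).pvalue
        if min(p1, p2) < alpha / 2:
            rejections += 1
    return rejections


def labelswap_equivalence_rejections(params: MSciParams, n_seeds: int = 20,
                                     n_loci: int = 500, seed: int = 0,
                                     alpha: float = 0.01,
                                     node_pair: str = "AB") -> int:
    """Count seeds where data from a parameter vector and its label-
    swapped twin are distinguished by a KS test on per-locus divergence.

    The exchange is exact in the near-trichotomy regime (tau_S = tau_T)
    for the A<->B pair, which is the regime the empirical posterior
    occupies; elsewhere the twin is only approximately equivalent.
    """
    from .msci import label_swap

    twin = label_swap(params, node_pair)
    rejections = 0
    for s in range(n_seeds):
        cfg_a = PopConfig(n_samples={"DST": 3, "STH": 3, "PLN": 3, "OG": 1},
                          n_loci=n_loci, locus_len=500,
                          seed=_seed_from(seed, 201, s))
        cfg_b = dataclasses.replace(cfg_a, seed=_seed_from(seed, 202, s))
        a_root, _ = _contrast_distances(simulate_msci(params, cfg_a))
        b_root, _ = _contrast_distances(simulate_msci(twin, cfg_b))
        if ks_2samp(a_root, b_root).pvalue < alpha:
            rejections += 1
    return rejections


#: generating values for the recovery experiment (relative sizes 1,
#: split times in 2*N_ref generations); locus theta is kept low so the
#: retained one-SNP-per-locus sample is an unbiased draw from the
#: branch-length proportions.
RECOVERY_TRUTH = dict(nu1=1.0, nuA=1.0, nu2=1.0, nu3=1.0, T1=0.5, T2=0.2)


def split_nomig_recovery(seed: int = 9, n_loci: int = 26_000,
                         n_samples: int = 6, mut_scale: float = 0.002,
                         n_reps: int = 2000, fit_seed: int = 2):
    """Simulate under split_nomig, rebuild the folded JSFS from one SNP
    per locus, refit the generating model; returns (results, rel_errors,
    n_snps)."""
    model = get_model("split_nomig").instantiate(RECOVERY_TRUTH)
    cfg = PopConfig(n_samples=n_samples, n_loci=n_loci, locus_len=100,
                    mut_scale=mut_scale, seed=seed)
    ls = simulate_msc(model, cfg)
    obs = build_jsfs(ls.to_genotype_frame(), ls.sample_labels,
                     fold_spectrum=True, one_per_locus=True)
    # the experiment varies the three terminal sizes and the two split
    # times; the ancestral (reference) size is held at 1, removing the
    # time-rescaling near-degeneracy from the refit
    sd = SFSDemography(obs, "split_nomig", n_reps=n_reps,
                       surface_seed=_seed_from(seed, 301),
                       fixed={"nuA": 1.0})
    res = sd.fit(seed=fit_seed)
    rel = {k: res.params[k] / RECOVERY_TRUTH[k] - 1.0 for k in RECOVERY_TRUTH}
    return res, rel, obs.total_mass()


_NULL_TRUTH = dict(nu1=1.0, nuA=1.0, nu2=1.0, nu3=1.0, m2=0.5, T1=0.5, T2=0.2)
_NULL_SCHEDULE = ((5, 3, 2), (8, 5, 1))


def _null_fit_pair(obs, surface_seed, fit_seed, n_reps=400):
    """Barrier-vs-adjacent-contact fit pair on one spectrum.

    The nested (barrier) hypothesis is the full model with the DST
    contact rate pinned at zero; after fitting both, the nested model is
    refitted from the full optimum so a basin found by only one arm
    cannot masquerade as evidence for gene flow.
    """
    start = {**_NULL_TRUTH, "m1": 0.0}
    sd_n = SFSDemography(obs, "refugia_adj_2", n_reps=n_reps,
                         surface_seed=surface_seed, fixed={"m1": 0.0})
    sd_f = SFSDemography(obs, "refugia_adj_2", n_reps=n_reps,
                         surface_seed=surface_seed)
    fit_n = sd_n.fit(seed=fit_seed, schedule=_NULL_SCHEDULE, polish=False,
                     start=start)
    fit_f = sd_f.fit(seed=fit_seed, schedule=_NULL_SCHEDULE, polish=False,
                     start={**fit_n.params, "m1": 1e-4})
    refit = sd_n.fit(seed=fit_seed, schedule=((6, 5, 1),), polish=False,
                     start={k: v for k, v in fit_f.params.items() if k != "m1"})
    if refit.lnL > fit_n.lnL:
        fit_n = refit
        back = sd_f.fit(seed=fit_seed, schedule=((6, 5, 1),), polish=False,
                        start={**fit_n.params, "m1": 1e-4})
        if back.lnL > fit_f.lnL:
            fit_f = back
    return fit_f, fit_n


def nesting_inequality(seed: int = 0, n_loci: int = 2000):
    """Fit the secondary-contact model and its barrier submodel on one
    spectrum simulated under the barrier truth; returns (lnL_full,
    lnL_nested)."""
    model = get_model("refugia_barrier").instantiate(
        {k: v for k, v in _NULL_TRUTH.items() if k != "m1"})
    cfg = PopConfig(n_samples=4, n_loci=n_loci, locus_len=100,
                    mut_scale=0.012, seed=_seed_from(seed, 401))
    ls = simulate_msc(model, cfg)
    obs = build_jsfs(ls.to_genotype_frame(), ls.sample_labels,
                     fold_spectrum=True, one_per_locus=True)
    fit_f, fit_n = _null_fit_pair(obs, _seed_from(seed, 402), fit_seed=1)
    return fit_f.lnL, fit_n.lnL


def null_lrt_rejection_rate(n_replicates: int = 50, seed: int = 0,
                            n_loci: int = 600, B: int = 20,
                            alpha: float = 0.05):
    """Rejection rate of the Godambe-adjusted LRT when the nested
    (barrier) model is true; returns (rate, n_replicates)."""
    model = get_model("refugia_barrier").instantiate(
        {k: v for k, v in _NULL_TRUTH.items() if k != "m1"})
    rejections = 0
    for r in range(n_replicates):
        cfg = PopConfig(n_samples=4, n_loci=n_loci, locus_len=100,
                        mut_scale=0.012, seed=_seed_from(seed, 501, r))
        ls = simulate_msc(model, cfg)
        gt = ls.to_genotype_frame()
        obs = build_jsfs(gt, ls.sample_labels, fold_spectrum=True,
                         one_per_locus=True)
        fit_f, fit_n = _null_fit_pair(obs, _seed_from(seed, 502, r),
                                      fit_seed=r)
        boots = bootstrap_spectra(gt, ls.sample_labels, B=B,
                                  seed=_seed_from(seed, 503, r),
                                  fold_spectrum=True, one_per_locus=True)
        res = lrt_godambe(fit_f, fit_n, boots)
        if res.p_value < alpha:
            rejections += 1
    return rejections / n_replicates, n_replicates
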