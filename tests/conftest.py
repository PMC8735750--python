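"""Shared fixtures: parameter vectors and small simulated data sets.

Everything is generated at run time from fixed seeds; module/session
scoping keeps the expensive simulations to one run each.
"""

import numpy as np
import pytest

from refugia.simulate import LocusSet, MSciParams, PopConfig

#: introgression-model posterior means (nonadmixed data, major peak),
#: raw per-site scale.
PEAK1_THETA = {
    "OG": 1.22e-3, "DST": 1.34e-3, "STH": 3.52e-3, "PLN": 0.93e-3,
    "R": 23.1e-3, "S": 2.69e-3, "T": 1.89e-3,
    "A": 2.55e-3, "B": 2.95e-3, "C": 4.27e-3, "D": 6.96e-3,
}
PEAK1_TAUS = dict(tau_R=9.75e-3, tau_S=6.14e-3, tau_T=3.86e-3,
                  tau_AB=1.42e-3, tau_CD=0.17e-3)


@pytest.fixture(scope="session")
def peak1_params() -> MSciParams:
    return MSciParams(theta=PEAK1_THETA, **PEAK1_TAUS,
                      phi_A=0.868, phi_B=0.090, phi_C=0.065, phi_D=0.935)


@pytest.fixture(scope="session")
def nogeneflow_params() -> MSciParams:
    return MSciParams(theta=PEAK1_THETA, **PEAK1_TAUS,
                      phi_A=0.0, phi_B=0.0, phi_C=0.0, phi_D=0.0)


@pytest.fixture(scope="session")
def small_config() -> PopConfig:
    return PopConfig(n_samples={"DST": 4, "STH": 4, "PLN": 4, "OG": 2},
                     n_loci=200, locus_len=500, seed=7)


def make_locus_set(genotypes, positions, labels, locus_len) -> LocusSet:
    """Hand-build a tiny LocusSet from explicit arrays."""
    samples = list(labels)
    return LocusSet(
        genotypes=[np.asarray(g, dtype=np.int8) for g in genotypes],
        positions=[np.asarray(p, dtype=int) for p in positions],
        samples=samples, sample_labels=dict(labels),
        locus_len=locus_len, truth={"kind": "handmade"}, seed=0)
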