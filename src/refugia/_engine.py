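"""Structured-coalescent branch-length engine.

Simulates genealogies backward in time under a piecewise-constant
multi-population demography (sizes, migration, mergers) and accumulates,
for every branch, its length into the joint leaf-count cell it subtends.
The normalised accumulation is the expected unfolded joint SFS under the
infinite-sites model (branch length is the Rao-Blackwellised sufficient
statistic for the Poisson mutation count).

Randomness is a pre-drawn uniform tensor consumed in a fixed pattern
(inverse-CDF waiting times, cumulative-rate event selection), so a fixed
(seed, n_reps) makes the map parameters -> spectrum deterministic and, to
the extent event orderings are stable, continuous in the parameters.
Time is measured in units of 2*N_ref generations; a population of relative
size nu has pairwise coalescence rate 1/nu, and a lineage in population i
migrates to j at backward rate M_ij (= 2*N_ref*m_ij per generation).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["EpochPlan", "branch_sfs_counts"]

_INF = np.inf

# Replicates whose event count overruns the pre-drawn uniform budget fall
# back to an inline splitmix64 stream and have migration frozen, which is
# the correct strong-migration (panmictic) limit and bounds the event loop.
_SPLITMIX_MULT = np.uint64(0x9E3779B97F4A7C15)


class EpochPlan:
    """Piecewise-constant demography over a fixed panel of populations.

    Parameters
    ----------
    boundaries : array of increasing epoch end-times (backward from 0);
        the final epoch is unbounded.
    nu : (n_epochs, n_pops) relative sizes.
    mig : (n_epochs, n_pops, n_pops) backward migration rates M_ij
        (lineage in i -> j); diagonal ignored.
    relabel : (n_epochs, n_pops) int map applied to every lineage's
        population label on *entering* each epoch (row 0 is identity).
        Mergers backward in time (population splits forward in time) are
        expressed by relabelling derived populations to their ancestor.
    """

    def __init__(self, boundaries, nu, mig, relabel):
        self.boundaries = np.asarray(boundaries, dtype=np.float64)
        self.nu = np.asarray(nu, dtype=np.float64)
        self.mig = np.asarray(mig, dtype=np.float64)
        self.relabel = np.asarray(relabel, dtype=np.int64)
        n_epochs, n_pops = self.nu.shape
        if self.boundaries.shape != (n_epochs - 1,):
            raise ValueError("boundaries must have n_epochs - 1 entries")
        if self.mig.shape != (n_epochs, n_pops, n_pops):
            raise ValueError("migration array shape mismatch")
        if self.relabel.shape != (n_epochs, n_pops):
            raise ValueError("relabel array shape mismatch")
        if np.any(np.diff(self.boundaries) <= 0) or np.any(self.boundaries <= 0):
            raise ValueError("epoch boundaries must be positive and increasing")
        if np.any(~np.isfinite(self.nu)) or np.any(self.nu <= 0):
            raise ValueError("population sizes must be positive and finite")
        if np.any(self.mig < 0):
            raise ValueError("migration rates must be non-negative")

    @property
    def n_pops(self) -> int:
        return self.nu.shape[1]

    @property
    def n_epochs(self) -> int:
        return self.nu.shape[0]


@njit(inline="always")
def _splitmix64(state):
    state = state + _SPLITMIX_MULT
    z = state
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return state, (np.float64(z >> np.uint64(11)) + 0.5) * (1.0 / 9007199254740992.0)


@njit
def _run_rep(u, rep_seed, pop, d1, d2, d3, alive, boundaries, nu, mig, mout,
             relabel, out, s1, s2):
    """Simulate one genealogy; accumulate branch lengths into ``out``."""
    n_pops = nu.shape[1]
    n_bound = boundaries.shape[0]
    n_lin = pop.shape[0]
    max_steps = u.shape[0]

    k = n_lin
    t = 0.0
    e = 0
    ui = 0
    state = rep_seed
    frozen = False  # migration switched off after uniform budget overrun

    kc = np.zeros(n_pops, dtype=np.int64)

    while k > 1:
        # --- rates under current epoch
        for p in range(n_pops):
            kc[p] = 0
        for l in range(n_lin):
            if alive[l]:
                kc[pop[l]] += 1
        coal_tot = 0.0
        mig_tot = 0.0
        for p in range(n_pops):
            if kc[p] > 1:
                coal_tot += kc[p] * (kc[p] - 1) * 0.5 / nu[e, p]
            if not frozen and kc[p] > 0:
                mig_tot += kc[p] * mout[e, p]
        total = coal_tot + mig_tot

        # --- uniforms for this step
        if ui < max_steps:
            u0 = u[ui, 0]
            u1 = u[ui, 1]
            u2 = u[ui, 2]
            ui += 1
        else:
            frozen = True
            state, u0 = _splitmix64(state)
            state, u1 = _splitmix64(state)
            state, u2 = _splitmix64(state)
            # recompute without migration
            total = coal_tot
            mig_tot = 0.0

        t_next = boundaries[e] if e < n_bound else _INF

        if total <= 0.0:
            w = _INF
        else:
            w = -np.log(u0) / total

        if t + w >= t_next:
            if not np.isfinite(t_next):
                break  # malformed plan: disconnected populations
            dt = t_next - t
            for l in range(n_lin):
                if alive[l]:
                    out[d1[l] * s1 + d2[l] * s2 + d3[l]] += dt
            t = t_next
            e += 1
            for l in range(n_lin):
                if alive[l]:
                    pop[l] = relabel[e, pop[l]]
            continue

        for l in range(n_lin):
            if alive[l]:
                out[d1[l] * s1 + d2[l] * s2 + d3[l]] += w
        t += w

        r = u1 * total
        if r < coal_tot:
            # coalescence: choose population, then an unordered pair
            p_sel = -1
            acc = 0.0
            for p in range(n_pops):
                if kc[p] > 1:
                    acc += kc[p] * (kc[p] - 1) * 0.5 / nu[e, p]
                    if r < acc:
                        p_sel = p
                        break
            if p_sel < 0:
                p_sel = n_pops - 1
                while kc[p_sel] < 2:
                    p_sel -= 1
            kp = kc[p_sel]
            a_idx = int(u2 * kp)
            if a_idx >= kp:
                a_idx = kp - 1
            frac = u2 * kp - a_idx
            b_idx = int(frac * (kp - 1))
            if b_idx >= kp - 1:
                b_idx = kp - 2
            if b_idx >= a_idx:
                b_idx += 1
            a = -1
            b = -1
            seen = 0
            for l in range(n_lin):
                if alive[l] and pop[l] == p_sel:
                    if seen == a_idx:
                        a = l
                    if seen == b_idx:
                        b = l
                    seen += 1
            d1[a] += d1[b]
            d2[a] += d2[b]
            d3[a] += d3[b]
            alive[b] = False
            k -= 1
        else:
            # migration: choose lineage by population, then destination
            r -= coal_tot
            p_sel = -1
            acc = 0.0
            for p in range(n_pops):
                if kc[p] > 0 and mout[e, p] > 0.0:
                    acc += kc[p] * mout[e, p]
                    if r < acc:
                        p_sel = p
                        break
            if p_sel < 0:
                continue  # numerical edge: no migration possible
            kp = kc[p_sel]
            l_idx = int(u2 * kp)
            if l_idx >= kp:
                l_idx = kp - 1
            lin = -1
            seen = 0
            for l in range(n_lin):
                if alive[l] and pop[l] == p_sel:
                    if seen == l_idx:
                        lin = l
                        break
                    seen += 1
            state, u3 = _splitmix64(state + np.uint64(ui))
            rd = u3 * mout[e, p_sel]
            acc = 0.0
            dest = -1
            for q in range(n_pops):
                if q != p_sel:
                    acc += mig[e, p_sel, q]
                    if rd < acc:
                        dest = q
                        break
            if dest >= 0:
                pop[lin] = dest


@njit
def _run_all(u_all, seeds, pop0, d10, d20, d30, boundaries, nu, mig, mout,
             relabel, out, s1, s2):
    n_reps = u_all.shape[0]
    n_lin = pop0.shape[0]
    pop = np.empty(n_lin, dtype=np.int64)
    d1 = np.empty(n_lin, dtype=np.int64)
    d2 = np.empty(n_lin, dtype=np.int64)
    d3 = np.empty(n_lin, dtype=np.int64)
    alive = np.empty(n_lin, dtype=np.bool_)
    for r in range(n_reps):
        for l in range(n_lin):
            pop[l] = pop0[l]
            d1[l] = d10[l]
            d2[l] = d20[l]
            d3[l] = d30[l]
            alive[l] = True
        _run_rep(u_all[r], seeds[r], pop, d1, d2, d3, alive, boundaries, nu,
                 mig, mout, relabel, out, s1, s2)


_UNIFORM_CACHE: dict = {}
_UNIFORM_CACHE_MAX = 4


def _uniforms(seed: int, n_reps: int, max_steps: int) -> np.ndarray:
    key = (int(seed), int(n_reps), int(max_steps))
    hit = _UNIFORM_CACHE.get(key)
    if hit is None:
        rng = np.random.default_rng(seed)
        hit = rng.random((n_reps, max_steps, 3))
        if len(_UNIFORM_CACHE) >= _UNIFORM_CACHE_MAX:
            _UNIFORM_CACHE.pop(next(iter(_UNIFORM_CACHE)))
        _UNIFORM_CACHE[key] = hit
    return hit


def branch_sfs_counts(plan: EpochPlan, sample_pops, sample_sizes, n_reps: int,
                      seed: int) -> np.ndarray:
    """Accumulated branch lengths per joint derived-allele configuration.

    Parameters
    ----------
    plan : EpochPlan
    sample_pops : the three engine population indices carrying samples,
        in axis order (axis 0, 1, 2 of the returned array).
    sample_sizes : haploid sample counts (n1, n2, n3).
    n_reps : number of independent genealogies.
    seed : master seed; the same (plan-shape, seed, n_reps) reuses the
        identical uniform tensor (common random numbers).

    Returns
    -------
    (n1+1, n2+1, n3+1) array of mean branch lengths (time units of
    2*N_ref generations) subtending each configuration.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n1, n2, n3 = (int(x) for x in sample_sizes)
    if min(n1, n2, n3) < 0 or n1 + n2 + n3 < 2:
        raise ValueError("need at least two sampled lineages")
    n_tot = n1 + n2 + n3
    pop0 = np.concatenate([
        np.full(n1, sample_pops[0], dtype=np.int64),
        np.full(n2, sample_pops[1], dtype=np.int64),
        np.full(n3, sample_pops[2], dtype=np.int64),
    ])
    d10 = np.zeros(n_tot, dtype=np.int64)
    d20 = np.zeros(n_tot, dtype=np.int64)
    d30 = np.zeros(n_tot, dtype=np.int64)
    d10[:n1] = 1
    d20[n1:n1 + n2] = 1
    d30[n1 + n2:] = 1

    max_steps = 8 * n_tot + 256
    u_all = _uniforms(seed, n_reps, max_steps)
    base = (int(seed) * 0x9E3779B97F4A7C15) % (2**64)
    seeds = np.uint64(base) + np.arange(1, n_reps + 1, dtype=np.uint64)

    mout = np.ascontiguousarray(plan.mig.sum(axis=2)
                                - np.einsum("eii->ei", plan.mig))
    out = np.zeros((n1 + 1) * (n2 + 1) * (n3 + 1), dtype=np.float64)
    s2 = n3 + 1
    s1 = (n2 + 1) * s2
    _run_all(u_all, seeds, pop0, d10, d20, d30, plan.boundaries, plan.nu,
             plan.mig, mout, plan.relabel, out, s1, s2)
    out /= n_reps
    return out.reshape(n1 + 1, n2 + 1, n3 + 1)
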