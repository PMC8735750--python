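"""Multi-locus coalescent simulation under MSC and MSci demographies.

Two unit systems coexist, each matching the sub-literature it serves:

* the ten model-comparison demographies (:mod:`refugia.registry`) use
  N_ref-relative units (sizes ``nu``, durations ``T`` in 2*N_ref
  generations, migration ``M = 2*N_ref*m``) as in dadi/moments;
* the introgression (MSci) model stores everything in mutation-scaled
  units: node ages ``tau`` in expected substitutions per site and
  ``theta = 4*N*mu`` per site, as in BPP.

:func:`coal_time_to_subs` / :func:`subs_to_coal_time` convert between
them given the reference theta.  Mutation follows the infinite-sites
model within each locus; the finite ``locus_len`` only expresses
distances per site.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import msprime
import numpy as np

from ._engine import EpochPlan, branch_sfs_counts
from .registry import ENGINE_POPS, POPS, DemographyModel, ParameterError
from .sfs import JSFS3

__all__ = [
    "PopConfig", "MSciParams", "HybridSpec", "LocusSet",
    "simulate_msc", "simulate_msci", "branch_spectrum",
    "plan_to_msprime", "msci_to_msprime",
    "coal_time_to_subs", "subs_to_coal_time",
]

#: arbitrary diploid reference size used to express N_ref-relative models
#: in msprime's absolute units; every observable depends only on the
#: scaled parameters, not on this constant.
N_REF = 10_000.0

#: per-generation per-site rate used internally to express mutation-scaled
#: MSci parameters in msprime's absolute units; cancels in all observables.
MSCI_U = 1e-7

#: branch labels of the introgression model (tips, root-ward branches and
#: the four introgression branches; theta_X is the size of the branch
#: above node X, e.g. theta_A for branch S-A, theta_B for branch T-B).
MSCI_BRANCHES = ("OG", "DST", "STH", "PLN", "R", "S", "T", "A", "B", "C", "D")

_DEFAULT_SAMPLES = {"DST": 8, "STH": 8, "PLN": 8, "OG": 2}


def coal_time_to_subs(T: float, theta_ref: float) -> float:
    """Convert a duration in 2*N_ref generations to expected subs/site."""
    return T * theta_ref / 2.0


def subs_to_coal_time(tau: float, theta_ref: float) -> float:
    """Convert expected substitutions/site to 2*N_ref-generation units."""
    return 2.0 * tau / theta_ref


@dataclass(frozen=True)
class PopConfig:
    """Sampling and mutation configuration shared by the simulators.

    ``n_samples`` is the haploid sample count per population (an int
    applies to every population); ``mut_scale`` is the reference theta
    (4*N_ref*mu per site) used to convert coalescent time to expected
    substitutions.
    """

    pop_names: tuple = ("DST", "STH", "PLN", "OG")
    n_samples: object = None
    n_loci: int = 500
    locus_len: int = 100
    mut_scale: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if self.n_loci < 1:
            raise ParameterError("n_loci must be >= 1")
        if self.locus_len < 1:
            raise ParameterError("locus_len must be >= 1")
        if self.mut_scale <= 0:
            raise ParameterError("mut_scale must be positive")
        for p in self.pop_names:
            if self.samples_for(p) < 1:
                raise ParameterError(f"n_samples for {p} must be >= 1")

    def samples_for(self, pop: str) -> int:
        if self.n_samples is None:
            return _DEFAULT_SAMPLES.get(pop, 8)
        if isinstance(self.n_samples, Mapping):
            try:
                return int(self.n_samples[pop])
            except KeyError:
                raise ParameterError(f"no sample count for population {pop!r}")
        return int(self.n_samples)


@dataclass(frozen=True)
class MSciParams:
    """Parameters of the two-BDI-event introgression model.

    The species tree is (((STH, PLN), DST), OG) with node ages
    ``tau_CD < tau_AB < tau_T <= tau_S < tau_R``.  Bidirectional
    introgression (BDI) node pairs: A (on the DST branch) <-> B (on the
    STH branch above C), and C (STH side) <-> D (PLN side).  Backward in
    time a lineage reaching node X reroutes across the horizontal edge
    with probability ``phi_X``.  theta and tau are raw per-site values
    (not the x1,000 presentation scale).
    """

    theta: Mapping[str, float]
    tau_R: float
    tau_S: float
    tau_T: float
    tau_AB: float
    tau_CD: float
    phi_A: float
    phi_B: float
    phi_C: float
    phi_D: float

    def __post_init__(self):
        missing = set(MSCI_BRANCHES) - set(self.theta)
        if missing:
            raise ParameterError(f"missing theta for branches {sorted(missing)}")
        for b in MSCI_BRANCHES:
            if not self.theta[b] > 0:
                raise ParameterError(f"theta[{b}] must be positive")
        if not (0 < self.tau_CD < self.tau_AB < self.tau_T <= self.tau_S
                < self.tau_R):
            raise ParameterError(
                "node ages must satisfy 0 < tau_CD < tau_AB < tau_T <= "
                "tau_S < tau_R")
        for name in ("phi_A", "phi_B", "phi_C", "phi_D"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["theta"] = dict(self.theta)
        return d


@dataclass(frozen=True)
class HybridSpec:
    """One extra, recently admixed individual appended to the sample.

    Each of its loci descends from ``parent_pops[0]`` with probability
    ``mixing_prob``, else from ``parent_pops[1]``; the individual is
    labelled ``host_pop`` regardless (emulating a recent hybrid assigned
    to its collection population).
    """

    host_pop: str = "DST"
    parent_pops: tuple = ("DST", "STH")
    mixing_prob: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.mixing_prob <= 1.0:
            raise ParameterError("mixing_prob must lie in [0, 1]")
        if len(self.parent_pops) != 2 or self.parent_pops[0] == self.parent_pops[1]:
            raise ParameterError("parent_pops must be two distinct populations")

    def validate_against(self, pops: Sequence[str]):
        for p in (self.host_pop, *self.parent_pops):
            if p not in pops:
                raise ParameterError(f"unknown population {p!r} in hybrid spec")


@dataclass
class LocusSet:
    """Simulated multi-locus haploid data with provenance.

    ``genotypes[l]`` is an (S_l, n_samples) 0/1 array of derived-allele
    calls at the segregating sites of locus ``l``; ``positions[l]`` holds
    their integer site indices within the locus.  ``sample_labels`` maps
    sample name -> population.
    """

    genotypes: list
    positions: list
    samples: list
    sample_labels: dict
    locus_len: int
    truth: dict
    seed: int

    def __post_init__(self):
        for name in self.samples:
            if name not in self.sample_labels:
                raise ValueError(f"sample {name!r} has no population label")

    @property
    def n_loci(self) -> int:
        return len(self.genotypes)

    def samples_of(self, pop: str) -> list:
        return [s for s in self.samples if self.sample_labels[s] == pop]

    def sample_index(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[n] for n in names], dtype=int)

    def drop_samples(self, names: Sequence[str]) -> "LocusSet":
        drop = set(names)
        keep = [i for i, s in enumerate(self.samples) if s not in drop]
        return LocusSet(
            genotypes=[g[:, keep] for g in self.genotypes],
            positions=[p.copy() for p in self.positions],
            samples=[self.samples[i] for i in keep],
            sample_labels={s: p for s, p in self.sample_labels.items()
                           if s not in drop},
            locus_len=self.locus_len,
            truth=dict(self.truth),
            seed=self.seed,
        )

    def to_genotype_frame(self):
        """Long-format genotype table (columns: locus, pos, one column per
        sample) consumable by :func:`refugia.sfs.build_jsfs`."""
        import pandas as pd

        frames = []
        for l in range(self.n_loci):
            g = self.genotypes[l]
            df = pd.DataFrame(g, columns=self.samples)
            df.insert(0, "pos", self.positions[l])
            df.insert(0, "locus", f"locus{l}")
            frames.append(df)
        if not frames:
            return pd.DataFrame(columns=["locus", "pos", *self.samples])
        return pd.concat(frames, ignore_index=True)

    def sequences(self, locus: int) -> dict:
        """Full-length sequences (ancestral 'A', derived 'T') per sample."""
        g = self.genotypes[locus]
        pos = self.positions[locus]
        out = {}
        for j, name in enumerate(self.samples):
            seq = np.full(self.locus_len, "A", dtype="U1")
            seq[pos[g[:, j] == 1]] = "T"
            out[name] = "".join(seq)
        return out

    def write_fasta(self, path):
        """Concatenated multi-FASTA; record ids ``locus{i}|{sample}``."""
        with open(path, "w") as fh:
            for l in range(self.n_loci):
                for name, seq in self.sequences(l).items():
                    fh.write(f">locus{l}|{name}\n{seq}\n")

    def write_tsv(self, path):
        """Genotype table: locus, pos, then one 0/1 column per sample."""
        with open(path, "w") as fh:
            fh.write("locus\tpos\t" + "\t".join(self.samples) + "\n")
            for l in range(self.n_loci):
                g = self.genotypes[l]
                for r in range(g.shape[0]):
                    row = "\t".join(str(int(x)) for x in g[r])
                    fh.write(f"locus{l}\t{self.positions[l][r]}\t{row}\n")

    def write_truth_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.truth, fh, indent=2, default=float)


def plan_to_msprime(plan: EpochPlan, n_ref: float = N_REF) -> msprime.Demography:
    """Express an N_ref-relative epoch plan as an msprime Demography."""
    dem = msprime.Demography()
    for p, name in enumerate(ENGINE_POPS):
        dem.add_population(name=name,
                           initial_size=_size_when_active(plan, p) * n_ref)
    for i in range(plan.n_pops):
        for j in range(plan.n_pops):
            if i != j and plan.mig[0, i, j] > 0:
                dem.set_migration_rate(source=ENGINE_POPS[i],
                                       dest=ENGINE_POPS[j],
                                       rate=plan.mig[0, i, j] / (2 * n_ref))
    active = set(range(len(POPS)))
    for b, t in enumerate(plan.boundaries):
        e = b + 1
        t_gen = t * 2 * n_ref
        groups: dict = {}
        for i in sorted(active):
            tgt = plan.relabel[e, i]
            if tgt != i:
                groups.setdefault(tgt, []).append(i)
        for tgt, derived in groups.items():
            dem.add_population_split(
                time=t_gen, derived=[ENGINE_POPS[i] for i in derived],
                ancestral=ENGINE_POPS[tgt])
            active -= set(derived)
            active.add(tgt)
        for i in sorted(active):
            for j in sorted(active):
                if i != j and plan.mig[e, i, j] != plan.mig[e - 1, i, j]:
                    dem.add_migration_rate_change(
                        time=t_gen, source=ENGINE_POPS[i], dest=ENGINE_POPS[j],
                        rate=plan.mig[e, i, j] / (2 * n_ref))
    dem.sort_events()
    return dem


def _size_when_active(plan: EpochPlan, p: int) -> float:
    """Relative size of pop p in the first epoch where it can hold lineages."""
    if p < len(POPS):
        return plan.nu[0, p]
    others = np.delete(np.arange(plan.n_pops), p)
    for e in range(1, plan.n_epochs):
        if np.any(plan.relabel[e, others] == p):
            return plan.nu[e, p]
    return plan.nu[-1, p]


#: loci are simulated in ancestry batches of this size; the chunk index is
#: part of the counter-based seed scheme, so any locus can be regenerated
#: by replaying at most one chunk.
CHUNK = 256


def _counter_seeds(seed: int, n: int, *key: int) -> np.ndarray:
    """Counter-based msprime seeds derived from the master seed."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    state = ss.generate_state(n, dtype=np.uint64)
    return (state % (2**31 - 2) + 1).astype(np.int64)


def _collect_loci(tree_seqs, n_samples_total, locus_len):
    genotypes, positions = [], []
    for ts in tree_seqs:
        g = ts.genotype_matrix() if ts.num_sites else np.zeros(
            (0, n_samples_total), dtype=np.int8)
        pos = np.array([s.position for s in ts.sites()])
        idx = _integer_positions(pos, locus_len)
        genotypes.append(np.asarray(g, dtype=np.int8))
        positions.append(idx)
    return genotypes, positions


def _integer_positions(pos: np.ndarray, locus_len: int) -> np.ndarray:
    """Map continuous infinite-sites positions to distinct integer columns."""
    if pos.size > locus_len:
        raise RuntimeError(
            f"{pos.size} segregating sites exceed locus_len={locus_len}; "
            "increase locus_len")
    idx = np.floor(pos).astype(int)
    used: set = set()
    out = np.empty_like(idx)
    for i, x in enumerate(idx):
        while x in used or x >= locus_len:
            x = (x + 1) % locus_len
        used.add(x)
        out[i] = x
    return out


def _simulate_loci(demography, sample_sets, config, stream, mut_rate,
                   extra_sample_pop=None):
    """Independent ancestries + infinite-sites mutations for every locus.

    Loci sharing a sample configuration are simulated in seeded chunks of
    :data:`CHUNK` replicates (sample sets are haploid but the coalescent
    timescale is diploid, so theta = 4*N*mu).  ``extra_sample_pop``
    optionally appends one haploid sample whose starting population
    varies per locus (the recent-hybrid device).
    """
    n = config.n_loci
    mut_seeds = _counter_seeds(config.seed, n, stream, 1)
    tree_seqs = [None] * n
    if extra_sample_pop is None:
        groups = [(None, np.arange(n))]
    else:
        groups = [(p, np.flatnonzero(extra_sample_pop == p))
                  for p in sorted(set(extra_sample_pop))]
    for gi, (parent, idx) in enumerate(groups):
        samples = list(sample_sets)
        if parent is not None:
            samples.append(msprime.SampleSet(1, population=parent, ploidy=1))
        n_chunks = (len(idx) + CHUNK - 1) // CHUNK
        chunk_seeds = _counter_seeds(config.seed, n_chunks, stream, 2, gi)
        pos = 0
        for c in range(n_chunks):
            size = min(CHUNK, len(idx) - pos)
            reps = msprime.sim_ancestry(
                samples=samples, demography=demography,
                sequence_length=config.locus_len, ploidy=2,
                discrete_genome=False, num_replicates=size,
                random_seed=int(chunk_seeds[c]))
            for k, ts in enumerate(reps):
                l = idx[pos + k]
                tree_seqs[l] = msprime.sim_mutations(
                    ts, rate=mut_rate, model=msprime.BinaryMutationModel(),
                    discrete_genome=False, random_seed=int(mut_seeds[l]))
            pos += size
    return tree_seqs


def simulate_msc(demography: DemographyModel, config: PopConfig) -> LocusSet:
    """Simulate independent loci under a registered three-population model.

    Genealogies follow the structured coalescent of the model's epochs and
    migration; mutations are Poisson on branches at ``mut_scale/4N_ref``
    per site per generation (infinite sites).
    """
    plan = demography.plan()  # validates parameters
    dem = plan_to_msprime(plan, N_REF)
    mut_rate = config.mut_scale / (4 * N_REF)
    sample_sets = [msprime.SampleSet(config.samples_for(p), population=p, ploidy=1)
                   for p in POPS]
    names, labels = [], {}
    for p in POPS:
        for i in range(config.samples_for(p)):
            nm = f"{p}_{i}"
            names.append(nm)
            labels[nm] = p
    tss = _simulate_loci(dem, sample_sets, config, 0, mut_rate)
    genotypes, positions = _collect_loci(tss, len(names), config.locus_len)
    truth = {"kind": "msc", "model": demography.name,
             "params": dict(demography.params),
             "mut_scale": config.mut_scale, "seed": config.seed}
    return LocusSet(genotypes, positions, names, labels, config.locus_len,
                    truth, config.seed)


def msci_to_msprime(params: MSciParams, u: float = MSCI_U) -> msprime.Demography:
    """Express the introgression model as an msprime Demography.

    Sizes are ``theta/(4u)`` and times ``tau/u`` generations; the
    BDI events become admixture events (backward-in-time rerouting with
    the phi probabilities).
    """
    th = params.theta
    dem = msprime.Demography()
    for tip in ("DST", "STH", "PLN", "OG"):
        dem.add_population(name=tip, initial_size=th[tip] / (4 * u))
    for br, label in (("A", "SA"), ("B", "TB"), ("C", "CB"), ("D", "DT")):
        dem.add_population(name=label, initial_size=th[br] / (4 * u))
    dem.add_population(name="ST", initial_size=th["T"] / (4 * u))
    dem.add_population(name="RS", initial_size=th["S"] / (4 * u))
    dem.add_population(name="R", initial_size=th["R"] / (4 * u))

    t_cd, t_ab = params.tau_CD / u, params.tau_AB / u
    t_t, t_s, t_r = params.tau_T / u, params.tau_S / u, params.tau_R / u
    # C<->D BDI at tau_CD: STH continues into CB unless rerouted (phi_C),
    # PLN reroutes into CB with phi_D else continues into DT.
    dem.add_admixture(time=t_cd, derived="STH", ancestral=["CB", "DT"],
                      proportions=[1 - params.phi_C, params.phi_C])
    dem.add_admixture(time=t_cd, derived="PLN", ancestral=["CB", "DT"],
                      proportions=[params.phi_D, 1 - params.phi_D])
    # A<->B BDI at tau_AB: DST reroutes into TB with phi_A else SA;
    # the STH-side branch CB reroutes into SA with phi_B else TB.
    dem.add_admixture(time=t_ab, derived="DST", ancestral=["SA", "TB"],
                      proportions=[1 - params.phi_A, params.phi_A])
    dem.add_admixture(time=t_ab, derived="CB", ancestral=["SA", "TB"],
                      proportions=[params.phi_B, 1 - params.phi_B])
    dem.add_population_split(time=t_t, derived=["TB", "DT"], ancestral="ST")
    dem.add_population_split(time=t_s, derived=["SA", "ST"], ancestral="RS")
    dem.add_population_split(time=t_r, derived=["OG", "RS"], ancestral="R")
    dem.sort_events()
    return dem


def simulate_msci(params: MSciParams, config: PopConfig,
                  hybrid: Optional[HybridSpec] = None) -> LocusSet:
    """Simulate loci under the introgression model, optionally appending
    one recently admixed individual (see :class:`HybridSpec`)."""
    dem = msci_to_msprime(params, MSCI_U)
    sampled = [p for p in ("DST", "STH", "PLN", "OG") if p in config.pop_names]
    sample_sets = [msprime.SampleSet(config.samples_for(p), population=p, ploidy=1)
                   for p in sampled]
    names, labels = [], {}
    for p in sampled:
        for i in range(config.samples_for(p)):
            nm = f"{p}_{i}"
            names.append(nm)
            labels[nm] = p

    extra = None
    if hybrid is not None:
        hybrid.validate_against(sampled)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(config.seed), spawn_key=(7,)))
        pick = rng.random(config.n_loci) < hybrid.mixing_prob
        extra = np.where(pick, hybrid.parent_pops[0], hybrid.parent_pops[1])
        nm = f"{hybrid.host_pop}_hyb"
        names.append(nm)
        labels[nm] = hybrid.host_pop

    tss = _simulate_loci(dem, sample_sets, config, 1, MSCI_U,
                         extra_sample_pop=extra)
    genotypes, positions = _collect_loci(tss, len(names), config.locus_len)
    truth = {"kind": "msci", "params": params.to_dict(),
             "hybrid": dataclasses.asdict(hybrid) if hybrid else None,
             "seed": config.seed}
    return LocusSet(genotypes, positions, names, labels, config.locus_len,
                    truth, config.seed)


def branch_spectrum(demography: DemographyModel, config: PopConfig,
                    n_reps: int, seed: Optional[int] = None) -> JSFS3:
    """Normalised expected unfolded joint SFS by branch-length Monte Carlo.

    Simulates ``n_reps`` genealogies under the model and accumulates the
    branch length subtending each joint derived-allele configuration;
    deterministic given (seed, n_reps) via a pre-drawn uniform stream.
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    plan = demography.plan()
    sizes = tuple(config.samples_for(p) for p in POPS)
    counts = branch_sfs_counts(plan, (0, 1, 2), sizes, n_reps,
                               config.seed if seed is None else seed)
    jsfs = JSFS3(counts, folded=False, pop_order=POPS)
    total = jsfs.total_mass()
    if total > 0:
        jsfs.counts[~jsfs.mask] /= total
    return jsfs
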