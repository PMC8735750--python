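"""Composite-likelihood fitting of demographic models to an observed JSFS.

The model object :class:`SFSDemography` pairs an observed joint SFS with a
registry model; its expected spectrum comes from the branch-length Monte
Carlo engine evaluated under common random numbers, so the likelihood
surface is a deterministic function of the parameters for a fixed
(surface seed, n_reps).  ``fit`` runs the staged simplex search of the
moments community pipeline: four consecutive rounds of
replicates = (10, 20, 30, 40) log-perturbed restarts (up to a factor
2**fold with fold = (3, 2, 2, 1)) of Nelder-Mead in log-parameter space
capped at maxiter = (3, 5, 10, 15), each round seeding the next with its
best scorer.

The likelihood is multinomial over unmasked cells; the parameter-
independent multinomial coefficient is omitted (it cancels from every
comparison), so reported lnL values are comparable across models on the
same spectrum but are not absolute log-probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .registry import DemographyModel, ModelSpec, ParameterError, get_model
from .sfs import JSFS3, fold as fold_sfs
from ._engine import branch_sfs_counts

__all__ = [
    "SFSDemography", "SFSDemographyResults", "FitError",
    "expected_sfs", "multinomial_loglik", "fit_model",
    "DEFAULT_SCHEDULE",
]

#: staged-optimisation schedule: (replicates, maxiter, fold) per round.
DEFAULT_SCHEDULE = ((10, 3, 3), (20, 5, 2), (30, 10, 2), (40, 15, 1))

#: probability floor applied to expected cells so observed mass on an
#: empty cell yields a large negative but finite log-likelihood.
P_FLOOR = 1e-300

#: default log10 search bounds; migration rates are capped lower because
#: the event-driven engine's cost grows with the migration rate.
SIZE_TIME_BOUNDS = (1e-3, 1e3)
MIG_BOUNDS = (1e-4, 1e2)


class FitError(RuntimeError):
    """All optimisation replicates failed; carries the best partial state."""

    def __init__(self, message, best_params=None, best_loglik=None):
        super().__init__(message)
        self.best_params = best_params
        self.best_loglik = best_loglik


def multinomial_loglik(obs: JSFS3, expected: JSFS3, alpha: float = 0.0) -> float:
    """Multinomial composite log-likelihood of ``obs`` given normalised
    cell probabilities ``expected`` (constant term omitted).

    ``alpha`` adds a uniform pseudo-probability before taking logs,
    regularising cells whose Monte-Carlo expectation is exactly zero;
    it is negligible wherever the expectation is resolved (p >> alpha)
    and is used only inside the optimiser."""
    if obs.counts.shape != expected.counts.shape:
        raise ValueError("observed and expected spectra differ in shape")
    if obs.folded != expected.folded:
        raise ValueError("observed and expected spectra differ in folding")
    use = ~(obs.mask | expected.mask)
    p = expected.counts[use]
    total = p.sum()
    if total <= 0:
        raise ValueError("expected spectrum carries no unmasked mass")
    p = p / total
    if alpha > 0:
        p = (p + alpha) / (1.0 + alpha * p.size)
    p = np.maximum(p, P_FLOOR)
    return float(np.sum(obs.counts[use] * np.log(p)))


def expected_sfs(model, params=None, sizes: Sequence[int] = (8, 8, 8),
                 fold: bool = True, n_reps: int = 3000, seed: int = 0) -> JSFS3:
    """Normalised expected JSFS of a registry model at given parameters.

    Deterministic for fixed (seed, n_reps) by common random numbers, so
    the map params -> spectrum is smooth enough for simplex optimisation.
    """
    dm = _as_model(model, params)
    counts = branch_sfs_counts(dm.plan(), (0, 1, 2), sizes, n_reps, seed)
    jsfs = JSFS3(counts, folded=False)
    if fold:
        jsfs = fold_sfs(jsfs)
    return jsfs.normalized()


def _as_model(model, params) -> DemographyModel:
    if isinstance(model, DemographyModel):
        return model
    spec = model if isinstance(model, ModelSpec) else get_model(model)
    if params is None:
        raise ParameterError("parameters required to instantiate the model")
    return spec.instantiate(params)


def _bounds_for(name: str) -> tuple:
    return MIG_BOUNDS if name.startswith("m") else SIZE_TIME_BOUNDS


class SFSDemography:
    """An observed joint SFS paired with a demographic model family.

    Parameters
    ----------
    obs : JSFS3 (folded or unfolded; the expected spectrum follows suit).
    model : registry model name or :class:`ModelSpec`.
    n_reps : genealogies per expected-spectrum evaluation.
    surface_seed : seed of the common-random-number surface.
    fixed : mapping of parameters held constant during fitting (the
        device used to fit nested hypotheses inside a full model).
    """

    def __init__(self, obs: JSFS3, model, *, n_reps: int = 3000,
                 surface_seed: int = 0, fixed: Optional[Mapping] = None):
        self.obs = obs
        self.spec = model if isinstance(model, ModelSpec) else get_model(model)
        self.n_reps = int(n_reps)
        self.surface_seed = int(surface_seed)
        self.fixed = dict(fixed or {})
        unknown = set(self.fixed) - set(self.spec.param_names)
        if unknown:
            raise ParameterError(f"fixed parameters not in model: {sorted(unknown)}")
        self.free_names = tuple(n for n in self.spec.param_names
                                if n not in self.fixed)
        self._sizes = obs.n_haploid

    # -- likelihood surface -------------------------------------------------

    def full_params(self, free_values: Sequence[float]) -> dict:
        p = dict(zip(self.free_names, free_values))
        p.update(self.fixed)
        return p

    def expected(self, params, n_reps: Optional[int] = None) -> JSFS3:
        return expected_sfs(self.spec, params, sizes=self._sizes,
                            fold=self.obs.folded,
                            n_reps=n_reps or self.n_reps,
                            seed=self.surface_seed)

    def loglike(self, params, n_reps: Optional[int] = None,
                alpha: float = 0.0) -> float:
        return multinomial_loglik(self.obs, self.expected(params, n_reps),
                                  alpha=alpha)

    def _objective(self, log_x: np.ndarray, n_reps: Optional[int] = None) -> float:
        penalty = 0.0
        vals = {}
        for name, lx in zip(self.free_names, log_x):
            lo, hi = _bounds_for(name)
            x = np.exp(lx)
            if x < lo:
                penalty += (np.log(lo) - lx) ** 2
                x = lo
            elif x > hi:
                penalty += (lx - np.log(hi)) ** 2
                x = hi
            vals[name] = x
        try:
            ll = self.loglike(self.full_params(list(vals.values())),
                              n_reps=n_reps, alpha=1e-6)
        except (ParameterError, ValueError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll + 1e4 * penalty

    # -- staged optimisation ------------------------------------------------

    def fit(self, start: Optional[Mapping] = None,
            schedule: Sequence = DEFAULT_SCHEDULE,
            seed: int = 0, polish: bool = True) -> "SFSDemographyResults":
        """Staged multi-replicate simplex search; deterministic in
        (obs, model, seed).

        The staged rounds localise the optimum; with ``polish`` (default)
        a terminal Nelder-Mead run from the incumbent is allowed to
        iterate to convergence, since the short per-replicate iteration
        caps of the staged schedule act as a stochastic search rather
        than a convergent one.
        """
        if not self.free_names:
            ll = self.loglike(self.full_params(()))
            return self._results({}, ll, [], seed)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(21,)))
        if start is None:
            x0 = np.zeros(len(self.free_names))  # log(1) for every parameter
        else:
            x0 = np.log([np.clip(float(start[n]), *_bounds_for(n))
                         for n in self.free_names])
        best_x, best_f = x0, self._objective(x0)
        schedule_log = []
        n_fail = 0
        n_total = 0
        for replicates, maxiter, fold_width in schedule:
            round_best_x, round_best_f = best_x, best_f
            for _ in range(replicates):
                n_total += 1
                pert = rng.uniform(-fold_width * np.log(2.0),
                                   fold_width * np.log(2.0), size=len(best_x))
                res = minimize(self._objective, best_x + pert,
                               method="Nelder-Mead",
                               options={"maxiter": maxiter, "xatol": 1e-8,
                                        "fatol": 1e-10})
                if not np.isfinite(res.fun) or res.fun >= 1e12:
                    n_fail += 1
                    continue
                if res.fun < round_best_f:
                    round_best_x, round_best_f = res.x, res.fun
            best_x, best_f = round_best_x, round_best_f
            schedule_log.append(float(-best_f))
        polish_reps = 4 * self.n_reps
        if polish:
            best_x, best_f = self._polish(best_x, best_f, n_reps=polish_reps)
            schedule_log.append(float(-best_f))
        if n_total and n_fail == n_total:
            raise FitError("every optimisation replicate failed",
                           best_params=self.full_params(np.exp(best_x)),
                           best_loglik=-best_f)
        params = {n: float(v) for n, v in zip(self.free_names, np.exp(best_x))}
        # report the exact (unsmoothed) likelihood at the high-fidelity surface
        lnl = self.loglike(self.full_params(np.exp(best_x)),
                           n_reps=polish_reps if polish else None)
        return self._results(params, lnl, schedule_log, seed)

    def _polish(self, x, fx, n_reps: Optional[int] = None):
        """Convergence polish: Nelder-Mead restarts with shrinking initial
        simplex spreads, alternated with a line search along the
        time-rescaling ridge (nu, T up / M down leaves the genealogy
        distribution invariant up to a time scaling, so the normalised
        spectrum identifies that direction only weakly).  Run at a higher
        replicate count than the staged search to push the Monte-Carlo
        jitter below the local curvature."""
        from scipy.optimize import minimize_scalar

        n = len(x)
        obj = lambda z: self._objective(z, n_reps=n_reps)  # noqa: E731
        fx = obj(x)
        ridge = np.array([-1.0 if name.startswith("m") else 1.0
                          for name in self.free_names])
        for _ in range(3):
            f_start = fx
            for spread in (0.4, 0.15, 0.05):
                simplex = np.vstack([x] + [x + spread * e for e in np.eye(n)])
                res = minimize(obj, x, method="Nelder-Mead",
                               options={"maxiter": 500, "xatol": 1e-7,
                                        "fatol": 1e-9,
                                        "initial_simplex": simplex})
                if np.isfinite(res.fun) and res.fun < fx:
                    x, fx = res.x, res.fun
            # line search along the scaling ridge
            grid = np.linspace(-1.0, 1.0, 11)
            vals = [obj(x + g * ridge) for g in grid]
            g0 = grid[int(np.argmin(vals))]
            r = minimize_scalar(lambda g: obj(x + g * ridge),
                                bounds=(g0 - 0.25, g0 + 0.25),
                                method="bounded", options={"xatol": 1e-3})
            if np.isfinite(r.fun) and r.fun < fx:
                x, fx = x + r.x * ridge, r.fun
            if f_start - fx < 0.1:
                break
        return x, fx

    def _results(self, free_params, loglik, schedule_log, seed):
        params = dict(free_params)
        params.update(self.fixed)
        ordered = {n: params[n] for n in self.spec.param_names}
        return SFSDemographyResults(
            model=self, model_name=self.spec.name, params=ordered,
            lnL=float(loglik), k=len(self.free_names),
            theta_hat=self.obs.total_mass(), seed=int(seed),
            schedule_log=list(schedule_log))


@dataclass
class SFSDemographyResults:
    """Optimised fit of one demographic model to one spectrum.

    ``k`` counts the free parameters actually searched (fixed parameters
    of a nested fit are excluded) and ``AIC = 2k - 2 lnL`` exactly;
    ``theta_hat`` is the scale factor mapping the normalised expected
    spectrum onto observed counts (the total observed segregating mass).
    """

    model: SFSDemography = field(repr=False)
    model_name: str = ""
    params: dict = field(default_factory=dict)
    lnL: float = np.nan
    k: int = 0
    theta_hat: float = np.nan
    seed: int = 0
    schedule_log: list = field(default_factory=list)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.lnL

    @property
    def AIC(self) -> float:
        return self.aic

    def expected(self) -> JSFS3:
        return self.model.expected(self.params)

    def plot_residuals(self, ax=None):
        """Anscombe residual panels of this fit against its data."""
        from .plots import plot_fit_residuals

        return plot_fit_residuals(self.model.obs, self.expected(), ax=ax)

    def to_dict(self) -> dict:
        return {"model": self.model_name, "params": dict(self.params),
                "lnL": self.lnL, "k": self.k, "AIC": self.aic,
                "theta_hat": self.theta_hat, "seed": self.seed,
                "schedule_log": list(self.schedule_log)}

    def summary(self) -> str:
        lines = [
            f"{'Model:':<14}{self.model_name}",
            f"{'lnL:':<14}{self.lnL:.4f}",
            f"{'k:':<14}{self.k}",
            f"{'AIC:':<14}{self.aic:.2f}",
            f"{'theta_hat:':<14}{self.theta_hat:.4f}",
            "",
            f"{'parameter':<12}{'estimate':>12}",
            "-" * 24,
        ]
        for name, value in self.params.items():
            tag = "  (fixed)" if name in self.model.fixed else ""
            lines.append(f"{name:<12}{value:>12.5g}{tag}")
        if self.schedule_log:
            lines.append("")
            lines.append("round best lnL: "
                         + ", ".join(f"{v:.2f}" for v in self.schedule_log))
        return "\n".join(lines)


def fit_model(obs: JSFS3, model, seed: int = 0, *, n_reps: int = 3000,
              fixed: Optional[Mapping] = None, start: Optional[Mapping] = None,
              schedule: Sequence = DEFAULT_SCHEDULE) -> SFSDemographyResults:
    """Convenience wrapper: build :class:`SFSDemography` and fit it."""
    sd = SFSDemography(obs, model, n_reps=n_reps, surface_seed=seed,
                       fixed=fixed)
    return sd.fit(start=start, schedule=schedule, seed=seed)
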