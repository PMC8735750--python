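"""Model ranking and testing: Akaike weights, confidence sets, locus
bootstrap spectra and Godambe-adjusted likelihood-ratio tests.

The composite (multinomial, linkage-ignoring) likelihood invalidates the
usual chi-square calibration of likelihood-ratio statistics; the Godambe
(sandwich) correction rescales the statistic using bootstrap variability
of the score, after which it is referred to the chi-square — by default a
50:50 mixture of a point mass at zero and chi2_df, because migration
rates fixed at zero sit on the boundary of the parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .likelihood import SFSDemographyResults, multinomial_loglik
from .registry import nested_fixes
from .sfs import JSFS3, build_jsfs

__all__ = ["AkaikeTable", "LRTResult", "akaike_table", "confidence_set",
           "bootstrap_spectra", "lrt_godambe"]

#: finite-difference step (absolute, since nested values sit at 0) used
#: for the Godambe score and Hessian estimates.
GODAMBE_EPS = 0.01


@dataclass
class AkaikeTable:
    """Ranked model-comparison table (ascending AIC).

    Columns: Model, AIC, dAIC (AIC - min AIC), relL (exp(-dAIC/2)) and
    wAIC (relL normalised to 1, the Akaike weight).
    """

    table: pd.DataFrame

    def confidence_set(self, level: float = 0.95) -> list:
        return confidence_set(self, level)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def __getitem__(self, model: str) -> pd.Series:
        row = self.table[self.table["Model"] == model]
        if row.empty:
            raise KeyError(model)
        return row.iloc[0]

    def __len__(self) -> int:
        return len(self.table)


def akaike_table(entries) -> AkaikeTable:
    """Build the AIC / dAIC / relL / wAIC ranking from (name, AIC) pairs,
    a mapping, or fit results objects."""
    pairs = []
    for e in entries if not isinstance(entries, Mapping) else entries.items():
        if isinstance(e, SFSDemographyResults):
            pairs.append((e.model_name, e.aic))
        elif hasattr(e, "model_name") and hasattr(e, "aic"):
            pairs.append((e.model_name, e.aic))
        else:
            name, aic = e
            pairs.append((str(name), float(aic)))
    if not pairs:
        raise ValueError("at least one model entry is required")
    aics = np.array([a for _, a in pairs])
    if not np.all(np.isfinite(aics)):
        raise ValueError("AIC values must be finite")
    d = aics - aics.min()
    rel = np.exp(-d / 2.0)
    w = rel / rel.sum()
    df = pd.DataFrame({"Model": [n for n, _ in pairs], "AIC": aics,
                       "dAIC": d, "relL": rel, "wAIC": w})
    df = df.sort_values("AIC", kind="stable").reset_index(drop=True)
    return AkaikeTable(df)


def confidence_set(table: AkaikeTable, level: float = 0.95) -> list:
    """Smallest prefix of the weight-sorted models whose cumulative
    Akaike weight reaches ``level``."""
    if not 0.0 < level <= 1.0:
        raise ValueError("level must lie in (0, 1]")
    df = table.table.sort_values("wAIC", ascending=False, kind="stable")
    cum = df["wAIC"].cumsum()
    n_keep = int(np.searchsorted(cum.to_numpy(), level - 1e-12) + 1)
    n_keep = min(n_keep, len(df))
    return df["Model"].head(n_keep).tolist()


def bootstrap_spectra(genotypes: pd.DataFrame, pop_map: Mapping, B: int,
                      seed: int = 0, **build_kwargs) -> list:
    """B spectra from resampling loci with replacement (the resampling
    unit is the locus, matching the one-SNP-per-locus design)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    loci = genotypes["locus"].unique()
    if len(loci) < 2:
        raise ValueError("need at least 2 loci to bootstrap")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                       spawn_key=(31,)))
    groups = dict(tuple(genotypes.groupby("locus", sort=False)))
    out = []
    for _ in range(B):
        draw = rng.choice(loci, size=len(loci), replace=True)
        frames = []
        for i, l in enumerate(draw):
            g = groups[l].copy()
            g["locus"] = f"b{i}_{l}"  # keep resampled copies distinct
            frames.append(g)
        boot = pd.concat(frames, ignore_index=True)
        out.append(build_jsfs(boot, pop_map, **build_kwargs))
    return out


@dataclass(frozen=True)
class LRTResult:
    """Godambe-adjusted likelihood-ratio test outcome.

    ``D = 2 (lnL_full - lnL_nested)``; ``D_adj = adjust * D`` with the
    sandwich adjustment ``df / tr(J H^-1)``; non-positive ``D_adj``
    yields p = 1 (the paper's own convention for its negative statistic).
    """

    D: float
    D_adj: float
    df: int
    p_value: float
    n_boot: int
    adjust: float

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _embed_nested_params(fit_full, fit_nested, fixes: Mapping) -> dict:
    """Nested optimum expressed in the full model's parameter space."""
    full_names = fit_full.model.spec.param_names
    params = dict(fixes)
    for name in full_names:
        if name not in params:
            try:
                params[name] = fit_nested.params[name]
            except KeyError:
                raise ValueError(
                    f"nested fit lacks parameter {name!r}; the pair is not "
                    "nested by parameter naming") from None
    return params


def lrt_godambe(fit_full: SFSDemographyResults,
                fit_nested: SFSDemographyResults,
                boot: Sequence[JSFS3],
                nested_map: Optional[Mapping] = None,
                eps: float = GODAMBE_EPS,
                boundary: bool = True) -> LRTResult:
    """Adjusted LRT of a nested model inside a full model.

    ``nested_map`` maps full-model parameter names to their fixed values
    under the nested hypothesis; when omitted it is looked up in the
    nesting registry from the two model names.  The adjustment is
    estimated at the nested optimum: bootstrap spectra give the score
    covariance J, the data spectrum the curvature H, both by one-sided
    finite differences of step ``eps`` in the tested directions.
    """
    if nested_map is None:
        nested_fixed = getattr(fit_nested.model, "fixed", None)
        if (fit_nested.model_name == fit_full.model_name and nested_fixed):
            nested_map = dict(nested_fixed)  # nested = full with pins
        else:
            nested_map = nested_fixes(fit_full.model_name,
                                      fit_nested.model_name)
    tested = sorted(nested_map)
    df = len(tested)
    if df == 0:
        raise ValueError("nested_map fixes no parameters")
    if len(boot) < max(2, df + 1):
        raise ValueError("too few bootstrap spectra for the adjustment")

    D = 2.0 * (fit_full.lnL - fit_nested.lnL)

    model = fit_full.model
    n_reps = 4 * model.n_reps
    theta0 = _embed_nested_params(fit_full, fit_nested, nested_map)

    def loglik_vec(params):
        expected = model.expected(params, n_reps=n_reps)
        lls = np.array([multinomial_loglik(b, expected) for b in boot])
        ll_data = multinomial_loglik(model.obs, expected)
        return lls, ll_data

    ll0_boot, ll0_data = loglik_vec(theta0)
    scores = np.zeros((len(boot), df))
    h_diag2: dict = {}
    grads_data = np.zeros(df)
    for a, name in enumerate(tested):
        p1 = dict(theta0)
        p1[name] = theta0[name] + eps
        ll1_boot, ll1_data = loglik_vec(p1)
        p2 = dict(theta0)
        p2[name] = theta0[name] + 2 * eps
        ll2_boot, ll2_data = loglik_vec(p2)
        scores[:, a] = (ll1_boot - ll0_boot) / eps
        grads_data[a] = (ll1_data - ll0_data) / eps
        h_diag2[name] = (ll2_data - 2 * ll1_data + ll0_data) / eps**2

    J = np.atleast_2d(np.cov(scores.T, bias=False))
    if df == 1:
        J = J.reshape(1, 1)
    H = -np.diag([h_diag2[name] for name in tested])

    try:
        tr = float(np.trace(J @ np.linalg.inv(H)))
    except np.linalg.LinAlgError:
        tr = np.nan
    adjust = df / tr if np.isfinite(tr) and tr > 0 else 1.0
    D_adj = adjust * D

    if D_adj <= 0:
        p = 1.0
    else:
        tail = float(chi2.sf(D_adj, df))
        p = 0.5 * tail if boundary else tail
    return LRTResult(D=float(D), D_adj=float(D_adj), df=df, p_value=p,
                     n_boot=len(boot), adjust=float(adjust))
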