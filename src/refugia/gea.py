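"""Genotype-environment association outlier rules.

Only the filtering arithmetic lives here: flagging SNPs whose ordination
locus scores fall more than a multiple of the standard deviation from
the axis mean, and assigning each candidate to the environmental
variable with the strongest Pearson correlation.  The ordination /
latent-factor estimation producing the loadings is deliberately out of
scope; any SNP x axis score matrix will do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["LoadingsMatrix", "loading_outliers", "assign_predictor"]


@dataclass
class LoadingsMatrix:
    """SNP x constrained-axis locus scores."""

    values: np.ndarray
    snp_ids: Sequence[str]
    axis_ids: Sequence[str]

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("loadings must be finite")
        if self.values.shape != (len(self.snp_ids), len(self.axis_ids)):
            raise ValueError("loadings shape does not match id lists")
        if self.values.shape[1] < 1:
            raise ValueError("at least one axis is required")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LoadingsMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


def loading_outliers(loadings: LoadingsMatrix,
                     sd_mult: float = 2.5) -> pd.DataFrame:
    """SNPs whose score lies beyond ``sd_mult`` sample standard deviations
    (n-1 denominator) of the mean on any axis.

    Returns one row per (SNP, triggering axis); the union of SNPs over
    axes is the candidate set.  A zero-variance axis contributes no
    outliers and is logged.
    """
    if not sd_mult > 0:
        raise ValueError("sd_mult must be positive")
    rows = []
    for a, axis in enumerate(loadings.axis_ids):
        scores = loadings.values[:, a]
        sd = scores.std(ddof=1) if len(scores) > 1 else 0.0
        if sd == 0.0:
            logger.info("axis %s has zero variance; no outliers", axis)
            continue
        centred = scores - scores.mean()
        for i in np.flatnonzero(np.abs(centred) > sd_mult * sd):
            rows.append({"snp": loadings.snp_ids[i], "axis": axis,
                         "score": scores[i],
                         "z": centred[i] / sd})
    return pd.DataFrame(rows, columns=["snp", "axis", "score", "z"])


def assign_predictor(candidates: Sequence[str],
                     corr: pd.DataFrame) -> pd.Series:
    """Map each candidate SNP to the environmental variable with the
    largest |Pearson r|; ties go to the first-listed variable (logged)."""
    missing = [c for c in candidates if c not in corr.index]
    if missing:
        raise KeyError(f"candidates missing from correlation matrix: {missing}")
    out = {}
    vals = corr.abs()
    for snp in candidates:
        row = vals.loc[snp]
        best = row.idxmax()  # first occurrence wins on ties
        if (row == row.max()).sum() > 1:
            logger.info("tie for SNP %s resolved to first-listed %s", snp, best)
        out[snp] = best
    return pd.Series(out, name="predictor")
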