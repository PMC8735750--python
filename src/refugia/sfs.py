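"""Joint site-frequency-spectrum construction, folding, projection and I/O.

The central container is :class:`JSFS3`, a 3-dimensional histogram of
per-population derived (or, once folded, minor) allele counts.  The two
fixed cells (0,0,0) and (n1,n2,n3) never carry likelihood mass and are
always masked; folding additionally masks the majority half of the
spectrum.  Text serialisation round-trips the dadi/moments SFS dialect.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "JSFS3", "SiteClassCounts", "build_jsfs", "fold", "project",
    "classify_sites", "count_quartets", "read_sfs", "write_sfs",
    "SFSParseError",
]


class SFSParseError(ValueError):
    """Malformed SFS text file; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


@dataclass
class JSFS3:
    """3D joint SFS with folding state, mask and population order.

    ``counts[i, j, k]`` is the (possibly expected) number of sites whose
    derived allele appears i, j and k times in the three populations;
    ``mask`` marks cells excluded from any likelihood (True = excluded).
    """

    counts: np.ndarray
    folded: bool = False
    mask: Optional[np.ndarray] = None
    pop_order: tuple = ("DST", "STH", "PLN")

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be a 3-dimensional array")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite and non-negative")
        base = self._fixed_mask(self.counts.shape)
        if self.folded:
            base |= self._majority_mask(self.counts.shape)
        if self.mask is None:
            self.mask = base
        else:
            self.mask = np.asarray(self.mask, dtype=bool) | base
        if self.folded and np.any(self.counts[self._majority_mask(self.counts.shape)] != 0):
            raise ValueError("folded spectrum carries mass in the majority half")

    @staticmethod
    def _fixed_mask(shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[0, 0, 0] = True
        m[-1, -1, -1] = True
        return m

    @staticmethod
    def _majority_mask(shape) -> np.ndarray:
        n = np.array(shape) - 1
        tot = _total_count_grid(shape)
        return 2 * tot > n.sum()

    @property
    def n_haploid(self) -> tuple:
        return tuple(s - 1 for s in self.counts.shape)

    def total_mass(self) -> float:
        return float(self.counts[~self.mask].sum())

    def normalized(self) -> "JSFS3":
        out = self.copy()
        total = out.total_mass()
        if total > 0:
            out.counts[~out.mask] /= total
        return out

    def copy(self) -> "JSFS3":
        return JSFS3(self.counts.copy(), folded=self.folded,
                     mask=self.mask.copy(), pop_order=self.pop_order)

    def __eq__(self, other) -> bool:
        return (isinstance(other, JSFS3)
                and self.folded == other.folded
                and self.pop_order == tuple(other.pop_order)
                and self.counts.shape == other.counts.shape
                and np.allclose(self.counts, other.counts)
                and np.array_equal(self.mask, other.mask))


def _total_count_grid(shape) -> np.ndarray:
    i, j, k = np.indices(shape)
    return i + j + k


@dataclass(frozen=True)
class SiteClassCounts:
    """Alignment column classification totals."""

    n_invariant: int
    n_variable_uninformative: int
    n_parsimony_informative: int

    @property
    def total(self) -> int:
        return (self.n_invariant + self.n_variable_uninformative
                + self.n_parsimony_informative)


def fold(jsfs: JSFS3) -> JSFS3:
    """Fold to minor-allele counts.

    Majority cells (total derived count > n_tot/2) add their mass to the
    mirror cell and are masked.  Tie cells (total exactly n_tot/2) are
    combined with their mirror and assigned to the lexicographically
    smaller index, the mirror being masked — a documented convention for
    a point on which SFS dialects differ.
    """
    if jsfs.folded:
        raise ValueError("spectrum is already folded")
    shape = jsfs.counts.shape
    n = np.array(shape) - 1
    n_tot = n.sum()
    tot = _total_count_grid(shape)
    out = jsfs.counts.copy()
    out_mask = jsfs.mask.copy()

    it = np.ndindex(shape)
    for idx in it:
        d = tot[idx]
        mirror = tuple(n - np.array(idx))
        if 2 * d > n_tot:
            out[mirror] += out[idx]
            out[idx] = 0.0
        elif 2 * d == n_tot and idx != mirror:
            if idx < mirror:  # lexicographic comparison
                out[idx] += out[mirror]
            else:
                continue  # handled from the smaller index
    # zero and mask the tie mirrors after combination
    for idx in np.ndindex(shape):
        if 2 * tot[idx] == n_tot:
            mirror = tuple(n - np.array(idx))
            if idx > mirror:
                out[idx] = 0.0
                out_mask[idx] = True
    return JSFS3(out, folded=True, mask=out_mask, pop_order=jsfs.pop_order)


def _projection_matrix(n: int, m: int) -> np.ndarray:
    """(m+1, n+1) hypergeometric down-projection weights."""
    P = np.zeros((m + 1, n + 1))
    for i in range(n + 1):
        P[:, i] = hypergeom.pmf(np.arange(m + 1), n, i, m)
    return P


def project(jsfs: JSFS3, target: Sequence[int]) -> JSFS3:
    """Hypergeometric down-projection to smaller sample sizes.

    Applied independently per axis; mass landing in the newly fixed cells
    remains in the array but is masked.
    """
    if jsfs.folded:
        raise ValueError("project operates on unfolded spectra; fold afterwards")
    n = jsfs.n_haploid
    target = tuple(int(m) for m in target)
    if len(target) != 3:
        raise ValueError("target must have three entries")
    for d, (m, nd) in enumerate(zip(target, n)):
        if m > nd:
            raise ValueError(f"cannot project axis {d} from {nd} up to {m}")
        if m < 1:
            raise ValueError("target sizes must be >= 1")
    if target == n:
        return jsfs.copy()
    out = jsfs.counts
    for axis, (m, nd) in enumerate(zip(target, n)):
        P = _projection_matrix(nd, m)
        out = np.tensordot(P, out, axes=(1, axis))
        out = np.moveaxis(out, 0, axis)
    return JSFS3(out, folded=False, pop_order=jsfs.pop_order)


def build_jsfs(genotypes: pd.DataFrame, pop_map: dict, *,
               fold_spectrum: bool = False, one_per_locus: bool = False,
               ploidy: int = 1, project_to: Optional[Sequence[int]] = None,
               pop_order: Sequence[str] = ("DST", "STH", "PLN")) -> JSFS3:
    """Build the 3D joint SFS from a genotype table.

    ``genotypes`` has columns ``locus``, ``pos`` and one allele-dosage
    column per sample (0..ploidy, NaN for missing).  ``pop_map`` assigns
    every sample column to a population.  With ``one_per_locus`` only the
    first SNP of each locus (in position order) is retained, minimising
    linkage.  Missing data are handled by hypergeometric projection to
    ``project_to`` haploid sizes (sites unprojectable at those sizes are
    dropped and logged); without ``project_to``, sites with missing calls
    are dropped.
    """
    sample_cols = [c for c in genotypes.columns if c not in ("locus", "pos")]
    missing = [c for c in sample_cols if c not in pop_map]
    if missing:
        raise KeyError(f"samples missing from pop_map: {missing}")
    pop_order = tuple(pop_order)
    pops = {p: [c for c in sample_cols if pop_map[c] == p] for p in pop_order}
    n_full = tuple(ploidy * len(pops[p]) for p in pop_order)
    for p, cols in pops.items():
        if not cols:
            raise ValueError(f"no samples assigned to population {p!r}")

    df = genotypes.sort_values(["locus", "pos"], kind="stable")
    if one_per_locus:
        df = df.groupby("locus", sort=False).head(1)

    shape = tuple(m + 1 for m in (project_to if project_to is not None else n_full))
    counts = np.zeros(shape)
    mat = df[sample_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    called = ~np.isnan(mat)
    with np.errstate(invalid="ignore"):
        invalid = called & ((mat < 0) | (mat > ploidy) | (mat != np.round(mat)))
    bad_rows = invalid.any(axis=1)
    if bad_rows.any():
        logger.warning("skipping %d non-biallelic/invalid sites",
                       int(bad_rows.sum()))
    col_idx = {c: i for i, c in enumerate(sample_cols)}
    pop_cols = [np.array([col_idx[c] for c in pops[p]]) for p in pop_order]
    derived = np.stack(
        [np.nansum(mat[:, ix], axis=1).astype(int) for ix in pop_cols], axis=1)
    avail = np.stack(
        [called[:, ix].sum(axis=1) * ploidy for ix in pop_cols], axis=1)
    n_dropped = 0
    if project_to is None:
        ok = ~bad_rows & np.all(avail == np.array(n_full), axis=1)
        n_dropped = int((~ok & ~bad_rows).sum())
        np.add.at(counts, tuple(derived[ok].T), 1.0)
    else:
        target = np.array(project_to, dtype=int)
        ok = ~bad_rows & np.all(avail >= target, axis=1)
        n_dropped = int((~ok & ~bad_rows).sum())
        for r in np.flatnonzero(ok):
            vecs = [hypergeom.pmf(np.arange(m + 1), a, d, m)
                    for a, d, m in zip(avail[r], derived[r], target)]
            counts += np.einsum("i,j,k->ijk", *vecs)
    if n_dropped:
        logger.info("dropped %d sites under the missing-data policy", n_dropped)
    jsfs = JSFS3(counts, folded=False, pop_order=pop_order)
    return fold(jsfs) if fold_spectrum else jsfs


def classify_sites(alignment) -> SiteClassCounts:
    """Classify alignment columns: invariant, variable-but-parsimony-
    uninformative, or parsimony informative (>=2 states each in >=2
    sequences).  Gaps and ambiguity codes are ignored within a column."""
    seqs = _as_sequences(alignment)
    if not seqs:
        raise ValueError("empty alignment")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("ragged alignment: sequences differ in length")
    n_inv = n_var = n_pi = 0
    valid = set("ACGT")
    for col in range(length):
        states: dict = {}
        for s in seqs:
            c = s[col].upper()
            if c in valid:
                states[c] = states.get(c, 0) + 1
        if len(states) <= 1:
            n_inv += 1
        elif sum(1 for v in states.values() if v >= 2) >= 2:
            n_pi += 1
        else:
            n_var += 1
    return SiteClassCounts(n_invariant=n_inv, n_variable_uninformative=n_var,
                           n_parsimony_informative=n_pi)


def _as_sequences(alignment) -> list:
    out = []
    for rec in alignment:
        if isinstance(rec, str):
            out.append(rec)
        elif isinstance(rec, (tuple, list)) and len(rec) == 2:
            out.append(str(rec[1]))
        else:  # Bio.SeqRecord or anything with .seq
            out.append(str(getattr(rec, "seq", rec)))
    return out


def count_quartets(n_taxa: int) -> int:
    """Number of 4-taxon subsets, C(n_taxa, 4)."""
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa to form a quartet")
    return math.comb(int(n_taxa), 4)


def write_sfs(jsfs: JSFS3, path) -> None:
    """Write the dadi/moments SFS text dialect (dims + folding header with
    quoted population ids, flattened counts, then a 0/1 mask line)."""
    dims = " ".join(str(s) for s in jsfs.counts.shape)
    names = " ".join(f'"{p}"' for p in jsfs.pop_order)
    state = "folded" if jsfs.folded else "unfolded"
    with open(path, "w") as fh:
        fh.write(f"{dims} {state} {names}\n")
        fh.write(" ".join(repr(float(x)) for x in jsfs.counts.ravel()) + "\n")
        fh.write(" ".join("1" if m else "0" for m in jsfs.mask.ravel()) + "\n")


def read_sfs(path) -> JSFS3:
    """Read the dialect written by :func:`write_sfs` (dadi-compatible)."""
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise SFSParseError("empty file", line=1)
    header = lines[0]
    m = re.match(r"\s*(\d+)\s+(\d+)\s+(\d+)\s+(folded|unfolded)\s*(.*)$", header)
    if not m:
        raise SFSParseError(
            "header must be 'n1 n2 n3 folded|unfolded [\"pop\" ...]'", line=1)
    shape = tuple(int(m.group(i)) for i in (1, 2, 3))
    folded = m.group(4) == "folded"
    names = re.findall(r'"([^"]*)"', m.group(5))
    pop_order = tuple(names) if len(names) == 3 else ("DST", "STH", "PLN")
    size = int(np.prod(shape))
    if len(lines) < 2:
        raise SFSParseError("missing counts line", line=2)
    try:
        counts = np.array([float(x) for x in lines[1].split()])
    except ValueError as exc:
        raise SFSParseError(f"bad count value ({exc})", line=2) from None
    if counts.size != size:
        raise SFSParseError(
            f"expected {size} counts, found {counts.size}", line=2)
    mask = None
    if len(lines) > 2:
        toks = lines[2].split()
        if len(toks) != size:
            raise SFSParseError(
                f"mask length {len(toks)} != {size}", line=3)
        if not set(toks) <= {"0", "1"}:
            raise SFSParseError("mask entries must be 0 or 1", line=3)
        mask = np.array([t == "1" for t in toks]).reshape(shape)
    try:
        return JSFS3(counts.reshape(shape), folded=folded, mask=mask,
                     pop_order=pop_order)
    except ValueError as exc:
        raise SFSParseError(str(exc), line=2) from None
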