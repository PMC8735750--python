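"""Spectrum construction, folding, projection, site classes, I/O."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refugia.sfs import (JSFS3, SFSParseError, build_jsfs, classify_sites,
                         count_quartets, fold, project, read_sfs, write_sfs)


def random_jsfs(rng, shape=(3, 3, 3)) -> JSFS3:
    return JSFS3(rng.random(shape) * 5)


# ---------------------------------------------------------------- build

def frame(rows, samples):
    return pd.DataFrame(rows, columns=["locus", "pos", *samples])


SAMPLES6 = [f"s{i}" for i in range(6)]
POPMAP6 = {f"s{i}": p for i, p in zip(range(6), ["DST"] * 2 + ["STH"] * 2 + ["PLN"] * 2)}


def test_build_monomorphic_is_empty():
    gt = frame([], SAMPLES6)
    jsfs = build_jsfs(gt, POPMAP6)
    assert jsfs.total_mass() == 0


def test_build_single_snp_lands_in_expected_cell():
    # derived counts (1, 0, 2) with 2 haploids per population
    gt = frame([["L1", 0, 1, 0, 0, 0, 1, 1]], SAMPLES6)
    jsfs = build_jsfs(gt, POPMAP6)
    assert jsfs.counts[1, 0, 2] == 1
    assert jsfs.total_mass() == 1


def test_build_one_per_locus_counts_loci():
    rows = []
    for l in range(10):
        for s in range(3):
            rows.append([f"L{l}", s, 1, 0, 0, 0, 0, 0])
    jsfs = build_jsfs(frame(rows, SAMPLES6), POPMAP6, one_per_locus=True)
    assert jsfs.total_mass() == 10


def test_build_missing_sample_in_popmap_raises():
    gt = frame([["L1", 0, 1, 0, 0, 0, 0, 0]], SAMPLES6)
    with pytest.raises(KeyError):
        build_jsfs(gt, {k: v for k, v in POPMAP6.items() if k != "s3"})


def test_build_missing_data_dropped_without_projection():
    gt = frame([["L1", 0, 1, 0, np.nan, 0, 0, 0],
                ["L1", 1, 1, 0, 0, 0, 0, 0]], SAMPLES6)
    jsfs = build_jsfs(gt, POPMAP6)
    assert jsfs.total_mass() == 1


def test_build_projection_keeps_partial_sites():
    # one missing call in STH; projectable to (2, 1, 2)
    gt = frame([["L1", 0, 1, 0, np.nan, 1, 0, 0]], SAMPLES6)
    jsfs = build_jsfs(gt, POPMAP6, project_to=(2, 1, 2))
    assert jsfs.counts.shape == (3, 2, 3)
    assert jsfs.total_mass() == pytest.approx(1.0)
    assert jsfs.counts[1, 1, 0] == pytest.approx(1.0)


# ---------------------------------------------------------------- fold

def fold_oracle(counts):
    """Independent mirror-arithmetic recount."""
    shape = counts.shape
    n = np.array(shape) - 1
    n_tot = n.sum()
    out = np.zeros(shape)
    for idx in np.ndindex(shape):
        d = sum(idx)
        mirror = tuple(n - np.array(idx))
        if 2 * d < n_tot:
            out[idx] += counts[idx]
        elif 2 * d > n_tot:
            out[mirror] += counts[idx]
        else:
            target = min(idx, mirror)
            out[target] += counts[idx] if idx != mirror else counts[idx]
            # mirror cell's mass handled when the loop reaches it
    return out


def test_fold_majority_unit_mass_moves_to_mirror():
    c = np.zeros((3, 3, 3))
    c[2, 2, 1] = 1.0  # total 5 of 6 > 3
    f = fold(JSFS3(c))
    assert f.counts[0, 0, 1] == 1.0
    assert f.counts[2, 2, 1] == 0.0
    assert f.mask[2, 2, 1]


def test_fold_conserves_mass_and_matches_oracle():
    rng = np.random.default_rng(0)
    for shape in [(3, 3, 3), (4, 3, 2), (5, 5, 5)]:
        j = random_jsfs(rng, shape)
        f = fold(j)
        expect = fold_oracle(j.counts)
        assert np.allclose(f.counts, expect)
        assert f.total_mass() == pytest.approx(
            j.counts.sum() - j.counts[0, 0, 0] - j.counts[-1, -1, -1], rel=1e-12)


def test_fold_symmetric_spectrum_doubles_lower_half():
    rng = np.random.default_rng(1)
    c = rng.random((3, 3, 3))
    sym = c + c[::-1, ::-1, ::-1]
    f = fold(JSFS3(sym))
    n_tot = 6
    for idx in np.ndindex((3, 3, 3)):
        if 2 * sum(idx) < n_tot and idx != (0, 0, 0):
            assert f.counts[idx] == pytest.approx(2 * sym[idx])


def test_fold_twice_rejected():
    f = fold(random_jsfs(np.random.default_rng(2)))
    with pytest.raises(ValueError):
        fold(f)


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 2**31 - 1),
       st.tuples(*[st.integers(2, 5)] * 3))
def test_fold_conserves_mass_property(seed, shape):
    """Folding never creates or destroys countable mass, whatever the
    spectrum's shape or contents."""
    j = random_jsfs(np.random.default_rng(seed), shape)
    f = fold(j)
    assert f.total_mass() == pytest.approx(j.total_mass(), rel=1e-12)
    assert np.all(f.counts >= 0)


# ---------------------------------------------------------------- project

def project_oracle(counts, target):
    """Exhaustive hypergeometric recount per cell (independent of the
    tensordot implementation)."""
    from math import comb

    shape = counts.shape
    n = [s - 1 for s in shape]
    out = np.zeros([m + 1 for m in target])
    for idx in np.ndindex(shape):
        w = counts[idx]
        if w == 0:
            continue
        for sub in np.ndindex(*[m + 1 for m in target]):
            p = 1.0
            for d in range(3):
                i, j, nd, md = idx[d], sub[d], n[d], target[d]
                num = comb(i, j) * comb(nd - i, md - j) if j <= i and md - j <= nd - i else 0
                p *= num / comb(nd, md)
            out[sub] += w * p
    return out


def test_project_matches_enumeration_and_identity():
    j = random_jsfs(np.random.default_rng(3), (4, 3, 3))
    p = project(j, (2, 2, 2))
    assert np.allclose(p.counts, project_oracle(j.counts, (2, 2, 2)))
    same = project(j, j.n_haploid)
    assert np.allclose(same.counts, j.counts)


def test_project_fixed_allele_stays_fixed():
    c = np.zeros((3, 3, 3))
    c[2, 0, 0] = 1.0  # fixed in pop 1
    p = project(JSFS3(c), (1, 2, 2))
    assert p.counts[1, 0, 0] == pytest.approx(1.0)


def test_project_up_rejected():
    with pytest.raises(ValueError):
        project(random_jsfs(np.random.default_rng(4)), (3, 2, 2))


def test_project_folded_rejected():
    f = fold(random_jsfs(np.random.default_rng(5)))
    with pytest.raises(ValueError):
        project(f, (1, 1, 1))


def test_project_one_population_law():
    # theta-scaled 1/i law at n=4 projected to n=2 keeps the law's ratios
    c = np.zeros((5, 2, 2))
    for i in range(1, 4):
        c[i, 0, 0] = 1.0 / i
    p = project(JSFS3(c), (2, 1, 1))
    # direct law at n=2: singleton 1, "doubleton" cell is fixed (masked)
    expect = project_oracle(c, (2, 1, 1))
    assert np.allclose(p.counts, expect)
    assert p.counts[1, 0, 0] == pytest.approx(expect[1, 0, 0])


# ------------------------------------------------------- site classes

def classify_oracle(seqs):
    inv = var = pi = 0
    for col in zip(*seqs):
        states = {}
        for c in col:
            if c.upper() in "ACGT":
                states[c.upper()] = states.get(c.upper(), 0) + 1
        if len(states) <= 1:
            inv += 1
        elif sum(1 for v in states.values() if v >= 2) >= 2:
            pi += 1
        else:
            var += 1
    return inv, var, pi


@pytest.mark.parametrize("col,expect", [
    ("AAAA", "invariant"), ("AAAT", "variable"), ("AATT", "informative"),
    ("AA-T", "variable"), ("A-N-", "invariant"), ("ACGT", "variable"),
    ("AACC", "informative"),
])
def test_classify_single_columns(col, expect):
    counts = classify_sites(list(col))
    got = {"invariant": counts.n_invariant,
           "variable": counts.n_variable_uninformative,
           "informative": counts.n_parsimony_informative}
    assert got[expect] == 1 and counts.total == 1


def test_classify_random_alignments_match_oracle():
    rng = np.random.default_rng(6)
    for n_seq in (2, 5, 12):
        seqs = ["".join(rng.choice(list("ACGT-N"), 40)) for _ in range(n_seq)]
        c = classify_sites(seqs)
        assert (c.n_invariant, c.n_variable_uninformative,
                c.n_parsimony_informative) == classify_oracle(seqs)
        assert c.total == 40


def test_classify_ragged_rejected():
    with pytest.raises(ValueError):
        classify_sites(["ACGT", "ACG"])


# ---------------------------------------------------------- quartets

def test_count_quartets_against_enumeration():
    for n in range(4, 13):
        brute = sum(1 for _ in itertools.combinations(range(n), 4))
        assert count_quartets(n) == brute
    assert count_quartets(4) == 1
    assert count_quartets(10) == 210


def test_count_quartets_reported_total():
    assert count_quartets(74) == 1_150_626


def test_count_quartets_too_few_taxa():
    with pytest.raises(ValueError):
        count_quartets(3)


# ---------------------------------------------------------------- I/O

@pytest.mark.parametrize("seed,folded", [(s, f) for s in range(10)
                                         for f in (False, True)])
def test_sfs_roundtrip(seed, folded, tmp_path):
    rng = np.random.default_rng(seed)
    j = random_jsfs(rng, (3, 4, 3))
    if folded:
        j = fold(j)
    path = tmp_path / "spec.fs"
    write_sfs(j, path)
    back = read_sfs(path)
    assert back == j


def test_read_sfs_folded_with_majority_mass_rejected(tmp_path):
    path = tmp_path / "bad.fs"
    counts = " ".join(["1.0"] * 27)
    path.write_text(f'3 3 3 folded "DST" "STH" "PLN"\n{counts}\n')
    with pytest.raises(SFSParseError):
        read_sfs(path)


def test_read_sfs_short_mask_rejected(tmp_path):
    path = tmp_path / "bad.fs"
    counts = " ".join(["0.0"] * 27)
    path.write_text(f"3 3 3 unfolded\n{counts}\n0 1\n")
    with pytest.raises(SFSParseError) as err:
        read_sfs(path)
    assert err.value.line == 3


def test_read_sfs_bad_header_rejected(tmp_path):
    path = tmp_path / "bad.fs"
    path.write_text("3 3 spam\n")
    with pytest.raises(SFSParseError):
        read_sfs(path)
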