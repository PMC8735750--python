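"""Readers for the external formats the toolkit consumes.

Genotype tables arrive either as the documented TSV dialect (columns
``locus``, ``pos``, then one allele-dosage column per sample; ``.`` for
missing) or as VCF (biallelic SNPs; CHROM is the locus id; the ancestral
allele is taken from the AA INFO field when present, else REF).  Locus
alignments are FASTA.  Population maps are two-column TSV
(sample, population).
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = ["read_genotype_tsv", "read_vcf", "read_popmap",
           "read_fasta_alignment"]


def read_genotype_tsv(path) -> pd.DataFrame:
    """Read the genotype TSV dialect; missing calls become NaN."""
    df = pd.read_csv(path, sep="\t", dtype={"locus": str})
    required = {"locus", "pos"}
    if not required <= set(df.columns):
        raise ValueError(f"genotype TSV must have columns {sorted(required)}")
    sample_cols = [c for c in df.columns if c not in required]
    df[sample_cols] = df[sample_cols].replace(".", np.nan).apply(
        pd.to_numeric, errors="coerce")
    return df


def read_popmap(path) -> dict:
    """sample -> population from two-column (whitespace or tab) text."""
    out = {}
    with open(path) as fh:
        for ln in fh:
            parts = ln.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 2:
                raise ValueError(f"popmap line lacks a population: {ln!r}")
            out[parts[0]] = parts[1]
    return out


def read_vcf(path, *, max_records: Optional[int] = None) -> pd.DataFrame:
    """Biallelic SNPs from a VCF as a genotype table.

    Returns the same long-format frame as :func:`read_genotype_tsv`, with
    diploid dosages 0/1/2 (use ``ploidy=2`` in ``build_jsfs``).  CHROM is
    used as the locus id and positions are converted to 0-based.  Sites
    whose AA INFO tag matches ALT are polarity-flipped so dosages always
    count the derived allele; non-biallelic or non-SNP records are
    skipped with a log message.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    n_skipped = 0
    for i, var in enumerate(vcf):
        if max_records is not None and i >= max_records:
            break
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        dosage = np.array([
            np.nan if g[0] < 0 else float(g[0] + g[1]) for g in var.genotypes
        ])
        aa = (var.INFO.get("AA") or "").upper()
        if aa and aa == var.ALT[0].upper():
            dosage = 2.0 - dosage
        rows.append([var.CHROM, var.POS - 1, *dosage])
    if n_skipped:
        logger.warning("skipped %d non-biallelic/non-SNP records", n_skipped)
    return pd.DataFrame(rows, columns=["locus", "pos", *samples])


def read_fasta_alignment(path) -> list:
    """(id, sequence) pairs from a FASTA alignment."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
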