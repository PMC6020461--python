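"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from m5ctopo.formats_io import CytosineSiteRecord, TranscriptModel


def fisher_one_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive hypergeometric upper tail for table [[a,b],[c,d]].

    Enumerates every table with the same margins and sums the exact
    probabilities of tables whose first cell is >= a (alternative: first
    row's odds greater).
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)
    num = sum(
        comb(r1, k) * comb(n - r1, c1 - k)
        for k in range(a, min(r1, c1) + 1)
        if c1 - k >= 0
    )
    return float(Fraction(num, denom))


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive two-sided Fisher p: sum of all same-margin tables whose
    exact probability does not exceed the observed table's (exact integer
    comparison, so ties are included without float hazards)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    nums = {k: comb(r1, k) * comb(n - r1, c1 - k) for k in range(lo, hi + 1)}
    obs = nums[a]
    return float(Fraction(sum(v for v in nums.values() if v <= obs), denom))


def make_site(
    chrom="chr1", pos=100, strand="+", n_meth=0, n_unmeth=10, context="ACA", **kw
) -> CytosineSiteRecord:
    return CytosineSiteRecord(
        chrom=chrom, pos=pos, strand=strand, n_meth=n_meth, n_unmeth=n_unmeth,
        context=context, **kw,
    )


def single_exon_tx(
    tx_id="t1", gene_id=None, chrom="chr1", strand="+", start=0, length=300,
    cds=(100, 250),
) -> TranscriptModel:
    return TranscriptModel(
        tx_id=tx_id,
        gene_id=gene_id or tx_id,
        chrom=chrom,
        strand=strand,
        exons=((start, start + length),),
        cds_start=None if cds is None else cds[0],
        cds_end=None if cds is None else cds[1],
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One seeded synthetic study shared by read-only tests."""
    from m5ctopo.synthetic_data import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(n_genes=40, seed=123, n_replicates=2)
    return cfg, simulate_dataset(cfg)
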