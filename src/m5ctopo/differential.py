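"""Site-level differential methylation between two conditions.

The methylation fold change at a site is the odds ratio

    OR = (n_meth_1 / n_unmeth_1) / (n_meth_2 / n_unmeth_2)

(> 1: hypermethylated in condition 1), with the Haldane-Anscombe +0.5
correction on all four cells whenever any cell is zero.  Significance is a
two-sided Fisher's exact test on the pooled 2x2 table; genes are classified
hyper / hypo / mixed by the directions of their significant sites, and the
region placement of hypermethylated sites is quantified by reusing the
enrichment machinery with hyper sites as the foreground and all
differentially methylated sites as the background.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .formats_io import TranscriptModel, ValidationError
from .site_calling import DEFAULT_MIN_COVERAGE, bh_adjust
from .topology import EnrichmentResult, TranscriptIndex, assign_region, enrichment_or

__all__ = [
    "DifferentialResult",
    "diff_or",
    "diff_test",
    "differential_sites",
    "classify_genes",
    "hyper_region_enrichment",
]


@dataclass(frozen=True)
class DifferentialResult:
    chrom: str
    pos: int
    strand: str
    counts_1: tuple[int, int]  # (n_meth, n_unmeth) condition 1
    counts_2: tuple[int, int]
    odds_ratio: float
    corrected: bool  # Haldane-Anscombe engaged
    pvalue: float
    fdr: float
    gene_id: str = ""

    @property
    def direction(self) -> str:
        return "hyper" if self.odds_ratio > 1 else "hypo"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


def diff_or(c1: tuple[int, int], c2: tuple[int, int]) -> tuple[float, bool]:
    """Methylation-fold-change odds ratio of condition 1 over condition 2.

    Returns (odds ratio, whether the +0.5 correction was engaged).  The
    correction is applied to all four cells only when some cell is zero.
    """
    (m1, u1), (m2, u2) = c1, c2
    if min(m1, u1, m2, u2) < 0:
        raise ValidationError("counts must be non-negative")
    if m1 + u1 == 0 or m2 + u2 == 0:
        raise ValidationError("zero coverage in one condition")
    if min(m1, u1, m2, u2) == 0:
        return ((m1 + 0.5) / (u1 + 0.5)) / ((m2 + 0.5) / (u2 + 0.5)), True
    return (m1 / u1) / (m2 / u2), False


def diff_test(c1: tuple[int, int], c2: tuple[int, int]) -> float:
    """Two-sided Fisher's exact p for unequal methylation odds."""
    (m1, u1), (m2, u2) = c1, c2
    if m1 + u1 == 0 or m2 + u2 == 0:
        raise ValidationError("zero coverage in one condition")
    return float(stats.fisher_exact([[m1, u1], [m2, u2]], alternative="two-sided")[1])


def differential_sites(
    cond1: Mapping[tuple[str, int, str], tuple[int, int]],
    cond2: Mapping[tuple[str, int, str], tuple[int, int]],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    alpha: float = 0.05,
    use_fdr: bool = False,
    gene_of: Mapping[tuple[str, int, str], str] | None = None,
) -> list[DifferentialResult]:
    """Test every site covered >= ``min_coverage`` in both conditions.

    Inputs map (chrom, pos, strand) to pooled (n_meth, n_unmeth) per
    condition (replicate counts summed beforehand).  Significance is
    ``p < alpha`` unadjusted by default, or ``FDR < alpha`` with
    ``use_fdr``; only significant sites are returned.
    """
    keys = sorted(set(cond1) & set(cond2))
    keys = [
        k
        for k in keys
        if sum(cond1[k]) >= min_coverage and sum(cond2[k]) >= min_coverage
    ]
    if not keys:
        return []
    pvals = np.array([diff_test(cond1[k], cond2[k]) for k in keys])
    fdrs = bh_adjust(np.clip(pvals, np.nextafter(0.0, 1.0), 1.0))
    out = []
    for k, p, f in zip(keys, pvals, fdrs):
        crit = f if use_fdr else p
        if crit >= alpha:
            continue
        orr, corrected = diff_or(cond1[k], cond2[k])
        out.append(
            DifferentialResult(
                chrom=k[0],
                pos=k[1],
                strand=k[2],
                counts_1=tuple(cond1[k]),
                counts_2=tuple(cond2[k]),
                odds_ratio=float(orr),
                corrected=corrected,
                pvalue=float(p),
                fdr=float(f),
                gene_id=gene_of.get(k, "") if gene_of else "",
            )
        )
    return out


def classify_genes(dms: Sequence[DifferentialResult]) -> dict[str, str]:
    """Per-gene direction: hyper if all DMS hyper, hypo if all hypo, else mixed."""
    by_gene: dict[str, set[str]] = defaultdict(set)
    for d in dms:
        if not d.gene_id:
            continue
        by_gene[d.gene_id].add(d.direction)
    return {
        g: ("mixed" if len(dirs) > 1 else next(iter(dirs)))
        for g, dirs in by_gene.items()
    }


def hyper_region_enrichment(
    dms: Sequence[DifferentialResult],
    transcripts: Sequence[TranscriptModel],
    regions: Sequence[str] = ("5UTR", "CDS", "3UTR"),
) -> list[EnrichmentResult]:
    """Per-region enrichment of hypermethylated sites among all DMS."""
    index = TranscriptIndex(transcripts)
    hyper_by: dict[str, float] = defaultdict(float)
    all_by: dict[str, float] = defaultdict(float)
    for d in dms:
        try:
            weights = assign_region(d.chrom, d.pos, index)
        except ValueError:
            continue
        for reg, w in weights.items():
            all_by[reg] += w
            if d.direction == "hyper":
                hyper_by[reg] += w
    k_total = sum(hyper_by.get(r, 0.0) for r in regions)
    n_total = sum(all_by.get(r, 0.0) for r in regions)
    return [
        enrichment_or(hyper_by.get(r, 0.0), all_by.get(r, 0.0), k_total, n_total, stratum=r)
        for r in regions
        if all_by.get(r, 0.0) > 0
    ]
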