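"""Where methylated cytosines sit: regions, chromosomes, contexts, metagene.

Enrichment within a stratum is quantified as

    OR = (m5C sites in stratum / covered C sites in stratum)
         / (total m5C sites / total covered C sites)

with the *covered cytosines*, not all nucleotides, as the denominator, and a
two-sided Fisher's exact test for significance.  Site-to-region assignment
splits each site's unit weight evenly across all (isoform, region)
associations at its position, so isoform information is retained instead of
collapsing to a primary transcript.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import CytosineSiteRecord, TranscriptModel
from .site_calling import CallResult

__all__ = [
    "EnrichmentResult",
    "TranscriptIndex",
    "assign_region",
    "enrichment_or",
    "region_enrichment",
    "chromosome_enrichment",
    "context_table",
    "context_proportion_correlation",
    "metagene_profile",
    "conserved_locus_association",
    "MRNA_REGIONS",
]

MRNA_REGIONS = ("5UTR", "CDS", "3UTR")

#: The 16 C-centred trinucleotides.
CONTEXTS = tuple(a + "C" + b for a in "ACGT" for b in "ACGT")


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 enrichment of one stratum against the transcriptome-wide rate.

    ``odds_ratio`` is the stratum rate over the *total* rate (the headline
    definition); ``rr_in_out`` is the in-stratum vs out-of-stratum rate
    ratio, the estimator that targets a simulated in/out enrichment factor,
    with its Katz log-scale 95% CI in ``(ci95_lo, ci95_hi)``; ``or_in_out``
    is the corresponding 2x2 sample odds ratio.  Both interval and odds
    ratio assume independently placed sites.
    """

    stratum: str
    k_in: float  # m5C sites in stratum (may carry isoform weights)
    n_in: float  # covered C sites in stratum
    k_total: float
    n_total: float
    odds_ratio: float
    pvalue: float
    rr_in_out: float = float("nan")
    or_in_out: float = float("nan")
    ci95_lo: float = float("nan")
    ci95_hi: float = float("nan")


class TranscriptIndex:
    """Point-query index over transcript exons (1-based query positions)."""

    def __init__(self, transcripts: Sequence[TranscriptModel]):
        from intervaltree import IntervalTree

        self.transcripts = list(transcripts)
        self._trees: dict[str, IntervalTree] = {}
        for t in transcripts:
            tree = self._trees.setdefault(t.chrom, IntervalTree())
            for s, e in t.exons:
                tree.addi(s, e, t)

    def transcripts_at(self, chrom: str, pos1: int) -> list[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = {id(iv.data): iv.data for iv in tree.at(pos1 - 1)}
        return sorted(hits.values(), key=lambda t: t.tx_id)


def assign_region(
    chrom: str,
    pos1: int,
    index: TranscriptIndex,
) -> dict[str, float]:
    """Weighted region labels at one exonic position.

    Unit weight is split evenly across every (transcript, region) assignment;
    the returned per-region weights sum to 1.  Non-exonic positions (which
    should have been filtered) raise ``ValueError``.
    """
    hits = index.transcripts_at(chrom, pos1)
    if not hits:
        raise ValueError(f"position {chrom}:{pos1} is not exonic in the annotation")
    labels = [t.region_of(pos1) for t in hits]
    w = 1.0 / len(labels)
    out: dict[str, float] = defaultdict(float)
    for lab in labels:
        out[lab] += w
    return dict(out)


def enrichment_or(
    k_in: float, n_in: float, k_total: float, n_total: float, stratum: str = ""
) -> EnrichmentResult:
    """Enrichment ratio of the stratum's m5C-per-C rate over the global rate.

    The Fisher test runs on the integer-rounded 2x2
    ``[[k_in, n_in - k_in], [k_total - k_in, (n_total - n_in) - (k_total - k_in)]]``.
    Zero denominators get a 0.5 continuity correction on the rate estimate,
    with a warning.
    """
    if not (k_in <= k_total and n_in <= n_total and k_in <= n_in and k_total <= n_total):
        raise ValueError(
            f"inconsistent counts k_in={k_in} n_in={n_in} k_total={k_total} n_total={n_total}"
        )
    if n_in > 0 and k_total > 0 and n_total > 0:
        odds = (k_in / n_in) / (k_total / n_total)
    else:
        warnings.warn("zero denominator in enrichment; continuity-corrected estimate")
        odds = ((k_in + 0.5) / (n_in + 0.5)) / ((k_total + 0.5) / (n_total + 0.5))
    a = int(round(k_in))
    b = int(round(n_in)) - a
    c = int(round(k_total)) - a
    d = (int(round(n_total)) - int(round(n_in))) - c
    if min(a, b, c, d) < 0:
        pvalue = rr = or22 = lo = hi = float("nan")
    else:
        _, pvalue = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        aa, bb, cc, dd = (
            (a, b, c, d) if min(a, b, c, d) > 0 else (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
        )
        m_in, m_out = aa + bb, cc + dd
        rr = (aa / m_in) / (cc / m_out)
        or22 = (aa * dd) / (bb * cc)
        # Katz log-interval for the rate ratio
        half = 1.959963984540054 * np.sqrt(1 / aa - 1 / m_in + 1 / cc - 1 / m_out)
        lo, hi = rr * np.exp(-half), rr * np.exp(half)
    return EnrichmentResult(
        stratum=stratum,
        k_in=k_in,
        n_in=n_in,
        k_total=k_total,
        n_total=n_total,
        odds_ratio=float(odds),
        pvalue=float(pvalue),
        rr_in_out=float(rr),
        or_in_out=float(or22),
        ci95_lo=float(lo),
        ci95_hi=float(hi),
    )


def _weighted_region_counts(
    results: Iterable[CallResult], index: TranscriptIndex
) -> dict[str, float]:
    counts: dict[str, float] = defaultdict(float)
    for r in results:
        try:
            weights = assign_region(r.site.chrom, r.site.pos, index)
        except ValueError:
            continue  # off-annotation (e.g. mitochondrial without models)
        for lab, w in weights.items():
            counts[lab] += w
    return counts


def region_enrichment(
    results: Sequence[CallResult],
    transcripts: Sequence[TranscriptModel],
    regions: Sequence[str] = MRNA_REGIONS,
) -> list[EnrichmentResult]:
    """Per-region enrichment of called sites among all covered cytosines."""
    index = TranscriptIndex(transcripts)
    called = [r for r in results if r.called]
    k_by = _weighted_region_counts(called, index)
    n_by = _weighted_region_counts(results, index)
    k_total = sum(k_by.get(reg, 0.0) for reg in regions)
    n_total = sum(n_by.get(reg, 0.0) for reg in regions)
    return [
        enrichment_or(
            k_by.get(reg, 0.0), n_by.get(reg, 0.0), k_total, n_total, stratum=reg
        )
        for reg in regions
    ]


def chromosome_enrichment(results: Sequence[CallResult]) -> list[EnrichmentResult]:
    """Per-chromosome enrichment of called sites among covered cytosines."""
    k_by: dict[str, int] = defaultdict(int)
    n_by: dict[str, int] = defaultdict(int)
    for r in results:
        n_by[r.site.chrom] += 1
        if r.called:
            k_by[r.site.chrom] += 1
    k_total = sum(k_by.values())
    n_total = sum(n_by.values())
    return [
        enrichment_or(k_by.get(c, 0), n_by[c], k_total, n_total, stratum=c)
        for c in sorted(n_by)
    ]


def context_table(results: Sequence[CallResult]) -> pd.DataFrame:
    """Per-trinucleotide proportions of called sites and context enrichment.

    Returns one row per context with the proportion of called sites, the
    background proportion of covered cytosines, and the enrichment OR with
    its Fisher p.  Contexts containing 'N' are bucketed under ``NCN``.
    """
    def bucket(ctx: str) -> str:
        return ctx if ctx in CONTEXTS else "NCN"

    k_by: dict[str, int] = defaultdict(int)
    n_by: dict[str, int] = defaultdict(int)
    for r in results:
        c = bucket(r.site.context)
        n_by[c] += 1
        if r.called:
            k_by[c] += 1
    k_total = sum(k_by.values())
    n_total = sum(n_by.values())
    rows = []
    for ctx in list(CONTEXTS) + (["NCN"] if "NCN" in n_by else []):
        k, n = k_by.get(ctx, 0), n_by.get(ctx, 0)
        er = enrichment_or(k, n, k_total, n_total, stratum=ctx) if n else None
        rows.append(
            {
                "context": ctx,
                "n_called": k,
                "n_covered": n,
                "prop_called": k / k_total if k_total else 0.0,
                "prop_covered": n / n_total if n_total else 0.0,
                "odds_ratio": er.odds_ratio if er else float("nan"),
                "pvalue": er.pvalue if er else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def context_proportion_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame) -> float:
    """Pearson correlation of the 16 per-context called proportions."""
    a = table_a.set_index("context").loc[list(CONTEXTS), "prop_called"]
    b = table_b.set_index("context").loc[list(CONTEXTS), "prop_called"]
    return float(np.corrcoef(a, b)[0, 1])


def metagene_profile(
    results: Sequence[CallResult],
    transcripts: Sequence[TranscriptModel],
    min_region_len: int = 100,
    n_bins: int = 150,
) -> pd.DataFrame:
    """Site density along the scaled tripartite mRNA axis [0, 3).

    Only transcripts whose 5'UTR, CDS and 3'UTR each exceed
    ``min_region_len`` are used.  A site on region ``u`` (0 = 5'UTR,
    1 = CDS, 2 = 3'UTR) at fractional offset ``f`` (5'->3' in transcript
    orientation) maps to coordinate ``u + f``; isoform-ambiguous sites
    contribute evenly split weight.  Returns per-bin masses for called and
    non-called sites, each normalised to total 1.
    """
    eligible = [
        t
        for t in transcripts
        if t.is_coding and all(v > min_region_len for v in t.region_lengths().values())
    ]
    if not eligible:
        raise ValueError("no transcript has all three regions above the minimum length")
    index = TranscriptIndex(eligible)
    edges = np.linspace(0.0, 3.0, n_bins + 1)
    hists = {True: np.zeros(n_bins), False: np.zeros(n_bins)}
    region_order = {"5UTR": 0, "CDS": 1, "3UTR": 2}
    for r in results:
        hits = index.transcripts_at(r.site.chrom, r.site.pos)
        coords = []
        for t in hits:
            reg = t.region_of(r.site.pos)
            if reg not in region_order:
                continue
            toff = t.genomic_to_transcript(r.site.pos)
            lens = t.region_lengths()
            starts = {
                "5UTR": 0,
                "CDS": lens["5UTR"],
                "3UTR": lens["5UTR"] + lens["CDS"],
            }
            f = (toff - starts[reg]) / lens[reg]
            coords.append(region_order[reg] + f)
        if not coords:
            continue
        w = 1.0 / len(coords)
        for x in coords:
            b = min(n_bins - 1, int(x / 3.0 * n_bins))
            hists[r.called][b] += w
    for key, h in hists.items():
        total = h.sum()
        if total > 0:
            hists[key] = h / total
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "weight_called": hists[True],
            "weight_background": hists[False],
        }
    )


@dataclass(frozen=True)
class AssociationResult:
    """Cross-sample called/not-called contingency at conserved loci."""

    stratum: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    pvalue: float
    n_loci: int
    n_unmapped: int


def conserved_locus_association(
    calls_a: Sequence[CallResult],
    calls_b: Sequence[CallResult],
    mapping: pd.DataFrame,
    transcripts_a: Sequence[TranscriptModel] | None = None,
) -> dict[str, AssociationResult]:
    """Fisher association of methylation calls across two samples.

    ``mapping`` pairs loci between samples (columns ``chrom_a, pos_a,
    strand_a, chrom_b, pos_b, strand_b``, e.g. a liftOver product or an
    identity map).  Loci absent from either call set are skipped and
    counted.  When ``transcripts_a`` is given the table is additionally
    stratified by the sample-A mRNA region.
    """
    a_by = {r.key: r for r in calls_a}
    b_by = {r.key: r for r in calls_b}
    index = TranscriptIndex(transcripts_a) if transcripts_a is not None else None
    tables: dict[str, np.ndarray] = defaultdict(lambda: np.zeros((2, 2), dtype=int))
    unmapped = 0
    for row in mapping.itertuples():
        ka = (row.chrom_a, int(row.pos_a), row.strand_a)
        kb = (row.chrom_b, int(row.pos_b), row.strand_b)
        if ka not in a_by or kb not in b_by:
            unmapped += 1
            continue
        ca, cb = a_by[ka].called, b_by[kb].called
        strata = ["all"]
        if index is not None:
            try:
                strata += list(assign_region(ka[0], ka[1], index))
            except ValueError:
                pass
        for s in strata:
            tables[s][0 if ca else 1][0 if cb else 1] += 1
    out: dict[str, AssociationResult] = {}
    for stratum, tab in tables.items():
        orr, p = stats.fisher_exact(tab, alternative="two-sided")
        out[stratum] = AssociationResult(
            stratum=stratum,
            table=((int(tab[0, 0]), int(tab[0, 1])), (int(tab[1, 0]), int(tab[1, 1]))),
            odds_ratio=float(orr),
            pvalue=float(p),
            n_loci=int(tab.sum()),
            n_unmapped=unmapped,
        )
    return out
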