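"""RNA vs DNA methylome comparison at matched genomic cytosines.

RNA and DNA sites are paired at identical (chromosome, position), with the
DNA strand required to equal the RNA site's strand (the RNA side is
intrinsically stranded, so CpG strand symmetry is not collapsed by
default).  The headline statistics are per-trinucleotide-context
correlations of the two methylation ratios — the CG-containing contexts
ACG/CCG/GCG/TCG being the strata where DNA methylation lives — and the
per-region distribution of RNA-called x DNA-called categories.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import TranscriptModel
from .site_calling import CallResult
from .topology import TranscriptIndex, assign_region, enrichment_or, EnrichmentResult

__all__ = [
    "MatchedPair",
    "match_sites",
    "context_correlation",
    "grouped_region_distribution",
    "CG_CONTEXTS",
]

CG_CONTEXTS = ("ACG", "CCG", "GCG", "TCG")


@dataclass(frozen=True)
class MatchedPair:
    chrom: str
    pos: int
    strand: str
    context: str
    rna: CallResult
    dna: CallResult


def match_sites(
    rna: Sequence[CallResult],
    dna: Sequence[CallResult],
    merge_cpg_strands: bool = False,
) -> tuple[list[MatchedPair], dict[str, int]]:
    """Pair RNA and DNA records by (chrom, pos), matching the RNA strand.

    With ``merge_cpg_strands`` the two DNA strands of a CpG are summed into
    one symmetric record before matching (sensitivity analysis only).
    Duplicate (chrom, pos, strand) keys within one input raise ``ValueError``.
    Returns the pairs and a log of unmatched counts.
    """
    def keyed(results: Sequence[CallResult], label: str) -> dict:
        out = {}
        for r in results:
            if r.key in out:
                raise ValueError(f"duplicate {label} site {r.key}")
            out[r.key] = r
        return out

    rna_by = keyed(rna, "RNA")
    dna_by = keyed(dna, "DNA")
    if merge_cpg_strands:
        dna_by = _merge_cpg(dna_by)
    pairs: list[MatchedPair] = []
    for key, r in sorted(rna_by.items()):
        chrom, pos, strand = key
        d = dna_by.get((chrom, pos, strand))
        if d is None:
            continue
        pairs.append(
            MatchedPair(chrom=chrom, pos=pos, strand=strand, context=r.site.context, rna=r, dna=d)
        )
    log = {
        "n_pairs": len(pairs),
        "n_rna_unmatched": len(rna_by) - len(pairs),
        "n_dna_unmatched": len(dna_by) - len(pairs),
    }
    return pairs, log


def _merge_cpg(dna_by: dict) -> dict:
    """Sum CpG counts across strands ('-' position maps to the '+' C)."""
    from dataclasses import replace
    from .site_calling import mratio as _mr

    merged: dict = {}
    for (chrom, pos, strand), r in dna_by.items():
        if r.site.context in CG_CONTEXTS and strand == "-":
            anchor = (chrom, pos - 1, "+")
        else:
            anchor = (chrom, pos, strand)
        if anchor in merged:
            prev = merged[anchor]
            nm = prev.site.n_meth + r.site.n_meth
            nu = prev.site.n_unmeth + r.site.n_unmeth
            site = replace(prev.site, n_meth=nm, n_unmeth=nu)
            merged[anchor] = CallResult(
                site=site,
                mratio=_mr(nm, nu),
                pvalue=min(prev.pvalue, r.pvalue),
                fdr=min(prev.fdr, r.fdr),
                called=prev.called or r.called,
            )
        else:
            merged[anchor] = r
    # re-key on both strands so the RNA strand rule still finds the merged record
    out = dict(merged)
    for (chrom, pos, strand), r in merged.items():
        if r.site.context in CG_CONTEXTS and strand == "+":
            out.setdefault((chrom, pos + 1, "-"), r)
    return out


def context_correlation(
    pairs: Sequence[MatchedPair],
    contexts: Sequence[str] | None = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-context Pearson and Spearman correlation of RNA vs DNA mRatios.

    Contexts with fewer than ``min_pairs`` pairs or with degenerate
    variance are reported with NaN correlations (and a warning for the
    latter).
    """
    by: dict[str, list[MatchedPair]] = defaultdict(list)
    for p in pairs:
        by[p.context].append(p)
    wanted = list(contexts) if contexts is not None else sorted(by)
    rows = []
    for ctx in wanted:
        sub = by.get(ctx, [])
        row = {
            "context": ctx,
            "n_pairs": len(sub),
            "is_cg": ctx in CG_CONTEXTS,
            "pearson_r": float("nan"),
            "pearson_p": float("nan"),
            "spearman_r": float("nan"),
            "spearman_p": float("nan"),
        }
        if len(sub) >= min_pairs:
            x = np.array([p.rna.mratio for p in sub])
            y = np.array([p.dna.mratio for p in sub])
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(f"degenerate mRatio variance in context {ctx}")
            else:
                pr = stats.pearsonr(x, y)
                sp = stats.spearmanr(x, y)
                row.update(
                    pearson_r=float(pr.statistic),
                    pearson_p=float(pr.pvalue),
                    spearman_r=float(sp.statistic),
                    spearman_p=float(sp.pvalue),
                )
        rows.append(row)
    return pd.DataFrame(rows)


def grouped_region_distribution(
    pairs: Sequence[MatchedPair],
    transcripts: Sequence[TranscriptModel],
) -> tuple[pd.DataFrame, EnrichmentResult]:
    """Per-region RNA-called x DNA-called categories with mean mRatios.

    Returns a frame with one row per (region, rna_called, dna_called)
    carrying the isoform-weighted count and group mean mRatios, plus the
    enrichment of (RNA-called, DNA-uncalled) pairs in the 5'UTR against all
    paired sites.
    """
    index = TranscriptIndex(transcripts)
    acc: dict[tuple[str, bool, bool], list] = defaultdict(lambda: [0.0, 0.0, 0.0])
    utr5_rna_only = 0.0
    utr5_all = 0.0
    total_rna_only = 0.0
    total_all = 0.0
    for p in pairs:
        try:
            weights = assign_region(p.chrom, p.pos, index)
        except ValueError:
            continue
        rna_only = p.rna.called and not p.dna.called
        for reg, w in weights.items():
            cell = acc[(reg, p.rna.called, p.dna.called)]
            cell[0] += w
            cell[1] += w * p.rna.mratio
            cell[2] += w * p.dna.mratio
            total_all += w
            if rna_only:
                total_rna_only += w
            if reg == "5UTR":
                utr5_all += w
                if rna_only:
                    utr5_rna_only += w
    rows = [
        {
            "region": reg,
            "rna_called": rc,
            "dna_called": dc,
            "weight": cell[0],
            "mean_rna_mratio": cell[1] / cell[0] if cell[0] else float("nan"),
            "mean_dna_mratio": cell[2] / cell[0] if cell[0] else float("nan"),
        }
        for (reg, rc, dc), cell in sorted(acc.items())
    ]
    er = enrichment_or(
        utr5_rna_only, utr5_all, total_rna_only, total_all, stratum="5UTR_rna_only"
    )
    return pd.DataFrame(rows), er
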