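"""False-positive filters applied before background estimation and calling.

Double-stranded RNA resists bisulfite conversion, so cytosines inside
predicted secondary-structure regions are removed; structure prediction
itself is external and consumed as a BED mask.  Intronic signal cannot be
structure-checked at scale, so sites off annotated exons are removed too —
except on the mitochondrial chromosome, which is kept wholesale.
"""

from __future__ import annotations

from typing import Sequence

from .formats_io import CytosineSiteRecord, GenomicIntervalSet, TranscriptModel

__all__ = [
    "filter_structured",
    "filter_nonexonic",
    "tile_windows",
    "project_mask_to_genomic",
    "LONG_TRANSCRIPT_THRESHOLD",
]

#: Transcripts longer than this are folded in sliding windows upstream.
LONG_TRANSCRIPT_THRESHOLD = 8000


def filter_structured(
    sites: Sequence[CytosineSiteRecord],
    mask: GenomicIntervalSet,
    stranded: bool = False,
) -> tuple[list[CytosineSiteRecord], list[CytosineSiteRecord]]:
    """Partition sites into (kept, removed) by structure-mask overlap."""
    kept: list[CytosineSiteRecord] = []
    removed: list[CytosineSiteRecord] = []
    for s in sites:
        strand = s.strand if stranded else None
        if mask.contains_point(s.chrom, s.pos, strand):
            removed.append(s)
        else:
            kept.append(s)
    return kept, removed


def filter_nonexonic(
    sites: Sequence[CytosineSiteRecord],
    transcripts: Sequence[TranscriptModel],
    mito_chrom: str = "chrM",
) -> tuple[list[CytosineSiteRecord], list[CytosineSiteRecord]]:
    """Partition sites into (kept, removed) by exon membership.

    Kept: sites on any exon of any transcript (any strand), or any site on
    the mitochondrial chromosome regardless of annotation.
    """
    exons = GenomicIntervalSet()
    for t in transcripts:
        for s0, e0 in t.exons:
            exons.add(t.chrom, s0, e0)
    kept: list[CytosineSiteRecord] = []
    removed: list[CytosineSiteRecord] = []
    for s in sites:
        if s.chrom == mito_chrom or exons.contains_point(s.chrom, s.pos):
            kept.append(s)
        else:
            removed.append(s)
    return kept, removed


def tile_windows(
    seq_length: int, window: int = 2000, step: int = 1000
) -> list[tuple[int, int]]:
    """0-based half-open sliding windows covering [0, seq_length).

    Windows start at 0 and every ``step`` thereafter; the last one is
    truncated at ``seq_length``.  This is the tiling used to fold long
    sequences piecewise upstream.
    """
    if seq_length < 1:
        raise ValueError(f"sequence length must be positive, got {seq_length}")
    if step < 1 or window < step:
        raise ValueError(f"need window >= step >= 1, got window={window} step={step}")
    out: list[tuple[int, int]] = []
    start = 0
    while True:
        end = min(start + window, seq_length)
        out.append((start, end))
        if end >= seq_length:
            break
        start += step
    return out


def project_mask_to_genomic(
    transcript_intervals: Sequence[tuple[str, int, int]],
    transcripts: Sequence[TranscriptModel],
) -> GenomicIntervalSet:
    """Project transcript-relative mask intervals onto genomic coordinates.

    ``transcript_intervals`` are (tx_id, start, end), 0-based half-open in
    transcript coordinates (5'->3').  Intervals spanning exon junctions are
    split into per-exon genomic pieces.
    """
    by_id = {t.tx_id: t for t in transcripts}
    out = GenomicIntervalSet()
    for tx_id, ts, te in transcript_intervals:
        if tx_id not in by_id:
            raise KeyError(f"unknown transcript {tx_id!r}")
        t = by_id[tx_id]
        if not (0 <= ts < te <= t.exonic_length):
            raise ValueError(
                f"interval [{ts},{te}) out of transcript {tx_id} length {t.exonic_length}"
            )
        # collect genomic 0-based positions, then merge runs
        gpos = sorted(t.transcript_to_genomic(off) - 1 for off in range(ts, te))
        run_start = prev = gpos[0]
        for p in gpos[1:]:
            if p != prev + 1:
                out.add(t.chrom, run_start, prev + 1)
                run_start = p
            prev = p
        out.add(t.chrom, run_start, prev + 1)
    return out
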