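"""Readers/writers for cytosine reports, BED12 transcript models and BED masks.

Coordinate conventions, fixed here once for the whole package:

* cytosine site positions are 1-based (the convention of per-cytosine
  methylation reports emitted by bisulfite callers);
* all interval arithmetic is 0-based half-open (the BED convention);
* conversion happens only at this I/O boundary: a BED interval ``[s, e)``
  contains 1-based position ``p`` iff ``s < p <= e``.

All readers are gzip-transparent (a ``.gz`` suffix triggers decompression).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

__all__ = [
    "CytosineSiteRecord",
    "TranscriptModel",
    "GenomicIntervalSet",
    "FormatError",
    "ValidationError",
    "read_cytosine_report",
    "write_cytosine_report",
    "read_bed12",
    "write_bed12",
    "read_interval_bed",
    "write_interval_bed",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect (names the line)."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


_VALID_STRANDS = ("+", "-")
_CONTEXT_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class CytosineSiteRecord:
    """One cytosine with its bisulfite conversion counts.

    ``n_meth`` counts unconverted (putatively methylated) reads, ``n_unmeth``
    counts converted reads.  ``context`` is the C-centred trinucleotide read
    on the sense strand of ``strand``.
    """

    chrom: str
    pos: int  # 1-based
    strand: str
    n_meth: int
    n_unmeth: int
    context: str = "NCN"
    sample_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.strand not in _VALID_STRANDS:
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValidationError(
                f"counts must be non-negative, got ({self.n_meth}, {self.n_unmeth})"
            )
        if (
            len(self.context) != 3
            or self.context[1] != "C"
            or not set(self.context) <= _CONTEXT_ALPHABET
        ):
            raise ValidationError(
                f"context must be a C-centred trinucleotide over ACGTN, got {self.context!r}"
            )

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


@dataclass(frozen=True)
class TranscriptModel:
    """BED12-style transcript: ordered exons plus optional CDS bounds.

    Exons are 0-based half-open genomic intervals, sorted and non-overlapping.
    ``cds_start``/``cds_end`` are genomic bounds (0-based half-open); both
    ``None`` for noncoding transcripts.
    """

    tx_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValidationError("transcript must have at least one exon")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValidationError(f"empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValidationError("exons must be sorted and non-overlapping")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValidationError("cds_start and cds_end must both be set or both absent")
        if self.cds_start is not None:
            if not (self.exons[0][0] <= self.cds_start <= self.cds_end <= self.exons[-1][1]):
                raise ValidationError("CDS bounds must fall inside the exon span")

    # -- derived geometry ---------------------------------------------------

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def _exonic_overlap(self, start: int, end: int) -> int:
        return sum(max(0, min(e, end) - max(s, start)) for s, e in self.exons)

    def region_lengths(self) -> dict[str, int]:
        """Exonic lengths of 5'UTR, CDS and 3'UTR in transcript orientation."""
        if not self.is_coding:
            return {"5UTR": 0, "CDS": 0, "3UTR": 0}
        left = self._exonic_overlap(self.exons[0][0], self.cds_start)
        cds = self._exonic_overlap(self.cds_start, self.cds_end)
        right = self._exonic_overlap(self.cds_end, self.exons[-1][1])
        if self.strand == "+":
            return {"5UTR": left, "CDS": cds, "3UTR": right}
        return {"5UTR": right, "CDS": cds, "3UTR": left}

    def contains(self, pos1: int) -> bool:
        """Whether 1-based genomic position ``pos1`` falls on an exon."""
        p0 = pos1 - 1
        return any(s <= p0 < e for s, e in self.exons)

    def genomic_to_transcript(self, pos1: int) -> int | None:
        """Map a 1-based genomic position to a 0-based transcript offset (5'->3')."""
        p0 = pos1 - 1
        off = 0
        for s, e in self.exons:
            if s <= p0 < e:
                fwd = off + (p0 - s)
                if self.strand == "+":
                    return fwd
                return self.exonic_length - 1 - fwd
            off += e - s
        return None

    def transcript_to_genomic(self, toff: int) -> int:
        """Map a 0-based transcript offset back to a 1-based genomic position."""
        if not (0 <= toff < self.exonic_length):
            raise ValidationError(f"transcript offset {toff} out of range")
        fwd = toff if self.strand == "+" else self.exonic_length - 1 - toff
        off = 0
        for s, e in self.exons:
            if fwd < off + (e - s):
                return s + (fwd - off) + 1
            off += e - s
        raise AssertionError("unreachable")

    def region_of(self, pos1: int) -> str | None:
        """Region label of an exonic position: 5UTR / CDS / 3UTR / ncRNA."""
        if not self.contains(pos1):
            return None
        if not self.is_coding:
            return "ncRNA"
        p0 = pos1 - 1
        if p0 < self.cds_start:
            left = True
        elif p0 >= self.cds_end:
            left = False
        else:
            return "CDS"
        if self.strand == "+":
            return "5UTR" if left else "3UTR"
        return "3UTR" if left else "5UTR"


class GenomicIntervalSet:
    """Set of genomic intervals (0-based half-open), point-queryable.

    Optionally stranded: intervals added with a strand only match queries on
    that strand; unstranded intervals match any strand.
    """

    def __init__(self) -> None:
        self._trees: dict[tuple[str, str | None], IntervalTree] = {}

    def add(self, chrom: str, start: int, end: int, strand: str | None = None) -> None:
        if start >= end:
            raise ValidationError(f"interval start must be < end, got [{start},{end})")
        self._trees.setdefault((chrom, strand), IntervalTree()).addi(start, end)

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def __iter__(self) -> Iterator[tuple[str, int, int, str | None]]:
        for (chrom, strand), tree in sorted(
            self._trees.items(), key=lambda kv: (kv[0][0], kv[0][1] or "")
        ):
            for iv in sorted(tree):
                yield chrom, iv.begin, iv.end, strand

    def contains_point(self, chrom: str, pos1: int, strand: str | None = None) -> bool:
        """Whether 1-based position ``pos1`` overlaps any interval.

        A BED interval [s, e) covers 1-based positions s+1 .. e.
        """
        p0 = pos1 - 1
        keys = [(chrom, None)]
        if strand is not None:
            keys.append((chrom, strand))
        else:
            keys.extend([(chrom, "+"), (chrom, "-")])
        return any(k in self._trees and self._trees[k].overlaps_point(p0) for k in keys)


# -- readers ----------------------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt") -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


#: Column orders of the supported cytosine-report dialects.
DIALECTS = {
    # chrom pos strand n_meth n_unmeth context  (package-native; MeRanCall-like)
    "standard": ("chrom", "pos", "strand", "n_meth", "n_unmeth", "context"),
    # Bismark cytosine report: chrom pos strand count_meth count_unmeth context-class trinucleotide
    "bismark": ("chrom", "pos", "strand", "n_meth", "n_unmeth", "_class", "context"),
}


def read_cytosine_report(
    path: str | Path,
    sample_id: str = "",
    replicate_id: str = "",
    dialect: str = "standard",
    has_context: bool = True,
) -> list[CytosineSiteRecord]:
    """Parse a per-cytosine conversion report TSV into site records.

    A header line (first field not a coordinate-bearing row) is skipped.
    Malformed lines raise :class:`FormatError` naming the line number;
    negative counts raise :class:`ValidationError`.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    cols = DIALECTS[dialect]
    min_fields = len(cols) if has_context else cols.index("n_unmeth") + 1
    records: list[CytosineSiteRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if lineno == 1 and fields and not _is_int(fields[min(1, len(fields) - 1)]):
                continue  # header
            if len(fields) < min_fields:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {min_fields} columns, got {len(fields)}"
                )
            row = dict(zip(cols, fields))
            if not _is_int(row["pos"]) or not _is_int(row["n_meth"]) or not _is_int(row["n_unmeth"]):
                raise FormatError(f"{path}:{lineno}: non-integer coordinate or count")
            try:
                rec = CytosineSiteRecord(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    strand=row["strand"],
                    n_meth=int(row["n_meth"]),
                    n_unmeth=int(row["n_unmeth"]),
                    context=row.get("context", "NCN") if has_context else "NCN",
                    sample_id=sample_id,
                    replicate_id=replicate_id,
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_cytosine_report(
    path: str | Path, records: Iterable[CytosineSiteRecord], header: bool = False
) -> None:
    with _open_text(path, "wt") as fh:
        if header:
            fh.write("chrom\tpos\tstrand\tn_meth\tn_unmeth\tcontext\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.n_meth}\t{r.n_unmeth}\t{r.context}\n")


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    """Parse standard BED12 into transcript models.

    ``thickStart == thickEnd`` marks a noncoding transcript.  The BED name
    field may be ``tx_id`` or ``gene_id|tx_id``.
    """
    out: list[TranscriptModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(f)}")
            chrom, chrom_start = f[0], int(f[1])
            name, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            block_count = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise FormatError(
                    f"{path}:{lineno}: blockCount {block_count} mismatches "
                    f"blockSizes/blockStarts lengths {len(sizes)}/{len(starts)}"
                )
            exons = tuple(
                (chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)
            )
            if "|" in name:
                gene_id, tx_id = name.split("|", 1)
            else:
                gene_id = tx_id = name
            coding = thick_start != thick_end
            out.append(
                TranscriptModel(
                    tx_id=tx_id,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds_start=thick_start if coding else None,
                    cds_end=thick_end if coding else None,
                )
            )
    return out


def write_bed12(path: str | Path, transcripts: Sequence[TranscriptModel]) -> None:
    with _open_text(path, "wt") as fh:
        for t in transcripts:
            start = t.exons[0][0]
            end = t.exons[-1][1]
            thick_s = t.cds_start if t.is_coding else start
            thick_e = t.cds_end if t.is_coding else start
            sizes = ",".join(str(e - s) for s, e in t.exons)
            starts = ",".join(str(s - start) for s, e in t.exons)
            name = t.tx_id if t.gene_id == t.tx_id else f"{t.gene_id}|{t.tx_id}"
            fh.write(
                f"{t.chrom}\t{start}\t{end}\t{name}\t0\t{t.strand}\t{thick_s}\t{thick_e}"
                f"\t0\t{len(t.exons)}\t{sizes}\t{starts}\n"
            )


def read_interval_bed(path: str | Path, stranded: bool = False) -> GenomicIntervalSet:
    """Parse BED3+ into an interval set (column 6 used as strand if ``stranded``)."""
    ivs = GenomicIntervalSet()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) == 1:
                f = line.split()
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start {start} >= end {end}")
            strand = f[5] if stranded and len(f) >= 6 and f[5] in _VALID_STRANDS else None
            ivs.add(f[0], start, end, strand)
    return ivs


def write_interval_bed(path: str | Path, ivs: GenomicIntervalSet) -> None:
    with _open_text(path, "wt") as fh:
        for chrom, start, end, strand in ivs:
            if strand is None:
                fh.write(f"{chrom}\t{start}\t{end}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\t.\t0\t{strand}\n")
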