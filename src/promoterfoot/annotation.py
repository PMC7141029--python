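"""Transcript annotation parsing and strand-aware promoter (pTSS) windows.

The primary transcription start site (pTSS) region of a transcript is the
interval from -1 kb to +1 kb around its TSS.  For a plus-strand transcript
the TSS is ``tx_start``; for a minus-strand transcript it is ``tx_end`` (the
half-open end coordinate, i.e. the first transcribed base is ``tx_end - 1``).
All coordinates are 0-based, half-open (BED convention); refFlat txStart is
treated as 0-based per the UCSC convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TranscriptModel",
    "PromoterWindow",
    "AnnotationParseError",
    "read_annotation",
    "build_ptss_windows",
    "write_windows_bed6",
]

_VALID_STRANDS = {"+", "-"}


class AnnotationParseError(ValueError):
    """Raised when an annotation file cannot be parsed."""


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with its genomic span.

    ``tx_start < tx_end`` always; strand is ``+`` or ``-``.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise AnnotationParseError(
                f"unknown strand {self.strand!r} for transcript {self.transcript_id}"
            )
        if not self.tx_start < self.tx_end:
            raise AnnotationParseError(
                f"transcript {self.transcript_id}: tx_start must be < tx_end "
                f"(got {self.tx_start}, {self.tx_end})"
            )


@dataclass(frozen=True)
class PromoterWindow:
    """A transcript's pTSS interval, clipped to chromosome bounds.

    ``effective_length`` equals ``window_end - window_start`` and is at most
    ``2 * flank`` (2000 bp at the default flank).
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    window_start: int
    window_end: int
    tss: int

    @property
    def effective_length(self) -> int:
        return self.window_end - self.window_start


def _parse_refflat_line(fields: Sequence[str], lineno: int) -> TranscriptModel:
    # refFlat: geneName name chrom strand txStart txEnd [...]; only the
    # first six columns are used.
    if len(fields) < 6:
        raise AnnotationParseError(
            f"line {lineno}: expected >= 6 tab-separated refFlat fields, got {len(fields)}"
        )
    gene, tid, chrom, strand, start, end = fields[:6]
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: non-integer coordinate") from exc
    if strand not in _VALID_STRANDS:
        raise AnnotationParseError(f"line {lineno}: unknown strand symbol {strand!r}")
    return TranscriptModel(tid, gene, chrom, strand, start_i, end_i)


def _parse_bed12_line(fields: Sequence[str], lineno: int) -> TranscriptModel:
    # BED12 (or BED6+): chrom start end name score strand.  The name column
    # holds the transcript id; a "gene|transcript" name carries both.
    if len(fields) < 6:
        raise AnnotationParseError(
            f"line {lineno}: expected >= 6 BED fields, got {len(fields)}"
        )
    chrom, start, end, name, _score, strand = fields[:6]
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: non-integer coordinate") from exc
    if strand not in _VALID_STRANDS:
        raise AnnotationParseError(f"line {lineno}: unknown strand symbol {strand!r}")
    gene, _, tid = name.partition("|")
    if not tid:
        gene = tid = name
    return TranscriptModel(tid, gene, chrom, strand, start_i, end_i)


def read_annotation(path: str | Path, format: str = "refflat") -> list[TranscriptModel]:
    """Read transcript models from a refFlat-style TSV or a BED12 file.

    Duplicate transcript ids are rejected; malformed lines raise
    :class:`AnnotationParseError` naming the line number.
    """
    if format not in ("refflat", "bed12"):
        raise ValueError(f"unknown annotation format {format!r}")
    parse = _parse_refflat_line if format == "refflat" else _parse_bed12_line
    transcripts: list[TranscriptModel] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            model = parse(line.split("\t"), lineno)
            if model.transcript_id in seen:
                raise AnnotationParseError(
                    f"line {lineno}: duplicate transcript id {model.transcript_id!r}"
                )
            seen.add(model.transcript_id)
            transcripts.append(model)
    return transcripts


def build_ptss_windows(
    transcripts: Iterable[TranscriptModel],
    flank: int = 1000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[PromoterWindow]:
    """Construct the ±``flank`` pTSS window for each transcript.

    TSS is ``tx_start`` on the plus strand and ``tx_end`` on the minus
    strand; the window ``[TSS - flank, TSS + flank)`` is clipped to
    ``[0, chromosome length)`` when sizes are supplied (and to 0 always).
    One window per transcript; overlapping windows from different
    transcripts are kept and counted independently.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    windows: list[PromoterWindow] = []
    for tx in transcripts:
        tss = tx.tx_start if tx.strand == "+" else tx.tx_end
        start = max(0, tss - flank)
        end = tss + flank
        if chrom_sizes is not None and tx.chrom in chrom_sizes:
            end = min(end, chrom_sizes[tx.chrom])
        windows.append(
            PromoterWindow(
                transcript_id=tx.transcript_id,
                gene_symbol=tx.gene_symbol,
                chrom=tx.chrom,
                strand=tx.strand,
                window_start=start,
                window_end=end,
                tss=tss,
            )
        )
    return windows


def write_windows_bed6(windows: Iterable[PromoterWindow], path: str | Path) -> None:
    """Write pTSS windows as BED6 (name = transcript id, strand preserved)."""
    with open(path, "w") as handle:
        for w in windows:
            handle.write(
                f"{w.chrom}\t{w.window_start}\t{w.window_end}\t"
                f"{w.transcript_id}\t0\t{w.strand}\n"
            )
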