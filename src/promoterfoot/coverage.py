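"""Fragment counting in pTSS windows, RPKM normalization, metagene profiles.

A fragment is an aligned, deduplicated cfDNA insert given as a 0-based
half-open genomic interval.  A fragment is counted in every window it
overlaps by at least 1 bp; per-base depth is used only for metagene
(TSS-centred) profiles.  RPKM uses the genome-wide mapped fragment count
of the sample, not the within-window sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .annotation import PromoterWindow

logger = logging.getLogger("promoterfoot")

__all__ = [
    "FragmentSet",
    "CoverageMatrix",
    "MetageneProfile",
    "read_fragments_bed",
    "read_fragments_sam",
    "count_fragments_in_windows",
    "per_base_depth",
    "rpkm_normalize",
    "build_coverage_matrix",
    "metagene_profile",
]


class ConfigurationError(ValueError):
    """Raised when inputs are inconsistent with the sample metadata/contract."""


@dataclass
class FragmentSet:
    """Aligned, deduplicated fragments of one sample.

    ``total_mapped`` is the genome-wide mapped fragment count and may exceed
    the number of stored fragments (e.g. when only promoter-proximal
    fragments were retained).
    """

    sample_id: str
    # per-chromosome (starts, ends, ends_sorted, max_length); starts/ends
    # sorted by start, ends_sorted for inclusion-exclusion counting,
    # max_length bounds the candidate slice for per-base depth
    _by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int]] = field(
        default_factory=dict, repr=False
    )
    total_mapped: int = 0

    @classmethod
    def from_fragments(
        cls,
        sample_id: str,
        fragments: Iterable[tuple[str, int, int]],
        total_mapped: int | None = None,
    ) -> "FragmentSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        n = 0
        for chrom, start, end in fragments:
            if not start < end:
                raise ValueError(
                    f"fragment {chrom}:{start}-{end} has start >= end"
                )
            by_chrom.setdefault(chrom, []).append((start, end))
            n += 1
        if total_mapped is None:
            total_mapped = n
        elif total_mapped < n:
            raise ValueError("total_mapped must be >= number of stored fragments")
        packed = {}
        for chrom, pairs in by_chrom.items():
            arr = np.asarray(pairs, dtype=np.int64)
            order = np.argsort(arr[:, 0], kind="stable")
            starts = arr[order, 0]
            ends = arr[order, 1]
            packed[chrom] = (starts, ends, np.sort(ends), int((ends - starts).max()))
        return cls(sample_id=sample_id, _by_chrom=packed, total_mapped=total_mapped)

    @property
    def n_fragments(self) -> int:
        return sum(len(s) for s, *_ in self._by_chrom.values())

    @property
    def chromosomes(self) -> set[str]:
        return set(self._by_chrom)

    def fragments(self) -> Iterator[tuple[str, int, int]]:
        """Iterate (chrom, start, end), sorted by chromosome then start."""
        for chrom in sorted(self._by_chrom):
            starts, ends, *_ = self._by_chrom[chrom]
            for s, e in zip(starts.tolist(), ends.tolist()):
                yield chrom, s, e

    def _chrom_arrays(self, chrom: str):
        return self._by_chrom.get(chrom)


def read_fragments_bed(
    path: str | Path,
    sample_id: str | None = None,
    total_mapped: int | None = None,
) -> FragmentSet:
    """Read a BED3+ fragment file (chrom, start, end[, name...])."""
    path = Path(path)
    frags: list[tuple[str, int, int]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            frags.append((fields[0], int(fields[1]), int(fields[2])))
    return FragmentSet.from_fragments(
        sample_id or path.stem, frags, total_mapped=total_mapped
    )


def read_fragments_sam(
    path: str | Path,
    sample_id: str | None = None,
) -> FragmentSet:
    """Read mapped reads from a coordinate-sorted SAM/BAM as fragments.

    Each mapped, non-secondary, non-duplicate read contributes one fragment
    spanning its aligned reference interval; ``total_mapped`` is the number
    of such reads.
    """
    import pysam

    path = Path(path)
    frags: list[tuple[str, int, int]] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_duplicate:
                continue
            frags.append((read.reference_name, read.reference_start, read.reference_end))
    return FragmentSet.from_fragments(sample_id or path.stem, frags)


def _warn_unannotated_chroms(fragments: FragmentSet, windows: Sequence[PromoterWindow]) -> None:
    extra = fragments.chromosomes - {w.chrom for w in windows}
    if extra:
        logger.warning(
            "sample %s: fragments on chromosome(s) %s absent from the annotation; "
            "they count toward total_mapped only",
            fragments.sample_id,
            ",".join(sorted(extra)),
        )


def count_fragments_in_windows(
    fragments: FragmentSet, windows: Sequence[PromoterWindow]
) -> np.ndarray:
    """Count fragments overlapping each window by >= 1 bp (half-open).

    A fragment is counted once in every window it overlaps, so a fragment
    spanning two overlapping windows increments both.
    """
    _warn_unannotated_chroms(fragments, windows)
    counts = np.zeros(len(windows), dtype=np.int64)
    for i, w in enumerate(windows):
        arrays = fragments._chrom_arrays(w.chrom)
        if arrays is None:
            continue
        starts, _ends, ends_sorted, _maxlen = arrays
        # overlap iff start < window_end and end > window_start;
        # #(start < we) - #(end <= ws), the latter a subset of the former
        n_start_before = np.searchsorted(starts, w.window_end, side="left")
        n_end_before = np.searchsorted(ends_sorted, w.window_start, side="right")
        counts[i] = n_start_before - n_end_before
    return counts


def per_base_depth(fragments: FragmentSet, window: PromoterWindow) -> np.ndarray:
    """Depth vector over the window: depth[i] covers base window_start+i."""
    length = window.effective_length
    depth_delta = np.zeros(length + 1, dtype=np.int64)
    arrays = fragments._chrom_arrays(window.chrom)
    if arrays is None:
        return np.zeros(length, dtype=np.int64)
    starts, ends, _ends_sorted, max_len = arrays
    hi = np.searchsorted(starts, window.window_end, side="left")
    lo = np.searchsorted(starts, window.window_start - max_len, side="left")
    cand_s = starts[lo:hi]
    cand_e = ends[lo:hi]
    mask = cand_e > window.window_start
    lo = np.clip(cand_s[mask] - window.window_start, 0, length)
    hi_off = np.clip(cand_e[mask] - window.window_start, 0, length)
    np.add.at(depth_delta, lo, 1)
    np.add.at(depth_delta, hi_off, -1)
    return np.cumsum(depth_delta[:-1])


def rpkm_normalize(count: float, window_length: int, total_mapped: int) -> float:
    """Reads per kilobase per million mapped reads.

    RPKM = count * 1e9 / (window_length * total_mapped).
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count * 1e9 / (window_length * total_mapped)


@dataclass
class CoverageMatrix:
    """Samples × promoter windows of RPKM values with per-sample metadata."""

    values: pd.DataFrame  # index: sample ids; columns: window (transcript) ids
    meta: pd.DataFrame  # index: sample ids; columns incl. label, bmi, ...
    window_genes: dict[str, str] = field(default_factory=dict)  # window id -> gene symbol

    def __post_init__(self) -> None:
        if not self.values.index.is_unique or not self.values.columns.is_unique:
            raise ValueError("sample and window ids must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("RPKM values must be nonnegative")
        missing = self.values.index.difference(self.meta.index)
        if len(missing):
            raise ConfigurationError(
                f"metadata missing sample(s): {', '.join(map(str, missing))}"
            )
        self.meta = self.meta.loc[self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def window_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CoverageMatrix":
        return CoverageMatrix(
            self.values.loc[list(sample_ids)].copy(),
            self.meta.loc[list(sample_ids)].copy(),
            dict(self.window_genes),
        )

    def to_tsv(self, values_path: str | Path, meta_path: str | Path | None = None) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="sample_id")
        if meta_path is not None:
            self.meta.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(
        cls,
        values_path: str | Path,
        meta_path: str | Path,
        window_genes: dict[str, str] | None = None,
    ) -> "CoverageMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="sample_id")
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
        return cls(values, meta, window_genes or {})


def build_coverage_matrix(
    samples: Sequence[FragmentSet],
    windows: Sequence[PromoterWindow],
    metadata: pd.DataFrame,
) -> CoverageMatrix:
    """RPKM matrix: entry (s, w) = RPKM of sample s's count in window w.

    ``metadata`` must be indexed by sample id (or carry a ``sample_id``
    column) and cover every sample.
    """
    if "sample_id" in metadata.columns:
        metadata = metadata.set_index("sample_id")
    lengths = np.array([w.effective_length for w in windows], dtype=float)
    rows = {}
    for fs in samples:
        if fs.sample_id not in metadata.index:
            raise ConfigurationError(f"metadata missing sample(s): {fs.sample_id}")
        counts = count_fragments_in_windows(fs, windows)
        rows[fs.sample_id] = counts * 1e9 / (lengths * fs.total_mapped)
    values = pd.DataFrame.from_dict(rows, orient="index")
    values.columns = [w.transcript_id for w in windows]
    window_genes = {w.transcript_id: w.gene_symbol for w in windows}
    return CoverageMatrix(values, metadata.loc[list(rows)], window_genes)


@dataclass
class MetageneProfile:
    """Mean relative depth around the TSS for a gene set.

    Offsets are bp relative to the TSS (bin left edges), strand-aware:
    positive offsets are downstream of transcription.  Depth is normalized
    to the mean over the outermost 10% of positions on each side, so a
    flat profile sits at 1.0.
    """

    positions: np.ndarray
    mean_relative_depth: np.ndarray
    gene_set: str
    n_genes: int

    def central_flank_ratio(self, central_fraction: float = 0.1) -> float:
        """Mean relative depth over the central ``central_fraction`` of offsets."""
        span = self.positions[-1] - self.positions[0]
        half = central_fraction * span / 2.0
        centre = (self.positions[0] + self.positions[-1]) / 2.0
        mask = np.abs(self.positions - centre) <= half
        return float(self.mean_relative_depth[mask].mean())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"offset": self.positions, "relative_depth": self.mean_relative_depth}
        ).to_csv(path, sep="\t", index=False)


def metagene_profile(
    samples: Sequence[FragmentSet],
    windows: Sequence[PromoterWindow],
    bin_size: int = 20,
    gene_set: str = "",
) -> MetageneProfile:
    """Average TSS-centred depth profile over a gene set's windows.

    Depth is summed over samples and windows per offset, minus-strand
    windows are reversed so positive offsets point downstream, the profile
    is binned, then divided by the mean over the outermost 10% of offsets
    on each side.  Only full-length (unclipped) windows enter the profile.
    """
    if not windows:
        raise ValueError("empty gene set")
    length = max(w.effective_length for w in windows)
    full = [w for w in windows if w.effective_length == length]
    if len(full) < len(windows):
        logger.warning(
            "metagene_profile: dropped %d edge-clipped window(s)",
            len(windows) - len(full),
        )
    if bin_size <= 0 or length % bin_size != 0:
        raise ValueError("bin_size must divide the window length")
    flank = length // 2
    total = np.zeros(length, dtype=float)
    for fs in samples:
        for w in full:
            d = per_base_depth(fs, w).astype(float)
            if w.strand == "-":
                d = d[::-1]
            total += d
    total /= max(1, len(samples) * len(full))
    binned = total.reshape(-1, bin_size).mean(axis=1)
    positions = np.arange(-flank, flank, bin_size)
    n_edge = max(1, int(round(0.10 * len(binned) / 2)))
    baseline = np.concatenate([binned[:n_edge], binned[-n_edge:]]).mean()
    if baseline <= 0:
        raise ValueError("flank baseline depth is zero; cannot normalize")
    return MetageneProfile(
        positions=positions,
        mean_relative_depth=binned / baseline,
        gene_set=gene_set,
        n_genes=len(full),
    )
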