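"""Streaming ingestion of transcriptome-aligned reads from SAM/BAM.

Reads are assumed aligned to a transcriptome reference on the sense strand,
so a footprint's 5' end is simply the SAM leftmost position. Reverse-strand,
unmapped, secondary and supplementary records are skipped and tallied.
Footprint length is the aligned reference span (soft clips excluded), since
the P-site offset arithmetic must count aligned bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pysam

from riboprof.annotation import TranscriptSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FootprintRecord:
    """One aligned read reduced to (transcript, 0-based 5'-end position, length)."""

    transcript_id: str
    five_prime: int
    length: int

    def __post_init__(self) -> None:
        if self.five_prime < 0:
            raise ValueError(f"negative 5'-end position {self.five_prime}")
        if self.length < 1:
            raise ValueError(f"non-positive footprint length {self.length}")


@dataclass
class IngestStats:
    """Tally of records seen and skipped while streaming a SAM/BAM file."""

    n_emitted: int = 0
    n_unmapped: int = 0
    n_secondary: int = 0
    n_supplementary: int = 0
    n_reverse: int = 0
    n_unknown_reference: int = 0

    @property
    def n_skipped(self) -> int:
        return (
            self.n_unmapped
            + self.n_secondary
            + self.n_supplementary
            + self.n_reverse
            + self.n_unknown_reference
        )


@dataclass
class LengthWindows:
    """Inclusive fragment-length windows, e.g. [(20, 22), (27, 29)].

    An empty window list disables filtering (every length passes).
    """

    windows: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for lo, hi in self.windows:
            if lo > hi:
                raise ValueError(f"window [{lo},{hi}] has lo > hi")
        ordered = sorted(self.windows)
        for (_, hi), (lo2, _) in zip(ordered, ordered[1:]):
            if lo2 <= hi:
                raise ValueError(f"overlapping windows in {self.windows}")

    def __contains__(self, length: int) -> bool:
        if not self.windows:
            return True
        return any(lo <= length <= hi for lo, hi in self.windows)

    def labels(self) -> list[str]:
        return [f"{lo}-{hi}" for lo, hi in self.windows]

    def label_of(self, length: int) -> Optional[str]:
        for lo, hi in self.windows:
            if lo <= length <= hi:
                return f"{lo}-{hi}"
        return None

    @classmethod
    def parse(cls, text: str) -> "LengthWindows":
        """Parse CLI syntax like ``"20-22,27-29"`` (empty string -> no filter)."""
        if not text.strip():
            return cls([])
        windows = []
        for part in text.split(","):
            lo, _, hi = part.partition("-")
            windows.append((int(lo), int(hi or lo)))
        return cls(windows)


RPF_WINDOWS = LengthWindows([(20, 22), (27, 29)])


@dataclass
class LengthHistogram:
    """Counts of footprints per exact fragment length."""

    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fraction(self, length: int) -> float:
        total = self.total
        return self.counts.get(length, 0) / total if total else 0.0

    def window_mass(self, windows: LengthWindows) -> float:
        """Fraction of all footprints whose length falls in ``windows``."""
        total = self.total
        if not total:
            return 0.0
        return sum(c for ln, c in self.counts.items() if ln in windows) / total


def read_alignments(
    sam_path: str | Path,
    transcripts: TranscriptSet,
    stats: Optional[IngestStats] = None,
) -> Iterator[FootprintRecord]:
    """Stream :class:`FootprintRecord` objects from a SAM/BAM file.

    One record per primary, mapped, forward-strand alignment whose reference
    is a known transcript; everything else is skipped and tallied in
    ``stats`` (pass an :class:`IngestStats` to inspect the tallies after the
    stream is consumed).
    """
    if stats is None:
        stats = IngestStats()
    # check_sq=False: headerless SAM fragments still stream
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                stats.n_unmapped += 1
                continue
            if aln.is_secondary:
                stats.n_secondary += 1
                continue
            if aln.is_supplementary:
                stats.n_supplementary += 1
                continue
            if aln.is_reverse:
                stats.n_reverse += 1
                continue
            ref = aln.reference_name
            if ref not in transcripts:
                stats.n_unknown_reference += 1
                continue
            stats.n_emitted += 1
            yield FootprintRecord(
                transcript_id=ref,
                five_prime=aln.reference_start,
                length=aln.reference_length,
            )
    if stats.n_skipped:
        logger.info(
            "%s: emitted %d, skipped %d (unmapped %d, secondary %d, "
            "supplementary %d, reverse %d, unknown reference %d)",
            sam_path,
            stats.n_emitted,
            stats.n_skipped,
            stats.n_unmapped,
            stats.n_secondary,
            stats.n_supplementary,
            stats.n_reverse,
            stats.n_unknown_reference,
        )


def filter_by_length(
    records: Iterable[FootprintRecord], windows: LengthWindows
) -> Iterator[FootprintRecord]:
    """Keep footprints whose length lies in any window; order preserved.

    With an empty window list every record passes (filtering disabled).
    """
    for rec in records:
        if rec.length in windows:
            yield rec


def length_histogram(records: Iterable[FootprintRecord]) -> LengthHistogram:
    """Exact fragment-length histogram of a footprint stream."""
    counts: dict[int, int] = {}
    for rec in records:
        counts[rec.length] = counts.get(rec.length, 0) + 1
    return LengthHistogram(counts=counts)
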