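"""P-site / A-site assignment with a fixed 5'-end offset.

The pipeline uses a single offset of 12 nt from the fragment 5' end to the
first nucleotide of the P-site codon, applied to every fragment length in
both RPF windows. The A-site codon sits one codon (3 nt) downstream, so an
initiating ribosome has the start codon in the P site and the second codon
in the A site. A per-length offset table is accepted for generality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional, Union

from riboprof.alignments import FootprintRecord
from riboprof.annotation import Region, TranscriptModel, TranscriptSet, region_of

DEFAULT_PSITE_OFFSET = 12
A_SITE_SHIFT = 3  # A-site codon starts one codon 3' of the P-site codon

OffsetSpec = Union[int, Mapping[int, int]]


@dataclass(frozen=True)
class SiteAnnotatedRecord:
    """A footprint with derived P-site, A-site, reading frame and region.

    ``frame`` is defined only when the P-site lies in the CDS of a transcript
    with a complete (length % 3 == 0) coding sequence; ``valid`` is False when
    the P- or A-site falls past the transcript end, and such records are
    excluded from all downstream counting.
    """

    base: FootprintRecord
    p_site: int
    a_site: int
    frame: Optional[int]
    region: Optional[Region]
    valid: bool


def _offset_for(length: int, offset: OffsetSpec) -> int:
    if isinstance(offset, int):
        return offset
    return offset[length]


def assign_sites(
    record: FootprintRecord,
    model: TranscriptModel,
    offset: OffsetSpec = DEFAULT_PSITE_OFFSET,
) -> SiteAnnotatedRecord:
    """Annotate one footprint: P-site = 5' end + offset, A-site = P-site + 3."""
    off = _offset_for(record.length, offset)
    p_site = record.five_prime + off
    a_site = p_site + A_SITE_SHIFT
    if p_site >= model.length or a_site >= model.length:
        return SiteAnnotatedRecord(record, p_site, a_site, None, None, valid=False)
    region = region_of(model, p_site)
    frame = frame_of(p_site, model)
    return SiteAnnotatedRecord(record, p_site, a_site, frame, region, valid=True)


def frame_of(p_site: int, model: TranscriptModel) -> Optional[int]:
    """Reading frame of a P-site position: (p_site - utr5_len) mod 3 within
    the CDS, undefined (None) outside it or on an incomplete CDS."""
    if not model.cds_complete:
        return None
    if model.cds_start <= p_site < model.cds_end:
        return (p_site - model.cds_start) % 3
    return None


def annotate_stream(
    records: Iterable[FootprintRecord],
    transcripts: TranscriptSet,
    offset: OffsetSpec = DEFAULT_PSITE_OFFSET,
) -> Iterator[SiteAnnotatedRecord]:
    """Assign sites across a footprint stream (unknown transcripts must have
    been filtered at ingestion)."""
    for rec in records:
        yield assign_sites(rec, transcripts[rec.transcript_id], offset)
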