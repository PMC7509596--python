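"""Transcript coordinate models built from GFF3 + FASTA.

Every downstream computation works in transcript space: position 0 is the
first transcribed nucleotide, the coding sequence (CDS) occupies
``[utr5_len, utr5_len + cds_len)`` and the 3'UTR the remainder. GFF3's
1-based closed genomic intervals are converted at this parser boundary and
nowhere else; multi-exon transcripts are projected onto the spliced
transcript, honouring strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import gffutils
from Bio import SeqIO

logger = logging.getLogger(__name__)


class Region(str, Enum):
    """The three functional regions of an mRNA."""

    UTR5 = "UTR5"
    CDS = "CDS"
    UTR3 = "UTR3"


class AnnotationError(ValueError):
    """Raised for unparsable or internally inconsistent annotation input."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript's coordinate frame in transcript space.

    ``utr5_len + cds_len + utr3_len == length`` always holds. A CDS whose
    length is not a multiple of 3 downgrades ``cds_complete`` rather than
    aborting the load; such transcripts are kept for length/region QC but
    excluded from reading-frame analysis.
    """

    transcript_id: str
    gene_id: str
    length: int
    utr5_len: int
    cds_len: int
    utr3_len: int
    sequence: Optional[str] = None
    cds_complete: bool = True

    def __post_init__(self) -> None:
        if self.length < 0 or self.utr5_len < 0 or self.utr3_len < 0:
            raise AnnotationError(f"{self.transcript_id}: negative extent")
        if self.cds_len <= 0:
            raise AnnotationError(f"{self.transcript_id}: CDS length must be positive")
        if self.utr5_len + self.cds_len + self.utr3_len != self.length:
            raise AnnotationError(
                f"{self.transcript_id}: UTR5+CDS+UTR3 "
                f"({self.utr5_len}+{self.cds_len}+{self.utr3_len}) != length {self.length}"
            )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise AnnotationError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} "
                f"!= annotated length {self.length}"
            )
        if self.cds_len % 3 != 0 and self.cds_complete:
            # cannot mutate a frozen dataclass in-place
            object.__setattr__(self, "cds_complete", False)

    @property
    def cds_start(self) -> int:
        """0-based transcript position of the first CDS nucleotide."""
        return self.utr5_len

    @property
    def cds_end(self) -> int:
        """0-based exclusive transcript position one past the last CDS nucleotide."""
        return self.utr5_len + self.cds_len


@dataclass
class TranscriptSet:
    """Collection of transcript models plus a gene -> representative index."""

    models: dict[str, TranscriptModel] = field(default_factory=dict)
    gene_index: dict[str, str] = field(default_factory=dict)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.models

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.models[transcript_id]

    def representative(self, gene_id: str) -> TranscriptModel:
        return self.models[self.gene_index[gene_id]]

    @classmethod
    def from_models(cls, models: Iterable[TranscriptModel]) -> "TranscriptSet":
        by_id = {m.transcript_id: m for m in models}
        by_gene: dict[str, list[TranscriptModel]] = {}
        for m in by_id.values():
            by_gene.setdefault(m.gene_id, []).append(m)
        index = {g: representative_transcript(ms) for g, ms in by_gene.items()}
        return cls(models=by_id, gene_index=index)


def region_of(model: TranscriptModel, pos: int) -> Region:
    """Region containing 0-based transcript position ``pos`` (half-open bounds)."""
    if not 0 <= pos < model.length:
        raise IndexError(
            f"position {pos} out of range [0, {model.length}) on {model.transcript_id}"
        )
    if pos < model.utr5_len:
        return Region.UTR5
    if pos < model.utr5_len + model.cds_len:
        return Region.CDS
    return Region.UTR3


def representative_transcript(models_for_gene: Iterable[TranscriptModel]) -> str:
    """Deterministic per-gene isoform choice: longest CDS, then longest
    transcript, then lexicographically smallest id."""
    models = list(models_for_gene)
    if not models:
        raise ValueError("empty transcript collection")
    gene_ids = {m.gene_id for m in models}
    if len(gene_ids) != 1:
        raise ValueError(f"transcripts span multiple genes: {sorted(gene_ids)}")
    best = max(models, key=lambda m: (m.cds_len, m.length, _neg_lex(m.transcript_id)))
    return best.transcript_id


def _neg_lex(s: str) -> tuple[int, ...]:
    # max() with this key picks the lexicographically SMALLEST id on full ties
    return tuple(-ord(c) for c in s)


def load_transcripts(
    gff3_path: str | Path, fasta_path: str | Path | None = None
) -> TranscriptSet:
    """Build :class:`TranscriptModel` objects from a GFF3 file, optionally
    attaching sequences from a matching FASTA.

    Recognises ``mRNA``/``transcript`` features with ``exon`` and ``CDS``
    children linked by ``Parent``. Transcripts with no CDS are excluded (count
    logged). With a FASTA, a missing or length-mismatched sequence drops the
    transcript with a per-transcript warning.
    """
    _validate_gff3_shape(gff3_path)
    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise AnnotationError(f"unparsable GFF3 {gff3_path}: {exc}") from exc

    sequences: Mapping[str, str] | None = None
    if fasta_path is not None:
        sequences = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
        }

    models: list[TranscriptModel] = []
    n_no_cds = 0
    n_dropped_fasta = 0
    for feature_type in ("mRNA", "transcript"):
        for tx in db.features_of_type(feature_type):
            tx_id = tx.id
            exons = sorted(db.children(tx, featuretype="exon"), key=lambda f: f.start)
            cds_parts = sorted(db.children(tx, featuretype="CDS"), key=lambda f: f.start)
            if not cds_parts:
                n_no_cds += 1
                continue
            if not exons:
                # exonless transcript: treat the transcript span as one exon
                exons = [tx]

            length = sum(e.end - e.start + 1 for e in exons)
            cds_len = sum(c.end - c.start + 1 for c in cds_parts)
            strand = tx.strand or "+"
            if strand == "-":
                cds_5p_genomic = max(c.end for c in cds_parts)
            else:
                cds_5p_genomic = min(c.start for c in cds_parts)
            utr5_len = _project(exons, strand, cds_5p_genomic)
            if utr5_len is None:
                logger.warning("%s: CDS start not inside any exon; dropped", tx_id)
                continue
            utr3_len = length - utr5_len - cds_len

            seq = None
            if sequences is not None:
                seq = sequences.get(tx_id)
                if seq is None or len(seq) != length:
                    n_dropped_fasta += 1
                    logger.warning(
                        "%s: FASTA sequence %s; transcript dropped",
                        tx_id,
                        "missing" if seq is None else
                        f"length {len(seq)} != annotated {length}",
                    )
                    continue

            gene_id = tx.attributes.get("gene_id", [None])[0]
            if gene_id is None:
                parents = tx.attributes.get("Parent", [])
                gene_id = parents[0] if parents else tx_id

            models.append(
                TranscriptModel(
                    transcript_id=tx_id,
                    gene_id=gene_id,
                    length=length,
                    utr5_len=utr5_len,
                    cds_len=cds_len,
                    utr3_len=utr3_len,
                    sequence=seq,
                )
            )

    if n_no_cds:
        logger.info("excluded %d transcripts with no annotated CDS", n_no_cds)
    if n_dropped_fasta:
        logger.info("dropped %d transcripts on FASTA mismatch", n_dropped_fasta)
    return TranscriptSet.from_models(models)


def _validate_gff3_shape(path: str | Path) -> None:
    """Reject files whose body lines are not 9 tab-separated GFF3 columns
    (gffutils would otherwise skip them silently)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith(">"):
                if line.startswith(">"):
                    break  # trailing ##FASTA section
                continue
            if line.count("\t") != 8:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated GFF3 columns"
                )


def _project(exons, strand: str, genomic_pos: int) -> Optional[int]:
    """Transcript-space offset of a 1-based genomic position within spliced exons."""
    if strand == "-":
        offset = 0
        for e in sorted(exons, key=lambda f: f.start, reverse=True):
            if e.start <= genomic_pos <= e.end:
                return offset + (e.end - genomic_pos)
            offset += e.end - e.start + 1
        return None
    offset = 0
    for e in sorted(exons, key=lambda f: f.start):
        if e.start <= genomic_pos <= e.end:
            return offset + (genomic_pos - e.start)
        offset += e.end - e.start + 1
    return None
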