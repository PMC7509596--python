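"""Gene-level CDS counting, RPKM and translation efficiency.

A read contributes to its gene's count only when the ribosome A site is
annotated at least 20 nt downstream of the CDS start codon and still within
the CDS — trimming the initiation-biased 5' region from quantification.
RPKM = count x 1e9 / (cds_len x library_size); translation efficiency is
the per-gene ratio RPKM_Ribo / RPKM_RNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from riboprof.alignments import (
    IngestStats,
    LengthWindows,
    filter_by_length,
    read_alignments,
)
from riboprof.annotation import Region, TranscriptSet, region_of
from riboprof.psite import DEFAULT_PSITE_OFFSET, SiteAnnotatedRecord, annotate_stream

logger = logging.getLogger(__name__)

DEFAULT_MIN_DOWNSTREAM = 20


@dataclass
class GeneExpressionTable:
    """Per-gene CDS-filtered counts and RPKM for one library.

    ``table`` is indexed by gene_id with columns ``cds_len``, ``count``,
    ``rpkm``. ``library_size`` is the denominator used for RPKM — the number
    of reads surviving ingestion and length filtering for this library —
    recorded so alternative denominators remain comparable.
    """

    table: pd.DataFrame
    library_size: int
    meta: dict = field(default_factory=dict)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.table.index)

    def rpkm_of(self, gene_id: str) -> float:
        return float(self.table.loc[gene_id, "rpkm"])

    def to_tsv(self, path) -> None:
        out = self.table.reset_index()
        out["rpkm"] = out["rpkm"].map(lambda x: float(f"{x:.6g}"))
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, library_size: int | None = None) -> "GeneExpressionTable":
        df = pd.read_csv(path, sep="\t").set_index("gene_id")
        if library_size is None:
            # recover the denominator from the RPKM identity on any counted gene
            counted = df[df["count"] > 0]
            if len(counted):
                row = counted.iloc[0]
                library_size = round(row["count"] * 1e9 / (row["cds_len"] * row["rpkm"]))
            else:
                library_size = 0
        return cls(table=df, library_size=int(library_size))


def count_cds_reads(
    records: Iterable[SiteAnnotatedRecord],
    models: TranscriptSet,
    min_downstream: int = DEFAULT_MIN_DOWNSTREAM,
) -> dict[str, int]:
    """Count reads per gene whose A site is >= ``min_downstream`` nt
    downstream of the CDS start (inclusive boundary) and inside the CDS.

    Downstream distance is ``a_site - utr5_len`` in nt, the first CDS
    nucleotide being 0 nt downstream.
    """
    counts: dict[str, int] = {}
    for rec in records:
        if not rec.valid:
            continue
        model = models[rec.base.transcript_id]
        downstream = rec.a_site - model.utr5_len
        if downstream < min_downstream:
            continue
        if region_of(model, rec.a_site) is not Region.CDS:
            continue
        counts[model.gene_id] = counts.get(model.gene_id, 0) + 1
    return counts


def rpkm(count: int, cds_len: int, library_size: int) -> float:
    """Reads per kilobase of CDS per million mapped reads."""
    if cds_len <= 0:
        raise ValueError(f"cds_len must be positive, got {cds_len}")
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    return count * 1e9 / (cds_len * library_size)


def build_expression_table(
    counts: Mapping[str, int],
    models: TranscriptSet,
    library_size: int,
    meta: dict | None = None,
) -> GeneExpressionTable:
    """Assemble a :class:`GeneExpressionTable` over every gene in the
    annotation (uncounted genes get count 0), using each gene's
    representative transcript CDS length."""
    rows = []
    for gene_id in sorted(models.gene_index):
        model = models.representative(gene_id)
        c = counts.get(gene_id, 0)
        rows.append(
            {
                "gene_id": gene_id,
                "cds_len": model.cds_len,
                "count": c,
                "rpkm": rpkm(c, model.cds_len, library_size),
            }
        )
    df = pd.DataFrame(rows).set_index("gene_id")
    return GeneExpressionTable(table=df, library_size=library_size, meta=meta or {})


def quantify_library(
    sam_path,
    transcripts: TranscriptSet,
    windows: LengthWindows | None = None,
    offset: int = DEFAULT_PSITE_OFFSET,
    min_downstream: int = DEFAULT_MIN_DOWNSTREAM,
) -> GeneExpressionTable:
    """End-to-end single-library quantification, fully streaming.

    Ingest -> length filter -> P-site assignment -> downstream-filtered CDS
    counting -> RPKM, with library_size = number of reads surviving
    ingestion and length filtering. Memory stays flat regardless of depth.
    """
    if windows is None:
        windows = LengthWindows([])
    stats = IngestStats()
    records = read_alignments(sam_path, transcripts, stats=stats)
    n_kept = 0

    def kept_stream():
        nonlocal n_kept
        for rec in filter_by_length(records, windows):
            n_kept += 1
            yield rec

    counts = count_cds_reads(
        annotate_stream(kept_stream(), transcripts, offset), transcripts, min_downstream
    )
    return build_expression_table(
        counts,
        transcripts,
        library_size=n_kept,
        meta={
            "library_size_definition": "records surviving ingestion + length filter",
            "psite_offset": offset,
            "min_downstream": min_downstream,
            "windows": windows.labels(),
            "n_skipped_ingest": stats.n_skipped,
        },
    )


def translation_efficiency(
    ribo: GeneExpressionTable, rna: GeneExpressionTable
) -> pd.DataFrame:
    """Per-gene TE = RPKM_Ribo / RPKM_RNA where RPKM_RNA > 0.

    Genes absent from either table, or with zero RNA signal, are omitted and
    tallied in the returned frame's ``attrs['n_omitted']``.
    """
    common = ribo.gene_ids & rna.gene_ids
    rows = []
    n_omitted = len(ribo.gene_ids | rna.gene_ids) - len(common)
    for g in sorted(common):
        r_rna = rna.rpkm_of(g)
        if r_rna <= 0:
            n_omitted += 1
            continue
        rows.append({"gene_id": g, "rpkm_ribo": ribo.rpkm_of(g),
                     "rpkm_rna": r_rna, "te": ribo.rpkm_of(g) / r_rna})
    df = pd.DataFrame(rows, columns=["gene_id", "rpkm_ribo", "rpkm_rna", "te"])
    if len(df):
        df = df.set_index("gene_id")
    df.attrs["n_omitted"] = n_omitted
    if n_omitted:
        logger.info("translation_efficiency: omitted %d genes", n_omitted)
    return df
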