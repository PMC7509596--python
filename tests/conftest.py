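"""Shared fixtures: toy transcript models, hand-written SAM/GFF3 text, and a
session-scoped small simulated dataset."""

from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from riboprof.alignments import FootprintRecord
from riboprof.annotation import TranscriptModel, TranscriptSet, load_transcripts
from riboprof.simulate import SimConfig, make_transcriptome, simulate_ribo, simulate_rna


def make_model(
    utr5: int = 100,
    cds: int = 600,
    utr3: int = 300,
    transcript_id: str = "txA",
    gene_id: str = "geneA",
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        length=utr5 + cds + utr3,
        utr5_len=utr5,
        cds_len=cds,
        utr3_len=utr3,
    )


def write_sam(path: Path, references: dict[str, int], body_lines: list[str]) -> Path:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in references.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    path.write_text("\n".join(lines + body_lines) + "\n")
    return path


def sam_line(
    qname: str,
    rname: str,
    pos_1based: int,
    cigar: str,
    flag: int = 0,
    seq: str = "*",
) -> str:
    return f"{qname}\t{flag}\t{rname}\t{pos_1based}\t255\t{cigar}\t*\t0\t0\t{seq}\t*"


@pytest.fixture
def toy_model() -> TranscriptModel:
    """(utr5, cds, utr3) = (100, 600, 300), the worked-example geometry."""
    return make_model()


@pytest.fixture
def toy_set(toy_model) -> TranscriptSet:
    return TranscriptSet.from_models([toy_model])


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """Small simulated dataset shared across tests: 30-gene transcriptome,
    one 20k-read Ribo library and one 20k-read RNA library, defaults
    otherwise (offset 12, fidelity 0.9)."""
    out = tmp_path_factory.mktemp("simdata")
    config = SimConfig(n_genes=30, n_reads=20_000, seed=7)
    tx = make_transcriptome(config, out)
    ribo_truth = simulate_ribo(config, tx, out / "ribo.sam", library_index=1)
    rna_truth = simulate_rna(config, tx, out / "rna.sam", library_index=101)
    transcripts = load_transcripts(out / "annotation.gff3", out / "transcripts.fa")
    return {
        "dir": out,
        "config": config,
        "transcriptome": tx,
        "transcripts": transcripts,
        "ribo_sam": out / "ribo.sam",
        "rna_sam": out / "rna.sam",
        "ribo_truth": ribo_truth,
        "rna_truth": rna_truth,
    }
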