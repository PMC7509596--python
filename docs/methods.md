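# Methods

## Coordinate conventions

All positions are 0-based, half-open, transcript-relative. GFF3's 1-based
closed genomic intervals are converted once, at the parser boundary
(`annotation.load_transcripts`), which projects exon/CDS children onto the
spliced transcript (both strands supported). A transcript is the triple of
extents (utr5_len, cds_len, utr3_len) summing to its length; `region_of`
partitions `[0, length)` accordingly. Multi-isoform genes collapse to one
representative transcript for quantification — longest CDS, ties broken by
longest transcript then lexicographic id — a deterministic policy chosen
because per-gene quantification needs a single CDS length. Transcripts whose
CDS length is not a multiple of 3 are kept for length/region QC but carry
`cds_complete=False` and are excluded from reading-frame analysis.

## Footprint model

An aligned read is reduced to (transcript, 5′-end position, aligned length).
Alignment is assumed to a transcriptome reference on the sense strand, so
the 5′ end is the SAM leftmost position; reverse-strand, unmapped, secondary
and supplementary records are skipped and tallied. Soft-clipped bases are
excluded from the length because the offset arithmetic must count aligned
bases. Duplicates are not collapsed.

The P site is placed at a fixed offset of 12 nt from the 5′ end for every
fragment length in both RPF windows (20–22 and 27–29 nt); the A site is one
codon further (P + 3). The reading frame of a P site inside the CDS is
`(p_site − utr5_len) mod 3`; frame 0 therefore means the P site is on a
codon boundary. "nt downstream of the start codon" is measured as
`a_site − utr5_len`, the first CDS nucleotide being 0 nt downstream.
Placements running past the transcript end are flagged invalid, tallied and
excluded, never raised as errors. A per-length offset table is accepted
wherever an offset is, for users who calibrate offsets per length class.

## QC statistics

- **Region distribution** anchors Ribo-seq reads at the P site (the
  biologically meaningful position of a footprint) and RNA-seq reads at the
  raw 5′ end (RNA has no P site); fractions are normalized over assigned
  records and flagged undefined on empty input.
- **Metagene start profile** counts 5′ ends at each position relative to
  the first start-codon nucleotide within a window, default [−40, +60]
  (configurable; wide enough to show the −12 initiation peak and several
  downstream codons), split by fragment-length class.
- **Frame distribution / periodicity score** give per-class frame fractions
  and their maximum (1/3 = no phasing, 1 = perfect phasing).

## Quantification and reproducibility

A read counts toward its gene when its A site is ≥ 20 nt downstream of the
CDS start (inclusive) and still inside the CDS, which trims the
initiation-biased 5′ region. RPKM uses the CDS length of the gene's
representative transcript; the library-size denominator is the number of
reads surviving ingestion plus length filtering for that library (recorded
in the table metadata so alternative denominators remain comparable).
Floats are written at 6 significant digits; full precision is kept
internally.

Replicate reports compute Pearson and Spearman (mid-ranks for ties, via
scipy) on the per-pair common subset of genes with RPKM ≥ 10 in both
members. Raw RPKM is the default; a `--log10` option exists and its use is
recorded, since either convention is defensible and the correlation on raw
values is dominated by high-expression genes. Pairs whose subset has fewer
than 3 genes are flagged undefined rather than reported.

## Simulator

The generator emulates the empirical structure of RPF libraries:

- **Transcriptome** — `n_genes` single-exon transcripts (the reference *is*
  the transcriptome, matching the alignment convention), CDS starting ATG
  and ending in a stop, internal codons uniform over the 61 sense codons,
  UTR lengths uniform in (50–200, 100–400) nt and CDS 100–400 codons —
  typical mRNA geometry at desk scale.
- **Abundances** — log-normal (σ = 1) shared across replicate libraries;
  an explicit vector and per-gene loading multipliers are accepted for
  translation-efficiency experiments.
- **Ribo-seq reads** — gene drawn ∝ abundance × loading × CDS length;
  P-site codon drawn from a dwell profile that is uniform except for a 5×
  weight on the initiation codon (`start_codon_peak`) — metagene profiles
  of real libraries show their dominant peak at the start codon, and
  without it the profile mode would be sampling noise; optional per-codon
  identity multipliers (`dwell_weights`) hook codon-dependent occupancy.
  With probability `periodicity_fidelity` (default 0.9) the 5′ end is
  placed exactly offset nt upstream of the P site, otherwise jittered
  ±1 nt. Lengths come from a bimodal mixture with 40% mass at 20–22 and
  60% at 27–29 nt. Reads that would overhang the transcript are redrawn and
  tallied (none occur under the default geometry).
- **RNA-seq reads** — gene drawn ∝ abundance × transcript length, 5′ end
  uniform over *all* transcript positions with the read truncated at the
  transcript 3′ end. The truncation keeps 5′-end coverage exactly uniform,
  so region fractions are exactly proportional to region lengths; without
  it the 3′UTR would be undercounted by roughly a read length.
- **Determinism** — one base seed; each library uses an independent
  substream (transcriptome index 0, Ribo libraries 1…, RNA libraries
  101…), so replicates are independent but every file is byte-identical
  across runs of the same seed. Reads are emitted pre-aligned as
  sense-strand SAM, keeping the external aligner out of the test loop; a
  FASTQ writer exists for end-to-end demos.

Default depth is 50,000 reads per library, which resolves the −12 metagene
mode and frame fractions to ±0.01 in under a minute on one CPU; the deep
recovery and replicate checks use 10⁶ reads.

What the simulator does *not* emulate: sequencing errors, adapter
contamination, rRNA/tRNA reads, multi-isoform genes, non-uniform
nucleotide composition, and upstream preprocessing generally. Passing tests
therefore demonstrate correctness of the analysis arithmetic and its
statistical behaviour under the stated generative model, not robustness to
real-library artifacts, which are assumed to be handled by the upstream
alignment stack.

## Numerical and degenerate-input choices

- Metagene ties break toward the smallest position (deterministic output).
- Empty inputs yield flagged-undefined fractions (NaN / None), never
  exceptions; malformed GFF3 and truncated SAM raise format/I-O errors.
- Correlation is undefined (None/NaN) below 3 points or at zero variance.
- RPKM with zero CDS length or zero library size is a domain error.
- Length-window filtering with an empty window list is a documented no-op.

## Known limitations

- One P-site offset for all lengths is the pipeline's convention; the
  metagene module is the tool to check whether a per-length table would fit
  a given library better.
- Real-data reproduction of published correlation tables would need the
  original raw libraries and reference annotation bundle; the replicate
  statistics here are validated behaviourally on simulated replicates.
- The quantification denominator definition (see above) is one of several
  in use; comparisons across toolkits should match denominators first.
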