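"""Dataset-validation analyses: region distribution, start-codon metagene
profiles, and reading-frame / triplet-periodicity summaries.

Genuine ribosome footprints concentrate in coding sequences and phase their
5' ends with the reading frame; total-RNA fragments do neither. These three
diagnostics quantify that contrast for a library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from riboprof.alignments import FootprintRecord, LengthWindows
from riboprof.annotation import Region, TranscriptSet, region_of
from riboprof.psite import SiteAnnotatedRecord

DEFAULT_METAGENE_WINDOW = (-40, 60)


@dataclass
class RegionDistribution:
    """Counts and fractions of reads per mRNA region (5'UTR / CDS / 3'UTR)."""

    counts: dict[Region, int] = field(
        default_factory=lambda: {r: 0 for r in Region}
    )
    n_skipped: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def defined(self) -> bool:
        return self.total > 0

    @property
    def fractions(self) -> dict[Region, float]:
        """Fractions over assigned records; all-NaN when no record assigned."""
        total = self.total
        if not total:
            return {r: float("nan") for r in Region}
        return {r: c / total for r, c in self.counts.items()}


@dataclass
class MetageneProfile:
    """5'-end counts relative to the first nucleotide of the start codon.

    ``counts`` covers every integer of ``[window[0], window[1]]`` exactly.
    """

    window: tuple[int, int]
    counts: dict[int, int]
    length_class: str

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def modal_position(self) -> Optional[int]:
        """Relative position with the highest count (smallest on ties);
        None for an empty profile."""
        if self.total == 0:
            return None
        return max(sorted(self.counts), key=lambda k: self.counts[k])

    def fractions(self) -> dict[int, float]:
        total = self.total
        return {k: (v / total if total else 0.0) for k, v in self.counts.items()}


@dataclass
class FrameDistribution:
    """Per-length-class counts of P-sites in each reading frame {0,1,2}."""

    counts: dict[str, list[int]] = field(default_factory=dict)

    def fractions(self, length_class: str) -> Optional[tuple[float, float, float]]:
        c = self.counts.get(length_class)
        if c is None or sum(c) == 0:
            return None
        total = sum(c)
        return tuple(x / total for x in c)  # type: ignore[return-value]

    @property
    def classes(self) -> list[str]:
        return sorted(self.counts)


RecordOrAnnotated = Union[FootprintRecord, SiteAnnotatedRecord]


def region_distribution(
    records: Iterable[RecordOrAnnotated],
    models: TranscriptSet,
    mode: str = "psite",
) -> RegionDistribution:
    """Assign each read to one region and tally.

    mode="psite" anchors Ribo-seq reads at the P-site (records must be
    :class:`SiteAnnotatedRecord`; invalid placements are skipped and
    tallied). mode="five_prime" anchors RNA-seq reads at the raw 5' end.
    """
    if mode not in ("psite", "five_prime"):
        raise ValueError(f"unknown mode {mode!r}")
    dist = RegionDistribution()
    for rec in records:
        if mode == "psite":
            assert isinstance(rec, SiteAnnotatedRecord)
            if not rec.valid or rec.region is None:
                dist.n_skipped += 1
                continue
            dist.counts[rec.region] += 1
        else:
            base = rec.base if isinstance(rec, SiteAnnotatedRecord) else rec
            if base.transcript_id not in models:
                dist.n_skipped += 1
                continue
            model = models[base.transcript_id]
            if not 0 <= base.five_prime < model.length:
                dist.n_skipped += 1
                continue
            dist.counts[region_of(model, base.five_prime)] += 1
    return dist


def metagene_start_profile(
    records: Iterable[FootprintRecord],
    models: TranscriptSet,
    window: tuple[int, int] = DEFAULT_METAGENE_WINDOW,
    length_classes: Optional[LengthWindows] = None,
) -> dict[str, MetageneProfile]:
    """Aggregate 5'-end positions relative to the start codon, one profile
    per fragment-length class.

    For each read the relative position is ``five_prime - utr5_len`` of its
    transcript; reads outside ``[lo, hi]`` or outside every length class are
    not counted. With ``length_classes=None`` a single profile labelled
    "all" is produced.
    """
    lo, hi = window
    if not (lo < 0 < hi):
        raise ValueError(f"metagene window must straddle 0, got [{lo},{hi}]")
    if length_classes is None or not length_classes.windows:
        labels = ["all"]
        label_of = lambda length: "all"  # noqa: E731
    else:
        labels = length_classes.labels()
        label_of = length_classes.label_of
    profiles = {
        lab: MetageneProfile(window=window, counts={k: 0 for k in range(lo, hi + 1)},
                             length_class=lab)
        for lab in labels
    }
    for rec in records:
        lab = label_of(rec.length)
        if lab is None or rec.transcript_id not in models:
            continue
        rel = rec.five_prime - models[rec.transcript_id].utr5_len
        if lo <= rel <= hi:
            profiles[lab].counts[rel] += 1
    return profiles


def frame_distribution(
    records: Iterable[SiteAnnotatedRecord],
    length_classes: Optional[LengthWindows] = None,
) -> FrameDistribution:
    """Per-length-class distribution of P-site reading frames.

    Only records with a defined frame (valid placement, P-site in a complete
    CDS) contribute.
    """
    if length_classes is None or not length_classes.windows:
        label_of = lambda length: "all"  # noqa: E731
        labels = ["all"]
    else:
        label_of = length_classes.label_of
        labels = length_classes.labels()
    fd = FrameDistribution(counts={lab: [0, 0, 0] for lab in labels})
    for rec in records:
        if rec.frame is None:
            continue
        lab = label_of(rec.base.length)
        if lab is None:
            continue
        fd.counts[lab][rec.frame] += 1
    return fd


def periodicity_score(fd: FrameDistribution) -> dict[str, Optional[float]]:
    """Maximum frame fraction per length class, in [1/3, 1].

    1.0 means perfect triplet phasing; 1/3 means none. None flags an empty
    (unpopulated) class.
    """
    scores: dict[str, Optional[float]] = {}
    for lab in fd.classes:
        fr = fd.fractions(lab)
        scores[lab] = max(fr) if fr is not None else None
    return scores
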