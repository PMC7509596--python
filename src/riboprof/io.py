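"""TSV writers for QC outputs.

One tabular dialect everywhere: tab-separated, header row, '.' decimal,
floats rounded to 6 significant digits at the writing layer only.
"""

from __future__ import annotations

from pathlib import Path

from riboprof.alignments import LengthHistogram
from riboprof.annotation import Region
from riboprof.qc import FrameDistribution, MetageneProfile, RegionDistribution


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_lengths_tsv(hist: LengthHistogram, path: str | Path) -> None:
    total = hist.total
    with open(path, "w") as fh:
        fh.write("length\tcount\tfraction\n")
        for length in sorted(hist.counts):
            c = hist.counts[length]
            frac = c / total if total else 0.0
            fh.write(f"{length}\t{c}\t{_fmt(frac)}\n")


def write_regions_tsv(dist: RegionDistribution, path: str | Path) -> None:
    fractions = dist.fractions
    with open(path, "w") as fh:
        fh.write("region\tcount\tfraction\n")
        for region in Region:
            frac = fractions[region]
            frac_s = _fmt(frac) if dist.defined else "NA"
            fh.write(f"{region.value}\t{dist.counts[region]}\t{frac_s}\n")


def write_metagene_tsv(profiles: dict[str, MetageneProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("length_class\tposition\tcount\tfraction\n")
        for label in sorted(profiles):
            prof = profiles[label]
            fracs = prof.fractions()
            for pos in sorted(prof.counts):
                fh.write(
                    f"{label}\t{pos}\t{prof.counts[pos]}\t{_fmt(fracs[pos])}\n"
                )


def write_frames_tsv(fd: FrameDistribution, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("length_class\tframe\tcount\tfraction\n")
        for label in fd.classes:
            fractions = fd.fractions(label)
            for frame in range(3):
                frac_s = _fmt(fractions[frame]) if fractions is not None else "NA"
                fh.write(f"{label}\t{frame}\t{fd.counts[label][frame]}\t{frac_s}\n")
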