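"""Library-normalized, region-scaled positional density profiles.

Point events (iCLIP RT stops, or ribosome footprints reduced to their
midpoints) are projected onto transcript coordinates, binned over a
composite region layout (e.g. 5'UTR/CDS/3'UTR each scaled to 200 bins, or
a scaled 5'UTR with fixed 50-nt flanks), normalized to a fixed library
size (counts per 10 million for iCLIP, counts per million for
footprints), and averaged over contributing transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import (
    FootprintRecord,
    RTStopRecord,
    TranscriptModel,
    canonical_transcripts,
)

UNIT_FACTORS = {"CP10M": 1e7, "CPM": 1e6}


class MetageneError(ValueError):
    pass


@dataclass(frozen=True)
class Segment:
    """One piece of a composite metagene layout."""

    name: str  # flank5 | UTR5 | CDS | UTR3 | flank3
    n_bins: int
    scaled: bool = True

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise MetageneError("segment needs >= 1 bin")


@dataclass(frozen=True)
class RegionSpec:
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise MetageneError("RegionSpec needs >= 1 segment")

    @property
    def total_bins(self) -> int:
        return sum(s.n_bins for s in self.segments)

    def offsets(self) -> list[int]:
        """Start bin of each segment in the concatenated profile."""
        out, acc = [], 0
        for s in self.segments:
            out.append(acc)
            acc += s.n_bins
        return out


def three_region_spec(n_bins: int = 200) -> RegionSpec:
    """UTR5/CDS/UTR3, each scaled to ``n_bins`` bins."""
    return RegionSpec(
        tuple(Segment(name, n_bins, True) for name in ("UTR5", "CDS", "UTR3"))
    )


def utr5_flank_spec(utr5_bins: int = 100, flank: int = 50) -> RegionSpec:
    """Scaled 5'UTR with fixed 1-nt/bin flanks up- and downstream."""
    return RegionSpec(
        (
            Segment("flank5", flank, False),
            Segment("UTR5", utr5_bins, True),
            Segment("flank3", flank, False),
        )
    )


@dataclass
class MetageneProfile:
    spec: RegionSpec
    values: np.ndarray
    unit: str
    n_transcripts: int
    library_size: int
    segment_n: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.total_bins,):
            raise MetageneError("value count must equal total bins")
        if not np.all(np.isfinite(self.values)) or (self.values < 0).any():
            raise MetageneError("profile values must be finite and >= 0")

    def segment_values(self, name: str) -> np.ndarray:
        for seg, off in zip(self.spec.segments, self.spec.offsets()):
            if seg.name == name:
                return self.values[off : off + seg.n_bins]
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for seg, off in zip(self.spec.segments, self.spec.offsets()):
            for b in range(seg.n_bins):
                rows.append((seg.name, b, self.values[off + b]))
        return pd.DataFrame(rows, columns=["segment", "bin", "value"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def normalize_density(count: float, library_size: float, unit: str = "CP10M") -> float:
    """Rescale an event count to a fixed library size (CP10M or CPM)."""
    if library_size <= 0:
        raise MetageneError("library_size must be > 0")
    return count * UNIT_FACTORS[unit] / library_size


def bin_scaled(pos: int, region_len: int, n_bins: int) -> int:
    """Bin index of a position within a region scaled to ``n_bins`` bins."""
    if region_len < 1:
        raise MetageneError("region_len must be >= 1")
    if not 0 <= pos < region_len:
        raise MetageneError(f"pos {pos} outside region [0, {region_len})")
    return pos * n_bins // region_len


@dataclass(frozen=True)
class TranscriptEvent:
    """A point event with a count, in mature-transcript coordinates.

    ``tpos`` may be negative (5' flank) or >= mature_length (3' flank)
    when projected with a flank allowance.
    """

    transcript_id: str
    tpos: int
    count: int


def project_stops(
    stops: Sequence[RTStopRecord],
    models: Sequence[TranscriptModel],
    flank: int = 0,
    coding_only: bool = True,
) -> list[TranscriptEvent]:
    """Project genomic point events onto canonical transcripts.

    Each event is assigned to at most one transcript (one canonical model
    per gene, sense strand only); events within ``flank`` nt outside the
    transcript ends project to flank coordinates.
    """
    usable = [m for m in models if m.is_coding or not coding_only]
    per_gene = canonical_transcripts(usable)
    trees: dict[tuple[str, str], IntervalTree] = {}
    for m in per_gene.values():
        g0 = m.exon_blocks[0][0] - flank
        g1 = m.exon_blocks[-1][1] + flank
        trees.setdefault((m.chrom, m.strand), IntervalTree()).addi(g0, g1, m)
    events: list[TranscriptEvent] = []
    for s in stops:
        tree = trees.get((s.chrom, s.strand))
        if tree is None:
            continue
        hits = sorted(
            (iv.data for iv in tree.at(s.pos)),
            key=lambda m: (-m.mature_length, m.transcript_id),
        )
        for m in hits:
            tpos = m.genomic_to_transcript_with_flank(s.pos, flank)
            if tpos is not None:
                events.append(TranscriptEvent(m.transcript_id, tpos, s.count))
                break
    return events


def _segment_interval(
    model: TranscriptModel, seg: Segment
) -> Optional[tuple[int, int]]:
    """Transcript-coordinate interval a segment covers for one model, or
    None when the model lacks that region."""
    if seg.name == "flank5":
        return (-seg.n_bins, 0)
    if seg.name == "flank3":
        return (model.mature_length, model.mature_length + seg.n_bins)
    if not model.is_coding:
        return None
    iv = model.partition_regions().get(seg.name)
    if iv is None or iv[1] <= iv[0]:
        return None
    return iv


def _flank_fits(
    model: TranscriptModel, flank: int, chrom_sizes: Optional[Mapping[str, int]]
) -> bool:
    g0 = model.exon_blocks[0][0] - flank
    g1 = model.exon_blocks[-1][1] + flank
    if g0 < 0:
        return False
    if chrom_sizes is not None and g1 > chrom_sizes[model.chrom]:
        return False
    return True


def metagene_profile(
    events: Sequence[TranscriptEvent],
    models: Mapping[str, TranscriptModel],
    spec: RegionSpec,
    unit: str = "CP10M",
    library_size: int = 0,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> MetageneProfile:
    """Average event density per bin over a composite region layout.

    Per bin: the library-normalized sum of event counts divided by the
    number of transcripts contributing to that bin's segment, so
    transcripts lacking a region (e.g. zero-length 5'UTR) do not dilute
    that segment's bins.
    """
    if library_size <= 0:
        raise MetageneError("library_size must be > 0")
    if unit not in UNIT_FACTORS:
        raise MetageneError(f"unknown unit {unit!r}")

    offsets = spec.offsets()
    segment_n: dict[str, int] = {}
    for seg in spec.segments:
        n = 0
        for m in models.values():
            if _segment_interval(m, seg) is None:
                continue
            if seg.name in ("flank5", "flank3") and not _flank_fits(
                m, seg.n_bins, chrom_sizes
            ):
                continue
            n += 1
        segment_n[seg.name] = n
    if all(n == 0 for n in segment_n.values()):
        raise MetageneError("no usable transcripts for any segment")

    raw = np.zeros(spec.total_bins, dtype=float)
    for ev in events:
        m = models.get(ev.transcript_id)
        if m is None:
            continue
        for seg, off in zip(spec.segments, offsets):
            iv = _segment_interval(m, seg)
            if iv is None or not iv[0] <= ev.tpos < iv[1]:
                continue
            if seg.name in ("flank5", "flank3") and not _flank_fits(
                m, seg.n_bins, chrom_sizes
            ):
                continue
            rel = ev.tpos - iv[0]
            b = rel if not seg.scaled else bin_scaled(rel, iv[1] - iv[0], seg.n_bins)
            raw[off + b] += ev.count
            break

    values = raw * UNIT_FACTORS[unit] / library_size
    for seg, off in zip(spec.segments, offsets):
        n = segment_n[seg.name]
        sl = slice(off, off + seg.n_bins)
        values[sl] = values[sl] / n if n > 0 else 0.0

    return MetageneProfile(
        spec=spec,
        values=values,
        unit=unit,
        n_transcripts=max(segment_n.values()),
        library_size=library_size,
        segment_n=segment_n,
    )


def total_events(profile: MetageneProfile) -> float:
    """Recover the total event count that landed in the layout's regions
    (inverts normalization and per-segment averaging)."""
    total = 0.0
    for seg, off in zip(profile.spec.segments, profile.spec.offsets()):
        n = profile.segment_n.get(seg.name, profile.n_transcripts)
        seg_sum = profile.values[off : off + seg.n_bins].sum()
        total += seg_sum * n * profile.library_size / UNIT_FACTORS[profile.unit]
    return total


def ratio_profile(
    treated: MetageneProfile,
    untreated: MetageneProfile,
    pseudocount: float = 0.1,
    log2: bool = False,
) -> np.ndarray:
    """Per-bin treated/untreated density ratio with a pseudocount in
    density units."""
    if treated.spec != untreated.spec or treated.unit != untreated.unit:
        raise MetageneError("profiles have mismatched layout or unit")
    if pseudocount <= 0:
        raise MetageneError("pseudocount must be > 0")
    ratio = (treated.values + pseudocount) / (untreated.values + pseudocount)
    return np.log2(ratio) if log2 else ratio


def reference_coverage(
    stops: Sequence[RTStopRecord],
    ref_len: int,
    library_size: int,
    unit: str = "CP10M",
) -> np.ndarray:
    """Per-nucleotide normalized RT-stop density along a single reference
    (e.g. the rRNA transcribed region)."""
    cov = np.zeros(ref_len, dtype=float)
    for s in stops:
        if s.pos >= ref_len:
            raise MetageneError(
                f"stop at {s.pos} beyond reference length {ref_len}"
            )
        cov[s.pos] += s.count
    return cov * UNIT_FACTORS[unit] / library_size if library_size > 0 else cov


def footprint_midpoints(
    fps: Sequence[FootprintRecord], anchor: str = "mid"
) -> list[RTStopRecord]:
    """Reduce footprint intervals to point events; duplicate points
    aggregate into one record with a summed count.

    ``anchor="mid"`` uses the fragment midpoint (length-robust);
    ``anchor="5p"`` uses the strand-aware 5' end.
    """
    if anchor not in ("mid", "5p"):
        raise MetageneError(f"unknown anchor {anchor!r}")
    agg: dict[tuple[str, int, str], int] = {}
    for f in fps:
        if anchor == "mid":
            pos = (f.start + f.end) // 2
        else:
            pos = f.start if f.strand == "+" else f.end - 1
        key = (f.chrom, pos, f.strand)
        agg[key] = agg.get(key, 0) + 1
    return [
        RTStopRecord(chrom, pos, strand, count)
        for (chrom, pos, strand), count in sorted(agg.items())
    ]
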