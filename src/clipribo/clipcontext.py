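"""Ribosome-footprint density and sequence context around merged
crosslink sites.

Crosslink positions on one transcript are merged by single-linkage
chaining (sites within 100 bp join one cluster, represented by its center)
so that dense binding regions do not dominate averages.  Footprints are
filtered by mapping quality, contracted to a fixed 30-bp interval around
their midpoint, and counted per offset around each site center; the
per-site coverage matrix is library-normalized, trimmed of the 0.1%
highest-coverage sites, and averaged to mean +/- SEM.  GC content around
sites uses a 10-bp sliding window whose 6th base is the queried position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import FootprintRecord, TranscriptModel, canonical_transcripts


class ClipContextError(ValueError):
    pass


@dataclass(frozen=True)
class MergedSite:
    seq_id: str
    center: int
    n_constituents: int = 1
    region_label: Optional[str] = None  # UTR5 | CDS | UTR3


@dataclass(frozen=True)
class ContractedInterval:
    """Half-open interval on one sequence (transcript or reference)."""

    seq_id: str
    start: int
    end: int


@dataclass
class SiteProfileMatrix:
    """Sites x offsets library-normalized coverage."""

    offsets: np.ndarray  # -F..F inclusive
    matrix: np.ndarray  # shape (n_sites, 2F+1)
    sites: list[MergedSite]
    library_size: float

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]


def merge_sites(
    positions: Sequence[int],
    merge_distance: int = 100,
    seq_id: str = "",
) -> list[MergedSite]:
    """Single-linkage chaining of crosslink positions on one sequence.

    Consecutive sorted positions <= ``merge_distance`` apart join one
    cluster; the cluster is represented by the rounded mean of its
    constituent positions (exact halves round down).
    """
    if not positions:
        return []
    pos = sorted(positions)
    clusters: list[list[int]] = [[pos[0]]]
    for p in pos[1:]:
        if p - clusters[-1][-1] <= merge_distance:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    out = []
    for c in clusters:
        mean = sum(c) / len(c)
        center = math.ceil(mean - 0.5)  # round half down
        out.append(MergedSite(seq_id=seq_id, center=center, n_constituents=len(c)))
    return out


def merge_sites_by_sequence(
    positions: Mapping[str, Sequence[int]], merge_distance: int = 100
) -> list[MergedSite]:
    out: list[MergedSite] = []
    for seq_id in sorted(positions):
        out.extend(merge_sites(positions[seq_id], merge_distance, seq_id))
    return out


def label_sites(
    sites: Sequence[MergedSite], models: Mapping[str, TranscriptModel]
) -> list[MergedSite]:
    """Attach UTR5/CDS/UTR3 labels from the transcript partition; sites on
    unknown transcripts or outside [0, mature_length) keep label None."""
    out = []
    for s in sites:
        m = models.get(s.seq_id)
        label = None
        if m is not None and m.is_coding and 0 <= s.center < m.mature_length:
            label = m.region_of(s.center)
        out.append(replace(s, region_label=label))
    return out


def contract_footprints(
    fps: Sequence[FootprintRecord],
    target_len: int = 30,
    mapq_min: int = 20,
    anchor: str = "mid",
) -> list[ContractedInterval]:
    """Drop low-quality alignments and replace each fragment by a
    ``target_len`` interval.

    ``anchor="mid"`` centers the interval on the fragment midpoint;
    ``anchor="5p"`` anchors it at the strand-aware 5' end.
    """
    if anchor not in ("mid", "5p"):
        raise ClipContextError(f"unknown anchor {anchor!r}")
    half = target_len // 2
    out = []
    for f in fps:
        if f.mapq < mapq_min:
            continue
        if anchor == "mid":
            start = (f.start + f.end) // 2 - half
        elif f.strand == "+":
            start = f.start
        else:
            start = f.end - target_len
        out.append(ContractedInterval(f.chrom, start, start + target_len))
    return out


def project_footprints(
    fps: Sequence[FootprintRecord],
    models: Sequence[TranscriptModel],
) -> list[FootprintRecord]:
    """Map genomic footprints onto canonical transcript coordinates.

    The fragment is assigned by its midpoint (sense strand, one canonical
    transcript per gene); unassignable fragments are dropped.  Returned
    records use the transcript id as ``chrom`` and '+' strand, preserving
    fragment length and MAPQ.
    """
    from intervaltree import IntervalTree

    per_gene = canonical_transcripts([m for m in models if m.is_coding])
    trees: dict[tuple[str, str], IntervalTree] = {}
    for m in per_gene.values():
        trees.setdefault((m.chrom, m.strand), IntervalTree()).addi(
            m.exon_blocks[0][0], m.exon_blocks[-1][1], m
        )
    out = []
    for f in fps:
        mid = (f.start + f.end) // 2
        tree = trees.get((f.chrom, f.strand))
        if tree is None:
            continue
        best = None
        for iv in tree.at(mid):
            m = iv.data
            t = m.genomic_to_transcript(mid)
            if t is not None and (
                best is None
                or (m.mature_length, m.transcript_id)
                > (best[0].mature_length, best[0].transcript_id)
            ):
                best = (m, t)
        if best is None:
            continue
        m, tmid = best
        length = f.end - f.start
        start = tmid - length // 2
        out.append(
            FootprintRecord(
                chrom=m.transcript_id,
                start=start,
                end=start + length,
                strand="+",
                mapq=f.mapq,
                sample_id=f.sample_id,
            )
        )
    return out


def coverage_matrix(
    intervals: Sequence[ContractedInterval],
    sites: Sequence[MergedSite],
    flank: int = 100,
    library_size: float = 1.0,
    unit_factor: float = 1e6,
) -> SiteProfileMatrix:
    """Per-site coverage of contracted fragments at offsets -flank..flank
    around each site center, normalized to counts per million."""
    if library_size <= 0:
        raise ClipContextError("library_size must be > 0")
    offsets = np.arange(-flank, flank + 1)
    width = 2 * flank + 1
    matrix = np.zeros((len(sites), width), dtype=float)

    by_seq: dict[str, list[ContractedInterval]] = {}
    for iv in intervals:
        by_seq.setdefault(iv.seq_id, []).append(iv)
    site_idx: dict[str, list[int]] = {}
    for i, s in enumerate(sites):
        site_idx.setdefault(s.seq_id, []).append(i)

    for seq_id, idxs in site_idx.items():
        ivs = by_seq.get(seq_id)
        if not ivs:
            continue
        centers = np.array([sites[i].center for i in idxs])
        lo = int(centers.min()) - flank
        hi = int(centers.max()) + flank + 1
        diff = np.zeros(hi - lo + 1, dtype=np.int64)
        for iv in ivs:
            a, b = max(iv.start, lo), min(iv.end, hi)
            if a < b:
                diff[a - lo] += 1
                diff[b - lo] -= 1
        cov = np.cumsum(diff)[:-1]
        for i, c in zip(idxs, centers):
            matrix[i] = cov[c - flank - lo : c + flank + 1 - lo]

    matrix *= unit_factor / library_size
    return SiteProfileMatrix(
        offsets=offsets, matrix=matrix, sites=list(sites), library_size=library_size
    )


def remove_outliers(
    matrix: SiteProfileMatrix, fraction: float = 0.001
) -> SiteProfileMatrix:
    """Drop the ceil(fraction * n_sites) sites with highest total row
    coverage, so rare extremely occupied sites do not skew the average."""
    if not 0 <= fraction < 1:
        raise ClipContextError("fraction must be in [0, 1)")
    n_drop = math.ceil(fraction * matrix.n_sites)
    if n_drop == 0:
        return matrix
    totals = matrix.matrix.sum(axis=1)
    # stable order: among ties, later rows dropped first is arbitrary; use
    # argsort (stable) and drop the top-n_drop by total
    order = np.argsort(totals, kind="stable")
    keep = np.sort(order[: matrix.n_sites - n_drop])
    return SiteProfileMatrix(
        offsets=matrix.offsets,
        matrix=matrix.matrix[keep],
        sites=[matrix.sites[i] for i in keep],
        library_size=matrix.library_size,
    )


def average_profile(matrix: SiteProfileMatrix) -> pd.DataFrame:
    """Mean and standard error of the mean per offset over sites."""
    if matrix.n_sites == 0:
        raise ClipContextError("no sites to average")
    mean = matrix.matrix.mean(axis=0)
    if matrix.n_sites >= 2:
        sem = matrix.matrix.std(axis=0, ddof=1) / math.sqrt(matrix.n_sites)
    else:
        sem = np.zeros_like(mean)
    return pd.DataFrame(
        {
            "offset": matrix.offsets,
            "mean": mean,
            "sem": sem,
            "n_sites": matrix.n_sites,
        }
    )


def cds_sites_excluding_start(
    sites: Sequence[MergedSite],
    models: Mapping[str, TranscriptModel],
    exclusion: int = 200,
) -> list[MergedSite]:
    """Keep CDS-labelled sites at least ``exclusion`` nt downstream of the
    start codon (initiation-proximal footprint pileups excluded)."""
    out = []
    for s in sites:
        if s.region_label != "CDS":
            continue
        m = models.get(s.seq_id)
        if m is None:
            continue
        if s.center >= m.utr5_len + exclusion:
            out.append(s)
    return out


def gc_profile(
    seq_source: Mapping[str, str],
    sites: Sequence[MergedSite],
    flank: int = 100,
    window: int = 10,
    center_index: int = 6,
) -> pd.DataFrame:
    """Mean GC fraction per offset around site centers.

    At offset o the window spans ``window`` bases with the queried base at
    position ``center_index`` (1-based) inside it.  Windows running off a
    sequence end are excluded at that offset only.
    """
    offsets = np.arange(-flank, flank + 1)
    lead = center_index - 1
    rows = np.full((len(sites), offsets.size), np.nan)
    for i, s in enumerate(sites):
        seq = str(seq_source[s.seq_id]).upper()
        gc = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_gc = ((gc == ord("G")) | (gc == ord("C"))).astype(float)
        csum = np.concatenate([[0.0], np.cumsum(is_gc)])
        for j, o in enumerate(offsets):
            a = s.center + o - lead
            b = a + window
            if a < 0 or b > len(seq):
                continue
            rows[i, j] = (csum[b] - csum[a]) / window
    n = np.sum(~np.isnan(rows), axis=0)
    with np.errstate(invalid="ignore"):
        sums = np.nansum(rows, axis=0)
    mean = np.divide(sums, n, out=np.full(n.shape, np.nan), where=n > 0)
    return pd.DataFrame({"offset": offsets, "gc": mean, "n_sites": n})


def base_composition_around_stops(
    positions: Sequence[tuple[str, int]],
    seq_source: Mapping[str, str],
    flank: int = 20,
    counts: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Per-offset A/C/G/U frequency around crosslink positions.

    ``positions`` are (sequence id, 0-based position) pairs; DNA input is
    reported with U in place of T.  Columns sum to 1 over offsets where
    any base is present.
    """
    offsets = np.arange(-flank, flank + 1)
    bases = "ACGU"
    tallies = np.zeros((4, offsets.size), dtype=float)
    if counts is None:
        counts = [1] * len(positions)
    for (seq_id, pos), w in zip(positions, counts):
        seq = str(seq_source[seq_id]).upper().replace("T", "U")
        for j, o in enumerate(offsets):
            p = pos + o
            if 0 <= p < len(seq):
                b = seq[p]
                if b in bases:
                    tallies[bases.index(b), j] += w
    col = tallies.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(col > 0, tallies / col, np.nan)
    df = pd.DataFrame(freq.T, columns=list(bases))
    df.insert(0, "offset", offsets)
    return df
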