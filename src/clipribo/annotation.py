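"""Transcript annotation, coordinate mapping, and event classification.

The transcript coordinate system is 0-based, half-open, and runs 5'->3'
along the mature (spliced) transcript.  Genomic input follows BED
conventions: BED12 for transcript models (thickStart/thickEnd encode the
CDS), BED6 for single-nucleotide RT-stop events (score = crosslink count)
and for ribosome footprints (score = mapping quality).

Transcript class (mRNA, rRNA, ...) is carried in the BED12 name field as
``transcript_id|gene_id|gene_class``; a bare name is treated as both
transcript and gene id, with class inferred from the thick interval
(mRNA if a CDS is present, otherwise "other").
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


class GeneClass(str, enum.Enum):
    MRNA = "mRNA"
    RRNA = "rRNA"
    PSEUDOGENE = "pseudogene"
    LNCRNA = "lncRNA"
    OTHER = "other"


#: assignment priority when an event overlaps several transcript classes
CLASS_PRIORITY = (
    GeneClass.RRNA,
    GeneClass.MRNA,
    GeneClass.PSEUDOGENE,
    GeneClass.LNCRNA,
    GeneClass.OTHER,
)

REGIONS = ("UTR5", "CDS", "UTR3")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript with its 5'UTR / CDS / 3'UTR partition."""

    transcript_id: str
    gene_id: str
    gene_class: GeneClass
    chrom: str
    strand: str  # '+' or '-'
    exon_blocks: tuple[tuple[int, int], ...]
    cds_genomic: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"bad strand {self.strand!r}")
        blocks = self.exon_blocks
        if not blocks:
            raise AnnotationError("transcript with no exon blocks")
        for (s, e) in blocks:
            if e <= s:
                raise AnnotationError(f"empty exon block ({s}, {e})")
        for (_, e0), (s1, _) in zip(blocks, blocks[1:]):
            if s1 < e0:
                raise AnnotationError("exon blocks overlap or are unsorted")
        if self.cds_genomic is not None:
            cs, ce = self.cds_genomic
            if ce <= cs:
                raise AnnotationError("empty CDS interval")
            if cs < blocks[0][0] or ce > blocks[-1][1]:
                raise AnnotationError("thick interval outside exons")

    # -- derived lengths ------------------------------------------------

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exon_blocks)

    @property
    def is_coding(self) -> bool:
        return self.cds_genomic is not None

    def _left_right_cds_lengths(self) -> tuple[int, int, int]:
        """Exonic nt left of, inside, and right of the thick interval."""
        cs, ce = self.cds_genomic  # type: ignore[misc]
        left = inside = right = 0
        for s, e in self.exon_blocks:
            left += max(0, min(e, cs) - s)
            inside += max(0, min(e, ce) - max(s, cs))
            right += max(0, e - max(s, ce))
        return left, inside, right

    @property
    def cds_len(self) -> int:
        if not self.is_coding:
            return 0
        return self._left_right_cds_lengths()[1]

    @property
    def utr5_len(self) -> int:
        if not self.is_coding:
            return 0
        left, _, right = self._left_right_cds_lengths()
        return left if self.strand == "+" else right

    @property
    def utr3_len(self) -> int:
        if not self.is_coding:
            return 0
        left, _, right = self._left_right_cds_lengths()
        return right if self.strand == "+" else left

    # -- coordinate mapping ---------------------------------------------

    def genomic_to_transcript(self, gpos: int) -> Optional[int]:
        """Mature-transcript position of a genomic nt, or None if intronic
        or outside the transcript."""
        offset = 0
        for s, e in self.exon_blocks:
            if s <= gpos < e:
                plus = offset + (gpos - s)
                if self.strand == "+":
                    return plus
                return self.mature_length - 1 - plus
            offset += e - s
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        """Inverse of :meth:`genomic_to_transcript` for exonic positions."""
        if not 0 <= tpos < self.mature_length:
            raise AnnotationError(f"transcript position {tpos} out of range")
        plus = tpos if self.strand == "+" else self.mature_length - 1 - tpos
        offset = 0
        for s, e in self.exon_blocks:
            if plus < offset + (e - s):
                return s + (plus - offset)
            offset += e - s
        raise AssertionError("unreachable")

    def genomic_to_transcript_with_flank(
        self, gpos: int, flank: int
    ) -> Optional[int]:
        """Like :meth:`genomic_to_transcript` but also projects genomic
        positions within ``flank`` nt outside the transcript ends, as
        negative coordinates (5' flank) or >= mature_length (3' flank)."""
        t = self.genomic_to_transcript(gpos)
        if t is not None:
            return t
        g0, g1 = self.exon_blocks[0][0], self.exon_blocks[-1][1]
        if g0 - flank <= gpos < g0:
            d = g0 - gpos  # 1..flank
            return -d if self.strand == "+" else self.mature_length - 1 + d
        if g1 <= gpos < g1 + flank:
            d = gpos - (g1 - 1)  # 1..flank
            return self.mature_length - 1 + d if self.strand == "+" else -d
        return None

    def partition_regions(self) -> dict[str, tuple[int, int]]:
        """UTR5/CDS/UTR3 as half-open transcript intervals tiling
        [0, mature_length)."""
        if not self.is_coding:
            raise AnnotationError(
                f"transcript {self.transcript_id} has no CDS"
            )
        u5, cds = self.utr5_len, self.cds_len
        return {
            "UTR5": (0, u5),
            "CDS": (u5, u5 + cds),
            "UTR3": (u5 + cds, self.mature_length),
        }

    def region_of(self, tpos: int) -> str:
        for name, (s, e) in self.partition_regions().items():
            if s <= tpos < e:
                return name
        raise AnnotationError(f"position {tpos} outside transcript")


@dataclass(frozen=True)
class RTStopRecord:
    """Single-nucleotide crosslink event (reverse-transcriptase stop)."""

    chrom: str
    pos: int
    strand: str
    count: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise AnnotationError("negative RT stop position")
        if self.count < 1:
            raise AnnotationError("RT stop count must be >= 1")


@dataclass(frozen=True)
class FootprintRecord:
    """Ribosome-protected fragment alignment interval."""

    chrom: str
    start: int
    end: int
    strand: str
    mapq: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError("footprint end must exceed start")
        if self.mapq < 0:
            raise AnnotationError("negative MAPQ")


@dataclass
class GeneCountTable:
    """Gene x sample count matrix plus per-sample metadata.

    ``counts`` is indexed by gene_id with one column per sample_id;
    ``samples`` is indexed by sample_id with columns assay
    (RPF|RNA), condition (untreated|arsenite) and cell_line.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise AnnotationError("negative counts")
        if set(self.counts.columns) - set(self.samples.index):
            raise AnnotationError("samples missing metadata")
        sizes = self.counts.sum(axis=0)
        if (sizes <= 0).any():
            bad = sizes[sizes <= 0].index.tolist()
            raise AnnotationError(f"zero library size for {bad}")

    def library_sizes(self) -> pd.Series:
        """Per-sample total mapped reads: the sidecar's library_size
        column when recorded (gene counts need not exhaust a library),
        otherwise the column sums."""
        if "library_size" in self.samples.columns:
            return self.samples.loc[self.counts.columns, "library_size"].astype(float)
        return self.counts.sum(axis=0)

    def select(self, **criteria: str) -> list[str]:
        """Sample ids matching all metadata criteria, e.g.
        ``select(assay="RPF", condition="arsenite")``."""
        mask = pd.Series(True, index=self.samples.index)
        for key, val in criteria.items():
            mask &= self.samples[key] == val
        return [s for s in self.samples.index[mask] if s in self.counts.columns]


# ---------------------------------------------------------------------------
# readers / writers


def _parse_name_field(name: str, has_cds: bool) -> tuple[str, str, GeneClass]:
    parts = name.split("|")
    if len(parts) >= 3:
        try:
            cls = GeneClass(parts[2])
        except ValueError as exc:
            raise AnnotationError(f"unknown gene class {parts[2]!r}") from exc
        return parts[0], parts[1], cls
    if len(parts) == 2:
        return parts[0], parts[1], GeneClass.MRNA if has_cds else GeneClass.OTHER
    return name, name, GeneClass.MRNA if has_cds else GeneClass.OTHER


def read_transcripts(path) -> list[TranscriptModel]:
    """Read transcript models from a BED12 file."""
    models: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 12 BED fields, got {len(f)}"
                )
            try:
                chrom, start = f[0], int(f[1])
                name, strand = f[3], f[5]
                thick_s, thick_e = int(f[6]), int(f[7])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise AnnotationError(
                    f"{path}:{lineno}: blockCount does not match block lists"
                )
            blocks = tuple(
                (start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)
            )
            has_cds = thick_e > thick_s
            tid, gid, cls = _parse_name_field(name, has_cds)
            try:
                models.append(
                    TranscriptModel(
                        transcript_id=tid,
                        gene_id=gid,
                        gene_class=cls,
                        chrom=chrom,
                        strand=strand,
                        exon_blocks=blocks,
                        cds_genomic=(thick_s, thick_e) if has_cds else None,
                    )
                )
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return models


def write_transcripts(models: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            start = m.exon_blocks[0][0]
            end = m.exon_blocks[-1][1]
            thick = m.cds_genomic or (start, start)
            sizes = ",".join(str(e - s) for s, e in m.exon_blocks)
            starts = ",".join(str(s - start) for s, _ in m.exon_blocks)
            name = f"{m.transcript_id}|{m.gene_id}|{m.gene_class.value}"
            fh.write(
                "\t".join(
                    map(
                        str,
                        (
                            m.chrom, start, end, name, 0, m.strand,
                            thick[0], thick[1], "0",
                            len(m.exon_blocks), sizes, starts,
                        ),
                    )
                )
                + "\n"
            )


_BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def _read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=_BED6_COLS, comment="#",
        dtype={"chrom": str, "name": str},
    )
    if df[["start", "end", "score"]].isna().any().any():
        raise AnnotationError(f"{path}: malformed BED6 numeric fields")
    return df


def read_rt_stops(path, sample_id: str = "") -> list[RTStopRecord]:
    """Read single-nucleotide RT stops from BED6 (score = count)."""
    df = _read_bed6(path)
    bad = df["end"] != df["start"] + 1
    if bad.any():
        raise AnnotationError(
            f"{path}: RT stop records must be 1 nt wide "
            f"(first bad line {bad.idxmax() + 1})"
        )
    return [
        RTStopRecord(r.chrom, int(r.start), r.strand, int(r.score), sample_id)
        for r in df.itertuples()
    ]


def write_rt_stops(stops: Iterable[RTStopRecord], path) -> None:
    with open(path, "w") as fh:
        for s in stops:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t.\t{s.count}\t{s.strand}\n"
            )


def read_footprints(path, sample_id: str = "") -> list[FootprintRecord]:
    """Read footprint intervals from BED6 (score = MAPQ)."""
    df = _read_bed6(path)
    return [
        FootprintRecord(
            r.chrom, int(r.start), int(r.end), r.strand, int(r.score), sample_id
        )
        for r in df.itertuples()
    ]


def write_footprints(fps: Iterable[FootprintRecord], path) -> None:
    with open(path, "w") as fh:
        for f in fps:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t.\t{f.mapq}\t{f.strand}\n"
            )


def read_count_table(counts_path, samples_path) -> GeneCountTable:
    """Count TSV (first column gene_id) + sample sidecar TSV
    (sample_id, assay, condition, cell_line)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    required = {"assay", "condition", "cell_line"}
    if not required <= set(samples.columns):
        raise AnnotationError(
            f"sample sidecar missing columns {required - set(samples.columns)}"
        )
    return GeneCountTable(counts=counts, samples=samples)


def write_count_table(table: GeneCountTable, counts_path, samples_path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    table.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# event assignment


def canonical_transcripts(
    models: Sequence[TranscriptModel],
) -> dict[str, TranscriptModel]:
    """One transcript per gene: the longest mature transcript (ties broken
    by transcript_id for determinism)."""
    best: dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if (
            cur is None
            or m.mature_length > cur.mature_length
            or (
                m.mature_length == cur.mature_length
                and m.transcript_id < cur.transcript_id
            )
        ):
            best[m.gene_id] = m
    return best


class TranscriptIndex:
    """Strand-aware exon interval lookup over a set of transcript models."""

    def __init__(self, models: Sequence[TranscriptModel]):
        self.models = list(models)
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for m in self.models:
            tree = self._trees.setdefault((m.chrom, m.strand), IntervalTree())
            for s, e in m.exon_blocks:
                tree.addi(s, e, m)

    def overlapping(self, chrom: str, pos: int, strand: str) -> list[TranscriptModel]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.at(pos)), key=lambda m: m.transcript_id
        )

    def assign_class(self, stop: RTStopRecord) -> GeneClass:
        """Class of the highest-priority sense-strand transcript at the stop;
        antisense or unannotated events fall to 'other'."""
        hits = self.overlapping(stop.chrom, stop.pos, stop.strand)
        if not hits:
            return GeneClass.OTHER
        classes = {m.gene_class for m in hits}
        for cls in CLASS_PRIORITY:
            if cls in classes:
                return cls
        return GeneClass.OTHER

    def assign_transcript(self, stop: RTStopRecord) -> Optional[TranscriptModel]:
        """Canonical coding-transcript assignment: among sense-strand coding
        hits, one transcript per gene (the longest), then the longest across
        genes for determinism."""
        hits = [m for m in self.overlapping(stop.chrom, stop.pos, stop.strand)
                if m.is_coding]
        if not hits:
            return None
        per_gene = canonical_transcripts(hits)
        return max(
            per_gene.values(),
            key=lambda m: (m.mature_length, m.transcript_id),
        )


def classify_rt_stops(
    stops: Sequence[RTStopRecord],
    models: Sequence[TranscriptModel],
    weight: str = "count",
) -> dict[str, float]:
    """Fraction of crosslink signal per RNA class.

    ``weight="count"`` weights by the RT-stop count (score field);
    ``weight="unique"`` weights each distinct position once.
    """
    if not stops:
        raise AnnotationError("no RT stops to classify")
    if weight not in ("count", "unique"):
        raise AnnotationError(f"unknown weighting {weight!r}")
    index = TranscriptIndex(models)
    totals = {cls.value: 0.0 for cls in GeneClass}
    for s in stops:
        w = s.count if weight == "count" else 1
        totals[index.assign_class(s).value] += w
    grand = sum(totals.values())
    return {k: v / grand for k, v in totals.items()}


def region_distribution(
    stops: Sequence[RTStopRecord],
    models: Sequence[TranscriptModel],
) -> dict[str, float]:
    """Count-weighted fraction of mRNA crosslink signal per transcript
    region (UTR5/CDS/UTR3)."""
    index = TranscriptIndex([m for m in models if m.is_coding])
    totals = dict.fromkeys(REGIONS, 0.0)
    for s in stops:
        m = index.assign_transcript(s)
        if m is None:
            continue
        tpos = m.genomic_to_transcript(s.pos)
        if tpos is None:
            continue
        totals[m.region_of(tpos)] += s.count
    grand = sum(totals.values())
    if grand == 0:
        raise AnnotationError("no RT stops on coding transcripts")
    return {k: v / grand for k, v in totals.items()}


def gene_stop_counts(
    stops: Sequence[RTStopRecord],
    models: Sequence[TranscriptModel],
) -> pd.Series:
    """Total RT-stop count per gene (canonical coding transcript, sense
    strand)."""
    index = TranscriptIndex([m for m in models if m.is_coding])
    totals: dict[str, int] = {}
    for s in stops:
        m = index.assign_transcript(s)
        if m is not None:
            totals[m.gene_id] = totals.get(m.gene_id, 0) + s.count
    return pd.Series(totals, dtype=float).sort_index()


def transcript_sequence(model: TranscriptModel, genome: Mapping[str, object]) -> str:
    """Mature transcript sequence (5'->3') from a genome mapping such as a
    pyfaidx.Fasta."""
    chrom_seq = genome[model.chrom]
    parts = [str(chrom_seq[s:e]) for s, e in model.exon_blocks]
    seq = "".join(parts).upper()
    if model.strand == "-":
        seq = _revcomp(seq)
    return seq


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
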