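"""Synthetic transcriptome, iCLIP, and ribosome-profiling generator.

Emulates the signal structure the analysis assumes, with ground truth for
recovery tests:

* a toy genome of single-exon transcripts (optional two-exon mode) whose
  5'UTR / CDS / 3'UTR sequences are drawn at configurable GC content,
  with a programmed "resistant" gene subset carrying elevated CDS and
  3'UTR GC;
* iCLIP RT stops drawn from a four-component positional mixture (5'UTR,
  TIS +/-3 nt, CDS, 3'UTR) over a per-gene set of discrete binding
  positions; under arsenite a configurable share of 5'UTR weight moves
  into the CDS, attenuated for the catalytically impaired R534H variant;
* RNA-seq counts from a gamma-Poisson (negative binomial) model whose
  gene-level overdispersion is shared across libraries of one clone, so
  between-condition ratios are shot-noise limited plus an explicit
  fold-change jitter;
* ribosome footprints and RPF counts proportional to RNA abundance times
  translation efficiency, globally repressed under arsenite (resistant
  genes exempt in the DDX3-expressing lines), with a configurable
  fraction of footprints displaced a fixed offset 3' of CLIP positions.

All outputs are deterministic given the config seed; each library uses an
independent stream derived from (seed, cell line, condition, assay).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    FootprintRecord,
    GeneClass,
    GeneCountTable,
    RTStopRecord,
    TranscriptModel,
    write_count_table,
    write_footprints,
    write_rt_stops,
    write_transcripts,
)

CELL_LINES = ("Rluc", "DDX3", "DDX3_R534H")
CONDITIONS = ("untreated", "arsenite")
CLIP_CELL_LINES = ("DDX3", "DDX3_R534H")
COMPONENTS = ("utr5", "tis", "cds", "utr3")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the study conditions the package
    is validated under."""

    n_genes: int = 2000
    utr5_range: tuple[int, int] = (100, 300)
    cds_range: tuple[int, int] = (300, 1500)  # rounded down to codons
    utr3_range: tuple[int, int] = (200, 800)
    intergenic_gap: int = 200
    chrom: str = "chrSim"
    multi_exon: bool = False
    intron_len: int = 120

    base_gc: float = 0.45
    resistant_gc_boost: float = 0.12  # added to CDS and UTR3 GC
    resistant_fraction: float = 0.05

    # iCLIP positional mixture (untreated weights)
    w_utr5: float = 0.45
    w_tis: float = 0.15
    w_cds: float = 0.30
    w_utr3: float = 0.10
    stress_shift: float = 0.25  # weight moved UTR5 -> CDS under arsenite
    variant_attenuation: float = 0.4  # scales stress_shift for R534H
    clip_events: int = 100_000
    sites_per_gene: tuple[int, int, int] = (2, 3, 1)  # utr5, cds, utr3

    # expression / translation
    abundance_sdlog: float = 1.0
    nb_dispersion: float = 10.0  # gamma shape k; variance = mu + mu^2/k
    te_sdlog: float = 0.35  # baseline TE spread (natural log)
    # per-gene jitter on the stress response; small enough that the
    # programmed escape effect is several reference SDs, the regime the
    # Z-classification is designed for
    te_fc_noise_sdlog: float = 0.10
    repression: dict = field(
        default_factory=lambda: {
            "Rluc": 1 / 5.34,
            "DDX3": 1 / 6.26,
            "DDX3_R534H": 1 / 4.5,
        }
    )
    escape_cell_lines: tuple[str, ...] = ("DDX3", "DDX3_R534H")

    # per-library depth, scaled from typical practice (~25M mapped reads
    # over ~10k expressed genes) to the 2000-gene toy transcriptome
    rna_depth: int = 5_000_000
    rpf_depth: int = 5_000_000
    n_footprints: int = 100_000
    footprint_len_range: tuple[int, int] = (28, 30)
    clip_assoc_fraction: float = 0.3
    ribo_offset: int = 30  # programmed 3' displacement from CLIP sites
    ribo_jitter: int = 10  # triangular jitter half-width (sum of 2 uniforms)
    low_mapq_fraction: float = 0.1
    mapq_good: int = 42
    mapq_low: int = 10

    seed: int = 0

    def __post_init__(self) -> None:
        w = self.w_utr5 + self.w_tis + self.w_cds + self.w_utr3
        if abs(w - 1.0) > 1e-9 or min(
            self.w_utr5, self.w_tis, self.w_cds, self.w_utr3
        ) < 0:
            raise SimulationError("mixture weights must be >= 0 and sum to 1")
        if not 0 <= self.stress_shift <= self.w_utr5:
            raise SimulationError("stress_shift must lie in [0, w_utr5]")
        if not 0 <= self.variant_attenuation <= 1:
            raise SimulationError("variant_attenuation must lie in [0, 1]")
        if not 0 <= self.resistant_fraction <= 1:
            raise SimulationError("resistant_fraction must lie in [0, 1]")
        for lo, hi in (self.utr5_range, self.cds_range, self.utr3_range):
            if lo < 1 or hi < lo:
                raise SimulationError("bad region length range")

    def clip_weights(self, cell_line: str, condition: str) -> dict[str, float]:
        """Effective mixture weights for one library."""
        shift = 0.0
        if condition == "arsenite":
            shift = self.stress_shift
            if cell_line == "DDX3_R534H":
                shift *= self.variant_attenuation
        return {
            "utr5": self.w_utr5 - shift,
            "tis": self.w_tis,
            "cds": self.w_cds + shift,
            "utr3": self.w_utr3,
        }


def _lib_rng(config: SimConfig, *tags: str) -> np.random.Generator:
    """Independent, reproducible stream per library."""
    key = [config.seed] + [
        int.from_bytes(t.encode(), "little") % (2**31) for t in tags
    ]
    return np.random.default_rng(key)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


_COMP = str.maketrans("ACGT", "TGCA")


class Simulator:
    """Deterministic generator for one configuration.

    Builds the transcriptome and ground truth on construction; library
    simulation methods can be called in any order.
    """

    def __init__(self, config: SimConfig):
        self.config = config
        self._build_transcriptome()

    # -- transcriptome ---------------------------------------------------

    def _build_transcriptome(self) -> None:
        cfg = self.config
        rng = _lib_rng(cfg, "transcriptome")
        n = cfg.n_genes

        utr5 = rng.integers(cfg.utr5_range[0], cfg.utr5_range[1] + 1, n)
        cds = rng.integers(cfg.cds_range[0], cfg.cds_range[1] + 1, n)
        cds = np.maximum(3, (cds // 3) * 3)
        utr3 = rng.integers(cfg.utr3_range[0], cfg.utr3_range[1] + 1, n)
        resistant = rng.random(n) < cfg.resistant_fraction

        # expression & translation truth
        abundance = rng.lognormal(mean=0.0, sigma=cfg.abundance_sdlog, size=n)
        bio = rng.gamma(shape=cfg.nb_dispersion, scale=1 / cfg.nb_dispersion, size=n)
        lam = abundance * bio  # latent expression, shared across libraries
        te_base = rng.lognormal(mean=0.0, sigma=cfg.te_sdlog, size=n)
        te_cols: dict[str, np.ndarray] = {}
        for cl in CELL_LINES:
            eta = rng.normal(0.0, cfg.te_fc_noise_sdlog, size=n)
            rep = cfg.repression[cl]
            te_u = te_base.copy()
            te_a = te_base * rep * np.exp(eta)
            if cl in cfg.escape_cell_lines:
                te_a = np.where(resistant, te_base, te_a)
            te_cols[f"te_{cl}_untreated"] = te_u
            te_cols[f"te_{cl}_arsenite"] = te_a

        gene_ids = [f"G{i:05d}" for i in range(n)]
        models: list[TranscriptModel] = []
        seqs: list[str] = []
        chrom_parts: list[str] = []
        pos = 0
        gc_real = np.zeros((n, 3))
        starts = np.zeros(n, dtype=int)
        for i in range(n):
            gc_cds = cfg.base_gc + (cfg.resistant_gc_boost if resistant[i] else 0.0)
            s5 = _random_seq(rng, int(utr5[i]), cfg.base_gc)
            sc = _random_seq(rng, int(cds[i]), min(gc_cds, 0.95))
            s3 = _random_seq(rng, int(utr3[i]), min(gc_cds, 0.95))
            seq = s5 + sc + s3
            for j, sub in enumerate((s5, sc, s3)):
                gc_real[i, j] = 100.0 * sum(c in "GC" for c in sub) / len(sub)
            strand = "+" if i % 2 == 0 else "-"
            gap = _random_seq(rng, cfg.intergenic_gap, cfg.base_gc)
            chrom_parts.append(gap)
            pos += cfg.intergenic_gap
            start = pos
            genomic = seq if strand == "+" else seq.translate(_COMP)[::-1]
            if cfg.multi_exon:
                # one intron in the middle of the genomic span
                half = len(genomic) // 2
                intron = _random_seq(rng, cfg.intron_len, cfg.base_gc)
                chrom_parts.append(genomic[:half] + intron + genomic[half:])
                blocks = (
                    (start, start + half),
                    (start + half + cfg.intron_len, start + len(genomic) + cfg.intron_len),
                )
                end = start + len(genomic) + cfg.intron_len
            else:
                chrom_parts.append(genomic)
                blocks = ((start, start + len(seq)),)
                end = start + len(seq)
            pos = end
            # CDS genomic interval: project transcript CDS bounds
            u5, c = int(utr5[i]), int(cds[i])
            if strand == "+":
                t0, t1 = u5, u5 + c
            else:
                t0, t1 = len(seq) - (u5 + c), len(seq) - u5
            # transcript offsets -> genomic through the block structure
            def to_g(toff: int) -> int:
                off = 0
                for bs, be in blocks:
                    if toff < off + (be - bs):
                        return bs + (toff - off)
                    off += be - bs
                return blocks[-1][1]

            cds_genomic = (to_g(t0), to_g(t1 - 1) + 1)
            starts[i] = start
            models.append(
                TranscriptModel(
                    transcript_id=f"T{i:05d}",
                    gene_id=gene_ids[i],
                    gene_class=GeneClass.MRNA,
                    chrom=cfg.chrom,
                    strand=strand,
                    exon_blocks=blocks,
                    cds_genomic=cds_genomic,
                )
            )
            seqs.append(seq)
        chrom_parts.append(_random_seq(rng, cfg.intergenic_gap, cfg.base_gc))

        self.models = models
        self.models_by_tid = {m.transcript_id: m for m in models}
        self.genome = {cfg.chrom: "".join(chrom_parts)}
        self.transcript_seqs = dict(zip((m.transcript_id for m in models), seqs))

        # discrete per-gene CLIP binding positions per mixture component
        n5, nc, n3 = cfg.sites_per_gene
        cand_rows = []
        self._candidates: dict[str, dict[str, np.ndarray]] = {}
        for i, m in enumerate(models):
            u5, c, u3 = int(utr5[i]), int(cds[i]), int(utr3[i])
            comp_pos = {
                "utr5": np.sort(rng.integers(0, u5, n5)),
                "tis": np.arange(max(0, u5 - 3), u5 + 4),
                "cds": np.sort(rng.integers(u5, u5 + c, nc)),
                "utr3": np.sort(rng.integers(u5 + c, u5 + c + u3, n3)),
            }
            self._candidates[m.transcript_id] = comp_pos
            for comp, arr in comp_pos.items():
                for p in arr:
                    cand_rows.append((gene_ids[i], m.transcript_id, comp, int(p)))
        self.clip_candidates = pd.DataFrame(
            cand_rows, columns=["gene_id", "transcript_id", "component", "tpos"]
        )

        truth = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "transcript_id": [m.transcript_id for m in models],
                "strand": [m.strand for m in models],
                "utr5_len": utr5,
                "cds_len": cds,
                "utr3_len": utr3,
                "gc_utr5": gc_real[:, 0],
                "gc_cds": gc_real[:, 1],
                "gc_utr3": gc_real[:, 2],
                "resistant": resistant,
                "abundance": abundance,
                "latent_expression": lam,
                "te_base": te_base,
                **te_cols,
            }
        ).set_index("gene_id")
        self.truth = truth

    # -- iCLIP -----------------------------------------------------------

    def simulate_clip(
        self, cell_line: str, condition: str
    ) -> list[RTStopRecord]:
        """RT stops for one library, as genomic BED-style records with
        counts aggregated per position."""
        cfg = self.config
        rng = _lib_rng(cfg, "clip", cell_line, condition)
        weights = cfg.clip_weights(cell_line, condition)
        lam = self.truth["latent_expression"].to_numpy()
        p_gene = lam / lam.sum()
        genes = rng.choice(len(self.models), size=cfg.clip_events, p=p_gene)
        comps = rng.choice(
            len(COMPONENTS),
            size=cfg.clip_events,
            p=[weights[c] for c in COMPONENTS],
        )
        counts: dict[tuple[int, int], int] = {}
        for gi, ci in zip(genes, comps):
            m = self.models[gi]
            cand = self._candidates[m.transcript_id][COMPONENTS[ci]]
            tpos = int(cand[rng.integers(len(cand))])
            key = (gi, tpos)
            counts[key] = counts.get(key, 0) + 1
        sample_id = f"CLIP_{cell_line}_{condition}"
        records = []
        for (gi, tpos), cnt in sorted(counts.items()):
            m = self.models[gi]
            gpos = m.transcript_to_genomic(tpos)
            records.append(
                RTStopRecord(m.chrom, gpos, m.strand, cnt, sample_id)
            )
        records.sort(key=lambda r: r.pos)
        return records

    # -- expression counts & footprints -----------------------------------

    def _count_means(self, cell_line: str, condition: str) -> tuple[np.ndarray, np.ndarray]:
        """Expected (rna, rpf) gene counts for one clone/condition.

        RPF depth is anchored to the untreated state, so global
        translational repression shows up as a reduced mRNA-mapping count
        at fixed sequencing depth.
        """
        cfg = self.config
        lam = self.truth["latent_expression"].to_numpy()
        rna_mean = lam / lam.sum() * cfg.rna_depth
        te_u = self.truth[f"te_{cell_line}_untreated"].to_numpy()
        te_c = self.truth[f"te_{cell_line}_{condition}"].to_numpy()
        scale = cfg.rpf_depth / (lam * te_u).sum()
        rpf_mean = lam * te_c * scale
        return rna_mean, rpf_mean

    def simulate_riboseq(
        self, cell_line: str, condition: str
    ) -> tuple[list[FootprintRecord], pd.DataFrame]:
        """Footprint records plus RPF/RNA gene counts for one library pair.

        Counts are Poisson around the gene's latent (gamma-shared)
        expectation; the footprint file is a positional subsample of
        ``n_footprints`` fragments drawn proportionally to RPF
        expectation.
        """
        cfg = self.config
        rng = _lib_rng(cfg, "ribo", cell_line, condition)
        rna_mean, rpf_mean = self._count_means(cell_line, condition)
        rna_counts = rng.poisson(rna_mean)
        rpf_counts = rng.poisson(rpf_mean)
        counts = pd.DataFrame(
            {
                f"RPF_{cell_line}_{condition}": rpf_counts,
                f"RNA_{cell_line}_{condition}": rna_counts,
            },
            index=self.truth.index,
        )

        p_gene = rpf_mean / rpf_mean.sum()
        genes = rng.choice(len(self.models), size=cfg.n_footprints, p=p_gene)
        lens = rng.integers(
            cfg.footprint_len_range[0], cfg.footprint_len_range[1] + 1,
            cfg.n_footprints,
        )
        at_clip = rng.random(cfg.n_footprints) < cfg.clip_assoc_fraction
        jit = rng.integers(
            -cfg.ribo_jitter, cfg.ribo_jitter + 1, cfg.n_footprints
        ) + rng.integers(-cfg.ribo_jitter, cfg.ribo_jitter + 1, cfg.n_footprints)
        mapq = np.where(
            rng.random(cfg.n_footprints) < cfg.low_mapq_fraction,
            cfg.mapq_low,
            cfg.mapq_good,
        )
        sample_id = f"FP_{cell_line}_{condition}"
        records: list[FootprintRecord] = []
        u5 = self.truth["utr5_len"].to_numpy()
        cds = self.truth["cds_len"].to_numpy()
        mature = u5 + cds + self.truth["utr3_len"].to_numpy()
        for k in range(cfg.n_footprints):
            gi = genes[k]
            m = self.models[gi]
            if at_clip[k]:
                cand = self._candidates[m.transcript_id]["cds"]
                site = int(cand[rng.integers(len(cand))])
                mid = site + cfg.ribo_offset + int(jit[k])
            else:
                mid = int(rng.integers(u5[gi], u5[gi] + cds[gi]))
            length = int(lens[k])
            start = mid - length // 2
            start = min(max(start, 0), int(mature[gi]) - length)
            # project both bounds (exact for the single-exon default;
            # multi-exon fragments spanning the intron keep their
            # transcript-space assignment via the midpoint downstream)
            g_lo = m.transcript_to_genomic(start)
            g_hi = m.transcript_to_genomic(start + length - 1)
            lo, hi = min(g_lo, g_hi), max(g_lo, g_hi) + 1
            records.append(
                FootprintRecord(m.chrom, lo, hi, m.strand, int(mapq[k]), sample_id)
            )
        records.sort(key=lambda r: (r.start, r.end))
        return records, counts

    def count_table(
        self,
        cell_lines: Sequence[str] = CELL_LINES,
        conditions: Sequence[str] = CONDITIONS,
    ) -> GeneCountTable:
        """Full RPF+RNA gene count table across clones and conditions,
        with per-library sequencing depth recorded in the sample
        metadata."""
        cfg = self.config
        frames, meta = [], []
        for cl in cell_lines:
            for cond in conditions:
                _, counts = self.simulate_riboseq(cl, cond)
                frames.append(counts)
                meta.append((f"RPF_{cl}_{cond}", "RPF", cond, cl, cfg.rpf_depth))
                meta.append((f"RNA_{cl}_{cond}", "RNA", cond, cl, cfg.rna_depth))
        samples = pd.DataFrame(
            meta,
            columns=["sample_id", "assay", "condition", "cell_line", "library_size"],
        ).set_index("sample_id")
        return GeneCountTable(counts=pd.concat(frames, axis=1), samples=samples)

    # -- output ----------------------------------------------------------

    def gene_lengths(self) -> pd.Series:
        return (
            self.truth["utr5_len"] + self.truth["cds_len"] + self.truth["utr3_len"]
        ).astype(float)

    def write_transcriptome(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "bed": out / "transcripts.bed",
            "fasta": out / "genome.fa",
            "truth": out / "truth_genes.tsv",
            "candidates": out / "truth_clip_sites.tsv",
        }
        write_transcripts(self.models, paths["bed"])
        with open(paths["fasta"], "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        self.truth.to_csv(paths["truth"], sep="\t")
        self.clip_candidates.to_csv(paths["candidates"], sep="\t", index=False)
        return paths

    def write_all(
        self,
        out_dir,
        clip_cell_lines: Sequence[str] = CLIP_CELL_LINES,
        cell_lines: Sequence[str] = CELL_LINES,
    ) -> dict[str, Path]:
        """Emit every file the analysis pipeline consumes."""
        out = Path(out_dir)
        paths = self.write_transcriptome(out)
        for cl in clip_cell_lines:
            for cond in CONDITIONS:
                p = out / f"clip_{cl}_{cond}.bed"
                write_rt_stops(self.simulate_clip(cl, cond), p)
                paths[f"clip_{cl}_{cond}"] = p
        for cl in cell_lines:
            for cond in CONDITIONS:
                fps, _ = self.simulate_riboseq(cl, cond)
                p = out / f"footprints_{cl}_{cond}.bed"
                write_footprints(fps, p)
                paths[f"footprints_{cl}_{cond}"] = p
        table = self.count_table(cell_lines)
        write_count_table(table, out / "gene_counts.tsv", out / "samples.tsv")
        paths["counts"] = out / "gene_counts.tsv"
        paths["samples"] = out / "samples.tsv"
        return paths
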