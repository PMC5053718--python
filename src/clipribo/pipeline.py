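"""End-to-end orchestration: simulate/load -> metagene -> translation ->
site context -> group statistics, with a reproducible run manifest."""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import annotation as ann
from . import clipcontext as cc
from . import groupstats as gs
from . import metagene as mg
from . import translation as tr
from .simulate import CLIP_CELL_LINES, CONDITIONS, CELL_LINES, SimConfig, Simulator

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs and parameters for one full analysis run.

    Either the input paths are given, or ``simulate=True`` generates them.
    Parameter defaults follow the published analysis settings (200 bins,
    50 nt flanks, 100 bp site merging, 30 bp contraction, MAPQ >= 20,
    0.1% outlier trim, RPF count >= 36, |Z| > 1.5, 200 nt CDS-start
    exclusion, 10 bp GC window centered at its 6th base).
    """

    out_dir: str = "clipribo_run"
    seed: int = 0
    simulate: bool = False
    sim_overrides: dict = field(default_factory=dict)

    annotation: Optional[str] = None
    genome: Optional[str] = None
    clip_beds: dict = field(default_factory=dict)  # (cell_line, condition) -> path
    footprint_beds: dict = field(default_factory=dict)
    counts: Optional[str] = None
    samples: Optional[str] = None

    n_bins: int = 200
    flank_nt: int = 50
    merge_distance: int = 100
    contract_len: int = 30
    mapq_min: int = 20
    outlier_fraction: float = 0.001
    rpf_min: int = 36
    z_threshold: float = 1.5
    pseudocount: float = 0.1
    cds_start_exclusion: int = 200
    profile_flank: int = 100
    gc_window: int = 10
    gc_center_index: int = 6

    def validate(self) -> None:
        if not (0 <= self.outlier_fraction < 1):
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if not self.simulate:
            for name in ("annotation", "genome", "counts", "samples"):
                if getattr(self, name) is None:
                    raise FileNotFoundError(
                        f"missing input: {name} (and no simulate block)"
                    )


def _stage(name: str, out: Path):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, etype, evalue, tb):
            if etype is not None:
                (out / "FAILED").write_text(f"stage {name}: {evalue}\n")
                raise PipelineError(name, evalue) from evalue
            log.info("stage %s: done in %.1fs", name, time.time() - self.t0)
            return False

    return _Ctx()


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the in-memory result bundle and
    writes every stage's tables under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if config.simulate:
        with _stage("simulate", out):
            sim = Simulator(SimConfig(seed=config.seed, **config.sim_overrides))
            paths = sim.write_all(out / "sim")
            config.annotation = str(paths["bed"])
            config.genome = str(paths["fasta"])
            config.counts = str(paths["counts"])
            config.samples = str(paths["samples"])
            config.clip_beds = {
                (cl, cond): str(paths[f"clip_{cl}_{cond}"])
                for cl in CLIP_CELL_LINES
                for cond in CONDITIONS
            }
            config.footprint_beds = {
                (cl, cond): str(paths[f"footprints_{cl}_{cond}"])
                for cl in CELL_LINES
                for cond in CONDITIONS
            }

    with _stage("annotation", out):
        models = ann.read_transcripts(config.annotation)
        import pyfaidx

        genome = pyfaidx.Fasta(str(config.genome))
        canonical = ann.canonical_transcripts(models)
        models_by_tid = {m.transcript_id: m for m in canonical.values()}
        tx_seqs = {
            m.transcript_id: ann.transcript_sequence(m, genome)
            for m in canonical.values()
        }
        lengths = pd.Series(
            {m.gene_id: float(m.mature_length) for m in canonical.values()}
        )
        table = ann.read_count_table(config.counts, config.samples)
        clip_stops = {
            key: ann.read_rt_stops(path, sample_id=f"CLIP_{key[0]}_{key[1]}")
            for key, path in config.clip_beds.items()
        }
        footprints = {
            key: ann.read_footprints(path, sample_id=f"FP_{key[0]}_{key[1]}")
            for key, path in config.footprint_beds.items()
        }

    with _stage("metagene", out):
        spec3 = mg.three_region_spec(config.n_bins)
        spec_flank = mg.utr5_flank_spec(config.n_bins // 2, config.flank_nt)
        chrom_sizes = {name: len(genome[name]) for name in genome.keys()}
        clip_profiles: dict = {}
        for (cl, cond), stops in clip_stops.items():
            lib = sum(s.count for s in stops)
            events = mg.project_stops(stops, models)
            prof = mg.metagene_profile(
                events, models_by_tid, spec3, unit="CP10M", library_size=lib
            )
            prof.write_tsv(out / f"metagene_clip_{cl}_{cond}.tsv")
            clip_profiles[(cl, cond)] = prof
            flank_events = mg.project_stops(stops, models, flank=config.flank_nt)
            mg.metagene_profile(
                flank_events, models_by_tid, spec_flank, unit="CP10M",
                library_size=lib, chrom_sizes=chrom_sizes,
            ).write_tsv(out / f"metagene_clip_utr5flank_{cl}_{cond}.tsv")
        clip_ratios: dict = {}
        for cl in sorted({k[0] for k in clip_profiles}):
            if (cl, "arsenite") in clip_profiles and (cl, "untreated") in clip_profiles:
                ratio = mg.ratio_profile(
                    clip_profiles[(cl, "arsenite")],
                    clip_profiles[(cl, "untreated")],
                    pseudocount=config.pseudocount,
                )
                pd.DataFrame(
                    {
                        "segment": clip_profiles[(cl, "arsenite")].to_frame()["segment"],
                        "bin": clip_profiles[(cl, "arsenite")].to_frame()["bin"],
                        "ratio": ratio,
                    }
                ).to_csv(out / f"metagene_clip_ratio_{cl}.tsv", sep="\t", index=False)
                clip_ratios[cl] = ratio
        fp_profiles: dict = {}
        for (cl, cond), fps in footprints.items():
            mids = mg.footprint_midpoints(fps)
            events = mg.project_stops(mids, models)
            prof = mg.metagene_profile(
                events, models_by_tid, spec3, unit="CPM", library_size=len(fps)
            )
            prof.write_tsv(out / f"metagene_fp_{cl}_{cond}.tsv")
            fp_profiles[(cl, cond)] = prof
        results["clip_profiles"] = clip_profiles
        results["clip_ratios"] = clip_ratios
        results["fp_profiles"] = fp_profiles

    with _stage("translation", out):
        filtered = tr.filter_low_rpf(table, threshold=config.rpf_min)
        te_by_cl = {}
        for cl in sorted(set(filtered.samples["cell_line"])):
            te = tr.te_results(
                filtered, lengths, cl, z_threshold=config.z_threshold
            )
            te.to_csv(out / f"te_results_{cl}.tsv", sep="\t", index_label="gene_id")
            te_by_cl[cl] = te
        clip_changes = {}
        for cl in sorted({k[0] for k in clip_stops}):
            if (cl, "arsenite") in clip_stops and (cl, "untreated") in clip_stops:
                change = tr.gene_iclip_change(
                    clip_stops[(cl, "arsenite")],
                    clip_stops[(cl, "untreated")],
                    models,
                    pseudocount=config.pseudocount,
                )
                change.to_frame().to_csv(
                    out / f"clip_change_{cl}.tsv", sep="\t", index_label="gene_id"
                )
                clip_changes[cl] = change
        results["te"] = te_by_cl
        results["clip_changes"] = clip_changes

    with _stage("clipcontext", out):
        site_profiles = {}
        gc_profiles = {}
        for (cl, cond), stops in clip_stops.items():
            if (cl, cond) not in footprints:
                continue
            events = mg.project_stops(stops, models)
            by_tx: dict[str, list[int]] = {}
            for ev in events:
                by_tx.setdefault(ev.transcript_id, []).append(ev.tpos)
            sites = cc.merge_sites_by_sequence(by_tx, config.merge_distance)
            sites = cc.label_sites(sites, models_by_tid)
            cds_sites = cc.cds_sites_excluding_start(
                sites, models_by_tid, config.cds_start_exclusion
            )
            tx_fps = cc.project_footprints(footprints[(cl, cond)], models)
            contracted = cc.contract_footprints(
                tx_fps, config.contract_len, config.mapq_min
            )
            matrix = cc.coverage_matrix(
                contracted,
                cds_sites,
                flank=config.profile_flank,
                library_size=len(footprints[(cl, cond)]),
            )
            matrix = cc.remove_outliers(matrix, config.outlier_fraction)
            prof = cc.average_profile(matrix)
            prof.to_csv(out / f"site_profile_{cl}_{cond}.tsv", sep="\t", index=False)
            site_profiles[(cl, cond)] = prof
            gc = cc.gc_profile(
                tx_seqs,
                cds_sites,
                flank=config.profile_flank,
                window=config.gc_window,
                center_index=config.gc_center_index,
            )
            gc.to_csv(out / f"gc_profile_{cl}_{cond}.tsv", sep="\t", index=False)
            gc_profiles[(cl, cond)] = gc
            comp = cc.base_composition_around_stops(
                [(ev.transcript_id, ev.tpos) for ev in events],
                tx_seqs,
                flank=20,
                counts=[ev.count for ev in events],
            )
            comp.to_csv(
                out / f"base_composition_{cl}_{cond}.tsv", sep="\t", index=False
            )
        results["site_profiles"] = site_profiles
        results["gc_profiles"] = gc_profiles

    with _stage("group_stats", out):
        gc_table = gs.region_gc_table(list(models_by_tid.values()), tx_seqs)
        manifest = {
            f"param.{k}": v
            for k, v in dataclasses.asdict(config).items()
            if isinstance(v, (int, float, str, bool))
        }
        manifest["library_sizes.counts"] = ",".join(
            f"{s}={int(v)}" for s, v in table.library_sizes().items()
        )
        report = gs.build_report(
            out,
            te_by_cell_line=results["te"],
            clip_changes=results.get("clip_changes") or None,
            gc_table=gc_table,
            manifest=manifest,
        )
        results["gc_table"] = gc_table
        results["report"] = report

    return results
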