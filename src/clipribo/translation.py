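"""Translation efficiency, stress fold change, and Z-score gene grouping.

TE per gene is FPKM(ribosome footprints) / FPKM(total RNA).  The stress
response of each gene is its TE fold change (arsenite vs untreated),
standardized against the fold-change distribution of the reference
(Rluc-expressing) cell line to a Z score; genes with z < -1.5 are
stress-sensitive, z > 1.5 stress-resistant, the rest bulk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    GeneCountTable,
    RTStopRecord,
    TranscriptModel,
    gene_stop_counts,
)

log = logging.getLogger(__name__)

GROUP_SENSITIVE = "sensitive"
GROUP_BULK = "bulk"
GROUP_RESISTANT = "resistant"


class TranslationError(ValueError):
    pass


def filter_low_rpf(
    table: GeneCountTable, threshold: int = 36, mode: str = "all"
) -> GeneCountTable:
    """Drop genes with insufficient footprint evidence.

    ``mode="all"`` (default): a gene is eliminated only if its RPF count is
    below ``threshold`` in every RPF sample, i.e. retained when any sample
    reaches the threshold.  ``mode="any"`` is the stricter reading
    (eliminated if any sample is below); ``mode="sum"`` thresholds the
    summed RPF count.
    """
    rpf_cols = table.select(assay="RPF")
    if not rpf_cols:
        raise TranslationError("count table has no RPF samples")
    rpf = table.counts[rpf_cols]
    if mode == "all":
        keep = (rpf >= threshold).any(axis=1)
    elif mode == "any":
        keep = (rpf >= threshold).all(axis=1)
    elif mode == "sum":
        keep = rpf.sum(axis=1) >= threshold
    else:
        raise TranslationError(f"unknown filter mode {mode!r}")
    return GeneCountTable(counts=table.counts.loc[keep], samples=table.samples)


def fpkm(count, effective_length, library_size):
    """Fragments per kilobase of transcript per million mapped reads."""
    effective_length = np.asarray(effective_length, dtype=float)
    library_size = float(library_size)
    if np.any(effective_length <= 0) or library_size <= 0:
        raise TranslationError("effective_length and library_size must be > 0")
    return np.asarray(count, dtype=float) * 1e9 / (effective_length * library_size)


def translation_efficiency(rpf_fpkm: float, rna_fpkm: float) -> float:
    if rna_fpkm <= 0:
        raise TranslationError("TE undefined for zero RNA FPKM")
    return rpf_fpkm / rna_fpkm


def te_table(
    table: GeneCountTable,
    lengths: Mapping[str, float],
    cell_line: str,
    conditions: Sequence[str] = ("untreated", "arsenite"),
) -> pd.DataFrame:
    """Per-gene TE for each condition of one cell line, with fold change.

    Effective length is the mature transcript length for both assays, so
    lengths cancel in TE.  Genes with zero RNA FPKM in either condition
    are dropped (logged).  Returns columns te_<condition>, fc
    (te_arsenite / te_untreated), log2fc.
    """
    lengths = pd.Series(lengths, dtype=float)
    genes = table.counts.index.intersection(lengths.index)
    if len(genes) < len(table.counts.index):
        log.warning(
            "dropping %d genes without length information",
            len(table.counts.index) - len(genes),
        )
    lib = table.library_sizes()
    out = pd.DataFrame(index=genes)
    for cond in conditions:
        te_cols = {}
        for assay in ("RPF", "RNA"):
            cols = table.select(assay=assay, condition=cond, cell_line=cell_line)
            if not cols:
                raise TranslationError(
                    f"no {assay} sample for {cell_line}/{cond}"
                )
            counts = table.counts.loc[genes, cols].sum(axis=1)
            size = lib[cols].sum()
            te_cols[assay] = fpkm(counts, lengths[genes], size)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"te_{cond}"] = np.asarray(te_cols["RPF"]) / np.asarray(
                te_cols["RNA"]
            )
    defined = np.isfinite(out).all(axis=1) & (out > 0).all(axis=1)
    n_drop = int((~defined).sum())
    if n_drop:
        log.info("dropping %d genes with undefined TE", n_drop)
    out = out.loc[defined]
    c0, c1 = conditions
    out["fc"] = out[f"te_{c1}"] / out[f"te_{c0}"]
    out["log2fc"] = np.log2(out["fc"])
    return out


def zscore_vs_reference(
    log2fc: pd.Series, reference_log2fc: pd.Series
) -> pd.Series:
    """Standardize fold changes against the reference cell line's
    distribution (sample sd, ddof=1)."""
    ref = np.asarray(reference_log2fc, dtype=float)
    ref = ref[np.isfinite(ref)]
    if ref.size < 2:
        raise TranslationError("reference needs >= 2 finite values")
    sd = ref.std(ddof=1)
    if sd == 0:
        raise TranslationError("reference has zero standard deviation")
    return (log2fc - ref.mean()) / sd


def assign_groups(z: pd.Series, threshold: float = 1.5) -> pd.Series:
    """sensitive (z < -threshold) / bulk / resistant (z > threshold);
    boundary values are bulk."""
    z = pd.Series(z, dtype=float)
    out = pd.Series(GROUP_BULK, index=z.index, dtype=object)
    out[z < -threshold] = GROUP_SENSITIVE
    out[z > threshold] = GROUP_RESISTANT
    return out


def median_fold_reduction(te: pd.DataFrame) -> float:
    """Median over genes of te_untreated / te_arsenite (a value of 5 means
    TE typically fell to one fifth under stress)."""
    if len(te) == 0:
        raise TranslationError("empty TE table")
    return float((te["te_untreated"] / te["te_arsenite"]).median())


def te_results(
    table: GeneCountTable,
    lengths: Mapping[str, float],
    cell_line: str,
    reference_cell_line: str = "Rluc",
    z_threshold: float = 1.5,
) -> pd.DataFrame:
    """Full TE pipeline for one cell line: TE per condition, fold change,
    Z against the reference cell line, and group labels."""
    te = te_table(table, lengths, cell_line)
    ref = te if cell_line == reference_cell_line else te_table(
        table, lengths, reference_cell_line
    )
    te = te.copy()
    te["z"] = zscore_vs_reference(te["log2fc"], ref["log2fc"])
    te["group"] = assign_groups(te["z"], z_threshold)
    return te


@dataclass(frozen=True)
class GeneClipChange:
    gene_id: str
    clip_log2_ratio: float


def gene_iclip_change(
    stops_treated: Sequence[RTStopRecord],
    stops_untreated: Sequence[RTStopRecord],
    models: Sequence[TranscriptModel],
    pseudocount: float = 0.1,
    library_sizes: Optional[tuple[float, float]] = None,
) -> pd.Series:
    """Per-gene log2 change in library-normalized (CP10M) RT-stop counts,
    arsenite vs untreated.

    ``library_sizes`` is (treated, untreated); defaults to each library's
    total RT-stop count.
    """
    if pseudocount <= 0:
        raise TranslationError("pseudocount must be > 0")
    if library_sizes is None:
        library_sizes = (
            float(sum(s.count for s in stops_treated)),
            float(sum(s.count for s in stops_untreated)),
        )
    lib_t, lib_u = library_sizes
    if lib_t <= 0 or lib_u <= 0:
        raise TranslationError("library sizes must be > 0")
    per_gene_t = gene_stop_counts(stops_treated, models)
    per_gene_u = gene_stop_counts(stops_untreated, models)
    genes = per_gene_t.index.union(per_gene_u.index)
    cp10m_t = per_gene_t.reindex(genes, fill_value=0.0) * 1e7 / lib_t
    cp10m_u = per_gene_u.reindex(genes, fill_value=0.0) * 1e7 / lib_u
    return np.log2((cp10m_t + pseudocount) / (cp10m_u + pseudocount)).rename(
        "clip_log2_ratio"
    )
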