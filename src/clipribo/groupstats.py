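"""Region GC content per gene, Z-group comparisons, and report tables."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TranscriptModel


class GroupStatsError(ValueError):
    pass


def region_gc(model: TranscriptModel, seq_source: Mapping[str, str]) -> dict:
    """GC percentage of the 5'UTR, CDS and 3'UTR of one transcript.

    ``seq_source`` maps transcript id to the mature (spliced) sequence.
    Empty regions yield NaN.
    """
    seq = str(seq_source[model.transcript_id]).upper()
    out = {}
    for name, (s, e) in model.partition_regions().items():
        if e <= s:
            out[name] = float("nan")
            continue
        sub = seq[s:e]
        out[name] = 100.0 * sum(c in "GC" for c in sub) / len(sub)
    return out


def region_gc_table(
    models: Sequence[TranscriptModel], seq_source: Mapping[str, str]
) -> pd.DataFrame:
    rows = {
        m.gene_id: region_gc(m, seq_source) for m in models if m.is_coding
    }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


@dataclass
class GroupComparison:
    """One-way fixed-effects ANOVA across gene groups."""

    table: pd.DataFrame  # index group; columns n, mean, sd, ci95
    f_stat: float
    p_value: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def group_compare(
    values: Sequence[float],
    groups: Sequence[str],
    ci: str = "normal",
) -> GroupComparison:
    """Compare a per-gene quantity across group labels by one-way ANOVA.

    Per group: n, mean, sample sd, and a 95% CI half-width (normal
    approximation 1.96*sd/sqrt(n) by default; ``ci="t"`` uses the t
    quantile instead).
    """
    df = pd.DataFrame({"value": np.asarray(values, float), "group": list(groups)})
    df = df.dropna()
    sizes = df.groupby("group").size()
    if len(sizes) < 2 or (sizes < 2).any():
        raise GroupStatsError("need >= 2 groups with >= 2 values each")
    arrays = [g["value"].to_numpy() for _, g in df.groupby("group")]
    if df["value"].nunique() == 1:
        # constant input: no between-group effect by definition
        f_stat, p_value = 0.0, 1.0
    else:
        f_stat, p_value = stats.f_oneway(*arrays)
    rows = {}
    for name, g in df.groupby("group"):
        v = g["value"].to_numpy()
        n, sd = len(v), v.std(ddof=1)
        if ci == "normal":
            q = 1.959963984540054
        elif ci == "t":
            q = stats.t.ppf(0.975, n - 1)
        else:
            raise GroupStatsError(f"unknown CI flavour {ci!r}")
        rows[name] = {"n": n, "mean": v.mean(), "sd": sd, "ci95": q * sd / np.sqrt(n)}
    return GroupComparison(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        f_stat=float(f_stat),
        p_value=float(p_value),
    )


def _compare_or_descriptive(values, groups) -> tuple[pd.DataFrame, float, float]:
    """ANOVA when the grouping supports it, otherwise descriptive stats
    with NaN F/p (e.g. a Z-group with fewer than two genes)."""
    try:
        cmp_ = group_compare(values, groups)
        return cmp_.table, cmp_.f_stat, cmp_.p_value
    except GroupStatsError:
        df = pd.DataFrame({"value": np.asarray(values, float), "group": list(groups)})
        rows = {}
        for name, g in df.dropna().groupby("group"):
            v = g["value"].to_numpy()
            sd = v.std(ddof=1) if len(v) > 1 else float("nan")
            rows[name] = {
                "n": len(v),
                "mean": v.mean(),
                "sd": sd,
                "ci95": 1.959963984540054 * sd / np.sqrt(len(v)),
            }
        return (
            pd.DataFrame.from_dict(rows, orient="index"),
            float("nan"),
            float("nan"),
        )


def build_report(
    out_dir,
    te_by_cell_line: Mapping[str, pd.DataFrame],
    clip_changes: Optional[Mapping[str, pd.Series]] = None,
    gc_table: Optional[pd.DataFrame] = None,
    manifest: Optional[Mapping[str, object]] = None,
) -> dict[str, object]:
    """Write the figure-analog summary tables and a run manifest.

    * te_summary.tsv — per cell line: n genes, median fold reduction,
      group sizes.
    * clip_change_by_group.tsv — per cell line x Z-group: mean/sd of the
      per-gene iCLIP log2 change, plus the ANOVA F and p.
    * gc_by_group.tsv — per region x Z-group GC%, plus per-region ANOVA.
    * manifest.txt — flat key=value parameters of the run.

    Returns the tables keyed by name.  Missing upstream inputs raise,
    naming the absent stage.
    """
    from pathlib import Path

    from .translation import median_fold_reduction

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not te_by_cell_line:
        raise GroupStatsError("missing stage input: translation (TE tables)")
    results: dict[str, object] = {}

    rows = []
    for cl, te in te_by_cell_line.items():
        counts = te["group"].value_counts() if "group" in te else pd.Series(dtype=int)
        rows.append(
            {
                "cell_line": cl,
                "n_genes": len(te),
                "median_fold_reduction": median_fold_reduction(te),
                "n_sensitive": int(counts.get("sensitive", 0)),
                "n_bulk": int(counts.get("bulk", 0)),
                "n_resistant": int(counts.get("resistant", 0)),
            }
        )
    te_summary = pd.DataFrame(rows)
    te_summary.to_csv(out_dir / "te_summary.tsv", sep="\t", index=False)
    results["te_summary"] = te_summary

    if clip_changes is not None:
        rows = []
        for cl, change in clip_changes.items():
            te = te_by_cell_line.get(cl)
            if te is None or "group" not in te:
                raise GroupStatsError(
                    f"missing stage input: translation groups for {cl}"
                )
            joined = pd.DataFrame(
                {"change": change, "group": te["group"]}
            ).dropna()
            tbl, f_stat, p_value = _compare_or_descriptive(
                joined["change"], joined["group"]
            )
            for grp, r in tbl.iterrows():
                rows.append(
                    {
                        "cell_line": cl,
                        "group": grp,
                        "n": int(r["n"]),
                        "mean": r["mean"],
                        "sd": r["sd"],
                        "ci95": r["ci95"],
                        "anova_F": f_stat,
                        "anova_p": p_value,
                    }
                )
        clip_tbl = pd.DataFrame(rows)
        clip_tbl.to_csv(out_dir / "clip_change_by_group.tsv", sep="\t", index=False)
        results["clip_change_by_group"] = clip_tbl

    if gc_table is not None:
        rows = []
        for cl, te in te_by_cell_line.items():
            if "group" not in te:
                continue
            joined = gc_table.join(te["group"], how="inner").dropna()
            for region in ("UTR5", "CDS", "UTR3"):
                tbl, f_stat, p_value = _compare_or_descriptive(
                    joined[region], joined["group"]
                )
                for grp, r in tbl.iterrows():
                    rows.append(
                        {
                            "cell_line": cl,
                            "region": region,
                            "group": grp,
                            "n": int(r["n"]),
                            "mean_gc": r["mean"],
                            "sd": r["sd"],
                            "ci95": r["ci95"],
                            "anova_F": f_stat,
                            "anova_p": p_value,
                        }
                    )
        gc_tbl = pd.DataFrame(rows)
        gc_tbl.to_csv(out_dir / "gc_by_group.tsv", sep="\t", index=False)
        results["gc_by_group"] = gc_tbl

    with open(out_dir / "manifest.txt", "w") as fh:
        for key in sorted(manifest or {}):
            fh.write(f"{key}={manifest[key]}\n")
    results["manifest"] = dict(manifest or {})
    return results
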