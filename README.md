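# clipribo

Joint analysis of DDX3 iCLIP crosslink sites and ribosome profiling under
arsenite stress.

DDX3 is a DEAD-box RNA helicase that binds mRNA 5′ leaders and the small
ribosomal subunit. Under oxidative stress (sodium arsenite), translation is
globally repressed and DDX3 binding redistributes from the 5′UTR/start-codon
region into the coding sequence; a catalytically impaired variant
(DDX3^R534H, recurrent in medulloblastoma) blunts both the binding shift and
the translational repression, letting a subset of transcripts — enriched for
high CDS/3′UTR GC content — escape. `clipribo` implements the quantitative
side of that analysis for anyone integrating single-nucleotide CLIP data
(RT stops) with ribosome-profiling libraries:

* **Metagene profiles** — crosslink or footprint density over a composite
  transcript layout (5′UTR/CDS/3′UTR each scaled to 200 bins, or a scaled
  5′UTR with fixed 50-nt flanks), library-normalized to counts per 10
  million (iCLIP) or per million (footprints), averaged per contributing
  transcript, plus stress/control per-bin ratios.
* **Translation efficiency and Z grouping** — per gene,
  TE = FPKM(RPF)/FPKM(RNA); genes with RPF counts below 36 in every sample
  are removed; the stress response is the TE fold change, standardized
  against the reference (Rluc) cell line:
  z = (log₂FC − μ_ref)/σ_ref, with z < −1.5 stress-sensitive and z > 1.5
  stress-resistant.
* **Binding-site context** — crosslink positions within 100 bp merge into
  single sites (cluster center); footprints with MAPQ ≥ 20 are contracted
  to 30 bp around their midpoints; per-site coverage at offsets ±100 nt is
  library-normalized, trimmed of the 0.1% highest-coverage sites, and
  averaged (mean ± SEM). GC content around sites uses a 10-bp sliding
  window whose queried base is the window's 6th position.
* **Group statistics** — region GC% per gene and one-way ANOVA of GC or
  per-gene iCLIP change across Z-groups, with 95% CIs.
* **Synthetic data** — a generator producing a toy transcriptome plus
  iCLIP/RPF/RNA libraries with the assumed signal structure and full
  ground truth, so every estimator is validated by parameter recovery.

Input formats: BED12 transcripts (thickStart/thickEnd = CDS), BED6 RT
stops (score = crosslink count), BED6 footprints (score = MAPQ), FASTA
genome, TSV gene-count tables with a sample-metadata sidecar.

## Worked example

```python
from clipribo import (SimConfig, Simulator, filter_low_rpf,
                      median_fold_reduction, te_results, te_table)

sim = Simulator(SimConfig(n_genes=500, clip_events=20_000,
                          n_footprints=5_000, seed=42))
table = filter_low_rpf(sim.count_table())
for cl in ("Rluc", "DDX3", "DDX3_R534H"):
    te = te_table(table, sim.gene_lengths(), cl)
    print(f"{cl:>10}: median TE fold reduction = {median_fold_reduction(te):.2f}")

res = te_results(table, sim.gene_lengths(), "DDX3")
print(res["group"].value_counts().to_string())
```

prints

```
      Rluc: median TE fold reduction = 5.31
      DDX3: median TE fold reduction = 6.20
DDX3_R534H: median TE fold reduction = 4.47
group
bulk         240
sensitive    231
resistant     29
```

The medians recover the programmed repression of each cell line (5.34×,
6.26×, 4.5×): wild-type DDX3 deepens stress repression beyond the Rluc
control while the R534H variant attenuates it. In the DDX3 line many genes
fall below z = −1.5 of the *Rluc* reference distribution (DDX3 represses
more than the reference on average), and the programmed escape subset
(25 of 500 genes here) is recovered in the resistant tail.

The same objects drive the positional analyses — e.g.
`clipribo.metagene.metagene_profile` for region-scaled density and
`clipribo.clipcontext.coverage_matrix` / `average_profile` for footprint
density around merged CLIP sites.

## Command line

```bash
clipribo run --simulate --out myrun --seed 1      # full synthetic study
clipribo simulate --out sim --seed 1 --n-genes 500
clipribo run --config run.cfg                      # key=value config file
```

`run` writes per-stage TSVs (metagene profiles and ratios, TE tables,
per-gene iCLIP change, site/GC profiles, group ANOVA tables) plus a
`manifest.txt` recording every parameter, and exits 0/2/3/4 for
success/config error/input error/stage failure.

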