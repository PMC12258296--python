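# concordx

Cross-platform transcriptome concordance analysis for paired count data:
the same RNA samples measured by a whole-transcriptome 3′-tag counting
assay (one read per transcript, "seq") and by a fixed ~800-gene
hybridization panel with control probes ("panel"), as is common when
profiling archival FFPE tumor tissue.  The package answers, with tested
numerics, the questions such comparisons raise:

* How many panel genes exist in the sequencing annotation at all?
* How strongly do the platforms correlate per matched **sample**
  (profile similarity across genes) and per **gene** (reproducibility
  across samples), under no/CPM/TMM/RLE normalization on the sequencing
  side and two-step positive-control + housekeeping normalization on the
  panel side?
* How does gene-wise agreement depend on expression strength
  (all / top-90 % / top-50 % strata)?
* How concordant are the two platforms' differential-expression calls —
  log2 fold-change correlation, per-gene direction classes, Venn counts
  and the Jaccard index |A∩B|/|A∪B| of the DEG sets?

A synthetic paired-platform study generator with known ground truth
(shared latent expression + platform-specific capture, depth, log-normal
and negative-binomial noise) makes the entire pipeline testable without
any external data.  The differential-expression engine is a compact,
self-contained two-group NB Wald test: per-gene log-link GLM at a
moment-based dispersion, normal-prior log2FC shrinkage
`lfc·s²/(s²+se²)`, and BH/BY step-up FDR adjustment, with DEG gates
padj ≤ 0.05 and |log2FC| ≥ 1.

## Worked example

```python
import concordx as cx

report = cx.run_pipeline({"study": "hga_vs_agasac"}, seed=7)

corr = report["correlations"]
print(f"sample-wise Pearson-log median (TMM): "
      f"{corr['samplewise']['tmm']['pearson_log']['median']:.2f}")
print(f"gene-wise Pearson median (TMM): "
      f"{corr['genewise']['tmm']['pearson']['median']:.2f}")
strata = report["strata"]["panel"]["pearson"]
print(f"stratified medians all/top90/top50: {strata['all']['median']:.2f} / "
      f"{strata['top90']['median']:.2f} / {strata['top50']['median']:.2f}")
conc = report["concordance"]
print(f"panel genes found in annotation: {conc['overlap']['n_found']}/"
      f"{conc['overlap']['n_panel']} ({conc['overlap']['pct_found_display']}%)")
print(f"DEGs: panel {conc['n_deg_a']}, seq {conc['n_deg_b']}, "
      f"overlap {conc['venn']['both']}, Jaccard {conc['jaccard_2dp']}")
```

prints

```
sample-wise Pearson-log median (TMM): 0.89
gene-wise Pearson median (TMM): 0.62
stratified medians all/top90/top50: 0.62 / 0.64 / 0.65
panel genes found in annotation: 821/830 (98.9%)
DEGs: panel 5, seq 6, overlap 3, Jaccard 0.38
```

Reading it: matched samples agree very strongly on their overall
expression profiles (median r ≈ 0.9 across the shared panel genes),
individual genes agree moderately (median r ≈ 0.6) and more strongly the
higher they are expressed; 9 of the 830 panel probes have no counterpart
in the sequencing annotation and are excluded from every comparison; and
the two platforms' DEG sets overlap partially, summarized by one Jaccard
number.  Gene-wise agreement is the weak point — exactly the axis on
which platform noise acts per-gene — while per-sample rank correlations
are *identical* under every per-sample normalization, a mathematical
property the test suite asserts exactly.

The same pipeline is scriptable from the shell:

```sh
concordx simulate --study cch_early_vs_late --seed 4 --out sim/
concordx normalize --method tmm --counts sim/seq_counts.tsv --out norm.tsv
concordx run --seed 7 --out results/
```

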