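# ironomics

Multi-omics analysis of intron retention (IR): quantification, differential
testing, chromatin-accessibility calling, feature integration, dual-model
classification, and accessibility-profile clustering — exercised end to end
on synthetic data with planted IR–chromatin structure.

## The problem

Most introns are spliced out; some are retained in the mature transcript,
and retention levels differ between cell types.  Whether an intron evades
splicing depends both on intrinsic sequence features (length, GC content,
splice-site and branch-point strength) and on the chromatin context it is
transcribed through (nucleosome-free regions near splice sites, H3K36me3,
DNA methylation).  This package implements the computational machinery to
quantify IR and dissect those contributions:

* **IRratio** per intron and sample:
  `IRratio = intronic abundance / (intronic + exonic abundance)`, with the
  intronic abundance a 30%-trimmed mean of exon-masked per-base depth and the
  exonic abundance the intron's own junction count.  Retained: IRratio ≥ 0.1,
  depth ≥ 10, ≥90% coverage, flanking-exon PSI ≥ 0.9.  Non-retained:
  IRratio ≤ 0.01 and depth < 10.
* **Audic–Claverie test** for differential IR between cell types
  (p ≤ 0.05, |ΔIR| ≥ 0.1) and **dynamic introns** (retained in ≥1, non-
  retained in ≥1 cell type).
* **NOMe-seq** nucleosome-free-region and nucleosome calling from GCH
  methylation via candidate segmentation plus one-sided Fisher exact tests
  against local background.
* **Feature tables** over three ±100 bp windows (5'ss, 3'ss, midpoint):
  sequence, methylation, NFR/nucleosome flags, and 0/1/2 histone-mark codes.
* **Elastic-net logistic regression** and a **conditional-inference random
  forest** (association-test split selection, permutation importance), with
  down-sampling, 10-fold CV and importances scaled to sum 1.
* **GCH profile clustering** (complete linkage, k = 5) around splice sites
  and a Poisson GLM that deconfounds H3K36me3 from chromatin accessibility.

A synthetic-data generator produces linked GTF/FASTA/bedGraph/junction/
cytosine-report/narrowPeak layers for five cell types with known ground
truth, so every stage is scored against what was planted.

## Worked example

```python
from ironomics import SimulationConfig, run_pipeline

cfg = SimulationConfig(seed=1)          # 150 genes x 4 introns, 5 cell types
res = run_pipeline(cfg, "out/", n_trees=100)
s = res.summary
print({"n_introns": s["n_introns"],
       "retention_concordance": s["retention_concordance"],
       "n_dynamic_called": s["n_dynamic_called"],
       "dynamic_sensitivity": s["dynamic_sensitivity"],
       "en_cv_auc": round(s["en_cv_auc"], 3),
       "crf_oob_auc": round(s["crf_oob_auc"], 3),
       "crf_top5": s["crf_top5"]})
```

prints

```
{'n_introns': 622, 'retention_concordance': 1.0, 'n_dynamic_called': 52,
 'dynamic_sensitivity': 1.0, 'en_cv_auc': 0.958, 'crf_oob_auc': 0.953,
 'crf_top5': ['gch_meth_ss5', 'nfr_ss5', 'gc_mid',
              'intron_length_log10', 'nfr_mid']}
```

All 622 simulated introns receive the planted retention state wherever the
truth is confidently banded (concordance 1.0), all 52 planted dynamic introns
are recovered, both classifiers separate retained from non-retained introns
(AUC ≈ 0.94–0.96), and the top-ranked features are exactly the planted
couplings — GCH methylation/NFRs at the 5' splice site plus intrinsic GC and
length.

The same stages are available from the shell:

```bash
ironomics simulate --out data/ --seed 1
ironomics quantify --gtf data/annotation.gtf --fasta data/genome.fa \
    --coverage Mo_r1=data/Mo_r1.coverage.bedgraph ... \
    --junctions data/junctions.tsv --expression data/expression.tsv \
    --out ir_table.tsv
ironomics diffir --ir-table ir_table.tsv --pair Mo,Ma --out diff.tsv
ironomics nome --gch data/Mo.gch_report.txt --mode nfr --out nfr.bed
ironomics classify --table features.tsv --model crf --out importance.tsv
```

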