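# misplice

Minor-intron mis-splicing analysis for bulk RNA-seq: intron cataloging with
minor (U12-type) / major (U2-type) classification, mis-splicing index
quantification from aligned reads, differential intron-retention calling,
gene-level event categorization, and summary/enrichment reporting — plus a
synthetic-data generator so every stage is testable without downloads.

## What it does

- **catalog** — parses GTF/GFF3 + FASTA, enumerates introns with flanking
  exons (collapsing identical coordinates across transcripts), and classifies
  each intron as minor or major either by lookup in a MiDB-style list or by
  log-odds PWM scoring of the 5' splice-site and branch-point windows.
- **quant** — counts exon–intron boundary reads (`n5`/`n3`, minimum-overhang
  rule), canonical and aberrant exon–exon junction reads, and intron-body
  coverage/depth from SAM/BAM, then computes per-intron per-sample
  `MSI_ret`, `MSI_AS` and the IR ratio. Both the bounded *fraction*
  denominator and the *literal* ratio-to-canonical denominator are available,
  and the two boundary counts can be combined by mean (default) or sum.
- **differential** — Welch's t-test on replicate MSI values (with a minimum
  delta), Audic–Claverie test on pooled counts, Benjamini–Hochberg FDR, the
  four-rule differential-retention filter (FDR ≤ 0.05, 100% coverage, ≥10%
  IR ratio, ≥5% delta), gene-level IR/AS/both categories, the
  flanking-major-intron analysis, and a chi-square goodness-of-fit test.
- **simulate** — deterministic toy genome/annotation with planted minor-type
  splice motifs and two-condition replicated SAM read sets with known
  per-intron retention (ρ) and aberrant-splicing (α) fractions; a verifier
  re-counts the emitted reads against the recorded truth.
- **report** — category percentages against the detected denominator,
  minor-vs-major retention enrichment, and cross-tabulation against an
  external differential-expression table (gene, log2FC, FDR).

## CLI

```sh
# generate a toy dataset (see tests/test_cli.py for a config example)
misplice simulate --config sim.yaml -o sim/

# build the intron catalog (list lookup, or --fasta for motif scoring)
misplice catalog --gtf sim/annotation.gtf --minor-list sim/minor_introns.tsv -o catalog/

# quantify MSI / IR ratio per intron per sample
misplice quant --catalog catalog/ --bam sim/treated_1.sam --bam sim/control_1.sam ... -o quant.tsv

# differential calling: MSI path (Welch + delta) or IR-ratio path (four-rule filter)
misplice diff --quant quant.tsv --design design.tsv --treated treated \
    --catalog catalog/ --method msi -o diff/
misplice diff --quant quant.tsv --design design.tsv --treated treated \
    --catalog catalog/ --method irratio -o diff_ir/

# summary tables (optionally cross-tab with an external DE table)
misplice report --diff diff/ --catalog catalog/ --de de.tsv -o report/
```

The design TSV has columns `sample` and `condition`; condition roles come
from the design (plus `--treated`), never from column order.

## Layout

```
src/misplice/
  catalog.py       intron extraction, PWM scoring, minor/major classification
  quant.py         CIGAR-block counting, MSI_ret / MSI_AS / IR ratio
  differential.py  Welch, Audic–Claverie, BH FDR, filter rules, categories
  simulate.py      toy reference + read generator + truth verifier
  report.py        summary tables and percentage arithmetic
  cli.py           click command group
tests/             unit + property + acceptance tests (pytest, hypothesis)
scripts/acceptance.py
```
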