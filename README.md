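# rloopscan

Analysis pipeline for strand-specific R-loop peak data, exercised end to end
on fully synthetic genomes. The package links a sequence grammar — an
upstream G-rich, GC-skewed cluster coupled to a downstream T-run on the
non-template strand — to knockdown-induced R-loop gain in gene bodies, and
to downregulation of long, motif-burdened genes.

Everything runs offline: the `simgen` module generates genomes, gene
models, planted motifs, stranded coverage for two conditions, and
negative-binomial count matrices with a complete ground-truth table, so
every downstream stage is testable without external data.

## Modules

| module | role |
| --- | --- |
| `rloopscan.simgen` | synthetic genomes, planted G-cluster/spacer/T-run motifs, Poisson coverage, NB counts, dataset writer (FASTA/GFF3/bedGraph/TSV + manifest) |
| `rloopscan.peakcall` | stranded Poisson-exceedance peak calling, condition comparison (common/gained/lost), TSS/GB/TTS/intergenic context, width stats, metaprofiles |
| `rloopscan.seqfeat` | sense-strand features: GC skew, G%, T%, maximal T-runs, summit head/tail split, T-run association, distance to 3'ss, G%-by-T-run bins, k-mer enrichment, matched random regions |
| `rloopscan.rloopclf` | RBF-SVM (or logistic) classifier on (GC skew, G%, T%), ROC/AUC, genome scanning for predicted prone regions, per-gene hit counts |
| `rloopscan.expr_assoc` | median-of-ratios normalization, moderated NB Wald test, BH adjustment, exact/approximate Mann-Whitney U, class-covariate association, two-species contrast |
| `rloopscan.workbench` | end-to-end orchestration of both species profiles plus the cross-species report |

## Command line

```sh
rloopscan simulate --profile human_like --seed 1 --out data/
rloopscan callpeaks --cov-plus data/cov.plus.ctrl.bedGraph \
    --cov-minus data/cov.minus.ctrl.bedGraph --genome data/genome.fa \
    --out ctrl.bed
rloopscan compare --a ctrl.bed --b kd.bed --out cmp.tsv
rloopscan features --peaks kd.bed --genome data/genome.fa \
    --gff data/genes.gff --out features.tsv
rloopscan train --pos pos_features.tsv --neg neg_features.tsv --out model.txt
rloopscan scan --model model.txt --genome data/genome.fa \
    --gff data/genes.gff --out hits.bed
rloopscan de --counts data/counts.tsv --design design.tsv --out de.tsv
rloopscan associate --de de.tsv --truth data/truth.tsv --out assoc.tsv
rloopscan run --seed 1 --out run/        # full two-species pipeline
```

`rloopscan run` accepts `--config cfg.yaml`; any `PipelineConfig` field can
be set there, with nested sections for `sim` (simulation), `motif_law`, and
`peaks` (caller parameters).

## Conventions

- Coordinates are 0-based half-open internally; GFF3 output is 1-based
  closed; bedGraph/BED are 0-based half-open.
- All sequence features are computed on the non-template (sense) strand:
  minus-strand regions are reverse-complemented before analysis.
- All randomness flows from explicit seeds; a fixed seed reproduces every
  output byte for byte.
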