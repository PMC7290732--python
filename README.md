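# editscan

Tools for three analyses of a knockout-vs-wild-type multi-omics comparison:

1. **Replicated differential RNA editing** — per-site editing frequencies
   with binomial likelihood-ratio (Wilks) confidence intervals, CI-weighted
   regression of frequency on group, a strict 3-standard-deviation
   significance rule, hyper/hypo classification and gene-panel summaries.
2. **Iterative random-forest marker selection** — repeated forest fits on a
   preprocessed (male-only, low-expression-filtered, natural-log)
   expression matrix, ranking genes by how often they appear among the top
   features, validated by leave-one-out LDA and visualized by PCA.
3. **SILAC / transcriptome integration** — peptide-to-protein H/L ratio
   pooling and threshold rules for replicated protein changes, concordant
   mRNA/protein changes, and protein-changed / mRNA-unchanged candidates.

A `synthetic_data` module provides seeded, truth-annotated generators
(binomial/beta-binomial pileups, two-group expression matrices, peptide
ratio tables) for every stage.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which checks the published
arithmetic summaries plus calibration, power, coverage and recovery
properties on synthetic data (a few minutes, one CPU).

## Command line

```sh
editscan ci --k 5 --n 10                      # Wilks CI for one site
editscan convert-mpileup sample.pileup --sites sites.tsv --edited-base G -o counts.tsv
editscan diffedit counts.tsv --design design.tsv --case-group KO \
    --panel apoptosis=apoptosis.txt -o results.tsv --summary summary.json
editscan rf-markers expr.tsv --meta meta.tsv --panel apoptosis=apoptosis.txt \
    --select apoptosis=40 --iterations 10000 --seed 17 -o markers.json
editscan silac peptides.tsv -o protein_ratios.tsv
editscan integrate peptides.tsv --mrna mrna_stats.tsv -o calls.tsv
editscan simulate pileups --seed 5 -o simdir/    # synthetic inputs + truth.tsv
```

Input formats (tab-delimited, `#` comments ignored):

- **site counts**: `chrom pos ref alt strand gene` then `<sample>_edited`,
  `<sample>_total` pairs; 1-based coordinates.
- **design**: `sample group` (exactly two groups).
- **expression**: genes x samples TSV plus a `sample group sex` metadata TSV.
- **gene panels**: one symbol per line; matching is case-insensitive.
- **peptide ratios**: `protein peptide ratio experiment`.
- **mRNA stats**: `gene log2fc pvalue`.

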