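# varbench

Depth-stratified, haplotype-aware benchmarking of small-variant callsets
against a truth set.

## The problem

Anyone developing or running a DNA-seq variant calling pipeline needs to
know how well it calls SNVs and indels. The standard approach compares a
callset (VCF) against a curated truth set inside *confident regions* —
intervals where the truth is complete, so every position without a truth
variant is known homozygous-reference. Done naively this comparison is
misleading in three ways that varbench addresses head-on:

1. **Read depth changes everything.** Precision and recall measured over a
   whole genome depend on that dataset's coverage profile and generalize
   poorly. varbench quantizes the genome into **low (0–9), medium (10–30)
   and high (>30)** read-depth strata — depth counted from reads with
   MAPQ ≥ 60 only — intersects them with the confident (and, for capture
   data, target) regions, and reports every metric per stratum.
2. **Representation is arbitrary.** The same haplotype edit can be written
   as a complex replacement (`ACCGCGT>ACGCT`), a right-shifted indel, or a
   multiallelic record. varbench normalizes everything first: multiallelic
   splitting, left-alignment, and **atomization** of complex replacements
   into SNVs and anchored indels (via global alignment of the alleles),
   with exact duplicates removed. Matching is then **haplotype-aware**: a
   window of nearby variants is replayed onto the reference and query and
   truth match when they imply the same pair of haplotype sequences.
3. **Genotyping and calling are different skills.** Every comparison runs
   in two modes: *genotyping* (the zygosity must be right) and *calling*
   (the allele must be present, ploidy squashed).

Because a truth variant can be predicted more than once (e.g. inside
several complex replacements), two TP counts are kept, and the headline
metrics are

```
precision = TP_query / (TP_query + FP)        TP_query ≥ TP_truth
recall    = TP_truth / (TP_truth + FN)
F*        = TP_query / (TP_query + FP + FN)
```

F* is a monotone transform of the F-measure with a direct interpretation:
the probability that a random variant from the union of prediction and
truth is predicted correctly (1.0 for a perfect callset). The fraction of
wrongly predicted genotypes among allele-matched calls is reported
alongside.

Finally, when several callsets are evaluated together, each annotated with
categorical **labels** (caller, mapper, kit, …), varbench tests every
shared FP/FN pattern for association with each label (Pearson χ² on the
presence/absence × label-value table) and controls the false discovery
rate with the **Benjamini–Yekutieli** procedure, which stays valid under
the arbitrary positive or negative correlation expected between nearby
variants on the same or different haplotypes.

A synthetic fixture generator (`varbench simulate` /
`varbench.synth`) produces reference, truth set, confident regions, depth
track and label-annotated callsets with controlled error injection, so the
entire pipeline is testable end-to-end without any external dataset.

## Worked example

Simulate a small benchmark (200 truth variants, two callsets with
depth-dependent error rates) and evaluate it:

```
$ varbench simulate --seed 7 --out-dir demo --truth-n 200 --callsets 2
$ varbench evaluate --config demo/config.yaml --out-dir demo/results
$ head -7 demo/results/metrics.tsv
callset  stratum  mode        tp_query  tp_truth  fp  fn  gt_mismatch  precision  recall    f_star    gt_mismatch_fraction
cs0      low      genotyping  49        49        17  25  3            0.742424   0.662162  0.538462  0.0576923
cs0      low      calling     52        52        14  22  3            0.787879   0.702703  0.590909  0.0576923
cs0      medium   genotyping  69        69        8   7   2            0.896104   0.907895  0.821429  0.028169
cs0      medium   calling     71        71        6   5   2            0.922078   0.934211  0.865854  0.028169
cs0      high     genotyping  63        63        4   5   2            0.940299   0.926471  0.875     0.0307692
cs0      high     calling     65        65        2   3   2            0.970149   0.955882  0.928571  0.0307692
```

Reading the numbers: the simulator drops 30% of truth variants in the low
stratum, 10% in medium and 5% in high, and calling-mode recall recovers
exactly that profile (0.70 / 0.93 / 0.96). Genotyping rows are always at
or below the calling rows — the gap is the cost of wrong zygosity calls,
also visible as the genotype-mismatch fraction. Precision rises with depth
because fewer spurious calls are injected at high coverage. An `f_star` of
0.93 in the high stratum says a random variant from the union of calls and
truth there is correct with ~93% probability. Undefined metrics in empty
strata print as `.`, never as 0.

The run directory also contains `fp_variants.tsv` / `fn_variants.tsv`
(variant × callset error matrices with label headers),
`assoc_<label>.tsv` (χ² p-values, BY q-values and significance per
variant), `summary.txt` and a `manifest.json` with per-stage counts.

Other subcommands: `normalize` (atomize a VCF standalone), `stratify`
(emit one BED per depth stratum, from a BED-graph or from SAM with
`--mapq-min`), `precheck` (local sanity checks for a callset before
submission), `associate` (re-run label association from written tables).

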