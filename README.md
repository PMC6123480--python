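# gepmi

Reference-free identification of individuals from shotgun metagenomes.

Human gut microbiomes are individual-specific and fairly stable over time:
two stool samples from the same person share far more microbial genomic
sequence than samples from two different people. `gepmi` turns that
observation into a calibrated statistical test. Given a cohort of shotgun
metagenome samples, it decides — without any reference genomes — which
pairs of samples come from the same individual, with an explicit
false-discovery-rate guarantee.

## Method in brief

1. **Sketching.** Each sample's reads are decomposed into canonical
   k-mers (k = 18 by default, abundance ≥ C = 2 to suppress sequencing
   errors). A bottom-n MinHash sketch keeps the n = 10 000 smallest
   64-bit hashes, and the Jaccard similarity of two samples' k-mer sets
   is estimated from the merged bottom-n:

   *Ĵ(A, B) = |U ∩ S(A) ∩ S(B)| / |U|*, where *U* is the bottom-n of
   *S(A) ∪ S(B)*.

2. **Per-target null.** For a target sample *t*, the similarities of *t*
   to all samples from *other* individuals are modelled as a beta
   distribution (shape parameters fitted by maximum likelihood;
   Kolmogorov–Smirnov selection among beta/gamma/normal families is
   available). The null hypothesis H₀ for a query *q* is that
   *Ĵ(q, t)* is a draw from this inter-individual distribution.

3. **Testing.** The p-value is the fitted survival function at the
   observed similarity, *p = Pr(X ≥ s | H₀)*. Every ordered pair
   (query, target) is tested — the test is directed because each target
   has its own null. P-values are adjusted per query with the
   Benjamini–Yekutieli procedure, which controls the FDR under arbitrary
   dependence. Pairs with q < 0.001 (default) become edges of a directed
   identification network; reciprocal edges connect samples of the same
   individual.

4. **Evaluation.** With known sample→individual labels the package
   reports ROC/PRC curves, empirical FDR at any cutoff, and edge-level
   accuracy against the combinatorially expected number of
   intra-individual edges, Σᵢ nᵢ(nᵢ − 1).

A synthetic cohort generator (`gepmi.synthgen`) produces labelled test
cohorts with per-individual private SNPs, abundance drift between visits,
sequencing error, and optional perturbations, so the whole pipeline can
be exercised and calibrated without any real data.

## Worked example

```python
from gepmi import SyntheticCohortConfig, generate_cohort, pipeline
from gepmi import LabeledScoreSet, network_edge_accuracy, roc_auc

config = SyntheticCohortConfig(n_individuals=12, samples_per_individual=3, seed=7)
cohort = generate_cohort(config)
matrix = pipeline.cohort_similarity(cohort.samples, k=18, n=1000, seed=7)
table, network = pipeline.run_identification(matrix, cohort.cohort_map(), q_cut=0.001)

scores = LabeledScoreSet.from_results(table, cohort.cohort_map(), "q")
print(roc_auc(scores)[1])                         # 0.9846
print(network_edge_accuracy(network, cohort.cohort_map()))
# 38 of 72 expected intra-individual edges recovered, 0 false positives
```

On this 36-sample cohort the run prints a q-value auROC of **0.9846**
and an auPRC of **0.9687**; all 38 network edges at q < 0.001 are true
intra-individual pairs (52.8 % recall at zero false positives — the
strict default cutoff trades recall for an empty false-positive set).
The same flow is available from the command line:

```bash
gepmi simulate --seed 7 -o cohort/
gepmi sketch cohort/*.fasta -k 18 -n 10000 -o sketches/
gepmi compare sketches/*.sig --csv similarity.csv
gepmi test -i similarity.csv --individuals cohort/truth.tsv -q 0.001 -o run/
gepmi evaluate --results run/results.tsv --individuals cohort/truth.tsv -o eval/
```

The `examples/` directory contains four short narrative scripts, one per
capability: `sketch_and_compare.py`, `fit_null_and_test.py`,
`identify_cohort.py`, and `simulate_cohort.py`. Each runs in seconds and
prints the numbers it computes.

## Documentation

See `docs/methods.md` for the full model description, parameter
rationale, numerical choices, and known limitations.
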