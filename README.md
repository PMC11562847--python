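# gexdist

Statistical tooling for gene-expression distributions in bulk and
single-cell RNA-seq. Most differential-expression and classification
methods assume genes are (log-)normally distributed; in large cohorts
the bulk of genes are not — they favour skewed, heavy-tailed laws such
as the generalized extreme value, log-normal and Gaussian-mixture
families, and the preferred family shifts between conditions. `gexdist`
turns that observation into three working tools for computational
biologists:

1. **Per-gene distribution fitting.** Each gene's expression vector is
   fitted with 16 candidate families; candidates are ranked by
   BIC = −2 ln L + k ln n and the first candidate passing a one-sample
   Kolmogorov–Smirnov gate (P ≥ 0.01) is the gene's optimal
   distribution, else the gene is *UNFITTED*.
2. **Skewness-ratio (SR) screening.** For a gene observed in two
   datasets, SR = (Skew₁ − Skew₂)/(|Skew₁| + |Skew₂|) ∈ [−1, 1]
   quantifies how the shape of its distribution differs; genes with
   |SR| > 0.5 and Wilcoxon rank-sum P < 0.05 are called differentially
   expressed on distributional grounds.
3. **A density-aware naive Bayes (INB).** Classical naive Bayes with
   the per-class Gaussian likelihood replaced, gene by gene, with the
   fitted gene-specific density:
   P(c|x) ∝ q_c ∏ⱼ f_cj(xⱼ). Evaluated against a Gaussian naive Bayes
   baseline by F1 and Youden index.

A seeded synthetic-data module generates two-class expression matrices
with per-feature, per-class distribution structure, and is the test bed
for everything above.

## Worked example

Generate a two-class synthetic cohort, fit distributions, screen DEGs,
train and apply the classifier — all from the shell:

```sh
gexdist synth --seed 3 --separation 1.5 --train-n 200 --test-n 40 \
        --out-prefix demo
gexdist deg demo.train.tsv demo.test.tsv --out demo.deg.tsv
gexdist train demo.train.tsv demo.train.labels.tsv --out demo.model.json
gexdist predict demo.model.json demo.test.tsv --out demo.pred.tsv
```

which prints, in order:

```
wrote demo.train/.test matrices, labels, and spec (config=0103cb4b4582)
2 DEGs of 200 genes
trained on 200 features (0 dropped), classes: C1, C2
predicted 80 samples
```

The `deg` table lists one gene per row with its skewness in each
dataset, SR, Wilcoxon P and DEG flag; here almost nothing is called
because the train and test files come from the same two-class mixture,
so per-gene distributions barely differ. The prediction table
carries one sample per row with the predicted class and per-class
posterior probabilities.

The same pipeline is available as a library
(`gexdist.fit_matrix`, `gexdist.call_degs`, `gexdist.train_inb`,
`gexdist.predict`, `gexdist.run_simulation_study`), operating on
`ExpressionMatrix` objects read from TSV/CSV or Matrix Market files.

The simulation study comparing the density-aware classifier with the
Gaussian baseline (two classes × 400 training samples, 100 GEV + 100
log-normal features, 80 test samples, 50 runs):

```sh
gexdist simulate --runs 50 --seed 1 --separation 1.0 --out sim.json
# INB F1=0.9995 YI=0.9990 | NB F1=0.8083 YI=0.5880 (50 runs)
```

The density-aware likelihood recovers the shape contrast between the
classes that a Gaussian likelihood cannot represent; see
`docs/methods.md` for the design of the benchmark and what it does and
does not demonstrate.

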