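# stabnet

Bootstrap-stable coexpression modules and negative-binomial differential
expression for two-population RNA-seq infestation designs.

## The problem

When a parasitoid fly (*Ormia ochracea*) larva develops inside a field
cricket (*Teleogryllus oceanicus*), the host transcriptome reorganizes over
the course of infestation. Comparing that response between a population
that coevolves with the fly (Kauai) and one that does not (Mangaia), with
18 pooled RNA-seq libraries — 2 populations x 3 infestation stages
(control, day 4, day 7) x 3 replicates — requires an inference chain in
which every step matters at n = 3 per cell:

1. **Preprocessing** — a CPM expression floor, TMM (trimmed mean of
   M-values) scaling factors, log2-CPM transformation, and a 40% variance
   prefilter before network construction.
2. **Differential expression** — a per-gene negative-binomial generalized
   log-linear model over the six design cells with likelihood-ratio tests
   of within-population infested-vs-control contrasts and
   difference-of-differences interaction contrasts, Benjamini–Hochberg
   adjusted.
3. **Coexpression network** — signed-hybrid adjacency
   `a_ij = cor(x_i, x_j)^beta` for positive correlations (0 otherwise),
   topological overlap, average-linkage clustering with an adaptive height
   cut (deepSplit 2, minimum module size 30), eigengene merging at
   `mergeCutHeight = 0.15`, blockwise above 10,000 genes.
4. **Bootstrap module-stability consensus** — the distinguishing step:
   networks are rebuilt on 250 with-replacement resamples of the samples;
   a resampled module "corresponds" to an original module when it contains
   at least 10% of its genes; a gene keeps its module only when at least
   70% of replicates support the assignment; survivors are re-merged at
   eigengene correlation r > .85 and modules under 30 genes dissolve.
5. **Eigengene analysis** — each module's first principal component is
   tested with a population x infestation ANOVA and classified into
   response categories: I (shared direction, amplified in one population),
   II (single-population response), III (opposing directions), IV
   (different timing).
6. **Ordination** — Bray–Curtis dissimilarities, nonmetric MDS in k = 4
   (Kruskal stress-1, isotonic-regression majorization) and a sequential
   PERMANOVA with 1,000 permutations.
7. **Enrichment** — per-term one-sided Fisher exact tests of gene-set
   over-representation ("classic" scoring).

Because the real libraries are not bundled, the package ships a
first-class synthetic-data module that emulates the full design —
negative-binomial counts, planted coexpression modules with the four
response categories, labelled immune/stress annotation sets — with
complete ground truth, so every stage of the chain is validated by
recovering what was planted.

## Worked example

```python
from stabnet import simulate, fixture_config
from stabnet.models import (
    DifferentialExpression, CoexpressionNetwork, EigengeneAnalysis, Ordination,
)
from stabnet.simulate import simulate_experiment

counts, design, truths, annotations = simulate_experiment(fixture_config(1))

de = DifferentialExpression(counts, design).fit()
print(de.summary())
net = CoexpressionNetwork.from_counts(counts).fit()
stable = net.consensus(n_boot=50, seed=11)
print(stable.summary())
eig = EigengeneAnalysis(net.expression, stable.assignment, design).fit()
print(eig.summary())
ord_ = Ordination.from_counts(counts, design).fit(n_perm=999, seed=0)
print(ord_.summary())
```

prints (abridged):

```
NB-GLM differential expression (LRT, chi2(1); BH FDR < 0.05)
common dispersion 0.1503, shrinkage weight 0.45
                         n_genes  n_significant
kauai_day4_vs_control       1918             49
kauai_day7_vs_control       1918            371
mangaia_day4_vs_control     1918             17
mangaia_day7_vs_control     1918            306
interaction_day7            1918             92

Bootstrap consensus over 50 replicates: 6 stable modules, 810 genes retained

Module eigengene ANOVA and categories
           n_genes  variance_explained  F_interaction  p_adj_interaction category
M1             295              0.7518         0.0158             0.9843   shared
M3             121              0.7554         0.4131             0.9843        I
M4              86              0.7298         1.4463             0.5474       II
M5              81              0.6710         9.9869             0.0130      III
M6              63              0.7161         8.8527             0.0130       IV

nMDS in k=4: stress-1 0.0277 (converged)
                        df      SS  pseudo_F      R2  p_perm
population               1  0.0543     1.423  0.0633   0.155
infestation              2  0.2458     3.222  0.2866   0.003
population:infestation   2  0.0997     1.307  0.1163   0.178
```

The day-7 response dwarfs the day-4 response (371 vs 49 significant genes
in Kauai), all six planted modules survive the stability filter, each
population-specific module lands in its planted category, and infestation
stage is the dominant axis of sample-level variation — the qualitative
behavior the chain is designed to expose.

A command-line interface mirrors the stages
(`stabnet simulate | preprocess | de | network | consensus | eigengene |
ordinate | enrich | all`); `stabnet all --outdir out --seed 1` runs
everything and writes a manifest with parameters and file checksums.

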