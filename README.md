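# g2vec

Network-based gene embeddings for prognostic biomarker selection.

Given a gene-by-sample expression matrix (log scale), binary good/poor
prognosis labels (or survival records plus a time criterion), and an
undirected reference gene-interaction network (e.g. the Reactome FI
network as a two-column edge list), the package identifies a panel of
prognostic biomarker genes and validates it by cross-validated outcome
prediction. It is aimed at computational biologists analyzing tumor
expression cohorts with matched clinical follow-up.

## Method

1. For each prognosis group *g*, build a **correlation network**: every
   reference edge *(i, j)* gets weight *w = |PCC(x_i, x_j)|* computed
   over group *g*'s samples; edges with *w* < 0.5 are removed.
2. Draw **constrained random walks** from every node of each network
   (10 per node): never revisit a node, step to an unvisited neighbor
   with probability proportional to edge weight, stop at a dead end or
   at 80 nodes. Paths produced by both networks are discarded; the rest
   split 80/20 into training/validation.
3. Train a **modified CBOW classifier**: a path is a multi-hot vector
   over the *N* genes, projected by a linear layer *W* (N x 128) to a
   single sigmoid unit predicting the path's network of origin (binary
   cross-entropy, Adam at learning rate 0.005, early stopping within 30
   epochs). The rows of *W* are the gene representations; genes in no
   path keep their random initial vectors.
4. **Score and select**: K-means (K = 3) separates the central cluster
   of untrained vectors from two *L-groups* tied to good and poor
   prognosis via path frequencies. Each gene gets
   *score = (d̃ + t̃) / 2*, the mean of the min-max-normalized d-score
   (‖gene vector‖₂, distance from the initial-vector center) and
   t-score (|Welch t| of expression between groups). The top 50 genes
   per L-group form the 100-gene biomarker panel.
5. **Validate**: stratified 10-fold cross-validation, rerunning the
   entire selection on each fold's training samples, then training a
   500-tree random forest on the panel and scoring held-out samples by
   AUC-ROC.

A synthetic-cohort simulator (`simulate_cohort`) generates networks
with planted co-expression modules, group-shifted expression, and
consistent survival records for testing and benchmarking.

## Worked example

```python
import g2vec as gv

cfg = gv.SyntheticCohortConfig(
    n_genes=500, n_samples_per_group=60, n_network_edges=2000,
    planted_module_sizes=[20, 20], planted_effect=1.0,
    within_module_corr=0.9, noise_sd=0.5, seed=11,
)
data, records, edges, planted = gv.simulate_cohort(cfg)

sel = gv.select_markers(data, edges, gv.PipelineConfig(), seed=3)
print(len(sel.markers.combined), "markers;",
      len(set(sel.markers.combined) & set(planted)), "of",
      len(planted), "planted genes recovered")

cv = gv.cross_validate(data, edges, n_folds=10, seed=3)
print(f"mean 10-fold AUC: {cv.mean_auc:.3f}")
```

prints

```
40 markers; 40 of 40 planted genes recovered
mean 10-fold AUC: 1.000
```

Both planted 20-gene modules end up in the L-groups and are selected in
full (the L-groups hold only ~20 eligible genes each here, so the panel
is 40 rather than 100 genes), and the cross-validated random forest
separates the two synthetic prognosis groups perfectly — the planted
mean shift is twice the noise SD, so this cohort is designed to be
easy; the point of the example is that the pipeline finds exactly the
genes that carry the signal.

The same pipeline runs from the shell:

```
g2vec simulate -o cohort/ --seed 11
g2vec run --simulate --seed 11 --folds 10 -o out/
g2vec select -e cohort/expression.tsv -l cohort/labels.tsv \
             -n cohort/network.tsv -o sel/ --seed 3
```

See `examples/` for short narrative scripts, one per capability.

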