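# Methods

## Problem and approach

Given a gene-by-sample expression matrix, binary good/poor prognosis
labels, and an undirected reference gene-interaction network, the
package selects a panel of prognostic biomarker genes and validates it
by cross-validated outcome prediction. The core idea is to learn a
distributed representation for every gene from random walks on
*prognosis-specific* correlation networks, so that genes whose local
co-expression neighborhood differs between outcome groups end up far
from the origin of the embedding space.

The pipeline has five stages, each a module:

1. **Correlation networks** (`corrnet`). For each prognosis group, every
   reference edge is weighted by the absolute Pearson correlation of its
   endpoint genes' expression over that group's samples only. Edges with
   weight strictly below 0.5 are removed (a weight exactly equal to the
   threshold is kept — the removal rule is a strict inequality). A gene
   with zero variance yields weight 0 on its edges rather than an error:
   a constant gene carries no correlation signal. The node set keeps
   every measured gene incident to a reference edge even if all of its
   edges fall below the threshold, because walks depart from all genes.

2. **Constrained random walks** (`walker`). From every node of each
   network, 10 walks depart. A walk never revisits a node, chooses the
   next node among unvisited neighbors with probability proportional to
   edge weight, and stops at a dead end or at 80 nodes. Path length is
   counted in nodes: an isolated node yields a single-node path, which
   is retained. A path whose exact ordered gene sequence is produced by
   both networks is removed from both label sets (set-based matching
   would remove more than intended; duplicates *within* one label are
   kept). Survivors are split 80/20 into training and validation,
   stratified by label so early stopping sees both classes.

3. **Path-origin classifier** (`embedder`). Each path is a multi-hot
   vector over the N genes. The model is a linear projection W (N x M,
   M = 128, no bias, no activation — the CBOW convention of summing the
   context vectors) followed by one sigmoid unit predicting whether the
   path came from the poor network. Training uses binary cross-entropy
   and Adam (learning rate 0.005, standard momentum parameters,
   batch size 64) for at most 30 epochs, with early stopping on
   validation loss (patience 3) and restoration of the best-validation
   weights. The model is implemented directly in numpy: with N*M + M + 1
   parameters and corpora of a few thousand paths, dense matrix products
   train in seconds on one CPU, and full bit-level determinism under a
   seed is straightforward to guarantee. No weight decay or dropout is
   applied — any regularization that touches all parameters would break
   the invariant that a gene absent from every training path keeps its
   initial row of W exactly (its gradient, and hence its Adam moments,
   stay identically zero). Rows of W are initialized i.i.d. Gaussian
   with scale 0.01, so the centroid of the initial vectors is the zero
   vector up to O(scale/sqrt(N)).

4. **Scoring and selection** (`scorer`). K-means with K = 3 partitions
   the gene vectors into the central cluster of untrained initial
   vectors and two "L-groups". The initial cluster is identified as the
   one holding the most untrained genes (ties resolved by the centroid
   nearest the origin). Each L-group is assigned to good or poor by the
   majority of its members' dominant path-frequency label; a gene whose
   good and poor path counts tie abstains, and if both clusters vote the
   same label the one with the stronger majority keeps it. Two scores
   rank genes: the d-score (Euclidean distance of the gene vector from
   the origin) and the t-score (absolute Welch two-sample t-statistic of
   the gene's expression between outcome groups; Welch rather than the
   pooled statistic because group variances need not match, and the two
   coincide under equal variance and size). Both are min-max normalized
   over the union of the two L-groups — not over all genes, because the
   thousands of near-origin initial vectors would compress the d-score
   range — and averaged into the gene score. The top 50 genes per
   L-group (ties broken by higher t-score, then gene id; the full chain
   makes selection a total order and hence input-order invariant) form
   the 100-gene panel; a smaller L-group contributes all its members
   with a warning. A frequency-difference baseline (Diff-Freq) selects
   the 50 genes with the largest positive and most negative
   good-minus-poor path-count differences.

5. **Evaluation** (`evaluator`). Stratified 10-fold cross-validation:
   the *entire* selection pipeline reruns on each fold's training
   samples only — correlations computed on training samples, walks,
   training and scoring all inside the fold — so no test-sample value
   can influence the panel. A random forest (500 trees, a size at which
   the AUC estimate is stable; otherwise library defaults) is trained on
   training-sample expression restricted to the fold's panel and scored
   on the held-out samples by AUC-ROC using the predicted
   poor-class probability. The small-sample experiment draws 10, 20 or
   30 samples per group as training (10 repeats), evaluating on the
   remainder.

## Synthetic cohorts

`datagen.simulate_cohort` produces the cohorts used throughout the test
suite. A configured number of planted modules are embedded in a random
background network as cliques. Module k is "active" in the good group
for even k and in the poor group for odd k: within the active group its
genes share a latent factor, `x = sqrt(rho) * z + sqrt(1 - rho) * eps`,
giving pairwise correlation rho (default 0.9) analytically, and their
mean is shifted up by `planted_effect` relative to the other group.
All other genes are i.i.d. Gaussian noise in both groups. Survival
times are drawn uniformly beyond the criterion (good, censored) or
within it (poor, death observed), so the labeling rule recovers the
generating labels exactly. Randomness flows from one seed through named
substreams (network, expression, survival), so every stage is
independently reproducible.

Default conditions — 500 genes, 60 samples per group, two 20-gene
modules, effect size twice the noise SD, correlation 0.9 — give a
cohort where the planted genes are unambiguously recoverable. What
passing tests on such cohorts shows is that the machinery is correct:
group-specific co-expression is detected, walks concentrate on the
planted modules, the embedding separates them, and selection returns
them. What it does not show is performance on real tumor cohorts, where
effect sizes are weaker, correlation structure is pervasive rather than
planted, modules overlap, and labels are noisy; the simulator has
neither batch effects nor censoring-informative dropout nor
heavy-tailed expression.

## Labeling rule

Patients surviving beyond the criterion without a death event are
"good"; patients with a recorded death within the criterion are "poor".
Patients censored before the criterion fit neither definition and are
excluded, which matches the binary classification framing; deaths after
the criterion are likewise excluded.

## Numerical and degenerate-case conventions

- Pearson weight of a zero-variance vector: 0 (not NaN, not an error).
- Edge retention: weight >= threshold (strict `< threshold` removal).
- Welch t with zero variance in both groups: 0 when means are equal.
- Min-max normalization of an all-equal score vector: all zeros.
- Single-gene scored set: normalized score 0 by the same convention.
- Dedup compares ordered sequences, is idempotent, and removes a
  redundant sequence from both labels.
- All stochastic components (simulation, walks, splits, initialization,
  batch order, K-means restarts, fold assignment, forests) derive from
  explicit seeds; identical inputs and seeds give bit-identical panels.

## Problem sizes

The test suite and the reproduction script run on the 500-gene /
120-sample cohorts described above, for which the full per-fold
pipeline takes well under a second per fold and the complete suite a
few minutes on one CPU. Larger cohorts scale linearly in samples for
correlation and in walks for corpus construction; the dense multi-hot
encoding is the memory bottleneck (paths x genes) and would move to a
sparse representation beyond ~50k genes x ~100k paths.

## Known limitations

- The embedding dimension (128), walk cap (80), walks per node (10) and
  learning rate (0.005) are sensible defaults, not re-optimized per
  dataset; no hyperparameter search is included.
- L-group assignment assumes the three K-means clusters are
  interpretable as one central and two separated groups; on data with
  no prognosis-specific structure the assignment degenerates (the null
  tests exercise this: AUC stays at chance).
- The random-forest validation inherits scikit-learn's determinism
  guarantees only for a fixed seed and version.
- t-SNE plotting is a qualitative aid; coordinates are stable under a
  fixed seed but carry no numeric contract.
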