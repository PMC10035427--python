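# Methods

## Problem and model

Each subject is represented as a graph whose nodes are brain regions of
interest (ROIs) and whose weighted edges encode statistical dependence
between the regions' resting-state fMRI time series. Classification
(e.g. patients vs. controls) uses a two-layer spectral graph
convolutional network

    F = ReLU( Â · ReLU( Â X W0 ) · W1 ),      Â = D^{-1/2} (A + I) D^{-1/2},

where `A` is the estimated connectivity ("brain functional network"),
`D` the degree matrix of `A + I`, and `X` the n × d node-feature matrix.
A graph-level embedding is read out as the concatenation of average and
maximum pooling over nodes, `H_G = mean_i f_i ‖ max_i f_i`, and a single
linear layer maps `H_G` to two class logits trained with softmax
cross-entropy. The scientific question the package is built around is
how the *choice of X* — raw signals (OS), one-hot position indicators
(OH), eight graph statistics (NS), correlation vectors (CV), or
concatenations — affects classification.

The GCN, its backward pass, Glorot-uniform initialization, and the Adam
optimizer are implemented directly in NumPy; a finite-difference check
verifies the analytic gradients to 1e-4. Weight decay is applied as an
L2 term added to the gradient inside Adam (the classic Adam-with-L2
variant, not decoupled AdamW). Training is full batch by default;
`batch_size` switches to seeded mini-batches.

Default training hyperparameters follow the study protocol: embedding
dimension 32 (both layers), 100 epochs, learning rate 0.001, weight
decay 1e-3. No dropout, early stopping, or inner validation split is
used by default. The classification head (linear 2d′ → 2 with softmax)
is the minimal standard choice for a mean‖max readout.

## Connectivity estimators

* **Pearson (PC)** — sample correlation between ROI time series; dense,
  signed, zero diagonal.
* **Sparse representation (SR)** — each ROI's z-scored series is
  regressed on all others under `min_w ½‖s_i − S_{−i}w‖² + λ‖w‖₁`
  (coordinate descent via scikit-learn; `alpha = λ/m` converts between
  the unnormalized objective and scikit-learn's per-sample scaling; max
  10⁴ iterations, tol 1e-6). Coefficients are assembled with zero
  diagonal and symmetrized as `(|W| + |Wᵀ|)/2`. Edge count is
  nonincreasing in λ.
* **Low rank (LR)** — nuclear-norm proximal denoising of the PC matrix,
  `min_W ½‖C − W‖²_F + λ‖W‖_*`, solved exactly by singular-value
  soft-thresholding; λ → 0 recovers C, λ above the top singular value
  gives the empty network. The same `(|W| + |Wᵀ|)/2` symmetrization is
  applied. This is the simplest convex low-rank estimator with a
  closed-form solution.

Because PC (and the symmetrization-free case) can produce negative
weights, the GCN normalization uses `|A|` when forming degrees, which
guarantees a real `D^{-1/2}` and a normalized spectrum inside [-1, 1].
Weighted adjacencies are used by default; an optional proportional
threshold (`bfn.binarize`, keep top fraction of |edges|) produces the
0/1 variant.

## Node features

Widths: OS → m (time points), OH → n (identity), NS → 8, CV → n. Blocks
concatenate in the fixed order OS, OH, NS, CV whatever order is
requested, and the final matrix is per-column z-scored across nodes by
default (`features.standardize`) because the blocks live on very
different scales.

The eight node statistics, in column order:

1. `cc_ws` — Watts–Strogatz binary clustering coefficient,
2. `cc_onnela` — Onnela geometric-mean weighted clustering,
3. `cc_zhang` — Zhang–Horvath weighted clustering (weights rescaled by
   their maximum),
4. `deg_c` — degree / (n−1),
5. `btw_c` — betweenness, normalized by (n−1)(n−2)/2,
6. `clo_c` — harmonic closeness / (n−1) (the harmonic convention keeps
   disconnected graphs well-defined; unreachable pairs contribute 0),
7. `eig_c` — eigenvector centrality: leading eigenvector of the |weight|
   matrix by dense symmetric eigendecomposition, L2-normalized,
8. `local_eff` — efficiency of the subgraph induced on each node's
   neighbors (unreachable pairs contribute 0).

Binary-definition statistics (1, 4, 5, 6, 8) are computed on a
proportionally thresholded graph (default keep top 30% of |edges|,
`features.ns_keep_fraction`); weighted definitions (2, 3, 7) use
|weights|. These conventions are choices — other clustering or
efficiency definitions would shift NS features somewhat — and each is
swappable in config. All eight are validated against brute-force
oracles (explicit path enumeration, triangle counting, power iteration)
on random small graphs.

## Evaluation protocol

Each repeat draws a random (unstratified) 80/20 split; a training half
missing a class is redrawn with a derived seed and logged. Test size is
`round(0.2·N)`. Metrics per repeat: Acc, Sen, Spe, Pre, F1 from the
confusion counts exactly as printed above, and AUC as the Mann–Whitney
rank statistic (equal to the fraction of correctly ordered
positive/negative score pairs, ties ½). Zero-denominator metrics are
reported as 0 and flagged rather than NaN so aggregation over repeats
stays total. Aggregation reports mean and *population* standard
deviation over repeats. Repeat k uses split seed `master_seed + k` and
training seed `train_seed + k`, so grids are bit-reproducible from the
config; every run directory stores the resolved config and seed list.

## Synthetic cohorts

The generator emulates the second-order structure the estimators
consume: each group has a unit-diagonal latent correlation matrix, equal
to `base_correlation` on a chosen block of ROI pairs (shifted by
`effect_delta` in group 1) and zero elsewhere; subjects are m i.i.d.
multivariate-normal time points plus N(0, noise_sd²) measurement noise.
Positive definiteness is verified by eigendecomposition, with a logged
diagonal-loading repair. Defaults: n_rois 116 and m 135 (mirroring a
116-ROI cohort with 135 retained volumes; m 175 matches the second
cohort shape), base_correlation 0.2 and noise_sd 0.25 — a modest
background coupling and measurement noise that attenuates observed
correlations by ~6%.

What the generator does **not** emulate: hemodynamic response,
autocorrelated BOLD noise, motion artifacts, scanner/site effects,
subject-level effect heterogeneity, or signed community structure.
Consequences for interpretation: a fixed strong block effect makes the
*adjacency itself* highly discriminative, so feature sets that carry no
subject information in X (one-hot) can still classify via the
degree-profile statistics the GCN extracts from Â. Passing tests on
synthetic cohorts therefore demonstrate pipeline correctness and signal
recovery, not the real-data ranking of feature sets — in particular the
near-chance one-hot performance reported on clinical cohorts arises
from weak, heterogeneous real effects that this Gaussian generator does
not reproduce (see `tests/test_acceptance.py::
test_feature_choice_drives_synthetic_classification`, which documents
the expectation and currently fails its one-hot bound for exactly this
reason).

## Numerical choices and edge cases

* Constant (zero-variance) ROI rows are rejected by the estimators with
  the offending ROI named; the loader tolerates them so they can be
  inspected.
* Symmetry of raw adjacencies is enforced to 1e-8; PC entries are
  clipped to [-1, 1] after floating-point symmetrization.
* Ties in max pooling route the gradient to the first maximal node.
* The lasso reports non-convergence (with the residual) instead of
  returning a silently unconverged estimate.
* Problem sizes in the test suite and acceptance script (30 ROIs, 150
  time points, 80 subjects, 20 repeats) are scaled-down analogues of the
  full 116-ROI, 100-repeat protocol; the pipeline runs the full sizes
  unchanged via config.

## Known limitations

* SR and LR hyperparameters are exposed, not tuned; no model selection
  is provided.
* No stratification, significance testing, dynamic connectivity,
  partial correlation, or population-graph variants.
* The NS clustering-coefficient trio is one defensible reading of
  "three definitions of local clustering coefficients"; results shift
  slightly under other definitions.
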