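# Methods

## Model

Regional brain features — mean FDG-PET uptake or gray-matter (GM)
density per atlas region — are modelled as draws from a multivariate
Gaussian, `x_1 … x_n ~ N(mu, Sigma)` over `p = 42` regions of the AAL
parcellation (frontal 12, parietal 8, occipital 6, temporal 16).  The
object of interest is the precision matrix `Theta = Sigma^{-1}`: its
off-diagonal zeros encode conditional independence between region pairs
given all other regions, so its support is an undirected connectivity
graph ("arcs") and its entries are, up to scaling, partial
correlations.  Because typical sample sizes are close to `p`, the
estimate is obtained by maximising the l1-penalised log-likelihood

```
Theta_hat = argmax_{Theta > 0}  log det(Theta) - tr(S Theta) - lambda * ||Theta||_1
```

with `S` the empirical covariance (divisor `n`) and `||.||_1` the sum of
absolute values of **all** entries.  The penalty drives weak partial
correlations to exact zero; larger `lambda` gives sparser graphs, and
the regularisation path has the monotone property that regions
disconnected at some `lambda` never reconnect at larger `lambda`, which
lets sparseness serve as a proxy for connection strength.

### Solver

The solve is delegated to the coordinate-descent graphical-lasso
routine of scikit-learn, which penalises only off-diagonal entries.
The full-matrix penalty above is recovered exactly through the identity
`tr((S + lambda I) Theta) = tr(S Theta) + lambda * sum_i |Theta_ii|`
(valid because the diagonal of an SPD matrix is positive): the solver
is run on `S + lambda I`.  `penalize_diagonal=False` switches to the
plain off-diagonal penalty.  At `lambda = 0` the estimator reduces to
direct inversion of `S` (refused when `S` is singular).  Near-singular
problems at tiny `lambda` occasionally break coordinate descent; the
solve then falls back to the LARS mode.  Correctness is anchored to
independent oracles: a dense grid search of the objective at `p = 2`, a
Nelder–Mead maximisation over the Cholesky factor at `p = 3`, and the
closed-form inversion at `lambda = 0` (tests and the acceptance
script).

### Numerical conventions

- `zero_tol = 1e-8`: solver output below this magnitude (off-diagonal)
  is truncated to exact zero before arcs are counted.
- Lambda sweep: bisection on `[1e-4 * s_max, s_max]`, `s_max` the
  largest off-diagonal `|S|` (the graph is empty above `s_max`).  Arc
  counts are non-increasing in `lambda`; when a target count falls in a
  jump of the solution path, the closest bracketing solution is
  returned (ties to the sparser side) and the realized count recorded.
- Binarization threshold is 0: every surviving off-diagonal entry is an
  arc, regardless of sign.
- Tie-breaks in `top_arcs` are lexicographic on region pairs, making
  arc selection deterministic.

## Cumulative network

Binarized estimates at arc levels `narcs = {10, 25, 50, 75, 100}` are
combined as `Theta_c = sum_n (10/n) * bin[Theta_hat_n]`.  The `10/n`
weight makes arcs that survive aggressive sparsification (strong
partial correlations, by the monotone property) dominate: an arc
present at every level accumulates `1 + 0.4 + 0.2 + 0.133 + 0.1 ≈
1.83`, one appearing only at 100 arcs just `0.1`.  The weight function
is a configuration hook.

## Graph metrics and lobe accounting

Two small-world-oriented metrics are computed for binary undirected
graphs: the average clustering coefficient `C = mean_i 2 t_i / (k_i
(k_i - 1))` with `t_i` the triangle count around node `i` (`C_i = 0`
for `k_i < 2`), and the average number of connections per hub `E =
mean_i sum_j a_ij k_j`.  Averages are taken over all nodes for
whole-network curves and over non-isolated nodes for cluster-level
reports (both exposed).  Clusters are connected components with at
least two nodes; hubs are the top-3 nodes by degree (ties included;
the cutoff is configurable because no canonical value exists).

Lobe-block cell accounting covers the full `42 x 42` matrix including
the diagonal: intra-lobe blocks hold `12^2 + 8^2 + 6^2 + 16^2 = 500` of
1764 cells, so inter-lobe cells are `1264/1764 = 71.65%` and the
occipital block `36/1764 = 2.04%`; report output truncates percentages
(71%, 2%), full precision is kept internally.

The fold-wise difference measure compares two collections of
connectivity matrices (one matrix per cross-validation fold) entry by
entry over the strict lower triangle: a pooled-variance two-sample
t-test on absolute entry values, reported as the percentage of the
`p(p-1)/2` entries with `p < alpha` (default 0.05).  Identical
zero-variance entries count as not different.  Under the null the
measure averages `100 * alpha` percent (verified by simulation).

## Discriminative pipeline

For classes A and B, each class's `Theta_hat` (estimated independently
on that class's training subjects at a matched arc count, default 100)
induces regression coefficients `beta_ij = -Theta_ij / Theta_ii`
(`beta_ii = 0`), and residuals `eps_i = f_i - sum_{j != i} beta_ij
f_j` with `var(eps_i) = 1/Theta_ii` under the generating model.  Since
`beta` is the optimal linear predictor only under its own class's
distribution, residuals are systematically smaller under the matching
model; the concatenated vector `(eps^A, eps^B)` (84 features for the
42-region atlas, 168 when PET and GM are combined) is fed to a linear
soft-margin SVM (`C = 1`).  The linear kernel is required so that the
primal weight vector `W = sum_j y_j lambda_j x_j` exists; region
relevance is `|W_i + W_{i+p}|` (the two class slots of region `i`),
affinely rescaled to `[1, 42]`.  Residuals are not standardised by
default (a training-fold-fitted z-scoring flag exists).

Evaluation is stratified 10-fold cross-validation with a seeded
shuffle.  Voxel preselection masks, per-class precision matrices,
`beta` and the SVM are all refit within each training split; the
held-out fold is only transformed and scored.  Sensitivity treats the
clinically worse group of the pair as positive.  AUC is computed from
decision scores pooled across folds; accuracy/sensitivity/specificity
are fold means ± sd.

## Voxel stages

PET intensity normalisation divides every volume by the mean of the
brightest `ceil(1%)` voxels of the across-subject mean volume (ties at
the cut included), making activation levels comparable across subjects
while remaining scale-equivariant.  GM density is `rho_i` = fraction of
region-`i` voxels with tissue probability `>= 0.5` (the natural
membership rule; threshold configurable).  Voxel preselection is a
two-sided pooled-variance two-sample t-test per labeled voxel at `p <
0.01`, computed whole-brain (the test is voxelwise, so per-region
computation would give identical results).  The PET region feature is
the mean over selected voxels of the region, falling back to the whole
region when the mask empties it.  Volumes are handled in voxel index
space; atlas and subject volumes must already be aligned (no
resampling).

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not imaging physics.  True precision matrices are sparse and
lobe-block-structured: intra-lobe pairs receive edges with probability
0.3 and weights uniform on `(0.2, 0.5)` with random sign; inter-lobe
pairs with probability 0.02 and the weak end of the range — intra-lobe
conditional dependencies are denser and stronger, the regime the
exploratory analysis is designed to expose.  Positive definiteness is
enforced by diagonal dominance (`Theta_ii` = row absolute off-diagonal
sum + 1), which bounds partial correlations below 0.5 — intentionally
modest coupling.  Subjects are i.i.d. draws from `N(mu_g,
Theta_g^{-1})`.

The default three-group scenario designates eight medial/inferior
temporal regions (temporal poles mid, fusiform, hippocampus,
parahippocampal, ids 33/34/37–42) as affected: for AD every edge
incident to an affected region is removed and affected means drop by
1.0 (about 1.4 within-group standard deviations); MCI attenuates edges
by 0.5 and means by 0.5.  The disconnection mirrors the loss of strong
temporal-lobe connections that characterises the disease, and the mean
effect size matches the large regional hypometabolism differences
reported for AD versus controls (standardised differences above 1);
note that with a linear decision function the class signal in the
residual features is carried by their means — precision differences
shape how mean differences propagate through `beta` — so realistic
mean effects are essential for the discriminative stage to have
signal at all.

Toy volumes place each region's feature value, plus i.i.d. Gaussian
noise (sd 0.05), on a contiguous block of exactly `voxels_per_region`
voxels in a 3-D block grid.  No spatial autocorrelation, partial-volume
effects or scanner physics are simulated, and region shape is
arbitrary; consequently passing tests demonstrate correctness of the
computations and recoverability under the model's own assumptions —
not performance on real images, where registration error, smoothing
and non-Gaussianity intervene.

## Validation problem sizes

Oracle equivalence uses `p = 2–4` instances; path monotonicity and
support recovery use `p = 10` with `n = 400–2000`; the residual
variance identity `n = 10000`; discriminative recovery the full `p =
42` atlas with 60 subjects per group and 10-fold CV — comparable to
the cohort sizes such studies actually enrol — with a negative control
(identical group models) expected at chance accuracy.

## Known limitations

- Edge strengths are uniform with random sign; real covariance
  structure of regional PET uptake is not characterised here.
- The lambda sweep assumes a monotone arc count; solver noise can
  produce isolated violations, which are tolerated (closest bracket is
  returned) rather than treated as errors.
- `sweep_lambda_to_arcs` at very small lambda on near-singular `S`
  relies on the LARS fallback, which is slow; pathological inputs
  (constant features) should be cleaned upstream.
- Classification metrics on synthetic data characterise the pipeline's
  recovery behaviour, not expected clinical performance.
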