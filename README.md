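# sicenet

Sparse inverse covariance estimation (SICE, a.k.a. the graphical
lasso) for inter-regional brain connectivity, with a discriminative
pipeline that classifies subjects from per-class regression
reconstruction errors.  Built for researchers studying connectivity
differences between cognitively normal (CN), mild cognitive impairment
(MCI) and Alzheimer's disease (AD) groups from FDG-PET uptake or
gray-matter density features over 42 AAL regions — and for anyone who
wants a tested, fully synthetic-reproducible implementation of this
class of analysis.

## The method

Regional features are modelled as `x ~ N(mu, Sigma)` over `p = 42`
regions.  The precision matrix `Theta = Sigma^{-1}` encodes conditional
independence: `Theta_ij = 0` iff regions `i` and `j` are independent
given the rest, so its support is an undirected connectivity graph.
`Theta` is estimated per subject group by maximising the penalised
log-likelihood

```
Theta_hat = argmax_{Theta > 0}  log det(Theta) - tr(S Theta) - lambda ||Theta||_1
```

sweeping `lambda` until a target arc (edge) count is reached so that
groups are compared at matched sparseness.  The exploratory side
binarizes these estimates, computes small-world graph metrics
(clustering coefficient, connections per hub), lobe-block connection
statistics and a cumulative network that scores each arc by its
resistance to sparsification.  The discriminative side derives
per-class regression coefficients `beta_ij = -Theta_ij / Theta_ii`,
computes each subject's reconstruction errors under both class models,
and feeds the concatenated error vectors (2 x 42 = 84 features) to a
linear SVM, evaluated by stratified 10-fold cross-validation; the SVM
weight vector ranks regions by discriminative relevance.

Everything runs end-to-end on synthetic data with known ground truth:
the generator draws group-labelled subjects from sparse,
lobe-block-structured precision matrices and can render toy NIfTI
volumes so the voxel stages (intensity normalisation, t-test voxel
preselection, region-feature extraction) are exercised too.  See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
import sicenet as sn

truth = sn.default_scenario(seed=7)             # CN/MCI/AD ground truth, p = 42
features = sn.sample_subjects(truth, n_per_group=60, seed=8)

cov = sn.empirical_covariance(features.group("CN"))
est = sn.sweep_lambda_to_arcs(cov, target_arcs=25)
net = sn.binarize(est, truth.partition)
metrics = sn.clustering_coefficient(net, node_scope="all")
stats = sn.lobe_connection_stats(truth.partition, net)
print(f"CN network at {net.arcs} arcs: lambda={est.lam:.4f}, "
      f"C={metrics.avg_clustering:.3f}, intra-lobe arcs {stats.intra_arc_share:.0f}%")

report = sn.cross_validate(features, ("CN", "AD"), target_arcs=100, k=10, seed=9)
print(f"CN/AD 10-fold CV: accuracy {report.accuracy:.2f} +/- {report.accuracy_sd:.2f}, "
      f"AUC {report.auc:.2f}")
print("most discriminative regions:", report.region_ranking.top(5))
```

prints

```
CN network at 25 arcs: lambda=0.1689, C=0.034, intra-lobe arcs 36%
CN/AD 10-fold CV: accuracy 0.95 +/- 0.08, AUC 0.99
most discriminative regions: [41, 34, 40, 38, 37]
```

The sweep found the `lambda` whose estimate has exactly 25 arcs; the
sparse CN network has low average clustering at this sparseness.  The
cross-validated classifier separates CN from AD almost perfectly on
this synthetic cohort, and the top-ranked regions (parahippocampal,
temporal pole, hippocampus, fusiform) are exactly where the generator
planted the group differences — the recovery the pipeline is designed
to demonstrate.

A command-line interface mirrors the library
(`sicenet synth | features | sice | network | classify | all`), e.g.

```
sicenet all --pair CN_AD --n-per-group 60 --seed 17 --out artifacts/
```

writes feature tables, per-group networks (edge-list TSV + GraphML),
metric curves, the cumulative matrices, cross-validation reports and
the region ranking into `artifacts/`.

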