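# Methods

`richconn` implements a weighted rich-club analysis of structural brain
connectomes together with a synthetic cohort generator that reproduces the
statistical structure such an analysis assumes. This note documents the
models, the defaults and why they were chosen, the numerical conventions,
and what the synthetic cohorts do and do not emulate.

## Network construction

Each subject contributes a symmetric streamline-count matrix `FN`, a mean
fractional-anisotropy matrix `FA` (support identical to `FN`) and per-node
volumes. The analysis weight of an edge is

    w_ij = FN_ij * FA_ij / ((vol_i + vol_j) / 2),    FN_ij >= t

with the FN threshold `t` defaulting to 1 (thresholds 1, 2, 3, 5 and 10 are
used in the reproducibility grid). The volume denominator is the arithmetic
mean of the two endpoint volumes — the plain reading of "average volume of
the two connecting nodes".

Group-consensus backbones retain an edge when it is present (`w > 0`) in at
least a prevalence fraction of subjects (default 0.75; 0.50 and 0.90 in the
grid). The backbone edge weight is the mean over the subjects in which the
edge is present; the prevalence rule only defines support, so the backbone
weight is our choice, and a binary backbone is available via
`ConsensusBackbone.to_network(binary=True)`.

Sparsity thresholding keeps the `round(s * N(N-1)/2)` largest-weight edges
(round half away from zero); ties at the cut are broken by lowest (i, j)
lexicographic index so results are deterministic.

## Graph metrics

Edge length is the reciprocal weight `1/w` — the standard convention for
structural connectomes, where stronger connections are "closer". Distances
are Dijkstra shortest paths; disconnected pairs have infinite distance.

* **Global efficiency** `Eg` = mean over ordered pairs of `1/d_ij`
  (disconnected pairs contribute 0); **nodal efficiency** is the per-node
  row mean.
* **Characteristic path length** `Lp` averages only the finite distances;
  an empty network reports `Lp = 0` by convention.
* **Clustering** `Cp` uses the Onnela geometric-mean triangle form with
  weights normalized by the network maximum; it reduces to the binary
  triangle fraction on uniform weights. Nodes of degree < 2 contribute 0
  and stay in the average.
* **Local efficiency** `Eloc` is the mean over all nodes of the global
  efficiency of the weighted subgraph induced by each node's neighbours.
* **Small-world indices**: `gamma = Cp / <Cp_null>`,
  `lambda = Lp / <Lp_null>`, `sigma = gamma / lambda`, with arithmetic means
  over the null ensemble.

Metric-versus-sparsity curves run over sparsity 0.10–0.40 in steps of 0.01
by default and are summarized by the trapezoidal area under the curve; group
comparisons default to the AUC but the per-threshold values are reported as
well, since either convention appears in the literature.

## Degree-preserving null model

Null networks are produced by Maslov–Sneppen double-edge swaps on the binary
topology (default 10 accepted swaps per edge), which preserves every node's
degree exactly, followed by a random reassignment of the original weight
multiset to the rewired edges. Both invariants (exact degree sequence, exact
weight multiset) are asserted in tests on every draw. Networks with fewer
than two edges cannot be swapped and are returned unchanged with a
`rewire_warning` flag. The default ensemble size is 1,000 networks;
analyses at test scale use smaller ensembles, chosen as the package's own
trade-off between Monte-Carlo error (the null mean of a curve stabilizes
quickly) and runtime.

## Weighted rich club

With node degree defined on the binary topology, the weighted rich-club
coefficient at level k is

    Phi_w(k) = W_{>k} / sum of the E_{>k} largest weights network-wide,

where `W_{>k}` and `E_{>k}` are the weight sum and count of edges joining
nodes of degree > k. `Phi_w` is undefined (flagged as NaN, never coerced to
0) when the club has no edges. Normalization divides by the ensemble mean of
`Phi_w` over rewired nulls; `Phi_norm > 1` across a k range indicates
rich-club organization.

Rich nodes are selected either as the top-n nodes by degree (default n = 32
on the group consensus backbone, ties broken by strength then node index) or
by a degree cutoff (`degree > k`, e.g. k = 7). Edges are classified as
rich-club (both endpoints rich), feeder (exactly one) or local (neither);
the three class strengths partition total strength exactly. Group
comparisons use each group's own rich set by default, with a shared
intersection option, because published analyses rarely state which set
parameterizes the comparison. Note that some reports verbally swap the
rich/feeder definitions; this package follows the standard ones.

## Statistics

* **Group tests** on network quantities use a two-tailed permutation test of
  the difference in group means with 10,000 permutations by default.
  Covariates (age, sex coded 0/1, education) are removed by the
  Freedman–Lane scheme: residualize the pooled values once by OLS, then
  permute group labels over the residuals. P-values use the add-one
  estimator `(1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm)`, so p > 0 always.
* **Multiple comparisons**: Holm–Bonferroni (FWE) by default, with
  Benjamini–Hochberg FDR available; the correction family for the edge-class
  comparison is the three class strengths per batch.
* **Clinical correlations**: Spearman rank correlation of
  covariate-residualized variables, two-tailed p by the t approximation;
  at least 4 observations required.
* **Demographics**: Mann–Whitney U (exact for min(n, m) <= 8 without ties,
  normal approximation with midrank tie correction otherwise) and the
  Pearson chi-square test for sex (continuity correction available by flag —
  published tables do not always state which variant was used, so both are
  exposed).

## Synthetic cohorts

The generator emulates a two-group DTI cohort (defaults: 43 patients, 42
controls, 90 nodes with 45 per hemisphere, 32 planted hubs):

* **Anatomical scaffold.** A cohort-level edge scaffold is drawn once with
  block densities hub–hub 0.75, hub–nonhub 0.25 and nonhub–nonhub solved so
  the expected scaffold density is 0.25. Subjects realize scaffold edges
  with reliability 0.9 and non-scaffold edges at a spurious rate of 0.02.
  This cross-subject consistency is what makes a 75% consensus backbone
  non-empty, as in real tractography cohorts; fully independent edges would
  not.
* **Streamline counts.** FN on present edges is `1 +` a negative-binomial
  count (dispersion 3 — streamline counts are overdispersed), with mean 20
  on local edges, enriched by a factor 4 on hub–hub edges (geometric
  midpoint 2 on feeder edges). In patients every hub-involved edge mean is
  multiplied by `group_deficit` (default 0.7), planting the rich-club and
  feeder strength reduction.
* **FA and volumes.** FA is Beta(4, 3) rescaled to (0.2, 0.9) — tracking
  masks exclude FA < 0.2 — independent of FN; volumes are lognormal
  (log-mean 7, log-sd 0.4), strictly positive and right-skewed like regional
  voxel counts.
* **Clinical scores.** PSQI/ISI/SAS/SDS follow group-specific normal
  marginals truncated at 0 (patient means far above controls); disease
  duration is lognormal in patients and 0 in controls. A score coupled to a
  connection class (defaults: ISI–rich-club rho 0.58, SDS–rich-club
  rho −0.31) is drawn through a Gaussian copula between the subject's
  realized class strength and the score marginal, with copula parameter
  `2 sin(pi rho / 6)` so the target rho is the Spearman correlation. The
  class strength is mapped to a normal score using moments estimated from a
  small internal calibration sample (200 draws, seeded and cached), since
  its marginal has no closed form; the strength is a sum over hundreds of
  edges, so the normal approximation is accurate.
* **Covariates.** Age (normal 40.4 ± 10.3 truncated to 18–60), education
  (normal 7.8 ± 4 truncated at 0) and sex (P(male) = 0.447) are independent
  of group, emulating a matched cohort; `group_age_shift` can inject a
  confound for exercising covariate removal.

What the generator does **not** emulate: spatial geometry (no
distance-dependent connectivity, so no genuine small-world clustering —
`gamma` of synthetic backbones is near 1 and `sigma` is not planted above
1), anatomically realistic hub placement, within-subject correlation between
FA and FN, scan-rescan noise, and any mechanistic link between the group
deficit and the within-group score couplings (the two are independent
knobs). Passing tests therefore validate the machinery — estimator
correctness, calibration, power against a planted effect — not anatomical
realism.

The paper-scale group effects themselves (specific regions, exact p-values,
exact correlation magnitudes of a real 85-subject MRI cohort) are not
reproducible without the original data; the tests instead verify the
pipeline's statistical contracts at the same sample sizes.

## Numerical and design choices

* Symmetry is enforced exactly on construction (upper triangle mirrored), so
  downstream code never sees asymmetries at machine precision.
* Undefined quantities (empty rich club, zero null mean, zero-denominator
  ratios) propagate as NaN flags and are excluded from curves, never set
  to 0.
* The pipeline expands a single seed into per-stage children via
  `SeedSequence`, so any stage can be re-run in isolation and a fixed
  configuration yields byte-identical JSON reports (floats serialized at 12
  significant digits).
* Problem sizes in the test-suite Monte-Carlo checks (replicate counts,
  null-ensemble sizes of 12–100, 1,000 permutations) are the package's
  balance of Monte-Carlo tolerance against desk-scale runtime; the defaults
  exposed to users remain the field-standard 1,000 nulls and 10,000
  permutations.

## Known limitations

* The weighted rich-club normalization reuses the same rewired ensemble
  family as the small-world indices; no weight-preserving alternatives
  (e.g. strength-sequence-preserving nulls) are provided.
* `Lp` on disconnected networks averages finite distances only, which can
  make sparser networks look "shorter"; efficiency metrics are the
  principled alternative and are always reported alongside.
* The copula coupling targets the cohort-level Spearman correlation; with
  very small groups (< ~20) the recovered correlation is noisy, as expected
  from the sampling distribution of rank correlations.
* Directed or signed networks, betweenness/eigenvector centrality,
  modularity and k-core decompositions are out of scope.
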