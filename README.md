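# richconn

Weighted rich-club analysis of structural brain connectomes, with a
synthetic-cohort simulator for end-to-end validation.

## The problem

Diffusion-MRI tractography yields, for every subject, a streamline-count
matrix `FN`, a mean fractional-anisotropy matrix `FA` and per-region volumes
over an atlas (e.g. the 90-node AAL parcellation). Clinical connectomics
studies build weighted networks

    w_ij = FN_ij · FA_ij / ((vol_i + vol_j) / 2)

from these ingredients and ask whether a patient group shows weakened
*rich-club organization* — whether the edges among high-degree hub regions
are disproportionately strong, and whether that core is selectively
affected by disease and related to symptom severity.

`richconn` provides that full analysis as a tested, reusable library and
CLI for researchers who have connectivity matrices (not raw images) and
want reproducible group inference:

* per-subject weighted network construction with FN thresholds, and
  group-consensus backbones (edges present in ≥ a prevalence of subjects);
* global/nodal graph metrics (Cp, Lp, Eg, Eloc, nodal efficiency), the
  small-world indices γ = Cp/⟨Cp_rand⟩, λ = Lp/⟨Lp_rand⟩, σ = γ/λ against
  degree-preserving Maslov–Sneppen nulls, and metric-vs-sparsity AUCs over
  sparsity 0.10–0.40;
* the weighted rich-club coefficient

      Φʷ(k) = W₍>k₎ / Σ of the E₍>k₎ largest weights network-wide,

  its null-normalized form Φ_norm(k) = Φʷ(k)/⟨Φʷ_null(k)⟩, rich-node
  selection (top-n by degree, or degree > k), and the decomposition of
  edges into rich-club / feeder / local classes with per-subject class
  strengths;
* nonparametric permutation group tests with Freedman–Lane covariate
  removal (age, sex, education), Holm–Bonferroni/BH correction,
  covariate-adjusted Spearman correlations with clinical scores
  (PSQI/ISI/SAS/SDS/duration), Mann–Whitney and χ² demographics;
* a seeded synthetic cohort generator (two groups, planted hub structure,
  planted group deficit on hub-involved edges, copula-coupled clinical
  scores) so every stage is testable without any data download;
* BrainNet Viewer `.node`/`.edge` exports.

See `docs/methods.md` for the model conventions and design decisions.

## Worked example

```python
import numpy as np
from richconn import (SimulationConfig, generate_cohort, build_network,
                      group_consensus, identify_rich_nodes,
                      subject_class_strengths, normalized_rich_club,
                      permutation_group_test, holm_bonferroni)

cfg = SimulationConfig(seed=7)        # 43 patients / 42 controls, 90 nodes
atlas, subjects = generate_cohort(cfg)
nets = [build_network(raw, fn_threshold=1, atlas=atlas) for _, raw in subjects]
groups = np.array([rec.group for rec, _ in subjects])

controls = [n for n, g in zip(nets, groups) if g == "control"]
patients = [n for n, g in zip(nets, groups) if g == "patient"]
backbone = group_consensus(controls, prevalence=0.75).to_network()
print(f"control backbone: {backbone.n_edges} edges")

curve = normalized_rich_club(backbone, n_null=100, seed=1)
k_above = curve.k_grid[np.nan_to_num(curve.phi_norm) > 1]
print(f"phi_norm > 1 for k = {k_above.min()}..{k_above.max()} "
      f"(peak {np.nanmax(curve.phi_norm):.2f})")

rich = identify_rich_nodes(backbone, top_n=32)
s_pat = subject_class_strengths(patients, rich)
s_con = subject_class_strengths(controls, rich)
ps = [permutation_group_test(s_pat[c], s_con[c], n_perm=10_000, seed=2).p_raw
      for c in ("rich_club", "feeder", "local")]
adj, _ = holm_bonferroni(ps)
for cls, p, a in zip(("rich-club", "feeder", "local"), ps, adj):
    print(f"{cls:9s}  p_raw={p:.4f}  p_holm={a:.4f}")
```

prints

```
control backbone: 987 edges
phi_norm > 1 for k = 1..44 (peak 1.61)
rich-club  p_raw=0.0001  p_holm=0.0003
feeder     p_raw=0.0001  p_holm=0.0003
local      p_raw=0.9074  p_holm=0.9074
```

The control backbone shows rich-club organization (Φ_norm above 1 over a
wide degree range), and the planted patient deficit — a 30% reduction of
streamline counts on hub-involved edges — is detected on rich-club and
feeder strengths but not on local connections, exactly the dissociation the
analysis is designed to isolate.

The same stages are available from a shell:

```bash
richconn simulate --out cohort/ --seed 7
richconn build --in cohort/ --out nets/ --fn-threshold 1
richconn run-all --out results/ --seed 7
```

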