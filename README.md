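# migconn

Resting-state functional-connectivity analysis of **chronic migraine (CM)
vs. episodic migraine (EM)**, built as a tested, reusable Python pipeline.

Chronic migraine — ≥ 15 headache days per month — affects roughly 1.5% of
people, and why some episodic migraineurs chronify is unknown. One
data-driven way to probe this is whole-brain resting-state fMRI: decompose
the BOLD signal of a patient cohort into large-scale networks, build a
weighted connectivity graph on those networks, and ask whether any node is
wired more strongly in CM than in EM. `migconn` implements that full chain
for methodologists and clinical neuroimaging researchers:

- **Synthetic cohorts** with planted connectivity structure (default: 44 EM
  vs. 18 CM subjects, 100 volumes at TR = 3 s, seven nodes), so every stage
  is testable without scanner data.
- **Preprocessing**: framewise-displacement scrubbing (FD > 0.5 mm), 12 s
  initial trim, global intensity normalization to 10,000, zero-phase
  0.009–0.08 Hz band-pass, 6 mm FWHM Gaussian smoothing.
- **Group ICA**: spatial ICA of temporally concatenated runs defines K
  network nodes; subject node time series by dual-regression stage 1;
  signal/noise labelling by template cross-correlation at the 0.25 rule.
- **Connectome**: edges, soft thresholding, Fisher z, degree centrality.
- **Inference**: label-permutation group test with Benjamini–Hochberg FDR,
  covariate-adjusted linear models, clinical correlations, interactions.
- **Seed analysis**: spherical hypothalamus / dorsal-raphe / periaqueductal-
  gray ROIs and their seed-to-network group contrasts.
- **Clinical statistics**: baseline-table chi-square / Fisher exact /
  Mann–Whitney comparisons.

## The statistic at the core

For a subject with node time series $x_1,\dots,x_K$ (columns standardized),
edges are **L2-regularized partial correlations**: with sample covariance
$\Sigma$ and $c = \operatorname{mean}(\operatorname{diag}\Sigma)$,

$$P = (\Sigma + \lambda c I)^{-1}, \qquad
  r_{ij} = -\,\frac{P_{ij}}{\sqrt{P_{ii}P_{jj}}} .$$

Edges are then **soft-thresholded** with the power adjacency
$w_{ij} = |r_{ij}|^{\beta}$ (default $\beta = 6$), variance-stabilized with
**Fisher's transform** $z_{ij} = \operatorname{arctanh}(w_{ij})$, and
summarized per node as **degree centrality**
$\mathrm{DC}_i = \sum_{j \ne i} z_{ij}$.

The group contrast $T_k = \overline{\mathrm{DC}}_k^{\,CM} -
\overline{\mathrm{DC}}_k^{\,EM}$ is tested by relabelling subjects
(preserving group sizes) $B = 5000$ times; the two-sided p-value is
$(1 + \#\{|T^{(b)}| \ge |T_{\mathrm{obs}}|\})/(B+1)$, FDR-corrected across
nodes (reject at $q = 0.05$).

## Worked example

Plant a 1.5× precision boost on node 2 in the CM group and recover it:

```python
from migconn import (CohortSpec, FunctionalConnectome,
                     generate_node_timeseries_cohort, permutation_group_test)

spec = CohortSpec(n_em=44, n_cm=18, n_volumes=100, n_nodes=7,
                  effect_node=2, effect_size=0.5, seed=42)
cohort = generate_node_timeseries_cohort(spec)

dc = FunctionalConnectome(ridge_lambda=0.1, soft_power_beta=6).fit() \
        .transform(cohort.node_timeseries)           # (62, 7) degrees
result = permutation_group_test(dc, cohort.groups,
                                n_permutations=5000, seed=42)
print(result.to_frame().round(4))
```

```
       observed       p   p_fdr  rejected
node0   -0.0014  0.5151  0.5963     False
node1   -0.0015  0.4979  0.5963     False
node2    0.0010  0.0002  0.0014      True
node3   -0.0011  0.5963  0.5963     False
node4   -0.0015  0.4627  0.5963     False
node5   -0.0022  0.4713  0.5963     False
node6   -0.0022  0.4729  0.5963     False
```

`observed` is the CM−EM difference of group-mean degree centrality (in
Fisher-z units of the β-powered edge weights — small numbers because
β = 6 strongly compresses weak edges); only the planted node survives FDR.

The same analysis runs end to end from the shell:

```bash
migconn all --seed 42 --out run/          # synthetic study-sized cohort
migconn simulate --n-em 44 --n-cm 18 --out cohort/
migconn baseline --dataset cohort/        # Table-1-style group comparison
```

`run/` contains the degree table, permutation and covariate-adjusted
results, the seed-region contrast, the baseline table, and a manifest with
the seed and configuration hash; re-running with the same configuration
reproduces every file byte for byte.

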