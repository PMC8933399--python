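# gfnet

Weighted brain-connectome group analysis: structural (tractography-derived)
and fast-oscillatory functional (amplitude-envelope correlation) networks,
graph-theoretical measures, and Monte-Carlo permutation inference for
comparing cohorts — built for studies contrasting high- versus
average-fluid-intelligence (Gf) groups, and usable for any two-group
whole-brain network comparison.

Subject-level neuroimaging data of this kind is rarely shareable, so the
package ships a first-class synthetic-cohort generator with planted,
controllable group effects; every stage of the pipeline is tested against
that known ground truth.

## What it computes

**Networks.** Nodes are `n` atlas parcels (ROIs). The structural network
normalizes direction-averaged streamline counts by parcel size,

```
w(a,b) = ((counts[a,b] + counts[b,a]) / 2) / ((size_a + size_b) / 2),
```

so large parcels do not look densely connected merely because they are
large. The functional network, per frequency band (δ 0.1–2, θ 2–8, α 8–12,
β 12–32, γ 32–75 Hz), is the Pearson correlation of Hilbert amplitude
envelopes of zero-phase band-pass-filtered source signals.

**Graph measures.** Weighted degree (strength) `d_i = Σ_j w_ij`;
Newman–Girvan modularity

```
Q = (1/2m) Σ_ij [w_ij − k_i k_j / 2m] δ(c_i, c_j)
```

maximized by Newman's leading-eigenvector spectral bisection with
Kernighan–Lin refinement; a *segregation coefficient* per node — the
within-module share of its strength, `s_i = Σ_{j: c_j=c_i} w_ij / Σ_j w_ij`
(1 = fully intra-module, near 0 = connector hub); characteristic path
length, global/local efficiency (edge length `1/w`), and edge density after
pruning the weakest 1 % of connections.

**Inference.** Rather than testing ROIs one at a time, the Monte-Carlo
permutation test (MCS) counts ROIs whose high-minus-average median metric
difference is positive / negative and compares those counts against
group-label permutations (default 10,000), with Bonferroni-corrected levels
0.05/2 (structural, two tails) and 0.05/10 (five bands × two tails).
Group-mean modularity is tested against a weight-shuffle null at the 99.9 %
rule (default 1,000 permutations). Global measures and per-subject SC–FC
coupling are compared by ANCOVA (`value ~ group + sex + age + education`,
type-II F, α = 0.05/24).

## Worked example

```python
from gfnet import CohortSpec, RunConfig, run_pipeline
from gfnet.synth import contiguous_partition

spec = CohortSpec(
    n_rois=30, n_high=15, n_avg=15,
    partition_true=contiguous_partition(30, 3),
    intra_weight_mean=0.5, inter_weight_mean=0.1,
    group_degree_shift=0.08,          # high group: uniformly stronger edges
    noise_sd=25.0, bands=["alpha"], duration_s=60.0, seed=11,
)
config = RunConfig(spec=spec, bands=["alpha"],
                   n_perm_node=2000, n_perm_modularity=200, seed=11)
report = run_pipeline(config)

sd = report["structural"]["degree_mcs"]
print(f"structural degree MCS: n_pos={sd['n_pos']}, n_neg={sd['n_neg']}, "
      f"p_pos={sd['p_pos']:.4g} (corrected alpha {sd['alpha_corrected']})")
mod = report["modularity"]["structural"]["high"]
print(f"high-group mean SC modularity Q={mod['q_observed']:.3f}, "
      f"null max={mod['q_permuted_max']:.3f}, significant={mod['significant']}")
part = report["modularity"]["structural"]["grand_partition"]
print(f"grand-mean partition: {part['n_modules']} modules, Q={part['q']:.3f}")
seg = report["segregation"]["structural"]
print(f"segregation MCS: n_pos={seg['n_pos']}, n_neg={seg['n_neg']}, "
      f"p_neg={seg['p_neg']:.4g}")
g = report["global"]["structural"]["per_subject_mean"]
print("mean global metrics:", {k: round(v, 3) for k, v in g.items()})
```

prints:

```
structural degree MCS: n_pos=30, n_neg=0, p_pos=0.0004998 (corrected alpha 0.025)
high-group mean SC modularity Q=0.258, null max=0.084, significant=True
grand-mean partition: 3 modules, Q=0.301
segregation MCS: n_pos=0, n_neg=30, p_neg=0.0004998
mean global metrics: {'char_path_length': 5.605, 'global_efficiency': 0.269,
                      'local_efficiency': 0.269, 'density': 0.989}
```

Every one of the 30 ROIs has higher median degree in the high group
(`n_pos=30`), no permutation exceeds that count, so `p_pos` sits at the
add-one floor `1/(n_perm+1)`. The planted three-module structure is
recovered exactly and its modularity dwarfs the shuffle null. Because the
uniform degree shift inflates inter-module weights relatively more than
intra ones, the high group's segregation coefficient drops in every ROI
(`n_neg=30`) — the degree-up / segregation-down pattern the structural
analysis is designed to detect.

The same stages are available from the shell:

```bash
gfnet synth --config spec.yaml --out cohort/ --seed 4
gfnet sc --counts cohort/sc/S001_counts.csv --sizes cohort/sc/S001_sizes.csv --out sc.csv
gfnet fc --ts cohort/ts/S001_alpha.csv --band alpha --out fc_alpha.csv
gfnet metrics --net sc.csv --partition-out part.csv --report metrics.json
gfnet run --config run.yaml --out report.json
```

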