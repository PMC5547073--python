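# entronet

Shannon entropy and integration metrics of functional brain networks, with
degree-preserving null ensembles and a paired-condition analysis pipeline.

## The problem

Resting-state fMRI studies of altered brain states (psychedelics,
anesthesia, sleep) often summarize whole-brain functional connectivity as a
binary graph: ROI time series are band-pass filtered, pairwise correlated,
and thresholded into networks whose topology is then compared between
conditions. A central quantity in the "entropic brain" literature is the
Shannon entropy of the degree distribution,

    S[P] = - Σ_k P(k) ln P(k)

where `P(k)` is the normalized histogram of node degrees. A regular graph
(every node the same degree) has `S = 0`; broader degree distributions —
hubs alongside weakly connected regions — score higher. Because the
comparison is only fair at matched edge density, networks are built at a
common grid of mean degrees `⟨k⟩` by choosing, per correlation matrix, the
threshold that yields exactly `L = round(⟨k⟩N/2)` edges. Standard
integration metrics complete the picture: mean geodesic distance `D`,
clustering coefficient `C`, global efficiency `E_g` (mean reciprocal
shortest-path length) and local efficiency `E_l` (the same quantity inside
each node's neighbor-induced subgraph). Each observed network is compared
against an ensemble of degree-preserving (edge-swap) randomizations — which
conserve `P(k)` and hence `S` exactly, so they are *iso-entropic* — via
ratios like `D/D_rand`. Before/after condition differences are tested with
paired Student's t-tests per mean-degree level.

`entronet` implements this whole analysis as a tested, reusable library and
CLI, plus a synthetic-data generator that produces paired multi-subject
datasets (default: 7 subjects, 104 regions × 150 volumes at TR = 1.7 s)
with a known planted effect — "after" networks with broader degree
distributions at matched density — so every stage is testable end-to-end
without any data download. It is aimed at researchers analyzing ROI-level
time series tables; voxel-level preprocessing, atlas segmentation and NIfTI
handling are explicitly out of scope.

## Worked example

Simulate a paired study and run the full analysis:

```sh
entronet simulate --out data --seed 42 --subjects 7
cat > config.yaml <<'YAML'
input_dir: data
output_dir: results
k_min: 14
k_max: 29
null_size: 30
metrics: [entropy, geodesic, clustering, global_efficiency, local_efficiency, degree_variance, degree_kurtosis]
compute_nulls: false
seed: 1
YAML
entronet all --config config.yaml
```

The exported `results/comparison_entropy.csv` begins:

```
 level  mean_before  sd_before  mean_after  sd_after  t_stat  p_value flag
    14       2.1095     0.2156      2.8984    0.0989 11.0002   0.0000    *
    15       1.8581     0.3301      3.0554    0.1034  9.2599   0.0001    *
    16       1.4166     0.5050      3.1318    0.1079  8.2072   0.0002    *
    17       1.5455     0.3913      3.2164    0.0930 10.6793   0.0000    *
    18       1.9107     0.2518      3.2797    0.1051 12.6442   0.0000    *
    19       2.1403     0.0830      3.3302    0.1347 18.2101   0.0000    *
```

Each row is one mean-degree level: the across-subject mean ± SD of the
degree-distribution entropy (nats) before and after, the paired t statistic
over the 7 subjects, its two-sided p-value, and the reporting flag
(`bold` for p < 0.05, `*` for p < 0.005). Here the generator's planted
broadening is recovered at every level: entropy is higher "after", with
p < 0.005 throughout. Setting `compute_nulls: true` additionally writes
null-normalized ratio tables (`comparison_ratio_geodesic.csv`, ...) against
30-member iso-entropic ensembles; omitting `k_min`/`k_max` lets the
pipeline determine the feasible mean-degree window from connectivity,
sparsity (`⟨k⟩ > 2 ln N`) and small-world-versus-null criteria, excluding
(and reporting) subjects with no overlapping window.

The same functionality is available as a library
(`entronet.run_pipeline`, `entronet.compute_metric_set`,
`entronet.null_ensemble_metrics`, `entronet.paired_timeseries_dataset`, ...);
see `docs/methods.md` for the full model description and conventions.

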