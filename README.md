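# tractnet

Weighted white-matter structural network analysis: from directed
tract-count matrices to connectivity backbones, small-world graph metrics,
degree-preserving null models and two-group statistics.

## What it is for

Diffusion-MRI tractography studies model the brain as a weighted graph:
nodes are the 90 regions of the AAL parcellation, and the edge weight
between regions i and j is built from probabilistic streamline counts,

    w_ij = c_ij / v_i + c_ji / v_j,

where c_ij counts pathways seeded in region i that reach region j and v_i
is the number of seed voxels in i. tractnet implements the full analysis
a two-group study of such networks needs:

* **motion QC** — scans with peak translation > 1 mm or rotation > 1° are
  excluded;
* **network construction** — voxel-normalised symmetric weight matrices,
  averaged over repeated scans;
* **backbone extraction** — maximum spanning tree plus strongest edges up
  to average degree K = 4 (180 edges on 90 nodes);
* **graph metrics** — degree, strength, raw-weight Onnela clustering
  C_i = 2/(K_i(K_i−1)) Σ (w_ij w_ih w_jh)^{1/3}, inverse-weight shortest
  paths, harmonic-mean characteristic path length, ordered-pair
  betweenness centrality, global and local efficiency;
* **null models** — Maslov–Sneppen degree-preserving rewiring and the
  small-world classification E_glob(G)/E_glob(G_rand) < 1 <
  E_loc(G)/E_loc(G_rand);
* **group statistics** — pooled two-sample two-tailed t-tests per
  (metric, node) and per global feature, plus Pearson correlation with
  training-onset age.

Since tractography data rarely travels with papers, the package includes
a first-class synthetic cohort generator (negative-binomial counts on a
spatially embedded anatomy, injected multiplicative group effects, motion
logs, onset ages) so every stage is testable end to end with known ground
truth. See `docs/methods.md` for the model details and conventions.

## Worked example

`examples/04_group_comparison.py` generates a 16 + 16 subject cohort with
a doubled connection strength at four nodes of the second group, computes
per-subject backbones and metric tables, and tests every (metric, node)
pair:

```
450 feature x node tests (5 metrics x 90 nodes)

smallest strength p-values (T < 0 means group 2 = musician larger):
 feature     node mean_g1 mean_g2     T   df      p
strength    SMA_R    2.55    8.70 -5.74 30.0 0.0000
strength    CAL_L    0.90    2.62 -4.16 30.0 0.0002
strength    SMA_L    2.19    4.84 -3.88 30.0 0.0005
strength SFGorb_R    1.59    3.46 -3.41 30.0 0.0019
strength    PCC_R    0.54    0.90 -2.94 30.0 0.0062
strength    CAU_R    3.99    6.91 -2.72 30.0 0.0107

injected nodes: SMA_L, SMA_R, CAL_L, CAU_R
```

All four injected nodes rank among the six smallest strength p-values;
the two extra rows are the false positives expected of 90 uncorrected
tests. `examples/03_small_world.py` prints the efficiency ratios of one
backbone against 100 rewired networks:

```
E_glob = 0.1630 vs random 0.1732 -> ratio 0.941
E_loc  = 0.1103 vs random 0.0276 -> ratio 3.991
small-world: True
```

Global efficiency just below the degree-matched ensemble with local
efficiency several times larger is the small-world signature of
white-matter networks. The other examples cover cohort simulation,
backbone metrics and the one-call pipeline (`run_pipeline` /
`tractnet run`), which writes backbones, metric tables, comparison CSVs
and a seed-recording run log that makes every run byte-reproducible.

There is also a thin CLI mirroring the stages: `tractnet simulate |
build-network | backbone | metrics | nullmodel | compare | run`.

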