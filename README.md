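# chromdyn

Chromatin-state dynamics from histone-mark time courses.

`chromdyn` reimplements, as a tested and reusable pipeline, the time-resolved
chromatin-state analysis used to follow an inflammation-to-cancer transition
(the AOM/DSS mouse model of colitis-associated colorectal cancer, sampled at
control, 2, 4, 7 and 10 weeks with three biological replicates): five histone
marks (H3K27ac, H3K4me1, H3K4me3, H3K27me3, H3K9me3) plus an input control are
binned, binarized, segmented into chromatin states with a hidden Markov model,
collapsed to five functional categories, and tracked across time — alongside a
matched analysis of dynamic gene expression and enhancer H3K27ac signal. It is
aimed at epigenomics analysts who want the method itself, at any scale, with
every stage verifiable against planted synthetic truth.

## The model

**Binarization.** The genome is tiled into non-overlapping 200-bp bins; each
mark's binned counts are reduced to presence calls against the input control:
a bin is called present iff `P(X >= observed | lambda) <= 1e-4`, with

```
lambda = max(global mark mean,  input count x library ratio,  1e-6)
```

**Segmentation.** The per-bin M-bit presence vectors are the observations of a
K-state multivariate-Bernoulli HMM (the ChromHMM model family): state `k`
emits vector `o` with probability `prod_m p_km^o_m (1 - p_km)^(1-o_m)`. The
model is trained by Baum-Welch EM jointly over all time points, one sequence
per chromosome, with replicates of a time point treated as conditionally
independent draws from a shared hidden state path. Decoding is per-bin
posterior argmax (Viterbi optional).

**Category collapse.** Learned states map onto five functional categories by
an emission-rule cascade: high H3K4me3 → promoter; else high H3K4me1 or
H3K27ac → enhancer; else high H3K9me3 → heterochromatin; else high
H3K27me3 → repressed; else quiescent.

**Dynamics.** Per-time-point segmentations assemble into the m x n state
matrix (m bins, n time points), from which the pipeline derives category
fractions over time, 5x5 transition flow (alluvial) tables, origin fractions
of any category, and each gene's dominant chromatin state (modal category over
gene body ± 2 kb).

**Time course.** Expression (TMM-normalized) and windowed enhancer H3K27ac
(RPM, gene body ± 1.5–10 kb) are fit per feature by degree-4 polynomial OLS in
time; features with R² > 0.7 are dynamic and are k-means clustered on z-scored
profiles (k = 3..9, silhouette-selected unless fixed). Per-gene Pearson r
between replicate-mean FPKM and RPM quantifies mark-expression coupling.

A synthetic-data generator plants known state trajectories, mark counts and
expression archetypes so that every one of these stages can be scored against
ground truth at desk scale.

## Worked example

```python
import chromdyn as cd

cfg = cd.load_config(seed=1)          # default: 2-Mb genome, 200 genes, K=6
report = cd.run_pipeline("runs/demo", cfg, seed=1)

print({tp: round(v["enhancer"], 3)
       for tp, v in report["category_fractions"].items()})
print({k: round(v, 3)
       for k, v in report["enhancer_origin_fractions"].items()})
print(report["n_dynamic_genes"], report["rna_cluster_k"])
```

prints

```
{'control': 0.081, '2w': 0.132, '4w': 0.168, '7w': 0.193, '10w': 0.232}
{'promoter': 0.172, 'enhancer': 0.329, 'heterochromatin': 0.001,
 'repressed': 0.089, 'quiescent': 0.409}
198 4
```

The decoded enhancer compartment grows from 8% to 23% of the genome across the
course (the generator plants a net enhancer gain), and of the bins that are
enhancer at 10 weeks, 41% were quiescent, 17% promoter and 9% repressed at
control — the origin-fraction readout of the planted trajectory mixture.
198 of 200 genes pass the R² > 0.7 dynamic filter and cluster into the four
planted temporal archetypes (k = 4). All tables (state matrix, flows,
fractions, origins, dominant gene states, fits, clusters, correlations) land
in the run directory as TSV, with the model as JSON and segmentations as BED.

The same pipeline is scriptable stage by stage:

```
chromdyn simulate --run-dir runs/demo --seed 1
chromdyn binarize --run-dir runs/demo
chromdyn train    --run-dir runs/demo --seed 1
chromdyn decode   --run-dir runs/demo
chromdyn dynamics --run-dir runs/demo
chromdyn timecourse --run-dir runs/demo
chromdyn correlate  --run-dir runs/demo
chromdyn report   --run-dir runs/demo
```

To analyze real data, bring your own binned tracks (bedGraph), gene BED6 and
count matrices and call the library functions directly
(`bin_coverage`, `binarize_samples`, `baum_welch_train`, `decode`,
`build_state_matrix`, `timecourse_analysis`, `timecourse_correlation`, ...);
the run directory layout is a convenience, not a requirement.

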