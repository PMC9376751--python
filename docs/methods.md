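# Methods

## Scope and data model

`chromdyn` analyzes a histone-mark ChIP time course at bin resolution. All
coordinates are 0-based half-open (BED convention); a `BinGrid` tiles each
chromosome with fixed 200-bp bins (configurable), keeps the last partial bin,
and is the single coordinate authority — every track, binarization,
segmentation and state matrix is a vector or matrix over its global bin index.
The central derived object is the m x n state matrix: m bins by n ordered time
points, holding both the raw HMM state and its collapsed functional category.

## Binarization

Counts are aggregated per bin either from bedGraph records (each record
contributes `value x overlap_bp / bin_size`, i.e. values are per-position
depth) or from read intervals (midpoint assignment). A mark is called present
in a bin iff the upper-tail Poisson probability of its count is at most
`pvalue_cutoff` (default 1e-4) under the background rate

```
lambda = max(global mark mean, input count x (mark library / input library), 1e-6)
```

The input-control term adapts the threshold to local background; the
global-mean floor guards bins where the input is sparse; the 1e-6 floor
avoids zero-rate degeneracies. Consequences worth knowing: a count of 0 is
never called (its tail probability is 1), scaling the control track and its
library together changes nothing, and in enriched genomes the global-mean
floor is conservative — it absorbs part of the enrichment and costs a few
percent of sensitivity (visible in the recovery experiments as detection
rates slightly below the planted emission probabilities).

Replicate handling is a design choice the upstream literature leaves open.
Default: replicate counts are pooled per time point before binarization (one
observation sequence per time point). A per-replicate mode
(`pool_replicates=False`) binarizes each replicate against its own input;
downstream, replicates of a time point are then modeled as conditionally
independent observations of a shared hidden state path, which is also how the
synthetic generator produces them. Per-replicate mode preserves the Bernoulli
scale of emissions (pooling effectively ORs presence across replicates and
inflates "on" probabilities), so the recovery experiments use it.

## The chromatin-state HMM

States emit independent Bernoulli bits per mark. Emission probabilities are
clamped to [1e-6, 1 - 1e-6] so log-likelihoods stay finite. Inference uses the
standard scaled forward-backward recursion with a per-bin row rescaling of the
emission likelihood matrix absorbed into the log-likelihood. For an (R, T, M)
replicate group the Bernoulli log-likelihood is linear in the observations, so
the joint emission term reduces exactly to `R x logB(replicate mean)`; EM
weights the emission sufficient statistics by R while the path statistics
(initial, transitions) count once.

Training is Baum-Welch over one sequence per chromosome (genomic adjacency is
undefined across chromosomes, so no transition spans a boundary) and per time
point, all contributing to a single model — mirroring the concatenated design
in which one state vocabulary serves every stage. Restarts: the first
initialization takes k-means centroids of the observation vectors as emissions
(with a sticky, 0.9 self-transition prior), the rest are random; the best
log-likelihood wins. The k-means start matters: random initializations of a
6-state model land in visibly inferior local optima in roughly half of runs,
while the k-means basin recovers the planted model reliably in a handful of EM
iterations. EM stops when the log-likelihood gain falls below `tol` or at
`max_iter`; the per-iteration history is kept on the model and is checked to
be non-decreasing in the tests.

Decoding is per-bin posterior argmax with ties broken toward the lower state
id; Viterbi is available where a single consistent path is preferred. Model
choice across a K range is reported as log-likelihood and BIC with
`(K-1) + K(K-1) + KM` free parameters — the choice itself is left to the
analyst, as is conventional for chromatin-state models.

## Category collapse

States map to five categories by a rule cascade on emissions, evaluated in
order with a presence threshold `high` (default 0.5): H3K4me3 → promoter
(this deliberately captures poised promoters that also carry H3K27me3);
else H3K4me1 or H3K27ac → enhancer (active, weak and poised enhancers
alike); else H3K9me3 → heterochromatin; else H3K27me3 → repressed; else
quiescent. The cascade is a pure function of the emission matrix (permuting
states permutes categories identically) and the threshold is configurable;
with well-separated fitted emissions the assignment is insensitive to it over
a wide range (anything between the planted "on" and "off" levels gives the
same answer).

## Transition accounting

Category fractions, 5x5 flow matrices and origin fractions are all computed
over 200-bp bins, not merged regions; a "region" here is a bin. Flows conserve
the total bin count exactly, and an origin-fraction vector is the normalized
target-category column of the corresponding flow matrix — both identities are
tested. The dominant chromatin state of a gene is the modal category over all
bins overlapping gene body ± `flank_bp` (default 2000), strand-independent,
with partially overlapping bins counting fully (bin-granularity accounting).
Modal ties break by the fixed priority promoter > enhancer > heterochromatin >
repressed > quiescent — the more information-rich annotation wins; the order
is a package decision (the rule's source is silent on ties) and is logged.

## Time-course analysis

Expression is TMM-normalized: scaling factors are 2 to the precision-weighted
trimmed mean of gene-wise log2 ratios against a reference column (upper
quartile closest to the mean upper quartile), trimming the extreme 30% of
M-values and 5% of A-values, rescaled to geometric mean 1. The implementation
is checked against a hand-worked toy and, as an independent dual route,
against edgeR's `calcNormFactors` on random counts. FPKM is
`count / (length/1e3) / (library/1e6)`; windowed signal is RPM (window count
sum per million library reads) over named schemes anchored at the TSS or the
gene body, solid (± b) or annular (± a–b, excluding every bin overlapping the
inner core — for enhancer schemes this removes TSS-proximal
nucleosome-free-region signal). Both the gene-body and TSS-anchored variants
of each annulus exist because the source analyses describe the same windows
both ways; neither is privileged.

Dynamic features: per feature, ordinary least squares on a degree-4
polynomial in time, replicates entering as repeated observations at the same
time coordinate. Time is the week number {0, 2, 4, 7, 10} (control = 0),
centred and scaled before building the Vandermonde design for conditioning.
R² = 1 - SSR/SST, clamped to [0, 1], defined as 0 for zero-variance features;
the dynamic filter is strictly R² > 0.7. This reduces the two-stage
significance machinery of time-course regression packages to exactly the
stated fit-plus-threshold rule — the only selection rule the analysis
specifies. Under the null (no trend, 5 x 3 design) the filter passes about 1%
of features; quartic trends at signal-to-noise 10 pass at ~100% (both rates
are recomputed by the tests and the reproduction script).

Dynamic profiles are clustered by k-means on per-feature z-scores of the
time-point means, so clusters capture shape, not magnitude. k is scanned over
3..9 and chosen by maximum mean silhouette unless the caller fixes it (k = 4
reproduces the four-cluster expression solution; fixing k = 9 reproduces the
enhancer-signal solution). Seeds are explicit everywhere.

## Correlation reporting

Per gene, FPKM and RPM are first averaged across replicates within each time
point; Pearson r is computed over the n time-point pairs. With only five
points r is reported without a p-value — magnitude, not significance, is the
readout. Zero-variance vectors yield a missing r with a reason. Stage-wise
clustering (k-means on z-scored time-point means, default k = 3, rows ordered
by cluster peak time) emits a plot-ready table for heatmap-style summaries of
a gene set. Gene sets are plain-text id lists supplied by the caller.

## The synthetic generator

The generator emulates the study design, not sequencing physics. Planted per
bin: a (start-category → end-category) trajectory with a single switch time
uniform over the course; trajectories are laid down in contiguous runs with
geometric lengths (mean 5 bins) to mimic chromatin-domain contiguity — i.i.d.
bins would make transition recovery trivially degenerate. Trajectory types are
allocated to runs by largest-remainder quotas so realized genome fractions
match the requested mixture to within one run length (tighter than multinomial
sampling); the default mixture grows the enhancer compartment at the expense
of quiescent, promoter and repressed ground over the course. The default
planted model has 6 states — one per category plus a weak/poised enhancer —
with on/off emission separation ≥ 0.6; richer (e.g. 13-state) configurations
are expressible through `SimulationConfig`. Counts are Poisson: rate 20 per
bin where a mark is present (Bernoulli draw from the planted emission, per
replicate), rate 1 otherwise, and pure rate-1 input tracks. Replicates share
the hidden state path and differ only in presence draws and count noise, like
same-condition animals.

Gene bodies (default 2 kb, 200 genes on 2 Mb) are placed deterministically,
evenly spaced and non-overlapping including their ± 2 kb flanks, and each
gene's window is planted as one homogeneous run — so every gene has an exact
dominant-state truth at every time point. Expression follows four planted
temporal archetypes (late induction; plateau-then-decline; early transient;
monotone decline) with per-replicate Gaussian noise on log2 FPKM (SD 0.2) and
Poisson counts at a nominal library size; archetype membership is balanced and
random, and independent of the chromatin trajectory unless a test couples them
explicitly.

What the generator does *not* emulate — and what passing tests therefore do
not demonstrate about real data: fragment-length and GC biases, mappability,
copy-number artifacts, duplicate reads, unbalanced or missing replicates,
overdispersed (non-Poisson) counts, overlapping transcription units, and any
real coupling between chromatin state and expression level.

## Verification scales and numerical choices

Recovery experiments run at 100,000 bins (20 Mb at 200 bp) for model recovery
and 10,000 bins for dynamics accounting; the full-pipeline default is a 2-Mb,
200-gene design — sizes chosen so the whole suite verifies every stage in a
few minutes on one CPU while keeping per-category bin counts large enough for
3-SD statistical checks. At these scales the package recovers planted
emissions with mean absolute error ≈ 0.04 (the residual is binarization
attenuation, not fitting error), decodes states at ≈ 98% per-bin accuracy, and
reproduces origin fractions within a fraction of a binomial SD.

Numerical conventions collected in one place: emission clamp 1e-6; transition
rows renormalized each M-step with a 1e-300 floor against division blowups;
posterior ties toward the lower state id; modal-category ties by the fixed
priority above; R² of a constant feature is 0; the dynamic cutoff is strict;
flat profiles z-score to all-zero rather than NaN; windows are truncated at
chromosome ends (logged); genes overlapping no bins are reported missing
(logged), never silently dropped mid-table.

## Limitations

The HMM assumes mark independence given the state and homogeneous transitions
along the genome; the binarization's global-mean floor is conservative in
strongly enriched genomes; joint-replicate decoding assumes replicates truly
share a state path (condition-level, not animal-level, chromatin); silhouette
k-selection on five-point profiles is coarse and an analyst fixing k from
inspection is expected; and the pipeline starts from binned coverage — read
alignment, duplicate handling, peak calling and differential expression are
out of scope.
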