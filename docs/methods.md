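# Methods

## Model and workflow

`cytobatch` corrects batch effects in single-cell cytometry by combining
overclustering with a per-cluster location/scale empirical Bayes adjustment.
The rationale: a location/scale batch model is a poor description of a whole
cytometry dataset (a mixture of phenotypically distinct populations whose
batch distortions differ), but a good one within a small, phenotypically
homogeneous cluster. The workflow therefore:

1. normalizes each marker within each batch (Z-score or average-tie ranks
   scaled to (0, 1]) purely to make batches co-clusterable;
2. partitions all cells with a self-organizing map (default 8×8 = 64 nodes,
   a deliberate overclustering) trained on the normalized values;
3. applies the ComBat-style adjustment independently to each node's cells
   **on the original ArcSinh-scale values** — the normalized matrix is
   discarded after clustering;
4. caps each marker's corrected values to that marker's global min/max over
   the input.

Within a node, marker *g* in batch *i* is modeled as
`y = alpha_g + X beta_g + gamma_ig + delta_ig eps`. The fit standardizes with
a batch-size-weighted grand mean and a pooled residual variance (n
denominator), estimates per-batch locations (means of the standardized data)
and scales (n−1 variances), fits batch-level priors across markers by
moments (normal on gamma; inverse-gamma on delta² with shape
`a = (2 s2 + m²)/s2` and rate `b = (m s2 + m³)/s2` from the mean m and
variance s2 of the delta² estimates), and iterates the coupled posterior
updates — precision-weighted gamma*, inverse-gamma-posterior delta²* — to a
maximum relative change below 1e-4 (cap 500 iterations, then a hard error
with diagnostics). The relative-change criterion deliberately uses *signed*
denominators, reproducing the reference implementation bit-for-bit; the
test suite verifies agreement with Bioconductor `sva::ComBat` to 1e-6 on
random cases with and without covariates.

### Assumptions and their limits

- Batch effects within a node are additive/multiplicative per marker. The
  SOM step is what makes this plausible; "err on the side of
  overclustering" — a finer grid costs little because clusters are
  corrected independently.
- Batch and condition must not be confounded: at least one condition in
  each batch must appear in some other batch. `check_design` enforces this
  before any computation and names the offending batches.
- Per cluster, every present batch needs ≥ 2 cells for a variance estimate.
  Clusters violating this are returned **uncorrected** with a warning — the
  package never fabricates an adjustment from an undefined variance.
  A cluster with a confounded covariate is refit without the covariate
  (logged). With a single marker there is no across-marker spread to fit
  priors from, so unshrunk estimates are used (logged).

## Parameters

| parameter | default | meaning |
|---|---|---|
| ArcSinh cofactor | 5 (CyTOF), 150 (flow), 6000 (spectral) | raw intensity divisor before asinh |
| norm_method | `scale` | `rank` recommended across instruments/platforms |
| grid | 8×8 | SOM nodes; overclustering granularity |
| covariate | none | metadata column whose effect is preserved |
| mean_only | false | adjust locations only, leave scales |
| cap | true | clamp corrected values to input range per marker |
| min_donors (merging) | 50 | donor floor below which imputations become NA |
| EMD bin size | 0.1 | histogram bin width, ArcSinh units |
| EMD filter | 2 (bins) | records with both EMDs below this are dropped |
| MAD constant | 1.4826 | normal-consistency scaling |

SOM training hyperparameters (10 passes, learning rate 0.05→0.01 linearly,
Gaussian neighborhood with radius max(grid)/2→0.5 linearly, codebook
initialized from seeded data rows) are conventional online-SOM defaults.
They are recorded on the model and configurable because the partition — and
therefore every downstream number — depends on them; given identical data,
grid and seed, training is exactly reproducible.

## Evaluation protocol

The evaluation SOM is trained on the **corrected** expression (raw, not
re-normalized) and its labels transferred to the uncorrected data by row
alignment, so each cell has one label in both datasets. EMDs are computed
per node × marker × batch pair on histograms with bin width 0.1 over each
marker's union range; the ground distance is measured in bins, so the
default filter "both EMDs < 2" means less than two bins ≈ 0.2 ArcSinh
units (the filter unit is configurable). If no record survives the filter
the reduction is reported as undefined (None), never as 0. The MAD score
uses per node × marker × batch MADs with the 1.4826 constant.

## Panel merging

Imputation simulates a draw from a multivariate KDE of the donor node:
one donor cell is drawn (uniformly, with replacement — recipients may
outnumber donors) per recipient for **all** missing markers jointly, then
per-marker Gaussian noise at Silverman's rule-of-thumb bandwidth computed
on the node's donor cells is added. Joint single-donor draws are what
preserve co-expression between imputed markers; the bandwidth smoothing
slightly attenuates extreme correlations (by roughly `1/(1 + (bw/sd)²)`).
The node-level donor set was chosen as the bandwidth "training population"
(a panel-level alternative is configurable in principle) because the
imputation is node-local. Imputed entries carry an explicit mask; measured
values are never modified; the FCS writer refuses NA sentinels. Imputed
values are intended for visualization and clustering, not for
differential-expression inference on the imputed markers.

## Synthetic data

The generator emulates what the correction model assumes plus controlled
violations: Gaussian-mixture populations on the ArcSinh scale (population ×
marker means drawn as "positive" ~U(2, 4.5) with probability 0.4, else
"negative" ~U(0, 0.6); within-population sd 0.35), condition effects as
population-abundance shifts, batch effects as per-batch per-marker additive
shifts ~N(0, 0.3) and multiplicative scales exp(N(0, 0.1)), and optional
zero-inflation (default off) to stress the model outside its assumption
family. Distortions are centered across batches by default so the
dataset-level grand location/scale is preserved and recovery against the
undistorted ground truth is well-posed (the adjustment aligns batches at
the weighted grand mean, so uncentered distortions would shift the target
itself).

What the simulation does **not** emulate: spillover between channels,
acquisition drift within a run, doublets, bead events, heavy-tailed or
strongly skewed marker noise, and batch effects that vary within a
population. Passing tests therefore demonstrate correctness of the
algorithm under its stated model and robustness to mild zero-inflation,
not performance on every real-data pathology.

Test and acceptance problem sizes (2 batches × 20,000 cells, 10–40 markers,
4 populations including a rare one) were chosen as the smallest sizes at
which the mixture, the rare population, and the per-node ≥ 8-cell regime
are all realistically exercised.

## Numerical choices and degenerate inputs

- Markers with zero pooled variance in a cluster are flagged and passed
  through untouched (standardization would divide by zero).
- Zero spread of the delta² estimates across markers makes the
  inverse-gamma moment fit degenerate; scale shrinkage is then disabled
  (delta²* = delta²̂) and only locations are shrunk.
- Flat-prior (tau² → ∞) and degenerate-prior (tau² = 0) limits are handled
  in closed form: gamma* equals gammâ or gamma-bar respectively.
- Nearest-node assignment breaks ties toward the lowest node index; SOM
  node labels are 1-based.
- De-randomization is the elementwise ceiling (acquisition randomization
  adds uniform(−1, 0) noise to integer counts; ceiling inverts it exactly)
  and is applied **before** the ArcSinh transform, so the transform acts on
  integer counts.
- FCS output is version 3.1, list mode, 32-bit little-endian float; reading
  supports 3.0/3.1 with float, double, or unsigned-integer storage. Channel
  identity is the short parameter name (`$PnN`), case-sensitive; stain
  names are display-only.

## Known limitations

- Non-parametric priors and reference-batch variants of the adjustment are
  not implemented.
- Only two panels are merged at a time; merge pairwise for more.
- Batch correction requires the marker in every batch; merging imputes
  non-overlapping markers but cannot batch-correct them.
- The EMD filter's unit (bins) is a documented interpretation; expression
  units are available via configuration.
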