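# cytobatch

Batch-effect correction, cross-panel marker imputation, and correction
quality metrics for single-cell protein cytometry — mass cytometry (CyTOF),
conventional and spectral flow, and CITE-seq antibody counts.

Cytometry experiments acquired in separate runs, on separate instruments, or
even on separate platforms carry systematic technical differences (batch
effects) that swamp biological signal when the data are pooled. `cytobatch`
removes them while preserving biology, for analysts integrating multi-batch
cohorts, external validation datasets, or split-panel designs.

## Method

The correction works per cell population rather than globally:

1. **Normalize per batch** — each marker is Z-scored (`scale`, for similar
   batches) or converted to average-tie ranks in (0, 1] (`rank`, for
   cross-instrument/cross-platform data) within each batch, so batches
   become co-clusterable.
2. **Overcluster with a SOM** — an 8×8 self-organizing map partitions all
   cells into 64 nodes on the normalized values; node labels are carried
   back to the original ArcSinh-scale expression.
3. **Empirical Bayes adjustment per node** — within each node the classic
   ComBat location/scale model is fit: per batch *i* and marker *g*,

   y = α_g + X β_g + γ_ig + δ_ig ε,

   with γ̂ (batch location) and δ̂² (batch scale) shrunk across markers
   toward batch-level priors (normal for γ, inverse-gamma for δ², moment
   estimated) and removed. An optional condition covariate X (e.g., disease
   status) is fit alongside and restored, so condition effects survive
   correction. Corrected values are finally capped per marker to the range
   of the input. The adjustment is well-defined down to very small nodes
   (eight cells across two batches).

Split-panel experiments are merged by co-clustering both panels on their
overlapping markers and imputing each cell's missing markers from a single
donor cell of the other panel within the same SOM node, plus Gaussian noise
at the donor population's kernel bandwidth — a draw from a multivariate KDE
that preserves marker co-expression. Nodes with fewer than 50 donors are
left as NA. The same mechanism salvages a single mis-stained channel using
good batches as donors.

Correction quality is quantified by two summaries computed per SOM node,
marker and batch (pair):

- **EMD reduction** = Σ(EMD_before − EMD_after) / Σ EMD_before over
  node × marker × batch-pair earth mover's distances (bin width 0.1;
  records with both EMDs below 2 are dropped). 1 = all cross-batch
  distance removed, 0 = none.
- **MAD score** = median |MAD_before − MAD_after| over node × marker ×
  batch median absolute deviations. 0 = within-batch (biological)
  variability fully preserved.

## Worked example

`examples/01_correct_batches.py` simulates 2 batches × 5,000 cells over 12
markers with injected per-marker shifts (sd 0.3 ArcSinh units) and scale
distortions (log-sd 0.1), corrects, and evaluates:

```
simulated 10000 cells, 12 markers, batches: ['batch1', 'batch2']
largest injected shift: 0.32 ArcSinh units
corrected over 56 SOM nodes (3 skipped as too small)
EMD reduction: 0.84   (fraction of cross-batch distributional distance removed; 1 = all)
MAD score:     0.012  (change in within-batch variability; 0 = biology fully preserved)
```

84% of the cross-batch distributional distance is removed while the
within-batch variability changes by ~0.01 ArcSinh units — technical effects
gone, biology intact. `examples/02_merge_panels.py` and
`examples/03_fcs_workflow.py` demonstrate panel merging and the
FCS-file/covariate workflow; the same flows are available from the shell:

```sh
cytobatch simulate --cells-per-batch 5000 --seed 3 --output-dir sim/ --table
cytobatch correct --input sim/dataset.csv --norm scale --grid 8x8 --seed 1 \
    --output corrected.csv --report report.json
cytobatch evaluate --before sim/dataset.csv --after corrected.csv \
    --seed 2 --output metrics.json
```

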