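# cinemotion

Surrogate-driven respiratory motion modelling from 2D cine-MR image
series — for researchers in MR-guided radiotherapy and motion modelling
who want a tested, reproducible pipeline for comparing surrogate signals.

During free breathing the diaphragm, lungs and abdominal organs move by
one to several centimetres, with the viscera sliding past the chest
wall. A surrogate-driven motion model estimates that motion from
low-dimensional signals that can be measured in real time. This package
implements the full 2D workflow:

- **synthetic data**: a seedable cine-MR generator (interleaved
  surrogate/motion slices, ~1.9 fps, 1.98 mm pixels) with known sliding
  ground-truth motion that is *exactly linear* in two latent respiratory
  components — so model fitting has an exact end-to-end oracle;
- **surrogate signals**: sub-pixel diaphragm (SI) and skin (AP) edge
  tracking, PCA on image intensities, and PCA on the control-point
  displacements (CPD_s) of a non-sliding B-spline registration of the
  surrogate slice;
- **correspondence models**: per-CPD-component linear models
  `M_i(s1,s2) = c2 s2 + c1 s1 + c0` (optionally with a third signal),
  fitted by ordinary least squares; the motion slice is parameterized by
  two full cubic-B-spline control-point grids, one per sliding region;
- **evaluation**: deformation field error (DFE, the per-pixel L2 norm of
  the difference between estimated and reference deformation fields),
  pooled mean and 95th percentile within evaluation/tumour masks, over a
  building/test split with evenly spaced training subsets (n = 20…6) in
  4-fold cross-validation.

## Worked example

```bash
python analysis/01_simulate_dataset.py     # simulate the default acquisition
python analysis/02_extract_signals.py      # extract and inspect the signals
python analysis/03_training_size_study.py  # fit and evaluate the model zoo
python analysis/04_breath_hold_study.py    # derivative vs independent signals
```

`02_extract_signals.py` prints, for one default dataset (seed 1):

```
pre-steady-state surrogate frames discarded: 3
intensity-PCA explained variance: [0.689 0.134 0.032]
CPD_s-PCA explained variance:     [0.964 0.016 0.013]
  diaphragm  r(primary) = +0.998   r(secondary) = +0.717
  pc1_cpd    r(primary) = +0.996   r(secondary) = +0.721
```

i.e. the three deliberately inflated pre-steady-state frames are caught
by the mean-intensity threshold, and both local and global surrogates
track the true primary respiratory component almost perfectly; the first
CPD_s principal component alone carries 96 % of the motion variance.

`03_training_size_study.py` then prints (same seed):

```
no-model baseline mean DFE: 3.30 mm (evaluation mask)
fold-averaged mean DFE at n = 10 training images:
  pc1+pc2+pc3_cpd           0.08 mm   (2% of baseline)
  pc1_cpd+deriv             0.13 mm   (4% of baseline)
  diaphragm+deriv           0.18 mm   (5% of baseline)
  diaphragm+skin            0.26 mm   (8% of baseline)
  ...
mean Spearman rho(n, DFE) over models: -0.51 (negative = more data helps)
3-signal / 2-signal mean DFE at n = 6: 1.02
```

The baseline quantifies how much motion the test frames contain
(3.3 mm mean displacement); every surrogate-driven model reduces the
error to a small fraction of that, accuracy improves with more training
images (negative rank correlation) and plateaus near n = 20, and by
n = 6 the three-signal models' advantage over two-signal models has
essentially vanished (ratio ≈ 1; on noisier motion measurements this is
where over-fitting sets in — see the limitations in
`docs/methods.md`). The breath-hold study shows the
flip side of derivative-driven models: when the breathing freezes
mid-phase, a signal plus its derivative no longer determines the
respiratory state, and those models degrade relative to models driven by
two independent signals.

All stages are also available as a CLI (`cinemotion simulate /
extract-signals / register / fit / evaluate / run-all`) operating on
NIfTI series, NIfTI control-point grids, CSV signals and a YAML dataset
manifest, so externally computed registrations and masks can be dropped
in. See `docs/methods.md` for the model, the generator's assumptions,
and every numerical choice.

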