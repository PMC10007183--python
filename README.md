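# fatiguefc

Source-space EEG functional-connectivity analysis and alert/fatigue
classification.

## The problem

Driver fatigue changes how brain regions synchronize. Scalp EEG shows this
only indirectly: volume conduction spreads every cortical source across many
electrodes, so sensor-level correlations are dominated by spurious zero-lag
coupling. This package implements the analysis chain that addresses both
problems at once — it reconstructs activity in **source space** and measures
coupling with a statistic that is blind to zero-lag effects:

1. **Preprocessing** — resampling, SOBI and BSS-CCA blind-source-separation
   artifact removal, decomposition into delta/theta/alpha/beta/gamma bands.
2. **Source localization** — sLORETA on a three-shell spherical head model.
   The minimum-norm kernel K = Gᵀ(GGᵀ + λC)⁺ is standardized per vertex by
   the inverse square root of its 3×3 resolution-matrix block R = KG, which
   gives zero localization error for noiseless single sources.
3. **Parcellation** — 34 ROIs per hemisphere (68 total at full scale); ROI
   time series are sign-flip averages over vertices, so opposed cortical
   orientations do not cancel.
4. **Connectivity** — the phase lag index per ROI pair and band,
   PLI = |E[sign(Im Sxy)]|, averaged over windows and in-band frequency
   bins. A 68-ROI matrix yields 68·67/2 = 2278 lower-triangle features.
5. **Classification** — recursive feature elimination (13 % retained = 296
   of 2278), a grid-searched SVM, repeated two-fold cross-validation with
   subject-level folds, and a paired permutation test for significance.

Because real driving-fatigue datasets are rarely shareable, the package
includes a first-class synthetic-data generator that plants band-specific,
phase-lagged couplings between source regions — every stage of the pipeline
is validated against known ground truth. It is intended for methods
researchers who want a tested, reproducible reference implementation of
this analysis, and for anyone who needs planted-truth EEG connectivity
benchmarks.

## Worked example

Simulate the canonical study at reduced size (12 subjects, two 20 s
recordings each, 32 channels at 256 Hz; a beta-band coupling that moves
between ROI pairs when fatigue sets in), run the source-space pipeline, and
classify:

```python
import fatiguefc as f
from fatiguefc.pipeline import (_build_geometry, _derive_seeds,
                                _get_recordings, extract_features)
from fatiguefc.inverse import compute_inverse_operator

cfg = f.PipelineConfig(simulation=f.default_study_config(n_subjects=12),
                       bands=["beta"], seed=7)
seeds = _derive_seeds(cfg.seed)
geom = _build_geometry(cfg, seeds)          # montage, sources, leadfield, atlas
recs = _get_recordings(cfg, seeds, geom)    # 24 recordings, 32 x 5120 each
op = compute_inverse_operator(geom[2])
feats = extract_features(recs, "source-fc", cfg.bands[0], geom, op)

model = f.FatigueClassifier(feats, rfe_keep_fraction=0.13,
                            rfe_step_fraction=0.05,
                            svm_params={"kernel": "linear", "C": 1.0})
res = model.fit(n_reps=50, seed=seeds["cv"])
print(res.summary())
print(model.permutation_test(n_perm=99, n_reps=10,
                             seed=seeds["permutation"], fast_mode=True))
```

Output:

```
Alert/fatigue classification (50 x two-fold cross-validation)
----------------------------------------------------------
metric            mean %      sd %
sensitivity        100.0       0.0
specificity        100.0       0.0
accuracy           100.0       0.0
...
observed accuracy 1.000, permutation p < 0.010101 (99 permutations)
```

The planted beta coupling is recovered perfectly at this noise level
(sensor SNR 5): all 50 cross-validation repetitions classify every
held-out subject pair correctly, and none of the 99 label permutations
reaches the observed accuracy. Running the same pipeline on the delta
band — where nothing was planted — gives chance-level accuracy (≈ 50 %),
and PSD (band-power) features cannot separate the conditions at all,
because the planted contrast rewires phase coupling without changing the
band-power topography.

The same run is available from the shell:

```sh
fatiguefc run-all config.yaml     # simulate -> localize -> classify -> contrast
fatiguefc compare config.yaml    # source-FC vs sensor-FC vs PSD accuracy table
fatiguefc simulate --out data/   # write a synthetic dataset as TSV + manifest
```

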