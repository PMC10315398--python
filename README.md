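# dcesom

Linking dynamic radiomics of dual-echo DCE-MRI to pharmacokinetic
nested-model tissue classes with self-organizing maps.

## The problem

Dynamic contrast-enhanced (DCE) MRI images a brain repeatedly while a
gadolinium bolus transits the vasculature. In tissue with an intact
blood–brain barrier the signal tracks the plasma concentration scaled by
the plasma volume fraction; in tumor, contrast leaks into the interstitium
and may flux back. Three physiologically nested observation models describe
the tissue concentration C(t) given the arterial input Cp(t):

* **model 1** (no leakage): `C = vp·Cp / (1−Hct)`
* **model 2** (leakage, no backflux): `C = [vp·Cp + Ktrans ∫ Cp] / (1−Hct)`
* **model 3** (leakage + backflux):
  `C = [vp·Cp + Ktrans ∫ Cp(λ) e^(−kep(t−λ)) dλ] / (1−Hct)`

with `vp` the plasma volume fraction, `Ktrans` (min⁻¹) the forward transfer
rate, `kep` (min⁻¹) the back-flux rate, `ve = Ktrans/kep`, and `Hct` the
hematocrit. Selecting the most parsimonious model that fits each voxel's
ΔR1(t) trace (nested model selection, NMS) labels the brain into three
tissue classes.

The question this package addresses: **do convolutional radiomics feature
maps of the raw dynamic images separate those tissue classes better than
the raw images themselves?** The analysis chain is:

1. **Synthesis** — a digital rat-brain phantom (normal tissue, tumor core,
   tumor rim, a caudate-putamen reference patch with vp = 1%) generates
   ground-truth ΔR1 curves and dual-gradient-echo signals
   (TR/TE1/TE2 = 24/2/4 ms, flip angle 18°, 400 acquisitions at 1.55 s,
   bolus at acquisition 15), with configurable noise.
2. **Relaxometry** — per-voxel flip angle and ΔR1(t) are estimated from the
   two echoes by exact inversion of the spoiled-gradient-echo steady state;
   the echo-ratio `F^(μ/(μ−1))/S^(1/(μ−1))` (μ = TE2/TE1) cancels T2*
   exactly, and ΔR1 is independent of the post-study T1 map.
3. **NMS** — the AIF is normalized so the reference region fits vp = 0.01,
   the three models are fitted per voxel, and sequential F-tests select the
   parsimonious model, yielding the model-choice map (the source of truth).
4. **Radiomics** — each normalized echo image is quantized to 128 gray
   levels (fixed bin number) and 133 IBSI-style features from 8 categories
   (IH, IBS, GLCM, GLRLM, GLSZM, GLDZM, NGTDM, NGLDM) are computed in a
   sliding 5×5 window at every timepoint, producing dynamic feature maps.
5. **Screening** — modalities with a tumor-to-normal normalized
   contrast-enhancement ratio (NCER) below 1.2 are discarded; the 13
   highest-NCER features per echo plus the two raw echoes form 28
   information modalities.
6. **K-SOM** — each modality's voxel profiles (390 timepoints after
   excluding the first 10) train a 10×10 hexagonal Kohonen map (batch mode);
   best-matching-unit hit maps, labeled by the model-choice map, give
   per-node class probability maps.
7. **Silhouette sweep** — nodes above each of 100 probability thresholds
   (0.01…1.00) are clustered by argmax class and scored by silhouette
   coefficients; a feature's distinction power versus its raw echo is
   `DSC% = 100·(SC_feature/SC_raw − 1)`, tested with Levene + ANOVA/Welch
   and Holm–Bonferroni correction.
8. **Nested CV** — 10-fold nested cross-validation retrains one SOM per
   modality per fold and scores held-out voxels by their BMU's class
   probabilities (micro-averaged AUC, balanced accuracy, F1 with bootstrap
   confidence bounds).

Everything runs on synthetic data generated by the package itself; no
download is needed.

## Worked example

```python
from dcesom import RunConfig, run_all

cfg = RunConfig(
    shape=(28, 28, 1), n_acq=400, snr=20.0, seed=3,
    dynamic_stride=10, features_per_echo=4,
    som_epochs=25, som_cover_steps=12, k_folds=5, n_bootstrap=200,
)
result = run_all(cfg)
print(result.n_modalities, result.profile_length,
      result.ncv_report.total_models_trained)
for r in result.ncv_report.results[:2]:
    print(r.modality_id, round(r.auc.value, 3),
          round(r.balanced_accuracy.value, 3), round(r.f1.value, 3))
```

prints (deterministically for this seed):

```
10 39 50
echo1 0.941 0.844 0.922
echo1:ih_minimum 0.914 0.741 0.863
```

Ten modalities (two raw echoes + four retained features each), profiles of
39 timepoints (390 surviving acquisitions, strided by 10), and 50 SOMs
trained in nested CV (10 modalities × 5 folds). The per-modality rows give
micro-averaged AUC / balanced accuracy / F1 of the SOM classifier for the
three nested-model classes on held-out voxels — here the raw first echo
separates the classes with AUC 0.94 on this phantom.

The same pipeline is available from the shell:

```bash
dcesom -v run-all --seed 3 --out runs/demo
dcesom simulate --seed 1 --out runs/sim     # stage-wise entry points
```

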