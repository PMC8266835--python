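# nigra

Multimodal substantia-nigra imaging analysis for Parkinson's disease
(PD) studies, exercised end to end on a synthetic multimodal phantom.

PD degrades the neuromelanin (NM)-pigmented dopaminergic neurons of the
substantia nigra (SN), deposits iron there, and depletes dopamine
synthesis in the striatum. Three imaging markers track these processes:

* **NM-sensitive MRI**, quantified as *effective SN values*
  `ESNV_i = S_i,SN − median(S_crus)` (per-voxel SN signal minus the crus
  cerebri background) and summarized per subject by the skewness of the
  ESNV distribution — depigmentation adds low-signal voxels and drives
  the skewness negative;
* **R2\* relaxometry**, the apparent transverse relaxation rate (s⁻¹)
  from a multi-echo gradient-echo decay `S(TE) = S0·exp(−R2*·TE)`,
  which rises with tissue iron;
* **[¹⁸F]DOPA PET**, the influx rate constant Ki (min⁻¹) from
  reference-tissue Patlak graphical analysis,
  `C_t(t)/C_ref(t) = Ki·∫₀ᵗC_ref/C_ref(t) + V` beyond t* = 30 min, with
  occipital cortex as the reference region.

The package implements the full analysis chain — probabilistic-atlas ROI
masking, side-flipping to the clinically most affected hemisphere,
Gaussian smoothing, the three quantifications, voxelwise GLMs with
Freedman–Lane max-statistic permutation FWE and small-volume correction,
and ROI statistics (mixed model on ESNV skewness, demographics,
clinical correlations, group × R2\* × ROI interaction) — plus a
synthetic cohort generator (`nigra.phantom`) with known ground truth, so
every stage is verifiable without any patient data.

## Worked example

```python
from nigra import phantom, pipeline

config = pipeline.validate_config({
    "seed": 7,
    "phantom": {"n_per_group": 10, "grid_shape": [44, 52, 40]},
    "analysis": {"n_perm": 150},
})
report = pipeline.run_pipeline(config, output_dir="runs/demo")
print(report.recovery.to_string(index=False))
print(report.sign_summary)
```

prints (numbers from this exact run):

```
                quantity  estimated      true
r2star_lateral_delta_s-1   1.905379  4.639709
ki_posterior_delta_min-1   0.003738  0.004729
 ki_anterior_delta_min-1   0.002019  0.002622
            skewness_gap  -0.423805 -0.423867
{'r2star_up_lateral_sn_pd': True, 'ki_down_pd': True,
 'ki_skew_positive_coupling_pd': True,
 'ki_r2star_negative_coupling_pd': True, 'skewness_down_pd': True}
```

The recovery table compares group differences estimated from the
generated images against the generator's ground truth: the skewness gap
is recovered almost exactly, while the R2\* and Ki deltas are attenuated
because this pipeline's maps are smoothed (4 mm FWHM) before voxelwise
statistics — smoothing trades ROI-level accuracy for voxelwise
detection power, and unsmoothed quantification (used by the acceptance
script) recovers the deltas to within estimator noise. The sign summary
confirms the five qualitative findings the coupled phantom builds in:
R2\* up in the (left) lateral SN of PD, putamen Ki down in PD, ESNV
skewness more negative in PD, and within PD, Ki falling as skewness
falls and as lateral-SN R2\* rises.

A command-line interface mirrors the library:

```sh
nigra phantom --seed 1 --n-per-group 5 --out cohort/
nigra esnv --dataset-dir cohort/ --out esnv.tsv
nigra run --config config.yaml --out runs/full
nigra roi-stats demographics --subjects cohort/subjects.tsv
```

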