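# adcconcord

Multisite concordance analysis of apparent-diffusion-coefficient (ADC)
mapping for diffusion-weighted MRI (DWI), on synthetic data with known
ground truth.

Quantitative DWI reduces the multi-b-value signal decay
`S(b) = S0·exp(−b·ADC)` to parametric maps — ADC in units of 1e-6 mm²/s,
or the perfusion-minimized pair (ADCslow, Pf) where the fit is restricted
to b ≥ 100 s/mm² and `Pf = [S(0) − S0slow]/S(0)`.  When many software
platforms analyze the same images, their maps disagree for reproducible
reasons: the choice between **log-linear** fitting (OLS of log S on b) and
**nonlinear least squares** on the untransformed signals, masking rules,
lost unit-rescale metadata, reversed slice order, and NaN pixels.  This
package rebuilds that entire measurement chain so the mechanisms can be
studied quantitatively:

* `adcconcord.synth` — 13-vial PVP diffusion phantom (b = 0/500/900/2000
  s/mm²) and two-component breast tumor studies (b = 0/100/600/800 s/mm²)
  with three-direction trace reconstruction, Rician magnitude noise, and
  the metadata pathologies seen in multisite map exchange;
* `adcconcord.fitting` — ADC2, ADC4, ADChi-low, ADCslow and PerfFrac maps
  in both fitting families, plus a brute-force grid-search validator;
* `adcconcord.mapio` — centralized harmonization (automatic power-of-ten
  scale detection against a reference map, slice-order detection, NaN
  sanitization) and NIfTI / NRRD / DICOM(read) interchange;
* `adcconcord.roi` — 1-cm vial circles and multislice tumor ROIs, means
  over unmasked voxels;
* `adcconcord.concordance` — pairwise within-subject CV (wCV) matrices,
  clique grouping at an intragroup wCV threshold, consensus references
  (median, or equal-weight two-group average), percent differences, paired
  t-tests, and bias-vs-ADC regression.

See `docs/methods.md` for the model, the defaults and their rationale, and
known limitations.

## Worked example

```python
import numpy as np
from adcconcord import (FitConfig, NoiseModel, add_noise, compute_trace,
                        default_breast_spec, make_breast, fit_volume,
                        make_tumor_roi, apply_rois)
from adcconcord.pipeline import simulate_breast_cohort, measure
from adcconcord.concordance import analyze

cohort = simulate_breast_cohort(3, seed=11, snr=30)      # three virtual patients
table = measure(cohort, ["ADC4"])                         # 4 implementations
rep = analyze(table, "ADC4", threshold=0.1, reference_mode="group_average")
print(rep.summary())
```

prints (seed 11):

```
{'metric': 'ADC4', 'n_implementations': 4, 'threshold_pct': 0.1,
 'groups': {'A': ['AI-LL1', 'AI-LL2'], 'B': ['AI-NLS1', 'AI-NLS2']},
 'ungrouped': [], 'reference_mode': 'group_average',
 'max_wcv_pct': 2.87408422659451,
 'intergroup': {'mean_pct_diff': 4.141977207269076,
                'sd_pct_diff': 0.3026523095434413,
                'p_value': 0.003277593019127698, 'n_pairs': 3},
 'bias_vs_adc': {'slope_pct_per_1e3': 7.201794555570116,
                 'r_squared': 0.9982744457946282}}
```

Reading: at b=0 SNR 30 the four virtual implementations separate perfectly
into the log-linear and NLS families (within-family wCV ≈ 0, between-family
≈ 2.9%), the tumor-mean ADC4 of the NLS family sits ~4.1% above the
log-linear family (paired t-test p ≈ 0.003 across the three patients), and
the intergroup difference grows with the ROI's mean ADC.  Rerun with
`snr=1e12` and both families collapse into a single group with zero percent
differences on monoexponential data — the divergence is a noise effect.

## The analysis

Numbered drivers under `analysis/` run the full virtual trial and write
tables under `results/` (image volumes go to `scratch/`):

1. `01_simulate_studies.py` — three phantom scans (SNR 100) and three
   breast studies (SNR 30) as noisy trace studies + ground-truth manifest;
2. `02_fit_maps.py` — 60 parametric maps: every implementation × dataset ×
   metric;
3. `03_harmonize_and_roi.py` — corrupts three maps (lost rescale factor,
   reversed slices, injected NaNs), harmonizes everything against a
   reference implementation, and reduces to ROI means
   (`results/measurements.csv`);
4. `04_concordance.py` — wCV matrices, groups, consensus references,
   percent differences and tests per metric
   (`results/concordance_summary.json`, `results/wcv_*.csv`,
   `results/percent_diffs.csv`).

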