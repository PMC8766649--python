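# ppolung

Predicting postoperative pulmonary function after lobectomy — and testing
how well each prediction route works.

Before removing a lobe for lung cancer, surgeons estimate the function the
patient will have left: the predicted postoperative (%ppo) values of FEV1
(forced expiratory volume in 1 s) and DLCO / DLCO' (carbon-monoxide
diffusing capacity), each as a percentage of the population-predicted
normal. A low ppo value flags high perioperative risk. `ppolung` implements
the three standard prediction routes, the imaging chain behind the most
detailed one, and the statistics used to compare them — exercised end to end
on digital thorax phantoms and simulated cohorts with known ground truth.

## The three calculators

With preoperative value `F` (%), `s` segments to be resected of `S_side`
on the operated side (19 bronchopulmonary segments in total: right 3+2+5,
left 5+4):

| method | formula | resected share estimated from |
|---|---|---|
| segment counting (SC, Ali's formula) | `ppo = F × (1 − s/19)` | anatomy only |
| planar | `ppo = F × (1 − f_side × s/S_side)` | side share of perfusion on planar scintigraphy |
| SPECT/CT | `ppo = F × (1 − f_lobe)` | resected lobes' share of SPECT counts within CT-delineated lobes |

The SPECT/CT route needs a lobe label map: the CT volume is thresholded
(lung is low attenuation), morphologically closed to repair vessel defects,
reduced to the two interior connected components (the lungs), and split
into five lobes from manually traced interlobar lines, interpolating the
boundary between traced slices. Lobar perfusion fractions are then ratios
of masked SPECT pixel counts. A patient is **high risk** when any available
ppo value is ≤ 60 %; crossing risk class with observed respiratory
complications gives the usual diagnostic 2×2 metrics and a two-sided exact
Fisher p.

Because no patient data ship with the package, a first-class synthetic-data
layer provides the test bed: a voxel phantom (two ellipsoidal lungs, five
lobes, configurable per-lobe flow, supine gravity gradient, emphysema-like
dropout lesions, 3.9 mm Gaussian PSF, Poisson counting noise) and a cohort
simulator whose risk-group complication rates are calibrated to a published
30-patient lobectomy series.

## Worked example

```python
from ppolung import sc_ppo, planar_ppo, spectct_ppo, segments_for_resection

s, s_side, side = segments_for_resection({"RLL"})   # (5, 10, 'right')
sc_ppo(95.0, s)                  # 70.0
planar_ppo(95.0, 0.55, s, s_side)  # 68.9
spectct_ppo(95.0, 0.29)          # 67.5
```

Running `python examples/02_ppo_calculators.py` prints:

```
resection: ['RLL'] -> 5 of 10 right-side segments
SC        ppoFEV1 = 70.0%
planar    ppoFEV1 = 68.9%
SPECT/CT  ppoFEV1 = 67.5%
```

Segment counting assumes every segment contributes equally (95 × 14/19 =
70.0 %); the perfusion-weighted routes predict less residual function here
because this lower lobe carries more than its anatomical share of blood
flow. And `python examples/04_risk_stratification.py`, fed the published
per-method risk tables, prints:

```
method    sens  spec  PPV   NPV   Fisher p
SC        0.60  0.84  0.43  0.91  0.0679
planar    0.60  0.88  0.50  0.92  0.0413
SPECT/CT  0.60  0.80  0.38  0.91  0.1020
```

Each `examples/` script covers one capability (phantom quantification, the
calculators, agreement analysis, risk stratification, the full pipeline).
A thin CLI mirrors the stages: `ppolung simulate|segment|quantify|predict|
compare|risk|run`.

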