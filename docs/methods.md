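# Methods

This note records the models, parameter choices, and numerical conventions
behind `ppolung`, and what the synthetic test bed does and does not
establish about real data.

## Prediction formulas

All pulmonary-function values are percent-of-predicted on the 0–100 scale;
nothing is rounded inside computations (reports round ppo values to 1
decimal, diagnostic metrics to 2, p-values to 4 significant digits). The
three calculators share the form `ppo = preop × (1 − resected share)`:

* **Segment counting**: share = `s/19`, with the standard segment anatomy
  (RUL 3, RML 2, RLL 5; LUL 5, LLL 4; sides 10/9). All anatomical segments
  are counted as functional — no down-weighting of tumour-destroyed
  segments is attempted, since no principled rule is available without
  additional imaging input.
* **Planar**: share = `f_side × s/S_side`, i.e. the side's measured share of
  total perfusion distributed over that side's segments.
* **SPECT/CT**: share = `f_lobe`, the resected lobes' fraction of total
  SPECT counts (bilobectomy sums two lobes).

All three are linear in the preoperative value, non-increasing in the
resected share, and coincide exactly when perfusion is proportional to
segment count. Resections spanning both lungs (pneumonectomy) are out of
scope and rejected.

## Imaging chain

* **Binarization**: lung = CT value strictly below a fixed threshold,
  default −320 on the phantom's HU-like scale (air −1000, lung −800, soft
  tissue +40). The threshold is a config parameter; −320 sits comfortably
  between parenchyma and soft tissue.
* **Closing**: ball structuring element, default radius 2 voxels (≈8 mm at
  3.9 mm spacing) — enough to repair vessel-scale defects without bridging
  the lungs. The mask is edge-replicate padded by the radius before closing
  so border-touching regions keep touching the border. Closing is
  idempotent, which the tests exploit.
* **Lung field**: the two largest connected components (6-connectivity)
  that do not touch the volume border; outside air touches the border and
  spurious blobs lose the size ranking. Left and right are assigned by
  component centroid along the patient-right→left axis.
* **Lobe splitting**: each traced axial slice contributes a signed
  in-plane distance field to its boundary polyline (positive on the
  superior lobe's side, which lies to the left of the traversal direction;
  exactly-on-the-line voxels go to the inferior lobe). Between traced
  slices the distance fields are linearly blended in z; beyond the
  first/last traced slice they are held constant. The right lung is split
  hierarchically: oblique boundary first (RLL vs rest), then RUL vs RML.
  This interpolation is a stated, reproducible substitute for the opaque
  3-D extraction of commercial workstation software; it is exact for
  boundaries linear in z and the phantom's recovery tests show ≥99 %
  voxel agreement under every-other-slice tracing.
* **Quantification**: lobar fractions are masked SPECT count sums divided
  by the whole-lung total; counts blurred outside the lung field are
  excluded from the denominator. Planar side fractions use the
  conjugate-view geometric mean √(anterior × posterior) of ROI sums, with
  ROIs given in anterior orientation and mirrored for the posterior view.

## Phantom

Two ellipsoidal lungs inside an ellipsoidal soft-tissue thorax on a ≥32³
grid (default 64³ at 3.9 mm isotropic voxels). The left lung is split by
one oblique plane; the right by an oblique plane plus a tilted "horizontal"
plane carving an anterior-inferior middle lobe, giving the clinical
2/3-lobe asymmetry and a small, hard-to-measure RML. One soft-tissue vessel
tube per lung (CT only) gives the closing step a real defect to repair.

Perfusion is parameterised by true per-lobe flow shares (defaults
physiologic: RUL 0.18, RML 0.08, RLL 0.25, LUL 0.22, LLL 0.27), uniform
within each lobe, then modulated by a supine ventral→dorsal gravity
gradient (default 0.3: dorsal voxels get 1.3× ventral flow) and optional
spherical dropout lesions (density × scale in [0,1]). Ground-truth lobar
fractions are recomputed by voxel integration of the final density, so
they stay exact under any modifier. SPECT rendering convolves the density
with an isotropic Gaussian PSF (FWHM 3.9 mm, emulating a reconstructed,
post-filtered acquisition), scales to the expected total counts (default
2×10⁶), and Poisson-samples with the configured seed. Attenuation and
scatter are not simulated: the volumes stand for attenuation-corrected
reconstructions, and the planar projections are ideal parallel sums. That
makes the planar and volumetric side fractions agree almost exactly in the
phantom — so phantom tests validate the *counting*, not planar imaging
physics. Ziostation-style automatic fissure detection is likewise out of
scope; traces are inputs, as in clinical practice.

## Cohort simulator

Each patient draws: a resection from the procedure mix of a representative
30-patient series (6 RUL, 5 RML, 8 RLL, 1 RUL+RML, 1 RML+RLL, 5 LUL,
4 LLL); true lobar fractions from a Dirichlet around the physiologic shares
(concentration 60 — between-patient SD of a lobe share ≈2–4 points);
preoperative %FEV1/%DLCO/%DLCO' from normals (means 95/98/95, SDs 15)
correlated at 0.85 through a shared latent function level, floored at 20 %.
The means/SDs/correlation were chosen so the high-risk group size matches a
series with mostly preserved function (≈6–7 of 30 high-risk). Imaging
fraction estimates add Gaussian noise (SD 0.02) to the true fractions; the
*true* ppo is defined by the SPECT/CT formula on the true lobar fraction;
observed postoperative values are true ppo + Gaussian noise (SD 8 points,
floored at 1 %), so with all noise at zero the observed value equals the
SPECT/CT prediction exactly. Complications are Bernoulli with rates by true
risk group, defaulting to 3/7 ≈ 42.9 % (high) and 2/23 ≈ 8.7 % (low);
DLCO' is missing with probability 1/30. Records missing DLCO' propagate as
missing — every downstream statistic is pairwise-complete per measure, and
risk stratification uses whichever ppo values exist.

Because observed outcomes are generated *from* the SPECT/CT formula, the
cohort cannot adjudicate between methods on real patients; it validates the
statistical machinery (bias ≈ 0 for SPECT/CT, the formulas' relative
behaviour, rate calibration), not clinical superiority.

## Statistics

* Differences are **observed − predicted** everywhere (and A − B for the
  interobserver analysis): a positive mean difference means the prediction
  underestimates.
* Bland–Altman: sample SD (n−1); limits at mean ± 1.96 SD with the fixed
  1.96 multiplier conventional for limits of agreement (not a t-quantile);
  SE of the mean = SD/√n. On fresh Gaussian data, limits from n=30 samples
  cover ≈94–95 % of new differences — the Monte-Carlo tests assert a
  0.93–0.97 band around that.
* Pearson r with two-tailed p from t on n−2 df; simple OLS with R² = r²;
  paired t-tests two-tailed. Identical paired series return t=0, p=1; a
  constant nonzero difference (zero variance) raises rather than fabricating
  a statistic. Zero-variance predictors raise; a constant *outcome* yields
  the degenerate fit slope 0, R² 0.
* Risk: high if any available ppo ≤ 60 (inclusive), low if all > 60.
  Diagnostic metrics treat high-risk as test-positive and complication as
  disease-positive; zero-denominator metrics are reported as explicitly
  undefined, never 0 or NaN.
* Fisher's exact test (two-sided) uses the point-probability convention:
  the sum of hypergeometric probabilities of all same-margin tables at most
  as likely as the observed one, with a 1e-12 relative tie tolerance. An
  exhaustive exact-fraction enumeration over every 2×2 table with total
  ≤ 40 agrees to 1e-12. No multiple-testing correction is applied anywhere.
* Subgroup filters (FEV1/FVC < 70 %, %FEV1 < 80, %DLCO < 80, %DLCO' < 80)
  are strict inequalities; records missing the criterion field are excluded.

## Reproducibility and problem sizes

Every stochastic component takes an explicit seed; the pipeline derives the
cohort seed as run seed + 1000 so stages draw independent streams, and
repeated runs produce byte-identical CSV/JSON reports. The standard
problem sizes — 64³ phantom grids at 10⁶–2×10⁶ counts, 100-seed recovery
sweeps, 30-patient cohorts (10⁴ for rate calibration), 1000-replicate
coverage runs — keep the full test suite under half a minute while leaving
Poisson noise clearly visible in the recovered fractions.

## Known limitations

* No attenuation, scatter, or respiratory-motion modelling; no
  projection-domain reconstruction (the PSF emulates the post-filter).
* Phantom fissure surfaces are planes linear in z; real fissures curve, so
  the linear-in-z boundary interpolation is exercised only in its exact
  regime. Incomplete or accessory fissures are not modelled.
* The ≤60 % rule is the only guideline logic implemented (no VO₂max or
  stair-climb tiers).
* The simulated cohort's outcome model favours the SPECT/CT route by
  construction (see above).
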