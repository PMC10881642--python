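# Methods

This note documents the statistical procedures implemented in
`fdgpattern`, the conventions and defaults chosen where the methodology
left room, and what the synthetic-data validation does and does not
establish.

## Regional preprocessing

Regional FDG-PET values are analysed as global-mean-scaled SUVr: each
subject's 77 regional values are divided by their volume-weighted
whole-brain mean (the union of all 77 VOIs), so the whole-brain mean of
every profile is exactly 1 and only *relative* metabolism is
identifiable. Composite regions (frontal, parietal, temporal, occipital,
insula, limbic, basal ganglia, cerebellum) are volume-weighted means of
their members; an unweighted fallback applies when volumes are absent.

The packaged atlas is a canonical 77-region grey-matter list following
the Hammers adult maximum-probability atlas naming (38 bilateral pairs
plus brainstem). Its volumes are indicative round numbers for weighting,
not measured atlas volumes. Image-space ingestion (optional) smooths with
a separable Gaussian of 8 mm FWHM (σ = FWHM / (2√(2 ln 2)) per axis,
reflect padding — deterministic and mass-preserving in the interior) and
extracts per-label means; inputs are assumed already in atlas space.

## DaT stratification

Putaminal DaT ratios (putamen / occipital reference) are z-scored per
hemisphere against an HC normative sample and averaged; the average
classifies DLB subjects as DaT(+) when z ≤ −2 and DaT(−) otherwise. The
boundary is closed at −2 (a z of exactly −2.0 is DaT(+)); z is signed,
binding *loss* being negative. Normative statistics are a user input; the
packaged defaults exist only so synthetic cohorts run and are not
clinically normative. DLB subjects without DaT data are excluded from the
stratified cohort with a warning.

## Regional statistics

Per region, a one-way ANCOVA (OLS of value on group, mean-centred age,
binary-coded sex; zero-variance covariates dropped) yields an omnibus
F-test plus two-sided t-tests of every pairwise group contrast on the
adjusted means. Both omnibus and contrast p-values are reported because
either family may be of interest. Bonferroni correction defaults to
m = 77 regions × number of contrasts and is user-overridable. Cohen's *d*
uses the classical pooled-SD form with no small-sample correction.
Single-subject abnormality uses z-scores against HC means/SDs with a
closed ±2 SD threshold (made robust to float round-off at the boundary);
a subject is "abnormal" when any composite-level |z| reaches the
threshold.

## Metabolic connectivity

Per group, the inter-region correlation (ICC, in this context the Pearson
correlation of two regions' SUVr values across the subjects of the group,
not an intraclass coefficient) is computed for all 77×77 pairs, clipped
to |r| ≤ 1 − 1e-7 (logged when triggered), and Fisher transformed.
Only the upper triangle is computed and mirrored, so symmetry is exact
despite float non-associativity. Delta matrices are elementwise
differences of Fisher-z matrices, antisymmetric under contrast reversal;
the diagonal is excluded everywhere.

The similarity of two delta matrices is an OLS regression over the 2 926
off-diagonal upper-triangle pairs. Pairs sharing a region are not
independent, so the parametric p-value is anti-conservative; a
region-label permutation test (joint row/column permutation of the
response matrix, default 500–1000 permutations) is reported alongside it
and should be treated as primary. No thresholding or sparsification is
applied — the full weighted matrix is analysed.

A design finding worth noting: when two disease groups' delta matrices
are both computed against the *same* HC group, the shared HC sampling
noise (variance ≈ 1/(n_HC − 3) per pair) is common to both deltas and by
itself induces a large R² between them. With the reference-sized
synthetic cohort the shared-reference design yields R² ≈ 0.7, whereas
fully independent replicates of the same planted alteration share only
the signal and give R² ≈ 0.002. Interpretation of delta-similarity R²
must therefore account for the shared reference; the permutation p-value
is valid either way.

## The pattern-expression model (SSM/PCA)

Training data are the HC and DaT(+) DLB subjects. The pipeline is:

1. **Log + double centring.** Y = ln X, minus each subject's row mean,
   minus each region's column mean of the row-centred matrix. All row and
   column means of Y are zero to float precision and the operation is
   idempotent.
2. **Component extraction.** PCA of the region × region correlation
   matrix of Y (covariance optional as a sensitivity switch). Components
   with eigenvalue > 1 are retained — the Kaiser criterion, applied with
   a 1e-8 guard band so numerically-unit eigenvalues of near-independent
   data are not retained. Eigenvector signs are fixed (largest-magnitude
   loading positive) for backend reproducibility.
3. **Varimax rotation** with Kaiser (row) normalization, SVD-update
   algorithm, tolerance 1e-10, ≤1000 iterations. Communalities are
   preserved and the rotation is orthonormal; rotated components are
   sign-oriented like the unrotated ones. The test suite checks the
   attained varimax criterion against an independent pairwise
   planar-rotation oracle.
4. **Factor scores** by the regression method, W = R⁺Λ (eigen
   pseudo-inverse, since double-centred data give a rank-deficient R),
   rescaled so training scores have zero mean and unit variance exactly.
5. **Weighting factors.** OLS of status (HC = 0, DLB-DaT(+) = 1) on the K
   factor scores plus mean-centred age and binary sex. The covariates act
   as adjusters of the regression only: a factor extraction has no
   covariate slot, so this is where "age and sex as covariates" can
   enter. The expression score is the β-weighted sum of the component
   scores alone, *without* the intercept and without covariate terms —
   the intercept cancels in HC-referenced z-scores anyway, and omitting
   it keeps HC raw scores bounded away from zero so that
   coefficient-of-variation stability summaries have a meaningful
   denominator. (`include_covariate_terms` is deliberately not offered as
   a score component; the coefficients are reported.)
6. **Leave-one-in scoring.** A test subject is appended to the training
   matrix and steps 1–4 are re-run. Rerun components are matched to the
   training components greedily by maximal |Pearson correlation| of
   loading vectors, sign-aligned; matches with |r| < 0.5 and unmatched
   components are logged, never silent. The raw score applies the frozen
   training β to the matched, sign-aligned factor scores; the z-score is
   referenced to the HC scores of the same run (training-run reference is
   available via the projection scoring path).
7. **Stability.** Each control's expression score is tracked across all
   leave-one-in runs; CoV = sample SD across runs / |mean|, in percent,
   summarized as the mean over controls. Controls with zero mean are
   excluded with a warning.
8. **ROC.** AUC by midranks (the Mann–Whitney statistic; ties count ½),
   curve by threshold sweep. Site/scanner checks use pairwise Welch
   t-tests within cohorts with Benjamini–Hochberg correction across all
   comparisons.

A display convention of the originating factor-analysis software —
suppressing loadings below 0.1 and sorting by magnitude — is implemented
purely in report rendering (`loading_report`) and never affects
computation.

### Numerical and edge-case behaviour

- Eigenvalue cut 1.0 + 1e-8; "no components retained" is a hard error.
- Correlation clipping at 1 − 1e-7 before atanh.
- Degenerate inputs (non-positive SUVr, constant regions, zero SDs,
  rank-deficient designs, empty ROC classes, single sites) raise errors
  naming the offending subject/region where possible.
- All stochastic procedures accept a seed; the pipeline derives per-group
  substreams from one seed in fixed group order, so changing one group's
  size never perturbs another group's draws.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes:
per group, regional log-SUVr profiles are drawn from a multivariate
normal with mean `base + δ·pattern` (log scale — the pattern model's
working quantity), exponentiated, and global-mean scaled. Defaults encode
the reference cohort: group sizes HC 23, DLB-DaT(+) 86, DLB-DaT(−) 22,
AD 49, PD 33, MSA 19; DaT z distributions N(−3.7, 0.9) for DaT(+) and
N(−1.1, 0.7) for DaT(−); ages and MMSE by group. The planted DLB pattern
is hypometabolic in parieto-occipital and frontal cortex, hypermetabolic
in motor cortex, basal ganglia, limbic system and cerebellum, and ~0 in
precuneus/posterior cingulate, re-centred to mean zero; its per-region
magnitudes (0.01–0.08 in log units, i.e. 1–8 % regional effects at
δ = 1) and the base covariance (6 % regional SD; correlations 0.1
background, +0.3 within composites, +0.2 for homologous pairs) are
generator conventions chosen for realism — the source analyses report
surface maps, not per-region effect sizes, so these magnitudes are free
parameters, fixed once and not tuned. Disease controls get simple
mean-shift profiles (temporo-parietal for AD, striato-cerebellar for MSA,
mild diffuse posterior for PD) so discrimination exercises are
non-trivial. Connectivity alterations are additive correlation boosts
(+0.10…+0.15) in basal-ganglia, limbic and frontal within-blocks and the
limbic↔basal-ganglia cross block, clipped at |r| ≤ 0.99 and repaired to
positive definiteness by eigenvalue flooring.

What the generator does **not** emulate: voxel-level structure, scanner
harmonization effects beyond a site label (the default site effect on
values is zero), non-Gaussian tails, longitudinal change, and any claim
that the planted effect sizes match patient data. A green test on
synthetic cohorts therefore establishes that the *machinery* recovers
planted structure with correct error control — not that any particular
clinical accuracy would be attained on real patients, and the packaged
defaults do not constitute a clinically valid trained model.

## Known limitations

- With realistic (non-sparse) covariance the Kaiser criterion retains
  ~20 components at n ≈ 109, many with eigenvalues barely above 1; the
  varimax solution among these trailing near-degenerate components is
  unstable across leave-one-in runs. Matching quality is logged per run,
  and their β weights are small, but single-subject scores inherit a few
  percent of run-to-run variability from this — visible in the control
  CoV (~7–14 % across seeds at the default specification).
- Leave-one-in scoring of a *duplicate* of a training subject reproduces
  that subject's training score to ~2 % for typical controls, but the
  deviation grows with the subject's own extremity (the duplicate
  perturbs the sample statistics by O(z²/n)).
- The ANCOVA is a linear model with homoscedastic errors; no
  non-parametric regional tests are provided.
- Spatial normalization, partial-volume correction, DICOM handling and
  voxel-based statistics are out of scope; image input must already be in
  atlas space.
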