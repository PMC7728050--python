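# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of `spectransfer`, in the order a study flows
through the package.

## Spectral containers and grid conventions

Spectra live on a strictly ascending wavenumber grid even though FTIR
instruments emit high-to-low scans; CSV writers emit the descending
instrument convention and the reader restores ascending order. One
canonical order removes any sign ambiguity in derivatives. The working
range is 4000–628 cm⁻¹ at 2 cm⁻¹ (1687 channels); resampling onto this
grid is piecewise-linear, which is deterministic, monotone, and exactly
reproduces linear spectra (interpolation family is a config choice; a
spline would differ only at sharp features relative to the 2 cm⁻¹
step). No extrapolation is ever performed. Region removal
(atmospheric CO₂, 2268–2389 cm⁻¹ inclusive on both ends) drops channels
without touching the rest; removing the whole grid is an error, not an
empty library.

## Pretreatments

* **Baseline offset**: per spectrum, subtract the row minimum; output
  minima are exactly zero. Removes a constant instrumental offset only.
* **First derivative**: lag-1 difference of adjacent channels in
  ascending order, labelled at channel midpoints; N channels become
  N−1. The difference is *not* divided by the 2 cm⁻¹ step — on a
  uniform grid the two conventions differ by a constant factor absorbed
  by any downstream regression; this is documented so results can be
  round-tripped against tools that do divide. On a grid with gaps
  (after CO₂ removal) differences are taken per contiguous block and
  never across a gap, costing one extra channel per gap.

## Piecewise direct standardization

Per output channel *i*, the primary channel is regressed on the
(2k+1)-channel secondary window centred at *i* by principal-component
regression: window columns are centred on transfer-set means, the first
`n_pc` principal components of the centred window are used, and an
intercept is included. Defaults k = 1 (3-point window) and n_pc = 1;
wider windows shift spectral peaks and more PCs admit noise. Edge
channels that cannot form a complete window are removed (no
interpolation), so the output grid is trimmed by k on each side. A
zero-variance window yields zero coefficients with the primary channel
mean as intercept. Fitting is fully vectorised (one batched SVD over
all windows) and bit-deterministic. PDS is fitted and applied *before*
CO₂-region removal.

Two variants are first-class: PDS fitted on raw spectra or on
first-derivative spectra. Raw-PDS output may subsequently be
baseline-corrected or derivatised for modelling (the default pairing);
derivative-PDS output feeds derivative models directly.

Because the window regression includes an intercept and centred
columns, any affine per-channel instrument difference on a rank-one
library is recovered exactly — the identity the acceptance suite checks
at 1e-10.

## Transfer-set selection

Kennard–Stone greedy max–min selection in PCA score space: the first
two picks are the globally most distant pair, each later pick maximises
its minimum distance to the already-selected set; all ties break to the
lowest index, making selection deterministic. The score space uses the
smallest number of components explaining ≥ 99% of variance, capped at
50. The transfer set defaults to ~5% of the synthetic library
(100 of 2000) and is withheld from calibration, mirroring how a
transfer set is carved out of a real library (real studies use ~1% of a
much larger library; at desk scale the absolute transfer-set size, not
the ratio, is what PDS estimation needs).

## Global PLSR with the one-sigma rule

PLS1 is computed by NIPALS; for a single response the inner loop needs
no iteration, and the implementation exposes the standard nested
identity (coefficients for *a* components are
`x_rotations[:, :a] @ y_loadings[:a]`), so one fit yields predictions at
every candidate component count. Component choice: 10-segment
cross-validation with seeded random segment assignment; the selected
count is the smallest whose mean CV-RMSE is within one standard error
(SE over segments) of the minimum. A tiny absolute floor
(1e-8 · sd(y)) is added to the one-sigma threshold so numerically-zero
CV errors on exact low-rank problems compare as equal rather than
chasing rounding noise; without it the rule can select above the true
rank on noise-free data. `max_ncomp` defaults to 20.

## Memory-based learning

Per prediction target:

1. **Dissimilarity**: Mahalanobis distance in standardized PCA score
   space (components explaining ≥ 99% variance, capped at 40; scores
   divided by their standard deviation).
2. **Neighbourhoods**: distance thresholds 0.4–5.0 in steps of 0.2
   (endpoints from the study design; the step is ours); each candidate
   neighbourhood is clamped to between 100 and 200 nearest calibration
   samples, so duplicated neighbourhood sizes are evaluated once.
3. **Local model**: weighted-average PLSR — predictions at each factor
   count in 5…20 (clamped by local rank) averaged with weights
   inversely proportional to the local fitted-residual norm at that
   factor, normalised to sum to one. The weighting follows the standard
   construction of the method family and is isolated behind one
   function for substitution.
4. **Threshold choice**: the neighbourhood with the smallest local
   10-fold CV RMSE wins (seeded folds; ties to the smaller threshold).

The local fits use the kernel (dual) form of PLS1: one Gram matrix per
target neighbourhood serves every CV fold and the final prediction,
which is what makes the per-target model grid affordable when a
~150-sample neighbourhood meets ~1600 channels. Dual and primal forms
agree to machine precision (tested). With a single infinite threshold
and min = max = n the learner reduces exactly to global
weighted-average PLSR.

## Plugin model slot

The third, rule-based model family is a registry slot honouring the
declared capacity limits (committees = 1, at most 100 rules). A
model-tree stand-in — a CART partition of PCA score space with ridge
models at the leaves — ships as `"model_tree"`; no Cubist
implementation is bundled, so a pipeline configured for `"cubist"`
marks that arm skipped rather than substituting silently.

## Outlier screening

* **Calibration screen (per property)**: fit the global PLSR on all
  samples, scan SD thresholds 0.1–3.0 in steps of 0.02 against the 1:1
  line, and keep the *smallest* threshold whose flagged fraction is ≤
  1% — i.e. flag the most samples the cap permits. If no grid value
  satisfies the cap the upper bound is used with a warning. A
  numerically perfect fit (residual SD below 1e-10·sd(y)) flags
  nothing. Screening runs on baseline-offset spectra before any
  transfer step.
* **F-ratio prediction screen**: PCA on the calibration spectra at the
  rank explaining ≥ 99.5% variance; for a new spectrum with squared
  off-subspace residual q, the statistic is F = q·(n−1)/Σq_cal with
  p-values from F(1, n−1), flagging p > 0.99. This pooled single-mode
  form is calibrated (null flag rate ≈ 1%) when the off-subspace
  residual is dominated by one mode; under broadband uncorrelated
  channel noise the statistic concentrates near its mean and the screen
  is *conservative* (flags fewer than nominal) — both behaviours are
  pinned by tests. Flags annotate predictions as potentially
  unreliable; they never remove samples.

## Evaluation

RMSE, bias = mean(pred − obs), R² = 1 − SSE/SST (a squared-correlation
convention is available as a config switch), and RPIQ = (Q3 − Q1)/RMSE
with quartiles by linear interpolation between order statistics — the
convention is pinned because RPIQ depends on it. R² quality bins:
≥ 0.85 excellent, 0.75–0.85 good, 0.65–0.75 fair, < 0.65 non-reliable
(lower bounds inclusive). Between-arm comparison uses
100·(RMSE_ref − RMSE_alt)/RMSE_ref, positive when the alternative
improves; when no primary-instrument scans exist for a prediction set
the reference is the untransferred secondary arm. Direct-calibration
models are assessed by leave-one-out CV; for PLSR the component count
is chosen once on the full set and held fixed across folds, and MBL
performs LOO naturally by excluding zero-distance neighbours.

## Synthetic two-instrument generator

The generator emulates the *structure* of a two-spectrometer soil MIR
study, not its physics:

* **Properties**: skewed marginals — OC lognormal (median 1.5 wt%,
  σ = 1.4, so mean > 2× median), CaCO₃ lognormal, clay scaled-beta, pH
  and BD clipped normals.
* **Primary spectra**: absorbance = Σ property × Gaussian band
  template + constant level + smooth random per-sample baseline
  (degree-2 Legendre, scale 0.06) + white noise (sd 0.003), clipped at
  zero. Band centres sit at soil-relevant wavenumbers (aliphatic C–H
  2920/2850, aromatic/amide 1630, carbonate 1450/880/2515, clay O–H/Si–O
  3620/1030/915) for interpretability only; the model is
  linear-in-properties by construction.
* **Secondary distortion**: a *shared deterministic instrument
  signature* — smooth baseline shift (amplitude 1.0 absorbance, the
  dominant term), smooth gain curve (±25%), and a 1 cm⁻¹ wavelength
  shift (edge values held) — plus small per-sample terms (baseline
  wiggle sd 0.003, scalar gain sd 0.003, noise sd 0.002) that no
  transfer model can remove.

The shared-signature dominance is deliberate and mirrors the study
design this package supports: the first PC of pooled raw
primary+secondary spectra is an instrument axis carrying most of the
variance, first-derivative pretreatment collapses that separation
(PC1 then reflects composition, chiefly OC), and a transfer operator
estimated on 100 samples generalises to unseen ones. Defaults were set
once, analytically, to realise those qualitative targets with margin,
and verified across seeds; they are study conditions, not tuning knobs.

What the generator does *not* reproduce: Kubelka–Munk/radiative-transfer
physics, nonlinear matrix effects, water-vapour lines, scatter artefacts
and property correlations. Passing tests therefore demonstrate that the
pipeline recovers known structure under realistic distortion geometry —
not that it attains any particular accuracy on real soils.

## Problem sizes and runtime

The default study uses a 2000-sample library (1900 after transfer-set
withholding), 100 transfer samples and 300 prediction samples — sizes
chosen so the full acceptance computation (PDS, screening, PLSR and MBL
on three arms, LOOCV direct calibration) completes in a few minutes on
one core while keeping every estimate stable across seeds. The unit
suite uses smaller scenarios (hundreds of samples) for everything that
does not need the default conditions.

## Known limitations

* The PDS operator corrects only the *shared* component of instrument
  difference; per-sample effects pass through, so transferred spectra
  are noisier than true primary scans (visible as the primary ≤ PDS
  ordering in every evaluation).
* The F-ratio screen's F(1, n−1) reference is conservative for
  broadband residuals (see above); an empirical-quantile reference
  would calibrate exactly but is not what this screen family uses.
* MBL threshold selection by local CV refits per neighbourhood; its
  cost grows linearly in prediction-set size.
* Cubist itself is not implemented; the plugin slot preserves its
  declared settings for an external implementation.
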