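# Methods

## The problem

Label-free LC-MS quantification drifts: the measured intensity of the same
analyte changes slowly with a sample's position in the injection sequence
(source contamination, column ageing, detector response). Interleaved
quality-control (QC) runs — repeated injections of one pooled sample — are
chemically identical, so any structure in their intensities along analysis
order is instrument drift and can be used to correct all runs.

## The drift model

Per feature (ion) `i`, intensities at analysis orders `t` are modelled as one
realization of a Gaussian process

```
x_i(t) ~ GP( mu0 + mu1 * t ,  sigma^2 * R_nu(|t - t'| ; ell) + sigma_eps^2 * delta(t,t') )
```

with a Matern correlation `R_nu` of smoothness `nu in {1/2, 3/2, 5/2}`
(closed forms for the three half-integer cases; the general Bessel-function
expression is retained as an independent cross-check). The linear mean
absorbs monotone drift; the Matern term captures the smooth nonlinear
component; `sigma_eps` is white measurement noise. The five parameters
`theta = [ell, sigma, sigma_eps, mu0, mu1]` are estimated by maximizing the
exact Gaussian likelihood on the QC runs of one (batch, experiment) block.
The posterior mean drift curve, evaluated at every sample's order, minus its
average over the block, is subtracted from each sample (in `log1p` space by
default; raw space by flag). A constant fitted curve therefore leaves the
data untouched.

Scan-level variants re-apply the same machinery to extracted-ion-chromatogram
(EIC) traces: per (feature, scan) independently (GPRM-EIC), or jointly over
the (order, scan) plane with a separable Matern product kernel and
independent scales per axis (2D-GPRM-EIC). Corrected traces are re-integrated
by the trapezoid rule; the per-sample correction integral (raw minus
corrected area) is reported. Scan-wise modelling requires alignment first:
each trace is shifted by whole scans so that its apex (first interior local
maximum above 50% of the trace maximum, detected on a 3-point moving
average) lands on the feature's median apex scan.

## Estimation choices

* **Optimizer.** Bounded L-BFGS-B on `log(ell, sigma, sigma_eps)` plus free
  `(mu0, mu1)`, with analytic gradients. Starts: moment-based values
  (OLS mean, detrended variance split half/half, `ell0` = quarter of the
  order span), two deterministic alternatives that attribute 90% / 10% of
  the detrended variance to the GP term (the two competing explanations of
  the data), and seeded multiplicative jitters. The reported optimum is
  never worse than the starting point.
* **Identifiability floor on `ell`.** Drift structure finer than the spacing
  of the reference runs cannot be distinguished from noise, and letting
  `ell` fall below it makes the posterior mean interpolate measurement
  noise. `ell` is therefore bounded below by the mean gap between training
  orders by default (override with `ell_min`). The same floor applies to the
  order axis of the 2-D model.
* **Smoothness regularization.** Following the model's own guard against
  overfitting the few QC points, the QC scale is constrained to
  `ell_QC >= ell_S`, where `ell_S` is fitted to the experimental samples of
  the same block. The constraint is implemented as a bound (the Lagrangian
  multiplier formulation is equivalent at the optimum and its multiplier is
  otherwise unspecified). When `ell_S` exceeds the span of the run, the
  experimental series carried no resolvable within-run smoothness and the
  constraint is skipped — flooring at such a value would degenerate the QC
  fit to its linear mean.
* **Cross-feature moderation.** Instrument noise is a property of the
  platform, not of one feature, and the dominant drift mode is common across
  features. After the per-feature fits of a block, `sigma_eps` estimates
  outside `[0.5, 2] x` the ensemble median are refitted inside that band
  (this stops a noise-free fit from interpolating its QC points), and
  collapsed drift amplitudes (`sigma < 0.3 x` ensemble median) are refitted
  with that lower bound (empirical-Bayes shrinkage of variance components,
  in the spirit of limma). Both moderations can be disabled
  (`moderate_noise=False`).
* **2-D conditioning.** The 2-D model's mean is linear in order and shared
  across scans, so each scan's QC series is centred before the joint fit —
  the 2-D analogue of the per-scan intercepts of the 1-D variant. Without
  this the single GP amplitude has to span the chromatographic peak shape,
  which is orders of magnitude larger than the drift.
* **Degenerate inputs.** Constant series produce a flagged zero-amplitude
  fit; features with fewer than 3 finite QC values, or whose fit fails, pass
  through unchanged and are listed on the result. Covariances carry a
  relative jitter of `1e-8 x (sigma^2 + sigma_eps^2)` on the diagonal.

## Evaluation framework

Reproducibility of the QC runs ranks the normalizers. Per feature:
CV = sd / |mean| within a group; and a two-way additive ANOVA of QC
intensities on (replicate block, run position) whose F test on the run
effect asks whether injection-order structure remains. The fraction of
features with run-effect q < 0.1 (Storey q-values, single lambda = 0.5,
`pi0_hat = #{p > lambda}/(m(1 - lambda))`; forcing `pi0 = 1` reproduces
Benjamini-Hochberg exactly) is the primary metric. Case/control ions are
counted with a paired two-way layout inside a batch (subjects blocked across
the forward/reverse experiments; group tested against between-subject
variation) or an independent two-way layout across batches; features with a
significant group x batch interaction (q < 0.1) are screened out before the
group test. All ANOVAs are explicit sums-of-squares decompositions,
vectorized across features, valid for balanced / proportional designs;
non-proportional layouts are rejected rather than approximated. ANOVAs and
CVs operate on `log1p` intensities by default.

## The synthetic generator

`simulate_experiment` emulates a two-batch serum study: per batch a forward
and a reverse experiment of the same subjects (run order reversed), each
with 10 QC + 20 case + 25 control injections and a QC every 5th run
(QC orders 1, 6, ..., 46). Log-intensities are

```
log x = log(baseline) + bio_subject + group_effect + d(t) + eps_run + eps_int
```

* `baseline` log-uniform over 1e4..1e6; `bio_subject ~ N(0, 0.2)` per
  subject (zero for the QC pool); 10% of features carry a +/- log(2) group
  effect.
* Drift `d(t)` = exponential sensitivity decay with injection count
  (amplitude `0.25 x U(0.3, 1)` per feature, time constant 0.3 of the block
  length — the canonical contamination/decay mode of real instruments)
  plus a Matern-3/2 GP (`ell = 10`, total sd 0.3) split into a component
  shared across blocks (60% of variance; the persistent instrument response
  that the QC run-effect ANOVA detects) and an independent per-block
  remainder, plus a small linear trend. A misspecified family (sinusoid +
  changepoint) is available for robustness checks.
* `eps_run ~ N(0, 0.03)` is per-run measurement noise, present in both the
  matrix and the scan data; `eps_int ~ N(0, 0.12)` is peak-integration
  (preprocessing) error and affects the integrated matrix only — raw
  scan-level traces are upstream of it. This is the mechanism by which
  scan-level normalization can outperform area-level normalization, and is
  the reason to use scan-level data at all.
* EICs: Gaussian peaks (width 2.5 scans) with an integer RT jitter per
  sample (<= 2 scans), per-scan noise sd 0.08, and a scan-dependent drift
  gain `w(s) = 1 + 0.5 (s - apex)/(S/2)` — drift hits the peak flanks
  harder than the apex, so scans carry strictly more drift information than
  the integrated area (Cauchy-Schwarz on the per-scan Fisher information).
  Traces are rescaled so the trapezoidal area equals the pre-integration-
  error intensity exactly.

Defaults produce a raw QC median CV around 25% — a strongly drifting run,
the regime the order-based methods exist for. What the generator does *not*
emulate: missing values mechanisms, intensity-dependent noise, correlated
features (isotopes/adducts), retention-time warping beyond whole-scan
shifts, or batch-specific ionization modes; passing tests therefore show
correctness of the algorithms under the stated model, not performance on
any particular real data set.

## Benchmark sizes and known limitations

* The acceptance suite runs the q-significance comparison at p = 500
  features over the full two-batch design, and the five-method ordering on
  median QC CV over 20 replicates at p = 12 features, one batch, 9 scans —
  sizes chosen so the whole suite completes on one CPU in well under half an
  hour. CVs in the ordering are compared at the field's reporting precision
  (0.1 percentage point), which is what makes ties between near-equivalent
  methods observable.
* Joint maximum likelihood of all five parameters on short series has wide
  sampling spread for the scale: at n = 50 orders with the mean estimated,
  `ell_hat` lands within 25% of truth in roughly 40% of replicates, versus
  about 80% when the other four parameters are known — co-estimating the
  mean and variance components consumes most of the information about
  `ell`. The per-feature drift *curve* is far better determined than `ell`
  itself, which is why correction quality does not track scale-recovery
  rates.
* The within-QC evaluation is in-sample for every QC-fitted method: a more
  flexible smoother can look better on QC CV by absorbing noise. The
  identifiability floor and the noise moderation keep the GP honest in this
  respect; the fixed-span LOESS baseline (span 0.75) is the standard
  comparator.
* Alignment recovers integer shifts exactly only when peak apexes are
  unambiguous (clean peaks); under heavy scan noise apex detection is
  occasionally off by one scan, and traces without a detectable apex are
  excluded rather than guessed.
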