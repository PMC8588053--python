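# Methods

## Problem and model

AFM feature extraction on nanoporous regenerated-cellulose membranes
yields per-pore radii (nm) collected at several scan locations in
acquisition order. Three membrane classes are defined by molecular weight
cutoff (50, 100, 1000 kDa), with theoretical Stokes radii as pore-size
references: the retained solute is modelled as a solid sphere of density
ρ = 1 g/cm³, giving `r_p = (3 M_w / (4 ρ π N_A))^(1/3)` (2.7, 3.4, 7.3 nm).
Measured mean radii exceed these references by 29–311%, and the error
grows as the pore shrinks, which is the signature of a lateral-resolution
floor near 5 nm rather than of hydrogel swelling: rescaling the reference
to a swollen state `r_p (1 + SR)` over SR = 50–200% cannot reduce the
error for all three membranes at any common ratio.

Pore-radius distributions are strongly right-skewed. The package
therefore (i) screens normality with the Jarque–Bera statistic before
any parametric comparison, (ii) models radii as Gamma(shape a, scale b),
and (iii) asks the operational question — can a logistic classifier on
the single covariate x = pore radius distinguish two membranes, and how
small can the scanned sample be before discrimination degrades — by a
parametric bootstrap from the fitted Gammas.

## Statistical components

**Moments and Jarque–Bera.** Skewness and kurtosis use uncorrected
central-moment estimators (`b₁ = m₃/m₂^1.5`, `b₂ = m₄/m₂²`, plain
kurtosis: Gaussian → 3); `JB = n(b₁²/6 + (b₂−3)²/24)`. These estimator
choices reproduce the published fluid-mode statistics (733, 1545, 17 919)
exactly from the published moments. JB is compared against finite-sample
Monte-Carlo critical values (the 95th percentile of JB over
standard-normal samples of the same n; ≈5.1 at n = 60, ≈5.8 at n = 304,
vs the asymptotic χ²₂ value 5.99). Default 10⁵ replicates, generated in
chunks; by construction the type-I error on Gaussian data is the nominal
α.

**Two-sample gate.** If both samples pass JB: Brown–Forsythe Levene test
(absolute deviations from the group median — robust under the skew seen
here; the center choice is ours, as only "Levene" is standard), then a
pooled or Welch t-test per its outcome. Otherwise Kruskal–Wallis
(midrank tie correction, χ² p-value) on the two groups. scipy.stats
provides these standard tests; the gate logic and JB are in-package.

**Gamma fitting.** Two routes: maximum likelihood with location fixed at
0 (scipy's profile-likelihood solver; the optimum is checked in tests to
dominate the method-of-moments start in log-likelihood), and moment
inversion `a = (2/skewness)², b = mean/a`, used to rebuild generating
parameters when only published summary moments are available.

**Drift QC.** A truncated Fourier series
`a₀ + Σ_k [a_k cos(kωt) + b_k sin(kωt)]` (default 2 harmonics) is fitted
over both coefficients and the fundamental ω; t is the acquisition index
1..n, the only time proxy available. The profile SSE in ω is solved
linearly per candidate frequency over 20 log-spaced starts in (1/n, 1/2)
cycles/index, then refined by bounded scalar minimisation (tolerance
1e-9) — the multistart guards against the many local minima of
periodic-fit objectives. The robust option re-estimates coefficients at
the selected ω by IRLS with bisquare weights (tuning constant 4.685, 10
iterations), with R² always reported on unweighted residuals. Adjusted
R² uses p = 2·harmonics + 1 predictors (the harmonic amplitudes plus the
fitted frequency). The drift flag defaults to adjusted R² ≥ 0.8:
raw-data values ≤ 0.45 are treated in this methodology as negligible
periodicity while genuine drift drives the fit toward unity, and 0.8
separates the regimes. Note the threshold's implied detection limit: a
sinusoid of amplitude A over noise σ has population R² = (A²/2)/(A²/2+σ²),
so A = 3σ sits exactly at the 0.8 boundary (coin-flip detection) and
reliable flagging needs A ≳ 4σ.

**Environmental shifts.** Kruskal–Wallis across scan-location groups; a
non-significant p is read as no chronological/spatial shift (drying or
progressive swelling) within the dataset.

**Classification.** Univariate logistic regression fitted by
Newton–Raphson (gradient norm < 1e-8; tiny ridge 1e-12 on the Hessian for
numerical safety). With one covariate, complete separation is exactly a
gap between the class ranges; it is detected directly, coefficients are
capped at |β| ≤ 50 and the model flagged — scores stay monotone in x so
ROC analysis is unaffected. ROC cutoffs are midpoints between
consecutive distinct scores plus ±∞ sentinels, positive call at score ≥
cutoff; trapezoidal AUC then equals the midrank Mann–Whitney estimate
exactly (a tested identity). The Youden index uses the halved convention
`Yi = max (Se + Sp − 1)/2` (range [0, 0.5]; a flag restores the standard
J = 2·Yi), with ties broken toward the lower cutoff. Accuracy is
evaluated at the Youden-optimal cutoff on the evaluation partition by
default (evaluation at p = 0.5 is also exposed via
`accuracy_at_cutoff`). The positive class is the larger-MWCO membrane,
so β₁ > 0 is the expected orientation.

**Bootstrap pipeline.** Per replicate: draw both classes from their
Gammas, split each class with evaluation fraction 0.8 — i.e. train on
20%, score the ROC on the held-out 80%; at fraction 0.7 of the tapping
design this yields the 34:8 evaluation:training partition per class.
(The conventional train-on-80% direction is available by setting
`eval_fraction=0.2`.) Evaluation counts round half-to-even. Aggregates
are mean ± SD over n_datasets = 10 replicates by default. The test-size
sweep scales the whole per-class dataset to `round(f·n)` for f =
0.1..1.0, regenerating datasets independently per fraction (substream
(seed, fraction index, replicate)); fractions whose partitions would be
empty are reported invalid and skipped. The optimal fraction is the
smallest with |ΔAUC to the next fraction| ≤ 0.01 and mean − SD > 0.7;
projected scan-time reduction is 100(1 − f)%, assuming scan time linear
in pore count. Raw-vs-bootstrap agreement uses a k·SD band (default
k = 2).

## Synthetic data: what it emulates and what it does not

The generator draws iid Gamma radii, organised into contiguous
scan-location blocks (tapping: 60 = 5×12, fluid: 304 = 4×76, balance
assumed) with optional additive sinusoidal drift, per-location offsets
and multiplicative outliers; perturbed values that would be non-positive
are regenerated, never truncated, to avoid a point mass at zero. Six
presets rebuild the published study conditions from the published
(mean, skewness) pairs via moment inversion — skewness rather than
kurtosis is used because the Gamma family ties skewness directly to its
shape parameter; published kurtosis then serves as an adequacy
diagnostic, not a constraint. Values are radii in nm throughout.

Limitations of the presets: two moments determine a Gamma exactly, so
none of the raw data's multimodality, measurement rounding or censoring
near the resolution floor is represented. For the fluid-mode 1000 kDa
preset the published skewness (4.776) forces shape a ≈ 0.175, a
distribution whose median (≈1.3 nm) lies below the fluid 100 kDa median
(≈7.6 nm) despite the larger mean — rank-based discrimination on these
presets therefore reverses, and bootstrap AUCs for fluid pairs fall at
or below chance. Passing tests on these fixtures validate the
*machinery* (splitting, fitting, ROC arithmetic, sweep logic and their
statistical calibration), not the laboratory discrimination levels,
which require the raw per-pore data. The same applies to the sweep's
optimisation criterion: with overlapping presets no fraction clears the
0.7 AUC floor, and the driver reports that honestly.

## Numerical and design choices

- Radii carried at full precision; display rounding (3 significant
  figures for relative errors, integer nm for absolute) only at
  formatting. Accuracy errors in the drivers are quoted against the
  1-dp tabulated Stokes radius.
- Logistic grouped-binomial notation reduces to the ungrouped Bernoulli
  case (one trial per measurement), which is what the data are.
- AUC category boundaries: high ≥ 0.8 > medium ≥ 0.7 > low; the 0.8 tie
  resolves upward.
- Seeding: `numpy` SeedSequence substreams (seed, …indices) everywhere;
  same seed ⇒ bit-identical datasets, reports byte-identical.
- Measurement files: strict comma-delimited UTF-8 with header
  `pore_radius_nm, mwco_kda, mode, location_id, acquisition_index`;
  parse errors name the offending line. One dialect avoids silent unit
  errors; radii are strictly positive nm.
- Problem sizes in tests and drivers (e.g. 10⁵-draw recovery checks,
  10⁴–10⁵ Monte-Carlo replicates, 50-seed sweep trend checks) are chosen
  so each check resolves its stated tolerance with comfortable margin.

## Known limitations

- The sphere-density model underlying the Stokes radius ignores solute
  hydration and shape; it is a reference convention, not a physical
  claim.
- JB critical values are Monte-Carlo estimates; quantile noise ≈ ±0.05
  at 10⁵ replicates.
- The drift model assumes a single fundamental with few harmonics;
  broadband or aperiodic drift is not captured (and the "filtered data"
  variant of the original workflow is represented only by the robust
  weighting option).
- The χ² p-value of Kruskal–Wallis is an approximation; at total n ≤ 8
  it tracks the exact mid-p permutation p within 0.05 for the group
  shapes tested, but the raw discrete permutation p can differ by more.
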