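# Methods

`circaphos` packages the computational analyses used to characterise CK1
(casein kinase 1) as a circadian clock component in a minimal eukaryotic
model: period estimation from luciferase-reporter time series,
dose–response and phase–response pharmacology of CK1 inhibitors, and
label-free phospho-proteomic comparison with kinase-motif enrichment.
This note describes the models, the parameters that matter, and the
choices made where the procedures were genuinely open.

## Rhythm estimation

A trace `x(t)` (luminescence counts, hours after transfer to constant
light) is modelled as a truncated Fourier series at an unknown
fundamental period `T`:

    x(t) = c0 + c1·(t − t̄) + Σ_{k=1..K} e^{−λt} [ a_k cos(2πkt/T) + b_k sin(2πkt/T) ] + ε

* **Grid stage.** For each `T` on a grid (window 16–40 h, step 0.05 h) the
  undamped model (λ = 0) is fitted by ordinary least squares and the RSS
  profile minimised. Factorised designs are cached per sampling grid, so
  plates of replicate wells fit in ~2 ms per trace.
* **Subharmonic fold-down.** With K > 1 harmonics, a trial period `k·T`
  reproduces any `T`-periodic signal through its k-th harmonic, so the RSS
  profile can have spurious minima at period multiples (e.g. 40 h for a
  20 h rhythm inside the 16–40 h window). When the best grid period
  carries its dominant amplitude in harmonic k > 1 and folding to `T/k`
  sacrifices less than 5% of the explained rhythmic variance, the
  fundamental is taken.
* **Damped refinement.** The grid optimum is refined by Nelder–Mead over
  `(T, λ)` with `λ ∈ [0, 0.2]/h`. This matters: reporter rhythms damp
  under constant light, and fitting a constant-amplitude basis to a damped
  cosine at a non-integer cycle count displaces the RSS minimum (≈0.18 h
  at T = 32 h, λ = 0.01/h, 120 h of data). With the joint fit, noiseless
  damped cosines are recovered to < 0.01 h and the Monte-Carlo bias at 20%
  noise is < 0.06 h across the circadian range.
* **Trend handling.** The linear term is estimated jointly (centred) rather
  than pre-subtracted: an OLS line fitted before the harmonics absorbs
  rhythmic signal whenever the record does not span an integer number of
  cycles, biasing long periods. A standalone `detrend` utility (linear or
  none) exists for exploratory use.
* **Phase and amplitude.** Phase φ is the peak time of the fundamental,
  `φ = T·atan2(b1, a1)/2π mod T`, referenced to t = 0 (release into
  constant light). Amplitude is the fundamental magnitude at trace start.
* **Rhythmicity gate.** A fit is rhythmic when the fundamental amplitude at
  mid-trace exceeds 2× the residual SD (configurable). Mid-trace, so a
  large-λ fit to early noise does not pass. Constant traces return an
  arrhythmic result (NaN period), not an exception.
* **Replicate comparison.** Periods are compared with a two-tailed Welch
  t-test (group variances not assumed equal); two zero-variance groups
  with unequal means report p as undefined (NaN).

Defaults: K = 3 harmonics (captures the non-sinusoidal waveforms of real
reporter traces without overfitting), burn-in 0 h (synthetic traces have
no release transient; real data can set 24 h), search window 16–40 h.

## Pharmacology

**Dose–response.** Treated wells are grouped by dose and compared to
vehicle wells in the identical well position on a different plate (the
bench pairing convention; 8 replicates by default). Per dose the mean and
SD of period and the difference from the paired vehicle mean are
reported. A 4-parameter logistic (Hill) summary is available but nothing
downstream depends on it.

**Phase–response curve.** For each 4-h inhibitor pulse starting at ZT
`s`, the phase change is

    Δφ = −60 · (φ_treated − φ_vehicle)   [minutes]

computed per well pair, wrapped into (−T/2, T/2], and averaged
circularly (phases are angles; naive averaging breaks near the wrap
point). Delays are negative by convention; a shift of exactly half a
cycle reports as an advance (+T/2). Each PRC point carries a one-sample
t-test of the per-pair Δφ against zero. Per-pair differencing (rather
than differencing group means) was chosen because it cancels shared plate
effects; the alternative is one flag away in `phase_change`.

## Phospho-proteomics

**Collation.** Quantified phospho-peptide occurrences (all charge states,
missed cleavages and further modifications of the same site) are summed
per sample into site-level profiles keyed by accession + sorted residue
positions. Total abundance is conserved exactly; conflicting residue
annotations at one position are an error, not a silent merge.

**Differential testing.** Abundances are arcsinh-transformed to
approximate normality and compared with a two-tailed t-test for
independent samples (Welch by default; pooled available). Fold changes
are ratios of *raw* within-group means — the transform never touches
them. A site is significantly differential when p < 0.05 and the fold
change is > 1.5 or < 1/1.5. No multiple-testing correction enters the
gate (a BH-FDR column is emitted for information). Sites with fewer than
two finite values per group, or a zero control mean, are reported as
untestable rather than dropped. Direction-resolved counts and pairwise
overlaps between comparisons feed a chord-diagram style summary table.

**Motif enrichment.** Given per-site CK1-target labels, the statistic is
the difference in mean fold change, targets minus non-targets. Labels are
permuted preserving the observed partition sizes; the two-tailed p is the
frequency with which the permuted |statistic| reaches the observed one
(ties count toward the tail — conservative). Default 10^5 permutations
(desk scale; the production scale of 10^7 is a parameter away). The
statistic uses raw fold-change ratios by default, log-scale optional. An
exhaustive enumerator over all C(n, k) label placements provides exact
p-values on small inputs and serves as the test oracle for the
Monte-Carlo path. Permutation sampling exploits that the statistic is
linear in the selected-subset sum, so only subset sums are drawn
(vectorised, chunked).

Labels normally come from an external kinase-substrate predictor. The
bundled consensus scanner (S/T or D/E at position p−3; score = acidic
count in p−7..p−1 plus a primed bonus) is a clearly-labelled stand-in so
the pipeline runs without external predictions — it is not a trained
classifier and should not be used for biological conclusions.

## Synthetic data

The generator states the world the tests measure against:

* **Traces.** Damped cosine with linear drift and Gaussian noise:
  baseline 1000, amplitude 300 counts, damping 0.005/h, period 24 h,
  first peak at 6 h, hourly sampling for 120 h (≥4 cycles at typical
  imaging cadence — the true cadence of such experiments is not
  standardised, so these are exposed as parameters). Condition defaults
  follow the bench design: 8 replicates, treated wells paired to the
  identical position on a control plate. Pulse experiments resume
  recording after washout with the treated phase shifted by the stated
  truth (−150 min ⇒ peak 2.5 h later).
* **Phospho tables.** Site base abundances are log-normal (between-site
  SD 1.0 natural-log units around log-mean 9); replicate noise is
  log-normal with SD 0.25 (≈25% CV, typical of label-free
  quantification); 5 replicates per group. A spiked fraction of sites
  multiplies the comparison-group mean by a true fold change
  (log-normal around e¹ ≈ 2.7, 85% up); motif labels are assigned at
  0.5 among up-spiked sites vs 0.1 background. Each site is emitted as
  ≥1 occurrence rows splitting the site value by fixed Dirichlet
  weights, so collation is exactly invertible. Missingness is off by
  default (rate configurable).

What the generator does **not** emulate: identification error, site
localisation ambiguity, intensity-dependent variance, batch effects,
non-Gaussian trace noise, or release transients. A green test therefore
establishes correctness of the estimators under the stated statistical
model, not robustness to every artefact of real plates or spectra.

## Numerical notes

* Grid RSS is computed via normal equations with cached factorisations;
  values are clamped at ≥0 against cancellation on near-perfect fits.
* Nelder–Mead tolerances: xatol 10⁻³ h (period), fatol relative to the
  trace energy; refinement falls back to the grid optimum if it fails to
  improve.
* Permutation p-value tie comparisons use a 10⁻¹² absolute guard.
* All generators and tests are pure functions of (params, seed); the
  pipeline manifest records every seed and parameter, so a run is
  reproducible byte for byte.

## Known limitations

* The period estimator assumes a single stationary oscillator; it does
  not model frequency drift or multiple components.
* Circular SD of Δφ uses the wrapped-normal approximation
  √(−2 ln R̄); it is optimistic for very dispersed phase sets.
* The consensus motif scanner is deliberately simple (see above).
* Supplementary spreadsheet ingestion is by column mapping only; no
  attempt is made to re-localise sites against a genome assembly.
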