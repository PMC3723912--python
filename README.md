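# circaphos

Analysis pipeline for characterising casein kinase 1 (CK1) as a circadian
clock component in a minimal eukaryotic model system. It covers the three
computational legs of such a study:

1. **Rhythm quantification** — period, phase and amplitude of
   bioluminescence reporter traces (e.g. CCA1-LUC) by truncated-Fourier
   harmonic regression with a damped-envelope refinement, plus Welch
   t-test comparison of replicate period groups.
2. **Pharmacology** — dose–response curves (free-running period vs CK1
   inhibitor dose, treated wells paired to identical well positions on a
   control plate) and phase–response curves (phase change Δφ in minutes vs
   pulse start time; delays negative by consensus, circular averaging).
3. **Phospho-proteomics** — collation of quantified phospho-peptide
   occurrences to site level, differential testing (arcsinh transform,
   two-tailed independent t-test, raw-mean fold changes, joint
   p < 0.05 / |FC| > 1.5 gate), direction-resolved overlap counts, and a
   Monte-Carlo permutation test for CK1-target motif enrichment with an
   exhaustive small-case oracle.

A synthetic-data module generates damped noisy reporter traces and
phospho quantification tables with known ground truth, so the whole
pipeline runs end to end with no external data.

## The core statistics

For a trace `x(t)` the period estimator minimises over `T` (grid 16–40 h,
then local refinement jointly with a decay rate λ):

    x(t) = c0 + c1 t + Σ_{k=1..K} e^{−λt} [a_k cos(2πkt/T) + b_k sin(2πkt/T)] + ε,

with phase `φ = T·atan2(b1, a1)/2π (mod T)` and amplitude `√(a1²+b1²)`.

A phospho-site is significantly differential when the t-test on
arcsinh-abundances gives p < 0.05 **and** the raw-mean fold change is
> 1.5 or < 0.67. Motif enrichment tests the observed difference in mean
fold change between CK1-target and non-target sites against the
distribution obtained by relabelling sites while preserving the observed
partition sizes; p is the two-tailed tail frequency.

## Worked example

```python
from circaphos.synthdata import TraceParams, simulate_trace
from circaphos.rhythm import estimate_period

params = TraceParams(period=31.7, phase=3.0, amplitude=300.0,
                     noise_sd=60.0, duration=120.0)
fit = estimate_period(simulate_trace(params, seed=2))
print(f"period {fit.period:.2f} h, phase {fit.phase:.2f} h, "
      f"rhythmic={fit.rhythmic_flag}")
```

prints

```
period 31.86 h, phase 2.83 h, rhythmic=True
```

— the estimator recovers the generated 31.7 h period to within its
single-trace scatter (a 24 h rhythm
lengthened by 7.7 h, the scale of the strongest inhibitor effect) from a
trace with noise at 20% of the oscillation amplitude.

The same flow from the shell:

```bash
circaphos simulate-traces --n-replicates 8 --seed 1 --out traces.csv
circaphos fit-rhythm --input traces.csv --out fits.csv
circaphos run --out-dir demo --seed 1     # full synthetic pipeline
```

`circaphos run` writes `traces.csv`, `fits.csv`, `dose_response.csv`,
`prc.csv`, the phospho occurrence/truth tables, `differential.csv`,
`enrichment.json` and a `manifest.json` recording every seed and
parameter. On the default configuration the dose–response difference
approaches +7.2 h at the top dose and the PRC shows its largest phase
delay (≈ −150 min) for the pulse starting at ZT12.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete synthetic pipeline from scratch under the given
seed (stage outputs land in `scratch/acceptance_run/`) and writes the
results JSON to `--out`.

## Layout

| module | contents |
|---|---|
| `circaphos.synthdata` | trace / plate / pulse-experiment / phospho-table generators with ground truth |
| `circaphos.rhythm` | `estimate_period`, `fit_harmonics`, `detrend`, `estimate_phase`, `compare_periods` |
| `circaphos.pharm` | `dose_response`, `phase_change`, `build_prc`, optional Hill summary |
| `circaphos.phospho` | `collate_sites`, `differential_sites`, `overlap_counts` |
| `circaphos.motif` | `scan_ck1_consensus` (stand-in scorer), `permutation_enrichment`, `exhaustive_enrichment` |
| `circaphos.io` | CSV/FASTA readers and writers, strict YAML config, `run_pipeline` |
| `circaphos.cli` | `circaphos` command group (simulate-traces, fit-rhythm, dose-response, prc, phospho-diff, overlap, motif-enrich, run, …) |

See `docs/methods.md` for the statistical models, defaults and their
rationale, and the limits of what the synthetic tests establish.
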