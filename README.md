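# gammacc

Case-control analysis of stimulus-induced gamma rhythms in elderly EEG,
with a synthetic-cohort generator that makes every stage testable without
access to raw recordings.

## The scientific problem

Large visual gratings induce two narrow-band gamma rhythms in occipital
EEG — slow (20–34 Hz) and fast (36–66 Hz) — whose power appears reduced in
elderly subjects with mild cognitive impairment (MCI) or Alzheimer's
disease (AD), while alpha suppression (8–12 Hz) and steady-state visually
evoked responses (SSVEP, 32 Hz for 16 cps counterphase gratings) are
spared. Because case groups are small and unbalanced against a large
healthy pool, the analysis is pairwise: each case is compared with the
mean of its age (±1 year) and gender-matched healthy controls.

The central per-subject statistic is the stimulus-induced change in band
power,

    ΔPower [dB] = 10 · log10( Σ_f ST(f) / Σ_f BL(f) )

with ST and BL the multitaper (single Slepian taper) power spectra of the
stimulus window (250–750 ms after onset) and the baseline window (−500–0
ms), averaged across analyzable repeats and the nine occipito-parietal
bipolar pairs (PO3-P1, PO3-P3, POz-PO3, PO4-P2, PO4-P4, POz-PO4, Oz-POz,
Oz-O1, Oz-O2), and summed over the band's frequency bins before the
log-ratio. Group inference uses bootstrap medians (10,000 iterations),
Kruskal-Wallis tests, directional JZS Bayes factors (Cauchy prior scale 1;
right-tailed for gamma, left-tailed for alpha), and an OLS severity model
ΔPower = β₀ + β_CDR·CDR + β_AGE·AGE + β_GENDER·GENDER + ε (gender coded
0 = male, 1 = female).

The package implements the full chain — 64-channel 10-10 montage with 112
bipolar pairs, fixation/artifact rejection cascade (robust repeat flags,
30%/10% rules, 56–84 Hz spectral-slope rule, three-group block rule),
spectral estimation, microsaccade and pupil analysis, matched statistics —
plus a seeded forward model of the cohort (1/f background, suppressed
alpha, gated gamma with a case amplitude deficit, SSVEP, evoked
transients, fixational eye movements, blinks, pupil dynamics).

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
synthetic cohort and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py    # 21 subjects -> scratch/cohort.h5
python analysis/02_analyze_subjects.py   # per-subject band powers
python analysis/03_compare_groups.py     # matched case-control statistics
python analysis/04_effect_pattern.py     # seeded replicate rejection rates
```

`03_compare_groups.py` prints (abridged):

```
5 cases, matched controls per case: {'a004': 1, 'm000': 1, 'm001': 1, 'm002': 1, 'm003': 1}
alpha        case -3.29+-0.20 dB vs control -3.07+-0.35 dB | H=1.32 p=0.2506 BF10(left)=0.17
slow_gamma   case +2.41+-0.52 dB vs control +5.71+-1.14 dB | H=6.82 p=0.0090 BF10(right)=7.55
fast_gamma   case +2.55+-0.53 dB vs control +5.33+-1.08 dB | H=6.82 p=0.0090 BF10(right)=4.87
ssvep_32Hz   H=0.53 p=0.4647
regression slow_gamma: beta_CDR=-5.634 (p=0.0090, matched n=10); -5.150 (p=0.0015, unmatched n=21)
```

Read: cases lose roughly 3 dB of induced gamma relative to their matched
controls (Kruskal-Wallis p < 0.01, substantial Bayesian evidence), while
alpha suppression and the 32 Hz steady-state response do not differ, and
the dementia-severity coefficient is significantly negative for gamma
only — the qualitative signature the analysis is designed to detect.

Library use mirrors the scripts:

```python
from gammacc import GeneratorParams, generate_cohort, run_subject, run_comparison
from gammacc.pipeline import PipelineConfig

cohort = generate_cohort(n_healthy=16, n_mci=4, n_ad=1,
                         repeats_per_condition=12,
                         params=GeneratorParams(seed=2021))
cfg = PipelineConfig(seed=2021)
summaries = [s for p, t in cohort if (s := run_subject(p, t, cfg))]
report = run_comparison(summaries, cfg)
```

## Layout

- `src/gammacc/` — library: `montage`, `synth`, `artifacts`, `spectral`,
  `eye`, `stats`, `pipeline`, `io`
- `analysis/` — numbered narrative drivers over the library
- `docs/methods.md` — model, parameter and design documentation
- `tests/` — unit, property and acceptance suites
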