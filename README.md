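# microstates

Resting-state EEG alternates every ~60–120 ms between a small set of
quasi-stable scalp topographies — *microstates*, classically labelled A–D.
Shifts in the temporal balance of classes C and D (an interoceptive /
attention-related imbalance) are a candidate transdiagnostic marker across
the psychosis spectrum.  `microstates` is a tested, reusable pipeline for
this analysis on routine 19-channel (10–20) clinical EEG:

1. **Preprocessing** — 0.5–40 Hz zero-phase bandpass, selection of
   annotated eyes-closed spans, average re-referencing, single-bad-channel
   interpolation, and an alpha-dominance (8–13 Hz) spectral QC with an
   exclusion rule for recordings with more than one bad channel.
2. **Map estimation** — global field power (GFP) peaks, polarity-invariant
   *modified K-means* clustering maximizing the global explained variance

   GEV = Σₚ GFPₚ² · r²(xₚ, m₍a(p)₎) / Σₚ GFPₚ² ,

   silhouette-based choice of K under the polarity-invariant distance
   d = 1 − |r|, and two-level (subject → group) clustering with Hungarian
   labeling against canonical A–D templates.
3. **Backfitting** — every sample of every subject is labelled with the
   best-|correlation| control-group map, temporally smoothed (82 ms full
   window majority vote with minimum-run enforcement), and summarized per
   class as occurrence (1/s), coverage (%), mean duration (ms) and C/D
   ratios.
4. **Group inference** — BEST-style robust Bayesian two-group comparison
   (t likelihoods with group means μ₁, μ₂, scales σ₁, σ₂ and shared
   normality ν), effect size d = (μ₁−μ₂)/√((σ₁²+σ₂²)/2), 90 % HDI, and a
   ROPE decision rule (significant when P(|d| > 0.1) ≥ 0.95); plus a
   one-way ANOVA adjusted for age and sex with Levene and Shapiro–Wilk
   assumption checks.
5. **Synthetic cohorts** — a generator producing 19-channel EDF+ cohorts
   with known ground truth (semi-Markov class sequences with gamma
   sojourns, 10 Hz alpha carrier, per-sojourn polarity flips, 1/f noise,
   between-subject parameter dispersion and group-level class-D
   perturbations), so every stage is verifiable by parameter recovery.

## Worked example

```python
import pandas as pd
from microstates import CohortSpec, PipelineConfig, analyze_cohort, simulate_cohort

spec = CohortSpec(groups=(("control", 25), ("disease", 25)), seed=0,
                  group_scales={"disease": {"duration": {"D": 0.75}}})
recordings, truth = simulate_cohort(spec)
flat, rows = {}, []
for meta, rec in zip(truth.subjects, [r for g in recordings.values() for r in g]):
    flat[meta["subject"]] = rec
    rows.append({"participant_id": meta["subject"], "group": meta["group"],
                 "age": meta["age"], "sex": meta["sex"]})
res = analyze_cohort(flat, pd.DataFrame(rows), PipelineConfig(seed=0))
print(res.best[["target", "parameter", "mean_d", "p_outside_rope", "significant"]]
      .to_string(index=False))
```

```
target     parameter    mean_d  p_outside_rope  significant
     C    occurrence  0.375748          0.8904        False
     C      coverage  0.228858          0.8072        False
     C mean_duration  0.064923          0.7366        False
     D    occurrence -0.971905          0.9987         True
     D      coverage -1.627405          1.0000         True
     D mean_duration -1.936900          1.0000         True
   C/D    occurrence  1.017588          0.9992         True
   C/D      coverage  1.380302          1.0000         True
   C/D mean_duration  1.267223          1.0000         True
```

The generator shortened class-D sojourns by 25 % in the disease-like
group; the pipeline (clustering on controls only, control maps backfitted
to everyone) declares every class-D parameter credibly reduced — posterior
effect sizes around −1.0 to −1.9 with ≥ 99.9 % of the posterior outside
the ROPE — elevates every C/D ratio, and flags no class-C parameter.

The same analysis runs from the shell over a BIDS-like EDF+ tree:

```sh
microstates simulate spec.yaml cohort/     # write a synthetic EDF+ cohort
microstates run config.yaml                # full pipeline -> CSV tables
```

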