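# postprime

Analysis pipeline for **fear-primed step-and-reach posturography**: how
does a primed fear of falling reshape the way people prepare and execute a
rapid whole-body step-and-reach movement?

In the underlying paradigm, young and older adults repeatedly perform a
self-initiated step-and-reach under four blocked surface conditions of
increasing slip threat (NL — no lubricant; LP — lubricant under the
planted leg; LL — under the landing area; LB — both).  Each trial records
16-channel surface EMG (2000 Hz), two tri-axial force plates (1000 Hz),
CoM and joint-angle kinematics (100 Hz) and an infrared reach beam; before
each block the participant marks two 100 mm visual-analog scales (VAS) for
"likely to fall" and "concerned about falling".  `postprime` implements
the full measurement chain:

1. **Signal conditioning** — Savitzky–Golay smoothing + quiet-stance DC
   removal for kinematics; notch → demean → rectify → zero-lag Butterworth
   envelope + per participant × muscle max-normalization for EMG.
2. **Event detection** — reach onset/offset from the beam; CoP onset
   (CoPon), landing-limb unloading (StepOn) and landing (StepOff) from the
   force plates; step length/width/time from malleoli geometry at landing.
3. **EMG metrics** — muscle onsets by the 7 SD / 50 ms sustained-threshold
   rule, reported relative to reach onset; co-contraction index
   CCI = mean[min(a,b)/max(a,b) · (a+b)] over four phases (early,
   preparatory, movement, termination).
4. **Movement metrics** — preparatory CoM excursion/peak acceleration on
   [CoPon, StepOn]; total CoM and peak-to-peak joint excursions over the
   movement.
5. **Statistics** — per-DV two-way mixed repeated-measures ANOVA
   (Condition × AgeGroup) with partial eta squared
   η²p = F·df1/(F·df1 + df2), Mauchly-gated Greenhouse–Geisser correction,
   family-wise divided alpha 0.05/(#DVs × 2), and Bonferroni post hocs.

Because the participant data are not publicly deposited, the package
includes a first-class **synthetic cohort generator** that reproduces the
design (2 groups × 10 participants × 4 blocked conditions × 3 trials, 8 s
multi-rate recordings) with exact ground truth for every event, onset and
metric — the basis of the validation suite.  See `docs/methods.md` for
the generative model and every documented convention.

## Worked example

Simulate a reduced cohort (4 participants per group, 2 trials per
condition) and run the whole pipeline in memory:

```python
from postprime import CohortSpec, PipelineConfig
from postprime.pipeline import run_pipeline

cfg = PipelineConfig(cohort=CohortSpec(n_per_group=4, trials_per_condition=2, seed=42))
run = run_pipeline(cfg)
sel = run.anova.query("dv in ('vas_likely_mm', 'step_width_m') and effect != 'group'")
print(sel[["dv", "effect", "F", "df1", "df2", "p", "eta_p2", "alpha_adj", "significant"]])
```

prints (abridged):

```
           dv          effect      F  df1  df2         p  eta_p2  alpha_adj  significant
vas_likely_mm       condition  224.7    3   18 1.894e-14   0.974     0.0125         True
vas_likely_mm condition:group 0.4678    3   18    0.7084 0.07233     0.0125        False
 step_width_m       condition  114.7    3   18 6.393e-12  0.9503    0.00625         True
 step_width_m condition:group  2.759    3   18   0.07229   0.315    0.00625        False
```

Reading it: fear ratings and step width both climb across the blocked
surface conditions (large condition main effects, judged against each
family's divided alpha — 0.0125 for the 2-DV VAS family, 0.00625 for the
4-DV compensatory-step family), with no age interaction for either under
this generator configuration.  `run.posthoc` holds the Bonferroni-adjusted
pairwise comparisons (e.g. OLDER NL vs LB on the "likely" VAS:
p_adj = 1.6e-05 with multiplier 6), `run.metrics` the long-format trial
metric table, and `run.qc` per-trial flags.

The same run from a shell:

```sh
postprime simulate --config cohort.yaml --out trials/ --seed 42
postprime analyze  --config cohort.yaml --in trials/ --out results/
```

Trial bundles are plain CSV + JSON (`emg.csv`, `force.csv`, `kin.csv`,
`sensor.csv`, `meta.json`, optional `truth.json`), one directory per
trial.

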