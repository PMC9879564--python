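# gart — gaze-based attention refocusing toolkit

`gart` is an offline, hardware-free implementation of a multimodal
attention-assessment and gaze-feedback paradigm for adult ADHD research: a
continuous performance task (CPT) performed in a virtual seminar room while
three-minute phases with and without audiovisual distractors alternate, under
three counterbalanced feedback conditions — *real* gaze-contingent feedback,
delayed *sham* feedback, and *no* feedback. It is aimed at researchers who
want to re-analyze such recordings, prototype gaze-contingent feedback
policies, or power-test the analysis battery on synthetic cohorts without an
eye tracker, EEG amplifier or head-mounted display.

## What it implements

* **CPT engine** — letter stream ('K' after 'A' is a target; 100 ms stimulus,
  1100 ms ISI, 900 trials/block; 30% targets, half of the remainder
  pseudo-targets) and scoring into omission errors, commission errors and
  reaction times, split by condition × phase.
* **Gaze states** — ray-cast classification of each gaze sample against scene
  colliders into task focus / distractor focus / gaze wandering, dwell-time
  percentages, and the distractibility score
  `(distractor % + wandering %) / task %`.
* **Feedback controller** — a deterministic state machine that fires after
  2 s off-canvas or 0.5 s on a distractor, caps events at 2 s, enforces a 5 s
  refractory period, and in sham mode delays onsets by U(20, 30) s.
* **Oculomotor pipeline** — binocular preprocessing (75 ms gap interpolation,
  one-eye compensation, averaging), Savitzky-Golay-smoothed angular
  velocities, an adaptive mean + 6·SD threshold, and saccade/fixation
  detection with the 60 ms minimum-fixation and 40 ms merge rules.
* **Physiology** — EEG theta/beta ratio at Fz (0–35 Hz filter, 5 s epochs,
  complex-Morlet CWT on 85 log-spaced frequencies, theta 4–7 / beta
  13–30 Hz over 0.5–4.5 s) and head actigraphy (~10 Hz downsample, mean
  consecutive 3D displacement).
* **Statistics** — 2×3×2 and 2×3 mixed ANOVAs with Greenhouse-Geisser /
  Huynh-Feldt sphericity handling and partial η², Bonferroni post-hocs,
  t-tests with Cohen's d, Pearson/Spearman correlation matrices with
  Benjamini-Hochberg correction, recognition-accuracy scoring, and a tidy
  outcome-table assembler.
* **Simulator** — a closed-loop semi-Markov participant model (on-task /
  distracted / wandering / blink) that renders gaze, keypresses, EEG and head
  streams with group-calibrated ADHD vs healthy-control profiles and keeps
  ground-truth labels for every stage.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate one ADHD participant (shortened blocks: one DP/NDP cycle of 90 s
each) and run the battery from the shell:

```bash
$ gart simulate --n-adhd 1 --n-hc 0 --seed 7 --out demo/ --n-phases 2 --phase-seconds 90
wrote demo/adhd00
$ gart io validate demo/adhd00
OK: participant adhd00 (ADHD), order ['real', 'sham', 'none']

$ gart cpt score demo/adhd00
real  DP: omissions=0 commissions=0 mean_rt=460.6 ms (n_targets=20)
real  NDP: omissions=0 commissions=0 mean_rt=496.8 ms (n_targets=25)
...

$ gart dwell demo/adhd00
condition phase  pct_task_focus  pct_distractor_focus  pct_gaze_wandering  pct_invalid  distractibility_score
     real    DP       90.344444              1.766667            5.288889     2.600000               0.078096
     sham    DP       89.022222              1.055556            7.644444     2.277778               0.097728
     none    DP       84.433333              1.666667           11.455556     2.444444               0.155415

$ gart detect demo/adhd00
real: 226 saccades, 236 fixations (data loss 2.60%)
sham: 232 saccades, 242 fixations (data loss 2.28%)
none: 195 saccades, 213 fixations (data loss 2.44%)
```

Reading the output: this synthetic participant spends ~84–90% of each block
on the task canvas, ~1–1.8% looking at distractors and the rest wandering or
blinking (`pct_invalid` ≈ the ~2.5% injected tracking loss). The
distractibility score summarizes off-task relative to on-task time — 0.16 in
the `none` block means roughly one off-task second per six on-task seconds.
Mean reaction times in the 460–500 ms range and near-zero error counts on 90 s
blocks are typical for the calibrated ADHD profile; omissions accumulate on
full 18-minute blocks (≈ 2–3 per block vs ≈ 1 for controls). The same
pipeline runs unchanged on recorded sessions in the documented CSV/JSON
layout (`gaze.csv`, `head.csv`, `eeg.csv`, `cpt.csv`, `responses.csv`,
`feedback.csv`, `session.json` per block directory).

The library API mirrors the CLI: `gart.simulate.simulate_cohort`,
`gart.stats.build_outcome_table` and `gart.stats.mixed_anova` reproduce the
full group × condition × phase analysis in a few lines.

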