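# triadstress

Analysis pipeline for status emergence in small conversing groups:
real-time stress from thumb photoplethysmography (PPG), conversational
turn analytics, dominance-hierarchy rank aggregation, and multilevel
statistics for the hormonal substrate (testosterone, cortisol,
salivary alpha-amylase).

## The problem

When three unacquainted men talk for ten minutes, a status hierarchy
usually forms. The biosocial model holds that speech itself is a
status signal: taking the floor is assertive and stressful, listening
is deferential, and high rank goes to those least stressed by
speaking. `triadstress` implements the measurement and modelling
chain needed to test this in a session where subjects first watch a
200 s relaxing video (baseline) and then converse for ~10 minutes:

* **PPG signal** (`triadstress.ppg`): per-beat pulse rate (BPM) and
  peak-to-peak amplitude — the thumb-blood-volume (TBV) proxy that
  *shrinks* under sympathetic stress. Raw amplitudes depend on cuff
  tightness, so only ratios are used:
  `TBV_conv / TBV_video` and, within the conversation,
  `TBV_speaking / TBV_listening` and the same ratio for pulse.
  Includes the artifact rules (interval excision; multiplicative
  step-gain correction from 20 s flanking windows).
* **Turns** (`triadstress.turns`): speaking turns are same-speaker
  utterance runs longer than 4 s (short pauses and interjections
  allowed); each subject gets disjoint speaking and listening interval
  sets.
* **Status ranks** (`triadstress.status`): seven component rankings
  (three judges, speaking seconds, topics, turn count, peer
  evaluation) aggregate into final ranks 1–3; a pair not consistently
  differentiated on ≥4 of 7 components is a tie (1.5 top / 2.5
  bottom); ranks always sum to 6 per triad.
* **Models** (`triadstress.mlm`, `triadstress.stats`): triads violate
  OLS independence, so fixed effects come from a marginal model with a
  *diagonal* residual covariance (one variance per repeated level,
  REML, Satterthwaite-type fractional df, small-sample-corrected SEs),
  built statsmodels-style as `DiagonalMLM(...).fit()` →
  `DiagonalMLMResults` with `summary()` and `simple_slopes()` (±1 SD
  moderation decomposition). Post-hoc power of the joint F-test uses
  Cohen's f² = R²/(1−R²) and the noncentral F with λ = f²·N.
* **Synthetic sessions** (`triadstress.synthetic`): a generator that
  emits complete sessions (waveforms, utterance tracks, saliva panels,
  status components) with known ground truth, calibrated to the study
  conditions, so every stage has a parameter-recovery test.
* **Pipeline/CLI** (`triadstress.pipeline`, `triadstress` command):
  simulate → signal → turns → status → stats in one seeded,
  reproducible run with tidy CSV/JSON reports.

## Worked example

```python
from triadstress.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(mode="synthetic", outdir="out", seed=1))
sc = report["scalars"]
print(f"video pulse        {sc['bpm_video_mean']:.1f} BPM")
print(f"conversation pulse {sc['bpm_conversation_mean']:.1f} BPM")
print(f"conversation TBV   {sc['tbv_conv_video_ratio_mean']:.2f} (video = 1)")
print(f"TBV speak/listen   {sc['tbv_speak_listen_ratio_mean']:.2f}")
print(f"pulse speak/listen {sc['bpm_speak_listen_ratio_mean']:.2f}")
print(f"rank -> lnAA B     {sc['status_rank_lnaa_B']:.2f}")
```

prints (seed 1, 15 synthetic triads, 45 subjects):

```
video pulse        77.8 BPM
conversation pulse 83.3 BPM
conversation TBV   0.78 (video = 1)
TBV speak/listen   0.89
pulse speak/listen 1.09
rank -> lnAA B     0.27
```

Read: conversation is more stressful than the video (pulse up ~6 BPM,
thumb blood volume compressed to ~0.78 of baseline); within the
conversation, speaking is more stressful than listening (TBV ratio
< 1, pulse ratio > 1); and lower status rank goes with higher
alpha-amylase (positive B on the 1 = high … 3 = low rank scale).

The same run from a shell:

```sh
triadstress run --seed 1 --out out
triadstress simulate --seed 1 --n-triads 15 --out sessions/
triadstress validate sessions/
triadstress run --mode files --config cfg.yaml --out out
```

`out/` then holds the per-subject metrics, final status ranks, analyte
model tables, proportion summaries, power table, the data behind the
rank-versus-ratio and lnAA-versus-rank figures, and a replayable run
log (`run_log.yaml` records the seed and every parameter).

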