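# phraseseg

Rule-based detection of phrase-boundary cues in symbolic pitch-event streams,
matching of listener keypress segmentations against those cue models, and the
mixed-design statistics that go with such experiments — plus a synthetic
stimulus/responder generator so the entire pipeline runs without any audio or
human data.

## What it does

- **events** — pitch-event streams (onset / duration / Hz), keypress logs,
  per-stimulus acoustic statistics (duration-weighted mean/SD pitch in Hz and
  mel, pitch-change rate, silence proportion), and I/O for CSV, Praat
  TextGrid/PitchTier and monophonic MIDI.
- **cues** — seven boundary-cue models detected from a stream: pauses
  (silences > 200 ms), pitch breaks (contrasts > 1 SD across a short
  silence), pitch rises and drops (wide-range or long-lasting unidirectional
  movements; drops must end in a low-frequency region), and the three
  pause-plus-X combinations. Every candidate is assigned to exactly one
  model; the merged, deduplicated timestamps form the stimulus' global array.
- **matching** — baseline-RT correction of keypresses, nearest-point
  assignment to the global array, and Russell–Rao similarity (co-present
  positions / array length) between each participant's binary array and each
  model's.
- **segstats** — segment lengths from corrected presses (segments anchored at
  0; each press closes one segment) and condition-level aggregation.
- **inference** — classical mixed ANOVAs (one between factor, one or two
  within factors) with partial eta squared and optional Greenhouse–Geisser
  correction, paired/independent/summary-statistics t-tests with Cohen's d,
  an exact Wilcoxon signed-rank test, and an experiment-level driver that
  gates per-model follow-ups on the three-way interaction.
- **synthetic** — a deterministic generator of ~60 s utterance-like stimuli
  with planted boundary cues (ground truth recorded), delexicalized
  (semitone-quantized) and natural versions sharing identical timing, and
  simulated responders with per-cue hit probabilities, reaction-time
  latencies, false alarms and a refractory period. In clean mode the
  realized margins are verified so detectors recover the planted cues with
  precision = recall = 1.
- **cli** — `phraseseg` with subcommands `simulate`, `detect`, `match`,
  `segstats`, `analyze`, `report` and `run-all`.

## CLI

```sh
# full pipeline on a synthetic experiment
phraseseg run-all --seed 1 --out run/
phraseseg report --results run/results --out run/report.md

# stage by stage
phraseseg simulate --seed 1 --out dataset/
phraseseg detect --events dataset/events_st1_natural.csv --out cues.csv
phraseseg match --cues cues.csv --presses dataset/presses.csv --out scores.csv
phraseseg segstats --presses dataset/presses.csv --out seglen.csv
phraseseg analyze --scores scores.csv --seglen seglen.csv --out results/
```

Detection thresholds can be overridden with `--thresholds th.yaml` (keys as
in `phraseseg.cues.CueThresholds`).

## File formats

- event CSV: `onset_ms,duration_ms,pitch_hz` (header required, UTF-8)
- keypress CSV: `participant_id,instruction,stimulus_id,version,press_ms,baseline_rt_ms`
  (one row per press; empty `press_ms` registers a zero-press cell)
- cue CSV: `stimulus_id,version,time_ms,model,extent_start_ms,extent_end_ms`
- score CSV: `participant_id,instruction,stimulus_id,version,model,score`
- TextGrid: first interval tier; numeric interval text = event pitch in Hz
- PitchTier: points mark event onsets (lossy: no silence information)
- MIDI: type 0/1, monophonic, tempo map honoured, velocities ignored
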