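# qeeg

Quantitative EEG analysis pipeline for paired pre/post-treatment studies:
automated interictal epileptiform discharge (IED) detection, interictal
epileptic activity (IEA) burden quantification, N2 sleep-spindle detection,
and nonparametric paired statistics — together with a synthetic 19-channel
EEG cohort generator that provides exact ground truth for every stage.

## What it does

| module | role |
|---|---|
| `qeeg.io` | Recordings (plain EDF read/write), hypnograms and annotations (CSV), montage transforms (common average, longitudinal bipolar) |
| `qeeg.synthio` | Synthetic EEG: 1/f background, spike(-wave) IEDs, multi-second bursts, N2 spindles, gamma precursors, block hypnograms, paired cohorts with configurable treatment effect |
| `qeeg.ieddet` | Windowed IED detector: channel-level label extraction (2-medoid clustering under banded DTW), leave-one-patient-out training, per-recording threshold calibration with a 75% sensitivity floor, sliding-window inference (500 ms windows, 75% overlap, channel-max combination) |
| `qeeg.iedmetrics` | IEA burden (% of analyzed time covered by 250-ms IED spans plus burst durations, overlap-unioned), channel involvement (95th percentile), gamma-precursor proportion (30–70 Hz), vigilance-state selection, percent change |
| `qeeg.spindles` | Spindle detection in N2 (10–16 Hz band-pass, squared, 300-ms smoothing, 80th-percentile threshold, 0.5–3 s duration gate), fast (≥12 Hz) / slow classification, IED-overlap exclusion, rates per minute of N2 |
| `qeeg.stats_compare` | Median [range] summaries, Wilcoxon signed-rank (exact ≤ 25), Cliff's delta, Benjamini–Hochberg FDR, cohort comparison tables |
| `qeeg.cli_pipeline` | Config-driven orchestration and the `qeeg` CLI |

## CLI

Everything runs from a YAML config (all keys optional; see
`qeeg.cli_pipeline.DEFAULT_CONFIG`):

```bash
# synthetic cohort -> train -> calibrate -> detect -> metrics -> compare
qeeg run-all --seed 1 --out runs/demo

# or stage by stage on files
qeeg simulate --seed 1 --out cohort/
qeeg train-detector --cohort-dir cohort/ --out model.pkl
qeeg detect-ieds --model model.pkl --recording cohort/s00_pre.edf \
    --patient s00 --annotations cohort/s00_pre.annot.csv --out det.csv
qeeg burden --detections det.csv --hypnogram cohort/s00_pre.hyp.csv --out burden.json
qeeg spindles --recording cohort/s00_pre.edf --hypnogram cohort/s00_pre.hyp.csv \
    --ieds det.csv --out spindles.csv
qeeg compare --metrics runs/demo/metrics.csv --endpoints burden,rate_fast --out cmp.csv
```

`run-all` writes `metrics.csv` (per-subject endpoints), `comparison.csv`
(medians [ranges], Wilcoxon p, Cliff's delta, FDR-adjusted p), detections,
and a `manifest.json` sufficient to re-run bit-identically.

## File formats

* **EDF** — plain EDF, int16, 1-s records, all channels at one rate.
* **Annotations CSV** — `recording_id,onset_s,duration_s,type,channels,source,score,freq_hz`,
  channels joined with `;`, times in seconds, half-open `[onset, onset+duration)` spans.
* **Hypnogram CSV** — `epoch_index,stage` with 30-s epochs over
  `{W, N1, N2, N3}` or the collapsed `NREM`.
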