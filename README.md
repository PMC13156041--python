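# ecdg

Analysis pipeline for two-photon calcium recordings of entorhinal-cortex
(LEC/MEC) axonal projections and dentate-gyrus granule cells (GCs) in mice
navigating a 4-m virtual linear track that alternates between a familiar
and a novel context.  The package takes per-ROI raw fluorescence traces
plus a behavior track and carries them through significant-transient
detection, spatial and speed tuning, place-field identification, remapping
statistics, rule-based cue/grid classification and population-vector
decoding.  Because such recordings are rarely shared, it also ships a
synthetic-session generator with ground-truth tuned units, so every stage
is testable end to end without external data.

It is aimed at systems neuroscientists analyzing head-fixed
virtual-navigation imaging experiments, and at method developers who need
a fully specified, reproducible reference implementation of this analysis
chain.

## The analysis in brief

**Transients.** Raw fluorescence is detrended by subtracting the rolling
8th percentile (20-s window), and baseline mean/s.d. are estimated from
samples within 1.9 s.d. of the trace mean, giving ΔF/F in units of the
baseline σ.  Transient detection scans onset thresholds (2–4 σ) and
minimum durations (0.2–1 s) and keeps the least stringent pair whose
false-positive rate — the count ratio of negative- to positive-going
events — stays below 5%.  All downstream analysis uses the
transient-masked trace (zero outside significant transients) and running
periods (speed ≥ 5 cm s⁻¹) only.

**Spatial information.** With λᵢ the mean masked ΔF/F and pᵢ the
occupancy fraction of 5-cm bin i (N = 80 bins), and λ̄ = Σᵢ pᵢ λᵢ,

    SI = Σᵢ pᵢ λᵢ log₂(λᵢ / λ̄)        [bits · s⁻¹]

Significance comes from 1,000 circular shifts of activity against
position (minimum offset 30 s).  Speed information is the same statistic
over 2-cm s⁻¹ speed bins; the speed score is the Pearson correlation of
masked ΔF/F with speed, classified +/−/NS against the 99th/1st shuffle
percentiles.

**Place fields.** Candidate fields are contiguous bins of the smoothed
map above baseline + 25% of the peak-to-baseline range (baseline = mean
of the 20 lowest bins); accepted fields span ≥ 3 bins, have an in/out
activity ratio ≥ 7 and contain transients ≥ 20% of in-field running
time, and must survive a bootstrap that permutes 50-frame segments of
the trace (p < 0.05).

**Classification.** Each active unit is tested in fixed order:
generalizing (fields in both contexts, map correlation ≥ 0.6), then
odor/reward/sound (field within 40 cm after the stimulus in both
contexts, lagged cross-correlation peaking inside the cue's displacement
window with r ≥ 0.6), single object and multi object (60-cm windows;
per-run identification frequency ≥ 0.7 for the same ≥ 2 objects in both
contexts), grid-like (≥ 2 fields, in/out transitions > L/(5W), largest
field < 5W, ≥ 30% of bins assigned, in/out ratio > 2), then place, else
nonspatial.

**Decoding.** Runs split into interleaved template/test halves; templates
hold each unit's mean activity per (context × bin).  Every 100-ms test
population vector is assigned to the template row with maximal Pearson
correlation.  Context error is the 0/1 mis-context rate; spatial error
the mean absolute decoded distance in cm; chance levels come from label
permutation.  Efficiency indices divide the decoding gain over chance by
the mean transient rate: CDE/SDE = ln(gain / rate).

## Worked example

```bash
ecdg all --config cfg.yaml --out demo_out
```

with `cfg.yaml`:

```yaml
seed: 5
n_units: 24
days: 1
metrics: {n_shuffles: 100}
fields: {n_bootstrap: 100}
decode: {sizes: [8, 16], n_draws: 3}
```

simulates one 30-run day (three familiar and three novel 5-run blocks) of
24 mixed-class units, detects transients, computes per-unit metrics,
fields, remapping and classification, and decodes context and position.
`demo_out/summary.json` then contains (values printed by the run above):

```
class_fractions: {generalizing: 0.167, nonspatial: 0.167, object: 0.042,
                  odor: 0.083, place: 0.458, sound: 0.083}
context_error            0.070     # 7% of 100-ms bins mis-contexted
spatial_error_cm         25.9      # vs. 130.8 cm at chance
chance_context_error     0.498
template_ratio_context   0.152     # spatial templates >> mean-rate templates
cde                      1.63      # ln(context gain / transient rate)
sde                      7.13
lick_ratio_familiar      21.1      # licking concentrates in reward zones
```

So with only 24 units the decoder recovers the context in 93% of 100-ms
bins and the position to ~26 cm (chance 130.8 cm), and the recovered
class fractions match the simulated mixture.  Per-stage tables
(`metrics.csv`, `fields.csv`, `classes.csv`, …) carry the per-unit
evidence.  The same stages are available as library functions
(`ecdg.process_traces`, `ecdg.find_place_fields`, `ecdg.classify_unit`,
`ecdg.decode_timebins`, …) and as per-stage CLI commands.

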