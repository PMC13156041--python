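# Methods

This note documents the models, parameter choices and numerical decisions
behind `ecdg`, in the spirit of a methods supplement: what each stage
assumes, which knobs matter, and what the synthetic benchmark does and
does not establish.

## Experimental design being modeled

One session is a day of head-fixed virtual navigation on a 4-m linear
track imaged at 15.5 Hz in a single plane: 30 runs in six alternating
blocks of five (familiar first), 15 runs per context, with 4–10-s screen
blanks at each teleport.  Two paradigms are supported: *corridor*
contexts that differ in texture and reward positions, and
*open-field-like* contexts that share the texture but redistribute an
odor, a sound, a reward and four objects along the track.  In the default
open-field pair the displacements (novel − familiar) are odor +1.0 m,
reward +1.0 m, sound −2.0 m, objects +1.0/+2.0/−2.0/−1.0 m — one value
inside each classifier offset window.  Cue positions are configurable;
layouts with objects closer than 0.6 m are rejected.

## Synthetic sessions

The generator is the package's test bed: it emulates the study design
above with ground-truth labeled units so that every downstream stage can
be scored against truth.

**Behavior.** Running speed follows an Ornstein–Uhlenbeck process with
mean 20 cm s⁻¹, stationary s.d. 8 cm s⁻¹ and mean-reversion 0.5 s⁻¹,
clipped to [0, 70] cm s⁻¹.  The clip keeps per-frame displacement below
one 5-cm bin, so every bin is visited on every run; the OU dips below
the 5-cm s⁻¹ running threshold occasionally, giving realistic
low-occupancy patches.  Licking is a Bernoulli process at 6 Hz inside
the 30-cm reward zones and 0.3 Hz elsewhere.

**Units.** Classes: place, generalizing, odor-, reward-, sound-,
single-object-, multi-object-anchored, grid-like and nonspatial, mixed by
default in proportions 0.35/0.06/0.05/0.03/0.03/0.06/0.04/0.08/0.30
(roughly the spread seen between input streams and GCs; fully
configurable, with an exact-count mode for recovery benchmarks).  Tuning
is Gaussian in position, per context:

- place: independent centers per context, ≥ 0.8 m apart and never jointly
  consistent with one cue's windows (± 0.25 m margin) — otherwise the
  unit would *be* generalizing or cue-tuned by definition;
- generalizing: one center shared across contexts (± 2 cm);
- odor/reward/sound: center 0.05–0.15 m after the cue in each context,
  the same offset in both;
- single-object: center within −0.10…+0.25 m of one object;
- multi-object: two objects that are ≥ 1.1 m apart in both contexts and
  whose displacements do not alias on the 4-m circle, offsets
  −0.10…+0.15 m, event rate 1.7× the base rate (the per-run voting rule
  demands near-every-run detection at each object);
- grid-like: 2–4 evenly spaced fields (spacing 1.15–1.35 m, width
  0.12 m), with the novel phase shifted by about half a spacing so the
  unit does not satisfy the generalization criterion;
- nonspatial: position-independent events at 0.15 Hz (active but never
  field-bearing).

These constraints are class-consistency rules, not free parameters: a
label is only meaningful if the unit's geometry satisfies the printed
criteria of its own class and no earlier-checked class.

**Fluorescence.** Each unit's trace is
`f0 + (events · amplitude) ⊛ exp(−t/τ) + N(0, σ)` with baseline f0 = 50
a.u., noise σ = 1 a.u., event amplitude 6 σ (uniform ±20% jitter) and
decay τ = 0.8 s.  Event probability per frame follows the unit's tuning
at the current position and context and is zero during blanks; true event
frames are recorded for recovery scoring.  τ = 0.8 s models slow-indicator
kinetics in small axonal and somatic structures; at 20 cm s⁻¹ it smears
each transient ~0.16 m downstream, which is why detected field peaks sit
about two bins after the latent tuning center.  Peak-recovery checks
therefore score against the *expressed* field — the smoothed map of the
unit's noise-free convolved event train (`expressed_field_peak_bin`) —
which the detector recovers to within one bin; the event realization, not
the detector, owns the sampling scatter around the latent center.
Decoder "noiseless limit" checks use `tuning_curve_activity`,
deterministic rate-proxy traces, because Poisson event sampling is itself
noise.

**What passing these benchmarks does not show.** The generator has no
neuropil contamination, no motion artifacts, no slow photobleaching
beyond what the percentile baseline removes, Gaussian (not shot) noise,
and stationary tuning within a day.  Recovery rates on it are upper
bounds for real recordings; they validate the implementation, not the
biology.

## Transient detection

Baseline correction subtracts the centered rolling 8th percentile over
20 s, truncating the window at the trace edges (no padding).  Baseline
mean and s.d. use samples within 1.9 total-s.d. of the trace mean;
ΔF/F = (corrected − f0)/σ.  The parameter grid is thresholds
{2.0, 2.5, 3.0, 3.5, 4.0} σ × minimum durations round(0.2·fs)…round(1.0·fs)
frames; events are counted pooled across the session's units, the
negative-going mirror (on −ΔF/F) estimates the false-positive count, and
the least stringent pair (smallest threshold, then shortest duration)
with neg/pos < 0.05 is selected for all units of the session — one
parameter pair per session keeps units comparable.  Detected events
extend until the trace falls back below 0.5 σ and are merged if they
touch.  Definitive f0/σ are then re-estimated from transient-free
samples and the intervals re-extracted on the re-standardized trace.
On event-free noise both polarities occur equally, so the search walks to
a stringency where both counts vanish (ratio 0); on real data the
asymmetry admits sensitive settings.  A 0/0 count ratio is defined as 0;
if no pair complies the most stringent pair is returned with a
non-compliance flag.

## Maps, information and speed

Analyses use running (≥ 5 cm s⁻¹), non-blank frames of one context.
λᵢ is the mean masked ΔF/F per 5-cm bin, pᵢ the occupancy fraction;
smoothing averages each bin with its neighbors (window shrinks to 2 at
the edges) and is applied for field detection and map correlations, while
SI uses the unsmoothed map.  SI is reported in bits (log₂), switchable to
natural log via the `log_base` argument — the information rate is
conventionally quoted in bits even where formulas are typeset with ln.
The shuffle null circularly shifts activity against position within the
context's running-frame sequence by ≥ 30 s, preserving autocorrelation;
p is the fraction of 1,000 shuffles with SI at or above the observed
value.  Speed bins are 2 cm s⁻¹ wide from 5 cm s⁻¹ to the 99th speed
percentile.  The active criterion is strictly more than one transient
onset per running minute.  The activity-difference score
|A−B|/(A+B) uses per-context transient rates; 0/0 is undefined (NaN).

## Place fields

Candidates: contiguous smoothed-map bins strictly above
baseline + 0.25·(peak − baseline), baseline = mean of the 20 lowest bins
(the baseline-relative reading of the 25% rule).  Criteria: width ≥ 3
bins, in/out mean ratio ≥ 7 (inclusive), transient occupancy ≥ 20% of
in-field running frames (inclusive).  The out-of-field region excludes
every *field-like* candidate (width and occupancy passers): with the
all-outside reading, three equal fields of ≥ 6 bins could never reach a
7× ratio, which would make multi-field and grid-like units impossible by
construction; excluding arbitrary noise clumps, on the other hand, would
hollow out the bootstrap null.  The bootstrap permutes whole 50-frame
segments of the context's running-frame masked trace (trace and
transient flags jointly; a trailing partial segment stays in place),
re-runs candidate detection plus criteria against the unshuffled
behavior, and counts a shuffle as positive if any accepted candidate
appears anywhere (a per-cell null).  Fields are accepted at p < 0.05;
`bootstrap_accept_high=True` flips the sense for literal replication of
the "exceeded 0.05" phrasing, which contradicts the stated p definition
and is off by default.  Shuffling within the analyzed context (not the
full dual-context trace) keeps the null's transient mass equal to the
observed context's.

## Remapping and reliability

Map similarity is the Pearson correlation of 80-bin maps; categories are
low (r ≤ 0.1), medium, high (r ≥ 0.6).  Zero-variance maps give an
undefined (NaN) correlation and are excluded from aggregates rather than
zero-filled, which would bias sparse units toward "low".  Trial-to-trial
reliability is the mean pairwise correlation of per-run smoothed maps,
dropping pairs with a silent run.

## Classification

Checks run in the fixed order generalizing → odor → reward → sound →
single object → multi object → grid-like → place → nonspatial; the first
match wins, so labels partition the active population.  Window geometry
is bin-resolved exactly as printed: stimulus windows are 8 bins starting
at the cue bin (40 cm), object windows 12 bins starting three bins
before the object bin (60 cm).  The lagged cross-correlation shifts the
two maps circularly in 1-bin steps; positive lag means the novel map is
displaced toward increasing position.  Offset windows (0.7–1.3 m for
odor/reward, 1.6–2.4 m for sound, 0.8–1.2/1.7–2.3/2.6–3.4 m for object
displacements of 1/2/3 m) take the sign of the actual displacement in
the environment pair, and membership is tested on the 4-m circle (a
+3-m displacement legitimately appears as a −1-m lag).  Multi-object
"cumulated frequency of identification" is implemented as per-run
voting: each run's map votes for objects whose window contains a
supra-threshold candidate peak; an object is represented at frequency
≥ 0.7, and the same set of ≥ 2 objects must be represented in both
contexts.  The grid transition criterion is parsed dimensionally as
transitions > L/(5·W) (more, narrower fields demand more transitions);
the literal (L/5)·W parse is available via `alt_transition_parse`.  Bin
assignment for the grid criteria: in-field above the 25% candidate
threshold, out-of-field below baseline + 10% of range, in between
unassigned.  Grid criteria are evaluated per context and the label is
given if they hold in at least one.  The conjunctive assay (≥ 2 PFs per
context, every peak inside some cue window, same ≥ 2 cues in both
contexts) runs alongside classification and excludes multi-object units.

## Decoding

Template/test splits alternate runs within each context (1st, 3rd, … →
template).  Spatial templates are per-(context × bin) mean masked ΔF/F
(160 rows); mean-rate templates collapse to one row per context.
Population vectors average the running frames falling in each 100-ms
wall-clock bin; at 15.5 Hz every bin inside a running segment contains at
least one frame, so no imputation path is needed.  Zero-variance vectors
(all units silent — common for sparse populations) are excluded from
error averages rather than assigned randomly; argmax ties break to the
lowest row index.  Chance levels permute the true (context, bin) labels
across time bins, 15 repetitions.  For a balanced series the chance
context error converges to 0.5 and, under near-uniform occupancy, the
chance spatial error approaches the closed form
mean|i−j|·5 cm = 133.3125 cm over 80 bins.  Ensemble sweeps and
removal analyses draw 15 random ensembles per condition and rebuild
templates per draw.  Cumulative context accuracy averages the per-bin
context decisions over non-overlapping Δt segments formed within runs (a
segment never spans a teleport); ties count as incorrect; the reported
time-to-target is the first Δt whose mean accuracy exceeds the target,
+∞ if never.  Efficiency indices use the natural log of
(accuracy gain over chance)/(mean transient rate) for context and
(error reduction over chance in cm)/(rate) for position; non-positive
gains give −∞.

## Determinism and problem sizes

Every stochastic step takes a seed; the pipeline derives stage seeds from
the config seed via CRC-stamped `SeedSequence`s, and output files are
written with fixed float formatting, so identical configs reproduce
byte-identical outputs.  The test suite runs its benchmarks at desk
scale — 200-shuffle bootstraps, 100–108-unit single-day sessions,
1,000-shuffle SI calibration on 200 units — sizes chosen so the full
suite completes in about a minute while keeping binomial confidence
bands tight enough for the stated recovery bounds.

## Known limitations

Only 1-D tracks: no 2-D place/grid analysis, no spatial autocorrelogram
hexagonality.  No spike inference, neuropil correction or image
registration — the pipeline starts from extracted ROI traces.  Group
level inferential statistics (ANOVA families, post hoc tests) are out of
scope; the tidy per-unit tables are the intended input to external
statistics tools.  The circular lag convention makes displacement
windows ambiguous between d and d−L on a looped track; layouts whose
cue displacements alias (e.g. +2 m vs −2 m on 4 m) cannot be
disambiguated by the cross-correlation criterion and should be avoided
in environment design.
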