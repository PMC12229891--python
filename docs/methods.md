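# Methods

`placeref` analyzes how hippocampal CA1 place fields on a circular
treadmill belt are anchored — to the fixed tactile cues of the belt
(*space-referenced*) or to a movable reward goal (*goal-referenced*) —
and decomposes the synaptic input underlying a field into the two
corresponding components. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
data do and do not establish.

## Task model

A head-fixed mouse runs laps on a circular belt (length `L`, default
180 cm for imaging sessions, 184 cm for intracellular sessions) for a
water reward at a fixed belt position. After `n_laps_pre` laps
(default 100) the reward moves half a belt forward (50 → 140 cm;
intracellular: lap origin → 92 cm). Because the post-reward stationary
period re-anchors the animal's run, moving the reward rotates the
goal-referenced frame by `L/2` while leaving the cue-referenced frame
untouched; the two frames are thereby dissociated.

## Calcium pipeline

**dF/F.** Raw fluorescence is baseline-corrected with a rolling
5,000-frame window (an 8th-percentile baseline evaluated every 250
frames and interpolated), `F0` is the histogram mode of the corrected
trace (100 bins, counts smoothed over 5 bins, median of the winning
bin), and dF/F = (F − F0)/F0. Noise is estimated from the reflected
sub-mode half-distribution; frames above mode + 3 s.d. are significant
transients. The mode estimator carries ~0.1 s.d. of jitter, so the
false-positive rate of the 3-s.d. rule on pure noise scatters around
the Gaussian tail value of 0.13%.

**Spatial maps.** Frames faster than 5 cm/s are binned into 50 bins of
3.6 cm. Per-lap maps store the per-bin *maximum* dF/F (event
detection); the trial-averaged map stores the per-bin *mean* (tuning,
SI, field location). Only the first 100 laps per condition are used.
Display smoothing is never applied before statistics.

**Place cells.** The onset lap is the first lap where the lap and at
least two of the next five laps contain ≥3 consecutive significant
bins within ±45 cm of the field peak. Spatial information is

    SI = Σᵢ pᵢ · xᵢ · log₂|xᵢ / x̄|,

with occupancy `pᵢ`, per-bin mean activity `xᵢ` and overall mean `x̄`.
Note the weight is `xᵢ` itself, so SI scales linearly with the map
(`SI(kx) = k·SI(x)`); the classical normalized form is available as
`si_classical` and is never silently substituted. Significance comes
from 200 shuffles (circular shift ≥500 frames, then six equal chunks
in permuted order; spatially modulated above the null's 95th
percentile). Reliability is the fraction of post-onset laps with an
in-field event; a place cell is spatially modulated *and* >20%
reliable.

**Reference frames.** Cells reliable in both conditions are classified
by the circular arc distance between their pre and post field peaks:
0–15 cm space, 75–90 cm goal, 16–74 cm intermediate (boundaries
inclusive). The random-remapping null places post fields uniformly on
the belt (a shift-uniform variant is provided), giving the chance
expectation 15/90 ≈ 0.167 per referenced category. Cross-day stability
is bootstrapped by resampling 80% of matched cells with replacement
(the sampled fraction is not pinned down externally; it is
config-exposed) and comparing an observed index against the 5th
percentile of the resampled distribution.

**Population vectors.** The 50×50 Pearson matrix between trial-averaged
PVs of two conditions is summarized by its diagonal mean (space
similarity) and the mean of the 25-bin circularly shifted diagonal
(goal similarity). Zero-variance PVs (constant across cells, up to a
relative tolerance of 1e−9) give undefined correlations stored as NaN
and excluded from the means — zeroing them would bias the summaries.

**BTSP events.** A putative event lap must (1) carry an amplitude in
the cell-condition's top decile of event amplitudes (pre and post
thresholds are separate), (2–3) be followed by significant events
within ±45 cm of the event peak on ≥4 of the next 5 laps, (4) at least
double the mean in-window per-lap maximum relative to the preceding
five laps, and (5) exceed 2 dF/F at peak; the last five laps of a
condition are excluded. A field is the contiguous circular bin run
above 35% of the map peak; fields of mean five-lap maps additionally
require width <90% of the track, in-field max >0.2 and in/out mean
ratio >2, else their COM is missing. COM uses within-field bins only.
Goal-referenced selectivity is (G − S)/(G + S) of the per-lap peak
dF/F in 13-bin (~45 cm) windows at the goal- and space-referenced
locations, categorized at ±0.33.

## Intracellular pipeline

Spikes are detected where dV/dt exceeds 20 mV/ms and the trace reaches
0 mV within 2 ms (plateau edges fail this), the threshold estimate
being the voltage at the last sub-threshold-slope sample. Waveforms are
excised from 1 ms before to 4 ms after onset and bridged linearly. Each
trial is baseline-corrected by subtracting (most negative 5th
percentile of its spike-threshold estimates) − (−50 mV); spikeless
trials inherit the session median offset. Plateau potentials are
supra-(−35 mV) segments lasting over 100 ms after merging gaps ≤10 ms.

Corrected traces are averaged in 1-cm bins twice: in belt coordinates
(space frame) and re-zeroed at each lap's running start (goal frame).
The running start is detected from behavior: post-reward stop (first
sub-1 cm/s frame within 5 s or 50 cm; fallbacks sub-5 cm/s, then
minimum speed), bouts travelling <8 cm zeroed, and the stationary
period's end read off a binarized >1 cm/s trace smoothed with a
centered 1-s moving average at threshold 0.5. The ambiguous printed
stationary-window figure is read as 18 cm past the stop.

**Decomposition.** ΔV_m = mean post ramp − mean pre ramp, computed in
both frames; pre means use trials after the last pre-switch plateau
(≥4), post means trials before the first post-switch plateau (≥3). The
first post-switch trial is additionally excluded: its running start is
still anchored to the old reward, so neither frame isolates a single
component on it. Averaging in the space frame cancels the
space-referenced input, so the signed area of space-frame ΔV_m within
±30 cm of (pre field + 92 cm) is **Area_Goal**; conversely the goal
frame cancels the goal input and the same window 92 cm from the
goal-frame pre field gives **Area_Space**. Then

    Index = (Area_Goal − Area_Space) / (Area_Goal + Area_Space),

and Symmetry = [min(G_l,G_r) + min(S_l,S_r)] / [max(G_l,G_r) +
max(S_l,S_r)], with left/right flanks of each ±30 cm window (the center
bin counts toward the area but toward neither flank, so a symmetric
bump scores 1). Negative lobes inside a window enter as signed area.
Cells are excluded only for the two stated reasons — an immediate
post-switch plateau, or two distinct fields after the switch (a second
above-threshold region of the smoothed post AP map peaking over half
the global maximum); symmetry is reported but never auto-excludes.

The field location is the circular COM of the smoothed (σ = 2 bins)
mean AP-rate map above 10% of its peak, computed per condition; for
recordings with too few spikes the subthreshold ramp itself (baselined
at its 20th percentile) substitutes. Reconstruction sums the extracted
goal component (space-frame ΔV_m in the goal window) and space
component (goal-frame ΔV_m in its window, mapped back to belt
coordinates through the median post-switch running-start position —
the exact relation between the frames) and reports
∫|recon − original| / ∫|original| over the union of the two windows,
the original being the post ramp minus its outside-window median.

## Synthetic data

The generator is the test bed: every analysis stage has a recovery test
against its ground truth.

*Behavior* is piecewise constant-acceleration: accelerate at 20 cm/s²
from each running start, cruise at a lap speed (default 15 cm/s, 10%
lap-to-lap s.d.), decelerate over the last 20 cm before the reward,
stop 1–6 cm past it, remain stationary for N(6.8 s, 0.6 s), then start
the next run. Licks ramp up over the deceleration window and continue
during consumption. Kinematics are analytic, so traces are
byte-identical under a fixed seed. Mid-track non-rewarded stops can be
scheduled to exercise their detector.

*Calcium*: cells are allocated to space/goal/intermediate/nonplace
categories by largest-remainder counts (cohort fractions are exact;
defaults 0.25/0.31/0.44). A cell fires a transient (instantaneous rise,
0.5-s exponential decay, GCaMP6f-like) with probability `reliability`
(default 0.8) when crossing its anchor: a fixed belt position (space),
a fixed arc-distance from the lap's running start (goal; the anchor
therefore rotates with the reward switch), or a belt position that
jumps by a uniform 16–74 cm draw at the switch (intermediate).
Transient amplitude is 1.0 dF/F with 20% jitter — the typical GCaMP6f
somatic transient, deliberately well below the BTSP amplitude floor of
2 so that ordinary activity does not mimic plasticity events. Raw F
adds a slow sinusoidal baseline drift and Gaussian noise (s.d. 0.1
dF/F) so extraction is exercised. Scheduled BTSP injections relocate
the cell's field to a given location at a given lap with a first-lap
amplitude of ≥2.5. Per-cell RNG streams keep each cell's draw
independent of cohort size and of other cells' schedules.

*V_m*: the subthreshold potential is −65 mV plus two smooth circular
Gaussian ramps (σ = 12 cm) — a space component at a fixed belt
position and a goal component at a fixed distance from the running
start — scaled so the combined pre-switch peak is 9 mV; the true index
is (w_goal − w_space)/(w_goal + w_space). Spikes are emitted at a rate
rising steeply with depolarization; each inserted waveform approaches
the stereotyped threshold (−50 mV plus the trial's recording offset) at
under 15 mV/ms before the fast upstroke, so threshold-based baseline
correction can recover per-trial drift exactly. Scheduled plateaus are
square depolarizations to −30 mV. One cell is simulated per call, as in
a whole-cell recording.

**What the synthetic data do not emulate:** optical artifacts and
neuropil contamination, multi-field cells, theta-timescale structure,
trial-to-trial field drift within a condition, behavioral lapses, or
any mechanistic model of plasticity (injected events are descriptive).
Passing recovery tests therefore demonstrates that the analysis
recovers what it is defined to measure under clean task statistics —
not that real data meet those assumptions.

## Problem sizes and numerical choices

Recovery checks run at: 10⁵ placements for the remapping null; 500
untuned cells × 200 shuffles for the type-I rate; 300 cells × 200 laps
for classification; 100-cell cohorts for PV geometry and BTSP (recall
on injected events, false rate on stable cells); a five-point
noise-free weight sweep at 20 kHz (16 pre / 20 post trials, matching
typical recording lengths) for the V_m index; 20 goal cells × 60 laps
with a 25% speed s.d. for the space/time dissociation. Ties in field
peaks break toward the lowest bin index; 0·log 0 := 0 in SI; unoccupied
bins are missing (NaN), never zero; all distances and COMs are circular
with positions half-open on [0, L). Analysis windows that cross the
belt origin wrap.

## Known limitations

The shuffle's six chunks are equal-length (the convention is not
otherwise determined). The goal frame of the first post-switch trial is
anchored to the pre-switch reward; downstream means handle this by
excluding the transition trial. The histogram-mode F0 estimator is
biased by up to half a bin for strongly skewed traces. BTSP detection
evaluates persistence within ±45 cm of the event peak, which can miss
events whose field drifts farther within five laps.
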