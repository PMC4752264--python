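# Methods

## Experiment model

A recording lives on a clock starting at t = 0 with contiguous phases
*baseline → hypoxia → recovery* (defaults 2 h / 6 h / 3 h). Each clock
hour is split into a 10-min stimulation block and 50 min of spontaneous
activity. Bath pO₂ follows first-order exponential relaxation between
set-points: 160 mmHg at baseline, 23 mmHg under severe hypoxia, with
time constants 0.95 h (falling) and 0.51 h (rising). Hypoxic depth
d(t) ∈ [0, 1] is the normalized pO₂ deficit; synaptic efficacy is
`1 − (1 − efficacy_min)·d(t)` (default `efficacy_min = 0.5` for severe
hypoxia), and by default baseline firing intensities follow the same
multiplier, reflecting that most spontaneous spiking in these cultures
is network-driven. Baseline-phase multipliers are identically 1.

## Synthetic recordings

The generator produces ground-truth-annotated spike trains and optional
raw traces with the statistical structure the analysis assumes. It is a
model of the *statistics the pipeline measures*, not of membrane
biophysics.

**Coupling.** Trains form a branching (Hawkes-like) point process:
baseline spikes are (in)homogeneous Poisson per unit; each spike of
unit *i* independently triggers a spike of *j* with probability
`adjacency[i,j] · efficacy(t)` at `delay_ms[i,j]` plus Gaussian jitter
(SD 0.2 ms), recursively up to a generation cap (6). Spikes of
inhibitory units instead delete target spikes within 10 ms after the
edge delay with the same probability. A 1-ms refractory period is
enforced greedily (earliest spike of a chain wins). This event-driven
construction has, for pair statistics (CFP peaks at the edge delay with
height ≈ the follow probability), the same content as a 1-ms-grid
conditionally-Poisson model, and runs multi-hour 60-unit simulations in
seconds. The default random network (60 units, one per electrode, 80%
excitatory / 20% inhibitory, edge probability 0.05, strengths
0.10–0.25, delays 2–10 ms) has branching ratio ≈ 0.5: activity is
amplified ~2× by reverberation, producing burst-like co-activation
while staying safely subcritical.

**Firing statistics.** Excitatory units fire near-Poisson at 0.5–2
spikes/s (2–5 /s in the recovery fixtures). Inhibitory units fire in
rare intense bursts — Poisson burst onsets at 2 /h, ~1.5 s long, with
log-normal intensity (σ = 0.8) around a mean set by the unit's mean
rate (default 0.06 spikes/s), over a 0.005 /s background. This is what
the 6-s-bin Fano factor (SD/mean) requires: a value above 12.47 forces
the occupied-bin fraction below ~0.6%, i.e. genuinely sparse intense
bursting, which a telegraph envelope with an appreciable ON fraction
cannot produce. The excitatory Fano of uncoupled units (~0.2–0.3) sits
far below the 7.21 threshold; coupled units are burstier but remain
well below it. Optional *intrinsic* (tonically active) units multiply
their rate by `1 + tonic_gain·d(t)` (default gain 4), emulating
disinhibited tonic firing during hypoxia; no calibrated rate is claimed
for them.

**Waveforms.** Per-unit biphasic templates (negative main lobe,
width ~0.25 ms, 96 samples at 16 kHz, peak at sample index 32;
amplitudes 40–120 signal units) plus i.i.d. Gaussian noise (SD 4) per
cutout. Hypoxic deformation is progressive widening plus amplitude
decay after a per-unit morph onset, ramping over 5 h; silencing onsets
zero a unit's intensity from a given hour. Raw traces are sums of
templates at spike times plus Gaussian noise, intended for short
segments (one electrode-hour is 57.6 M samples).

**Stimulation.** Pulses occupy the first 10 min of each hour,
interleaved across the selected electrodes in random order with
inter-pulse intervals uniform on 5–10 s and truncated at the block end
(40 pulses per electrode at these intervals do not always fit; averages
are per delivered pulse). Evoked responses have an early direct
component (fixed probability per pulse, latency 2–12 ms, not scaled by
efficacy) and a late synaptic component (Poisson count with mean
`late_mean · efficacy(t)`, latencies Beta-shaped over exactly
15–150 ms), so the expected late count — hence A_syn — scales linearly
with efficacy.

**What passing tests do not show.** The generator omits genuine network
bursts' spatiotemporal propagation structure, electrode crosstalk,
drifting noise floors, multi-unit electrodes outside dedicated
fixtures, and any biochemistry of cell death; recovery of planted
parameters here demonstrates the estimators' correctness, not their
robustness to every pathology of real MEA data.

## Analysis choices

**Noise estimate.** MAD/0.6745 per 10-s window, median across windows.
The real-time estimator of the original acquisition software is
unspecified; MAD is the standard spike-robust choice and is validated
against known σ with and without spike contamination.

**Detection.** Threshold 5.5σ on |signal|; supra-threshold runs closer
than 1 ms merge into one event (dead time); the peak is the local
maximum of |signal|; cutouts span −2 ms…+4 ms (96 samples, 1-based peak
sample 33, so the variability window "samples 9–59" runs from 1.5 ms
before to ~1.6 ms after the peak). An event must contain at least two
supra-threshold samples: a one-sample rule on i.i.d. Gaussian noise
fires at P(|Z| > 5.5) ≈ 3.8·10⁻⁸ per sample ≈ 0.6 false events per
electrode-hour at 16 kHz, while genuine spikes at ≥8σ keep several
near-peak samples above threshold (neighbour samples are ≥0.95 of the
peak for the template widths used). Cutouts crossing the trace edge are
dropped. The artefact screen is a documented stand-in for the original
off-line procedure: it rejects saturated cutouts (≥4 samples pinned at
the extreme) and groups of >10 electrodes firing within ±0.2 ms with
near-identical waveforms (mean correlation to the group mean > 0.95) —
the signature of electrical pickup, which shape-diverse network bursts
do not match.

**AWFR.** Bins aligned to t = 0; a partial trailing bin is reported but
excluded from statistics; the normalization divisor is the mean count
over complete baseline bins, so the normalized baseline mean is exactly
1; zero baseline activity flags the series instead of dividing. The
focal-electrode rule makes the published post-hoc observation
operational: flag electrodes whose hypoxia-phase mean rate exceeds
baseline while the median normalized rate of the other electrodes is
below 0.75 (both thresholds configurable); global elevation therefore
never counts as focal.

**CFP.** Blocks of exactly 10,000 spikes (remainder dropped, keeping
block statistics homogeneous); active electrodes need ≥50 spikes per
block; τ grid 0.5 ms over 0–500 ms (configurable); bin k covers
(kΔ, (k+1)Δ] and the reported latency is the upper edge of the peak
bin; simultaneous spikes are not followers; autocorrelations (i = j)
are excluded. The estimator is exactly equivalent to an O(n²)
per-conditioning-spike pair counter (tested). Whether a peak counts as
a connection is an explicitly calibrated design choice, since no
acceptance rule is published for this block size: the chance level λ
(followers per bin) is estimated from the last 20% of the τ window, and
the peak's follower count must reach the Bonferroni-corrected upper
Poisson tail across all bins at pair-level α = 0.05, with an absolute
floor of 5 follower events. A fixed per-bin "mean + 3 SD" rule fails
here because the peak is a maximum over ~1000 bins: with realistic
chance rates its per-pair false-positive probability approaches 1,
whereas the corrected rule holds the measured null rate at or below the
nominal 5% (tested on independent-Poisson pairs). Detectability bound:
an edge is reliably recovered when its expected peak-bin follower count
`strength · capture · n_i` (capture ≈ 0.5–0.7 of followers landing in
one 0.5-ms bin at 0.2-ms jitter; n_i = conditioning spikes of the
source in the block) comfortably exceeds the critical count (~7 at
λ ≈ 1); with 10,000-spike blocks this means strengths ≳ 0.1 at
source rates ≳ 1 /s.

**Similarity index.** SI = |A ∩ B|²/(|A||B|) over the nonzero-strength
sets; the printed formula's typography is ambiguous, and this reading
is adopted because it lies in [0, 1] with SI = 1 iff the sets coincide.
SI is undefined (NaN, not 0) when either block has no connections;
blocks with fewer than 30 connections are excluded from SI series.
Strength normalization divides each connection by its mean over
baseline blocks (zeros included, so the baseline mean of every
normalized connection is exactly 1); connections absent from every
baseline block are flagged new rather than normalized.

**Waveform variability.** As printed, the statistic
|Σ SD·Mean/51| / max|Mean| carries signal units; cutouts are therefore
divided by the mean-waveform amplitude first, making the statistic
dimensionless and the threshold of 1 meaningful. It is invariant under
a global sign flip and zero for identical cutouts. Shape tracking uses
clock hours; hours with <5 spontaneous spikes are missing and never
break constancy by themselves; stimulation-block spikes are excluded
from shape averages when a schedule is attached; the mean correlation
of an hour is taken against *all* preceding non-missing hours
(including hypoxic ones — the alternative is not specified anywhere);
the baseline amplitude for the 80% rule is the mean hourly amplitude
over baseline-phase hours. A unit is inactive when it fired no spikes
from some complete hour to the end of the recording; the fate label
splits on whether a constancy violation preceded the silence.

**E/I classification.** Fano = sample SD (n−1) / mean of 6-s counts,
exactly as the thresholds were derived (SD, not variance). The counting
window is the baseline phase only, so classification precedes the
perturbation; the window is configurable since the original epoch is
unstated. At least 10 complete bins and a nonzero mean are required.
Fate fractions use exact rational arithmetic before rounding.

**Stimulus responses.** PSTH latency bins of 1 ms (A_syn, being a sum
over the window, is bin-width-invariant); 0–2 ms after each pulse is
blanked on all electrodes (artefacts are not modelled as spikes);
A_syn sums the per-pulse-averaged counts over the half-open window
[15, 150) ms, i.e. the expected spike count per pulse in the synaptic
phase. Normalization is per stimulation electrode to its baseline mean
with the 6-spike floor.

**Group summaries.** Mean ± SEM (n−1 SD / √n) per time bin across
replicates, with per-replicate normalization applied first; fewer than
two replicates is an error, and singleton bins are flagged. Inferential
statistics (ANOVA etc.) are intentionally out of scope — the tidy
tables feed any stats package.

## Numerical details

Bin-edge epsilons (10⁻⁹ in units of the bin) guard spikes landing
exactly on edges after floating-point subtraction, in both the CFP and
PSTH binning. CFP follower windows use strict dt > 0 and dt ≤ τ_max.
Seeds: one master seed per simulation, with independent child streams
(NumPy `SeedSequence.spawn`) for baseline spiking, cascades, and
waveform noise; identical seeds and configurations reproduce recordings
bit for bit.

## Problem sizes

The test suite and acceptance script run scaled problems chosen to
exercise every code path at meaningful statistical power: CFP oracle
equivalence on 50 random blocks of ≤2,000 spikes; planted-edge recovery
with 20 units at 2–5 spikes/s for 30 min (10 source→sink edges, follow
probabilities 0.25–0.40, so no indirect path can masquerade as a false
positive); E/I recovery with 50 units per class over a 2-h baseline
(1,200 six-second bins); detection on 10 × 60 s rendered traces; and a
1 h / 3 h / 2 h hypoxia dynamics run with 60 units and two hourly
stimulated electrodes. A full-scale default experiment (2/6/3 h) runs
through the same code paths unchanged.

## Known limitations

The connection-acceptance rule and the artefact screen are documented
substitutes for procedures the original acquisition chain delegated to
external references. The branching simulator cannot represent
subtractive inhibition of membrane potential, only spike deletion.
Fano-factor classification of real electrodes depends on the reference
distributions transferring across preparations; the package only
verifies that the arithmetic and the recovery on its own generator are
correct. The similarity index reading, while the only one that is a
proper overlap coefficient, is an interpretation.
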