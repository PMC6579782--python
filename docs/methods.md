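# Methods

`emodoc` implements an end-to-end analysis of emotional-oddball EEG in
three cohorts — healthy controls (HC), minimally conscious state (MCS) and
unresponsive wakefulness syndrome (UWS) — together with a synthetic-data
generator that emulates the study design the analyses target. This note
records the models, the defaults and why, the numerical choices, and what
the synthetic validation does and does not establish.

## Study design emulated by the generator

One block of 110 auditory stimuli: 86 neutral standards, 12 happy and 12
angry deviants, in randomized order with no two deviants in adjacent
positions, 700 ms stimuli with a 1500 ms interstimulus interval (2200 ms
onset asynchrony), recorded at 500 Hz from a standard 10-20 cap.  The two
deviant classes are always pooled into a single *emotional* condition;
happy-vs-angry contrasts are never analysed.

The deviant-position sampler uses the gap construction (choose positions
in a sequence shortened by the number of deviants, then shift), which
draws uniformly from all arrangements without adjacent deviants and is
feasible whenever `n_standard >= n_deviant - 1`.

### Signal model

Each synthetic subject is a sum of three parts, in microvolt:

1. **Background**: independent 1/f (pink) noise per channel, scaled to
   `noise_scale` RMS.  Default 10 µV — a typical broadband scalp EEG
   background.  Spatial correlation of real EEG backgrounds is *not*
   modelled; after mastoid re-referencing a common reference component
   appears, which mimics part of it.
2. **Event-related components**, identical deterministic templates added
   at every stimulus onset and scaled per condition:
   * N1 — Gaussian, peak 150 ms, width (sigma) 25 ms, frontal channels;
   * P3a — Gaussian, peak 300 ms, sigma 40 ms, frontal channels;
   * LPP — 400–1000 ms plateau with 100 ms raised-cosine ramps over the
     central and parieto-occipital rows (the late positivity is broadest
     and highest over central parieto-occipital sites).
   Amplitudes are per-component x per-condition, so group profiles are a
   table of numbers.  Trial-to-trial amplitude/latency jitter is not
   modelled; consequences below.
3. **Phase-coupled oscillation**: for each coupled channel pair, a 10 Hz
   cosine burst over the first second after each matching event.  Channel
   *a* receives a uniformly random per-trial phase, channel *b* the same
   phase plus a von Mises offset with concentration kappa.  The
   across-trial phase-locking value of the pair then tends to the mean
   resultant length of the von Mises distribution, the Bessel ratio
   I1(kappa)/I0(kappa) — 0 at kappa=0, ~0.45 at 1, ~0.70 at 2, ~0.86 at 4.
   This closed form is what makes coupling recovery testable.  Burst
   amplitude defaults to 20 µV (a realistic alpha-band burst), frequency
   to 10 Hz (inside the 0.1–30 Hz analysis band; the band in which real
   group differences would arise is unknown, so it is a parameter).

Default cohort profiles (microvolt; neutral / emotional):

| group | N1 | P3a | LPP | coupling (emotional only) |
|---|---|---|---|---|
| HC  | -3 / -4 | 2 / 2.5 | 1 / 8 | six fronto- and parieto-occipital pairs, kappa 8 |
| MCS | -3 / -4 | 2 / 5   | —     | two temporal pairs, kappa 2 |
| UWS | -2 / -4 | —       | —     | one temporal pair, kappa 0.5 |

These encode the qualitative cohort signatures the pipeline must recover:
an emotional LPP and strong emotional coupling in HC, an emotional P3a
and weak coupling in MCS, only an N1 modulation and a faint coupling in
UWS.  They are scenario definitions, not estimates of any real effect.

All generation is a pure function of the spec and a seed; per-subject
seeds derive from `SeedSequence(master, group_index, subject_index)`, so
adding subjects never changes existing ones.

## Preprocessing

Offline re-reference to the mastoid average (M1/M2), zero-phase 4th-order
Butterworth band-pass 0.1–30 Hz plus a zero-phase 50 Hz IIR notch (Q=30),
half-open [-200, 1000) ms epochs (600 samples at 500 Hz), baseline mean
of [-200, 0) ms subtracted per trial and channel.  The half-open window
convention is stated explicitly because closed-bracket notation is
ambiguous at the endpoint.  Forward-backward filtering uses reflect
padding of three high-pass time constants (min. the signal length),
because the 0.1 Hz stage has a multi-second impulse response and default
padding leaves visible edge drift.

Artifact handling is a deterministic peak-to-peak criterion (default
150 µV on any scalp channel; the original threshold is unreported) rather
than an ICA decomposition: ICA is an external algorithm with no testable
contract, whereas amplitude rejection is reproducible; a hook on
`preprocess_recording` accepts an external component-removal step.  Bad
channels are rebuilt by inverse great-circle-distance weighted averages
of the remaining scalp channels (weights normalized to sum to one) — the
standard spherical approach for 10-20 caps.

## ERP statistics

Mass-univariate paired t-tests at every (channel, timepoint) cell, with
p-values from the sign-flip permutation distribution of the same t
statistic: the exact null for exchangeable paired differences.  All 2^n
flips are enumerated when n <= 12; otherwise 1000 random flips with the
add-one estimate p = (b+1)/(m+1).  The family for FDR control is all
cells of one contrast (here 20 channels x 600 timepoints), corrected by
the Benjamini–Yekutieli step-up, which is valid under arbitrary
dependence at the price of the harmonic factor c(m) = sum 1/i.

**Known granularity ceiling.** With m = 1000 random flips the smallest
achievable p is 1/1001.  BY over N cells rejects the floor-level block
only if roughly `p_floor * N * c(N) / q` cells sit at the floor (~2390
of 12000 cells at q=0.05): a *small* cluster of cells can be maximally
significant by permutation yet never survive BY at this resolution.
Detection therefore requires spatially/temporally extended effects, more
permutations, or a smaller family.  This is a property of the prescribed
procedure, not of the implementation.

Component measures are window x channel-set mean amplitudes: N1
100–200 ms frontal, LPP 400–1000 ms parieto-occipital, P3a 250–400 ms
frontal (no standard window exists for P3a; it is configurable and the
default is a package choice).

## PLV networks

Instantaneous phase is the angle of the analytic signal (Hilbert
transform) per trial and channel.  No additional band-pass is applied by
default: the recording is already restricted to 0.1–30 Hz, and a 1.2 s
epoch cannot hold one cycle of a 0.1 Hz low edge; passing `band_hz`
explicitly enables a narrower band with that feasibility check enforced.

The PLV of a pair is the across-trial mean resultant length of the phase
difference at each timepoint, averaged over the post-stimulus 0–1000 ms
window (the pre-stimulus baseline would dilute condition effects).
Matrices are kept fully weighted; only scalp channels enter (190 edges
for the 20-channel cap).

**Finite-trial bias and trial-count matching.**  For K independent
phases E[PLV] ~ sqrt(pi)/(2 sqrt(K)), so an 86-trial neutral matrix and a
24-trial emotional matrix differ under the null purely through K.  The
pipeline therefore subsamples the standard trials (seeded, deterministic)
to the deviant count before computing condition matrices; disable with
`match_trial_counts: false`.

**Evoked phase locking.**  Deterministic stimulus-locked components
phase-lock every channel that carries them, so condition contrasts detect
many more edges than the explicitly coupled pairs — frontal and posterior
ERP topographies light up as connectivity.  This is the classic
evoked/induced confound of event-related PLV and is why the end-to-end
validation asserts the *ordering* of group mask cardinalities rather
than exact edge identities.

## Graph metrics

PLV matrices are dense and weighted, so weighted definitions are used
throughout (the original property formulas are not public; these are the
field's standard choices and are treated as assumptions):

* C — Onnela geometric-mean triangle intensity, weights normalized by
  the network maximum; nodes of degree < 2 contribute zero (delegated to
  networkx).
* L — Dijkstra shortest paths with edge length 1/w, averaged over
  unordered pairs; undefined (error) on disconnected graphs.
* Ge — Latora–Marchiori mean inverse distance; unreachable pairs
  contribute zero.
* Le — mean over nodes of Ge of the subgraph induced by the node's
  neighbours.
* sigma — (C/C_rand)/(L/L_rand) over degree-preserving double-edge-swap
  nulls with the observed weights shuffled onto the rewired edges; for
  complete graphs (every PLV > 0) no swap exists and the null reduces to
  a pure weight shuffle, which is the correct degree-preserving null
  there.  Diagonal PLV entries (trivially 1) are zeroed on conversion.

Node strength is exported as a descriptive hub indicator; no hub
threshold is asserted.

## Group inference

Per metric, a mixed 3 (group) x 2 (stimulation) ANOVA: group tested
against subject-within-group, stimulation and the interaction against
stimulation x subject-within-group, with the weighted-means sums of
squares (valid for unequal group sizes since every subject has both
conditions).  Sums of squares below 1e-12 of the total are treated as
exact zeros so that degenerate inputs yield F = 0 rather than ratios of
rounding noise.  Mauchly's W and Greenhouse–Geisser epsilon come from the
orthonormal-contrast covariance; with two conditions there is a single
contrast, sphericity holds trivially, epsilon = 1 exactly and Mauchly is
reported "not applicable".  Post hoc group contrasts are pairwise t-tests
on subject means with Bonferroni over the three comparisons; simple
effects are per-group paired t-tests with Bonferroni over groups.

Edge-wise contrasts use paired (within-group) or two-sample
(between-group) t-tests per edge with dual masks: p < 0.05 uncorrected
and p < 0.05/190 Bonferroni (family = all scalp edges of one contrast,
matching one figure panel).  The original edge statistic is unreported;
t was chosen to mirror the property-level parametrics, and a sign-flip
permutation option exists behind `method="permutation"` for paired
contrasts.

## Problem sizes used in validation

The end-to-end run uses 15 subjects per group (the study's cohort size)
with the full 110-event block at 500 Hz on a 20-scalp-channel cap; FDR
calibration uses 200 null datasets of 20 paired subjects x 200 cells;
coupling recovery uses 50 subjects per kappa in {0, 1, 2, 4} with
86-trial noiseless blocks, compared against a direct circular-statistics
Monte-Carlo of the finite-trial mean resultant length (the Bessel ratio
is its large-K limit; at kappa = 0 the finite-K expectation is
sqrt(pi)/(2 sqrt(K)), not 0, which is why the oracle is the finite-K
expectation).

## What passing tests do and do not show

The generator validates the *machinery*: exact design constants, FDR
control under the null, coupling-parameter recovery, oracle-exact graph
and ANOVA arithmetic, and recovery of a planted three-group pattern.  It
does not establish anything about real patients: templates have no
latency/amplitude jitter, noise has no true spatial structure or
artifacts beyond injected spikes, coupling is narrow-band and stationary,
and EOG physiology is absent.  Note also that the planted coupling
profiles produce strong property-level group differences, whereas the
study reported null property-level effects; the property-level ANOVA is
exercised, not expected to reproduce the study's table.
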