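# Methods

This note documents the models, conventions, and numerical choices behind
`activetouch`, in the order data flows through the pipeline. Times are in
milliseconds on a 1 kHz grid; all intervals are half-open `[start, end)`
and events on a boundary belong to the later interval; angles are degrees,
curvature is 1/mm, rates are spikes/s.

## Synthetic sessions (module `synth`)

The generator stands in for loose-seal juxtacellular recordings from L4
barrel-cortex neurons during head-fixed pole localization. One session is
one neuron over `n_trials` trials (default 160, matching the scale of
real recordings at ~115 ± 60 trials/cell). Each 5 s trial contains a
sample epoch `[1000, 3400)` ms during which the pole is in reach.

**Whisking.** Trials alternate rest and whisking bouts. Bout durations are
gamma (shape 4, mean 261 ms) — gamma for positivity and dispersion
control, the calibration target being the mean; rests are gamma (shape 2,
mean 112 ms), giving ~70% whisking duty. Each bout carries a raised-cosine
amplitude envelope (50 ms ramps), a peak-to-peak amplitude drawn gamma
(shape 9, mean 15.7°), and a carrier frequency N(15.4, 1) Hz with random
initial phase, added to a 10° setpoint. θ is otherwise noiseless; the
bandpass stage therefore sees idealized kinematics (see Limitations).

**Touches.** Candidate touch onsets are carrier protraction peaks inside
the sample epoch. Candidates are thinned binomially so that the expected
touch count per trial is 2.33 times a per-trial gamma "vigor" multiplier
(shape 2, mean 1). The multiplier produces the across-trial dispersion of
touch counts seen in real behavior (negative-binomial-like, Var = μ +
μ²/2); without it, sample-period spike counts would be artificially
regular and the condition-1 Fano factor unrealistically low. Touch
durations are gamma (shape 3, mean 30 ms, min 5 ms); overlapping contacts
keep the earlier touch. Δκ follows a linear 10 ms rise to a peak
|N(0.004, 0.0015)| 1/mm, a plateau to touch offset, then an exponential
release (τ = 5 ms). Only max |Δκ| within 0–20 ms of onset matters
downstream, so the profile shape is otherwise free. Licks occur on 80% of
touch trials at the first touch onset plus a reaction time N(367, 234) ms
(floored at 50 ms), followed by two more licks.

**Spikes.** Three labeled processes:

1. *Touch-evoked*: per touch, a count drawn Bernoulli(p) (`binomial`
   mode, the default — capping counts at one spike per touch, which is
   what strong feedforward inhibition produces in L4) or Poisson(p). The
   default p = 0.7 for first and later touches: under the binomial cap
   the attainable calibration point is the later-touch population mean
   (~0.74 spikes/touch). Spike times are onset + latency + half-normal
   jitter (defaults 8 ms and scale 2 ms). The half-normal makes the
   configured latency the *onset* of the response — the quantity the
   latency estimator measures — rather than its center.
   A log-linear link can modulate p by touch order and by z-scored
   pretouch velocity and max |Δκ|; the default gains are zero (constant
   p), since the per-touch probability is the calibration anchor.
   Feature-tuning studies enable the gains explicitly.
2. *Phase-coupled*: an inhomogeneous Poisson process with rate
   A[1 + cos(ϕ − φ_pref)] + B during whisking cycles (defaults A = 0.15,
   B = 0, φ_pref = 0).
3. *Baseline*: homogeneous Poisson at r₀ = 0.15 spk/s throughout the
   trial.

Because the baseline runs during whisking too, the recoverable modulation
depth of the whisking-epoch rate is A/(A + B + r₀) = 0.5, and this is the
value stored as ground truth. With these defaults ~70% of
exploration-epoch spikes are touch-evoked, whisking/non-whisking rates
fall near the published medians (~0.3 spk/s), and the whisking rate is
~0.02 spikes per whisk cycle — the low-rate regime in which phase
decoding is hard.

Spikes closer than the absolute refractory period (default 2.3 ms) to the
previous kept spike are deleted (forward deletion, keeping the earlier
spike — the same construction as the refractory-Poisson null). Deleted
spikes remain in the ground-truth table flagged `deleted`, so labels
partition all generated spikes. All randomness derives from
`(config.seed, trial_index, stream)` via `numpy` `SeedSequence`; identical
configs give identical sessions.

## Kinematics

θ is bandpassed 6–60 Hz with a 4th-order Butterworth applied
forward-backward (`filtfilt`): zero-phase filtering avoids group delay
between θ and spike times (the filter direction is a package choice). The
analytic signal gives phase ϕ (0 at maximum protraction, ±π at maximum
retraction — the phase origin is a package convention) and envelope.
Whisk cycles are delimited at the −π wrap; cycles with non-monotonic
unwrapped phase are flagged.

Epoch rules, applied bit-exactly:

- *whisking*: cycles with bandpassed peak-to-peak amplitude > 2.5°, minus
  touch intervals (touch has priority, keeping the epoch classes
  mutually exclusive). The 2.5° threshold is read as peak-to-peak, which
  reconciles it with the 1.25° envelope threshold below.
- *non-whisking*: runs ≥ 100 ms with envelope < 1.25°, no touch, no
  lick, and outside whisking cycles (long bout-edge cycles can dip below
  the envelope threshold mid-cycle).
- *exploration*: (whisking ∪ touches ≤ 100 ms) ∩ sample epoch; prolonged
  touches (> 100 ms) are excluded.
- *phase-valid cycles* (for tuning fits): whisking cycles with monotonic
  phase, no lick inside the cycle, and no overlap with a touch or the
  70 ms after it.

Touch features: pretouch velocity is the least-squares slope of θ over
the 5 ms ending at onset (NaN if the trial starts mid-window); max |Δκ|
is taken over `[onset, onset+20)` against the median κ of the 20 ms
before onset; the inter-contact interval (ICI) is onset minus the
previous touch's offset (∞ for first touches). Reaction time is first
lick minus first touch onset; a lick preceding the first touch yields a
negative value, returned as-is for the caller to filter.

## Spike metrics

PSTHs count spikes in bins relative to touch onsets (first/later/all
modes), normalized to spikes/s by event count and bin width. Onset
latency is the first 1 ms bin after onset whose rate strictly exceeds
the pre-touch (−50–0 ms) mean + 2 s.d. For sparse baselines that
threshold can fall below a single spike's worth of rate, so the rise must
be sustained: ≥ 2 spikes in the onset bin and ≥ 1 in the next. Cells with
completely silent baselines trigger on their first spike. The search is
capped at +50 ms; unresponsive cells return "undetermined".

Phase tuning pools phase-valid cycles across trials: spike phases by
linear interpolation of the phase series, occupancy as the time spent per
12-bin phase histogram, rates as counts/occupancy. The cosine model
A[1 + cos(ϕ − φ_pref)] + B is fitted by occupancy-weighted nonlinear
least squares (A, B ≥ 0) with 12 starts of φ_pref spread over the circle
to avoid local minima; occupancy weighting reflects the 1/occupancy
variance of a bin's rate estimate. Zero whisking time raises; zero spikes
returns depth = NaN (flagged, not fabricated). The binned fit attenuates
the amplitude by sinc(π/12) ≈ 0.989 — negligible at the tested
tolerances.

## Attribution

Exploration-epoch spikes are indexed by time since the closest preceding
touch onset. The cumulative curve y_ton(t) counts spikes within
`[onset + latency, onset + t)` on a 1 ms grid from the cell's latency to
latency + 100 ms. Chance is estimated from 1000 surrogates that
redistribute each trial's exploration spikes uniformly over that trial's
exploration epochs (support chosen to match the analysis domain).
Empirical and surrogate cumulative curves are both smoothed with a
degree-11 polynomial (domain scaled to [−1, 1] for conditioning) before
differentiation — a raw 1 ms Δy is integer-valued and would cut the
window at the first empty millisecond — and the cutoff t_on is the first
grid point where the empirical slope falls below the surrogate slopes'
95th percentile. The touch-coupled fraction is y_ton(t_on) divided by all
exploration spikes; occupancy is the windows' share of exploration time.

Residual spikes are then indexed by |time to the preferred-phase point of
their own whisk cycle| (the sample of maximal cos(ϕ − φ_pref), robust to
non-monotonic cycles, which are included here); windows truncate at cycle
margins, surrogates redistribute residuals over exploration minus the
touch windows, and the same cutoff rule yields t_w and the touch-or-phase
fraction. Touch wins ties by construction (touch windows are removed
before phase attribution). Zero touches give frac_touch = 0; zero
exploration spikes give NaN.

## Touch tuning

Per-touch counts (in the touch-coupled window, or a fixed
`[latency, latency+30)` ms fallback) are sorted by a feature — touch
order, pretouch velocity, max |Δκ| — with ties broken by chronology
(stable sort), split into 10 equal-occupancy bins (sizes differ by ≤ 1),
summarized by per-bin means with 1000-resample bootstrap 95% CIs and the
modulation index (max − min)/(max + min) (NaN for all-zero curves).
Feature covariation across cells is plain Pearson correlation of per-cell
indices (NaN against constant vectors).

## Fano analysis

FF uses the population (ddof = 0) variance, switchable via `ddof`. The
integer-count minimum at mean μ is (μ − ⌊μ⌋)(⌊μ⌋ + 1 − μ)/μ — two-point
support on the bracketing integers — reducing to 1 − μ for μ < 1 and 0
at integers; μ = 0 returns NaN (FF undefined).

Touch selection for variance analysis keeps ICI strictly > 250 ms.
Grouping z-scores (pretouch velocity, max |Δκ|), runs OPTICS
(min_samples = 10, unbounded reachability — small relative to group
size, configurable), scans all windows of N consecutive points in the
reachability ordering for the minimal sum of pairwise Euclidean
distances, takes that window as a group, removes it, and repeats to five
groups; N = max(20, 20% of the remaining points). Identical features make
every window optimal; the first is taken.

Sliding FF counts spikes in 10 ms windows at offsets 0–20 ms after
onset (1 ms steps), with binomial minima and 1000-resample bootstrap
CIs. The refractory-Poisson null draws event-aligned inhomogeneous
Poisson trains from the PSTH rate profile, applies forward refractory
deletion, and is scored identically. The five alignment conditions are:
(1) sample-period counts per trial; (2) random 38 ms windows in the
sample period, count-matched to each trial's touches (uniform placement,
overlap allowed); (3) 38 ms windows at onset + 6 ms; (4) the minimum
sliding-window FF over all ICI-filtered touches; (5) as 4 within the
five similar-touch groups, reported as the mean over groups of the
per-group minimum. Conditions 2–3 use all touches, 4–5 the ICI-filtered
set. Minima over the 21 offsets are slightly biased down (minimum of
correlated noisy estimates), and the cross-group minimum more so at
group sizes of ~20–60; the per-cell condition-5 value therefore averages
the per-group minima rather than taking their minimum.

## Decoding

Touch-aligned responses r(t) span −30 to +50 ms around onset, causally
integrated over w = 10 ms; touches with a second touch within 50 ms
post-onset are excluded. Neurons are sampled with replacement (so
populations beyond the recorded pool are valid), each contributing 1000
resampled touch responses; responses are independent across neurons by
assumption — correlated variability is out of scope.

*Presence*: at each time point, an integer threshold on the pooled count
maximizes balanced accuracy on the training half and is scored on the
held-out half (balanced accuracy chosen over raw accuracy; classes are
balanced by construction). Non-touch pools are drawn from exploration at
least 100 ms from any touch (buffer configurable). *Time since touch*:
multinomial naive Bayes (add-one smoothing) over per-neuron integrated
counts, one class per 1 ms time point in 0–50 ms, scored by RMS time
error with bootstrap bounds (default 100 runs). *Phase*: tuning curves on
120 phase bins; sampled neurons are circularly shifted to uniformize
preferred phases; two-class Poisson naive Bayes (class-conditional rates
from the binned curves, 10 ms observation window) is simulated at
candidate phase separations Δ (3° steps), and the performance is the
smallest Δ reaching 76% correct — the d′ = 1 criterion under the
equal-variance Gaussian model, Φ(1/√2) ≈ 0.76. Untuned or silent
populations never reach criterion and report the separation as
unresolvable (∞).

## Problem sizes in the test suite

The suite favors depth over bulk: parameter recovery runs 40 default
sessions (~370 touches and ~9–12 min whisking per cell) and averages
per-cell estimates across the population, because a single cell's
modulation-depth estimate at ~0.3 spk/s whisking rates carries an
irreducible s.d. of ~0.15 (near the information limit); null controls run
100 touch-independent sessions against the shuffle chance band; decoder
checks use closed-form oracles at small population sizes. The acceptance
script simulates 20,000 Poisson count draws per rate/window setting and
solves the minimum-FF linear program exactly.

## Limitations

- θ is noiseless and single-whisker; tracking error, setpoint drift, and
  multi-whisker interactions are not modeled. Filter and Hilbert edge
  effects are therefore milder than on real data.
- Touch generation (protraction-peak placement with binomial thinning) is
  a convenience model: real contact statistics depend on pole position
  and motor strategy.
- The generator's per-touch probability is constant by default; real L4
  responses adapt with touch order and scale with contact strength. The
  log-linear feature link is a deliberately simple stand-in.
- Passing recovery tests shows the estimators are calibrated *under this
  generative model*; it does not validate the model against raw cortical
  data, and population-level comparisons between recorded cell groups are
  out of scope.
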