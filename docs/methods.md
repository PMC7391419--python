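# Methods

## Scope

`perispace` implements three linked pieces of the computational study of
rapid (trial-to-trial) recalibration of peri-personal space (PPS):

1. a firing-rate neural network of visuo-tactile PPS with Hebbian
   plasticity and forgetting (`perispace.network`),
2. the psychophysical analysis of tactile reaction times (RTs) as a
   function of visuo-tactile distance and trial history
   (`perispace.psychophysics`),
3. a global-field-power (GFP) analysis of epoched multichannel EEG for
   multisensory nonlinearity and its distance/history modulation
   (`perispace.eeg`),

plus synthetic-data generators (`perispace.synth`) that produce schedules,
RT tables and evoked epochs with known ground truth so every analysis
stage can be validated end to end.

## The network model

Two 41 × 41 sheets of unisensory neurons tile a 20 × 20 cm patch of skin
(tactile, 0.5 cm spacing) and a 400 × 400 cm slab of external space
(visual, 10 cm spacing).  A single multisensory neuron stands in for a
body-part-centred PPS population.  Each neuron low-pass filters its net
input u with a first-order membrane equation,

    tau dq/dt = -q + u,        z = f(q),

where f is a logistic squashed between f_min and f_max with centre theta
and steepness r.  Unisensory net input is external drive + Mexican-hat
lateral input (difference of Gaussians over the sheet, zero-padded) +
feedback B·z_m from the multisensory neuron; the multisensory input is
u_m = Σ W_t z_t + Σ W_v z_v through the feedforward weights.

Feedforward weights are the only plastic elements.  Every update step T
(1 ms):

    ΔW = rho0 · (W_max − W) · z_pre · (z_m − theta_gate)^+  −  k_H · (W − W(0)),

i.e. gated Hebbian reinforcement whose rate vanishes at the ceiling
W_max, plus unconditional exponential forgetting toward the basal map
W(0) with rate k_H = T / tau_H.  The gate theta_gate is 5% of the
multisensory neuron's maximum activation.  Basal tactile weights are
uniform and already at their ceiling (so the tactile pathway cannot
strengthen further); basal visual weights are maximal on/near the body
and decay exponentially with the receptive field's distance from it
(decay length lambda_v), sharing their ceiling with the on-body value —
far-space visual synapses therefore have headroom, and PPS "extension" is
exactly the transient strengthening of those far synapses.

A trial presents a looming visual Gaussian approaching along the midline
at constant velocity and a tactile Gaussian at the face centre at a
scheduled onset; the network RT is the first time, from tactile onset,
at which summed tactile-sheet activity reaches P_th = 4 (a few neurons
near saturation).  Membrane state is reset to rest between trials; the
weights — the model's only cross-trial memory — are carried through the
whole session, with the stimulus-free inter-trial gap applied in closed
form (see Numerics).

### Why recalibration emerges

During and just after a touch event the multisensory neuron is strongly
active, so the visual synapses whose receptive fields the looming
stimulus is then traversing (a band just inside the probed distance) are
reinforced.  If the next trial probes a smaller disparity ("T−1 larger"),
the stimulus passes through that freshly strengthened band, activates the
multisensory neuron earlier, and the feedback pre-excites the tactile
sheet: RTs speed up at farther distances and the fitted central point
moves away from the body.  Forgetting erases the band on the time scale
tau_H, so the effect exists only when tau_H is commensurate with the
inter-touch interval (a few seconds here): much faster forgetting leaves
no memory at the next trial, much slower forgetting lets the bands
accumulate across trials until the whole trajectory saturates and the
distance gradient — the PPS itself — collapses.  With the shipped
defaults these three regimes are expressed at tau_H = 1 s (no
recalibration, intact gradient), 4 s (recalibration), and 60 s (flat
gradient), as computed by the sweep test; the boundaries sit higher than
the 2 s / 7.5 s values the three-regime narrative is usually quoted with,
which is expected since they trade off against the learning-rate scale.

### Parameters

All parameters live in `NetworkConfig` (YAML-serialisable; the shipped
default is registered as "reference-default").  The values are this package's
own calibrated operating point — the upstream model's inherited parameter
table is not public — chosen once to satisfy the qualitative constraints:
a sigmoidal RT-distance curve with its central point inside the probed
55–175 cm range at 75 cm/s, distance-independent unisensory RTs, and
history recalibration of a few cm at tau_H = 4 s.

| parameter | default | meaning |
|---|---|---|
| tau (all populations) | 20 ms | membrane time constant |
| f_min, f_max | 0, 1 | activation bounds (firing-rate units) |
| theta, r (unisensory) | 12, 2.0 | activation centre / steepness |
| theta, r (multisensory) | 12, 0.37 | shallow, so activation is graded over the probed distances |
| lateral kernel | 1.2·G(1) − 0.6·G(4) (index units) | near excitation, far inhibition |
| W0_t (= ceiling) | 2.2 | uniform tactile feedforward |
| W0_v (= ceiling), lambda_v | 26, 70 cm | on-body visual feedforward and decay length |
| B0_t, B0_v | 6, 2 | feedback, same spatial pattern as basal feedforward |
| rho0 (both modalities) | 2.4e-4 /ms | Hebbian rate scale (several trials to saturate a band) |
| gate theta_gate | 0.05 · f_max | postsynaptic learning gate |
| tau_H | 4 s | forgetting time constant (k_H = 1/tau_H per 1-ms step) |
| tactile stimulus | amp 14, sigma 1 cm, 300 ms | just suprathreshold; ~10 neurons recruited |
| visual stimulus | amp 20, sigma 5 cm, looming 200 cm → 0 | filtered by 8-cm visual receptive fields |
| P_th | 4 | detection threshold on summed tactile activity |
| post window | 500 ms | simulated time past tactile onset (RT timeout horizon) |
| inter-trial gap | 2 s | stimulus-free; forgetting only |

The multisensory steepness, W0_v and lambda_v jointly place the
activation transition: at tactile onset the multisensory activity is
≈1.0/0.97/0.55/0.26/0.10/0.06 across the six probed distances, which is
what makes the RT curve sigmoidal rather than merely concave.

### Numerics

* Explicit Euler, fixed dt = 1 ms.  Stability is enforced by requiring
  tau ≥ 5 dt at configuration time.
* The Mexican-hat convolution is separable; it is evaluated as two
  banded-matrix products per Gaussian (`G z G`), truncated at 4 sigma,
  with zero padding at the sheet edges.
* RTs are decoded at the 1-ms step resolution; trials that never reach
  P_th within the post window return NaN and are counted as timeouts.
* Stimulus-free gaps are not stepped: with the network at rest the
  Hebbian rule reduces to (W − W(0)) ← (1 − k_H)(W − W(0)) per step, so
  the gap is applied as the exact closed-form power.  A unit test checks
  the stepped and closed-form paths agree to machine precision.
* All dynamics are deterministic; randomness enters only through the
  seeded permutation of the trial schedule (and the unisensory-trial
  onset draws), so identical seeds give bit-identical RT tables.

## RT psychophysics

Condition-mean RTs are fitted with the logistic

    y(x) = (y_min + y_max e^{(x−x_c)/b}) / (1 + e^{(x−x_c)/b}),

so y rises from y_min (near) to y_max (far); x is oriented with larger
values = larger visuo-tactile disparity.  x_c is the PPS central point,
b the transition scale (larger b = shallower).  Fitting is trust-region
nonlinear least squares on the condition means (per-trial fitting is
exposed but non-default), initialised from the data range with bounds
b ∈ (1e-3, 100] level-spacings and x_c within the probed range ± 2
levels.  Non-convergence is flagged with an R² of −inf; subjects are
discarded when any of their pooled/smaller/larger fits has R² < 0.50.

History splitting labels each trial by the immediately preceding trial's
disparity (smaller / larger), excluding trials preceded by the same
distance or by a trial without a disparity (catch, and tactile-only in
the static design), and excluding current trials at the extreme smallest
or largest level, which have no smaller/larger counterpart.  The rapid
recalibration index is x_c(larger) − x_c(smaller).

Because the split curves only span the interior levels (4–5 points), a
free four-parameter fit leaves the central point essentially
unidentified — in simulation its estimate drifts to the box bounds and
the recalibration index picks up ±25 cm excursions with no change in the
generative truth.  `history_split_fits` (and the network session
analysis) therefore anchor the split fits' asymptotes to the pooled fit
and re-estimate only (x_c, b).  Under the synthetic generator this
reduces the null spread of the index by ~4× and recovers injected shifts
of 0.3–1.0 levels with 6–9% bias at the static-design trial counts.

The trial-history GLM regresses RT on the disparity at lags 0..9 with a
gamma family and canonical inverse link (delegated to statsmodels),
main effects only; the per-lag influence is summarised as the ratio of
each lag's coefficient to the lag-0 coefficient.

## EEG global field power

GFP at each time point is the standard deviation of the trial-averaged
voltages across the montage, population form (denominator N channels) —
fixed, documented, and reference-independent.  The pipeline: amplitude
rejection at ±100 µV (the threshold is read in µV, a physiologically
meaningful EEG bound), nearest-neighbour bad-channel interpolation on the
unit sphere, per-channel baseline subtraction over −200..0 ms, then
average reference.  Band-pass (0.1–40 Hz) and 60-Hz notch filtering are
thin zero-phase scipy.signal delegations.

Multisensory nonlinearity is tested by contrasting the GFP of the paired
visuo-tactile average with the GFP of the channel-wise sum of the
unisensory averages.  Time-resolved one-sample t-tests (two-sided by
default; sidedness configurable) are thresholded at alpha = 0.01 and
only runs of ≥ 10 consecutive samples are reported as windows — on white
noise this run criterion pushes the family-wise false-window rate below
2% (measured over 150 replicates in the test suite), far under the
per-point alpha.  Window statistics average GFP over a fixed
poststimulus window (default 130–150 ms) per subject and condition;
repeated-measures ANOVAs and pairwise tests are delegated to pingouin.
A seeded trial-subsampling helper provides the count-matched control for
the paired-vs-summed trial-count imbalance.  Note that with unequal
noise levels the GFP of a noisier average is biased upward, which is
exactly why the additive null is only exactly null when the paired
response is constructed channel-wise from the same averages — the test
suite does so — and why the count-matched control exists.

## Synthetic data

The generators encode the two behavioural designs exactly: the looming
design (fixation 1.2 s, motion onset +0.3 s, 200 cm start, 75 cm/s,
tactile offsets 1.83–3.43 s ⇒ disparities 55.25–175.25 cm, 36/8/36
experimental/baseline/catch repetitions, 300 trials) and the static
design (7 distances 3.3–62.9 cm, 40 VT per distance + 10 V at the five
interior distances + 30 T per 360-trial block, ITI uniform 1250–2250 ms).

RTs are drawn from a gamma distribution (CV 0.2 by default — a typical
simple-RT dispersion, an assumption rather than a reported value) around
a distance sigmoid whose central point is shifted ±delta/2 by the
preceding trial's disparity, so the pooled curve sits between the split
curves.  Tactile-only RTs are distance-independent and slower.  Evoked
epochs are rank-one signals (fixed zero-mean channel topography × a
canonical post-onset waveform) plus white channel noise; the paired
response is the channel-wise sum of the unisensory signals scaled by a
gain inside a configurable window (default 124–158 ms), with gain 1
reducing exactly to the additive model.

What the generators do **not** emulate: realistic EEG spectra and
artefacts, RT sequential dependencies beyond lag 1, motor/launch-time
components of human RTs, or attention/expectancy effects.  Passing tests
therefore validate the analysis machinery and the model's mechanism, not
claims about any particular empirical dataset.

## Known limitations

* The network's RT scale (tens of ms) is threshold-crossing time and
  does not include motor latency; comparisons are meaningful for
  differences and shapes, not absolute human RTs.
* The velocity dependence of the PPS boundary reported for looming
  paradigms is driven by firing-rate adaptation in the lineage of this
  model; adaptation is outside this package's equations, and with the
  shipped defaults the pooled central point does not grow with velocity
  (it mildly shrinks), although the recalibration effect is absent at
  25 cm/s and clearly present at 75 cm/s, as expected.
* The tau_H regime boundaries depend on the calibrated learning-rate
  scale; only the three-regime structure, not the particular boundary
  values, should be read as the model's prediction.
* Central-point recovery from a single subject at 36 repetitions per
  condition under CV-0.2 RT noise is limited to ~0.5 distance levels
  (median); subject-level QC and the much larger static-design counts
  are what make the split analyses informative.
* Simulated sessions in the tests and the acceptance script use 20
  trials per condition and 3 session replicates, the package's chosen
  problem size for a single-workstation run.
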