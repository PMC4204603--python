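# Methods

## The model

`satnet` simulates and analyses the two-variable mean-field reduction of a
biophysically based cortical decision network (the Wong–Wang reduced model).
Two populations, selective for the two alternatives of a random-dot-motion
(RDM) discrimination, are each described by a slow NMDA-type synaptic gating
variable `S_i ∈ [0, 1]`:

    dS_i/dt = -S_i/τ_S + (1 - S_i) · γ · H(x_i)

    H(x)    = (a·x - b) / (1 - exp(-d·(a·x - b)))          (rate, Hz)

    x_1     = J_self·S_1 - J_cross·S_2 + I_0 + I_stim,1 + I_noise,1
    x_2     = J_self·S_2 - J_cross·S_1 + I_0 + I_stim,2 + I_noise,2

`H` is the effective frequency–current curve of a population of spiking
neurons (with the removable singularity at `a·x = b` filled by its limit
`1/d`), `J_self > 0` is effective recurrent self-excitation, and
`J_cross > 0` effective cross-inhibition via a shared inhibitory pool. The
stimulus at motion coherence `c` (percent) drives the two populations
asymmetrically,

    I_stim,1 = J_ext·μ_0·(1 + c/100),   I_stim,2 = J_ext·μ_0·(1 - c/100),

so population 1 is the *target* and population 2 the *distractor*. The
background current `I_0` is spatially nonselective — identical for both
populations — and is the study's experimental knob: accuracy (316 pA) <
neutral (321 pA) < speed (325 pA). Each population additionally receives an
independent Ornstein–Uhlenbeck noise current with correlation time
`τ_noise` and stationary standard deviation `σ_noise`.

### Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| a, b, d | f–I curve gain / offset / curvature | 270, 108, 0.154 | Hz/nA, Hz, s |
| γ | rate→gating coupling | 0.641 | – |
| τ_S | gating (NMDA) time constant | 100 | ms |
| τ_noise | noise correlation time | 2 | ms |
| J_self, J_cross | recurrent couplings | 0.2609, 0.0497 | nA |
| J_ext | stimulus scaling | 5.2·10⁻⁴ | nA/Hz |
| μ_0 | stimulus reference rate | 30 | Hz |
| I_0 | nonselective background current | 0.316–0.325 | nA |
| σ_noise | noise-current std | 0.02 | nA |
| θ | choice threshold on firing rate | 15 | Hz |

These are the canonical published values of the reduced model; only `I_0`
(and, configurably, `σ_noise`) varies across conditions. Time is kept in ms
internally, rates in Hz (scaled by 10⁻³ where they enter `dS/dt`), currents
in nA; configuration files accept `I_0` in pA.

## Trial simulation

A trial is 2.5 s of pre-stimulus followed by 5 s of stimulus, integrated by
Euler–Maruyama at `dt = 0.1 ms` (a 0.5 ms fast mode is used in smoke
tests; it coarsens decision-time statistics slightly but preserves all
orderings). `S` is clipped to `[0, 1]` after each step because the explicit
scheme can overshoot the invariant interval by O(dt). The noise current
update is

    I ← I·(1 - dt/τ_noise) + σ_noise·√(1 - (1 - dt/τ_noise)²)·ξ,

whose stationary law is *exactly* mean 0 / std `σ_noise` (the innovation
amplitude equals the familiar `σ√(2dt/τ)` to first order in `dt`; the exact
form avoids a ~1% std bias at `dt/τ = 0.05`). Noise is initialized at its
stationary distribution, so there is no burn-in transient.

A choice is registered at the first step during the stimulus epoch at which
either population's instantaneous rate `r_i = H(x_i)` (noise included)
reaches the choice threshold `θ = 15 Hz`; integration nevertheless
continues to stimulus end so full-length traces are available for paired
threshold re-detection and observer analyses. An optional sustained-crossing
requirement (`k` consecutive steps above `θ`, default `k = 1`, i.e. off)
can damp noise-spike artifacts. Trials with no crossing are *undecided*:
excluded from accuracy and decision-time summaries and counted separately.
At `c = 0` "correct" is defined as choosing population 1, giving ≈50%
accuracy by symmetry. Baseline activity is the mean of `(r_1 + r_2)/2` over
the last 1000 ms of the pre-stimulus epoch. Trial-averaged traces use
correct trials only, at 10 ms output resolution (raw averaging, no
smoothing).

Randomness: every trial owns a generator seeded from
`(master_seed, condition index, coherence index, trial index)`, so a batch
is reproducible bit-for-bit and any single trial can be re-run in
isolation; the two populations' streams come interleaved from the trial's
generator and are independent.

## Phase-plane analysis

All dynamical analysis is noise-free. Fixed points are found by damped
Newton refinement (`scipy.optimize.root` with the analytic Jacobian) from a
21×21 lattice of initial guesses, certified by drift norm < 10⁻⁹ ms⁻¹,
deduplicated within 10⁻⁶ and classified by the Jacobian's eigenvalues. In
the study regime every stimulus-on cell is bistable: two choice attractors
separated by one saddle. The *effective time constant of integration* is
`τ_eff = 1/λ₊`, the reciprocal of the saddle's positive eigenvalue — the
time scale over which the network is repelled from the saddle toward a
choice.

Manifolds are integrated in arclength parameterization (`dS/dl = ±f/‖f‖`,
RK45, rtol 10⁻⁸) from the saddle displaced by `ε = 10⁻⁴` along the
corresponding eigenvector: the unstable manifold forward until the drift
norm certifies arrival at an attractor, the stable manifold in backward
time until it leaves `[0, 1]²` (truncated and flagged — the basin boundary
genuinely exits the physical domain). Branches are resampled to ~800
points. The *initial state* is the across-trial mean gating state at the
end of the pre-stimulus epoch, mapped to rate coordinates under the same
stimulus-on currents as the manifolds (the framing is that stimulus onset
drops the resting state onto the new landscape; the gating state itself is
identical under either mapping and both are exported). Its distance to the
stable manifold is the minimal point-to-segment distance over the polyline
in rate space (Hz), matching the coordinates in which the geometry is
usually drawn.

## Behavioral analysis

Accuracy vs coherence is fit per condition with a Weibull function
`P(c) = 0.5 + 0.5(1 - exp(-(c/α)^β))` by binomial maximum likelihood
(Nelder–Mead on log-parameters, three shape initializations); the 75%
threshold is `c75 = α·(ln 2)^{1/β}`. No coherences are excluded; `c = 0`
contributes its ≈50% cell.

The threshold-compensation experiment re-detects choices from the stored
10 ms traces for every threshold in a grid (default 9–21 Hz in 1 Hz steps,
bracketing θ = 15 Hz). This paired design — the same trials under every
threshold — removes between-threshold Monte-Carlo variance: raising θ can
only delay a decision or turn it undecided. The speed condition is
additionally evaluated at `θ + Δ_ns` and the accuracy condition at
`θ - Δ_na`, where `Δ_ns`/`Δ_na` are the measured baseline differences
(speed − neutral, neutral − accuracy). The summary statistic is the
fraction of each condition-to-neutral gap (in c75 and in mean decision time
at c = 1% and 32%, correct and error trials pooled) closed by the
adjustment. Cells in which more than 5% of trials cross θ before stimulus
onset are flagged as broken down rather than silently included.

## Ideal-observer analysis

At each 10 ms bin of the stimulus epoch the across-trial distribution of
target rates is compared with the distribution of distractor rates by the
ROC area (Mann–Whitney, ties counted half), using all trials of a cell.
The discrimination time is the first bin at which AUC ≥ 0.75 holds for 3
consecutive bins (both knobs configurable; they are reconstructions of a
standard target-selection criterion, not published values). The reported
rate is the mean target rate at that bin; the discrimination–baseline
difference subtracts the condition's mean baseline rate. The pooled
("across all positive coherences") variant is the unweighted mean over
coherences of each coherence's own rate-at-discrimination. The alternative
per-trial reading takes the last intersection of 50 ms moving-average
smoothed traces (smoothing suppresses spurious micro-crossings from the
2 ms-correlated noise); the implied choice is the population ahead after
the last crossing.

## What the generator emulates — and what it does not

All inputs are synthetic by construction: the OU noise and stimulus
schedule *are* the study's stimulus model, not a stand-in for recorded
data. The model omits everything upstream of the integrator circuit (no
MT-like sensory populations, no motor/non-decision time, no trial-history
effects), uses perfectly symmetric couplings, and represents each
population by a single rate. Passing tests therefore certify properties of
the model and analyses, not of biological recordings: e.g. the prediction
that errors are slower than correct decisions is a known attractor-model
signature that some empirical paradigms violate.

## Numerical choices and known limitations

- Problem sizes: the stochastic test suite uses 1000 trials/cell over
  coherences {0, 1, 2, 4, 8, 16, 32}% at dt = 0.1 ms; the acceptance
  script uses 400 trials/cell. Orderings are stable at these sizes; exact
  decision-time means retain Monte-Carlo error of a few ms.
- Threshold detection on the instantaneous noisy rate makes the speed
  condition's crossings partly noise-driven (its saddle rate ~11 Hz lies
  within ~1.2 rate-noise SDs of θ), which compresses the error-vs-correct
  decision-time asymmetry there; the error-slower signature is robust in
  the neutral and accuracy conditions and in sign at intermediate
  coherence.
- Re-detection for the threshold sweep reads 10 ms samples, so sweep
  decision times are quantized to 10 ms; first-crossing times from
  subsampled traces can differ slightly from the in-simulation 0.1 ms
  detection. Both adjusted and unadjusted sweep entries share this
  convention, so paired comparisons are unaffected.
- The per-condition noise std is not separately specified by the study
  conditions; it defaults to 0.02 nA for all three conditions and is
  configurable per condition.
- Weibull fit failures (degenerate accuracy data) raise a diagnostic error
  in direct use and are flagged (`fit_ok = False`) inside the sweep.
- Fixed-point search assumes ≤ 5 fixed points (true throughout the study
  grid); no continuation/bifurcation tracking across continuous `I_0`
  sweeps is attempted.
- The rise of saddle rates with `I_0` holds coordinate-wise at low and
  intermediate coherence (where the geometry argument lives); at c = 32%
  the distractor-side saddle rate of the accuracy condition slightly
  exceeds neutral's. The effective-time-constant ordering holds at every
  coherence in the study grid.
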