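# Methods

## Task and design

The simulated experiment shows a ball flying along a fronto-parallel
parabola 6.15 m from the observer, launched with vertical velocity 4.5 or
6 m/s and horizontal velocity 3 or 4 m/s under gravity 0.7g, 0.85g, 1g,
1.15g, 1.3g or inverted −1g. The ball disappears at 50–55 % (Long
occlusion) or 75–80 % (Short occlusion) of its flight time and the observer
times its unseen return to launch height. The default design is four
blocks: three blocks crossing the five positive gravities × 2 vyi × 2 vxi ×
2 occlusion classes at 8 repetitions (320 trials each), and one block with
{1g, −1g} at 24 repetitions (384 trials), 1344 trials in total
(`stimulus_design.build_design`). Occlusion fractions are drawn uniformly
within the class window per trial; a deterministic midpoint mode
(0.525/0.775) is used for mean-model predictions and sweeps.

Trajectories are available drag-free (closed form) and with linear drag
(`F = −c·v`, m = 0.057 kg, c = 0.005 kg/s, time constant m/c = 11.4 s).
Flight-time differences between the two are at most a few hundredths of a
second on this grid, so the prediction model and the synthetic generator
default to the ballistic form; the drag solution is retained for generating
"true" kinematics and is verified against direct ODE integration in the
tests. Inverted-gravity trials are mirrored vertically so every downstream
quantity is sign-agnostic.

## Coordinate conventions

Trajectory generation uses launch height = 0 with upward positive. The
post-disappearance prediction problem uses a downward-positive local frame:
`dy` is the remaining drop and `vy` the downward speed, so the remaining
flight time solves `dy = g/2·t² + vy·t`. Conversion between frames is a
single sign flip, asserted by tests. The tangential-to-vertical angle is
`α = arccos(vy/vtan)` (90° at the apex); the vertical speed percept is
reconstructed as `cos(α_perceived)·vtan_perceived`.

## Noise parameters

| parameter | meaning | default | origin |
|---|---|---|---|
| `af_factor` | Aubert–Fleischl bias on pursued-target speed | 0.8 | pursuit literature |
| `sd_vtan_rel` | standardized SD of perceived tangential speed | 0.148 | 10 % Weber fraction |
| `sd_alpha` | additive SD of perceived angle (rad) | 0.089 | ~6° orientation JND |
| `sd_dy_rel` | standardized SD of perceived remaining drop | 0.148 | 2 × 5 % distance Weber fraction |
| `g_prior_mean` | mean represented gravity (m/s²) | 9.81 | fixed |
| `sd_g_rel` | standardized SD of represented gravity | 0.208 (fitted) | free parameter |
| `sd_g_rel_inverted` | same, −1g trials | 0.295 | 20 % Weber fraction |
| `sd_motor` | additive motor SD (s) | 0.058 (fitted) | free parameter |

Weber fractions are converted at the 75 % discrimination point:
`SD = w / Φ⁻¹(0.75)`. This rule reproduces 0.148 for w = 0.10 exactly. Note
two documented mismatches in the published constants: 0.20/Φ⁻¹(0.75) is
0.2965 while the embedded default is the printed 0.295, and 0.089 rad is
not the image of a 6° JND under the same rule (that would be 0.155 rad ≈
8.9°). The printed constants are used as defaults; the conversion helpers
implement the exact rule. Standardized SDs act multiplicatively
(constant-Weber-fraction assumption); angle noise is additive in radians.

## Generative model and guards

Per trial: `vtan_p ~ N(0.8·vtan, 0.148·0.8·vtan)`, `α_p ~ N(α, 0.089)`,
`vy_p = max(cos(α_p)·vtan_p, 0)`, `dy_p ~ N(dy, 0.148·dy)`,
`g_p ~ N(9.81, sd_g_rel·9.81)`, response = ballistic root + `N(0,
sd_motor)`. The AF factor is applied to the tangential speed before the
angle decomposition, so the vertical-speed percept inherits it. Draws that
violate positivity (g ≤ 0 at ~3.4σ when `sd_g_rel = 0.295`; dy or vtan < 0
only beyond 6σ) are resampled up to 8 times and then clamped; `vy_p < 0`
(angle noise flipping `cos` near the apex) is clamped at zero. All guard
counts are surfaced via `SimDiagnostics` so the choices are auditable.

## Objectives and common random numbers

`simulated_sd_table` simulates `n_datasets` replicates of a trial set,
computes each cell's per-replicate sample SD — cells are
gravity × vyi × occlusion (× participant), collapsed across horizontal
velocity — and averages across replicates. Because every call draws one
block of standard normals from a fixed seed, the table is an exact,
smooth, deterministic function of the noise parameters. Consequently the
RMSE objective evaluates to exactly zero at the generating parameters under
shared seeds, and 1-D bounded searches and Nelder–Mead run on a noiseless
surface. Using the per-replicate sample SD (same n per cell as the observed
tables) means the small-sample bias of the SD estimator cancels between
simulated and observed sides. Fits run on the absolute-error SD scale and
report the error-ratio scale alongside; cells are unweighted (weighting is
configurable in principle but not exposed, as nothing suggested the original
analysis weighted cells).

Numerical choices: bounded scalar searches use Brent-style minimization
with `xatol = 1e-4`; Nelder–Mead uses `xatol = 1e-3`, `fatol = 1e-4` and a
200-evaluation cap, started at (0.04 s, 0.2) with no bounds — negative
simplex proposals are reflected through their absolute value before
entering the simulator, which is inert at the (interior, positive) optimum.
The Method 1 coarse grid spans 0–0.28 in steps of 0.03; a warning is issued
if its minimum falls outside the refinement bounds [0.16, 0.26].

## Synthetic studies and recovery

`generate_study` composes the design with the generative model for 9
participants, each with independently sampled occlusion fractions and
noise draws derived from one master seed, and a lognormal multiplier
(CV 0.10, zeroable) on the motor SD as mild between-participant
heterogeneity — an invention needed to make participant-stratified fitting
meaningful, since the original analysis fits per participant but reports no
participant-level parameter spread. Exclusions drop responses before
disappearance and absolute errors above 2 s (interpreted in seconds, per
the rule's units; early responses are covered by the first rule).

The recovery pipeline per replicate: generate → exclude → per-participant
condition SDs → motor fit on the −1g cells (with `sd_g_rel_inverted`
fixed at 0.295) → Method 1 with the recovered motor SD → Method 2. At the
fitted truth values (0.058 s, 0.208) and 100 simulated replicates per
objective evaluation, median recovery errors are a few thousandths on both
parameters — well inside the ±0.01 s and ±0.03 tolerances the tests
assert. Reduced problem sizes (100 objective replicates rather than 1000,
5–10 recovery replicates) are the package's default operating point; both
are parameters.

## What the generator does and does not emulate

It reproduces the design geometry, the multiplicative/additive noise
structure, a strong earth-gravity prior with configurable spread, motor
noise and the exclusion rules. It does not emulate lapses, saccade
interference, learning or trial-order effects, between-participant mean
biases, or eye-movement dynamics. Two consequences, visible in the
adequacy smoke test:

- Synthetic exclusion rates are far below the ~1.6 % observed in real
  data — Gaussian noise at the fitted levels produces almost no |error| > 2 s
  trials; real participants have heavier tails.
- Published pooled per-cell SDs include between-participant mean offsets
  that the generator keeps mild, so synthetic pooled SDs sit below them;
  the adequacy test checks synthetic SDs do not *exceed* the published
  pooled values, and that the ratio-SD ordering across gravities
  (increasing with g) matches the published mixed-model pattern. Cell
  means are checked within ±0.35 (the deterministic mean model deviates
  from the observed means by up to ~0.3 in Short cells; the −1g means are
  excluded because the late bias observed there is outside the model's
  scope).

Passing tests therefore validate the pipeline's internal consistency and
estimator behavior, not the adequacy of the generative model for every
feature of real data.

## Known limitations

- The prior's SD estimate is a point fit; no bootstrap or posterior
  uncertainty is computed.
- The analytic inversion for g (solving the prediction equation for the
  represented gravity) is implemented only as a round-trip consistency
  check; propagating distributions through the quotient has no closed form,
  which is why the simulation route exists.
- The AF factor is fixed at 0.8, not fitted.
- Mean-model RMSEs against the packaged aggregate condition means differ
  somewhat from values computed on raw per-participant data (which also
  include participant-level spread); only the ordering and approximate
  magnitudes are expected to match, and that is what the tests assert.
- The display-latency constant (0.049259 s) is applied only when ingesting
  real response tables, never in synthesis.
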