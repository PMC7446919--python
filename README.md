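# gravityprior

Humans predict the motion of falling objects as if they carry an internal
model of earth gravity — in Bayesian terms, a *strong prior* on g so precise
that it overrides conflicting sensory evidence. `gravityprior` implements a
simulation pipeline that characterizes this prior from a coincidence-timing
task: observers watch a ball fly along a parabola under one of several
gravity levels (0.7g–1.3g, or inverted −1g), the ball disappears partway
through its flight, and they press a button when it would have returned to
launch height. From the timing errors the pipeline estimates both the
**mean** and the **standard deviation** of the gravity prior.

It is intended for researchers in computational psychophysics who want to
reproduce, probe or extend this style of noise-budget modelling, including
full synthetic-data parameter recovery.

## The model

**Mean.** At disappearance the observer knows the remaining drop `d_y` and
the downward speed `v_y`. Extrapolating with a fixed internal gravity
`g = 9.81 m/s²`, the predicted remaining flight time is the positive root of
`d_y = g/2·t² + v_y·t`:

    t = (−v_y + √(v_y² + 2·g·d_y)) / g

Because observers pursue the ball with their eyes, the Aubert–Fleischl
phenomenon makes it appear ~20 % slower than it is; the AF variant uses
`v_y,perceived = 0.8·v_y`. This lengthens predictions most when `v_y` is
large (short occlusions, disappearance well after the apex) and captures the
late bias observed there.

**Standard deviation.** Response variability is decomposed into perceptual,
representational and motor sources. Perceived quantities carry
multiplicative noise with standardized SDs derived from Weber fractions
(`SD = w / Φ⁻¹(0.75)`; a 10 % Weber fraction ⇒ 0.148), the perceived
tangential-to-vertical angle carries additive noise (SD 0.089 rad), the
vertical speed is recovered as `v_y = cos(α)·v_tan`, and the represented
gravity is drawn from `N(9.81, σ_g,rel·9.81)`. Monte-Carlo simulation of
whole datasets, with common random numbers, yields model-implied per-cell
response SDs; the free parameters are fitted by minimizing the RMSE against
observed per-cell SDs:

1. **Motor SD** — from inverted-gravity (−1g) trials, where the earth-gravity
   representation is assumed inactive and the acceleration is represented
   like an arbitrary one (20 % Weber fraction ⇒ standardized SD 0.295);
   bounded 1-D search on [0.01, 0.06] s.
2. **Method 1** — with the motor SD fixed, a coarse grid plus a bounded 1-D
   search on [0.16, 0.26] for the prior's standardized SD.
3. **Method 2** — a joint, unbounded Nelder–Mead fit of both parameters,
   identifiable because motor noise lifts all conditions uniformly while
   gravity noise disproportionately inflates long extrapolations.

## Worked example

```python
import gravityprior as gp
from gravityprior.noise_calibration import NoiseConfig

# 1. a 10% Weber fraction as a standardized SD
print("standardized SD for a 10% Weber fraction:", round(gp.weber_to_sd(0.10), 3))

# 2. AF vs no-AF mean model against the packaged condition means
obs = gp.table1_fixture()
report = gp.compare_af_models(obs[obs["block"] == "main"])
print(report.round(3).to_string(index=False))

# 3. one synthetic study at the published fitted parameters, re-estimated
truth = NoiseConfig(sd_motor=0.058, sd_g_rel=0.208)
estimates, summary = gp.recovery_experiment(truth=truth, n_replicates=1,
                                            n_datasets=100, seed=7)
print("recovered motor SD: %.3f s" % summary["median_sd_motor"])
print("recovered prior SD (Method 1): %.3f  -> %.2f m/s^2"
      % (summary["median_sd_g_rel_method1"],
         gp.standardized_to_absolute(summary["median_sd_g_rel_method1"])))
```

prints

```
standardized SD for a 10% Weber fraction: 0.148
occlusion_class  vyi  rmse_af  rmse_noaf winner
           Long  4.5    0.194      0.204     AF
           Long  6.0    0.175      0.185     AF
          Short  4.5    0.251      0.370     AF
          Short  6.0    0.273      0.392     AF
        overall  NaN    0.227      0.303     AF
recovered motor SD: 0.059 s
recovered prior SD (Method 1): 0.203  -> 1.99 m/s^2
```

Reading the output: the AF-corrected mean model fits the observed condition
means better everywhere, and by a wide margin for short occlusions — the
signature of pursuit-driven speed underestimation. The recovery run
generates a full synthetic study (9 participants × 1344 trials) at known
parameters and re-estimates them through the whole pipeline; the recovered
motor SD (0.059 s) and prior SD (standardized 0.203, i.e. ≈2 m/s², a Weber
fraction of ~14 %) return the generating values.

A thin CLI mirrors the library: `gravityprior design`, `synth`, `simulate`,
`sweep`, `predict`, `compare-af`, `fit-motor`, `fit-method1`, `fit-method2`,
`recover` (all seeded; see `gravityprior --help`).

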