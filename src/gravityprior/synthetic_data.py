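"""Synthetic study generation, exclusion rules and the published summary
fixture.

``generate_study`` composes the design enumeration and the generative
response model into a full 9-participant, 4-block, 1344-trials-per-
participant dataset with known ground-truth parameters, so the whole
estimation pipeline can be exercised and validated (parameter recovery)
without any external download.  Between-participant heterogeneity is
modelled as a lognormal multiplier on the motor SD (coefficient of
variation configurable, default 0.10, zeroable); the published study fits
per participant but reports no participant-level parameter spread, so this
is deliberately mild plumbing rather than an empirical claim.

``apply_exclusions`` reproduces the study's trial filters: responses before
target disappearance, and absolute temporal errors above 2 s.

``table1_fixture`` packages the published per-condition means and SDs of
the error ratio (typed constants) for use as an aggregate observed table
when the raw per-participant data are not available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import (
    GravityPriorSDEstimator,
    JointNoiseEstimator,
    MotorSDEstimator,
)
from .noise_calibration import NoiseConfig
from .response_simulator import condition_sds, simulate_responses
from .stimulus_design import build_design, trial_table


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Ground-truth configuration of a synthetic study."""

    n_participants: int = 9
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    between_participant_cv: float = 0.10
    master_seed: int = 0
    exclusion_threshold: float = 2.0
    repetitions_main: int = 8
    repetitions_inverted: int = 24
    trajectory_model: str = "ballistic"

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.between_participant_cv < 0:
            raise ValueError("between_participant_cv must be >= 0")


def generate_study(cfg: SyntheticStudyConfig) -> tuple[pd.DataFrame, dict]:
    """One row per trial per participant over the full design.

    Occlusion fractions are drawn uniformly within each trial's window, and
    every participant receives an independent presentation (fractions and
    noise draws) derived deterministically from ``master_seed``.  Returns
    the response table and a metadata dict recording the ground truth.
    """
    design = build_design(cfg.repetitions_main, cfg.repetitions_inverted)
    root = np.random.SeedSequence(cfg.master_seed)
    participant_seeds = root.spawn(cfg.n_participants + 1)
    rng_between = np.random.default_rng(participant_seeds[-1])
    cv = cfg.between_participant_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        multipliers = rng_between.lognormal(-0.5 * sigma**2, sigma, cfg.n_participants)
    else:
        multipliers = np.ones(cfg.n_participants)

    frames = []
    for p in range(cfg.n_participants):
        rng = np.random.default_rng(participant_seeds[p])
        trials = trial_table(
            design, fractions="uniform", seed=rng, model=cfg.trajectory_model
        )
        resp = simulate_responses(
            trials,
            cfg.noise,
            n_datasets=1,
            seed=rng,
            sd_motor=cfg.noise.sd_motor * multipliers[p],
        )[0]
        df = trials.copy()
        df.insert(0, "participant", p + 1)
        df["response_time"] = resp
        df["temporal_error"] = resp - df["t_occluded"]
        df["error_ratio"] = resp / df["t_occluded"]
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    meta = {
        "truth": cfg.noise.to_dict(),
        "motor_multipliers": multipliers.tolist(),
        "n_participants": cfg.n_participants,
        "master_seed": cfg.master_seed,
        "trajectory_model": cfg.trajectory_model,
    }
    return table, meta


def apply_exclusions(raw_table: pd.DataFrame, threshold: float = 2.0) -> tuple[pd.DataFrame, dict]:
    """Drop pre-disappearance responses and trials with |error| > threshold.

    ``response_time`` is measured from disappearance, so a negative value
    means the button was pressed before the target vanished.  Idempotent.
    Returns the filtered table and a report of counts and the overall
    percentage excluded.
    """
    for col in ("response_time", "temporal_error"):
        if col not in raw_table.columns:
            raise ValueError(f"table lacks required column {col!r}")
    before_disappearance = raw_table["response_time"] < 0
    large_error = raw_table["temporal_error"].abs() > threshold
    keep = ~(before_disappearance | large_error)
    report = {
        "n_total": int(len(raw_table)),
        "n_before_disappearance": int(before_disappearance.sum()),
        "n_large_error": int((large_error & ~before_disappearance).sum()),
        "n_excluded": int((~keep).sum()),
        "fraction_excluded": float((~keep).mean()) if len(raw_table) else 0.0,
        "threshold": float(threshold),
    }
    return raw_table.loc[keep].reset_index(drop=True), report


def read_response_table(path, display_latency: float = 0.049259) -> pd.DataFrame:
    """Load a real per-trial response CSV, subtracting the display latency.

    Expects at least ``participant, gravity, vyi, vxi, occlusion_class,
    occlusion_fraction, response_time`` (response times measured from
    disappearance).  Synthetic tables never carry the latency and should not
    pass through this reader.
    """
    df = pd.read_csv(path)
    if "gravity" in df.columns and "gravity_multiple" not in df.columns:
        df = df.rename(columns={"gravity": "gravity_multiple"})
    df["response_time"] = df["response_time"] - display_latency
    return df


# ---------------------------------------------------------------------------
# published summary fixture

# Per-condition mean and SD of the error ratio: (occlusion, vyi) ->
# {gravity or inverted-block column: (mean, sd)}.  "1g_inv" is the 1g cell
# of the inverted-gravity block.
_TABLE1 = {
    ("Long", 4.5): {
        0.7: (1.12, 0.47), 0.85: (1.11, 0.49), 1.0: (1.20, 0.53),
        1.15: (1.24, 0.42), 1.3: (1.30, 0.44),
        "-1g": (1.33, 0.53), "1g_inv": (1.17, 0.38),
    },
    ("Long", 6.0): {
        0.7: (1.05, 0.49), 0.85: (1.11, 0.55), 1.0: (1.17, 0.57),
        1.15: (1.24, 0.54), 1.3: (1.32, 0.57),
        "-1g": (1.23, 0.56), "1g_inv": (1.16, 0.46),
    },
    ("Short", 4.5): {
        0.7: (1.22, 0.64), 0.85: (1.31, 0.65), 1.0: (1.34, 0.65),
        1.15: (1.41, 0.56), 1.3: (1.52, 0.88),
        "-1g": (1.68, 0.86), "1g_inv": (1.35, 0.58),
    },
    ("Short", 6.0): {
        0.7: (1.26, 0.65), 0.85: (1.33, 0.77), 1.0: (1.37, 0.77),
        1.15: (1.47, 0.88), 1.3: (1.49, 0.75),
        "-1g": (1.51, 0.80), "1g_inv": (1.35, 0.76),
    },
}


def table1_fixture() -> pd.DataFrame:
    """Published per-condition error-ratio means and SDs as a DataFrame.

    Columns: ``occlusion_class, vyi, gravity_multiple, block, mean_ratio,
    sd_ratio``; ``block`` is ``"main"`` for the 0.7g-1.3g blocks and
    ``"inverted"`` for the -1g/1g block (28 rows in total).
    """
    rows = []
    for (occ, vyi), cells in _TABLE1.items():
        for key, (mean, sd) in cells.items():
            if key == "-1g":
                g, block = -1.0, "inverted"
            elif key == "1g_inv":
                g, block = 1.0, "inverted"
            else:
                g, block = float(key), "main"
            rows.append((occ, vyi, g, block, mean, sd))
    return pd.DataFrame(
        rows,
        columns=["occlusion_class", "vyi", "gravity_multiple", "block", "mean_ratio", "sd_ratio"],
    )


# ---------------------------------------------------------------------------
# end-to-end parameter recovery


def recovery_experiment(
    truth: NoiseConfig | None = None,
    n_replicates: int = 10,
    n_datasets: int = 100,
    seed: int = 0,
    n_participants: int = 9,
    between_participant_cv: float = 0.10,
    run_method2: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Generate synthetic studies at known truth and re-estimate the
    parameters, replicate by replicate.

    Per replicate: generate -> apply exclusions -> per-participant condition
    SDs -> fit motor SD on the -1g cells -> Method 1 (prior SD, motor fixed
    at the recovered value) -> optionally Method 2 (joint fit).  Returns the
    per-replicate estimates and a summary (medians, median absolute
    deviations from truth).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    truth = truth if truth is not None else NoiseConfig()
    rep_seeds = np.random.SeedSequence(seed).generate_state(2 * n_replicates) % (2**31)
    rows = []
    for r in range(n_replicates):
        study_cfg = SyntheticStudyConfig(
            n_participants=n_participants,
            noise=truth,
            between_participant_cv=between_participant_cv,
            master_seed=int(rep_seeds[2 * r]),
        )
        table, _meta = generate_study(study_cfg)
        filtered, report = apply_exclusions(table, study_cfg.exclusion_threshold)

        minus1g = filtered[(filtered["block"] == 4) & (filtered["gravity_multiple"] < 0)]
        positive = filtered[filtered["block"].isin([1, 2, 3])]
        obs_minus1g = condition_sds(minus1g, by_participant=True)
        obs_positive = condition_sds(positive, by_participant=True)
        fit_seed = int(rep_seeds[2 * r + 1])

        motor = MotorSDEstimator(
            base_config=truth, n_datasets=n_datasets, seed=fit_seed,
            grid=np.arange(0.0, 0.0701, 0.01),
        ).fit(minus1g, obs_minus1g)
        m1 = GravityPriorSDEstimator(
            sd_motor=motor.sd_motor_, base_config=truth,
            n_datasets=n_datasets, seed=fit_seed,
        ).fit(positive, obs_positive)
        row = {
            "replicate": r,
            "sd_motor_hat": motor.sd_motor_,
            "sd_g_rel_method1": m1.sd_g_rel_,
            "rmse_motor": motor.rmse_,
            "rmse_method1": m1.rmse_,
            "fraction_excluded": report["fraction_excluded"],
        }
        if run_method2:
            m2 = JointNoiseEstimator(
                base_config=truth, n_datasets=n_datasets, seed=fit_seed,
            ).fit(positive, obs_positive)
            row.update(
                sd_motor_method2=m2.sd_motor_,
                sd_g_rel_method2=m2.sd_g_rel_,
                rmse_method2=m2.rmse_,
            )
        rows.append(row)
    estimates = pd.DataFrame(rows)
    summary = {
        "truth_sd_motor": truth.sd_motor,
        "truth_sd_g_rel": truth.sd_g_rel,
        "median_sd_motor": float(estimates["sd_motor_hat"].median()),
        "median_sd_g_rel_method1": float(estimates["sd_g_rel_method1"].median()),
        "median_abs_err_sd_motor": float(
            (estimates["sd_motor_hat"] - truth.sd_motor).abs().median()
        ),
        "median_abs_err_sd_g_rel_method1": float(
            (estimates["sd_g_rel_method1"] - truth.sd_g_rel).abs().median()
        ),
        "median_fraction_excluded": float(estimates["fraction_excluded"].median()),
    }
    if run_method2:
        summary["median_sd_g_rel_method2"] = float(estimates["sd_g_rel_method2"].median())
        summary["median_sd_motor_method2"] = float(estimates["sd_motor_method2"].median())
        summary["median_abs_method_gap"] = float(
            (estimates["sd_g_rel_method1"] - estimates["sd_g_rel_method2"]).abs().median()
        )
    return estimates, summary
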