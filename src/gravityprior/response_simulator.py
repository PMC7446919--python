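"""Monte-Carlo generative model of interception-timing responses.

Each trial's response is produced by (i) sampling a percept of the
disappearance kinematics — tangential speed (AF-biased, multiplicative
noise), tangential-to-vertical angle (additive noise), remaining drop
(multiplicative noise) — and a represented gravity drawn around the prior
mean; (ii) solving the ballistic prediction for the remaining flight time;
and (iii) adding Gaussian motor noise:

    vtan_p ~ N(af * vtan, sd_vtan_rel * af * vtan)
    alpha_p ~ N(alpha, sd_alpha)
    vy_p    = max(cos(alpha_p) * vtan_p, 0)
    dy_p   ~ N(dy, sd_dy_rel * dy)
    g_p    ~ N(g_mean, sd_g_rel * g_mean)
    response = t(dy_p, vy_p, g_p) + N(0, sd_motor)

Inverted (-1g) trials run through the same machinery in the mirrored frame
with ``sd_g_rel_inverted`` (the earth-gravity representation is assumed
inactive there).  Invalid draws (nonpositive g, negative dy or vtan) are
resampled a bounded number of times, then clamped and counted; negative
``vy_p`` (possible near the apex where the angle is ~90 deg) is clamped at
zero and counted.

The heavy path is fully vectorized over (replicate x trial) arrays.  All
randomness flows through a single seed, and re-running with the same seed
reproduces the draws exactly — this is what makes RMSE objectives smooth in
the noise parameters (common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .noise_calibration import NoiseConfig
from .stimulus_design import TrialSpec
from .timing_model import error_ratio as _error_ratio
from .timing_model import predict_remaining_time

_MAX_RESAMPLE = 8

CELL_KEYS = ["gravity_multiple", "vyi", "occlusion_class"]
"""Condition-cell keys; horizontal velocity is collapsed because it barely
affects flight duration (not at all without drag)."""


@dataclass(frozen=True)
class PerceptSample:
    """One sampled percept of a trial's disappearance kinematics."""

    vtan_perceived: float
    alpha_perceived: float
    vy_perceived: float
    dy_perceived: float
    g_represented: float


@dataclass
class SimDiagnostics:
    """Counts of guarded draws (all rare at published noise levels)."""

    n_draws: int = 0
    n_resampled: dict = field(default_factory=dict)
    n_clamped: dict = field(default_factory=dict)
    n_vy_clamped: int = 0


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _guarded_normal(
    rng: np.random.Generator,
    mean: np.ndarray,
    sd: np.ndarray,
    z: np.ndarray,
    lower_ok,
    clamp_to: float,
    name: str,
    diag: SimDiagnostics,
) -> np.ndarray:
    """mean + sd*z with bounded resampling of draws failing ``lower_ok``."""
    x = mean + sd * z
    bad = ~lower_ok(x)
    tries = 0
    n_res = 0
    while bad.any() and tries < _MAX_RESAMPLE:
        idx = np.nonzero(bad)
        x[idx] = (np.broadcast_to(mean, x.shape)[idx]
                  + np.broadcast_to(sd, x.shape)[idx] * rng.standard_normal(idx[0].size))
        n_res += idx[0].size
        bad = ~lower_ok(x)
        tries += 1
    if bad.any():
        diag.n_clamped[name] = diag.n_clamped.get(name, 0) + int(bad.sum())
        x[bad] = clamp_to
    if n_res:
        diag.n_resampled[name] = diag.n_resampled.get(name, 0) + n_res
    return x


def simulate_responses(
    trials: pd.DataFrame,
    cfg: NoiseConfig,
    n_datasets: int = 1,
    seed=0,
    sd_motor: float | np.ndarray | None = None,
    return_diagnostics: bool = False,
):
    """Simulate response times for every trial row, ``n_datasets`` times.

    Parameters
    ----------
    trials
        Trial table with columns ``gravity_multiple, vyi, vtan, alpha, dy,
        t_occluded`` (see :func:`gravityprior.stimulus_design.trial_table`).
    cfg
        Noise configuration; ``cfg.sd_g_rel_inverted`` is used for rows with
        negative ``gravity_multiple``.
    sd_motor
        Optional override of ``cfg.sd_motor``; may be a per-row array (used
        for participant-specific motor variability).
    seed
        Integer seed or ``numpy.random.Generator``.  A fixed integer seed
        gives common random numbers across calls with different ``cfg``.

    Returns
    -------
    responses : ndarray, shape (n_datasets, n_trials)
        Response times in seconds from disappearance.
    diagnostics : SimDiagnostics, only if ``return_diagnostics``.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    rng = _as_rng(seed)
    diag = SimDiagnostics()

    vtan = trials["vtan"].to_numpy(float)
    alpha = trials["alpha"].to_numpy(float)
    dy = trials["dy"].to_numpy(float)
    gmul = trials["gravity_multiple"].to_numpy(float)
    n = len(trials)
    shape = (n_datasets, n)
    diag.n_draws = n_datasets * n

    sd_g_rel = np.where(gmul < 0, cfg.sd_g_rel_inverted, cfg.sd_g_rel)
    sd_m = cfg.sd_motor if sd_motor is None else sd_motor
    sd_m = np.broadcast_to(np.asarray(sd_m, float), (n,))

    # one block of standard normals up front: CRN across parameter values
    z = rng.standard_normal((5,) + shape)

    vtan_mean = cfg.af_factor * vtan
    vtan_p = _guarded_normal(
        rng, vtan_mean, cfg.sd_vtan_rel * vtan_mean, z[0],
        lambda x: x >= 0, 0.0, "vtan", diag,
    )
    alpha_p = alpha + cfg.sd_alpha * z[1]
    dy_p = _guarded_normal(
        rng, dy, cfg.sd_dy_rel * dy, z[2],
        lambda x: x >= 0, 0.0, "dy", diag,
    )
    g_p = _guarded_normal(
        rng, cfg.g_prior_mean, sd_g_rel * cfg.g_prior_mean, z[3],
        lambda x: x > 0, 1e-6, "g", diag,
    )

    vy_p = np.cos(alpha_p) * vtan_p
    neg = vy_p < 0
    diag.n_vy_clamped = int(neg.sum())
    vy_p[neg] = 0.0

    t_pred = (-vy_p + np.sqrt(vy_p**2 + 2.0 * g_p * dy_p)) / g_p
    responses = t_pred + sd_m * z[4]
    if return_diagnostics:
        return responses, diag
    return responses


# ---------------------------------------------------------------------------
# single-trial API


def sample_percept(trial: TrialSpec, cfg: NoiseConfig, rng) -> PerceptSample:
    """Sample one percept for a single trial (thin wrapper over the
    vectorized core)."""
    rng = _as_rng(rng)
    row = _trial_to_row(trial)
    z = rng.standard_normal(5)
    diag = SimDiagnostics()
    vtan_mean = cfg.af_factor * row["vtan"]
    vtan_p = float(
        _guarded_normal(rng, np.array([vtan_mean]), np.array([cfg.sd_vtan_rel * vtan_mean]),
                        np.array([z[0]]), lambda x: x >= 0, 0.0, "vtan", diag)[0]
    )
    alpha_p = row["alpha"] + cfg.sd_alpha * z[1]
    dy_p = float(
        _guarded_normal(rng, np.array([row["dy"]]), np.array([cfg.sd_dy_rel * row["dy"]]),
                        np.array([z[2]]), lambda x: x >= 0, 0.0, "dy", diag)[0]
    )
    sd_g = cfg.sd_g_rel_inverted if row["gravity_multiple"] < 0 else cfg.sd_g_rel
    g_p = float(
        _guarded_normal(rng, np.array([cfg.g_prior_mean]), np.array([sd_g * cfg.g_prior_mean]),
                        np.array([z[3]]), lambda x: x > 0, 1e-6, "g", diag)[0]
    )
    vy_p = max(np.cos(alpha_p) * vtan_p, 0.0)
    return PerceptSample(vtan_p, alpha_p, vy_p, dy_p, g_p)


def simulate_trial(trial: TrialSpec, cfg: NoiseConfig, rng, participant=None):
    """Simulate one response for a single trial."""
    rng = _as_rng(rng)
    percept = sample_percept(trial, cfg, rng)
    t_pred = predict_remaining_time(percept.dy_perceived, percept.vy_perceived,
                                    percept.g_represented)
    response = t_pred + cfg.sd_motor * rng.standard_normal()
    err = response - trial.t_occluded
    from .timing_model import ResponseRecord

    return ResponseRecord(
        trial=trial,
        participant=participant,
        response_time=response,
        temporal_error=err,
        error_ratio=_error_ratio(err, trial.t_occluded),
    )


def _trial_to_row(trial: TrialSpec) -> dict:
    return {
        "gravity_multiple": trial.condition.gravity_multiple,
        "vyi": trial.condition.vyi,
        "vtan": trial.vtan_at_disappear,
        "alpha": trial.alpha_at_disappear,
        "dy": trial.dy_at_disappear,
        "t_occluded": trial.t_occluded,
    }


# ---------------------------------------------------------------------------
# datasets and summaries


def simulate_dataset(trials: pd.DataFrame, cfg: NoiseConfig, n_datasets: int = 1, seed=0) -> pd.DataFrame:
    """Long-format table of simulated responses: the trial columns plus
    ``dataset``, ``response_time``, ``temporal_error`` and ``error_ratio``."""
    resp = simulate_responses(trials, cfg, n_datasets=n_datasets, seed=seed)
    t_occ = trials["t_occluded"].to_numpy(float)
    frames = []
    for d in range(n_datasets):
        df = trials.copy().reset_index(drop=True)
        df.insert(0, "dataset", d)
        df["response_time"] = resp[d]
        df["temporal_error"] = resp[d] - t_occ
        df["error_ratio"] = resp[d] / t_occ
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def condition_sds(responses: pd.DataFrame, by_participant: bool = False) -> pd.DataFrame:
    """Per-cell SDs of temporal error and error ratio.

    Cells are (gravity x vyi x occlusion class), collapsed across horizontal
    velocity, optionally stratified by participant.  Cells with fewer than
    two observations are flagged.
    """
    keys = CELL_KEYS + (["participant"] if by_participant else [])
    if by_participant and "participant" not in responses.columns:
        raise ValueError("responses table has no participant column")
    grouped = responses.groupby(keys, sort=True)
    out = grouped.agg(
        sd_error=("temporal_error", "std"),
        sd_ratio=("error_ratio", "std"),
        n_trials=("temporal_error", "size"),
    ).reset_index()
    out["flagged"] = out["n_trials"] < 2
    return out


def _cell_layout(trials: pd.DataFrame, by_participant: bool):
    """Stable column ordering and reduceat boundaries for grouped SDs."""
    keys = CELL_KEYS + (["participant"] if by_participant else [])
    codes = trials.groupby(keys, sort=True).ngroup().to_numpy()
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    starts = np.flatnonzero(np.r_[True, sorted_codes[1:] != sorted_codes[:-1]])
    counts = np.diff(np.r_[starts, sorted_codes.size])
    key_df = (
        trials.iloc[order[starts]][keys].reset_index(drop=True)
    )
    return keys, order, starts, counts, key_df


def _grouped_sd(values: np.ndarray, order, starts, counts) -> np.ndarray:
    """Sample SD per group per row of a (D, N) array; returns (D, G)."""
    v = values[:, order]
    s = np.add.reduceat(v, starts, axis=1)
    ss = np.add.reduceat(v * v, starts, axis=1)
    var = (ss - s * s / counts) / np.maximum(counts - 1, 1)
    return np.sqrt(np.clip(var, 0.0, None))


def simulated_sd_table(
    trials: pd.DataFrame,
    cfg: NoiseConfig,
    n_datasets: int = 100,
    seed=0,
    by_participant: bool | None = None,
) -> pd.DataFrame:
    """Model-implied per-cell SDs: simulate ``n_datasets`` replicates of the
    trial set and average each cell's per-replicate sample SD.

    With the same ``seed`` and ``n_datasets`` this is an exact, deterministic
    function of ``cfg`` (common random numbers), which keeps RMSE objectives
    smooth and makes self-matches exact.
    """
    if by_participant is None:
        by_participant = "participant" in trials.columns
    resp = simulate_responses(trials, cfg, n_datasets=n_datasets, seed=seed)
    t_occ = trials["t_occluded"].to_numpy(float)
    keys, order, starts, counts, key_df = _cell_layout(trials, by_participant)
    sd_err = _grouped_sd(resp - t_occ, order, starts, counts).mean(axis=0)
    sd_rat = _grouped_sd(resp / t_occ, order, starts, counts).mean(axis=0)
    out = key_df.copy()
    out["sd_error"] = sd_err
    out["sd_ratio"] = sd_rat
    out["n_trials"] = counts
    return out


def sensitivity_sweep(
    param_name: str,
    values,
    cfg_baseline: NoiseConfig,
    trials: pd.DataFrame,
    seed=0,
    n_datasets: int = 1000,
) -> pd.DataFrame:
    """Per-cell simulated SDs across a range of one noise parameter.

    ``param_name`` is one of ``sd_dy_rel, sd_motor, sd_vtan_rel, sd_g_rel``.
    The same seed is reused for every value (common random numbers), so
    differences between values are not masked by Monte-Carlo jitter.
    """
    valid = {"sd_dy_rel", "sd_motor", "sd_vtan_rel", "sd_g_rel"}
    if param_name not in valid:
        raise ValueError(f"unknown parameter {param_name!r}; expected one of {sorted(valid)}")
    frames = []
    for v in values:
        cfg_v = cfg_baseline.replace(**{param_name: float(v)})
        tbl = simulated_sd_table(trials, cfg_v, n_datasets=n_datasets, seed=seed)
        tbl.insert(0, "value", float(v))
        tbl.insert(0, "param", param_name)
        frames.append(tbl)
    return pd.concat(frames, ignore_index=True)


DEFAULT_SWEEP_RANGES = {
    "sd_dy_rel": np.linspace(0.1, 0.3, 5),
    "sd_motor": np.linspace(0.02, 0.1, 5),
    "sd_vtan_rel": np.linspace(0.1, 0.3, 5),
    "sd_g_rel": np.linspace(0.02, 0.18, 5),
}
"""Published sweep ranges for the four noise parameters."""
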