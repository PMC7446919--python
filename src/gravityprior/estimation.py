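"""Fitting the free parameters of the generative response model.

Two quantities are free: the motor SD (residual response variability) and
the standardized SD of the gravity prior.  Both are estimated by matching
model-implied per-cell response-SD tables to observed ones under a
root-mean-square-error objective, with common random numbers so the
stochastic objective is a smooth deterministic function of the parameters.

The pipeline mirrors the study's logic:

1. ``MotorSDEstimator`` — the earth-gravity representation is assumed
   inactive for inverted (-1g) motion, whose acceleration is instead
   represented like an arbitrary one (standardized SD 0.295, from a 20 %
   Weber fraction).  Fitting the -1g cells with that gravity noise fixed
   isolates the motor SD; bounded 1-D search on [0.01, 0.06] s plus a
   diagnostic grid over 0.00-0.07 s.
2. ``GravityPriorSDEstimator`` (Method 1) — with the motor SD fixed, fit the
   prior's standardized SD to the positive-gravity cells: a coarse grid
   (0 to 0.28 in steps of 0.03) to locate the basin, then a bounded 1-D
   search on [0.16, 0.26].
3. ``JointNoiseEstimator`` (Method 2) — fit motor SD and prior SD
   simultaneously by Nelder-Mead from (0.04, 0.2) with no bounds.  The two
   parameters are separately identifiable because motor noise lifts all
   cells uniformly while gravity noise disproportionately inflates cells
   with long extrapolation intervals.

Fits run on the absolute temporal-error SD scale by default; the
error-ratio-scale RMSE is reported alongside.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from sklearn.base import BaseEstimator

from .noise_calibration import NoiseConfig, sd_to_weber
from .response_simulator import CELL_KEYS, simulated_sd_table
from .stimulus_design import G_EARTH

_SCALE_COLS = {"error": "sd_error", "ratio": "sd_ratio"}


@dataclass
class FitResult:
    """Outcome of one fitting procedure."""

    params: dict
    rmse: float
    scale: str
    n_datasets: int
    seed: int
    bounds: tuple | None = None
    start: tuple | None = None
    trace: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["extras"] = {k: v for k, v in d["extras"].items() if not isinstance(v, pd.DataFrame)}
        text = json.dumps(d, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def standardized_to_absolute(sd_rel: float, mean: float = G_EARTH) -> float:
    """Convert a standardized SD to absolute units (``sd_rel * mean``)."""
    if sd_rel < 0 or mean < 0:
        raise ValueError("inputs must be >= 0")
    return sd_rel * mean


def _align(observed: pd.DataFrame, simulated: pd.DataFrame) -> pd.DataFrame:
    keys = CELL_KEYS + (["participant"] if "participant" in observed.columns else [])
    merged = observed.merge(simulated, on=keys, how="inner", suffixes=("_obs", "_sim"))
    if len(merged) != len(observed) or len(merged) != len(simulated):
        raise ValueError(
            f"observed ({len(observed)}) and simulated ({len(simulated)}) SD tables "
            "do not share the same cell keys"
        )
    return merged


def rmse_objective(
    params: dict,
    observed: pd.DataFrame,
    trials: pd.DataFrame,
    cfg_base: NoiseConfig,
    n_datasets: int = 100,
    seed: int = 0,
    scale: str = "error",
) -> float:
    """RMSE between observed and model-implied per-cell SDs.

    ``params`` updates ``cfg_base`` (keys among the :class:`NoiseConfig`
    fields, typically ``sd_motor`` and/or ``sd_g_rel``).  The simulation
    reuses the same ``seed`` for every call, so the objective is a
    deterministic function of ``params`` and evaluates to exactly 0 when
    ``observed`` was produced by :func:`simulated_sd_table` with the same
    parameters, seed and replicate count.
    """
    col = _SCALE_COLS[scale]
    cfg = cfg_base.replace(**{k: abs(float(v)) for k, v in params.items()})
    sim = simulated_sd_table(
        trials, cfg, n_datasets=n_datasets, seed=seed,
        by_participant="participant" in observed.columns,
    )
    merged = _align(observed, sim)
    return float(np.sqrt(np.mean((merged[f"{col}_obs"] - merged[f"{col}_sim"]) ** 2)))


def _rmse_both_scales(params, observed, trials, cfg_base, n_datasets, seed):
    return {
        s: rmse_objective(params, observed, trials, cfg_base, n_datasets, seed, scale=s)
        for s in ("error", "ratio")
        if _SCALE_COLS[s] in observed.columns or f"{_SCALE_COLS[s]}" in observed.columns
    }


class _BaseSDFitter(BaseEstimator):
    """Shared plumbing: every concrete estimator exposes sklearn-style
    ``get_params``/``set_params`` and stores a :class:`FitResult`."""

    def _cfg(self) -> NoiseConfig:
        return self.base_config if self.base_config is not None else NoiseConfig()

    def _check_observed(self, observed: pd.DataFrame) -> None:
        if len(observed) == 0:
            raise ValueError("observed SD table is empty")
        col = _SCALE_COLS[self.scale]
        if col not in observed.columns:
            raise ValueError(f"observed table lacks the {col!r} column")


class MotorSDEstimator(_BaseSDFitter):
    """Motor SD from inverted-gravity trials (bounded 1-D RMSE fit).

    Parameters
    ----------
    bounds : (float, float)
        Search interval in seconds (default (0.01, 0.06)).
    grid : array-like or None
        Diagnostic grid of motor SDs (default 0.00-0.07 s in 0.005 steps);
        stored as ``grid_`` with the objective at each point.
    sd_g_rel_inverted : float
        Standardized SD of the represented (arbitrary) gravity on -1g
        trials, fixed during the fit (default 0.295).
    n_datasets : int
        Simulated replicates per objective evaluation.
    scale : {"error", "ratio"}
        SD scale the RMSE is computed on.

    Attributes
    ----------
    sd_motor_ : fitted motor SD, s
    rmse_ : objective at the optimum
    grid_ : DataFrame of (sd_motor, rmse) over the diagnostic grid
    fit_result_ : full :class:`FitResult`
    """

    def __init__(
        self,
        bounds=(0.01, 0.06),
        grid=None,
        sd_g_rel_inverted: float = 0.295,
        base_config: NoiseConfig | None = None,
        n_datasets: int = 100,
        seed: int = 0,
        scale: str = "error",
    ):
        self.bounds = bounds
        self.grid = grid
        self.sd_g_rel_inverted = sd_g_rel_inverted
        self.base_config = base_config
        self.n_datasets = n_datasets
        self.seed = seed
        self.scale = scale

    def fit(self, X: pd.DataFrame, y: pd.DataFrame):
        """Fit to -1g trials ``X`` (trial table) and observed SD table ``y``."""
        self._check_observed(y)
        cfg = self._cfg().replace(sd_g_rel_inverted=self.sd_g_rel_inverted)
        trace: list = []

        def obj(m: float) -> float:
            r = rmse_objective({"sd_motor": m}, y, X, cfg, self.n_datasets, self.seed, self.scale)
            trace.append(({"sd_motor": float(m)}, r))
            return r

        grid = np.arange(0.0, 0.0701, 0.005) if self.grid is None else np.asarray(self.grid)
        self.grid_ = pd.DataFrame({"sd_motor": grid, "rmse": [obj(m) for m in grid]})
        res = minimize_scalar(obj, bounds=tuple(self.bounds), method="bounded",
                              options={"xatol": 1e-4})
        self.sd_motor_ = float(res.x)
        self.rmse_ = float(res.fun)
        self.fit_result_ = FitResult(
            params={"sd_motor": self.sd_motor_},
            rmse=self.rmse_,
            scale=self.scale,
            n_datasets=self.n_datasets,
            seed=self.seed,
            bounds=tuple(self.bounds),
            trace=trace,
            extras={"grid": self.grid_},
        )
        return self


class GravityPriorSDEstimator(_BaseSDFitter):
    """Standardized SD of the gravity prior, motor SD fixed (Method 1).

    A coarse grid scan (default 0 to 0.28 in steps of 0.03) locates the
    objective's basin, then a bounded 1-D search (default [0.16, 0.26])
    refines it.  A warning is issued if the grid minimum falls outside the
    refinement bounds.

    Attributes
    ----------
    sd_g_rel_ : fitted standardized SD
    sd_g_abs_ : same in m/s^2 (x 9.81)
    weber_fraction_ : implied Weber fraction (sd * z0.75)
    rmse_, grid_, fit_result_ : as in :class:`MotorSDEstimator`
    """

    def __init__(
        self,
        sd_motor: float = 0.058,
        coarse_grid=None,
        bounds=(0.16, 0.26),
        base_config: NoiseConfig | None = None,
        n_datasets: int = 100,
        seed: int = 0,
        scale: str = "error",
    ):
        self.sd_motor = sd_motor
        self.coarse_grid = coarse_grid
        self.bounds = bounds
        self.base_config = base_config
        self.n_datasets = n_datasets
        self.seed = seed
        self.scale = scale

    def fit(self, X: pd.DataFrame, y: pd.DataFrame):
        """Fit to positive-gravity trials ``X`` and observed SD table ``y``."""
        self._check_observed(y)
        cfg = self._cfg().replace(sd_motor=self.sd_motor)
        trace: list = []

        def obj(s: float) -> float:
            r = rmse_objective({"sd_g_rel": s}, y, X, cfg, self.n_datasets, self.seed, self.scale)
            trace.append(({"sd_g_rel": float(s)}, r))
            return r

        grid = (np.arange(0.0, 0.2801, 0.03) if self.coarse_grid is None
                else np.asarray(self.coarse_grid))
        self.grid_ = pd.DataFrame({"sd_g_rel": grid, "rmse": [obj(s) for s in grid]})
        g_min = float(self.grid_.loc[self.grid_["rmse"].idxmin(), "sd_g_rel"])
        lo, hi = self.bounds
        if not (lo <= g_min <= hi):
            warnings.warn(
                f"coarse-grid minimum at sd_g_rel={g_min:.3f} lies outside the "
                f"refinement bounds [{lo}, {hi}]",
                stacklevel=2,
            )
        res = minimize_scalar(obj, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4})
        self.sd_g_rel_ = float(res.x)
        self.rmse_ = float(res.fun)
        self.sd_g_abs_ = standardized_to_absolute(self.sd_g_rel_, cfg.g_prior_mean)
        self.weber_fraction_ = sd_to_weber(self.sd_g_rel_)
        self.fit_result_ = FitResult(
            params={"sd_g_rel": self.sd_g_rel_},
            rmse=self.rmse_,
            scale=self.scale,
            n_datasets=self.n_datasets,
            seed=self.seed,
            bounds=(lo, hi),
            trace=trace,
            extras={
                "grid": self.grid_,
                "sd_motor_fixed": self.sd_motor,
                "sd_g_abs": self.sd_g_abs_,
                "weber_fraction": self.weber_fraction_,
                "grid_minimum": g_min,
            },
        )
        return self


class JointNoiseEstimator(_BaseSDFitter):
    """Simultaneous Nelder-Mead fit of motor SD and gravity-prior SD
    (Method 2): unbounded, started at (0.04 s, 0.2).

    Negative simplex proposals are reflected through their absolute value
    before entering the simulator (the optimum is interior and positive, so
    this only affects exploratory steps).

    Attributes
    ----------
    sd_motor_, sd_g_rel_, sd_g_abs_, weber_fraction_, rmse_, converged_,
    fit_result_
    """

    def __init__(
        self,
        start=(0.04, 0.2),
        base_config: NoiseConfig | None = None,
        n_datasets: int = 100,
        seed: int = 0,
        scale: str = "error",
        xatol: float = 1e-3,
        fatol: float = 1e-4,
        maxfev: int = 200,
    ):
        self.start = start
        self.base_config = base_config
        self.n_datasets = n_datasets
        self.seed = seed
        self.scale = scale
        self.xatol = xatol
        self.fatol = fatol
        self.maxfev = maxfev

    def fit(self, X: pd.DataFrame, y: pd.DataFrame):
        """Fit to positive-gravity trials ``X`` and observed SD table ``y``."""
        self._check_observed(y)
        cfg = self._cfg()
        trace: list = []

        def obj(p) -> float:
            params = {"sd_motor": abs(float(p[0])), "sd_g_rel": abs(float(p[1]))}
            r = rmse_objective(params, y, X, cfg, self.n_datasets, self.seed, self.scale)
            trace.append((params, r))
            return r

        res = minimize(
            obj,
            x0=np.asarray(self.start, float),
            method="Nelder-Mead",
            options={
                "xatol": self.xatol,
                "fatol": self.fatol,
                "maxfev": self.maxfev,
            },
        )
        self.sd_motor_ = abs(float(res.x[0]))
        self.sd_g_rel_ = abs(float(res.x[1]))
        self.rmse_ = float(res.fun)
        self.converged_ = bool(res.success)
        self.sd_g_abs_ = standardized_to_absolute(self.sd_g_rel_, cfg.g_prior_mean)
        self.weber_fraction_ = sd_to_weber(self.sd_g_rel_)
        if not res.success:
            warnings.warn(
                f"Nelder-Mead did not converge after {res.nfev} evaluations "
                f"({res.message}); see fit_result_.trace",
                stacklevel=2,
            )
        self.fit_result_ = FitResult(
            params={"sd_motor": self.sd_motor_, "sd_g_rel": self.sd_g_rel_},
            rmse=self.rmse_,
            scale=self.scale,
            n_datasets=self.n_datasets,
            seed=self.seed,
            start=tuple(self.start),
            trace=trace,
            extras={
                "converged": self.converged_,
                "n_evaluations": int(res.nfev),
                "sd_g_abs": self.sd_g_abs_,
                "weber_fraction": self.weber_fraction_,
            },
        )
        return self


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_motor_sd(observed_minus1g: pd.DataFrame, trials_minus1g: pd.DataFrame, **kwargs) -> FitResult:
    """Functional wrapper over :class:`MotorSDEstimator`."""
    est = MotorSDEstimator(**kwargs).fit(trials_minus1g, observed_minus1g)
    return est.fit_result_


def fit_prior_sd_method1(
    observed_positive_g: pd.DataFrame, trials_positive_g: pd.DataFrame,
    sd_motor_fixed: float = 0.058, **kwargs,
) -> FitResult:
    """Functional wrapper over :class:`GravityPriorSDEstimator`."""
    est = GravityPriorSDEstimator(sd_motor=sd_motor_fixed, **kwargs).fit(
        trials_positive_g, observed_positive_g
    )
    return est.fit_result_


def fit_joint_method2(
    observed_positive_g: pd.DataFrame, trials_positive_g: pd.DataFrame, **kwargs
) -> FitResult:
    """Functional wrapper over :class:`JointNoiseEstimator`."""
    est = JointNoiseEstimator(**kwargs).fit(trials_positive_g, observed_positive_g)
    return est.fit_result_
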