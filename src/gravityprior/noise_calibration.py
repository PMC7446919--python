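"""Psychophysical noise calibration: Weber fractions, JNDs and the noise
configuration of the generative response model.

A Weber fraction ``w`` at the conventional 75 % discrimination point maps to
the standardized SD of a unit-mean normal internal representation as
``w / z_0.75`` where ``z_0.75 = Phi^-1(0.75) ~= 0.6745``: a stimulus ``w``
above the mean is then judged greater 75 % of the time.  A 10 % Weber
fraction (typical for linear speeds and, doubled from fronto-parallel
distance discrimination, adopted for the height-above-table judgement) gives
a standardized SD of 0.148.

The published default constants (0.148 velocity, 0.148 distance, 0.089 rad
angle, 0.295 for the 20 % Weber fraction assumed for arbitrary gravities)
are embedded verbatim in :class:`NoiseConfig`; note that 0.089 and 0.295 are
not exactly reproduced by the ``w / z_0.75`` rule (0.20 / z_0.75 = 0.2965,
and a 6 deg orientation JND / z_0.75 is 8.9 deg = 0.155 rad).  The constants
take precedence over the rule; the conversion helpers implement the exact
rule.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass

import numpy as np
import yaml
from scipy.stats import norm

Z75 = float(norm.ppf(0.75))
"""75th-percentile standard-normal quantile (~0.6744897501960817)."""


def weber_to_sd(weber_fraction):
    """Standardized SD of a unit-mean normal with 75 %-point ``weber_fraction``."""
    w = np.asarray(weber_fraction, dtype=float)
    if np.any(w < 0):
        raise ValueError("weber_fraction must be >= 0")
    out = w / Z75
    return float(out) if np.isscalar(weber_fraction) else out


def sd_to_weber(sd):
    """Exact inverse of :func:`weber_to_sd`."""
    s = np.asarray(sd, dtype=float)
    if np.any(s < 0):
        raise ValueError("sd must be >= 0")
    out = s * Z75
    return float(out) if np.isscalar(sd) else out


def angular_speed_deg(v: float, distance: float) -> float:
    """Instantaneous retinal speed (deg/s) of a fronto-parallel target.

    Small-angle rate at fixation: ``(v / distance)`` rad/s in degrees.  A
    1 m/s target at 6 m gives ~9.5 deg/s.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    return float(np.degrees(v / distance))


def apply_af(v, af_factor):
    """Aubert-Fleischl speed bias: pursued targets appear ``af_factor`` slower."""
    return af_factor * v


@dataclass(frozen=True)
class NoiseConfig:
    """All noise/bias parameters of the generative response model.

    Parameters
    ----------
    af_factor
        Multiplicative Aubert-Fleischl bias on perceived tangential speed
        (pursued targets look ~20 % slower; default 0.8).
    sd_vtan_rel
        Standardized (multiplicative) SD of perceived tangential speed
        (10 % Weber fraction -> 0.148).
    sd_alpha
        Additive SD (radians) of the perceived tangential-to-vertical angle
        (orientation JND ~6 deg -> 0.089).
    sd_dy_rel
        Standardized SD of perceived remaining drop (0.148).
    g_prior_mean
        Mean of the represented gravity, m/s^2.
    sd_g_rel
        Standardized SD of the represented gravity for downward-gravity
        trials; the free parameter of the model (default: the fitted 0.208).
    sd_g_rel_inverted
        Standardized SD used for inverted (-1g) trials where the earth
        gravity representation is assumed inactive and the acceleration is
        represented like an arbitrary one (20 % Weber fraction -> 0.295).
    sd_motor
        Additive SD (s) of the motor response (default: the fitted 0.058 s).
    """

    af_factor: float = 0.8
    sd_vtan_rel: float = 0.148
    sd_alpha: float = 0.089
    sd_dy_rel: float = 0.148
    g_prior_mean: float = 9.81
    sd_g_rel: float = 0.208
    sd_g_rel_inverted: float = 0.295
    sd_motor: float = 0.058

    def __post_init__(self) -> None:
        if not (0 < self.af_factor <= 1):
            raise ValueError("af_factor must be in (0, 1]")
        if self.g_prior_mean <= 0:
            raise ValueError("g_prior_mean must be positive")
        for name in (
            "sd_vtan_rel",
            "sd_alpha",
            "sd_dy_rel",
            "sd_g_rel",
            "sd_g_rel_inverted",
            "sd_motor",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **changes) -> "NoiseConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseConfig":
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "NoiseConfig":
        if isinstance(source, (str, bytes)) and "\n" not in str(source):
            with open(source) as fh:
                d = yaml.safe_load(fh)
        elif isinstance(source, io.IOBase):
            d = yaml.safe_load(source)
        else:
            d = yaml.safe_load(source)
        return cls.from_dict(d)


def sweep_baseline_config() -> NoiseConfig:
    """Baseline configuration for the sensitivity sweeps (0.148 distance and
    velocity, 0.1 gravity, 0.05 s motor)."""
    return NoiseConfig(sd_g_rel=0.1, sd_motor=0.05)
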