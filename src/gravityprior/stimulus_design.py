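"""Experiment design grid and target kinematics for the interception-timing task.

Targets are launched in the fronto-parallel plane with an initial vertical
velocity ``vyi`` (4.5 or 6 m/s) and horizontal velocity ``vxi`` (3 or 4 m/s)
under one of six gravity levels (0.7g, 0.85g, 1g, 1.15g, 1.3g or inverted
-1g).  The target disappears partway through its flight (Long occlusion:
50-55 % of the flight time; Short occlusion: 75-80 %) and the observer must
indicate when it would have returned to launch height.

Two trajectory models are provided: the ideal ballistic parabola and the
linear-drag closed form (a 57 g ball with drag parameter c = 0.005 kg/s,
time constant m/c = 11.4 s; drag shifts flight times by ~0.02 s at most over
this grid).

Conventions
-----------
Trajectory generation uses a launch-height-origin, upward-positive frame.
The quantities stored on a :class:`TrialSpec` for the post-disappearance
prediction problem use a downward-positive local frame: ``vy_at_disappear``
is the downward speed at disappearance and ``dy_at_disappear`` the remaining
drop to launch height.  Inverted (-1g) trials are mirrored vertically so all
derived kinematics are sign-agnostic downstream.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

G_EARTH = 9.81
"""Standard earth gravity, m/s^2."""

BALL_MASS = 0.057
"""Target mass, kg (tennis-ball size)."""

DRAG_COEFF = 0.005
"""Linear drag parameter c, kg/s."""

GRAVITY_MULTIPLES_MAIN = (0.7, 0.85, 1.0, 1.15, 1.3)
GRAVITY_MULTIPLES_INVERTED = (1.0, -1.0)
VERTICAL_VELOCITIES = (4.5, 6.0)
HORIZONTAL_VELOCITIES = (3.0, 4.0)
OCCLUSION_CLASSES = ("Long", "Short")

OCCLUSION_WINDOWS = {"Long": (0.50, 0.55), "Short": (0.75, 0.80)}
"""Occluded-fraction window of total flight time per occlusion class."""

OCCLUSION_MIDPOINTS = {"Long": 0.525, "Short": 0.775}

DISPLAY_LATENCY = 0.049259
"""Projector delay (s) subtracted from measured response times when
ingesting real data; never applied in synthesis."""


@dataclass(frozen=True)
class StimulusCondition:
    """One cell of the design grid."""

    gravity_multiple: float
    vyi: float
    vxi: float
    occlusion_class: str
    block_id: int = 1

    def __post_init__(self) -> None:
        if self.occlusion_class not in OCCLUSION_CLASSES:
            raise ValueError(f"occlusion_class must be one of {OCCLUSION_CLASSES}")
        if self.gravity_multiple == 0:
            raise ValueError("gravity_multiple must be nonzero")
        if self.vyi <= 0:
            raise ValueError("vyi must be positive (mirrored frame for -1g)")

    @property
    def g_presented(self) -> float:
        """Signed presented gravity, m/s^2 (negative for inverted trials)."""
        return self.gravity_multiple * G_EARTH

    @property
    def g_magnitude(self) -> float:
        """|g| used in the mirrored, sign-agnostic frame."""
        return abs(self.gravity_multiple) * G_EARTH


@dataclass(frozen=True)
class KinematicState:
    """Position/velocity at time ``t`` in the launch frame (upward positive)."""

    t: float
    x: float
    y: float
    vx: float
    vy: float


@dataclass(frozen=True)
class TrialSpec:
    """A realized trial: condition, occlusion timing and disappearance state.

    ``vy_at_disappear`` is downward-positive; ``alpha_at_disappear`` is the
    angle between the tangential velocity vector and the (downward) vertical,
    so the vertical speed is recovered as ``cos(alpha) * vtan``.
    """

    condition: StimulusCondition
    occlusion_fraction: float
    t_flight: float
    t_disappear: float
    t_occluded: float
    dy_at_disappear: float
    vy_at_disappear: float
    vtan_at_disappear: float
    alpha_at_disappear: float


# ---------------------------------------------------------------------------
# design enumeration


def build_design(repetitions_main: int = 8, repetitions_inverted: int = 24) -> pd.DataFrame:
    """Enumerate the four-block design, one row per trial.

    Blocks 1-3 cross the five positive gravities with both initial velocities
    and both occlusion classes at ``repetitions_main`` repetitions each
    (320 trials per block at the default 8).  Block 4 crosses {1g, -1g} at
    ``repetitions_inverted`` repetitions (384 trials at the default 24).
    The default design therefore has 1344 rows.

    Rows are in deterministic lexicographic order; use :func:`shuffle_design`
    for a seeded presentation order.
    """
    if repetitions_main < 1 or repetitions_inverted < 1:
        raise ValueError("repetition counts must be >= 1")
    rows = []
    for block in (1, 2, 3):
        for g, vyi, vxi, occ, _rep in itertools.product(
            GRAVITY_MULTIPLES_MAIN,
            VERTICAL_VELOCITIES,
            HORIZONTAL_VELOCITIES,
            OCCLUSION_CLASSES,
            range(repetitions_main),
        ):
            rows.append((block, g, vyi, vxi, occ))
    for g, vyi, vxi, occ, _rep in itertools.product(
        GRAVITY_MULTIPLES_INVERTED,
        VERTICAL_VELOCITIES,
        HORIZONTAL_VELOCITIES,
        OCCLUSION_CLASSES,
        range(repetitions_inverted),
    ):
        rows.append((4, g, vyi, vxi, occ))
    return pd.DataFrame(
        rows, columns=["block", "gravity_multiple", "vyi", "vxi", "occlusion_class"]
    )


def shuffle_design(design: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Return a seeded random permutation of the design rows."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(design))
    return design.iloc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# trajectories


def ballistic_state(condition: StimulusCondition, t: float) -> KinematicState:
    """Drag-free state at time ``t`` (launch frame, upward positive)."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be >= 0")
    g = condition.g_magnitude
    return KinematicState(
        t=t,
        x=condition.vxi * t,
        y=condition.vyi * t - 0.5 * g * t * t,
        vx=condition.vxi,
        vy=condition.vyi - g * t,
    )


def drag_state(
    condition: StimulusCondition,
    t: float,
    mass: float = BALL_MASS,
    drag_coeff: float = DRAG_COEFF,
) -> KinematicState:
    """Linear-drag state at time ``t``.

    Drag force is ``-c * v`` so the time constant is ``m / c``.  Uses
    ``expm1`` for numerical stability; converges to :func:`ballistic_state`
    as ``c -> 0``.
    """
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be >= 0")
    if drag_coeff <= 0:
        raise ValueError("drag_coeff must be positive (use ballistic_state for c=0)")
    g = condition.g_magnitude
    k = drag_coeff / mass
    decay = -np.expm1(-k * t)  # 1 - exp(-k t), stable for small k t
    return KinematicState(
        t=t,
        x=condition.vxi * decay / k,
        y=(condition.vyi + g / k) * decay / k - g * t / k,
        vx=condition.vxi * (1.0 - decay),
        vy=(condition.vyi + g / k) * (1.0 - decay) - g / k,
    )


def flight_time(
    condition: StimulusCondition,
    model: str = "ballistic",
    mass: float = BALL_MASS,
    drag_coeff: float = DRAG_COEFF,
) -> float:
    """Time for the target to return to launch height.

    Ballistic: exactly ``2 vyi / g``.  Drag: smallest positive root of
    ``y(t) = 0``, found by bracketed root finding.
    """
    g = condition.g_magnitude
    t_ballistic = 2.0 * condition.vyi / g
    if model == "ballistic":
        return t_ballistic
    if model != "drag":
        raise ValueError("model must be 'ballistic' or 'drag'")

    def f(t: float) -> float:
        return drag_state(condition, t, mass, drag_coeff).y

    hi = t_ballistic
    while f(hi) > 0:
        hi *= 1.25
        if hi > 100 * t_ballistic:
            raise RuntimeError("no positive root found for drag flight time")
    return brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-14)


def make_trial(
    condition: StimulusCondition,
    occlusion_fraction: float,
    model: str = "ballistic",
) -> TrialSpec:
    """Realize a trial: occlusion timing and kinematic state at disappearance.

    ``occlusion_fraction`` must lie in the window of the condition's
    occlusion class (Long: [0.50, 0.55]; Short: [0.75, 0.80]).
    """
    lo, hi = OCCLUSION_WINDOWS[condition.occlusion_class]
    if not (lo <= occlusion_fraction <= hi):
        raise ValueError(
            f"occlusion_fraction {occlusion_fraction} outside the "
            f"{condition.occlusion_class} window [{lo}, {hi}]"
        )
    t_fl = flight_time(condition, model=model)
    t_dis = occlusion_fraction * t_fl
    state = (
        ballistic_state(condition, t_dis)
        if model == "ballistic"
        else drag_state(condition, t_dis)
    )
    dy = max(state.y, 0.0)
    vy_down = -state.vy  # downward-positive prediction frame
    vtan = math.hypot(state.vx, state.vy)
    alpha = math.acos(np.clip(vy_down / vtan, -1.0, 1.0))
    return TrialSpec(
        condition=condition,
        occlusion_fraction=occlusion_fraction,
        t_flight=t_fl,
        t_disappear=t_dis,
        t_occluded=t_fl - t_dis,
        dy_at_disappear=dy,
        vy_at_disappear=vy_down,
        vtan_at_disappear=vtan,
        alpha_at_disappear=alpha,
    )


# ---------------------------------------------------------------------------
# tabular interface


def trial_table(
    design: pd.DataFrame,
    fractions: str | np.ndarray = "midpoint",
    seed: int | None = None,
    model: str = "ballistic",
) -> pd.DataFrame:
    """Vectorized :func:`make_trial` over a design table.

    Parameters
    ----------
    design
        Output of :func:`build_design` (or any table with columns
        ``gravity_multiple, vyi, vxi, occlusion_class``; a ``block`` column
        is carried through if present).
    fractions
        ``"midpoint"`` for the deterministic window midpoints (0.525 /
        0.775), ``"uniform"`` for a seeded uniform draw within each trial's
        window, or an explicit array of per-row fractions.
    """
    n = len(design)
    occ = design["occlusion_class"].to_numpy()
    lo = np.array([OCCLUSION_WINDOWS[c][0] for c in occ])
    hi = np.array([OCCLUSION_WINDOWS[c][1] for c in occ])
    if isinstance(fractions, str):
        if fractions == "midpoint":
            frac = (lo + hi) / 2.0
        elif fractions == "uniform":
            rng = np.random.default_rng(seed)
            frac = lo + (hi - lo) * rng.random(n)
        else:
            raise ValueError("fractions must be 'midpoint', 'uniform' or an array")
    else:
        frac = np.asarray(fractions, dtype=float)
        if frac.shape != (n,):
            raise ValueError("fractions array must have one entry per design row")
        if np.any(frac < lo) or np.any(frac > hi):
            raise ValueError("some fractions fall outside their occlusion window")

    # flight time per unique (gravity, vyi, vxi) triple; cheap cache since
    # the grid only has a handful of distinct conditions
    tf_cache: dict[tuple, float] = {}

    def _tf(g: float, vyi: float, vxi: float) -> float:
        key = (g, vyi, vxi)
        if key not in tf_cache:
            cond = StimulusCondition(g, vyi, vxi, "Long")
            tf_cache[key] = flight_time(cond, model=model)
        return tf_cache[key]

    gmul = design["gravity_multiple"].to_numpy(float)
    vyi = design["vyi"].to_numpy(float)
    vxi = design["vxi"].to_numpy(float)
    t_fl = np.array([_tf(g, a, b) for g, a, b in zip(gmul, vyi, vxi)])
    t_dis = frac * t_fl
    g_mag = np.abs(gmul) * G_EARTH

    if model == "ballistic":
        y = vyi * t_dis - 0.5 * g_mag * t_dis**2
        vy_up = vyi - g_mag * t_dis
        vx = vxi
    else:
        k = DRAG_COEFF / BALL_MASS
        decay = -np.expm1(-k * t_dis)
        y = (vyi + g_mag / k) * decay / k - g_mag * t_dis / k
        vy_up = (vyi + g_mag / k) * (1.0 - decay) - g_mag / k
        vx = vxi * (1.0 - decay)

    dy = np.maximum(y, 0.0)
    vy_down = -vy_up
    vtan = np.hypot(vx, vy_up)
    alpha = np.arccos(np.clip(vy_down / vtan, -1.0, 1.0))

    out = design.copy().reset_index(drop=True)
    out["occlusion_fraction"] = frac
    out["t_flight"] = t_fl
    out["t_disappear"] = t_dis
    out["t_occluded"] = t_fl - t_dis
    out["dy"] = dy
    out["vy"] = vy_down
    out["vtan"] = vtan
    out["alpha"] = alpha
    return out
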