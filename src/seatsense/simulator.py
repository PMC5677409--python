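"""Synthetic sitting-behaviour generator.

No public recording of the cushion's signals exists, so this module
generates labelled streams with the statistical structure the recognition
method relies on:

* a **latent CoP trajectory** per activity block — a mean-reverting
  (Ornstein-Uhlenbeck) sway around the subject's resting position for the
  three light activities (with occasional posture micro-shifts), a sinusoid
  on one axis for swinging, and high-amplitude irregular bursts for
  exercise;
* **six non-negative forces** realised so that their force-weighted average
  (the CoP equation) reproduces the latent trajectory exactly, scaled by the
  subject's total seated load;
* **gyroscope channels** proportional to the smoothed angular excursion rate
  of the latent trajectory plus activity-dependent Gaussian noise.

The three light activities differ only in sway magnitude (conversation >
desk work > reading), deliberately making them confusable; swinging and
exercise are distinct by amplitude and regularity.  Subjects vary in BMI
(which drives total load), resting load distribution and an idle-sway scale,
so leave-one-subject-out evaluation is non-trivial.

Forces from CoP: with 6 sensors and only 3 constraints (CoP_x, CoP_y, unit
weight sum) the per-sample weight vector is under-determined; the generator
takes the solution closest to the subject's resting weights by alternating
projections onto the affine constraint set and the non-negative orthant,
which yields smooth per-sensor traces and exact CoP reproduction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_GEOMETRY,
    Activity,
    CushionGeometry,
    RawStream,
    ValidationError,
)

__all__ = [
    "SubjectProfile",
    "ActivityGenParams",
    "SessionPlan",
    "DEFAULT_ACTIVITY_PARAMS",
    "simulate_session",
    "simulate_cohort",
    "forces_from_cop",
]

logger = logging.getLogger(__name__)

#: Latent CoP is kept inside the sensor hull shrunk by this factor, so the
#: force realisation always has a strictly feasible non-negative solution.
HULL_MARGIN = 0.9

#: Gyro output per unit of latent CoP velocity, deg/s per (grid unit / s).
GYRO_SCALE = 30.0

#: Resting load pattern: buttocks load the mid and rear sensors more than
#: the front ones (order Fsr1..Fsr6 = front L/R, mid L/R, rear L/R).
CANONICAL_WEIGHTS = np.array([0.12, 0.12, 0.19, 0.19, 0.19, 0.19])


@dataclass(frozen=True)
class SubjectProfile:
    """A simulated sitter.

    ``total_force`` (arbitrary units) grows monotonically with BMI;
    ``baseline_weights`` is the resting load split over the six sensors;
    ``sway_scale`` multiplies idle-sway amplitudes for the light activities.
    """

    id: str
    bmi: float
    total_force: float
    baseline_weights: np.ndarray
    sway_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 16.0 <= self.bmi <= 34.0:
            raise ValidationError("bmi must lie in [16, 34]")
        w = np.asarray(self.baseline_weights, dtype=float)
        if w.shape != (6,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("baseline_weights must be 6 non-negative "
                                  "fractions summing to 1")
        object.__setattr__(self, "baseline_weights", w)


@dataclass(frozen=True)
class ActivityGenParams:
    """Generative knobs for one activity (amplitudes in grid units).

    ``cop_jitter_sd`` is the stationary SD of the OU sway; ``ou_theta`` its
    mean-reversion rate (1/s).  ``shift_rate`` is the Poisson rate of posture
    micro-shifts per minute, each a baseline jump of ~``shift_magnitude``.
    Swing adds a sinusoid of ``swing_amp`` at ``swing_freq`` on the chosen
    axis (with a small cross-axis coupling); exercise adds Poisson bursts of
    large, irregularly shaped displacement.
    """

    cop_jitter_sd: float = 0.02
    ou_theta: float = 1.0
    gyro_noise_sd: float = 1.0
    shift_rate: float = 0.0
    shift_magnitude: float = 0.0
    swing_amp: float = 0.0
    swing_freq: float = 0.0
    swing_axis: str = "left_right"
    swing_coupling: float = 0.2
    burst_rate: float = 0.0
    burst_amp: float = 0.0


#: Default per-activity parameters.  Light activities share dynamics and
#: differ only in magnitude; amplitudes are free choices (no quantitative
#: reference signal exists) set to satisfy the documented ordering
#: light < moderate < vigorous in windowed dispersion on every channel.
DEFAULT_ACTIVITY_PARAMS: dict[Activity, ActivityGenParams] = {
    Activity.READING: ActivityGenParams(
        cop_jitter_sd=0.010, gyro_noise_sd=0.5,
        shift_rate=2.0, shift_magnitude=0.10,
    ),
    Activity.DESK_WORKING: ActivityGenParams(
        cop_jitter_sd=0.020, gyro_noise_sd=1.0,
        shift_rate=2.0, shift_magnitude=0.12,
    ),
    Activity.CONVERSATION: ActivityGenParams(
        cop_jitter_sd=0.035, gyro_noise_sd=1.5,
        shift_rate=3.0, shift_magnitude=0.15,
    ),
    Activity.SWING: ActivityGenParams(
        cop_jitter_sd=0.05, gyro_noise_sd=2.0,
        swing_amp=0.8, swing_freq=0.4,
    ),
    Activity.EXERCISE: ActivityGenParams(
        cop_jitter_sd=0.65, ou_theta=2.5, gyro_noise_sd=15.0,
        burst_rate=12.0, burst_amp=1.5,
    ),
}


@dataclass(frozen=True)
class SessionPlan:
    """One recording session: a subject and an ordered activity schedule."""

    subject: SubjectProfile
    schedule: tuple[tuple[Activity, float], ...]  # (activity, duration s)
    fs: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.schedule:
            raise ValidationError("schedule must not be empty")
        if any(d <= 0 for _, d in self.schedule):
            raise ValidationError("block durations must be > 0")


# ---------------------------------------------------------------------------
# Latent trajectory pieces
# ---------------------------------------------------------------------------


def _ou(n: int, dt: float, sd: float, theta: float,
        rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path, exact discretisation.

    x[i] = a x[i-1] + eps, a = exp(-theta dt), stationary SD = sd; realised
    as an AR(1) filter so long blocks stay cheap.
    """
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    a = np.exp(-theta * dt)
    innov_sd = sd * np.sqrt(1.0 - a * a)
    driver = np.empty(n)
    driver[0] = rng.normal(0.0, sd)  # stationary start
    driver[1:] = rng.normal(0.0, innov_sd, size=n - 1)
    return lfilter([1.0], [1.0, -a], driver)


def _shift_track(n: int, dt: float, rate_per_min: float, magnitude: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Piecewise-constant baseline offsets from Poisson posture micro-shifts."""
    out = np.zeros((n, 2))
    if rate_per_min <= 0 or magnitude <= 0:
        return out
    p_event = rate_per_min / 60.0 * dt
    events = np.flatnonzero(rng.random(n) < p_event)
    offset = np.zeros(2)
    prev = 0
    for idx in events:
        out[prev:idx] = offset
        step = rng.uniform(-1.0, 1.0, size=2) * magnitude
        offset = np.clip(offset + step, -0.3, 0.3)
        prev = idx
    out[prev:] = offset
    return out


def _bursts(n: int, dt: float, rate_per_min: float, amp: float,
            rng: np.random.Generator) -> np.ndarray:
    """Half-sine displacement bursts in random directions, with rough edges."""
    out = np.zeros((n, 2))
    if rate_per_min <= 0 or amp <= 0:
        return out
    p_event = rate_per_min / 60.0 * dt
    starts = np.flatnonzero(rng.random(n) < p_event)
    for s in starts:
        dur = int(round(rng.uniform(1.0, 3.0) / dt))
        e = min(n, s + dur)
        if e <= s + 1:
            continue
        angle = rng.uniform(0.0, 2.0 * np.pi)
        a = amp * rng.uniform(0.5, 1.5)
        envelope = np.sin(np.linspace(0.0, np.pi, e - s))
        rough = 1.0 + 0.3 * rng.standard_normal(e - s)
        disp = a * envelope * rough
        out[s:e, 0] += disp * np.cos(angle)
        out[s:e, 1] += disp * np.sin(angle)
    return out


def _hull_clip(points: np.ndarray, geometry: CushionGeometry,
               margin: float = HULL_MARGIN) -> tuple[np.ndarray, int]:
    """Pull points outside the shrunken sensor hull toward the centroid.

    Returns the clipped points and the number of samples that moved.
    """
    from scipy.spatial import ConvexHull

    coords = np.column_stack([geometry.x, geometry.y])
    hull = ConvexHull(coords)
    A = hull.equations[:, :2]
    b = -hull.equations[:, 2] * margin  # A p <= b inside the shrunken hull
    centroid = coords.mean(axis=0)
    rel = points - centroid
    proj = rel @ A.T  # (n, n_facets)
    rhs = b - A @ centroid
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(proj > rhs, rhs / proj, np.inf)
    scale = np.minimum(1.0, ratios.min(axis=1))
    clipped = centroid + rel * scale[:, None]
    n_clipped = int((scale < 1.0).sum())
    return clipped, n_clipped


# ---------------------------------------------------------------------------
# Force realisation (inverse CoP)
# ---------------------------------------------------------------------------


def forces_from_cop(
    cop_xy: np.ndarray,
    baseline_weights: np.ndarray,
    geometry: CushionGeometry = DEFAULT_GEOMETRY,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> np.ndarray:
    """Non-negative sensor weights (rows sum to 1) whose CoP is ``cop_xy``.

    Alternating projections between the affine set {W : A W^T = B} (unit sum
    and the two CoP equations) and the non-negative orthant, started from the
    resting weights.  The final iterate satisfies the affine constraints
    exactly (up to floating point); tiny residual negatives below ``tol``
    are clipped.
    """
    cop_xy = np.atleast_2d(np.asarray(cop_xy, dtype=float))
    n = len(cop_xy)
    A = np.vstack([np.ones(6), geometry.x, geometry.y])  # (3, 6)
    B = np.column_stack([np.ones(n), cop_xy])            # (n, 3)
    G_inv = np.linalg.inv(A @ A.T)
    W = np.tile(np.asarray(baseline_weights, dtype=float), (n, 1))
    for _ in range(max_iter):
        # project onto the affine constraint set
        residual = W @ A.T - B                            # (n, 3)
        W = W - residual @ G_inv @ A
        if W.min() >= -tol:
            break
        W = np.maximum(W, 0.0)
    W = np.maximum(W, 0.0)
    # samples whose optimal weights sit on the orthant boundary converge
    # only asymptotically; what matters is the realised constraint residual
    worst = float(np.abs(W @ A.T - B).max())
    if worst > 1e-6:
        logger.warning("force realisation residual %.3g exceeds 1e-6", worst)
    return W


# ---------------------------------------------------------------------------
# Session and cohort generation
# ---------------------------------------------------------------------------


def _block_latent(
    n: int,
    dt: float,
    gen: ActivityGenParams,
    sway_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent CoP displacement (relative to the resting point) for one block."""
    level_is_light = gen.swing_amp == 0.0 and gen.burst_rate == 0.0
    scale = sway_scale if level_is_light else 1.0
    xy = np.column_stack(
        [
            _ou(n, dt, gen.cop_jitter_sd * scale, gen.ou_theta, rng),
            _ou(n, dt, gen.cop_jitter_sd * scale, gen.ou_theta, rng),
        ]
    )
    xy += _shift_track(n, dt, gen.shift_rate, gen.shift_magnitude * scale, rng)
    if gen.swing_amp > 0.0:
        t = np.arange(n) * dt
        phase = rng.uniform(0.0, 2.0 * np.pi)
        main = gen.swing_amp * np.sin(2.0 * np.pi * gen.swing_freq * t + phase)
        cross = (
            gen.swing_coupling
            * gen.swing_amp
            * np.sin(2.0 * np.pi * gen.swing_freq * t + phase + np.pi / 2.0)
        )
        if gen.swing_axis == "left_right":
            xy[:, 0] += main
            xy[:, 1] += cross
        elif gen.swing_axis == "front_back":
            xy[:, 1] += main
            xy[:, 0] += cross
        else:
            raise ValidationError(f"unknown swing axis {gen.swing_axis!r}")
    xy += _bursts(n, dt, gen.burst_rate, gen.burst_amp, rng)
    return xy


def _smooth_gradient(x: np.ndarray, dt: float, width: int = 5) -> np.ndarray:
    """Time derivative of a moving-average-smoothed signal."""
    if len(x) < 2:
        return np.zeros_like(x)
    pad = width // 2
    xp = np.pad(x, (pad, width - 1 - pad), mode="edge")
    smoothed = np.convolve(xp, np.ones(width) / width, mode="valid")
    return np.gradient(smoothed, dt)


def simulate_session(
    plan: SessionPlan,
    gen_params: Optional[dict[Activity, ActivityGenParams]] = None,
    geometry: CushionGeometry = DEFAULT_GEOMETRY,
    return_latent: bool = False,
) -> RawStream | tuple[RawStream, np.ndarray]:
    """Generate one labelled session stream for ``plan``.

    Deterministic given the plan (same seed, bit-identical stream).  The
    latent CoP is clipped to the interior of the sensor hull when an
    excursion would leave it (logged); the realised forces reproduce the
    latent CoP exactly and sum to the subject's total load modulated by a
    slow breathing-like oscillation (within +-20%).

    With ``return_latent=True`` also returns the (n, 2) latent CoP
    trajectory the forces were realised from, for validation.
    """
    gen_params = dict(DEFAULT_ACTIVITY_PARAMS if gen_params is None else gen_params)
    rng = np.random.default_rng(plan.seed)
    dt = 1.0 / plan.fs
    subject = plan.subject
    rest_xy = np.array(
        [
            float(subject.baseline_weights @ geometry.x),
            float(subject.baseline_weights @ geometry.y),
        ]
    )
    latent_parts: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for activity, duration in plan.schedule:
        n = int(round(duration * plan.fs))
        gen = gen_params[Activity(activity)]
        xy = rest_xy + _block_latent(n, dt, gen, subject.sway_scale, rng)
        latent_parts.append(xy)
        labels.append(np.full(n, Activity(activity).value, dtype=object))
    latent = np.concatenate(latent_parts)
    label = np.concatenate(labels)
    latent, n_clipped = _hull_clip(latent, geometry)
    if n_clipped:
        logger.info("clipped %d latent CoP sample(s) to the sensor hull", n_clipped)
    n_total = len(latent)
    weights = forces_from_cop(latent, subject.baseline_weights, geometry)
    # slow load modulation: breathing plus a bounded drift, well inside +-20%
    t = np.arange(n_total) * dt
    breathing = 0.03 * np.sin(2.0 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    drift = np.clip(_ou(n_total, dt, 0.04, 0.05, rng), -0.1, 0.1)
    total = subject.total_force * (1.0 + breathing + drift)
    fsr = weights * total[:, None]
    gyro_x = GYRO_SCALE * _smooth_gradient(latent[:, 1], dt)
    gyro_y = GYRO_SCALE * _smooth_gradient(latent[:, 0], dt)
    # per-block gyro measurement noise
    offset = 0
    for activity, duration in plan.schedule:
        n = int(round(duration * plan.fs))
        sd = gen_params[Activity(activity)].gyro_noise_sd
        gyro_x[offset:offset + n] += rng.normal(0.0, sd, size=n)
        gyro_y[offset:offset + n] += rng.normal(0.0, sd, size=n)
        offset += n
    stream = RawStream(
        t=t,
        fsr=fsr,
        gyro_x=gyro_x,
        gyro_y=gyro_y,
        fs=plan.fs,
        label=label,
        subject=subject.id,
    )
    return (stream, latent) if return_latent else stream


def _bmi_bins(n_subjects: int) -> list[tuple[float, float]]:
    """BMI ranges per subject following the 2:4:2 under/normal/over pattern.

    Exactly (2, 4, 2) for n = 8; proportional (with the remainder going to
    the normal bin) otherwise.
    """
    under, normal, over = (16.0, 18.5), (18.5, 25.0), (25.0, 34.0)
    n_under = round(n_subjects * 0.25)
    n_over = round(n_subjects * 0.25)
    n_normal = n_subjects - n_under - n_over
    if n_normal < 0:  # tiny cohorts: everyone normal-weight
        n_under = n_over = 0
        n_normal = n_subjects
    return [under] * n_under + [normal] * n_normal + [over] * n_over


def make_subject(
    subject_id: str,
    bmi_range: tuple[float, float],
    rng: np.random.Generator,
) -> SubjectProfile:
    """Draw one subject: BMI in range, load monotone in BMI, resting weights."""
    bmi = rng.uniform(*bmi_range)
    total_force = 180.0 + 14.0 * (bmi - 16.0)
    perturb = rng.uniform(0.7, 1.3, size=6)
    weights = CANONICAL_WEIGHTS * perturb
    weights = weights / weights.sum()
    sway_scale = rng.uniform(0.85, 1.15)
    return SubjectProfile(
        id=subject_id,
        bmi=float(bmi),
        total_force=float(total_force),
        baseline_weights=weights,
        sway_scale=float(sway_scale),
    )


def simulate_cohort(
    n_subjects: int = 8,
    per_activity_minutes: float = 50.0,
    seed: int = 0,
    fs: float = 10.0,
    gen_params: Optional[dict[Activity, ActivityGenParams]] = None,
) -> tuple[list[RawStream], pd.DataFrame]:
    """Generate one labelled stream per subject plus a cohort manifest.

    Every subject performs all five activities for ``per_activity_minutes``
    each, in a randomised order; the BMI spread follows the 2:4:2
    underweight/normal/overweight pattern (exactly (2, 4, 2) for n = 8).
    Swing axis (left-right vs front-back) is drawn per subject.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   seed_seq.spawn(n_subjects)]
    bins = _bmi_bins(n_subjects)
    streams: list[RawStream] = []
    records = []
    base_params = dict(DEFAULT_ACTIVITY_PARAMS if gen_params is None else gen_params)
    for i in range(n_subjects):
        subject = make_subject(f"S{i + 1}", bins[i], rng)
        axis = "left_right" if rng.random() < 0.5 else "front_back"
        params_i = dict(base_params)
        params_i[Activity.SWING] = replace(params_i[Activity.SWING],
                                           swing_axis=axis)
        order = list(Activity)
        rng.shuffle(order)
        plan = SessionPlan(
            subject=subject,
            schedule=tuple((a, per_activity_minutes * 60.0) for a in order),
            fs=fs,
            seed=child_seeds[i],
        )
        streams.append(simulate_session(plan, params_i))
        records.append(
            {
                "subject": subject.id,
                "bmi": subject.bmi,
                "total_force": subject.total_force,
                "sway_scale": subject.sway_scale,
                "swing_axis": axis,
                "activity_order": ",".join(a.value for a in order),
                "seed": child_seeds[i],
            }
        )
    return streams, pd.DataFrame.from_records(records)
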