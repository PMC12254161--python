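"""Synthetic study generator.

Emulates the statistical structure of a chronic-exposure behavioural assay:
single fish swimming in shallow circular arenas filmed at video rate, whose
mean speed and turning variability shift with the exposure concentration,
plus a replicate-level twelve-biomarker table whose means follow monotone
log-dose curves with optional low-dose hormetic stimulation and
multiplicative replicate noise.

The trajectory model is a correlated random walk: per-frame speed is an
AR(1) log-normal process (stationary mean set by the dose-response curve,
coefficient of variation ``speed_cv``, log-scale autocorrelation
``speed_ar1``), headings accumulate zero-mean normal increments with
dose-dependent standard deviation, and the arena wall reflects specularly
so that speed statistics stay dose-driven rather than wall-driven.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ArenaSpec, BIOMARKER_NAMES, DoseResponseCurve, Trajectory

__all__ = [
    "TrajectorySimParams",
    "BiomarkerSimParams",
    "StudyDesign",
    "SimulatedStudy",
    "simulate_trajectory",
    "simulate_biomarkers",
    "simulate_study",
    "default_trajectory_params",
    "default_biomarker_params",
]

#: Nominal exposure concentrations of the reference design, µg/L;
#: the first entry is the negative control.
DEFAULT_CONCENTRATIONS = (0.00, 0.16, 0.42, 1.09, 2.84, 7.40, 19.23, 50.0)


@dataclass(frozen=True)
class TrajectorySimParams:
    """Parameters of the correlated-random-walk trajectory model."""

    speed_curve: DoseResponseCurve        # mean speed mm/s vs dose
    turn_sd_curve: DoseResponseCurve      # per-frame heading-change s.d., degrees
    speed_cv: float = 0.35                # CV of instantaneous speed
    speed_ar1: float = 0.6                # lag-1 autocorrelation of log-speed
    duration: float = 41.0                # seconds recorded per fish
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("speed_cv", "speed_ar1", "duration"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"TrajectorySimParams.{name} must be finite, got {v!r}")
        if self.speed_cv < 0:
            raise ValueError(f"TrajectorySimParams.speed_cv must be >= 0, got {self.speed_cv}")
        if not 0 <= self.speed_ar1 < 1:
            raise ValueError(
                f"TrajectorySimParams.speed_ar1 must be in [0, 1), got {self.speed_ar1}"
            )


@dataclass(frozen=True)
class BiomarkerSimParams:
    """Dose-response curves and replicate noise for the 12-biomarker panel."""

    curves: dict[str, DoseResponseCurve]
    noise_cv: float = 0.08
    replicates_per_condition: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        missing = [n for n in BIOMARKER_NAMES if n not in self.curves]
        extra = [n for n in self.curves if n not in BIOMARKER_NAMES]
        if missing or extra:
            raise ValueError(
                f"BiomarkerSimParams.curves must cover exactly the 12 biomarkers; "
                f"missing={missing}, unexpected={extra}"
            )
        if not np.isfinite(self.noise_cv) or self.noise_cv < 0:
            raise ValueError(
                f"BiomarkerSimParams.noise_cv must be >= 0, got {self.noise_cv!r}"
            )
        if self.replicates_per_condition < 1:
            raise ValueError("BiomarkerSimParams.replicates_per_condition must be >= 1")


@dataclass(frozen=True)
class StudyDesign:
    """Exposure concentrations and per-condition sample sizes."""

    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    fish_per_condition: int = 3

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if len(c) < 2 or np.any(np.diff(c) <= 0):
            raise ValueError("StudyDesign.concentrations must be strictly increasing")
        if c[0] != 0:
            raise ValueError("StudyDesign: first concentration must be 0 (control)")
        if self.fish_per_condition < 1:
            raise ValueError("StudyDesign.fish_per_condition must be >= 1")

    @property
    def n_conditions(self) -> int:
        return len(self.concentrations)


@dataclass
class SimulatedStudy:
    """Bundle of one simulated study: trajectories, biomarkers, condition map.

    ``condition_map`` has one row per fish with columns ``fish_id``,
    ``condition`` (µg/L) and ``replicate`` (1-based index within condition);
    fish *i* of a condition is paired with biomarker replicate *i* of the
    same condition.
    """

    design: StudyDesign
    arena: ArenaSpec
    trajectories: list[Trajectory]
    biomarkers: pd.DataFrame
    condition_map: pd.DataFrame
    seed: int


def _substream_seed(master_seed: int, *key: int) -> int:
    """Counter-based derivation of an independent child seed (< 2**31)."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def _reflect_step(p0: np.ndarray, step: np.ndarray, arena: ArenaSpec) -> tuple[np.ndarray, np.ndarray]:
    """Advance from p0 (inside) by `step`, reflecting specularly at the wall.

    Returns the final position (strictly inside) and the final unit direction.
    """
    c = arena.centre
    R = arena.radius
    u = step.copy()
    length = float(np.hypot(*u))
    if length == 0.0:
        return p0.copy(), np.array([1.0, 0.0])
    u /= length
    p = p0.copy()
    for _ in range(64):
        q = p + length * u
        if np.hypot(*(q - c)) < R:
            return q, u
        # solve |p + t*u - c|^2 = R^2 for the exit point
        w = p - c
        b = float(np.dot(w, u))
        disc = b * b - (float(np.dot(w, w)) - R * R)
        t_hit = -b + math.sqrt(max(disc, 0.0))
        t_hit = min(max(t_hit, 0.0), length)
        hit = p + t_hit * u
        n = (hit - c) / max(np.hypot(*(hit - c)), 1e-300)
        u = u - 2.0 * float(np.dot(u, n)) * n
        nu = float(np.hypot(*u))
        u = u / nu if nu > 0 else -n
        # nudge inward so the remaining segment starts strictly inside
        p = c + (hit - c) * (1.0 - 1e-12)
        length -= t_hit
        if length <= 0:
            return p, u
    # pathological many-reflection step: stop at the last wall contact
    return p, u


def simulate_trajectory(
    arena: ArenaSpec,
    params: TrajectorySimParams,
    dose: float,
    *,
    fish_id: str = "fish",
) -> Trajectory:
    """Simulate one fish's trajectory at the given exposure concentration.

    The fish starts at the arena centre with a random initial heading. Every
    returned position lies strictly inside the arena; the walk is fully
    reproducible from ``params.seed``.
    """
    if not np.isfinite(dose) or dose < 0:
        raise ValueError(f"dose must be a finite non-negative concentration, got {dose!r}")
    n = int(round(params.duration * arena.frame_rate))
    if n < 2:
        raise ValueError("duration * frame_rate must be >= 2 frames")
    rng = np.random.default_rng(params.seed)
    dt = 1.0 / arena.frame_rate
    t = np.arange(n) * dt

    mean_speed = params.speed_curve.value(float(dose))
    turn_sd = params.turn_sd_curve.value(float(dose))
    if mean_speed < 0 or turn_sd < 0:
        raise ValueError("speed and turn-s.d. curves must be non-negative at this dose")

    # stationary log-normal AR(1) speed process
    if mean_speed == 0.0:
        v = np.zeros(n)
    elif params.speed_cv == 0.0:
        v = np.full(n, mean_speed)
    else:
        sigma2 = math.log1p(params.speed_cv**2)
        mu = math.log(mean_speed) - sigma2 / 2.0
        phi = params.speed_ar1
        eps = rng.normal(0.0, math.sqrt(sigma2 * (1.0 - phi**2)), size=n)
        logv = np.empty(n)
        logv[0] = mu + rng.normal(0.0, math.sqrt(sigma2))
        for i in range(1, n):
            logv[i] = mu + phi * (logv[i - 1] - mu) + eps[i]
        v = np.exp(logv)

    turns = rng.normal(0.0, turn_sd, size=n)
    heading = rng.uniform(-180.0, 180.0)

    x = np.empty(n)
    y = np.empty(n)
    p = arena.centre.astype(float)
    x[0], y[0] = p
    for i in range(1, n):
        heading = ((heading + turns[i] + 180.0) % 360.0) - 180.0
        step_len = v[i] * dt
        h_rad = math.radians(heading)
        step = step_len * np.array([math.cos(h_rad), math.sin(h_rad)])
        p, direction = _reflect_step(p, step, arena)
        if step_len > 0:
            heading = math.degrees(math.atan2(direction[1], direction[0]))
        x[i], y[i] = p

    return Trajectory(fish_id=fish_id, condition=float(dose), arena=arena, t=t, x=x, y=y)


def simulate_biomarkers(design: StudyDesign, params: BiomarkerSimParams) -> pd.DataFrame:
    """Simulate the replicate-level biomarker table.

    One row per replicate (``len(design.concentrations) *
    params.replicates_per_condition`` rows), columns ``condition``,
    ``replicate`` and the 12 biomarkers. Each value is
    ``curve(dose) * (1 + eps)`` with ``eps ~ Normal(0, noise_cv**2)``.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for dose in design.concentrations:
        for rep in range(1, params.replicates_per_condition + 1):
            noise = rng.normal(0.0, params.noise_cv, size=len(BIOMARKER_NAMES))
            values = {
                name: params.curves[name].value(float(dose)) * (1.0 + noise[j])
                for j, name in enumerate(BIOMARKER_NAMES)
            }
            rows.append({"condition": float(dose), "replicate": rep, **values})
    return pd.DataFrame(rows, columns=["condition", "replicate", *BIOMARKER_NAMES])


def simulate_study(
    design: StudyDesign,
    arena: ArenaSpec,
    tparams: TrajectorySimParams,
    bparams: BiomarkerSimParams,
) -> SimulatedStudy:
    """Simulate a full study: trajectories + biomarker table + condition map.

    Each fish is paired one-to-one with the biomarker replicate of the same
    index within its condition, so behavioural and biochemical regressors can
    be joined row-wise downstream. Per-fish seeds are derived deterministically
    from the master seed (``tparams.seed``) via counter-based substreams, so
    generation order does not matter.
    """
    if design.fish_per_condition != bparams.replicates_per_condition:
        raise ValueError(
            "fish_per_condition must equal replicates_per_condition "
            f"({design.fish_per_condition} != {bparams.replicates_per_condition})"
        )
    master = int(tparams.seed)
    trajectories: list[Trajectory] = []
    map_rows = []
    for ci, dose in enumerate(design.concentrations):
        for rep in range(1, design.fish_per_condition + 1):
            fish_id = f"c{ci}_f{rep}"
            sub = _substream_seed(master, ci, rep)
            p = TrajectorySimParams(
                speed_curve=tparams.speed_curve,
                turn_sd_curve=tparams.turn_sd_curve,
                speed_cv=tparams.speed_cv,
                speed_ar1=tparams.speed_ar1,
                duration=tparams.duration,
                seed=sub,
            )
            trajectories.append(simulate_trajectory(arena, p, dose, fish_id=fish_id))
            map_rows.append({"fish_id": fish_id, "condition": float(dose), "replicate": rep})

    bseed = _substream_seed(master, 999_983)
    bio = simulate_biomarkers(
        design,
        BiomarkerSimParams(
            curves=bparams.curves,
            noise_cv=bparams.noise_cv,
            replicates_per_condition=bparams.replicates_per_condition,
            seed=bseed,
        ),
    )
    condition_map = pd.DataFrame(map_rows)
    return SimulatedStudy(
        design=design,
        arena=arena,
        trajectories=trajectories,
        biomarkers=bio,
        condition_map=condition_map,
        seed=master,
    )


def default_trajectory_params(seed: int = 0, duration: float = 41.0) -> TrajectorySimParams:
    """Reference trajectory conditions: caffeine-like hyperactivity.

    Mean speed rises from 12 mm/s towards ~21 mm/s with a low-dose hormetic
    bump peaking near the lowest tested concentration; turning variability
    rises in parallel (more erratic swimming under exposure).
    """
    return TrajectorySimParams(
        speed_curve=DoseResponseCurve(
            baseline=12.0, emax=0.8, ed50=2.0, hill=1.2,
            hormesis_amp=0.25, hormesis_scale=0.2,
        ),
        turn_sd_curve=DoseResponseCurve(
            baseline=4.0, emax=0.7, ed50=3.0, hill=1.3,
        ),
        speed_cv=0.35,
        speed_ar1=0.6,
        duration=duration,
        seed=seed,
    )


def default_biomarker_params(seed: int = 0, noise_cv: float = 0.05) -> BiomarkerSimParams:
    """Reference biomarker conditions.

    Directions follow the oxidative-stress / energy-cost narrative typical of
    chronic stimulant exposure in fish: antioxidant enzymes and lipid
    peroxidation up; energy reserves, LDH and AChE down. Baselines are
    arbitrary natural units; ed50 values are spread over the tested range so
    conditions separate, and the phase-I/antioxidant endpoints (SOD, CAT,
    GSTs) carry hormetic low-dose bumps so the lowest exposure level is
    biochemically distinguishable from the control — the signature of
    low-dose stimulation this assessment framework is designed to detect.
    """
    c = DoseResponseCurve
    curves = {
        "SOD":   c(baseline=50.0, emax=0.8,  ed50=2.0, hill=1.2, hormesis_amp=0.25, hormesis_scale=0.2),
        "CAT":   c(baseline=30.0, emax=0.6,  ed50=1.0, hill=1.0, hormesis_amp=0.15, hormesis_scale=0.4),
        "GPx":   c(baseline=20.0, emax=0.7,  ed50=4.0, hill=1.5),
        "GRed":  c(baseline=15.0, emax=0.4,  ed50=6.0, hill=1.2),
        "GSH":   c(baseline=80.0, emax=-0.3, ed50=3.0, hill=1.0),
        "GSTs":  c(baseline=40.0, emax=0.5,  ed50=1.5, hill=1.3, hormesis_amp=0.12, hormesis_scale=0.16),
        "TBARS": c(baseline=10.0, emax=0.9,  ed50=5.0, hill=1.4),
        "GLY":   c(baseline=120.0, emax=-0.4, ed50=2.5, hill=1.1),
        "LIP":   c(baseline=60.0, emax=-0.35, ed50=4.0, hill=1.2),
        "PROT":  c(baseline=200.0, emax=-0.25, ed50=8.0, hill=1.5),
        "LDH":   c(baseline=90.0, emax=-0.5, ed50=0.8, hill=1.0),
        "AChE":  c(baseline=25.0, emax=-0.45, ed50=3.0, hill=1.2),
    }
    return BiomarkerSimParams(curves=curves, noise_cv=noise_cv, seed=seed)
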