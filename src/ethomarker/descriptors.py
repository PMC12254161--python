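"""Per-frame movement descriptors of a tracked trajectory.

From the raw (t, x, y) track, six kinematic descriptors are computed per
frame — the feature space in which swimming modes are later clustered:

* instantaneous velocity (mm/s) — step displacement over the step interval;
* instantaneous acceleration (mm/s², signed) — forward difference of the
  instantaneous velocity, so decelerations are negative;
* mean velocity (mm/s) — centred moving average of instantaneous velocity;
* mean angular velocity (degrees/s) — centred moving average of the absolute
  per-step heading change rate;
* mean meander (degrees/mm) — centred moving average of path curvature,
  absolute heading change per unit path length;
* distance to the arena centre (mm).

Finite differences use the per-step time interval throughout (timestamps may
be irregular). Frames lacking a full difference stencil, or where the fish
moved less than a motion threshold (sub-resolution jitter makes the heading,
and hence curvature, undefined), are flagged invalid and excluded downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import DESCRIPTOR_COLUMNS, Trajectory

__all__ = [
    "wrap_angle",
    "step_kinematics",
    "turning_metrics",
    "distance_to_centre",
    "assemble_descriptors",
]

#: Steps shorter than this (mm) are treated as tracking jitter: the heading
#: is carried forward from the last moving step and the frame's turning
#: metrics are not defined.
DEFAULT_MOTION_THRESHOLD = 0.1


def wrap_angle(angle):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    w = -((-a + 180.0) % 360.0 - 180.0)
    return float(w) if np.isscalar(angle) else w


def step_kinematics(traj: Trajectory, motion_threshold: float = DEFAULT_MOTION_THRESHOLD) -> pd.DataFrame:
    """Instantaneous velocity, heading and signed acceleration per frame.

    Returns a DataFrame aligned with the trajectory frames with columns
    ``t, dt, step_length, instantaneous_velocity, heading, heading_valid,
    instantaneous_acceleration, accel_valid``. For frame ``i >= 1``:
    ``v_i = |p_i - p_{i-1}| / dt_i`` and
    ``heading_i = atan2(dy, dx)`` in degrees. Acceleration is the forward
    difference ``a_i = (v_{i+1} - v_i) / dt_{i+1}`` (signed). Headings of
    sub-threshold steps are carried forward from the last moving step.
    """
    t, x, y = traj.t, traj.x, traj.y
    n = len(t)
    dt = np.full(n, np.nan)
    dt[1:] = np.diff(t)
    if np.any(dt[1:] <= 0):
        raise ValueError("duplicate or non-increasing timestamps")

    dx = np.full(n, np.nan)
    dy = np.full(n, np.nan)
    dx[1:] = np.diff(x)
    dy[1:] = np.diff(y)
    step_length = np.hypot(dx, dy)
    v = step_length / dt

    moved = step_length >= motion_threshold
    heading = np.full(n, np.nan)
    heading[moved & ~np.isnan(step_length)] = np.degrees(
        np.arctan2(dy[moved & ~np.isnan(step_length)], dx[moved & ~np.isnan(step_length)])
    )
    # carry heading forward over sub-threshold steps
    heading_valid = np.zeros(n, dtype=bool)
    last = np.nan
    for i in range(1, n):
        if moved[i]:
            last = heading[i]
        elif np.isfinite(last):
            heading[i] = last
        heading_valid[i] = np.isfinite(heading[i])

    a = np.full(n, np.nan)
    # a_i defined for 1 <= i <= n-2 (needs v_i and v_{i+1})
    a[1:-1] = (v[2:] - v[1:-1]) / dt[2:]
    accel_valid = np.isfinite(a)

    return pd.DataFrame(
        {
            "t": t,
            "dt": dt,
            "step_length": step_length,
            "instantaneous_velocity": v,
            "heading": heading,
            "heading_valid": heading_valid,
            "moved": moved & np.isfinite(step_length),
            "instantaneous_acceleration": a,
            "accel_valid": accel_valid,
        }
    )


def turning_metrics(
    headings: np.ndarray,
    step_lengths: np.ndarray,
    dt: np.ndarray,
    moved: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-frame turn, angular velocity and meander from step headings.

    ``turn_i = wrap(heading_i - heading_{i-1})`` in (-180, 180];
    ``angular_velocity_i = |turn_i| / dt_i`` (degrees/s);
    ``meander_i = |turn_i| / step_length_i`` (degrees/mm).

    Frames whose own step is below the motion threshold (``moved`` False)
    have no defined curvature: their turning metrics are NaN and flagged
    invalid, even though the carried-forward heading keeps later turns
    well defined.
    """
    h = np.asarray(headings, dtype=float)
    L = np.asarray(step_lengths, dtype=float)
    dt = np.asarray(dt, dtype=float)
    n = len(h)
    if moved is None:
        moved = L > 0
    turn = np.full(n, np.nan)
    turn[1:] = wrap_angle(h[1:] - h[:-1])
    defined = np.isfinite(turn) & np.asarray(moved, dtype=bool)
    turn[~defined] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        ang_vel = np.abs(turn) / dt
        meander = np.abs(turn) / L
    ang_vel[~defined] = np.nan
    meander[~defined] = np.nan
    return pd.DataFrame(
        {
            "turn": turn,
            "instantaneous_angular_velocity": ang_vel,
            "instantaneous_meander": meander,
            "turn_valid": defined,
        }
    )


def distance_to_centre(traj: Trajectory) -> np.ndarray:
    """Euclidean distance (mm) of every frame's position to the arena centre."""
    return np.hypot(traj.x - traj.arena.centre_x, traj.y - traj.arena.centre_y)


def _windowed_mean(t: np.ndarray, values: np.ndarray, half_window: float) -> np.ndarray:
    """Centred time-window mean ignoring NaNs: mean over |t_j - t_i| <= half_window."""
    finite = np.isfinite(values)
    vals = np.where(finite, values, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(finite)])
    lo = np.searchsorted(t, t - half_window, side="left")
    hi = np.searchsorted(t, t + half_window, side="right")
    total = csum[hi] - csum[lo]
    count = ccnt[hi] - ccnt[lo]
    out = np.full(len(t), np.nan)
    nz = count > 0
    out[nz] = total[nz] / count[nz]
    # a frame whose own value is undefined stays undefined
    out[~finite] = np.nan
    return out


def assemble_descriptors(
    traj: Trajectory,
    window: float = 1.0,
    motion_threshold: float = DEFAULT_MOTION_THRESHOLD,
) -> pd.DataFrame:
    """Compute the six-descriptor matrix for one trajectory.

    ``window`` (seconds) is the width of the centred moving average behind the
    "mean" descriptors; the instantaneous columns stay un-smoothed. Returns a
    DataFrame with ``frame_index``, ``t``, the six descriptor columns in
    canonical order, and a ``valid`` flag; only rows where all six are defined
    are valid. Metadata (window, threshold, fish/condition) is stored in
    ``DataFrame.attrs``.
    """
    sk = step_kinematics(traj, motion_threshold=motion_threshold)
    min_dt = float(np.nanmin(sk["dt"].to_numpy()))
    if not window >= min_dt:
        raise ValueError(
            f"window ({window} s) must be at least one frame interval ({min_dt} s)"
        )
    tm = turning_metrics(
        sk["heading"].to_numpy(),
        sk["step_length"].to_numpy(),
        sk["dt"].to_numpy(),
        moved=sk["moved"].to_numpy(),
    )
    half = window / 2.0
    t = traj.t
    mean_velocity = _windowed_mean(t, sk["instantaneous_velocity"].to_numpy(), half)
    mean_ang_vel = _windowed_mean(t, tm["instantaneous_angular_velocity"].to_numpy(), half)
    mean_meander = _windowed_mean(t, tm["instantaneous_meander"].to_numpy(), half)

    out = pd.DataFrame(
        {
            "frame_index": np.arange(len(t)),
            "t": t,
            "mean_meander": mean_meander,
            "mean_velocity": mean_velocity,
            "instantaneous_velocity": sk["instantaneous_velocity"].to_numpy(),
            "distance_to_centre": distance_to_centre(traj),
            "mean_angular_velocity": mean_ang_vel,
            "instantaneous_acceleration": sk["instantaneous_acceleration"].to_numpy(),
        }
    )
    out["valid"] = np.all(np.isfinite(out[list(DESCRIPTOR_COLUMNS)].to_numpy()), axis=1)
    out.attrs.update(
        {
            "fish_id": traj.fish_id,
            "condition": traj.condition,
            "window_s": window,
            "motion_threshold_mm": motion_threshold,
        }
    )
    return out
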