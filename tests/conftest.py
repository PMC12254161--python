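"""Shared fixtures: a small synthetic study and derived stages.

Everything is generated at test time from fixed seeds; session scope keeps
the expensive stages (trajectory simulation, SOM training, subset search)
shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ethomarker as em
from ethomarker import contingency as ct
from ethomarker import discriminant as da
from ethomarker import ethogram as eg
from ethomarker import synthetic as syn
from ethomarker.core import BIOMARKER_NAMES


@pytest.fixture(scope="session")
def arena() -> em.ArenaSpec:
    return em.ArenaSpec()


@pytest.fixture(scope="session")
def small_study(arena) -> syn.SimulatedStudy:
    """Default-conditions study at reduced recording length (8 s/fish)."""
    return em.simulate_study(
        syn.StudyDesign(),
        arena,
        syn.default_trajectory_params(seed=123, duration=8.0),
        syn.default_biomarker_params(seed=123),
    )


@pytest.fixture(scope="session")
def pooled_descriptors(small_study) -> pd.DataFrame:
    frames = []
    for traj in small_study.trajectories:
        d = em.assemble_descriptors(traj)
        frames.append(d[d["valid"]].assign(fish_id=traj.fish_id))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def ethogram_model(pooled_descriptors) -> eg.EthogramModel:
    return eg.train_som(pooled_descriptors, eg.SOMConfig(seed=7, epochs=10))


@pytest.fixture(scope="session")
def frame_labels(ethogram_model, pooled_descriptors) -> np.ndarray:
    return eg.assign_classes(ethogram_model, pooled_descriptors)


@pytest.fixture(scope="session")
def labels_by_fish(frame_labels, pooled_descriptors) -> dict[str, np.ndarray]:
    s = pd.Series(frame_labels)
    return {f: g.to_numpy() for f, g in s.groupby(pooled_descriptors["fish_id"].to_numpy())}


@pytest.fixture(scope="session")
def condition_table(labels_by_fish, small_study) -> pd.DataFrame:
    return ct.build_profile(
        labels_by_fish, small_study.condition_map, "condition",
        tuple(sorted({l for v in labels_by_fish.values() for l in v})),
    )


@pytest.fixture(scope="session")
def biomarker_features(small_study) -> da.FeatureTable:
    bio = small_study.biomarkers
    return da.FeatureTable(
        X=bio[list(BIOMARKER_NAMES)].reset_index(drop=True),
        groups=bio["condition"].reset_index(drop=True),
        provenance={c: "biomarker" for c in BIOMARKER_NAMES},
    )


def make_circle_trajectory(
    r: float = 200.0,
    step_angle_rad: float = 1e-3,
    n: int = 400,
    frame_rate: float = 25.0,
) -> em.Trajectory:
    """Uniform circular motion fixture (closed-form curvature (180/pi)/r)."""
    arena = em.ArenaSpec(radius=r * 1.5, frame_rate=frame_rate)
    theta = np.arange(n) * step_angle_rad
    t = np.arange(n) / frame_rate
    return em.Trajectory(
        fish_id="circle", condition=0.0, arena=arena,
        t=t, x=r * np.cos(theta), y=r * np.sin(theta),
    )


def make_line_trajectory(
    speed: float = 10.0, n: int = 200, frame_rate: float = 25.0
) -> em.Trajectory:
    """Uniform straight-line motion inside a large arena."""
    arena = em.ArenaSpec(radius=1000.0, frame_rate=frame_rate)
    t = np.arange(n) / frame_rate
    return em.Trajectory(
        fish_id="line", condition=0.0, arena=arena,
        t=t, x=-400.0 + speed * t, y=np.zeros(n),
    )
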