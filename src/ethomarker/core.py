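"""Core domain types shared across the pipeline.

The package analyses single-fish swimming trajectories recorded in shallow
circular arenas, together with a replicate-level panel of twelve biochemical
markers. These types carry the raw observational units: the arena geometry,
one fish's time-ordered positions, and the saturating (optionally hormetic)
dose-response curves that drive the synthetic study generator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArenaSpec",
    "DoseResponseCurve",
    "Trajectory",
    "BIOMARKER_NAMES",
    "DESCRIPTOR_COLUMNS",
]

#: The twelve biochemical endpoints of the biomarker panel, in canonical
#: column order: antioxidant enzymes (SOD, CAT, GPx, GRed), glutathione
#: status (GSH, GSTs), lipid peroxidation (TBARS), energy reserves
#: (GLY, LIP, PROT), anaerobic metabolism (LDH) and neurotoxicity (AChE).
BIOMARKER_NAMES = (
    "SOD", "CAT", "GPx", "GRed", "GSH", "GSTs",
    "TBARS", "GLY", "LIP", "PROT", "LDH", "AChE",
)

#: The six movement descriptors, in canonical column order.
DESCRIPTOR_COLUMNS = (
    "mean_meander",              # degrees/mm
    "mean_velocity",             # mm/s
    "instantaneous_velocity",    # mm/s
    "distance_to_centre",        # mm
    "mean_angular_velocity",     # degrees/s
    "instantaneous_acceleration",  # mm/s^2, signed
)


def _require_finite(obj, fields_) -> None:
    for name in fields_:
        value = getattr(obj, name)
        if not np.all(np.isfinite(value)):
            raise ValueError(
                f"{type(obj).__name__}.{name} must be finite, got {value!r}"
            )


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry and sampling rate of one circular test arena.

    The default 52 mm radius corresponds to a shallow dish holding roughly
    150 mL at 5 cm depth; the default 25 frames/s is the PAL video standard.
    """

    centre_x: float = 0.0  # mm
    centre_y: float = 0.0  # mm
    radius: float = 52.0  # mm
    frame_rate: float = 25.0  # frames / s

    def __post_init__(self) -> None:
        _require_finite(self, ("centre_x", "centre_y", "radius", "frame_rate"))
        if self.radius <= 0:
            raise ValueError(f"ArenaSpec.radius must be > 0, got {self.radius}")
        if self.frame_rate <= 0:
            raise ValueError(
                f"ArenaSpec.frame_rate must be > 0, got {self.frame_rate}"
            )

    @property
    def centre(self) -> np.ndarray:
        return np.array([self.centre_x, self.centre_y])


@dataclass(frozen=True)
class DoseResponseCurve:
    """Saturating dose-response profile with an optional hormetic bump.

    The mean level of a descriptor or biomarker at dose ``d`` (µg/L) is

        baseline * (1 + emax * d^hill / (ed50^hill + d^hill)
                      + hormesis_amp * (d/hs) * exp(1 - d/hs))

    with ``hs = hormesis_scale``. The Hill term saturates at a fractional
    change of ``emax`` (which may be negative for inhibited endpoints); the
    hormetic term is a single low-dose bump peaking exactly at
    ``d = hormesis_scale`` with fractional height ``hormesis_amp``, and
    vanishing at dose 0 and as dose grows, so ``value(0) == baseline``
    always.
    """

    baseline: float
    emax: float = 0.0
    ed50: float = 1.0  # µg/L
    hill: float = 1.0
    hormesis_amp: float = 0.0
    hormesis_scale: float = 1.0  # µg/L

    def __post_init__(self) -> None:
        _require_finite(
            self,
            ("baseline", "emax", "ed50", "hill", "hormesis_amp", "hormesis_scale"),
        )
        if self.ed50 <= 0:
            raise ValueError(f"DoseResponseCurve.ed50 must be > 0, got {self.ed50}")
        if self.hill <= 0:
            raise ValueError(f"DoseResponseCurve.hill must be > 0, got {self.hill}")
        if self.hormesis_scale <= 0:
            raise ValueError(
                f"DoseResponseCurve.hormesis_scale must be > 0, got {self.hormesis_scale}"
            )

    def value(self, dose) -> np.ndarray | float:
        """Mean level at the given dose(s); dose 0 returns the baseline exactly."""
        d = np.asarray(dose, dtype=float)
        if np.any(d < 0):
            raise ValueError("dose must be >= 0")
        dh = d**self.hill
        hill_term = self.emax * dh / (self.ed50**self.hill + dh)
        u = d / self.hormesis_scale
        horm_term = self.hormesis_amp * u * np.exp(1.0 - u)
        out = self.baseline * (1.0 + hill_term + horm_term)
        return float(out) if np.isscalar(dose) else out

    def __call__(self, dose):
        return self.value(dose)


@dataclass
class Trajectory:
    """Time-ordered positions of one fish in one arena.

    ``t`` is in seconds (strictly increasing), ``x``/``y`` in mm.
    ``condition`` is the nominal exposure concentration in µg/L.
    """

    fish_id: str
    condition: float
    arena: ArenaSpec
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("Trajectory t, x, y must have equal length")
        if len(self.t) < 3:
            raise ValueError("Trajectory needs at least 3 frames")
        for name in ("t", "x", "y"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"Trajectory.{name} contains non-finite values")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("Trajectory timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def positions(self) -> np.ndarray:
        """(n, 2) array of positions in mm."""
        return np.column_stack([self.x, self.y])

    def replace(self, **changes) -> "Trajectory":
        return dataclasses.replace(self, **changes)
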