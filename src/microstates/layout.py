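"""Standard 19-channel 10-20 sensor layout on the unit sphere.

Coordinates follow the idealized spherical 10-20 scheme: the head is a unit
sphere, Cz sits at the vertex (+z pole), the nasion direction is +y and the
subject's right is +x.  Midline and coronal electrodes lie at 20 %
increments of the nasion-inion / ear-to-ear arcs (36 deg of inclination per
step); the circumferential ring (Fp1/2, F7/8, T3/4, T5/6, O1/2) lies at
72 deg inclination with 10 % (36 deg) azimuthal spacing and Fp1/Fp2 at
+-18 deg off the midline.  F3/F4 and P3/P4 are placed at the spherical
midpoints of their neighbouring ring electrodes, as in the placement rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical channel order used throughout the package
CHANNELS_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

#: 10-20 synonyms (modern combinatorial names) -> classic names
CHANNEL_SYNONYMS = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}


def _unit(inclination_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector at given inclination from vertex and azimuth from nasion.

    Azimuth is measured from +y (nasion), positive toward the subject's left.
    """
    th = np.deg2rad(inclination_deg)
    az = np.deg2rad(azimuth_deg)
    return np.array([-np.sin(th) * np.sin(az), np.sin(th) * np.cos(az), np.cos(th)])


def _midpoint(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    m = a + b
    return m / np.linalg.norm(m)


@dataclass(frozen=True)
class SensorLayout:
    """Electrode names with unit-sphere 3D positions and a 2D projection."""

    channel_names: tuple[str, ...]
    positions: np.ndarray          # (n_channels, 3), unit norm rows
    positions_2d: np.ndarray = field(repr=False, default=None)  # (n_channels, 2)

    def __post_init__(self) -> None:
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("electrode positions must lie on the unit sphere")
        if self.positions_2d is None:
            object.__setattr__(self, "positions_2d", _project_2d(self.positions))

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        name = CHANNEL_SYNONYMS.get(name, name)
        return self.channel_names.index(name)


def _project_2d(positions: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant projection (vertex at the origin)."""
    z = np.clip(positions[:, 2], -1.0, 1.0)
    incl = np.arccos(z)
    r = incl / (np.pi / 2)
    xy = positions[:, :2].copy()
    plane = np.linalg.norm(xy, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xy = np.where(plane[:, None] > 0, xy / np.maximum(plane, 1e-300)[:, None], 0.0)
    return xy * r[:, None]


def make_layout() -> SensorLayout:
    """The canonical 19-channel 10-20 montage on the unit sphere."""
    pos: dict[str, np.ndarray] = {}
    pos["Cz"] = _unit(0.0, 0.0)
    pos["Fz"] = _unit(36.0, 0.0)
    pos["Pz"] = _unit(36.0, 180.0)
    pos["C3"] = _unit(36.0, 90.0)
    pos["C4"] = _unit(36.0, -90.0)
    ring = {
        "Fp1": 18.0, "Fp2": -18.0,
        "F7": 54.0, "F8": -54.0,
        "T3": 90.0, "T4": -90.0,
        "T5": 126.0, "T6": -126.0,
        "O1": 162.0, "O2": -162.0,
    }
    for name, az in ring.items():
        pos[name] = _unit(72.0, az)
    pos["F3"] = _midpoint(pos["Fz"], pos["F7"])
    pos["F4"] = _midpoint(pos["Fz"], pos["F8"])
    pos["P3"] = _midpoint(pos["Pz"], pos["T5"])
    pos["P4"] = _midpoint(pos["Pz"], pos["T6"])
    positions = np.array([pos[name] for name in CHANNELS_1020])
    return SensorLayout(channel_names=CHANNELS_1020, positions=positions)
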