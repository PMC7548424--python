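"""32-channel 10/20 recording montage: positions, mirror pairs, electrode subsets.

The montage is the single source of truth for electrode bookkeeping used
throughout the pipeline: left/right mirror swapping, the 13-electrode
posterior subset entering the biomarkers, and spatial adjacency for
cluster-based statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["Montage", "standard_montage", "POSTERIOR_13", "MIDLINE"]

# (inclination from vertex, azimuth from nasion; degrees, negative = left)
_POSITIONS_DEG: dict[str, tuple[float, float]] = {
    "FP1": (90, -18), "FP2": (90, 18),
    "F7": (90, -54), "F8": (90, 54),
    "F3": (62, -39), "F4": (62, 39),
    "Fz": (45, 0),
    "FC5": (72, -69), "FC6": (72, 69),
    "FC1": (31, -45), "FC2": (31, 45),
    "FCz": (22, 0),
    "T7": (90, -90), "T8": (90, 90),
    "C3": (45, -90), "C4": (45, 90),
    "Cz": (0, 0),
    "TP9": (108, -108), "TP10": (108, 108),
    "CP5": (72, -111), "CP6": (72, 111),
    "CP1": (31, -135), "CP2": (31, 135),
    "P7": (90, -126), "P8": (90, 126),
    "P3": (62, -141), "P4": (62, 141),
    "Pz": (45, 180),
    "O1": (90, -162), "O2": (90, 162),
    "F9": (108, -54), "F10": (108, 54),
}

_NAMES: tuple[str, ...] = (
    "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FCz",
    "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8", "TP9", "CP5", "CP1",
    "CP2", "CP6", "TP10", "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
    "F9", "F10",
)

POSTERIOR_13: tuple[str, ...] = (
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)

MIDLINE: tuple[str, ...] = ("Fz", "FCz", "Cz", "Pz")

_MIRROR_PAIRS: tuple[tuple[str, str], ...] = (
    ("FP1", "FP2"), ("F7", "F8"), ("F3", "F4"), ("FC5", "FC6"),
    ("FC1", "FC2"), ("T7", "T8"), ("C3", "C4"), ("TP9", "TP10"),
    ("CP5", "CP6"), ("CP1", "CP2"), ("P7", "P8"), ("P3", "P4"),
    ("O1", "O2"), ("F9", "F10"),
)


def _unit_position(inclination_deg: float, azimuth_deg: float) -> np.ndarray:
    """Head frame: +x right, +y nasion, +z vertex; unit sphere."""
    inc = np.deg2rad(inclination_deg)
    az = np.deg2rad(azimuth_deg)
    return np.array(
        [np.sin(inc) * np.sin(az), np.sin(inc) * np.cos(az), np.cos(inc)]
    )


@dataclass(frozen=True)
class Montage:
    """Electrode set with unit-sphere positions and left/right mirror map."""

    names: tuple[str, ...]
    positions: np.ndarray  # (n_electrodes, 3)
    mirror: Mapping[str, str]
    posterior: tuple[str, ...] = POSTERIOR_13
    midline: tuple[str, ...] = MIDLINE
    _index: Mapping[str, int] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {name: i for i, name in enumerate(self.names)}
        )

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self._index[name]

    def indices(self, names) -> np.ndarray:
        return np.array([self._index[n] for n in names], dtype=int)

    @property
    def posterior_indices(self) -> np.ndarray:
        return self.indices(self.posterior)

    def mirror_permutation(self) -> np.ndarray:
        """Index permutation exchanging each electrode with its mirror partner."""
        return np.array(
            [self._index[self.mirror[n]] for n in self.names], dtype=int
        )

    def adjacency(self, names=None, radius: float = 0.7) -> np.ndarray:
        """Boolean neighbor matrix for electrodes within ``radius`` chord units.

        Diagonal is False. Default radius connects nearest 10/20 neighbors
        (inter-electrode chord distances run ~0.45-0.65 on the unit sphere).
        """
        if names is None:
            names = self.names
        pos = self.positions[self.indices(names)]
        dists = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        adj = dists < radius
        np.fill_diagonal(adj, False)
        return adj


def standard_montage() -> Montage:
    """Build the 32-electrode 10/20 montage used for acquisition.

    Positions are idealized 10/20 placements on the unit sphere, exactly
    left/right symmetric about the nasion-inion plane; TP9/TP10 and F9/F10
    sit below the FP1-T7-O1 great circle.
    """
    positions = np.vstack([_unit_position(*_POSITIONS_DEG[n]) for n in _NAMES])
    mirror = {n: n for n in MIDLINE}
    for left, right in _MIRROR_PAIRS:
        mirror[left] = right
        mirror[right] = left
    return Montage(names=_NAMES, positions=positions, mirror=mirror)
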