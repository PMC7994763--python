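"""Electrode montage: 10/10 positions, earlobe references, and channel adjacency.

The recording layout emulated throughout the package is a 63-channel scalp
montage on the extended 10/10 system plus the two earlobe electrodes A1/A2
used for re-referencing.  Positions come from MNE's bundled ``standard_1005``
montage, re-centred by a least-squares sphere fit and projected onto the unit
sphere; adjacency is a great-circle distance rule used only by the
cluster-permutation statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

EARLOBES = ("A1", "A2")

# easycap-M1 74-channel list minus the inferior ring -> 63 scalp channels.
_SCALP_63 = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "Fz", "Cz", "Pz", "F1",
    "F2", "FC1", "FC2", "C1", "C2", "CP1", "CP2", "P1", "P2", "AF3",
    "AF4", "FC3", "FC4", "CP3", "CP4", "PO3", "PO4", "F5", "F6", "FC5",
    "FC6", "C5", "C6", "CP5", "CP6", "P5", "P6", "AF7", "AF8", "FT7",
    "FT8", "TP7", "TP8", "PO7", "PO8", "Fpz", "AFz", "FCz", "CPz", "POz",
    "Oz", "Iz", "TP9",
]
# keep exactly 63 entries; Iz/TP9 round out the cap where the inferior ring
# was dropped
assert len(_SCALP_63) == 63

#: great-circle adjacency threshold (rad); with realistic 10/10 coordinates
#: nearest-neighbour arcs run ~0.29-0.44 rad, so 0.5 rad links each channel
#: to its immediate ring (2-8 neighbours) without bridging across the cap
ADJACENCY_RADIUS_RAD = 0.5

DEFAULT_HEAD_RADIUS_MM = 92.0


class MontageError(ValueError):
    """Raised when a montage cannot be constructed as requested."""


@dataclass
class Montage:
    """Channel labels, unit-sphere positions and neighbour relation.

    Attributes
    ----------
    labels : list of str
        Scalp channels first, then the earlobe channels.
    positions : ndarray, shape (n_channels, 3)
        Unit vectors on the fitted sphere.
    head_radius_mm : float
        Physical head radius used to give the surface Laplacian units.
    adjacency : ndarray of bool, shape (n_scalp, n_scalp)
        Symmetric, irreflexive neighbour relation over scalp channels.
    """

    labels: list[str]
    positions: np.ndarray
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
    adjacency: np.ndarray = field(default=None, repr=False)

    @property
    def scalp_labels(self) -> list[str]:
        return [l for l in self.labels if l not in EARLOBES]

    @property
    def n_scalp(self) -> int:
        return len(self.scalp_labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def positions_for(self, labels) -> np.ndarray:
        return self.positions[[self.index(l) for l in labels]]

    def neighbours(self, label: str) -> list[str]:
        scalp = self.scalp_labels
        i = scalp.index(label)
        return [scalp[j] for j in np.flatnonzero(self.adjacency[i])]


def _standard_positions(labels) -> np.ndarray:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mont = mne.channels.make_standard_montage("standard_1005")
    pos = mont.get_positions()["ch_pos"]
    missing = [l for l in labels if l not in pos]
    if missing:
        raise MontageError(f"labels absent from standard_1005: {missing}")
    return np.array([pos[l] for l in labels], dtype=float)


def _fit_unit_sphere(xyz: np.ndarray, n_fit: int) -> np.ndarray:
    """Least-squares sphere fit on the first ``n_fit`` rows, then normalise."""
    x = xyz[:n_fit]
    a = np.c_[2.0 * x, np.ones(len(x))]
    b = (x**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    centre = sol[:3]
    u = xyz - centre
    return u / np.linalg.norm(u, axis=1, keepdims=True)


def great_circle_distances(positions: np.ndarray) -> np.ndarray:
    """Pairwise great-circle (arc) distances between unit vectors, in rad."""
    return np.arccos(np.clip(positions @ positions.T, -1.0, 1.0))


def build_adjacency(positions: np.ndarray,
                    radius_rad: float = ADJACENCY_RADIUS_RAD) -> np.ndarray:
    d = great_circle_distances(positions)
    adj = (d < radius_rad) & (d > 1e-9)
    np.fill_diagonal(adj, False)
    return adj


def make_montage(n_scalp: int = 63, seed: int | None = None,
                 head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM) -> Montage:
    """Build the 63-channel 10/10 montage with A1/A2 earlobes.

    Parameters
    ----------
    n_scalp : int
        Number of scalp channels; only the built-in 63-channel table is
        supported.
    seed : int, optional
        Unused; accepted for a uniform construction signature.

    Raises
    ------
    MontageError
        If ``n_scalp`` is not covered by the built-in label table.
    """
    if n_scalp != 63:
        raise MontageError(
            f"n_scalp={n_scalp} not supported; built-in table has 63 scalp "
            "channels")
    labels = list(_SCALP_63) + list(EARLOBES)
    xyz = _standard_positions(labels)
    positions = _fit_unit_sphere(xyz, n_fit=n_scalp)
    adjacency = build_adjacency(positions[:n_scalp])
    return Montage(labels=labels, positions=positions,
                   head_radius_mm=head_radius_mm, adjacency=adjacency)
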