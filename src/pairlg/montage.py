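"""64-channel 10-20 montage, neighbor graph, and nested sensor subsets.

Electrode positions come from MNE's standard 10-05 template; the 64 labels
mirror a typical 64-channel ANT cap (including the mastoids M1/M2 used for
offline re-referencing and CPz, the online reference).  The channel
adjacency used by the spatiotemporal cluster statistics is a Delaunay
triangulation of the azimuthally projected positions with overlong edges
pruned, which reproduces the usual "neighboring electrodes" notion of
sensor-level EEG statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import Delaunay

__all__ = ["CHANNELS_64", "SUBSETS", "Montage", "standard_montage"]

CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "M1", "T7", "C3", "Cz",
    "C4", "T8", "M2", "CP5", "CP1", "CP2", "CP6", "P7",
    "P3", "Pz", "P4", "P8", "POz", "O1", "Oz", "O2",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FC3", "FCz", "FC4", "C5", "C1", "C2", "C6", "CP3",
    "CPz", "CP4", "P5", "P1", "P2", "P6", "PO5", "PO3",
    "PO4", "PO6", "FT7", "FT8", "TP7", "TP8", "PO7", "PO8",
)

_SUBSET_8 = ("Fz", "Cz", "Pz", "C3", "C4", "P3", "P4", "Oz")
_SUBSET_16 = _SUBSET_8 + ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "P7", "P8")
_SUBSET_32 = _SUBSET_16 + (
    "FC1", "FC2", "FC5", "FC6", "CP1", "CP2", "CP5", "CP6",
    "T7", "T8", "O1", "O2", "AF3", "AF4", "FCz", "POz",
)

#: Nested sensor subsets emulating realistic 8/16/32/64-channel caps.
SUBSETS: dict[int, tuple[str, ...]] = {
    8: _SUBSET_8,
    16: _SUBSET_16,
    32: _SUBSET_32,
    64: CHANNELS_64,
}

#: Channels excluded from analysis maps and classifier features.
REFERENCE_CHANNELS: tuple[str, str] = ("M1", "M2")


@dataclass
class Montage:
    labels: tuple[str, ...]
    positions: np.ndarray               # (n, 3) unit-sphere coordinates
    adjacency: np.ndarray               # (n, n) bool, symmetric, no self-edges
    subsets: dict[int, tuple[str, ...]] = field(default_factory=dict)
    online_reference: str = "CPz"
    offline_reference: tuple[str, str] = REFERENCE_CHANNELS

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def indices(self, labels) -> np.ndarray:
        return np.array([self.index(l) for l in labels], dtype=int)

    @property
    def analysis_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if l not in self.offline_reference)

    def sub_adjacency(self, labels) -> np.ndarray:
        idx = self.indices(labels)
        return self.adjacency[np.ix_(idx, idx)]


def _project_2d(pos: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant projection of unit-sphere electrode positions."""
    x, y, z = pos.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))   # angle from vertex
    phi = np.arctan2(y, x)
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


def _delaunay_adjacency(pts2d: np.ndarray, prune_factor: float = 1.5) -> np.ndarray:
    n = len(pts2d)
    adj = np.zeros((n, n), dtype=bool)
    tri = Delaunay(pts2d)
    for simplex in tri.simplices:
        for a in range(3):
            i, j = simplex[a], simplex[(a + 1) % 3]
            adj[i, j] = adj[j, i] = True
    lengths = np.linalg.norm(pts2d[:, None] - pts2d[None, :], axis=-1)
    cutoff = prune_factor * np.median(lengths[adj]) if adj.any() else np.inf
    adj &= lengths <= cutoff
    np.fill_diagonal(adj, False)
    return adj


@lru_cache(maxsize=2)
def standard_montage() -> Montage:
    """Build the 64-channel montage with positions, adjacency, and subsets."""
    import mne

    try:
        std = mne.channels.make_standard_montage("colin27_1005")
    except ValueError:  # older MNE naming
        std = mne.channels.make_standard_montage("standard_1005")
    ch_pos = std.get_positions()["ch_pos"]
    pos = np.array([ch_pos[name] for name in CHANNELS_64], dtype=float)
    pos -= pos.mean(axis=0)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    adj = _delaunay_adjacency(_project_2d(pos))
    return Montage(labels=CHANNELS_64, positions=pos, adjacency=adj,
                   subsets=dict(SUBSETS))
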