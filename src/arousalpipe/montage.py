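"""64-channel EEG montage with 2-D coordinates and neighbor computation.

The package ships a static 10-20/10-10 layout (actiCap-64 style naming) whose
flat coordinates are a projection of the standard spherical electrode
positions.  Channel adjacency -- needed for spatiotemporal clustering -- is
derived from pairwise distances with a configurable cutoff.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

#: Centroparietal channels used for P300 mean-amplitude extraction.
CENTROPARIETAL_24 = (
    "C3", "CP5", "CP1", "Pz", "P3", "P4", "P8", "CP6", "CP2", "C4", "C1",
    "C5", "CP3", "P1", "P5", "PO7", "PO3", "PO4", "P6", "P2", "CPz", "CP4",
    "C2", "Cz",
)


@dataclass(frozen=True)
class Montage:
    """Channel names and 2-D coordinates (meters, head-centered)."""

    names: tuple[str, ...]
    xy: np.ndarray  # (n_channels, 2)

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def subset(self, names) -> "Montage":
        idx = [self.index(n) for n in names]
        return Montage(tuple(self.names[i] for i in idx), self.xy[idx])

    def adjacency(self, cutoff: float | None = None) -> np.ndarray:
        """Boolean neighbor matrix from the distance ``cutoff`` (meters).

        The default cutoff is chosen so that the median neighbor count on the
        shipped 64-channel layout is in the 4-8 range.  The matrix is
        symmetric with a zero diagonal.
        """
        if cutoff is None:
            cutoff = default_cutoff(self)
        d = np.linalg.norm(self.xy[:, None, :] - self.xy[None, :, :], axis=-1)
        adj = d <= cutoff
        np.fill_diagonal(adj, False)
        return adj


def default_cutoff(montage: Montage) -> float:
    """Distance cutoff = 1.6x the median nearest-neighbor distance."""
    d = np.linalg.norm(montage.xy[:, None, :] - montage.xy[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return 1.6 * float(np.median(d.min(axis=1)))


def load_montage(n_channels: int = 64) -> Montage:
    """Load the shipped montage, optionally truncated to its first channels.

    Truncation keeps a valid sub-layout for scaled-down simulations (e.g.
    24-channel calibration cohorts).
    """
    ref = resources.files("arousalpipe.data").joinpath("montage64.csv")
    names: list[str] = []
    xy: list[tuple[float, float]] = []
    with ref.open() as fh:
        for row in csv.DictReader(fh):
            names.append(row["name"])
            xy.append((float(row["x"]), float(row["y"])))
    if not 1 <= n_channels <= len(names):
        raise ValueError(f"n_channels must be in [1, {len(names)}]")
    return Montage(tuple(names[:n_channels]), np.asarray(xy[:n_channels]))
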