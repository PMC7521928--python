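"""Core containers: rectangular image frames and the annotated cells they hold.

Coordinates are continuous micrometres with the origin at the lower-left
corner of the image; annotation exports are assumed to be converted to μm
upstream.  Only X and Y are used — the myenteric plexus is treated as a
two-dimensional sheet.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

# Default phenotype vocabulary for the EdU pulse-chase experiment:
# her4.3:EGFP marks the glial/progenitor compartment, HuC/D marks neurons,
# EdU marks cells that passed through S-phase during the pulse.
GLIA_EDU = "GFP+EdU+"
NEURON_EDU = "HuC/D+EdU+"
GLIA = "GFP+EdU-"
NEURON = "HuC/D+EdU-"
OTHER = "other"

DEFAULT_VOCABULARY: tuple[str, ...] = (GLIA_EDU, NEURON_EDU, GLIA, NEURON, OTHER)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangular image frame with origin fixed at (0, 0)."""

    width: float = 450.0
    height: float = 450.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(f"frame dimensions must be positive, got {self.width} x {self.height}")

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x, y) -> np.ndarray:
        """Boundary-inclusive membership test, vectorised."""
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height)


@dataclass(frozen=True)
class CellRecord:
    """One annotated nucleus."""

    x: float
    y: float
    phenotype: str
    image_id: str = ""
    fish_id: str = ""
    group: str = ""


@dataclass
class ImageFrame:
    """A rectangular field of annotated cells; the unit of reshuffling.

    ``pair_id`` optionally records ground-truth doublet membership from the
    synthetic generator (-1 = background cell); it survives file round-trips
    so parameter-recovery tests can use it, and is ignored by the analysis.
    """

    image_id: str
    rect: Rect
    x: np.ndarray
    y: np.ndarray
    phenotype: np.ndarray
    fish_id: str = ""
    group: str = ""
    pair_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.phenotype = np.asarray(self.phenotype, dtype=object)
        if not (self.x.shape == self.y.shape == self.phenotype.shape):
            raise ValueError("x, y and phenotype must have identical length")
        if self.pair_id is not None:
            self.pair_id = np.asarray(self.pair_id, dtype=int)
            if self.pair_id.shape != self.x.shape:
                raise ValueError("pair_id must have one entry per cell")
        if self.x.size and not np.all(self.rect.contains(self.x, self.y)):
            bad = int(np.flatnonzero(~self.rect.contains(self.x, self.y))[0])
            raise ValueError(
                f"cell {bad} at ({self.x[bad]:g}, {self.y[bad]:g}) lies outside the "
                f"{self.rect.width:g} x {self.rect.height:g} frame"
            )

    @property
    def n_cells(self) -> int:
        return int(self.x.size)

    def phenotype_counts(self) -> Counter:
        return Counter(self.phenotype.tolist())

    def indices_of(self, phenotype: str) -> np.ndarray:
        return np.flatnonzero(self.phenotype == phenotype)

    def cells(self):
        """Iterate as CellRecord objects (convenience for small frames)."""
        for i in range(self.n_cells):
            yield CellRecord(
                float(self.x[i]), float(self.y[i]), str(self.phenotype[i]),
                self.image_id, self.fish_id, self.group,
            )
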