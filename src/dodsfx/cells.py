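"""Unit-cell and indexed-frame containers.

An *indexed frame* is one detector exposure whose diffraction pattern was
successfully indexed: it carries the train it belongs to, its pulse position
within the train, the unit cell the indexer reported, and the photon energy
and detector distance that were *assumed* during indexing.  Because Bragg
angles are fixed by the recorded spot positions, the apparent cell scales
with the assumed wavelength and camera length — which is what the whole
calibration rests on.

Collections of frames are held in a pandas DataFrame with the columns in
:data:`FRAME_COLUMNS`; the dataclasses here are the record-level view used
at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

#: Cell parameter names in canonical order (lengths in Å, angles in degrees).
CELL_PARAMS = ("a", "b", "c", "alpha", "beta", "gamma")
CELL_LENGTHS = ("a", "b", "c")
CELL_ANGLES = ("alpha", "beta", "gamma")

#: DataFrame schema for frame collections.
FRAME_COLUMNS = (
    "train_id",
    "pulse_id",
    "indexed",
    "a",
    "b",
    "c",
    "alpha",
    "beta",
    "gamma",
    "photon_energy",
    "detector_distance",
)


@dataclass(frozen=True)
class UnitCell:
    """Six lattice parameters: a, b, c in Å; alpha, beta, gamma in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        for name in CELL_LENGTHS:
            if not getattr(self, name) > 0:
                raise ConfigurationError(name, "cell lengths must be > 0")
        for name in CELL_ANGLES:
            if not 0 < getattr(self, name) < 180:
                raise ConfigurationError(name, "cell angles must lie in (0, 180) degrees")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in CELL_PARAMS], dtype=float)

    @classmethod
    def from_array(cls, values) -> "UnitCell":
        return cls(*(float(v) for v in values))

    def scaled(self, factor: float) -> "UnitCell":
        """Cell with lengths multiplied by ``factor``; angles unchanged."""
        return UnitCell(self.a * factor, self.b * factor, self.c * factor,
                        self.alpha, self.beta, self.gamma)


@dataclass(frozen=True)
class IndexedFrame:
    """One indexed exposure (record view of a frame-table row)."""

    train_id: int
    pulse_id: int
    cell: UnitCell
    photon_energy: float  # eV assumed during indexing
    detector_distance: float  # mm assumed during indexing
    indexed: bool = True


def frames_to_dataframe(frames) -> pd.DataFrame:
    """Build the canonical frame table from IndexedFrame records."""
    rows = []
    for f in frames:
        rows.append((f.train_id, f.pulse_id, f.indexed,
                     *f.cell.as_array(), f.photon_energy, f.detector_distance))
    return pd.DataFrame(rows, columns=list(FRAME_COLUMNS))


def dataframe_to_frames(df: pd.DataFrame):
    """Iterate IndexedFrame records from a frame table."""
    for row in df.itertuples(index=False):
        yield IndexedFrame(
            train_id=int(row.train_id),
            pulse_id=int(row.pulse_id),
            cell=UnitCell(row.a, row.b, row.c, row.alpha, row.beta, row.gamma),
            photon_energy=float(row.photon_energy),
            detector_distance=float(row.detector_distance),
            indexed=bool(row.indexed),
        )
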