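"""Read/write the subset of the CrystFEL stream format the pipeline needs.

Only the post-indexing content is handled: chunk boundaries, the event
identifier carrying train and pulse, the indexing flag, the per-chunk photon
energy and camera length, and the crystal "Cell parameters" line.
Reflection lists and geometry blocks are skipped.  Cell lengths appear in nm
in stream files and are converted to Å on read.

Event-id convention: ``Event: //<train_id>-<pulse_id>`` with pulse_id
0-based within the train (CrystFEL leaves the event string free-form; this
is the convention this package both writes and expects).

Masks are stored as JSON (shape + masked pixel list + provenance), with an
optional flat 0/1 text-matrix export; per-pixel statistic maps go to HDF5 or
plain-text matrices.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cells import FRAME_COLUMNS, UnitCell
from .exceptions import MaskShapeError, StreamParseError, StreamValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "StreamChunk",
    "MaskFile",
    "read_stream",
    "write_stream",
    "read_stream_dataframe",
    "write_stream_dataframe",
    "read_mask",
    "write_mask",
    "write_mask_matrix",
    "read_pixel_stats",
    "write_pixel_stats",
    "read_peaks",
    "write_peaks",
    "energy_wavelength",
    "HC_EV_ANGSTROM",
]

#: hc in eV·Å: E [eV] = HC_EV_ANGSTROM / λ [Å]
HC_EV_ANGSTROM = 12398.42

_BEGIN_CHUNK = "----- Begin chunk -----"
_END_CHUNK = "----- End chunk -----"
_BEGIN_CRYSTAL = "--- Begin crystal"
_END_CRYSTAL = "--- End crystal"

_EVENT_RE = re.compile(r"^Event:\s*//(\d+)-(\d+)\s*$")
_CELL_RE = re.compile(
    r"^Cell parameters\s+([-\d.eE+]+)\s+([-\d.eE+]+)\s+([-\d.eE+]+)\s+nm,"
    r"\s+([-\d.eE+]+)\s+([-\d.eE+]+)\s+([-\d.eE+]+)\s+deg\s*$"
)


@dataclass(frozen=True)
class StreamChunk:
    """One stream chunk: a single detector exposure, indexed or not."""

    train_id: int
    pulse_id: int
    indexed: bool
    cell: UnitCell | None
    photon_energy: float
    detector_distance: float  # mm

    def __post_init__(self):
        if self.indexed and self.cell is None:
            raise StreamValidationError(
                f"chunk //{self.train_id}-{self.pulse_id}: indexed chunk without a cell"
            )


def write_stream(chunks, path) -> None:
    """Write chunks to a CrystFEL-style stream (subset)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("CrystFEL stream format 2.3\n")
        fh.write("Generated by dodsfx\n")
        for i, ch in enumerate(chunks):
            fh.write(f"{_BEGIN_CHUNK}\n")
            fh.write("Image filename: synthetic.h5\n")
            fh.write(f"Event: //{ch.train_id}-{ch.pulse_id}\n")
            fh.write(f"Image serial number: {i}\n")
            fh.write(f"hit = {1 if ch.indexed else 0}\n")
            fh.write(f"indexed_by = {'xgandalf' if ch.indexed else 'none'}\n")
            fh.write(f"photon_energy_eV = {ch.photon_energy:.6f}\n")
            fh.write(f"average_camera_length = {ch.detector_distance / 1000.0:.6f} m\n")
            if ch.indexed:
                c = ch.cell
                fh.write(f"{_BEGIN_CRYSTAL}\n")
                fh.write(
                    "Cell parameters "
                    f"{c.a / 10.0:.7f} {c.b / 10.0:.7f} {c.c / 10.0:.7f} nm, "
                    f"{c.alpha:.5f} {c.beta:.5f} {c.gamma:.5f} deg\n"
                )
                fh.write(f"{_END_CRYSTAL}\n")
            fh.write(f"{_END_CHUNK}\n")


def read_stream(path) -> list[StreamChunk]:
    """Parse a stream (subset) into chunks.

    Unindexed chunks are retained with ``indexed=False``.  Malformed chunks
    raise :class:`StreamParseError` with the offending line number; an
    indexed chunk without a cell raises :class:`StreamValidationError`.
    """
    path = Path(path)
    chunks: list[StreamChunk] = []
    in_chunk = False
    fields: dict = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line == _BEGIN_CHUNK:
                if in_chunk:
                    raise StreamParseError(lineno, "nested 'Begin chunk'")
                in_chunk = True
                fields = {}
                continue
            if line == _END_CHUNK:
                if not in_chunk:
                    raise StreamParseError(lineno, "'End chunk' outside a chunk")
                chunks.append(_finish_chunk(fields, lineno))
                in_chunk = False
                continue
            if not in_chunk:
                continue
            _parse_chunk_line(line, lineno, fields)
    if in_chunk:
        raise StreamParseError(lineno, "unterminated chunk at end of file")
    if not chunks:
        logger.warning("stream %s contained no chunks", path)
    return chunks


def _parse_chunk_line(line: str, lineno: int, fields: dict) -> None:
    m = _EVENT_RE.match(line)
    if m:
        fields["train_id"] = int(m.group(1))
        fields["pulse_id"] = int(m.group(2))
        return
    if line.startswith("indexed_by"):
        try:
            fields["indexed"] = line.split("=", 1)[1].strip() != "none"
        except IndexError:
            raise StreamParseError(lineno, "malformed indexed_by line") from None
        return
    if line.startswith("photon_energy_eV"):
        fields["photon_energy"] = _parse_number(line, lineno)
        return
    if line.startswith("average_camera_length"):
        fields["detector_distance"] = _parse_number(line, lineno) * 1000.0  # m -> mm
        return
    if line.startswith("Cell parameters"):
        m = _CELL_RE.match(line)
        if not m:
            raise StreamParseError(lineno, f"malformed cell line: {line!r}")
        a, b, c, al, be, ga = (float(g) for g in m.groups())
        fields["cell"] = UnitCell(a * 10.0, b * 10.0, c * 10.0, al, be, ga)  # nm -> Å
        return
    # Everything else (filename, serial number, peak/reflection lists) is skipped.


def _parse_number(line: str, lineno: int) -> float:
    try:
        return float(line.split("=", 1)[1].split()[0])
    except (IndexError, ValueError):
        raise StreamParseError(lineno, f"malformed numeric line: {line!r}") from None


def _finish_chunk(fields: dict, lineno: int) -> StreamChunk:
    for required in ("train_id", "photon_energy"):
        if required not in fields:
            raise StreamParseError(lineno, f"chunk missing required field {required!r}")
    indexed = fields.get("indexed", "cell" in fields)
    return StreamChunk(
        train_id=fields["train_id"],
        pulse_id=fields.get("pulse_id", 0),
        indexed=indexed,
        cell=fields.get("cell"),
        photon_energy=fields["photon_energy"],
        detector_distance=fields.get("detector_distance", float("nan")),
    )


def write_stream_dataframe(frames, path) -> None:
    """Write a frame DataFrame (FRAME_COLUMNS schema) as a stream file."""
    chunks = (
        StreamChunk(
            train_id=int(r.train_id), pulse_id=int(r.pulse_id), indexed=bool(r.indexed),
            cell=UnitCell(r.a, r.b, r.c, r.alpha, r.beta, r.gamma) if r.indexed else None,
            photon_energy=float(r.photon_energy),
            detector_distance=float(r.detector_distance),
        )
        for r in frames.itertuples(index=False)
    )
    write_stream(chunks, path)


def read_stream_dataframe(path):
    """Read a stream file into the canonical frame DataFrame (indexed chunks only)."""
    import pandas as pd

    rows = []
    for ch in read_stream(path):
        if not ch.indexed:
            continue
        c = ch.cell
        rows.append((ch.train_id, ch.pulse_id, True, c.a, c.b, c.c,
                     c.alpha, c.beta, c.gamma, ch.photon_energy, ch.detector_distance))
    return pd.DataFrame(rows, columns=list(FRAME_COLUMNS))


# ---------------------------------------------------------------------------
# masks


@dataclass
class MaskFile:
    """Bad-pixel mask with per-pixel provenance.

    ``masked`` holds 0-based (row, col) pixels; ``provenance`` maps a pixel
    to the list of rule names that flagged it.
    """

    shape: tuple[int, int]
    masked: set = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.shape = (int(self.shape[0]), int(self.shape[1]))
        self.masked = {(int(r), int(c)) for r, c in self.masked}
        for r, c in self.masked:
            if not (0 <= r < self.shape[0] and 0 <= c < self.shape[1]):
                raise MaskShapeError(f"pixel ({r}, {c}) outside shape {self.shape}")
        extra = set(self.provenance) - self.masked
        if extra:
            raise MaskShapeError(f"provenance for unmasked pixels: {sorted(extra)[:5]}")

    @property
    def fraction(self) -> float:
        return len(self.masked) / (self.shape[0] * self.shape[1])

    def to_array(self) -> np.ndarray:
        """0/1 matrix with 1 = masked."""
        arr = np.zeros(self.shape, dtype=np.uint8)
        for r, c in self.masked:
            arr[r, c] = 1
        return arr


def write_mask(mask: MaskFile, path) -> None:
    payload = {
        "shape": list(mask.shape),
        "masked": sorted(list(p) for p in mask.masked),
        "provenance": {f"{r},{c}": sorted(rules) for (r, c), rules in mask.provenance.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_mask(path, expected_shape: tuple[int, int] | None = None) -> MaskFile:
    payload = json.loads(Path(path).read_text())
    shape = tuple(payload["shape"])
    if expected_shape is not None and tuple(expected_shape) != shape:
        raise MaskShapeError(f"mask shape {shape} != expected {tuple(expected_shape)}")
    provenance = {}
    for key, rules in payload.get("provenance", {}).items():
        r, c = key.split(",")
        provenance[(int(r), int(c))] = list(rules)
    return MaskFile(shape=shape, masked={tuple(p) for p in payload["masked"]},
                    provenance=provenance)


def write_mask_matrix(mask: MaskFile, path) -> None:
    """Flat 0/1 text-matrix export for interchange."""
    np.savetxt(path, mask.to_array(), fmt="%d")


# ---------------------------------------------------------------------------
# pixel statistics and peak lists

_STAT_NAMES = ("mean", "std", "skewness", "kurtosis")


def write_pixel_stats(stats: dict, path) -> None:
    """Write the four per-pixel statistic matrices to one HDF5 file."""
    import h5py

    with h5py.File(path, "w") as fh:
        for name in _STAT_NAMES:
            fh.create_dataset(name, data=np.asarray(stats[name], dtype=float))


def read_pixel_stats(path) -> dict:
    import h5py

    with h5py.File(path, "r") as fh:
        return {name: fh[name][...] for name in _STAT_NAMES}


def write_peaks(peaks, path) -> None:
    """Write a peak list (row, col, intensity, inv_d columns) as CSV."""
    peaks.to_csv(path, index=False)


def read_peaks(path):
    import pandas as pd

    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# unit conversion


def energy_wavelength(value: float, direction: str = "to_wavelength") -> float:
    """Convert photon energy (eV) <-> wavelength (Å).

    The relation E = hc/λ = 12398.42 eV·Å / λ is an involution: applying it
    twice returns the input.  ``direction`` is informational only.
    """
    if value <= 0:
        raise ValueError("energy/wavelength must be > 0")
    if direction not in ("to_wavelength", "to_energy"):
        raise ValueError(f"unknown direction {direction!r}")
    return HC_EV_ANGSTROM / value
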