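"""Chunk-delimited stream text format for processed still images.

The dialect follows the layout serial-crystallography stream files use:
a run is a sequence of chunks, one per detector image, each carrying the
image identifier, the two per-colour wavelengths, the peak table, and
zero, one or two crystal blocks (one per indexed colour) with cell,
wavelength and reflection table.  Lines the parser does not recognise are
preserved verbatim so foreign fields survive a round trip.

Grammar (docs/stream_dialect.md) in brief::

    ----- Begin chunk -----
    Image filename: <str>
    Acquisition number: <int>
    wavelength_A_1 = <float>
    wavelength_A_2 = <float>
    Peaks from peak search
      fast/px slow/px intensity/ADU snr
      <rows...>
    End of peak list
    --- Begin crystal
    Cell parameters <a> <b> <c> A, <alpha> <beta> <gamma> deg
    colour = <label>
    wavelength_A = <float>
    Reflections measured after indexing
      h k l intensity/ADU sigma/ADU fast/px slow/px
      <rows...>
    End of reflections
    --- End crystal
    ----- End chunk -----
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BEGIN_CHUNK = "----- Begin chunk -----"
END_CHUNK = "----- End chunk -----"
BEGIN_CRYSTAL = "--- Begin crystal"
END_CRYSTAL = "--- End crystal"

PEAK_COLUMNS = ["fast", "slow", "intensity", "snr"]
REFLECTION_COLUMNS = ["h", "k", "l", "intensity", "sigma", "fast", "slow"]


def _frames_close(a: pd.DataFrame, b: pd.DataFrame, rtol=1e-5) -> bool:
    """Table equality up to single-precision storage of the values."""
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    if len(a) == 0:
        return True
    return np.allclose(a.to_numpy(dtype=float), b.to_numpy(dtype=float),
                       rtol=rtol, atol=1e-4)


@dataclass
class CrystalBlock:
    cell: tuple[float, float, float, float, float, float]
    colour: str
    wavelength: float
    reflections: pd.DataFrame  # REFLECTION_COLUMNS

    def __eq__(self, other):
        return (isinstance(other, CrystalBlock)
                and np.allclose(self.cell, other.cell)
                and self.colour == other.colour
                and np.isclose(self.wavelength, other.wavelength)
                and _frames_close(self.reflections, other.reflections))


@dataclass
class StreamRecord:
    """One processed image: identity, beam state, peaks, solutions."""

    image_id: str
    acquisition_index: int
    wavelengths: tuple[float, float]
    peaks: pd.DataFrame  # PEAK_COLUMNS
    crystals: list[CrystalBlock] = field(default_factory=list)
    raw_lines: list[str] = field(default_factory=list)

    def __eq__(self, other):
        return (isinstance(other, StreamRecord)
                and self.image_id == other.image_id
                and self.acquisition_index == other.acquisition_index
                and np.allclose(self.wavelengths, other.wavelengths)
                and _frames_close(self.peaks, other.peaks)
                and self.crystals == other.crystals
                and self.raw_lines == other.raw_lines)


class StreamParseError(ValueError):
    pass


def parse_stream(text: str) -> list[StreamRecord]:
    """Single-pass parse of a stream document into records.

    Unbalanced chunk/crystal markers raise StreamParseError naming the
    offending line number (1-based).
    """
    records: list[StreamRecord] = []
    state = "outside"  # outside | chunk | peaks | crystal | reflections
    rec = crystal = None
    table_rows: list = []
    open_line = 0

    def finish_peaks():
        nonlocal table_rows
        rec.peaks = pd.DataFrame(table_rows, columns=PEAK_COLUMNS)
        table_rows = []

    def finish_reflections():
        nonlocal table_rows
        crystal.reflections = pd.DataFrame(table_rows, columns=REFLECTION_COLUMNS)
        crystal.reflections[["h", "k", "l"]] = crystal.reflections[
            ["h", "k", "l"]].astype(int)
        table_rows = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if state == "outside":
            if line == BEGIN_CHUNK:
                rec = StreamRecord("", -1, (0.0, 0.0),
                                   pd.DataFrame(columns=PEAK_COLUMNS))
                state, open_line = "chunk", lineno
            elif line in (END_CHUNK, BEGIN_CRYSTAL, END_CRYSTAL):
                raise StreamParseError(f"unexpected {line!r} at line {lineno}")
            # text between chunks is ignored
            continue
        if line == BEGIN_CHUNK:
            raise StreamParseError(
                f"nested chunk at line {lineno} (chunk opened at {open_line})")
        if state == "chunk":
            if line == END_CHUNK:
                records.append(rec)
                rec, state = None, "outside"
            elif line.startswith("Image filename:"):
                rec.image_id = line.partition(":")[2].strip()
            elif line.startswith("Acquisition number:"):
                rec.acquisition_index = int(line.partition(":")[2])
            elif line.startswith("wavelength_A_1"):
                rec.wavelengths = (float(line.partition("=")[2]),
                                   rec.wavelengths[1])
            elif line.startswith("wavelength_A_2"):
                rec.wavelengths = (rec.wavelengths[0],
                                   float(line.partition("=")[2]))
            elif line == "Peaks from peak search":
                state = "peaks"
            elif line == BEGIN_CRYSTAL:
                crystal = CrystalBlock((0,) * 6, "", 0.0,
                                       pd.DataFrame(columns=REFLECTION_COLUMNS))
                state = "crystal"
            elif line:
                rec.raw_lines.append(raw)
        elif state == "peaks":
            if line == "End of peak list":
                finish_peaks()
                state = "chunk"
            elif line.startswith("fast/px"):
                continue  # header
            else:
                vals = line.split()
                if len(vals) != len(PEAK_COLUMNS):
                    raise StreamParseError(
                        f"malformed peak row at line {lineno}: {raw!r}")
                table_rows.append([float(v) for v in vals])
        elif state == "crystal":
            if line == END_CRYSTAL:
                rec.crystals.append(crystal)
                crystal, state = None, "chunk"
            elif line.startswith("Cell parameters"):
                parts = line.replace("A,", "").replace("deg", "").split()[2:]
                crystal.cell = tuple(float(v) for v in parts[:6])
            elif line.startswith("colour"):
                crystal.colour = line.partition("=")[2].strip()
            elif line.startswith("wavelength_A"):
                crystal.wavelength = float(line.partition("=")[2])
            elif line == "Reflections measured after indexing":
                state = "reflections"
            elif line:
                rec.raw_lines.append(raw)
        elif state == "reflections":
            if line == "End of reflections":
                finish_reflections()
                state = "crystal"
            elif line.startswith("h k l") or line.startswith("h  k"):
                continue
            else:
                vals = line.split()
                if len(vals) != len(REFLECTION_COLUMNS):
                    raise StreamParseError(
                        f"malformed reflection row at line {lineno}: {raw!r}")
                table_rows.append([float(v) for v in vals])
    if state != "outside":
        raise StreamParseError(
            f"unterminated block (opened at line {open_line})")
    return records


def write_stream(records) -> str:
    """Inverse of parse_stream (up to float formatting)."""
    out = []
    for rec in records:
        out.append(BEGIN_CHUNK)
        out.append(f"Image filename: {rec.image_id}")
        out.append(f"Acquisition number: {rec.acquisition_index}")
        out.append(f"wavelength_A_1 = {rec.wavelengths[0]:.6f}")
        out.append(f"wavelength_A_2 = {rec.wavelengths[1]:.6f}")
        out.extend(rec.raw_lines)
        out.append("Peaks from peak search")
        out.append("  fast/px slow/px intensity/ADU snr")
        for r in rec.peaks.itertuples(index=False):
            out.append(f"  {r.fast:.3f} {r.slow:.3f} {r.intensity:.3f} {r.snr:.3f}")
        out.append("End of peak list")
        for c in rec.crystals:
            out.append(BEGIN_CRYSTAL)
            a, b, cc, al, be, ga = c.cell
            out.append(f"Cell parameters {a:.4f} {b:.4f} {cc:.4f} A, "
                       f"{al:.4f} {be:.4f} {ga:.4f} deg")
            out.append(f"colour = {c.colour}")
            out.append(f"wavelength_A = {c.wavelength:.6f}")
            out.append("Reflections measured after indexing")
            out.append("  h k l intensity/ADU sigma/ADU fast/px slow/px")
            for r in c.reflections.itertuples(index=False):
                out.append(f"  {int(r.h)} {int(r.k)} {int(r.l)} "
                           f"{r.intensity:.3f} {r.sigma:.3f} "
                           f"{r.fast:.3f} {r.slow:.3f}")
            out.append("End of reflections")
            out.append(END_CRYSTAL)
        out.append(END_CHUNK)
    return "\n".join(out) + ("\n" if out else "")
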