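"""HDF5 run container: the package's native exchange format.

Layout (one file per run)::

    /config            seed and free-text configuration echo (attrs)
    /log               string dataset of log lines
    /records/<iii>     one group per stream record / image:
        attrs: image_id, acquisition_index, wavelength_1, wavelength_2
        peaks              (n, 4) float  [fast, slow, intensity, snr]
        crystal_<k>/       attrs: colour, wavelength, cell (6 floats)
            reflections    (n, 7) float [h k l I sigma fast slow]
    /images/<iii>      optional raw detector images
    /spectra/<iii>     optional spectrometer traces / fit parameters

Datasets are written with track_times disabled so identical inputs give
byte-identical files.  Every group records the producing operation in a
`provenance` attribute.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import h5py

from .streamio import (
    CrystalBlock,
    PEAK_COLUMNS,
    REFLECTION_COLUMNS,
    StreamRecord,
)


def _write_ds(group, name, data):
    group.create_dataset(name, data=np.asarray(data), track_times=False)


def write_container(records, path, seed: int | None = None,
                    config_text: str = "", log_lines=(), images=None,
                    spectra=None) -> None:
    """Serialise stream records (plus optional images/spectra) to HDF5."""
    with h5py.File(path, "w", track_order=True) as fh:
        cfg = fh.create_group("config")
        cfg.attrs["provenance"] = "sfx2c.container.write_container"
        if seed is not None:
            cfg.attrs["seed"] = int(seed)
        cfg.attrs["config_text"] = config_text
        _write_ds(fh, "log", np.array(list(log_lines), dtype="S256"))
        recs = fh.create_group("records")
        for i, rec in enumerate(records):
            g = recs.create_group(f"{i:06d}")
            g.attrs["image_id"] = rec.image_id
            g.attrs["acquisition_index"] = int(rec.acquisition_index)
            g.attrs["wavelength_1"] = float(rec.wavelengths[0])
            g.attrs["wavelength_2"] = float(rec.wavelengths[1])
            g.attrs["units"] = "wavelengths: Angstrom; peaks: px, ADU"
            g.attrs["raw_lines"] = "\n".join(rec.raw_lines)
            _write_ds(g, "peaks",
                      rec.peaks[PEAK_COLUMNS].to_numpy(dtype=np.float32))
            for k, c in enumerate(rec.crystals):
                cg = g.create_group(f"crystal_{k}")
                cg.attrs["colour"] = c.colour
                cg.attrs["wavelength"] = float(c.wavelength)
                cg.attrs["cell"] = np.asarray(c.cell, dtype=float)
                _write_ds(cg, "reflections",
                          c.reflections[REFLECTION_COLUMNS].to_numpy(
                              dtype=np.float32))
        if images is not None:
            ig = fh.create_group("images")
            for i, img in enumerate(images):
                _write_ds(ig, f"{i:06d}", np.asarray(img, dtype=np.float32))
        if spectra is not None:
            sg = fh.create_group("spectra")
            for i, tr in enumerate(spectra):
                _write_ds(sg, f"{i:06d}", np.asarray(tr, dtype=np.float32))


def read_container(path) -> list[StreamRecord]:
    """Read back the stream records of a container."""
    records = []
    with h5py.File(path, "r") as fh:
        if "records" not in fh:
            raise IOError(f"{path}: not an sfx2c run container")
        for name in sorted(fh["records"]):
            g = fh["records"][name]
            raw = g.attrs.get("raw_lines", "")
            rec = StreamRecord(
                image_id=str(g.attrs["image_id"]),
                acquisition_index=int(g.attrs["acquisition_index"]),
                wavelengths=(float(g.attrs["wavelength_1"]),
                             float(g.attrs["wavelength_2"])),
                peaks=pd.DataFrame(np.asarray(g["peaks"]),
                                   columns=PEAK_COLUMNS),
                raw_lines=raw.split("\n") if raw else [],
            )
            for key in sorted(k for k in g if k.startswith("crystal_")):
                cg = g[key]
                refl = pd.DataFrame(np.asarray(cg["reflections"]),
                                    columns=REFLECTION_COLUMNS)
                refl[["h", "k", "l"]] = refl[["h", "k", "l"]].astype(int)
                rec.crystals.append(CrystalBlock(
                    cell=tuple(float(v) for v in cg.attrs["cell"]),
                    colour=str(cg.attrs["colour"]),
                    wavelength=float(cg.attrs["wavelength"]),
                    reflections=refl,
                ))
            records.append(rec)
    return records


def read_images(path) -> list[np.ndarray]:
    with h5py.File(path, "r") as fh:
        if "images" not in fh:
            return []
        return [np.asarray(fh["images"][k]) for k in sorted(fh["images"])]


def container_seed(path) -> int | None:
    with h5py.File(path, "r") as fh:
        return int(fh["config"].attrs["seed"]) if "seed" in fh["config"].attrs else None
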