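"""Readers/writers for the portable HDF5 container and CSV exchange tables.

Container layout (schema version 1)::

    /                         attrs: ibspec_schema, kind ("pair" | "dataset")
    /transform                (pairs only, optional) 3x3 alignment matrix
    /maps/<wavenumber>/       attrs: wavenumber, pixel_size_nm, fov_w_um,
                                     fov_h_um, sample_id, session_id
    /maps/<wn>/<channel>/<direction>/data   2D float64
    /maps/<wn>/<channel>/<direction>/mask   2D bool (only when masked)

Round-trips are bit-identical for all arrays and lossless for metadata.
Vendor binary formats are intentionally not parsed; convert instrument
exports to TIFF/CSV and assemble datasets with these types instead.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .data_model import (
    AFMIRDataset,
    Category,
    ChannelMap,
    DatasetPair,
    DEFAULT_UNITS,
    Spectrum,
    WavenumberGrid,
)

SCHEMA_VERSION = 1

#: Channels every complete dataset must carry (trace direction).
REQUIRED_TRACE_CHANNELS = (
    ("Height", "trace"),
    ("Deflection", "trace"),
    ("IRAmplitude", "trace"),
    ("PLLFrequency", "trace"),
    ("IRPhase", "trace"),
)


def _write_dataset(root: h5py.Group, ds: AFMIRDataset) -> None:
    g = root.require_group(f"maps/{ds.wavenumber:g}")
    g.attrs["wavenumber"] = float(ds.wavenumber)
    g.attrs["pixel_size_nm"] = float(ds.pixel_size_nm)
    g.attrs["fov_w_um"] = float(ds.field_of_view_um[0])
    g.attrs["fov_h_um"] = float(ds.field_of_view_um[1])
    g.attrs["sample_id"] = ds.sample_id
    g.attrs["session_id"] = ds.session_id
    for (ch, direction), cm in ds.channels.items():
        cg = g.require_group(f"{ch}/{direction}")
        cg.create_dataset("data", data=cm.data)
        cg.attrs["units"] = cm.units
        if cm.mask is not None:
            cg.create_dataset("mask", data=cm.mask)


def _read_dataset(g: h5py.Group, strict: bool) -> AFMIRDataset:
    channels: dict[tuple[str, str], ChannelMap] = {}
    for ch in g:
        for direction in g[ch]:
            cg = g[ch][direction]
            mask = cg["mask"][()] if "mask" in cg else None
            channels[(ch, direction)] = ChannelMap(
                channel=ch,
                direction=direction,
                data=cg["data"][()],
                units=str(cg.attrs.get("units", "")),
                mask=mask,
            )
    if strict:
        missing = [f"{c}/{d}" for c, d in REQUIRED_TRACE_CHANNELS if (c, d) not in channels]
        if missing:
            raise KeyError(f"container missing required channel(s): {', '.join(missing)}")
    return AFMIRDataset(
        wavenumber=float(g.attrs["wavenumber"]),
        channels=channels,
        field_of_view_um=(float(g.attrs["fov_w_um"]), float(g.attrs["fov_h_um"])),
        pixel_size_nm=float(g.attrs["pixel_size_nm"]),
        sample_id=str(g.attrs.get("sample_id", "")),
        session_id=str(g.attrs.get("session_id", "")),
    )


def write_container(obj: DatasetPair | AFMIRDataset, path) -> None:
    """Write a dataset or dataset pair to a single-file HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["ibspec_schema"] = SCHEMA_VERSION
        if isinstance(obj, DatasetPair):
            f.attrs["kind"] = "pair"
            _write_dataset(f, obj.ds_1650)
            _write_dataset(f, obj.ds_1625)
            if obj.transform is not None:
                f.create_dataset("transform", data=obj.transform)
        elif isinstance(obj, AFMIRDataset):
            f.attrs["kind"] = "dataset"
            _write_dataset(f, obj)
        else:
            raise TypeError(f"cannot write object of type {type(obj).__name__}")


def read_container(path, strict: bool = True) -> DatasetPair | AFMIRDataset:
    """Read a container written by :func:`write_container`.

    With ``strict`` (default) every dataset must contain the five canonical
    trace channels; a missing one raises ``KeyError`` naming it.
    """
    with h5py.File(path, "r") as f:
        kind = f.attrs.get("kind")
        datasets = {
            float(f["maps"][k].attrs["wavenumber"]): _read_dataset(f["maps"][k], strict)
            for k in f["maps"]
        }
        if kind == "pair":
            transform = f["transform"][()] if "transform" in f else None
            return DatasetPair(
                ds_1650=datasets[1650.0], ds_1625=datasets[1625.0], transform=transform
            )
        if len(datasets) != 1:
            raise ValueError("single-dataset container holds multiple datasets")
        return next(iter(datasets.values()))


_SPECTRA_COLUMNS = [
    "spectrum_id",
    "wavenumber",
    "amplitude",
    "pll",
    "sample_id",
    "session_id",
    "category",
    "x_um",
    "y_um",
]


def export_spectra_table(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra as a long-format CSV (one row per grid point).

    All spectra must share a common wavenumber grid.  Numeric round-trip is
    lossless at float64 precision.
    """
    spectra = list(spectra)
    if spectra:
        g0 = spectra[0].grid
        for s in spectra[1:]:
            if not g0.matches(s.grid):
                raise ValueError("spectra have mixed wavenumber grids")
    frames = []
    for i, s in enumerate(spectra):
        n = len(s.grid)
        frames.append(
            pd.DataFrame(
                {
                    "spectrum_id": np.full(n, i),
                    "wavenumber": s.grid.values,
                    "amplitude": s.ir_amplitude,
                    "pll": s.pll_frequency if s.pll_frequency is not None else np.full(n, np.nan),
                    "sample_id": s.sample_id,
                    "session_id": s.session_id,
                    "category": s.category.value,
                    "x_um": s.position[0] if s.position else np.nan,
                    "y_um": s.position[1] if s.position else np.nan,
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=_SPECTRA_COLUMNS)
    # %.17g round-trips float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")


def import_spectra_table(path) -> list[Spectrum]:
    """Read spectra from a CSV written by :func:`export_spectra_table`."""
    df = pd.read_csv(path, float_precision="round_trip")
    out: list[Spectrum] = []
    for _, sub in df.groupby("spectrum_id", sort=True):
        sub = sub.sort_values("wavenumber")
        grid = WavenumberGrid(sub["wavenumber"].to_numpy())
        pll = sub["pll"].to_numpy()
        x = sub["x_um"].iloc[0]
        out.append(
            Spectrum(
                grid=grid,
                ir_amplitude=sub["amplitude"].to_numpy(),
                pll_frequency=None if np.all(np.isnan(pll)) else pll,
                sample_id=str(sub["sample_id"].iloc[0]),
                session_id=str(sub["session_id"].iloc[0]),
                category=Category(sub["category"].iloc[0]),
                position=None
                if pd.isna(x)
                else (float(x), float(sub["y_um"].iloc[0])),
            )
        )
    return out


def export_channel_tiff(cm: ChannelMap, path) -> None:
    """Export one channel as a 32-bit float TIFF for interoperability."""
    import tifffile

    tifffile.imwrite(path, cm.data.astype(np.float32))
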