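"""File formats: recordings (EDF or delimited matrix + JSON sidecar), cohort
manifests, and HDF5 containers for band-filtered data and IAC tensors."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dfc_core import IACTensor
from .preprocess import BandFilteredSet
from .recording import BandDefinition, EEGRecording

_DELIMITED = {".csv": ",", ".tsv": "\t", ".txt": None}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_recording(path, fs: float | None = None) -> EEGRecording:
    """Read an EEG recording from EDF, a delimited channels x samples matrix
    with a ``<file>.<ext>.json`` sidecar (fs, labels, metadata), or an HDF5
    container written by :func:`write_recording`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        import mne  # EDF parsing is delegated to MNE

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return EEGRecording(
            data=raw.get_data() * 1e6,  # volts -> microvolts
            fs=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
            subject_id=path.stem,
        )
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            g = f["recording"]
            return EEGRecording(
                data=g["data"][()],
                fs=float(g.attrs["fs"]),
                channel_labels=[str(x) for x in g.attrs["channel_labels"]],
                subject_id=str(g.attrs.get("subject_id", "")),
                group=str(g.attrs.get("group", "")),
                covariates=json.loads(g.attrs.get("covariates", "{}")),
            )
    if suffix in _DELIMITED:
        sidecar = _sidecar_path(path)
        meta: dict = {}
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        if fs is None:
            fs = meta.get("fs")
        if fs is None:
            raise ValueError(
                f"no sampling rate: provide fs= or a sidecar file {sidecar.name}"
            )
        data = np.loadtxt(path, delimiter=_DELIMITED[suffix], ndmin=2)
        return EEGRecording(
            data=data,
            fs=float(fs),
            channel_labels=meta.get("channel_labels"),
            subject_id=meta.get("subject_id", path.stem),
            group=meta.get("group", ""),
            covariates=meta.get("covariates", {}),
        )
    raise ValueError(f"unsupported recording format: {path.suffix!r}")


def write_recording(rec: EEGRecording, path) -> Path:
    """Write a recording as a delimited matrix + JSON sidecar, or as HDF5."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            g = f.create_group("recording")
            g.create_dataset("data", data=rec.data, compression="gzip")
            g.attrs["fs"] = rec.fs
            g.attrs["channel_labels"] = rec.channel_labels
            g.attrs["subject_id"] = rec.subject_id
            g.attrs["group"] = rec.group
            g.attrs["covariates"] = json.dumps(rec.covariates)
        return path
    if suffix in _DELIMITED:
        delim = _DELIMITED[suffix] or " "
        np.savetxt(path, rec.data, delimiter=delim)
        meta = {
            "fs": rec.fs,
            "channel_labels": rec.channel_labels,
            "subject_id": rec.subject_id,
            "group": rec.group,
            "covariates": rec.covariates,
            "meta": rec.meta,
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
        return path
    raise ValueError(f"unsupported output format: {path.suffix!r}")


def write_cohort(recordings, out_dir, fmt: str = ".csv") -> Path:
    """Write one file per recording plus a tabular manifest
    (subject_id, group, seed, covariates, path); returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id or 'subject'}{fmt}"
        write_recording(rec, out_dir / fname)
        row = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "seed": rec.meta.get("seed", ""),
            "path": fname,
        }
        row.update(rec.covariates)
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path) -> list[EEGRecording]:
    """Load every recording referenced by a cohort manifest."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    base = manifest_path.parent
    recs = []
    for _, row in table.iterrows():
        rec = read_recording(base / row["path"])
        rec.subject_id = str(row["subject_id"])
        rec.group = str(row.get("group", rec.group))
        for col in table.columns:
            if col not in ("subject_id", "group", "seed", "path"):
                val = row[col]
                if pd.notna(val):
                    rec.covariates[col] = float(val)
        recs.append(rec)
    return recs


def save_band_set(bands: BandFilteredSet, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = bands.fs
        f.attrs["subject_id"] = bands.subject_id
        f.attrs["group"] = bands.group
        f.attrs["covariates"] = json.dumps(bands.covariates)
        f.attrs["provenance"] = json.dumps(bands.provenance)
        for bdef in bands.band_defs:
            d = f.create_dataset(f"bands/{bdef.name}", data=bands.bands[bdef.name],
                                 compression="gzip")
            d.attrs["f_lo"] = bdef.f_lo
            d.attrs["f_hi"] = bdef.f_hi
    return path


def load_band_set(path) -> BandFilteredSet:
    with h5py.File(path, "r") as f:
        defs, arrays = [], {}
        for name, d in f["bands"].items():
            defs.append(BandDefinition(name, float(d.attrs["f_lo"]),
                                       float(d.attrs["f_hi"])))
            arrays[name] = d[()]
        defs.sort(key=lambda b: b.f_lo)
        return BandFilteredSet(
            bands=arrays, band_defs=defs, fs=float(f.attrs["fs"]),
            subject_id=str(f.attrs.get("subject_id", "")),
            group=str(f.attrs.get("group", "")),
            covariates=json.loads(f.attrs.get("covariates", "{}")),
            provenance=json.loads(f.attrs.get("provenance", "{}")),
        )


def save_iac(tensor: IACTensor, path) -> Path:
    """Chunked HDF5 container: samples x pairs values plus the pair map."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=tensor.values,
                         chunks=(min(4096, tensor.n_samples), tensor.n_pairs),
                         compression="gzip")
        f.create_dataset("pairs", data=tensor.pairs)
        f.attrs.update({
            "n_channels": tensor.n_channels, "band": tensor.band,
            "subject_id": tensor.subject_id, "trim": tensor.trim,
            "orthogonalized": tensor.orthogonalized,
        })
    return path


def load_iac(path) -> IACTensor:
    with h5py.File(path, "r") as f:
        return IACTensor(
            values=f["values"][()], pairs=f["pairs"][()],
            n_channels=int(f.attrs["n_channels"]), band=str(f.attrs["band"]),
            subject_id=str(f.attrs["subject_id"]), trim=int(f.attrs["trim"]),
            orthogonalized=bool(f.attrs["orthogonalized"]),
        )
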