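"""Readers and writers for the pipeline's on-disk formats.

Images are NIfTI-1 (one 4D file per TI, slices ascending with a constant
acquisition delay), the physio trace is a two-column TSV
(time_ms, amplitude) with a JSON sidecar for fs/t0, per-series acquisition
metadata live in JSON sidecars, and tables are tidy TSV/CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import nibabel as nib
import numpy as np
import pandas as pd

from .cardiac_sync import AcquisitionTiming, MultiTIASLSeries, PhysioTrace
from .voxel_fit import KineticParamMaps

__all__ = [
    "save_series",
    "load_series",
    "save_physio",
    "load_physio",
    "save_labels",
    "load_labels",
    "save_param_maps",
    "load_param_maps",
    "save_nifti",
    "load_nifti",
]

_PARAMS = ("abv", "dt", "sigma", "rmse")


def _to_nifti_order(vol_first: np.ndarray) -> np.ndarray:
    """(n_vol, nz, ny, nx) -> NIfTI (nx, ny, nz, n_vol)."""
    return np.transpose(vol_first, (3, 2, 1, 0))


def _from_nifti_order(xyzt: np.ndarray) -> np.ndarray:
    return np.transpose(xyzt, (3, 2, 1, 0))


def save_nifti(arr3d: np.ndarray, path: Path) -> None:
    """Write a (nz, ny, nx) volume as NIfTI."""
    img = nib.Nifti1Image(np.transpose(np.asarray(arr3d), (2, 1, 0)), np.eye(4))
    nib.save(img, str(path))


def load_nifti(path: Path) -> np.ndarray:
    """Read a NIfTI volume back into (nz, ny, nx) order."""
    arr = np.asanyarray(nib.load(str(path)).dataobj)
    return np.transpose(arr, (2, 1, 0))


def save_series(series: MultiTIASLSeries, outdir: Path) -> None:
    """Write one 4D NIfTI plus JSON sidecar per TI series."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = series.timing
    for ti, arr in series.data.items():
        stem = f"asl_ti{int(round(ti))}"
        img = nib.Nifti1Image(_to_nifti_order(arr), np.eye(4))
        nib.save(img, str(outdir / f"{stem}.nii.gz"))
        sidecar = {
            "ti_ms": ti,
            "tr_ms": t.tr,
            "n_pairs": t.n_pairs,
            "slice_delay_ms": t.slice_delay,
            "quipss_cutoff_ms": t.quipss_cutoff,
            "series_start_ms": series.series_start.get(ti, 0.0),
            "label_order": list(t.label_order),
            "slice_convention": "ascending, constant inter-slice delay",
        }
        (outdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))


def load_series(indir: Path) -> MultiTIASLSeries:
    """Read the per-TI NIfTI + sidecar files written by :func:`save_series`."""
    indir = Path(indir)
    data: Dict[float, np.ndarray] = {}
    starts: Dict[float, float] = {}
    meta = None
    for sidecar_path in sorted(indir.glob("asl_ti*.json")):
        meta = json.loads(sidecar_path.read_text())
        ti = float(meta["ti_ms"])
        arr = np.asanyarray(
            nib.load(str(sidecar_path.with_suffix("").with_suffix(".nii.gz"))).dataobj
        )
        data[ti] = _from_nifti_order(arr)
        starts[ti] = float(meta["series_start_ms"])
    if meta is None:
        raise FileNotFoundError(f"no asl_ti*.json sidecars found in {indir}")
    timing = AcquisitionTiming(
        tr=float(meta["tr_ms"]),
        ti_list=tuple(sorted(data)),
        n_pairs=int(meta["n_pairs"]),
        n_slices=next(iter(data.values())).shape[1],
        slice_delay=float(meta["slice_delay_ms"]),
        quipss_cutoff=float(meta["quipss_cutoff_ms"]),
        label_order=tuple(meta["label_order"]),
    )
    return MultiTIASLSeries(data=data, timing=timing, series_start=starts)


def save_physio(trace: PhysioTrace, path: Path) -> None:
    """Two-column TSV (time_ms, amplitude) plus a JSON sidecar (fs, t0)."""
    path = Path(path)
    df = pd.DataFrame({"time_ms": trace.times, "amplitude": trace.samples})
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    sidecar = {"fs_hz": trace.fs, "t0_ms": trace.t0}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_physio(path: Path) -> PhysioTrace:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        fs, t0 = float(meta["fs_hz"]), float(meta["t0_ms"])
    else:
        dt = np.median(np.diff(df["time_ms"].to_numpy()))
        fs, t0 = 1000.0 / dt, float(df["time_ms"].iloc[0])
    return PhysioTrace(samples=df["amplitude"].to_numpy(), fs=fs, t0=t0)


def save_labels(labels: np.ndarray, names: Dict[int, str], path: Path) -> None:
    """Integer label NIfTI with a JSON label dictionary."""
    path = Path(path)
    save_nifti(np.asarray(labels, dtype=np.int16), path)
    label_path = path.parent / (path.name.split(".")[0] + "_labels.json")
    label_path.write_text(json.dumps({str(k): v for k, v in names.items()},
                                     indent=2))


def load_labels(path: Path):
    path = Path(path)
    labels = load_nifti(path).astype(int)
    label_path = path.parent / (path.name.split(".")[0] + "_labels.json")
    names = {int(k): v for k, v in json.loads(label_path.read_text()).items()}
    return labels, names


def save_param_maps(maps: KineticParamMaps, outdir: Path,
                    prefix: str = "fit") -> None:
    """Per-bin, per-parameter NIfTI maps: <prefix>_bin<k>_<param>.nii.gz."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for b in maps.bins:
        for param in _PARAMS:
            vol = getattr(maps, param)[b]
            save_nifti(vol, outdir / f"{prefix}_bin{b}_{param}.nii.gz")


def load_param_maps(indir: Path, n_bins: int, shape,
                    prefix: str = "fit") -> KineticParamMaps:
    indir = Path(indir)
    arrays = {p: np.full((n_bins, *shape), np.nan) for p in _PARAMS}
    bins = []
    for b in range(n_bins):
        path = indir / f"{prefix}_bin{b}_abv.nii.gz"
        if not path.exists():
            continue
        bins.append(b)
        for param in _PARAMS:
            arrays[param][b] = load_nifti(indir / f"{prefix}_bin{b}_{param}.nii.gz")
    return KineticParamMaps(abv=arrays["abv"], dt=arrays["dt"],
                            sigma=arrays["sigma"], rmse=arrays["rmse"],
                            bins=tuple(bins))
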