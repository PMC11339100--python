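"""NIfTI / JSON / CSV interchange for the pipeline.

A 4D series is stored as one 3D NIfTI file per frame plus a JSON sidecar
carrying the acquisition timing (frame start times, integration windows,
mask-frame count). Maps are single NIfTI volumes on the same grid; masks
are unsigned 8-bit. Voxel spacing travels in the NIfTI header (mm).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .engine import PerfusionMaps, TimeSeries4D
from .volumetry import VolumeReport

SIDECAR = "series.json"


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def write_series(series: TimeSeries4D, outdir: str | Path) -> list[Path]:
    """Write a 4D series as per-frame NIfTI files plus the timing sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    aff = _affine(series.spacing)
    for i in range(series.n_frames):
        p = outdir / f"frame_{i:03d}.nii"
        nib.save(nib.Nifti1Image(series.data[i].astype(np.float32), aff), p)
        paths.append(p)
    sidecar = {
        "frame_times": series.frame_times.tolist(),
        "durations": series.durations.tolist(),
        "n_mask": int(series.n_mask),
        "spacing": list(series.spacing),
    }
    sp = outdir / SIDECAR
    sp.write_text(json.dumps(sidecar, indent=2))
    paths.append(sp)
    return paths


def read_nifti_series(indir: str | Path) -> TimeSeries4D:
    """Read a per-frame NIfTI series written by :func:`write_series`."""
    indir = Path(indir)
    sp = indir / SIDECAR
    if not sp.exists():
        raise FileNotFoundError(f"missing timing sidecar {sp}")
    meta = json.loads(sp.read_text())
    files = sorted(indir.glob("frame_*.nii*"))
    if len(files) != len(meta["frame_times"]):
        raise ValueError(f"{indir}: found {len(files)} frames, sidecar lists "
                         f"{len(meta['frame_times'])}")
    frames = []
    shape = None
    spacing = None
    for f in files:
        img = nib.load(f)
        arr = np.asarray(img.dataobj, dtype=float)
        if shape is None:
            shape = arr.shape
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        elif arr.shape != shape:
            raise ValueError(f"frame {f.name} has shape {arr.shape}, expected {shape}")
        frames.append(arr)
    return TimeSeries4D(data=np.stack(frames), frame_times=np.asarray(meta["frame_times"]),
                        durations=np.asarray(meta["durations"]),
                        n_mask=int(meta["n_mask"]), spacing=spacing)


def write_map(arr: np.ndarray, spacing, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), _affine(spacing)), path)
    return path


def write_mask(mask: np.ndarray, spacing, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _affine(spacing)), path)
    return path


def read_map(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(path)
    return (np.asarray(img.dataobj, dtype=float),
            tuple(float(z) for z in img.header.get_zooms()[:3]))


def write_maps(maps: PerfusionMaps, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    written = []
    for name in ("tmax", "ttp", "cbf", "cbv", "mtt"):
        written.append(write_map(getattr(maps, name), maps.spacing,
                                 outdir / f"{name}.nii"))
    written.append(write_mask(maps.mask, maps.spacing, outdir / "tissue_mask.nii"))
    return written


def read_maps(indir: str | Path) -> PerfusionMaps:
    indir = Path(indir)
    vols = {}
    spacing = None
    for name in ("tmax", "ttp", "cbf", "cbv", "mtt"):
        vols[name], spacing = read_map(indir / f"{name}.nii")
    mask, _ = read_map(indir / "tissue_mask.nii")
    return PerfusionMaps(mask=mask.astype(bool), spacing=spacing, **vols)


def write_volume_report(report: VolumeReport, basepath: str | Path) -> list[Path]:
    """Write a volume report as JSON (full) and CSV (flat rows)."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    jpath = base.with_suffix(".json")
    jpath.write_text(json.dumps(dataclasses.asdict(report), indent=2))
    rows = [{"measure": k, "volume_ml": v, "voxels": report.counts.get(k)}
            for k, v in report.volumes_ml.items()]
    rows += [{"measure": k, "volume_ml": v, "voxels": None}
             for k, v in report.mismatch_ml.items()]
    cpath = base.with_suffix(".csv")
    pd.DataFrame(rows).to_csv(cpath, index=False)
    return [jpath, cpath]


def resample_to_spacing(arr: np.ndarray, spacing, new_spacing,
                        is_mask: bool = False) -> np.ndarray:
    """Resample a volume to a new voxel spacing (e.g. reformat to 3 mm slices).

    Masks use nearest-neighbour interpolation, maps trilinear.
    """
    zoom = [s / ns for s, ns in zip(spacing, new_spacing)]
    order = 0 if is_mask else 1
    out = ndimage.zoom(arr.astype(float), zoom, order=order)
    return out > 0.5 if is_mask else out


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
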