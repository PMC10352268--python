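"""File-format glue: NIfTI image series with JSON sidecars, CSV curves/profiles."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .magnetometry import MagnetizationCurve
from .mapping import ImageSeries, ParametricMap
from .nmrd import NMRDProfile

__all__ = [
    "write_image_series",
    "read_image_series",
    "write_parametric_map",
    "write_magnetization_curve",
    "read_magnetization_curve",
    "write_nmrd_profile",
    "read_nmrd_profile",
]


def write_image_series(series: ImageSeries, outdir, prefix: str,
                       voxel_size_mm=(1.6, 1.6, 5.0), extra_meta=None) -> Path:
    """One NIfTI volume per TI/TE plus a JSON sidecar with the protocol."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(voxel_size_mm) + [1.0])
    for i in range(series.index_ms.size):
        img = nib.Nifti1Image(series.data[..., i], affine)
        nib.save(img, outdir / f"{prefix}_{i:03d}.nii.gz")
    meta = {
        "index_ms": series.index_ms.tolist(),
        "tr_ms": series.tr_ms,
        "field_T": series.field_T,
        "mode": series.mode,
        "voxel_size_mm": list(voxel_size_mm),
    }
    if extra_meta:
        meta.update(extra_meta)
    sidecar = outdir / f"{prefix}.json"
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_image_series(outdir, prefix: str) -> ImageSeries:
    outdir = Path(outdir)
    meta = json.loads((outdir / f"{prefix}.json").read_text())
    vols = []
    for i in range(len(meta["index_ms"])):
        vols.append(np.asarray(nib.load(outdir / f"{prefix}_{i:03d}.nii.gz").dataobj))
    return ImageSeries(data=np.stack(vols, axis=-1), index_ms=np.array(meta["index_ms"]),
                       tr_ms=meta["tr_ms"], field_T=meta["field_T"], mode=meta["mode"])


def write_parametric_map(pmap: ParametricMap, outdir, prefix: str,
                         voxel_size_mm=(1.6, 1.6, 5.0)) -> Path:
    """T map, S0 map and convergence mask as NIfTI volumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(pmap.T_ms, affine), outdir / f"{prefix}_T.nii.gz")
    nib.save(nib.Nifti1Image(pmap.S0, affine), outdir / f"{prefix}_S0.nii.gz")
    nib.save(nib.Nifti1Image(pmap.converged.astype(np.uint8), affine),
             outdir / f"{prefix}_converged.nii.gz")
    return outdir / f"{prefix}_T.nii.gz"


def write_magnetization_curve(curve: MagnetizationCurve, path) -> Path:
    path = Path(path)
    pd.DataFrame({"field_T": curve.fields_T, "M_Am2_per_kg": curve.M_Am2_per_kg}).to_csv(
        path, index=False
    )
    return path


def read_magnetization_curve(path, temperature_K: float = 294.65,
                             label: str = "") -> MagnetizationCurve:
    df = pd.read_csv(path)
    return MagnetizationCurve(fields_T=df["field_T"].to_numpy(),
                              M_Am2_per_kg=df["M_Am2_per_kg"].to_numpy(),
                              temperature_K=temperature_K, label=label)


def write_nmrd_profile(profile: NMRDProfile, path) -> Path:
    path = Path(path)
    cols = {"freq_MHz": profile.freqs_MHz, "r1": profile.r1}
    if profile.sd is not None:
        cols["sd"] = profile.sd
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


def read_nmrd_profile(path, temperature_C: float = 21.5, label: str = "") -> NMRDProfile:
    df = pd.read_csv(path)
    return NMRDProfile(freqs_MHz=df["freq_MHz"].to_numpy(), r1=df["r1"].to_numpy(),
                       temperature_C=temperature_C, label=label,
                       sd=df["sd"].to_numpy() if "sd" in df else None)
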