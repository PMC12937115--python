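"""NIfTI + JSON-manifest persistence for phantoms, series and spectra.

Arrays are stored internally as (z, y, x, frame/bin) and written to NIfTI
in (x, y, z, frame/bin) order with an isotropic affine carried through the
pipeline. Every series/spectrum gets a JSON sidecar manifest (gamma,
moment values, scheme, frame ordering, velocity axis) sufficient to re-run
the decode without the generating config.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .constants import GAMMA
from .encode import EncodedSeries
from .phantom import PhantomImage
from .physics import LadderScheme, MomentLadder, VelocityAxis, velocity_axis
from .recon import SpectrumImage

MANIFEST_SUFFIX = ".manifest.json"


def _p(stem: Path, ext: str) -> Path:
    """Append a multi-dot extension without clobbering dots in the stem."""
    return stem.parent / (stem.name + ext)


def _to_disk_order(arr: np.ndarray) -> np.ndarray:
    """(z,y,x,...) -> (x,y,z,...)."""
    return np.transpose(arr, (2, 1, 0) + tuple(range(3, arr.ndim)))


def _from_disk_order(arr: np.ndarray) -> np.ndarray:
    return np.transpose(arr, (2, 1, 0) + tuple(range(3, arr.ndim)))


def _save_nifti(path: Path, arr: np.ndarray, voxel_size_mm: float, dtype=None):
    data = _to_disk_order(arr)
    if dtype is not None:
        data = data.astype(dtype)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def _load_nifti(path: Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    voxel = float(img.header.get_zooms()[0])
    return _from_disk_order(np.asarray(img.dataobj)), voxel


def ladder_manifest(ladder: MomentLadder) -> dict:
    return {
        "gamma": GAMMA,
        "m1_values": [float(m) for m in ladder.m1_values],
        "scheme": ladder.scheme.value,
        "zero_index": ladder.zero_index,
        "delta_m1": ladder.delta_m1,
        "m1_max": ladder.m1_max,
        "units": {"m1": "T*s^2/m", "gamma": "rad/s/T"},
    }


def ladder_from_manifest(d: dict) -> MomentLadder:
    return MomentLadder(
        m1_values=np.array(d["m1_values"], dtype=float),
        scheme=LadderScheme(d["scheme"]),
        zero_index=int(d["zero_index"]),
        delta_m1=float(d["delta_m1"]),
        m1_max=float(d["m1_max"]),
    )


def axis_manifest(axis: VelocityAxis) -> dict:
    return {
        "centers_cm_s": [float(c) for c in axis.centers],
        "delta_v_cm_s": axis.delta_v,
        "v_max_cm_s": axis.v_max,
        "n_bins": axis.n_bins,
    }


def axis_from_manifest(d: dict) -> VelocityAxis:
    return VelocityAxis(
        centers=np.array(d["centers_cm_s"], dtype=float),
        delta_v=float(d["delta_v_cm_s"]),
        v_max=float(d["v_max_cm_s"]),
        n_bins=int(d["n_bins"]),
    )


def save_phantom(path_stem: str | Path, phantom: PhantomImage):
    """Write density NIfTI, label NIfTI and axis manifest next to path_stem."""
    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    _save_nifti(_p(stem, ".density.nii.gz"), phantom.densities, phantom.voxel_size_mm, np.float64)
    _save_nifti(_p(stem, ".labels.nii.gz"), phantom.labels, phantom.voxel_size_mm, np.int16)
    manifest = {
        "kind": "phantom",
        "axis": axis_manifest(phantom.axis),
        "voxel_size_mm": phantom.voxel_size_mm,
        "tubes": [
            {
                "center_mm": list(t.center),
                "diameter_mm": t.diameter,
                "flow_sign": t.flow_sign,
                "v_mean_cm_s": t.v_mean,
                "v_max_tube_cm_s": t.v_max_tube,
            }
            for t in phantom.tubes
        ],
    }
    _p(stem, ".phantom" + MANIFEST_SUFFIX).write_text(json.dumps(manifest, indent=2))


def load_phantom(path_stem: str | Path) -> PhantomImage:
    stem = Path(path_stem)
    manifest = json.loads(_p(stem, ".phantom" + MANIFEST_SUFFIX).read_text())
    densities, voxel = _load_nifti(_p(stem, ".density.nii.gz"))
    labels, _ = _load_nifti(_p(stem, ".labels.nii.gz"))
    from .phantom import TubeSpec

    tubes = [
        TubeSpec(
            center=tuple(t["center_mm"]),
            diameter=t["diameter_mm"],
            flow_sign=t["flow_sign"],
            v_mean=t["v_mean_cm_s"],
        )
        for t in manifest.get("tubes", [])
    ]
    return PhantomImage(
        densities=densities.astype(float),
        axis=axis_from_manifest(manifest["axis"]),
        labels=labels.astype(np.int16),
        voxel_size_mm=manifest["voxel_size_mm"],
        tubes=tubes,
    )


def save_series(path_stem: str | Path, series: EncodedSeries):
    """Write the encoded frames (complex NIfTI) + ladder/frame manifest."""
    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    _save_nifti(_p(stem, ".series.nii.gz"), series.frames, series.voxel_size_mm, np.complex128)
    manifest = {
        "kind": "encoded_series",
        "ladder": ladder_manifest(series.ladder),
        "frames": [{"m1": m, "variant": v} for m, v in series.frame_manifest],
        "frame_order": "cos precedes sin within each encode pair, ascending moment",
        "provenance": series.provenance,
        "axis": axis_manifest(velocity_axis(series.ladder)),
        "voxel_size_mm": series.voxel_size_mm,
    }
    _p(stem, ".series" + MANIFEST_SUFFIX).write_text(json.dumps(manifest, indent=2))


def load_series(path_stem: str | Path) -> EncodedSeries:
    stem = Path(path_stem)
    manifest = json.loads(_p(stem, ".series" + MANIFEST_SUFFIX).read_text())
    frames, voxel = _load_nifti(_p(stem, ".series.nii.gz"))
    return EncodedSeries(
        frames=frames.astype(complex),
        frame_manifest=[(f["m1"], f["variant"]) for f in manifest["frames"]],
        ladder=ladder_from_manifest(manifest["ladder"]),
        provenance=manifest.get("provenance", "clean"),
        voxel_size_mm=manifest.get("voxel_size_mm", 1.0),
    )


def save_spectrum(path_stem: str | Path, image: SpectrumImage, voxel_size_mm: float = 1.0):
    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    _save_nifti(_p(stem, ".spectrum.nii.gz"), image.spectra, voxel_size_mm, np.float64)
    if image.mask is not None:
        _save_nifti(_p(stem, ".mask.nii.gz"), image.mask.astype(np.uint8), voxel_size_mm)
    manifest = {
        "kind": "spectrum_image",
        "axis": axis_manifest(image.axis),
        "normalized": image.normalized,
        "voxel_size_mm": voxel_size_mm,
    }
    _p(stem, ".spectrum" + MANIFEST_SUFFIX).write_text(json.dumps(manifest, indent=2))


def load_spectrum(path_stem: str | Path) -> SpectrumImage:
    stem = Path(path_stem)
    manifest = json.loads(_p(stem, ".spectrum" + MANIFEST_SUFFIX).read_text())
    spectra, _ = _load_nifti(_p(stem, ".spectrum.nii.gz"))
    mask = None
    mask_path = _p(stem, ".mask.nii.gz")
    if mask_path.exists():
        m, _ = _load_nifti(mask_path)
        mask = m.astype(bool)
    return SpectrumImage(
        spectra=spectra.astype(float),
        axis=axis_from_manifest(manifest["axis"]),
        normalized=manifest["normalized"],
        mask=mask,
    )


def save_roi_csv(path: str | Path, density) -> None:
    """ROI spectrum as CSV (bin_center_cm_s, fraction)."""
    lines = ["bin_center_cm_s,fraction"]
    for c, f in zip(density.axis.centers, density.fractions):
        lines.append(f"{c:.6g},{f:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")
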