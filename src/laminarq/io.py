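"""NIfTI and CSV plumbing.

World coordinates are ignored beyond voxel size: affines are diagonal
scalings by the voxel size, indexing is 0-based.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_nifti", "load_nifti", "export_phantom"]


def save_nifti(volume: np.ndarray, path, voxel_size=(0.7, 0.7, 0.7)) -> None:
    affine = np.diag([*voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(volume), affine)
    img.header.set_zooms(voxel_size)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def export_phantom(truth, images: dict | None, out_dir) -> None:
    """Write one phantom's truth fields (and rendered images) as NIfTI."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vs = truth.voxel_size
    save_nifti(truth.labels.astype(np.int16), out / "labels.nii.gz", vs)
    save_nifti(truth.roi_labels.astype(np.int16), out / "roi_labels.nii.gz", vs)
    save_nifti(truth.depth_truth, out / "depth_truth.nii.gz", vs)
    save_nifti(truth.t1_truth, out / "t1_truth.nii.gz", vs)
    save_nifti(truth.t2star_truth, out / "t2star_truth.nii.gz", vs)
    if images:
        save_nifti(images["uni"], out / "uni.nii.gz", vs)
        save_nifti(images["inv1"], out / "inv1.nii.gz", vs)
        for k, echo in enumerate(images["echoes"], start=1):
            save_nifti(echo, out / f"echo{k}.nii.gz", vs)
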