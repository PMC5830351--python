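"""NIfTI round-trip helpers for ROI time series.

ROI data travel either as a plain matrix TSV with a JSON sidecar (see
``RoiTimeSeries.to_tsv``) or as a 4-D NIfTI volume plus a 3-D binary mask;
these helpers cover the NIfTI path.  Voxels are extracted in the mask's
C-order so a write/read round trip preserves the voxel ordering.
"""
from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .betaseries import RoiTimeSeries

__all__ = ["roi_to_nifti", "roi_from_nifti"]


def roi_to_nifti(roi: RoiTimeSeries, bold_path: str | Path,
                 mask_path: str | Path, shape: tuple[int, int, int] | None = None
                 ) -> None:
    """Write a voxel x scan matrix as a 4-D NIfTI plus its ROI mask.

    Without an explicit 3-D shape the voxels are laid out along one axis.
    """
    if shape is None:
        shape = (roi.n_voxels, 1, 1)
    if int(np.prod(shape)) < roi.n_voxels:
        raise ValueError("shape too small for the number of voxels")
    vol = np.zeros(shape + (roi.n_scans,), dtype=np.float32)
    mask = np.zeros(shape, dtype=np.uint8)
    flat_idx = np.arange(roi.n_voxels)
    coords = np.unravel_index(flat_idx, shape)
    vol[coords] = roi.data.astype(np.float32)
    mask[coords] = 1
    affine = np.eye(4)
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((1.0, 1.0, 1.0, roi.tr_s))
    nib.save(img, str(bold_path))
    nib.save(nib.Nifti1Image(mask, affine), str(mask_path))


def roi_from_nifti(bold_path: str | Path, mask_path: str | Path,
                   tr_s: float | None = None, roi: str = "roi",
                   subject: str = "sub-01") -> RoiTimeSeries:
    """Extract the masked voxel x scan matrix from a 4-D NIfTI."""
    img = nib.load(str(bold_path))
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    data = np.asarray(img.dataobj)[mask]  # voxel x scan, mask C-order
    if tr_s is None:
        tr_s = float(img.header.get_zooms()[3])
    if tr_s <= 0:
        raise ValueError("repetition time missing from header; pass tr_s")
    return RoiTimeSeries(data=np.asarray(data, dtype=float), tr_s=tr_s,
                         roi=roi, subject=subject)
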