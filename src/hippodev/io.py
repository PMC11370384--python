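"""Thin NIfTI / table I/O wrappers (nibabel-backed).

Internal conventions: isotropic voxels with centers at ``index * voxel_mm``
(diagonal affine), b-values in ms/um^2 (FSL-dialect files in s/mm^2 are
converted on read and the conversion logged).
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np

log = logging.getLogger("hippodev")

__all__ = ["save_nifti", "load_nifti", "load_dwi"]


def save_nifti(data: np.ndarray, voxel_mm: float, path) -> None:
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.dataobj), float(zooms[0])


def load_dwi(nifti_path, bval_path, bvec_path, timing_json=None):
    """4-D diffusion volume + FSL bval/bvec -> (data, protocol).

    b-values above 50 are interpreted as s/mm^2 and converted to ms/um^2.
    """
    import json

    from .protocol import AcquisitionProtocol, DEFAULT_BIG_DELTA, DEFAULT_DELTA

    data, _ = load_nifti(nifti_path)
    bvals = np.loadtxt(bval_path).ravel().astype(float)
    if bvals.max() > 50:
        log.info("b-values look like s/mm^2; converting to ms/um^2 (x1e-3)")
        bvals = bvals * 1e-3
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    delta, big_delta = DEFAULT_DELTA, DEFAULT_BIG_DELTA
    if timing_json is not None:
        timing = json.loads(Path(timing_json).read_text())
        delta = timing.get("delta_ms", delta)
        big_delta = timing.get("big_delta_ms", big_delta)
    return data, AcquisitionProtocol(bvals, bvecs, delta, big_delta)
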