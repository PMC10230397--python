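"""Automatic cleanup of body and GI-gas masks.

Replicates the routine corrections applied to manually edited segmentations:
stray islands outside the body, unfilled internal cavities, and speckle in
the gas mask. Both operations are idempotent and the cleaned gas mask is
always a subset of the cleaned body mask.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import LabelVolume, ScanRecord

#: 26-connectivity structuring element for component analysis
_CONN26 = np.ones((3, 3, 3), dtype=bool)
#: face (6-) connectivity used for the one-voxel body erosion
_CONN6 = ndimage.generate_binary_structure(3, 1)

DEFAULT_MIN_COMPONENT_ML = 0.1


def largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n <= 1:
        return mask.copy()
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def clean_body_mask(body: LabelVolume) -> LabelVolume:
    """Keep the largest 26-connected component and fill internal cavities.

    Cavities are filled both slice-wise (axial planes, catching tunnels open
    along z such as the bowel lumen crossing the volume border) and in 3D.
    """
    if not body.voxels.any():
        raise ValueError("cannot clean an empty body mask")
    voxels = largest_component(body.voxels)
    filled = voxels.copy()
    for iz in range(filled.shape[2]):
        filled[:, :, iz] = ndimage.binary_fill_holes(filled[:, :, iz])
    filled = ndimage.binary_fill_holes(filled)
    return body.with_voxels(filled)


def clean_gas_mask(
    gas: LabelVolume,
    body: LabelVolume,
    min_component_ml: float = DEFAULT_MIN_COMPONENT_ML,
) -> LabelVolume:
    """Restrict gas to the body interior and drop sub-threshold speckle.

    The body is eroded by one voxel before intersecting so that air adjacent
    to the skin surface (a common contouring slip) is excluded; 26-connected
    components smaller than ``min_component_ml`` are removed.
    """
    if not gas.same_grid(body):
        raise ValueError("gas and body masks must share the same grid")
    interior = ndimage.binary_erosion(body.voxels, structure=_CONN6)
    voxels = gas.voxels & interior
    if min_component_ml > 0 and voxels.any():
        labels, n = ndimage.label(voxels, structure=_CONN26)
        counts = np.bincount(labels.ravel())
        min_vox = min_component_ml / gas.voxel_volume_ml
        drop = np.flatnonzero(counts < min_vox)
        keep = ~np.isin(labels, drop[drop > 0])
        voxels = voxels & keep
    return gas.with_voxels(voxels)


def clean_scan(
    scan: ScanRecord, min_component_ml: float = DEFAULT_MIN_COMPONENT_ML
) -> ScanRecord:
    body = clean_body_mask(scan.body)
    gas = clean_gas_mask(scan.gas, body, min_component_ml=min_component_ml)
    return ScanRecord(scan.patient_id, scan.timepoint, body, gas)
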