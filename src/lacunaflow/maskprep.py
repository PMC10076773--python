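"""Template- and subject-space mask preparation.

The candidate gate of the segmentation pipeline is assembled from two mask
sets:

* a *template* set built once per processing space — the white-matter mask
  (including basal ganglia), its signed distance map and interior, and the
  3x3x3-dilated ventricle and basal-ganglia masks;
* a *subject* set built from the follow-up scan — the CSF mask, the external
  (subarachnoid) CSF as the largest connected CSF component, and a thin
  sulcal skeleton used as an exclusion locus.

Conventions used throughout: connected components use 26-connectivity,
boundary detection uses 6-connectivity, and the grid border counts as
background (a mask voxel on the grid face is a boundary voxel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .volume import BinaryMask, ImageVolume, assert_common_grid

__all__ = [
    "TemplateMaskSet",
    "SubjectMaskSet",
    "segment_csf",
    "external_csf_component",
    "dilate_mask",
    "wm_distance_map",
    "skeletonize_sulci",
    "build_template_masks",
    "build_subject_masks",
]

#: full 3x3x3 box; the only structuring element the pipeline uses for dilation
BOX_3x3x3 = np.ones((3, 3, 3), dtype=bool)

#: 26-connectivity structuring element for component labeling
CONN_26 = np.ones((3, 3, 3), dtype=bool)

#: 6-connectivity structuring element for boundary detection
CONN_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class TemplateMaskSet:
    """Masks derived from the template: gate candidates to deep white matter.

    ``wm_distance`` is the signed Euclidean distance (mm) to the white-matter
    mask boundary, negative strictly inside; ``wm_interior`` is the d < 0 set
    (voxels at d >= 0, i.e. the boundary shell and everything outside, are
    excluded).
    """

    wm_mask: BinaryMask
    ventricles_dilated: BinaryMask
    basal_ganglia_dilated: BinaryMask
    wm_distance: np.ndarray
    wm_interior: BinaryMask


@dataclass
class SubjectMaskSet:
    """Masks derived from the follow-up scan of one subject."""

    brain_mask: BinaryMask
    csf_mask: BinaryMask
    external_csf: BinaryMask
    sulci_skeleton: BinaryMask


def segment_csf(
    t1: ImageVolume,
    brain_mask: BinaryMask,
    n_classes: int = 3,
    seed: int = 0,
) -> BinaryMask:
    """Segment CSF as the darkest of ``n_classes`` intensity classes.

    A 1D K-means over in-brain intensities partitions the brain into
    ``n_classes`` tissue tiers (CSF / grey / white on T1); CSF is the class
    with the lowest mean since fluid is darkest on T1-weighted images.
    """
    assert_common_grid([t1, brain_mask])
    inside = brain_mask.as_bool()
    if not inside.any():
        raise ValueError("brain mask is empty")
    values = t1.data[inside]
    if np.unique(values).size < n_classes:
        raise ValueError(
            f"fewer than {n_classes} distinct intensities inside the brain mask"
        )
    km = KMeans(n_clusters=n_classes, n_init=10, random_state=seed)
    labels = km.fit_predict(values.reshape(-1, 1))
    csf_label = int(np.argmin(km.cluster_centers_.ravel()))
    out = np.zeros(t1.grid_shape, dtype=np.uint8)
    out[inside] = (labels == csf_label).astype(np.uint8)
    return BinaryMask(data=out, spacing=t1.spacing, affine=t1.affine.copy())


def external_csf_component(csf_mask: BinaryMask) -> BinaryMask:
    """Largest 26-connected component of the CSF mask.

    The subarachnoid (external) CSF covers the brain surface and sulci and is
    by far the largest connected CSF structure; ventricles and cavities form
    separate components.  Size ties are broken by the smallest label index of
    the deterministic raster-order labeling.
    """
    if not csf_mask.as_bool().any():
        raise ValueError("CSF mask is empty")
    labels, n = ndimage.label(csf_mask.as_bool(), structure=CONN_26)
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    best = int(np.argmax(sizes)) + 1  # argmax returns first maximum -> lowest label
    out = (labels == best).astype(np.uint8)
    return BinaryMask(data=out, spacing=csf_mask.spacing, affine=csf_mask.affine.copy())


def dilate_mask(mask: BinaryMask, kernel: np.ndarray | None = None) -> BinaryMask:
    """Morphological dilation, by the full 3x3x3 box unless configured."""
    if kernel is None:
        kernel = BOX_3x3x3
    out = ndimage.binary_dilation(mask.as_bool(), structure=np.asarray(kernel, bool))
    return BinaryMask(
        data=out.astype(np.uint8), spacing=mask.spacing, affine=mask.affine.copy()
    )


def wm_distance_map(wm_mask: BinaryMask) -> tuple[np.ndarray, BinaryMask]:
    """Signed Euclidean distance (mm) to the white-matter mask boundary.

    The boundary shell is the set of mask voxels with a 6-neighbor outside
    the mask (the grid border counts as outside).  Shell voxels have d = 0;
    voxels strictly inside have d < 0 (minus the distance to the nearest
    shell voxel); voxels outside have d > 0.  Returns the distance volume and
    the interior mask {d < 0}.
    """
    inside = wm_mask.as_bool()
    if not inside.any():
        raise ValueError("white-matter mask is empty")
    eroded = ndimage.binary_erosion(inside, structure=CONN_6, border_value=0)
    shell = inside & ~eroded
    # distance from every voxel to the nearest shell voxel, in mm
    dist = ndimage.distance_transform_edt(~shell, sampling=wm_mask.spacing)
    signed = np.where(inside & ~shell, -dist, dist)
    interior = (signed < 0).astype(np.uint8)
    return signed, BinaryMask(
        data=interior, spacing=wm_mask.spacing, affine=wm_mask.affine.copy()
    )


def skeletonize_sulci(external_csf: BinaryMask) -> BinaryMask:
    """Thin medial-surface skeleton of the external CSF.

    Keeps the voxels where the Euclidean distance to the background is a
    local maximum over the 6-neighborhood — the medial ridge of the mask.  A
    1-voxel-thick sheet is its own skeleton; a 3-voxel slab reduces to its
    medial plane.  The result is a subset of the input, at most ~2 voxels
    wide almost everywhere, which is all the pipeline needs: a thin exclusion
    locus running along the sulci.
    """
    inside = external_csf.as_bool()
    if not inside.any():
        raise ValueError("external CSF mask is empty")
    dist = ndimage.distance_transform_edt(inside, sampling=external_csf.spacing)
    ridge = np.ones_like(inside)
    for ax in range(3):
        for shift in (1, -1):
            neighbor = np.roll(dist, shift, axis=ax)
            # voxels rolled in from the far side see distance 0 (background)
            idx = [slice(None)] * 3
            idx[ax] = 0 if shift == 1 else -1
            neighbor[tuple(idx)] = 0.0
            ridge &= dist >= neighbor
    out = (inside & ridge).astype(np.uint8)
    return BinaryMask(
        data=out, spacing=external_csf.spacing, affine=external_csf.affine.copy()
    )


def build_template_masks(
    wm_mask: BinaryMask,
    ventricles: BinaryMask,
    basal_ganglia: BinaryMask,
) -> TemplateMaskSet:
    """Assemble the template mask set from its undilated sources.

    Ventricles and basal ganglia are dilated by the 3x3x3 box so candidate
    lesions touching the ventricle wall or the inner white-matter edge are
    retained despite the interior-distance exclusion.
    """
    assert_common_grid([wm_mask, ventricles, basal_ganglia])
    distance, interior = wm_distance_map(wm_mask)
    return TemplateMaskSet(
        wm_mask=wm_mask,
        ventricles_dilated=dilate_mask(ventricles),
        basal_ganglia_dilated=dilate_mask(basal_ganglia),
        wm_distance=distance,
        wm_interior=interior,
    )


def build_subject_masks(
    followup: ImageVolume,
    brain_mask: BinaryMask,
    n_classes: int = 3,
    seed: int = 0,
) -> SubjectMaskSet:
    """Assemble the subject mask set from the follow-up scan."""
    csf = segment_csf(followup, brain_mask, n_classes=n_classes, seed=seed)
    external = external_csf_component(csf)
    skeleton = skeletonize_sulci(external)
    return SubjectMaskSet(
        brain_mask=brain_mask,
        csf_mask=csf,
        external_csf=external,
        sulci_skeleton=skeleton,
    )
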