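"""Incident-lacune segmentation from a co-registered baseline/follow-up pair.

An incident lacune is a small (3–15 mm) CSF-filled cavity present on the
follow-up T1 scan but absent at baseline.  Because a new cavity replaces
tissue with fluid, its T1 signal drops between the two time points, so the
pipeline works on the *difference map* (normalized baseline minus normalized
follow-up):

1. normalize both scans in intensity within the brain mask;
2. subtract follow-up from baseline;
3. keep voxels with a positive difference that lie in the follow-up CSF mask
   and in deep white matter (white-matter interior, dilated basal ganglia,
   and optionally the dilated ventricle margin);
4. threshold those candidate values with a two-class K-means, cutting at the
   minimum of the high-intensity class;
5. group supra-threshold voxels into 26-connected clusters, measure their
   diameters;
6. reject clusters outside the 3–15 mm diameter bounds or overlapping the
   external CSF, the sulcal skeleton, or the white-matter edge shell;
7. label survivors touching the dilated baseline-lacune mask as extensions
   of former lacunes, the rest as incident.

Rejected clusters are kept (with their first matching rejection reason) so
that an expert can audit and, if needed, manually correct the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .config import PipelineConfig
from .maskprep import SubjectMaskSet, TemplateMaskSet, dilate_mask
from .volume import BinaryMask, ImageVolume, assert_common_grid

__all__ = [
    "LesionCluster",
    "CandidateSet",
    "SegmentationResult",
    "normalize_intensity",
    "difference_map",
    "select_candidates",
    "kmeans_threshold",
    "extract_clusters",
    "cluster_diameter",
    "filter_clusters",
    "label_extensions",
    "segment_incident_lacunes",
    "clusters_to_label_volume",
]

REJECTION_REASONS = ("none", "too_small", "too_large", "external_csf", "sulci", "wm_edge", "manual")


@dataclass
class LesionCluster:
    """A 26-connected set of supra-threshold voxels with its audit state."""

    cluster_id: int
    voxels: np.ndarray  # (N, 3) int voxel indices
    volume_mm3: float
    diameter_mm: float
    centroid: tuple[float, float, float]
    label: str = "pending"  # pending | incident | extension | rejected
    rejection_reason: str = "none"

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=np.int64))
        if self.voxels.shape[0] == 0:
            raise ValueError("cluster has no voxels")
        if (self.label == "rejected") != (self.rejection_reason != "none"):
            raise ValueError("label 'rejected' must pair with a rejection reason")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])


@dataclass
class CandidateSet:
    """Voxels eligible for thresholding: positive difference inside the gate."""

    indices: np.ndarray  # (N, 3) int voxel indices
    values: np.ndarray  # (N,) difference values, all > 0
    grid_shape: tuple[int, int, int]

    def __len__(self) -> int:
        return int(self.indices.shape[0])


@dataclass
class SegmentationResult:
    """All clusters (kept and rejected) plus the run diagnostics."""

    clusters: list[LesionCluster]
    threshold: float | None
    n_candidates: int

    @property
    def incident(self) -> list[LesionCluster]:
        return [c for c in self.clusters if c.label == "incident"]

    @property
    def extensions(self) -> list[LesionCluster]:
        return [c for c in self.clusters if c.label == "extension"]

    @property
    def rejected(self) -> list[LesionCluster]:
        return [c for c in self.clusters if c.label == "rejected"]


def normalize_intensity(vol: ImageVolume, brain_mask: BinaryMask) -> ImageVolume:
    """Robust z-score of the intensities within the brain mask.

    In-brain values are centred on their median and scaled by their
    interquartile range, which makes the output invariant to any positive
    affine rescaling of the scanner units and insensitive to lesion
    outliers; voxels outside the mask are set to 0.
    """
    assert_common_grid([vol, brain_mask])
    inside = brain_mask.as_bool()
    if not inside.any():
        raise ValueError("brain mask is empty")
    values = vol.data[inside]
    med = np.median(values)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    if iqr <= 0:
        if values.max() == values.min():
            raise ValueError("constant image within the brain mask")
        # degenerate but non-constant distribution: fall back to full range
        iqr = float(values.max() - values.min())
    out = np.zeros_like(vol.data, dtype=np.float64)
    out[inside] = (values - med) / iqr
    return vol.with_data(out)


def difference_map(baseline_norm: ImageVolume, followup_norm: ImageVolume) -> ImageVolume:
    """Voxelwise baseline minus follow-up (positive where signal dropped)."""
    assert_common_grid([baseline_norm, followup_norm])
    return baseline_norm.with_data(baseline_norm.data - followup_norm.data)


def select_candidates(
    diff: ImageVolume,
    subject_masks: SubjectMaskSet,
    template_masks: TemplateMaskSet,
    cfg: PipelineConfig | None = None,
) -> CandidateSet:
    """Gate the difference map down to plausible new-cavity voxels.

    A candidate voxel must have a strictly positive difference (signal drop),
    be CSF on the follow-up scan, and sit in deep white matter: the
    white-matter interior, the dilated basal ganglia, or (by default) the
    dilated ventricle margin, which retains periventricular cavities that the
    interior-distance exclusion would otherwise drop.
    """
    cfg = cfg or PipelineConfig()
    assert_common_grid([diff, subject_masks.csf_mask, template_masks.wm_interior])
    gate = template_masks.wm_interior.as_bool() | template_masks.basal_ganglia_dilated.as_bool()
    if cfg.include_ventricle_margin:
        gate = gate | template_masks.ventricles_dilated.as_bool()
    eligible = (diff.data > 0) & subject_masks.csf_mask.as_bool() & gate
    idx = np.argwhere(eligible)
    return CandidateSet(
        indices=idx, values=diff.data[eligible], grid_shape=diff.grid_shape
    )


def kmeans_threshold(values: np.ndarray, k: int = 2, seed: int = 0) -> float:
    """Threshold 1D values at the minimum of the K-means class with the highest mean.

    The values are partitioned into ``k`` classes minimizing the within-class
    sum of squares; the returned threshold is the smallest member of the
    brightest class, so the cut keeps exactly the high-signal-change voxels.
    In 1D the optimal K-means partition is a split of the sorted values, so
    for the default k = 2 the global optimum is found exactly by scanning all
    n−1 sorted splits in O(n log n) — Lloyd's algorithm, which can stall in
    local minima, is only used for k > 2 (seeded k-means++ restarts).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if np.unique(values).size < 2:
        raise ValueError("need at least 2 distinct values to threshold")
    if k == 2:
        v = np.sort(values)
        n = v.size
        csum = np.cumsum(v)
        csum2 = np.cumsum(v * v)
        counts = np.arange(1, n, dtype=np.float64)  # low-class sizes 1..n-1
        sse_lo = csum2[:-1] - csum[:-1] ** 2 / counts
        sse_hi = (csum2[-1] - csum2[:-1]) - (csum[-1] - csum[:-1]) ** 2 / (n - counts)
        split = int(np.argmin(sse_lo + sse_hi)) + 1  # first optimum on ties
        return float(v[split])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed, tol=1e-10)
    labels = km.fit_predict(values.reshape(-1, 1))
    top = int(np.argmax(km.cluster_centers_.ravel()))
    return float(values[labels == top].min())


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, order)


def cluster_diameter(voxels: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Caliper (Feret) diameter of a voxel set in mm, plus one voxel extent.

    The maximum pairwise center-to-center distance measures the span between
    voxel centres; adding the mean voxel extent accounts for the finite voxel
    width, so a single voxel at 1 mm spacing reads 1 mm, the way a
    radiologist would caliper it.
    """
    voxels = np.atleast_2d(np.asarray(voxels, dtype=np.float64))
    if voxels.shape[0] == 0:
        raise ValueError("empty cluster")
    extent = float(np.mean(spacing))
    if voxels.shape[0] == 1:
        return extent
    pts = voxels * np.asarray(spacing, dtype=np.float64)
    if pts.shape[0] > 300:
        # the caliper diameter only depends on the convex hull
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) sets: brute force below
    return float(pdist(pts).max()) + extent


def extract_clusters(
    candidates: CandidateSet,
    threshold: float,
    cfg: PipelineConfig | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> list[LesionCluster]:
    """Connected components of the supra-threshold candidate voxels.

    Voxels whose value equals the threshold are kept (the threshold is the
    smallest member of the bright class, so that member belongs in).
    Components are labeled in deterministic raster order.
    """
    cfg = cfg or PipelineConfig()
    keep = candidates.values >= threshold
    vol = np.zeros(candidates.grid_shape, dtype=bool)
    idx = candidates.indices[keep]
    vol[tuple(idx.T)] = True
    labels, n = ndimage.label(vol, structure=_connectivity_structure(cfg.connectivity))
    voxel_volume = float(np.prod(spacing))
    clusters: list[LesionCluster] = []
    slices = ndimage.find_objects(labels)
    for cid in range(1, n + 1):
        sl = slices[cid - 1]
        local = np.argwhere(labels[sl] == cid)
        voxels = local + np.array([s.start for s in sl])
        clusters.append(
            LesionCluster(
                cluster_id=cid,
                voxels=voxels,
                volume_mm3=voxels.shape[0] * voxel_volume,
                diameter_mm=cluster_diameter(voxels, spacing),
                centroid=tuple(voxels.mean(axis=0)),
            )
        )
    return clusters


def filter_clusters(
    clusters: list[LesionCluster],
    subject_masks: SubjectMaskSet,
    template_masks: TemplateMaskSet,
    cfg: PipelineConfig | None = None,
) -> list[LesionCluster]:
    """Apply the size and location exclusion rules, recording one reason each.

    Rules are checked in a fixed order — diameter below 3 mm, diameter above
    15 mm, overlap with external CSF, overlap with the sulcal skeleton,
    overlap with the white-matter edge shell — and the first match is
    recorded, giving a reproducible audit trail.  Survivors keep label
    ``pending`` until extension labeling.
    """
    cfg = cfg or PipelineConfig()
    external = subject_masks.external_csf.as_bool()
    sulci = subject_masks.sulci_skeleton.as_bool()
    shell = template_masks.wm_mask.as_bool() & ~template_masks.wm_interior.as_bool()
    out: list[LesionCluster] = []
    for c in clusters:
        ix = tuple(c.voxels.T)
        reason = "none"
        if c.diameter_mm < cfg.diameter_min_mm:
            reason = "too_small"
        elif c.diameter_mm > cfg.diameter_max_mm:
            reason = "too_large"
        elif external[ix].any():
            reason = "external_csf"
        elif sulci[ix].any():
            reason = "sulci"
        elif shell[ix].any():
            reason = "wm_edge"
        label = "rejected" if reason != "none" else "pending"
        out.append(
            LesionCluster(
                cluster_id=c.cluster_id,
                voxels=c.voxels,
                volume_mm3=c.volume_mm3,
                diameter_mm=c.diameter_mm,
                centroid=c.centroid,
                label=label,
                rejection_reason=reason,
            )
        )
    return out


def label_extensions(
    clusters: list[LesionCluster],
    baseline_lacunes: BinaryMask,
    cfg: PipelineConfig | None = None,
) -> list[LesionCluster]:
    """Split survivors into incident lacunes and extensions of former lacunes.

    A surviving cluster that overlaps the 3x3x3-dilated baseline-lacune mask
    is new CSF contiguous with an old cavity — an *extension of a former
    lacune* — and is labeled separately from truly incident lesions.
    """
    cfg = cfg or PipelineConfig()
    neighborhood = dilate_mask(baseline_lacunes, cfg.dilation_kernel).as_bool()
    out: list[LesionCluster] = []
    for c in clusters:
        if c.label == "rejected":
            out.append(c)
            continue
        ix = tuple(c.voxels.T)
        label = "extension" if neighborhood[ix].any() else "incident"
        out.append(
            LesionCluster(
                cluster_id=c.cluster_id,
                voxels=c.voxels,
                volume_mm3=c.volume_mm3,
                diameter_mm=c.diameter_mm,
                centroid=c.centroid,
                label=label,
                rejection_reason="none",
            )
        )
    return out


def segment_incident_lacunes(
    baseline: ImageVolume,
    followup: ImageVolume,
    subject_masks: SubjectMaskSet,
    template_masks: TemplateMaskSet,
    baseline_lacunes: BinaryMask,
    cfg: PipelineConfig | None = None,
) -> SegmentationResult:
    """Run the full per-patient pipeline; returns every cluster with its label.

    An empty candidate set (or one with a single distinct value, where a
    two-class split is undefined) short-circuits: with one distinct value all
    candidates are equally strong signal changes, so the threshold degrades
    to that value and no K-means is run.
    """
    cfg = cfg or PipelineConfig()
    assert_common_grid([baseline, followup, baseline_lacunes, subject_masks.brain_mask])
    baseline_n = normalize_intensity(baseline, subject_masks.brain_mask)
    followup_n = normalize_intensity(followup, subject_masks.brain_mask)
    diff = difference_map(baseline_n, followup_n)
    candidates = select_candidates(diff, subject_masks, template_masks, cfg)
    if len(candidates) == 0:
        return SegmentationResult(clusters=[], threshold=None, n_candidates=0)
    if np.unique(candidates.values).size < 2:
        threshold = float(candidates.values.min())
    else:
        threshold = kmeans_threshold(candidates.values, k=cfg.k_classes, seed=cfg.kmeans_seed)
    clusters = extract_clusters(candidates, threshold, cfg, spacing=baseline.spacing)
    clusters = filter_clusters(clusters, subject_masks, template_masks, cfg)
    clusters = label_extensions(clusters, baseline_lacunes, cfg)
    return SegmentationResult(
        clusters=clusters, threshold=threshold, n_candidates=len(candidates)
    )


def clusters_to_label_volume(
    clusters: list[LesionCluster],
    like: ImageVolume,
    labels: tuple[str, ...] = ("incident", "extension"),
) -> ImageVolume:
    """Paint cluster ids into an integer volume (0 = background)."""
    out = np.zeros(like.grid_shape, dtype=np.int32)
    for c in clusters:
        if c.label in labels:
            out[tuple(c.voxels.T)] = c.cluster_id
    return ImageVolume(data=out, spacing=like.spacing, affine=like.affine.copy())
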