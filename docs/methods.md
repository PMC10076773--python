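# Methods

## Model and assumptions

An incident lacune is modeled as a compact set of voxels that is brain
tissue (white matter or basal ganglia) at baseline and CSF at follow-up.
On T1-weighted MRI this conversion lowers the signal, so on the voxelwise
difference map `d = baseline − follow-up` (both intensity-normalized) a new
cavity is a strongly positive cluster. The pipeline assumes its inputs are
already on a common 1 mm isotropic grid (co-registered, e.g. to MNI space)
and bias-corrected; it performs no registration or resampling and raises on
any grid mismatch beyond 1e-4 mm. All coordinates are 0-based voxel indices
in stored axis order; all geometry is computed in mm via the voxel spacing.

Detection is deliberately *not* a learned model: it is a chain of fully
specified classical operations (normalization, subtraction, mask gating,
1D clustering, connected components, morphology) whose every intermediate
is auditable. The price is a known false-positive burden at the brain
surface and in perivascular spaces; the rejected-cluster audit trail and
the manual-correction bookkeeping exist precisely to manage it.

## Pipeline stages and parameters

**Normalization.** Robust z-score within the brain mask: subtract the
in-mask median, divide by the in-mask IQR, zero outside. Invariant to
positive affine rescaling of scanner units and insensitive to lesion
outliers. A constant in-mask image is an error.

**Candidate gate.** A voxel is a candidate iff `d > 0`, it is CSF on the
follow-up scan, and it lies in `wm_interior ∪ basal_ganglia_dilated ∪
ventricles_dilated` (the last term switchable via
`include_ventricle_margin`, default on — it retains periventricular
cavities that the interior-distance exclusion would drop, and in practice
also supplies the low-intensity noise population that anchors the K-means
low class).

**Tissue masks.** Follow-up CSF comes from a 3-class 1D K-means over
in-brain intensities (CSF is the lowest-mean class on T1); the external
(subarachnoid) CSF is the largest 26-connected CSF component (ties broken
by the lowest raster-order label); the sulcal skeleton is the medial
surface of the external CSF, computed as the set of voxels whose Euclidean
distance to background is a 6-neighborhood local maximum. This medial
ridge keeps a 1-voxel sheet unchanged and reduces a 3-voxel slab to its
central plane, which is all the pipeline needs — a thin exclusion locus
along the sulci. (A curve-thinning skeletonizer would collapse CSF sheets
to lines and miss sulcal overlap.)

**White-matter interior.** The signed distance `d_wm` to the white-matter
mask boundary is computed with the exact Euclidean distance transform:
the boundary shell is the set of mask voxels with a 6-neighbor outside the
mask (the grid border counts as outside), shell voxels have `d_wm = 0`,
strictly interior voxels are negative. Candidates require `d_wm < 0`;
voxels with `d_wm ≥ 0` are excluded, which drops the subcortical edge of
the white matter where registration jitter and atrophy create spurious
signal changes.

**Threshold.** A two-class K-means over the candidate difference values;
the threshold is the minimum of the class with the higher mean, and voxels
equal to the threshold are kept (that minimum is itself a member of the
bright class). In 1D the optimal K-means partition is a split of the
sorted values, so for k = 2 the implementation finds the global optimum
exactly by scanning all n−1 splits (O(n log n), prefix-sum SSE); Lloyd's
algorithm with seeded k-means++ restarts, which can stall in local minima
on 1D data, is used only for k > 2. With fewer than two distinct candidate
values a two-class split is undefined and the threshold degrades to the
single value (all candidates kept); an empty candidate set short-circuits
to an empty result.

**Clusters and diameter.** Supra-threshold candidates are grouped under
26-connectivity in deterministic raster label order. The diameter is the
caliper (Feret) read-out: maximum pairwise voxel-centre distance in mm
plus one mean voxel extent, so a single voxel at 1 mm spacing reads
1 mm. For clusters above 300 voxels the maximum is taken over convex-hull
vertices (identical result, much faster), with a brute-force fallback for
degenerate point sets.

**Filtering.** Rules run in a fixed order and record the first match:
diameter < 3 mm (`too_small`), > 15 mm (`too_large`, the STRIVE band,
inclusive at both ends), any voxel on the external CSF (`external_csf`),
on the sulcal skeleton (`sulci`), on the white-matter edge shell
(`wm_edge`). The fixed order makes the audit report reproducible.

**Extension labeling.** Survivors overlapping the 3×3×3-box-dilated
baseline-lacune mask are `extension`, others `incident`. The 3×3×3 box is
the single neighborhood notion used everywhere (ventricle/basal-ganglia
dilation, extension labeling, gold matching).

Defaults (`PipelineConfig`): `k_classes=2`, diameter band `[3, 15]` mm,
3×3×3 kernels, 26-connectivity for clusters / 6 for boundaries,
`include_ventricle_margin=True`, seeds explicit everywhere.

## Evaluation protocol

Gold-standard lesions are single-voxel point marks. A cluster matches a
mark when any cluster voxel lies within the mark's 3×3×3-dilated
neighborhood; matching is one-to-one, greedy by increasing
centroid-to-mark distance (ties by cluster id then mark row), so one
cluster can never claim two marks — the multiplicity rule is a package
choice, made deterministic and conservative. Extensions are never counted
as incident detections. Per patient: TP + FN = gold marks, TP + FP =
incident clusters. Lesion-level sensitivity and F1 are summarized by
median and IQR over patients with at least one gold lesion (sensitivity is
undefined otherwise). Patient-level metrics binarize lesion presence;
specificity's denominator is the set of gold-negative patients — the only
definition consistent with the binarized 2×2 table.

Paired automatic vs gold counts are compared with a two-sided Wilcoxon
signed-rank test, zero differences dropped, conventional alpha 0.05. For
up to 25 non-zero pairs the p-value is exact: midranks are doubled to
integers and the null distribution of W+ is built by convolution over sign
flips (this handles ties, which the usual exact tables do not); beyond 25
pairs the normal approximation with tie and continuity corrections is
used. The exact branch is certified in the tests against full 2^n
enumeration to 1e-9.

Manual corrections (`remove_fp`, `confirm_tp`) mirror the combined
automatic + expert-review workflow: removed clusters are relabeled
rejected/`manual`; confirmed clusters stay incident and augment the
reference marks on re-evaluation (a real cavity the raters missed);
lesions the algorithm missed are never added back, so corrections can
reduce FP and increase TP but never repair an FN.

## The phantom: what it emulates, and what it does not

The phantom is a single-ellipsoid digital head — CSF rim, grey-matter
shell, white-matter core, two deep ventricles deliberately disconnected
from the surface CSF, a sulcal CSF channel cutting from the rim into the
white matter, and two basal-ganglia nuclei. Lesions are rasterized spheres
or ovoids with *strict* centre containment, which keeps the caliper
read-out within one voxel of nominal on the correct side of both diameter
bounds (a nominal 2 mm sphere collapses to its centre voxel and is
rejected as sub-3 mm, as it should be). Incident-like lesions keep
baseline anatomy and turn to CSF at follow-up; baseline lacunes are CSF at
both time points; the sulcal-widening confounder converts tissue at the
channel wall (sulcus "opens up"); the perivascular confounder is a sub-3 mm
incident-like change. Follow-up CSF can drift additively (scanner-to-
scanner CSF signal variation) and both images get independent seeded
Gaussian noise; geometry never depends on the seed.

The reference spec is a 96³ grid at 1 mm with tissue means CSF 10 / GM 60 /
WM 100, noise σ = 2 (2% of WM), and seven lesions: incident 4/6/10 mm, one
6 mm baseline lacune with a 5 mm extension abutting it, a 2 mm
perivascular confounder, a 7 mm sulcal-widening confounder. The 96³ size
keeps a full end-to-end run around a second while leaving room for every
gate to act on realistic-scale lesions.

What passing on phantoms does **not** show: the phantom has no bias field,
no partial-volume effect beyond rasterization, no registration error, no
anatomically realistic sulcal geometry, and its tissue classes are exactly
Gaussian. Real-data performance — in particular the false-positive rate in
real perivascular spaces and deep sulci — cannot be inferred from phantom
recovery; the phantom certifies the *logic* of every gate, not clinical
accuracy.

## Numerical choices and degenerate inputs

- Masks read from float NIfTIs are binarized at > 0.5 with a warning
  (registration interpolation residue).
- Component-size ties: lowest raster-order label, for reproducibility.
- Threshold comparison is `≥` (the class minimum belongs to the class).
- Grid-equality tolerance 1e-4 mm on spacings; shapes and orientation
  codes must match exactly.
- Degenerate normalization (IQR 0 but non-constant) falls back to the full
  range; fully constant in-mask images are errors.
- Determinism: identical inputs and seeds give bit-identical cluster
  tables and label volumes (verified in the tests byte-for-byte).

## Known limitations

- No shape constraint beyond the diameter band: elongated supra-threshold
  structures up to 15 mm caliper length pass the filter.
- Per-patient thresholding: the K-means cut is computed per pair, so the
  operating point adapts to each subject's candidate distribution; cohorts
  with pathologically few candidates fall back to the degenerate threshold.
- The ventricle-margin gate is an interpretation of how the dilated
  ventricle mask re-enters candidate selection (retaining periventricular
  candidates); it is exposed as a config flag rather than hard-wired.
- The evaluation consumes a consensus mark table; inter-rater agreement
  itself is out of scope.
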