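# lacunaflow

Automatic segmentation and evaluation of **incident lacunes** from paired
(baseline, follow-up) 3D T1-weighted brain MRIs.

Lacunes are small (3–15 mm) fluid-filled cavities left behind by small
subcortical infarcts, a key imaging marker of cerebral small vessel disease
(cSVD), including its severe hereditary form CADASIL. Counting *incident*
lacunes — cavities present at follow-up but absent at baseline — is a central
outcome in longitudinal cSVD studies and clinical trials, yet doing it
visually is slow and error-prone: perivascular spaces mimic small lacunes,
and brain atrophy makes sulci appear to "open up" between scans.

`lacunaflow` automates the detection. Given two co-registered, bias-corrected,
intensity-comparable T1 volumes on a common 1 mm grid (e.g. in MNI space), it:

1. robustly z-scores both scans within the brain mask (median/IQR);
2. forms the **difference map** `d = baseline − follow-up`, in which a new
   CSF-filled cavity is a strongly positive blob (T1 signal dropped);
3. keeps voxels with `d > 0` that are CSF on follow-up **and** lie in deep
   white matter: inside the white-matter mask at signed boundary distance
   `< 0 mm`, in the 3×3×3-dilated basal ganglia, or in the 3×3×3-dilated
   ventricle margin;
4. runs a two-class K-means on the candidate values and thresholds at the
   minimum of the high-intensity class;
5. groups supra-threshold voxels into 26-connected clusters and measures
   their caliper (Feret) diameter in mm;
6. rejects clusters outside the 3–15 mm STRIVE diameter band, or touching
   the external (subarachnoid) CSF, the skeletonized sulci, or the
   white-matter edge shell — the classic false-positive locations;
7. labels surviving clusters that touch the 3×3×3-dilated baseline-lacune
   mask as **extensions of former lacunes**, the rest as **incident**.

Rejected clusters are retained with their rejection reason so an expert can
audit the output and strike residual false positives in minutes; the
evaluation module scores clusters against expert point marks (lesion-level
sensitivity/F1 per patient, patient-level sensitivity/specificity/F1 on
binarized presence, Wilcoxon signed-rank on paired counts) and implements
that manual-correction bookkeeping.

The package also ships a **synthetic longitudinal phantom** — an ellipsoidal
digital brain with CSF rim, ventricles, a sulcal channel, and configurable
incident lesions, extensions, perivascular and sulcal-widening confounders,
CSF drift and noise — so the entire pipeline is testable end to end with
exact ground truth and no patient data.

## Worked example

Run the whole chain — phantom generation, mask preparation, segmentation,
evaluation — on the reference 96³ phantom (three incident lacunes of 4, 6
and 10 mm, one extension of a baseline lacune, a 2 mm perivascular
confounder and a 7 mm sulcal-widening confounder, Gaussian noise at 2% of
the white-matter intensity):

```bash
lacunaflow run-all --seed 1 --out-dir demo/
```

```
INFO lacunaflow: run-all done: 3 incident, 1 extension, 2 rejected
```

`demo/clusters.csv` is the audit report:

```
cluster_id,label,diameter_mm,centroid_x,centroid_y,centroid_z,n_voxels,volume_mm3,rejection_reason
1,incident,4.4641,30.0,38.0,44.0,27,27.0,none
2,extension,5.899,39.0,58.0,52.0,81,81.0,none
3,incident,10.798,48.0,48.0,30.0,485,485.0,none
4,rejected,1.0,56.0,60.0,38.0,1,1.0,too_small
5,incident,6.6569,62.0,36.0,40.0,93,93.0,none
6,rejected,7.9282,75.06,46.56,47.0,84,84.0,external_csf
```

All three inserted incident lacunes are found at their true centroids with
diameters within one voxel of nominal; the extension is labeled separately;
the perivascular mimic is rejected for being below 3 mm and the sulcal
widening for overlapping the external CSF. `demo/metrics.json` scores the
result against the phantom's consensus marks — here median lesion-level
sensitivity and F1 are 1.0 with totals `{"gold": 3, "auto": 3}` (the
Wilcoxon entry is null for a single patient with a zero paired difference,
and patient-level specificity is null because the cohort has no
lesion-free patient).

The stages are also available individually (`lacunaflow phantom`,
`prepare-masks`, `segment`, `evaluate`) and as library functions; see
`docs/methods.md` for the model, parameters and design choices.

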