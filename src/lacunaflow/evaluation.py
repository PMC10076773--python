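"""Evaluation of automatic clusters against expert gold-standard marks.

The gold standard is a set of point marks (one voxel per lesion, placed on a
single slice by expert consensus).  A cluster matches a mark when any of its
voxels falls in the mark's 3x3x3-dilated neighborhood; matching is one-to-one
and greedy by increasing centroid-to-mark distance, so one cluster can never
absorb two marks.  From the per-patient true/false positive/negative counts
the module derives lesion-level sensitivity and F1 (per patient, summarized
by median and IQR over patients with at least one gold lesion), patient-level
sensitivity/specificity/F1 on the binarized presence of incident lacunes, and
a Wilcoxon signed-rank comparison of the paired automatic and gold counts.

Manual corrections mirror the combined automatic-plus-expert workflow:
obvious false positives are struck from the cluster list, and clusters the
expert confirms as real lacunes missed by the gold standard augment the
reference; lesions the automatic method missed are never added back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import LesionCluster

__all__ = [
    "LesionConfusion",
    "CohortMetrics",
    "match_lesions",
    "cohort_metrics",
    "wilcoxon_signed_rank",
    "apply_corrections",
]


@dataclass
class LesionConfusion:
    """Per-patient lesion-level confusion counts and matched pairs."""

    patient_id: str
    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int]] = field(default_factory=list)  # (cluster_id, mark row)

    @property
    def sensitivity(self) -> float | None:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def f1(self) -> float | None:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else None

    @property
    def n_gold(self) -> int:
        return self.tp + self.fn

    @property
    def n_auto(self) -> int:
        return self.tp + self.fp


@dataclass
class CohortMetrics:
    per_patient: list[LesionConfusion]
    median_sensitivity: float | None
    sensitivity_iqr: tuple[float, float] | None
    median_f1: float | None
    f1_iqr: tuple[float, float] | None
    patient_level_sensitivity: float | None
    patient_level_specificity: float | None
    patient_level_f1: float | None
    wilcoxon_statistic: float | None
    wilcoxon_p: float | None

    @property
    def total_gold(self) -> int:
        return sum(c.n_gold for c in self.per_patient)

    @property
    def total_auto(self) -> int:
        return sum(c.n_auto for c in self.per_patient)

    def to_dict(self) -> dict:
        return {
            "per_patient": [
                {
                    "patient_id": c.patient_id,
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "sensitivity": c.sensitivity,
                    "f1": c.f1,
                }
                for c in self.per_patient
            ],
            "medians": {
                "sensitivity": self.median_sensitivity,
                "sensitivity_iqr": list(self.sensitivity_iqr) if self.sensitivity_iqr else None,
                "f1": self.median_f1,
                "f1_iqr": list(self.f1_iqr) if self.f1_iqr else None,
            },
            "patient_level": {
                "sensitivity": self.patient_level_sensitivity,
                "specificity": self.patient_level_specificity,
                "f1": self.patient_level_f1,
            },
            "totals": {"gold": self.total_gold, "auto": self.total_auto},
            "wilcoxon": {"statistic": self.wilcoxon_statistic, "p": self.wilcoxon_p},
        }


def match_lesions(
    clusters: list[LesionCluster],
    marks: pd.DataFrame,
    patient_id: str = "unknown",
    kernel_shape: tuple[int, int, int] = (3, 3, 3),
) -> LesionConfusion:
    """One-to-one greedy matching of incident clusters to gold marks.

    Only clusters labeled ``incident`` take part (extensions of former
    lacunes are bookkept separately and never counted).  A (cluster, mark)
    pair is eligible when some cluster voxel lies within the mark's dilated
    neighborhood (Chebyshev radius from ``kernel_shape``); eligible pairs are
    consumed greedily by increasing cluster-centroid-to-mark distance, ties
    broken by cluster id then mark row.
    """
    incident = [c for c in clusters if c.label == "incident"]
    radius = np.array([(k - 1) // 2 for k in kernel_shape])
    mark_xyz = marks[["x", "y", "z"]].to_numpy(dtype=np.int64) if len(marks) else np.empty((0, 3), int)

    eligible: list[tuple[float, int, int]] = []  # (centroid distance, cluster idx, mark idx)
    for ci, c in enumerate(incident):
        centroid = np.asarray(c.centroid)
        for mi in range(mark_xyz.shape[0]):
            cheb = np.abs(c.voxels - mark_xyz[mi])
            if (cheb <= radius).all(axis=1).any():
                dist = float(np.linalg.norm(centroid - mark_xyz[mi]))
                eligible.append((dist, ci, mi))
    eligible.sort(key=lambda t: (t[0], incident[t[1]].cluster_id, t[2]))

    used_c: set[int] = set()
    used_m: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, ci, mi in eligible:
        if ci in used_c or mi in used_m:
            continue
        used_c.add(ci)
        used_m.add(mi)
        pairs.append((incident[ci].cluster_id, mi))
    tp = len(pairs)
    return LesionConfusion(
        patient_id=patient_id,
        tp=tp,
        fp=len(incident) - tp,
        fn=mark_xyz.shape[0] - tp,
        matched_pairs=sorted(pairs),
    )


def _exact_wilcoxon_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact signed-rank p by dynamic programming over sign flips.

    Ranks may be midranks (ties), so they are doubled to integers and the
    null distribution of 2*W+ is built by convolving (1 + x^(2r)) terms.
    """
    r2 = np.round(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    w_low = min(w2, total - w2)
    w_high = max(w2, total - w2)
    p = counts[: w_low + 1].sum() + counts[w_high:].sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 25
) -> tuple[float | None, float | None]:
    """Two-sided Wilcoxon signed-rank test on paired counts.

    Zero differences are dropped.  With ``n`` non-zero pairs at most
    ``exact_max_n``, the p-value comes from the exact sign-flip distribution
    (midranks for tied magnitudes); beyond that, the normal approximation
    with tie correction and continuity correction is used.  Returns
    ``(W+, p)`` or ``(None, None)`` when every difference is zero.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return None, None
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return w_plus, _exact_wilcoxon_p(ranks, w_plus)
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
    return w_plus, float(res.pvalue)


def _median_iqr(values: list[float]) -> tuple[float | None, tuple[float, float] | None]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), (float(q1), float(q3))


def cohort_metrics(confusions: list[LesionConfusion]) -> CohortMetrics:
    """Aggregate per-patient confusions into the cohort summary.

    Lesion-level medians and IQRs are taken over patients with at least one
    gold lesion (sensitivity is undefined otherwise).  Patient-level metrics
    binarize the presence of incident lacunes: sensitivity over gold-positive
    patients, specificity over gold-negative patients, F1 from the 2x2
    table.  The Wilcoxon signed-rank test compares the paired per-patient
    automatic and gold counts (two-sided, alpha 0.05 by convention).
    """
    if not confusions:
        raise ValueError("no patients to aggregate")
    eligible = [c for c in confusions if c.n_gold >= 1]
    med_sens, iqr_sens = _median_iqr([c.sensitivity for c in eligible])
    med_f1, iqr_f1 = _median_iqr([c.f1 for c in eligible if c.f1 is not None])

    gold_pos = np.array([c.n_gold > 0 for c in confusions])
    auto_pos = np.array([c.n_auto > 0 for c in confusions])
    tp = int((gold_pos & auto_pos).sum())
    fn = int((gold_pos & ~auto_pos).sum())
    fp = int((~gold_pos & auto_pos).sum())
    tn = int((~gold_pos & ~auto_pos).sum())
    pl_sens = tp / (tp + fn) if (tp + fn) else None
    pl_spec = tn / (tn + fp) if (tn + fp) else None
    pl_f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else None

    w_stat, w_p = wilcoxon_signed_rank(
        np.array([c.n_auto for c in confusions]),
        np.array([c.n_gold for c in confusions]),
    )
    return CohortMetrics(
        per_patient=list(confusions),
        median_sensitivity=med_sens,
        sensitivity_iqr=iqr_sens,
        median_f1=med_f1,
        f1_iqr=iqr_f1,
        patient_level_sensitivity=pl_sens,
        patient_level_specificity=pl_spec,
        patient_level_f1=pl_f1,
        wilcoxon_statistic=w_stat,
        wilcoxon_p=w_p,
    )


def apply_corrections(
    clusters: list[LesionCluster],
    corrections: pd.DataFrame,
) -> tuple[list[LesionCluster], list[int]]:
    """Apply expert corrections to a patient's cluster list.

    ``corrections`` has columns (patient_id, cluster_id, action) with action
    in {remove_fp, confirm_tp}.  ``remove_fp`` relabels the cluster as
    rejected with reason ``manual``; ``confirm_tp`` keeps the cluster as
    incident and returns its id so the caller can augment the reference
    marks with it (a real lacune the experts initially missed).  False
    negatives are never repaired.  Returns the corrected cluster list and
    the confirmed cluster ids.
    """
    required = {"cluster_id", "action"}
    if len(corrections) and not required.issubset(corrections.columns):
        raise ValueError(f"corrections need columns {sorted(required)}")
    by_id = {c.cluster_id: c for c in clusters}
    actions: dict[int, str] = {}
    for _, row in corrections.iterrows():
        cid = int(row["cluster_id"])
        action = str(row["action"])
        if cid not in by_id:
            raise ValueError(f"correction references unknown cluster_id {cid}")
        if action not in {"remove_fp", "confirm_tp"}:
            raise ValueError(f"unknown correction action {action!r}")
        actions[cid] = action

    out: list[LesionCluster] = []
    confirmed: list[int] = []
    for c in clusters:
        action = actions.get(c.cluster_id)
        if action == "remove_fp":
            out.append(
                LesionCluster(
                    cluster_id=c.cluster_id,
                    voxels=c.voxels,
                    volume_mm3=c.volume_mm3,
                    diameter_mm=c.diameter_mm,
                    centroid=c.centroid,
                    label="rejected",
                    rejection_reason="manual",
                )
            )
        else:
            if action == "confirm_tp":
                confirmed.append(c.cluster_id)
            out.append(c)
    return out, confirmed


def corrected_reference(
    marks: pd.DataFrame,
    clusters: list[LesionCluster],
    confirmed_ids: list[int],
    patient_id: str = "unknown",
) -> pd.DataFrame:
    """Augment gold marks with the centroids of expert-confirmed clusters."""
    rows = []
    by_id = {c.cluster_id: c for c in clusters}
    for cid in confirmed_ids:
        cx, cy, cz = by_id[cid].centroid
        rows.append(
            {
                "patient_id": patient_id,
                "x": int(round(cx)),
                "y": int(round(cy)),
                "z": int(round(cz)),
                "source": "consensus",
            }
        )
    if not rows:
        return marks
    return pd.concat([marks, pd.DataFrame(rows)], ignore_index=True)
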