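"""Core segmentation stages: normalization, difference map, candidate gating,
K-means threshold, cluster extraction, diameter, filtering, extension labels."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist

from lacunaflow import (
    BinaryMask,
    PipelineConfig,
    cluster_diameter,
    difference_map,
    extract_clusters,
    filter_clusters,
    kmeans_threshold,
    label_extensions,
    normalize_intensity,
    select_candidates,
)
from lacunaflow.maskprep import SubjectMaskSet, TemplateMaskSet
from lacunaflow.segmentation import CandidateSet, LesionCluster

from conftest import make_mask, make_volume


def oracle_split_threshold(values):
    """Exhaustive optimal 1D 2-partition: scan every sorted split, return the
    minimum of the high class of the split with the least within-class SSE."""
    v = np.sort(np.asarray(values, dtype=float))
    best_sse, best_split = None, None
    for s in range(1, v.size):
        lo, hi = v[:s], v[s:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if best_sse is None or sse < best_sse - 1e-12:
            best_sse, best_split = sse, s
    return float(v[best_split])


def trivial_masks(shape, csf=None, external=None, sulci=None, wm=None, interior=None):
    """Mask sets for unit tests: everything permissive unless overridden."""
    ones = np.ones(shape, dtype=np.uint8)
    zeros = np.zeros(shape, dtype=np.uint8)
    m = lambda a: make_mask(a if a is not None else ones)
    z = lambda a: make_mask(a if a is not None else zeros)
    sset = SubjectMaskSet(
        brain_mask=m(None),
        csf_mask=m(csf),
        external_csf=z(external),
        sulci_skeleton=z(sulci),
    )
    wm_mask = m(wm)
    wm_interior = m(interior if interior is not None else (wm if wm is not None else None))
    tset = TemplateMaskSet(
        wm_mask=wm_mask,
        ventricles_dilated=z(None),
        basal_ganglia_dilated=z(None),
        wm_distance=np.zeros(shape),
        wm_interior=wm_interior,
    )
    return sset, tset


class TestNormalize:
    def test_median_zero_iqr_one_within_mask(self):
        data = np.zeros((3, 3, 3))
        data.flat[:27] = np.arange(27.0)
        vol = make_volume(data)
        brain = make_mask(np.ones((3, 3, 3)))
        out = normalize_intensity(vol, brain)
        assert np.median(out.data) == pytest.approx(0.0)
        q1, q3 = np.percentile(out.data, [25, 75])
        assert q3 - q1 == pytest.approx(1.0)

    def test_affine_invariance(self, tiny_brain):
        t1, brain, _ = tiny_brain
        a = normalize_intensity(t1, brain)
        b = normalize_intensity(make_volume(3.7 * t1.data + 11.0), brain)
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_outside_mask_zeroed(self, tiny_brain):
        t1, brain, _ = tiny_brain
        out = normalize_intensity(t1, brain)
        assert (out.data[~brain.as_bool()] == 0).all()

    def test_constant_image_rejected(self):
        vol = make_volume(np.full((4, 4, 4), 5.0))
        with pytest.raises(ValueError, match="constant"):
            normalize_intensity(vol, make_mask(np.ones((4, 4, 4))))


class TestDifferenceMap:
    def test_identical_inputs_all_zero(self, tiny_brain):
        t1, _, _ = tiny_brain
        d = difference_map(t1, t1)
        assert (d.data == 0).all()

    def test_unit_difference(self):
        a = make_volume(np.ones((4, 4, 4)))
        b = make_volume(np.zeros((4, 4, 4)))
        assert (difference_map(a, b).data == 1).all()

    def test_antisymmetric(self):
        rng = np.random.default_rng(2)
        a = make_volume(rng.normal(size=(5, 5, 5)))
        b = make_volume(rng.normal(size=(5, 5, 5)))
        np.testing.assert_array_equal(
            difference_map(a, b).data, -difference_map(b, a).data
        )


class TestSelectCandidates:
    def test_nonpositive_difference_yields_empty(self):
        shape = (5, 5, 5)
        sset, tset = trivial_masks(shape)
        diff = make_volume(np.full(shape, -1.0))
        assert len(select_candidates(diff, sset, tset)) == 0

    def test_singleton_inside_all_gates(self):
        shape = (5, 5, 5)
        sset, tset = trivial_masks(shape)
        data = np.zeros(shape)
        data[2, 2, 2] = 3.0
        cands = select_candidates(make_volume(data), sset, tset)
        assert len(cands) == 1
        assert tuple(cands.indices[0]) == (2, 2, 2)
        assert cands.values[0] == 3.0

    def test_positive_voxel_outside_csf_excluded(self):
        shape = (5, 5, 5)
        csf = np.ones(shape)
        csf[2, 2, 2] = 0
        sset, tset = trivial_masks(shape, csf=csf)
        data = np.zeros(shape)
        data[2, 2, 2] = 3.0
        assert len(select_candidates(make_volume(data), sset, tset)) == 0

    def test_ventricle_margin_gate_is_switchable(self):
        shape = (5, 5, 5)
        sset, tset = trivial_masks(shape, wm=np.zeros(shape), interior=np.zeros(shape))
        vents = np.zeros(shape)
        vents[2, 2, 2] = 1
        tset.ventricles_dilated = make_mask(vents)
        data = np.zeros(shape)
        data[2, 2, 2] = 3.0
        diff = make_volume(data)
        on = select_candidates(diff, sset, tset, PipelineConfig(include_ventricle_margin=True))
        off = select_candidates(diff, sset, tset, PipelineConfig(include_ventricle_margin=False))
        assert len(on) == 1 and len(off) == 0


class TestKmeansThreshold:
    def test_perfectly_separated_classes(self):
        assert kmeans_threshold(np.array([1.0, 1, 1, 9, 9, 9])) == 9.0

    def test_derived_two_cluster_example(self):
        vals = np.array([0.1, 0.2, 0.3, 5.0, 5.1, 6.0])
        assert kmeans_threshold(vals) == 5.0
        assert oracle_split_threshold(vals) == 5.0

    def test_no_spread_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            kmeans_threshold(np.array([2.0, 2, 2, 2]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_agrees_with_exhaustive_oracle(self, data):
        n = data.draw(st.integers(2, 200))
        seed = data.draw(st.integers(0, 2**16))
        rng = np.random.default_rng(seed)
        kind = data.draw(st.sampled_from(["uniform", "bimodal", "exponential"]))
        if kind == "uniform":
            vals = rng.uniform(0.01, 10.0, n)
        elif kind == "bimodal":
            vals = np.concatenate(
                [rng.normal(1, 0.2, n // 2 + 1), rng.normal(8, 0.5, n // 2 + 1)]
            )
        else:
            vals = rng.exponential(2.0, n) + 0.01
        if np.unique(vals).size < 2:
            return
        assert kmeans_threshold(vals, 2, seed=seed) == pytest.approx(
            oracle_split_threshold(vals), abs=1e-12
        )


class TestClusterDiameter:
    def test_single_voxel_is_one_voxel_extent(self):
        assert cluster_diameter(np.array([[3, 3, 3]]), (1, 1, 1)) == 1.0

    def test_two_face_adjacent_voxels(self):
        vox = np.array([[1, 1, 1], [2, 1, 1]])
        assert cluster_diameter(vox, (1, 1, 1)) == 2.0

    def test_digital_ball_radius_3(self):
        # digital ball: voxel centres within 3 mm of the centre (inclusive)
        offs = np.array(
            [o for o in itertools.product(range(-3, 4), repeat=3) if np.dot(o, o) <= 9]
        )
        expect = pdist(offs.astype(float)).max() + 1.0
        assert expect == 7.0  # brute-force oracle
        assert cluster_diameter(offs + 5, (1, 1, 1)) == pytest.approx(7.0)

    def test_anisotropic_spacing_uses_mm(self):
        vox = np.array([[0, 0, 0], [0, 0, 3]])
        d = cluster_diameter(vox, (1, 1, 2))
        assert d == pytest.approx(6.0 + (1 + 1 + 2) / 3)

    def test_hull_path_matches_brute_force(self):
        rng = np.random.default_rng(9)
        vox = rng.integers(0, 20, size=(400, 3))
        d_hull = cluster_diameter(vox, (1, 1, 1))
        d_brute = pdist(vox.astype(float)).max() + 1.0
        assert d_hull == pytest.approx(d_brute)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_diameter(np.empty((0, 3)), (1, 1, 1))


def make_candidates(shape, voxel_values: dict):
    idx = np.array(list(voxel_values.keys()))
    vals = np.array(list(voxel_values.values()), dtype=float)
    return CandidateSet(indices=idx, values=vals, grid_shape=shape)


class TestExtractClusters:
    def test_corner_sharing_voxels_join_under_26_connectivity(self):
        cands = make_candidates((5, 5, 5), {(1, 1, 1): 2.0, (2, 2, 2): 2.0})
        out = extract_clusters(cands, threshold=1.0)
        assert len(out) == 1 and out[0].n_voxels == 2

    def test_gap_separates_clusters(self):
        cands = make_candidates((7, 7, 7), {(1, 1, 1): 2.0, (4, 4, 4): 2.0})
        out = extract_clusters(cands, threshold=1.0)
        assert len(out) == 2

    def test_no_supra_threshold_voxel_gives_empty(self):
        cands = make_candidates((5, 5, 5), {(1, 1, 1): 0.5})
        assert extract_clusters(cands, threshold=1.0) == []

    def test_threshold_value_itself_is_kept(self):
        cands = make_candidates((5, 5, 5), {(1, 1, 1): 1.0})
        assert len(extract_clusters(cands, threshold=1.0)) == 1

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        voxels = {}
        for _ in range(60):
            voxels[tuple(rng.integers(0, 10, 3))] = float(rng.uniform(0, 5))
        cands = make_candidates((10, 10, 10), voxels)
        prev = None
        for thr in (0.5, 1.5, 2.5, 3.5):
            cur = set()
            for c in extract_clusters(cands, threshold=thr):
                cur |= {tuple(v) for v in c.voxels}
            if prev is not None:
                assert cur <= prev  # raising the threshold never adds a voxel
            prev = cur


def cluster_at(voxels, shape=(24, 24, 24), cid=1):
    vox = np.atleast_2d(np.asarray(voxels))
    return LesionCluster(
        cluster_id=cid,
        voxels=vox,
        volume_mm3=float(vox.shape[0]),
        diameter_mm=cluster_diameter(vox, (1, 1, 1)),
        centroid=tuple(vox.mean(axis=0)),
    )


class TestFilterClusters:
    def test_size_bounds_and_reasons(self):
        shape = (40, 40, 40)
        sset, tset = trivial_masks(shape, wm=np.zeros(shape), interior=np.zeros(shape))
        small = cluster_at([[5, 5, 5]], cid=1)  # diameter 1 mm
        big = cluster_at([[2, 2, 2], [2, 2, 22]], cid=2)  # 21 mm
        ok = cluster_at([[10, 10, 10], [10, 10, 14]], cid=3)  # 5 mm
        out = filter_clusters([small, big, ok], sset, tset)
        assert [c.rejection_reason for c in out] == ["too_small", "too_large", "none"]
        assert [c.label for c in out] == ["rejected", "rejected", "pending"]

    def test_location_rules_in_order(self):
        shape = (24, 24, 24)
        external = np.zeros(shape)
        external[5, 5, 5] = 1
        sulci = np.zeros(shape)
        sulci[10, 10, 10] = 1
        wm = np.ones(shape)
        interior = np.zeros(shape)  # everything is WM edge shell
        sset, tset = trivial_masks(
            shape, external=external, sulci=sulci, wm=wm, interior=interior
        )
        on_external = cluster_at([[5, 5, 5], [5, 5, 9]], cid=1)
        on_sulci = cluster_at([[10, 10, 10], [10, 10, 14]], cid=2)
        on_edge = cluster_at([[15, 15, 15], [15, 15, 19]], cid=3)
        out = filter_clusters([on_external, on_sulci, on_edge], sset, tset)
        assert [c.rejection_reason for c in out] == ["external_csf", "sulci", "wm_edge"]

    def test_size_rejection_takes_precedence_over_location(self):
        shape = (24, 24, 24)
        external = np.ones(shape)
        sset, tset = trivial_masks(shape, external=external, wm=np.zeros(shape), interior=np.zeros(shape))
        tiny_on_external = cluster_at([[5, 5, 5]], cid=1)
        out = filter_clusters([tiny_on_external], sset, tset)
        assert out[0].rejection_reason == "too_small"


class TestLabelExtensions:
    def _lacunes(self, shape=(16, 16, 16)):
        m = np.zeros(shape)
        m[8, 8, 8] = 1
        return make_mask(m)

    def test_face_adjacent_cluster_is_extension(self):
        c = cluster_at([[9, 8, 8], [10, 8, 8], [9, 8, 9], [10, 8, 9]], shape=(16,) * 3)
        out = label_extensions([c], self._lacunes())
        assert out[0].label == "extension"

    def test_two_voxels_away_is_incident(self):
        c = cluster_at([[11, 8, 8], [12, 8, 8], [11, 9, 8], [12, 9, 8]], shape=(16,) * 3)
        out = label_extensions([c], self._lacunes())
        assert out[0].label == "incident"

    def test_empty_baseline_mask_gives_all_incident(self):
        c = cluster_at([[9, 8, 8], [10, 8, 8]], shape=(16,) * 3)
        out = label_extensions([c], make_mask(np.zeros((16, 16, 16))))
        assert out[0].label == "incident"

    def test_rejected_clusters_pass_through_untouched(self):
        c = LesionCluster(
            cluster_id=1,
            voxels=np.array([[9, 8, 8]]),
            volume_mm3=1.0,
            diameter_mm=1.0,
            centroid=(9.0, 8.0, 8.0),
            label="rejected",
            rejection_reason="too_small",
        )
        out = label_extensions([c], self._lacunes())
        assert out[0].label == "rejected" and out[0].rejection_reason == "too_small"
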