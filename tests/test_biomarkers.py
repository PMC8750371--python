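import numpy as np
import pytest

from petresponse import ValueKind, label_lesions, lesion_stats, sul_peak, biomarker_panel
from petresponse.biomarkers import Organ, assign_organ, pet_bone_index, pet_liver_index, sphere_offsets

from conftest import flood_fill_components, mask, random_scene, sul_peak_oracle, volume


class TestLabeling:
    def test_two_disjoint_cubes(self):
        m = np.zeros((10, 10, 10), dtype=bool)
        m[1:3, 1:3, 1:3] = True
        m[6:8, 6:8, 6:8] = True
        assert label_lesions(mask(m)).n_lesions == 2

    def test_corner_touching_cubes_depend_on_connectivity(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[1:3, 1:3, 1:3] = True
        m[3:5, 3:5, 3:5] = True  # shares only the corner at (2,2,2)-(3,3,3)
        assert label_lesions(mask(m), connectivity=26).n_lesions == 1
        assert label_lesions(mask(m), connectivity=6).n_lesions == 2
        # agrees with an independent flood fill
        assert len(flood_fill_components(m, 26)) == 1
        assert len(flood_fill_components(m, 6)) == 2

    def test_empty_mask(self):
        assert label_lesions(mask(np.zeros((4, 4, 4), dtype=bool))).n_lesions == 0

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_on_random_masks(self, connectivity):
        for seed in range(8):
            m = random_scene(np.random.default_rng(seed), shape=(12, 12, 12))
            ours = label_lesions(mask(m), connectivity)
            comps = flood_fill_components(m, connectivity)
            assert ours.n_lesions == len(comps)
            # same partition: every component maps to exactly one label
            for comp in comps:
                labels = {ours.labels[v] for v in comp}
                assert len(labels) == 1

    def test_label_order_is_scan_deterministic(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[4, 4, 0] = True  # first in a (z,y,x) lexicographic scan
        m[0, 0, 4] = True
        labels = label_lesions(mask(m)).labels
        assert labels[4, 4, 0] == 1
        assert labels[0, 0, 4] == 2


class TestSulPeak:
    def test_sphere_offset_count_on_2mm_grid(self):
        assert len(sphere_offsets((2.0, 2.0, 2.0), 12.0)) == 123

    def test_uniform_volume_gives_background(self):
        v = volume(np.full((9, 9, 9), 2.0), spacing=(2.0, 2.0, 2.0))
        m = np.zeros((9, 9, 9), dtype=bool)
        m[4, 4, 4] = True
        res = sul_peak(v, mask(m, spacing=(2.0, 2.0, 2.0)))
        assert res.value == pytest.approx(2.0)

    def test_single_hot_voxel_worked_example(self):
        # 12 mm sphere on a 2 mm grid holds 123 voxels; one voxel at 10 in
        # background 1 gives mean (10 + 122) / 123
        v = np.ones((15, 15, 15))
        v[7, 7, 7] = 10.0
        m = np.zeros_like(v, dtype=bool)
        m[7, 7, 7] = True
        res = sul_peak(volume(v, spacing=(2.0, 2.0, 2.0)), mask(m, spacing=(2.0, 2.0, 2.0)))
        assert res.value == 132.0 / 123.0
        assert res.center == (7, 7, 7)

    def test_peak_not_centered_on_hottest_voxel(self):
        # a hot voxel beside a hotter neighbourhood: the best sphere centre
        # is the mask voxel whose sphere catches the plateau, not the max
        v = np.ones((13, 13, 13))
        v[2, 2, 2] = 50.0
        v[8:11, 8:11, 8:11] = 20.0
        m = np.zeros_like(v, dtype=bool)
        m[2, 2, 2] = True
        m[9, 9, 9] = True
        res = sul_peak(volume(v, spacing=(3.0, 3.0, 3.0)), mask(m, spacing=(3.0, 3.0, 3.0)))
        assert res.center == (9, 9, 9)
        hottest = np.unravel_index(np.argmax(v), v.shape)
        assert res.center != hottest

    @pytest.mark.parametrize("spacing", [(1.0, 1.0, 1.0), (2.0, 2.0, 2.0), (1.5, 2.0, 3.0)])
    def test_matches_brute_force_oracle(self, spacing):
        rng = np.random.default_rng(42)
        for _ in range(6):
            shape = tuple(rng.integers(6, 13, size=3))
            v = volume(rng.random(shape) * 10, spacing=spacing)
            m_arr = rng.random(shape) < 0.05
            if not m_arr.any():
                m_arr[tuple(rng.integers(0, s) for s in shape)] = True
            res = sul_peak(v, mask(m_arr, spacing=spacing))
            expect, center = sul_peak_oracle(v, mask(m_arr, spacing=spacing))
            assert res.value == expect
            assert res.center == center

    def test_monotone_in_added_activity(self):
        rng = np.random.default_rng(7)
        v = rng.random((10, 10, 10)) * 5
        m_arr = rng.random((10, 10, 10)) < 0.1
        base = sul_peak(volume(v, spacing=(2.0, 2.0, 2.0)), mask(m_arr, spacing=(2.0, 2.0, 2.0))).value
        v2 = v.copy()
        v2[3, 4, 5] += 2.5
        bumped = sul_peak(volume(v2, spacing=(2.0, 2.0, 2.0)), mask(m_arr, spacing=(2.0, 2.0, 2.0))).value
        assert bumped >= base

    def test_empty_mask_flagged(self):
        res = sul_peak(volume(np.ones((4, 4, 4))), mask(np.zeros((4, 4, 4), dtype=bool)))
        assert not res.defined
        assert np.isnan(res.value)


class TestLesionStats:
    def test_uniform_lesion_worked_example(self):
        # 100 voxels of 2x2x2 mm (0.008 mL), SUV 5 -> MTV 0.8 mL, TLG 4.0
        m = np.zeros((10, 10, 10), dtype=bool)
        m[2:6, 2:7, 2:7] = True  # 4*5*5 = 100 voxels
        suv = np.where(m, 5.0, 1.0)
        lm = label_lesions(mask(m, spacing=(2.0, 2.0, 2.0)))
        (stats,) = lesion_stats(lm, volume(suv, spacing=(2.0, 2.0, 2.0), kind=ValueKind.SUV_BW))
        assert stats.n_voxels == 100
        assert stats.mtv_ml == pytest.approx(0.8)
        assert stats.tlg == pytest.approx(4.0)

    def test_mean_of_mixed_uptake(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[0, 0, :2] = True
        suv = np.zeros((4, 4, 4))
        suv[0, 0, 0], suv[0, 0, 1] = 2.0, 4.0
        (stats,) = lesion_stats(label_lesions(mask(m)), volume(suv, kind=ValueKind.SUV_BW))
        assert stats.suv_mean == pytest.approx(3.0)

    def test_split_conserves_total_tlg(self):
        rng = np.random.default_rng(3)
        suv = volume(rng.random((12, 12, 12)) * 8, kind=ValueKind.SUV_BW)
        joined = np.zeros((12, 12, 12), dtype=bool)
        joined[2:5, 2:5, 2:8] = True
        split = joined.copy()
        split[:, :, 5] = False  # cut into two disconnected slabs
        tlg_joined = sum(s.tlg for s in lesion_stats(label_lesions(mask(joined)), suv))
        total_split = sum(s.tlg for s in lesion_stats(label_lesions(mask(split)), suv))
        missing = suv.values[joined & ~split].sum() * 0.001
        assert total_split + missing == pytest.approx(tlg_joined, rel=1e-12)


class TestOrganIndices:
    def _boxes(self):
        bone = np.zeros((20, 20, 20), dtype=bool)
        bone[:, :, :10] = True
        liver = np.zeros_like(bone)
        liver[:, :, 12:18] = True
        return bone, liver

    def test_lesion_fully_in_bone(self):
        bone, liver = self._boxes()
        m = np.zeros_like(bone)
        m[5:7, 5:7, 2:4] = True
        lm = label_lesions(mask(m))
        assert assign_organ(lm, mask(bone), mask(liver)) == [Organ.BONE]

    def test_minority_overlap_is_other(self):
        bone, liver = self._boxes()
        m = np.zeros_like(bone)
        m[5, 5, 9:14] = True  # 2 of 5 voxels in liver (40%)
        lm = label_lesions(mask(m))
        assert assign_organ(lm, mask(bone), mask(liver)) == [Organ.OTHER]

    def test_bone_precedence_on_overlapping_masks(self):
        bone, _ = self._boxes()
        liver = bone.copy()  # fully overlapping organ masks
        m = np.zeros_like(bone)
        m[3:5, 3:5, 3:5] = True
        lm = label_lesions(mask(m))
        assert assign_organ(lm, mask(bone), mask(liver)) == [Organ.BONE]

    def test_pbi_worked_examples(self):
        # bone 1000 mL at 1 mm voxels = 1e6 voxels; lesions 5 + 10 mL
        bone = np.zeros((100, 100, 110), dtype=bool)
        bone[:, :, :100] = True  # 1e6 voxels = 1000 mL
        m = np.zeros_like(bone)
        m[:10, :25, :20] = True  # 5000 voxels = 5 mL
        m[50:70, 50:75, 50:70] = True  # 10000 voxels = 10 mL
        lm = label_lesions(mask(m))
        assert pet_bone_index(lm, mask(bone)) == pytest.approx(1.5)

    def test_pbi_no_lesions_is_zero_and_empty_bone_errors(self):
        bone = np.ones((5, 5, 5), dtype=bool)
        lm = label_lesions(mask(np.zeros((5, 5, 5), dtype=bool)))
        assert pet_bone_index(lm, mask(bone)) == 0.0
        with pytest.raises(ValueError, match="empty bone mask"):
            pet_bone_index(lm, mask(np.zeros((5, 5, 5), dtype=bool)))

    def test_pli_of_liver_as_its_own_lesion_is_100(self):
        liver = np.zeros((10, 10, 10), dtype=bool)
        liver[2:8, 2:8, 2:8] = True
        lm = label_lesions(mask(liver))
        assert pet_liver_index(lm, mask(liver)) == pytest.approx(100.0)


class TestPanel:
    def _inputs(self, lesion=True):
        shape = (16, 16, 16)
        sp = (3.0, 3.0, 3.0)
        bone = np.zeros(shape, dtype=bool)
        bone[:, :, :5] = True
        liver = np.zeros(shape, dtype=bool)
        liver[:, :, 8:12] = True
        m = np.zeros(shape, dtype=bool)
        if lesion:
            m[6:9, 6:9, 9:11] = True  # inside liver
        suv = np.where(m, 6.0, 1.0)
        sul = suv * 0.75
        return (
            volume(sul, spacing=sp, kind=ValueKind.SUL),
            volume(suv, spacing=sp, kind=ValueKind.SUV_BW),
            mask(m, spacing=sp),
            mask(bone, spacing=sp),
            mask(liver, spacing=sp),
        )

    def test_empty_mask_panel(self):
        panel = biomarker_panel(*self._inputs(lesion=False))
        assert not panel.sul_peak.defined
        assert panel.mtv_total_ml == 0.0
        assert panel.tlg_total == 0.0
        assert panel.pbi_pct == 0.0
        assert panel.pli_pct == 0.0

    def test_single_lesion_panel_consistent_with_components(self):
        sul, suv, m, bone, liver = self._inputs()
        panel = biomarker_panel(sul, suv, m, bone, liver)
        lm = label_lesions(m)
        stats = lesion_stats(lm, suv)
        assert panel.mtv_total_ml == pytest.approx(sum(s.mtv_ml for s in stats))
        assert panel.tlg_total == pytest.approx(sum(s.tlg for s in stats))
        assert panel.sul_peak.value == sul_peak(sul, m).value
        assert panel.pli_pct == pytest.approx(pet_liver_index(lm, liver, bone=bone))
        assert panel.per_lesion[0].organ is Organ.LIVER

    def test_tlg_total_invariant_to_connectivity(self):
        rng = np.random.default_rng(11)
        suv = volume(rng.random((14, 14, 14)) * 10, kind=ValueKind.SUV_BW)
        m = random_scene(rng, shape=(14, 14, 14), n_blobs=(2, 6))
        totals = []
        for conn in (6, 18, 26):
            stats = lesion_stats(label_lesions(mask(m), conn), suv)
            totals.append(sum(s.tlg for s in stats))
        assert totals[0] == pytest.approx(totals[1], rel=1e-12)
        assert totals[1] == pytest.approx(totals[2], rel=1e-12)
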