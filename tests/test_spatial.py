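"""Geometry: NIfTI round-trips, sphere ROIs, COM collapse, distances,
volumes and overlap metrics, and the pairing rules of the distance table."""

import math

import nibabel as nib
import numpy as np
import pytest

import tractval as tv
from tractval.spatial import DistanceRecord, StimulationPoint

from conftest import all_voxel_world_centers, random_affine, random_mask_volume


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestVolumeIO:
    def test_roundtrip_identity(self, rng, tmp_path):
        vol = random_mask_volume(rng, n_voxels=100)
        path = tmp_path / "m.nii.gz"
        tv.write_volume(vol, path)
        back = tv.read_volume(path)
        np.testing.assert_array_equal(back.mask, vol.mask)
        np.testing.assert_allclose(back.affine, vol.affine, atol=1e-5)

    def test_read_binarizes_at_zero(self, tmp_path):
        data = np.zeros((3, 3, 3), dtype=np.float32)
        data[0, 0, 0], data[1, 1, 1] = 0.5, 2.0
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "v.nii"))
        vol = tv.read_volume(tmp_path / "v.nii")
        assert vol.mask.sum() == 2
        assert vol.mask[0, 0, 0] == 1 and vol.mask[1, 1, 1] == 1

    def test_singular_affine_rejected(self):
        aff = np.eye(4)
        aff[0, 0] = 0.0
        with pytest.raises(ValueError, match="singular"):
            tv.LabeledVolume(np.zeros((2, 2, 2), dtype=int), aff)

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            tv.LabeledVolume(np.full((2, 2, 2), 2), np.eye(4))

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            tv.read_volume(tmp_path / "nope.nii.gz")


# ---------------------------------------------------------------------------
# Spheres and COM
# ---------------------------------------------------------------------------

class TestSphere:
    def test_radius_zero_at_voxel_center_is_single_voxel(self):
        ref = tv.LabeledVolume(np.zeros((9, 9, 9), dtype=int), np.eye(4))
        s = tv.make_sphere((4.0, 4.0, 4.0), 0.0, ref)
        assert s.n_voxels == 1
        assert s.mask[4, 4, 4] == 1

    def test_default_radius_is_5mm(self):
        ref = tv.LabeledVolume(np.zeros((15, 15, 15), dtype=int), np.eye(4))
        assert tv.make_sphere((7, 7, 7), reference=ref).n_voxels == \
            tv.make_sphere((7, 7, 7), 5.0, ref).n_voxels

    def test_matches_exhaustive_scan_on_identity_grid(self):
        ref = tv.LabeledVolume(np.zeros((13, 13, 13), dtype=int), np.eye(4))
        center, radius = (6.2, 5.9, 6.5), 5.0
        s = tv.make_sphere(center, radius, ref)
        expected = np.zeros((13, 13, 13), dtype=np.uint8)
        for i in range(13):
            for j in range(13):
                for k in range(13):
                    d = math.dist((i, j, k), center)
                    if d <= radius:
                        expected[i, j, k] = 1
        np.testing.assert_array_equal(s.mask, expected)

    def test_center_outside_fov_rejected(self):
        ref = tv.LabeledVolume(np.zeros((5, 5, 5), dtype=int), np.eye(4))
        with pytest.raises(ValueError, match="field of view"):
            tv.make_sphere((50.0, 0.0, 0.0), 5.0, ref)

    def test_negative_radius_rejected(self):
        ref = tv.LabeledVolume(np.zeros((5, 5, 5), dtype=int), np.eye(4))
        with pytest.raises(ValueError, match="radius"):
            tv.make_sphere((2, 2, 2), -1.0, ref)

    def test_voxel_count_nondecreasing_in_radius(self, rng):
        ref = tv.LabeledVolume(np.zeros((16, 16, 16), dtype=int), random_affine(rng))
        center = ref.voxel_to_world([8, 8, 8])[0]
        counts = [tv.make_sphere(center, r, ref).n_voxels for r in np.linspace(0, 8, 12)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestCenterOfMass:
    def test_single_voxel(self, rng):
        aff = random_affine(rng)
        mask = np.zeros((6, 6, 6), dtype=np.uint8)
        mask[2, 3, 4] = 1
        vol = tv.LabeledVolume(mask, aff)
        np.testing.assert_allclose(
            tv.center_of_mass(vol), vol.voxel_to_world([2, 3, 4])[0], atol=1e-12
        )

    def test_symmetric_sphere_recovers_center(self):
        ref = tv.LabeledVolume(np.zeros((15, 15, 15), dtype=int), np.eye(4))
        s = tv.make_sphere((7.0, 7.0, 7.0), 4.0, ref)
        np.testing.assert_allclose(tv.center_of_mass(s), (7, 7, 7), atol=1e-12)

    def test_random_mask_matches_direct_mean(self, rng):
        vol = random_mask_volume(rng, n_voxels=20)
        idx, world = all_voxel_world_centers(vol)
        expected = world[vol.mask.ravel() > 0].mean(axis=0)
        np.testing.assert_allclose(tv.center_of_mass(vol), expected, atol=1e-10)

    def test_empty_mask_rejected(self):
        vol = tv.LabeledVolume(np.zeros((3, 3, 3), dtype=int), np.eye(4))
        with pytest.raises(ValueError, match="empty"):
            tv.center_of_mass(vol)


class TestCollapseAndRecreate:
    def test_undeformed_sphere_is_fixed_point(self):
        ref = tv.LabeledVolume(np.zeros((17, 17, 17), dtype=int), np.eye(4))
        s = tv.make_sphere((8.0, 8.0, 8.0), 5.0, ref)
        s2 = tv.collapse_and_recreate(s, 5.0, ref)
        np.testing.assert_array_equal(s2.mask, s.mask)

    def test_warped_mask_becomes_sphere_at_com(self):
        ref = tv.LabeledVolume(np.zeros((21, 21, 21), dtype=int), np.eye(4))
        # ellipsoid: stretched along x
        ii, jj, kk = np.meshgrid(*(np.arange(21),) * 3, indexing="ij")
        ell = ((ii - 10) / 7.0) ** 2 + ((jj - 10) / 3.0) ** 2 + ((kk - 10) / 3.0) ** 2 <= 1
        warped = tv.LabeledVolume(ell.astype(np.uint8), np.eye(4))
        out = tv.collapse_and_recreate(warped, 5.0, ref)
        expected = tv.make_sphere(tv.center_of_mass(warped), 5.0, ref)
        np.testing.assert_array_equal(out.mask, expected.mask)

    def test_idempotent_after_one_application(self, rng):
        ref = tv.LabeledVolume(np.zeros((19, 19, 19), dtype=int), np.eye(4))
        warped = random_mask_volume(rng, shape=(19, 19, 19), n_voxels=40, affine=np.eye(4))
        once = tv.collapse_and_recreate(warped, 5.0, ref)
        twice = tv.collapse_and_recreate(once, 5.0, ref)
        np.testing.assert_array_equal(once.mask, twice.mask)

    def test_empty_mask_rejected(self):
        vol = tv.LabeledVolume(np.zeros((3, 3, 3), dtype=int), np.eye(4))
        with pytest.raises(ValueError, match="empty"):
            tv.collapse_and_recreate(vol, 5.0, vol)


# ---------------------------------------------------------------------------
# Minimum distances
# ---------------------------------------------------------------------------

def oracle_min_distance(xyz, vol):
    """Exhaustive all-voxel scan, with the containment rule applied through an
    independently computed nearest-voxel lookup."""
    idx, world = all_voxel_world_centers(vol)
    inside = vol.mask.ravel() > 0
    aff = vol.affine
    vox = np.linalg.solve(aff, np.append(np.asarray(xyz, float), 1.0))[:3]
    nearest = np.rint(vox).astype(int)
    if np.all(nearest >= 0) and np.all(nearest < vol.shape) and vol.mask[tuple(nearest)]:
        return 0
    d = np.sqrt(((world[inside] - np.asarray(xyz)) ** 2).sum(axis=1)).min()
    return int(math.ceil(d - 1e-6))


class TestMinDistance:
    def test_point_at_mask_voxel_center_is_zero(self):
        vol = random_mask_volume(np.random.default_rng(0), n_voxels=5)
        ijk = np.argwhere(vol.mask)[0]
        assert tv.min_distance(vol.voxel_to_world(ijk)[0], vol) == 0

    def test_ceiling_rule(self):
        mask = np.zeros((5, 5, 5), dtype=np.uint8)
        mask[0, 0, 0] = 1
        vol = tv.LabeledVolume(mask, np.eye(4))
        assert tv.min_distance((3.2, 0.0, 0.0), vol) == 4  # raw 3.2 -> 4
        assert tv.min_distance((3.0, 0.0, 0.0), vol) == 3  # exact integer stays

    def test_empty_mask_is_error_not_large_distance(self):
        vol = tv.LabeledVolume(np.zeros((4, 4, 4), dtype=int), np.eye(4))
        with pytest.raises(ValueError, match="empty tractogram"):
            tv.min_distance((1.0, 1.0, 1.0), vol)

    def test_matches_bruteforce_on_sheared_grids(self, rng):
        for _ in range(50):
            vol = random_mask_volume(rng, shape=(8, 9, 7), n_voxels=30)
            for _ in range(5):
                xyz = rng.uniform(-15, 25, size=3)
                assert tv.min_distance(xyz, vol) == oracle_min_distance(xyz, vol)

    def test_monotone_under_mask_growth(self, rng):
        for _ in range(20):
            vol = random_mask_volume(rng, shape=(10, 10, 10), n_voxels=10)
            xyz = rng.uniform(-5, 15, size=3)
            d1 = tv.min_distance(xyz, vol)
            grown = vol.mask.copy()
            zeros = np.argwhere(grown == 0)
            add = zeros[rng.choice(len(zeros), size=20, replace=False)]
            grown[add[:, 0], add[:, 1], add[:, 2]] = 1
            d2 = tv.min_distance(xyz, tv.LabeledVolume(grown, vol.affine))
            assert d2 <= d1


# ---------------------------------------------------------------------------
# Volumes and overlap
# ---------------------------------------------------------------------------

class TestVolumes:
    def test_1000_voxels_at_1mm_is_1ml(self, rng):
        vol = random_mask_volume(rng, shape=(12, 12, 12), n_voxels=1000, affine=np.eye(4))
        assert tv.volume_ml(vol) == pytest.approx(1.0)

    def test_anisotropic_voxels(self, rng):
        aff = np.diag([1.0, 1.0, 2.0, 1.0])
        vol = random_mask_volume(rng, shape=(10, 10, 10), n_voxels=500, affine=aff)
        assert tv.volume_ml(vol) == pytest.approx(1.0)

    def test_ratio_of_identical_masks_is_one(self, rng):
        vol = random_mask_volume(rng, n_voxels=50)
        assert tv.ratio_to(vol, vol) == pytest.approx(1.0)

    def test_empty_brain_rejected(self, rng):
        vol = random_mask_volume(rng, n_voxels=50)
        empty = tv.LabeledVolume(np.zeros(vol.shape, dtype=int), vol.affine)
        with pytest.raises(ValueError, match="empty brain"):
            tv.ratio_to(vol, empty)


class TestOverlapMetrics:
    def test_identical_and_disjoint(self, rng):
        a = random_mask_volume(rng, n_voxels=40, affine=np.eye(4))
        assert tv.dice(a, a) == 1.0 and tv.jaccard(a, a) == 1.0
        b_mask = 1 - a.mask
        b = tv.LabeledVolume(b_mask, a.affine)
        assert tv.dice(a, b) == 0.0 and tv.jaccard(a, b) == 0.0

    def test_formula_arithmetic(self):
        a_mask = np.zeros((4, 4, 4), dtype=np.uint8)
        b_mask = np.zeros((4, 4, 4), dtype=np.uint8)
        a_mask.ravel()[:8] = 1          # |A| = 8
        b_mask.ravel()[6:10] = 1        # |B| = 4, |A∩B| = 2
        a = tv.LabeledVolume(a_mask, np.eye(4))
        b = tv.LabeledVolume(b_mask, np.eye(4))
        assert tv.dice(a, b) == pytest.approx(1 / 3)
        assert tv.jaccard(a, b) == pytest.approx(1 / 5)

    def test_both_empty_convention(self):
        e = tv.LabeledVolume(np.zeros((3, 3, 3), dtype=int), np.eye(4))
        assert tv.dice(e, e) == 0.0 and tv.jaccard(e, e) == 0.0

    def test_mismatched_grids_rejected(self, rng):
        a = random_mask_volume(rng, shape=(5, 5, 5), n_voxels=10)
        b = random_mask_volume(rng, shape=(6, 6, 6), n_voxels=10)
        with pytest.raises(ValueError, match="grid"):
            tv.dice(a, b)

    def test_symmetry_and_dsc_jaccard_identity(self, rng):
        for _ in range(30):
            aff = np.eye(4)
            a = random_mask_volume(rng, shape=(6, 6, 6), n_voxels=int(rng.integers(1, 40)), affine=aff)
            b = random_mask_volume(rng, shape=(6, 6, 6), n_voxels=int(rng.integers(1, 40)), affine=aff)
            dsc, j = tv.dice(a, b), tv.jaccard(a, b)
            assert dsc == tv.dice(b, a)
            assert j <= dsc + 1e-15
            assert abs(dsc - 2 * j / (1 + j)) < 1e-12


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------

def _point(pid, pt, xyz, response, bundle="CST", hemi="L", depth="cortical"):
    return StimulationPoint(pid, pt, tuple(xyz), response, depth, bundle, hemi)


def _tract_volume(seed=0):
    rng = np.random.default_rng(seed)
    mask = np.zeros((12, 12, 12), dtype=np.uint8)
    mask[4:8, 4:8, 2:10] = 1
    return tv.LabeledVolume(mask, np.eye(4), "tractogram")


class TestDistanceTable:
    def test_pair_counting(self):
        vol = _tract_volume()
        volumes = {("P1", "CST", "L", m): vol for m in tv.METHODS}
        points = [
            _point("P1", "p1", (5, 5, 5), "positive"),
            _point("P1", "p2", (6, 6, 6), "positive"),
            _point("P1", "n1", (1, 1, 1), "negative"),
            _point("P1", "n2", (2, 2, 2), "negative"),
            _point("P1", "n3", (9, 9, 9), "negative"),
        ]
        records = tv.compute_distance_table(points, volumes, collapse=False)
        assert len(records) == 25

    def test_missing_reconstruction_drops_pairs(self):
        vol = _tract_volume()
        volumes = {("P1", "CST", "L", m): vol for m in tv.METHODS if m != "TP"}
        points = [
            _point("P1", "p1", (5, 5, 5), "positive"),
            _point("P1", "p2", (6, 6, 6), "positive"),
            _point("P1", "n1", (1, 1, 1), "negative"),
            _point("P1", "n2", (2, 2, 2), "negative"),
            _point("P1", "n3", (9, 9, 9), "negative"),
        ]
        assert len(tv.compute_distance_table(points, volumes, collapse=False)) == 20

    def test_unknown_patient_rejected(self):
        volumes = {("P1", "CST", "L", "FACT"): _tract_volume()}
        with pytest.raises(KeyError, match="unknown patient"):
            tv.compute_distance_table([_point("P9", "x", (5, 5, 5), "negative")], volumes)

    def test_pdes_pairs_only_with_designated_bundle(self):
        vol = _tract_volume()
        volumes = {
            ("P1", "CST", "L", "FACT"): vol,
            ("P1", "AF", "L", "FACT"): vol,
        }
        points = [_point("P1", "p1", (5, 5, 5), "positive", bundle="CST")]
        records = tv.compute_distance_table(points, volumes, collapse=False)
        assert len(records) == 1 and records[0].bundle == "CST"

    def test_matches_scripted_nested_loop(self, rng):
        """Pairing oracle: an independent nested loop over patients, methods
        and points reproduces the record set exactly."""
        vol = _tract_volume()
        volumes = {}
        for pid in ("P1", "P2"):
            for bundle in ("CST", "AF"):
                for m in tv.METHODS[:3]:
                    volumes[(pid, bundle, "R", m)] = vol
        del volumes[("P2", "AF", "R", "ATP")]  # a failed reconstruction
        points = []
        for pid in ("P1", "P2"):
            for i in range(3):
                xyz = rng.uniform(2, 9, size=3)
                resp = "positive" if i == 0 else "negative"
                bundle = "AF" if i == 1 else "CST"
                points.append(_point(pid, f"{pid}_{i}", xyz, resp, bundle=bundle, hemi="R"))
        records = tv.compute_distance_table(points, volumes, collapse=False)
        expected = set()
        for p in points:
            for key, v in volumes.items():
                if key[0] != p.patient_id:
                    continue
                if p.response == "positive" and (key[1], key[2]) != (p.bundle, p.hemisphere):
                    continue
                expected.add((key, p.point_id, tv.min_distance(p.xyz_mm, v)))
        got = {((r.patient_id, r.bundle, r.hemisphere, r.method), r.point_id, r.distance_mm)
               for r in records}
        assert got == expected
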