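import numpy as np
import pytest

from grafteval import (
    DendriteSkeleton,
    PunctaScene,
    RosetteSurface,
    SceneSpec,
    detect_spots,
    detect_synapses,
    forming_rbc_density,
    gen_puncta_scene,
    select_rbcs_near_rosette,
    synapses_per_rbc,
)

from oracles import detect_synapses_bruteforce


def _scene(ctbp2, mglur6, dendrites):
    return PunctaScene(
        ctbp2=PunctaScene.spots_frame(np.array(ctbp2, float)),
        mglur6=PunctaScene.spots_frame(np.array(mglur6, float)),
        dendrites=dendrites,
    )


def _vertical_dendrite(cell_id, x, y, z_top=0.0, z_bot=-8.0):
    return DendriteSkeleton(cell_id, [np.array([[x, y, z_bot], [x, y, z_top]])])


class TestDetectSynapses:
    def test_coincident_triplet_has_zero_distances(self):
        scene = _scene([[5, 5, 0]], [[5, 5, 0]],
                       [_vertical_dendrite("rbc0", 5, 5)])
        (rec,) = detect_synapses(scene)
        assert rec.d_ctbp2_mglur6 == 0.0
        assert rec.d_ctbp2_dendrite == 0.0
        assert rec.rbc_id == "rbc0"

    def test_threshold_rule_on_mglur6_distance(self):
        dend = [_vertical_dendrite("rbc0", 5, 6, z_top=0.0)]
        near = _scene([[5, 5, 0]], [[5, 5 + 1.4, 0]], dend)
        assert len(detect_synapses(near)) == 1
        far = _scene([[5, 5, 0]], [[5, 5 + 2.0, 0]], dend)
        assert len(detect_synapses(far)) == 0

    def test_inclusive_at_exactly_radius(self):
        scene = _scene([[5, 5, 0]], [[5, 6.5, 0]],
                       [_vertical_dendrite("rbc0", 5, 3.5)])
        (rec,) = detect_synapses(scene)
        assert rec.d_ctbp2_mglur6 == pytest.approx(1.5)
        assert rec.d_ctbp2_dendrite == pytest.approx(1.5)

    def test_empty_channels_yield_empty_result(self):
        scene = _scene(np.empty((0, 3)), [[0, 0, 0]],
                       [_vertical_dendrite("rbc0", 0, 0)])
        assert detect_synapses(scene) == []

    def test_planted_scene_recovered_exactly(self):
        scene, truth = gen_puncta_scene(
            SceneSpec(n_true_synapses=20, n_distractor_ctbp2=100,
                      n_distractor_mglur6=100, volume_extent=(80.0, 80.0, 40.0)),
            seed=2)
        records = detect_synapses(scene)
        detected = {(int(r.ctbp2_id), int(r.mglur6_id), r.rbc_id) for r in records}
        assert detected == set(truth.planted_synapses)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_allpairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scene = _scene(rng.uniform(0, 30, (120, 3)), rng.uniform(0, 30, (120, 3)),
                       [DendriteSkeleton(f"rbc{k}", [rng.uniform(0, 30, (4, 3))])
                        for k in range(5)])
        got = {(r.ctbp2_id, r.mglur6_id, r.rbc_id) for r in detect_synapses(scene)}
        assert got == detect_synapses_bruteforce(scene)

    def test_record_set_monotone_in_radius(self):
        rng = np.random.default_rng(6)
        scene = _scene(rng.uniform(0, 25, (80, 3)), rng.uniform(0, 25, (80, 3)),
                       [DendriteSkeleton(f"rbc{k}", [rng.uniform(0, 25, (3, 3))])
                        for k in range(4)])
        prev: set = set()
        for radius in (0.5, 1.0, 1.5, 2.5, 4.0):
            cur = {r.ctbp2_id for r in detect_synapses(scene, radius)}
            assert prev <= cur
            prev = cur

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(8)
        c = rng.uniform(0, 20, (40, 3))
        m = rng.uniform(0, 20, (40, 3))
        polys = [rng.uniform(0, 20, (4, 3)) for _ in range(3)]
        theta = 0.61
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        shift = np.array([7.0, -3.0, 11.0])
        a = _scene(c, m, [DendriteSkeleton(f"r{k}", [p]) for k, p in enumerate(polys)])
        b = _scene(c @ rot.T + shift, m @ rot.T + shift,
                   [DendriteSkeleton(f"r{k}", [p @ rot.T + shift])
                    for k, p in enumerate(polys)])
        ra, rb = detect_synapses(a), detect_synapses(b)
        assert [(r.ctbp2_id, r.mglur6_id, r.rbc_id) for r in ra] == \
               [(r.ctbp2_id, r.mglur6_id, r.rbc_id) for r in rb]
        assert np.allclose([r.d_ctbp2_mglur6 for r in ra],
                           [r.d_ctbp2_mglur6 for r in rb], atol=1e-9)


class TestRosetteSelection:
    def _point_surface(self):
        mask = np.zeros((21, 21, 21), bool)
        mask[10, 10, 10] = True  # physical (x, y, z) = (10, 10, 10)
        return RosetteSurface(mask, (1.0, 1.0, 1.0))

    def test_touching_vertex_included_and_far_skeleton_excluded(self):
        surf = self._point_surface()
        touch = DendriteSkeleton("a", [np.array([[10.0, 10, 10], [10, 10, 5]])])
        far = DendriteSkeleton("b", [np.array([[10.0, 10, 40], [10, 10, 45]])])
        assert select_rbcs_near_rosette([touch, far], surf) == {"a"}

    def test_segment_interior_closer_than_endpoints(self):
        """Endpoints at 12 um but the chord midpoint at 8 um: the cell must
        be selected at a 10-um reach."""
        surf = self._point_surface()
        a = np.sqrt(144.0 - 64.0)
        seg = DendriteSkeleton("mid", [np.array(
            [[10.0 - a, 18.0, 10.0], [10.0 + a, 18.0, 10.0]])])
        d_end = np.linalg.norm(np.array([10 - a, 18, 10]) - np.array([10, 10, 10]))
        assert d_end == pytest.approx(12.0)
        assert select_rbcs_near_rosette([seg], surf, reach=10.0) == {"mid"}

    def test_anisotropic_voxels(self):
        mask = np.zeros((5, 40, 40), bool)
        mask[0, :, :] = True  # slab at z in [0, 2) with dz = 2
        surf = RosetteSurface(mask, (2.0, 1.0, 1.0))
        near = DendriteSkeleton("n", [np.array([[20.0, 20, 9], [20, 20, 11]])])
        far = DendriteSkeleton("f", [np.array([[20.0, 20, 30], [20, 20, 35]])])
        sel = select_rbcs_near_rosette([near, far], surf, reach=10.0)
        assert sel == {"n"}


class TestRBCSummaries:
    def test_counts_and_forming_labels(self):
        scene, truth = gen_puncta_scene(SceneSpec(n_true_synapses=12,
                                                  n_rbc=4), seed=3)
        records = detect_synapses(scene)
        selected = {f"rbc{k:03d}" for k in range(4)} | {"rbc_lonely"}
        summary = synapses_per_rbc(records, selected)
        assert summary.counts["rbc000"] == 3
        assert summary.counts["rbc_lonely"] == 0
        assert summary.forming == {f"rbc{k:03d}" for k in range(4)}
        assert summary.mean_per_rbc == pytest.approx(12 / 5)

    def test_no_records(self):
        summary = synapses_per_rbc([], {"a", "b"})
        assert summary.counts == {"a": 0, "b": 0}
        assert summary.forming == set()
        assert summary.mean_per_rbc == 0.0

    def test_density_proportionality(self):
        assert forming_rbc_density({"a", "b", "c", "d"}, 0.2) == pytest.approx(20.0)
        assert forming_rbc_density(set(), 1.0) == 0.0
        assert forming_rbc_density({"a"}, 0.5) == 2 * forming_rbc_density({"a"}, 1.0)
        with pytest.raises(ValueError):
            forming_rbc_density({"a"}, 0.0)


class TestDetectSpots:
    def _blob(self, shape, center_vox, sigma_vox):
        zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
        r2 = ((zz - center_vox[0]) / sigma_vox[0]) ** 2 + \
             ((yy - center_vox[1]) / sigma_vox[1]) ** 2 + \
             ((xx - center_vox[2]) / sigma_vox[2]) ** 2
        return np.exp(-r2 / 2.0)

    def test_single_matched_blob_found_at_center(self):
        vol = self._blob((32, 32, 32), (16, 12, 20), (2, 2, 2))
        spots = detect_spots(vol, (1.0, 1.0, 1.0), sigma=2.0, min_intensity=0.05)
        assert len(spots) == 1
        assert abs(spots["x_um"].iloc[0] - 20) <= 1
        assert abs(spots["y_um"].iloc[0] - 12) <= 1
        assert abs(spots["z_um"].iloc[0] - 16) <= 1

    def test_all_zero_volume_has_no_spots(self):
        spots = detect_spots(np.zeros((16, 16, 16)), (1, 1, 1), 2.0, 0.05)
        assert len(spots) == 0

    def test_two_well_separated_blobs(self):
        vol = self._blob((24, 24, 48), (12, 12, 12), (2, 2, 2)) + \
              self._blob((24, 24, 48), (12, 12, 36), (2, 2, 2))
        spots = detect_spots(vol, (1, 1, 1), 2.0, 0.05)
        assert len(spots) == 2

    def test_anisotropic_voxels_recover_physical_center(self):
        # dz = 2 um: a blob of physical sigma 2 um spans 1 voxel in z
        vol = self._blob((16, 32, 32), (8, 16, 16), (1, 2, 2))
        spots = detect_spots(vol, (2.0, 1.0, 1.0), sigma=2.0, min_intensity=0.05)
        assert len(spots) == 1
        assert abs(spots["z_um"].iloc[0] - 16) <= 2

    def test_missing_z_spacing_rejected(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((4, 4, 4)), (1.0, 1.0), 2.0, 0.05)
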