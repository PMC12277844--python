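import numpy as np
import pytest
from scipy.spatial.distance import pdist

from grafteval import (
    CellSpec,
    FieldSpec,
    IRParams,
    SceneSpec,
    StimulusProtocol,
    ThinningPatch,
    baseline_stats,
    binomial_smooth,
    compute_psth,
    gen_hc_pattern,
    gen_puncta_scene,
    gen_spike_trains,
    naka_rushton,
    peak_response,
)

from oracles import point_segment_distance

class TestGenSpikeTrains:
    def test_unresponsive_cell_is_homogeneous_poisson(self):
        """A NONE cell at 5 spikes/s over 10 s should average 50 spikes/trial
        (within 3 standard errors over 200 trials)."""
        protocol = StimulusProtocol(trial_duration=12.0, t_on=0.1, t_off=1.7,
                                    dark_window=(2.0, 12.0),
                                    intensities=(95.23,), trials_per_intensity=200)
        cell = CellSpec(cell_id="c", response_type="NONE", baseline_rate=5.0)
        ds, _ = gen_spike_trains(protocol, [cell], seed=0)
        counts = [len(v) for v in ds.units["c"].spikes.values()]
        mean_rate_10s = np.mean(counts) * 10.0 / 12.0
        se = np.sqrt(50.0 / 200)
        assert abs(mean_rate_10s - 50.0) <= 3 * se

    def test_seeded_determinism_byte_identical(self):
        protocol = StimulusProtocol(trials_per_intensity=3)
        cells = [CellSpec(cell_id="a", response_type="ON"),
                 CellSpec(cell_id="b", response_type="LOW")]
        ds1, _ = gen_spike_trains(protocol, cells, seed=11)
        ds2, _ = gen_spike_trains(protocol, cells, seed=11)
        assert ds1.to_frame().to_csv() == ds2.to_frame().to_csv()

    def test_zero_rate_process_is_silent(self):
        protocol = StimulusProtocol(trials_per_intensity=3)
        cell = CellSpec(cell_id="z", response_type="NONE", baseline_rate=0.0)
        ds, _ = gen_spike_trains(protocol, [cell], seed=1)
        assert all(len(v) == 0 for v in ds.units["z"].spikes.values())

    def test_unknown_response_type_rejected(self):
        with pytest.raises(ValueError):
            CellSpec(cell_id="x", response_type="WIBBLE")

    def test_psth_peak_converges_to_intensity_response_curve(self):
        """With many trials, the corrected smoothed-PSTH peak approaches the
        Naka-Rushton value at each intensity (3-SE tolerance)."""
        protocol = StimulusProtocol(trials_per_intensity=500)
        params = IRParams(0.0, 25.0, 10.0, 1.0)
        cell = CellSpec(cell_id="on", response_type="ON", baseline_rate=3.0,
                        ir_params=params)
        ds, _ = gen_spike_trains(protocol, [cell], seed=3)
        rec = ds.units["on"]
        for intensity in protocol.intensities[-4:]:
            raw = compute_psth(rec.trials_at(intensity), protocol.trial_duration)
            base = baseline_stats(raw, protocol.dark_window)
            peak = peak_response(binomial_smooth(raw), base,
                                 (protocol.t_on, protocol.t_on + 0.5),
                                 closed_left=False)
            expected = float(naka_rushton(intensity, *params))
            rate_at_peak = cell.baseline_rate + expected
            se = np.sqrt(rate_at_peak / (0.020 * 500)) * 0.523  # smoothed SD
            assert abs(peak - expected) <= 3 * se


class TestGenHcPattern:
    def test_realized_count_matches_target(self):
        # field area of 1 mm^2 once the optic disc is carved out
        radius = np.sqrt((1.0 + np.pi * 0.075**2) / np.pi) * 1000.0
        spec = FieldSpec(field_radius=radius, target_density=1000.0,
                         hardcore_radius=10.0)
        pat = gen_hc_pattern(spec, seed=0)
        expected = spec.target_density * spec.usable_area_mm2
        assert abs(pat.n - expected) <= 3 * np.sqrt(expected)

    def test_hardcore_distance_enforced(self):
        for seed in (0, 1):
            pat = gen_hc_pattern(FieldSpec(hardcore_radius=18.0,
                                           target_density=600.0), seed=seed)
            assert pdist(pat.points).min() >= 18.0

    def test_points_avoid_optic_disc(self):
        spec = FieldSpec(disc_center=(100.0, -50.0), disc_diameter=200.0)
        pat = gen_hc_pattern(spec, seed=2)
        d = np.linalg.norm(pat.points - np.array([100.0, -50.0]), axis=1)
        assert d.min() > 100.0
        assert np.linalg.norm(pat.points, axis=1).max() <= spec.field_radius

    def test_total_deletion_patch_empties_field(self):
        spec = FieldSpec(thinning_patches=(
            ThinningPatch(center=(0.0, 0.0), radius=5000.0, deletion_prob=1.0),))
        assert gen_hc_pattern(spec, seed=3).n == 0

    def test_density_scales_linearly(self):
        n = [gen_hc_pattern(FieldSpec(target_density=d), seed=4).n
             for d in (400.0, 800.0)]
        assert n[1] == pytest.approx(2 * n[0], rel=0.01)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            gen_hc_pattern(FieldSpec(target_density=5000.0,
                                     hardcore_radius=30.0), seed=0)

    def test_seeded_determinism(self):
        a = gen_hc_pattern(FieldSpec(), seed=9)
        b = gen_hc_pattern(FieldSpec(), seed=9)
        assert np.array_equal(a.points, b.points)


class TestGenPunctaScene:
    def test_planted_triplets_satisfy_rule_and_distractors_violate_it(self):
        scene, truth = gen_puncta_scene(SceneSpec(), seed=1)
        c = scene.ctbp2.set_index("id")[["x_um", "y_um", "z_um"]]
        m = scene.mglur6.set_index("id")[["x_um", "y_um", "z_um"]]
        planted_c = {p[0] for p in truth.planted_synapses}
        planted_m = {p[1] for p in truth.planted_synapses}
        segs = [(skel.cell_id, a, b) for skel in scene.dendrites
                for poly in skel.polylines for a, b in zip(poly[:-1], poly[1:])]
        for cid, mid, rbc in truth.planted_synapses:
            assert np.linalg.norm(c.loc[cid] - m.loc[mid]) <= 1.5
            dmin = min(point_segment_distance(c.loc[cid].to_numpy(), a, b)
                       for cell, a, b in segs if cell == rbc)
            assert dmin <= 1.5
        for cid in set(c.index) - planted_c:
            dm = np.linalg.norm(m.to_numpy() - c.loc[cid].to_numpy(), axis=1).min()
            assert dm > 1.5
            dd = min(point_segment_distance(c.loc[cid].to_numpy(), a, b)
                     for _, a, b in segs)
            assert dd > 1.5
        assert planted_m <= set(m.index)

    def test_empty_truth_for_zero_synapses(self):
        scene, truth = gen_puncta_scene(
            SceneSpec(n_true_synapses=0, n_rbc=0), seed=0)
        assert truth.planted_synapses == []
        assert scene.dendrites == []

    def test_seeded_determinism(self):
        s1, t1 = gen_puncta_scene(SceneSpec(), seed=7)
        s2, t2 = gen_puncta_scene(SceneSpec(), seed=7)
        assert s1.ctbp2.equals(s2.ctbp2)
        assert s1.mglur6.equals(s2.mglur6)
        assert t1.planted_synapses == t2.planted_synapses

    def test_min_separation_must_clear_detection_radius(self):
        with pytest.raises(ValueError):
            SceneSpec(min_separation=2.0)
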