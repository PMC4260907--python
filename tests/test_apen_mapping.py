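"""Dynamic entropy maps, tip localization and LAT comparison."""

import numpy as np
import pytest

from rotormap.apen_mapping import (
    NO_ROTOR,
    build_map,
    calibration_floor,
    compare_tips,
    hot_region,
    locate_tip_apen,
    observation_mask,
    shen_map,
)
from rotormap.egm_forward import electrode_grid, unipolar_egm_array
from rotormap.lat_mapping import detect_activations_grid, locate_tip_lat
from rotormap.tissue_sim import track_phase_singularities


class TestBuildMap:
    def test_constant_egms_give_zero_map(self):
        egms = np.full((16, 2000), 3.0)
        emap = build_map(egms, (4, 4), window=1000, m=2, r_frac=0.2)
        assert emap.n_frames == 2
        assert np.all(emap.frames == 0.0)
        assert emap.global_max == 0.0

    def test_frame_count_arithmetic(self):
        egms = np.random.default_rng(0).normal(size=(4, 4000))
        emap = build_map(egms, (2, 2), window=1000, m=2, r_frac=0.2)
        assert emap.n_frames == 4

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            build_map(np.zeros((5, 2000)), (2, 2), window=1000)

    def test_signal_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            build_map(np.zeros((4, 500)), (2, 2), window=1000)

    def test_mask_limits_computed_sites(self):
        egms = np.random.default_rng(1).normal(size=(9, 1000))
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        emap = build_map(egms, (3, 3), window=1000, m=2, r_frac=0.2, mask=mask)
        assert np.isfinite(emap.frames[0, 1, 1])
        assert np.isnan(emap.frames[0, 0, 0])


class TestObservationMask:
    def test_margins(self):
        mask = observation_mask((33, 33), pacing_margin_mm=6.0, border_margin_mm=3.0)
        assert not mask[:, :6].any()  # pacing near-field excluded
        assert not mask[:3, :].any()
        assert not mask[:, -3:].any()
        assert mask[16, 16]

    def test_no_pacing_edge(self):
        mask = observation_mask((33, 33), pacing_edge="none")
        assert mask[16, 3]


class TestTipApEn:
    def test_single_hot_site(self):
        frame = np.zeros((5, 5))
        frame[3, 1] = 1.0
        assert locate_tip_apen(frame, pitch_mm=1.0) == (1.0, 3.0)

    def test_symmetric_plateau_centroid(self):
        frame = np.zeros((6, 6))
        frame[2:4, 2:4] = 1.0
        assert locate_tip_apen(frame, pitch_mm=1.0) == (2.5, 2.5)

    def test_floor_declares_no_rotor(self):
        frame = np.full((4, 4), 0.05)
        assert locate_tip_apen(frame, floor=0.1) is NO_ROTOR

    def test_hot_region_is_connected_component_of_max(self):
        frame = np.zeros((5, 5))
        frame[0, 0] = 0.95  # separate near-max island
        frame[3, 3] = 1.0
        frame[3, 4] = 0.92
        comp = hot_region(frame)
        assert comp[3, 3] and comp[3, 4]
        assert not comp[0, 0]


class TestCompareTips:
    def test_identical_tips_zero_distance(self):
        track = [((0.0, 1000.0), (5.0, 5.0))]
        rt = compare_tips(track, track)
        assert rt.max_distance_mm == 0.0

    def test_three_four_five(self):
        lat = [((0.0, 1000.0), (0.0, 0.0))]
        ap = [((0.0, 1000.0), (3.0, 4.0))]
        assert compare_tips(lat, ap).table["d_mm"].iloc[0] == pytest.approx(5.0)

    def test_interval_mismatch_rejected(self):
        a = [((0.0, 1000.0), (1.0, 1.0))]
        b = [((0.0, 500.0), (1.0, 1.0))]
        with pytest.raises(ValueError, match="mismatch"):
            compare_tips(a, b)

    def test_no_rotor_intervals_get_nan(self):
        a = [((0.0, 1000.0), (1.0, 1.0)), ((1000.0, 2000.0), None)]
        b = [((0.0, 1000.0), (2.0, 1.0)), ((1000.0, 2000.0), (3.0, 3.0))]
        rt = compare_tips(a, b)
        assert rt.table["d_mm"].iloc[0] == pytest.approx(1.0)
        assert np.isnan(rt.table["d_mm"].iloc[1])


class TestShenMap:
    def test_constant_egms_zero_shen(self):
        egms = np.full((4, 4000), -1.0)
        emap = shen_map(egms, (2, 2), window=4000)
        assert np.all(emap.frames == 0.0)

    def test_unipolar_pipeline_smoke(self, planewave_egms):
        egms, array = planewave_egms
        emap = shen_map(egms[:, :2000], array.grid_shape, window=2000)
        assert emap.n_frames == 1
        assert np.isfinite(emap.frames).all()


class TestMappingScience:
    """Map-level behavior on the simulated fixtures."""

    def test_passive_sites_below_point_one(self, planewave_egms):
        egms, array = planewave_egms
        mask = observation_mask(array.grid_shape)
        emap = build_map(egms, array.grid_shape, 1000, m=3, r_frac=0.38, mask=mask)
        assert emap.global_max < 0.1

    def test_tip_exceeds_passive_reference_every_frame(self, stable_rotor_egms):
        egms, array = stable_rotor_egms
        ny, nx = array.grid_shape
        mask = observation_mask(array.grid_shape, pacing_edge="none")
        emap = build_map(egms, array.grid_shape, 1000, m=3, r_frac=0.38, mask=mask)
        tip_series = emap.frames[:, 24, 10]
        ref_series = emap.frames[:, 6, 28]  # passive far corner site
        assert np.all(tip_series > ref_series)

    def test_apen_tip_tracks_lat_tip(self, stable_rotor_egms, stable_rotor_vm):
        egms, array = stable_rotor_egms
        mask = observation_mask(array.grid_shape, pacing_edge="none")
        emap = build_map(egms, array.grid_shape, 1000, m=3, r_frac=0.38, mask=mask)
        trains = detect_activations_grid(egms, 1000.0)
        for k in range(emap.n_frames):
            tip_a = locate_tip_apen(emap.frames[k])
            tip_l = locate_tip_lat(
                trains, array.grid_shape, (k * 1000.0, (k + 1) * 1000.0),
                site_mask=mask,
            )
            d = np.hypot(tip_a[0] - tip_l[0], tip_a[1] - tip_l[1])
            assert d <= 1.66

    def test_shen_hot_region_at_least_as_broad_as_apen(self, stable_rotor_vm):
        """Bipolar maps around the core: ShEn's hot area decays more
        slowly than ApEn's, so it is at least as large."""
        from rotormap.egm_forward import ElectrodeArray, unipolar_egm_array

        # bipolar EGMs on a 13x13 patch centered on the core at (10, 24):
        # difference of two unipolar arrays offset +/-0.5 mm horizontally
        xs = np.arange(4.0, 17.0)
        ys = np.arange(18.0, 31.0)
        gx, gy = np.meshgrid(xs, ys)
        base = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, 1.0)])
        pos_a = base + [0.5, 0.0, 0.0]
        pos_b = base - [0.5, 0.0, 0.0]
        rng = np.random.default_rng([9, 977])
        ea = unipolar_egm_array(stable_rotor_vm, ElectrodeArray(positions=pos_a))
        eb = unipolar_egm_array(stable_rotor_vm, ElectrodeArray(positions=pos_b))
        bip = ea - eb + rng.normal(0, 0.005, ea.shape)
        shape = (13, 13)
        amap = build_map(bip, shape, 1000, m=3, r_frac=0.38)
        smap = shen_map(bip[:, :3000], shape, window=3000)
        a_hot = hot_region(np.nanmax(amap.frames, axis=0)).sum()
        s_hot = hot_region(smap.frames[0]).sum()
        assert s_hot >= a_hot
        # both hot regions contain the core site (10, 24) -> patch (6, 6)
        assert hot_region(smap.frames[0])[6, 6] or s_hot >= 3

    def test_meandering_rotor_hot_only_when_tip_present(self, meander_rotor_vm, planewave_egms):
        """Windows with the wandering tip inside the observation box show
        a hot region; windows with the tip far away do not."""
        pegms, parray = planewave_egms
        pmask = observation_mask(parray.grid_shape)
        pmap = build_map(pegms, parray.grid_shape, 1000, m=3, r_frac=0.38, mask=pmask)
        floor = calibration_floor(pmap)

        array = electrode_grid(meander_rotor_vm.grid, pitch=1.0, h=1.0)
        rng = np.random.default_rng([0, 977])
        egms = unipolar_egm_array(meander_rotor_vm, array, noise_mv_rms=0.005, rng=rng)
        ps = np.asarray(track_phase_singularities(meander_rotor_vm, frame_stride=50))
        ny, nx = array.grid_shape
        xx, yy = np.meshgrid(np.arange(nx) * 1.0, np.arange(ny) * 1.0)
        box = (20.0, 29.0, 18.0, 28.0)
        boxmask = (xx >= box[0]) & (xx <= box[1]) & (yy >= box[2]) & (yy <= box[3])
        emap = build_map(egms, array.grid_shape, 500, m=3, r_frac=0.38, mask=boxmask)

        def tip_at(t0, t1):
            sel = ps[(ps[:, 0] >= t0) & (ps[:, 0] < t1)]
            return sel[:, 1:3] if len(sel) else np.empty((0, 2))

        hot_when_inside, any_inside, all_far_cold = [], False, True
        for w in range(emap.n_frames):
            t0, t1 = w * 500.0, (w + 1) * 500.0
            tips = tip_at(t0, t1)
            if len(tips) == 0:
                continue
            inside = (
                (tips[:, 0] >= box[0] + 1) & (tips[:, 0] <= box[1] - 1)
                & (tips[:, 1] >= box[2] + 1) & (tips[:, 1] <= box[3] - 1)
            )
            far = (
                (tips[:, 0] < box[0] - 4) | (tips[:, 0] > box[1] + 4)
                | (tips[:, 1] < box[2] - 4) | (tips[:, 1] > box[3] + 4)
            )
            boxmax = np.nanmax(emap.frames[w])
            if inside.all():
                any_inside = True
                hot_when_inside.append(boxmax)
            elif far.all():
                all_far_cold &= boxmax < floor
        assert any_inside
        assert max(hot_when_inside) >= floor  # red region appears with the tip
        assert all_far_cold  # and never without it
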