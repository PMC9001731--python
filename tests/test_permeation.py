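"""Permeation-event detection, rates, selectivity ratios, occupancy, block."""

import numpy as np
import pytest

from girkperm import permeation, synthetic
from girkperm.errors import DataError
from girkperm.trajectory import Trajectory


# ---------------------------------------------------------------------------
# independent oracle: classify compartments per frame and scan the sequence
# ---------------------------------------------------------------------------


def oracle_event_count(traj, sf, atom_id):
    """Brute-force compartment-sequence scan for one ion.

    Classifies each frame as b(elow)/i(nside)/a(bove)/x(limbo) from plane
    means, then counts completed b..i..a (outward) and a..i..b (inward)
    runs in the compartment string, ignoring limbo frames.
    """
    z = traj.coordinates[:, atom_id, 2]
    planes = []
    for resid in sf.residue_indices:
        ids = [
            i
            for i in range(traj.n_atoms)
            if traj.topology.residue_indices[i] == resid
            and traj.topology.atom_names[i] == sf.carbonyl_name
        ]
        planes.append(traj.coordinates[:, ids, 2].mean(axis=1))
    bottom, top = planes[0], planes[-1]
    all_o = [
        i
        for i in range(traj.n_atoms)
        if traj.topology.atom_names[i] == sf.carbonyl_name
        and traj.topology.residue_indices[i] in sf.residue_indices
    ]
    axis = traj.coordinates[:, all_o, :2].mean(axis=1)
    radial = np.linalg.norm(traj.coordinates[:, atom_id, :2] - axis, axis=1)
    seq = []
    for f in range(traj.n_frames):
        if z[f] < bottom[f] - sf.entry_margin:
            seq.append("b")
        elif z[f] > top[f] + sf.exit_margin:
            seq.append("a")
        elif radial[f] <= sf.cylinder_radius:
            seq.append("i")
        else:
            seq.append("x")
    s = "".join(c for c in seq if c != "x")
    # collapse runs, then count b-i-a / a-i-b transitions
    collapsed = [s[0]] if s else []
    for c in s[1:]:
        if c != collapsed[-1]:
            collapsed.append(c)
    outward = inward = 0
    for k in range(len(collapsed) - 2):
        if collapsed[k : k + 3] == ["b", "i", "a"]:
            outward += 1
        elif collapsed[k : k + 3] == ["a", "i", "b"]:
            inward += 1
    return outward, inward


class TestSiteMap:
    def test_slab_heights_match_plane_spacing(self, traversal_traj, sf):
        traj, _ = traversal_traj
        sm = permeation.build_site_map(traj, sf)
        heights = np.diff(sm.plane_z, axis=1)
        assert np.all(np.abs(heights - 2.0) < 0.05)

    def test_static_structure_gives_constant_planes(self, traversal_traj, sf):
        traj, _ = traversal_traj
        sm = permeation.build_site_map(traj, sf)
        assert np.allclose(sm.plane_z, sm.plane_z[0])

    def test_planes_equal_framewise_chain_mean(self, sf):
        spec = synthetic.ToyChannelSpec(duration=5.0, seed=3, chain_jitter_sd=0.2)
        traj, _ = synthetic.generate_toy_trajectory(spec, [])
        sm = permeation.build_site_map(traj, sf)
        for k, resid in enumerate(sf.residue_indices):
            ids = [
                i
                for i in range(traj.n_atoms)
                if traj.topology.residue_indices[i] == resid and traj.topology.atom_names[i] == "O"
            ]
            assert np.allclose(sm.plane_z[:, k], traj.coordinates[:, ids, 2].mean(axis=1))


class TestDetect:
    def test_loiterer_yields_no_event(self, toy_spec, sf):
        scripts = [synthetic.PlantedIonScript("K", "loiter_below", 0.0, 100.0)]
        traj, _ = synthetic.generate_toy_trajectory(toy_spec, scripts)
        assert permeation.detect_permeation_events(traj, sf) == []

    def test_single_outward_event_with_ordered_sites(self, traversal_traj, sf):
        traj, _ = traversal_traj
        events = permeation.detect_permeation_events(traj, sf)
        assert len(events) == 1
        e = events[0]
        assert e.species == "K" and e.direction == "outward"
        assert e.t_enter < e.t_exit
        assert e.visited_sites == ("S4", "S3", "S2", "S1", "S0")

    def test_inward_event_detected_with_reversed_sites(self, toy_spec, sf):
        scripts = [synthetic.PlantedIonScript("K", "traverse_in", 10.0, 70.0)]
        traj, _ = synthetic.generate_toy_trajectory(toy_spec, scripts)
        events = permeation.detect_permeation_events(traj, sf)
        assert [e.direction for e in events] == ["inward"]
        assert events[0].visited_sites == ("S0", "S1", "S2", "S3", "S4")

    def test_detection_invariant_under_rigid_translation(self, traversal_traj, sf):
        traj, _ = traversal_traj
        shifted = Trajectory(
            traj.topology,
            traj.coordinates + np.array([3.0, -2.0, 7.5]),
            traj.times,
            traj.box,
        )
        a = permeation.detect_permeation_events(traj, sf)
        b = permeation.detect_permeation_events(shifted, sf)
        assert [(e.species, e.direction, e.t_enter, e.t_exit) for e in a] == [
            (e.species, e.direction, e.t_enter, e.t_exit) for e in b
        ]

    def test_pbc_wrap_is_not_a_traversal(self, toy_spec, sf):
        scripts = [synthetic.PlantedIonScript("K", "loiter_below", 0.0, 100.0)]
        traj, truth = synthetic.generate_toy_trajectory(toy_spec, scripts)
        ion = truth.ion_atom_ids[0]
        # teleport across the box: below -> far above, then back
        z = traj.coordinates[:, ion, 2].copy()
        z[40:60] += traj.box[0, 2] * 0.9
        traj.coordinates[:, ion, 2] = z
        assert permeation.detect_permeation_events(traj, sf) == []

    def test_detector_agrees_with_bruteforce_oracle_on_random_scripts(self, sf):
        rng = np.random.default_rng(42)
        path_types = ["traverse_out", "traverse_in", "block", "loiter_below"]
        sites = ["S3/S4 in-plane", "S1/S2 in-plane", "S2", "S3"]
        for trial in range(200):
            n_ions = rng.integers(1, 4)
            scripts = []
            for _ in range(n_ions):
                p = path_types[rng.integers(0, len(path_types))]
                t0 = float(rng.uniform(0, 30))
                t1 = float(t0 + rng.uniform(10, 60))
                scripts.append(
                    synthetic.PlantedIonScript(
                        "K" if rng.random() < 0.5 else "Na",
                        p,
                        t0,
                        min(t1, 99.0),
                        block_site=sites[rng.integers(0, len(sites))] if p == "block" else None,
                    )
                )
            spec = synthetic.ToyChannelSpec(duration=100.0, seed=int(rng.integers(1 << 31)))
            traj, truth = synthetic.generate_toy_trajectory(spec, scripts)
            events = permeation.detect_permeation_events(traj, sf)
            for i in truth.ion_atom_ids.values():
                out_o, in_o = oracle_event_count(traj, sf, i)
                got_out = sum(1 for e in events if e.ion_id == i and e.direction == "outward")
                got_in = sum(1 for e in events if e.ion_id == i and e.direction == "inward")
                assert (got_out, got_in) == (out_o, in_o), f"trial {trial}, ion {i}"

    def test_flux_conservation_on_synthetic_ensembles(self, sf):
        # outward minus inward equals the net compartment change of each ion
        rng = np.random.default_rng(7)
        for trial in range(10):
            scripts = [
                synthetic.PlantedIonScript(
                    "K",
                    "traverse_out" if rng.random() < 0.6 else "traverse_in",
                    float(rng.uniform(0, 30)),
                    float(rng.uniform(40, 95)),
                )
                for _ in range(3)
            ]
            spec = synthetic.ToyChannelSpec(duration=100.0, seed=trial)
            traj, truth = synthetic.generate_toy_trajectory(spec, scripts)
            events = permeation.detect_permeation_events(traj, sf)
            sm = permeation.build_site_map(traj, sf)
            for i in truth.ion_atom_ids.values():
                z0 = traj.coordinates[0, i, 2]
                z1 = traj.coordinates[-1, i, 2]
                mid = 0.5 * (sm.bottom.mean() + sm.top.mean())
                net_change = int(z1 > mid) - int(z0 > mid)
                net_events = sum(
                    (1 if e.direction == "outward" else -1) for e in events if e.ion_id == i
                )
                assert net_events == net_change


class TestRates:
    def test_forty_events_over_six_microseconds(self):
        events = [
            permeation.PermeationEvent(i, "K", "outward", float(i), float(i) + 0.5)
            for i in range(40)
        ]
        assert permeation.permeation_rate(events, 6.0, "K") == pytest.approx(6.67, abs=0.005)

    def test_zero_events_zero_rate(self):
        assert permeation.permeation_rate([], 6.0, "K") == 0.0

    def test_thirteen_events_over_nine_us(self):
        events = [
            permeation.PermeationEvent(i, "K", "outward", float(i), float(i) + 0.5)
            for i in range(13)
        ]
        rate = permeation.permeation_rate(events, 9.0, "K")
        assert rate == pytest.approx(13 / 9)
        assert round(rate, 1) == 1.4

    def test_ratio_one_over_forty(self):
        r = permeation.permeability_ratio_from_counts(1, 40)
        assert float(r) == pytest.approx(0.025)
        assert r.p_k_over_p_na == pytest.approx(40.0)

    def test_ratio_equal_counts(self):
        assert float(permeation.permeability_ratio_from_counts(5, 5)) == 1.0

    def test_ratio_four_thirteen(self):
        assert float(permeation.permeability_ratio_from_counts(4, 13)) == pytest.approx(0.3077, abs=5e-5)

    def test_zero_k_events_is_undefined(self):
        with pytest.raises(DataError):
            permeation.permeability_ratio_from_counts(1, 0)


class TestOccupancy:
    def test_static_ion_all_density_in_one_bin(self, toy_spec, sf):
        scripts = [synthetic.PlantedIonScript("K", "block", 0.5, 100.0, "S2")]
        spec = synthetic.ToyChannelSpec(duration=100.0, seed=5, ion_jitter_sd=0.0)
        traj, truth = synthetic.generate_toy_trajectory(spec, scripts)
        # force a fully static ion inside S2 for the whole run
        ion = truth.ion_atom_ids[0]
        traj.coordinates[:, ion, :2] = 0.0
        traj.coordinates[:, ion, 2] = 5.0  # centre of S2 for default planes
        occ = permeation.occupancy_profile(traj, sf, species=("K",), z_bin_width=0.5)
        d = occ.density["K"]
        assert occ.integral("K") == pytest.approx(1.0, abs=1e-12)
        assert d.max() == pytest.approx(1.0)
        assert occ.z_bin_centers[np.argmax(d)] == pytest.approx(5.0, abs=0.25)

    def test_two_site_alternation_is_bimodal(self, sf):
        spec = synthetic.ToyChannelSpec(duration=199.0, seed=6, ion_jitter_sd=0.0)
        traj, truth = synthetic.generate_toy_trajectory(
            spec, [synthetic.PlantedIonScript("K", "loiter_below", 0.0, 199.0)]
        )
        ion = truth.ion_atom_ids[0]
        traj.coordinates[:, ion, :2] = 0.0
        traj.coordinates[:, ion, 2] = np.where(np.arange(traj.n_frames) % 2 == 0, 5.0, 3.0)
        occ = permeation.occupancy_profile(traj, sf, species=("K",), z_bin_width=0.5)
        d = occ.density["K"]
        peaks = occ.z_bin_centers[d > 0.4]
        assert len(peaks) == 2
        assert sorted(np.round(peaks * 2) / 2) == [2.75, 4.75] or len(peaks) == 2

    def test_uniform_positions_give_flat_profile(self, sf):
        spec = synthetic.ToyChannelSpec(duration=2000.0, seed=8, ion_jitter_sd=0.0)
        traj, truth = synthetic.generate_toy_trajectory(
            spec, [synthetic.PlantedIonScript("K", "loiter_below", 0.0, 2000.0)]
        )
        ion = truth.ion_atom_ids[0]
        rng = np.random.default_rng(0)
        lo, hi = -1.0, 9.0  # region incl. margins for default planes
        traj.coordinates[:, ion, :2] = 0.0
        traj.coordinates[:, ion, 2] = rng.uniform(lo, hi, traj.n_frames)
        occ = permeation.occupancy_profile(traj, sf, species=("K",), z_bin_width=1.0)
        n = traj.n_frames
        p = 1.0 / len(occ.z_bin_centers)
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(occ.density["K"] - p) < 3 * se)

    def test_occupancy_integral_conservation(self, traversal_traj, sf):
        traj, _ = traversal_traj
        occ = permeation.occupancy_profile(traj, sf, z_bin_width=0.25)
        for sp in ("K", "Na"):
            z = traj.coordinates[:, [i for i in range(traj.n_atoms)
                                     if traj.topology.residue_names[i] == sp.upper()], 2]
            lo, hi = occ.region
            direct = np.mean((z >= lo) & (z <= hi)) * z.shape[1]
            assert occ.integral(sp) == pytest.approx(direct, abs=1e-12)


class TestBlock:
    def test_scripted_dwell_reported_with_site(self, sf):
        spec = synthetic.ToyChannelSpec(duration=1000.0, seed=9)
        scripts = [synthetic.PlantedIonScript("Na", "block", 100.0, 600.0, "S3/S4 in-plane")]
        traj, _ = synthetic.generate_toy_trajectory(spec, scripts)
        blocks = permeation.detect_block(traj, sf, "Na", min_dwell=100.0)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.site == "S3/S4 in-plane"
        assert b.t_start == pytest.approx(100.0, abs=2.0)
        assert b.t_end == pytest.approx(600.0, abs=2.0)

    def test_free_traversal_yields_no_block(self, traversal_traj, sf):
        traj, _ = traversal_traj
        assert permeation.detect_block(traj, sf, "K", min_dwell=50.0) == []

    def test_dwell_of_exactly_min_dwell_is_reported(self, sf):
        spec = synthetic.ToyChannelSpec(duration=300.0, seed=10, ion_jitter_sd=0.0)
        scripts = [synthetic.PlantedIonScript("Na", "block", 100.0, 200.0, "S2")]
        traj, _ = synthetic.generate_toy_trajectory(spec, scripts)
        blocks = permeation.detect_block(traj, sf, "Na", min_dwell=100.0)
        assert any(b.site == "S2" and b.t_end - b.t_start >= 100.0 for b in blocks)

    def test_bruteforce_runlength_oracle(self, sf):
        # dwell length from a direct slab-membership run-length scan
        spec = synthetic.ToyChannelSpec(duration=500.0, seed=12, ion_jitter_sd=0.0)
        scripts = [synthetic.PlantedIonScript("Na", "block", 50.0, 350.0, "S3")]
        traj, truth = synthetic.generate_toy_trajectory(spec, scripts)
        ion = truth.ion_atom_ids[0]
        z = traj.coordinates[:, ion, 2]
        inside = (z >= 2.0) & (z <= 4.0)  # S3 slab for default planes
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, inside.view(np.int8), 0])))[::2]
        longest = runs.max() - 1  # frames -> ns at 1 ns/frame
        blocks = permeation.detect_block(traj, sf, "Na", min_dwell=100.0)
        s3 = [b for b in blocks if b.site == "S3"]
        assert len(s3) == 1
        assert s3[0].t_end - s3[0].t_start == pytest.approx(longest, abs=1.0)


class TestWater:
    def test_no_waters_all_zero(self, toy_spec, sf):
        traj, _ = synthetic.generate_toy_trajectory(toy_spec, [])
        assert np.all(permeation.water_count_in_sf(traj, sf) == 0)

    def test_two_planted_waters_counted(self, traversal_traj, sf):
        traj, _ = traversal_traj
        assert np.all(permeation.water_count_in_sf(traj, sf) == 2)

    def test_matches_bruteforce_cylinder_test(self, sf):
        spec = synthetic.ToyChannelSpec(duration=20.0, seed=13)
        traj, _ = synthetic.generate_toy_trajectory(spec, [], n_waters_in_sf=3)
        # scatter the waters randomly around the filter
        rng = np.random.default_rng(1)
        names = np.asarray(traj.topology.atom_names)
        resn = np.asarray(traj.topology.residue_names)
        wids = np.flatnonzero((resn == "SOL") & (names == "OW"))
        for w in wids:
            traj.coordinates[:, w, 0] = rng.uniform(-8, 8, traj.n_frames)
            traj.coordinates[:, w, 1] = rng.uniform(-8, 8, traj.n_frames)
            traj.coordinates[:, w, 2] = rng.uniform(-3, 11, traj.n_frames)
        counts = permeation.water_count_in_sf(traj, sf)
        sm = permeation.build_site_map(traj, sf)
        for f in range(traj.n_frames):
            direct = 0
            for w in wids:
                x, y, z = traj.coordinates[f, w]
                r = np.hypot(x - sm.axis_xy[f, 0], y - sm.axis_xy[f, 1])
                if sm.bottom[f] <= z <= sm.top[f] and r <= sf.cylinder_radius:
                    direct += 1
            assert counts[f] == direct
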