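import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionsite.states import (
    ZoneRule,
    assign_sites,
    classify_distances,
    classify_states,
    detect_transitions,
    summarize_stability,
)
from ionsite.structure import BindingSite, SiteSet
from ionsite.trajectory import ParticleTable, Trajectory


def _single_ion_traj(positions, extra_protein=True):
    positions = np.asarray(positions, float)
    n = len(positions)
    rows = {"id": [1], "species": ["ZN"], "charge": [2], "role": ["tracked"]}
    coords = positions[:, None, :]
    if extra_protein:
        prot = np.array([[0.0, 0, 30], [30, 0, 0], [0, 30, 0], [30, 30, 30]])
        rows = {"id": [1, 2, 3, 4, 5], "species": ["ZN"] + ["PRT"] * 4,
                "charge": [2, 0, 0, 0, 0],
                "role": ["tracked"] + ["protein"] * 4}
        coords = np.concatenate(
            [positions[:, None, :], np.repeat(prot[None], n, axis=0)], axis=1
        )
    table = ParticleTable(pd.DataFrame(rows))
    return Trajectory(particles=table, coords=coords,
                      times=np.arange(n) / 10.0, frame_rate=10.0)


class TestZoneRule:
    def test_boundary_convention(self):
        """≤5 Å bound, ≤15 Å excursed, >15 Å free (inclusive thresholds)."""
        states = classify_distances([0.0, 4.9, 5.1, 15.1], ZoneRule())
        assert list(states) == ["BOUND", "BOUND", "EXCURSED", "FREE"]

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            ZoneRule(bound_radius=15.0, free_radius=5.0)

    def test_stationary_ion_all_bound(self):
        traj = _single_ion_traj([[10.0, 10, 10]] * 20)
        s = classify_states(traj, [1], align=False)[0]
        assert set(s.states) == {"BOUND"}
        np.testing.assert_allclose(s.distances, 0.0)

    def test_linear_walk_matches_per_frame_distance_oracle(self):
        start = np.array([8.0, 8.0, 8.0])
        positions = start + np.linspace(0, 20, 21)[:, None] * np.array([1.0, 0, 0])
        traj = _single_ion_traj(positions)
        s = classify_states(traj, [1], align=False)[0]
        rule = ZoneRule()
        for f in range(21):
            d = float(np.linalg.norm(positions[f] - start))
            expect = "BOUND" if d <= rule.bound_radius else (
                "FREE" if d > rule.free_radius else "EXCURSED")
            assert s.states[f] == expect

    def test_unknown_ion_id_raises(self):
        traj = _single_ion_traj([[0.0, 0, 0]])
        with pytest.raises(KeyError):
            classify_states(traj, [99], align=False)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(d=st.floats(0, 30, allow_nan=False),
           r=st.floats(0.5, 10), gap=st.floats(0.1, 10))
    def test_zone_monotonicity(self, d, r, gap):
        """Growing the radii never moves a frame toward a farther state."""
        order = {"BOUND": 0, "EXCURSED": 1, "FREE": 2}
        a = classify_distances([d], ZoneRule(bound_radius=r, free_radius=r + gap))[0]
        b = classify_distances(
            [d], ZoneRule(bound_radius=r + 1, free_radius=r + gap + 2))[0]
        assert order[b] <= order[a]


class TestSiteCenterReference:
    def test_distances_measured_from_named_site(self):
        sites = SiteSet(sites=[BindingSite(name="M1", center=np.array([20.0, 10, 10]))])
        traj = _single_ion_traj([[10.0, 10, 10], [18.0, 10, 10], [20.0, 10, 10]])
        rule = ZoneRule(reference="M1")
        s = classify_states(traj, [1], rule, sites=sites, align=False)[0]
        np.testing.assert_allclose(s.distances, [10.0, 2.0, 0.0])
        assert list(s.states) == ["EXCURSED", "BOUND", "BOUND"]

    def test_missing_siteset_raises(self):
        traj = _single_ion_traj([[0.0, 0, 0]])
        with pytest.raises(ValueError, match="M9"):
            classify_states(traj, [1], ZoneRule(reference="M9"), align=False)


class TestAlignment:
    def test_classification_invariant_under_global_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(0)
        positions = np.array([10.0, 10, 10]) + rng.normal(0, 3, (30, 3)).cumsum(0) * 0.2
        traj = _single_ion_traj(positions)
        s0 = classify_states(traj, [1], align=True)[0]
        # apply a different rigid motion to every frame (protein + ion together)
        coords = traj.coords.copy()
        for f in range(traj.n_frames):
            R = Rotation.from_rotvec(rng.normal(0, 0.3, 3)).as_matrix()
            t = rng.normal(0, 5, 3)
            coords[f] = coords[f] @ R.T + t
        moved = Trajectory(particles=traj.particles, coords=coords,
                           times=traj.times, frame_rate=traj.frame_rate)
        s1 = classify_states(moved, [1], align=True)[0]
        np.testing.assert_allclose(s1.distances, s0.distances, atol=1e-6)
        assert list(s1.states) == list(s0.states)


class TestAssignSites:
    def _sites(self):
        return SiteSet(sites=[
            BindingSite(name="M1", center=np.array([10.0, 10, 10])),
            BindingSite(name="M2", center=np.array([16.0, 10, 10])),
        ])

    def test_nearest_within_radius(self):
        traj = _single_ion_traj([[12.0, 10, 10]])  # 2 Å from M1, 4 Å from M2
        lab = assign_sites(traj, [1], self._sites(), align=False)
        assert lab[1][0] == "M1"

    def test_none_when_outside_all_radii(self):
        traj = _single_ion_traj([[10.0, 18, 10]])  # 8 Å and 10 Å away
        lab = assign_sites(traj, [1], self._sites(), align=False)
        assert lab[1][0] is None

    def test_tie_broken_by_site_order(self):
        traj = _single_ion_traj([[13.0, 10, 10]])  # exactly 3 Å from both
        lab = assign_sites(traj, [1], self._sites(), align=False)
        assert lab[1][0] == "M1"

    def test_random_walk_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        sites = self._sites()
        positions = rng.uniform(5, 20, (100, 3))
        traj = _single_ion_traj(positions)
        lab = assign_sites(traj, [1], sites, align=False)[1]
        for f in range(100):
            best, best_d = None, np.inf
            for s in sites:
                d = float(np.linalg.norm(positions[f] - s.center))
                if d <= s.capture_radius and d < best_d:
                    best, best_d = s.name, d
            assert lab[f] == best

    def test_empty_siteset_rejected(self):
        traj = _single_ion_traj([[0.0, 0, 0]])
        with pytest.raises(ValueError):
            assign_sites(traj, [1], None, align=False)


def _brute_force_transitions(labels, min_dwell):
    """Direct restatement of the dwell-filter rule, kept deliberately dumb."""
    accepted = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        if j - i >= min_dwell:
            accepted.append((labels[i], i))
        i = j
    out = []
    cur = accepted[0][0] if accepted else None
    for lab, start in accepted[1:]:
        if lab != cur:
            out.append((cur, lab, start))
            cur = lab
    return out


class TestDetectTransitions:
    def test_constant_label_no_events(self):
        assert detect_transitions(np.array(["M2"] * 100, object), 5) == []

    def test_forced_single_event(self):
        labels = np.array(["M2"] * 50 + ["M4"] * 50, object)
        events = detect_transitions(labels, 5, frame_rate=10.0, ion_id=1)
        assert len(events) == 1
        e = events[0]
        assert (e.from_site, e.to_site, e.frame, e.time_ns) == ("M2", "M4", 50, 5.0)

    def test_single_frame_flicker_absorbed(self):
        labels = np.array(["M2"] * 10 + ["M1"] + ["M2"] * 10, object)
        assert detect_transitions(labels, 3) == []

    def test_exhaustive_small_sequences_match_bruteforce(self):
        """All label sequences of length ≤ 8 over {A, B, None}, dwell 1–3."""
        alphabet = ["A", "B", None]
        for n in range(1, 9):
            for seq in itertools.product(alphabet, repeat=n):
                for dwell in (1, 2, 3):
                    got = [(e.from_site, e.to_site, e.frame)
                           for e in detect_transitions(np.array(seq, object), dwell)]
                    assert got == _brute_force_transitions(list(seq), dwell), (
                        seq, dwell)

    def test_event_count_bounded_by_label_changes(self):
        rng = np.random.default_rng(3)
        labels = np.array(rng.choice(["A", "B", "C"], 200), object)
        changes = int(np.sum(labels[1:] != labels[:-1]))
        assert len(detect_transitions(labels, 2)) <= changes

    def test_min_dwell_must_be_positive(self):
        with pytest.raises(ValueError):
            detect_transitions(np.array(["A"], object), 0)


class TestStabilitySummary:
    def test_all_bound(self):
        traj = _single_ion_traj([[10.0, 10, 10]] * 100)
        s = classify_states(traj, [1], align=False)[0]
        summ = summarize_stability(s, frame_rate=10.0)
        assert summ.state_fractions["BOUND"] == 1.0
        assert summ.first_exit_time_ns is None
        assert not summ.left_protein
        assert summ.mean_residence_ns == {"bound": 10.0}

    def test_half_bound_half_free(self):
        positions = [[10.0, 10, 10]] * 50 + [[40.0, 10, 10]] * 50
        traj = _single_ion_traj(positions)
        s = classify_states(traj, [1], align=False)[0]
        summ = summarize_stability(s, frame_rate=10.0)
        assert summ.state_fractions["BOUND"] == pytest.approx(0.5)
        assert summ.state_fractions["FREE"] == pytest.approx(0.5)
        assert summ.first_exit_time_ns == pytest.approx(5.0)
        assert summ.left_protein and summ.final_state == "FREE"

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        traj = _single_ion_traj(rng.uniform(0, 40, (60, 3)))
        s = classify_states(traj, [1], align=False)[0]
        summ = summarize_stability(s)
        assert sum(summ.state_fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_residence_matches_ground_truth_dwells(self, full_occupancy_run,
                                                   layout_siteset):
        traj, truth = full_occupancy_run
        ions = sorted(truth.membership)
        labels = assign_sites(traj, ions, layout_siteset, align=True)
        for ion, lab in labels.items():
            s = classify_states(traj, [ion], align=True)[0]
            summ = summarize_stability(s, lab, traj.frame_rate)
            # ground-truth dwell: runs of the true membership
            truth_lab = truth.membership[ion]
            runs, cur = {}, 0
            prev = None
            for x in list(truth_lab) + [object()]:
                if x == prev:
                    cur += 1
                else:
                    if prev is not None and cur:
                        runs.setdefault(prev, []).append(cur)
                    prev, cur = x, 1
            for site, mean_ns in summ.mean_residence_ns.items():
                if site in runs:
                    expect = np.mean(runs[site]) / traj.frame_rate
                    assert mean_ns == pytest.approx(expect, abs=0.1 + 0.02 * expect)
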