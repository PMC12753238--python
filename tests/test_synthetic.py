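import numpy as np
import pytest

from ionsite.synthetic import (
    SimulationConfig,
    TrackedIon,
    Well,
    _Field,
    _filter_runs,
    scenario,
    simulate,
)


def _single_well_cfg(**overrides):
    kw = dict(
        wells=[Well(name="W", center=(20.0, 20.0, 20.0), depth=10.0, width=1.5,
                    charge_bias=-1.0)],
        tracked=[TrackedIon(species="ZN", start="W")],
        background={},
        n_frames=20,
        seed=0,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


class TestConfig:
    def test_inconsistent_output_rate_rejected(self):
        with pytest.raises(ValueError, match="output rate"):
            _single_well_cfg(dt=3e-4)

    def test_unknown_well_start_rejected(self):
        with pytest.raises(ValueError, match="not a well name"):
            _single_well_cfg(tracked=[TrackedIon(species="ZN", start="NOPE")])

    def test_species_without_diffusion_rejected(self):
        with pytest.raises(ValueError, match="diffusion"):
            _single_well_cfg(
                tracked=[TrackedIon(species="XX", start=(0.0, 0, 0), charge=1)])

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario("wild_type_typo")


class TestForces:
    def test_forces_are_minus_gradient(self):
        cfg = scenario("full_occupancy", n_frames=2)
        q = np.array([2.0, 2.0, -1.0, -1.0, 1.0, -1.0])
        species = ["ZN", "ZN", "BCT", "BCT", "NA", "CL"]
        f = _Field(cfg, q, species)
        rng = np.random.default_rng(0)
        x = rng.uniform(10, 30, (6, 3))
        F = f.forces(x)
        eps = 1e-6
        for i in range(6):
            for d in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, d] += eps
                xm[i, d] -= eps
                num = -(f.potential(xp) - f.potential(xm)) / (2 * eps)
                assert F[i, d] == pytest.approx(num, abs=1e-5)

    def test_species_restricted_well_ignores_other_anions(self):
        w = Well(name="B", center=(0.0, 0, 0), depth=16.0, width=1.5,
                 charge_bias=2.0, species=("BCT",))
        assert w.effective_depth(-1, "BCT") == 16.0
        assert w.effective_depth(-1, "CL") == 0.0
        assert w.effective_depth(2, "BCT") == 0.0  # wrong charge sign


class TestDynamics:
    def test_zero_noise_fixed_point(self):
        cfg = _single_well_cfg(noise_scale=0.0, protein_jitter=0.0)
        traj, truth = simulate(cfg)
        np.testing.assert_array_equal(
            traj.coords[:, 0, :], np.full((20, 3), 20.0))
        assert all(m == "W" for m in truth.membership[1])

    def test_zero_noise_energy_nonincreasing(self):
        cfg = _single_well_cfg(
            noise_scale=0.0, protein_jitter=0.0,
            tracked=[TrackedIon(species="ZN", start=(22.0, 21.0, 20.0))],
            n_frames=30,
        )
        traj, _ = simulate(cfg)
        f = _Field(cfg, np.array([2.0]), ["ZN"])
        energies = [f.potential(traj.coords[k, :1, :]) for k in range(30)]
        assert np.all(np.diff(energies) <= 1e-9)

    def test_determinism_bit_identical(self):
        a, _ = simulate(scenario("full_occupancy", n_frames=30, seed=123))
        b, _ = simulate(scenario("full_occupancy", n_frames=30, seed=123))
        assert np.array_equal(a.coords, b.coords)
        c, _ = simulate(scenario("full_occupancy", n_frames=30, seed=124))
        assert not np.array_equal(a.coords, c.coords)

    def test_divergent_step_aborts_with_diagnostic(self):
        cfg = _single_well_cfg(dt=0.01, diffusion={"ZN": 1e7})
        with pytest.raises(RuntimeError, match="divergent step"):
            simulate(cfg)

    def test_reflective_walls_keep_particles_inside(self):
        cfg = SimulationConfig(
            wells=[], tracked=[TrackedIon(species="NA", start=(1.0, 1.0, 1.0))],
            background={}, box=(10.0, 10.0, 10.0), diffusion={"NA": 133.0},
            n_frames=50, seed=4, n_protein_atoms=3, protein_jitter=0.0,
        )
        traj, _ = simulate(cfg)
        ion = traj.coords[:, 0, :]
        assert np.all(ion >= 0.0) and np.all(ion <= 10.0)


class TestScenarios:
    def test_full_occupancy_composition(self):
        cfg = scenario("full_occupancy")
        assert [i.species for i in cfg.tracked] == ["ZN", "ZN", "BCT", "BCT"]
        assert [i.start for i in cfg.tracked] == ["M1", "M2", "BCT1", "BCT2"]
        assert cfg.background == {"NA": 6, "CL": 6}
        assert cfg.n_frames == 2000 and cfg.frames_per_ns == 10.0

    def test_no_bicarbonate_is_set_difference(self):
        full = scenario("full_occupancy")
        nob = scenario("no_bicarbonate")
        assert [i.species for i in nob.tracked] == ["ZN", "ZN"]
        assert nob.wells == full.wells
        assert nob.background == full.background

    def test_mutant_reduces_only_affected_wells(self):
        wt = {w.name: w for w in scenario("electroneutral_M2").wells}
        mut = {w.name: w for w in scenario("mutant_D318A").wells}
        for name in ("M1", "M2"):
            assert mut[name].depth < wt[name].depth
            assert abs(mut[name].charge_bias) < abs(wt[name].charge_bias)
        for name in ("M4", "BCT1", "BCT2"):
            assert mut[name] == wt[name]

    def test_ground_truth_never_leaks_from_analysis(self):
        """Truth labels derive from generator state: membership uses the
        2×width energy criterion, not the 5 Å capture radius."""
        traj, truth = simulate(scenario("full_occupancy", n_frames=30, seed=0))
        centers = {w.name: np.array(w.center)
                   for w in scenario("full_occupancy").wells}
        for ion, lab in truth.membership.items():
            pos = traj.coords[:, ion - 1, :]
            for f, name in enumerate(lab):
                if name is not None:
                    assert np.linalg.norm(pos[f] - centers[name]) <= 3.0


class TestRigidDrift:
    def test_alignment_recovers_states_under_lab_frame_drift(self):
        """With rigid lab-frame drift on, protein superposition restores
        site assignments that match the (drift-free) ground truth."""
        from ionsite.states import assign_sites
        from ionsite.structure import BindingSite, SiteSet
        from ionsite.synthetic import SITE_LAYOUT

        cfg = scenario("electroneutral_M1", n_frames=60, seed=2,
                       drift_translation=0.5, drift_rotation=0.02)
        traj, truth = simulate(cfg)
        sites = SiteSet(sites=[BindingSite(name=n, center=np.array(c))
                               for n, c in SITE_LAYOUT.items()])
        labels = assign_sites(traj, sorted(truth.membership), sites, align=True)
        agree = total = 0
        for ion, lab in truth.membership.items():
            agree += sum(str(a) == str(b) for a, b in zip(labels[ion], lab))
            total += len(lab)
        assert agree / total >= 0.95
        # without alignment the drift (tens of Å over the run) breaks it
        raw = assign_sites(traj, sorted(truth.membership), sites, align=False)
        raw_agree = sum(
            sum(str(a) == str(b) for a, b in zip(raw[ion], truth.membership[ion]))
            for ion in truth.membership
        )
        assert raw_agree < agree


class TestGroundTruthFilter:
    @pytest.mark.parametrize(
        "labels,dwell,expect",
        [
            (["A"] * 10, 3, []),
            (["A"] * 5 + ["B"] * 5, 3, [("A", "B", 5)]),
            (["A", "B", "A", "A", "A"], 2, []),          # flicker absorbed
            ([None] * 4 + ["A"] * 4, 3, [(None, "A", 4)]),
        ],
    )
    def test_dwell_filter(self, labels, dwell, expect):
        assert _filter_runs(labels, dwell) == expect
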