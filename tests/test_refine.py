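"""Restraint potential, time averaging, energies, gradients and dynamics."""
import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from noeturn.builder import CapSpec, build_extended
from noeturn.noe import RestraintRecord, RestraintSet
from noeturn.refine import (
    KB,
    Ensemble,
    RefinementConfig,
    RefinementError,
    _TorsionSystem,
    refine_ensemble,
    restraint_energy_force,
    time_averaged_distance,
    total_energy,
    violation_report,
)

CFG = RefinementConfig()


class TestRestraintPotential:
    def test_zero_inside_the_accepted_range(self):
        assert restraint_energy_force(0.30, CFG) == (0.0, 0.0)

    def test_harmonic_branch_closed_form(self):
        e, f = restraint_energy_force(0.55, CFG)
        assert e == pytest.approx(0.5 * 1250 * 0.05 ** 2)  # 1.5625 kJ/mol
        assert f == pytest.approx(62.5)

    def test_linear_branch_with_capped_force(self):
        e, f = restraint_energy_force(0.65, CFG)
        assert f == pytest.approx(125.0)  # k * (0.6 - 0.5)
        assert e == pytest.approx(6.25 + 125.0 * 0.05)  # 12.5 kJ/mol

    @pytest.mark.parametrize("boundary", [0.5, 0.6])
    def test_continuity_at_branch_points(self, boundary):
        e1, f1 = restraint_energy_force(boundary - 1e-9, CFG)
        e2, f2 = restraint_energy_force(boundary + 1e-9, CFG)
        assert abs(e1 - e2) < 1e-6
        assert abs(f1 - f2) < 1e-5

    def test_per_restraint_bound_shifts_the_branch_points(self):
        e, f = restraint_energy_force(0.30, CFG, flat_upper=0.25)
        assert e == pytest.approx(0.5 * 1250 * 0.05 ** 2)
        _, fcap = restraint_energy_force(1.0, CFG, flat_upper=0.25)
        assert fcap == pytest.approx(125.0)  # cap unchanged

    @given(st.floats(0.5, 2.0), st.floats(0.0, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_energy_is_monotone_beyond_the_flat_region(self, d, delta):
        e1, _ = restraint_energy_force(d, CFG)
        e2, _ = restraint_energy_force(d + delta, CFG)
        assert e2 >= e1

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            restraint_energy_force(-0.1, CFG)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RefinementConfig(flat_upper=0.7, linearize_at=0.6)
        with pytest.raises(ValueError):
            RefinementConfig(k=-1.0)


class TestTimeAveraging:
    def test_constant_history(self):
        assert time_averaged_distance([0.4, 0.4, 0.4]) == pytest.approx(0.4)

    def test_two_point_inverse_cube_average(self):
        # (0.5*(0.3^-3 + 0.5^-3))^(-1/3), computed independently
        expected = (0.5 * (0.3 ** -3 + 0.5 ** -3)) ** (-1.0 / 3.0)
        assert time_averaged_distance([0.3, 0.5], -3) == pytest.approx(expected)
        assert expected == pytest.approx(0.35413, abs=1e-5)

    @given(st.lists(st.floats(0.1, 1.0), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_shorter_than_arithmetic_mean(self, history):
        avg = time_averaged_distance(history, -3)
        assert avg <= np.mean(history) + 1e-12

    def test_exponential_memory_weights_recent_values(self):
        recent_short = time_averaged_distance([0.5] * 10 + [0.3], -3, memory=2)
        recent_long = time_averaged_distance([0.3] + [0.5] * 10, -3, memory=2)
        assert recent_short < recent_long

    def test_errors(self):
        with pytest.raises(ValueError):
            time_averaged_distance([])
        with pytest.raises(ValueError):
            time_averaged_distance([0.3, -0.1])
        with pytest.raises(ValueError):
            time_averaged_distance([0.3], exponent=-2)


class TestEnergies:
    def test_satisfied_restraints_cost_nothing(self):
        conf = build_extended("AVA", CapSpec())
        rs = RestraintSet([RestraintRecord(1, "HA", 2, "HN", upper_bound=0.5)])
        e_r, _, _ = total_energy(conf, rs)
        assert e_r == 0.0

    def test_single_violated_restraint_closed_form(self):
        conf = build_extended("AVA", CapSpec())
        rs0 = RestraintSet([RestraintRecord(1, "HA", 3, "HN", upper_bound=0.5)])
        sys_ = _TorsionSystem(conf, rs0, replace(CFG, time_averaging=False))
        d = sys_.restraint_distances(conf.coord)[0]
        rs = RestraintSet([
            RestraintRecord(1, "HA", 3, "HN", upper_bound=round(d - 0.05, 6))
        ])
        e_r, _, _ = total_energy(conf, rs)
        assert e_r == pytest.approx(0.5 * 1250 * 0.05 ** 2, rel=1e-4)

    def test_unresolvable_restraint_atom_is_named(self):
        conf = build_extended("AVA", CapSpec())
        rs = RestraintSet([RestraintRecord(2, "HZ", 3, "HN", upper_bound=0.5)])
        with pytest.raises(RefinementError, match="HZ"):
            total_energy(conf, rs)

    def test_analytic_gradient_matches_finite_differences(self):
        conf = build_extended("AVA", CapSpec())
        rs = RestraintSet([RestraintRecord(1, "HA", 3, "HN", upper_bound=0.3)])
        cfg = replace(CFG, time_averaging=False)
        sys_ = _TorsionSystem(conf, rs, cfg)
        g = sys_.torsion_gradient(conf.coord.copy())
        eps = 1e-5
        for k in range(len(g)):
            fd = 0.0
            for sign in (1.0, -1.0):
                s2 = _TorsionSystem(conf, rs, cfg)
                delta = np.zeros(len(g))
                delta[k] = sign * eps
                c2 = s2.apply_moves(conf.coord.copy(), delta)
                fd += sign * sum(s2.energy_terms(c2))
            fd /= 2 * eps * np.pi / 180.0
            if abs(fd) > 1e-3:
                assert abs(g[k] - fd) / abs(fd) < 1e-4


class TestRefineEnsemble:
    def test_default_step_ratio_gives_five_snapshots(self):
        cfg = RefinementConfig()
        assert cfg.prod_steps == 5 * cfg.snapshot_interval
        assert cfg.equil_steps * 5 == cfg.prod_steps * 3  # 3 ns : 5 ns

    def test_five_snapshots_and_determinism(self, fast_refinement_kwargs,
                                            second_turn_inputs):
        conf, restraints, _ = second_turn_inputs
        cfg = RefinementConfig(seed=11, **fast_refinement_kwargs)
        ens1 = refine_ensemble(conf, restraints, cfg)
        ens2 = refine_ensemble(conf, restraints, cfg)
        assert len(ens1) == 5
        for a, b in zip(ens1.snapshots, ens2.snapshots):
            assert np.array_equal(a.coord, b.coord)

    def test_different_seeds_differ(self, fast_refinement_kwargs,
                                    second_turn_inputs):
        conf, restraints, _ = second_turn_inputs
        k = dict(fast_refinement_kwargs)
        k.update(equil_steps=500, prod_steps=500, snapshot_interval=100,
                 minimize_steps=0)
        e1 = refine_ensemble(conf, restraints, RefinementConfig(seed=1, **k))
        e2 = refine_ensemble(conf, restraints, RefinementConfig(seed=2, **k))
        assert not np.array_equal(e1.snapshots[-1].coord, e2.snapshots[-1].coord)

    def test_zero_production_gives_empty_ensemble(self, second_turn_inputs):
        conf, restraints, _ = second_turn_inputs
        cfg = RefinementConfig(equil_steps=100, prod_steps=0,
                               snapshot_interval=100, minimize_steps=0)
        ens = refine_ensemble(conf, restraints, cfg)
        assert len(ens) == 0

    def test_thermostat_samples_the_target_temperature(self):
        """Boltzmann check: var(theta) = kT/kappa for a quadratic pin."""
        conf = build_extended("A", CapSpec())
        kappa = 50.0
        cfg = RefinementConfig(
            w_torsion=0, w_steric=0, w_hbond=0, w_elec=0,
            torsion_restraints=((1, "phi", -120.0, kappa),
                                (1, "psi", 120.0, kappa)),
            mobility=5e-4, max_step_deg=15.0, seed=3, time_averaging=False,
        )
        sys_ = _TorsionSystem(conf, RestraintSet([]), cfg)
        rng = np.random.default_rng(cfg.seed)
        coord = sys_.conf.coord
        temp = 300.0
        samples = []
        for t in range(30000):
            g = sys_.torsion_gradient(coord)
            step = (-cfg.mobility * g
                    + np.sqrt(2 * KB * temp * cfg.mobility)
                    * rng.standard_normal(len(g))) * 180.0 / np.pi
            np.clip(step, -cfg.max_step_deg, cfg.max_step_deg, out=step)
            coord = sys_.apply_moves(coord, step)
            if t > 2000:
                samples.append(np.radians(sys_.theta_arr - [-120.0, 120.0]))
        var = np.asarray(samples).var(axis=0)
        t_eff = var * kappa / KB
        assert np.all(np.abs(t_eff - temp) / temp < 0.10)


class TestViolationReport:
    def test_all_satisfied_ensemble(self, second_turn_inputs,
                                    fast_refinement_kwargs):
        conf, _, noe_only = second_turn_inputs
        ens = Ensemble([conf], RefinementConfig(), noe_only)
        report = violation_report(ens)
        # sequential restraints are satisfied in the extended build
        assert report.satisfied_fraction == 1.0
        assert np.all(report.excess == 0.0)

    def test_hand_placed_excess(self, second_turn_inputs):
        conf, _, _ = second_turn_inputs
        sys_probe = _TorsionSystem(
            conf, RestraintSet([RestraintRecord(36, "HA", 39, "HN",
                                                upper_bound=0.5)]),
            replace(CFG, time_averaging=False),
        )
        d = sys_probe.restraint_distances(conf.coord)[0]
        upper = d - 0.12
        ens = Ensemble([conf], RefinementConfig(),
                       RestraintSet([RestraintRecord(36, "HA", 39, "HN",
                                                     upper_bound=upper)]))
        report = violation_report(ens)
        assert report.excess[0, 0] == pytest.approx(0.12, abs=1e-9)

    def test_empty_ensemble_is_an_error(self):
        ens = Ensemble([], RefinementConfig(), RestraintSet([]))
        with pytest.raises(RefinementError):
            violation_report(ens)
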