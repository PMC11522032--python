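"""Unit tests for the MD engine: minimization, integration, thermostat,
break bookkeeping and steered pulling."""

import numpy as np
import pytest

from fibrilmd.builder import make_fixture
from fibrilmd.crosslinker import CrosslinkConfig, insert_ages
from fibrilmd.engine import (
    PackedModel,
    Protocol,
    equilibrate,
    integrate,
    minimize,
    tensile_test,
)
from fibrilmd.forcefield import bond_force, total_energy
from tests.conftest import mini_protocol


class TestMinimize:
    def test_dimer_converges_to_equilibrium(self, params):
        system, topo = make_fixture("dimer", r=15.0)
        out, info = minimize(system, topo, params)
        r = np.linalg.norm(out.positions[1] - out.positions[0])
        assert r == pytest.approx(14.0, abs=1e-4)
        assert info["e_final"] <= info["e_initial"]

    def test_already_minimal_does_not_move(self, params):
        system, topo = make_fixture("dimer")  # exactly at r0
        out, _ = minimize(system, topo, params)
        assert np.allclose(out.positions, system.positions, atol=1e-6)

    def test_descent_property_on_fibril(self, params, mini_minimized):
        # energy after minimization ≤ energy before (fixture built once)
        system, topo = make_fixture("mini-fibril")
        pk0 = PackedModel(system, topo, params)
        e0 = pk0.potential_energy()
        pk1 = PackedModel(mini_minimized[0], topo, params)
        assert pk1.potential_energy() <= e0


class TestForceRoutes:
    def test_neighbor_list_matches_brute_force(self, params, mini_minimized):
        """Neighbor-list energies equal O(N²) double-loop summation."""
        system, topo = mini_minimized
        pk = PackedModel(system, topo, params)
        eb, ea, ei = pk.compute_forces()
        eb2, ea2, ei2, _ = total_energy(system, topo, params)
        assert eb == pytest.approx(eb2, rel=1e-10, abs=1e-8)
        assert ea == pytest.approx(ea2, rel=1e-10, abs=1e-8)
        assert ei == pytest.approx(ei2, rel=1e-9, abs=1e-7)

    def test_newtons_third_law(self, params, mini_minimized):
        system, topo = mini_minimized
        pk = PackedModel(system, topo, params)
        pk.compute_forces()
        net = np.abs(pk.forces.sum(axis=0)).max()
        fmax = np.abs(pk.forces).max()
        assert net < 1e-10 * max(fmax, 1.0)

    def test_angle_forces_match_energy_gradient(self, params):
        """Kernel angle forces agree with central differences of the
        harmonic bending energy."""
        system, topo = make_fixture("angle-triplet", phi=174.0, phi0=178.0)
        pk = PackedModel(system, topo, params)
        pk.compute_forces()
        h = 1e-6
        for bead in range(3):
            for dim in range(3):
                for sgn, store in ((+1, "p"), (-1, "m")):
                    pk.pos[bead, dim] += sgn * h
                    e = pk.potential_energy()
                    pk.pos[bead, dim] -= sgn * h
                    if store == "p":
                        ep = e
                    else:
                        em = e
                pk.compute_forces()
                assert pk.forces[bead, dim] == pytest.approx(
                    -(ep - em) / (2 * h), abs=1e-4
                )


class TestIntegration:
    def test_nve_energy_conservation(self, params, mini_minimized):
        """Thermostat off, 1 fs steps: |ΔE|/|E| < 1e-4 over 10⁴ steps."""
        system, topo = mini_minimized
        system = system.copy()
        prot = Protocol(seed=3, sample_interval=1000.0)
        system, topo2, _ = equilibrate(system, topo, params, prot, duration=2e4)
        system, _, info = integrate(
            system, topo2, params, prot, n_steps=10_000, dt=1.0, thermostat=False
        )
        e = info["total_energy_series"]
        drift = abs(e[-1] - e[0]) / abs(e[0])
        assert drift < 1e-4

    def test_thermostat_holds_temperature(self, params, mini_minimized):
        system, topo = mini_minimized
        prot = Protocol(seed=4, temperature=300.0)
        _, _, info = equilibrate(system.copy(), topo, params, prot, duration=8e4)
        temps = info["temperature_series"]
        mean_t = float(np.mean(temps[len(temps) // 2 :]))
        assert mean_t == pytest.approx(300.0, rel=0.05)

    def test_cold_dimer_is_exact_fixed_point(self, params):
        # bonded pairs are excluded from the pair sum, so a dimer at r0 with
        # zero velocities is an exact fixed point
        system, topo = make_fixture("dimer")
        prot = Protocol(seed=5, temperature=0.0)
        out, _, _ = integrate(
            system, topo, params, prot, n_steps=500, dt=1.0, thermostat=False
        )
        assert np.array_equal(out.positions, system.positions)
        assert np.all(out.velocities == 0.0)

    def test_cold_straight_chain_nearly_at_rest(self, params):
        # a straight chain at r0 feels only the weak 1–3+ intrachain LJ
        # attraction (bonded 1–2 pairs are excluded): the cold chain contracts
        # by far less than a bead spacing, and never transversely
        system, topo = make_fixture("two-molecule", n_beads=8, spacing=40.0)
        prot = Protocol(seed=5, temperature=0.0)
        out, _, _ = integrate(
            system, topo, params, prot, n_steps=500, dt=1.0, thermostat=False
        )
        assert np.allclose(out.positions[:, 1:], system.positions[:, 1:], atol=1e-9)
        assert np.max(np.abs(out.positions[:, 0] - system.positions[:, 0])) < 0.05

    def test_momentum_conservation_without_thermostat(self, params):
        system, topo = make_fixture("two-molecule", n_beads=10)
        rng = np.random.default_rng(0)
        system.velocities = rng.normal(0, 1e-4, system.positions.shape)
        prot = Protocol(seed=6)
        out, _, _ = integrate(
            system, topo, params, prot, n_steps=1000, dt=1.0, thermostat=False
        )
        p0 = (system.masses[:, None] * system.velocities).sum(axis=0)
        p1 = (out.masses[:, None] * out.velocities).sum(axis=0)
        scale = np.abs(system.masses[:, None] * system.velocities).sum()
        assert np.abs(p1 - p0).max() < 1e-10 * scale

    def test_oversized_timestep_aborts(self, params):
        system, topo = make_fixture("dimer", r=20.0)
        prot = Protocol(seed=7)
        with pytest.raises(RuntimeError, match="timestep|displacement"):
            integrate(system, topo, params, prot, n_steps=100, dt=1e5,
                      thermostat=False)


class TestBreakBookkeeping:
    def test_dimer_break_single_event_then_force_free(self, params):
        """A dimer pulled past r_break + a logs exactly one event and the
        bond never carries force again."""
        system, topo = make_fixture("dimer", clamped=True)
        prot = Protocol(
            seed=8, tensile_timestep=1.0, pulling_speed=0.01,
            sample_interval=100.0, max_strain=0.8, temperature=300.0,
        )
        series, events, _, topo_out = tensile_test(system, topo, params, prot)
        assert len(events) == 1
        assert events[0].species_name == "backbone"
        law = params.law("backbone")
        assert events[0].separation >= law.r_break
        assert topo_out.bond_state[0] == 2
        # force identically zero after rupture completes
        r = 14.0 * (1.0 + series.strain)
        post = r > law.r_break + law.a + 0.05
        assert np.all(np.abs(series.clamp_force[post]) < 1e-9)

    def test_intact_count_monotone_and_no_spurious_events(self, params):
        system, topo = make_fixture("two-molecule", n_beads=10)
        system.equilibrated = True
        prot = Protocol(seed=9)
        _, _, info = integrate(system, topo, params, prot, n_steps=500, dt=10.0)
        assert info["events"] == []

    def test_break_states_never_revert(self, params, mini_minimized):
        from tests.conftest import mini_run

        res = mini_run(1.0, 25.0, 1)
        intact = (
            res.series.broken_tc + res.series.broken_ecl + res.series.broken_age
        )
        assert np.all(np.diff(intact) >= 0)  # cumulative broken counts


class TestSteeredPulling:
    def test_quasi_static_dimer_matches_trilinear_law(self, params):
        """Force–extension of a clamped dimer reproduces the bond law."""
        system, topo = make_fixture("dimer", clamped=True)
        prot = Protocol(seed=10, tensile_timestep=1.0, pulling_speed=0.002,
                        sample_interval=50.0, max_strain=0.75)
        series, _, _, _ = tensile_test(system, topo, params, prot)
        law = params.law("backbone")
        r = 14.0 * (1.0 + series.strain)
        expected = bond_force(r, law)
        mask = expected > 1.0
        assert np.max(
            np.abs(series.clamp_force[mask] - expected[mask]) / expected[mask]
        ) < 0.02

    def test_age_dimer_pull_recovers_table_stiffnesses(self, params):
        """Slopes of the simulated AGE force–extension recover k0 and k1
        within 5%."""
        system, topo = make_fixture("dimer", species="age", clamped=True)
        prot = Protocol(seed=11, tensile_timestep=1.0, pulling_speed=0.002,
                        sample_interval=20.0, max_strain=0.8)
        series, _, _, _ = tensile_test(system, topo, params, prot)
        law = params.law("age")
        r = law.r0 * (1.0 + series.strain)
        soft = (r > law.r0 + 0.3) & (r < law.r1 - 0.3)
        stiff = (r > law.r1 + 0.3) & (r < law.r_break - 0.3)
        k0 = np.polyfit(r[soft], series.clamp_force[soft], 1)[0]
        k1 = np.polyfit(r[stiff], series.clamp_force[stiff], 1)[0]
        assert k0 == pytest.approx(law.k0, rel=0.05)
        assert k1 == pytest.approx(law.k1, rel=0.05)

    def test_zero_speed_control(self, params, mini_minimized):
        system, topo = mini_minimized
        system = system.copy()
        prot = mini_protocol(12, pulling_speed=0.0, sample_interval=2000.0)
        system.equilibrated = True
        series, _, _, _ = tensile_test(system, topo, params, prot)
        assert np.max(np.abs(series.strain)) < 1e-9
        # a constrained thermal fibril carries a small equilibrium prestress;
        # without pulling the stress stays at that level, far below the
        # tensile peak scale (~0.3 in these units)
        assert abs(np.mean(series.stress)) < 0.05
        assert np.std(series.stress) < 0.05

    def test_insertion_requires_prior_equilibration(self, params):
        system, topo = make_fixture("mini-fibril")
        cc = CrosslinkConfig(n_age=1.0, seed=1)
        with pytest.raises(RuntimeError, match="equilibrat"):
            insert_ages(system, topo, cc)
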