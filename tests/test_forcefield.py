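"""Unit tests for the interaction laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibrilmd.forcefield import (
    AngleLaw,
    BondLaw,
    ForceFieldParams,
    SPECIES_NAMES,
    angle_energy,
    angle_moment,
    bond_energy,
    bond_force,
    pair_energy,
    pair_force,
    total_energy,
)


@pytest.fixture(scope="module")
def params():
    return ForceFieldParams.default()


class TestBondLaw:
    @pytest.mark.parametrize(
        "r, expected",
        [
            (14.00, 0.0),  # equilibrium
            (18.20, 71.946),  # k0·(r1−r0) = 17.13·4.2
            (21.00, 345.394),  # k0·(r1−r0) + k1·(r_break−r1)
        ],
    )
    def test_backbone_reference_points(self, params, r, expected):
        law = params.law("backbone")
        assert bond_force(r, law) == pytest.approx(expected, rel=1e-12)

    def test_zero_beyond_rupture(self, params):
        for name in SPECIES_NAMES:
            law = params.law(name)
            r = law.r_break + law.a
            assert bond_force(r, law) == 0.0
            assert bond_force(r + 5.0, law) == 0.0

    def test_force_continuity_all_species(self, params):
        """Max jump across branch boundaries < 1e-8 of the peak force."""
        for name in SPECIES_NAMES:
            law = params.law(name)
            for edge in (law.r1, law.r_break, law.r_break + law.a):
                # one-sided limits: the residual slope·ε term is ~1e-9 even on
                # the steep post-peak ramp
                f = bond_force(edge + np.array([-1e-12, 1e-12]), law)
                assert abs(f[1] - f[0]) < 1e-8 * law.peak_force, (name, edge)
                # and the law is piecewise smooth on a 1e-4 grid around edges
                grid = edge + np.arange(-50, 51) * 1e-4
                grid = grid[grid > 0]
                df = np.abs(np.diff(bond_force(grid, law)))
                max_slope = max(law.k0, law.k1, law.peak_force / law.a)
                assert df.max() <= max_slope * 1.01e-4, (name, edge)

    def test_energy_force_consistency(self, params):
        """−dE/dr matches the force to 1e−6 relative away from branch points."""
        for name in SPECIES_NAMES:
            law = params.law(name)
            r = np.linspace(law.r0 * 0.5, law.r_break + law.a + 2, 500)
            edges = np.array([law.r0, law.r1, law.r_break, law.r_break + law.a])
            keep = np.min(np.abs(r[:, None] - edges[None, :]), axis=1) > 1e-3
            r = r[keep]
            h = 1e-6
            dEdr = (bond_energy(r + h, law) - bond_energy(r - h, law)) / (2 * h)
            f = bond_force(r, law)
            scale = np.maximum(np.abs(f), 1e-3 * law.peak_force)
            assert np.max(np.abs(dEdr - f) / scale) < 1e-6

    def test_energy_reference_and_plateau(self, params):
        law = params.law("backbone")
        assert bond_energy(law.r0, law) == 0.0
        # beyond rupture: finite plateau equal to the work to rupture
        from scipy.integrate import quad

        work, _ = quad(lambda r: bond_force(r, law), law.r0, law.r_break + law.a,
                       points=[law.r1, law.r_break], limit=200)
        assert bond_energy(1e4, law) == pytest.approx(work, rel=1e-8)

    def test_peak_force_ordering_and_age_reach(self, params):
        """Backbone is the strongest bond, AGEs the most extensible."""
        peaks = {n: params.law(n).peak_force for n in SPECIES_NAMES}
        assert peaks["backbone"] > peaks["trivalent"] > peaks["divalent"]
        assert params.law("age").r_break == max(
            params.law(n).r_break for n in ("divalent", "trivalent", "age")
        )
        assert params.law("age").r_break == pytest.approx(31.72)

    def test_invalid_laws_rejected(self):
        with pytest.raises(ValueError):
            BondLaw("x", r0=14, r1=13, r_break=21, k0=1, k1=1, z=0.05)
        with pytest.raises(ValueError):
            BondLaw("x", r0=14, r1=18, r_break=21, k0=-1, k1=1, z=0.05)
        with pytest.raises(ValueError):
            BondLaw("x", r0=14, r1=18, r_break=21, k0=1, k1=1, z=1.5)

    def test_nonfinite_rejected(self, params):
        law = params.law("backbone")
        with pytest.raises(ValueError):
            bond_force(np.nan, law)
        with pytest.raises(ValueError):
            bond_energy(np.inf, law)

    @given(st.floats(min_value=1.0, max_value=60.0))
    @settings(max_examples=50, deadline=None)
    def test_energy_is_nonnegative_and_bounded(self, r):
        law = ForceFieldParams.default().law("backbone")
        e = bond_energy(r, law)
        assert e >= 0.0
        assert e <= bond_energy(law.r_break + law.a, law) or r < law.r_break + law.a


class TestAngleLaw:
    def test_moment_vanishes_at_equilibrium(self, params):
        assert angle_moment(175.0, 175.0, params.angle) == 0.0

    def test_energy_even_about_equilibrium(self, params):
        e1 = angle_energy(175.0 + 3.0, 175.0, params.angle)
        e2 = angle_energy(175.0 - 3.0, 175.0, params.angle)
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_moment_magnitude(self, params):
        """0.1 rad deviation at k_B = 14.98 → 2·k_B·Δφ = 2.996."""
        phi = 180.0 - np.rad2deg(0.1)
        assert angle_moment(phi, 180.0, params.angle) == pytest.approx(
            -2.996, rel=1e-9
        )

    def test_half_convention_flag(self, params):
        alt = AngleLaw(k_b=params.angle.k_b, convention_factor=0.5)
        phi = 180.0 - np.rad2deg(0.1)
        assert angle_moment(phi, 180.0, alt) == pytest.approx(-1.498, rel=1e-9)

    def test_angle_domain_checked(self, params):
        with pytest.raises(ValueError):
            angle_moment(0.0, 175.0, params.angle)


class TestPairLaw:
    def test_zero_crossing_at_sigma(self, params):
        """The unshifted LJ energy is zero at σ; the truncated-shifted form
        differs only by the (small) cutoff shift."""
        pair = params.pair
        assert pair_energy(pair.sigma, pair) == pytest.approx(
            -pair.energy_shift, rel=1e-12
        )
        assert abs(pair_energy(pair.sigma, pair)) < 0.02 * pair.epsilon

    def test_force_zero_at_lj_minimum(self, params):
        r_min = 2.0 ** (1.0 / 6.0) * params.pair.sigma
        assert pair_force(r_min, params.pair) == pytest.approx(0.0, abs=1e-10)

    def test_soft_core_constant_force(self, params):
        pair = params.pair
        f_core = pair_force(pair.r_core, pair)
        assert pair_force(13.0, pair) == pytest.approx(f_core, rel=1e-12)
        assert pair_force(5.0, pair) == pytest.approx(f_core, rel=1e-12)
        assert f_core > 0  # repulsive cap

    def test_zero_beyond_cutoff(self, params):
        pair = params.pair
        assert pair_force(pair.cutoff + 1e-9, pair) == 0.0
        assert pair_energy(pair.cutoff + 1e-9, pair) == 0.0

    def test_energy_force_consistency(self, params):
        pair = params.pair
        r = np.linspace(8.0, pair.cutoff - 1e-3, 400)
        r = r[np.abs(r - pair.r_core) > 1e-3]
        h = 1e-7
        dEdr = (pair_energy(r + h, pair) - pair_energy(r - h, pair)) / (2 * h)
        f = pair_force(r, pair)
        scale = np.maximum(np.abs(f), 1e-6)
        assert np.max(np.abs(-dEdr - f) / scale) < 1e-5

    def test_r_zero_rejected(self, params):
        with pytest.raises(ValueError):
            pair_force(0.0, params.pair)


class TestTotalEnergy:
    def test_single_bead_and_dimer(self, params):
        from fibrilmd.builder import make_fixture

        system, topo = make_fixture("dimer")
        eb, ea, ei, et = total_energy(system, topo, params)
        assert (eb, ea, ei, et) == (0.0, 0.0, 0.0, 0.0)

    def test_dangling_bond_rejected(self, params):
        from fibrilmd.builder import make_fixture

        system, topo = make_fixture("dimer")
        topo.bonds = np.array([[0, 5]], dtype=np.int32)
        with pytest.raises(ValueError):
            total_energy(system, topo, params)

    def test_components_sum(self, params):
        from fibrilmd.builder import make_fixture

        system, topo = make_fixture("two-molecule", n_beads=10)
        eb, ea, ei, et = total_energy(system, topo, params)
        assert et == pytest.approx(eb + ea + ei, rel=1e-12)
        assert ei != 0.0  # chains are within pair range


class TestParameterTable:
    def test_table_round_trip_and_overrides(self, params):
        assert params.law("backbone").r0 == 14.0
        assert params.law("extension").r_break == 70.0
        assert params.mass == pytest.approx(1358.7)
        mod = params.with_overrides({"bonds": {"age": {"k1": 10.0}}})
        assert mod.law("age").k1 == 10.0
        assert params.law("age").k1 == 8.0  # original untouched
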