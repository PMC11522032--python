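"""Unit tests for stress–strain analysis and failure statistics."""

import numpy as np
import pytest

from fibrilmd.builder import make_fixture
from fibrilmd.engine import BreakEvent
from fibrilmd.forcefield import ForceFieldParams, bond_force
from fibrilmd.mechanics import (
    MechanicsSeries,
    broken_fraction_by_type,
    compute_bond_type_forces,
    compute_eps_tc,
    detect_linear_limit,
    failure_strain_of,
    sliding_decomposition,
    smooth_curve,
    stress_strain,
    summarize,
)


def make_series(strain, force, area=2.0, **extra):
    n = len(strain)
    zeros = np.zeros(n)
    fields = dict(
        time_fs=np.arange(n, dtype=float),
        strain=np.asarray(strain, dtype=float),
        clamp_force=np.asarray(force, dtype=float),
        stress=np.asarray(force, dtype=float) / area,
        f_tc=zeros.copy(), f_ecl=zeros.copy(), f_age=zeros.copy(),
        eps_tc=zeros.copy(), broken_tc=zeros.copy(),
        broken_ecl=zeros.copy(), broken_age=zeros.copy(),
        meta={"area": area},
    )
    fields.update(extra)
    return MechanicsSeries(**fields)


class TestStressStrain:
    def test_constant_force_flat_curve(self):
        s = make_series(np.linspace(0, 0.1, 50), np.full(50, 10.0), area=4.0)
        eps, sigma = stress_strain(s)
        assert np.allclose(sigma, 2.5)

    def test_area_scaling(self):
        s = make_series(np.linspace(0, 0.1, 50), np.linspace(0, 5, 50))
        _, s1 = stress_strain(s, area=1.0)
        _, s2 = stress_strain(s, area=2.0)
        assert np.allclose(s1, 2.0 * s2)

    def test_empty_series_rejected(self):
        s = make_series([], [])
        with pytest.raises(ValueError):
            stress_strain(s)

    def test_smoothing_recorded_in_metadata(self):
        s = make_series(np.linspace(0, 0.1, 200), np.random.default_rng(0).normal(5, 1, 200))
        stress_strain(s, smooth_window=0.01)
        assert s.meta["smooth_window"] == 0.01


class TestSummarize:
    def test_triangle_curve_closed_form(self):
        """(0,0)→(0.2,100)→(0.4,0): W_f = 20, σ_peak = 100."""
        eps = np.linspace(0, 0.4, 4001)
        sigma = np.where(eps <= 0.2, 500 * eps, 100 - 500 * (eps - 0.2))
        m = summarize(eps, sigma, smooth_window=0.0)
        assert m.sigma_peak == pytest.approx(100.0, rel=1e-6)
        assert m.work_to_failure == pytest.approx(20.0, rel=1e-2)
        assert not m.partial

    def test_monotone_truncated_curve_delta_sigma_exact(self):
        eps = np.linspace(0, 0.3, 301)
        sigma = 10 * eps
        m = summarize(eps, sigma, smooth_window=0.0)
        assert m.partial  # never reaches the failure criterion
        assert m.delta_sigma == pytest.approx(m.sigma_peak - np.interp(0.15, eps, sigma))

    def test_all_zero_curve(self):
        eps = np.linspace(0, 0.3, 100)
        m = summarize(eps, np.zeros(100))
        assert m.sigma_peak == 0.0
        assert m.work_to_failure == 0.0
        assert m.delta_sigma == 0.0

    def test_delta_sigma_clipped_at_zero(self):
        # softening-only curve: peak before ε₀ → Δσ would be negative
        eps = np.linspace(0, 0.3, 301)
        sigma = np.where(eps < 0.1, 100 * eps, 10 - 33 * (eps - 0.1))
        m = summarize(eps, np.maximum(sigma, 0), smooth_window=0.0)
        assert m.delta_sigma >= 0.0

    def test_work_matches_refined_grid(self):
        """Trapezoid on the sampled grid agrees with a 10×-refined grid."""
        eps = np.linspace(0, 0.35, 400)
        sigma = 50 * eps * np.exp(-((eps / 0.2) ** 4))
        fine = np.linspace(0, 0.35, 4000)
        ref = np.trapezoid(np.interp(fine, eps, sigma), fine)
        m = summarize(eps, sigma, smooth_window=0.0, stop_fraction=0.05)
        mask = eps <= m.failure_strain
        ref_mask = fine <= m.failure_strain
        ref = np.trapezoid(np.interp(fine[ref_mask], eps, sigma), fine[ref_mask])
        assert m.work_to_failure == pytest.approx(ref, rel=0.01)


class TestLinearLimit:
    def test_fixed_policy(self):
        eps = np.linspace(0, 0.3, 1000)
        assert detect_linear_limit(eps, eps, policy="fixed") == 0.15

    def test_exactly_linear_returns_curve_end(self):
        eps = np.linspace(0, 0.3, 2000)
        out = detect_linear_limit(eps, 2.0 * eps, policy="detect")
        assert out == pytest.approx(eps[-1], abs=1e-9)

    def test_bilinear_kink_recovered(self):
        eps = np.arange(0, 0.3, 2e-4)
        sigma = np.where(eps < 0.15, eps, 0.15 + 2.5 * (eps - 0.15))
        out = detect_linear_limit(eps, sigma, policy="detect")
        assert out == pytest.approx(0.15, abs=0.005)

    def test_noisy_bilinear_kink_recovered(self):
        rng = np.random.default_rng(1)
        eps = np.arange(0, 0.3, 2e-4)
        sigma = np.where(eps < 0.15, eps, 0.15 + 2.5 * (eps - 0.15))
        sigma = sigma + rng.normal(0, 0.007, len(eps))
        out = detect_linear_limit(eps, sigma, policy="detect")
        assert out == pytest.approx(0.15, abs=0.02)

    def test_short_curve_requires_fixed_policy(self):
        eps = np.linspace(0, 0.05, 30)
        with pytest.raises(ValueError):
            detect_linear_limit(eps, eps, policy="detect")


class TestSnapshotObservables:
    def test_dimer_mean_force_equals_bond_force(self):
        params = ForceFieldParams.default()
        system, topo = make_fixture("dimer", r=16.0)
        out = compute_bond_type_forces(system.positions, topo, params)
        assert out["tc"] == pytest.approx(bond_force(16.0, params.law("backbone")))
        assert np.isnan(out["ecl"])  # species absent → empty, not zero
        assert np.isnan(out["age"])

    def test_eps_tc_affine_stretch(self):
        system, topo = make_fixture("two-molecule", n_beads=10)
        assert compute_eps_tc(system.positions, topo, 14.0) == pytest.approx(0.0)
        stretched = system.positions.copy()
        stretched[:, 0] *= 1.01
        assert compute_eps_tc(stretched, topo, 14.0) == pytest.approx(0.01)

    def test_eps_tc_invariant_under_rigid_translation(self):
        system, topo = make_fixture("two-molecule", n_beads=10)
        moved = system.positions + np.array([123.0, -4.0, 5.0])
        assert compute_eps_tc(moved, topo, 14.0) == pytest.approx(0.0)


class TestFailureStatistics:
    def _events(self, strains, species=4):
        return [
            BreakEvent(step=i, time_fs=0.0, bond=i, species=species,
                       separation=32.0, strain=s)
            for i, s in enumerate(strains)
        ]

    def test_no_events_identically_zero(self):
        census = {n: {"count": 10 if n == "age" else 0}
                  for n in ("backbone", "extension", "divalent", "trivalent", "age")}
        out = broken_fraction_by_type([], census)
        xs, ys = out["age"]
        assert np.all(ys == 0.0)

    def test_three_of_ten(self):
        census = {n: {"count": 10 if n == "age" else 0}
                  for n in ("backbone", "extension", "divalent", "trivalent", "age")}
        out = broken_fraction_by_type(self._events([0.1, 0.2, 0.25]), census)
        xs, ys = out["age"]
        assert ys[-1] == pytest.approx(0.30)

    def test_zero_count_species_absent(self):
        census = {n: {"count": 0}
                  for n in ("backbone", "extension", "divalent", "trivalent", "age")}
        out = broken_fraction_by_type(self._events([0.1]), census)
        assert out == {}

    def test_failure_strain_of(self):
        eps = np.linspace(0, 0.4, 400)
        sigma = np.where(eps <= 0.2, eps, 0.2 - (eps - 0.2))
        f = failure_strain_of(eps, np.maximum(sigma, 0.0), 0.05)
        assert f == pytest.approx(0.39, abs=0.01)
        assert failure_strain_of(eps, eps, 0.05) is None


class TestSliding:
    def test_rigid_translation_gives_zero_eps_tc(self):
        s = make_series(np.linspace(0, 0.1, 10), np.zeros(10))
        df = sliding_decomposition(s)
        assert np.allclose(df["strain_tc"], 0.0)
        assert np.allclose(df["delta_strain"], df["strain"])

    def test_affine_case(self):
        strain = np.linspace(0, 0.1, 10)
        s = make_series(strain, np.zeros(10), eps_tc=np.full(10, 0.01))
        df = sliding_decomposition(s)
        assert np.allclose(df["delta_strain"], strain - 0.01)


class TestSmoothing:
    def test_window_smaller_than_sampling_is_identity(self):
        eps = np.linspace(0, 1, 11)
        y = np.random.default_rng(2).normal(size=11)
        assert np.allclose(smooth_curve(eps, y, 1e-6), y)

    def test_preserves_constant(self):
        eps = np.linspace(0, 1, 500)
        assert np.allclose(smooth_curve(eps, np.full(500, 3.0), 0.05), 3.0)
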