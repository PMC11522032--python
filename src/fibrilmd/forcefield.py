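"""Interaction laws of the coarse-grained collagen model.

Three interaction kinds act between beads:

* **Bonds** — a trilinear, breakable spring.  Tension rises with slope
  ``k0`` up to the critical hyperelastic distance ``r1``, continues with the
  stiffer slope ``k1`` up to the breaking distance ``r_break``, then descends
  linearly to zero over a short regularization ramp of width
  ``a = z (r_break - r1)``.  Beyond ``r_break + a`` the bond carries no force.
* **Angles** — a harmonic bending penalty about a per-triplet equilibrium
  angle sampled from the gently wavy molecule geometry (170°–180°).
* **Pairs** — a truncated, shifted 12-6 Lennard-Jones potential with a soft
  core: below ``λσ`` the force is capped at its value at ``λσ``.

Scalar laws here are plain numpy and serve as the reference implementation;
the MD engine re-implements them inside numba kernels and is tested against
these functions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml


class BondSpecies(enum.IntEnum):
    """Bond species indices used throughout topology arrays."""

    BACKBONE = 0
    EXTENSION = 1
    DIVALENT = 2
    TRIVALENT = 3
    AGE = 4


N_SPECIES = len(BondSpecies)

SPECIES_NAMES = tuple(s.name.lower() for s in BondSpecies)


@dataclass(frozen=True)
class BondLaw:
    """Trilinear breakable bond law for one species."""

    species: str
    r0: float
    r1: float
    r_break: float
    k0: float
    k1: float
    z: float

    def __post_init__(self) -> None:
        if not (self.r0 < self.r1 < self.r_break):
            raise ValueError(
                f"{self.species}: require r0 < r1 < r_break, got "
                f"{self.r0}, {self.r1}, {self.r_break}"
            )
        if self.k0 <= 0 or self.k1 <= 0:
            raise ValueError(f"{self.species}: stiffnesses must be positive")
        if not (0.0 < self.z < 1.0):
            raise ValueError(f"{self.species}: z must lie in (0, 1)")

    @property
    def a(self) -> float:
        """Width of the post-rupture regularization ramp (Å)."""
        return self.z * (self.r_break - self.r1)

    @property
    def peak_force(self) -> float:
        """Tension at the onset of rupture (kcal mol⁻¹ Å⁻¹)."""
        return self.k0 * (self.r1 - self.r0) + self.k1 * (self.r_break - self.r1)

    @property
    def r_zero_force(self) -> float:
        """Separation beyond which the bond is force-free."""
        return self.r_break + self.a


@dataclass(frozen=True)
class AngleLaw:
    """Harmonic bending law, E = c·k_B (φ − φ_i)².

    ``convention_factor`` c is 1.0 by default (moment 2 k_B Δφ); the
    ½-convention (c = 0.5) is available for cross-comparison with force
    fields that absorb the factor 2 into k_B.
    """

    k_b: float
    phi_min_deg: float = 170.0
    phi_max_deg: float = 180.0
    convention_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.k_b <= 0:
            raise ValueError("k_b must be positive")


@dataclass(frozen=True)
class PairLaw:
    """Soft-core truncated/shifted 12-6 Lennard-Jones law."""

    epsilon: float
    sigma: float
    lamda: float = 0.9
    cutoff_factor: float = 2.5

    @property
    def cutoff(self) -> float:
        return self.cutoff_factor * self.sigma

    @property
    def r_core(self) -> float:
        """Soft-core radius λσ below which the force is constant."""
        return self.lamda * self.sigma

    @property
    def energy_shift(self) -> float:
        """Unshifted LJ energy at the cutoff (subtracted so E(cutoff) = 0)."""
        sr6 = (self.sigma / self.cutoff) ** 6
        return 4.0 * self.epsilon * (sr6 * sr6 - sr6)


@dataclass
class ForceFieldParams:
    """Complete parameter set: per-species bond laws, angle, pair, bead mass."""

    bonds: dict[str, BondLaw]
    angle: AngleLaw
    pair: PairLaw
    mass: float
    version: int = 1

    @classmethod
    def default(cls) -> "ForceFieldParams":
        """Load the packaged parameter table."""
        text = resources.files("fibrilmd.data").joinpath("forcefield.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_dict(cls, raw: dict) -> "ForceFieldParams":
        bonds = {
            name: BondLaw(species=name, **vals) for name, vals in raw["bonds"].items()
        }
        missing = set(SPECIES_NAMES) - set(bonds)
        if missing:
            raise ValueError(f"parameter table missing bond species: {sorted(missing)}")
        return cls(
            bonds=bonds,
            angle=AngleLaw(**raw["angle"]),
            pair=PairLaw(**raw["pair"]),
            mass=float(raw["mass"]),
            version=int(raw.get("version", 1)),
        )

    def with_overrides(self, overrides: dict) -> "ForceFieldParams":
        """Return a copy with nested fields overridden, e.g.
        ``{"bonds": {"age": {"k1": 10.0}}, "pair": {"epsilon": 5.0}}``."""
        bonds = dict(self.bonds)
        for name, vals in overrides.get("bonds", {}).items():
            bonds[name] = replace(bonds[name], **vals)
        angle = replace(self.angle, **overrides.get("angle", {}))
        pair = replace(self.pair, **overrides.get("pair", {}))
        mass = float(overrides.get("mass", self.mass))
        return ForceFieldParams(
            bonds=bonds, angle=angle, pair=pair, mass=mass, version=self.version
        )

    def law(self, species: int | str) -> BondLaw:
        if isinstance(species, str):
            return self.bonds[species]
        return self.bonds[SPECIES_NAMES[int(species)]]

    def bond_arrays(self) -> dict[str, np.ndarray]:
        """Pack per-species bond constants into arrays indexed by species id."""
        out = {k: np.empty(N_SPECIES) for k in ("r0", "r1", "r_break", "k0", "k1", "a")}
        for i, name in enumerate(SPECIES_NAMES):
            law = self.bonds[name]
            out["r0"][i] = law.r0
            out["r1"][i] = law.r1
            out["r_break"][i] = law.r_break
            out["k0"][i] = law.k0
            out["k1"][i] = law.k1
            out["a"][i] = law.a
        return out


# ---------------------------------------------------------------------------
# scalar interaction laws (numpy-vectorized reference implementations)
# ---------------------------------------------------------------------------


def _check_r(r: np.ndarray | float) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("separation must be finite")
    return r


def bond_force(r: np.ndarray | float, law: BondLaw):
    """Bond tension at separation ``r`` (kcal mol⁻¹ Å⁻¹).

    Positive values are restoring: they pull the beads back toward ``r0``
    when stretched and push them apart when compressed (negative sign).
    Identically zero for ``r ≥ r_break + a``.
    """
    r = _check_r(r)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    f1 = law.k0 * (law.r1 - law.r0)
    fp = law.peak_force
    out = np.where(
        r < law.r1,
        law.k0 * (r - law.r0),
        np.where(
            r < law.r_break,
            f1 + law.k1 * (r - law.r1),
            np.where(
                r < law.r_zero_force,
                fp * (1.0 - (r - law.r_break) / law.a),
                0.0,
            ),
        ),
    )
    return out if out.ndim else float(out)


def bond_energy(r: np.ndarray | float, law: BondLaw):
    """Bond stretching energy, zero at ``r0``, constant beyond rupture."""
    r = _check_r(r)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    f1 = law.k0 * (law.r1 - law.r0)
    fp = law.peak_force
    e_r1 = 0.5 * law.k0 * (law.r1 - law.r0) ** 2
    d2 = law.r_break - law.r1
    e_rb = e_r1 + f1 * d2 + 0.5 * law.k1 * d2 * d2
    e_plateau = e_rb + 0.5 * fp * law.a

    d_soft = r - law.r1
    d_ramp = r - law.r_break
    out = np.where(
        r < law.r1,
        0.5 * law.k0 * (r - law.r0) ** 2,
        np.where(
            r < law.r_break,
            e_r1 + f1 * d_soft + 0.5 * law.k1 * d_soft * d_soft,
            np.where(
                r < law.r_zero_force,
                e_rb + fp * d_ramp - 0.5 * fp * d_ramp * d_ramp / law.a,
                e_plateau,
            ),
        ),
    )
    return out if out.ndim else float(out)


def angle_energy(phi_deg: np.ndarray | float, phi0_deg: float, law: AngleLaw):
    """Bending energy for angle φ (degrees) about equilibrium φ₀."""
    dphi = np.deg2rad(_check_r(phi_deg) - phi0_deg)
    out = law.convention_factor * law.k_b * dphi * dphi
    return out if out.ndim else float(out)


def angle_moment(phi_deg: np.ndarray | float, phi0_deg: float, law: AngleLaw):
    """Restoring moment dE/dφ (kcal mol⁻¹ rad⁻¹); zero at φ = φ₀."""
    phi = _check_r(phi_deg)
    if np.any((phi <= 0) | (phi >= 360)):
        raise ValueError("angle must lie in (0, 360) degrees")
    dphi = np.deg2rad(phi - phi0_deg)
    out = 2.0 * law.convention_factor * law.k_b * dphi
    return out if out.ndim else float(out)


def _lj_force(r: np.ndarray, law: PairLaw) -> np.ndarray:
    sr6 = (law.sigma / r) ** 6
    return (1.0 / r) * (48.0 * law.epsilon * sr6 * sr6 - 24.0 * law.epsilon * sr6)


def _lj_energy(r: np.ndarray, law: PairLaw) -> np.ndarray:
    sr6 = (law.sigma / r) ** 6
    return 4.0 * law.epsilon * (sr6 * sr6 - sr6)


def pair_force(r: np.ndarray | float, law: PairLaw):
    """Nonbonded force; positive = repulsive.  Constant below the soft core
    λσ, zero beyond the cutoff."""
    r = _check_r(r)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    rc = law.cutoff
    core = law.r_core
    r_eval = np.maximum(r, core)
    out = np.where(r < rc, _lj_force(r_eval, law), 0.0)
    return out if out.ndim else float(out)


def pair_energy(r: np.ndarray | float, law: PairLaw):
    """Nonbonded energy, shifted to zero at the cutoff; linear continuation
    below the soft core so that −dE/dr matches the capped force."""
    r = _check_r(r)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    rc = law.cutoff
    core = law.r_core
    e_core = _lj_energy(np.asarray(core), law) - law.energy_shift
    f_core = _lj_force(np.asarray(core), law)
    out = np.where(
        r >= rc,
        0.0,
        np.where(
            r >= core,
            _lj_energy(np.maximum(r, 1e-12), law) - law.energy_shift,
            e_core + f_core * (core - r),
        ),
    )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# brute-force system energy (O(N²) reference for the neighbor-list engine)
# ---------------------------------------------------------------------------


def _angle_deg(pos: np.ndarray, tri: np.ndarray) -> np.ndarray:
    u = pos[tri[:, 0]] - pos[tri[:, 1]]
    v = pos[tri[:, 2]] - pos[tri[:, 1]]
    c = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0)))


def total_energy(system, topology, params: ForceFieldParams):
    """Exact total energy by double-loop summation.

    Returns ``(E_bond, E_angle, E_inter, E_total)``.  Dead bonds (beyond
    ``r_break + a``) contribute their rupture plateau; the pair sum excludes
    directly bonded bead pairs.  Intended as the independent reference for
    the neighbor-list engine — O(N²), use on small systems only.
    """
    pos = np.asarray(system.positions, dtype=float)
    n = len(pos)
    bonds = np.asarray(topology.bonds)
    if bonds.size and (bonds.min() < 0 or bonds.max() >= n):
        raise ValueError("topology references bead indices outside the system")

    e_bond = 0.0
    for s in range(N_SPECIES):
        mask = topology.bond_species == s
        if not mask.any():
            continue
        law = params.law(s)
        b = bonds[mask]
        r = np.linalg.norm(pos[b[:, 1]] - pos[b[:, 0]], axis=1)
        dead = topology.bond_state[mask] == 2
        e = bond_energy(np.where(dead, law.r_zero_force + 1.0, r), law)
        e_bond += float(np.sum(e))

    e_angle = 0.0
    tri = np.asarray(topology.angles)
    if tri.size:
        phi = _angle_deg(pos, tri)
        e_angle = float(np.sum(angle_energy(phi, topology.phi0_deg, params.angle)))

    excluded = {tuple(sorted(b)) for b in bonds.tolist()} if bonds.size else set()
    e_inter = 0.0
    rc = params.pair.cutoff
    for i in range(n):
        d = pos[i + 1 :] - pos[i]
        r = np.linalg.norm(d, axis=1)
        for jj in np.nonzero(r < rc)[0]:
            j = i + 1 + jj
            if (i, j) in excluded:
                continue
            e_inter += pair_energy(float(r[jj]), params.pair)

    return e_bond, e_angle, e_inter, e_bond + e_angle + e_inter
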