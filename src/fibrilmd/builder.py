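"""Fibril geometry generation.

A collagen fibril is modelled as a bundle of bead chains (one chain of
``beads_per_molecule`` beads per tropocollagen molecule) packed on a
triangular cross-section lattice and staggered axially by multiples of the
D-period.  The construction follows the classic staggered-packing picture:
the axial window has length ``W = L_mol + 0.6 D`` (molecule length plus one
gap zone) and each lattice site hosts one molecule whose start is offset by
``(stagger index · D) mod W``.  Chains crossing the window boundary are
wrapped, so each line carries exactly one molecule's worth of beads, a gap
of 0.6 D, and an overlap pattern with banding period D.

Chain ends that terminate at the axial window faces are continued with
reinforced extension beads (species ``extension``, late rupture) whose
outermost beads form the two rigid clamp groups used to load the fibril.
Interior (natural) molecule ends carry the 4-bead telopeptide flag and are
the only sites of enzymatic cross-linking.

Molecule waviness: beads are laid out with exact consecutive spacing ``r0``
along a gently undulating path; the per-triplet angles of the generated
geometry are recorded as the equilibrium angles of the bending terms, so the
as-built fibril is stress-free in its bonded terms.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .forcefield import BondSpecies, ForceFieldParams

log = logging.getLogger(__name__)


class Role(enum.IntEnum):
    HELICAL = 0
    TELOPEPTIDE = 1
    EXTENSION = 2
    CLAMP = 3


TELO_BEADS = 4  # beads flagged telopeptide at each natural molecule end


@dataclass
class FibrilSpec:
    """Geometric recipe for one fibril."""

    beads_per_molecule: int = 218
    r0: float = 14.0
    diameter: float = 202.0
    lattice_spacing: float = 15.45
    d_period: float = 670.0
    gap_fraction: float = 0.6
    n_periods: int = 5
    extension_beads: int = 40
    clamp_beads: int = 10
    waviness: float = 1.2  # transverse undulation amplitude, Å
    waviness_period: float = 5.0  # undulation period, beads
    seed: int = 0

    @property
    def overlap_fraction(self) -> float:
        return 1.0 - self.gap_fraction

    @property
    def molecule_length(self) -> float:
        return (self.beads_per_molecule - 1) * self.r0

    @property
    def window(self) -> float:
        """Axial window length: molecule plus one gap zone."""
        return self.molecule_length + self.gap_fraction * self.d_period

    @property
    def cross_section_area(self) -> float:
        return math.pi * self.diameter**2 / 4.0

    def validate(self) -> None:
        if self.beads_per_molecule < 3 * TELO_BEADS:
            raise ValueError("molecule too short for telopeptide bookkeeping")
        if self.n_periods < 1:
            raise ValueError("need at least one D-period")
        if not 0.0 < self.gap_fraction < 1.0:
            raise ValueError("gap fraction must lie in (0, 1)")
        if self.extension_beads < self.clamp_beads:
            raise ValueError("extensions must be at least as long as the clamps")
        if self.diameter <= 2 * self.lattice_spacing:
            raise ValueError("fibril diameter must exceed two lattice spacings")
        if self.r0 <= 0 or self.d_period <= 0:
            raise ValueError("lengths must be positive")


@dataclass
class ParticleSystem:
    """Beads of one fibril: coordinates, identity flags and masses.

    The axial direction is the first coordinate (x).  ``clamp_group`` is −1
    for free beads, 0 for the left rigid clamp and 1 for the right one.
    """

    positions: np.ndarray  # (n, 3) Å
    velocities: np.ndarray  # (n, 3) Å/fs
    molecule_id: np.ndarray  # (n,) int32
    role: np.ndarray  # (n,) int8
    clamp_group: np.ndarray  # (n,) int8
    masses: np.ndarray  # (n,) amu
    equilibrated: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_id.max()) + 1 if self.n_beads else 0

    def clamp_indices(self, group: int) -> np.ndarray:
        return np.nonzero(self.clamp_group == group)[0]

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            molecule_id=self.molecule_id.copy(),
            role=self.role.copy(),
            clamp_group=self.clamp_group.copy(),
            masses=self.masses.copy(),
            equilibrated=self.equilibrated,
            meta=dict(self.meta),
        )


@dataclass
class Topology:
    """Typed bonds and angle triplets.

    ``bond_state``: 0 intact, 1 broken (separation exceeded ``r_break`` at
    least once), 2 dead (exceeded ``r_break + a``; removed from force
    evaluation permanently).
    """

    bonds: np.ndarray  # (nb, 2) int32
    bond_species: np.ndarray  # (nb,) int8
    bond_state: np.ndarray  # (nb,) int8
    angles: np.ndarray  # (na, 3) int32
    phi0_deg: np.ndarray  # (na,) float64

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def copy(self) -> "Topology":
        return Topology(
            self.bonds.copy(),
            self.bond_species.copy(),
            self.bond_state.copy(),
            self.angles.copy(),
            self.phi0_deg.copy(),
        )

    def add_bonds(self, pairs: np.ndarray, species: int) -> None:
        pairs = np.asarray(pairs, dtype=np.int32).reshape(-1, 2)
        existing = {tuple(sorted(b)) for b in self.bonds.tolist()}
        for p in pairs.tolist():
            if tuple(sorted(p)) in existing:
                raise ValueError(f"duplicate bond between beads {p}")
        self.bonds = np.vstack([self.bonds, pairs]).astype(np.int32)
        self.bond_species = np.concatenate(
            [self.bond_species, np.full(len(pairs), species, dtype=np.int8)]
        )
        self.bond_state = np.concatenate(
            [self.bond_state, np.zeros(len(pairs), dtype=np.int8)]
        )

    def species_mask(self, species: int) -> np.ndarray:
        return self.bond_species == np.int8(species)


def _empty_topology() -> Topology:
    return Topology(
        bonds=np.empty((0, 2), dtype=np.int32),
        bond_species=np.empty(0, dtype=np.int8),
        bond_state=np.empty(0, dtype=np.int8),
        angles=np.empty((0, 3), dtype=np.int32),
        phi0_deg=np.empty(0),
    )


def triplet_angles_deg(positions: np.ndarray) -> np.ndarray:
    """Interior angles (degrees) of consecutive bead triplets of one chain."""
    u = positions[:-2] - positions[1:-1]
    v = positions[2:] - positions[1:-1]
    c = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0)))


def build_molecule(
    spec: FibrilSpec,
    axial_offset: float,
    lattice_site: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Lay out one bead chain with exact spacing ``r0`` along a wavy path.

    Returns ``(positions, phi0_deg)`` where ``phi0_deg`` are the per-triplet
    equilibrium angles read off the generated geometry.  Raises if the
    waviness produces an angle below 170°.
    """
    spec.validate()
    n = spec.beads_per_molecule
    j = np.arange(n)
    if spec.waviness > 0:
        ph = rng.uniform(0, 2 * np.pi, size=2)
        w = 2 * np.pi / spec.waviness_period
        y = spec.waviness * np.sin(w * j + ph[0])
        z = spec.waviness * np.sin(w * j + ph[1])
    else:
        y = np.zeros(n)
        z = np.zeros(n)
    dy = np.diff(y)
    dz = np.diff(z)
    trans2 = dy**2 + dz**2
    if np.any(trans2 >= spec.r0**2):
        raise ValueError("waviness too large for the bead spacing")
    dx = np.sqrt(spec.r0**2 - trans2)
    x = axial_offset + np.concatenate([[0.0], np.cumsum(dx)])
    pos = np.column_stack([x, y + lattice_site[0], z + lattice_site[1]])

    phi0 = triplet_angles_deg(pos)
    bad = np.nonzero(phi0 < 170.0)[0]
    if bad.size:
        raise ValueError(
            f"waviness produced equilibrium angle {phi0[bad[0]]:.2f}° < 170° "
            f"at triplet {int(bad[0])}"
        )
    return pos, phi0


def mesh_cross_section(diameter: float, spacing: float) -> np.ndarray:
    """Triangular-lattice sites within a circle of the given diameter.

    Returns an (m, 2) array of (y, z) coordinates in a deterministic order
    (sorted by distance from the axis, then polar angle).
    """
    if diameter <= 2 * spacing:
        raise ValueError("diameter must exceed two lattice spacings")
    radius = diameter / 2.0
    m = int(math.ceil(radius / spacing)) + 2
    pts = []
    row_h = spacing * math.sqrt(3.0) / 2.0
    for jrow in range(-m, m + 1):
        z = jrow * row_h
        off = 0.5 * spacing if (jrow % 2) else 0.0
        for i in range(-m, m + 1):
            y = i * spacing + off
            if y * y + z * z <= radius * radius + 1e-9:
                pts.append((y, z))
    pts = np.array(pts)
    d = np.hypot(pts[:, 0], pts[:, 1])
    ang = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2 * np.pi)
    order = np.lexsort((np.round(ang, 9), np.round(d, 6)))
    return pts[order]


def build_fibril(
    spec: FibrilSpec, params: ForceFieldParams | None = None
) -> tuple[ParticleSystem, Topology]:
    """Assemble the full staggered fibril.

    Each lattice site hosts one molecule staggered by ``(site index mod
    n_periods) · D``; chains are wrapped at the axial window, boundary faces
    get reinforced extensions and the outermost ``clamp_beads`` of each
    extension are collected into two rigid clamp groups.
    """
    spec.validate()
    params = params or ForceFieldParams.default()
    rng = np.random.default_rng(spec.seed)
    sites = mesh_cross_section(spec.diameter, spec.lattice_spacing)
    W = spec.window
    r0 = spec.r0

    pos_list: list[np.ndarray] = []
    mol_list: list[np.ndarray] = []
    role_list: list[np.ndarray] = []
    clamp_list: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    bond_species: list[int] = []
    angles: list[tuple[int, int, int]] = []
    phi0: list[float] = []
    offset = 0
    n_ext_faces = 0

    def add_chain_bonded(pos, phis, species_bond, roles):
        """Append a contiguous bonded chain; returns global index range."""
        nonlocal offset
        n = len(pos)
        pos_list.append(pos)
        idx = np.arange(offset, offset + n)
        for a, b in zip(idx[:-1], idx[1:]):
            bonds.append((a, b))
            bond_species.append(species_bond)
        for t, ph in zip(range(n - 2), phis):
            angles.append((idx[t], idx[t + 1], idx[t + 2]))
            phi0.append(ph)
        role_list.append(roles)
        offset += n
        return idx

    for site_idx, (sy, sz) in enumerate(sites):
        stagger = site_idx % spec.n_periods
        start = (stagger * spec.d_period) % W
        mpos, mphi = build_molecule(spec, 0.0, (sy, sz), rng)
        x = mpos[:, 0] + start
        wrapped = np.mod(x, W)
        # contiguous pieces of the wrapped chain
        cut = np.nonzero(np.diff(wrapped) < 0)[0]
        pieces = np.split(np.arange(spec.beads_per_molecule), cut + 1)

        roles_mol = np.full(spec.beads_per_molecule, Role.HELICAL, dtype=np.int8)
        roles_mol[:TELO_BEADS] = Role.TELOPEPTIDE
        roles_mol[-TELO_BEADS:] = Role.TELOPEPTIDE

        mol_global: list[np.ndarray] = []
        for piece in pieces:
            ppos = mpos[piece].copy()
            ppos[:, 0] = wrapped[piece]
            # angles only over triplets fully inside the piece
            pphi = mphi[piece[0] : piece[-1] - 1] if len(piece) >= 3 else mphi[:0]
            idx = add_chain_bonded(
                ppos, pphi, int(BondSpecies.BACKBONE), roles_mol[piece].copy()
            )
            mol_global.append(idx)

            # extensions at faces near the axial window boundaries
            for end, direction in ((0, -1.0), (len(piece) - 1, +1.0)):
                fx = ppos[end, 0]
                at_left = direction < 0 and fx < r0
                at_right = direction > 0 and fx > W - r0
                if not (at_left or at_right):
                    continue
                n_ext_faces += 1
                ne = spec.extension_beads
                ex = fx + direction * r0 * np.arange(1, ne + 1)
                epos = np.column_stack(
                    [ex, np.full(ne, ppos[end, 1]), np.full(ne, ppos[end, 2])]
                )
                eroles = np.full(ne, Role.EXTENSION, dtype=np.int8)
                eroles[-spec.clamp_beads :] = Role.CLAMP
                eidx = add_chain_bonded(
                    epos, np.full(max(ne - 2, 0), 180.0), int(BondSpecies.EXTENSION), eroles
                )
                # joint bond + straight joint angles between chain and extension
                bonds.append((int(idx[end]), int(eidx[0])))
                bond_species.append(int(BondSpecies.EXTENSION))
                clamp = np.full(ne, -1, dtype=np.int8)
                clamp[-spec.clamp_beads :] = 0 if direction < 0 else 1
                clamp_list.append(clamp)

        for idx in mol_global:
            mol_list.append(np.full(len(idx), site_idx, dtype=np.int32))

    # molecule ids for extension beads: inherit from the nearest chain append
    # order; rebuild flat arrays in append order
    positions = np.vstack(pos_list)
    roles = np.concatenate(role_list)
    n_total = len(positions)
    molecule_id = np.full(n_total, -1, dtype=np.int32)
    clamp_group = np.full(n_total, -1, dtype=np.int8)

    # walk chains again to assign molecule ids and clamp groups in order
    ptr = 0
    chain_lengths = [len(p) for p in pos_list]
    mol_iter = iter(mol_list)
    clamp_iter = iter(clamp_list)
    current_mol = -1
    for length, block in zip(chain_lengths, pos_list):
        is_ext = roles[ptr] in (Role.EXTENSION, Role.CLAMP)
        if is_ext:
            molecule_id[ptr : ptr + length] = current_mol
            clamp_group[ptr : ptr + length] = next(clamp_iter)
        else:
            ids = next(mol_iter)
            molecule_id[ptr : ptr + length] = ids
            current_mol = int(ids[0])
        ptr += length

    system = ParticleSystem(
        positions=positions,
        velocities=np.zeros_like(positions),
        molecule_id=molecule_id,
        role=roles,
        clamp_group=clamp_group,
        masses=np.full(n_total, params.mass),
        meta={
            "spec": asdict(spec),
            "area": spec.cross_section_area,
            "window": W,
            "n_molecules": len(sites),
            "n_extension_faces": n_ext_faces,
        },
    )
    topology = Topology(
        bonds=np.array(bonds, dtype=np.int32),
        bond_species=np.array(bond_species, dtype=np.int8),
        bond_state=np.zeros(len(bonds), dtype=np.int8),
        angles=np.array(angles, dtype=np.int32),
        phi0_deg=np.array(phi0),
    )
    return system, topology


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

MINI_SPEC = FibrilSpec(
    beads_per_molecule=68,
    diameter=2.1 * 15.45,
    n_periods=2,
    extension_beads=15,
    waviness=1.2,
)


def make_fixture(kind: str, **overrides):
    """Deterministic minimal systems for tests and calibration.

    Kinds: ``dimer`` (2 beads, 1 bond), ``angle-triplet`` (3 beads, 1
    angle), ``two-molecule`` (2 parallel chains), ``mini-fibril`` (7 lattice
    sites, 2 D-periods).
    """
    params = overrides.pop("params", None) or ForceFieldParams.default()

    if kind == "dimer":
        species = overrides.pop("species", int(BondSpecies.BACKBONE))
        if isinstance(species, str):
            species = int(BondSpecies[species.upper()])
        r = overrides.pop("r", params.law(species).r0)
        clamped = overrides.pop("clamped", False)
        _reject_extras(kind, overrides)
        pos = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
        system = ParticleSystem(
            positions=pos,
            velocities=np.zeros_like(pos),
            molecule_id=np.array([0, 1], dtype=np.int32),
            role=np.zeros(2, dtype=np.int8),
            clamp_group=np.array([0, 1] if clamped else [-1, -1], dtype=np.int8),
            masses=np.full(2, params.mass),
            meta={"area": 1.0},
        )
        topo = _empty_topology()
        topo.bonds = np.array([[0, 1]], dtype=np.int32)
        topo.bond_species = np.array([species], dtype=np.int8)
        topo.bond_state = np.zeros(1, dtype=np.int8)
        return system, topo

    if kind == "angle-triplet":
        phi = overrides.pop("phi", 175.0)
        phi0 = overrides.pop("phi0", 175.0)
        r0 = overrides.pop("r0", 14.0)
        _reject_extras(kind, overrides)
        th = np.deg2rad(180.0 - phi)
        pos = np.array(
            [
                [-r0, 0.0, 0.0],
                [0.0, 0.0, 0.0],
                [r0 * np.cos(th), r0 * np.sin(th), 0.0],
            ]
        )
        system = ParticleSystem(
            positions=pos,
            velocities=np.zeros_like(pos),
            molecule_id=np.zeros(3, dtype=np.int32),
            role=np.zeros(3, dtype=np.int8),
            clamp_group=np.full(3, -1, dtype=np.int8),
            masses=np.full(3, params.mass),
            meta={"area": 1.0},
        )
        topo = _empty_topology()
        topo.bonds = np.array([[0, 1], [1, 2]], dtype=np.int32)
        topo.bond_species = np.zeros(2, dtype=np.int8)
        topo.bond_state = np.zeros(2, dtype=np.int8)
        topo.angles = np.array([[0, 1, 2]], dtype=np.int32)
        topo.phi0_deg = np.array([phi0])
        return system, topo

    if kind == "two-molecule":
        n = overrides.pop("n_beads", 30)
        spacing = overrides.pop("spacing", 15.45)
        shift = overrides.pop("axial_shift", 0.0)
        _reject_extras(kind, overrides)
        x = 14.0 * np.arange(n)
        pos = np.vstack(
            [
                np.column_stack([x, np.zeros(n), np.zeros(n)]),
                np.column_stack([x + shift, np.full(n, spacing), np.zeros(n)]),
            ]
        )
        roles = np.full(2 * n, Role.HELICAL, dtype=np.int8)
        for s in (0, n):
            roles[s : s + TELO_BEADS] = Role.TELOPEPTIDE
            roles[s + n - TELO_BEADS : s + n] = Role.TELOPEPTIDE
        system = ParticleSystem(
            positions=pos,
            velocities=np.zeros_like(pos),
            molecule_id=np.repeat(np.array([0, 1], dtype=np.int32), n),
            role=roles,
            clamp_group=np.full(2 * n, -1, dtype=np.int8),
            masses=np.full(2 * n, params.mass),
            meta={"area": 1.0, "molecule_end_beads": [[0, n - 1], [n, 2 * n - 1]]},
        )
        topo = _empty_topology()
        b = []
        for s in (0, n):
            b += [(s + i, s + i + 1) for i in range(n - 1)]
        topo.bonds = np.array(b, dtype=np.int32)
        topo.bond_species = np.zeros(len(b), dtype=np.int8)
        topo.bond_state = np.zeros(len(b), dtype=np.int8)
        ang = []
        for s in (0, n):
            ang += [(s + i, s + i + 1, s + i + 2) for i in range(n - 2)]
        topo.angles = np.array(ang, dtype=np.int32)
        topo.phi0_deg = np.full(len(ang), 180.0)
        return system, topo

    if kind == "mini-fibril":
        spec_kwargs = {**asdict(MINI_SPEC), **overrides}
        spec = FibrilSpec(**spec_kwargs)
        return build_fibril(spec, params)

    raise ValueError(f"unknown fixture kind: {kind!r}")


def _reject_extras(kind: str, overrides: dict) -> None:
    if overrides:
        raise TypeError(f"unknown overrides for {kind!r}: {sorted(overrides)}")


# ---------------------------------------------------------------------------
# optional reference-structure reader
# ---------------------------------------------------------------------------


def read_reference_structure(path) -> list[np.ndarray]:
    """Read per-chain axial control points from a PDB-format structure.

    Returns a list of smoothed per-chain control-point arrays (m, 3) that can
    replace the synthetic waviness via :func:`molecule_from_control_points`.
    Falls back (with a logged notice) to synthetic geometry when the file is
    absent; unparsable records raise with the offending line.
    """
    import os

    if not os.path.exists(path):
        log.info("reference structure %s absent; using synthetic geometry", path)
        return []
    from scipy.interpolate import splev, splprep

    chains: dict[str, list[list[float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                chain = line[21]
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except (ValueError, IndexError) as exc:
                raise ValueError(f"unparsable coordinate record at line {ln}") from exc
            chains.setdefault(chain, []).append(xyz)

    out = []
    for chain, coords in sorted(chains.items()):
        arr = np.asarray(coords)
        if len(arr) < 4:
            continue
        try:
            tck, _ = splprep(arr.T, s=len(arr) * 4.0, k=min(3, len(arr) - 1))
            u = np.linspace(0, 1, max(len(arr) // 3, 8))
            out.append(np.column_stack(splev(u, tck)))
        except Exception:
            out.append(arr)
    return out


def molecule_from_control_points(points: np.ndarray, r0: float = 14.0) -> np.ndarray:
    """Place beads with exact chord spacing ``r0`` along a control polyline."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    # dense resample then walk with exact chords
    from scipy.interpolate import interp1d

    dense_s = np.linspace(0, s[-1], max(int(s[-1] / 0.5), 50))
    dense = interp1d(s, pts, axis=0)(dense_s)
    beads = [dense[0]]
    i = 0
    while True:
        last = beads[-1]
        j = i
        while j < len(dense) and np.linalg.norm(dense[j] - last) < r0:
            j += 1
        if j >= len(dense):
            break
        beads.append(dense[j])
        i = j
    return np.asarray(beads)
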