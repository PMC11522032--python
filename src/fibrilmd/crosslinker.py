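"""Insertion of enzymatic and AGE cross-links into an equilibrated fibril.

Enzymatic cross-links (ECLs) attach at telopeptide chain ends: a fraction of
all ends (the *content*, 0–100%, where 100% means two cross-links per
molecule) is selected at random, and each selected end is bonded to the
nearest bead of the nearest distinct molecule within the capture radius.
Divalent ECLs place one such bond (joining 2 molecules); trivalent ECLs
place two bonds from the same telopeptide bead to the two nearest distinct
molecules (joining 3).

AGE cross-links (glucosepane as the representative species) are placed
randomly between helical beads of neighbouring molecules; telopeptide ends
and the reinforced extensions are excluded as binding sites.  The requested
density ``n_age`` is counted per molecule; below one per molecule, host
molecules are drawn first and a site on each is then drawn at random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .builder import ParticleSystem, Role, Topology
from .forcefield import BondSpecies, SPECIES_NAMES

log = logging.getLogger(__name__)


@dataclass
class CrosslinkConfig:
    """Cross-link populations to insert."""

    ecl_content: float = 0.0  # percent of telopeptide ends cross-linked
    ecl_valence: str = "divalent"  # or "trivalent"
    n_age: float = 0.0  # AGE cross-links per molecule
    # Å; must separate the first (≈15.5–19 Å) from the second (≈26.8 Å)
    # lattice-neighbour shell so "neighbouring molecules" means adjacent lines
    capture_radius: float = 24.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.ecl_content <= 100.0:
            raise ValueError("ECL content must lie in [0, 100] percent")
        if self.ecl_valence not in ("divalent", "trivalent"):
            raise ValueError(f"unknown ECL valence {self.ecl_valence!r}")
        if self.n_age < 0:
            raise ValueError("AGE density must be non-negative")
        if self.capture_radius <= 0:
            raise ValueError("capture radius must be positive")


@dataclass
class InsertionReport:
    """Bookkeeping of one insertion pass."""

    requested: int = 0
    inserted: int = 0
    skipped_ends: list = field(default_factory=list)


def _require_equilibrated(system: ParticleSystem, require: bool) -> None:
    if require and not system.equilibrated:
        raise RuntimeError(
            "cross-links must be inserted into an equilibrated system; "
            "run the equilibration stage first"
        )


def telopeptide_end_beads(system: ParticleSystem, topology: Topology) -> np.ndarray:
    """Bead indices of natural chain termini (one per telopeptide end).

    A terminus is a telopeptide-flagged bead with exactly one backbone bond.
    """
    n = system.n_beads
    degree = np.zeros(n, dtype=np.int32)
    bb = topology.bonds[topology.species_mask(int(BondSpecies.BACKBONE))]
    np.add.at(degree, bb.ravel(), 1)
    mask = (system.role == np.int8(Role.TELOPEPTIDE)) & (degree == 1)
    return np.nonzero(mask)[0]


def insert_ecl(
    system: ParticleSystem,
    topology: Topology,
    config: CrosslinkConfig,
    rng: np.random.Generator | None = None,
    require_equilibrated: bool = True,
) -> tuple[Topology, InsertionReport]:
    """Insert enzymatic cross-links; returns (new topology, shortfall report)."""
    config.validate()
    _require_equilibrated(system, require_equilibrated)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    topo = topology.copy()
    report = InsertionReport()

    ends = telopeptide_end_beads(system, topo)
    n_select = int(round(config.ecl_content / 100.0 * len(ends)))
    report.requested = n_select
    if n_select == 0:
        return topo, report
    chosen = np.sort(rng.choice(ends, size=n_select, replace=False))

    eligible = np.nonzero(system.role == np.int8(Role.HELICAL))[0]
    tree = cKDTree(system.positions[eligible])
    species = (
        int(BondSpecies.DIVALENT)
        if config.ecl_valence == "divalent"
        else int(BondSpecies.TRIVALENT)
    )
    n_partners = 1 if species == int(BondSpecies.DIVALENT) else 2

    new_pairs = []
    for e in chosen:
        idx = tree.query_ball_point(system.positions[e], config.capture_radius)
        cand = eligible[np.asarray(idx, dtype=int)] if idx else np.empty(0, dtype=int)
        cand = cand[system.molecule_id[cand] != system.molecule_id[e]]
        if cand.size == 0:
            report.skipped_ends.append(int(e))
            continue
        d = np.linalg.norm(system.positions[cand] - system.positions[e], axis=1)
        order = cand[np.argsort(d, kind="stable")]
        partners = []
        seen_mols = set()
        for c in order:
            m = int(system.molecule_id[c])
            if m in seen_mols:
                continue
            partners.append(int(c))
            seen_mols.add(m)
            if len(partners) == n_partners:
                break
        if len(partners) < n_partners:
            report.skipped_ends.append(int(e))
            continue
        for p in partners:
            new_pairs.append((int(e), p))

    if new_pairs:
        topo.add_bonds(np.array(new_pairs), species)
        report.inserted = len(new_pairs)
    if report.skipped_ends:
        log.info(
            "ECL insertion: %d of %d ends skipped (no partner within %.1f Å)",
            len(report.skipped_ends),
            n_select,
            config.capture_radius,
        )
    return topo, report


def insert_ages(
    system: ParticleSystem,
    topology: Topology,
    config: CrosslinkConfig,
    rng: np.random.Generator | None = None,
    require_equilibrated: bool = True,
) -> tuple[Topology, InsertionReport]:
    """Insert AGE cross-links between helical beads of distinct molecules."""
    config.validate()
    _require_equilibrated(system, require_equilibrated)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    topo = topology.copy()
    report = InsertionReport()

    n_mol = system.n_molecules
    n_req = int(round(config.n_age * n_mol))
    report.requested = n_req
    if n_req == 0:
        return topo, report

    eligible = np.nonzero(system.role == np.int8(Role.HELICAL))[0]
    tree = cKDTree(system.positions[eligible])
    pairs_local = tree.query_pairs(config.capture_radius, output_type="ndarray")
    pairs = eligible[pairs_local]
    mols = system.molecule_id[pairs]
    pairs = pairs[mols[:, 0] != mols[:, 1]]
    existing = {tuple(sorted(b)) for b in topo.bonds.tolist()}
    keep = np.array(
        [tuple(sorted(p)) not in existing for p in pairs.tolist()], dtype=bool
    )
    pairs = pairs[keep]
    if n_req > len(pairs):
        raise ValueError(
            f"requested {n_req} AGE cross-links but only {len(pairs)} distinct "
            "candidate site pairs exist"
        )

    if config.n_age < 1.0:
        hosts = rng.choice(n_mol, size=n_req, replace=False)
        chosen_rows = []
        used = set()
        pair_mols = system.molecule_id[pairs]
        for h in hosts:
            rows = np.nonzero(
                ((pair_mols[:, 0] == h) | (pair_mols[:, 1] == h))
            )[0]
            rows = [r for r in rows if r not in used]
            if not rows:
                log.info("AGE insertion: no free site on molecule %d; skipped", h)
                continue
            r = int(rng.choice(rows))
            chosen_rows.append(r)
            used.add(r)
        chosen = pairs[chosen_rows]
    else:
        rows = rng.choice(len(pairs), size=n_req, replace=False)
        chosen = pairs[rows]

    if len(chosen):
        topo.add_bonds(chosen, int(BondSpecies.AGE))
        report.inserted = len(chosen)
    return topo, report


def crosslink_census(
    topology: Topology, n_molecules: int | None = None
) -> dict[str, dict[str, float]]:
    """Exact per-species bond counts, broken states and per-molecule densities."""
    out: dict[str, dict[str, float]] = {}
    for s, name in enumerate(SPECIES_NAMES):
        mask = topology.species_mask(s)
        count = int(mask.sum())
        broken = int((topology.bond_state[mask] >= 1).sum())
        entry: dict[str, float] = {
            "count": count,
            "intact": count - broken,
            "broken": broken,
        }
        if n_molecules:
            entry["density"] = count / n_molecules
        out[name] = entry
    return out
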