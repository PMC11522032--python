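"""Plain-text input/output: XYZ frames, LAMMPS data decks, cross-link
tables and run archives (CSV/JSON/YAML)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .builder import ParticleSystem, Topology
from .forcefield import ForceFieldParams, SPECIES_NAMES


def write_xyz(path, system: ParticleSystem, comment: str = "fibrilmd frame") -> None:
    """One-frame XYZ export; element column encodes the bead role."""
    names = {0: "C", 1: "N", 2: "O", 3: "S"}  # helical/telo/extension/clamp
    with open(path, "w") as fh:
        fh.write(f"{system.n_beads}\n{comment}\n")
        for p, role in zip(system.positions, system.role):
            fh.write(
                f"{names[int(role)]} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n"
            )


def write_lammps_data(
    path, system: ParticleSystem, topology: Topology, params: ForceFieldParams
) -> None:
    """Export the initial state as a LAMMPS molecular data file.

    Bond types map 1:1 to species (1-based); each angle gets its own type so
    its equilibrium angle can be carried in the Angle Coeffs section
    (harmonic convention, K = convention·k_B).
    """
    pos = system.positions
    lo = pos.min(axis=0) - 100.0
    hi = pos.max(axis=0) + 100.0
    n_angle_types = max(len(topology.angles), 1)
    with open(path, "w") as fh:
        fh.write("fibrilmd coarse-grained collagen fibril (units real)\n\n")
        fh.write(f"{system.n_beads} atoms\n")
        fh.write(f"{len(topology.bonds)} bonds\n")
        fh.write(f"{len(topology.angles)} angles\n\n")
        fh.write("1 atom types\n")
        fh.write(f"{len(SPECIES_NAMES)} bond types\n")
        fh.write(f"{n_angle_types} angle types\n\n")
        for d, nm in zip(range(3), "xyz"):
            fh.write(f"{lo[d]:.4f} {hi[d]:.4f} {nm}lo {nm}hi\n")
        fh.write("\nMasses\n\n")
        fh.write(f"1 {params.mass}\n")
        fh.write("\nAngle Coeffs # harmonic\n\n")
        k = params.angle.convention_factor * params.angle.k_b
        for t, phi0 in enumerate(topology.phi0_deg, start=1):
            fh.write(f"{t} {k:.4f} {phi0:.4f}\n")
        if len(topology.angles) == 0:
            fh.write(f"1 {k:.4f} 180.0\n")
        fh.write("\nAtoms # molecular\n\n")
        for i, (p, m) in enumerate(zip(pos, system.molecule_id), start=1):
            fh.write(f"{i} {int(m)+1} 1 {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        if len(topology.bonds):
            fh.write("\nBonds\n\n")
            for b, (ij, sp) in enumerate(
                zip(topology.bonds, topology.bond_species), start=1
            ):
                fh.write(f"{b} {int(sp)+1} {int(ij[0])+1} {int(ij[1])+1}\n")
        if len(topology.angles):
            fh.write("\nAngles\n\n")
            for t, tri in enumerate(topology.angles, start=1):
                fh.write(f"{t} {t} {int(tri[0])+1} {int(tri[1])+1} {int(tri[2])+1}\n")


def write_crosslinks(path, topology: Topology, system: ParticleSystem) -> None:
    """Freeze the inserted cross-link set as a plain-text table."""
    rows = []
    for (i, j), sp in zip(topology.bonds, topology.bond_species):
        if int(sp) < 2:  # backbone/extension bonds are structural
            continue
        rows.append(
            {
                "species": SPECIES_NAMES[int(sp)],
                "bead_i": int(i),
                "bead_j": int(j),
                "mol_i": int(system.molecule_id[i]),
                "mol_j": int(system.molecule_id[j]),
            }
        )
    pd.DataFrame(rows, columns=["species", "bead_i", "bead_j", "mol_i", "mol_j"]).to_csv(
        path, sep="\t", index=False
    )


def read_crosslinks(path, topology: Topology) -> Topology:
    """Re-apply a frozen cross-link table to a pristine topology."""
    df = pd.read_csv(path, sep="\t")
    topo = topology.copy()
    for name, grp in df.groupby("species", sort=False):
        sp = SPECIES_NAMES.index(name)
        topo.add_bonds(grp[["bead_i", "bead_j"]].to_numpy(), sp)
    return topo


def archive_run(outdir, result, config: dict | None = None) -> Path:
    """Write series/events/census/summary (+ manifest) for one run."""
    from . import __version__
    from .mechanics import summarize, terminal_broken_fractions

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.series.to_dataframe().to_csv(out / "series.csv", index=False)
    pd.DataFrame(
        [
            {
                "step": ev.step,
                "time_fs": ev.time_fs,
                "bond": ev.bond,
                "species": ev.species_name,
                "separation_A": ev.separation,
                "strain": ev.strain,
            }
            for ev in result.events
        ]
    ).to_csv(out / "events.csv", index=False)

    metrics = summarize(result.series.strain, result.series.stress)
    metrics.broken_fractions = terminal_broken_fractions(result.topology)
    summary = metrics.to_dict()
    summary["census"] = result.census
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    manifest = {
        "package_version": __version__,
        "stages": result.stages,
        "config": config or {},
        "n_beads": int(result.system.n_beads),
        "n_molecules": int(result.system.n_molecules),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out
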