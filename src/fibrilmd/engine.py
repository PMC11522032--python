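"""Minimization, equilibration and steered tensile testing.

The integration scheme is velocity Verlet with a Langevin thermostat
(impulsive Ornstein–Uhlenbeck velocity update applied every
``thermostat_interval`` steps to non-clamp beads).  The two clamp groups are
kinematic rigid bodies: held at fixed separation during equilibration and
displaced symmetrically along the fibril axis at the prescribed speed during
the tensile test, while the net force the rest of the system exerts on them
is recorded as the load signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import kernels
from .builder import ParticleSystem, Topology
from .forcefield import (
    ForceFieldParams,
    SPECIES_NAMES,
    _lj_energy,
    _lj_force,
)
from .mechanics import MechanicsSeries, compute_bond_type_forces, compute_eps_tc
from .units import KB, KCAL_TO_AMU_A2_FS2

log = logging.getLogger(__name__)


@dataclass
class Protocol:
    """Thermodynamic state and loading schedule of one run."""

    temperature: float = 300.0  # K
    equil_timestep: float = 10.0  # fs
    equil_duration: float = 1.0e5  # fs
    reequil_duration: float = 5.0e4  # fs
    tensile_timestep: float = 1.0  # fs
    pulling_speed: float = 1.0e-4  # Å/fs of clamp separation (= 10 m/s)
    damping: float = 1000.0  # fs, Langevin relaxation time
    thermostat_interval: int = 10  # steps between OU velocity updates
    skin: float = 6.0  # Å, neighbor-list skin
    sample_interval: float = 2000.0  # fs between recorded samples
    max_strain: float = 1.0
    stop_fraction: float = 0.05  # stop when σ < fraction × running peak
    seed: int = 0
    deterministic: bool = True

    def validate(self) -> None:
        if self.equil_timestep <= 0 or self.tensile_timestep <= 0:
            raise ValueError("timesteps must be positive")
        if self.pulling_speed < 0:
            raise ValueError("pulling speed must be non-negative")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


@dataclass
class BreakEvent:
    """One bond-rupture record (first crossing of r_break)."""

    step: int
    time_fs: float
    bond: int
    species: int
    separation: float
    strain: float

    @property
    def species_name(self) -> str:
        return SPECIES_NAMES[self.species]


class PackedModel:
    """System + topology + parameters packed into kernel-ready arrays."""

    def __init__(
        self,
        system: ParticleSystem,
        topology: Topology,
        params: ForceFieldParams,
        skin: float = 6.0,
    ):
        self.system = system
        self.topology = topology
        self.params = params
        self.skin = float(skin)

        self.pos = np.ascontiguousarray(system.positions, dtype=np.float64).copy()
        self.vel = np.ascontiguousarray(system.velocities, dtype=np.float64).copy()
        self.masses = np.ascontiguousarray(system.masses, dtype=np.float64)
        self.clamp_member = system.clamp_group.astype(np.int64)
        self.free = self.clamp_member < 0
        self.n = len(self.pos)

        self.bonds = topology.bonds.astype(np.int64).reshape(-1, 2)
        self.bspec = topology.bond_species.astype(np.int64)
        self.bstate = topology.bond_state.astype(np.int64)
        arr = params.bond_arrays()
        self.b_r0 = arr["r0"]
        self.b_r1 = arr["r1"]
        self.b_rb = arr["r_break"]
        self.b_k0 = arr["k0"]
        self.b_k1 = arr["k1"]
        self.b_a = arr["a"]

        self.angles = topology.angles.astype(np.int64).reshape(-1, 3)
        self.phi0_rad = np.deg2rad(topology.phi0_deg.astype(np.float64))
        self.kb_eff = params.angle.convention_factor * params.angle.k_b

        pair = params.pair
        self.eps = pair.epsilon
        self.sig = pair.sigma
        self.r_core = pair.r_core
        self.f_core = float(_lj_force(np.asarray(pair.r_core), pair))
        self.e_shift = pair.energy_shift
        self.e_core = float(_lj_energy(np.asarray(pair.r_core), pair)) - self.e_shift
        self.rc = pair.cutoff
        self.rc2 = self.rc**2
        self.rlist = self.rc + self.skin
        self.rlist2 = self.rlist**2

        if len(self.bonds):
            i = np.minimum(self.bonds[:, 0], self.bonds[:, 1])
            j = np.maximum(self.bonds[:, 0], self.bonds[:, 1])
            self.excl_keys = np.sort(i * self.n + j)
        else:
            self.excl_keys = np.empty(0, dtype=np.int64)

        cap = max(64 * self.n, 4096)
        self.pair_i = np.empty(cap, dtype=np.int64)
        self.pair_j = np.empty(cap, dtype=np.int64)
        self.n_pairs = np.zeros(1, dtype=np.int64)
        self.ref_pos = self.pos.copy()
        self.forces = np.zeros_like(self.pos)

        # bonded chains (backbone + extension bonds) for the profile-unbiased
        # thermostat: axial damping is taken relative to each chain's mean
        # axial velocity during steered pulling
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        struct = self.bonds[self.bspec <= 1]
        if len(struct):
            m = coo_matrix(
                (np.ones(len(struct)), (struct[:, 0], struct[:, 1])),
                shape=(self.n, self.n),
            )
            self.n_chains, labels = connected_components(m, directed=False)
            self.chain_id = labels.astype(np.int64)
        else:
            self.n_chains = self.n
            self.chain_id = np.arange(self.n, dtype=np.int64)

        nb = max(len(self.bonds), 1)
        self.ev_step = np.zeros(nb, dtype=np.int64)
        self.ev_bond = np.zeros(nb, dtype=np.int64)
        self.ev_r = np.zeros(nb)
        self.ev_n = np.zeros(1, dtype=np.int64)
        self._events_drained = 0
        self.global_step = 0

        self.rebuild_neighbors()
        self.energies = self.compute_forces()

    # -- force/energy -----------------------------------------------------
    def rebuild_neighbors(self) -> None:
        while True:
            cnt = kernels.build_neighbors(
                self.pos, self.rlist2, self.excl_keys, self.pair_i, self.pair_j
            )
            if cnt >= 0:
                self.n_pairs[0] = cnt
                self.ref_pos[:] = self.pos
                return
            cap = 2 * len(self.pair_i)
            self.pair_i = np.empty(cap, dtype=np.int64)
            self.pair_j = np.empty(cap, dtype=np.int64)

    def compute_forces(self) -> tuple[float, float, float]:
        """Fill ``self.forces``; returns (E_bond, E_angle, E_pair)."""
        return kernels.compute_forces(
            self.pos, self.forces, self.bonds, self.bspec, self.bstate,
            self.b_r0, self.b_r1, self.b_rb, self.b_k0, self.b_k1, self.b_a,
            self.angles, self.phi0_rad, self.kb_eff,
            self.eps, self.sig, self.r_core, self.f_core, self.e_core,
            self.rc2, self.e_shift,
            self.pair_i, self.pair_j, self.n_pairs[0],
            self.global_step, self.ev_step, self.ev_bond, self.ev_r, self.ev_n,
        )

    def potential_energy(self) -> float:
        return float(sum(self.compute_forces()))

    def kinetic_energy(self) -> float:
        """Kinetic energy of free beads, kcal/mol."""
        v2 = np.sum(self.vel[self.free] ** 2, axis=1)
        return float(0.5 * np.sum(self.masses[self.free] * v2) / KCAL_TO_AMU_A2_FS2)

    def kinetic_temperature(self) -> float:
        nf = int(self.free.sum())
        if nf == 0:
            return 0.0
        return 2.0 * self.kinetic_energy() / (3.0 * nf * KB)

    # -- dynamics ----------------------------------------------------------
    def run(
        self,
        n_steps: int,
        dt: float,
        gamma: float,
        temperature: float,
        clamp_speed: float,
        seed: int,
        thermostat_interval: int = 10,
    ) -> None:
        """Advance ``n_steps``; raises on integrator failure."""
        kbt_u = KB * temperature * KCAL_TO_AMU_A2_FS2
        clamp_vx = np.array([-0.5 * clamp_speed, 0.5 * clamp_speed])
        remaining = n_steps
        attempt = 0
        steps_done = np.zeros(1, dtype=np.int64)
        while remaining > 0:
            status = kernels.run_block(
                self.pos, self.vel, self.masses, self.clamp_member, clamp_vx,
                self.bonds, self.bspec, self.bstate,
                self.b_r0, self.b_r1, self.b_rb, self.b_k0, self.b_k1, self.b_a,
                self.angles, self.phi0_rad, self.kb_eff,
                self.eps, self.sig, self.r_core, self.f_core, self.e_core,
                self.rc2, self.e_shift,
                self.excl_keys, self.pair_i, self.pair_j, self.n_pairs,
                self.ref_pos, self.rlist2, self.skin, self.forces,
                dt, gamma, kbt_u, thermostat_interval,
                (seed + 7919 * attempt) & 0x7FFFFFFF,
                remaining, self.global_step,
                self.ev_step, self.ev_bond, self.ev_r, self.ev_n,
                steps_done,
                self.chain_id, self.n_chains, clamp_speed > 0.0,
            )
            done = int(steps_done[0])
            self.global_step += done
            remaining -= done
            if status == kernels.OK:
                break
            if status == kernels.NEIGHBOR_OVERFLOW:
                attempt += 1
                self.rebuild_neighbors()
                continue
            if status == kernels.STEP_TOO_LARGE:
                raise RuntimeError(
                    "per-step displacement exceeded half the neighbor skin; "
                    "the timestep is too large for this system"
                )
            raise RuntimeError("non-finite state encountered during integration")
        self.energies = self.compute_forces()

    def drain_events(self, dt: float, strain_fn) -> list[BreakEvent]:
        """Convert newly recorded kernel break records into BreakEvents."""
        out = []
        for k in range(self._events_drained, int(self.ev_n[0])):
            step = int(self.ev_step[k])
            b = int(self.ev_bond[k])
            out.append(
                BreakEvent(
                    step=step,
                    time_fs=step * dt,
                    bond=b,
                    species=int(self.bspec[b]),
                    separation=float(self.ev_r[k]),
                    strain=float(strain_fn(step)),
                )
            )
        self._events_drained = int(self.ev_n[0])
        return out

    # -- observables -------------------------------------------------------
    def clamp_axial_force(self) -> tuple[float, float]:
        """Net axial force exerted by the system on each clamp group."""
        f0 = float(np.sum(self.forces[self.clamp_member == 0, 0]))
        f1 = float(np.sum(self.forces[self.clamp_member == 1, 0]))
        return f0, f1

    def clamp_separation(self) -> float:
        x0 = float(np.mean(self.pos[self.clamp_member == 0, 0]))
        x1 = float(np.mean(self.pos[self.clamp_member == 1, 0]))
        return x1 - x0

    # -- sync back ---------------------------------------------------------
    def writeback(self) -> tuple[ParticleSystem, Topology]:
        system = self.system.copy()
        system.positions = self.pos.copy()
        system.velocities = self.vel.copy()
        topo = self.topology.copy()
        topo.bond_state = self.bstate.astype(np.int8)
        return system, topo


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------


def minimize(
    system: ParticleSystem,
    topology: Topology,
    params: ForceFieldParams,
    ftol: float = 1e-3,
    max_sd_steps: int = 200,
    max_cg_steps: int = 300,
) -> tuple[ParticleSystem, dict]:
    """Relax the system: steepest descent, then conjugate gradients.

    Clamp beads are held fixed.  Returns the relaxed system and an info dict
    with initial/final energies and iteration counts.
    """
    from scipy.optimize import minimize as scipy_minimize

    pk = PackedModel(system, topology, params)
    free = np.nonzero(pk.free)[0]
    e0 = pk.potential_energy()
    if not np.isfinite(e0):
        bead = int(np.argmax(~np.isfinite(pk.forces).all(axis=1)))
        raise RuntimeError(f"non-finite energy at start of minimization (bead {bead})")
    info = {"e_initial": e0, "sd_steps": 0, "cg_iterations": 0}

    if free.size == 0:
        info["e_final"] = e0
        sysout, _ = pk.writeback()
        return sysout, info

    # steepest descent with adaptive step
    alpha = 1e-4
    e_prev = e0
    sd = 0
    for _ in range(max_sd_steps):
        pk.compute_forces()
        fmax = float(np.max(np.abs(pk.forces[free])))
        if fmax < ftol:
            break
        trial = pk.pos.copy()
        trial[free] += alpha * pk.forces[free]
        saved = pk.pos.copy()
        pk.pos[:] = trial
        pk.rebuild_neighbors()
        e_new = pk.potential_energy()
        if np.isfinite(e_new) and e_new <= e_prev:
            e_prev = e_new
            alpha = min(alpha * 1.25, 0.05)
        else:
            pk.pos[:] = saved
            pk.rebuild_neighbors()
            alpha *= 0.5
            if alpha < 1e-12:
                break
        sd += 1
    info["sd_steps"] = sd

    def fun(x):
        pk.pos[free] = x.reshape(-1, 3)
        pk.rebuild_neighbors()
        e = pk.potential_energy()
        g = -pk.forces[free].ravel()
        return e, g

    res = scipy_minimize(
        fun,
        pk.pos[free].ravel(),
        jac=True,
        method="CG",
        options={"maxiter": max_cg_steps, "gtol": ftol},
    )
    if np.isfinite(res.fun) and res.fun <= e_prev:
        pk.pos[free] = res.x.reshape(-1, 3)
        info["cg_iterations"] = int(res.nit)
        info["e_final"] = float(res.fun)
    else:
        info["e_final"] = e_prev
    pk.rebuild_neighbors()
    sysout, _ = pk.writeback()
    sysout.velocities[:] = 0.0
    return sysout, info


# ---------------------------------------------------------------------------
# dynamics drivers
# ---------------------------------------------------------------------------


def _maxwell_boltzmann(pk: PackedModel, temperature: float, seed: int) -> None:
    rng = np.random.default_rng(seed)
    sd = np.sqrt(KB * temperature * KCAL_TO_AMU_A2_FS2 / pk.masses)
    pk.vel[:] = rng.standard_normal(pk.vel.shape) * sd[:, None]
    pk.vel[~pk.free] = 0.0


def integrate(
    system: ParticleSystem,
    topology: Topology,
    params: ForceFieldParams,
    protocol: Protocol,
    n_steps: int,
    dt: float | None = None,
    thermostat: bool = True,
    init_velocities: bool = False,
) -> tuple[ParticleSystem, Topology, dict]:
    """Plain NVT (or NVE with ``thermostat=False``) dynamics with clamps held.

    Returns the advanced system/topology and an info dict with the kinetic
    temperature history sampled every ``protocol.sample_interval``.
    """
    protocol.validate()
    dt = float(dt if dt is not None else protocol.equil_timestep)
    pk = PackedModel(system, topology, params, skin=protocol.skin)
    if init_velocities:
        _maxwell_boltzmann(pk, protocol.temperature, protocol.seed)
    gamma = 1.0 / protocol.damping if thermostat else 0.0
    block = max(int(round(protocol.sample_interval / dt)), 1)
    temps, e_tot = [], []
    done = 0
    bi = 0
    while done < n_steps:
        todo = min(block, n_steps - done)
        pk.run(
            todo, dt, gamma, protocol.temperature, 0.0,
            seed=(protocol.seed + 1000003 * bi) & 0x7FFFFFFF,
            thermostat_interval=protocol.thermostat_interval,
        )
        done += todo
        bi += 1
        temps.append(pk.kinetic_temperature())
        e_tot.append(pk.kinetic_energy() + sum(pk.energies))
    sysout, topoout = pk.writeback()
    sysout.equilibrated = True
    events = pk.drain_events(dt, lambda s: 0.0)
    info = {
        "temperature_series": np.array(temps),
        "total_energy_series": np.array(e_tot),
        "events": events,
        "dt": dt,
        "n_steps": n_steps,
    }
    return sysout, topoout, info


def equilibrate(
    system: ParticleSystem,
    topology: Topology,
    params: ForceFieldParams,
    protocol: Protocol,
    duration: float | None = None,
) -> tuple[ParticleSystem, Topology, dict]:
    """NVT equilibration at the protocol temperature with clamps held."""
    duration = float(duration if duration is not None else protocol.equil_duration)
    n_steps = max(int(round(duration / protocol.equil_timestep)), 1)
    return integrate(
        system, topology, params, protocol, n_steps,
        dt=protocol.equil_timestep, thermostat=True,
        init_velocities=not system.equilibrated,
    )


def tensile_test(
    system: ParticleSystem,
    topology: Topology,
    params: ForceFieldParams,
    protocol: Protocol,
) -> tuple[MechanicsSeries, list[BreakEvent], ParticleSystem, Topology]:
    """Steered tensile test: displace the clamps apart at constant speed.

    Engineering strain is the relative change of clamp separation from the
    start of pulling; the load signal is the mean of the two clamp axial
    force magnitudes.  The run stops when the smoothed stress falls below
    ``stop_fraction`` of its running peak, or at ``max_strain``.
    """
    protocol.validate()
    dt = protocol.tensile_timestep
    v = protocol.pulling_speed
    pk = PackedModel(system, topology, params, skin=protocol.skin)
    if not np.any(pk.vel):
        _maxwell_boltzmann(pk, protocol.temperature, protocol.seed)
    gamma = 1.0 / protocol.damping
    d0 = pk.clamp_separation()
    if d0 <= 0:
        raise ValueError("system has no usable clamp groups")
    area = float(system.meta.get("area", 1.0))
    r0_tc = params.law(0).r0

    block = max(int(round(protocol.sample_interval / dt)), 1)
    if v > 0:
        max_steps = int(np.ceil(protocol.max_strain * d0 / v / dt))
    else:
        max_steps = 50 * block  # zero-speed control runs: fixed duration
    rows: dict[str, list] = {k: [] for k in (
        "time_fs", "strain", "clamp_force", "f_tc", "f_ecl", "f_age",
        "eps_tc", "broken_tc", "broken_ecl", "broken_age")}
    peak = 0.0
    recent: list[float] = []
    done = 0
    bi = 0
    while done < max_steps:
        todo = min(block, max_steps - done)
        pk.run(
            todo, dt, gamma, protocol.temperature, v,
            seed=(protocol.seed + 2000003 * bi + 1) & 0x7FFFFFFF,
            thermostat_interval=protocol.thermostat_interval,
        )
        done += todo
        bi += 1
        strain = (pk.clamp_separation() - d0) / d0
        f0, f1 = pk.clamp_axial_force()
        # signed tension, averaged over both clamps: under tension the system
        # pulls the left clamp toward +x (f0 > 0) and the right toward −x
        force = 0.5 * (f0 - f1)
        tf = compute_bond_type_forces(pk.pos, _topo_view(pk), params)
        rows["time_fs"].append(done * dt)
        rows["strain"].append(strain)
        rows["clamp_force"].append(force)
        rows["f_tc"].append(tf["tc"])
        rows["f_ecl"].append(tf["ecl"])
        rows["f_age"].append(tf["age"])
        rows["eps_tc"].append(compute_eps_tc(pk.pos, _topo_view(pk), r0_tc))
        for key, specs in (("broken_tc", (0,)), ("broken_ecl", (2, 3)), ("broken_age", (4,))):
            rows[key].append(int(np.sum((np.isin(pk.bspec, specs)) & (pk.bstate >= 1))))

        # stopping: smoothed stress below stop_fraction of the running peak
        recent.append(force)
        if len(recent) > 25:
            recent.pop(0)
        sm = float(np.mean(recent))
        peak = max(peak, sm)
        if strain > 0.05 and peak > 0 and sm < protocol.stop_fraction * peak:
            break

    strain_fn = lambda s: (v * dt * s) / d0  # noqa: E731  (kinematic clamps)
    events = pk.drain_events(dt, strain_fn)
    sysout, topoout = pk.writeback()
    series = MechanicsSeries(
        time_fs=np.array(rows["time_fs"]),
        strain=np.array(rows["strain"]),
        clamp_force=np.array(rows["clamp_force"]),
        stress=np.array(rows["clamp_force"]) / area,
        f_tc=np.array(rows["f_tc"]),
        f_ecl=np.array(rows["f_ecl"]),
        f_age=np.array(rows["f_age"]),
        eps_tc=np.array(rows["eps_tc"]),
        broken_tc=np.array(rows["broken_tc"]),
        broken_ecl=np.array(rows["broken_ecl"]),
        broken_age=np.array(rows["broken_age"]),
        meta={
            "area": area,
            "d0": d0,
            "dt": dt,
            "pulling_speed": v,
            "seed": protocol.seed,
        },
    )
    return series, events, sysout, topoout


def _topo_view(pk: PackedModel) -> Topology:
    """Lightweight Topology view over the packed (live) bond state."""
    return Topology(
        bonds=pk.bonds,
        bond_species=pk.bspec.astype(np.int8),
        bond_state=pk.bstate.astype(np.int8),
        angles=pk.angles,
        phi0_deg=np.rad2deg(pk.phi0_rad),
    )


# ---------------------------------------------------------------------------
# full protocol
# ---------------------------------------------------------------------------


@dataclass
class RunResult:
    """Everything one protocol run produces."""

    system: ParticleSystem
    topology: Topology
    series: MechanicsSeries
    events: list
    census: dict
    stages: list = field(default_factory=list)


def run_protocol(
    spec,
    crosslink_config,
    protocol: Protocol,
    params: ForceFieldParams | None = None,
) -> RunResult:
    """Execute the full pipeline: build → minimize → equilibrate →
    cross-link → re-equilibrate → tensile test."""
    from .builder import build_fibril
    from .crosslinker import crosslink_census, insert_ages, insert_ecl

    params = params or ForceFieldParams.default()
    stages = []

    system, topology = build_fibril(spec, params)
    stages.append("build")

    system, info = minimize(system, topology, params)
    stages.append("minimize")
    log.info("minimization: E %.1f → %.1f kcal/mol", info["e_initial"], info["e_final"])

    system, topology, info = equilibrate(system, topology, params, protocol)
    stages.append("equilibrate")
    log.info("equilibration: <T> = %.1f K", float(np.mean(info["temperature_series"])))

    rng = np.random.default_rng(crosslink_config.seed)
    topology, rep_ecl = insert_ecl(system, topology, crosslink_config, rng)
    topology, rep_age = insert_ages(system, topology, crosslink_config, rng)
    stages.append("crosslink")
    log.info("cross-links: %d ECL, %d AGE", rep_ecl.inserted, rep_age.inserted)

    system, topology, _ = equilibrate(
        system, topology, params, protocol, duration=protocol.reequil_duration
    )
    stages.append("re-equilibrate")

    census = crosslink_census(topology, system.n_molecules)
    series, events, system, topology = tensile_test(system, topology, params, protocol)
    stages.append("tensile")

    return RunResult(
        system=system,
        topology=topology,
        series=series,
        events=events,
        census=census,
        stages=stages,
    )
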