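"""Molecular dynamics: velocity-Verlet integration with optional Berendsen
weak-coupling temperature control and an orthorhombic periodic box.

Units: positions Angstrom, time fs, velocities A/fs, energies kcal/mol,
masses amu.  The acceleration conversion is a = F/m * KCAL_CONV with
KCAL_CONV = 4.184e-4 (kcal/mol per amu A^2/fs^2), and kB =
0.0019872041 kcal/(mol K).  Degrees of freedom: 3N - 3 (centre-of-mass
momentum is removed at start-up; no constraint algorithms).

The Berendsen thermostat rescales velocities after each update by
``lambda = sqrt(1 + (dt/tau) (T0/T - 1))``; in the tau -> infinity limit the
trajectory reduces bitwise to the unthermostatted one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forcefield import NonbondedSettings, ParameterSet, energy_and_gradient
from .molsys import ATOMIC_MASSES, MolecularSystem, Topology

__all__ = [
    "KB", "KCAL_CONV", "MDOptions", "MDState", "Trajectory", "BlowUpError",
    "initialize_velocities", "berendsen_lambda", "md_step", "run_md",
    "kinetic_energy", "temperature",
]

KB = 0.0019872041       # kcal/(mol K)
KCAL_CONV = 4.184e-4    # kcal/mol per (amu A^2 / fs^2)


class BlowUpError(RuntimeError):
    pass


@dataclass
class MDOptions:
    dt: float = 1.0            # fs
    n_steps: int = 1000
    T0: float = 300.0          # K
    tau: float = 100.0         # fs, Berendsen coupling time
    thermostat: bool = True
    seed: int = 0
    report_interval: int = 10

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.thermostat and self.tau < self.dt:
            raise ValueError("tau must be >= dt when the thermostat is on")


@dataclass
class MDState:
    positions: np.ndarray      # (N, 3) A
    velocities: np.ndarray     # (N, 3) A/fs
    kinetic: float = 0.0       # kcal/mol
    potential: float = 0.0     # kcal/mol
    temperature: float = 0.0   # K

    @property
    def total_energy(self) -> float:
        return self.kinetic + self.potential


@dataclass
class Trajectory:
    frames: list[tuple[int, MDState]] = field(default_factory=list)

    def append(self, step: int, state: MDState) -> None:
        if self.frames and step <= self.frames[-1][0]:
            raise ValueError("trajectory steps must be strictly increasing")
        self.frames.append((step, MDState(
            positions=state.positions.copy(), velocities=state.velocities.copy(),
            kinetic=state.kinetic, potential=state.potential,
            temperature=state.temperature)))

    def energy_log(self) -> str:
        """TSV log: step, kinetic, potential, total, temperature."""
        lines = ["# step\tKE\tPE\tE\tT"]
        for step, s in self.frames:
            lines.append(f"{step}\t{s.kinetic:.6f}\t{s.potential:.6f}"
                         f"\t{s.total_energy:.6f}\t{s.temperature:.3f}")
        return "\n".join(lines) + "\n"


def masses_of(system: MolecularSystem) -> np.ndarray:
    try:
        return np.array([ATOMIC_MASSES[a.element] for a in system.atoms])
    except KeyError as exc:
        raise ValueError(f"no mass for element {exc}") from None


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    return float(0.5 * np.sum(masses[:, None] * velocities ** 2) / KCAL_CONV)


def temperature(velocities: np.ndarray, masses: np.ndarray, ndof: int | None = None) -> float:
    n = len(masses)
    if ndof is None:
        ndof = max(3 * n - 3, 1)
    return 2.0 * kinetic_energy(velocities, masses) / (ndof * KB)


def initialize_velocities(system: MolecularSystem, T0: float, seed: int = 0) -> np.ndarray:
    """Maxwell-Boltzmann velocities at T0 with centre-of-mass momentum
    removed; deterministic under a fixed seed."""
    if T0 < 0:
        raise ValueError("temperature must be non-negative")
    m = masses_of(system)
    n = len(m)
    if T0 == 0:
        return np.zeros((n, 3))
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB * T0 * KCAL_CONV / m)   # A/fs per component
    v = rng.normal(size=(n, 3)) * sigma[:, None]
    if n > 1:
        v -= np.sum(m[:, None] * v, axis=0) / np.sum(m)
    return v


def berendsen_lambda(T: float, T0: float, dt_over_tau: float) -> float:
    """Velocity scaling factor sqrt(1 + (dt/tau)(T0/T - 1))."""
    if T <= 0 or dt_over_tau == 0.0:
        return 1.0   # tau -> infinity reduces exactly to no thermostat
    return math.sqrt(max(1.0 + dt_over_tau * (T0 / T - 1.0), 0.0))


def md_step(state: MDState, force_fun, masses: np.ndarray, options: MDOptions,
            forces: np.ndarray | None = None, step: int = 0,
            ndof: int | None = None) -> tuple[MDState, np.ndarray]:
    """One velocity-Verlet step; returns the new state and the forces at the
    new positions (reusable for the next step)."""
    dt = options.dt
    if forces is None:
        _, forces = force_fun(state.positions)
    a = forces / masses[:, None] * KCAL_CONV
    v_half = state.velocities + 0.5 * dt * a
    x_new = state.positions + dt * v_half
    if not np.all(np.isfinite(x_new)):
        raise BlowUpError(f"non-finite coordinates at step {step}")
    pot, f_new = force_fun(x_new)
    a_new = f_new / masses[:, None] * KCAL_CONV
    v_new = v_half + 0.5 * dt * a_new
    if options.thermostat:
        T = temperature(v_new, masses, ndof)
        v_new = v_new * berendsen_lambda(T, options.T0, dt / options.tau)
    ke = kinetic_energy(v_new, masses)
    T = temperature(v_new, masses, ndof)
    return MDState(positions=x_new, velocities=v_new, kinetic=ke,
                   potential=pot, temperature=T), f_new


def run_md(system: MolecularSystem, topology: Topology, params: ParameterSet,
           settings: NonbondedSettings | None = None,
           options: MDOptions | None = None,
           velocities: np.ndarray | None = None) -> Trajectory:
    """Integrate the system for ``options.n_steps`` steps and return snapshot
    frames every ``report_interval`` steps (plus the initial state)."""
    if options is None:
        options = MDOptions()
    masses = masses_of(system)
    ndof = max(3 * len(masses) - 3, 1)

    def force_fun(x):
        rep, grad = energy_and_gradient(system, topology, params, settings, coords=x)
        return rep.total, -grad

    if velocities is None:
        velocities = initialize_velocities(system, options.T0, options.seed)
    pot, forces = force_fun(system.coords())
    state = MDState(positions=system.coords(), velocities=velocities,
                    kinetic=kinetic_energy(velocities, masses), potential=pot,
                    temperature=temperature(velocities, masses, ndof))
    traj = Trajectory()
    traj.append(0, state)
    for step in range(1, options.n_steps + 1):
        state, forces = md_step(state, force_fun, masses, options,
                                forces=forces, step=step, ndof=ndof)
        if step % options.report_interval == 0 or step == options.n_steps:
            traj.append(step, state)
    return traj


def write_xyz_frames(system: MolecularSystem, traj: Trajectory) -> str:
    """Multi-frame XYZ text for a trajectory."""
    from .molsys import write_xyz
    chunks = []
    saved = system.coords()
    try:
        for step, s in traj.frames:
            system.set_coords(s.positions)
            chunks.append(write_xyz(system, comment=f"step {step} E={s.total_energy:.6f}"))
    finally:
        system.set_coords(saved)
    return "".join(chunks)
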