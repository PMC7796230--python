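"""Replica exchange over a solute-temperature ladder.

All replicas share one bath temperature T0; replica *m* propagates under the
solute-tempered potential E_m with a BAOAB-discretized Langevin integrator
thermostatted at T0.  Neighbor exchanges are attempted at a fixed interval
with deterministic even/odd pair alternation; for configurations X_a at rung
m and X_b at rung n the Metropolis argument is

    Δ = β0 · [E_m(X_b) + E_n(X_a) − E_m(X_a) − E_n(X_b)],

accepted with probability min(1, e^{−Δ}).  Velocities are resampled from the
bath Maxwell–Boltzmann distribution after an accepted exchange (all rungs
share T0, so rescaling would be a no-op).

Randomness: one stream per replica (it follows the replica through
exchanges) plus one stream for the exchange coin, all spawned from the run
seed, so identical seeds give bitwise-identical logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB, KCAL_PER_MOL_IN_AMU_A2_FS2, LADDER_RBP12
from .energy import (
    DEFAULT_SCALED_CLASSES,
    SoluteTemperatureState,
    decompose_energy,
    energy_and_forces,
    pair_scale_arrays,
)
from .errors import IntegrationError, ValidationError
from .structure import Trajectory
from .toy import reference_conformation

__all__ = [
    "ReplicaLadder",
    "ExchangeLog",
    "ExchangeStats",
    "RunConfig",
    "make_ladder",
    "rbp_ladder",
    "GrestPotential",
    "DoubleWell1D",
    "maxwell_boltzmann_velocities",
    "langevin_step",
    "exchange_delta",
    "run_replica_exchange",
    "run_remd",
    "exchange_statistics",
    "energy_overlap_histograms",
]

_CONV = KCAL_PER_MOL_IN_AMU_A2_FS2


@dataclass(frozen=True)
class ReplicaLadder:
    """Ordered solute temperatures (K) sharing one bath temperature."""

    temperatures: tuple
    bath_temperature: float = 300.0
    scheme: str = "explicit"

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if t.size < 2:
            raise ValidationError("a ladder needs at least two rungs")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("ladder temperatures must be strictly "
                                  "increasing")
        if t[0] < self.bath_temperature:
            raise ValidationError("first rung must be >= bath temperature")

    def __len__(self) -> int:
        return len(self.temperatures)

    def states(self):
        return [SoluteTemperatureState(t, self.bath_temperature)
                for t in self.temperatures]


def make_ladder(t_min: float, t_max: float, n: int, scheme: str = "geometric",
                temperatures=None, bath_temperature: float | None = None
                ) -> ReplicaLadder:
    """Geometric ladder Tᵢ = t_min·(t_max/t_min)^{i/(n−1)}, or an explicit
    user list passed through unchanged."""
    bath = bath_temperature if bath_temperature is not None else t_min
    if scheme == "geometric":
        if t_min > t_max or n < 2:
            raise ValidationError("need t_min <= t_max and n >= 2")
        i = np.arange(n)
        temps = t_min * (t_max / t_min) ** (i / (n - 1))
        return ReplicaLadder(tuple(float(t) for t in temps), bath, "geometric")
    if scheme == "explicit":
        if temperatures is None:
            raise ValidationError("explicit scheme requires a temperature list")
        return ReplicaLadder(tuple(float(t) for t in temperatures), bath,
                             "explicit")
    raise ValidationError(f"unknown ladder scheme {scheme!r}")


def rbp_ladder() -> ReplicaLadder:
    """The 12-rung 300.00–550.00 K ladder used for ribose binding protein."""
    return ReplicaLadder(LADDER_RBP12, 300.0, "explicit")


# ---------------------------------------------------------------------------
# tempered potentials
# ---------------------------------------------------------------------------

class GrestPotential:
    """Solute-tempered toy-system potential family over a ladder."""

    def __init__(self, system, solute_atoms, ladder: ReplicaLadder,
                 scaled_classes=DEFAULT_SCALED_CLASSES):
        self.system = system
        self.solute_atoms = tuple(int(a) for a in solute_atoms)
        self.ladder = ladder
        self.scaled_classes = tuple(scaled_classes)
        self.states = ladder.states()
        self.scales = [pair_scale_arrays(system, self.solute_atoms, st,
                                         self.scaled_classes)
                       for st in self.states]
        self.masses = system.masses[:, None]

    def energy_and_forces(self, coords, rung: int):
        return energy_and_forces(self.system, coords, self.scales[rung])

    def energy(self, coords, rung: int) -> float:
        return self.energy_and_forces(coords, rung)[0]

    def decompose(self, coords):
        return decompose_energy(self.system, coords, self.solute_atoms,
                                self.scaled_classes)

    def energy_from_parts(self, decomposition, rung: int) -> float:
        return decomposition.scaled(self.states[rung])

    def initial_coords(self, label: str = "closed"):
        return reference_conformation(self.system, label)


class DoubleWell1D:
    """1-D double well U(x) = h·(x²−1)², fully tempered: E_m = (T0/Tm)·U."""

    def __init__(self, barrier: float, ladder: ReplicaLadder,
                 mass: float = 12.0):
        self.h = barrier
        self.ladder = ladder
        self.states = ladder.states()
        self.masses = np.array([mass])

    def energy_and_forces(self, x, rung: int):
        s = self.states[rung].beta_ratio
        u = self.h * (x ** 2 - 1.0) ** 2
        f = -4.0 * self.h * x * (x ** 2 - 1.0)
        return float(s * np.sum(u)), s * f

    def energy(self, x, rung: int) -> float:
        return self.energy_and_forces(x, rung)[0]

    def initial_coords(self, label: str = "closed"):
        return np.array([-1.0 if label == "closed" else 1.0])


# ---------------------------------------------------------------------------
# Langevin propagator (BAOAB)
# ---------------------------------------------------------------------------

def maxwell_boltzmann_velocities(masses, temperature, rng, shape=None):
    """Velocities in Å/fs drawn from the bath Maxwell–Boltzmann distribution."""
    m = np.asarray(masses, dtype=float)
    shape = shape if shape is not None else m.shape
    sigma = np.sqrt(KB * temperature * _CONV / m)
    return sigma * rng.standard_normal(shape)


def langevin_step(potential, rung, coords, velocities, dt, friction,
                  rng, forces=None):
    """One BAOAB step under the rung's scaled potential at the bath
    temperature.  Returns ``(coords, velocities, forces)``; passing the
    previous step's forces avoids one evaluation."""
    m = potential.masses
    kbt = KB * potential.ladder.bath_temperature * _CONV
    if forces is None:
        _, forces = potential.energy_and_forces(coords, rung)
    if not np.all(np.isfinite(forces)):
        raise IntegrationError(
            f"non-finite force at rung {rung}; frame dump: {coords!r}")
    v = velocities + 0.5 * dt * _CONV * forces / m
    x = coords + 0.5 * dt * v
    if friction > 0:
        c1 = np.exp(-friction * dt)
        v = c1 * v + np.sqrt((1.0 - c1 * c1) * kbt / m) \
            * rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v
    e, f_new = potential.energy_and_forces(x, rung)
    if not np.isfinite(e) or not np.all(np.isfinite(f_new)):
        raise IntegrationError(
            f"non-finite force at rung {rung}; frame dump: {x!r}")
    v = v + 0.5 * dt * _CONV * f_new / m
    return x, v, f_new


# ---------------------------------------------------------------------------
# exchanges
# ---------------------------------------------------------------------------

def exchange_delta(state_m: SoluteTemperatureState,
                   state_n: SoluteTemperatureState,
                   e_m_of_a: float, e_m_of_b: float,
                   e_n_of_a: float, e_n_of_b: float) -> float:
    """Metropolis argument for swapping configurations a (at rung m) and b
    (at rung n); acceptance probability is min(1, e^{−Δ})."""
    if state_m.bath_temperature != state_n.bath_temperature:
        raise ValidationError("rungs must share the bath temperature")
    beta0 = state_m.beta_bath
    return beta0 * (e_m_of_b + e_n_of_a - e_m_of_a - e_n_of_b)


@dataclass
class ExchangeLog:
    """Per-attempt records and the replica → rung time series."""

    attempts: list = field(default_factory=list)   # (step, (m, n), Δ, accepted)
    replica_rungs: np.ndarray | None = None        # (n_attempt_rounds+1, R)
    ladder: ReplicaLadder | None = None

    def acceptance_by_pair(self) -> dict:
        out: dict[tuple, list] = {}
        for _, pair, _, acc in self.attempts:
            out.setdefault(pair, []).append(acc)
        return out


@dataclass(frozen=True)
class ExchangeStats:
    per_pair: dict                 # (m, m+1) -> acceptance ratio or None
    attempts_per_pair: dict
    mean_acceptance: float
    round_trips: int


def exchange_statistics(log: ExchangeLog) -> ExchangeStats:
    """Acceptance ratios per neighbor pair (undefined pairs reported as
    ``None``), their mean, and the number of completed bottom→top→bottom
    round trips summed over replicas."""
    if not log.attempts:
        raise ValidationError("empty exchange log")
    per_pair: dict[tuple, float | None] = {}
    n_per_pair: dict[tuple, int] = {}
    for pair, accs in log.acceptance_by_pair().items():
        n_per_pair[pair] = len(accs)
        per_pair[pair] = float(np.mean(accs)) if accs else None
    defined = [v for v in per_pair.values() if v is not None]
    mean_acc = float(np.mean(defined)) if defined else float("nan")

    round_trips = 0
    if log.replica_rungs is not None and log.replica_rungs.size:
        top = log.replica_rungs.max()
        for series in log.replica_rungs.T:
            stage = 0  # 0: waiting for bottom, 1: climbing, 2: returning
            for rung in series:
                if stage == 0 and rung == 0:
                    stage = 1
                elif stage == 1 and rung == top:
                    stage = 2
                elif stage == 2 and rung == 0:
                    round_trips += 1
                    stage = 1
    return ExchangeStats(per_pair=per_pair, attempts_per_pair=n_per_pair,
                         mean_acceptance=mean_acc, round_trips=round_trips)


# ---------------------------------------------------------------------------
# the main loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Desk-scale run settings (fs, steps)."""

    n_steps: int = 100_000
    dt: float = 15.0                   # fs
    friction: float = 0.002            # fs^-1
    exchange_interval: int = 500       # steps between exchange attempts
    save_interval: int = 100           # steps between saved frames
    seed: int = 0
    initial_state: str = "closed"
    scaled_classes: tuple = DEFAULT_SCALED_CLASSES

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.friction < 0:
            raise ValidationError("need dt > 0 and friction >= 0")


def run_replica_exchange(potential, config: RunConfig):
    """Propagate every rung and attempt alternating even/odd neighbor swaps.

    Returns ``(frames, log)`` where ``frames[m]`` is the array of saved
    configurations at rung m (rung-indexed: analysis uses ``frames[0]``, the
    bottom rung) and ``log`` is the :class:`ExchangeLog`.
    """
    ladder = potential.ladder
    n_rungs = len(ladder)
    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(n_rungs + 1)]
    coin = streams[-1]

    x = [potential.initial_coords(config.initial_state).astype(float)
         for _ in range(n_rungs)]
    replica_at_rung = list(range(n_rungs))
    v = [maxwell_boltzmann_velocities(potential.masses,
                                      ladder.bath_temperature,
                                      streams[replica_at_rung[m]],
                                      shape=x[m].shape)
         for m in range(n_rungs)]
    f = [potential.energy_and_forces(x[m], m)[1] for m in range(n_rungs)]

    frames: list[list] = [[] for _ in range(n_rungs)]
    log = ExchangeLog(ladder=ladder)
    rung_series = [list(range(n_rungs))]
    n_cycles = config.n_steps // config.exchange_interval
    step = 0
    for cycle in range(n_cycles):
        for _ in range(config.exchange_interval):
            for m in range(n_rungs):
                rng = streams[replica_at_rung[m]]
                x[m], v[m], f[m] = langevin_step(
                    potential, m, x[m], v[m], config.dt, config.friction,
                    rng, forces=f[m])
            step += 1
            if step % config.save_interval == 0:
                for m in range(n_rungs):
                    frames[m].append(x[m].copy())
        # alternating even/odd neighbor attempts
        use_parts = hasattr(potential, "decompose")
        decs = [potential.decompose(x[m]) for m in range(n_rungs)] \
            if use_parts else None
        for m in range(cycle % 2, n_rungs - 1, 2):
            n_ = m + 1
            if use_parts:
                e_m_a = potential.energy_from_parts(decs[m], m)
                e_m_b = potential.energy_from_parts(decs[n_], m)
                e_n_a = potential.energy_from_parts(decs[m], n_)
                e_n_b = potential.energy_from_parts(decs[n_], n_)
            else:
                e_m_a = potential.energy(x[m], m)
                e_m_b = potential.energy(x[n_], m)
                e_n_a = potential.energy(x[m], n_)
                e_n_b = potential.energy(x[n_], n_)
            states = potential.states
            delta = exchange_delta(states[m], states[n_],
                                   e_m_a, e_m_b, e_n_a, e_n_b)
            accepted = bool(coin.random() < np.exp(-max(delta, -700.0)))
            log.attempts.append((step, (m, n_), float(delta), accepted))
            if accepted:
                x[m], x[n_] = x[n_], x[m]
                if use_parts:
                    decs[m], decs[n_] = decs[n_], decs[m]
                replica_at_rung[m], replica_at_rung[n_] = \
                    replica_at_rung[n_], replica_at_rung[m]
                for k in (m, n_):
                    v[k] = maxwell_boltzmann_velocities(
                        potential.masses, ladder.bath_temperature,
                        streams[replica_at_rung[k]], shape=x[k].shape)
                    f[k] = potential.energy_and_forces(x[k], k)[1]
        rung_of_replica = np.empty(n_rungs, dtype=int)
        for rung, rep in enumerate(replica_at_rung):
            rung_of_replica[rep] = rung
        rung_series.append(list(rung_of_replica))
    log.replica_rungs = np.asarray(rung_series, dtype=int)
    return [np.asarray(fr) for fr in frames], log


def run_remd(system, solute_region, ladder: ReplicaLadder,
             config: RunConfig):
    """Toy-system front end: returns per-rung :class:`Trajectory` objects
    labeled by solute temperature, and the exchange log."""
    atoms = solute_region.atoms if hasattr(solute_region, "atoms") \
        else solute_region
    potential = GrestPotential(system, atoms, ladder, config.scaled_classes)
    frames, log = run_replica_exchange(potential, config)
    structure = system.to_structure("closed")
    trajs = [Trajectory(coords=frames[m], structure=structure,
                        frame_interval=config.save_interval,
                        label=f"T{ladder.temperatures[m]:.2f}")
             for m in range(len(ladder))]
    return trajs, log


def energy_overlap_histograms(trajectories, potential, bins: int = 40):
    """Normalized per-rung histograms of the rung-evaluated scaled potential
    and the overlap coefficient of neighboring rungs.

    Returns ``(bin_edges, densities, overlaps)``.
    """
    energies = []
    for m, traj in enumerate(trajectories):
        coords = traj.coords if hasattr(traj, "coords") else traj
        energies.append(np.array([potential.energy(c, m) for c in coords]))
    lo = min(e.min() for e in energies)
    hi = max(e.max() for e in energies)
    edges = np.linspace(lo, hi, bins + 1)
    width = edges[1] - edges[0]
    dens = np.array([np.histogram(e, bins=edges, density=True)[0]
                     for e in energies])
    overlaps = np.array([np.minimum(dens[m], dens[m + 1]).sum() * width
                         for m in range(len(dens) - 1)])
    return edges, dens, overlaps
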