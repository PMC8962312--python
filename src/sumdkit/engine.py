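"""Toy Langevin-dynamics backend and the propagator contract.

The supervisor (:mod:`sumdkit.supervisor`) only needs a *propagator*: an
object it can ask to advance by a time span, report its current frame,
reassign velocities from the thermostat, and save/restore its state. Any
MD engine honoring :class:`Propagator` plugs in; the bundled
:class:`ToyLangevinEngine` makes the whole SuMD workflow runnable at desk
scale.

The toy system is a pseudo-ligand — a rigid set of beads propagated as one
Langevin particle at its center of mass — diffusing around a static
pseudo-receptor in a *binding funnel* potential: a Gaussian attraction
basin at the binding site plus a harmonic wall confining the particle to a
sphere (the stand-in for the solvent box).

Integrator: BAOAB Langevin splitting, which is stable at the default
2 fs / 0.1 ps⁻¹ settings and samples the Maxwell–Boltzmann velocity
marginal exactly. Internal energy units are amu·Å²/ps²
(1 kcal/mol = 418.4 amu·Å²/ps²); the public surface speaks kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from numba import njit

from .system_model import Frame, Selection, Topology, center_of_mass

__all__ = [
    "KB_KCAL",
    "KCAL_TO_INTERNAL",
    "PropagatorConfig",
    "FunnelPotential",
    "PropagatorState",
    "Propagator",
    "ToyLangevinEngine",
    "IntegrationError",
    "potential_energy",
    "potential_force",
    "maxwell_boltzmann_velocities",
]

#: Boltzmann constant in kcal/mol/K.
KB_KCAL = 0.0019872041
#: 1 kcal/mol expressed in the internal energy unit amu·Å²/ps².
KCAL_TO_INTERNAL = 418.4
_KB_INT = KB_KCAL * KCAL_TO_INTERNAL  # ≈ 0.83145 amu·Å²/ps²/K


class IntegrationError(RuntimeError):
    """The integrator produced a non-finite coordinate."""


@dataclass(frozen=True)
class PropagatorConfig:
    """Thermostat and integration settings.

    Defaults follow common explicit-solvent practice for this class of
    simulation: 2 fs timestep, 310 K, Langevin friction 0.1 ps⁻¹.
    ``frame_interval_ps`` is the sampling stride for emitted frames;
    ``None`` emits only the final frame of each propagation call.
    """

    timestep_fs: float = 2.0
    temperature: float = 310.0
    friction: float = 0.1
    seed: int = 0
    frame_interval_ps: float | None = None

    def __post_init__(self) -> None:
        if self.timestep_fs <= 0 or self.temperature <= 0 or self.friction <= 0:
            raise ValueError("timestep, temperature and friction must all be positive")

    @property
    def timestep_ps(self) -> float:
        return self.timestep_fs * 1e-3


@dataclass(frozen=True)
class FunnelPotential:
    """Gaussian binding basin plus harmonic spherical confinement.

    ``U(r) = -well_depth · exp(-|r-c|²/(2σ²)) + ½·k·max(0, |r-c|-R)²``
    with c = ``site_center``, σ = ``well_width_sigma``, R =
    ``confinement_radius``, k = ``confinement_k``. Energies kcal/mol,
    lengths Å. ``well_depth = 0`` with ``confinement_k = 0`` gives a free
    particle (flat potential).
    """

    well_depth: float = 8.0
    well_width_sigma: float = 4.0
    site_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    confinement_radius: float = 50.0
    confinement_k: float = 1.0

    def __post_init__(self) -> None:
        if self.well_depth < 0 or self.well_width_sigma <= 0 or self.confinement_k < 0:
            raise ValueError("well_depth/confinement_k must be >= 0 and sigma > 0")

    @classmethod
    def flat(cls) -> "FunnelPotential":
        return cls(well_depth=0.0, confinement_k=0.0)


@dataclass
class PropagatorState:
    """Positions (Å), velocities (Å/ps) and clock (ps) of the propagated particle."""

    positions: np.ndarray
    velocities: np.ndarray
    time: float

    def copy(self) -> "PropagatorState":
        return PropagatorState(self.positions.copy(), self.velocities.copy(), self.time)


def potential_energy(position, potential: FunnelPotential) -> float:
    """Funnel potential energy (kcal/mol) at a point."""
    r = np.asarray(position, dtype=float) - np.asarray(potential.site_center)
    d2 = float(r @ r)
    u = -potential.well_depth * math.exp(-d2 / (2.0 * potential.well_width_sigma**2))
    d = math.sqrt(d2)
    if d > potential.confinement_radius:
        u += 0.5 * potential.confinement_k * (d - potential.confinement_radius) ** 2
    return u


def potential_force(position, potential: FunnelPotential) -> np.ndarray:
    """Analytic force −∇U (kcal/mol/Å) at a point."""
    r = np.asarray(position, dtype=float) - np.asarray(potential.site_center)
    d2 = float(r @ r)
    sig2 = potential.well_width_sigma**2
    f = -potential.well_depth * math.exp(-d2 / (2.0 * sig2)) / sig2 * r
    d = math.sqrt(d2)
    if d > potential.confinement_radius and d > 0:
        f += -potential.confinement_k * (d - potential.confinement_radius) * r / d
    return f


def maxwell_boltzmann_velocities(
    mass: float, temperature: float, rng: np.random.Generator, shape=(3,)
) -> np.ndarray:
    """Velocities (Å/ps) drawn from the Maxwell–Boltzmann distribution."""
    sigma = math.sqrt(_KB_INT * temperature / mass)
    return sigma * rng.standard_normal(shape)


@njit(cache=True)
def _baoab_kernel(
    x, v, n_steps, dt, c1, c2, mass,
    w_int, inv_sig2, cx, cy, cz, rconf, k_int,
    noise, stride, out_positions,
):  # pragma: no cover - exercised through ToyLangevinEngine
    half = 0.5 * dt
    # force at current x, internal units amu·Å/ps²
    def _force(px, py, pz):
        rx, ry, rz = px - cx, py - cy, pz - cz
        d2 = rx * rx + ry * ry + rz * rz
        g = -w_int * math.exp(-0.5 * d2 * inv_sig2) * inv_sig2
        fx, fy, fz = g * rx, g * ry, g * rz
        d = math.sqrt(d2)
        if d > rconf and d > 0.0:
            h = -k_int * (d - rconf) / d
            fx += h * rx
            fy += h * ry
            fz += h * rz
        return fx, fy, fz

    fx, fy, fz = _force(x[0], x[1], x[2])
    sum_vsq = 0.0
    for i in range(n_steps):
        v[0] += half * fx / mass
        v[1] += half * fy / mass
        v[2] += half * fz / mass
        x[0] += half * v[0]
        x[1] += half * v[1]
        x[2] += half * v[2]
        v[0] = c1 * v[0] + c2 * noise[i, 0]
        v[1] = c1 * v[1] + c2 * noise[i, 1]
        v[2] = c1 * v[2] + c2 * noise[i, 2]
        x[0] += half * v[0]
        x[1] += half * v[1]
        x[2] += half * v[2]
        fx, fy, fz = _force(x[0], x[1], x[2])
        v[0] += half * fx / mass
        v[1] += half * fy / mass
        v[2] += half * fz / mass
        sum_vsq += v[0] * v[0] + v[1] * v[1] + v[2] * v[2]
        if stride > 0 and (i + 1) % stride == 0:
            j = (i + 1) // stride - 1
            out_positions[j, 0] = x[0]
            out_positions[j, 1] = x[1]
            out_positions[j, 2] = x[2]
    return sum_vsq


@runtime_checkable
class Propagator(Protocol):
    """The contract the supervisor requires of any MD backend."""

    def propagate(self, duration: float) -> tuple[PropagatorState, list[Frame]]: ...

    def resample_velocities(self) -> None: ...

    def current_frame(self) -> Frame: ...

    def get_state(self) -> PropagatorState: ...

    def set_state(self, state: PropagatorState) -> None: ...


class ToyLangevinEngine:
    """Langevin dynamics of a rigid pseudo-ligand in a binding funnel.

    The ligand selection is propagated as a single particle at its center
    of mass (total mass = sum of selected atom masses unless ``mass`` is
    given); bead offsets are carried rigidly, all other atoms stay fixed.
    One seeded generator drives both the thermostat noise and velocity
    reassignments, so a run is reproducible from (config, seed) alone.
    """

    def __init__(
        self,
        topology: Topology,
        frame: Frame,
        config: PropagatorConfig,
        potential: FunnelPotential,
        ligand: Selection,
        mass: float | None = None,
    ):
        self.topology = topology
        self.config = config
        self.potential = potential
        self.ligand = ligand
        self._lig_idx = ligand.sorted_indices
        self.mass = float(mass if mass is not None else topology.masses[self._lig_idx].sum())
        if self.mass <= 0:
            raise ValueError("ligand mass must be positive")
        self._static = frame.coordinates.copy()
        self._box = None if frame.box_lengths is None else frame.box_lengths.copy()
        com = center_of_mass(frame, ligand, topology)
        self._offsets = frame.coordinates[self._lig_idx] - com
        self.rng = np.random.default_rng(config.seed)
        v0 = maxwell_boltzmann_velocities(self.mass, config.temperature, self.rng)
        self.state = PropagatorState(positions=com.astype(float), velocities=v0, time=frame.time)
        self._vsq_sum = 0.0
        self._vsq_steps = 0

    # -- propagator contract -------------------------------------------------

    def get_state(self) -> PropagatorState:
        return self.state.copy()

    def set_state(self, state: PropagatorState) -> None:
        self.state = state.copy()

    def resample_velocities(self) -> None:
        """Redraw velocities from the Maxwell–Boltzmann distribution; positions unchanged."""
        self.state.velocities = maxwell_boltzmann_velocities(
            self.mass, self.config.temperature, self.rng
        )

    def current_frame(self) -> Frame:
        coords = self._static.copy()
        coords[self._lig_idx] = self.state.positions + self._offsets
        return Frame(time=self.state.time, coordinates=coords, box_lengths=self._box)

    def propagate(self, duration: float) -> tuple[PropagatorState, list[Frame]]:
        """Advance by ``duration`` ps; returns the new state and sampled frames.

        ``duration`` must be a positive multiple of the timestep. Frames
        are sampled every ``config.frame_interval_ps`` (default: final
        frame only). Raises :class:`IntegrationError` if a coordinate
        becomes non-finite.
        """
        dt = self.config.timestep_ps
        if duration == 0:
            return self.get_state(), []
        n_steps = int(round(duration / dt))
        if n_steps <= 0 or abs(n_steps * dt - duration) > 1e-9:
            raise ValueError(
                f"duration {duration} ps is not a positive multiple of the "
                f"{self.config.timestep_fs} fs timestep"
            )
        if self.config.frame_interval_ps is None:
            stride = n_steps
        else:
            stride = max(1, int(round(self.config.frame_interval_ps / dt)))
        n_out = n_steps // stride
        out = np.empty((n_out, 3))
        noise = self.rng.standard_normal((n_steps, 3))
        c1 = math.exp(-self.config.friction * dt)
        c2 = math.sqrt((1.0 - c1 * c1) * _KB_INT * self.config.temperature / self.mass)
        pot = self.potential
        x = self.state.positions.copy()
        v = self.state.velocities.copy()
        vsq = _baoab_kernel(
            x, v, n_steps, dt, c1, c2, self.mass,
            pot.well_depth * KCAL_TO_INTERNAL,
            1.0 / pot.well_width_sigma**2,
            pot.site_center[0], pot.site_center[1], pot.site_center[2],
            pot.confinement_radius,
            pot.confinement_k * KCAL_TO_INTERNAL,
            noise, stride, out,
        )
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
            bad = int(np.flatnonzero(~np.isfinite(x))[0]) if not np.all(np.isfinite(x)) else -1
            raise IntegrationError(
                f"non-finite coordinate after {n_steps} steps "
                f"(coordinate axis {bad}, t = {self.state.time:.3f} ps)"
            )
        self._vsq_sum += vsq
        self._vsq_steps += n_steps
        t0 = self.state.time
        frames = []
        for j in range(n_out):
            coords = self._static.copy()
            coords[self._lig_idx] = out[j] + self._offsets
            frames.append(
                Frame(time=t0 + (j + 1) * stride * dt, coordinates=coords, box_lengths=self._box)
            )
        self.state = PropagatorState(positions=x, velocities=v, time=t0 + n_steps * dt)
        return self.get_state(), frames

    # -- diagnostics ---------------------------------------------------------

    def mean_temperature(self) -> float:
        """Time-averaged instantaneous temperature 2·KE/(3·k_B) over all steps so far (K)."""
        if self._vsq_steps == 0:
            raise RuntimeError("no steps propagated yet")
        return self.mass * self._vsq_sum / (self._vsq_steps * 3.0 * _KB_INT)

    def reset_temperature_accumulator(self) -> None:
        self._vsq_sum = 0.0
        self._vsq_steps = 0
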