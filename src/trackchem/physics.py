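"""Discrete (step-by-step) transport of charged particles in liquid water.

Every interaction is a discrete process drawn from tabulated total cross
sections: per-process exponential free paths compete and the shortest wins.
No condensed-history grouping is performed, so nanometer spatial structure
is preserved. The module emits energy deposits, activated-water sites (the
input of the physicochemical stage) and sub-excitation electrons.

Cross sections come from :class:`CrossSectionTable` objects (log-log
interpolated totals plus simple declarative samplers for energy loss and
secondaries). A bundled toy table set makes the full pipeline runnable and
testable without external high-fidelity data; see :func:`toy_tables`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .registry import Registry, default_registry

WATER_MOLAR_MASS = 18.0153  # g/mol

PARTICLE_KINDS = ("electron", "proton", "hydrogen", "He0", "He+", "He++", "generic_ion")
PROCESSES = (
    "elastic",
    "electronic_excitation",
    "ionization",
    "vibrational_excitation",
    "dissociative_attachment",
    "charge_increase",
    "charge_decrease",
)
# permitted charge-exchange transitions along the helium/hydrogen ladder
CHARGE_INCREASE = {"He0": "He+", "He+": "He++", "hydrogen": "proton"}
CHARGE_DECREASE = {"He++": "He+", "He+": "He0", "proton": "hydrogen"}
# map excitation levels to activation parent states
EXCITATION_STATES = ("A1B1", "B1A1", "rydberg_diffuse")


def molecule_number_density(density_g_cm3: float = 1.0) -> float:
    """Water molecules per nm^3 at the given mass density."""
    from .registry import AVOGADRO

    return density_g_cm3 * AVOGADRO / WATER_MOLAR_MASS * 1e-21


@dataclass
class ParticleState:
    kind: str
    kinetic_energy: float  # eV
    position: np.ndarray  # (3,) nm
    direction: np.ndarray  # (3,) unit vector
    time: float = 0.0  # ps
    alive: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0:
            raise ValueError("direction must be a nonzero vector")
        self.direction = d / n
        if self.kinetic_energy < 0:
            raise ValueError("kinetic energy must be non-negative")
        if self.kind not in PARTICLE_KINDS:
            raise ValueError(f"unknown particle kind {self.kind!r}")


@dataclass(frozen=True)
class EnergyDeposit:
    position: np.ndarray
    amount: float  # eV
    process: str


@dataclass(frozen=True)
class WaterActivation:
    """An excited/ionized/attached water molecule awaiting dissociation."""

    position: np.ndarray
    state: str  # a dissociation parent state
    time: float  # ps
    potential_energy: float = 0.0  # eV stored in the channel


@dataclass(frozen=True)
class SolvationCandidate:
    """A sub-excitation electron handed to the physicochemical stage."""

    position: np.ndarray
    residual_energy: float  # eV
    time: float


@dataclass
class CrossSectionTable:
    """Tabulated total cross section and interaction samplers for a process.

    ``sampler`` is a small declarative dict:

    - energy loss: ``{"loss": {"type": "fixed", "value": eV}}`` or
      ``{"loss": {"type": "table", "x": [...], "cdf": [...]}}`` (inverse CDF)
    - ionization extras: ``"binding"`` (eV, deposited locally) and
      ``"secondary"`` (same forms as loss; sampled secondary kinetic energy,
      capped at the energetically available maximum)
    - excitation extras: ``"state"`` (activation parent state)
    """

    particle: str
    process: str
    energy_grid: np.ndarray  # eV, strictly increasing
    sigma: np.ndarray  # nm^2 per molecule
    sampler: dict = field(default_factory=dict)
    level: str | None = None

    def __post_init__(self):
        self.energy_grid = np.asarray(self.energy_grid, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(np.diff(self.energy_grid) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(self.sigma < 0):
            raise ValueError("cross sections must be non-negative")
        if self.process not in PROCESSES:
            raise ValueError(f"unknown process {self.process!r}")

    @property
    def valid_range(self) -> tuple[float, float]:
        return float(self.energy_grid[0]), float(self.energy_grid[-1])

    def total_cross_section(self, energy: float) -> float:
        """Log-log interpolated total cross section; 0 outside the range."""
        lo, hi = self.valid_range
        if energy < lo or energy > hi:
            return 0.0
        if np.all(self.sigma == self.sigma[0]):
            return float(self.sigma[0])
        # log-log interpolation with zeros handled linearly
        s = self.sigma
        if np.any(s <= 0):
            return float(np.interp(energy, self.energy_grid, s))
        return float(
            np.exp(
                np.interp(
                    math.log(energy), np.log(self.energy_grid), np.log(s)
                )
            )
        )


def _sample_law(law: dict, rng: np.random.Generator) -> float:
    if law["type"] == "fixed":
        return float(law["value"])
    if law["type"] == "table":
        u = rng.random()
        return float(np.interp(u, law["cdf"], law["x"]))
    if law["type"] == "uniform":
        return float(rng.uniform(law["low"], law["high"]))
    raise ValueError(f"unknown sampling law {law['type']!r}")


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n == 0:  # pragma: no cover - measure-zero
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


@dataclass(frozen=True)
class Box:
    """Axis-aligned box, bounds in nm."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def cube(cls, side_nm: float, center=(0.0, 0.0, 0.0)) -> "Box":
        c = np.asarray(center, dtype=float)
        h = side_nm / 2.0
        return cls(c - h, c + h)

    @classmethod
    def from_bounds(cls, lo, hi) -> "Box":
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        if np.any(hi <= lo):
            raise ValueError("box upper bounds must exceed lower bounds")
        return cls(lo, hi)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.all((p >= self.lo) & (p <= self.hi), axis=1)


def sample_step_and_process(
    p: ParticleState,
    tables: Sequence[CrossSectionTable],
    number_density: float,
    rng: np.random.Generator,
) -> tuple[float, CrossSectionTable | None]:
    """Competing exponential free paths; the shortest step wins.

    Returns (step length nm, winning table). If every applicable cross
    section is zero the step is infinite and the table is None (the
    particle will exit the geometry). Raises if no table covers the
    particle's kind/energy at all.
    """
    applicable = [t for t in tables if t.particle == p.kind]
    covering = [
        t
        for t in applicable
        if t.valid_range[0] <= p.kinetic_energy <= t.valid_range[1]
    ]
    if not covering:
        raise ValueError(
            f"no applicable process for {p.kind} at {p.kinetic_energy:.3g} eV"
        )
    best_step = math.inf
    best_table = None
    for t in covering:
        sigma = t.total_cross_section(p.kinetic_energy)
        if sigma <= 0:
            continue
        step = rng.exponential(1.0 / (number_density * sigma))
        if step < best_step:
            best_step = step
            best_table = t
    return best_step, best_table


def apply_interaction(
    p: ParticleState,
    table: CrossSectionTable,
    rng: np.random.Generator,
) -> tuple[list[ParticleState], list[EnergyDeposit], list[WaterActivation]]:
    """Apply the selected process to the particle at its current position.

    Mutates ``p`` in place (energy, direction, kind, alive) and returns
    (secondaries, deposits, activations). Energy is conserved per
    interaction: primary energy loss = local deposits + secondary kinetic
    energy + stored channel potential energy.
    """
    proc = table.process
    pos = p.position.copy()
    secondaries: list[ParticleState] = []
    deposits: list[EnergyDeposit] = []
    activations: list[WaterActivation] = []

    if proc == "elastic":
        p.direction = random_unit_vector(rng)
        return secondaries, deposits, activations

    if proc == "ionization":
        binding = float(table.sampler.get("binding", 16.0))
        sec_law = table.sampler.get("secondary", {"type": "fixed", "value": 0.0})
        avail = p.kinetic_energy - binding
        if avail <= 0:
            # below the effective threshold: deposit everything locally
            deposits.append(EnergyDeposit(pos, p.kinetic_energy, proc))
            p.kinetic_energy = 0.0
            return secondaries, deposits, activations
        t_sec = min(max(_sample_law(sec_law, rng), 0.0), avail)
        p.kinetic_energy -= binding + t_sec
        deposits.append(EnergyDeposit(pos, binding, proc))
        if t_sec > 0:
            secondaries.append(
                ParticleState(
                    "electron", t_sec, pos, random_unit_vector(rng), p.time
                )
            )
        activations.append(WaterActivation(pos, "ionized", p.time))
        return secondaries, deposits, activations

    if proc == "electronic_excitation":
        state = table.sampler.get("state", table.level or "A1B1")
        loss = _sample_law(table.sampler["loss"], rng)
        loss = min(loss, p.kinetic_energy)
        p.kinetic_energy -= loss
        activations.append(WaterActivation(pos, state, p.time, potential_energy=loss))
        return secondaries, deposits, activations

    if proc == "vibrational_excitation":
        loss = min(_sample_law(table.sampler["loss"], rng), p.kinetic_energy)
        p.kinetic_energy -= loss
        if loss > 0:
            deposits.append(EnergyDeposit(pos, loss, proc))
        return secondaries, deposits, activations

    if proc == "dissociative_attachment":
        if p.kind != "electron":
            raise ValueError("dissociative attachment applies to electrons only")
        if p.kinetic_energy > 0:
            deposits.append(EnergyDeposit(pos, p.kinetic_energy, proc))
        activations.append(WaterActivation(pos, "dissoc_attachment", p.time))
        p.kinetic_energy = 0.0
        p.alive = False
        return secondaries, deposits, activations

    if proc == "charge_increase":
        if p.kind not in CHARGE_INCREASE:
            raise ValueError(f"charge increase invalid for {p.kind}")
        p.kind = CHARGE_INCREASE[p.kind]
        return secondaries, deposits, activations

    if proc == "charge_decrease":
        if p.kind not in CHARGE_DECREASE:
            raise ValueError(f"charge decrease invalid for {p.kind}")
        p.kind = CHARGE_DECREASE[p.kind]
        return secondaries, deposits, activations

    raise ValueError(f"unknown process {proc!r}")  # pragma: no cover


@dataclass
class PhysicsEvent:
    """Everything one primary (plus its secondaries) left in the box."""

    deposits: list[EnergyDeposit] = field(default_factory=list)
    activations: list[WaterActivation] = field(default_factory=list)
    solvation_candidates: list[SolvationCandidate] = field(default_factory=list)
    escaped_energy: float = 0.0

    @property
    def total_deposit(self) -> float:
        return sum(d.amount for d in self.deposits)

    @property
    def total_potential(self) -> float:
        return sum(a.potential_energy for a in self.activations)

    @property
    def total_solvation_energy(self) -> float:
        return sum(c.residual_energy for c in self.solvation_candidates)


def _tracking_cut(kind: str, registry: Registry) -> float:
    cuts = registry.constants.tracking_cuts_eV
    if kind == "generic_ion":
        return float(cuts.get("generic_ion_per_u", 0.5e6))
    return float(cuts.get(kind, 0.0))


def transport_event(
    primary: ParticleState,
    box: Box,
    tables: Sequence[CrossSectionTable],
    registry: Registry | None = None,
    rng: np.random.Generator | None = None,
    density_g_cm3: float | None = None,
    max_iterations: int = 10_000_000,
) -> PhysicsEvent:
    """Transport a primary and all its secondaries to cut or exit.

    Particles are processed LIFO (track stack, secondaries pushed at
    creation) so a fixed seed reproduces the event bit-exactly. Electrons
    reaching the sub-excitation threshold (8.22 eV) leave the loop as
    solvation candidates; below the hard tracking cut (7.4 eV for
    electrons) the remaining kinetic energy is deposited locally. The
    density scaling multiplies the interaction probability per unit length.
    """
    registry = registry or default_registry()
    rng = rng if rng is not None else np.random.default_rng()
    if density_g_cm3 is None:
        density_g_cm3 = registry.constants.water_density_g_cm3
    n_density = molecule_number_density(density_g_cm3)
    sub_exc = registry.constants.sub_excitation_threshold_eV

    event = PhysicsEvent()
    stack = [primary]
    iterations = 0
    while stack:
        iterations += 1
        if iterations > max_iterations:
            raise RuntimeError("transport failed to terminate (max iterations)")
        p = stack.pop()
        if not p.alive:
            continue
        if not box.contains(p.position)[0]:
            event.escaped_energy += p.kinetic_energy
            continue
        cut = _tracking_cut(p.kind, registry)
        if p.kind == "electron" and cut < p.kinetic_energy <= sub_exc:
            event.solvation_candidates.append(
                SolvationCandidate(p.position.copy(), p.kinetic_energy, p.time)
            )
            continue
        if p.kinetic_energy <= cut:
            if p.kinetic_energy > 0:
                event.deposits.append(
                    EnergyDeposit(p.position.copy(), p.kinetic_energy, "tracking_cut")
                )
            continue

        step, table = sample_step_and_process(p, tables, n_density, rng)
        if not math.isfinite(step):
            event.escaped_energy += p.kinetic_energy
            continue
        p.position = p.position + step * p.direction
        if not box.contains(p.position)[0]:
            event.escaped_energy += p.kinetic_energy
            continue
        secondaries, deposits, activations = apply_interaction(p, table, rng)
        event.deposits.extend(deposits)
        event.activations.extend(activations)
        if p.alive and p.kinetic_energy > 0:
            stack.append(p)
        elif p.alive and p.kinetic_energy == 0:
            pass  # fully stopped, nothing left to deposit
        stack.extend(secondaries)
    return event


# ---------------------------------------------------------------------------
# scoring


@dataclass(frozen=True)
class RadialDoseConfig:
    inner_radius_nm: float = 1.0
    outer_radius_nm: float = 250.0
    n_shells: int = 100
    height_nm: float = 1.0e4  # 10 um

    def __post_init__(self):
        if self.inner_radius_nm <= 0 or self.outer_radius_nm <= 0:
            raise ValueError("radii must be positive")
        if self.inner_radius_nm >= self.outer_radius_nm:
            raise ValueError("inner radius must be below outer radius")

    @property
    def edges_nm(self) -> np.ndarray:
        return np.logspace(
            math.log10(self.inner_radius_nm),
            math.log10(self.outer_radius_nm),
            self.n_shells + 1,
        )

    @property
    def shell_volumes_nm3(self) -> np.ndarray:
        e = self.edges_nm
        return math.pi * (e[1:] ** 2 - e[:-1] ** 2) * self.height_nm


EV_TO_J = 1.602176634e-19


def radial_dose(
    deposits: Iterable[EnergyDeposit],
    n_events: int,
    config: RadialDoseConfig = RadialDoseConfig(),
    density_g_cm3: float = 1.0,
    axis_origin=(0.0, 0.0, 0.0),
) -> pd.DataFrame:
    """Radial dose around the z axis in logarithmic cylindrical shells.

    dose_i = (energy in shell i) / (rho * V_i), normalized per incident
    particle, reported in Gy. Deposits outside the radial range or the
    cylinder height are ignored.
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    origin = np.asarray(axis_origin, dtype=float)
    edges = config.edges_nm
    energy = np.zeros(config.n_shells)
    for d in deposits:
        rel = d.position - origin
        r = math.hypot(rel[0], rel[1])
        z = rel[2]
        if not (0.0 <= z <= config.height_nm):
            continue
        if r < edges[0] or r > edges[-1]:
            continue
        i = min(np.searchsorted(edges, r, side="right") - 1, config.n_shells - 1)
        energy[i] += d.amount
    mass_g = density_g_cm3 * config.shell_volumes_nm3 * 1e-21  # nm^3 -> cm^3
    dose_gy = energy * EV_TO_J / (mass_g * 1e-3) / n_events
    return pd.DataFrame(
        {
            "r_inner_nm": edges[:-1],
            "r_outer_nm": edges[1:],
            "energy_eV": energy,
            "dose_Gy_per_event": dose_gy,
        }
    )


def compute_let(per_event_deposits_eV: Sequence[float], path_length_nm: float) -> float:
    """LET = mean per-event energy deposit / path length, in eV/nm.

    Numerically equal to keV/um. Zero-deposit events count in the mean.
    """
    deposits = np.asarray(list(per_event_deposits_eV), dtype=float)
    if deposits.size == 0:
        raise ValueError("LET requires at least one event")
    if path_length_nm <= 0:
        raise ValueError("path length must be positive")
    return float(deposits.mean() / path_length_nm)


# ---------------------------------------------------------------------------
# toy cross-section tables


def toy_tables(
    sigma_scale: float = 1.0,
) -> list[CrossSectionTable]:
    """A small self-consistent toy cross-section set for electrons/protons.

    Not a physical model: constant or power-law totals with fixed or
    uniform loss spectra, sized so that a keV-scale electron produces a
    compact track with ionizations, the three excitation levels,
    vibrational losses and dissociative attachment. Useful for exercising
    and testing the full pipeline without external data.
    """
    grids = {
        "e_ion": np.array([11.0, 1.0e6]),
        "e_exc": np.array([9.0, 1.0e6]),
        "e_vib": np.array([2.0, 100.0]),
        "e_att": np.array([4.0, 13.0]),
        "e_ela": np.array([7.4, 1.0e6]),
        "p_ion": np.array([100.0, 1.0e8]),
        "p_exc": np.array([100.0, 1.0e8]),
    }
    s = sigma_scale
    return [
        CrossSectionTable(
            "electron", "ionization", grids["e_ion"], [5e-3 * s, 5e-3 * s],
            sampler={
                "binding": 16.0,
                "secondary": {"type": "uniform", "low": 1.0, "high": 30.0},
            },
        ),
        CrossSectionTable(
            "electron", "electronic_excitation", grids["e_exc"],
            [1.5e-3 * s, 1.5e-3 * s], level="A1B1",
            sampler={"loss": {"type": "fixed", "value": 8.22}},
        ),
        CrossSectionTable(
            "electron", "electronic_excitation", grids["e_exc"],
            [1.0e-3 * s, 1.0e-3 * s], level="B1A1",
            sampler={"loss": {"type": "fixed", "value": 10.0}},
        ),
        CrossSectionTable(
            "electron", "electronic_excitation", grids["e_exc"],
            [0.5e-3 * s, 0.5e-3 * s], level="rydberg_diffuse",
            sampler={"loss": {"type": "fixed", "value": 11.5}},
        ),
        CrossSectionTable(
            "electron", "vibrational_excitation", grids["e_vib"],
            [2.0e-3 * s, 2.0e-3 * s],
            sampler={"loss": {"type": "fixed", "value": 0.5}},
        ),
        CrossSectionTable(
            "electron", "dissociative_attachment", grids["e_att"],
            [1.0e-4 * s, 1.0e-4 * s],
        ),
        CrossSectionTable(
            "electron", "elastic", grids["e_ela"], [1.0e-2 * s, 1.0e-2 * s]
        ),
        # proton totals fall like 1/E so that LET decreases with energy
        CrossSectionTable(
            "proton", "ionization", np.array([100.0, 1.0e8]),
            [2.0e1 * s, 2.0e-5 * s],
            sampler={
                "binding": 16.0,
                "secondary": {"type": "uniform", "low": 1.0, "high": 50.0},
            },
        ),
        CrossSectionTable(
            "proton", "electronic_excitation", np.array([100.0, 1.0e8]),
            [4.0e0 * s, 4.0e-6 * s], level="A1B1",
            sampler={"loss": {"type": "fixed", "value": 8.22}},
        ),
    ]


def tables_to_frame(tables: Sequence[CrossSectionTable]) -> pd.DataFrame:
    """Flatten tables to the columnar interchange schema."""
    rows = []
    for t in tables:
        for e, sg in zip(t.energy_grid, t.sigma):
            rows.append(
                {
                    "particle": t.particle,
                    "process": t.process,
                    "level": t.level or "",
                    "E_eV": e,
                    "sigma_nm2": sg,
                }
            )
    return pd.DataFrame(rows)
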