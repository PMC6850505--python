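"""Parameter registry: species, reactions, dissociation channels, constants.

All tabulated physical chemistry lives here. Internal units are nm, ps and
eV throughout the package; SI-configured values (m^2/s diffusion
coefficients, dm^3/(mol s) rate constants) are converted exactly once when
the registry is built. Reaction radii are derived from the configured rate
constants through the Smoluchowski relation for diffusion-controlled
encounters,

    R = k / (4 pi N_A D_sum),

with D_sum the summed diffusion coefficient of the two reactants.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

AVOGADRO = 6.02214076e23  # 1/mol
#: multiply a diffusion coefficient in m^2/s by this to get nm^2/ps
M2_S_TO_NM2_PS = 1.0e6

PARENT_STATES = ("ionized", "A1B1", "B1A1", "rydberg_diffuse", "dissoc_attachment")
CHANNEL_MODES = ("dissociative_decay", "auto_ionization", "relaxation")


class RegistryError(ValueError):
    """Malformed parameter tables."""


def reaction_radius(k_dm3_per_mol_s: float, d_sum_m2_per_s: float) -> float:
    """Smoluchowski encounter radius in nm.

    Parameters
    ----------
    k_dm3_per_mol_s : rate constant in dm^3/(mol s).
    d_sum_m2_per_s : summed diffusion coefficient of the pair in m^2/s.
    """
    if k_dm3_per_mol_s <= 0 or d_sum_m2_per_s <= 0:
        raise ValueError("rate constant and diffusion coefficient must be positive")
    k_m3 = k_dm3_per_mol_s * 1e-3  # dm^3 -> m^3
    r_m = k_m3 / (4.0 * math.pi * AVOGADRO * d_sum_m2_per_s)
    return r_m * 1e9


@dataclass(frozen=True)
class Species:
    name: str
    diffusion_coefficient: float  # nm^2/ps
    charge: int
    index: int

    @property
    def d_m2_per_s(self) -> float:
        return self.diffusion_coefficient / M2_S_TO_NM2_PS


@dataclass(frozen=True)
class Reaction:
    """A bimolecular channel; the reactant pair is unordered."""

    reactants: tuple[str, str]
    products: tuple[str, ...]
    rate_constant: float  # dm^3/(mol s)
    radius: float  # nm, derived
    index: int


@dataclass(frozen=True)
class DissociationChannel:
    parent_state: str
    mode: str
    products: tuple[str, ...]
    fraction: float  # percent


@dataclass(frozen=True)
class Constants:
    avogadro: float = AVOGADRO
    water_density_g_cm3: float = 1.0
    tracking_cuts_eV: Mapping[str, float] = field(default_factory=dict)
    sub_excitation_threshold_eV: float = 8.22
    dt_min_ps: float = 1.0
    chem_t_start_ps: float = 1.0
    chem_t_end_ps: float = 1.0e6

    def __post_init__(self):
        if self.chem_t_start_ps >= self.chem_t_end_ps:
            raise RegistryError("chemical window start must precede its end")
        for name, value in (
            ("water_density_g_cm3", self.water_density_g_cm3),
            ("sub_excitation_threshold_eV", self.sub_excitation_threshold_eV),
            ("dt_min_ps", self.dt_min_ps),
            ("chem_t_start_ps", self.chem_t_start_ps),
        ):
            if value <= 0:
                raise RegistryError(f"constant {name} must be positive")


class Registry:
    """Validated parameter set with derived quantities and fast lookups.

    Attributes of note (all numpy arrays are indexed by species or reaction
    integer ids):

    ``D``            per-species diffusion coefficients, nm^2/ps
    ``reaction_table`` (S, S) int array mapping a species pair to a reaction
                       id, or -1 for non-reactive pairs
    ``radii``        per-reaction Smoluchowski radii, nm
    ``d_sum``        per-reaction summed diffusion coefficients, nm^2/ps
    ``step_denom``   per-reaction 8(sqrt(D_A)+sqrt(D_B))^2, nm^2/ps — the
                     denominator of the dynamic-time-step formula
    """

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        channels: Sequence[DissociationChannel],
        constants: Constants,
    ):
        self.species = list(species)
        self.reactions = list(reactions)
        self.channels = list(channels)
        self.constants = constants
        self.species_index = {s.name: s.index for s in self.species}

        n = len(self.species)
        self.D = np.array([s.diffusion_coefficient for s in self.species])
        self.reaction_table = np.full((n, n), -1, dtype=np.int64)
        for r in self.reactions:
            a = self.species_index[r.reactants[0]]
            b = self.species_index[r.reactants[1]]
            self.reaction_table[a, b] = r.index
            self.reaction_table[b, a] = r.index
        self.radii = np.array([r.radius for r in self.reactions])
        d_a = np.array(
            [self.D[self.species_index[r.reactants[0]]] for r in self.reactions]
        )
        d_b = np.array(
            [self.D[self.species_index[r.reactants[1]]] for r in self.reactions]
        )
        self.d_sum = d_a + d_b
        self.step_denom = 8.0 * (np.sqrt(d_a) + np.sqrt(d_b)) ** 2
        self.products_ids = [
            tuple(self.species_index[p] for p in r.products) for r in self.reactions
        ]
        self.channels_by_parent: dict[str, list[DissociationChannel]] = {}
        for ch in self.channels:
            self.channels_by_parent.setdefault(ch.parent_state, []).append(ch)

    # -- lookups ---------------------------------------------------------
    def species_id(self, name: str) -> int:
        try:
            return self.species_index[name]
        except KeyError:
            raise RegistryError(f"unknown species {name!r}") from None

    def lookup_reaction(self, a: str, b: str) -> Reaction | None:
        """Reaction for an unordered species pair, or None if non-reactive."""
        idx = self.reaction_table[self.species_id(a), self.species_id(b)]
        return None if idx < 0 else self.reactions[idx]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def max_radius(self) -> float:
        return float(self.radii.max())

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "species": {
                s.name: {"D_m2_per_s": s.d_m2_per_s, "charge": s.charge}
                for s in self.species
            },
            "reactions": [
                {
                    "reactants": list(r.reactants),
                    "products": list(r.products),
                    "k_dm3_per_mol_s": r.rate_constant,
                }
                for r in self.reactions
            ],
            "dissociation": [
                {
                    "parent": c.parent_state,
                    "mode": c.mode,
                    "products": list(c.products),
                    "fraction_percent": c.fraction,
                }
                for c in self.channels
            ],
            "constants": {
                "water_density_g_cm3": self.constants.water_density_g_cm3,
                "sub_excitation_threshold_eV": self.constants.sub_excitation_threshold_eV,
                "dt_min_ps": self.constants.dt_min_ps,
                "chem_t_start_ps": self.constants.chem_t_start_ps,
                "chem_t_end_ps": self.constants.chem_t_end_ps,
                "tracking_cuts_eV": dict(self.constants.tracking_cuts_eV),
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def _validate_and_build(cfg: Mapping) -> Registry:
    try:
        species_cfg = cfg["species"]
        reactions_cfg = cfg["reactions"]
        dissociation_cfg = cfg["dissociation"]
    except KeyError as exc:
        raise RegistryError(f"missing table {exc.args[0]!r}") from None

    species = []
    for i, (name, sc) in enumerate(species_cfg.items()):
        d = float(sc["D_m2_per_s"])
        if d <= 0:
            raise RegistryError(f"species {name!r}: non-positive diffusion coefficient")
        species.append(
            Species(name, d * M2_S_TO_NM2_PS, int(sc.get("charge", 0)), i)
        )
    names = {s.name for s in species}
    if len(names) != len(species):
        raise RegistryError("duplicate species names")
    index = {s.name: s.index for s in species}
    D = {s.name: s.d_m2_per_s for s in species}

    reactions = []
    seen_pairs = set()
    for i, rc in enumerate(reactions_cfg):
        a, b = rc["reactants"]
        for nm in (a, b, *rc["products"]):
            if nm not in names:
                raise RegistryError(f"reaction references unknown species {nm!r}")
        key = frozenset({a, b}) if a != b else frozenset({a})
        if key in seen_pairs:
            raise RegistryError(f"duplicate reactant pair ({a}, {b})")
        seen_pairs.add(key)
        k = float(rc["k_dm3_per_mol_s"])
        if k <= 0:
            raise RegistryError(f"reaction ({a}, {b}): non-positive rate constant")
        if len(rc["products"]) > 3:
            raise RegistryError(f"reaction ({a}, {b}): too many products")
        radius = reaction_radius(k, D[a] + D[b])
        reactions.append(Reaction((a, b), tuple(rc["products"]), k, radius, i))

    channels = []
    sums: dict[str, float] = {}
    for cc in dissociation_cfg:
        parent = cc["parent"]
        mode = cc["mode"]
        if parent not in PARENT_STATES:
            raise RegistryError(f"unknown parent state {parent!r}")
        if mode not in CHANNEL_MODES:
            raise RegistryError(f"unknown channel mode {mode!r}")
        for nm in cc["products"]:
            if nm not in names:
                raise RegistryError(f"channel references unknown species {nm!r}")
        frac = float(cc["fraction_percent"])
        if frac < 0:
            raise RegistryError(f"{parent}: negative fraction")
        channels.append(DissociationChannel(parent, mode, tuple(cc["products"]), frac))
        sums[parent] = sums.get(parent, 0.0) + frac
    for parent, total in sums.items():
        if abs(total - 100.0) > 1e-9:
            raise RegistryError(
                f"dissociation fractions for {parent!r} sum to {total}, not 100"
            )

    const_cfg = dict(cfg.get("constants", {}))
    cuts = dict(const_cfg.pop("tracking_cuts_eV", {}))
    constants = Constants(tracking_cuts_eV=cuts, **const_cfg)
    return Registry(species, reactions, channels, constants)


def build_registry(config: Mapping | str | Path | None = None) -> Registry:
    """Build and validate a registry.

    ``config`` may be a mapping with the ``species`` / ``reactions`` /
    ``dissociation`` / ``constants`` tables, a path to a TOML file with the
    same structure, or None for the bundled liquid-water defaults.
    """
    if config is None:
        text = resources.files("trackchem.data").joinpath("chemistry.toml").read_text()
        cfg = tomllib.loads(text)
    elif isinstance(config, (str, Path)):
        with open(config, "rb") as fh:
            cfg = tomllib.load(fh)
    else:
        cfg = config
    return _validate_and_build(cfg)


_default: Registry | None = None


def default_registry() -> Registry:
    """The bundled liquid-water registry (cached)."""
    global _default
    if _default is None:
        _default = build_registry()
    return _default
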