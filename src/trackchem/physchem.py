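"""Physicochemical stage: activated water -> molecular species at 1 ps.

Activated water molecules (ionized, excited, or having captured an
electron) decay on femtosecond timescales into radicals, ions and
molecules according to the branching table in the registry; relaxation
channels release their excess energy and yield nothing. Sub-excitation
electrons thermalize and appear as hydrated electrons. The output is the
t = 1 ps molecular population that seeds the chemical stage.

Placement rules (the branching table has no geometry of its own):
fragments are placed back-to-back along a random axis at a configurable
separation; hydrated electrons additionally receive an isotropic
thermalization displacement with an exponentially distributed magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .physics import PhysicsEvent, SolvationCandidate, WaterActivation, random_unit_vector
from .registry import Registry, RegistryError

#: default fragment separation on dissociation, nm (order of an O-H bond
#: plus one water diameter; a declared knob affecting early recombination)
DEFAULT_FRAGMENT_SEPARATION = 0.24
#: default mean of the exponential thermalization displacement for hydrated
#: electrons, nm. Sub-excitation electrons in liquid water travel of the
#: order of 10 nm before solvating (Meesungnoen-type thermalization
#: distances, the law adopted by the reference chemistry codes this
#: simulator emulates); without this offset the hydrated electron sits
#: inside the radical spur and unphysically scavenges its own products.
DEFAULT_THERMALIZATION_MEAN = 10.0

EAQ = "eaq-"


@dataclass(frozen=True)
class PlacedMolecule:
    species: str
    position: np.ndarray
    time: float  # ps


def _place_fragments(
    products: tuple[str, ...],
    center: np.ndarray,
    rng: np.random.Generator,
    separation: float,
) -> list[tuple[str, np.ndarray]]:
    """Back-to-back placement along a random axis around the site.

    One product sits at the site; two products sit at +/- separation/2; a
    third goes on a perpendicular random axis at the same distance.
    """
    if len(products) == 0:
        return []
    if len(products) == 1:
        return [(products[0], center.copy())]
    axis = random_unit_vector(rng)
    placed = [
        (products[0], center + 0.5 * separation * axis),
        (products[1], center - 0.5 * separation * axis),
    ]
    for extra in products[2:]:
        perp = np.cross(axis, random_unit_vector(rng))
        n = np.linalg.norm(perp)
        perp = perp / n if n > 0 else random_unit_vector(rng)
        placed.append((extra, center + 0.5 * separation * perp))
    return placed


def dissociate(
    activation: WaterActivation,
    registry: Registry,
    rng: np.random.Generator,
    separation: float = DEFAULT_FRAGMENT_SEPARATION,
    thermalization_mean: float = DEFAULT_THERMALIZATION_MEAN,
) -> list[PlacedMolecule]:
    """Draw one branching channel for an activation and place its products.

    Relaxation yields no species (the excess energy is released locally).
    Hydrated electrons among the products (auto-ionization channels) get
    the extra thermalization displacement.
    """
    channels = registry.channels_by_parent.get(activation.state)
    if not channels:
        raise RegistryError(f"unknown activation state {activation.state!r}")
    fractions = np.array([c.fraction for c in channels]) / 100.0
    choice = channels[rng.choice(len(channels), p=fractions)]
    if choice.mode == "relaxation":
        return []
    center = np.asarray(activation.position, dtype=float)
    placed = _place_fragments(choice.products, center, rng, separation)
    out = []
    for name, pos in placed:
        if name == EAQ:
            pos = thermalize_electron(
                pos, 0.0, rng, mean_displacement=thermalization_mean
            )
        out.append(PlacedMolecule(name, pos, activation.time))
    return out


#: Maxwell mean-to-sigma factor: E|r| = 2 sigma sqrt(2/pi) for an
#: isotropic 3D Gaussian displacement
_MAXWELL_MEAN_FACTOR = 2.0 * np.sqrt(2.0 / np.pi)


def thermalize_electron(
    position: np.ndarray,
    residual_energy: float,
    rng: np.random.Generator,
    mean_displacement: float = DEFAULT_THERMALIZATION_MEAN,
) -> np.ndarray:
    """Final position of a thermalizing sub-excitation electron.

    Isotropic 3D Gaussian displacement (Maxwell-distributed magnitude,
    the endpoint distribution of a random flight) scaled so the mean
    magnitude equals the configured mean; a zero mean collapses to the
    stopping point. The magnitude density vanishes at r = 0, so the
    electron never solvates inside its parent radical cluster.
    """
    position = np.asarray(position, dtype=float)
    if mean_displacement <= 0:
        return position.copy()
    sigma = mean_displacement / _MAXWELL_MEAN_FACTOR
    return position + rng.normal(scale=sigma, size=3)


def build_initial_population(
    event: PhysicsEvent,
    registry: Registry,
    rng: np.random.Generator,
    box=None,
    separation: float = DEFAULT_FRAGMENT_SEPARATION,
    thermalization_mean: float = DEFAULT_THERMALIZATION_MEAN,
):
    """Dissociate all activations and solvate all candidate electrons.

    Returns a :class:`trackchem.chem.MoleculeSet` timestamped at the start
    of the chemical window (1 ps).
    """
    from .chem import MoleculeSet

    t_start = registry.constants.chem_t_start_ps
    names: list[str] = []
    positions: list[np.ndarray] = []
    for act in event.activations:
        for m in dissociate(
            act, registry, rng, separation=separation,
            thermalization_mean=thermalization_mean,
        ):
            names.append(m.species)
            positions.append(m.position)
    for cand in event.solvation_candidates:
        names.append(EAQ)
        positions.append(
            thermalize_electron(
                cand.position, cand.residual_energy, rng,
                mean_displacement=thermalization_mean,
            )
        )
    return MoleculeSet.from_names(
        names, positions, registry, t=t_start, box=box
    )
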