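"""Synthetic 1 ps track generator and test fixtures for the chemical stage.

The chemical stage only needs a molecular population at 1 ps. This module
supplies three sources of such populations without running the full
physics transport:

* :func:`toy_pair` and :func:`homogeneous_box` — deterministic/well-mixed
  fixtures for unit tests and kinetics cross-checks;
* :func:`simplified_track` — a calibratable generator that emulates the
  near-track clustering of real 1 ps populations: energy is deposited in
  spurs (localized clusters of a few tens of eV) spaced exponentially
  along a straight track with mean spacing E_spur / LET, each spur
  dissociating into product bundles whose per-100 eV frequencies are
  solved from target 1 ps yields by :func:`calibrate`.

Bundled presets ("e750keV", "p20MeV", "p5MeV") carry the 1 ps yields and
LET of the standard validation setups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import MoleculeSet
from .physics import Box, random_unit_vector
from .physchem import (
    DEFAULT_FRAGMENT_SEPARATION,
    DEFAULT_THERMALIZATION_MEAN,
    EAQ,
    _place_fragments,
    thermalize_electron,
)
from .registry import AVOGADRO, Registry, RegistryError, default_registry

#: mean spur energy, eV. Spur energies are drawn from an exponential
#: truncated to [6, 100] eV (the classical spur band); the mean sets the
#: spur linear density E_spur / LET along the track.
DEFAULT_SPUR_ENERGY = 50.0
SPUR_ENERGY_RANGE = (6.0, 100.0)
#: exponential mean of the isotropic site displacement around a spur
#: center, nm (the spur radius scale)
DEFAULT_SITE_SPREAD = 1.0


def toy_pair(
    a: str,
    b: str,
    distance: float,
    registry: Registry | None = None,
    box: Box | None = None,
) -> MoleculeSet:
    """Two molecules on the x axis at the given separation, t = 1 ps."""
    registry = registry or default_registry()
    if distance < 0:
        raise ValueError("distance must be non-negative")
    for name in (a, b):
        registry.species_id(name)
    pos = np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]])
    return MoleculeSet.from_names(
        [a, b], pos, registry, t=registry.constants.chem_t_start_ps, box=box
    )


def homogeneous_box(
    concentrations_mol_per_dm3: dict[str, float],
    box_side_nm: float,
    registry: Registry | None = None,
    rng: np.random.Generator | None = None,
) -> MoleculeSet:
    """Uniform random placement at given molar concentrations.

    Counts are Poisson with mean c * N_A * V; the realized counts are
    recoverable from the returned set.
    """
    registry = registry or default_registry()
    rng = rng if rng is not None else np.random.default_rng()
    volume_dm3 = (box_side_nm * 1e-8) ** 3  # nm -> dm
    names: list[str] = []
    for name, c in concentrations_mol_per_dm3.items():
        if c < 0:
            raise ValueError(f"negative concentration for {name!r}")
        n = rng.poisson(c * AVOGADRO * volume_dm3)
        names.extend([name] * n)
    box = Box.cube(box_side_nm)
    pos = rng.uniform(box.lo, box.hi, size=(len(names), 3))
    return MoleculeSet.from_names(
        names, pos, registry, t=registry.constants.chem_t_start_ps, box=box
    )


# ---------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class Calibration:
    """Channel frequencies per 100 eV plus track-structure parameters."""

    channels: tuple[tuple[tuple[str, ...], float], ...]  # (products, per 100 eV)
    let_ev_per_nm: float
    spur_energy_eV: float = DEFAULT_SPUR_ENERGY
    site_spread_nm: float = DEFAULT_SITE_SPREAD
    fragment_separation_nm: float = DEFAULT_FRAGMENT_SEPARATION
    thermalization_mean_nm: float = DEFAULT_THERMALIZATION_MEAN

    @property
    def total_frequency(self) -> float:
        return sum(f for _, f in self.channels)

    def expected_yields(self) -> dict[str, float]:
        """Per-100 eV species yields implied by the channel frequencies."""
        out: dict[str, float] = {}
        for products, f in self.channels:
            for p in products:
                out[p] = out.get(p, 0.0) + f
        return out


def calibrate(
    target_yields: dict[str, float],
    let_ev_per_nm: float,
    registry: Registry | None = None,
    **track_params,
) -> Calibration:
    """Solve channel frequencies per 100 eV from target 1 ps yields.

    Channels are the product bundles of the dissociation table — the
    ion pair {H3O+, OH}, auto-ionization {H3O+, OH, eaq-}, {OH, H},
    {2OH, H2} and attachment {OH, OH-, H2} — plus residual singleton
    channels ({OH}, {H2}, {H2O2}) that absorb the overdetermined part so
    the target yields are matched exactly. Raises if any frequency would
    be negative (infeasible yields).
    """
    registry = registry or default_registry()
    y = {s.name: float(target_yields.get(s.name, 0.0)) for s in registry.species}
    for name in target_yields:
        registry.species_id(name)  # validate
    if any(v < 0 for v in y.values()):
        raise ValueError("yields must be non-negative")

    f_att = y["OH-"]
    f_auto = y[EAQ]
    f_ion = y["H3O+"] - f_auto
    f_a1b1 = y["H"]
    r_h2 = y["H2"] - f_att
    r_oh = y["OH"] - (f_ion + f_auto + f_a1b1 + f_att)
    f_b1a1 = min(r_h2, r_oh / 2.0) if min(r_h2, r_oh) > 0 else 0.0
    f_oh_extra = r_oh - 2.0 * f_b1a1
    f_h2_extra = r_h2 - f_b1a1
    f_h2o2 = y["H2O2"]

    channels = [
        (("H3O+", "OH"), f_ion),
        (("H3O+", "OH", EAQ), f_auto),
        (("OH", "H"), f_a1b1),
        (("OH", "OH", "H2"), f_b1a1),
        (("OH", "OH-", "H2"), f_att),
        (("OH",), f_oh_extra),
        (("H2",), f_h2_extra),
        (("H2O2",), f_h2o2),
    ]
    for products, f in channels:
        if f < -1e-12:
            raise ValueError(
                f"infeasible yields: channel {products} would need frequency {f:.4g}"
            )
    channels = tuple((p, max(f, 0.0)) for p, f in channels if f > 1e-12)
    return Calibration(channels=channels, let_ev_per_nm=let_ev_per_nm, **track_params)


# 1 ps yields (molecules per 100 eV) of the reference validation setups,
# with their track-averaged LET in the corresponding target geometry.
PRESET_YIELDS: dict[str, dict] = {
    "e750keV": {
        "yields": {
            "OH": 5.45, EAQ: 4.61, "H3O+": 4.63, "H": 0.58,
            "H2": 0.13, "OH-": 0.03, "H2O2": 0.0,
        },
        "let_ev_per_nm": 0.2,
    },
    "p20MeV": {
        "yields": {
            "OH": 5.48, EAQ: 4.61, "H3O+": 4.64, "H": 0.60,
            "H2": 0.14, "OH-": 0.02, "H2O2": 0.0,
        },
        "let_ev_per_nm": 2.7,
    },
    "p5MeV": {
        "yields": {
            "OH": 5.48, EAQ: 4.61, "H3O+": 4.64, "H": 0.60,
            "H2": 0.14, "OH-": 0.02, "H2O2": 0.0,
        },
        "let_ev_per_nm": 8.0,
    },
}


def preset_calibration(name: str, registry: Registry | None = None) -> Calibration:
    try:
        preset = PRESET_YIELDS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESET_YIELDS)}"
        ) from None
    return calibrate(preset["yields"], preset["let_ev_per_nm"], registry)


# ---------------------------------------------------------------------------
# simplified track


def simplified_track(
    calibration: Calibration,
    target_edep_eV: float,
    registry: Registry | None = None,
    rng: np.random.Generator | None = None,
    transverse_halfwidth_nm: float = 500.0,
    margin_nm: float = 200.0,
) -> tuple[MoleculeSet, float]:
    """A 1 ps population emulating the near-track species distribution.

    Energy is laid down in spurs along the z axis until the target deposit
    is reached: spur spacing ~ Exp(E_spur / LET), spur energy ~ truncated
    Exp(mean E_spur) on [6, 100] eV. Each spur spawns Poisson(sum_f * e /
    100) sites; each site draws a product bundle with probability
    proportional to its calibrated frequency and places the fragments
    back-to-back around an isotropically displaced site position;
    hydrated electrons get the extra thermalization displacement. The
    simulation box is a long box around the track. Returns (population,
    realized deposit in eV).
    """
    registry = registry or default_registry()
    rng = rng if rng is not None else np.random.default_rng()
    if target_edep_eV < 0:
        raise ValueError("target deposit must be non-negative")
    if target_edep_eV == 0:
        box = Box.cube(2 * transverse_halfwidth_nm)
        return (
            MoleculeSet.from_names(
                [], [], registry, t=registry.constants.chem_t_start_ps, box=box
            ),
            0.0,
        )

    let = calibration.let_ev_per_nm
    mean_spacing = calibration.spur_energy_eV / let
    lo_e, hi_e = SPUR_ENERGY_RANGE

    freqs = np.array([f for _, f in calibration.channels])
    bundles = [p for p, _ in calibration.channels]
    f_total = freqs.sum()
    probs = freqs / f_total

    spur_z: list[float] = []
    spur_e: list[float] = []
    z = 0.0
    edep = 0.0
    while edep < target_edep_eV:
        z += rng.exponential(mean_spacing)
        # truncated exponential via inverse CDF
        u = rng.random()
        lam = 1.0 / calibration.spur_energy_eV
        c_lo = 1.0 - math.exp(-lam * lo_e)
        c_hi = 1.0 - math.exp(-lam * hi_e)
        e = -math.log(1.0 - (c_lo + u * (c_hi - c_lo))) / lam
        spur_z.append(z)
        spur_e.append(e)
        edep += e

    track_length = spur_z[-1]
    box = Box.from_bounds(
        [-transverse_halfwidth_nm, -transverse_halfwidth_nm, -margin_nm],
        [
            transverse_halfwidth_nm,
            transverse_halfwidth_nm,
            track_length + margin_nm,
        ],
    )

    names: list[str] = []
    positions: list[np.ndarray] = []
    for zc, e in zip(spur_z, spur_e):
        center = np.array([0.0, 0.0, zc])
        n_sites = rng.poisson(f_total * e / 100.0)
        for _ in range(n_sites):
            site = center + rng.exponential(
                calibration.site_spread_nm
            ) * random_unit_vector(rng)
            bundle = bundles[rng.choice(len(bundles), p=probs)]
            if "OH-" in bundle:
                # dissociative attachment happens at the end of a slowing
                # sub-excitation electron's path, not in the spur core —
                # same displacement scale as solvation (in the full physics
                # path the activation is naturally placed there)
                site = thermalize_electron(
                    site, 0.0, rng,
                    mean_displacement=calibration.thermalization_mean_nm,
                )
            for name, pos in _place_fragments(
                bundle, site, rng, calibration.fragment_separation_nm
            ):
                if name == EAQ:
                    pos = thermalize_electron(
                        pos, 0.0, rng,
                        mean_displacement=calibration.thermalization_mean_nm,
                    )
                names.append(name)
                positions.append(pos)

    m = MoleculeSet.from_names(
        names, positions, registry, t=registry.constants.chem_t_start_ps, box=box
    )
    # clip any thermalization outlier into the box rather than losing it
    # before the chemistry starts
    m.positions = np.clip(m.positions, box.lo, box.hi)
    return m, edep
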