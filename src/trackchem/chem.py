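"""Chemical stage: step-by-step diffusion-reaction loop, 1 ps to 1 us.

The population of radiolysis species evolves through repeated application
of four kernels:

1. find all reactant pairs and react those already in contact
   (intermolecular distance below the pair's Smoluchowski radius);
2. compute a dynamic time step Delta_t = (d - R)^2 / (8 (sqrt(D_A) +
   sqrt(D_B))^2) from the closest candidate pair, clamped from below at
   Delta_t_min = 1 ps;
3. diffuse every molecule by an isotropic Gaussian step with per-axis
   standard deviation sqrt(2 D Delta_t); molecules leaving the simulation
   box are removed for good;
4. when the step was clamped, test surviving candidate pairs for an
   encounter *during* the step with the Brownian-bridge probability
   p = exp(-(d_i - R)(d_f - R) / (D_sum Delta_t)).

The pair search is exact: a brute-force O(N^2) reference and a k-d-tree
accelerated search that returns the identical pair set. Conflicts (a
molecule wanted by several reactions in one step) are resolved greedily by
increasing distance with a stable index tie-break; each molecule reacts at
most once per step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .physics import Box
from .registry import Registry, RegistryError

#: ignore bridge probabilities below this (numerical cutoff; at the 1 ps
#: clamp this corresponds to pairs within ~0.7 nm of contact)
BRIDGE_P_FLOOR = 1e-12


class MoleculeSet:
    """The chemical-stage population: positions, species, alive flags.

    Positions are nm, time is ps. ``box`` is the simulation region
    (molecules diffusing out are removed); None means unbounded.
    """

    def __init__(
        self,
        positions: np.ndarray,
        species_ids: np.ndarray,
        registry: Registry,
        t: float = 1.0,
        box: Box | None = None,
        alive: np.ndarray | None = None,
    ):
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        self.species_ids = np.asarray(species_ids, dtype=np.int64)
        if self.positions.shape[0] != self.species_ids.shape[0]:
            raise ValueError("positions and species ids must align")
        self.registry = registry
        self.t = float(t)
        self.box = box
        self.alive = (
            np.ones(len(self.species_ids), dtype=bool)
            if alive is None
            else np.asarray(alive, dtype=bool).copy()
        )

    @classmethod
    def from_names(
        cls,
        names,
        positions,
        registry: Registry,
        t: float = 1.0,
        box: Box | None = None,
    ) -> "MoleculeSet":
        ids = np.array([registry.species_id(n) for n in names], dtype=np.int64)
        pos = (
            np.asarray(positions, dtype=float).reshape(-1, 3)
            if len(ids)
            else np.empty((0, 3))
        )
        return cls(pos, ids, registry, t=t, box=box)

    def __len__(self) -> int:
        return int(self.alive.sum())

    @property
    def n_total(self) -> int:
        return len(self.species_ids)

    def counts(self) -> np.ndarray:
        """Alive molecules per species id."""
        return np.bincount(
            self.species_ids[self.alive], minlength=self.registry.n_species
        )

    def counts_by_name(self) -> dict[str, int]:
        c = self.counts()
        return {s.name: int(c[s.index]) for s in self.registry.species}

    def compact(self) -> None:
        """Drop dead molecules from the backing arrays."""
        keep = self.alive
        self.positions = self.positions[keep]
        self.species_ids = self.species_ids[keep]
        self.alive = np.ones(len(self.species_ids), dtype=bool)

    def add(self, species_ids: np.ndarray, positions: np.ndarray) -> None:
        if len(species_ids) == 0:
            return
        self.positions = np.vstack([self.positions, positions])
        self.species_ids = np.concatenate(
            [self.species_ids, np.asarray(species_ids, dtype=np.int64)]
        )
        self.alive = np.concatenate(
            [self.alive, np.ones(len(species_ids), dtype=bool)]
        )

    def copy(self) -> "MoleculeSet":
        return MoleculeSet(
            self.positions.copy(),
            self.species_ids.copy(),
            self.registry,
            t=self.t,
            box=self.box,
            alive=self.alive.copy(),
        )


@dataclass
class CandidatePairs:
    """Unordered reactive pairs with distances (global molecule indices)."""

    i: np.ndarray
    j: np.ndarray
    reaction: np.ndarray
    d: np.ndarray

    def __len__(self) -> int:
        return len(self.i)

    @classmethod
    def empty(cls) -> "CandidatePairs":
        z = np.empty(0, dtype=np.int64)
        return cls(z, z.copy(), z.copy(), np.empty(0))

    def select(self, mask: np.ndarray) -> "CandidatePairs":
        return CandidatePairs(
            self.i[mask], self.j[mask], self.reaction[mask], self.d[mask]
        )

    def canonical_set(self) -> set[tuple[int, int]]:
        return {
            (min(a, b), max(a, b)) for a, b in zip(self.i.tolist(), self.j.tolist())
        }


def find_candidate_pairs(
    m: MoleculeSet,
    registry: Registry | None = None,
    max_distance: float | None = None,
    method: str = "auto",
) -> CandidatePairs:
    """All unordered alive pairs whose species react, with distances.

    ``method`` is "brute" (exhaustive O(N^2) reference), "tree"
    (k-d-tree accelerated; identical result), or "auto". ``max_distance``
    restricts the search radius; None returns every reactive pair.
    """
    registry = registry or m.registry
    alive_idx = np.flatnonzero(m.alive)
    n = len(alive_idx)
    if n < 2:
        return CandidatePairs.empty()
    if method == "auto":
        method = "tree" if (max_distance is not None or n > 400) else "brute"
    pos = m.positions[alive_idx]
    sp = m.species_ids[alive_idx]

    if method == "brute":
        iu, ju = np.triu_indices(n, k=1)
        rxn = registry.reaction_table[sp[iu], sp[ju]]
        keep = rxn >= 0
        iu, ju, rxn = iu[keep], ju[keep], rxn[keep]
        d = np.linalg.norm(pos[iu] - pos[ju], axis=1)
        if max_distance is not None:
            keep = d <= max_distance
            iu, ju, rxn, d = iu[keep], ju[keep], rxn[keep], d[keep]
    elif method == "tree":
        if max_distance is None:
            span = pos.max(axis=0) - pos.min(axis=0)
            radius = float(np.linalg.norm(span)) + 1.0
        else:
            radius = max_distance
        tree = cKDTree(pos)
        pairs = tree.query_pairs(radius, output_type="ndarray")
        if len(pairs) == 0:
            return CandidatePairs.empty()
        iu, ju = pairs[:, 0], pairs[:, 1]
        rxn = registry.reaction_table[sp[iu], sp[ju]]
        keep = rxn >= 0
        iu, ju, rxn = iu[keep], ju[keep], rxn[keep]
        d = np.linalg.norm(pos[iu] - pos[ju], axis=1)
        if max_distance is not None:
            keep = d <= max_distance
            iu, ju, rxn, d = iu[keep], ju[keep], rxn[keep], d[keep]
    else:
        raise ValueError(f"unknown method {method!r}")

    gi, gj = alive_idx[iu], alive_idx[ju]
    swap = gi > gj
    gi2 = np.where(swap, gj, gi)
    gj2 = np.where(swap, gi, gj)
    return CandidatePairs(gi2, gj2, rxn, d)


@dataclass(frozen=True)
class ReactionEvent:
    i: int
    j: int
    reaction: int
    d: float


def resolve_conflicts(pairs: CandidatePairs) -> list[ReactionEvent]:
    """Greedy resolution: increasing distance, stable index tie-break.

    Each molecule is consumed at most once.
    """
    if len(pairs) == 0:
        return []
    order = np.lexsort((pairs.j, pairs.i, pairs.d))
    used: set[int] = set()
    events = []
    for k in order:
        a, b = int(pairs.i[k]), int(pairs.j[k])
        if a in used or b in used:
            continue
        used.add(a)
        used.add(b)
        events.append(ReactionEvent(a, b, int(pairs.reaction[k]), float(pairs.d[k])))
    return events


def react_contacts(
    m: MoleculeSet, pairs: CandidatePairs, registry: Registry | None = None
) -> list[ReactionEvent]:
    """Contact rule: every pair with d < R reacts, subject to conflicts."""
    registry = registry or m.registry
    in_contact = pairs.select(pairs.d < registry.radii[pairs.reaction])
    return resolve_conflicts(in_contact)


def place_products(
    event: ReactionEvent,
    registry: Registry,
    pos_i: np.ndarray,
    pos_j: np.ndarray,
    species_i: int,
) -> tuple[list[int], np.ndarray]:
    """Positions for the products of a resolved reaction event.

    One product sits at the reactants' midpoint; two products inherit the
    two parent positions, assigned stably: the first listed product goes
    to the parent matching the first listed reactant. A third product
    (the two-electron channel) goes to the midpoint.
    """
    products = registry.products_ids[event.reaction]
    if len(products) == 0:
        return [], np.empty((0, 3))
    mid = 0.5 * (pos_i + pos_j)
    if len(products) == 1:
        return list(products), mid.reshape(1, 3)
    first_reactant = registry.species_id(
        registry.reactions[event.reaction].reactants[0]
    )
    if species_i == first_reactant:
        anchors = [pos_i, pos_j]
    else:
        anchors = [pos_j, pos_i]
    coords = [anchors[0], anchors[1]] + [mid] * (len(products) - 2)
    return list(products), np.vstack(coords)


def apply_events(
    m: MoleculeSet,
    events: list[ReactionEvent],
    registry: Registry,
    positions_override: np.ndarray | None = None,
) -> np.ndarray:
    """Consume reactants, place products. Returns per-reaction counts.

    ``positions_override``, if given, supplies the effective parent
    positions (used by the bridge kernel, where the encounter happened
    somewhere along the step).
    """
    rxn_counts = np.zeros(len(registry.reactions), dtype=np.int64)
    if not events:
        return rxn_counts
    new_ids: list[int] = []
    new_pos: list[np.ndarray] = []
    src = positions_override if positions_override is not None else m.positions
    for ev in events:
        m.alive[ev.i] = False
        m.alive[ev.j] = False
        rxn_counts[ev.reaction] += 1
        ids, coords = place_products(
            ev, registry, src[ev.i], src[ev.j], int(m.species_ids[ev.i])
        )
        new_ids.extend(ids)
        new_pos.extend(coords)
    if new_ids:
        m.add(np.array(new_ids), np.vstack(new_pos))
    return rxn_counts


@dataclass
class StepContext:
    """Outcome of the dynamic-time-step kernel."""

    dt: float  # ps, final (after clamping and checkpoint capping)
    dt_raw: float  # ps, as computed from the closest pair (inf if none)
    clamped: bool
    d_min: float  # nm, distance of the governing pair (inf if none)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("time step must be positive")


def compute_time_step(
    m: MoleculeSet,
    pairs: CandidatePairs,
    registry: Registry | None = None,
    t_bound: float | None = None,
) -> StepContext:
    """Dynamic time step from the closest candidate pairs.

    Delta_t = (d - R)^2 / (8 (sqrt(D_A) + sqrt(D_B))^2), minimized over
    candidate pairs; below 1 ps the step is clamped to 1 ps and flagged
    (triggering the bridge kernel). With no candidate pairs the step runs
    to ``t_bound``. The step never overshoots ``t_bound``.
    """
    registry = registry or m.registry
    dt_min = registry.constants.dt_min_ps
    if len(pairs) > 0:
        gap = np.maximum(pairs.d - registry.radii[pairs.reaction], 0.0)
        per_pair = gap**2 / registry.step_denom[pairs.reaction]
        k = int(np.argmin(per_pair))
        dt_raw = float(per_pair[k])
        d_min = float(pairs.d[k])
    else:
        dt_raw = math.inf
        d_min = math.inf
    clamped = dt_raw < dt_min
    dt = max(dt_raw, dt_min)
    if t_bound is not None:
        remaining = t_bound - m.t
        if remaining <= 0:
            raise ValueError("time bound is not in the future")
        dt = min(dt, remaining)
    if not math.isfinite(dt):
        raise ValueError("unbounded time step: provide t_bound when no pairs exist")
    return StepContext(dt=dt, dt_raw=dt_raw, clamped=clamped, d_min=d_min)


def diffuse(
    m: MoleculeSet, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian diffusion step; removes molecules leaving the box.

    Per-axis displacement sigma = sqrt(2 D dt) (so the mean squared
    displacement is 6 D dt). Returns per-species counts of removed
    molecules. dt = 0 is a no-op.
    """
    escaped = np.zeros(m.registry.n_species, dtype=np.int64)
    if dt < 0:
        raise ValueError("time step must be non-negative")
    if dt == 0:
        return escaped
    idx = np.flatnonzero(m.alive)
    if len(idx):
        sigma = np.sqrt(2.0 * m.registry.D[m.species_ids[idx]] * dt)
        m.positions[idx] += rng.normal(size=(len(idx), 3)) * sigma[:, None]
        if m.box is not None:
            inside = m.box.contains(m.positions[idx])
            out = idx[~inside]
            if len(out):
                m.alive[out] = False
                escaped = np.bincount(
                    m.species_ids[out], minlength=m.registry.n_species
                )
    m.t += dt
    return escaped


def bridge_probability(
    d_i: np.ndarray, d_f: np.ndarray, radius: np.ndarray, d_sum: np.ndarray, dt: float
) -> np.ndarray:
    """Brownian-bridge encounter probability for a diffusing pair.

    p = exp(-(d_i - R)(d_f - R) / (D_sum dt)), clipped to [0, 1]; contact
    at either endpoint (d <= R) gives p = 1.
    """
    gi = np.asarray(d_i) - radius
    gf = np.asarray(d_f) - radius
    with np.errstate(over="ignore"):
        p = np.exp(-gi * gf / (d_sum * dt))
    p = np.clip(p, 0.0, 1.0)
    return np.where((gi <= 0) | (gf <= 0), 1.0, p)


def bridge_check(
    m: MoleculeSet,
    pre_positions: np.ndarray,
    pairs: CandidatePairs,
    dt: float,
    registry: Registry | None = None,
    rng: np.random.Generator | None = None,
) -> list[ReactionEvent]:
    """Kernel 4: encounters during a clamped step.

    ``pairs`` are the surviving candidate pairs (identified before the
    diffusion step); ``pre_positions`` the positions before diffusion.
    Accepted events are conflict-resolved by post-step distance and their
    products are anchored at the average of each parent's pre- and
    post-step positions.
    """
    registry = registry or m.registry
    rng = rng if rng is not None else np.random.default_rng()
    ok = m.alive[pairs.i] & m.alive[pairs.j]
    pairs = pairs.select(ok)
    if len(pairs) == 0:
        return []
    d_f = np.linalg.norm(m.positions[pairs.i] - m.positions[pairs.j], axis=1)
    p = bridge_probability(
        pairs.d,
        d_f,
        registry.radii[pairs.reaction],
        registry.d_sum[pairs.reaction],
        dt,
    )
    accept = (p >= BRIDGE_P_FLOOR) & (rng.random(len(p)) < p)
    chosen = CandidatePairs(
        pairs.i[accept], pairs.j[accept], pairs.reaction[accept], d_f[accept]
    )
    return resolve_conflicts(chosen)


@dataclass
class ChemResult:
    """Species-count time series for one chemical-stage run."""

    times: np.ndarray  # ps
    counts: np.ndarray  # (T, S)
    species_names: list[str]
    reaction_counts: np.ndarray  # per Table-row channel
    escaped_counts: np.ndarray  # per species
    n_steps: int
    final: MoleculeSet

    def count_series(self, species: str) -> np.ndarray:
        return self.counts[:, self.final.registry.species_id(species)]


def run_chemical_stage(
    initial: MoleculeSet,
    registry: Registry | None = None,
    sample_times: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    bridge_all_pairs: bool = False,
    max_steps: int = 5_000_000,
) -> ChemResult:
    """Evolve a 1 ps population to the end of the chemical window.

    ``sample_times`` (ps) default to a 10-points-per-decade log grid over
    [1 ps, 1 us]; the stepper lands on each sample time exactly. With
    ``bridge_all_pairs`` the bridge kernel re-searches every reactive pair
    instead of the pre-identified candidates (slower; for cross-checks).
    """
    registry = registry or initial.registry
    rng = rng if rng is not None else np.random.default_rng()
    const = registry.constants
    if sample_times is None:
        sample_times = np.logspace(
            math.log10(const.chem_t_start_ps), math.log10(const.chem_t_end_ps), 61
        )
    sample_times = np.asarray(sorted(sample_times), dtype=float)
    if sample_times[0] < const.chem_t_start_ps - 1e-9 or sample_times[-1] > const.chem_t_end_ps + 1e-9:
        raise ValueError("sample times must lie inside the chemical window")

    m = initial.copy()
    if abs(m.t - const.chem_t_start_ps) > 1e-9:
        raise ValueError("initial population must be timestamped at the window start")

    S = registry.n_species
    counts_out = np.zeros((len(sample_times), S), dtype=np.int64)
    rxn_counts = np.zeros(len(registry.reactions), dtype=np.int64)
    escaped = np.zeros(S, dtype=np.int64)

    # relevance horizon for the bridge kernel at the clamp: beyond this
    # gap the acceptance probability is below BRIDGE_P_FLOOR
    bridge_margin = math.sqrt(
        -math.log(BRIDGE_P_FLOOR) * float(registry.d_sum.max()) * const.dt_min_ps
    )
    r_contact = registry.max_radius + bridge_margin
    denom_max = float(registry.step_denom.max())
    r_work = max(4.0 * r_contact, 5.0)

    next_sample = 0
    eps = 1e-9
    # record any sample times already reached (the first is t_start)
    while next_sample < len(sample_times) and sample_times[next_sample] <= m.t + eps:
        counts_out[next_sample] = m.counts()
        next_sample += 1

    n_steps = 0
    t_end = sample_times[-1]
    while m.t < t_end - eps:
        n_steps += 1
        if n_steps > max_steps:
            raise RuntimeError("chemical stage failed to finish (max steps)")
        if m.n_total > 2 * len(m) + 64:
            m.compact()
        if len(m) == 0:
            m.t = t_end
            break

        # Kernel 1: pair search within the working radius + contact reactions
        pairs = find_candidate_pairs(m, registry, max_distance=r_work, method="tree")
        rxn_counts += apply_events(m, react_contacts(m, pairs, registry), registry)
        ok = m.alive[pairs.i] & m.alive[pairs.j]
        pairs = pairs.select(ok)

        # Kernel 2: dynamic time step. The working radius bounds the
        # smallest step a pair beyond it could demand; expand until the
        # in-radius minimum is authoritative.
        t_bound = sample_times[next_sample]
        ctx = compute_time_step(m, pairs, registry, t_bound=t_bound)
        while True:
            dt_outside_bound = max(r_work - registry.max_radius, 0.0) ** 2 / denom_max
            if ctx.dt_raw <= dt_outside_bound or len(m) < 2:
                break
            span = m.positions[m.alive].max(axis=0) - m.positions[m.alive].min(axis=0)
            diam = float(np.linalg.norm(span))
            if r_work >= diam:
                break
            r_work = min(2.5 * r_work, max(diam, r_work))
            pairs = find_candidate_pairs(
                m, registry, max_distance=r_work, method="tree"
            )
            rxn_counts += apply_events(m, react_contacts(m, pairs, registry), registry)
            ok = m.alive[pairs.i] & m.alive[pairs.j]
            pairs = pairs.select(ok)
            ctx = compute_time_step(m, pairs, registry, t_bound=t_bound)
        # shrink the working radius when the population has spread out
        target = max(4.0 * r_contact, 3.0 * ctx.d_min if math.isfinite(ctx.d_min) else r_work)
        r_work = max(min(r_work, target), 4.0 * r_contact)

        # Kernel 3: diffusion
        pre_positions = m.positions.copy()
        escaped += diffuse(m, ctx.dt, rng)

        # Kernel 4: bridge check for clamped steps
        if ctx.clamped:
            if bridge_all_pairs:
                check = find_candidate_pairs(m, registry, method="brute")
                # distances before the step for these indices
                valid = (check.i < len(pre_positions)) & (check.j < len(pre_positions))
                check = check.select(valid)
                check = CandidatePairs(
                    check.i,
                    check.j,
                    check.reaction,
                    np.linalg.norm(
                        pre_positions[check.i] - pre_positions[check.j], axis=1
                    ),
                )
            else:
                check = pairs
            events = bridge_check(m, pre_positions, check, ctx.dt, registry, rng)
            if events:
                effective = 0.5 * (pre_positions + m.positions[: len(pre_positions)])
                rxn_counts += apply_events(
                    m, events, registry, positions_override=effective
                )

        while next_sample < len(sample_times) and sample_times[next_sample] <= m.t + eps:
            counts_out[next_sample] = m.counts()
            next_sample += 1

    while next_sample < len(sample_times):
        counts_out[next_sample] = m.counts()
        next_sample += 1

    return ChemResult(
        times=sample_times,
        counts=counts_out,
        species_names=[s.name for s in registry.species],
        reaction_counts=rxn_counts,
        escaped_counts=escaped,
        n_steps=n_steps,
        final=m,
    )
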