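"""Chemical stage: pair search, contact rule, time step, diffusion, bridge."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trackchem as tc
from trackchem.chem import (
    CandidatePairs,
    MoleculeSet,
    apply_events,
    bridge_check,
    bridge_probability,
    compute_time_step,
    diffuse,
    find_candidate_pairs,
    react_contacts,
    resolve_conflicts,
    run_chemical_stage,
)
from trackchem.physics import Box
from trackchem.trackgen import toy_pair


def _random_set(registry, rng, n, box_side=20.0):
    ids = rng.integers(0, registry.n_species, size=n)
    pos = rng.uniform(-box_side / 2, box_side / 2, size=(n, 3))
    return MoleculeSet(pos, ids, registry, t=1.0)


class TestPairSearch:
    def test_single_molecule_no_pairs(self, registry):
        m = MoleculeSet.from_names(["OH"], [[0, 0, 0]], registry)
        assert len(find_candidate_pairs(m, registry)) == 0

    def test_only_reactive_pairs_reported(self, registry):
        m = MoleculeSet.from_names(
            ["eaq-", "OH", "H2"],
            [[0, 0, 0], [1, 0, 0], [0, 1, 0]],
            registry,
        )
        pairs = find_candidate_pairs(m, registry)
        assert len(pairs) == 1
        assert {registry.species[m.species_ids[pairs.i[0]]].name,
                registry.species[m.species_ids[pairs.j[0]]].name} == {"eaq-", "OH"}

    @pytest.mark.parametrize("max_distance", [None, 2.5])
    def test_tree_matches_bruteforce(self, registry, rng, max_distance):
        for _ in range(20):
            m = _random_set(registry, rng, 50, box_side=8.0)
            brute = find_candidate_pairs(m, registry, max_distance, "brute")
            tree = find_candidate_pairs(m, registry, max_distance, "tree")
            assert brute.canonical_set() == tree.canonical_set()
            assert sorted(brute.d.tolist()) == pytest.approx(sorted(tree.d.tolist()))

    def test_dead_molecules_ignored(self, registry):
        m = MoleculeSet.from_names(
            ["eaq-", "OH"], [[0, 0, 0], [0.1, 0, 0]], registry
        )
        m.alive[1] = False
        assert len(find_candidate_pairs(m, registry)) == 0


class TestContactRule:
    def test_pair_inside_radius_reacts(self, registry):
        # R(eaq-, OH) ~ 0.5063 nm
        m = toy_pair("eaq-", "OH", 0.40, registry)
        pairs = find_candidate_pairs(m, registry)
        events = react_contacts(m, pairs, registry)
        assert len(events) == 1
        apply_events(m, events, registry)
        assert m.counts_by_name()["OH-"] == 1
        assert m.counts_by_name()["eaq-"] == 0 and m.counts_by_name()["OH"] == 0

    def test_pair_outside_radius_does_not(self, registry):
        m = toy_pair("eaq-", "OH", 0.60, registry)
        assert react_contacts(m, find_candidate_pairs(m, registry), registry) == []

    def test_three_close_hydroxyls_single_peroxide(self, registry):
        m = MoleculeSet.from_names(
            ["OH", "OH", "OH"],
            [[0, 0, 0], [0.05, 0, 0], [0.0, 0.05, 0]],
            registry,
        )
        events = react_contacts(m, find_candidate_pairs(m, registry), registry)
        assert len(events) == 1
        apply_events(m, events, registry)
        c = m.counts_by_name()
        assert c["H2O2"] == 1 and c["OH"] == 1

    def test_conflict_resolution_prefers_closest(self, registry):
        pairs = CandidatePairs(
            i=np.array([0, 0]), j=np.array([1, 2]),
            reaction=np.array([0, 0]), d=np.array([0.3, 0.1]),
        )
        events = resolve_conflicts(pairs)
        assert len(events) == 1 and events[0].j == 2


class TestPlacement:
    def test_single_product_at_midpoint(self, registry):
        m = toy_pair("H", "H", 0.05, registry)
        events = react_contacts(m, find_candidate_pairs(m, registry), registry)
        apply_events(m, events, registry)
        idx = np.flatnonzero(m.alive)
        assert registry.species[m.species_ids[idx[0]]].name == "H2"
        assert np.allclose(m.positions[idx[0]], [0.025, 0.0, 0.0])

    def test_two_products_inherit_parent_positions(self, registry):
        m = MoleculeSet.from_names(
            ["eaq-", "H2O2"], [[0, 0, 0], [0.2, 0, 0]], registry
        )
        events = react_contacts(m, find_candidate_pairs(m, registry), registry)
        apply_events(m, events, registry)
        pos = {
            registry.species[m.species_ids[k]].name: m.positions[k]
            for k in np.flatnonzero(m.alive)
        }
        # products (OH-, OH) map to reactant order (eaq-, H2O2)
        assert np.allclose(pos["OH-"], [0, 0, 0])
        assert np.allclose(pos["OH"], [0.2, 0, 0])

    def test_three_products_stay_in_box(self, registry):
        box = Box.cube(10.0)
        m = MoleculeSet.from_names(
            ["eaq-", "eaq-"], [[0, 0, 0], [0.05, 0, 0]], registry, box=box
        )
        events = react_contacts(m, find_candidate_pairs(m, registry), registry)
        apply_events(m, events, registry)
        c = m.counts_by_name()
        assert c["H2"] == 1 and c["OH-"] == 2
        assert box.contains(m.positions[m.alive]).all()


class TestTimeStep:
    def test_contact_limit_clamps(self, registry):
        rxn = registry.lookup_reaction("OH", "OH")
        m = toy_pair("OH", "OH", rxn.radius, registry)
        ctx = compute_time_step(m, find_candidate_pairs(m, registry), registry)
        assert ctx.clamped and ctx.dt == registry.constants.dt_min_ps
        assert ctx.dt_raw == 0.0

    def test_hydroxyl_pair_gap_one_nm(self, registry):
        # (1 nm)^2 / (8 (2 sqrt(D))^2) with D = 2.8e-3 nm^2/ps -> 11.16 ps
        rxn = registry.lookup_reaction("OH", "OH")
        m = toy_pair("OH", "OH", rxn.radius + 1.0, registry)
        ctx = compute_time_step(m, find_candidate_pairs(m, registry), registry)
        assert not ctx.clamped
        assert ctx.dt == pytest.approx(1.0 / (32.0 * 2.8e-3), rel=1e-9)
        assert ctx.dt == pytest.approx(11.16, abs=0.01)

    @settings(derandomize=True, max_examples=30)
    @given(gap=st.floats(0.1, 50.0), d=st.floats(1e-4, 1e-1))
    def test_equal_coefficients_reduce_to_32d(self, gap, d):
        denom = 8.0 * (math.sqrt(d) + math.sqrt(d)) ** 2
        assert denom == pytest.approx(32.0 * d, rel=1e-12)
        assert gap**2 / denom == pytest.approx(gap**2 / (32.0 * d), rel=1e-12)

    def test_no_pairs_runs_to_bound(self, registry):
        m = MoleculeSet.from_names(["H2"], [[0, 0, 0]], registry, t=1.0)
        ctx = compute_time_step(
            m, find_candidate_pairs(m, registry), registry, t_bound=101.0
        )
        assert ctx.dt == pytest.approx(100.0) and not ctx.clamped

    def test_checkpoint_capping(self, registry):
        rxn = registry.lookup_reaction("OH", "OH")
        m = toy_pair("OH", "OH", rxn.radius + 1.0, registry)
        ctx = compute_time_step(
            m, find_candidate_pairs(m, registry), registry, t_bound=3.0
        )
        assert ctx.dt == pytest.approx(2.0)


class TestDiffusion:
    def test_zero_step_is_noop(self, registry, rng):
        m = toy_pair("OH", "OH", 5.0, registry)
        before = m.positions.copy()
        diffuse(m, 0.0, rng)
        assert np.array_equal(m.positions, before)

    def test_msd_matches_einstein_relation(self, registry, rng):
        # 1e5 hydronium ions over 1 ps: MSD = 6 D dt
        n = 100_000
        ids = np.full(n, registry.species_id("H3O+"))
        m = MoleculeSet(np.zeros((n, 3)), ids, registry, t=1.0)
        diffuse(m, 1.0, rng)
        msd = (m.positions**2).sum(axis=1).mean()
        assert msd == pytest.approx(6.0 * 9.0e-3 * 1.0, rel=0.01)
        assert math.sqrt(msd) == pytest.approx(0.2324, abs=0.002)

    def test_box_exit_removes_permanently(self, registry, rng):
        box = Box.cube(1.0)
        n = 1000
        ids = np.full(n, registry.species_id("H3O+"))
        m = MoleculeSet(np.zeros((n, 3)), ids, registry, t=1.0, box=box)
        escaped = diffuse(m, 1.0e6, rng)  # sigma ~ 134 nm >> box
        assert escaped[registry.species_id("H3O+")] == n
        assert len(m) == 0


class TestBridge:
    def test_contact_gives_certainty(self):
        p = bridge_probability(
            np.array([0.5]), np.array([3.0]), np.array([0.5]), np.array([5.6e-3]), 1.0
        )
        assert p[0] == 1.0

    def test_symmetric_tenth_nanometer_gap(self):
        # gaps of 0.1 nm, D_sum = 5.6e-3 nm^2/ps, dt = 1 ps
        p = bridge_probability(
            np.array([0.2038]), np.array([0.2038]),
            np.array([0.1038]), np.array([5.6e-3]), 1.0,
        )
        assert p[0] == pytest.approx(math.exp(-0.01 / 5.6e-3), rel=1e-9)
        assert p[0] == pytest.approx(0.1676, abs=2e-4)

    def test_wide_gap_is_negligible(self):
        p = bridge_probability(
            np.array([1.1038]), np.array([1.1038]),
            np.array([0.1038]), np.array([5.6e-3]), 1.0,
        )
        assert p[0] < 1e-50

    @settings(derandomize=True, max_examples=60)
    @given(
        di=st.floats(0.0, 5.0),
        df=st.floats(0.0, 5.0),
        radius=st.floats(0.05, 1.5),
        dsum=st.floats(1e-3, 2e-2),
    )
    def test_probability_bounds(self, di, df, radius, dsum):
        p = float(
            bridge_probability(
                np.array([di]), np.array([df]), np.array([radius]),
                np.array([dsum]), 1.0,
            )[0]
        )
        assert 0.0 <= p <= 1.0
        if di <= radius or df <= radius:
            assert p == 1.0

    def test_bridge_reacts_clamped_near_pair(self, registry):
        """A pair just outside contact reacts during a clamped step with
        the analytic bridge frequency."""
        rxn = registry.lookup_reaction("OH", "OH")
        hits = 0
        trials = 2000
        rng = np.random.default_rng(8)
        for _ in range(trials):
            m = toy_pair("OH", "OH", rxn.radius + 0.05, registry)
            pre = m.positions.copy()
            pairs = find_candidate_pairs(m, registry)
            diffuse(m, 1.0, rng)
            events = bridge_check(m, pre, pairs, 1.0, registry, rng)
            hits += len(events)
        # acceptance frequency is E[p(d_f)] under the diffusion kernel;
        # loose physical bracket: well above 0, well below 1
        assert 0.3 < hits / trials < 0.95


class TestRunChemicalStage:
    def test_empty_population(self, registry, rng):
        m = MoleculeSet.from_names([], [], registry, t=1.0)
        res = run_chemical_stage(m, registry, rng=rng)
        assert res.counts.sum() == 0
        assert res.times[0] == 1.0 and res.times[-1] == pytest.approx(1e6)

    def test_contact_pair_reacts_first_iteration(self, registry, rng):
        m = toy_pair("eaq-", "OH", 0.3, registry)
        res = run_chemical_stage(m, registry, rng=rng)
        # the first sample is the 1 ps initial state; the contact reaction
        # fires in the first iteration after it
        assert res.count_series("OH-")[1] == 1
        assert res.count_series("OH-")[-1] == 1
        assert res.count_series("eaq-")[1:].sum() == 0

    def test_nonreactive_pair_unchanged(self, registry, rng):
        m = toy_pair("H2", "H2O2", 1.0, registry)
        res = run_chemical_stage(m, registry, rng=rng)
        assert res.count_series("H2")[-1] == 1
        assert res.count_series("H2O2")[-1] == 1

    def test_species_change_ledger(self, registry, rng):
        """Every count change is a tabulated reaction or a boundary exit."""
        box = Box.cube(40.0)
        n = 120
        ids = rng.integers(0, registry.n_species, size=n)
        pos = rng.uniform(-15, 15, size=(n, 3))
        m = MoleculeSet(pos, ids, registry, t=1.0, box=box)
        initial = m.counts()
        res = run_chemical_stage(m, registry, rng=rng)
        stoich = np.zeros((len(registry.reactions), registry.n_species), int)
        for r in registry.reactions:
            a, b = (registry.species_id(x) for x in r.reactants)
            stoich[r.index, a] -= 1
            stoich[r.index, b] -= 1
            for pid in registry.products_ids[r.index]:
                stoich[r.index, pid] += 1
        predicted = initial + res.reaction_counts @ stoich - res.escaped_counts
        assert np.array_equal(predicted, res.counts[-1])

    def test_deterministic_for_fixed_seed(self, registry):
        results = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            m = _random_set(registry, rng, 60, box_side=10.0)
            m.box = Box.cube(200.0)
            results.append(run_chemical_stage(m, registry, rng=rng))
        assert np.array_equal(results[0].counts, results[1].counts)
        assert np.array_equal(
            results[0].final.positions[results[0].final.alive],
            results[1].final.positions[results[1].final.alive],
        )

    def test_unclamped_step_rarely_overshoots_contact(self, registry):
        """The dynamic step keeps pairs outside R at step end (statistical
        form: < 2% of trials end inside the reaction radius)."""
        rxn = registry.lookup_reaction("OH", "OH")
        gap = 0.7  # unclamped: dt_raw = 0.49/0.0896 ~ 5.5 ps
        dt = gap**2 / (32.0 * 2.8e-3)
        assert dt > registry.constants.dt_min_ps
        rng = np.random.default_rng(4)
        inside = 0
        trials = 10_000
        sigma = math.sqrt(2.0 * 2.8e-3 * dt)
        d0 = np.array([rxn.radius + gap, 0.0, 0.0])
        for _ in range(trials):
            delta = (rng.normal(size=3) - rng.normal(size=3)) * sigma
            if np.linalg.norm(d0 + delta) < rxn.radius:
                inside += 1
        assert inside / trials < 0.02

    def test_reaction_events_identical_across_search_methods(self, registry):
        """Conflict-resolved contact events from the accelerated search
        match the exhaustive O(N^2) reference exactly."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = _random_set(registry, rng, 80, box_side=4.0)
            ev_brute = react_contacts(
                m, find_candidate_pairs(m, registry, method="brute"), registry
            )
            ev_tree = react_contacts(
                m, find_candidate_pairs(m, registry, method="tree"), registry
            )
            assert [(e.i, e.j, e.reaction) for e in ev_brute] == [
                (e.i, e.j, e.reaction) for e in ev_tree
            ]
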