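"""Occupancy dynamics: rate formulas, update semantics, and two
independent oracles (single-patch stationary law, exact 3-patch
enumeration)."""

import itertools

import numpy as np
import pytest

from dynspom.landscape import advance_age
from dynspom.species import SpeciesParams, colonization_modifier, extinction_modifier
from dynspom.spom import (
    OccupancyState,
    bernoulli_update,
    colonization_spatial,
    combine_rates,
    connectivity,
    extinction_spatial,
    initial_state,
    simulate_trajectory,
    step_occupancy,
    step_rates,
)
from conftest import make_landscape


def state_for(landscape, occupied):
    return OccupancyState(patch_ids=landscape.ids.copy(),
                          occupied=np.asarray(occupied, dtype=bool))


class TestConnectivity:
    def test_no_occupied_neighbours_gives_zero(self, two_patch_landscape, mid_species):
        S = connectivity(two_patch_landscape, state_for(two_patch_landscape, [0, 0]),
                         mid_species)
        np.testing.assert_array_equal(S, 0.0)

    def test_kernel_at_mean_dispersal_distance(self, mid_species):
        """One occupied 1-ha neighbour at d = 1/alpha: S = exp(-1)."""
        ls = make_landscape([0.0, 1 / mid_species.alpha], [0.0, 0.0], [1.0, 1.0])
        S = connectivity(ls, state_for(ls, [0, 1]), mid_species)
        assert S[0] == pytest.approx(np.exp(-1))
        assert S[1] == 0.0  # its only neighbour is empty

    def test_degenerate_zero_distance_unit_areas(self, mid_species):
        ls = make_landscape([5.0, 5.0], [5.0, 5.0], [1.0, 1.0])
        S = connectivity(ls, state_for(ls, [0, 1]), mid_species)
        assert S[0] == pytest.approx(1.0)

    def test_misaligned_state_rejected(self, two_patch_landscape, mid_species):
        bad = OccupancyState(patch_ids=np.array([5, 9]),
                             occupied=np.array([True, False]))
        with pytest.raises(ValueError, match="aligned"):
            connectivity(two_patch_landscape, bad, mid_species)

    def test_lower_alpha_never_decreases_connectivity(self, rng):
        """Better dispersers (smaller alpha) see higher connectivity."""
        from dynspom.landscape import generate_landscape

        ls = generate_landscape(cover=0.05, seed=21)
        occ = rng.random(ls.n_patches) < 0.5
        st = state_for(ls, occ)
        base = dict(species_id=0, y=10.0, A0=0.05, preference="mid")
        S_low = connectivity(ls, st, SpeciesParams(alpha=0.02, **base))
        S_high = connectivity(ls, st, SpeciesParams(alpha=0.001, **base))
        assert np.all(S_high >= S_low)


@pytest.mark.parametrize("S,y,expected", [
    (0.0, 5.0, 0.0),
    (5.0, 5.0, 0.5),
    (2.0, 5.0, 4 / 29),
])
def test_colonization_spatial_examples(S, y, expected):
    assert colonization_spatial(S, y) == pytest.approx(expected)


@pytest.mark.parametrize("A,e,x,expected", [
    (0.5, 0.05, 1.0, 0.1),
    (0.04, 0.05, 1.0, 1.0),   # below critical area: certain extinction
    (0.05, 0.05, 1.0, 1.0),   # threshold uses <=
    (1.0, 0.1, 1.0, 0.1),     # unit-area definition of e
])
def test_extinction_spatial_examples(A, e, x, expected):
    assert extinction_spatial(A, e, x) == pytest.approx(expected)


class TestCombineRates:
    def test_unsuitable_stage_vetoes_colonization(self):
        C, _ = combine_rates(0.9, 0.0, 0.1, 0.1)
        assert C == 0.0

    def test_or_rule_examples(self):
        _, E = combine_rates(0.5, 0.5, 0.1, 0.1, extinction_rule="or")
        assert E == pytest.approx(0.19)
        _, E = combine_rates(0.5, 0.5, 0.3, 1.0, extinction_rule="or")
        assert E == 1.0  # certain successional extinction under OR

    def test_product_rule_default(self):
        C, E = combine_rates(0.4, 0.5, 0.3, 0.5)
        assert C == pytest.approx(0.2)
        assert E == pytest.approx(0.15)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            combine_rates(1.2, 0.5, 0.1, 0.1)
        with pytest.raises(ValueError):
            combine_rates(0.5, 0.5, -0.1, 0.1)


class TestStepOccupancy:
    def test_empty_state_is_absorbing_under_allee(self, mid_species, rng):
        """S=0 => C_is=0: an empty metapopulation stays empty."""
        ls = make_landscape([100, 400, 800], [100, 400, 800],
                            [0.5, 0.5, 0.5], age=[50, 50, 50])
        st = state_for(ls, [0, 0, 0])
        for _ in range(20):
            st = step_occupancy(ls, st, mid_species, rng)
        assert not st.occupied.any()

    def test_zero_extinction_keeps_occupied(self, rng):
        occ = np.array([True, True, False])
        out = bernoulli_update(occ, C=np.zeros(3), E=np.zeros(3), rng=rng)
        np.testing.assert_array_equal(out, occ)

    def test_no_rescue_effect(self, late_species):
        """E is invariant to connectivity changes at fixed area and age."""
        ls = make_landscape([0, 200, 400], [0, 0, 0], [0.5, 0.5, 0.5],
                            age=[80, 80, 80])
        r_empty = step_rates(ls, state_for(ls, [1, 0, 0]), late_species)
        r_full = step_rates(ls, state_for(ls, [1, 1, 1]), late_species)
        assert not np.allclose(r_empty.S, r_full.S)
        np.testing.assert_array_equal(r_empty.E, r_full.E)

    def test_single_patch_stationary_occupancy(self):
        """Two-state chain with constant forced rates: long-run occupancy
        matches the stationary law J = C/(C+E) within 3 corrected SEs."""
        C, E, n_steps = 0.3, 0.1, 100_000
        rng = np.random.default_rng(77)
        occ = np.array([True])
        Ca, Ea = np.array([C]), np.array([E])
        hits = 0
        for _ in range(n_steps):
            occ = bernoulli_update(occ, Ca, Ea, rng)
            hits += int(occ[0])
        J = C / (C + E)
        # autocorrelated chain: inflate the binomial SE by (1+rho)/(1-rho),
        # rho = 1 - C - E
        rho = 1 - C - E
        se = np.sqrt(J * (1 - J) / n_steps * (1 + rho) / (1 - rho))
        assert abs(hits / n_steps - J) < 3 * se


class TestEnumerationOracle:
    """Exact two-step distribution over the 8 occupancy configurations of
    a static 3-patch system, by direct enumeration of the transition
    probabilities, versus simulated frequencies."""

    @staticmethod
    def _exact_rates(ls, occ, sp):
        """Independent evaluation of the per-patch rates from the model
        definition (kernel sum, Allee colonization, area extinction,
        product combination) without using the library's rate code."""
        n = ls.n_patches
        C = np.empty(n)
        E = np.empty(n)
        for i in range(n):
            S = 0.0
            for j in range(n):
                if j == i or not occ[j]:
                    continue
                d = np.hypot(ls.x[i] - ls.x[j], ls.y[i] - ls.y[j])
                S += np.exp(-sp.alpha * d) * ls.area[j] ** sp.b
            S *= ls.area[i] ** sp.c
            C_is = S**2 / (S**2 + sp.y**2)
            E_is = min(1.0, sp.e / ls.area[i] ** sp.x)
            if ls.area[i] <= sp.e ** (1 / sp.x):
                E_is = 1.0
            C_it = colonization_modifier(sp.preference, ls.age[i])
            E_it = extinction_modifier(sp.preference, ls.age[i])
            C[i] = C_is * C_it
            E[i] = E_is * E_it
        return C, E

    def _two_step_distribution(self, ls, sp, init):
        states = list(itertools.product([0, 1], repeat=3))
        dist = {s: 0.0 for s in states}
        dist[tuple(init)] = 1.0
        cur = ls
        for _ in range(2):
            C, E = {}, {}
            for s in states:
                C[s], E[s] = self._exact_rates(cur, np.array(s, bool), sp)
            new = {s: 0.0 for s in states}
            for s, p in dist.items():
                if p == 0.0:
                    continue
                for t in states:
                    q = 1.0
                    for i in range(3):
                        if s[i]:
                            q *= (1 - E[s][i]) if t[i] else E[s][i]
                        else:
                            q *= C[s][i] if t[i] else (1 - C[s][i])
                    new[t] += p * q
            dist = new
            cur = advance_age(cur)
        return dist

    def test_simulation_matches_exact_enumeration(self, rng):
        sp = SpeciesParams(species_id=0, alpha=0.004, y=2.0, A0=0.05,
                           preference="mid")
        ls = make_landscape([0, 150, 320], [0, 120, 40], [0.8, 0.5, 0.3],
                            age=[20, 45, 70])
        init = np.array([1, 0, 1], bool)
        exact = self._two_step_distribution(ls, sp, init)
        assert abs(sum(exact.values()) - 1.0) < 1e-12

        n_rep = 50_000
        counts = {s: 0 for s in exact}
        for _ in range(n_rep):
            st = state_for(ls, init)
            cur = ls
            for _ in range(2):
                st = step_occupancy(cur, st, sp, rng)
                cur = advance_age(cur)
            counts[tuple(int(v) for v in st.occupied)] += 1
        for s, p in exact.items():
            se = np.sqrt(max(p * (1 - p), 1e-12) / n_rep)
            assert abs(counts[s] / n_rep - p) < 4 * se + 2 / n_rep, (
                f"configuration {s}: simulated {counts[s] / n_rep:.5f} "
                f"vs exact {p:.5f}")


class TestTrajectory:
    def test_static_landscape_keeps_patch_ids(self, late_species):
        from dynspom.landscape import generate_landscape

        ls = generate_landscape(side=1500, cover=0.05, seed=3)
        frac, final_ls, _ = simulate_trajectory(
            ls, late_species, dynamism=0.0, steps=10, seed=5, return_state=True)
        np.testing.assert_array_equal(final_ls.ids, ls.ids)
        np.testing.assert_array_equal(final_ls.age, ls.age + 10)
        assert frac.shape == (11,)

    def test_empty_start_stays_empty(self, late_species):
        from dynspom.landscape import generate_landscape

        ls = generate_landscape(side=1500, cover=0.05, seed=3)
        frac = simulate_trajectory(ls, late_species, dynamism=0.1, steps=20,
                                   init_occupancy=0.0, seed=5)
        np.testing.assert_array_equal(frac, 0.0)

    def test_fixed_seed_reproduces_trajectory(self, mid_species):
        from dynspom.landscape import generate_landscape

        ls = generate_landscape(side=1500, cover=0.05, seed=3)
        a = simulate_trajectory(ls, mid_species, 0.1, steps=30, seed=9)
        b = simulate_trajectory(ls, mid_species, 0.1, steps=30, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_initial_occupancy_fraction(self, mid_species, rng):
        from dynspom.landscape import generate_landscape

        ls = generate_landscape(side=3163, cover=0.10, seed=3)
        st = initial_state(ls, 0.5, rng)
        assert st.occupied.sum() == 100
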