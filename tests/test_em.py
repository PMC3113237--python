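"""EM core: candidate counting, noisy-OR arithmetic, and convergence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domgi.em import (
    EMConfig,
    PairCounts,
    count_k,
    em_fit,
    enumerate_candidate_pairs,
    penalized_loglik,
    protein_pair_probability,
)
from domgi.io import DomainAssignment, InteractionCatalog
from domgi.simulate import WorldParams, generate_world


def brute_force_noisy_or(theta_values):
    """Oracle: sum over all 2^k on/off configurations with >= 1 pair on."""
    k = len(theta_values)
    total = 0.0
    for mask in range(1, 2**k):
        prob = 1.0
        for pos, t in enumerate(theta_values):
            prob *= t if mask & (1 << pos) else 1.0 - t
        total += prob
    return total


class TestCandidateEnumeration:
    def test_single_domain_pair(self, toy_catalog, toy_assignments):
        counts = enumerate_candidate_pairs(toy_catalog, toy_assignments)
        assert set(counts) == {("d1", "d2")}
        assert counts[("d1", "d2")].m0 == 1

    def test_double_orientation_counted_once(self):
        assign = DomainAssignment(
            {"A": frozenset({"d1", "d2"}), "B": frozenset({"d1", "d2"})}
        )
        counts = enumerate_candidate_pairs(
            InteractionCatalog(frozenset({("A", "B")})), assign
        )
        assert {k: c.m0 for k, c in counts.items()} == {
            ("d1", "d1"): 1,
            ("d1", "d2"): 1,
            ("d2", "d2"): 1,
        }

    def test_m0_accumulates_across_slgis(self, toy_assignments):
        catalog = InteractionCatalog(frozenset({("A", "B"), ("A", "C")}))
        counts = enumerate_candidate_pairs(catalog, toy_assignments)
        assert counts[("d1", "d2")].m0 == 2


class TestCountK:
    def test_excludes_catalog_pairs(self):
        assign = DomainAssignment(
            {
                "A": frozenset({"d1"}),
                "B": frozenset({"d2"}),
                "C": frozenset({"d2"}),
            }
        )
        catalog = InteractionCatalog(frozenset({("A", "B")}))
        assert count_k(("d1", "d2"), assign, {"A", "B", "C"}, catalog) == 1

    def test_self_domain_pair_counts_choose_two(self):
        assign = DomainAssignment({p: frozenset({"d"}) for p in "XYZ"})
        catalog = InteractionCatalog(frozenset())
        assert count_k(("d", "d"), assign, {"X", "Y", "Z"}, catalog) == 3

    def test_absent_domain_gives_zero(self, toy_assignments, toy_catalog):
        assert count_k(("d1", "zz"), toy_assignments, {"A", "B", "C"}, toy_catalog) == 0

    def test_matches_exhaustive_enumeration_on_random_worlds(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n_prot, n_dom = 8, 5
            assign = DomainAssignment(
                {
                    f"P{i}": frozenset(
                        f"d{j}" for j in rng.choice(n_dom, rng.integers(1, 4),
                                                    replace=False)
                    )
                    for i in range(n_prot)
                }
            )
            proteins = sorted(assign.proteins)
            all_pairs = [
                (proteins[i], proteins[j])
                for i in range(n_prot)
                for j in range(i + 1, n_prot)
            ]
            chosen = rng.choice(len(all_pairs), 4, replace=False)
            catalog = InteractionCatalog(
                frozenset(all_pairs[int(c)] for c in chosen)
            )
            for pair in enumerate_candidate_pairs(catalog, assign):
                i, j = pair
                expected = 0
                for m, n in all_pairs:
                    dm, dn = assign.domains_of(m), assign.domains_of(n)
                    realizes = (i in dm and j in dn) or (j in dm and i in dn)
                    if realizes and (m, n) not in catalog:
                        expected += 1
                assert count_k(pair, assign, proteins, catalog) == expected


class TestNoisyOr:
    def test_direct_arithmetic(self):
        theta = {("d1", "d3"): 0.5, ("d2", "d3"): 0.2}
        p = protein_pair_probability(theta, {"d1", "d2"}, {"d3"})
        assert p == pytest.approx(0.6, abs=1e-12)

    def test_empty_theta_gives_zero(self):
        assert protein_pair_probability({}, {"d1"}, {"d2"}) == 0.0

    def test_shared_domain_sets_count_pair_once(self):
        theta = {("d1", "d2"): 0.37}
        p = protein_pair_probability(theta, {"d1", "d2"}, {"d1", "d2"})
        assert p == pytest.approx(0.37, abs=1e-12)

    @given(st.integers(2, 10), st.integers(0, 2**31 - 1))
    @settings(max_examples=30)
    def test_agrees_with_configuration_enumeration(self, k, seed):
        rng = np.random.default_rng(seed)
        thetas = rng.uniform(0.0, 0.99, size=k)
        doms_m = {f"m{i}" for i in range(1)}  # one domain vs k domains
        doms_n = {f"n{i}" for i in range(k)}
        theta = {
            tuple(sorted((f"m0", f"n{i}"))): float(thetas[i]) for i in range(k)
        }
        p = protein_pair_probability(theta, doms_m, doms_n)
        assert p == pytest.approx(brute_force_noisy_or(thetas), abs=1e-12)


class TestPenalizedLoglik:
    def test_hand_value_single_pair(self, toy_catalog, toy_assignments):
        cands = {("d1", "d2"): PairCounts(m0=1, k=1)}
        ll = penalized_loglik(
            {("d1", "d2"): 0.5}, cands, toy_catalog, toy_assignments, EMConfig()
        )
        assert ll == pytest.approx(4 * math.log(0.5), abs=1e-12)

    def test_boundary_theta_with_pseudocounts_is_domain_error(
        self, toy_catalog, toy_assignments
    ):
        cands = {("d1", "d2"): PairCounts(m0=1, k=1)}
        with pytest.raises(ValueError, match="boundary"):
            penalized_loglik(
                {("d1", "d2"): 0.0}, cands, toy_catalog, toy_assignments, EMConfig()
            )

    def test_no_pseudocounts_reduces_to_observed_loglik(
        self, toy_catalog, toy_assignments
    ):
        cands = {("d1", "d2"): PairCounts(m0=1, k=2)}
        cfg = EMConfig(a=0.0, b=0.0)
        theta = {("d1", "d2"): 0.3}
        ll = penalized_loglik(theta, cands, toy_catalog, toy_assignments, cfg)
        assert ll == pytest.approx(math.log(0.3) + 2 * math.log(0.7), abs=1e-12)

    def test_empty_catalog_no_candidates_is_zero(self):
        assign = DomainAssignment({"A": frozenset({"d1"})})
        empty = InteractionCatalog(frozenset())
        assert penalized_loglik({}, {}, empty, assign, EMConfig()) == 0.0


class TestEMFit:
    def test_toy_world_fixed_point_at_first_iteration(
        self, toy_catalog, toy_assignments
    ):
        res = em_fit(toy_catalog, toy_assignments, EMConfig())
        assert res.theta[("d1", "d2")] == pytest.approx(0.5, abs=1e-12)
        assert res.n_iter == 1
        assert res.converged

    def test_two_slgis_zero_k_converges_to_three_quarters(self):
        assign = DomainAssignment(
            {
                "A": frozenset({"d1"}),
                "B": frozenset({"d2"}),
                "C": frozenset({"d2"}),
            }
        )
        catalog = InteractionCatalog(frozenset({("A", "B"), ("A", "C")}))
        res = em_fit(catalog, assign, EMConfig())
        # realizable pairs equal the two SLGIs, so K = 0: (2+1)/(2+0+2)
        assert res.theta[("d1", "d2")] == pytest.approx(0.75, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_single_domain_worlds_match_closed_form(self, seed):
        """With one domain per protein, E[M] = M0 and theta has a closed form."""
        rng = np.random.default_rng(seed)
        n_prot = 12
        assign = DomainAssignment(
            {
                f"P{i}": frozenset({f"d{rng.integers(0, 4)}"})
                for i in range(n_prot)
            }
        )
        proteins = sorted(assign.proteins)
        pairs = [
            (proteins[i], proteins[j])
            for i in range(n_prot)
            for j in range(i + 1, n_prot)
        ]
        chosen = rng.choice(len(pairs), 8, replace=False)
        catalog = InteractionCatalog(frozenset(pairs[int(c)] for c in chosen))
        res = em_fit(catalog, assign, EMConfig())
        for key, counts in res.counts.items():
            expected = (counts.m0 + 1) / (counts.m0 + counts.k + 2)
            assert res.theta[key] == pytest.approx(expected, abs=1e-12)

    def test_trace_monotone_and_theta_in_open_interval(self):
        params = WorldParams(n_domains=15, n_proteins=40, n_planted_pairs=4,
                             background=0.02)
        for seed in range(5):
            world = generate_world(params, seed=seed)
            if len(world.catalog) == 0:
                continue
            res = em_fit(world.catalog, world.assignments, EMConfig())
            trace = np.asarray(res.loglik_trace)
            assert np.all(np.diff(trace) >= -1e-9)
            values = np.array(list(res.theta.values()))
            assert np.all((values > 0.0) & (values < 1.0))

    def test_catalog_iteration_order_does_not_change_theta(self):
        world = generate_world(
            WorldParams(n_domains=12, n_proteins=30, n_planted_pairs=3), seed=3
        )
        res1 = em_fit(world.catalog, world.assignments, EMConfig())
        # rebuild the catalog from a shuffled pair list
        rng = np.random.default_rng(0)
        pairs = sorted(world.catalog.pairs)
        rng.shuffle(pairs)
        catalog2 = InteractionCatalog(frozenset(pairs))
        res2 = em_fit(catalog2, world.assignments, EMConfig())
        for key, value in res1.theta.items():
            assert res2.theta[key] == pytest.approx(value, abs=1e-12)

    def test_empty_catalog_is_an_error(self, toy_assignments):
        with pytest.raises(ValueError, match="empty"):
            em_fit(InteractionCatalog(frozenset()), toy_assignments, EMConfig())

    def test_unassigned_catalog_protein_is_an_error(self, toy_catalog):
        assign = DomainAssignment({"A": frozenset({"d1"})})
        with pytest.raises(ValueError, match="lack domain"):
            em_fit(toy_catalog, assign, EMConfig())

    def test_nonconvergence_flagged_not_raised(self, caplog):
        world = generate_world(
            WorldParams(n_domains=20, n_proteins=50, n_planted_pairs=5), seed=2
        )
        res = em_fit(world.catalog, world.assignments, EMConfig(max_iter=1, tol=1e-15))
        assert not res.converged
        assert res.n_iter == 1
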