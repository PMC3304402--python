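"""Fixed-point expansion semantics, oracle equivalence, and resampling."""

import numpy as np
import pandas as pd
import pytest

import drivernet as dn
from drivernet.expansion import (
    fixed_point_members,
    prepare_expansion_context,
    run_single_expansion,
    stratified_subsample,
)


def brute_force_fixed_point(seeds, adjacency, de_genes, qualifying_edges):
    """Independent oracle: rescan every candidate inclusion until closure."""
    qual = {frozenset(e) for e in qualifying_edges}
    members = set(seeds)
    changed = True
    while changed:
        changed = False
        for m in list(members):
            for v in adjacency.get(m, set()):
                if v in members:
                    continue
                if v in de_genes or (m in de_genes and frozenset((m, v)) in qual):
                    members.add(v)
                    changed = True
    return members


def random_instance(rng, max_nodes=50):
    n = rng.integers(5, max_nodes + 1)
    nodes = [f"N{i}" for i in range(n)]
    adjacency = {v: set() for v in nodes}
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.1:
                adjacency[nodes[i]].add(nodes[j])
                adjacency[nodes[j]].add(nodes[i])
                edges.append((nodes[i], nodes[j]))
    de = {v for v in nodes if rng.random() < 0.3}
    qual = {e for e in edges if rng.random() < 0.2}
    seeds = set(rng.choice(nodes, size=min(3, n), replace=False))
    return seeds, adjacency, de, qual


class TestFixedPoint:
    def test_two_hop_chain_through_de_genes(self):
        adjacency = {"S": {"N1", "N2"}, "N1": {"S", "N3"},
                     "N2": {"S"}, "N3": {"N1"}}
        members, reasons = fixed_point_members({"S"}, adjacency, {"N1", "N3"}, set())
        assert members == {"S", "N1", "N3"}
        assert reasons["N1"] == reasons["N3"] == "differential_expression"

    def test_coexpression_blocked_when_member_not_de(self):
        adjacency = {"S": {"N1"}, "N1": {"S"}}
        members, _ = fixed_point_members({"S"}, adjacency, set(), {("S", "N1")})
        assert members == {"S"}

    def test_coexpression_path_through_de_member(self):
        adjacency = {"S": {"N1"}, "N1": {"S"}}
        members, reasons = fixed_point_members({"S"}, adjacency, {"S"}, {("S", "N1")})
        assert members == {"S", "N1"}
        assert reasons["S"] == "seed+differential_expression"
        assert reasons["N1"] == "coexpression_only"

    def test_de_gene_with_no_path_never_enters(self):
        adjacency = {"S": set(), "X": {"Y"}, "Y": {"X"}}
        members, _ = fixed_point_members({"S"}, adjacency, {"X", "Y"}, set())
        assert members == {"S"}

    def test_seed_absent_from_network_kept_isolated(self):
        members, reasons = fixed_point_members({"GHOST"}, {}, set(), set())
        assert members == {"GHOST"} and reasons["GHOST"] == "seed"

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(100)
        for _ in range(50):
            seeds, adjacency, de, qual = random_instance(rng)
            got, _ = fixed_point_members(seeds, adjacency, de, qual)
            assert got == brute_force_fixed_point(seeds, adjacency, de, qual)

    def test_order_independent(self):
        """Any frontier processing order yields the same fixed point."""
        rng = np.random.default_rng(101)
        for _ in range(10):
            seeds, adjacency, de, qual = random_instance(rng, max_nodes=30)
            ref, _ = fixed_point_members(seeds, adjacency, de, qual)
            for _ in range(3):
                order = list(rng.permutation(sorted(adjacency)))
                shuffled = {k: set(adjacency[k]) for k in order}
                got, _ = fixed_point_members(seeds, shuffled, de, qual)
                assert got == ref

    def test_monotone_in_de_set(self):
        rng = np.random.default_rng(102)
        for _ in range(20):
            seeds, adjacency, de, qual = random_instance(rng, max_nodes=30)
            base, _ = fixed_point_members(seeds, adjacency, de, qual)
            extra = de | {rng.choice(sorted(adjacency))}
            bigger, _ = fixed_point_members(seeds, adjacency, extra, qual)
            assert base <= bigger

    def test_coexpression_members_have_qualifying_edge_to_de_member(self):
        rng = np.random.default_rng(103)
        for _ in range(20):
            seeds, adjacency, de, qual = random_instance(rng)
            members, reasons = fixed_point_members(seeds, adjacency, de, qual)
            qual_sets = {frozenset(e) for e in qual}
            for g, why in reasons.items():
                if why == "coexpression_only":
                    assert any(
                        frozenset((g, m)) in qual_sets and m in de and m in members
                        for m in adjacency.get(g, set()))


class TestExpandDriverNetwork:
    def test_seeds_always_members_and_reasons_consistent(self, small_study):
        net, cfg, cohort, truth = small_study
        de = dn.differential_expression(cohort.expression, cohort.probe_map,
                                        cohort.labels, "TNBC")
        ctx = prepare_expansion_context(net, cohort.expression, cohort.probe_map,
                                        cohort.labels, "TNBC")
        thr = run_single_expansion(ctx, truth.seed_genes)["threshold"]
        dnw = dn.expand_driver_network(truth.seed_genes, net, de, thr, cohort)
        assert truth.seed_genes <= dnw.members
        for g in dnw.members:
            assert dnw.inclusion_reason[g] in (
                "seed", "seed+differential_expression",
                "differential_expression", "coexpression_only")
        assert all(f == 1.0 for f in dnw.membership_frequency.values())

    def test_node_and_edge_tables_well_formed(self, small_study):
        net, cfg, cohort, truth = small_study
        dnw = dn.resampled_driver_network(truth.seed_genes, net, cohort, "TNBC",
                                          reps=5, rng_seed=3)
        nodes = dnw.node_table()
        assert set(nodes.columns) == {"gene", "subtype", "inclusion_reason",
                                      "membership_frequency", "is_seed"}
        edges = dnw.edge_table()
        assert {r.source for r in edges.itertuples()} <= dnw.members
        assert ((edges["delta"].dropna() >= -2) & (edges["delta"].dropna() <= 2)).all()


class TestResampling:
    def test_full_fraction_reproduces_single_run(self, small_study):
        """sample_frac = 1 must equal the one-shot expansion exactly."""
        net, cfg, cohort, truth = small_study
        res = dn.resampled_driver_network(truth.seed_genes, net, cohort, "TNBC",
                                          sample_frac=1.0, reps=5, rng_seed=1)
        de = dn.differential_expression(cohort.expression, cohort.probe_map,
                                        cohort.labels, "TNBC")
        single = dn.expand_driver_network(truth.seed_genes, net, de,
                                          res.delta_threshold, cohort)
        assert res.members == single.members
        assert all(f == 1.0 for f in res.membership_frequency.values())

    def test_fixed_seed_is_bit_reproducible(self, small_study):
        net, cfg, cohort, truth = small_study
        a = dn.resampled_driver_network(truth.seed_genes, net, cohort, "TNBC",
                                        reps=20, rng_seed=11)
        b = dn.resampled_driver_network(truth.seed_genes, net, cohort, "TNBC",
                                        reps=20, rng_seed=11)
        assert a.membership_frequency == b.membership_frequency
        assert a.members == b.members

    def test_membership_threshold_is_inclusive_at_boundary(self, small_study):
        net, cfg, cohort, truth = small_study
        res = dn.resampled_driver_network(truth.seed_genes, net, cohort, "TNBC",
                                          reps=20, rng_seed=2, membership_min=0.5)
        for g, f in res.membership_frequency.items():
            if g in res.seeds:
                continue
            assert (g in res.members) == (f >= 0.5)

    def test_seeds_exempt_unless_strict(self, small_study):
        net, cfg, cohort, truth = small_study
        lax = dn.resampled_driver_network(truth.seed_genes, net, cohort, "TNBC",
                                          reps=10, rng_seed=4, keep_seeds=True)
        assert truth.seed_genes <= lax.members
        strict = dn.resampled_driver_network(truth.seed_genes, net, cohort, "TNBC",
                                             reps=10, rng_seed=4, keep_seeds=False)
        for s in truth.seed_genes:
            assert (s in strict.members) == (strict.membership_frequency.get(s, 0) >= 0.5)

    def test_stratified_subsample_preserves_proportions(self):
        labels = pd.Series(["A"] * 10 + ["B"] * 20, index=[f"s{i}" for i in range(30)])
        rng = np.random.default_rng(0)
        sub = stratified_subsample(labels, list(labels.index), 0.8, rng)
        counts = labels.loc[sub].value_counts()
        assert counts["A"] == 8 and counts["B"] == 16

    def test_subsample_too_small_errors(self):
        labels = pd.Series(["A"] * 2 + ["B"] * 20, index=[f"s{i}" for i in range(22)])
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="sample_frac"):
            stratified_subsample(labels, list(labels.index), 0.8, rng)
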