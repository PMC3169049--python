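"""Constrained trees, SH/RELL, posterior matching, RF null."""

import numpy as np
import pytest

from cophylo.congruence import (
    CongruenceConfig,
    CongruenceReport,
    build_constrained_tree,
    posterior_match_proportion,
    rell_sh_pvalues,
    rf_null_test,
    run_congruence_suite,
    sh_test,
)
from cophylo.mcmc import MCMCConfig
from cophylo.model import jc
from cophylo.posterior import PosteriorSample
from cophylo.simulate import CophylogenyScenario, make_bundle
from cophylo.tree import (
    HostAssociation,
    TreeError,
    bipartition_set,
    enumerate_topologies,
    map_and_prune,
    parse_newick,
    random_topology,
    rf_distance,
    topologies_equal,
)


def full_assoc(n):
    return HostAssociation({f"v{i}": f"H{i}" for i in range(n)})


def relabel(tree, prefix="v"):
    t = tree.copy()
    for leaf in t.leaves():
        leaf.name = leaf.name.replace("H", prefix)
    return t


class TestConstrainedTree:
    def test_all_mapped_gives_host_topology(self):
        rng = np.random.default_rng(0)
        host = random_topology([f"H{i}" for i in range(7)], rng)
        ml = relabel(random_topology([f"H{i}" for i in range(7)], rng))
        assoc = full_assoc(7)
        out = build_constrained_tree(ml, host, assoc)
        assert topologies_equal(map_and_prune(out, assoc), host)

    def test_idempotent_when_already_congruent(self):
        rng = np.random.default_rng(1)
        host = random_topology([f"H{i}" for i in range(6)], rng)
        ml = relabel(host)
        out = build_constrained_tree(ml, host, full_assoc(6))
        assert topologies_equal(out, ml)

    def test_outgroups_keep_their_splits(self):
        # 9-taxon ML tree with a monophyletic 7-taxon mapped clade + 2 outgroups
        rng = np.random.default_rng(2)
        clade = random_topology([f"v{i}" for i in range(7)], rng)
        ml = parse_newick(
            f"(out1,(out2,{str(clade)[:-1]}));"
        )
        host = random_topology([f"H{i}" for i in range(7)], rng)
        assoc = full_assoc(7)
        out = build_constrained_tree(ml, host, assoc)
        assert topologies_equal(map_and_prune(out, assoc), host)
        # splits of the ML tree not involving the mapped clade's interior
        mapped = assoc.virus_taxa
        ml_splits = {
            s for s in bipartition_set(ml)
            if mapped.issubset(s) or not (mapped & s)
        }
        assert ml_splits.issubset(bipartition_set(out))

    def test_missing_host_taxon_error(self):
        rng = np.random.default_rng(3)
        host = random_topology(["H0", "H1", "H2", "H3"], rng)
        ml = relabel(random_topology([f"H{i}" for i in range(5)], rng))
        with pytest.raises(TreeError, match="H4"):
            build_constrained_tree(ml, host, full_assoc(5))


class TestSHTest:
    def test_identical_topologies_null_result(self, cospec_bundle):
        b = cospec_bundle
        t1 = b.virus_tree.copy()
        t2 = b.virus_tree.rerooted_at(sorted(t1.leaf_names())[2])
        res = sh_test(b.alignment, b.model, [t1, t2], n_rell=200, seed=1)
        assert res.delta2 == 0.0
        assert res.p_value == 1.0

    def test_rell_pvalue_properties(self):
        rng = np.random.default_rng(4)
        good = rng.normal(-1.0, 0.5, 500)
        bad = good - rng.uniform(0.05, 0.2, 500)  # uniformly worse sites
        deltas, p = rell_sh_pvalues([good, bad], n_rell=1000, seed=2)
        assert deltas[0] == 0.0
        assert p[0] == 1.0
        assert deltas[1] > 0
        assert p[1] < 0.05

    def test_rell_requires_enough_replicates(self, cospec_bundle):
        b = cospec_bundle
        with pytest.raises(ValueError):
            sh_test(b.alignment, b.model, [b.virus_tree, b.virus_tree], n_rell=10)

    def test_mismatched_taxa_rejected(self, cospec_bundle):
        b = cospec_bundle
        other = random_topology(["x", "y", "z", "w"], np.random.default_rng(0))
        with pytest.raises(TreeError):
            sh_test(b.alignment, b.model, [b.virus_tree, other], n_rell=100)


class TestPosteriorMatch:
    def test_all_matching_posterior(self, cospec_bundle):
        b = cospec_bundle
        trees = [b.virus_tree.copy() for _ in range(10)]
        sample = PosteriorSample(trees=trees, burnin_applied=True)
        res = posterior_match_proportion(sample, b.host_tree, b.association)
        assert res.proportion == 1.0
        assert res.count == 10

    def test_rerooting_invariance(self, cospec_bundle):
        b = cospec_bundle
        names = sorted(b.virus_tree.leaf_names())
        trees = [b.virus_tree.rerooted_at(names[i % len(names)]) for i in range(6)]
        sample = PosteriorSample(trees=trees, burnin_applied=True)
        host_rerooted = b.host_tree.rerooted_at(sorted(b.host_tree.leaf_names())[3])
        res = posterior_match_proportion(sample, host_rerooted, b.association)
        assert res.proportion == 1.0

    def test_empty_posterior_rejected(self, cospec_bundle):
        b = cospec_bundle
        with pytest.raises(ValueError):
            posterior_match_proportion(
                PosteriorSample(trees=[], burnin_applied=True),
                b.host_tree, b.association,
            )


class TestRFNull:
    def test_perfect_posterior_gives_zero_fraction(self, cospec_bundle):
        b = cospec_bundle
        sample = PosteriorSample(
            trees=[b.virus_tree.copy() for _ in range(5)], burnin_applied=True
        )
        res = rf_null_test(sample, b.host_tree, b.association,
                           n_random=500, seed=3)
        assert res.posterior_rf == [0] * 5
        assert res.fraction == 0.0

    def test_exhaustive_enumeration_oracle_n7(self):
        # uniform "posterior" on 7 taxa: the null fraction must agree with
        # the exact computation over all 945 labelled topologies
        rng = np.random.default_rng(5)
        taxa = [f"H{i}" for i in range(7)]
        host = random_topology(taxa, rng)
        assoc = HostAssociation({f"v{i}": f"H{i}" for i in range(7)})
        post_trees = []
        for _ in range(300):
            t = random_topology([f"v{i}" for i in range(7)], rng)
            post_trees.append(t)
        sample = PosteriorSample(trees=post_trees, burnin_applied=True)
        res = rf_null_test(sample, host, assoc, n_random=10_000,
                           summary="mean", seed=6)
        exact_rf = [
            rf_distance(host, t) for t in enumerate_topologies(taxa)
        ]
        exact_fraction = float(np.mean(np.asarray(exact_rf) < res.d_star))
        se = np.sqrt(exact_fraction * (1 - exact_fraction) / 10_000)
        assert abs(res.fraction - exact_fraction) <= max(4 * se, 0.01)

    def test_settings_validated(self, cospec_bundle):
        b = cospec_bundle
        sample = PosteriorSample(trees=[b.virus_tree.copy()], burnin_applied=True)
        with pytest.raises(ValueError):
            rf_null_test(sample, b.host_tree, b.association, n_random=10)
        with pytest.raises(ValueError):
            rf_null_test(sample, b.host_tree, b.association, summary="mode")


class TestReportSerialization:
    def test_round_trip(self):
        report = CongruenceReport(
            sh_delta=328.0, sh_p=0.004, match_proportion=0.0, match_count=0,
            posterior_size=7500, rf_null_fraction=0.02,
            rf_null_fraction_mean=0.02, rf_null_fraction_median=0.015,
            rf_null_fraction_pairwise=0.03, rf_summary="mean",
            posterior_rf_distribution=[4, 4, 6, 4], null_rf_distribution=[8, 10, 6],
            settings={"seed": 1, "n_rell": 1000}, selected_model="GTR+G+I",
            ml_lnL=-100.5, constrained_lnL=-264.5,
        )
        back = CongruenceReport.from_text(report.to_text())
        assert back == report


class TestSuite:
    def test_end_to_end_small(self):
        scenario = CophylogenyScenario(n_hosts=6, n_switches=2, seed=9)
        b = make_bundle(scenario, L=600)
        config = CongruenceConfig(
            candidates=("JC",), n_rell=200, n_random=300, seed=5,
            mcmc=MCMCConfig(generations=4000, sample_interval=40,
                            burnin_fraction=0.25, seed=6),
        )
        capture = {}
        report = run_congruence_suite(
            b.alignment, b.host_tree, b.association, config, capture=capture
        )
        assert report.sh_delta >= -1e-6
        assert 0.0 <= report.sh_p <= 1.0
        assert 0.0 <= report.match_proportion <= 1.0
        assert len(report.null_rf_distribution) == 300
        assert report.posterior_size == len(capture["posterior"])
        assert report.constrained_lnL <= report.ml_lnL + 1e-4
        back = CongruenceReport.from_text(report.to_text())
        assert back == report

    def test_external_posterior_path(self, cospec_bundle):
        b = cospec_bundle
        trees = [b.virus_tree.copy() for _ in range(8)]
        config = CongruenceConfig(
            candidates=("JC",), n_rell=150, n_random=200, seed=1,
            posterior=PosteriorSample(trees=trees), burnin_fraction=0.25,
        )
        report = run_congruence_suite(b.alignment, b.host_tree, b.association, config)
        assert report.posterior_size == 6  # 25% burn-in applied to 8
        assert report.match_proportion == 1.0
        assert report.rf_null_fraction == 0.0
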