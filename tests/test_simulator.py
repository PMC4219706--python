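"""Tests for the birth-death-transfer simulator and its ground truth."""

import math

import numpy as np
import pytest

from refog_bench.benchmark_core import benchmark_dataset
from refog_bench.function_tests import (
    FeatureMap,
    build_neighbor_families,
    conserved_features,
    extract_neighborhood,
    gene_order_score,
)
from refog_bench.simulator import (
    PerturbationConfig,
    SimConfig,
    ground_truth_ogs,
    perturb_predictions,
    random_species_tree,
    simulate_family,
    simulate_world,
)


class TestSimulateFamily:
    def test_pure_speciation_limit_is_congruent_with_species_tree(self):
        tree, clades = random_species_tree(n_ingroup=8, n_close=3, n_distant=3,
                                           seed=1)
        config = SimConfig(species_tree=tree, dup_rate=0, loss_rate=0,
                           transfer_rate=0, seed=1)
        gtree, log = simulate_family(config)
        species = {l.taxon.label.split(".")[0] for l in gtree.leaf_node_iter()}
        assert species == set(clades)
        assert len(gtree.leaf_nodes()) == len(clades)  # one gene per species
        # topology congruence: the gene tree induces the species-tree splits
        species_splits = {
            frozenset(l.taxon.label for l in n.leaf_iter())
            for n in tree.preorder_internal_node_iter()
        }
        gene_splits = {
            frozenset(l.taxon.label.split(".")[0] for l in n.leaf_iter())
            for n in gtree.preorder_internal_node_iter()
        }
        assert species_splits == gene_splits

    def test_duplications_only_make_paralogs_not_xenologs(self):
        tree, _ = random_species_tree(n_ingroup=6, n_close=2, n_distant=2, seed=2)
        config = SimConfig(species_tree=tree, dup_rate=0.6, loss_rate=0,
                           transfer_rate=0, seed=2)
        _, log = simulate_family(config)
        _, xenologs = ground_truth_ogs(log)
        assert xenologs == frozenset()
        kinds = {e[0] for e in log.events}
        assert "transfer" not in kinds

    def test_mean_family_size_matches_birth_process_expectation(self):
        # pure-birth process: E[copies per species] = exp(lambda * T), T = 1
        tree, clades = random_species_tree(n_ingroup=2, n_close=1, n_distant=1,
                                           seed=0)
        lam = 0.5
        config = SimConfig(species_tree=tree, dup_rate=lam, loss_rate=0,
                           transfer_rate=0, seed=0)
        rng = np.random.default_rng(2024)
        means = []
        for _ in range(500):
            _, log = simulate_family(config, rng=rng)
            per = {}
            for lin in log.extant():
                sp = lin.gene_id.split(".")[0]
                per[sp] = per.get(sp, 0) + 1
            means.append(np.mean([per.get(s, 0) for s in clades]))
        assert np.mean(means) == pytest.approx(math.exp(lam), rel=0.05)

    def test_non_ultrametric_tree_with_transfers_raises(self):
        import dendropy
        t = dendropy.Tree.get(data="((101:1,102:2)ING:1,901:3);", schema="newick",
                              suppress_internal_node_taxa=True)
        with pytest.raises(ValueError, match="ultrametric"):
            simulate_family(SimConfig(species_tree=t, transfer_rate=0.2))

    def test_seed_determinism_is_bit_identical(self):
        tree, clades = random_species_tree(n_ingroup=6, n_close=2, n_distant=2,
                                           seed=7)
        config = SimConfig(species_tree=tree, n_families=4, seed=7)
        w1 = simulate_world(config, clades=clades)
        w2 = simulate_world(config, clades=clades)
        assert [r.members for r in w1.refogs] == [r.members for r in w2.refogs]
        assert w1.xenologs == w2.xenologs
        assert w1.predictions.groups == w2.predictions.groups
        assert w1.expected_counts == w2.expected_counts
        assert w1.hits == w2.hits
        assert {s: g.replicons for s, g in w1.genomes.items()} == {
            s: g.replicons for s, g in w2.genomes.items()
        }


class TestGroundTruth:
    def test_duplication_above_reference_node_splits_groups(self):
        # force an early duplication by simulating until one appears pre-LCA
        for seed in range(80):
            tree, _ = random_species_tree(n_ingroup=6, n_close=2, n_distant=2,
                                          seed=seed)
            config = SimConfig(species_tree=tree, dup_rate=0.8, loss_rate=0,
                               transfer_rate=0, seed=seed)
            _, log = simulate_family(config)
            ogs, _ = ground_truth_ogs(log)
            if len(ogs) > 1:
                # several founding copies at the LCA: groups are disjoint and
                # jointly cover all ingroup genes
                all_genes = [g for og in ogs for g in og]
                assert len(all_genes) == len(set(all_genes))
                return
        pytest.fail("no pre-LCA duplication arose in 80 seeds")

    def test_every_nonxenolog_ingroup_gene_in_exactly_one_group(
        self, small_world_factory
    ):
        world = small_world_factory(seed=5, transfer_rate=0.3,
                                    with_genomes=False, with_annotations=False,
                                    with_hits=False)
        ingroup = {s for s, c in world.clades.items() if c == "ingroup"}
        for fam in world.logs:
            ogs, xenologs = ground_truth_ogs(world.logs[fam])
            genes = [
                lin.gene_id for lin in world.logs[fam].extant()
                if lin.gene_id.split(".")[0] in ingroup
            ]
            covered = [g for og in ogs for g in og] + list(xenologs)
            assert sorted(covered) == sorted(genes)

    def test_no_transfer_rate_means_no_xenologs_across_seeds(self):
        for seed in range(20):
            tree, _ = random_species_tree(n_ingroup=6, n_close=2, n_distant=2,
                                          seed=seed)
            config = SimConfig(species_tree=tree, transfer_rate=0.0, seed=seed)
            _, log = simulate_family(config)
            _, xenologs = ground_truth_ogs(log)
            assert xenologs == frozenset()


class TestGenomesAnnotationsHits:
    def test_full_synteny_means_identical_family_order(self, small_world_factory):
        world = small_world_factory(seed=4, transfer_rate=0.0, p_syn=1.0)
        gene_family = {
            g: fam for fam in world.logs for g in world.family_genes(fam)
        }
        orders = set()
        for genome in world.genomes.values():
            fams = []
            for g in genome.replicons["chr"]:
                fam = gene_family[g]
                if not fams or fams[-1] != fam:
                    fams.append(fam)
            orders.add(tuple(fams))
        # all genomes list their families in a consistent ancestral order:
        # every genome's family sequence is a subsequence of a common order
        longest = max(orders, key=len)
        for order in orders:
            it = iter(longest)
            assert all(f in it for f in order)

    def test_randomly_placed_xenologs_score_below_syntenic_members(
        self, small_world_factory
    ):
        """With full synteny retention only xenologs sit at random positions,
        so member gene-order scores dominate xenolog scores family by family
        (a xenolog's window can still shift its neighbours' windows by one,
        hence the comparison is on means, not an exact equality)."""
        world = small_world_factory(seed=12, transfer_rate=0.5, p_syn=1.0,
                                    n_families=14, n_ingroup=12)
        assert world.xenologs  # scenario needs at least one transfer
        fams = build_neighbor_families(world.hits)
        compared = 0
        for refog in world.refogs:
            fam = world.refog_family[refog.refog_id]
            xeno = world.family_xenologs(fam)
            if len(refog.members) < 4 or not xeno:
                continue
            nmap = FeatureMap("neighbor_family", {
                g: frozenset(
                    fams.get(n, n) for n in extract_neighborhood(
                        world.genomes[g.split(".")[0]], g
                    )
                )
                for g in refog.members
            })
            cons = conserved_features(refog.members, nmap)
            if not cons.conserved:
                continue
            member_scores = [
                gene_order_score(g, world.genomes, fams, cons)
                for g in sorted(refog.members)
            ]
            xeno_scores = [
                gene_order_score(g, world.genomes, fams, cons)
                for g in sorted(xeno)
            ]
            assert np.mean(member_scores) > np.mean(xeno_scores)
            compared += 1
        assert compared >= 1

    def test_domain_inheritance_fraction_approximates_q_dom(
        self, small_world_factory
    ):
        q = 0.7
        world = small_world_factory(seed=8, n_ingroup=14, n_families=16, q_dom=q)
        present = total = 0
        for fam in world.logs:
            genes = world.family_genes(fam)
            tokens = {
                t for g in genes for t in world.domains.features(g)
            }
            for g in genes:
                for t in tokens:
                    total += 1
                    present += t in world.domains.features(g)
        assert total > 500
        assert present / total == pytest.approx(q, abs=0.05)

    def test_hits_roundtrip_recovers_family_partition(self, small_world_factory):
        world = small_world_factory(seed=2)
        fams = build_neighbor_families(world.hits)
        got = {}
        for g, tok in fams.items():
            got.setdefault(tok, set()).add(g)
        truth = {
            frozenset(world.family_genes(f))
            for f in world.logs if world.family_genes(f)
        }
        assert {frozenset(v) for v in got.values()} == truth

    def test_single_family_link_count(self, small_world_factory):
        world = small_world_factory(seed=6, n_families=1, transfer_rate=0.0)
        (fam,) = world.logs
        n = len(world.family_genes(fam))
        qualifying = [
            h for h in world.hits
            if h.e_value <= 1e-5
            and h.aligned_length >= 0.9 * min(h.query_length, h.subject_length)
        ]
        assert len(qualifying) == n * (n - 1) // 2


class TestPerturbations:
    def test_all_zero_probabilities_give_identity(self, small_world_factory):
        world = small_world_factory(
            seed=1, transfer_rate=0.0,
            with_genomes=False, with_annotations=False, with_hits=False,
        )
        pconfig = PerturbationConfig(p_split=0, p_merge=0, p_contaminate=0,
                                     p_drop=0, include_xenologs=False)
        preds, expected, _ = perturb_predictions(world.refogs, pconfig)
        for refog in world.refogs:
            assert expected[refog.refog_id] == (len(refog.members), 0, 0)
            assert preds.groups[f"P_{refog.refog_id}"] == refog.members

    def test_split_bookkeeping(self):
        from refog_bench.benchmark_core import RefOG
        refog = RefOG("R1", frozenset(f"1.g{i}" for i in range(10)))
        pconfig = PerturbationConfig(p_split=1.0, p_merge=0, p_contaminate=0,
                                     p_drop=0, seed=3, include_xenologs=False)
        preds, expected, plog = perturb_predictions([refog], pconfig)
        ta, fa, ma = expected["R1"]
        assert fa == 0 and ta + ma == 10 and 1 <= ma <= 4  # strict minority
        sizes = sorted(len(g) for g in preds.groups.values())
        assert sizes == [ma, ta]

    def test_classification_recovers_expected_counts(self, small_world_factory):
        for seed in range(25):
            world = small_world_factory(
                seed=seed, with_genomes=False, with_annotations=False,
                with_hits=False,
            )
            report = benchmark_dataset(world.refogs, world.predictions)
            for cls in report.classifications:
                assert (cls.n_ta, cls.n_fa, cls.n_ma) == (
                    world.expected_counts[cls.refog_id]
                ), (seed, cls.refog_id, world.perturbation_log)


class TestSpeciesCoverageEffect:
    def test_denser_sampling_is_usually_no_worse(self):
        """Distance-threshold clustering degrades with sparser species sampling.

        Predictions are rebuilt by single-linkage clustering of patristic
        distances on each gene tree at a fixed threshold.  Removing species
        stretches nearest-neighbour distances, so bona-fide groups
        fragment; combined FA+MA (evaluated on the sparse species set) is
        no worse for denser sampling in a clear majority of worlds.
        """
        from refog_bench.benchmark_core import (
            PredictedOGSet, restrict_to_species,
        )
        wins = ties = losses = 0
        for seed in range(50):
            tree, clades = random_species_tree(
                n_ingroup=12, n_close=3, n_distant=3, seed=seed
            )
            config = SimConfig(species_tree=tree, n_families=5, seed=seed)
            world = simulate_world(config, clades=clades, with_genomes=False,
                                   with_annotations=False, with_hits=False)
            ingroup = sorted(s for s, c in clades.items() if c == "ingroup")
            sparse = set(ingroup[::2])  # half the species, same span

            def cluster_predictions(species_subset):
                groups = {}
                for fam, gtree in world.trees.items():
                    pdm = gtree.phylogenetic_distance_matrix()
                    taxa = [
                        t for t in gtree.taxon_namespace
                        if t.label.split(".")[0] in species_subset
                    ]
                    import networkx as nx
                    g = nx.Graph()
                    g.add_nodes_from(t.label for t in taxa)
                    for i, a in enumerate(taxa):
                        for b in taxa[i + 1:]:
                            if pdm.patristic_distance(a, b) <= 0.9:
                                g.add_edge(a.label, b.label)
                    for comp in nx.connected_components(g):
                        groups[f"{fam}_{min(comp)}"] = frozenset(comp)
                return PredictedOGSet("clustered", groups)

            refogs_eval = restrict_to_species(world.refogs, sparse)
            if not refogs_eval:
                ties += 1
                continue
            dense_preds = restrict_to_species(
                cluster_predictions(set(ingroup)), sparse
            )
            sparse_preds = cluster_predictions(sparse)
            err = lambda preds: sum(
                benchmark_dataset(refogs_eval, preds).totals[1:]
            )
            e_dense, e_sparse = err(dense_preds), err(sparse_preds)
            if e_dense < e_sparse:
                wins += 1
            elif e_dense == e_sparse:
                ties += 1
            else:
                losses += 1
        assert (wins + ties) / (wins + ties + losses) >= 0.7
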