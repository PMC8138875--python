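import numpy as np
import pytest

from orthoeval.cooccurrence import (
    InteractionTable,
    build_pseudo_negative,
    filter_positive,
)
from orthoeval.leca import PresenceProfile, count_independent_losses
from orthoeval.synthetic_data import (
    GroundTruth,
    SimulationConfig,
    default_reference_species,
    emit_truth_orthology,
    perturb_orthology,
    simulate_gene_content,
    simulate_interactions,
    simulate_study,
    simulate_taxonomy,
    substream,
    write_study,
)
from orthoeval.taxonomy import Side


def cfg(**kw):
    return SimulationConfig(**kw)


class TestSimulateTaxonomy:
    def test_counts_and_monophyly(self):
        tax = simulate_taxonomy(cfg(n_supergroups_per_side=2, species_per_supergroup=3))
        assert len(tax.species) == 12
        assert len(tax.sg_map.supergroups) == 4
        # first split separates the two sides
        left, right = tax.tree.seed_node.child_nodes()
        left_sides = {tax.sg_map.side(lf.taxon.label) for lf in left.leaf_iter()}
        right_sides = {tax.sg_map.side(lf.taxon.label) for lf in right.leaf_iter()}
        assert left_sides == {Side.AMORPHAE} and right_sides == {Side.DIAPHORETICKES}

    def test_deterministic_given_config(self):
        a = simulate_taxonomy(cfg(seed=1))
        b = simulate_taxonomy(cfg(seed=1))
        assert a.tree.as_string(schema="newick") == b.tree.as_string(schema="newick")

    def test_validates_cleanly(self):
        assert simulate_taxonomy(cfg()).validate().ok

    def test_zero_species_rejected(self):
        with pytest.raises(ValueError):
            cfg(species_per_supergroup=0)


class TestSimulateGeneContent:
    def test_no_loss_means_all_present(self):
        tax = simulate_taxonomy(cfg(p_loss=0.0))
        presence, events, _ = simulate_gene_content(tax, cfg(p_loss=0.0))
        assert presence.to_numpy().all()
        assert set(events.values()) == {0}

    def test_total_loss_wipes_every_leaf(self):
        c = cfg(p_loss=1.0, rho=0.0, n_modules=0, n_families=20)
        tax = simulate_taxonomy(c)
        presence, events, _ = simulate_gene_content(tax, c)
        assert presence.to_numpy().sum() == 0
        # lost independently on both edges out of the root
        assert set(events.values()) == {2}

    def test_full_coupling_gives_identical_module_rows(self):
        c = cfg(rho=1.0, p_loss=0.3, n_modules=1, module_size_mean=4,
                module_size_max=4, n_families=10, seed=3)
        tax = simulate_taxonomy(c)
        presence, _, modules = simulate_gene_content(tax, c)
        fams = [f for f, m in modules.items() if m]
        assert len(fams) >= 2
        rows = presence.loc[fams].to_numpy()
        assert (rows == rows[0]).all()

    def test_reference_species_shielded_for_module_families(self):
        c = cfg(p_loss=0.5, rho=0.5, seed=5)
        tax = simulate_taxonomy(c)
        ref = default_reference_species(tax)
        presence, _, modules = simulate_gene_content(tax, c, ref)
        module_fams = [f for f, m in modules.items() if m]
        assert presence.loc[module_fams, ref].all()

    def test_dollo_estimate_never_exceeds_simulated_events(self):
        c = cfg(p_loss=0.2, rho=0.3, n_families=100, seed=7)
        tax = simulate_taxonomy(c)
        presence, events, _ = simulate_gene_content(tax, c)
        for fam, row in presence.iterrows():
            if row.sum() == 0:
                continue
            est = count_independent_losses(
                PresenceProfile(str(fam), dict(row)), tax.tree
            ).n_independent_losses
            assert est <= events[fam]


class TestTruthOrthology:
    def test_one_gene_per_present_species(self):
        c = cfg(p_loss=0.1, seed=2)
        tax = simulate_taxonomy(c)
        presence, _, _ = simulate_gene_content(tax, c)
        truth, index = emit_truth_orthology(presence, tax)
        for fam, row in presence.iterrows():
            if row.sum():
                assert len(truth.groups[str(fam)]) == row.sum()
        assert truth.disjoint

    def test_reference_index_covers_module_families(self):
        c = cfg(p_loss=0.4, seed=4)
        tax = simulate_taxonomy(c)
        presence, _, modules = simulate_gene_content(tax, c)
        truth, index = emit_truth_orthology(presence, tax)
        mapped_ogs = set(index.gene_to_og.values())
        for fam, m in modules.items():
            if m:
                assert fam in mapped_ogs


class TestPerturb:
    TRUTH = None

    @pytest.fixture
    def truth(self):
        c = cfg(p_loss=0.1, n_families=30, seed=6)
        tax = simulate_taxonomy(c)
        presence, _, _ = simulate_gene_content(tax, c)
        t, _ = emit_truth_orthology(presence, tax)
        return t

    def test_zero_rates_is_identity(self, truth):
        mock = perturb_orthology(truth, {}, seed=1)
        assert set(map(frozenset, mock.groups.values())) == set(
            map(frozenset, truth.groups.values())
        )

    def test_split_all_partitions_groups(self, truth):
        mock = perturb_orthology(truth, {"p_split": 1.0}, seed=1)
        assert mock.disjoint
        assert mock.all_genes() == truth.all_genes()
        originals = {og: genes for og, genes in truth.groups.items() if len(genes) >= 2}
        for og, genes in originals.items():
            parts = [g for o, g in mock.groups.items() if o == og or o == f"{og}_sp"]
            assert len(parts) == 2
            assert frozenset().union(*parts) == genes

    def test_merge_all_two_groups(self):
        from conftest import make_orthology

        truth = make_orthology({"O1": ["A|p1", "B|p2"], "O2": ["C|p3", "D|p4"]})
        mock = perturb_orthology(truth, {"p_merge": 1.0}, seed=1)
        assert mock.n_groups == 1
        assert next(iter(mock.groups.values())) == truth.all_genes()

    def test_invalid_rate_rejected(self, truth):
        with pytest.raises(ValueError):
            perturb_orthology(truth, {"p_drop": 1.5}, seed=1)

    def test_deterministic_under_seed(self, truth):
        rates = {"p_merge": 0.2, "p_split": 0.2, "p_drop": 0.1, "p_misassign": 0.1}
        a = perturb_orthology(truth, rates, seed=9)
        b = perturb_orthology(truth, rates, seed=9)
        assert a.groups == b.groups


class TestInteractions:
    def test_one_module_of_three_gives_three_positives(self):
        modules = {"F0": "M0", "F1": "M0", "F2": "M0", "F3": ""}
        df, positives = simulate_interactions(
            modules, cfg(n_decoys_per_positive=0.0), "REF"
        )
        assert len(positives) == 3
        assert (df["n_publications"] == 6).all()

    def test_positive_filter_recovers_exactly_the_positives(self):
        c = cfg(seed=8)
        tax = simulate_taxonomy(c)
        _, _, modules = simulate_gene_content(tax, c)
        df, positives = simulate_interactions(modules, c, "REF")
        table = InteractionTable(df)
        kept = filter_positive(table, min_pubs=5)
        assert kept.pair_set() == {tuple(sorted(p)) for p in positives}

    def test_pseudo_negatives_are_unrecorded_cross_module_pairs(self):
        modules = {"F0": "M0", "F1": "M0", "F2": "M1", "F3": "M1"}
        df, _ = simulate_interactions(
            modules, cfg(n_decoys_per_positive=0.0), "REF"
        )
        table = InteractionTable(df)
        negs = build_pseudo_negative(table, min_pubs=5, max_pairs=100, seed=0)
        assert set(negs) == {
            ("F0p", "F2p"), ("F0p", "F3p"), ("F1p", "F2p"), ("F1p", "F3p")
        }

    def test_no_module_rejected(self):
        with pytest.raises(ValueError, match="module"):
            simulate_interactions({"F0": "", "F1": ""}, cfg(), "REF")


class TestStudyAndStreams:
    def test_substreams_are_independent_and_stable(self):
        a = substream(1, "content").random(3)
        b = substream(1, "content").random(3)
        c = substream(1, "perturb").random(3)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        with pytest.raises(KeyError):
            substream(1, "nope")

    def test_simulate_study_round_trips_through_files(self, tmp_path):
        tax, gt, orths, inter = simulate_study(cfg(seed=11, n_families=50))
        paths = write_study(tmp_path, tax, gt, orths, inter)
        from orthoeval.orthology_io import read_orthogroups_long
        from orthoeval.taxonomy import read_species_tree, read_supergroup_map

        tree = read_species_tree(paths["tree"])
        sg = read_supergroup_map(paths["supergroup_map"])
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == set(sg.species)
        truth = read_orthogroups_long(paths["orthology_truth"], "truth")
        assert truth.groups == gt.truth.groups
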