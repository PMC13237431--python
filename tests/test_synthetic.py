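"""Synthetic-data generator: determinism, ground-truth consistency,
parameter recovery by the downstream analyses."""

import dataclasses

import numpy as np
import pytest

from hcarkit.align_io import Group, ReferenceAlignment
from hcarkit.fingerprint import classify_cohort, discover_diagnostic_positions
from hcarkit.indels import IndelKind, detect_indel_blocks
from hcarkit.reconcile import LabeledTree, lca_reconcile
from hcarkit.structcompare import kabsch_superpose, paired_ttest
from hcarkit.synthetic import (
    ConfigError,
    CoordSpec,
    DuplicationEvent,
    IndelSpec,
    SimulationConfig,
    hcar_like_config,
    profile_labels,
    simulate_coord_pairs,
    simulate_family,
    simulate_hcar_like,
    validate_ground_truth,
)

SMALL_TREE = "((h:0.02,(c:0.01,b:0.01):0.01):0.03,g:0.05);"


def small_config(**overrides):
    base = dict(
        seed=11,
        species_tree=SMALL_TREE,
        duplication_events=(DuplicationEvent(branch={"h", "c", "b"}),),
        seq_length=120,
        n_diagnostic_sites=12,
        background_rate_scale=1.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def relabeled(dataset):
    labels = profile_labels(dataset)
    records = [
        dataclasses.replace(rec, group=labels[rec.id][1])
        for rec in dataset.alignment.records
    ]
    return ReferenceAlignment.from_records(records, dataset.alignment.reference_id)


class TestSimulateFamily:
    def test_zero_background_rate_recovers_exactly_the_true_sites(self):
        ds = simulate_family(small_config(background_rate_scale=0.0))
        profile = discover_diagnostic_positions(ds.alignment, min_group_size=2)
        assert list(profile.positions) == ds.truth.true_diagnostic_positions
        for pos, sa, sb in zip(profile.positions, profile.state_a, profile.state_b):
            assert sa == frozenset(ds.truth.state_a[pos])
            assert sb == frozenset(ds.truth.state_b[pos])

    def test_lossless_reconciliation_recovers_event_counts(self):
        config = small_config(
            duplication_events=(
                DuplicationEvent(branch={"h", "c", "b"}),
                DuplicationEvent(branch={"c", "b"}, target_lineage="0a"),
            ),
            loss_probability=0.0,
        )
        ds = simulate_family(config)
        species = LabeledTree.from_newick(config.species_tree)
        recon = lca_reconcile(ds.gene_tree, species)
        assert recon.n_duplications == len(config.duplication_events)
        assert recon.n_losses == 0

    def test_forced_loss_is_placed_and_counted(self):
        config = small_config(
            forced_losses=((frozenset({"c"}), "0b"),),
        )
        ds = simulate_family(config)
        assert ds.truth.true_loss_branches == [["c"]]
        species = LabeledTree.from_newick(config.species_tree)
        recon = lca_reconcile(ds.gene_tree, species)
        assert recon.n_duplications == 1
        assert recon.n_losses == 1
        assert frozenset({"c"}) in recon.loss_branches

    def test_same_seed_gives_byte_identical_output(self, tmp_path):
        d1 = simulate_family(small_config())
        d2 = simulate_family(small_config())
        p1 = d1.write(tmp_path / "one")
        p2 = d2.write(tmp_path / "two")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_different_seed_changes_output(self):
        d1 = simulate_family(small_config(seed=1))
        d2 = simulate_family(small_config(seed=2))
        assert any(
            a.residues != b.residues
            for a, b in zip(d1.alignment.records, d2.alignment.records)
        )

    def test_indel_spec_emitted_and_detected(self):
        config = small_config(
            indel_specs=(
                IndelSpec(clade=frozenset({"h", "c"}), length=9,
                          kind=IndelKind.INSERTION, group="B", ref_anchor=100),
            ),
        )
        ds = simulate_family(config)
        feats = detect_indel_blocks(ds.alignment, min_length=3)
        assert len(feats) == 1
        feat = feats[0]
        assert feat.kind is IndelKind.INSERTION
        assert feat.ref_anchor == 100 and feat.length == 9
        assert feat.carriers == {"h_0b", "c_0b"}
        assert ds.truth.true_indels[0].carriers == feat.carriers

    def test_truth_validates_against_emitted_files(self):
        validate_ground_truth(simulate_family(small_config()))

    def test_impossible_configs_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(seed=1, species_tree=SMALL_TREE,
                             seq_length=10, n_diagnostic_sites=11)
        with pytest.raises(ConfigError):
            simulate_family(small_config(
                duplication_events=(DuplicationEvent(branch={"h", "zz"}),)
            ))
        with pytest.raises(ConfigError):
            simulate_family(small_config(
                indel_specs=(IndelSpec(clade=frozenset({"zz"}), length=5),)
            ))


class TestHcarLikePreset:
    def test_copy_number_pattern_matches_the_emulated_history(self):
        ds = simulate_hcar_like(3)
        per_species = {}
        for rec in ds.alignment.records:
            per_species.setdefault(rec.species, []).append(rec)
        # duplicated lineages: hominines, orangutans, gibbons (2 copies);
        # Hoolock keeps two copies of the derived lineage only
        for sp in ("Homo_sapiens", "Pongo_abelii", "Symphalangus_syndactylus"):
            assert len(per_species[sp]) == 2
        hoolock = per_species["Hoolock_leuconedys"]
        assert len(hoolock) == 2
        assert all(r.group is Group.GROUP_B for r in hoolock)
        for sp in ("Macaca_fascicularis", "Callithrix_jacchus", "Lemur_catta"):
            assert len(per_species[sp]) == 1
            assert per_species[sp][0].group is Group.GROUP_A

    def test_reconciliation_recovers_four_duplications_one_loss(self):
        config = hcar_like_config(5)
        ds = simulate_hcar_like(5)
        species = LabeledTree.from_newick(config.species_tree)
        recon = lca_reconcile(ds.gene_tree, species)
        assert recon.n_duplications == 4
        assert recon.n_losses == 1
        assert frozenset({"Hoolock_leuconedys"}) in recon.loss_branches

    def test_single_copy_outgroups_classify_a_like(self):
        ds = simulate_hcar_like(9)
        aln = relabeled(ds)
        profile = discover_diagnostic_positions(aln)
        queries = [r.id for r in aln.records if r.group is Group.QUERY]
        results, _ = classify_cohort(queries, profile, aln)
        assert all(res.verdict.value == "A_LIKE" for res in results)
        assert all(res.n_b == 0 for res in results)

    def test_clustering_test_false_for_cross_lineage_duplicates(self):
        ds = simulate_hcar_like(13)
        from hcarkit.reconcile import species_clustering_test

        per_species, _ = species_clustering_test(ds.gene_tree)
        # copies of hominine/orangutan/gibbon species derive from pre-species
        # duplications, so they never form species-specific clades ...
        for sp in ("Homo_sapiens", "Pongo_abelii", "Symphalangus_syndactylus"):
            assert per_species[sp] is False
        # ... except Hoolock, whose two copies come from a within-lineage event
        assert per_species["Hoolock_leuconedys"] is True

    def test_insertion_carried_by_the_hominine_b_clade_only(self):
        ds = simulate_hcar_like(21)
        feats = detect_indel_blocks(ds.alignment, min_length=3)
        assert len(feats) == 1
        assert feats[0].length == 24
        assert feats[0].carriers == {
            "Homo_sapiens_0b", "Pan_troglodytes_0b", "Pan_paniscus_0b"
        }


class TestCoordPairs:
    def test_zero_noise_gives_zero_rmsd_and_recovers_transform(self):
        spec = CoordSpec(n_models=3, n_residues=40, noise_sd_a=0.0, noise_sd_b=0.0)
        ds = simulate_coord_pairs(spec, seed=4)
        to_a, to_b = ds.rmsd_vectors()
        assert max(to_a + to_b) < 1e-9
        # the fitted transform must invert the applied one
        model = ds.models_a[0]
        applied = ds.truth.true_transforms[0]
        result = kabsch_superpose(model, ds.base)
        R_applied = np.array(applied["rotation"])
        assert np.allclose(result.rotation @ R_applied, np.eye(3), atol=1e-8)

    def test_rmsd_scales_with_noise_sd(self):
        spec = CoordSpec(n_models=4, n_residues=200, noise_sd_a=0.8, noise_sd_b=1.3)
        ds = simulate_coord_pairs(spec, seed=8)
        to_a, to_b = ds.rmsd_vectors()
        # expected approximately sd * sqrt(3), slightly shrunk by the fit
        assert np.mean(to_a) == pytest.approx(0.8 * np.sqrt(3), rel=0.1)
        assert np.mean(to_b) == pytest.approx(1.3 * np.sqrt(3), rel=0.1)
        res = paired_ttest(to_a, to_b)
        assert res.p_value < 0.05

    def test_pdb_emission_roundtrip(self, tmp_path):
        from hcarkit.structcompare import read_ca_coords

        spec = CoordSpec(n_models=2, n_residues=20)
        ds = simulate_coord_pairs(spec, seed=6)
        paths = ds.write(tmp_path)
        back = read_ca_coords(paths["base"])
        assert back.residue_numbers == ds.base.residue_numbers
        assert np.allclose(back.coords, ds.base.coords, atol=1e-3)

    def test_degenerate_spec_rejected(self):
        with pytest.raises(ConfigError):
            CoordSpec(n_residues=2)
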