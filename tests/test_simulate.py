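"""Synthetic-data generators: determinism, planting soundness, truth."""

import dataclasses

import numpy as np
import pytest

from prxfam import (
    SynthConfig,
    classify_pattern,
    aggregate_tissue_means,
    gen_expression_compendium,
    gen_interaction_table,
    gen_motif_library,
    gen_promoter_set,
    gen_protein_family,
    nj_tree,
    p_distance_matrix,
    pearson,
    scan_sequence,
    top_k_coexpressed,
)
from prxfam.simulate import ConfigurationError, REFERENCE_MOTIFS


class TestConfig:
    def test_floor_must_be_below_ceiling(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(intensity_floor=15, intensity_ceiling=5)

    def test_nonpositive_reps_rejected(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(reps_per_tissue=0)

    def test_default_tissues_are_the_six_organs(self):
        assert SynthConfig().tissues == (
            "leaf", "shoot", "root", "flower", "pollen", "seed"
        )


class TestMotifLibrary:
    def test_no_decoys_gives_reference_thirteen(self):
        lib = gen_motif_library(0, seed=0)
        assert len(lib) == 13
        assert lib["ABREOSRAB21"].consensus == "ACGTSSSC"
        assert lib["TATCCAYMOTIFOSRAMY3D"].consensus == "TATCCAY"
        assert lib["PBOX1"].consensus == "TGRAAG"

    def test_decoys_appended_and_valid(self):
        lib = gen_motif_library(7, seed=4)
        assert len(lib) == 20
        # MotifRecord construction validates the IUPAC alphabet
        for rec in lib:
            assert 4 <= len(rec.consensus) <= 10

    def test_reference_entries_cover_all_pairs(self):
        lib = gen_motif_library(0, seed=0)
        assert {(r.name, r.consensus) for r in lib} == set(REFERENCE_MOTIFS)


class TestExpressionCompendium:
    def test_same_seed_identical_matrices(self):
        cfg = SynthConfig(seed=1, n_genes=40)
        m1, _ = gen_expression_compendium(cfg)
        m2, _ = gen_expression_compendium(cfg)
        assert m1.values.equals(m2.values)
        assert m1.values.to_csv() == m2.values.to_csv()

    def test_zero_noise_block_members_perfectly_correlated(self):
        cfg = SynthConfig(seed=2, n_genes=30, noise_sd=0.0)
        m, truth = gen_expression_compendium(cfg)
        for bait, members in truth.coexpr_blocks.items():
            base = m.values.loc[members[0]].to_numpy()
            for g in members[1:]:
                assert pearson(base, m.values.loc[g].to_numpy()) == pytest.approx(1.0)

    def test_zero_effect_makes_expressed_genes_ubiquitous(self):
        cfg = SynthConfig(seed=3, n_genes=50, effect_size=0.0, noise_sd=0.0)
        m, _ = gen_expression_compendium(cfg)
        calls = classify_pattern(aggregate_tissue_means(m))
        for call in calls:
            assert call.cls in {"ubiquitous", "suppressed"}
            if call.cls == "ubiquitous":
                assert call.score == pytest.approx(0.0)

    def test_values_clipped_to_range(self):
        cfg = SynthConfig(seed=4, n_genes=40, noise_sd=3.0)
        m, _ = gen_expression_compendium(cfg)
        assert m.values.to_numpy().min() >= cfg.intensity_floor
        assert m.values.to_numpy().max() <= cfg.intensity_ceiling

    def test_planted_block_recovered_by_top_k(self):
        cfg = SynthConfig(seed=5)
        m, truth = gen_expression_compendium(cfg)
        for bait, members in truth.coexpr_blocks.items():
            group = top_k_coexpressed(m, bait, k=len(members) - 1)
            assert set(group.gene_ids) == set(members) - {bait}


class TestPromoterSet:
    def test_planting_soundness_and_purity(self, library_with_decoys):
        cfg = SynthConfig(seed=6)
        proms, truth = gen_promoter_set(cfg, library_with_decoys)
        planted_a = set(truth.planted_motifs["A"])
        planted_b = set(truth.planted_motifs["B"])
        assert planted_a.isdisjoint(planted_b)
        for gene, placements in truth.planted_positions.items():
            rec = proms[gene]
            own = planted_a if gene.startswith("blkA") else planted_b
            other = planted_b if gene.startswith("blkA") else planted_a
            for name, start, _ in placements:
                hits = scan_sequence(rec, library_with_decoys[name])
                assert start in {h.start for h in hits}
            for name in other:
                assert scan_sequence(rec, library_with_decoys[name]) == []

    def test_same_seed_identical_sequences(self, library_with_decoys):
        cfg = SynthConfig(seed=7)
        p1, _ = gen_promoter_set(cfg, library_with_decoys)
        p2, _ = gen_promoter_set(cfg, library_with_decoys)
        assert [r.sequence for r in p1] == [r.sequence for r in p2]

    def test_at_only_background_at_gc_zero(self, library):
        cfg = SynthConfig(seed=8, gc_content=0.0, planted_motifs_per_group=1)
        proms, truth = gen_promoter_set(cfg, library)
        for rec in proms:
            planted = {
                (s, s + len(library[n].consensus))
                for n, s, _ in truth.planted_positions[rec.gene_id]
            }
            for i, base in enumerate(rec.sequence):
                if any(a <= i < b for a, b in planted):
                    continue
                assert base in "AT"

    def test_motif_longer_than_promoter_rejected(self, library):
        cfg = SynthConfig(seed=9, promoter_length=5)
        with pytest.raises(ConfigurationError, match="longer"):
            gen_promoter_set(cfg, library)

    def test_overlapping_planted_sets_rejected(self, library):
        cfg = SynthConfig(seed=10)
        with pytest.raises(ConfigurationError, match="disjoint"):
            gen_promoter_set(cfg, library, planted_a=["PBOX1"], planted_b=["PBOX1"])


class TestProteinFamily:
    def test_zero_rates_give_identical_sequences(self):
        cfg = SynthConfig(seed=11, within_clade_rate=0.0, between_clade_rate=0.0)
        aligned, _, _ = gen_protein_family(cfg)
        assert len(set(aligned.rows)) == 1
        assert (p_distance_matrix(aligned).to_numpy() == 0).all()

    def test_same_seed_identical_fasta(self):
        cfg = SynthConfig(seed=12)
        a1, n1, _ = gen_protein_family(cfg)
        a2, n2, _ = gen_protein_family(cfg)
        assert a1.rows == a2.rows and n1 == n2

    def test_nj_recovers_true_four_way_partition(self):
        from prxfam import assign_subgroups

        cfg = SynthConfig(seed=13)
        aligned, _, truth = gen_protein_family(cfg)
        tree = nj_tree(p_distance_matrix(aligned))
        exemplars = {f"SG{c}_t1": f"SG{c}" for c in range(1, 5)}
        asg = assign_subgroups(tree, exemplars)
        assert asg.labels == truth.clade_membership
        assert all(asg.monophyletic.values())

    def test_within_clade_distances_below_between(self):
        cfg = SynthConfig(seed=14)
        aligned, _, truth = gen_protein_family(cfg)
        d = p_distance_matrix(aligned)
        within, between = [], []
        for a in d.index:
            for b in d.columns:
                if a >= b:
                    continue
                pair = within if (
                    truth.clade_membership[a] == truth.clade_membership[b]
                ) else between
                pair.append(d.loc[a, b])
        assert max(within) < min(between)


class TestInteractionTable:
    def test_default_degrees_union_82(self):
        from prxfam import build_network, hub_summary

        cfg = SynthConfig(seed=15)
        table, truth = gen_interaction_table(cfg)
        g = build_network(table, list(truth.hub_partners))
        s = hub_summary(g)
        assert sorted(s.degrees.values(), reverse=True) == [60, 16, 3, 3]
        assert s.union == 82

    def test_single_edge_case(self):
        cfg = SynthConfig(seed=16, hub_degrees=(1,))
        table, truth = gen_interaction_table(cfg)
        assert len(table.edges) == 1
        assert len(set(table.edges["hub"]) | set(table.edges["partner"])) == 2

    def test_full_overlap_equal_degrees_union_is_degree(self):
        from prxfam import build_network, hub_summary

        cfg = SynthConfig(seed=17, hub_degrees=(5, 5), hub_overlap=1.0)
        table, truth = gen_interaction_table(cfg)
        s = hub_summary(build_network(table, list(truth.hub_partners)))
        assert s.union == 5

    def test_classes_from_fixed_vocabulary(self):
        from prxfam import CLASS_VOCABULARY

        cfg = SynthConfig(seed=18, hub_degrees=(20,))
        table, _ = gen_interaction_table(cfg)
        assert set(table.edges["class"]) <= set(CLASS_VOCABULARY)


class TestDeterminismAcrossArtifacts:
    def test_config_roundtrips_as_dict(self):
        cfg = SynthConfig(seed=19, n_genes=33)
        clone = SynthConfig(**dataclasses.asdict(cfg))
        assert clone == cfg
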