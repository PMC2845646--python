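"""Generator contracts: determinism, planted structure, the RA recursion."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from trra.errors import ConfigError
from trra.operons import extract_adjacent_pairs
from trra.synthetic_data import (
    SynthConfig,
    generate_expression,
    generate_genomes,
    generate_similarity_scores,
    generate_training_pairs,
)

from conftest import SMALL


def _cooperon_genomes(truth, a, b):
    """Genomes where both orthologs exist and sit in one planted unit."""
    out = []
    for genome in truth.genomes:
        ma, mb = truth.true_orthologs[a], truth.true_orthologs[b]
        if genome in ma and genome in mb:
            units = truth.unit_membership[genome]
            if units[ma[genome]] == units[mb[genome]]:
                out.append(genome)
    return out


class TestGenerateGenomes:
    def test_seeded_runs_are_bit_identical(self):
        a1, t1 = generate_genomes(SMALL)
        a2, t2 = generate_genomes(SMALL)
        assert set(a1) == set(a2)
        for g in a1:
            pd.testing.assert_frame_equal(a1[g], a2[g])
        assert t1.true_orthologs == t2.true_orthologs
        assert t1.true_operons == t2.true_operons

    def test_full_cooperon_probability_places_every_group_pair(self):
        cfg = replace(SMALL, p_cooperon=1.0)
        _, truth = generate_genomes(cfg)
        groups = {}
        for f, g in truth.functional_groups.items():
            if g >= 0:
                groups.setdefault(g, []).append(f)
        for members in groups.values():
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    both = [
                        genome for genome in truth.genomes
                        if genome in truth.true_orthologs[a]
                        and genome in truth.true_orthologs[b]
                    ]
                    assert _cooperon_genomes(truth, a, b) == both

    def test_zero_cooperon_probability_plants_nothing(self):
        cfg = replace(SMALL, p_cooperon=0.0)
        _, truth = generate_genomes(cfg)
        focal = truth.focal_genes
        for i, a in enumerate(focal):
            for b in focal[i + 1:]:
                assert _cooperon_genomes(truth, a, b) == []

    def test_oversized_groups_rejected(self):
        with pytest.raises(ConfigError):
            replace(SMALL, group_size=10, n_functional_groups=10).validate()

    def test_orthologs_one_to_one_within_each_genome(self, small_genomes):
        _, truth = small_genomes
        for genome in truth.genomes:
            genes = [
                m[genome] for m in truth.true_orthologs.values() if genome in m
            ]
            assert len(genes) == len(set(genes))

    def test_intergenic_distances_respect_planted_classes(self, small_genomes):
        annotations, truth = small_genomes
        for genome, ann in annotations.items():
            pairs = extract_adjacent_pairs(ann)
            units = truth.unit_membership[genome]
            for row in pairs.itertuples(index=False):
                same_unit = units[row.upstream_gene] == units[row.downstream_gene]
                if same_unit:
                    assert row.intergenic_distance >= -20
                    assert row.same_strand
                else:
                    assert row.intergenic_distance >= 50

    def test_redundant_copies_share_operon_structure(self, small_genomes):
        annotations, truth = small_genomes
        by_group = {}
        for genome, label in truth.genome_groups.items():
            by_group.setdefault(label, []).append(genome)
        redundant = [g for g in by_group.values() if len(g) > 1]
        assert redundant
        for members in redundant:
            sizes = {
                m: sorted(len(op) for op in truth.true_operons[m]) for m in members
            }
            first = sizes[members[0]]
            assert all(s == first for s in sizes.values())


class TestGenerateScores:
    def test_seeded_tables_are_identical(self, small_genomes):
        _, truth = small_genomes
        s1 = generate_similarity_scores(truth, decoy_rate=0.5, seed=3)
        s2 = generate_similarity_scores(truth, decoy_rate=0.5, seed=3)
        for genome in truth.genomes:
            pd.testing.assert_frame_equal(s1[genome][0], s2[genome][0])
            pd.testing.assert_frame_equal(s1[genome][1], s2[genome][1])

    def test_true_pairs_top_score_in_both_directions(self, small_genomes):
        _, truth = small_genomes
        scores = generate_similarity_scores(truth, decoy_rate=1.0, seed=5)
        for genome in truth.genomes:
            fwd, rev = scores[genome]
            for f, m in truth.true_orthologs.items():
                if genome not in m:
                    continue
                b = m[genome]
                mine = fwd[fwd["qseqid"] == f]
                best = mine.loc[mine["bitscore"].idxmax()]
                assert best["sseqid"] == b
                theirs = rev[rev["qseqid"] == b]
                best_rev = theirs.loc[theirs["bitscore"].idxmax()]
                assert best_rev["sseqid"] == f


class TestGenerateExpression:
    def test_pure_lag_when_noise_and_carryover_off(self):
        cfg = replace(
            SMALL, noise_sd_tr=0.0, noise_sd_ra=0.0,
            degradation_sd=0.0, ra_alpha=0.0, ra_beta=1.5,
        )
        _, truth = generate_genomes(cfg)
        tr, ra = generate_expression(truth, cfg)
        t, r = tr.data.to_numpy(), ra.data.to_numpy()
        np.testing.assert_allclose(r[:, 1:], 1.5 * t[:, :-1], rtol=1e-12)

    def test_same_group_noise_free_profiles_correlate_perfectly(self):
        cfg = replace(SMALL, noise_sd_tr=0.0)
        _, truth = generate_genomes(cfg)
        tr, _ = generate_expression(truth, cfg)
        groups = {}
        for f, g in truth.functional_groups.items():
            if g >= 0:
                groups.setdefault(g, []).append(f)
        for members in groups.values():
            rows = tr.data.loc[members].to_numpy()
            r = np.corrcoef(rows)
            np.testing.assert_allclose(r, 1.0, atol=1e-12)

    def test_matrices_positive_and_seeded(self):
        _, truth = generate_genomes(SMALL)
        tr1, ra1 = generate_expression(truth, SMALL)
        tr2, ra2 = generate_expression(truth, SMALL)
        pd.testing.assert_frame_equal(tr1.data, tr2.data)
        pd.testing.assert_frame_equal(ra1.data, ra2.data)
        assert (tr1.data.to_numpy() > 0).all()
        assert (ra1.data.to_numpy() > 0).all()

    def test_degradation_spread_decouples_ra_from_tr(self):
        """More degradation-rate spread lowers mean TR/RA profile agreement."""
        def mean_lag_corr(cfg):
            _, truth = generate_genomes(cfg)
            tr, ra = generate_expression(truth, cfg)
            t, r = tr.data.to_numpy(), ra.data.to_numpy()
            cs = []
            for i in range(t.shape[0]):
                a, b = t[i, :-1], r[i, 1:]
                if a.std() > 0 and b.std() > 0:
                    cs.append(np.corrcoef(a, b)[0, 1])
            return float(np.mean(cs))

        clean = replace(
            SMALL, degradation_sd=0.0, noise_sd_ra=0.0, noise_sd_tr=0.0, ra_alpha=0.0,
        )
        noisy = replace(clean, degradation_sd=0.5)
        assert mean_lag_corr(clean) == pytest.approx(1.0, abs=1e-9)
        assert mean_lag_corr(noisy) < mean_lag_corr(clean)


class TestTrainingPairs:
    def test_labels_follow_planted_units(self, small_genomes):
        annotations, truth = small_genomes
        genome = truth.genomes[0]
        pairs = generate_training_pairs(annotations[genome], truth, genome)
        units = truth.unit_membership[genome]
        for row in pairs.itertuples(index=False):
            same_unit = units[row.upstream_gene] == units[row.downstream_gene]
            if same_unit:
                assert row.label == "same_operon"
            elif row.same_strand:
                assert row.label == "different_operon"
            else:
                assert row.label == "unlabeled"
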