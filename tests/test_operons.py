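"""Adjacent-pair geometry, SVM threshold extraction, operon chaining."""

import numpy as np
import pandas as pd
import pytest

from trra.errors import InputError, TrainingError
from trra.operons import (
    OperonClassifier,
    extract_adjacent_pairs,
    predict_operons,
    train_operon_classifier,
)
from trra.synthetic_data import generate_training_pairs

from conftest import SEPARABLE


def _annotation(rows, genome="G1"):
    return pd.DataFrame(
        [(g, genome, s, e, st) for g, s, e, st in rows],
        columns=["gene_id", "genome_id", "start", "end", "strand"],
    )


def _pairs(distances, same_strand=True):
    return pd.DataFrame({
        "upstream_gene": [f"u{i}" for i in range(len(distances))],
        "downstream_gene": [f"d{i}" for i in range(len(distances))],
        "intergenic_distance": distances,
        "same_strand": same_strand,
    })


class TestExtractAdjacentPairs:
    def test_distance_convention_positive_gap(self):
        ann = _annotation([("a", 1, 100, "+"), ("b", 141, 300, "+")])
        pairs = extract_adjacent_pairs(ann)
        assert pairs.iloc[0]["intergenic_distance"] == 40
        assert bool(pairs.iloc[0]["same_strand"]) is True

    def test_distance_convention_overlap(self):
        ann = _annotation([("a", 1, 100, "+"), ("b", 90, 200, "-")])
        pairs = extract_adjacent_pairs(ann)
        assert pairs.iloc[0]["intergenic_distance"] == -11
        assert bool(pairs.iloc[0]["same_strand"]) is False

    def test_linear_genome_pair_count(self, small_genomes):
        annotations, _ = small_genomes
        for ann in annotations.values():
            assert len(extract_adjacent_pairs(ann)) == len(ann) - 1

    def test_duplicate_gene_ids_rejected(self):
        ann = _annotation([("a", 1, 100, "+"), ("a", 141, 300, "+")])
        with pytest.raises(InputError):
            extract_adjacent_pairs(ann)

    def test_circular_wraparound_pair(self):
        ann = _annotation([("a", 1, 100, "+"), ("b", 141, 300, "+")])
        pairs = extract_adjacent_pairs(ann, circular=True, genome_length=400)
        assert len(pairs) == 2
        wrap = pairs.iloc[1]
        assert wrap["upstream_gene"] == "b"
        assert wrap["intergenic_distance"] == 400 - 300 + 1 - 1
        with pytest.raises(InputError):
            extract_adjacent_pairs(ann, circular=True)


class TestTrainClassifier:
    def test_separable_threshold_lies_in_margin(self):
        clf = train_operon_classifier(
            _pairs([10, 25, 40, 50]), _pairs([250, 300, 400, 500])
        )
        assert 50 < clf.threshold_bp < 250

    def test_single_example_per_class_rejected(self):
        with pytest.raises(TrainingError):
            train_operon_classifier(_pairs([40]), _pairs([240]))

    def test_identical_distances_rejected(self):
        with pytest.raises(TrainingError):
            train_operon_classifier(_pairs([100, 100]), _pairs([100, 100]))

    def test_inseparable_classes_warn_but_train(self):
        pos = _pairs(list(range(0, 400, 20)))
        neg = _pairs(list(range(0, 400, 20)))
        with pytest.warns(UserWarning):
            clf = train_operon_classifier(pos, neg)
        assert np.isfinite(clf.threshold_bp)

    def test_opposite_strand_pairs_excluded_from_training(self):
        pos = pd.concat([_pairs([10, 20, 30]), _pairs([5000], same_strand=False)])
        neg = _pairs([250, 300, 400])
        clf = train_operon_classifier(pos, neg)
        assert 30 < clf.threshold_bp < 250

    def test_roundtrip_through_model_file(self, tmp_path):
        clf = train_operon_classifier(_pairs([10, 25, 40]), _pairs([250, 300, 400]))
        path = tmp_path / "model.txt"
        clf.to_file(path)
        clf2 = OperonClassifier.from_file(path)
        assert clf2 == clf

    def test_held_out_accuracy_on_realistic_distances(self, small_genomes):
        """Overlapping distance classes are still separated well."""
        annotations, truth = small_genomes
        genomes = truth.genomes
        train = pd.concat([
            generate_training_pairs(annotations[g], truth, g) for g in genomes[:5]
        ])
        test = pd.concat([
            generate_training_pairs(annotations[g], truth, g) for g in genomes[5:]
        ])
        clf = train_operon_classifier(
            train[train["label"] == "same_operon"],
            train[train["label"] == "different_operon"],
        )
        held = test[test["label"].isin(["same_operon", "different_operon"])]
        predicted = clf.is_link(held["intergenic_distance"])
        truth_labels = (held["label"] == "same_operon").to_numpy()
        accuracy = (predicted == truth_labels).mean()
        assert accuracy >= 0.9


class TestPredictOperons:
    def _clf(self):
        return OperonClassifier(threshold_bp=100.0, mean_=0.0, sd_=1.0)

    def test_three_linked_genes_form_one_operon(self):
        ann = _annotation([
            ("a", 1, 100, "+"), ("b", 121, 220, "+"), ("c", 241, 340, "+"),
        ])
        ops = predict_operons(ann, self._clf())
        assert len(ops) == 1
        assert ops[0].genes == ("a", "b", "c")

    def test_strand_flips_break_every_link(self):
        ann = _annotation([
            ("a", 1, 100, "+"), ("b", 121, 220, "-"), ("c", 241, 340, "+"),
        ])
        assert predict_operons(ann, self._clf()) == []

    def test_decision_is_monotone_in_distance(self):
        clf = self._clf()
        linked = clf.is_link(np.arange(-50, 300))
        assert not np.any(np.diff(linked.astype(int)) > 0)

    def test_operons_partition_their_genes(self, separable_genomes):
        annotations, truth = separable_genomes
        genome = truth.genomes[0]
        pairs = generate_training_pairs(annotations[genome], truth, genome)
        clf = train_operon_classifier(
            pairs[pairs["label"] == "same_operon"],
            pairs[pairs["label"] == "different_operon"],
        )
        for g, ann in annotations.items():
            seen = set()
            for op in predict_operons(ann, clf):
                assert not (set(op.genes) & seen)
                seen |= set(op.genes)

    def test_separable_config_recovers_planted_operons(self, separable_genomes):
        annotations, truth = separable_genomes
        genome = truth.genomes[0]
        pairs = generate_training_pairs(annotations[genome], truth, genome)
        clf = train_operon_classifier(
            pairs[pairs["label"] == "same_operon"],
            pairs[pairs["label"] == "different_operon"],
        )
        for g, ann in annotations.items():
            predicted = {op.genes for op in predict_operons(ann, clf)}
            assert predicted == set(truth.true_operons[g])
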