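"""Operon prediction from intergenic distances with a linear SVM.

Adjacent, co-directional bacterial genes separated by a short (often
negative, i.e. overlapping) intergenic gap tend to belong to one
transcription unit.  A maximum-margin classifier is trained on the single
feature *intergenic distance* from labeled adjacent pairs; because the
problem is one-dimensional the fitted margin reduces to a distance
threshold in base pairs, which is extracted and applied as a monotone rule
(shorter gap => same operon).  Predicted operons are maximal chains of
linked, same-strand adjacent pairs with at least two genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import InputError, TrainingError

__all__ = [
    "Operon",
    "OperonClassifier",
    "extract_adjacent_pairs",
    "train_operon_classifier",
    "predict_operons",
]


@dataclass(frozen=True)
class Operon:
    """A predicted or planted poly-cistronic transcription unit (>= 2 genes)."""

    genome_id: str
    genes: tuple[str, ...]
    strand: str

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise InputError("an operon needs at least two genes")


def extract_adjacent_pairs(
    annotation: pd.DataFrame,
    circular: bool = False,
    genome_length: int | None = None,
) -> pd.DataFrame:
    """List consecutive gene pairs with their intergenic distances.

    Coordinates are 1-based inclusive; the distance is
    ``start(downstream) - end(upstream) - 1`` and is negative when the genes
    overlap.  With ``circular=True`` the wrap-around pair from the last to
    the first gene is appended (requires ``genome_length``).
    """
    if annotation["gene_id"].duplicated().any():
        raise InputError("duplicate gene ids in annotation")
    rows = []
    for genome_id, sub in annotation.groupby("genome_id", sort=True):
        sub = sub.sort_values(["start", "end"], kind="mergesort").reset_index(drop=True)
        for i in range(len(sub) - 1):
            up, down = sub.iloc[i], sub.iloc[i + 1]
            rows.append((
                genome_id, up["gene_id"], down["gene_id"],
                int(down["start"]) - int(up["end"]) - 1,
                up["strand"] == down["strand"],
            ))
        if circular and len(sub) >= 2:
            if genome_length is None:
                raise InputError("circular=True requires genome_length")
            last, first = sub.iloc[-1], sub.iloc[0]
            dist = genome_length - int(last["end"]) + int(first["start"]) - 1
            rows.append((
                genome_id, last["gene_id"], first["gene_id"], dist,
                last["strand"] == first["strand"],
            ))
    return pd.DataFrame(
        rows,
        columns=["genome_id", "upstream_gene", "downstream_gene",
                 "intergenic_distance", "same_strand"],
    )


@dataclass(frozen=True)
class OperonClassifier:
    """Distance-threshold rule extracted from a fitted linear SVM.

    ``threshold_bp`` is the decision boundary in base pairs; an adjacent
    same-strand pair is an operon link iff its intergenic distance is
    <= ``threshold_bp``.  ``mean_`` and ``sd_`` are the standardization
    constants of the training distances.
    """

    threshold_bp: float
    mean_: float
    sd_: float

    def is_link(self, distance) -> np.ndarray:
        return np.asarray(distance, dtype=float) <= self.threshold_bp

    def to_file(self, path) -> None:
        Path(path).write_text(
            f"threshold_bp\t{self.threshold_bp!r}\n"
            f"mean\t{self.mean_!r}\nsd\t{self.sd_!r}\n"
        )

    @classmethod
    def from_file(cls, path) -> "OperonClassifier":
        kv = dict(
            line.split("\t") for line in Path(path).read_text().splitlines() if line
        )
        return cls(float(kv["threshold_bp"]), float(kv["mean"]), float(kv["sd"]))


def train_operon_classifier(
    positives: pd.DataFrame,
    negatives: pd.DataFrame,
    C: float = 100.0,
) -> OperonClassifier:
    """Fit the margin between same-operon and different-operon distances.

    ``positives`` are adjacent same-operon pairs, ``negatives`` adjacent
    same-strand pairs from different operons; both need an
    ``intergenic_distance`` column and, if present, a ``same_strand``
    column restricts training to co-directional pairs.  Training is
    deterministic (no randomness enters a 1-D hard-margin fit).
    """
    pos = _training_distances(positives, "positives")
    neg = _training_distances(negatives, "negatives")
    if len(pos) < 2 or len(neg) < 2:
        raise TrainingError("each class needs at least two same-strand examples")
    x = np.concatenate([pos, neg]).astype(float)
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    mean, sd = float(x.mean()), float(x.std())
    if sd == 0:
        raise TrainingError("all training distances are identical")
    z = ((x - mean) / sd).reshape(-1, 1)
    svm = SVC(kernel="linear", C=C)
    svm.fit(z, y)
    w = float(svm.coef_[0, 0])
    b = float(svm.intercept_[0])
    if w == 0:
        raise TrainingError("degenerate margin (zero weight)")
    threshold = mean - sd * b / w
    if w > 0:
        # Positive class sits at *larger* distances: the fixture contradicts
        # the operon geometry.  Keep the monotone short-gap rule but warn.
        warnings.warn(
            "training distances place same-operon pairs at larger gaps; "
            "the monotone short-gap rule is retained",
            stacklevel=2,
        )
    clf = OperonClassifier(threshold_bp=float(threshold), mean_=mean, sd_=sd)
    accuracy = (
        clf.is_link(pos).sum() + (~clf.is_link(neg)).sum()
    ) / (len(pos) + len(neg))
    if accuracy < 0.75:
        warnings.warn(
            f"training classes barely separable (accuracy {accuracy:.2f}); "
            "classifier returned anyway",
            stacklevel=2,
        )
    return clf


def _training_distances(pairs: pd.DataFrame, what: str) -> np.ndarray:
    if "intergenic_distance" not in pairs.columns:
        raise InputError(f"{what} lack an intergenic_distance column")
    sub = pairs
    if "same_strand" in pairs.columns:
        sub = pairs[pairs["same_strand"].astype(bool)]
    return sub["intergenic_distance"].to_numpy(dtype=float)


def predict_operons(annotation: pd.DataFrame, classifier: OperonClassifier) -> list[Operon]:
    """Chain linked adjacent pairs into maximal operons, per genome.

    Opposite-strand adjacencies are never links; a predicted operon is a
    maximal run of linked pairs and has at least two genes.
    """
    pairs = extract_adjacent_pairs(annotation)
    strand_of = dict(zip(annotation["gene_id"], annotation["strand"]))
    operons: list[Operon] = []
    for genome_id, sub in pairs.groupby("genome_id", sort=True):
        sub = sub.reset_index(drop=True)
        linked = classifier.is_link(sub["intergenic_distance"]) & sub["same_strand"].to_numpy()
        chain: list[str] = []
        for i in range(len(sub)):
            if linked[i]:
                if not chain:
                    chain = [sub.at[i, "upstream_gene"]]
                chain.append(sub.at[i, "downstream_gene"])
            elif chain:
                operons.append(Operon(genome_id, tuple(chain), strand_of[chain[0]]))
                chain = []
        if chain:
            operons.append(Operon(genome_id, tuple(chain), strand_of[chain[0]]))
    return operons
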