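"""Co-operon frequency: counting, normalization, and the species filter.

For a pair of focal genes, the raw co-operon count is the number of
bacterial genomes in which their orthologs lie in the same predicted
operon (0 or 1 per genome, since the ortholog map is one-to-one per
genome).  The count is normalized by the larger of the two genes'
ortholog-bearing species counts — the larger count preserves the
phylogenetic-profile information carried by genomes where only one of the
two genes occurs.  Pairs whose larger species count falls below a minimum
(50 at full scale) are eliminated, since co-occurrence restricted to a few
related genomes is weak evidence of functional linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InputError
from .operons import Operon
from .orthology import OrthologMap

__all__ = [
    "CoOperonRecord",
    "count_cooperon",
    "normalize_cooperon",
    "filter_pairs",
    "records_to_frame",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class CoOperonRecord:
    """Normalized co-operon frequency for one unordered focal gene pair."""

    gene_a: str
    gene_b: str
    raw_count: int
    species_count_max: int
    normalized_freq: float

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise InputError("gene_a must sort before gene_b")
        if not 0 <= self.raw_count <= self.species_count_max:
            raise InputError("raw_count outside [0, species_count_max]")

    @property
    def pair(self) -> Pair:
        return (self.gene_a, self.gene_b)


def _ordered(a: str, b: str) -> Pair:
    return (a, b) if a < b else (b, a)


def count_cooperon(
    operons_by_genome: Mapping[str, Sequence[Operon]],
    orthologs: OrthologMap,
    annotations: Mapping[str, pd.DataFrame] | None = None,
) -> dict[Pair, int]:
    """Raw co-operon counts for every focal pair sharing >= 1 genome.

    Pairs whose orthologs co-occur in at least one common genome but never
    in one operon are retained with count 0.  When ``annotations`` is
    given, operons referencing unannotated genes raise ``InputError``.
    """
    by_focal = orthologs.as_dict()
    focal_by_genome: dict[str, dict[str, str]] = {}
    for f, per_genome in by_focal.items():
        for genome, b in per_genome.items():
            focal_by_genome.setdefault(genome, {})[b] = f

    counts: dict[Pair, int] = {}
    for genome, present in focal_by_genome.items():
        for a, b in combinations(sorted(present.values()), 2):
            counts.setdefault(_ordered(a, b), 0)

    for genome, operons in operons_by_genome.items():
        known = None
        if annotations is not None:
            known = set(annotations[genome]["gene_id"])
        bacterial_to_focal = focal_by_genome.get(genome, {})
        cooccurring: set[Pair] = set()
        for op in operons:
            if known is not None:
                stray = set(op.genes) - known
                if stray:
                    raise InputError(
                        f"operon in {genome} references unannotated genes {sorted(stray)}"
                    )
            members = sorted(
                bacterial_to_focal[g] for g in op.genes if g in bacterial_to_focal
            )
            for a, b in combinations(members, 2):
                cooccurring.add(_ordered(a, b))
        for pair in cooccurring:
            counts[pair] = counts.get(pair, 0) + 1
    return counts


def normalize_cooperon(
    raw_counts: Mapping[Pair, int],
    species_counts: Mapping[str, int],
) -> list[CoOperonRecord]:
    """Divide each raw count by the larger of the two species counts."""
    records = []
    for (a, b), raw in sorted(raw_counts.items()):
        try:
            ca, cb = species_counts[a], species_counts[b]
        except KeyError as exc:
            raise InputError(f"missing species count for gene {exc.args[0]!r}") from None
        if min(ca, cb) < 1:
            raise InputError(f"species count below 1 for pair ({a}, {b})")
        if raw > min(ca, cb):
            raise InputError(
                f"raw count {raw} exceeds the smaller species count for ({a}, {b})"
            )
        m = max(ca, cb)
        records.append(CoOperonRecord(a, b, int(raw), int(m), raw / m))
    return records


def filter_pairs(
    records: Iterable[CoOperonRecord],
    min_species: int = 50,
) -> list[CoOperonRecord]:
    """Keep pairs whose larger species count is at least ``min_species``."""
    return [r for r in records if r.species_count_max >= min_species]


def records_to_frame(records: Iterable[CoOperonRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_a, r.gene_b, r.raw_count, r.species_count_max, r.normalized_freq)
         for r in records],
        columns=["gene_a", "gene_b", "raw_count", "species_count_max", "normalized_freq"],
    )
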