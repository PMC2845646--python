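"""Bidirectional-best-hit orthology and genome redundancy reduction.

Orthology between a focal (yeast-like) gene and a bacterial gene is called
only when each is the other's best similarity hit below the E-value cutoff
(default 1e-4).  Best means highest bitscore, with ties broken by lower
E-value and then lexicographic subject id, so the result is deterministic.
Redundant, nearly identical genomes are collapsed by keeping, per
redundancy group, the genome sharing the most orthologs with the focal set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import InputError

__all__ = [
    "OrthologMap",
    "bidirectional_best_hits",
    "reduce_redundancy",
    "merge_maps",
]

_ENTRY_COLUMNS = ["focal_gene", "genome_id", "bacterial_gene"]


@dataclass
class OrthologMap:
    """One-to-one focal-to-bacterial gene map, possibly spanning genomes."""

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_ENTRY_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in _ENTRY_COLUMNS if c not in self.entries.columns]
        if missing:
            raise InputError(f"ortholog entries missing columns {missing}")
        self.entries = self.entries[_ENTRY_COLUMNS].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        e = self.entries
        if e.duplicated(["focal_gene", "genome_id"]).any():
            raise InputError("more than one bacterial gene for a (focal, genome) pair")
        if e.duplicated(["genome_id", "bacterial_gene"]).any():
            raise InputError("a bacterial gene is claimed by more than one focal gene")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genomes(self) -> list[str]:
        return sorted(self.entries["genome_id"].unique())

    @property
    def species_count(self) -> dict[str, int]:
        """Number of genomes with an ortholog, per focal gene."""
        return self.entries.groupby("focal_gene")["genome_id"].nunique().to_dict()

    def as_dict(self) -> dict[str, dict[str, str]]:
        """focal gene -> {genome -> bacterial gene}."""
        out: dict[str, dict[str, str]] = {}
        for row in self.entries.itertuples(index=False):
            out.setdefault(row.focal_gene, {})[row.genome_id] = row.bacterial_gene
        return out


def _best_hits(hits: pd.DataFrame, e_cutoff: float) -> dict[str, str]:
    """Best subject per query among hits with e_value < cutoff."""
    if hits.duplicated(["qseqid", "sseqid"]).any():
        raise InputError("duplicate (query, subject) rows in similarity table")
    sig = hits[hits["evalue"] < e_cutoff]
    if sig.empty:
        return {}
    ranked = sig.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = ranked.drop_duplicates("qseqid", keep="first")
    return dict(zip(best["qseqid"], best["sseqid"]))


def bidirectional_best_hits(
    forward: pd.DataFrame,
    reverse: pd.DataFrame,
    genome_id: str,
    e_cutoff: float = 1e-4,
) -> OrthologMap:
    """Call orthologs for one genome from forward and reverse hit tables.

    ``forward`` queries are focal genes, ``reverse`` queries bacterial
    genes; both tables need (at least) the BLAST tabular columns ``qseqid``,
    ``sseqid``, ``evalue``, ``bitscore``.
    """
    if e_cutoff <= 0:
        raise InputError("e_cutoff must be positive")
    fwd_best = _best_hits(forward, e_cutoff)
    rev_best = _best_hits(reverse, e_cutoff)
    rows = [
        (f, genome_id, b)
        for f, b in sorted(fwd_best.items())
        if rev_best.get(b) == f
    ]
    return OrthologMap(pd.DataFrame(rows, columns=_ENTRY_COLUMNS))


def reduce_redundancy(
    maps: Mapping[str, OrthologMap],
    groups: Mapping[str, str],
) -> list[str]:
    """Keep one genome per redundancy group: the one with the most orthologs.

    Ties go to the lexicographically smaller genome id.  Every genome named
    in ``groups`` must have a map.
    """
    missing = sorted(set(groups) - set(maps))
    if missing:
        raise InputError(f"genomes without an ortholog map: {missing}")
    by_group: dict[str, list[str]] = {}
    for genome, label in groups.items():
        by_group.setdefault(label, []).append(genome)
    survivors = []
    for label in sorted(by_group):
        members = sorted(by_group[label])
        survivors.append(min(members, key=lambda g: (-len(maps[g]), g)))
    return sorted(survivors)


def merge_maps(maps: Iterable[OrthologMap]) -> OrthologMap:
    """Concatenate per-genome maps into one global map.

    Genomes must be disjoint across the inputs; species counts are then
    recomputed from the concatenation.
    """
    frames = [m.entries for m in maps]
    if not frames:
        return OrthologMap()
    merged = pd.concat(frames, ignore_index=True)
    seen: set[str] = set()
    for m_genomes in (set(f["genome_id"].unique()) for f in frames):
        if seen & m_genomes:
            raise InputError(f"genomes appear in more than one map: {sorted(seen & m_genomes)}")
        seen |= m_genomes
    merged = merged.sort_values(_ENTRY_COLUMNS, kind="mergesort").reset_index(drop=True)
    return OrthologMap(merged)
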