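"""Synthetic bacterial genomes, similarity scores and TR/RA expression series.

The generator plants every statistical feature the downstream analysis
assumes, so each stage can be tested against known truth:

* bacterial genomes with operon structure, where members of a "functional
  group" of focal (yeast-like) genes are co-placed in one operon with a
  configurable probability, and intergenic distances differ between
  same-operon neighbours and operon boundaries;
* groups of nearly identical genomes (redundant genomes) for testing
  redundancy reduction;
* bidirectional similarity-score tables in which every true ortholog pair
  is the mutual best hit, with optional decoy hits;
* transcription-rate (TR) and mRNA-abundance (RA) time series in which RA
  follows a first-order synthesis–degradation recursion of TR, planting a
  one-timepoint TR→RA lag and, through per-gene degradation-rate spread,
  the TR/RA decoupling the comparison stage is meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import ConfigError

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "generate_genomes",
    "generate_similarity_scores",
    "generate_expression",
    "generate_training_pairs",
]

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Distance parameters are ``(mean, sd, lower_truncation)`` of a truncated
    normal in base pairs.  TR profiles live on a log2 scale (slopes in log2
    units per timepoint) and are exponentiated onto a positive linear scale
    before noise is added, so the raw matrices behave like intensity data.
    """

    n_genomes: int = 32
    n_redundant_groups: int = 2
    redundant_group_size: int = 2
    genes_per_genome: int = 220
    n_focal_genes: int = 200
    n_functional_groups: int = 15
    group_size: int = 6
    p_cooperon: float = 0.8
    ortholog_coverage: float = 0.9
    redundant_dropout: float = 0.1
    intergenic_within: tuple[float, float, float] = (40.0, 30.0, -20.0)
    intergenic_between: tuple[float, float, float] = (300.0, 150.0, 50.0)
    gene_length: tuple[float, float, float] = (900.0, 200.0, 100.0)
    n_timepoints: int = 6
    tr_slope_max: float = 0.6
    tr_baseline: float = 100.0
    ra_alpha: float = 0.35
    ra_beta: float = 1.0
    noise_sd_tr: float = 10.0
    noise_sd_ra: float = 15.0
    degradation_sd: float = 0.30
    n_degradation_regulons: int = 8
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genomes": self.n_genomes,
            "n_redundant_groups": self.n_redundant_groups,
            "redundant_group_size": self.redundant_group_size,
            "genes_per_genome": self.genes_per_genome,
            "n_focal_genes": self.n_focal_genes,
            "n_functional_groups": self.n_functional_groups,
            "group_size": self.group_size,
            "n_timepoints": self.n_timepoints,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        for name in ("p_cooperon", "ortholog_coverage", "redundant_dropout"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p!r}")
        if not 0.0 <= self.ra_alpha < 1.0:
            raise ConfigError(f"ra_alpha must lie in [0, 1), got {self.ra_alpha!r}")
        if self.ra_beta <= 0:
            raise ConfigError(f"ra_beta must be positive, got {self.ra_beta!r}")
        for name in ("noise_sd_tr", "noise_sd_ra", "degradation_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_functional_groups * self.group_size > self.n_focal_genes:
            raise ConfigError(
                "group_size * n_functional_groups exceeds n_focal_genes "
                f"({self.group_size} * {self.n_functional_groups} > {self.n_focal_genes})"
            )
        if self.n_redundant_groups * self.redundant_group_size > self.n_genomes:
            raise ConfigError("redundant groups do not fit into n_genomes")
        if self.genes_per_genome < self.n_focal_genes:
            raise ConfigError("genes_per_genome must be >= n_focal_genes")

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


@dataclass
class SynthTruth:
    """Ground truth recorded while generating the benchmark.

    ``true_orthologs`` maps each focal gene to its bacterial gene per genome
    (one-to-one within a genome); ``true_operons`` lists, per genome, every
    planted transcription unit with at least two genes.
    """

    focal_genes: list[str]
    functional_groups: dict[str, int]          # focal gene -> group index (-1 = none)
    true_orthologs: dict[str, dict[str, str]]  # focal -> {genome -> bacterial gene}
    true_operons: dict[str, list[tuple[str, ...]]]
    genome_groups: dict[str, str]              # genome -> redundancy-group label
    bacterial_genes: dict[str, list[str]]      # genome -> all gene ids, genomic order
    unit_membership: dict[str, dict[str, int]] = field(default_factory=dict)
    group_coherence: dict[int, float] = field(default_factory=dict)
    true_lag: int = 1

    @property
    def genomes(self) -> list[str]:
        return sorted(self.bacterial_genes)

    def species_count(self) -> dict[str, int]:
        """Number of genomes carrying an ortholog, per focal gene."""
        return {f: len(m) for f, m in self.true_orthologs.items()}


def _trunc_normal(rng: np.random.Generator, params: tuple[float, float, float], size=None):
    mean, sd, lower = params
    draw = rng.normal(mean, sd, size=size)
    return np.maximum(draw, lower)


def _plan_units(cfg: SynthConfig, rng: np.random.Generator,
                present: dict[str, bool], groups: dict[str, int],
                p_group: Mapping[int, float]):
    """Lay out one base genome as an ordered list of transcription units.

    Returns ``(units, strands, cooperon_flags)`` where each unit is a list
    of slot labels: focal gene ids for ortholog slots, ``None`` for filler
    genes.  Functional-group members present in the genome are co-placed as
    one operon with the group's probability ``p_group[g]``; filler operons
    never contain two focal genes, so cross-group pairs are never planted
    together.
    """
    focal_present = [f for f in sorted(present) if present[f]]
    units: list[list] = []
    cooperon_flags = {}
    grouped: dict[int, list[str]] = {}
    for f in focal_present:
        g = groups[f]
        if g >= 0:
            grouped.setdefault(g, []).append(f)
    placed = set()
    for g in sorted(grouped):
        members = grouped[g]
        co = len(members) >= 2 and rng.random() < p_group[g]
        cooperon_flags[g] = co
        if co:
            units.append(list(members))
            placed.update(members)
    for f in focal_present:
        if f not in placed:
            units.append([f])
    n_filler = cfg.genes_per_genome - len(focal_present)
    sizes = []
    remaining = n_filler
    while remaining > 0:
        s = int(rng.choice([1, 2, 3, 4], p=[0.4, 0.3, 0.2, 0.1]))
        s = min(s, remaining)
        sizes.append(s)
        remaining -= s
    for s in sizes:
        units.append([None] * s)
    order = rng.permutation(len(units))
    units = [units[i] for i in order]
    strands = rng.choice(["+", "-"], size=len(units))
    return units, list(strands), cooperon_flags


def _realize_genome(cfg: SynthConfig, rng: np.random.Generator, genome_id: str,
                    units, strands):
    """Assign ids and coordinates to a planned genome."""
    rows = []
    gene_ids_order: list[str] = []
    ortholog_of: dict[str, str] = {}
    unit_of: dict[str, int] = {}
    operons: list[tuple[str, ...]] = []
    cursor = 0
    idx = 0
    for u, (slots, strand) in enumerate(zip(units, strands)):
        unit_genes = []
        for j, slot in enumerate(slots):
            gene_id = f"{genome_id}_{idx:04d}"
            idx += 1
            length = int(round(_trunc_normal(rng, cfg.gene_length)))
            if j == 0:
                gap = int(round(_trunc_normal(rng, cfg.intergenic_between)))
            else:
                gap = int(round(_trunc_normal(rng, cfg.intergenic_within)))
            start = cursor + 1 + gap
            end = start + length - 1
            cursor = end
            rows.append((gene_id, genome_id, start, end, strand))
            unit_genes.append(gene_id)
            gene_ids_order.append(gene_id)
            unit_of[gene_id] = u
            if slot is not None:
                ortholog_of[slot] = gene_id
        if len(unit_genes) >= 2:
            operons.append(tuple(unit_genes))
    annotation = pd.DataFrame(
        rows, columns=["gene_id", "genome_id", "start", "end", "strand"]
    )
    return annotation, gene_ids_order, ortholog_of, unit_of, operons


def generate_genomes(config: SynthConfig) -> tuple[dict[str, pd.DataFrame], SynthTruth]:
    """Generate annotated genomes with planted operons and ortholog slots.

    Returns per-genome annotation tables (gene_id, genome_id, start, end,
    strand; 1-based inclusive coordinates, sorted by start) and the truth.
    Genomes within a redundancy group share gene content, unit structure and
    strands; only their coordinates are redrawn, and each ortholog link is
    independently dropped with probability ``redundant_dropout`` in the
    non-first copies, so shared-ortholog counts vary within a group.
    """
    config.validate()
    rng = substream(config.seed, "genomes")

    focal = [f"Y{i + 1:04d}" for i in range(config.n_focal_genes)]
    groups: dict[str, int] = {f: -1 for f in focal}
    for g in range(config.n_functional_groups):
        for j in range(config.group_size):
            groups[focal[g * config.group_size + j]] = g

    # Graded relatedness: each group's coherence scales both how reliably
    # its members are co-placed in one operon and (in the expression
    # generator) how tightly they co-transcribe.  p_cooperon ** (1/c) keeps
    # the p_cooperon = 0 and = 1 limiting cases exact.
    coherence = {
        g: float(c)
        for g, c in enumerate(rng.uniform(0.3, 1.0, config.n_functional_groups))
    }
    p_group = {g: config.p_cooperon ** (1.0 / c) for g, c in coherence.items()}

    # Redundancy layout: the first k*r genomes form k groups of near-copies.
    genome_ids = [f"G{i + 1:02d}" for i in range(config.n_genomes)]
    genome_groups: dict[str, str] = {}
    base_of: dict[str, str] = {}
    i = 0
    for r in range(config.n_redundant_groups):
        label = f"R{r + 1}"
        members = genome_ids[i:i + config.redundant_group_size]
        for m in members:
            genome_groups[m] = label
            base_of[m] = members[0]
        i += config.redundant_group_size
    for gid in genome_ids[i:]:
        genome_groups[gid] = gid
        base_of[gid] = gid

    annotations: dict[str, pd.DataFrame] = {}
    true_orthologs: dict[str, dict[str, str]] = {f: {} for f in focal}
    true_operons: dict[str, list[tuple[str, ...]]] = {}
    bacterial_genes: dict[str, list[str]] = {}
    unit_membership: dict[str, dict[str, int]] = {}

    plans: dict[str, tuple] = {}
    for gid in genome_ids:
        base = base_of[gid]
        if base == gid:
            present = {f: bool(rng.random() < config.ortholog_coverage) for f in focal}
            units, strands, _ = _plan_units(config, rng, present, groups, p_group)
            plans[gid] = (units, strands)
        else:
            units, strands = plans[base]
        annotation, order, ortholog_of, unit_of, operons = _realize_genome(
            config, rng, gid, units, strands
        )
        if base != gid:
            kept = {}
            for f, b in ortholog_of.items():
                if rng.random() >= config.redundant_dropout:
                    kept[f] = b
            ortholog_of = kept
        annotations[gid] = annotation
        bacterial_genes[gid] = order
        true_operons[gid] = operons
        unit_membership[gid] = unit_of
        for f, b in ortholog_of.items():
            true_orthologs[f][gid] = b

    truth = SynthTruth(
        focal_genes=focal,
        functional_groups=groups,
        true_orthologs=true_orthologs,
        true_operons=true_operons,
        genome_groups=genome_groups,
        bacterial_genes=bacterial_genes,
        unit_membership=unit_membership,
        group_coherence=coherence,
        true_lag=1,
    )
    return annotations, truth


def generate_similarity_scores(
    truth: SynthTruth,
    decoy_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Emit bidirectional similarity tables (BLAST tabular layout) per genome.

    Every true ortholog pair is the top-scoring hit in both directions with
    an E-value far below 1e-4.  ``decoy_rate`` injects, per direction,
    ``round(decoy_rate * n_true)`` spurious hits.  A decoy attached to a
    gene that has a true partner always scores below that partner's hit; a
    decoy between two unpartnered genes is emitted with a supra-threshold
    E-value only (a weak local alignment), so decoys can never form a
    significant mutual best pair.
    """
    if not 0.0 <= decoy_rate:
        raise ConfigError("decoy_rate must be non-negative")
    rng = substream(seed, "scores")
    out: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for genome in truth.genomes:
        pairs = sorted(
            (f, m[genome]) for f, m in truth.true_orthologs.items() if genome in m
        )
        fwd_rows, rev_rows = [], []
        true_bits_f: dict[str, float] = {}
        true_bits_b: dict[str, float] = {}
        for f, b in pairs:
            bits = float(rng.uniform(200.0, 400.0))
            ev = 10.0 ** -float(rng.uniform(20.0, 80.0))
            fwd_rows.append((f, b, ev, bits))
            rev_rows.append((b, f, ev, bits))
            true_bits_f[f] = bits
            true_bits_b[b] = bits
        n_decoys = int(round(decoy_rate * len(pairs)))
        all_b = truth.bacterial_genes[genome]
        all_f = truth.focal_genes
        true_set = set(pairs)

        def _add_decoys(rows, queries, subjects, q_bits, s_bits, flip):
            seen = {(r[0], r[1]) for r in rows}
            made = 0
            while made < n_decoys:
                q = queries[int(rng.integers(len(queries)))]
                s = subjects[int(rng.integers(len(subjects)))]
                key = (q, s)
                pair = (s, q) if flip else (q, s)
                if key in seen or pair in true_set:
                    continue
                seen.add(key)
                ceiling = min(
                    q_bits.get(q, np.inf) - 20.0, s_bits.get(s, np.inf) - 20.0
                )
                if np.isfinite(ceiling):
                    bits = float(rng.uniform(30.0, max(31.0, ceiling)))
                    ev = 10.0 ** -float(rng.uniform(0.0, 10.0))
                else:
                    bits = float(rng.uniform(30.0, 80.0))
                    ev = 10.0 ** -float(rng.uniform(0.0, 3.0))  # >= 1e-3
                rows.append((q, s, ev, bits))
                made += 1

        if n_decoys and all_b:
            _add_decoys(fwd_rows, all_f, all_b, true_bits_f, true_bits_b, flip=False)
            _add_decoys(rev_rows, all_b, all_f, true_bits_b, true_bits_f, flip=True)
        out[genome] = (_as_blast_table(fwd_rows), _as_blast_table(rev_rows))
    return out


def _as_blast_table(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue", "bitscore"])
    full = pd.DataFrame({
        "qseqid": df["qseqid"], "sseqid": df["sseqid"],
        "pident": 40.0, "length": 250, "mismatch": 120, "gapopen": 5,
        "qstart": 1, "qend": 250, "sstart": 1, "send": 250,
        "evalue": df["evalue"], "bitscore": df["bitscore"],
    })
    return full[BLAST_COLUMNS]


def _piecewise_profile(rng: np.random.Generator, n_t: int, slope_max: float) -> np.ndarray:
    """Random piecewise-linear log2 profile starting at 0.

    An independent slope ~ Uniform(-slope_max, slope_max) per interval makes
    profiles fluctuate rather than rise or fall monotonically, as real
    time-course profiles do.
    """
    slopes = rng.uniform(-slope_max, slope_max, size=n_t - 1)
    return np.concatenate([[0.0], np.cumsum(slopes)])


def generate_expression(truth: SynthTruth, config: SynthConfig):
    """Generate raw TR and RA matrices (genes x timepoints, positive values).

    Genes of one functional group share a log2 TR base profile; each other
    focal gene gets its own.  On the linear scale,

        RA(t) = alpha_g(t) * RA(t-1) + ra_beta * TR(t-1) + eps,

    with ``RA(t1)`` at the steady state of the initial TR.  The carry-over
    coefficient (one minus the degradation rate) varies both per gene and
    over time:

        alpha_g(t) = clip(ra_alpha + D*z_g/2 + D*w_{k(g)}(t), 0.02, 0.95)

    where ``D = degradation_sd``, ``z_g`` is a static per-gene jitter, and
    ``w_k(t)`` is a time profile shared by the genes of degradation regulon
    ``k`` — mRNA decay is co-regulated, but in groups drawn independently
    of the functional (co-operon) groups.  With ``degradation_sd = 0`` the
    coefficient is exactly ``ra_alpha`` for every gene and timepoint.  This
    plants a one-timepoint TR-to-RA lag, and the degradation structure
    decouples RA profile similarity from functional relatedness, as decay
    regulation does in real data.
    """
    from .expression import ExpressionMatrix

    config.validate()
    if config.n_timepoints < 3:
        raise ConfigError("n_timepoints must be >= 3 for expression generation")
    rng = substream(config.seed, "expression")
    genes = truth.focal_genes
    n_t = config.n_timepoints
    n_groups = max([g for g in truth.functional_groups.values()] + [-1]) + 1

    group_profiles = [
        _piecewise_profile(rng, n_t, config.tr_slope_max) for _ in range(n_groups)
    ]
    log_profiles = np.empty((len(genes), n_t))
    for i, g in enumerate(genes):
        grp = truth.functional_groups.get(g, -1)
        if grp >= 0:
            log_profiles[i] = group_profiles[grp]
        else:
            log_profiles[i] = _piecewise_profile(rng, n_t, config.tr_slope_max)

    tr = config.tr_baseline * np.power(2.0, log_profiles)
    if config.noise_sd_tr > 0:
        # Tighter co-transcription for more coherent groups: the gene-level
        # noise SD is scaled by (1.6 - coherence), i.e. 0.6x for a fully
        # coherent group up to 1.3x for a barely coherent one.
        scale = np.ones(len(genes))
        for i, g in enumerate(genes):
            grp = truth.functional_groups.get(g, -1)
            if grp >= 0:
                scale[i] = 1.6 - truth.group_coherence.get(grp, 1.0)
        tr = tr + rng.normal(0.0, 1.0, size=tr.shape) * (
            config.noise_sd_tr * scale[:, None]
        )
    tr = np.maximum(tr, 1e-3)

    if config.degradation_sd > 0:
        d = config.degradation_sd
        static = rng.normal(0.0, d / 2.0, size=len(genes))
        regulon = rng.integers(0, config.n_degradation_regulons, size=len(genes))
        w = rng.normal(0.0, d, size=(config.n_degradation_regulons, n_t))
        alpha = np.clip(
            config.ra_alpha + static[:, None] + w[regulon, :], 0.02, 0.95
        )
    else:
        alpha = np.full((len(genes), n_t), config.ra_alpha)

    ra = np.empty_like(tr)
    denom = np.where(1.0 - alpha[:, 0] > 1e-9, 1.0 - alpha[:, 0], 1e-9)
    ra[:, 0] = config.ra_beta * tr[:, 0] / denom
    for t in range(1, n_t):
        ra[:, t] = alpha[:, t] * ra[:, t - 1] + config.ra_beta * tr[:, t - 1]
    if config.noise_sd_ra > 0:
        ra = ra + rng.normal(0.0, config.noise_sd_ra, size=ra.shape)
    ra = np.maximum(ra, 1e-3)

    columns = [f"t{i + 1}" for i in range(n_t)]
    tr_m = ExpressionMatrix(pd.DataFrame(tr, index=genes, columns=columns),
                            stage="raw", assay="TR")
    ra_m = ExpressionMatrix(pd.DataFrame(ra, index=genes, columns=columns),
                            stage="raw", assay="RA")
    return tr_m, ra_m


def generate_training_pairs(annotation: pd.DataFrame, truth: SynthTruth,
                            genome_id: str) -> pd.DataFrame:
    """Label a genome's adjacent gene pairs from the planted unit structure.

    Stands in for a curated operon database: adjacent same-unit pairs are
    ``same_operon``; same-strand pairs straddling a unit boundary are
    ``different_operon``; opposite-strand pairs are ``unlabeled``.
    """
    from .operons import extract_adjacent_pairs

    pairs = extract_adjacent_pairs(annotation)
    unit_of: Mapping[str, int] = truth.unit_membership[genome_id]
    labels = []
    for row in pairs.itertuples(index=False):
        if unit_of[row.upstream_gene] == unit_of[row.downstream_gene]:
            labels.append("same_operon")
        elif row.same_strand:
            labels.append("different_operon")
        else:
            labels.append("unlabeled")
    out = pairs.copy()
    out["label"] = labels
    return out
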