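"""Readers and writers for the plain-text formats flowing between stages.

Everything is tab-separated.  Annotation may also be written/read as GFF3
(gene features only).  Expression matrices carry their stage and assay in
a leading ``# stage=... assay=...`` comment line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .cooperon import CoOperonRecord, records_to_frame
from .errors import InputError
from .expression import CorrelationSet, ExpressionMatrix
from .operons import Operon
from .orthology import OrthologMap
from .synthetic_data import BLAST_COLUMNS

ANNOTATION_COLUMNS = ["gene_id", "genome_id", "start", "end", "strand"]


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"annotation {path} missing columns {missing}")
    return df[ANNOTATION_COLUMNS]


def write_annotation_gff3(annotation: pd.DataFrame, path) -> None:
    lines = ["##gff-version 3"]
    for row in annotation.itertuples(index=False):
        lines.append(
            f"{row.genome_id}\ttrra\tgene\t{row.start}\t{row.end}\t."
            f"\t{row.strand}\t.\tID={row.gene_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation_gff3(path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9 or fields[2] != "gene":
            continue
        attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
        if "ID" not in attrs:
            raise InputError(f"gene feature without ID in {path}")
        rows.append((attrs["ID"], fields[0], int(fields[3]), int(fields[4]), fields[6]))
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_blast_table(hits: pd.DataFrame, path) -> None:
    hits[BLAST_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_blast_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, float_precision="round_trip")
    if df.shape[1] < 12:
        raise InputError(f"{path}: expected 12 BLAST tabular columns, got {df.shape[1]}")
    df = df.iloc[:, :12]
    df.columns = BLAST_COLUMNS
    return df


def write_ortholog_map(omap: OrthologMap, entries_path, counts_path=None) -> None:
    omap.entries.to_csv(entries_path, sep="\t", index=False)
    if counts_path is not None:
        counts = pd.DataFrame(
            sorted(omap.species_count.items()), columns=["focal_gene", "species_count"]
        )
        counts.to_csv(counts_path, sep="\t", index=False)


def read_ortholog_map(entries_path) -> OrthologMap:
    return OrthologMap(pd.read_csv(entries_path, sep="\t"))


def write_operons(operons: Iterable[Operon], path) -> None:
    rows = []
    for i, op in enumerate(operons):
        for j, gene in enumerate(op.genes):
            rows.append((op.genome_id, i, gene, j, op.strand))
    pd.DataFrame(
        rows, columns=["genome_id", "operon_id", "gene_id", "position_in_operon", "strand"]
    ).to_csv(path, sep="\t", index=False)


def read_operons(path) -> list[Operon]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (genome_id, _), sub in df.groupby(["genome_id", "operon_id"], sort=True):
        sub = sub.sort_values("position_in_operon")
        out.append(Operon(genome_id, tuple(sub["gene_id"]), sub["strand"].iloc[0]))
    return out


def write_expression(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={matrix.stage} assay={matrix.assay}\n")
        matrix.data.to_csv(fh, sep="\t", index_label="gene_id")


def read_expression(path) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise InputError(f"{path}: missing '# stage=... assay=...' metadata line")
        meta = dict(kv.split("=", 1) for kv in header.lstrip("# ").split())
        data = pd.read_csv(fh, sep="\t", index_col="gene_id", float_precision="round_trip")
        data.index.name = None
    return ExpressionMatrix(data, stage=meta["stage"], assay=meta["assay"])


def write_cooperon_records(records: Iterable[CoOperonRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_cooperon_records(path) -> list[CoOperonRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        CoOperonRecord(r.gene_a, r.gene_b, int(r.raw_count),
                       int(r.species_count_max), float(r.normalized_freq))
        for r in df.itertuples(index=False)
    ]


def write_correlations(cs: CorrelationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# assay={cs.assay}\n")
        cs.to_frame().to_csv(fh, sep="\t", index=False)


def read_correlations(path) -> CorrelationSet:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise InputError(f"{path}: missing '# assay=...' metadata line")
        meta = dict(kv.split("=", 1) for kv in header.lstrip("# ").split())
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    r = {(row.gene_a, row.gene_b): float(row.r) for row in df.itertuples(index=False)}
    return CorrelationSet(meta["assay"], r)


def write_training_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_training_pairs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_sidecars(truth, out_dir) -> None:
    """Persist the generator's ground truth as a set of sidecar TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(f, g) for f, g in sorted(truth.functional_groups.items())],
        columns=["focal_gene", "group"],
    ).to_csv(out / "functional_groups.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(f, genome, b) for f, m in sorted(truth.true_orthologs.items())
         for genome, b in sorted(m.items())],
        columns=["focal_gene", "genome_id", "bacterial_gene"],
    ).to_csv(out / "true_orthologs.tsv", sep="\t", index=False)
    rows = []
    for genome, ops in sorted(truth.true_operons.items()):
        for i, genes in enumerate(ops):
            for j, gene in enumerate(genes):
                rows.append((genome, i, gene, j))
    pd.DataFrame(
        rows, columns=["genome_id", "operon_id", "gene_id", "position_in_operon"]
    ).to_csv(out / "true_operons.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.genome_groups.items()), columns=["genome_id", "group"]
    ).to_csv(out / "genome_groups.tsv", sep="\t", index=False)


def read_genome_groups(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["genome_id"], df["group"]))
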