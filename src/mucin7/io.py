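"""File-format plumbing: FASTA, TSV, BED, newick and YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import ExpressionMatrix
from .repeats import CodingSequence, RepeatAnnotation


def read_fasta(path) -> list[CodingSequence]:
    """Load CDS records; the species defaults to the record id."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            CodingSequence(id=rec.id, species=rec.id, sequence=str(rec.seq))
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences: dict[str, str], path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_annotation(ann: RepeatAnnotation, prefix) -> None:
    """Emit detected repeats as BED (0-based half-open) plus a units TSV."""
    prefix = Path(prefix)
    with open(f"{prefix}.bed", "w") as bed:
        for i, (start, end, _) in enumerate(ann.units):
            bed.write(f"{ann.source_id}\t{start}\t{end}\tunit_{i + 1}\n")
        if ann.partial_trailing:
            s, e, _ = ann.partial_trailing
            bed.write(f"{ann.source_id}\t{s}\t{e}\tpartial\n")
    rows = [
        {"source": ann.source_id, "unit": i + 1, "start": s, "end": e, "sequence": u}
        for i, (s, e, u) in enumerate(ann.units)
    ]
    pd.DataFrame(
        rows, columns=["source", "unit", "start", "end", "sequence"]
    ).to_csv(f"{prefix}.units.tsv", sep="\t", index=False)


def read_units_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"source", "unit", "sequence"} - set(df.columns)
    if missing:
        raise ValueError(f"units TSV missing columns {sorted(missing)}")
    return df


def read_genotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_observed_states(path) -> dict[str, tuple[int, ...]]:
    """obs.tsv: tip<TAB>comma-separated alleles."""
    out: dict[str, tuple[int, ...]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        tip, alleles = line.split("\t")
        out[tip] = tuple(int(a) for a in alleles.split(","))
    return out


def write_expression(matrix: ExpressionMatrix, prefix) -> None:
    prefix = Path(prefix)
    df = matrix.gene_info.join(matrix.values)
    df.to_csv(f"{prefix}.matrix.tsv", sep="\t", index_label="gene")
    matrix.tissues.to_csv(f"{prefix}.tissues.tsv", sep="\t", index_label="sample")


def read_expression(matrix_path, tissues_path) -> ExpressionMatrix:
    df = pd.read_csv(matrix_path, sep="\t", index_col="gene")
    tissues = pd.read_csv(tissues_path, sep="\t", index_col="sample")["tissue"]
    return ExpressionMatrix(
        values=df.drop(columns=["chrom", "position"]),
        gene_info=df[["chrom", "position"]],
        tissues=tissues,
    )


def read_protein_alignment(path) -> tuple[list[str], list[str]]:
    labels, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not labels:
        raise ValueError(f"no records in {path}")
    return labels, seqs


def read_segments_tsv(path) -> dict[str, tuple[int, int]]:
    """BED-like TSV over alignment columns: name<TAB>start<TAB>end."""
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "start", "end"])
    return {r["name"]: (int(r["start"]), int(r["end"])) for _, r in df.iterrows()}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
        fh.write("\n")
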