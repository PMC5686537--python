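"""FASTA and table readers/writers, report serialization, code comparison."""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codes import (
    ChemicalClassTable,
    GeneticCode,
    count_reassignments,
    parse_classes,
    parse_code,
    standard_code,
)
from .metrics import combined_fitness, mean_evolvability


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping.

    Duplicate ids get a ``.2``, ``.3``, ... suffix (with a warning); an
    empty file yields an empty mapping.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in records:
            k = 2
            while f"{rid}.{k}" in records:
                k += 1
            warnings.warn(f"duplicate FASTA id {rid!r}; renamed to {rid}.{k}")
            rid = f"{rid}.{k}"
        records[rid] = str(rec.seq).upper()
    return records


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    """Write sequences wrapped at 70 columns."""
    seq_records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(seq_records)


def load_code(path: str | Path, name: str | None = None) -> GeneticCode:
    text = Path(path).read_text()
    return parse_code(text, name=name or Path(path).stem)


def save_code(code: GeneticCode, path: str | Path) -> None:
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(code.to_json() + "\n")
    else:
        p.write_text(code.to_tsv())


def load_classes(path: str | Path) -> ChemicalClassTable:
    return parse_classes(Path(path).read_text())


def save_classes(classes: ChemicalClassTable, path: str | Path) -> None:
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(classes.to_json() + "\n")
    else:
        p.write_text(classes.to_tsv())


def read_substitutions(path: str | Path) -> pd.DataFrame:
    """TSV with columns wt, mut, count."""
    df = pd.read_csv(path, sep="\t")
    missing = {"wt", "mut", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"substitution table missing column(s) {sorted(missing)}")
    return df


def write_report_json(report, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def write_report_tsv(report, path: str | Path) -> None:
    d = report.to_dict()
    lines = ["metric\tvalue"] + [f"{k}\t{v}" for k, v in d.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def compare_codes(
    codes: Sequence[GeneticCode],
    classes: ChemicalClassTable | None = None,
    genes: Iterable[str] | None = None,
    *,
    recode_genes: bool = False,
    reference: GeneticCode | None = None,
) -> pd.DataFrame:
    """One row of fitness metrics per code, plus optional mean evolvability.

    With ``genes`` given, each code gains a ``mean_evolvability`` column:
    the mean per-gene evolvability score, computed either on the genes as
    supplied (codon identities reinterpreted under each code) or — with
    ``recode_genes=True`` — after recoding each gene from the reference
    code onto the target code.
    """
    if not codes:
        raise ValueError("need at least one code")
    classes = classes or ChemicalClassTable()
    reference = reference or standard_code()
    gene_list = list(genes) if genes is not None else None
    rows = []
    for code in codes:
        rep = combined_fitness(code, classes, reference)
        row = {
            "code": code.name,
            "f_unique": rep.f_unique,
            "f_ratio": rep.f_ratio,
            "f_chem": rep.f_chem,
            "f_combined": rep.f_combined,
            "reassignments": count_reassignments(code, reference),
        }
        if gene_list is not None:
            if recode_genes and code.translation != reference.translation:
                from .recode import recode_gene

                recoded = [
                    recode_gene("AGGA", g, reference, code).recoded for g in gene_list
                ]
                row["mean_evolvability"] = mean_evolvability(recoded, code)
            else:
                row["mean_evolvability"] = mean_evolvability(gene_list, code)
        rows.append(row)
    return pd.DataFrame(rows)
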