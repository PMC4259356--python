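"""Readers/writers for the plain-text formats the pipeline exchanges:
FASTA (Biopython), GMT gene sets, TSV tables (pandas), YAML configs, JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: one gene set per line (name, description, symbols...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need >=3 fields): {line[:80]!r}")
            sets[fields[0]] = [s for s in fields[2:] if s]
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, symbols in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *symbols]) + "\n")


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True,
              header_comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, 2-space indent, trailing newline."""
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
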