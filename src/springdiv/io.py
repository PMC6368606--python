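"""Reading and writing the plain-text formats the pipeline exchanges.

Protein FASTA headers follow the convention ``<metagenome>|<protein_id>``;
tables are tab-separated text with header rows.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import InvalidInputError
from .seqcluster import ProteinRecord


def read_protein_fasta(path, metagenome_id: str | None = None) -> list[ProteinRecord]:
    """Read one metagenome's proteins from FASTA.

    Headers of the form ``mg|pid`` carry the metagenome id; otherwise
    ``metagenome_id`` must be supplied and the whole header is the protein id.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if "|" in header:
            mg, pid = header.split("|", 1)
        elif metagenome_id is not None:
            mg, pid = metagenome_id, header
        else:
            raise InvalidInputError(
                f"header {header!r} lacks the '<metagenome>|<protein_id>' form and no "
                "metagenome_id was given"
            )
        records.append(ProteinRecord(protein_id=pid, metagenome_id=mg, seq=str(rec.seq).upper()))
    if not records:
        raise InvalidInputError(f"no sequences in {path}")
    return records


def read_protein_fasta_dir(directory) -> list[ProteinRecord]:
    """Read every ``*.faa``/``*.fasta`` file under a directory."""
    directory = Path(directory)
    paths = sorted(list(directory.glob("*.faa")) + list(directory.glob("*.fasta")))
    if not paths:
        raise InvalidInputError(f"no FASTA files under {directory}")
    out: list[ProteinRecord] = []
    for p in paths:
        out.extend(read_protein_fasta(p, metagenome_id=p.stem))
    return out


def write_protein_fasta(records: Iterable[ProteinRecord], path) -> None:
    seq_records = [
        SeqRecord(Seq(r.seq), id=f"{r.metagenome_id}|{r.protein_id}", description="")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_annotation_table(path) -> pd.DataFrame:
    """Per-genome KO annotations: columns protein_id, ko (extra columns kept)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"protein_id", "ko"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"annotation table lacks column(s) {sorted(missing)}")
    return df


def read_tip_set(path) -> set[str]:
    """One tip label per line; blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
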