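"""File I/O: FASTA (via Biopython), TSV, JSON, Newick.

Conventions: FASTA reads tolerate wrapped lines and CRLF and upper-case the
sequence; duplicate ids are an error.  TSV writers use fixed column orders
so outputs are byte-reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import EnzymeEntry, GenomeRecord, PathwayCatalog


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: SEQUENCE}`` dict.

    Tolerates wrapped lines and CRLF; upper-cases sequences; rejects
    duplicate ids and data before the first header (naming file and line).
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}:{lineno}: expected a '>' header, got {stripped[:30]!r}"
                )
            break
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_genome_fasta(path: str | Path, genome_id: str | None = None) -> GenomeRecord:
    path = Path(path)
    gid = genome_id or path.stem
    return GenomeRecord(genome_id=gid, contigs=read_fasta(path))


def write_genome_fasta(genome: GenomeRecord, path: str | Path) -> None:
    write_fasta(genome.contigs, path)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


# -- catalog ---------------------------------------------------------------

def write_catalog(catalog: PathwayCatalog, fasta_path: str | Path, tsv_path: str | Path) -> None:
    seqs = {e.enzyme: e.sequence for e in catalog.enzymes}
    seqs.update(catalog.extras)
    write_fasta(seqs, fasta_path)
    write_tsv(catalog.to_frame(), tsv_path)


def read_catalog(fasta_path: str | Path, tsv_path: str | Path) -> PathwayCatalog:
    seqs = read_fasta(fasta_path)
    table = read_tsv(tsv_path)
    pathways: dict[str, list[EnzymeEntry]] = {}
    for row in table.itertuples(index=False):
        pathways.setdefault(row.pathway, []).append(
            EnzymeEntry(row.enzyme, row.pathway, seqs[row.enzyme], bool(row.is_unique))
        )
    roster_names = {row.enzyme for row in table.itertuples(index=False)}
    extras = {name: seq for name, seq in seqs.items() if name not in roster_names}
    return PathwayCatalog(pathways=pathways, extras=extras)


# -- quality table ---------------------------------------------------------

def read_quality(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    required = {"genome_id", "completeness", "contamination", "N50"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"quality table {path} missing columns: {sorted(missing)}")
    return df
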