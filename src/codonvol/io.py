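"""FASTA and TSV input/output helpers."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)


class FastaFormatError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-FASTA into (id, sequence) tuples.

    Tolerates wrapped lines and CRLF endings; record ids run up to the first
    whitespace.  Duplicate ids and sequence data before the first header are
    errors; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    with open(path, newline=None) as fh:
        first_content = None
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first_content = (lineno, line)
                break
        if first_content is None:
            logger.warning("read_fasta: %s is empty", path)
            return []
        if not first_content[1].lstrip().startswith(">"):
            raise FastaFormatError(
                f"{path}:{first_content[0]}: expected a FASTA header line starting with '>'"
            )
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    ids = [r[0] for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise FastaFormatError(f"{path}: duplicate record ids: {', '.join(dupes)}")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """UTF-8, header-bearing, newline-terminated TSV with stable float format."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g", lineterminator="\n")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_expression(path: str | Path) -> pd.Series:
    """Gene id -> log2 expression from a two-column TSV (gene_id, log2_expr)."""
    df = read_tsv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expression table needs gene_id and value columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))
    s.index.name = "gene_id"
    s.name = "log2_expr"
    return s
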