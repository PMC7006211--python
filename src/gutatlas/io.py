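"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything is a standard, line-oriented text format: protein FASTA
(Biopython), TSV tables (pandas) and 12-column tabular homology hit
tables in the BLAST ``outfmt 6`` dialect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TISSUES = ("M1", "M2", "M3", "M4", "carcass")
MIDGUT_TISSUES = ("M1", "M2", "M3", "M4")

#: Trinity-style accession, e.g. ``TRINITY_DN1000_c115_g1_i1``.
TRINITY_RE = re.compile(
    r"^(?P<gene>(?:TRINITY_)?DN\d+_c\d+_g\d+)_(?P<isoform>i\d+)$"
)

OUTFMT6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class HitRecord:
    """One pairwise homology hit (outfmt-6 dialect)."""

    query: str
    subject: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int  # 1-based, inclusive
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"percent identity out of range: {self.pident}")
        if self.qstart > self.qend or self.sstart > self.send:
            raise ValueError("alignment start must not exceed end")
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")


def parse_trinity_id(accession: str) -> tuple[str, str]:
    """Split a Trinity accession into (gene_id, isoform_id).

    Raises ``ValueError`` for accessions that do not follow the
    ``DN..._c..._g..._i...`` scheme.
    """
    m = TRINITY_RE.match(accession)
    if m is None:
        raise ValueError(f"unparseable Trinity accession: {accession!r}")
    return m.group("gene"), m.group("isoform")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an ordered {accession: sequence} dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a replicate TPM matrix (gene_id column + tissue_replicate columns)."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if (df.values < 0).any():
        raise ValueError("TPM values must be non-negative")
    if df.isna().any().any():
        raise ValueError("expression matrix has missing cells")
    return df


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_taxon_annotation(path: str | Path) -> pd.DataFrame:
    """Read a taxon-annotation table (gene_id, taxon_group, e_value)."""
    return pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "taxon_group": str}
    )


def read_term_annotation(path: str | Path) -> pd.DataFrame:
    """Read a term-annotation table (gene_id, term_id, term_kind)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"gene_id", "term_id", "term_kind"}
    if not expected.issubset(df.columns):
        raise ValueError(f"term table must have columns {sorted(expected)}")
    return df


def read_hits(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tabular hit file (BLAST outfmt-6 dialect)."""
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS)
    return [
        HitRecord(
            query=str(r.qseqid),
            subject=str(r.sseqid),
            pident=float(r.pident),
            length=int(r.length),
            mismatch=int(r.mismatch),
            gapopen=int(r.gapopen),
            qstart=int(r.qstart),
            qend=int(r.qend),
            sstart=int(r.sstart),
            send=int(r.send),
            evalue=float(r.evalue),
            bitscore=float(r.bitscore),
        )
        for r in df.itertuples(index=False)
    ]


def write_hits(hits: Iterable[HitRecord], path: str | Path) -> None:
    rows = [
        [
            h.query, h.subject, f"{h.pident:.2f}", h.length, h.mismatch,
            h.gapopen, h.qstart, h.qend, h.sstart, h.send,
            f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
        ]
        for h in hits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
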