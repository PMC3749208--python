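"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; BLAST outfmt-6 tables, taxonomy node tables
and depth profiles are plain TSV/CSV via pandas.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .annotation import SimilarityHit
from .synthetic import SequenceRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_blast6",
    "write_blast6",
    "read_profile_csv",
    "write_profile_csv",
]

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_fasta(path, sample_id: str = "", depth: float = 0.0, molecule: str = "DNA"):
    """Load a FASTA file as :class:`SequenceRecord` objects.

    Sample metadata not expressible in FASTA (sample id, depth, molecule)
    is supplied by the caller and attached to every record.
    """
    return [
        SequenceRecord(
            id=rec.id, sample_id=sample_id, depth=depth,
            molecule=molecule, bases=str(rec.seq).upper(),
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord] | dict, path) -> None:
    """Write reads (or an id -> sequence mapping) as FASTA."""
    if isinstance(records, dict):
        bio = [BioSeqRecord(Seq(seq), id=rid, description="") for rid, seq in records.items()]
    else:
        bio = [BioSeqRecord(Seq(r.bases), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_blast6(path, subject_taxa: dict | None = None) -> list[SimilarityHit]:
    """Import an external aligner's tabular output (BLAST outfmt 6)."""
    table = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, header=None)
    return [
        SimilarityHit(
            query_id=str(r.qseqid),
            subject_id=str(r.sseqid),
            bit_score=float(r.bitscore),
            percent_identity=float(r.pident),
            alignment_length=int(r.length),
            subject_taxon=None if subject_taxa is None else subject_taxa.get(str(r.sseqid)),
        )
        for r in table.itertuples(index=False)
    ]


def write_blast6(hits: Iterable[SimilarityHit], path) -> None:
    """Export hits as a BLAST outfmt-6 table.

    Columns not tracked by the toy search (mismatches, gap opens, exact
    coordinates, e-value) are written as zero placeholders.
    """
    rows = [
        {
            "qseqid": h.query_id, "sseqid": h.subject_id,
            "pident": round(h.percent_identity, 3), "length": h.alignment_length,
            "mismatch": 0, "gapopen": 0, "qstart": 0, "qend": 0,
            "sstart": 0, "send": 0, "evalue": 0.0, "bitscore": round(h.bit_score, 2),
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=BLAST6_COLUMNS).to_csv(path, sep="\t", index=False, header=False)


def write_profile_csv(profile: pd.DataFrame, path) -> None:
    profile.to_csv(path, index=False)


def read_profile_csv(path) -> pd.DataFrame:
    profile = pd.read_csv(path)
    if "depth" not in profile.columns:
        raise ValueError("profile CSV needs a 'depth' column")
    return profile
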