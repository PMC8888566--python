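"""File-format helpers: FASTA/FASTQ, variant TSVs, GenBank construct maps."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .seqcore import NucleotideSequence, SequenceError, as_bases

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_reads",
    "write_fastq",
    "read_variant_table",
    "construct_to_genbank",
]


def read_fasta(path) -> list[NucleotideSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return [NucleotideSequence(str(r.seq), name=r.id) for r in records]


def write_fasta(seqs, path) -> None:
    records = [
        SeqRecord(Seq(as_bases(s)), id=getattr(s, "name", "") or f"seq{i + 1}", description="")
        for i, s in enumerate(seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path) -> list[str]:
    """Read merged amplicon reads from FASTA or FASTQ (by extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fq", ".fastq") else "fasta"
    return [str(r.seq) for r in SeqIO.parse(str(path), fmt)]


def write_fastq(reads, path, quality: int = 40) -> None:
    """Write reads with a constant quality; deterministic byte output."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            s = as_bases(r)
            fh.write(f"@read{i + 1}\n{s}\n+\n{chr(quality + 33) * len(s)}\n")


def read_variant_table(path) -> pd.DataFrame:
    """TSV with columns variant_id, flank, edit_pos, kind, ref, alt."""
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    missing = {"variant_id", "flank", "edit_pos", "kind"} - set(df.columns)
    if missing:
        raise SequenceError(f"variant table missing columns {sorted(missing)}")
    return df


def construct_to_genbank(insert, path, which: str = "pre") -> None:
    """Export the assembled reporter construct map as a GenBank flat file."""
    from .reporter_design import ReporterConstruct

    seq = insert.pre_edit_seq if which == "pre" else insert.post_edit_seq
    construct = ReporterConstruct.from_insert_seq(seq)
    full = "".join(s for _, s in construct.layout)
    record = SeqRecord(Seq(full), id=f"{insert.name}-{which}", description="reporter construct map")
    record.annotations["molecule_type"] = "DNA"
    pos = 0
    for name, segment in construct.layout:
        record.features.append(
            SeqFeature(
                FeatureLocation(pos, pos + len(segment)),
                type="misc_feature",
                qualifiers={"label": [name]},
            )
        )
        pos += len(segment)
    SeqIO.write(record, str(path), "genbank")
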