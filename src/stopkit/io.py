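"""File-format helpers: FASTA/FASTQ via Biopython, tables via pandas."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .stop_design import CandidateStopEdit, CodingSequence


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as an ordered id -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """FASTQ reads as (id, sequence) pairs; qualities are ignored downstream.

    The full header line (mate suffix included) is kept as the id so paired
    mates can be re-associated.
    """
    return [
        (rec.description if " " in rec.description else rec.id,
         str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(
    path: str | Path,
    reads: Iterable[tuple[str, str]],
    quality_char: str = "?",  # constant Phred 30; the pipeline ignores qualities
) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_loci_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns id, cds_start, cds_end joined to a FASTA elsewhere."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "cds_start", "cds_end"}
    if not required.issubset(df.columns):
        raise ValueError(f"loci table needs columns {sorted(required)}")
    return df


def coding_sequences(
    fasta: dict[str, str], loci: pd.DataFrame
) -> list[CodingSequence]:
    out = []
    for row in loci.itertuples():
        if row.id not in fasta:
            raise KeyError(f"locus {row.id} not in FASTA")
        out.append(
            CodingSequence(
                id=row.id,
                seq=fasta[row.id],
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
            )
        )
    return out


def candidates_to_frame(cands: Sequence[CandidateStopEdit]) -> pd.DataFrame:
    rows = []
    for c in cands:
        d = {k: getattr(c, k) for k in CandidateStopEdit.TSV_COLUMNS}
        d["other_window_cytosines"] = ",".join(
            str(p) for p in c.other_window_cytosines
        )
        rows.append(d)
    return pd.DataFrame(rows, columns=list(CandidateStopEdit.TSV_COLUMNS))


def hits_to_frame(hits: Sequence) -> pd.DataFrame:
    """OffTargetHit list as a TSV-ready frame."""
    from .offtarget import OffTargetHit

    rows = []
    for h in hits:
        d = {k: getattr(h, k) for k in OffTargetHit.TSV_COLUMNS}
        d["mismatch_positions"] = ",".join(str(p) for p in h.mismatch_positions)
        rows.append(d)
    return pd.DataFrame(rows, columns=list(OffTargetHit.TSV_COLUMNS))


def hits_to_bed(hits: Sequence, spacer_len: int) -> pd.DataFrame:
    """Hit protospacer+PAM intervals as 0-based half-open BED records."""
    rows = []
    for h in hits:
        if h.strand == "sense":
            start, end = h.pam_start - spacer_len, h.pam_start + 3
        else:
            start, end = h.pam_start, h.pam_start + 3 + spacer_len
        rows.append(
            {
                "chrom": h.subject_id,
                "start": start,
                "end": end,
                "name": f"mm{h.mismatch_count}",
                "score": h.mismatch_count,
                "strand": "+" if h.strand == "sense" else "-",
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def spectrum_to_frame(spec) -> pd.DataFrame:
    """MutationSpectrum table rounded to the 2 decimals used in reports."""
    df = spec.table.copy()
    for col in ("A", "C", "G", "T", "del"):
        df[col] = df[col].round(2)
    return df.reset_index()
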