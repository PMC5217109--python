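"""File formats: clone FASTA, sample sheets, TSV outputs.

The sample sheet (TSV: clone_id, line_id, genotype, nuclease) is the
canonical metadata channel; as a fallback, metadata may be encoded in the
FASTA header as ``cloneID|line|genotype|nuclease``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .caller import CloneRead

SAMPLE_SHEET_COLUMNS = ["clone_id", "line_id", "genotype", "nuclease"]


def write_reads_fasta(reads: Sequence[CloneRead], path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.clone_id,
            description=f"{r.clone_id}|{r.line_id}|{r.genotype}|{r.nuclease}",
        )
        for r in reads
    ]
    SeqIO.write(records, str(path), "fasta")


def write_sample_sheet(reads: Sequence[CloneRead], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"clone_id": r.clone_id, "line_id": r.line_id, "genotype": r.genotype,
             "nuclease": r.nuclease}
            for r in reads
        ]
    ).to_csv(path, sep="\t", index=False)


def read_clones(
    fasta_path: str | Path, sample_sheet: str | Path | None = None
) -> list[CloneRead]:
    """Load clone reads, joining metadata from the sample sheet.

    Without a sheet, headers must follow ``cloneID|line|genotype|nuclease``.
    Every FASTA id must be present in the sheet; missing ids raise with the
    offending list.
    """
    seqs = {rec.id: (str(rec.seq).upper(), rec.description)
            for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise ValueError(f"{fasta_path}: no FASTA records")
    if sample_sheet is not None:
        sheet = pd.read_csv(sample_sheet, sep="\t", dtype=str)
        missing_cols = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
        if missing_cols:
            raise ValueError(f"{sample_sheet}: missing columns {sorted(missing_cols)}")
        meta = {row.clone_id: row for row in sheet.itertuples()}
        missing = sorted(set(seqs) - set(meta))
        if missing:
            raise ValueError(
                f"{fasta_path}: {len(missing)} FASTA ids absent from the sample "
                f"sheet, e.g. {missing[:5]}"
            )
        return [
            CloneRead(cid, meta[cid].line_id, meta[cid].genotype, meta[cid].nuclease, seq)
            for cid, (seq, _desc) in seqs.items()
        ]
    reads = []
    for cid, (seq, desc) in seqs.items():
        parts = desc.split("|")
        if len(parts) != 4:
            raise ValueError(
                f"record {cid}: no sample sheet given and header does not follow "
                "'cloneID|line|genotype|nuclease'"
            )
        reads.append(CloneRead(parts[0].split()[-1] or cid, parts[1], parts[2], parts[3], seq))
    return reads
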