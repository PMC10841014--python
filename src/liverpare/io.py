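"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; GFF3 transcript models are read with
gffutils and written by a small serializer (the models are flat:
one mRNA with five_prime_UTR / CDS / three_prime_UTR children per
transcript, in transcript-local coordinates); tables are pandas TSV.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Sequence, Tuple

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import MiRNARecord, TranscriptModel, canonical_dna

_GFF_TYPES = {
    "utr5": "five_prime_UTR",
    "cds": "CDS",
    "utr3": "three_prime_UTR",
}
_GFF_TYPES_INV = {v: k for k, v in _GFF_TYPES.items()}


def read_fasta(path: str) -> Dict[str, str]:
    """FASTA -> {id: canonical DNA sequence}, order-preserving."""
    return {rec.id: canonical_dna(str(rec.seq)) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, records: Iterable[Tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        path,
        "fasta",
    )


def read_mirnas(path: str) -> List[MiRNARecord]:
    return [MiRNARecord(name, seq) for name, seq in read_fasta(path).items()]


def read_fastq_sequences(path: str) -> List[str]:
    """FASTQ (Phred+33) -> list of read sequences (qualities discarded)."""
    return [str(rec.seq).upper() for rec in SeqIO.parse(path, "fastq")]


def write_fastq(path: str, reads: Sequence[Tuple[str, str]], quality_char: str = "I") -> None:
    """Write (read_id, sequence) pairs with a constant Sanger quality."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_transcript_models(path: str, models: Sequence[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{m.transcript_id}\tliverpare\tmRNA\t1\t{m.length}\t.\t+\t.\t"
                f"ID={m.transcript_id}.mRNA\n"
            )
            for region, ftype in _GFF_TYPES.items():
                iv = m.interval(region)
                if iv is None:
                    continue
                phase = "0" if region == "cds" else "."
                fh.write(
                    f"{m.transcript_id}\tliverpare\t{ftype}\t{iv[0]}\t{iv[1]}\t.\t+\t{phase}\t"
                    f"ID={m.transcript_id}.{region};Parent={m.transcript_id}.mRNA\n"
                )


def read_transcript_models(path: str) -> List[TranscriptModel]:
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    models: Dict[str, TranscriptModel] = {}
    for mrna in db.features_of_type("mRNA"):
        models[mrna.seqid] = TranscriptModel(transcript_id=mrna.seqid, length=mrna.end)
    for ftype, region in _GFF_TYPES_INV.items():
        for feat in db.features_of_type(ftype):
            model = models.get(feat.seqid)
            if model is None:
                model = TranscriptModel(transcript_id=feat.seqid, length=feat.end)
                models[feat.seqid] = model
            setattr(model, region, (feat.start, feat.end))
            model.length = max(model.length, feat.end)
    out = list(models.values())
    for m in out:
        m.validate_tiling()
    return out


def write_collapsed_fasta(path: str, collapsed: Iterable[Tuple[str, int]]) -> None:
    """Collapsed-read FASTA in the `>seq{i}_x{count}` dialect."""
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(collapsed, start=1):
            fh.write(f">seq{i}_x{count}\n{seq}\n")


def read_ct_table(path: str) -> pd.DataFrame:
    """Ct TSV with columns organ, replicate, gene, ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"organ", "replicate", "gene", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def write_tsv(path: str, df: pd.DataFrame, index: bool = False) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
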