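"""Reading and writing the pipeline's file formats.

Sequences travel as FASTA (via Biopython); gene models as GFF3 with
transcript-local coordinates (1-based inclusive); tag libraries as
FASTA with the copy number encoded in the header (``>tag12_x57``, the
common collapsed-read convention); tables as TSV.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import Hairpin, SignalProfile, TranscriptModel


def read_fasta(path: str | Path) -> dict[str, str]:
    """id -> uppercase sequence from a FASTA file."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no sequences found in {path}")
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


_COPY_RE = re.compile(r"_x(\d+)$")


def read_tag_library(path: str | Path) -> dict[str, int]:
    """Tag multiset from FASTA/FASTQ; ``_xN`` header suffixes give copies."""
    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    tags: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), fmt):
        m = _COPY_RE.search(rec.id)
        copies = int(m.group(1)) if m else 1
        seq = str(rec.seq).upper()
        tags[seq] = tags.get(seq, 0) + copies
    if not tags:
        raise ValueError(f"no tags found in {path}")
    return tags


def write_tag_fasta(path: str | Path, tags: Mapping[str, int]) -> None:
    write_fasta(
        path,
        ((f"tag{i}_x{c}", seq) for i, (seq, c) in enumerate(sorted(tags.items()))),
    )


GFF_COLUMNS = ["seqid", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"]


def write_gff3(path: str | Path, transcripts: Sequence[TranscriptModel]) -> None:
    """Transcript-local gene models: gene/mRNA/UTR/CDS rows per transcript."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            n = len(t.sequence)
            rows = [
                ("gene", 1, n, f"ID={t.gene_id}"),
                ("mRNA", 1, n,
                 f"ID={t.transcript_id};Parent={t.gene_id};"
                 f"intron_count={t.intron_count}"),
            ]
            if t.utr5:
                rows.append(("five_prime_UTR", *t.utr5,
                             f"Parent={t.transcript_id}"))
            rows.append(("CDS", *t.cds, f"Parent={t.transcript_id}"))
            if t.utr3:
                rows.append(("three_prime_UTR", *t.utr3,
                             f"Parent={t.transcript_id}"))
            for ftype, start, end, attrs in rows:
                fh.write(
                    f"{t.transcript_id}\tdegradome_kit\t{ftype}\t{start}\t{end}"
                    f"\t.\t+\t.\t{attrs}\n"
                )


def _attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        if part.startswith(f"{key}="):
            return part.split("=", 1)[1]
    return None


def read_gff3(
    path: str | Path, sequences: Mapping[str, str]
) -> list[TranscriptModel]:
    """Rebuild TranscriptModel objects from a GFF3 plus a sequence map."""
    df = pd.read_csv(
        path, sep="\t", comment="#", names=GFF_COLUMNS, dtype={"attributes": str}
    )
    models: list[TranscriptModel] = []
    for tid, grp in df[df["type"] == "mRNA"].groupby(
        df.loc[df["type"] == "mRNA", "attributes"].map(lambda a: _attr(a, "ID"))
    ):
        attrs = grp.iloc[0]["attributes"]
        gene_id = _attr(attrs, "Parent") or tid
        intron_count = int(_attr(attrs, "intron_count") or 0)
        feats = df[
            (df["attributes"].map(lambda a: _attr(a, "Parent")) == tid)
            & df["type"].isin(["five_prime_UTR", "CDS", "three_prime_UTR"])
        ]
        if tid not in sequences:
            raise ValueError(f"no sequence for transcript {tid}")

        def interval(ftype: str):
            sel = feats[feats["type"] == ftype]
            if sel.empty:
                return None
            return (int(sel["start"].min()), int(sel["end"].max()))

        cds = interval("CDS")
        if cds is None:
            raise ValueError(f"transcript {tid} lacks a CDS")
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                sequence=sequences[tid],
                utr5=interval("five_prime_UTR"),
                cds=cds,
                utr3=interval("three_prime_UTR"),
                intron_count=intron_count,
            )
        )
    models.sort(key=lambda t: t.transcript_id)
    return models


def write_hairpin_table(path: str | Path, hairpins: Sequence[Hairpin]) -> None:
    rows = [
        {
            "hairpin_id": h.hairpin_id,
            "mir_start": h.mir_interval[0],
            "mir_end": h.mir_interval[1],
            "star_start": h.star_interval[0],
            "star_end": h.star_interval[1],
            "arm": h.mir_arm,
        }
        for h in hairpins
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_hairpins(
    table_path: str | Path, fasta_path: str | Path
) -> list[Hairpin]:
    seqs = read_fasta(fasta_path)
    df = pd.read_csv(table_path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(
            Hairpin(
                hairpin_id=r["hairpin_id"],
                sequence=seqs[r["hairpin_id"]],
                mir_interval=(int(r["mir_start"]), int(r["mir_end"])),
                star_interval=(int(r["star_start"]), int(r["star_end"])),
                mir_arm=r["arm"],
            )
        )
    return out


def write_profiles(
    path: str | Path, profiles: Mapping[str, SignalProfile]
) -> None:
    """Sparse bedGraph-like TSV: transcript_id, 1-based position, mass."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tpos\tmass\n")
        for tid in sorted(profiles):
            counts = profiles[tid].counts
            for i in counts.nonzero()[0]:
                fh.write(f"{tid}\t{i + 1}\t{counts[i]:.6g}\n")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Gene count table: gene_id index, one column per library."""
    return pd.read_csv(path, sep="\t", index_col="gene_id")
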