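"""Tag-to-transcriptome mapping, 5'-end signal profiles and abundance units.

PARE tags are short (by default 20 nt) 5' signatures of uncapped RNA
fragments.  Mapping is sense-strand, substitution-only, against the
transcriptome.  Tags matching several loci are split equally (1/k of
their copy number per locus), so total profile mass over a library
equals the number of matched tag copies exactly.

Degradation level is reported as RPM (reads per million mapped tags);
transcription level as FPKM (fragments per kilobase of transcript per
million fragments).
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import SignalProfile, TranscriptModel

_ACGT = frozenset("ACGT")


@dataclass
class AbundanceTable:
    """gene_id -> abundance for one library, in a declared unit."""

    values: pd.Series
    unit: str  # "RPM" | "FPKM" | "raw"
    library_id: str = ""

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("abundances must be non-negative")

    def __getitem__(self, gene_id: str) -> float:
        return float(self.values[gene_id])


@dataclass
class MapResult:
    """Tag -> match loci assignments plus mapping bookkeeping."""

    assignments: dict[str, list[tuple[str, int]]]
    tag_counts: dict[str, int]
    n_matched_copies: int
    n_unmatched_copies: int
    n_skipped: int = 0  # tags with non-ACGT characters


def _as_tag_counts(tags: Mapping[str, int] | Iterable[str]) -> dict[str, int]:
    if isinstance(tags, Mapping):
        return {t: int(c) for t, c in tags.items()}
    return dict(Counter(tags))


class TranscriptomeIndex:
    """Seed index over transcript sequences for substitution-only matching.

    Tags are located by pigeonhole seeding: a tag with at most m
    substitutions against some locus must match one of m+1 disjoint
    seed pieces exactly.  Candidates from the seed lookup are verified
    by direct comparison.
    """

    def __init__(self, transcripts: Sequence[TranscriptModel], seed_len: int = 10):
        self.transcripts = {t.transcript_id: t for t in transcripts}
        self.seed_len = seed_len
        self._seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for t in transcripts:
            seq = t.sequence
            for i in range(len(seq) - seed_len + 1):
                self._seeds[seq[i : i + seed_len]].append((t.transcript_id, i))

    def match(self, tag: str, max_mismatch: int) -> list[tuple[str, int]]:
        """All (transcript_id, 1-based position) loci with <= max_mismatch subs."""
        L = len(tag)
        n_pieces = max_mismatch + 1
        piece = L // n_pieces
        if piece < self.seed_len:
            return self._match_brute(tag, max_mismatch)
        hits: set[tuple[str, int]] = set()
        seen: set[tuple[str, int]] = set()
        for k in range(n_pieces):
            off = k * piece
            for tid, i in self._seeds.get(tag[off : off + self.seed_len], ()):
                start = i - off
                if start < 0:
                    continue
                key = (tid, start)
                if key in seen:
                    continue
                seen.add(key)
                seq = self.transcripts[tid].sequence
                if start + L > len(seq):
                    continue
                mm = sum(a != b for a, b in zip(tag, seq[start : start + L]))
                if mm <= max_mismatch:
                    hits.add((tid, start + 1))
        return sorted(hits)

    def _match_brute(self, tag: str, max_mismatch: int) -> list[tuple[str, int]]:
        hits = []
        L = len(tag)
        for tid, t in self.transcripts.items():
            seq = t.sequence
            for start in range(len(seq) - L + 1):
                mm = sum(a != b for a, b in zip(tag, seq[start : start + L]))
                if mm <= max_mismatch:
                    hits.append((tid, start + 1))
        return sorted(hits)


def map_tags(
    tags: Mapping[str, int] | Iterable[str],
    transcripts: Sequence[TranscriptModel] | TranscriptomeIndex,
    max_mismatch: int = 1,
) -> MapResult:
    """Map a tag multiset to transcripts, allowing substitutions only.

    A tag matches at a position when its full length aligns on the
    sense strand with at most ``max_mismatch`` substitutions.  All
    match loci are reported.  Tags containing non-ACGT characters are
    skipped and counted.
    """
    counts = _as_tag_counts(tags)
    index = (
        transcripts
        if isinstance(transcripts, TranscriptomeIndex)
        else TranscriptomeIndex(transcripts)
    )
    assignments: dict[str, list[tuple[str, int]]] = {}
    matched = unmatched = skipped = 0
    for tag, c in counts.items():
        if not set(tag) <= _ACGT:
            skipped += 1
            continue
        loci = index.match(tag, max_mismatch)
        if loci:
            assignments[tag] = loci
            matched += c
        else:
            unmatched += c
    return MapResult(assignments, counts, matched, unmatched, skipped)


def map_tags_bruteforce(
    tags: Mapping[str, int] | Iterable[str],
    transcripts: Sequence[TranscriptModel],
    max_mismatch: int = 1,
) -> dict[str, list[tuple[str, int]]]:
    """Exhaustive all-positions scan; reference oracle for map_tags."""
    counts = _as_tag_counts(tags)
    out: dict[str, list[tuple[str, int]]] = {}
    for tag in counts:
        if not set(tag) <= _ACGT:
            continue
        loci = []
        for t in transcripts:
            seq = t.sequence
            for start in range(len(seq) - len(tag) + 1):
                mm = sum(a != b for a, b in zip(tag, seq[start : start + len(tag)]))
                if mm <= max_mismatch:
                    loci.append((t.transcript_id, start + 1))
        if loci:
            out[tag] = sorted(loci)
    return out


def build_profiles(
    result: MapResult,
    transcripts: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
    library_id: str = "",
) -> dict[str, SignalProfile]:
    """Accumulate per-position 5'-end mass, splitting multi-mappers 1/k.

    Each tag contributes total mass equal to its copy number, divided
    equally among its k match loci; the profile position is the 1-based
    coordinate of the tag's 5' end.
    """
    tmap = (
        transcripts
        if isinstance(transcripts, Mapping)
        else {t.transcript_id: t for t in transcripts}
    )
    arrays = {tid: np.zeros(len(t.sequence)) for tid, t in tmap.items()}
    for tag, loci in result.assignments.items():
        mass = result.tag_counts[tag] / len(loci)
        for tid, pos in loci:
            arrays[tid][pos - 1] += mass
    return {
        tid: SignalProfile(tid, arr, library_id=library_id)
        for tid, arr in arrays.items()
    }


def gene_rpm(
    profiles: Mapping[str, SignalProfile],
    total_mapped: float,
    transcripts: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
    library_id: str = "",
) -> AbundanceTable:
    """Per-gene RPM: summed profile mass x 1e6 / total mapped tag copies."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    tmap = (
        transcripts
        if isinstance(transcripts, Mapping)
        else {t.transcript_id: t for t in transcripts}
    )
    gene_mass: dict[str, float] = defaultdict(float)
    for tid, prof in profiles.items():
        gene_mass[tmap[tid].gene_id] += prof.total_mass
    for t in tmap.values():  # genes with zero signal still get a row
        gene_mass.setdefault(t.gene_id, 0.0)
    values = pd.Series(gene_mass).sort_index() * 1e6 / total_mapped
    return AbundanceTable(values, unit="RPM", library_id=library_id)


def gene_fpkm(
    counts: AbundanceTable,
    transcripts: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
    library_id: str = "",
) -> AbundanceTable:
    """FPKM = count / ((length/1e3) x (library total/1e6))."""
    if counts.unit != "raw":
        raise ValueError("gene_fpkm expects raw counts")
    total = float(counts.values.sum())
    if total <= 0:
        raise ValueError("library total must be positive")
    tmap = (
        transcripts
        if isinstance(transcripts, Mapping)
        else {t.transcript_id: t for t in transcripts}
    )
    lengths = {}
    for t in tmap.values():
        if len(t.sequence) == 0:
            raise ValueError(f"zero-length transcript {t.transcript_id}")
        lengths[t.gene_id] = len(t.sequence)
    lens = pd.Series(lengths).reindex(counts.values.index)
    fpkm = counts.values / ((lens / 1e3) * (total / 1e6))
    return AbundanceTable(fpkm, unit="FPKM", library_id=library_id or counts.library_id)


def merge_replicates(
    tables: Sequence[AbundanceTable],
) -> tuple[AbundanceTable, float]:
    """Average replicate abundances; QC by squared Pearson r of log2(v+1).

    With two replicates, r^2 is their squared Pearson correlation on the
    log2(value + 1) scale; with more, the mean of all pairwise r^2.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 replicates")
    genes = tables[0].values.index
    for t in tables[1:]:
        if not t.values.index.equals(genes):
            raise ValueError("replicates must cover identical gene sets")
        if t.unit != tables[0].unit:
            raise ValueError("replicates must share a unit")
    mat = np.column_stack([t.values.to_numpy() for t in tables])
    mean = AbundanceTable(
        pd.Series(mat.mean(axis=1), index=genes), unit=tables[0].unit
    )
    logs = np.log2(mat + 1.0)
    r2s = []
    for i, j in itertools.combinations(range(mat.shape[1]), 2):
        r = np.corrcoef(logs[:, i], logs[:, j])[0, 1]
        r2s.append(r * r)
    return mean, float(np.mean(r2s))
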