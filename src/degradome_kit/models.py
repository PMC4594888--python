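"""Shared domain types for degradome analysis.

The unit of all per-gene quantities is the transcript model; the core
degradome observable is the per-position 5'-end signal profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (returned as DNA)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C fraction of a sequence; 0.0 for the empty string."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass
class TranscriptModel:
    """One mRNA: sequence plus 1-based inclusive region coordinates.

    ``utr5``/``utr3`` may be ``None`` when the transcript lacks that
    region; ``cds`` is always present.  ``intron_count`` is carried from
    the annotation (the mature transcript sequence is intron-free).
    """

    transcript_id: str
    gene_id: str
    sequence: str
    utr5: tuple[int, int] | None
    cds: tuple[int, int]
    utr3: tuple[int, int] | None
    intron_count: int = 0

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for iv in (self.utr5, self.cds, self.utr3):
            if iv is not None and not (1 <= iv[0] <= iv[1] <= n):
                raise ValueError(
                    f"{self.transcript_id}: interval {iv} outside [1, {n}]"
                )
        if self.utr5 is not None and self.utr5[1] >= self.cds[0]:
            raise ValueError(f"{self.transcript_id}: 5'UTR must precede CDS")
        if self.utr3 is not None and self.utr3[0] <= self.cds[1]:
            raise ValueError(f"{self.transcript_id}: 3'UTR must follow CDS")

    def __len__(self) -> int:
        return len(self.sequence)

    def region_seq(self, region: str) -> str | None:
        iv = {"mrna": (1, len(self.sequence)), "utr5": self.utr5,
              "cds": self.cds, "utr3": self.utr3}[region]
        if iv is None:
            return None
        return self.sequence[iv[0] - 1 : iv[1]]


@dataclass
class SignalProfile:
    """Per-transcript vector of PARE-tag 5'-end mass by position.

    ``counts[i]`` is the (possibly fractional, after multi-mapper
    splitting) tag mass whose 5' end maps at 1-based position ``i + 1``.
    """

    transcript_id: str
    counts: np.ndarray
    library_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError("profile mass must be non-negative")

    @property
    def total_mass(self) -> float:
        return float(self.counts.sum())

    def mass_at(self, pos: int, window: int = 0) -> float:
        """Mass within ``pos +/- window`` (1-based), clipped to bounds."""
        lo = max(pos - window - 1, 0)
        hi = min(pos + window, len(self.counts))
        if lo >= len(self.counts) or hi <= 0:
            raise IndexError(f"position {pos} outside profile")
        return float(self.counts[lo:hi].sum())


@dataclass
class Hairpin:
    """A pre-miRNA stem-loop with annotated duplex coordinates.

    Intervals are 1-based inclusive, ordered 5'->3'; the loop lies
    strictly between the two duplex strands.  ``mir_arm`` records which
    arm carries the mature miRNA.
    """

    hairpin_id: str
    sequence: str
    mir_interval: tuple[int, int]
    star_interval: tuple[int, int]
    mir_arm: str  # "five_prime" | "three_prime"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for iv in (self.mir_interval, self.star_interval):
            if not (1 <= iv[0] <= iv[1] <= n):
                raise ValueError(f"{self.hairpin_id}: interval {iv} outside [1, {n}]")
        a, b = sorted((self.mir_interval, self.star_interval))
        if a[1] >= b[0]:
            raise ValueError(f"{self.hairpin_id}: duplex intervals overlap")
        if self.mir_arm not in ("five_prime", "three_prime"):
            raise ValueError(f"bad arm {self.mir_arm!r}")

    @property
    def arm5_interval(self) -> tuple[int, int]:
        return min(self.mir_interval, self.star_interval)

    @property
    def arm3_interval(self) -> tuple[int, int]:
        return max(self.mir_interval, self.star_interval)

    @property
    def loop_interval(self) -> tuple[int, int]:
        return (self.arm5_interval[1] + 1, self.arm3_interval[0] - 1)


@dataclass
class TargetAlignment:
    """A gapless miRNA-target duplex with its complementarity score."""

    mirna_id: str
    transcript_id: str
    target_start: int  # 1-based inclusive
    target_end: int
    score: float
    mismatch_count: int
    gu_count: int
    pairing: str = ""  # |, o (G:U), . per miRNA position 5'->3'


@dataclass
class TargetHit:
    """A degradome-validated cleavage record."""

    alignment: TargetAlignment
    slice_pos: int
    peak_reads: float
    category: int
    library_id: str = ""


@dataclass
class ProcessingCall:
    """Per-hairpin processing-mode verdict with signal evidence."""

    hairpin_id: str
    mode: str  # loop_last | loop_first | ambiguous | dispersed | no_signal
    distal_mass: float = 0.0
    proximal_mass: float = 0.0
    arm5_fraction: float = float("nan")
    mid_duplex_flag: bool = False
    total_mass: float = 0.0
    arm_verdict: str = "no_signal"
    mid_duplex_positions: list[int] = field(default_factory=list)
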