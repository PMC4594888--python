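"""Per-transcript structural features and group comparisons.

Features: region lengths, GC content, intron count and the minimal
folding free energy index

    MFEI = MFE / length * 100 / GC%

i.e. folding energy per nucleotide per GC percentage point — a length-
and composition-normalised stability measure (kcal/mol based; more
negative = more stably folded relative to composition).

Folding is delegated to an injectable backend.  When the ViennaRNA
thermodynamic engine is importable it is used; the built-in fallback is
a deliberately simple base-pair maximisation score (-1 kcal/mol per
canonical pair, hairpin loops of at least 3 nt) and is clearly labelled
approximate — its absolute values are not thermodynamic energies, but
it is exactly reproducible and has an exhaustive-enumeration oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import TranscriptModel, gc_fraction

CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)
MIN_HAIRPIN_LOOP = 3


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def mfei(mfe: float, length: int, gc: float) -> float:
    """Minimal folding free energy index: MFE / length x 100 / GC%."""
    if length <= 0:
        raise ValueError("length must be positive")
    if gc <= 0:
        raise ValueError("MFEI undefined for GC fraction 0")
    return mfe / length * 100.0 / (gc * 100.0)


def fold_mfe_fallback(sequence: str) -> float:
    """Approximate MFE by base-pair maximisation (Nussinov recurrence).

    Scores -1 per canonical pair (Watson-Crick or G:U wobble) in the
    best nested, pseudoknot-free pairing with hairpin loops >= 3 nt.
    Not a thermodynamic energy; exactly reproducible and checkable by
    exhaustive enumeration on short sequences.
    """
    s = _to_rna(sequence)
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    if n <= MIN_HAIRPIN_LOOP + 1:
        return 0.0
    enc = np.frombuffer(s.encode(), dtype=np.uint8)
    pair_ok = np.zeros((n, n), dtype=bool)
    for a, b in CANONICAL_PAIRS:
        pair_ok |= (enc[:, None] == ord(a)) & (enc[None, :] == ord(b))
    best = np.zeros((n, n), dtype=np.int32)
    # fill by increasing span; inner maximisation vectorised over i
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        i = np.arange(n - span)
        j = i + span
        b = best[i, j - 1]  # j unpaired
        for d in range(span - MIN_HAIRPIN_LOOP):  # k = i + d pairs with j
            k = i + d
            left = best[i, k - 1] if d > 0 else 0
            cand = left + 1 + best[k + 1, j - 1]
            b = np.where(pair_ok[k, j], np.maximum(b, cand), b)
        best[i, j] = b
    return -float(best[0, n - 1])


def enumerate_max_pairs(sequence: str) -> int:
    """Maximum canonical pair count by exhaustive backtracking over all
    sets of disjoint, non-crossing candidate pairs; oracle for the
    fallback on short sequences (exponential — keep inputs <= ~14 nt).
    """
    s = _to_rna(sequence)
    cand = [
        (i, j)
        for i in range(len(s))
        for j in range(i + MIN_HAIRPIN_LOOP + 1, len(s))
        if (s[i], s[j]) in CANONICAL_PAIRS
    ]

    def compatible(a: tuple[int, int], b: tuple[int, int]) -> bool:
        (i, j), (k, l) = a, b
        if len({i, j, k, l}) < 4:
            return False  # shared nucleotide
        crossing = (i < k < j < l) or (k < i < l < j)
        return not crossing

    best = 0

    def extend(start: int, chosen: list[tuple[int, int]]) -> None:
        nonlocal best
        best = max(best, len(chosen))
        if len(chosen) + (len(cand) - start) <= best:
            return
        for idx in range(start, len(cand)):
            p = cand[idx]
            if all(compatible(p, q) for q in chosen):
                chosen.append(p)
                extend(idx + 1, chosen)
                chosen.pop()

    extend(0, [])
    return best


def _vienna_fold(sequence: str) -> float:
    import RNA  # ViennaRNA python bindings

    return float(RNA.fold(_to_rna(sequence))[1])


def get_fold_engine(name: str = "auto") -> tuple[Callable[[str], float], str]:
    """Resolve a folding backend: 'vienna', 'fallback' or 'auto'.

    Returns (callable, backend label); the label is recorded in output
    so downstream consumers know which engine produced the MFEs.
    """
    if name in ("vienna", "auto"):
        try:
            import RNA  # noqa: F401

            return _vienna_fold, "vienna"
        except ImportError:
            if name == "vienna":
                raise RuntimeError("ViennaRNA backend requested but not importable")
    if name in ("fallback", "auto"):
        return fold_mfe_fallback, "fallback"
    raise ValueError(f"unknown fold engine {name!r}")


def fold_mfe(sequence: str, engine: Callable[[str], float] | None = None) -> float:
    """MFE (kcal/mol) of a sequence via the given or default backend."""
    seq = _to_rna(sequence)
    if not seq or set(seq) - set("ACGU"):
        raise ValueError("sequence must be non-empty ACGU/ACGT")
    if engine is None:
        engine = fold_mfe_fallback
    return engine(seq)


@dataclass
class FeatureRecord:
    """Structural features of one transcript; missing regions are None."""

    transcript_id: str
    mrna_len: int
    utr5_len: int | None
    utr3_len: int | None
    gc_mrna: float
    gc_utr5: float | None
    gc_utr3: float | None
    intron_count: int
    mfei_mrna: float
    mfei_utr5: float | None
    mfei_utr3: float | None
    fold_backend: str = "fallback"


def compute_features(
    transcript: TranscriptModel,
    fold_engine: Callable[[str], float] | None = None,
    backend_label: str = "fallback",
    max_fold_len: int | None = None,
) -> FeatureRecord:
    """Lengths, GC and MFEI for the full mRNA and each UTR.

    Empty UTRs yield None (missing), never zero; region MFEIs are
    computed on the region's own sequence and composition.  Regions
    longer than ``max_fold_len`` skip folding (MFEI None) — the
    fallback engine is cubic in length and meant for short regions.
    """

    def region(seq: str | None):
        if seq is None or len(seq) == 0:
            return None, None, None
        gc = gc_fraction(seq)
        mf = None
        if gc > 0 and (max_fold_len is None or len(seq) <= max_fold_len):
            mf = mfei(fold_mfe(seq, fold_engine), len(seq), gc)
        return len(seq), gc, mf

    mlen, mgc, mmfei = region(transcript.sequence)
    u5len, u5gc, u5mfei = region(transcript.region_seq("utr5"))
    u3len, u3gc, u3mfei = region(transcript.region_seq("utr3"))
    return FeatureRecord(
        transcript_id=transcript.transcript_id,
        mrna_len=mlen,
        utr5_len=u5len,
        utr3_len=u3len,
        gc_mrna=mgc,
        gc_utr5=u5gc,
        gc_utr3=u3gc,
        intron_count=transcript.intron_count,
        mfei_mrna=mmfei,
        mfei_utr5=u5mfei,
        mfei_utr3=u3mfei,
        fold_backend=backend_label,
    )


def feature_table(
    transcripts: Sequence[TranscriptModel],
    fold_engine_name: str = "auto",
    max_fold_len: int | None = None,
) -> pd.DataFrame:
    """FeatureRecord rows for a transcript set, indexed by transcript_id.

    With the fallback engine, folding defaults to regions of at most
    500 nt; the thermodynamic backend has no default limit.
    """
    engine, label = get_fold_engine(fold_engine_name)
    if max_fold_len is None and label == "fallback":
        max_fold_len = 500
    recs = [compute_features(t, engine, label, max_fold_len) for t in transcripts]
    return pd.DataFrame([r.__dict__ for r in recs]).set_index(
        "transcript_id", drop=False
    )


def random_control_set(
    all_ids: Sequence[str], size: int, seed: int
) -> list[str]:
    """Size-matched random gene set, sampled without replacement, seeded."""
    rng = np.random.default_rng(seed)
    if size > len(all_ids):
        raise ValueError("control size exceeds population")
    return sorted(rng.choice(np.asarray(all_ids, dtype=object), size=size,
                             replace=False).tolist())


def compare_feature(
    features: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    feature: str,
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests of one feature across groups.

    Missing feature values (absent UTRs) are dropped per group; groups
    with fewer than 3 usable values are reported with p omitted (NaN)
    rather than tested.
    """
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("groups must be non-empty")
    vals = {
        name: features.loc[
            features.index.intersection(ids), feature
        ].dropna().astype(float)
        for name, ids in groups.items()
    }
    rows = []
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va, vb = vals[a], vals[b]
            if len(va) < 3 or len(vb) < 3:
                p = np.nan
            else:
                p = float(
                    stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue
                )
            rows.append(
                (feature, a, b, len(va), len(vb),
                 float(va.mean()) if len(va) else np.nan,
                 float(vb.mean()) if len(vb) else np.nan, p)
            )
    return pd.DataFrame(
        rows,
        columns=["feature", "group_a", "group_b", "n_a", "n_b",
                 "mean_a", "mean_b", "p_value"],
    )
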