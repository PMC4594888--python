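"""Joint degradation/transcription classification of genes.

Genes called in both layers are placed on a 3x3 grid of
(D status, R status) cells lettered A..I, and the letters collapse to
four decay-pattern types:

    type I   — concordant change (D and R move together): classes C, G
    type II  — degradation-only change:                    classes B, H
    type III — discordant change (D and R oppose):         classes A, I
    type IV  — transcription-only change:                  classes D, F
    none     — unchanged in both layers:                   class E

The letter layout is row-major with rows D up/unchanged/down and
columns R down/unchanged/up; the centre cell E is the doubly-unchanged
class.  Genes ambiguous in either layer are not classified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import AbundanceTable

# (d_status, r_status) -> (class letter, decay type); rows = D up/unch/down,
# columns = R down/unch/up, letters row-major A..I.
CLASS_GRID: dict[tuple[str, str], tuple[str, str]] = {
    ("up", "down"): ("A", "III"),
    ("up", "unchanged"): ("B", "II"),
    ("up", "up"): ("C", "I"),
    ("unchanged", "down"): ("D", "IV"),
    ("unchanged", "unchanged"): ("E", "none"),
    ("unchanged", "up"): ("F", "IV"),
    ("down", "down"): ("G", "I"),
    ("down", "unchanged"): ("H", "II"),
    ("down", "up"): ("I", "III"),
}


@dataclass
class DecayAssignment:
    gene_id: str
    d_status: str
    r_status: str
    class_letter: str | None  # None when either status is ambiguous
    decay_type: str | None


def assign_class(d_status: str, r_status: str) -> tuple[str, str]:
    """Map a (D, R) status pair to its class letter and decay type."""
    try:
        return CLASS_GRID[(d_status, r_status)]
    except KeyError:
        raise ValueError(
            f"unclassifiable status pair ({d_status!r}, {r_status!r}); "
            "ambiguous genes are excluded from the grid"
        ) from None


def classify_genes(d_calls: pd.DataFrame, r_calls: pd.DataFrame) -> pd.DataFrame:
    """Join per-layer call tables and assign classes over the shared genes.

    Only genes present in both layers are classified; a gene ambiguous
    in either layer gets class/type NA and is reported separately.
    """
    shared = d_calls.index.intersection(r_calls.index)
    rows = []
    for g in shared:
        d_s = d_calls.loc[g, "status"]
        r_s = r_calls.loc[g, "status"]
        if d_s == "ambiguous" or r_s == "ambiguous":
            letter = dtype = None
        else:
            letter, dtype = assign_class(d_s, r_s)
        rows.append((g, d_s, r_s, letter, dtype))
    return pd.DataFrame(
        rows, columns=["gene_id", "d_status", "r_status", "class", "type"]
    ).set_index("gene_id", drop=False)


def summarize_types(assignments: pd.DataFrame) -> pd.DataFrame:
    """Count classified genes per (decay type, change direction).

    Mirrors the four-pattern summary: each type is split by direction,
    e.g. type I into D-up/R-up versus D-down/R-down.
    """
    dir_label = {
        "A": "D↑R↓", "B": "D↑R-", "C": "D↑R↑",
        "D": "D-R↓", "E": "D-R-", "F": "D-R↑",
        "G": "D↓R↓", "H": "D↓R-", "I": "D↓R↑",
    }
    classified = assignments.dropna(subset=["class"])
    rows = []
    for letter in "ABCDEFGHI":
        n = int((classified["class"] == letter).sum())
        dtype = next(v[1] for k, v in CLASS_GRID.items() if v[0] == letter)
        rows.append((dtype, dir_label[letter], letter, n))
    out = pd.DataFrame(rows, columns=["type", "change", "class", "n_genes"])
    return out.sort_values(["type", "class"]).reset_index(drop=True)


def uncapped_total_ratio(
    rpm: AbundanceTable,
    fpkm: AbundanceTable,
    gene_sets: Mapping[str, Sequence[str]],
) -> tuple[pd.Series, pd.DataFrame, int]:
    """Per-gene uncapped/total abundance ratio (RPM / FPKM) with group tests.

    Genes with FPKM = 0 are excluded and counted.  When two or more
    gene sets are given, every pair is compared by a two-sided
    Mann-Whitney U test on their ratio distributions.

    Returns (ratios over all requested genes, pairwise test table,
    number of excluded genes).
    """
    if not gene_sets or any(len(v) == 0 for v in gene_sets.values()):
        raise ValueError("gene sets must be non-empty")
    all_genes = sorted({g for gs in gene_sets.values() for g in gs})
    f = fpkm.values.reindex(all_genes)
    r = rpm.values.reindex(all_genes)
    if f.isna().any() or r.isna().any():
        raise ValueError("both tables must cover every requested gene")
    keep = f > 0
    n_excluded = int((~keep).sum())
    ratios = (r[keep] / f[keep]).rename("rpm_fpkm_ratio")
    rows = []
    names = list(gene_sets)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ra = ratios.reindex([g for g in gene_sets[a] if g in ratios.index]).dropna()
            rb = ratios.reindex([g for g in gene_sets[b] if g in ratios.index]).dropna()
            if len(ra) == 0 or len(rb) == 0:
                continue
            p = stats.mannwhitneyu(ra, rb, alternative="two-sided").pvalue
            rows.append((a, b, float(ra.mean()), float(rb.mean()), float(p)))
    tests = pd.DataFrame(
        rows, columns=["set_a", "set_b", "mean_a", "mean_b", "p_value"]
    )
    return ratios, tests, n_excluded
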