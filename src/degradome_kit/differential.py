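"""Two-library differential abundance testing and status calls.

Both data layers — degradation (D, PARE tag counts) and transcription
(R, RNA-seq counts) — are compared between two libraries under a
random-sampling null: each gene's count is a draw from the library
total with a gene-specific proportion, and the test asks whether that
proportion differs between libraries.  This is the pooled two-proportion
z-test; its accept/reject decisions agree with the exact conditional
binomial test away from very small counts.

Status calls use the thresholds |log2FC| >= 1 and adjusted p < 0.001.
Genes falling in threshold cells covered by neither the up/down nor the
unchanged rule (e.g. large fold change with weak evidence) are called
``ambiguous`` and excluded from downstream class assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

STATUSES = ("up", "down", "unchanged", "ambiguous")


@dataclass
class DiffCall:
    gene_id: str
    layer: str  # "D" | "R"
    log2fc: float
    p_raw: float
    p_adj: float
    status: str

    def __post_init__(self) -> None:
        if not (0 <= self.p_raw <= 1 and 0 <= self.p_adj <= 1):
            raise ValueError("p-values must lie in [0, 1]")
        if self.status not in STATUSES:
            raise ValueError(f"bad status {self.status!r}")


def two_library_test(c1, n1, c2, n2):
    """Two-sided p-value for equal sampling proportions in two libraries.

    Pooled two-proportion z-test: with p_hat = (c1+c2)/(n1+n2),

        z = (c1/n1 - c2/n2) / sqrt(p_hat (1 - p_hat) (1/n1 + 1/n2))

    and p = 2 Phi(-|z|).  Genes with c1 = c2 = 0 carry no evidence and
    get p = 1.  Accepts scalars or arrays.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if (n1 <= 0).any() or (n2 <= 0).any():
        raise ValueError("library totals must be positive")
    if (c1 < 0).any() or (c2 < 0).any() or (c1 > n1).any() or (c2 > n2).any():
        raise ValueError("counts must satisfy 0 <= c <= n")
    phat = (c1 + c2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(phat * (1.0 - phat) * (1.0 / n1 + 1.0 / n2))
        z = (c1 / n1 - c2 / n2) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    # no counts (se = 0, z = nan) -> no evidence against the null
    p = np.where(np.isnan(p), 1.0, p)
    if p.ndim == 0:
        return float(p)
    return p


def exact_binomial_test(c1, c2, n1, n2):
    """Exact conditional binomial oracle for the two-library comparison.

    Conditional on the pooled count t = c1 + c2, c1 ~ Bin(t, n1/(n1+n2))
    under the null; the two-sided p sums all outcomes no more probable
    than the observed one.  Vectorised only over genes with equal library
    sizes; the general scalar case delegates to scipy.stats.binomtest.
    """
    c1a = np.atleast_1d(np.asarray(c1, dtype=int))
    c2a = np.atleast_1d(np.asarray(c2, dtype=int))
    n1a = np.broadcast_to(np.atleast_1d(np.asarray(n1, dtype=float)), c1a.shape)
    n2a = np.broadcast_to(np.atleast_1d(np.asarray(n2, dtype=float)), c1a.shape)
    t = c1a + c2a
    p0 = n1a / (n1a + n2a)
    out = np.ones(c1a.shape, dtype=float)
    sym = np.isclose(p0, 0.5)
    nz = t > 0
    # symmetric case: p = P(X <= min(c1, c2)) + P(X >= max(c1, c2))
    m = sym & nz
    if m.any():
        lo = np.minimum(c1a[m], c2a[m])
        hi = np.maximum(c1a[m], c2a[m])
        p = stats.binom.cdf(lo, t[m], 0.5) + stats.binom.sf(hi - 1, t[m], 0.5)
        tie = lo == hi  # central point counted twice
        p = np.where(tie, p - stats.binom.pmf(lo, t[m], 0.5), p)
        out[m] = np.minimum(p, 1.0)
    for i in np.nonzero(~sym & nz)[0]:
        out[i] = stats.binomtest(int(c1a[i]), int(t[i]), p0[i]).pvalue
    if np.isscalar(c1) or np.asarray(c1).ndim == 0:
        return float(out[0])
    return out


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def log2_fold_change(v_treated, v_control, eps: float = 0.5):
    """log2((treated + eps) / (control + eps)).

    ``eps`` is a pseudo-abundance in the same unit as the inputs,
    keeping fold changes of zero-count genes finite.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    v_t = np.asarray(v_treated, dtype=float)
    v_c = np.asarray(v_control, dtype=float)
    if (v_t < 0).any() or (v_c < 0).any():
        raise ValueError("abundances must be non-negative")
    out = np.log2((v_t + eps) / (v_c + eps))
    if out.ndim == 0:
        return float(out)
    return out


def call_status(
    log2fc: float, p_adj: float, fc_thresh: float = 1.0, p_up: float = 0.001
) -> str:
    """Status from the fold-change/significance threshold grid.

    up:        log2fc >= fc_thresh  and p_adj < p_up
    down:      log2fc <= -fc_thresh and p_adj < p_up
    unchanged: |log2fc| < fc_thresh and p_adj > p_up
    ambiguous: every remaining cell (significant but small change,
               large change without significance, or p_adj == p_up)
    """
    if log2fc >= fc_thresh and p_adj < p_up:
        return "up"
    if log2fc <= -fc_thresh and p_adj < p_up:
        return "down"
    if abs(log2fc) < fc_thresh and p_adj > p_up:
        return "unchanged"
    return "ambiguous"


def diff_table(
    counts_control,
    counts_treated,
    layer: str,
    gene_ids: Sequence[str] | None = None,
    fc_thresh: float = 1.0,
    p_thresh: float = 0.001,
    eps: float = 0.5,
) -> pd.DataFrame:
    """Full differential call table for one data layer.

    Counts are summed per condition (replicates pooled before testing);
    fold changes are computed on counts normalised to the mean library
    size, with pseudo-abundance ``eps``.
    """
    c_c = np.asarray(counts_control, dtype=float)
    c_t = np.asarray(counts_treated, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(c_c.size)]
    n_c, n_t = c_c.sum(), c_t.sum()
    p_raw = two_library_test(c_t, n_t, c_c, n_c)
    p_adj = bh_adjust(p_raw)
    scale = (n_c + n_t) / 2.0
    fc = log2_fold_change(c_t * scale / n_t, c_c * scale / n_c, eps=eps)
    status = [
        call_status(f, p, fc_thresh=fc_thresh, p_up=p_thresh)
        for f, p in zip(fc, p_adj)
    ]
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "layer": layer,
            "c_control": c_c,
            "c_treated": c_t,
            "log2fc": fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "status": status,
        }
    ).set_index("gene_id", drop=False)
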