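"""Co-occurrence statistics: Fisher's exact test and two-stage FDR control.

Two domain variants residing on the same ~38 kb cloned insert are co-captured
into the same subpools far more often than independent loci, so physical
linkage shows up as an excess of jointly-occupied subpools.  For every
candidate pair (sharing at least ``min_shared`` subpools) we build the 2x2
contingency table over all library subpools and compute the one-sided
(enrichment) Fisher exact p-value — the hypergeometric right tail — in
log-space via log-gamma so that populations of thousands of subpools and
p-values far below 1e-300 in magnitude remain exact.  P-values are adjusted
with the two-stage Benjamini-Krieger-Yekutieli step-up, and pairs with
adjusted p below ``alpha`` (default 1e-6) are declared physically linked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy import sparse

from .variant_table import OccurrenceMatrix

__all__ = [
    "ContingencyTable",
    "LinkTest",
    "LinkSet",
    "contingency",
    "fisher_right_tail",
    "fisher_right_tail_many",
    "candidate_pairs",
    "adjust_fdr_tsbky",
    "tsbky_reject",
    "detect_links",
]

DEFAULT_ALPHA = 1e-6
DEFAULT_MIN_SHARED = 3


class ContingencyTable(NamedTuple):
    """Subpool counts for a variant pair: both, A only, B only, neither."""

    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def validate(self) -> "ContingencyTable":
        if min(self) < 0:
            raise ValueError("contingency counts must be non-negative")
        return self


@dataclass(frozen=True)
class LinkTest:
    """One tested variant pair with raw and adjusted p-values."""

    variant_a: str
    variant_b: str
    table: ContingencyTable
    p_raw: float
    p_adj: float
    significant: bool


@dataclass
class LinkSet:
    """All tested pairs of one run plus the thresholds that defined the run."""

    alpha: float
    min_shared: int
    tests: list[LinkTest] = field(default_factory=list)

    def significant_links(self) -> list[LinkTest]:
        return [t for t in self.tests if t.significant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            [
                {
                    "variant_a": t.variant_a,
                    "variant_b": t.variant_b,
                    "n11": t.table.n11,
                    "n10": t.table.n10,
                    "n01": t.table.n01,
                    "n00": t.table.n00,
                    "p_raw": t.p_raw,
                    "p_adj": t.p_adj,
                    "significant": t.significant,
                }
                for t in self.tests
            ],
            columns=[
                "variant_a",
                "variant_b",
                "n11",
                "n10",
                "n01",
                "n00",
                "p_raw",
                "p_adj",
                "significant",
            ],
        )

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def contingency(matrix: OccurrenceMatrix, a, b) -> ContingencyTable:
    """2x2 subpool contingency table for variants ``a`` and ``b``.

    The population is every subpool in the library, so subpools where neither
    variant was detected contribute to ``n00``.
    """
    if a == b:
        raise ValueError("contingency requires two distinct variants")
    try:
        pa = matrix.presence.loc[a].to_numpy()
        pb = matrix.presence.loc[b].to_numpy()
    except KeyError as exc:
        raise KeyError(f"unknown variant: {exc.args[0]!r}") from exc
    n11 = int(np.sum(pa & pb))
    n10 = int(np.sum(pa & ~pb))
    n01 = int(np.sum(~pa & pb))
    n00 = matrix.n_subpools - n11 - n10 - n01
    return ContingencyTable(n11, n10, n01, n00).validate()


def fisher_right_tail_many(
    n11: np.ndarray, k_a: np.ndarray, k_b: np.ndarray, n_total: int
) -> np.ndarray:
    """Vectorized one-sided (enrichment) Fisher p-values.

    For each pair: p = P(X >= n11) with X ~ Hypergeom(N=n_total, K=k_a,
    n=k_b).  Terms are accumulated in log-space (log-gamma binomial
    coefficients) and summed relative to the largest term, which keeps the
    relative error near machine precision even for tails below 1e-300.
    """
    n11 = np.asarray(n11, dtype=np.int64)
    k_a = np.asarray(k_a, dtype=np.int64)
    k_b = np.asarray(k_b, dtype=np.int64)
    if np.any((k_a > n_total) | (k_b > n_total) | (n11 > np.minimum(k_a, k_b))):
        raise ValueError("inconsistent margins")

    upper = np.minimum(k_a, k_b)
    n_pairs = n11.shape[0]
    if n_pairs == 0:
        return np.empty(0)
    max_terms = int(np.max(upper - n11)) + 1

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    log_denom = log_comb(np.full(n_pairs, n_total), k_b)
    # log pmf at k = n11 + j for j = 0..max_terms-1, masked past the support
    log_terms = np.full((max_terms, n_pairs), -np.inf)
    for j in range(max_terms):
        k = n11 + j
        valid = k <= upper
        if not np.any(valid):
            break
        kv = k[valid]
        log_terms[j, valid] = (
            log_comb(k_a[valid], kv)
            + log_comb(n_total - k_a[valid], k_b[valid] - kv)
            - log_denom[valid]
        )
    peak = log_terms.max(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.exp(peak) * np.exp(log_terms - peak).sum(axis=0)
    p = np.where(np.isfinite(peak), p, 0.0)
    return np.minimum(p, 1.0)


def fisher_right_tail(t: ContingencyTable) -> float:
    """One-sided Fisher exact p-value P(X >= n11) for one 2x2 table."""
    t.validate()
    k_a = t.n11 + t.n10
    k_b = t.n11 + t.n01
    return float(
        fisher_right_tail_many(
            np.array([t.n11]), np.array([k_a]), np.array([k_b]), t.total
        )[0]
    )


def candidate_pairs(
    matrix: OccurrenceMatrix, min_shared: int = DEFAULT_MIN_SHARED
) -> list[tuple]:
    """Unordered variant pairs co-occurring in at least ``min_shared`` subpools.

    Computed through a sparse presence product, so the all-pairs matrix of
    shared-subpool counts is never densified over non-co-occurring pairs.
    """
    if matrix.n_variants == 0:
        return []
    presence = sparse.csr_matrix(matrix.presence_array().astype(np.int32))
    co = sparse.triu(presence @ presence.T, k=1).tocoo()
    keep = co.data >= min_shared
    variants = matrix.variants
    pairs = [
        (variants[i], variants[j])
        for i, j in zip(co.row[keep], co.col[keep])
    ]
    pairs.sort()
    return pairs


def _bh_adjusted(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    m = p.shape[0]
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _tsbky_reject_from_bh(bh_adj_sorted: np.ndarray, bh_adj: np.ndarray, q) -> np.ndarray:
    """Two-stage BKY rejection flags given BH-adjusted values.

    Stage 1 runs BH at q' = q/(1+q); with r1 rejections, stage 2 reruns BH at
    q' * m / (m - r1).  r1 = 0 rejects nothing; r1 = m rejects everything.
    ``q`` may be a scalar or an array (evaluated elementwise for bisection).
    """
    q = np.asarray(q, dtype=float)
    m = bh_adj.shape[0]
    q1 = q / (1.0 + q)
    r1 = np.searchsorted(bh_adj_sorted, q1, side="right")
    if q.ndim == 0:
        if r1 == 0:
            return np.zeros(m, dtype=bool)
        if r1 == m:
            return np.ones(m, dtype=bool)
        return bh_adj <= q1 * m / (m - r1)
    # vectorized over q: one flag per (q_i, hypothesis_i) pair
    level = np.where(r1 < m, q1 * m / np.maximum(m - r1, 1), np.inf)
    flags = bh_adj <= level
    flags[r1 == 0] = False
    flags[r1 == m] = True
    return flags


def tsbky_reject(p_values: Sequence[float], q: float) -> np.ndarray:
    """Rejection flags of the two-stage BKY procedure at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    _check_unit_interval(p)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    bh = _bh_adjusted(p)
    return _tsbky_reject_from_bh(np.sort(bh), bh, float(q))


def adjust_fdr_tsbky(
    p_values: Sequence[float], q: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage Benjamini-Krieger-Yekutieli FDR adjustment.

    Returns ``(adjusted, rejected)``.  ``rejected`` are the exact step-up
    flags at level ``q``.  Each adjusted value is the smallest FDR level at
    which the two-stage procedure rejects that hypothesis (the step-up
    q-value convention), found by bisection — the rejection set is monotone
    in the level, so the threshold is well defined; hypotheses not rejected
    even at level 1 are reported as 1.  Adjusted values are non-decreasing in
    the raw p-value rank.
    """
    p = np.asarray(p_values, dtype=float)
    _check_unit_interval(p)
    m = p.size
    if m == 0:
        return np.empty(0), np.zeros(0, dtype=bool)
    bh = _bh_adjusted(p)
    bh_sorted = np.sort(bh)
    rejected = _tsbky_reject_from_bh(bh_sorted, bh, float(q))

    lo = np.zeros(m)
    hi = np.ones(m)
    rejected_at_one = _tsbky_reject_from_bh(bh_sorted, bh, np.ones(m))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        flags = _tsbky_reject_from_bh(bh_sorted, bh, mid)
        hi = np.where(flags, mid, hi)
        lo = np.where(flags, lo, mid)
    adjusted = np.where(rejected_at_one, hi, 1.0)
    return adjusted, rejected


def _check_unit_interval(p: np.ndarray) -> None:
    if p.size and (np.min(p) < 0 or np.max(p) > 1 or not np.all(np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")


def detect_links(
    matrix: OccurrenceMatrix,
    alpha: float = DEFAULT_ALPHA,
    min_shared: int = DEFAULT_MIN_SHARED,
    q: Optional[float] = None,
) -> LinkSet:
    """Test all candidate variant pairs for non-random co-occurrence.

    The multiple-testing family is the set of pairs actually tested (those
    sharing >= ``min_shared`` subpools).  ``q`` is the FDR level fed to the
    two-stage adjustment and defaults to ``alpha``; a pair is significant
    when its adjusted p-value is below ``alpha``.  Output is deterministic
    given the matrix and invariant to variant/subpool ordering.
    """
    if q is None:
        q = alpha
    pairs = candidate_pairs(matrix, min_shared=min_shared)
    result = LinkSet(alpha=alpha, min_shared=min_shared)
    if not pairs:
        return result

    presence = matrix.presence
    prevalence = presence.sum(axis=1)
    pa = np.array([prevalence[a] for a, _ in pairs], dtype=np.int64)
    pb = np.array([prevalence[b] for _, b in pairs], dtype=np.int64)
    arr = matrix.presence_array()
    idx = {v: i for i, v in enumerate(matrix.variants)}
    n11 = np.array(
        [int(np.sum(arr[idx[a]] & arr[idx[b]])) for a, b in pairs], dtype=np.int64
    )
    p_raw = fisher_right_tail_many(n11, pa, pb, matrix.n_subpools)
    p_adj, _ = adjust_fdr_tsbky(p_raw, q=q)

    for (a, b), ka, kb, k11, pr, padj in zip(pairs, pa, pb, n11, p_raw, p_adj):
        table = ContingencyTable(
            int(k11), int(ka - k11), int(kb - k11), int(matrix.n_subpools - ka - kb + k11)
        )
        result.tests.append(
            LinkTest(
                variant_a=a,
                variant_b=b,
                table=table,
                p_raw=float(pr),
                p_adj=float(padj),
                significant=bool(padj < alpha),
            )
        )
    return result
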