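"""Hypergeometric over-representation analysis of a microbe list.

Given a query list of M microbes drawn from a background universe of N
microbes, and an annotated set containing n of those background microbes,
the overlap m between query and set follows a hypergeometric distribution
under the null of random draws. The reported p-value is the inclusive upper
tail P(X >= m), i.e. the probability of matching at least as many set
members by chance. P-values across all tested sets are corrected by
Bonferroni and by the Benjamini-Hochberg step-up FDR procedure.

Fold of over-representation is the observed/expected ratio
(m/M)/(n/N); percent is the fraction m/M of the query matching the set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .setdb import Category, SetDatabase, normalize_name

__all__ = [
    "EnrichmentInput",
    "EnrichmentResult",
    "EmptyQueryError",
    "hypergeom_pvalue",
    "fold_enrichment",
    "bonferroni",
    "bh_fdr",
    "prepare_input",
    "run_enrichment",
    "results_to_frame",
]


class EmptyQueryError(ValueError):
    """Raised when no query microbe survives intersection with the background."""


def _validate_counts(N: int, n: int, M: int, m: int) -> None:
    for label, v in (("N", N), ("n", n), ("M", M), ("m", m)):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError(f"{label} must be a nonnegative integer, got {v!r}")
    if n > N or M > N:
        raise ValueError(f"set size n={n} and query size M={M} must not exceed background N={N}")
    if m > min(n, M):
        raise ValueError(f"overlap m={m} exceeds min(n={n}, M={M})")


def hypergeom_pvalue(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail probability P(X >= m) of the hypergeometric null.

    X counts successes when M microbes are drawn without replacement from a
    background of N microbes of which n belong to the tested set. Computed
    exactly via the survival function (no normal approximation); the result
    lies in (0, 1].
    """
    _validate_counts(N, n, M, m)
    if m == 0:
        return 1.0
    return float(hypergeom.sf(m - 1, N, n, M))


def fold_enrichment(N: int, n: int, M: int, m: int) -> float:
    """Observed/expected overlap ratio (m/M)/(n/N)."""
    _validate_counts(N, n, M, m)
    if n == 0 or M == 0:
        raise ValueError("fold enrichment undefined for n=0 or M=0")
    return (m / M) / (n / N)


def _check_pvalues(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Family-wise correction: each p mapped to min(1, p * k), k = len(p_values)."""
    p = _check_pvalues(p_values)
    return np.minimum(p * p.size, 1.0).tolist()


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sort ascending, scale p_(i) by k/i, enforce monotonicity by a running
    minimum from the largest rank down, cap at 1, and return in the input
    order.
    """
    p = _check_pvalues(p_values)
    k = p.size
    if k == 0:
        return []
    order = np.argsort(p, kind="stable")
    scaled = p[order] * k / np.arange(1, k + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(k)
    q[order] = q_sorted
    return q.tolist()


@dataclass(frozen=True)
class EnrichmentInput:
    """A prepared enrichment problem.

    ``query`` is the de-duplicated, normalized query intersected with the
    background (its size is M); ``background`` is the effective universe of
    size N; ``dropped`` lists query names absent from the background, which
    do not count toward M.
    """

    query: frozenset[str]
    background: frozenset[str]
    db: SetDatabase
    min_size: int = 2
    category: Category | None = None
    dropped: tuple[str, ...] = ()


@dataclass(frozen=True)
class EnrichmentResult:
    """One row of the enrichment report, for a single tested microbe set."""

    set_name: str
    category: Category
    n: int
    m: int
    percent: float
    fold: float
    p: float
    bonferroni: float = field(default=float("nan"))
    fdr: float = field(default=float("nan"))
    matched: tuple[str, ...] = ()
    unmatched: tuple[str, ...] = ()


def prepare_input(
    query: Iterable[str],
    db: SetDatabase,
    background: Iterable[str] | None = None,
    min_size: int = 2,
    category: Category | str | None = None,
) -> EnrichmentInput:
    """Normalize and intersect query/background against the database universe.

    The background defaults to the database universe (all microbes in all
    sets); a user-supplied background is intersected with the universe
    first. Query names outside the effective background are dropped with a
    warning and excluded from M.
    """
    if len(db) == 0:
        raise ValueError("set database is empty")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    universe = db.universe
    if background is None:
        bg = universe
    else:
        bg = frozenset(normalize_name(b) for b in background) & universe
    q_all = {normalize_name(q) for q in query}
    q = frozenset(q_all & bg)
    dropped = tuple(sorted(q_all - bg))
    if dropped:
        warnings.warn(
            f"{len(dropped)} query name(s) absent from the background were dropped: "
            + ", ".join(dropped),
            stacklevel=2,
        )
    if not q:
        raise EmptyQueryError("no query microbe overlaps the background universe")
    cat = Category(category) if category is not None else None
    return EnrichmentInput(
        query=q, background=bg, db=db, min_size=min_size, category=cat, dropped=dropped
    )


def run_enrichment(
    query: Iterable[str] | EnrichmentInput,
    db: SetDatabase | None = None,
    background: Iterable[str] | None = None,
    min_size: int = 2,
    category: Category | str | None = None,
) -> list[EnrichmentResult]:
    """Test every eligible microbe set for over-representation in the query.

    A set is tested if, after intersection with the background, it has at
    least ``min_size`` members. Bonferroni and BH-FDR corrections are
    applied across exactly the tested sets. Results are sorted by p-value
    ascending, ties broken by set name.
    """
    if isinstance(query, EnrichmentInput):
        inp = query
    else:
        if db is None:
            raise TypeError("db is required when query is a name list")
        inp = prepare_input(query, db, background=background, min_size=min_size, category=category)

    N = len(inp.background)
    M = len(inp.query)
    rows: list[EnrichmentResult] = []
    for s in inp.db:
        if inp.category is not None and s.category != inp.category:
            continue
        members = s.members & inp.background
        n = len(members)
        if n < inp.min_size:
            continue
        matched = tuple(sorted(members & inp.query))
        m = len(matched)
        rows.append(
            EnrichmentResult(
                set_name=s.name,
                category=s.category,
                n=n,
                m=m,
                percent=m / M,
                fold=fold_enrichment(N, n, M, m),
                p=hypergeom_pvalue(N, n, M, m),
                matched=matched,
                unmatched=tuple(sorted(members - inp.query)),
            )
        )
    if not rows:
        return []
    p = [r.p for r in rows]
    bonf = bonferroni(p)
    fdr = bh_fdr(p)
    rows = [
        EnrichmentResult(
            set_name=r.set_name,
            category=r.category,
            n=r.n,
            m=r.m,
            percent=r.percent,
            fold=r.fold,
            p=r.p,
            bonferroni=b,
            fdr=q,
            matched=r.matched,
            unmatched=r.unmatched,
        )
        for r, b, q in zip(rows, bonf, fdr)
    ]
    rows.sort(key=lambda r: (r.p, r.set_name))
    return rows


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Result rows as a DataFrame in the canonical column order."""
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "category": [r.category.value for r in results],
            "n": [r.n for r in results],
            "m": [r.m for r in results],
            "percent": [r.percent for r in results],
            "fold": [r.fold for r in results],
            "p_value": [r.p for r in results],
            "bonferroni": [r.bonferroni for r in results],
            "fdr": [r.fdr for r in results],
            "matched": ["; ".join(r.matched) for r in results],
            "unmatched": ["; ".join(r.unmatched) for r in results],
        }
    )
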