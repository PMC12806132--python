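"""Hypergeometric over-representation of pathway (subsystem) terms.

Given a universe of N features, a term covering m of them, and n
significant features of which x fall in the term, the point probability is

    P(X = x) = C(m, x) * C(N - m, n - x) / C(N, n)

computed in log space.  The over-representation call uses the upper tail
P(X >= x) including the observed count, thresholded at alpha (0.1 by
default, with no cross-term correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .gsmm import MetabolicModel

__all__ = [
    "TermMap",
    "EnrichmentRow",
    "hypergeom_pmf",
    "hypergeom_tail",
    "enrich_terms",
    "enrichment_heat_table",
    "subsystem_term_map",
    "DEFAULT_ENRICH_ALPHA",
]

DEFAULT_ENRICH_ALPHA = 0.1


@dataclass(frozen=True)
class TermMap:
    """Term label -> feature-id set over a fixed universe."""

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("TermMap requires at least one term")
        object.__setattr__(
            self, "terms", {t: frozenset(f) for t, f in self.terms.items()}
        )
        object.__setattr__(self, "universe", frozenset(self.universe))
        for term, features in self.terms.items():
            stray = features - self.universe
            if stray:
                raise ValueError(
                    f"term {term!r} maps features outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    @classmethod
    def from_tsv(
        cls, path: Union[str, Path], universe: Optional[Iterable[str]] = None
    ) -> "TermMap":
        """Two-column TSV (feature_id, term), no header required."""
        df = pd.read_csv(path, sep="\t", header=None, names=["feature_id", "term"])
        terms: dict[str, set[str]] = {}
        for feature, term in zip(df["feature_id"], df["term"]):
            terms.setdefault(str(term), set()).add(str(feature))
        mapped = set().union(*terms.values())
        uni = frozenset(universe) if universe is not None else frozenset(mapped)
        return cls(terms={t: frozenset(f) for t, f in terms.items()}, universe=uni)

    @classmethod
    def from_gmt(
        cls, path: Union[str, Path], universe: Optional[Iterable[str]] = None
    ) -> "TermMap":
        """GMT: term <tab> description <tab> feature ids..."""
        terms: dict[str, frozenset[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                terms[parts[0]] = frozenset(parts[2:])
        mapped = set().union(*terms.values()) if terms else set()
        uni = frozenset(universe) if universe is not None else frozenset(mapped)
        return cls(terms=terms, universe=uni)


def subsystem_term_map(model: MetabolicModel, collapse_split: bool = True) -> TermMap:
    """Subsystem labels as a term map over the model's reactions.

    With ``collapse_split`` (default), forward/backward halves produced by
    irreversibilization collapse to their parent reaction id so a pathway is
    not double-counted.  Reactions without a subsystem label are outside the
    universe.
    """
    terms: dict[str, set[str]] = {}
    universe: set[str] = set()
    for rxn in model.reactions:
        if not rxn.subsystem:
            continue
        fid = (rxn.parent_id or rxn.id) if collapse_split else rxn.id
        universe.add(fid)
        terms.setdefault(rxn.subsystem, set()).add(fid)
    return TermMap(
        terms={t: frozenset(f) for t, f in terms.items()}, universe=frozenset(universe)
    )


def collapse_split_ids(features: Iterable[str], model: MetabolicModel) -> set[str]:
    """Map split-model reaction ids onto parent ids."""
    parent = {r.id: (r.parent_id or r.id) for r in model.reactions}
    return {parent.get(f, f) for f in features}


def _check_counts(N: int, m: int, n: int, x: int) -> None:
    for name, val in (("N", N), ("m", m), ("n", n), ("x", x)):
        if not isinstance(val, (int, np.integer)) or val < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {val!r}")
    if m > N or n > N:
        raise ValueError(f"m={m} and n={n} must not exceed N={N}")


def _log_pmf(N: int, m: int, n: int, k) -> np.ndarray:
    """Vectorized log point probability over an array of counts k."""
    k = np.asarray(k, dtype=float)
    return (
        gammaln(m + 1)
        - gammaln(k + 1)
        - gammaln(m - k + 1)
        + gammaln(N - m + 1)
        - gammaln(n - k + 1)
        - gammaln(N - m - (n - k) + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeom_pmf(N: int, m: int, n: int, x):
    """P(X = x) for x term features among n draws from N with m marked.

    ``x`` may be a scalar or an integer array (vectorized evaluation).
    """
    scalar = np.isscalar(x)
    xs = np.atleast_1d(np.asarray(x))
    _check_counts(N, m, n, int(xs.min()) if xs.size else 0)
    if xs.size and int(xs.max()) > N:
        raise ValueError(f"x must not exceed N={N}")
    support = (xs <= min(m, n)) & (n - xs <= N - m)
    out = np.zeros(xs.shape)
    if support.any():
        out[support] = np.exp(_log_pmf(N, m, n, xs[support]))
    return float(out[0]) if scalar else out


def hypergeom_tail(N: int, m: int, n: int, x):
    """Upper tail P(X >= x), including the observed count.

    ``x`` may be a scalar or an integer array (vectorized evaluation).
    """
    scalar = np.isscalar(x)
    xs = np.atleast_1d(np.asarray(x))
    _check_counts(N, m, n, int(xs.min()) if xs.size else 0)
    hi = min(m, n)
    lo = max(0, n - (N - m))  # support floor
    out = np.zeros(xs.shape)
    if lo <= hi:
        logs = _log_pmf(N, m, n, np.arange(lo, hi + 1))
        # suffix log-sum-exp: tail at k = sum of pmf over k..hi
        suffix = np.logaddexp.accumulate(logs[::-1])[::-1]
        inside = (xs >= lo) & (xs <= hi)
        below = xs < lo
        out[inside] = np.minimum(1.0, np.exp(suffix[xs[inside] - lo]))
        out[below] = 1.0
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    N: int
    m: int
    n: int
    x: int
    p_point: float
    p_tail: float
    over_represented: bool

    def __post_init__(self) -> None:
        if self.x > min(self.n, self.m):
            raise ValueError(f"term {self.term!r}: x={self.x} exceeds min(n, m)")


def enrich_terms(
    significant: Iterable[str],
    term_map: TermMap,
    alpha: float = DEFAULT_ENRICH_ALPHA,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of every term, sorted by p_tail.

    Term sizes ``m`` are recomputed from the map; the significant set must
    be a subset of the universe.
    """
    sig = set(significant)
    stray = sig - term_map.universe
    if stray:
        raise ValueError(
            f"significant features outside the universe: {sorted(stray)[:10]}"
        )
    N = len(term_map.universe)
    n = len(sig)
    rows = []
    for term, features in term_map.terms.items():
        m = len(features)
        x = len(sig & features)
        p_point = hypergeom_pmf(N, m, n, x)
        p_tail = hypergeom_tail(N, m, n, x)
        rows.append(
            EnrichmentRow(
                term=term,
                N=N,
                m=m,
                n=n,
                x=x,
                p_point=p_point,
                p_tail=p_tail,
                over_represented=bool(p_tail < alpha),
            )
        )
    rows.sort(key=lambda r: (r.p_tail, r.term))
    return rows


def enrichment_rows_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "N": r.N,
                "m": r.m,
                "n": r.n,
                "x": r.x,
                "p_point": r.p_point,
                "p_tail": r.p_tail,
                "over_represented": r.over_represented,
            }
            for r in rows
        ],
        columns=["term", "N", "m", "n", "x", "p_point", "p_tail", "over_represented"],
    )


def enrichment_heat_table(
    rows_by_comparison: Mapping[str, Sequence[EnrichmentRow]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long and wide (term x comparison) p_tail tables for heatmap plotting.

    A term absent from a comparison is an explicit NaN in the wide table,
    never silently 1.0.
    """
    records = []
    for comparison, rows in rows_by_comparison.items():
        for r in rows:
            records.append(
                {"comparison": comparison, "term": r.term, "p_tail": r.p_tail}
            )
    long = pd.DataFrame(records, columns=["comparison", "term", "p_tail"])
    if long.empty:
        return long, pd.DataFrame()
    wide = long.pivot(index="term", columns="comparison", values="p_tail")
    wide = wide.sort_index()
    return long, wide
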