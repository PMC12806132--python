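"""Differential statistics: comparison groups, rank tests, FDR control.

Flux distributions are heavy-tailed and zero-inflated, so the pipeline
always applies nonparametric rank tests; a seeded Monte-Carlo Lilliefors
normality screen is computed for the record.  Raw p-values are adjusted per
comparison with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .eflux import evaluate_gpr_minsum
from .expression import ExpressionMatrix
from .gsmm import MetabolicModel

__all__ = [
    "ComparisonGroup",
    "DifferentialResult",
    "LillieforsResult",
    "build_groups",
    "lilliefors_test",
    "rank_test",
    "bh_adjust",
    "reaction_expression",
    "differential_analysis",
]

logger = logging.getLogger(__name__)

#: Combined-sample-size cutover between exact enumeration and the normal
#: approximation for the two-sample rank test.
EXACT_CUTOVER = 20

MIN_PER_SET = 2


@dataclass(frozen=True)
class ComparisonGroup:
    """Named comparison: ordered (label, sample-id set) member sets."""

    name: str
    member_sets: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        if len(self.member_sets) < 2:
            raise ValueError(f"group {self.name!r}: needs >= 2 member sets")
        seen: set[str] = set()
        for label, members in self.member_sets:
            if not members:
                raise ValueError(f"group {self.name!r}: set {label!r} is empty")
            if seen & members:
                raise ValueError(f"group {self.name!r}: member sets overlap")
            seen |= members
        object.__setattr__(
            self,
            "member_sets",
            tuple((lab, frozenset(m)) for lab, m in self.member_sets),
        )

    @property
    def test_kind(self) -> str:
        return "two_sample" if len(self.member_sets) == 2 else "k_sample"

    @property
    def all_samples(self) -> set[str]:
        out: set[str] = set()
        for _, members in self.member_sets:
            out |= members
        return out


def _samples(meta: pd.DataFrame, mask) -> frozenset[str]:
    return frozenset(meta.loc[mask, "sample_id"])


def _maybe_group(
    name: str, sets: Sequence[tuple[str, frozenset[str]]]
) -> Optional[ComparisonGroup]:
    kept = [(lab, m) for lab, m in sets if len(m) >= MIN_PER_SET]
    if len(kept) < 2 or len(kept) < len(sets):
        dropped = [lab for lab, m in sets if len(m) < MIN_PER_SET]
        logger.warning("comparison %s dropped (undersized sets: %s)", name, dropped)
        return None
    return ComparisonGroup(name=name, member_sets=tuple(kept))


def build_groups(
    metadata: pd.DataFrame,
    scheme: str = "custom",
    label_column: str = "condition",
) -> list[ComparisonGroup]:
    """Construct comparison groups from a sample metadata table.

    ``metadata`` needs columns ``sample_id`` and ``condition``; the lung and
    pancreas schemes additionally use ``subtype`` and ``stage``.  Groups
    whose member sets are empty (or below 2 samples) in the data are dropped
    with a logged warning.

    Schemes
    -------
    ``lung36``
        The full lung-cancer battery: C-N, SCLC-NSCLC, N-AD-SC, AD-N, SC-N,
        SC-AD, per-subtype all-stages and stage pairs, and per-stage vs N /
        AD-SC comparisons.
    ``pancreas2``
        N-C and N-S1.
    ``custom``
        One comparison over the distinct values of ``label_column``.
    """
    meta = metadata.copy()
    if "sample_id" not in meta.columns:
        raise ValueError("metadata requires a sample_id column")
    groups: list[Optional[ComparisonGroup]] = []

    if scheme == "pancreas2":
        n = _samples(meta, meta["condition"] == "N")
        c = _samples(meta, meta["condition"] == "C")
        s1 = _samples(meta, (meta["condition"] == "C") & (meta.get("stage") == "S1"))
        groups.append(_maybe_group("N-C", [("N", n), ("C", c)]))
        groups.append(_maybe_group("N-S1", [("N", n), ("S1", s1)]))
    elif scheme == "lung36":
        sub = meta.get("subtype", pd.Series("", index=meta.index))
        stage = meta.get("stage", pd.Series("", index=meta.index))
        n = _samples(meta, meta["condition"] == "N")
        c = _samples(meta, meta["condition"] == "C")
        ad = _samples(meta, sub == "AD")
        sc = _samples(meta, sub == "SC")
        sclc = _samples(meta, sub == "SCLC")
        nsclc = ad | sc
        groups.append(_maybe_group("C-N", [("C", c), ("N", n)]))
        groups.append(_maybe_group("SCLC-NSCLC", [("SCLC", sclc), ("NSCLC", nsclc)]))
        groups.append(_maybe_group("N-AD-SC", [("N", n), ("AD", ad), ("SC", sc)]))
        groups.append(_maybe_group("AD-N", [("AD", ad), ("N", n)]))
        groups.append(_maybe_group("SC-N", [("SC", sc), ("N", n)]))
        groups.append(_maybe_group("SC-AD", [("SC", sc), ("AD", ad)]))
        stages = ("S1", "S2", "S3", "S4")
        for label, members in (("AD", ad), ("SC", sc)):
            per_stage = [
                (s, _samples(meta, (sub == label) & (stage == s))) for s in stages
            ]
            groups.append(_maybe_group(f"{label}-stages", per_stage))
            for hi, lo in (
                ("S2", "S1"),
                ("S3", "S1"),
                ("S4", "S1"),
                ("S3", "S2"),
                ("S4", "S2"),
                ("S4", "S3"),
            ):
                pair = dict(per_stage)
                groups.append(
                    _maybe_group(
                        f"{label}-{hi}-{lo}", [(hi, pair[hi]), (lo, pair[lo])]
                    )
                )
        for s in stages:
            ad_s = _samples(meta, (sub == "AD") & (stage == s))
            sc_s = _samples(meta, (sub == "SC") & (stage == s))
            groups.append(_maybe_group(f"AD{s}-N", [("AD", ad_s), ("N", n)]))
            groups.append(_maybe_group(f"SC{s}-N", [("SC", sc_s), ("N", n)]))
            groups.append(_maybe_group(f"AD{s}-SC{s}", [("AD", ad_s), ("SC", sc_s)]))
    elif scheme == "custom":
        if label_column not in meta.columns:
            raise ValueError(f"metadata lacks column {label_column!r}")
        labels = sorted(meta[label_column].dropna().unique())
        sets = [(str(lab), _samples(meta, meta[label_column] == lab)) for lab in labels]
        groups.append(_maybe_group("-".join(str(lab) for lab in labels), sets))
    else:
        raise ValueError(f"unknown grouping scheme {scheme!r}")

    return [g for g in groups if g is not None]


# ---------------------------------------------------------------------------
# Normality screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LillieforsResult:
    statistic: float
    pvalue: float
    n_mc: int
    degenerate: bool = False


def _ks_normal_distance(x: np.ndarray) -> float:
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return np.inf
    return sps.kstest(x, "norm", args=(mu, sd)).statistic


def lilliefors_test(
    x: Sequence[float], n_mc: int = 2000, seed: int = 0
) -> LillieforsResult:
    """Composite normality test with a seeded Monte-Carlo null.

    The Kolmogorov-Smirnov distance to a normal with estimated mean and
    standard deviation is compared against ``n_mc`` resampled null
    distances (parameters re-estimated per resample).  Constant input is
    degenerate and reported as ``p < 1/n_mc``.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size < 4:
        raise ValueError(f"lilliefors_test needs n >= 4, got {arr.size}")
    if np.ptp(arr) == 0:
        return LillieforsResult(
            statistic=np.inf, pvalue=1.0 / n_mc, n_mc=n_mc, degenerate=True
        )
    d_obs = _ks_normal_distance(arr)
    rng = np.random.default_rng(seed)
    null = rng.standard_normal((n_mc, arr.size))
    exceed = 0
    for row in null:
        if _ks_normal_distance(row) >= d_obs:
            exceed += 1
    pvalue = (1 + exceed) / (1 + n_mc)
    return LillieforsResult(statistic=d_obs, pvalue=pvalue, n_mc=n_mc)


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------


def _mannwhitney_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney by full enumeration with mid-ranks."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    combos = np.fromiter(
        itertools.chain.from_iterable(
            itertools.combinations(range(n1 + n2), n1)
        ),
        dtype=np.intp,
    ).reshape(-1, n1)
    u_null = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2.0
    eps = 1e-9
    p_le = np.mean(u_null <= u_obs + eps)
    p_ge = np.mean(u_null >= u_obs - eps)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return float(u_obs), float(p)


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_raw: float
    method: str
    degenerate: bool = False


def rank_test(
    group: ComparisonGroup, values: Mapping[str, float]
) -> RankTestResult:
    """Two-sided Mann-Whitney (2 sets) or Kruskal-Wallis (k sets).

    Two-sample comparisons use exact enumeration with mid-rank ties while
    the combined sample size is at most 20, then the tie-corrected normal
    approximation with continuity correction.  If all observations are
    identical across sets the test is degenerate and p = 1.
    """
    arrays = []
    for label, members in group.member_sets:
        vals = np.asarray([values[s] for s in sorted(members)], dtype=float)
        if vals.size < MIN_PER_SET:
            raise ValueError(
                f"group {group.name!r}, set {label!r}: needs >= "
                f"{MIN_PER_SET} observations"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"group {group.name!r}, set {label!r}: non-finite values")
        arrays.append(vals)

    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return RankTestResult(
            statistic=float("nan"), p_raw=1.0, method="degenerate", degenerate=True
        )

    if group.test_kind == "two_sample":
        x, y = arrays
        if len(x) + len(y) <= EXACT_CUTOVER:
            stat, p = _mannwhitney_exact(x, y)
            return RankTestResult(statistic=stat, p_raw=p, method="mw_exact")
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        return RankTestResult(
            statistic=float(res.statistic), p_raw=float(res.pvalue), method="mw_normal"
        )
    stat, p = sps.kruskal(*arrays)
    return RankTestResult(statistic=float(stat), p_raw=float(p), method="kruskal")


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Reaction-level expression & differential analysis
# ---------------------------------------------------------------------------


def reaction_expression(
    model: MetabolicModel,
    expr: ExpressionMatrix,
    missing_policy: str = "skip",
) -> ExpressionMatrix:
    """Reactions x samples matrix of minSum GPR scores.

    Reactions without a GPR (or with no gene present in the data under
    ``skip``) are omitted.  OR-sums are reported uncapped — the cap is a
    flux-bound decision, not a property of the score.
    """
    sample_maps = {s: expr.sample(s) for s in expr.sample_ids}
    rows: dict[str, list[float]] = {}
    for rxn in model.reactions:
        if rxn.gpr is None:
            continue
        scores = [
            evaluate_gpr_minsum(rxn.gpr, sample_maps[s], missing_policy)
            for s in expr.sample_ids
        ]
        if any(s is None for s in scores):
            continue
        rows[rxn.id] = scores  # type: ignore[assignment]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=expr.sample_ids)
    return ExpressionMatrix(values=df, layer="reaction_expression")


@dataclass
class DifferentialResult:
    """Per-feature statistics for one comparison on one data layer."""

    group: ComparisonGroup
    data_layer: str
    table: pd.DataFrame  # feature_id, statistic, p_raw, p_adj, method
    excluded_features: list[str] = field(default_factory=list)

    def significant(self, alpha: float = 0.05) -> list[str]:
        hit = self.table["p_adj"] < alpha
        return self.table.loc[hit, "feature_id"].tolist()

    def to_tsv(self, path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index=False, lineterminator="\n")


def differential_analysis(
    matrix: ExpressionMatrix,
    groups: Sequence[ComparisonGroup],
    alpha: float = 0.05,
) -> list[DifferentialResult]:
    """Rank-test every feature per comparison group with BH adjustment.

    Features with zero variance across the comparison's samples are
    excluded from testing (degenerate ranks) and recorded.
    """
    results = []
    for group in groups:
        missing = group.all_samples - set(matrix.sample_ids)
        if missing:
            raise ValueError(
                f"group {group.name!r}: samples absent from the "
                f"{matrix.layer} matrix: {sorted(missing)[:5]}"
            )
        cols = sorted(group.all_samples)
        sub = matrix.values[cols]
        variances = sub.var(axis=1)
        excluded = variances[variances == 0].index.tolist()
        tested = [f for f in matrix.gene_ids if f not in set(excluded)]
        records = []
        for feature in tested:
            row = sub.loc[feature].to_dict()
            res = rank_test(group, row)
            records.append(
                {
                    "feature_id": feature,
                    "statistic": res.statistic,
                    "p_raw": res.p_raw,
                    "method": res.method,
                }
            )
        table = pd.DataFrame.from_records(
            records, columns=["feature_id", "statistic", "p_raw", "method"]
        )
        table["p_adj"] = bh_adjust(table["p_raw"].to_numpy()) if len(table) else []
        table = table[["feature_id", "statistic", "p_raw", "p_adj", "method"]]
        results.append(
            DifferentialResult(
                group=group,
                data_layer=matrix.layer,
                table=table,
                excluded_features=excluded,
            )
        )
    return results
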