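"""Radiomic signature selection by four-criterion rank aggregation.

Each of the 235 features is ranked four ways:

1. test/retest stability — concordance correlation coefficient (CCC)
   between the two acquisitions of each tumour position, high to low;
2. normalized dynamic range — biological spread relative to the
   test/retest measurement variability, high to low;
3. observer independence — Quade test p-value over the three independent
   tumour delineations (scans as blocks, observers as treatments), high
   to low;
4. discriminative power — Kruskal-Wallis p-value across the three
   phenotype groups, low to high.

The four ranks are averaged into a final ranking.  The best-ranked
feature of each imaging biomarker class forms the candidate signature;
any pair with Pearson |r| > 0.75 triggers replacement of the
worse-ranked member by the next feature of its class until the four
features are pairwise non-redundant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import BIOMARKER_CLASSES, FEATURE_NAMES, feature_class

__all__ = [
    "RankingConfig",
    "RadiomicSignature",
    "concordance_cc",
    "normalized_dynamic_range",
    "quade_test",
    "quade_user_independence",
    "kruskal_wallis_power",
    "compute_rankings",
    "aggregate_rankings",
    "select_signature",
]


def concordance_cc(x, y) -> float:
    """Lin's concordance correlation coefficient with 1/n moments.

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2).  Two identical
    constant vectors are perfectly concordant (1.0 by convention).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = np.mean((x - mx) * (y - my))
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        return 1.0  # identical constants
    return float(2.0 * cov / denom)


def normalized_dynamic_range(test, retest) -> float:
    """Mean of 1 - |test_i - retest_i| / R with R the pooled value range.

    Lies in [0, 1]; 1 means repeat differences vanish against the
    biological range.  A degenerate pooled range (R = 0) carries no
    biological information and yields 0 by convention.
    """
    test = np.asarray(test, dtype=np.float64)
    retest = np.asarray(retest, dtype=np.float64)
    if test.shape != retest.shape:
        raise ValueError("test and retest must have equal length")
    pooled = np.concatenate([test, retest])
    r = float(pooled.max() - pooled.min())
    if r == 0.0:
        return 0.0
    dr = float(np.mean(1.0 - np.abs(test - retest) / r))
    return min(max(dr, 0.0), 1.0)


def quade_test(data: np.ndarray) -> tuple[float, float]:
    """Quade test for treatment differences in a randomized block design.

    ``data`` is (n_blocks, k_treatments).  Within-block ranks are weighted
    by the ranks of the block ranges; the statistic is F-distributed with
    (k-1, (n-1)(k-1)) degrees of freedom.  Returns (statistic, p).  When
    every block is internally constant the statistic is 0 and p = 1; a
    perfect separation (zero residual) yields p at the numerical floor.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (blocks x treatments)")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    r = np.apply_along_axis(stats.rankdata, 1, data)
    q = stats.rankdata(data.max(axis=1) - data.min(axis=1))
    s = q[:, None] * (r - (k + 1) / 2.0)
    a = float(np.sum(s * s))
    col = s.sum(axis=0)
    b = float(np.sum(col * col) / n)
    if a == 0.0:
        return 0.0, 1.0
    if a == b:
        return np.inf, np.nextafter(0.0, 1.0)
    f = (n - 1.0) * b / (a - b)
    p = float(stats.f.sf(f, k - 1, (n - 1) * (k - 1)))
    return float(f), max(p, np.nextafter(0.0, 1.0))


def quade_user_independence(values: np.ndarray) -> float:
    """p-value of the Quade test on a (scans x 3 observers) table.

    A high p-value means the three delineations leave the feature
    statistically indistinguishable, i.e. the feature is user-independent.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[1] != 3:
        raise ValueError("expected a (scans x 3 users) table")
    if values.shape[0] < 3:
        raise ValueError("need at least 3 scans (blocks)")
    return quade_test(values)[1]


def kruskal_wallis_power(values, labels) -> float:
    """Kruskal-Wallis p-value of a feature across the phenotype groups."""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in np.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(values) == 0:
        return 1.0
    return float(stats.kruskal(*groups).pvalue)


@dataclass(frozen=True)
class RankingConfig:
    """Which slices of the study feed each ranking statistic."""

    kw_dataset: int = 1          # dataset used for the Kruskal-Wallis ranking
    pearson_dataset: int = 1     # dataset used for the correlation pruning
    pearson_user: str = "user1"
    r_max: float = 0.75


def _unique_rank(values: np.ndarray, names: list[str], ascending: bool) -> np.ndarray:
    """Dense 1..N ranking with deterministic name tie-break."""
    v = np.asarray(values, dtype=np.float64)
    key = v if ascending else -v
    order = np.lexsort((np.asarray(names), key))
    ranks = np.empty(len(v), dtype=np.int64)
    ranks[order] = np.arange(1, len(v) + 1)
    return ranks


def _paired_pivots(features: pd.DataFrame, name: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Align dataset-1 and dataset-2 values of one feature by (mouse, position, user)."""
    wide = features.pivot_table(index=["mouse_id", "position_id", "user_id"],
                                columns="dataset", values=name)
    wide = wide.dropna()
    users = wide.index.get_level_values("user_id")
    return wide[1].to_numpy(), wide[2].to_numpy(), list(users)


def compute_rankings(features: pd.DataFrame,
                     config: RankingConfig | None = None) -> pd.DataFrame:
    """Per-feature stability/discrimination statistics and the final ranking.

    ``features`` is the long table produced by
    :func:`ceus_radiomics.features.extract_study` (metadata columns plus
    the 235 feature columns; both datasets, all observers).  Returns a
    DataFrame indexed by feature name with columns ``ccc``,
    ``dynamic_range``, ``quade_p``, ``kw_p``, the four rank columns and
    ``final_rank`` (each rank column a permutation of 1..N).
    """
    if config is None:
        config = RankingConfig()
    feat_names = [c for c in FEATURE_NAMES if c in features.columns]
    if not feat_names:
        raise ValueError("no feature columns found")

    users = sorted(features["user_id"].unique())
    kw_slice = features[(features["dataset"] == config.kw_dataset)
                        & (features["user_id"] == config.pearson_user)]
    labels = kw_slice["model_label"].to_numpy()

    rows = []
    for name in feat_names:
        d1, d2, pair_users = _paired_pivots(features, name)
        pair_users = np.asarray(pair_users)
        # CCC and dynamic range: per observer, averaged
        cccs, drs = [], []
        for u in users:
            sel = pair_users == u
            cccs.append(concordance_cc(d1[sel], d2[sel]))
            drs.append(normalized_dynamic_range(d1[sel], d2[sel]))
        # Quade blocks: every (scan, dataset) acquisition, observers as treatments
        table = features.pivot_table(index=["scan_id", "dataset"],
                                     columns="user_id", values=name).dropna()
        quade_p = quade_user_independence(table.to_numpy())
        kw_p = kruskal_wallis_power(kw_slice[name].to_numpy(), labels)
        rows.append(dict(feature=name, ccc=float(np.mean(cccs)),
                         dynamic_range=float(np.mean(drs)),
                         quade_p=quade_p, kw_p=kw_p))

    ranking = pd.DataFrame(rows).set_index("feature")
    ranking["rank_ccc"] = _unique_rank(ranking["ccc"].to_numpy(), feat_names, ascending=False)
    ranking["rank_dr"] = _unique_rank(ranking["dynamic_range"].to_numpy(), feat_names,
                                      ascending=False)
    ranking["rank_user"] = _unique_rank(ranking["quade_p"].to_numpy(), feat_names,
                                        ascending=False)
    ranking["rank_power"] = _unique_rank(ranking["kw_p"].to_numpy(), feat_names,
                                         ascending=True)
    return aggregate_rankings(ranking)


def aggregate_rankings(ranking: pd.DataFrame) -> pd.DataFrame:
    """Final ranking: ascending mean of the four ranks, ties by rank_ccc then name."""
    required = ["rank_ccc", "rank_dr", "rank_user", "rank_power"]
    if any(c not in ranking.columns for c in required):
        raise ValueError(f"ranking table must contain {required}")
    out = ranking.copy()
    score = out[required].mean(axis=1).to_numpy()
    order = np.lexsort((out.index.to_numpy(), out["rank_ccc"].to_numpy(), score))
    final = np.empty(len(out), dtype=np.int64)
    final[order] = np.arange(1, len(out) + 1)
    out["final_score"] = score
    out["final_rank"] = final
    return out


@dataclass
class RadiomicSignature:
    """Four selected features, one per imaging biomarker class."""

    features: dict[str, str]           # biomarker class -> feature name
    correlation: pd.DataFrame = field(repr=False, default=None)

    @property
    def names(self) -> list[str]:
        return [self.features[c] for c in BIOMARKER_CLASSES]


def select_signature(ranking: pd.DataFrame, features: pd.DataFrame,
                     config: RankingConfig | None = None) -> RadiomicSignature:
    """Pick the best-ranked feature per class and prune correlated pairs.

    Pearson correlations are computed on the configured (dataset, user)
    slice.  While any pair exceeds |r| = ``r_max``, the worse-final-ranked
    member of the most correlated offending pair is replaced by the next
    best feature of its biomarker class.

    Raises
    ------
    RuntimeError
        If a biomarker class runs out of candidates before the constraint
        is satisfied.
    """
    if config is None:
        config = RankingConfig()
    values = features[(features["dataset"] == config.pearson_dataset)
                      & (features["user_id"] == config.pearson_user)]
    if values.empty:
        raise ValueError("no rows for the configured correlation slice")

    by_class: dict[str, list[str]] = {c: [] for c in BIOMARKER_CLASSES}
    for name in ranking.sort_values("final_rank").index:
        by_class[feature_class(name)].append(name)

    pointer = {c: 0 for c in BIOMARKER_CLASSES}
    current = {c: by_class[c][0] for c in BIOMARKER_CLASSES}

    while True:
        names = [current[c] for c in BIOMARKER_CLASSES]
        corr = values[names].corr(method="pearson").fillna(0.0)
        np.fill_diagonal(corr.values, 1.0)
        worst_pair, worst_r = None, config.r_max
        for a in range(4):
            for b in range(a + 1, 4):
                r = abs(corr.iloc[a, b])
                if r > worst_r:
                    worst_r = r
                    worst_pair = (BIOMARKER_CLASSES[a], BIOMARKER_CLASSES[b])
        if worst_pair is None:
            return RadiomicSignature(features=dict(current), correlation=corr)
        ca, cb = worst_pair
        ranks = ranking["final_rank"]
        loser = ca if ranks[current[ca]] > ranks[current[cb]] else cb
        pointer[loser] += 1
        if pointer[loser] >= len(by_class[loser]):
            raise RuntimeError(
                f"biomarker class {loser!r} exhausted without satisfying "
                f"|r| <= {config.r_max}")
        current[loser] = by_class[loser][pointer[loser]]
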