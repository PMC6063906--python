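"""Phenotype classification and unsupervised clustering.

Supervised: the four-feature radiomic signature is z-scored and fed to a
linear soft-margin SVM (C = 1) evaluated by stratified 4-fold
cross-validation; held-out predictions are pooled into a single confusion
matrix and the accuracy carries a Wilson score confidence interval.

Unsupervised: agglomerative clustering of the full z-scored feature table
(Euclidean distance, average/UPGMA linkage) cut to three clusters, with
exact multinomial enrichment tests of the phenotype composition per
cluster, exact binomial post-hoc tests per (cluster, phenotype) and
Bonferroni correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "ClassificationResult",
    "ClusterResult",
    "zscore_table",
    "wilson_interval",
    "cv_svm",
    "hierarchical_cluster",
    "exact_multinomial_test",
    "cluster_enrichment",
    "group_difference_posthoc",
]


def zscore_table(features: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-score; constant columns map to all zeros."""
    x = features.astype(np.float64)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = sd.replace(0.0, np.nan)
    out = (x - mean).div(sd, axis=1).fillna(0.0)
    return out


def wilson_interval(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    z = stats.norm.ppf(0.5 + level / 2.0)
    phat = successes / n
    denom = 1.0 + z * z / n
    centre = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return (max(centre - half, 0.0), min(centre + half, 1.0))


@dataclass
class ClassificationResult:
    """Pooled cross-validated classification performance."""

    confusion_matrix: pd.DataFrame   # true (rows) x predicted (columns)
    accuracy: float
    wilson_ci: tuple[float, float]
    fold_assignments: dict = field(default_factory=dict)
    predictions: pd.Series = None


def cv_svm(features: pd.DataFrame, labels, k: int = 4, seed: int = 0,
           C: float = 1.0, level: float = 0.95) -> ClassificationResult:
    """Linear SVM with seeded stratified k-fold cross-validation.

    Per fold, the SVM (linear kernel, one-vs-one multiclass, soft margin
    ``C``) is trained on the remaining folds and predicts the held-out
    fold; predictions are pooled into one confusion matrix.  Falls back
    to unstratified folds when a class has fewer members than folds.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(x, y)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(x)

    pred = np.empty(len(y), dtype=y.dtype)
    folds = {}
    for fold, (train, test) in enumerate(splits):
        clf = SVC(kernel="linear", C=C, decision_function_shape="ovo")
        clf.fit(x[train], y[train])
        pred[test] = clf.predict(x[test])
        for i in test:
            folds[int(i)] = fold

    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y, pred):
        cm.loc[t, p] += 1
    correct = int(np.trace(cm.to_numpy()))
    acc = correct / len(y)
    return ClassificationResult(confusion_matrix=cm, accuracy=acc,
                                wilson_ci=wilson_interval(correct, len(y), level),
                                fold_assignments=folds,
                                predictions=pd.Series(pred))


@dataclass
class ClusterResult:
    """Hierarchical clustering with phenotype enrichment."""

    linkage: np.ndarray
    cluster_labels: np.ndarray        # 1..n_clusters per row
    enrichment: pd.DataFrame = None   # per (cluster, model) post-hoc tests
    cluster_p: pd.Series = None       # per-cluster exact multinomial p


def hierarchical_cluster(features: pd.DataFrame, n_clusters: int = 3) -> ClusterResult:
    """Agglomerative clustering, Euclidean distance, average (UPGMA) linkage."""
    x = np.asarray(features, dtype=np.float64)
    if len(x) < n_clusters:
        raise ValueError("need at least n_clusters rows")
    z = hierarchy.linkage(x, method="average", metric="euclidean")
    labels = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    return ClusterResult(linkage=z, cluster_labels=labels)


def exact_multinomial_test(observed, probs) -> float:
    """Exact multinomial goodness-of-fit p-value.

    Enumerates all compositions of n into the categories and sums the
    probability of every outcome no more likely than the observed one.
    """
    observed = np.asarray(observed, dtype=int)
    probs = np.asarray(probs, dtype=np.float64)
    if observed.ndim != 1 or observed.shape != probs.shape:
        raise ValueError("observed and probs must be 1-D and aligned")
    if not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("probs must sum to 1")
    n = int(observed.sum())
    k = len(observed)
    p_obs = stats.multinomial.pmf(observed, n, probs)
    total = 0.0
    for cut in itertools.combinations(range(n + k - 1), k - 1):
        counts = np.diff([-1, *cut, n + k - 1]) - 1
        pr = stats.multinomial.pmf(counts, n, probs)
        if pr <= p_obs * (1 + 1e-9):
            total += pr
    return min(float(total), 1.0)


def cluster_enrichment(cluster_labels, model_labels) -> ClusterResult:
    """Phenotype enrichment of each cluster.

    Per cluster: exact multinomial test of the observed phenotype
    composition against the overall phenotype frequencies; post-hoc exact
    binomial tests per phenotype for over/under-representation;
    Bonferroni correction over all (cluster, phenotype) post-hoc tests.
    Empty clusters are skipped.
    """
    cluster_labels = np.asarray(cluster_labels)
    model_labels = np.asarray(model_labels)
    if cluster_labels.shape != model_labels.shape:
        raise ValueError("label vectors must be aligned")
    models = np.unique(model_labels)
    freqs = np.array([(model_labels == m).mean() for m in models])
    clusters = np.unique(cluster_labels)

    rows = []
    cluster_p = {}
    for c in clusters:
        in_c = cluster_labels == c
        n_c = int(in_c.sum())
        if n_c == 0:
            continue
        obs = np.array([int((model_labels[in_c] == m).sum()) for m in models])
        cluster_p[c] = exact_multinomial_test(obs, freqs)
        for m, o, f in zip(models, obs, freqs):
            test = stats.binomtest(int(o), n_c, p=float(f), alternative="two-sided")
            rows.append(dict(cluster=c, model=m, observed=int(o),
                             expected=float(n_c * f), p_raw=float(test.pvalue)))
    enr = pd.DataFrame(rows)
    m_tests = len(enr)
    enr["p_adj"] = np.minimum(1.0, enr["p_raw"] * m_tests)
    return ClusterResult(linkage=None, cluster_labels=cluster_labels,
                         enrichment=enr, cluster_p=pd.Series(cluster_p))


def group_difference_posthoc(values, labels) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons of group means.

    Returns one row per unordered group pair with the mean difference and
    the studentized-range adjusted p-value.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    samples = [values[labels == g] for g in groups]
    if len(groups) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    res = stats.tukey_hsd(*samples)
    rows = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            rows.append(dict(group_a=groups[a], group_b=groups[b],
                             mean_difference=float(samples[a].mean() - samples[b].mean()),
                             p_adj=float(res.pvalue[a, b])))
    return pd.DataFrame(rows)
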