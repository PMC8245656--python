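"""Diversity summaries, group comparisons, beta-diversity clustering, and
random-forest indicator genera.

Group comparisons follow a normality gate: Shapiro-Wilk per group decides
between one-way ANOVA (all groups normal) and Kruskal-Wallis, followed by
rank-based all-pairs multiple comparisons (Dunn tests, Holm-adjusted) that
are summarized as a compact letter display — groups that share a letter do
not differ significantly.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from itertools import combinations
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import confusion_matrix as _sk_confusion

from .matrix_io import GroupMap, IncidenceMatrix, SiteTaxonTable, ValidationError


def richness(m: IncidenceMatrix, groups: GroupMap | None = None) -> pd.DataFrame:
    """Per-sample genus richness (row sums of the incidence matrix).

    With a group map attached, per-group min/max/median summaries are
    available under ``.attrs["group_summary"]``.
    """
    out = pd.DataFrame({"richness": m.presence.sum(axis=1)}, index=m.sample_ids)
    if groups is not None:
        out["group"] = groups.labels_for(m.sample_ids)
        out.attrs["group_summary"] = out.groupby("group")["richness"].agg(
            ["min", "max", "median", "count"])
    return out


# ---------------------------------------------------------------------------
# group comparison with compact letter display

@dataclass
class GroupComparison:
    method: str            # "anova" or "kruskal"
    statistic: float
    p_omnibus: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, z, p, p_adjusted
    letters: dict[str, str]


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def _dunn_pairwise(values: np.ndarray, labels: np.ndarray, group_names: list[str]) -> pd.DataFrame:
    """All-pairs Dunn tests on pooled ranks with tie correction, Holm-adjusted."""
    ranks = stats.rankdata(values)
    N = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12 * (N - 1)))
    var_base = N * (N + 1) / 12 - tie_term
    mean_rank = {g: ranks[labels == g].mean() for g in group_names}
    n = {g: int((labels == g).sum()) for g in group_names}
    rows = []
    for a, b in combinations(group_names, 2):
        se = np.sqrt(var_base * (1 / n[a] + 1 / n[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        rows.append({"group_a": a, "group_b": b, "z": z,
                     "p": float(2 * stats.norm.sf(abs(z)))})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = _holm(df["p"].to_numpy())
    return df


def _letter_display(group_names: list[str], different: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one set holding every group and splits it for each
    significantly different pair, absorbing redundant subsets, so that two
    groups share a letter iff they are never declared different.
    """
    sets: list[set[str]] = [set(group_names)]
    for a, b in different:
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        sets = []
        for s in new_sets:  # absorb: drop empties, strict subsets, duplicates
            if not s or any(s < t for t in new_sets) or any(s == t for t in sets):
                continue
            sets.append(s)
    order = {g: i for i, g in enumerate(group_names)}
    sets.sort(key=lambda s: min(order[g] for g in s))
    letters = {g: "" for g in group_names}
    for letter, s in zip(string.ascii_lowercase, sets):
        for g in sorted(s, key=order.get):
            letters[g] += letter
    return letters


def compare_groups(values: pd.Series | np.ndarray, groups: GroupMap | list[str],
                   alpha: float = 0.05) -> GroupComparison:
    """Omnibus test (normality-gated) plus pairwise letters.

    ``values`` is a per-sample series; ``groups`` maps each sample to its
    label (a GroupMap keyed by the series index, or an aligned label list).
    """
    if isinstance(values, pd.Series):
        labels = np.array(groups.labels_for(list(values.index))
                          if isinstance(groups, GroupMap) else list(groups))
        vals = values.to_numpy(dtype=float)
    else:
        vals = np.asarray(values, dtype=float)
        labels = np.asarray(list(groups))
    if np.ptp(vals) == 0:
        raise ValidationError("constant values: group comparison undefined")
    group_names = list(dict.fromkeys(labels))
    if len(group_names) < 2:
        raise ValidationError("need at least 2 groups")
    samples = [vals[labels == g] for g in group_names]
    if min(len(s) for s in samples) < 3:
        raise ValidationError("every group needs n >= 3")

    normal = all(np.ptp(s) > 0 and stats.shapiro(s).pvalue > alpha for s in samples)
    if normal:
        stat, p = stats.f_oneway(*samples)
        method = "anova"
    else:
        stat, p = stats.kruskal(*samples)
        method = "kruskal"
    pairwise = _dunn_pairwise(vals, labels, group_names)
    different = {(r.group_a, r.group_b) for r in pairwise.itertuples()
                 if r.p_adjusted < alpha}
    # no pairwise claims when the omnibus is not significant
    if p >= alpha:
        different = set()
    letters = _letter_display(group_names, different)
    return GroupComparison(method, float(stat), float(p), pairwise, letters)


# ---------------------------------------------------------------------------
# beta-diversity clustering

@dataclass
class BetaClustering:
    group_names: list[str]
    distance: np.ndarray      # condensed
    linkage_matrix: np.ndarray
    newick: str

    def distance_square(self) -> pd.DataFrame:
        return pd.DataFrame(squareform(self.distance),
                            index=self.group_names, columns=self.group_names)


def _to_newick(Z: np.ndarray, names: list[str]) -> str:
    tree = to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left, right = node.get_left(), node.get_right()
        lb = node.dist - left.dist if not left.is_leaf() else node.dist
        rb = node.dist - right.dist if not right.is_leaf() else node.dist
        return f"({rec(left)}:{lb:g},{rec(right)}:{rb:g})"

    return rec(tree) + ";"


def beta_cluster(m: IncidenceMatrix, groups: GroupMap,
                 method: str = "complete") -> BetaClustering:
    """Agglomerative clustering of per-group pooled incidence vectors.

    A genus counts as present in a group when it occurs in at least one of
    the group's samples; groups are compared by Euclidean distance of these
    pooled presence/absence vectors.
    """
    labels = np.array(groups.labels_for(m.sample_ids))
    group_names = list(dict.fromkeys(labels))
    if len(group_names) < 2:
        raise ValidationError("beta clustering needs at least 2 groups")
    pooled = np.vstack([(m.presence[labels == g].sum(axis=0) > 0).astype(float)
                        for g in group_names])
    d = pdist(pooled, metric="euclidean")
    Z = linkage(d, method=method)
    if np.any(np.diff(Z[:, 2]) < -1e-9):
        raise ValidationError(f"non-monotone merge heights with linkage {method!r}")
    return BetaClustering(group_names, d, Z, _to_newick(Z, group_names))


# ---------------------------------------------------------------------------
# random-forest indicator genera

@dataclass
class IndicatorReport:
    importance: pd.Series       # mean decrease in node impurity, per genus
    selected: pd.Series         # bool, top ceil(fraction * n_genera)
    confusion_matrix: pd.DataFrame
    oob_accuracy: float
    permutation_importance: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"importance": self.importance, "selected": self.selected})
        if self.permutation_importance is not None:
            df["permutation_importance"] = self.permutation_importance
        return df.sort_values("importance", ascending=False)


def indicator_genera(table: SiteTaxonTable, groups: GroupMap, n_trees: int = 131,
                     top_fraction: float = 0.10, seed: int = 0,
                     n_permutations: int | None = None) -> IndicatorReport:
    """Random-forest ranking of genera that discriminate the groups.

    A classifier of group labels from genus abundances is fitted; genera are
    ranked by mean decrease in Gini impurity and the top
    ``ceil(top_fraction * n_genera)`` flagged as indicators.  Validation uses
    out-of-bag predictions summarized as a confusion matrix and accuracy.
    Permutation importance (``n_permutations`` shuffles per genus) can be
    reported alongside; selection always uses the impurity ranking.
    """
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    labels = np.array(groups.labels_for(table.sample_ids))
    names, counts = np.unique(labels, return_counts=True)
    if len(names) < 2:
        raise ValidationError("need at least 2 groups")
    if counts.min() < 2:
        small = names[counts.argmin()]
        raise ValidationError(f"group {small!r} has fewer than 2 samples")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=int(seed) % (2**31),
                                oob_score=True, bootstrap=True)
    X, y = table.counts, labels
    rf.fit(X, y)
    importance = pd.Series(rf.feature_importances_, index=table.taxon_ids,
                           name="mean_decrease_gini")
    k = ceil(top_fraction * len(table.taxon_ids))
    top = importance.sort_values(ascending=False, kind="stable").index[:k]
    selected = pd.Series(importance.index.isin(top), index=importance.index, name="selected")

    oob_votes = rf.oob_decision_function_
    voted = ~np.isnan(oob_votes).any(axis=1) & (oob_votes.sum(axis=1) > 0)
    pred = rf.classes_[np.argmax(oob_votes[voted], axis=1)]
    cm = _sk_confusion(y[voted], pred, labels=list(names))
    cm_df = pd.DataFrame(cm, index=list(names), columns=list(names))
    acc = float((pred == y[voted]).mean()) if voted.any() else float("nan")

    perm = None
    if n_permutations:
        res = permutation_importance(rf, X, y, n_repeats=n_permutations,
                                     random_state=int(seed) % (2**31))
        perm = pd.Series(res.importances_mean, index=table.taxon_ids,
                         name="permutation_importance")
    return IndicatorReport(importance, selected, cm_df, acc, perm)
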