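"""Canonical correspondence analysis linking community variation to environment.

CCA constrains correspondence-analysis axes to be linear combinations of the
(standardized) environmental variables: the chi-square residual matrix is
projected, with row-mass weighting, onto the column space of the environment
matrix and the dominant axis of the fitted values is extracted.  Per-variable
axis-1 *loadings* — row-weighted Pearson correlations between each variable
and the community-derived (weighted-average) site scores — measure how
strongly each water-quality variable tracks the community gradient;
|loading| above a threshold (0.5 by default) flags a variable as important.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix_io import EnvTable, GroupMap, SiteTaxonTable, ValidationError

_CONDITION_LIMIT = 1e8


@dataclass
class CCAResult:
    """Axis-1 constrained ordination with per-variable loadings."""

    sample_ids: list[str]
    variables: list[str]
    site_scores_lc: np.ndarray
    site_scores_wa: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray  # axis-1 weighted correlation per variable (WA scores)
    group: str = "ALL"

    @property
    def eigenvalue_1(self) -> float:
        return float(self.eigenvalues[0])

    def loadings_series(self) -> pd.Series:
        return pd.Series(self.loadings, index=self.variables, name=self.group)


def _weighted_standardize(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    mu = w @ X
    Xc = X - mu
    sd = np.sqrt(w @ Xc**2)
    if np.any(sd == 0):
        return Xc, sd  # caller raises with variable names
    return Xc / sd, sd


def cca(community: SiteTaxonTable, env: EnvTable, hellinger: bool = False,
        group: str = "ALL") -> CCAResult:
    """Constrained correspondence analysis of abundances on environment.

    Community input is the abundance table (untransformed by default;
    ``hellinger`` applies the Hellinger transform first).  Axis orientation
    is fixed so the variable with the largest |loading| loads positively.
    """
    if community.sample_ids != env.sample_ids:
        raise ValidationError("community and environment tables have mismatched samples")
    Y = np.asarray(community.counts, dtype=float)
    if hellinger:
        rs = Y.sum(axis=1, keepdims=True)
        Y = np.sqrt(np.where(rs > 0, Y / np.where(rs == 0, 1, rs), 0))
    keep_rows = Y.sum(axis=1) > 0
    if not keep_rows.all():
        warnings.warn(f"dropping {int((~keep_rows).sum())} empty community rows from CCA",
                      stacklevel=2)
    keep_cols = Y.sum(axis=0) > 0
    Y = Y[np.ix_(keep_rows, keep_cols)]
    sample_ids = [s for s, k in zip(community.sample_ids, keep_rows) if k]
    X = np.asarray(env.values, dtype=float)[keep_rows]
    n, q = X.shape
    if n <= q + 1:
        raise ValidationError(f"need more than {q + 1} samples for {q} variables, got {n}")

    total = Y.sum()
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))

    Xs, sd = _weighted_standardize(X, r)
    if np.any(sd <= 1e-12 * np.maximum(1.0, np.abs(r @ X))):
        bad = [env.variables[j] for j in
               np.nonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(r @ X)))[0]]
        raise ValidationError(f"zero-variance environment variables: {bad}")
    Xw = np.sqrt(r)[:, None] * Xs
    G = Xw.T @ Xw
    cond = np.linalg.cond(G)
    if cond > _CONDITION_LIMIT:
        vif = np.diag(np.linalg.pinv(np.corrcoef(Xs, rowvar=False)))
        order = np.argsort(vif)[::-1]
        aliased = [f"{env.variables[j]} (VIF {vif[j]:.3g})" for j in order[:3]]
        raise ValidationError(
            f"collinear environment matrix (condition number {cond:.3g}); "
            f"highest variance inflation: {aliased}")
    B = np.linalg.solve(G, Xw.T @ S)
    fitted = Xw @ B
    U, sv, Vt = np.linalg.svd(fitted, full_matrices=False)
    rank = int(np.sum(sv > 1e-12))
    eigenvalues = sv[:rank] ** 2
    lc = U[:, 0] / np.sqrt(r)  # standard coordinates of the constrained axis
    wa = (S @ Vt[0]) / np.sqrt(r) / sv[0] if sv[0] > 0 else np.zeros(n)

    # loadings: row-weighted correlation of each variable with the
    # community-derived (WA) axis-1 scores.  Correlating with the LC scores
    # instead is uninformative: the LC axis lies in the span of the
    # environment matrix, so even pure-noise variables load heavily on it.
    wa_c = wa - r @ wa
    wa_sd = np.sqrt(r @ wa_c**2)
    if wa_sd == 0:
        raise ValidationError("degenerate constrained axis: no community variance")
    loadings = (Xs * np.sqrt(r)[:, None]).T @ (np.sqrt(r) * wa_c) / wa_sd
    flip = 1.0
    if loadings[np.argmax(np.abs(loadings))] < 0:
        flip = -1.0
    return CCAResult(sample_ids, list(env.variables), flip * lc, flip * wa,
                     eigenvalues, flip * loadings, group=group)


def loadings_table(r: CCAResult, threshold: float = 0.5) -> pd.DataFrame:
    """Axis-1 loadings with an importance flag for |loading| > threshold."""
    if not (0 < threshold <= 1):
        raise ValidationError("threshold must be in (0, 1]")
    return pd.DataFrame({
        "loading": r.loadings,
        "important": np.abs(r.loadings) > threshold,
    }, index=r.variables)


def correlate_rank_axis(site_ranks: pd.Series | np.ndarray, r: CCAResult,
                        normality_alpha: float = 0.05,
                        scores: str = "wa") -> tuple[float, float, str]:
    """Correlate EMS site ranks with CCA axis-1 site scores.

    Uses the WA (community-derived) site scores by default — the scores
    ordination software displays for sites — with ``scores="lc"`` for the
    linear-combination scores, which carry the environment measurement
    noise and therefore correlate systematically lower.  Shapiro-Wilk on
    both inputs gates the method: Pearson when both pass normality at
    ``normality_alpha``, Spearman otherwise.  Returns
    (coefficient, p, method).
    """
    axis = r.site_scores_lc if scores == "lc" else r.site_scores_wa
    if isinstance(site_ranks, pd.Series):
        site_ranks = site_ranks.loc[r.sample_ids].to_numpy()
    ranks = np.asarray(site_ranks, dtype=float)
    if len(ranks) != len(axis):
        raise ValidationError("rank vector does not match CCA samples")
    if len(ranks) < 4:
        raise ValidationError("need at least 4 samples to correlate")
    normal = (stats.shapiro(ranks).pvalue > normality_alpha
              and stats.shapiro(axis).pvalue > normality_alpha)
    if normal:
        res = stats.pearsonr(ranks, axis)
        return float(res.statistic), float(res.pvalue), "pearson"
    res = stats.spearmanr(ranks, axis)
    return float(res.statistic), float(res.pvalue), "spearman"


def per_group_cca(community: SiteTaxonTable, env: EnvTable, groups: GroupMap,
                  hellinger: bool = False, include_pooled: bool = True) -> list[CCAResult]:
    """CCA per group label (plus pooled "ALL"); undersized groups are skipped."""
    from .matrix_io import _env_subset, _table_subset

    results: list[CCAResult] = []
    if include_pooled:
        results.append(cca(community, env, hellinger=hellinger, group="ALL"))
    labels = groups.labels_for(community.sample_ids)
    for g in groups.groups():
        keep = [s for s, lab in zip(community.sample_ids, labels) if lab == g]
        if len(keep) <= len(env.variables) + 1:
            warnings.warn(f"group {g!r} has too few samples ({len(keep)}) for CCA; skipped",
                          stacklevel=2)
            continue
        sub_c = _table_subset(community, keep)
        sub_e = _env_subset(env, keep)
        results.append(cca(sub_c, sub_e, hellinger=hellinger, group=g))
    return results


def loadings_matrix(results: list[CCAResult], threshold: float = 0.5) -> pd.DataFrame:
    """Variables x groups matrix of axis-1 loadings (report-table layout)."""
    df = pd.concat([r.loadings_series() for r in results], axis=1)
    df.attrs["threshold"] = threshold
    return df
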