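"""Reciprocal averaging (correspondence analysis) of incidence matrices.

The first non-trivial CA axis is the latent gradient on which all
elements-of-metacommunity-structure statistics are evaluated: the matrix is
re-ordered by ascending site and taxon scores and range-based statistics are
read off the ordered matrix.

The axis is computed by singular value decomposition of the chi-square
standardized matrix ``(P - r c^T) / sqrt(r c)`` where ``P`` is the matrix of
relative frequencies and ``r``, ``c`` its row and column masses.  This is
numerically identical (up to sign) to the fixed point of the classical
reciprocal-averaging iteration, which is kept available as an independent
cross-check (:func:`reciprocal_averaging_power`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import iqr

from .matrix_io import GroupMap, IncidenceMatrix, ValidationError

_RANK_TOL = 1e-10


@dataclass
class CAResult:
    """First non-trivial correspondence axis of an incidence matrix.

    ``site_scores`` and ``taxon_scores`` are standard coordinates (weighted
    mean 0, weighted variance 1 with masses as weights); ``eigenvalue_1`` is
    the squared first non-trivial singular value, in (0, 1].
    """

    site_scores: np.ndarray
    taxon_scores: np.ndarray
    eigenvalue_1: float
    axis_orientation: int = 1  # +1 as computed, -1 if flipped for the convention


@dataclass
class OrdinatedMatrix:
    """Incidence matrix with rows/columns sorted by ascending CA scores."""

    presence: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    site_order: np.ndarray  # permutation of original row indices
    taxon_order: np.ndarray
    site_rank: np.ndarray   # rank 1..n of each *original* row along the axis

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence, index=self.sample_ids, columns=self.taxon_ids)


def _chi_square_residuals(pres: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    total = pres.sum()
    P = pres / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return S, r, c


def reciprocal_averaging(m: IncidenceMatrix) -> CAResult:
    """First non-trivial correspondence axis of ``m``.

    Requires a non-degenerate matrix with at least two rows and columns and
    a genuine gradient axis (first non-trivial singular value > 0).

    Orientation is fixed so the first input-order site scores no higher than
    the last input-order site; ranking statistics downstream are invariant
    to this choice but reproducibility requires fixing it.
    """
    pres = np.asarray(m.presence, dtype=float)
    if pres.shape[0] < 2 or pres.shape[1] < 2:
        raise ValidationError("reciprocal averaging needs at least 2 sites and 2 taxa")
    if (pres.sum(axis=1) == 0).any() or (pres.sum(axis=0) == 0).any():
        raise ValidationError("matrix has zero margins; run drop_degenerate first")
    S, r, c = _chi_square_residuals(pres)
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    if sv[0] <= _RANK_TOL:
        raise ValidationError("no gradient axis: matrix is structurally rank deficient")
    site = U[:, 0] / np.sqrt(r)
    taxon = Vt[0] / np.sqrt(c)
    orientation = 1
    if site[0] > site[-1]:
        site, taxon, orientation = -site, -taxon, -1
    # disconnected blocks give eigenvalue exactly 1; clamp rounding overshoot
    return CAResult(site, taxon, min(float(sv[0] ** 2), 1.0), orientation)


def reciprocal_averaging_power(m: IncidenceMatrix, max_iter: int = 10_000,
                               tol: float = 1e-12) -> CAResult:
    """Classical iterative reciprocal averaging (power iteration).

    Site scores are repeatedly set to the weighted average of the scores of
    the taxa they hold, and vice versa, renormalizing each round; the fixed
    point is the dominant non-trivial axis.  Kept as an independent check of
    :func:`reciprocal_averaging`.
    """
    pres = np.asarray(m.presence, dtype=float)
    rt = pres.sum(axis=1)
    ct = pres.sum(axis=0)
    r = rt / rt.sum()
    n = pres.shape[0]
    x = np.cos(np.linspace(0.0, 3.0, n))  # fixed start, not axis-aligned
    x -= (r * x).sum()
    x /= np.sqrt((r * x**2).sum())
    ev = 0.0
    for _ in range(max_iter):
        y = pres.T @ x / ct          # taxon scores = averages of site scores
        x_new = pres @ y / rt        # site scores = averages of taxon scores
        x_new -= (r * x_new).sum()   # project out the trivial axis
        norm = np.sqrt((r * x_new**2).sum())
        if norm == 0:
            raise ValidationError("no gradient axis: power iteration collapsed")
        ev = norm
        x_new /= norm
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    y = pres.T @ x / ct
    cmass = ct / ct.sum()
    y -= (cmass * y).sum()
    y /= np.sqrt((cmass * y**2).sum())
    orientation = 1
    if x[0] > x[-1]:
        x, y, orientation = -x, -y, -1
    return CAResult(x, y, min(float(ev), 1.0), orientation)


def order_matrix(m: IncidenceMatrix, ca: CAResult) -> OrdinatedMatrix:
    """Sort rows and columns by ascending CA scores (stable in original index)."""
    if len(ca.site_scores) != m.shape[0] or len(ca.taxon_scores) != m.shape[1]:
        raise ValidationError("CA result does not match matrix dimensions")
    site_order = np.argsort(ca.site_scores, kind="stable")
    taxon_order = np.argsort(ca.taxon_scores, kind="stable")
    rank = np.empty(m.shape[0], dtype=int)
    rank[site_order] = np.arange(1, m.shape[0] + 1)
    return OrdinatedMatrix(
        presence=m.presence[np.ix_(site_order, taxon_order)],
        sample_ids=[m.sample_ids[i] for i in site_order],
        taxon_ids=[m.taxon_ids[j] for j in taxon_order],
        site_order=site_order,
        taxon_order=taxon_order,
        site_rank=rank,
    )


def ordinate(m: IncidenceMatrix) -> OrdinatedMatrix:
    """Convenience: reciprocal averaging followed by matrix ordering."""
    return order_matrix(m, reciprocal_averaging(m))


def rank_site_scores(ca: CAResult, groups: GroupMap | None = None,
                     sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Dense ranks 1..n of site scores with optional per-group summaries.

    Ties receive ranks in original-index order (stable), so ranks are always
    a permutation of 1..n.  Returns a frame with columns ``score``, ``rank``
    and, when groups are given, ``group``; per-group medians/IQRs are
    attached as ``.attrs["group_summary"]``.
    """
    scores = np.asarray(ca.site_scores, dtype=float)
    order = np.argsort(scores, kind="stable")
    rank = np.empty(len(scores), dtype=int)
    rank[order] = np.arange(1, len(scores) + 1)
    idx = sample_ids if sample_ids is not None else list(range(len(scores)))
    out = pd.DataFrame({"score": scores, "rank": rank}, index=idx)
    if groups is not None:
        if sample_ids is None:
            raise ValidationError("grouped ranking requires sample ids")
        out["group"] = groups.labels_for(sample_ids)
        summary = out.groupby("group")["rank"].agg(
            median="median", iqr=lambda s: iqr(s), n="count")
        out.attrs["group_summary"] = summary
    return out
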