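"""Elements of metacommunity structure: coherence, turnover, boundary clumping.

The three statistics are evaluated on the incidence matrix ordered by its
first reciprocal-averaging axis:

* **coherence** — the number of embedded absences (gaps strictly inside a
  taxon's, and by default also a site's, occupied range);
* **turnover** — the number of pairwise species replacements on the
  range-filled matrix, ``Rep = sum over taxon pairs of
  (#sites with i only) x (#sites with j only)``;
* **boundary clumping** — Morisita's index of dispersion of range-boundary
  counts across sites, with its chi-square test against an equiprobable
  distribution of boundaries.

Coherence is referred to a fixed-fixed (R1) null model: random binary
matrices preserving both row and column totals, each independently
re-ordinated before the statistic is evaluated (burn-in and thinning are
counted on the proposal clock; see :mod:`algalmeta._swaps`).  Turnover is
referred, by
default, to the classical range-shift null: each taxon keeps its range size
but the range is placed uniformly at random along the ordination axis.  (A
fixed-fixed turnover null is available, but it is degenerate for strongly
nested matrices: a perfect staircase matrix contains no swappable 2x2
checkerboard and is the *only* matrix with its margins, so the null
distribution collapses.)  The z statistic follows the
``z = (sim_mean - observed) / sim_sd`` convention, so positive coherence z
means fewer embedded absences than expected (a coherent metacommunity) and
negative turnover z means more replacements than expected (a gradient).

The classification tree assigns one of the idealized structures
(checkerboard, random, nested, evenly spaced, Gleasonian, Clementsian, with
nested sub-modes and quasi- variants) from the three components.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from ._swaps import _has_checkerboard_unit, _sample_chain
from .matrix_io import IncidenceMatrix, ValidationError, drop_degenerate
from .ordination import OrdinatedMatrix, ordinate

Statistic = Literal["embedded_absences", "replacements"]
AbsenceMode = Literal["both_axes", "columns_only"]


@dataclass
class NullModelConfig:
    """Configuration of the fixed-fixed swap null.

    ``burn_in`` and ``thin`` count proposal steps of the swap chain (the
    proposal clock keeps snapshots exactly uniform; clocks based on accepted
    swaps oversample swap-rich states).  When left ``None`` they default to
    80x and 40x the cell count of the matrix being randomized — enough, on
    an enumerable 4x4 class, for successive draws to pass a chi-square
    uniformity test across seeds.  ``turnover_null`` selects the
    replacement-statistic null: ``"range_shift"`` (default) or
    ``"fixed_fixed"``.
    """

    seed: int
    n_sims: int = 1000
    algorithm: str = "fixed_fixed_swap"
    burn_in: int | None = None
    thin: int | None = None
    turnover_null: str = "range_shift"

    def __post_init__(self) -> None:
        if self.n_sims < 2:
            raise ValidationError("n_sims must be >= 2")
        if (self.burn_in is not None and self.burn_in < 0) or (
                self.thin is not None and self.thin < 0):
            raise ValidationError("burn_in and thin must be >= 0")
        if self.algorithm != "fixed_fixed_swap":
            raise ValidationError(f"unknown null algorithm {self.algorithm!r}")
        if self.turnover_null not in ("range_shift", "fixed_fixed"):
            raise ValidationError(f"unknown turnover null {self.turnover_null!r}")


@dataclass
class NullDistribution:
    observed: float
    sims: np.ndarray
    sim_mean: float = field(init=False)
    sim_sd: float = field(init=False)
    z: float = field(init=False)
    p_normal: float = field(init=False)
    p_empirical: float = field(init=False)

    def __post_init__(self) -> None:
        self.sims = np.asarray(self.sims, dtype=float)
        self.sim_mean = float(self.sims.mean())
        self.sim_sd = float(self.sims.std(ddof=1))
        if self.sim_sd == 0:
            raise ValidationError(
                "zero null variance: all simulated statistics identical "
                f"(value {self.sims[0]}); margins may force a unique matrix")
        self.z = zscore(self.observed, self.sim_mean, self.sim_sd)
        self.p_normal = float(2 * stats.norm.sf(abs(self.z)))
        dev = abs(self.observed - self.sim_mean)
        n = len(self.sims)
        self.p_empirical = float((1 + np.sum(np.abs(self.sims - self.sim_mean) >= dev)) / (n + 1))


def zscore(observed: float, sim_mean: float, sim_sd: float) -> float:
    """z = (sim_mean - observed) / sim_sd.

    With this convention a coherent matrix (fewer embedded absences than the
    null) has positive coherence z, and a high-turnover matrix has negative
    turnover z.
    """
    return float((sim_mean - observed) / sim_sd)


# ---------------------------------------------------------------------------
# range statistics on the ordered matrix

def _embedded_in_columns(a: np.ndarray) -> int:
    """Zeros strictly between the first and last 1 of each column, summed."""
    a = np.asarray(a)
    if a.size == 0:
        return 0
    n = a.shape[0]
    occupied = a.any(axis=0)
    if not occupied.any():
        return 0
    first = a.argmax(axis=0)
    last = n - 1 - a[::-1].argmax(axis=0)
    span = last - first + 1
    gaps = span - a.sum(axis=0)
    return int(gaps[occupied].sum())


def count_embedded_absences(om: OrdinatedMatrix | np.ndarray,
                            mode: AbsenceMode = "both_axes") -> int:
    """Embedded absences of an ordered matrix (columns, plus rows by default)."""
    a = om.presence if isinstance(om, OrdinatedMatrix) else np.asarray(om)
    total = _embedded_in_columns(a)
    if mode == "both_axes":
        total += _embedded_in_columns(a.T)
    elif mode != "columns_only":
        raise ValidationError(f"unknown embedded-absence mode {mode!r}")
    return total


def fill_ranges(om: OrdinatedMatrix | np.ndarray) -> np.ndarray:
    """Make every column's range contiguous by filling its embedded absences."""
    a = np.array(om.presence if isinstance(om, OrdinatedMatrix) else om, dtype=np.int8)
    n = a.shape[0]
    for j in range(a.shape[1]):
        col = a[:, j]
        if col.any():
            first = int(col.argmax())
            last = n - 1 - int(col[::-1].argmax())
            a[first:last + 1, j] = 1
    return a


def count_replacements(filled: np.ndarray) -> int:
    """Pairwise species replacements Rep on a range-filled ordered matrix."""
    f = np.asarray(filled, dtype=np.int64)
    co = f.T @ f                      # co-occurrence counts per taxon pair
    s = f.sum(axis=0)
    only_i = s[:, None] - co          # sites with i but not j
    rep = only_i * only_i.T           # (i only) x (j only)
    iu = np.triu_indices(f.shape[1], k=1)
    return int(rep[iu].sum())


# ---------------------------------------------------------------------------
# fixed-fixed null model

def _resolve_swaps(m: IncidenceMatrix, cfg: NullModelConfig) -> tuple[int, int]:
    cells = int(m.presence.size)
    burn_in = cfg.burn_in if cfg.burn_in is not None else 80 * cells
    thin = cfg.thin if cfg.thin is not None else 40 * cells
    return burn_in, thin


def generate_null_matrices(m: IncidenceMatrix, cfg: NullModelConfig) -> list[IncidenceMatrix]:
    """Draw ``cfg.n_sims`` fixed-fixed null matrices (both margins preserved).

    If the margins admit no checkerboard swap the matrix class is a
    singleton: a warning is issued and all draws equal the input.
    """
    base = drop_degenerate(m)  # nulls inherit the non-degenerate core
    work = np.array(base.presence, dtype=np.int8)
    burn_in, thin = _resolve_swaps(base, cfg)
    out = np.empty((cfg.n_sims, *work.shape), dtype=np.int8)
    accepted = _sample_chain(work, burn_in, thin, cfg.n_sims,
                             int(cfg.seed) % (2**31 - 1), out)
    if accepted == 0 and (burn_in + thin) > 0:
        if not _has_checkerboard_unit(np.array(base.presence, dtype=np.int8)):
            warnings.warn("margins force a unique matrix; null draws equal the input",
                          stacklevel=2)
        else:
            raise ValidationError("swap chain failed to mix within the attempt cap")
    return [IncidenceMatrix(base.sample_ids, base.taxon_ids, out[k])
            for k in range(cfg.n_sims)]


def shift_ranges_null(filled: np.ndarray, n_sims: int, seed: int) -> np.ndarray:
    """Replacement counts under the range-shift null.

    Each taxon's contiguous range on the ordered axis keeps its length but
    is placed uniformly at random; ``Rep`` is evaluated on each shifted
    matrix.  Returns the vector of simulated replacement counts.
    """
    f = np.asarray(filled, dtype=np.int8)
    n, t = f.shape
    lengths = f.sum(axis=0)
    rng = np.random.default_rng((int(seed), 389))
    sims = np.empty(n_sims)
    shifted = np.zeros_like(f)
    for k in range(n_sims):
        shifted[:] = 0
        starts = rng.integers(0, n - lengths + 1)
        for j in range(t):
            shifted[starts[j]:starts[j] + lengths[j], j] = 1
        sims[k] = count_replacements(shifted)
    return sims


def _statistic_on(m: IncidenceMatrix, statistic: Statistic, mode: AbsenceMode) -> int:
    om = ordinate(drop_degenerate(m))
    if statistic == "embedded_absences":
        return count_embedded_absences(om, mode=mode)
    if statistic == "replacements":
        return count_replacements(fill_ranges(om))
    raise ValidationError(f"unknown statistic {statistic!r}")


def null_test(m: IncidenceMatrix, statistic: Statistic, cfg: NullModelConfig,
              mode: AbsenceMode = "both_axes",
              nulls: Sequence[IncidenceMatrix] | None = None) -> NullDistribution:
    """Null test of one statistic.

    Embedded absences are referred to fixed-fixed draws, each re-ordinated
    before evaluation; replacements use the range-shift null unless
    ``cfg.turnover_null == "fixed_fixed"``.  ``nulls`` allows sharing one
    set of fixed-fixed draws between statistics.
    """
    observed = _statistic_on(m, statistic, mode)
    if statistic == "replacements" and cfg.turnover_null == "range_shift":
        filled = fill_ranges(ordinate(drop_degenerate(m)))
        sims = shift_ranges_null(filled, cfg.n_sims, cfg.seed)
    else:
        if nulls is None:
            nulls = generate_null_matrices(m, cfg)
        sims = np.array([_statistic_on(nm, statistic, mode) for nm in nulls], dtype=float)
    return NullDistribution(float(observed), sims)


# ---------------------------------------------------------------------------
# boundary clumping

@dataclass
class BoundaryClumpResult:
    """Morisita's index of range-boundary dispersion with its chi-square test.

    ``p`` is the upper-tail probability of the chi-square statistic; the
    two-sided clumped/overdispersed decision is taken downstream in
    :func:`classify_structure`.
    """

    boundary_counts: np.ndarray
    morisita_I: float
    chi2: float
    df: int
    p: float


def boundary_clumping(om: OrdinatedMatrix | np.ndarray) -> BoundaryClumpResult:
    """Morisita's I on the counts of range starts+ends per site.

    Each taxon contributes one range start and one range end (a single-site
    range contributes both at that site).  With counts ``x_i`` over ``n``
    sites and ``X = sum(x)``: ``I = n * sum(x(x-1)) / (X(X-1))``,
    ``chi2 = I*(X-1) + n - X``, ``df = n - 1``.
    """
    a = om.presence if isinstance(om, OrdinatedMatrix) else np.asarray(om)
    n = a.shape[0]
    counts = np.zeros(n, dtype=int)
    n_taxa_used = 0
    for j in range(a.shape[1]):
        col = a[:, j]
        if col.any():
            n_taxa_used += 1
            counts[int(col.argmax())] += 1
            counts[n - 1 - int(col[::-1].argmax())] += 1
    if n_taxa_used < 2:
        raise ValidationError("boundary clumping needs at least 2 occupied taxa")
    X = int(counts.sum())
    if X < 2:
        raise ValidationError("fewer than 2 range boundaries")
    I = n * float((counts * (counts - 1)).sum()) / (X * (X - 1))
    chi2 = I * (X - 1) + n - X
    df = n - 1
    p = float(stats.chi2.sf(chi2, df))
    return BoundaryClumpResult(counts, float(I), float(chi2), df, p)


# ---------------------------------------------------------------------------
# classification

_FAMILIES = ("Checkerboard", "Random", "Nested", "EvenlySpaced", "Gleasonian", "Clementsian")


@dataclass(frozen=True)
class StructureLabel:
    """Idealized metacommunity structure with optional nested mode and quasi flag."""

    family: str
    nested_mode: str | None = None
    quasi: bool = False

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(f"unknown structure family {self.family!r}")

    def __str__(self) -> str:
        name = "Evenly spaced" if self.family == "EvenlySpaced" else self.family
        if self.nested_mode:
            name = f"{name} ({self.nested_mode})"
        return f"Quasi-{name[0].lower()}{name[1:]}" if self.quasi else name


def classify_structure(coh: NullDistribution, tur: NullDistribution,
                       bc: BoundaryClumpResult, alpha: float = 0.05) -> StructureLabel:
    """Decision tree over coherence, turnover and boundary clumping.

    1. Coherence not significant -> Random; significant with more embedded
       absences than the null mean -> Checkerboard; otherwise continue.
    2. Turnover significant with fewer replacements than the null mean ->
       nested family; with more -> gradient family; non-significant -> the
       family picked by the sign of the deviation, flagged quasi.
    3. Morisita's I with a significant (two-sided at alpha) chi-square:
       I > 1 -> Clementsian / nested-clumped, I < 1 -> evenly spaced /
       nested-hyperdispersed; otherwise Gleasonian / nested-stochastic.

    Significance of the null tests uses the normal-approximation p, matching
    the +/-1.96 convention at alpha = 0.05.
    """
    if coh.p_normal >= alpha:
        return StructureLabel("Random")
    if coh.observed > coh.sim_mean:
        return StructureLabel("Checkerboard")

    dev = tur.observed - tur.sim_mean
    quasi = tur.p_normal >= alpha
    nested = dev < 0  # fewer replacements than expected; ties fall to gradient

    clumped = bc.p < alpha / 2 and bc.morisita_I > 1
    dispersed = (1 - bc.p) < alpha / 2 and bc.morisita_I < 1
    if nested:
        mode = "clumped" if clumped else ("hyperdispersed" if dispersed else "stochastic")
        return StructureLabel("Nested", nested_mode=mode, quasi=quasi)
    if clumped:
        return StructureLabel("Clementsian", quasi=quasi)
    if dispersed:
        return StructureLabel("EvenlySpaced", quasi=quasi)
    return StructureLabel("Gleasonian", quasi=quasi)


# ---------------------------------------------------------------------------
# one-shot analysis

@dataclass
class EMSResult:
    coherence: NullDistribution
    turnover: NullDistribution
    boundary: BoundaryClumpResult
    label: StructureLabel
    n_sites: int = 0
    n_taxa: int = 0

    def to_dict(self) -> dict:
        return {
            "abs": self.coherence.observed,
            "coherence_z": self.coherence.z,
            "coherence_p": self.coherence.p_normal,
            "coherence_p_empirical": self.coherence.p_empirical,
            "coherence_sim_mean": self.coherence.sim_mean,
            "coherence_sim_sd": self.coherence.sim_sd,
            "rep": self.turnover.observed,
            "turnover_z": self.turnover.z,
            "turnover_p": self.turnover.p_normal,
            "turnover_p_empirical": self.turnover.p_empirical,
            "turnover_sim_mean": self.turnover.sim_mean,
            "turnover_sim_sd": self.turnover.sim_sd,
            "morisita_index": self.boundary.morisita_I,
            "boundary_chi2": self.boundary.chi2,
            "boundary_p": self.boundary.p,
            "df": self.boundary.df,
            "structure": str(self.label),
            "n_sites": self.n_sites,
            "n_taxa": self.n_taxa,
        }

    def to_json(self, cfg: NullModelConfig | None = None) -> str:
        d = self.to_dict()
        d["coherence_sims"] = list(self.coherence.sims)
        d["turnover_sims"] = list(self.turnover.sims)
        if cfg is not None:
            d["null_config"] = {"seed": cfg.seed, "n_sims": cfg.n_sims,
                                "algorithm": cfg.algorithm,
                                "burn_in": cfg.burn_in, "thin": cfg.thin}
        return json.dumps(d, indent=1, sort_keys=True)


def _both_statistics(m: IncidenceMatrix, mode: AbsenceMode) -> tuple[int, int]:
    om = ordinate(drop_degenerate(m))
    return (count_embedded_absences(om, mode=mode),
            count_replacements(fill_ranges(om)))


def ems_analysis(m: IncidenceMatrix, cfg: NullModelConfig, alpha: float = 0.05,
                 mode: AbsenceMode = "both_axes") -> EMSResult:
    """Full EMS of one incidence matrix.

    Coherence uses fixed-fixed draws (one ordination per draw); turnover
    uses the range-shift null by default, or shares the fixed-fixed draws
    when ``cfg.turnover_null == "fixed_fixed"``.
    """
    core = drop_degenerate(m)
    om = ordinate(core)
    filled = fill_ranges(om)
    obs_abs = count_embedded_absences(om, mode=mode)
    obs_rep = count_replacements(filled)
    nulls = generate_null_matrices(core, cfg)
    if cfg.turnover_null == "range_shift":
        abs_sims = np.array([_statistic_on(nm, "embedded_absences", mode) for nm in nulls],
                            dtype=float)
        rep_sims = shift_ranges_null(filled, cfg.n_sims, cfg.seed)
    else:
        sims = np.array([_both_statistics(nm, mode) for nm in nulls], dtype=float)
        abs_sims, rep_sims = sims[:, 0], sims[:, 1]
    coh = NullDistribution(float(obs_abs), abs_sims)
    tur = NullDistribution(float(obs_rep), rep_sims)
    bc = boundary_clumping(om)
    label = classify_structure(coh, tur, bc, alpha=alpha)
    return EMSResult(coh, tur, bc, label, n_sites=core.shape[0], n_taxa=core.shape[1])
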