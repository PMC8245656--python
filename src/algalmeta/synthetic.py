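"""Generators of incidence matrices with known metacommunity structure.

Each generator places taxa along a latent gradient (equally spaced site
positions on [0, 1]) according to one idealized structure, flips a small
fraction of cells as observation noise, and then shuffles the site order so
that structure can only be recovered by ordination, never from input order.
Linked environment tables and abundance overlays give every downstream stage
(EMS, CCA, richness, random forest) a verifiable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix_io import (STANDARD_ENV_VARIABLES, EnvTable, GroupMap,
                        IncidenceMatrix, SiteTaxonTable, ValidationError)

STRUCTURES = ("clementsian", "gleasonian", "evenly_spaced", "nested",
              "checkerboard", "random")


@dataclass
class SyntheticScenario:
    """Parameters of one structured-matrix draw.

    ``noise`` is the per-cell flip probability that keeps matrices from
    being perfectly idealized; ``n_compartments`` applies to clementsian,
    ``range_width_mean``/``range_width_sd`` to gleasonian and evenly spaced,
    ``fill`` to the random structure and checkerboard leftovers.
    """

    structure: str
    n_sites: int = 40
    n_taxa: int = 25
    seed: int = 0
    n_compartments: int = 3
    range_width_mean: float = 0.35
    range_width_sd: float = 0.10
    fill: float = 0.30
    noise: float = 0.02
    nested_hole_prob: float = 0.20

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValidationError(f"unknown structure {self.structure!r}")
        if self.n_sites < 10 or self.n_taxa < 6:
            raise ValidationError("need n_sites >= 10 and n_taxa >= 6")
        if self.structure == "clementsian" and self.n_compartments > self.n_taxa:
            raise ValidationError("more compartments than taxa")


@dataclass
class SyntheticTruth:
    """Ground truth sufficient to recompute the noiseless matrix."""

    structure: str
    gradient: np.ndarray                     # latent position per (shuffled) site
    ranges: list[tuple[float, float]] | None  # per-taxon (start, end) on [0,1]
    noise: float
    linked_variables: list[str] = field(default_factory=list)


def _ranges_matrix(g: np.ndarray, ranges: list[tuple[float, float]]) -> np.ndarray:
    out = np.zeros((len(g), len(ranges)), dtype=np.int8)
    for j, (lo, hi) in enumerate(ranges):
        out[:, j] = ((g >= lo) & (g <= hi)).astype(np.int8)
    return out


def _checkerboard(n: int, t: int, fill: float, rng: np.random.Generator,
                  proposals_per_cell: int = 12) -> np.ndarray:
    """Plant checkerboard (anti-coherent) structure.

    In the EMS framework the checkerboard pattern is *defined* by its excess
    of embedded absences over the fixed-margin null, so the planted ideal is
    the anti-coherent extreme of a random margin class: starting from a
    Bernoulli(fill) matrix, margin-preserving 2x2 swaps are annealed
    (Metropolis, linearly cooled) to maximize the ordinated embedded-absence
    count.  Simple mutual-exclusion constructions (complementary or
    block-paired taxa) do not work: their exclusions can be laid out as
    prefix/suffix site intervals, which makes them *coherent*.

    Cell-flip noise is folded into the Bernoulli start rather than applied
    after annealing: the pattern is defined as an extreme of its (random)
    margin class, and post-hoc flips would only walk it back toward the
    class typical set, i.e. un-plant the structure.
    """
    from ._swaps import _anneal_incoherence

    mat = (rng.random((n, t)) < fill).astype(np.int8)
    for i in np.nonzero(mat.sum(axis=1) == 0)[0]:
        mat[i, rng.integers(t)] = 1
    for j in np.nonzero(mat.sum(axis=0) == 0)[0]:
        mat[rng.integers(n), j] = 1
    return _anneal_incoherence(mat, proposals_per_cell * n * t,
                               int(rng.integers(2**31 - 1)), 8.0)


def _build(scenario: SyntheticScenario, rng: np.random.Generator) -> tuple[np.ndarray, list | None]:
    n, t = scenario.n_sites, scenario.n_taxa
    g = np.linspace(0.0, 1.0, n)
    eps = 0.5 / n  # half a site spacing, so interval ends land on sites
    if scenario.structure == "clementsian":
        k = scenario.n_compartments
        bounds = np.linspace(0.0, 1.0, k + 1)
        ranges = [(bounds[j % k] - eps, bounds[j % k + 1] + eps) for j in range(t)]
        return _ranges_matrix(g, ranges), ranges
    if scenario.structure == "gleasonian":
        # centers drawn so ranges fit inside the gradient: truncation at the
        # ends would pile boundaries up there and mimic clumping
        widths = np.clip(rng.normal(scenario.range_width_mean,
                                    scenario.range_width_sd, t), 0.08, 0.96)
        centers = np.array([rng.uniform(w / 2, 1 - w / 2) for w in widths])
        ranges = [(c - w / 2, c + w / 2) for c, w in zip(centers, widths)]
        return _ranges_matrix(g, ranges), ranges
    if scenario.structure == "evenly_spaced":
        w = scenario.range_width_mean
        centers = w / 2 + (1 - w) * (np.arange(t) + 0.5) / t
        ranges = [(c - w / 2, c + w / 2) for c in centers]
        return _ranges_matrix(g, ranges), ranges
    if scenario.structure == "nested":
        # stochastically nested: ranges share the gradient-start anchor with
        # ordered widths, and cells inside a range drop out with probability
        # nested_hole_prob (anchor site always kept).  A perfect staircase
        # would be the unique matrix with its margins, which degenerates the
        # fixed-fixed null, and real nested communities are imperfect anyway.
        widths = np.linspace(1.0, 0.15, t)
        ranges = [(-eps, w) for w in widths]
        out = _ranges_matrix(g, ranges)
        if scenario.nested_hole_prob > 0:
            holes = rng.random(out.shape) < scenario.nested_hole_prob
            holes[0] = False  # anchor site keeps every taxon
            out = np.where(holes, 0, out).astype(np.int8)
        return out, ranges
    if scenario.structure == "checkerboard":
        return _checkerboard(n, t, scenario.fill, rng), None
    # random
    return (rng.random((n, t)) < scenario.fill).astype(np.int8), None


def make_structure(scenario: SyntheticScenario,
                   max_retries: int = 20) -> tuple[IncidenceMatrix, SyntheticTruth]:
    """Generate one structured incidence matrix with its ground truth.

    Sites never covered by any range (and taxa with no site) are dropped,
    exactly as a single degenerate-removal pass would; the matrix is
    regenerated (bounded retries, advancing the seed stream) if one pass
    does not suffice.  Site ids reflect the original gradient positions.
    """
    for attempt in range(max_retries):
        rng = np.random.default_rng((int(scenario.seed), attempt))
        mat, ranges = _build(scenario, rng)
        if scenario.noise > 0 and scenario.structure != "checkerboard":
            flips = rng.random(mat.shape) < scenario.noise
            mat = np.where(flips, 1 - mat, mat).astype(np.int8)
        perm = rng.permutation(scenario.n_sites)
        mat = mat[perm]
        g = np.linspace(0.0, 1.0, scenario.n_sites)[perm]
        keep_r = mat.sum(axis=1) > 0
        keep_c = mat.sum(axis=0) > 0
        sub = mat[np.ix_(keep_r, keep_c)]
        if sub.size and sub.sum(axis=1).min() > 0 and sub.sum(axis=0).min() > 0:
            sample_ids = [f"S{i + 1:03d}" for i in np.nonzero(keep_r)[0]]
            taxon_ids = [f"T{j + 1:02d}" for j in np.nonzero(keep_c)[0]]
            m = IncidenceMatrix(sample_ids, taxon_ids, sub)
            kept_ranges = ([rg for rg, k in zip(ranges, keep_c) if k]
                           if ranges is not None else None)
            return m, SyntheticTruth(scenario.structure, g[keep_r], kept_ranges,
                                     scenario.noise)
    raise ValidationError(
        f"could not generate a non-degenerate {scenario.structure} matrix "
        f"in {max_retries} attempts")


def make_env(truth: SyntheticTruth, k_linked: int = 1, k_noise: int = 3,
             noise_sd: float = 0.2, seed: int = 0,
             sample_ids: list[str] | None = None,
             linked_names: list[str] | None = None) -> EnvTable:
    """Environment table with gradient-linked and pure-noise variables.

    Linked variables are affine transforms of the latent gradient (slope of
    alternating sign) plus Gaussian noise of standard deviation ``noise_sd``
    (the gradient spans one unit, so 0.2 emulates the moderately noisy
    loadings seen for water-quality drivers).  Variable names echo the
    standard water-quality panel where counts permit.
    """
    if k_linked + k_noise < 1:
        raise ValidationError("need at least one environment variable")
    rng = np.random.default_rng((int(seed), 97))
    n = len(truth.gradient)
    total = k_linked + k_noise
    if linked_names is not None:
        if len(linked_names) != k_linked:
            raise ValidationError("linked_names must have k_linked entries")
        names = list(linked_names) + [v for v in STANDARD_ENV_VARIABLES
                                      if v not in linked_names][:k_noise]
        if len(names) < total:
            names += [f"var{i + 1}" for i in range(len(names), total)]
    elif total <= len(STANDARD_ENV_VARIABLES):
        names = list(STANDARD_ENV_VARIABLES[:total])
    else:
        names = [f"var{i + 1}" for i in range(total)]
    cols = []
    for i in range(k_linked):
        slope = 1.0 if i % 2 == 0 else -1.0
        cols.append(slope * truth.gradient + rng.normal(0, noise_sd, n))
    for _ in range(k_noise):
        cols.append(rng.normal(0, 1, n))
    values = np.column_stack(cols)
    truth.linked_variables = names[:k_linked]
    ids = sample_ids if sample_ids is not None else [f"S{i + 1:03d}" for i in range(n)]
    return EnvTable(ids, names, values)


def make_abundances(m: IncidenceMatrix, truth: SyntheticTruth,
                    seed: int = 0, sigma: float = 0.6) -> SiteTaxonTable:
    """Overlay log-normal cell densities on presences.

    Where a taxon has a known range, the log-mean decreases linearly with
    the site's distance from the range center, peaking at roughly 10^3
    cells per liter; structureless taxa get a flat log-mean.  Absences stay
    exactly zero so binarization round-trips.
    """
    rng = np.random.default_rng((int(seed), 131))
    n, t = m.shape
    mu = np.full((n, t), np.log(300.0))
    if truth.ranges is not None:
        for j, (lo, hi) in enumerate(truth.ranges):
            center = (lo + hi) / 2
            half = max((hi - lo) / 2, 1e-6)
            d = np.minimum(np.abs(truth.gradient - center) / half, 1.5)
            mu[:, j] = np.log(1000.0) - 1.5 * d
    counts = np.exp(rng.normal(mu, sigma)) * m.presence
    return SiteTaxonTable(m.sample_ids, m.taxon_ids, counts)


# ---------------------------------------------------------------------------
# the full monitoring-design scenario

LAKES = ("PD", "CP", "UM", "CC", "SY", "HC")
LAKE_REGION = {"PD": "Down", "CP": "Mid", "UM": "Mid", "CC": "Mid",
               "SY": "Up", "HC": "Up"}
_LAKE_CENTER = {"PD": 0.08, "CP": 0.32, "UM": 0.42, "CC": 0.52,
                "SY": 0.80, "HC": 0.92}
_YEARS = (2008, 2009, 2010, 2011, 2012, 2013, 2015, 2016)
_MONTHS = tuple(range(3, 12))


@dataclass
class StudyShapeData:
    """Six lakes x 72 monthly samples x 55 genera with 9 water-quality variables."""

    community: SiteTaxonTable
    env: EnvTable
    groups: GroupMap          # sample -> lake
    regions: GroupMap         # sample -> Up / Mid / Down
    truth: SyntheticTruth


def study_shape_scenario(seed: int = 0, noise: float = 0.02) -> StudyShapeData:
    """Synthetic analogue of the six-lake monitoring design.

    432 samples (6 lakes x 9 months x 8 years) x 55 genera, with three
    latent compartments along the river gradient (Down: PD; Mid: CP, UM,
    CC; Up: SY, HC) and nine environment variables of which conductivity,
    COD and BOD track the gradient.  The pooled community is Clementsian by
    construction.
    """
    rng = np.random.default_rng((int(seed), 7))
    sample_ids, lakes, meta_rows, gradient = [], [], [], []
    for lake in LAKES:
        for year in _YEARS:
            for month in _MONTHS:
                sample_ids.append(f"{lake}_{year}_{month:02d}")
                lakes.append(lake)
                meta_rows.append({"lake": lake, "year": year, "month": month})
                gradient.append(np.clip(_LAKE_CENTER[lake] + rng.normal(0, 0.05), 0, 1))
    gradient = np.array(gradient)
    n, t = len(sample_ids), 55

    # three compartments with shared boundaries at the region breaks
    bounds = (0.0, 0.20, 0.65, 1.0)
    ranges = [(bounds[j % 3] - 1e-9, bounds[j % 3 + 1] + 1e-9) for j in range(t)]
    mat = _ranges_matrix(gradient, ranges)
    flips = rng.random(mat.shape) < noise
    mat = np.where(flips, 1 - mat, mat).astype(np.int8)
    # monitoring data have no empty samples; give any all-zero row one genus
    for i in np.nonzero(mat.sum(axis=1) == 0)[0]:
        mat[i, rng.integers(t)] = 1
    for j in np.nonzero(mat.sum(axis=0) == 0)[0]:
        mat[rng.integers(n), j] = 1

    taxon_ids = [f"G{j + 1:02d}" for j in range(t)]
    m = IncidenceMatrix(sample_ids, taxon_ids, mat)
    truth = SyntheticTruth("clementsian", gradient, ranges, noise)
    env = make_env(truth, k_linked=3, k_noise=6, noise_sd=0.2, seed=seed,
                   sample_ids=sample_ids,
                   linked_names=["conductivity", "COD", "BOD"])
    table = make_abundances(m, truth, seed=seed)
    table.meta = pd.DataFrame(meta_rows, index=sample_ids)
    groups = GroupMap(dict(zip(sample_ids, lakes)))
    regions = GroupMap({s: LAKE_REGION[lk] for s, lk in zip(sample_ids, lakes)})
    return StudyShapeData(table, env, groups, regions, truth)
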