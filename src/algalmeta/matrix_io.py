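"""Reading, validation, aggregation and binarization of community tables.

The canonical orientation throughout the package is rows = samples/sites,
columns = taxa (the site-by-species matrix of community ecology).  Community
tables are cell-density counts (cells per liter); environment tables carry
the water-quality variables measured alongside each sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Water-quality variables of the monitoring design this package targets.
STANDARD_ENV_VARIABLES = (
    "temperature",
    "conductivity",
    "pH",
    "BOD",
    "COD",
    "TN",
    "NH4",
    "TP",
    "PO4",
)


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    for i, x in enumerate(ids):
        if x in seen:
            raise ValidationError(f"duplicate {what} {x!r} (positions {seen[x]} and {i})")
        seen[x] = i


@dataclass
class SiteTaxonTable:
    """Sample-by-taxon abundance matrix with identifiers and optional metadata.

    Parameters
    ----------
    sample_ids, taxon_ids
        Ordered, unique identifiers for rows and columns.
    counts
        Non-negative, finite float matrix of shape ``(n_samples, n_taxa)``.
    meta
        Optional per-sample attribute frame (e.g. lake, year, month), indexed
        like ``sample_ids``.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if not np.all(np.isfinite(self.counts)):
            bad = np.argwhere(~np.isfinite(self.counts))[0]
            raise ValidationError(
                f"non-finite count at sample {self.sample_ids[bad[0]]!r}, taxon {self.taxon_ids[bad[1]]!r}"
            )
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, taxon {self.taxon_ids[bad[1]]!r}"
            )
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.taxon_ids, "taxon id")
        if self.meta is not None:
            self.meta = self.meta.loc[[*self.sample_ids]]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: pd.DataFrame | None = None) -> "SiteTaxonTable":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(dtype=float), meta)


@dataclass
class IncidenceMatrix:
    """Binary presence/absence matrix derived from a :class:`SiteTaxonTable`."""

    sample_ids: list[str]
    taxon_ids: list[str]
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.presence = np.asarray(self.presence)
        if not np.isin(self.presence, (0, 1)).all():
            raise ValidationError("presence entries must be 0 or 1")
        self.presence = self.presence.astype(np.int8)
        if self.presence.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError("presence shape does not match id lists")
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.taxon_ids, "taxon id")

    @property
    def shape(self) -> tuple[int, int]:
        return self.presence.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence, index=self.sample_ids, columns=self.taxon_ids)


@dataclass
class EnvTable:
    """Per-sample environmental measurements (one row per community sample)."""

    sample_ids: list[str]
    variables: list[str]
    values: np.ndarray
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variables = [str(v) for v in self.variables]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.variables)):
            raise ValidationError("env values shape does not match id lists")
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.variables, "variable name")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.variables)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, units: dict[str, str] | None = None) -> "EnvTable":
        return cls(list(map(str, df.index)), list(map(str, df.columns)),
                   df.to_numpy(dtype=float), units or {})


@dataclass
class GroupMap:
    """Mapping from sample id to a single group label (lake, region, ...)."""

    labels: dict[str, str]

    def __getitem__(self, sample_id: str) -> str:
        return self.labels[sample_id]

    def labels_for(self, sample_ids: Sequence[str]) -> list[str]:
        missing = [s for s in sample_ids if s not in self.labels]
        if missing:
            raise ValidationError(f"samples without a group label: {missing[:5]}")
        return [self.labels[s] for s in sample_ids]

    def groups(self) -> list[str]:
        out: list[str] = []
        for g in self.labels.values():
            if g not in out:
                out.append(g)
        return out

    @classmethod
    def read(cls, path: str | Path) -> "GroupMap":
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
        if df.shape[1] < 2:
            raise ValidationError("group map needs two columns: sample id, group label")
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.labels), "group": list(self.labels.values())}
        ).to_csv(path, index=False)


def _sep_for(path: str | Path, dialect: str | None = None) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def _read_checked(path: str | Path, dialect: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path, dialect)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    cols = header[1:]
    if len(set(cols)) != len(cols):
        dup = next(c for c in cols if cols.count(c) > 1)
        raise ValidationError(f"duplicate column {dup!r} in {path}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.map(str)
    df.columns = [str(c) for c in cols]
    return df


def read_site_taxon_table(path: str | Path, dialect: str | None = None,
                          transpose: bool = False) -> SiteTaxonTable:
    """Read a community table: first column sample ids, header row taxon ids.

    ``dialect`` forces ``"csv"`` or ``"tsv"``; by default the separator is
    inferred from the extension (tab for .tsv/.tab/.txt, comma otherwise).
    ``transpose`` flips a taxon-by-sample file into canonical orientation.
    """
    df = _read_checked(path, dialect)
    if transpose:
        df = df.T
    try:
        return SiteTaxonTable.from_frame(df)
    except ValidationError:
        raise
    except (TypeError, ValueError) as e:
        raise ValidationError(f"malformed community table {path}: {e}") from e


def write_site_taxon_table(table: SiteTaxonTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep=_sep_for(path))


def read_env_table(path: str | Path, dialect: str | None = None,
                   community: SiteTaxonTable | None = None) -> tuple[EnvTable, SiteTaxonTable | None]:
    """Read an environment table; rows with missing values are dropped.

    If ``community`` is given, the paired community rows of dropped samples
    are dropped too and the (possibly reduced) table is returned alongside.
    """
    df = _read_checked(path, dialect)
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        logger.warning("dropping %d samples with missing environment values: %s",
                       len(bad), list(bad[:10]))
        df = df.drop(index=bad)
    env = EnvTable.from_frame(df)
    if community is None:
        return env, None
    keep = [s for s in community.sample_ids if s in set(env.sample_ids)]
    env = _env_subset(env, keep)
    comm = _table_subset(community, keep)
    return env, comm


def aggregate_to_genus(table: SiteTaxonTable, taxonomy: Mapping[str, str],
                       strict: bool = False) -> SiteTaxonTable:
    """Sum species-level columns into genus-level columns.

    Genus order is first-appearance order over the input taxon list.  Taxa
    absent from ``taxonomy`` pass through as their own genus with a warning
    (or raise if ``strict``).
    """
    if strict and not taxonomy:
        raise ValidationError("empty taxonomy map in strict mode")
    unmapped = [t for t in table.taxon_ids if t not in taxonomy]
    if unmapped:
        if strict:
            raise ValidationError(f"taxa missing from taxonomy map: {unmapped[:5]}")
        warnings.warn(f"{len(unmapped)} taxa not in taxonomy map kept as their own genus",
                      stacklevel=2)
    genus_of = [taxonomy.get(t, t) for t in table.taxon_ids]
    genera: list[str] = []
    for g in genus_of:
        if g not in genera:
            genera.append(g)
    out = np.zeros((table.shape[0], len(genera)))
    pos = {g: j for j, g in enumerate(genera)}
    for col, g in enumerate(genus_of):
        out[:, pos[g]] += table.counts[:, col]
    return SiteTaxonTable(table.sample_ids, genera, out, table.meta)


def to_incidence(table: SiteTaxonTable, threshold: float = 0.0) -> IncidenceMatrix:
    """Binarize counts: present iff count strictly exceeds ``threshold``."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    return IncidenceMatrix(table.sample_ids, table.taxon_ids,
                           (table.counts > threshold).astype(np.int8))


def drop_degenerate(m: IncidenceMatrix) -> IncidenceMatrix:
    """Remove all-zero rows and columns (iterated until none remain).

    Reciprocal averaging is undefined on zero margins, so this runs before
    every ordination, including inside null-model replicates.
    """
    pres = m.presence
    rows = list(range(pres.shape[0]))
    cols = list(range(pres.shape[1]))
    while True:
        sub = pres[np.ix_(rows, cols)]
        if sub.size == 0:
            raise ValidationError("no community signal: matrix is entirely empty")
        rkeep = sub.sum(axis=1) > 0
        ckeep = sub.sum(axis=0) > 0
        if rkeep.all() and ckeep.all():
            break
        dropped_r = [m.sample_ids[rows[i]] for i in np.nonzero(~rkeep)[0]]
        dropped_c = [m.taxon_ids[cols[j]] for j in np.nonzero(~ckeep)[0]]
        if dropped_r or dropped_c:
            logger.info("dropping degenerate rows %s and columns %s", dropped_r, dropped_c)
        rows = [r for r, k in zip(rows, rkeep) if k]
        cols = [c for c, k in zip(cols, ckeep) if k]
    if not rows or not cols:
        raise ValidationError("no community signal: matrix is entirely empty")
    return IncidenceMatrix([m.sample_ids[i] for i in rows],
                           [m.taxon_ids[j] for j in cols],
                           pres[np.ix_(rows, cols)])


def _table_subset(table: SiteTaxonTable, keep: Sequence[str]) -> SiteTaxonTable:
    idx = {s: i for i, s in enumerate(table.sample_ids)}
    rows = [idx[s] for s in keep]
    meta = table.meta.loc[list(keep)] if table.meta is not None else None
    return SiteTaxonTable(list(keep), table.taxon_ids, table.counts[rows], meta)


def _env_subset(env: EnvTable, keep: Sequence[str]) -> EnvTable:
    idx = {s: i for i, s in enumerate(env.sample_ids)}
    rows = [idx[s] for s in keep]
    return EnvTable(list(keep), env.variables, env.values[rows], env.units)


def subset(table: SiteTaxonTable, env: EnvTable | None, groups: GroupMap | None,
           predicate: Callable[[pd.Series], bool]) -> tuple[SiteTaxonTable, EnvTable | None]:
    """Filter samples by a predicate over per-sample metadata.

    The predicate receives each sample's metadata row (including its group
    label under ``"group"`` when a :class:`GroupMap` is supplied) and the
    community and environment tables are filtered consistently.
    """
    if table.meta is None and groups is None:
        raise ValidationError("subset requires sample metadata or a group map")
    meta = table.meta.copy() if table.meta is not None else pd.DataFrame(index=table.sample_ids)
    if groups is not None:
        meta["group"] = groups.labels_for(table.sample_ids)
    keep = [s for s in table.sample_ids if predicate(meta.loc[s])]
    if not keep:
        raise ValidationError("empty selection: no samples match the predicate")
    sub_t = _table_subset(table, keep)
    sub_e = _env_subset(env, keep) if env is not None else None
    return sub_t, sub_e
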