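"""Config-driven orchestration of the full metacommunity analysis.

One run produces, for a community table + environment table + group maps:
per-group and pooled EMS rows (a Table-1-style report), pooled and
per-region CCA loadings (Table-2 style), richness comparisons with letter
display, a beta-diversity dendrogram, a random-forest indicator report, and
a manifest echoing the configuration and seeds.  Optional season
definitions add per-group x per-season EMS rows.

Seeds for the different subsets are expanded deterministically from the
base seed via a CRC-32 hash of the subset name, so no two subsets share a
null-model seed and any subset can be recomputed in isolation.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community_stats import beta_cluster, compare_groups, indicator_genera, richness
from .ems import NullModelConfig, ems_analysis
from .gradient_link import correlate_rank_axis, loadings_matrix, per_group_cca
from .matrix_io import (EnvTable, GroupMap, SiteTaxonTable, ValidationError,
                        _table_subset, drop_degenerate, read_env_table,
                        read_site_taxon_table, to_incidence)
from .ordination import ordinate, rank_site_scores, reciprocal_averaging

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``groups`` maps sample ids to primary labels (lakes); ``regions`` maps
    primary labels to region labels for the per-region CCA.  ``seasons``
    maps season names to month sets (requires a ``month`` column in the
    community metadata).
    """

    community_path: Path
    env_path: Path
    groups_path: Path
    out_dir: Path
    seed: int
    regions: dict[str, str] = field(default_factory=dict)
    seasons: dict[str, list[int]] = field(default_factory=dict)
    n_sims: int = 1000
    alpha: float = 0.05
    loading_threshold: float = 0.5
    top_fraction: float = 0.10
    n_trees: int = 131
    presence_threshold: float = 0.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        try:
            cfg = cls(
                community_path=base / raw["community"],
                env_path=base / raw["env"],
                groups_path=base / raw["groups"],
                out_dir=base / raw.get("out_dir", "ems_out"),
                seed=int(raw["seed"]),
                regions=raw.get("regions", {}) or {},
                seasons={k: list(v) for k, v in (raw.get("seasons") or {}).items()},
                n_sims=int(raw.get("n_sims", 1000)),
                alpha=float(raw.get("alpha", 0.05)),
                loading_threshold=float(raw.get("loading_threshold", 0.5)),
                top_fraction=float(raw.get("top_fraction", 0.10)),
                n_trees=int(raw.get("n_trees", 131)),
                presence_threshold=float(raw.get("presence_threshold", 0.0)),
            )
        except KeyError as e:
            raise ValidationError(f"config missing required key {e.args[0]!r}") from e
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in (self.community_path, self.env_path, self.groups_path):
            if not Path(p).exists():
                raise ValidationError(f"input file not found: {p}")
        for name, months in self.seasons.items():
            if not months:
                raise ValidationError(f"season {name!r} has an empty month set")


def subset_seed(base_seed: int, name: str) -> int:
    """Deterministic per-subset seed: CRC-32 expansion of the base seed."""
    return (int(base_seed) + zlib.crc32(name.encode())) % (2**31 - 1)


def _ems_row(name: str, table: SiteTaxonTable, cfg: RunConfig,
             rows: list[str] | None = None) -> dict:
    sub = _table_subset(table, rows) if rows is not None else table
    inc = to_incidence(sub, cfg.presence_threshold)
    null_cfg = NullModelConfig(seed=subset_seed(cfg.seed, name), n_sims=cfg.n_sims)
    try:
        res = ems_analysis(inc, null_cfg, alpha=cfg.alpha)
    except ValidationError as e:
        # e.g. margins (nearly) freeze the null class for a homogeneous subset
        logger.warning("EMS indeterminate for subset %s: %s", name, e)
        return {"subset": name, "structure": "Indeterminate", "error": str(e),
                "_result": None, "_null_config": null_cfg}
    row = {"subset": name, **res.to_dict()}
    row["_result"] = res
    row["_null_config"] = null_cfg
    return row


def run_pipeline(cfg: RunConfig, community: SiteTaxonTable | None = None,
                 env: EnvTable | None = None, groups: GroupMap | None = None) -> dict:
    """Execute the full analysis; returns the report bundle (also written to disk).

    In-memory tables may be passed directly (the paths in ``cfg`` are then
    only echoed in the manifest); otherwise they are read from the
    configured paths.
    """
    t_start = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def _stage(name: str, t0: float) -> None:
        stages.append({"stage": name, "seconds": round(time.time() - t0, 3)})
        logger.info("stage %s done in %.2fs", name, time.time() - t0)

    if community is None:
        community = read_site_taxon_table(cfg.community_path)
    if groups is None:
        groups = GroupMap.read(cfg.groups_path)
    if env is None:
        env, community = read_env_table(cfg.env_path, community=community)

    labels = groups.labels_for(community.sample_ids)
    group_names = list(dict.fromkeys(labels))

    # ---- EMS: pooled + per group ------------------------------------------
    t0 = time.time()
    ems_rows = []
    for g in group_names:
        keep = [s for s, lab in zip(community.sample_ids, labels) if lab == g]
        ems_rows.append(_ems_row(g, community, cfg, keep))
    ems_rows.append(_ems_row("All", community, cfg))
    ems_df = pd.DataFrame([{k: v for k, v in r.items() if not k.startswith("_")}
                           for r in ems_rows])
    ems_df.to_csv(out / "ems_table.tsv", sep="\t", index=False)
    for r in ems_rows:
        if r["_result"] is not None:
            (out / f"ems_{r['subset']}.json").write_text(
                r["_result"].to_json(r["_null_config"]))
    _stage("ems", t0)

    # ---- seasons (optional) -----------------------------------------------
    season_rows = []
    if cfg.seasons:
        t0 = time.time()
        season_rows = season_subsets(cfg, community, groups)
        if season_rows:
            pd.DataFrame(season_rows).to_csv(out / "ems_seasons.tsv", sep="\t", index=False)
        _stage("seasons", t0)

    # ---- ordination ranks + CCA -------------------------------------------
    t0 = time.time()
    inc_all = to_incidence(community, cfg.presence_threshold)
    core = drop_degenerate(inc_all)
    ca = reciprocal_averaging(core)
    ranks = rank_site_scores(ca, groups, core.sample_ids)
    ranks.to_csv(out / "site_ranks.tsv", sep="\t")
    ordered = ordinate(core)
    ordered.to_frame().to_csv(out / "ordinated_matrix.tsv", sep="\t")

    region_map = (GroupMap({s: cfg.regions[lab] for s, lab in zip(community.sample_ids, labels)})
                  if cfg.regions else groups)
    cca_results = per_group_cca(community, env, region_map)
    load_df = loadings_matrix(cca_results, cfg.loading_threshold)
    load_df.to_csv(out / "cca_loadings.tsv", sep="\t")
    rho, rho_p, method = correlate_rank_axis(
        ranks["rank"], cca_results[0], normality_alpha=cfg.alpha)
    _stage("cca", t0)

    # ---- community statistics ---------------------------------------------
    t0 = time.time()
    rich = richness(core, groups)
    rich.to_csv(out / "richness.tsv", sep="\t")
    rich_cmp = compare_groups(rich["richness"], groups, alpha=cfg.alpha)
    dendro = beta_cluster(core, groups)
    (out / "beta_dendrogram.nwk").write_text(dendro.newick + "\n")
    indicators = indicator_genera(community, region_map, n_trees=cfg.n_trees,
                                  top_fraction=cfg.top_fraction,
                                  seed=subset_seed(cfg.seed, "indicator"))
    indicators.to_frame().to_csv(out / "indicator_genera.tsv", sep="\t")
    indicators.confusion_matrix.to_csv(out / "indicator_confusion.csv")
    _stage("community_stats", t0)

    report = {
        "version": __version__,
        "seed": cfg.seed,
        "n_sims": cfg.n_sims,
        "alpha": cfg.alpha,
        "inputs": {"community": str(cfg.community_path), "env": str(cfg.env_path),
                   "groups": str(cfg.groups_path)},
        "n_samples": len(community.sample_ids),
        "n_taxa": len(community.taxon_ids),
        "ems": [{k: v for k, v in r.items() if not k.startswith("_")} for r in ems_rows],
        "ems_seasons": season_rows,
        "cca_loadings": {r.group: dict(zip(r.variables, map(float, r.loadings)))
                         for r in cca_results},
        "loading_threshold": cfg.loading_threshold,
        "rank_axis_correlation": {"coefficient": rho, "p": rho_p, "method": method},
        "richness_comparison": {"method": rich_cmp.method, "p": rich_cmp.p_omnibus,
                                "letters": rich_cmp.letters},
        "beta_dendrogram": dendro.newick,
        "indicator_selected": list(indicators.selected[indicators.selected].index),
        "indicator_oob_accuracy": indicators.oob_accuracy,
    }
    # timings live outside report.json so reports stay byte-reproducible
    (out / "run_log.json").write_text(_stable_json(
        {"stages": stages, "total_seconds": round(time.time() - t_start, 3)}))
    (out / "report.json").write_text(_stable_json(report))
    return report


def _stable_json(obj: dict) -> str:
    def default(x):
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        raise TypeError(type(x))
    return json.dumps(obj, indent=1, sort_keys=True, default=default)


def season_subsets(cfg: RunConfig, community: SiteTaxonTable,
                   groups: GroupMap) -> list[dict]:
    """EMS per group x season; undersized subsets are skipped with a warning."""
    if community.meta is None or "month" not in community.meta.columns:
        raise ValidationError("season analysis requires a 'month' metadata column")
    for name, months in cfg.seasons.items():
        if not months:
            raise ValidationError(f"season {name!r} has an empty month set")
    labels = groups.labels_for(community.sample_ids)
    months = community.meta["month"].astype(int)
    rows = []
    for season, month_set in cfg.seasons.items():
        for g in dict.fromkeys(labels):
            keep = [s for s, lab in zip(community.sample_ids, labels)
                    if lab == g and int(months.loc[s]) in month_set]
            if len(keep) < 10:
                logger.warning("skipping %s x %s: only %d samples", g, season, len(keep))
                continue
            sub = _table_subset(community, keep)
            inc = to_incidence(sub, cfg.presence_threshold)
            if inc.presence.shape[1] < 6 or int(inc.presence.sum(axis=0).astype(bool).sum()) < 6:
                logger.warning("skipping %s x %s: fewer than 6 occupied taxa", g, season)
                continue
            name = f"{g}|{season}"
            null_cfg = NullModelConfig(seed=subset_seed(cfg.seed, name), n_sims=cfg.n_sims)
            try:
                res = ems_analysis(inc, null_cfg, alpha=cfg.alpha)
            except ValidationError as e:
                logger.warning("EMS indeterminate for %s: %s", name, e)
                rows.append({"subset": g, "season": season,
                             "structure": "Indeterminate", "error": str(e)})
                continue
            rows.append({"subset": g, "season": season, **res.to_dict()})
    return rows
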