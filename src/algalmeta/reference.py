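"""Published summary statistics shipped with the package.

These are the printed EMS and CCA summaries of an eight-year algal
monitoring study of six interconnected North Han River lakes (PD, CP, UM,
CC, SY, HC).  The raw site-by-genus monitoring data are not public, so
these tables serve as worked-example inputs: the z-score arithmetic and the
structure-classification tree can be re-derived from the printed component
statistics and checked against the printed labels.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("algalmeta").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, **kwargs)


def han_river_ems_summary() -> pd.DataFrame:
    """Per-subset EMS summaries (Abs, Rep, z, sim mean/SD, Morisita I, label).

    One row per analysis subset: the six lakes and the pooled metacommunity
    ("All").  z follows the ``(sim_mean - observed)/sim_sd`` convention.
    """
    return _load("han_river_ems_summary.csv", index_col="subset")


def han_river_cca_loadings() -> pd.DataFrame:
    """Axis-1 CCA intraset loadings of the nine water-quality variables.

    Columns are the pooled analysis (ALL) and the three river regions
    (Up, Mid, Down).
    """
    return _load("han_river_cca_loadings.csv", index_col="variable")
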