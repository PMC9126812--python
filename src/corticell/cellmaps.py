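"""Cell-type transcriptional maps and their association with mean CTh.

A cell-type map is the per-region mean expression of that cell type's marker
gene set, z-scored across regions (sample SD, n-1).  The seven maps estimate
the regional distribution of each neural cell class and are the spatial
reference the coupling stage correlates patient deviation profiles against.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import bh_fdr, pearson_with_p, zscore_columns
from .containers import GeneSetCollection
from .errors import InputError

log = logging.getLogger(__name__)


def build_cell_map(expression: pd.DataFrame, sets: GeneSetCollection) -> pd.DataFrame:
    """Region x cell-type map of z-scored mean marker expression.

    Genes listed in a set but absent from the expression matrix are dropped
    with a logged warning; an entirely absent set is an error naming the cell
    type, as is a set whose regional means have zero variance.
    """
    if len(expression.index) < 3:
        raise InputError("need at least 3 regions to build cell-type maps")
    restricted, dropped = sets.restrict_to(expression.columns)
    for name, n in dropped.items():
        if n:
            log.warning("gene set %s: dropped %d genes absent from expression", name, n)
    means = pd.DataFrame(
        {name: expression[list(restricted[name])].mean(axis=1) for name in restricted.names}
    )
    return zscore_columns(means, ddof=1)


def map_vs_mean_cth(
    cell_map: pd.DataFrame,
    mean_cth: pd.Series,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate each cell-type map with mean CTh over regions, with BH-FDR.

    One test per cell type (7 by default).  ``method`` may be ``pearson``
    (default, matching linear-fit scatterplots) or ``spearman``.
    """
    if list(cell_map.index) != list(mean_cth.index):
        raise InputError("cell map and mean CTh index different regions")
    from scipy import stats

    rows = {}
    for ct in cell_map.columns:
        if method == "pearson":
            r, p = pearson_with_p(cell_map[ct].to_numpy(), mean_cth.to_numpy())
        elif method == "spearman":
            r, p = stats.spearmanr(cell_map[ct].to_numpy(), mean_cth.to_numpy())
            r, p = float(r), float(p)
        else:
            raise InputError(f"unknown correlation method {method!r}")
        rows[ct] = {"r": r, "p": p}
    out = pd.DataFrame(rows).T
    out["fdr_p"] = bh_fdr(out["p"])
    return out
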