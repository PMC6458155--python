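"""Astroglial network morphometry from point tables.

Combinatorial colour labeling makes clones of astrocytes visible as
colour clusters: sets of cells expressing the same colour combination
and continuously in contact with each other (isolated cells count as
clusters of size 1).  Soma positions, colour ids, contact counts and
layer labels enter as tables — these annotations are pointed by hand on
real data — and the module assembles clusters, computes the
contacted-cells-per-astrocyte ratio, and produces per-layer descriptive
summaries.  Inferential statistics are deliberately left to general
statistics packages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import InvalidParameterError

__all__ = [
    "ColorCluster",
    "build_color_clusters",
    "contacts_per_astrocyte",
    "cluster_table",
    "layer_summaries",
]

logger = logging.getLogger(__name__)

#: Required columns of the astrocyte record table.
ASTROCYTE_COLUMNS = ("id", "x", "y", "z", "color")


@dataclass
class ColorCluster:
    """A connected set of same-colour astrocytes and its contact count."""

    members: tuple
    color: int | str
    contacted_cells: int = 0
    layers: tuple = ()
    pial: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


def _validate_astrocytes(astrocytes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("id", "color") if c not in astrocytes.columns]
    if missing:
        raise InvalidParameterError(f"astrocyte table is missing columns {missing}")
    if astrocytes["id"].duplicated().any():
        raise InvalidParameterError("astrocyte ids must be unique")
    if "volume" in astrocytes.columns:
        vols = astrocytes["volume"].dropna()
        if (vols <= 0).any():
            raise InvalidParameterError("domain volumes must be positive")
    return astrocytes


def build_color_clusters(
    astrocytes: pd.DataFrame,
    adjacency: Iterable[tuple],
) -> list[ColorCluster]:
    """Connected components of the same-colour contact graph.

    ``adjacency`` lists astrocyte id pairs in physical contact.  Edges
    between astrocytes of different colours cannot join one clone and are
    ignored (logged); unreferenced ids raise.  Per-cluster contact counts
    sum the members' ``contacts`` column when present.
    """
    astrocytes = _validate_astrocytes(astrocytes)
    by_id = astrocytes.set_index("id")
    graph = nx.Graph()
    graph.add_nodes_from(by_id.index)
    for a, b in adjacency:
        if a not in by_id.index or b not in by_id.index:
            raise InvalidParameterError(f"adjacency references unknown id in ({a}, {b})")
        if by_id.at[a, "color"] != by_id.at[b, "color"]:
            logger.info("ignoring contact between different colours: (%s, %s)", a, b)
            continue
        graph.add_edge(a, b)
    clusters = []
    for component in nx.connected_components(graph):
        members = tuple(sorted(component))
        rows = by_id.loc[list(members)]
        contacted = int(rows["contacts"].sum()) if "contacts" in rows else 0
        layers = tuple(rows["layer"].unique()) if "layer" in rows else ()
        pial = bool(rows["pial"].any()) if "pial" in rows else False
        clusters.append(
            ColorCluster(
                members=members,
                color=rows["color"].iloc[0],
                contacted_cells=contacted,
                layers=layers,
                pial=pial,
            )
        )
    clusters.sort(key=lambda c: c.members)
    return clusters


def contacts_per_astrocyte(cluster: ColorCluster) -> float:
    """Contacted cells divided by the number of labelled astrocytes."""
    if cluster.size == 0:
        raise InvalidParameterError("cluster has no members")
    return cluster.contacted_cells / cluster.size


def cluster_table(
    clusters: Sequence[ColorCluster], exclude_pial: bool = True
) -> pd.DataFrame:
    """Tabulate clusters with their contacts-per-astrocyte ratio.

    Pial clusters are excluded from the ratio analysis by default, as
    their flattened geometry is not comparable to protoplasmic domains.
    """
    rows = []
    for c in clusters:
        if exclude_pial and c.pial:
            continue
        rows.append(
            {
                "size": c.size,
                "color": c.color,
                "contacted_cells": c.contacted_cells,
                "contacts_per_astrocyte": contacts_per_astrocyte(c),
                "n_layers": len(c.layers),
                "layer": c.layers[0] if len(c.layers) == 1 else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "size", "color", "contacted_cells", "contacts_per_astrocyte",
            "n_layers", "layer",
        ],
    )


def layer_summaries(
    clusters: Sequence[ColorCluster],
    value: str = "contacts_per_astrocyte",
    max_cluster_size: int = 3,
    exclude_pial: bool = True,
) -> pd.DataFrame:
    """Descriptive per-layer statistics of a cluster-level quantity.

    Only clusters of size at most ``max_cluster_size`` lying entirely
    within one identified layer are comparable across layers and enter
    the summary.  Columns: n, mean, sd, median; ``sd`` is reported as 0
    for single observations with ``sd_defined`` flagging the convention.
    Returns an empty table when nothing survives the filter.
    """
    table = cluster_table(clusters, exclude_pial=exclude_pial)
    table = table[(table["size"] <= max_cluster_size) & (table["n_layers"] == 1)]
    table = table[table["layer"].notna()]
    if table.empty:
        return pd.DataFrame(columns=["layer", "n", "mean", "sd", "median", "sd_defined"])
    out = []
    for layer, group in table.groupby("layer", sort=True):
        vals = group[value].to_numpy(dtype=float)
        out.append(
            {
                "layer": layer,
                "n": len(vals),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "median": float(np.median(vals)),
                "sd_defined": len(vals) > 1,
            }
        )
    return pd.DataFrame(out)
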