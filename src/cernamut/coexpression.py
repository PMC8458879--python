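"""Driver-centred co-expression networks.

Edges connect a driver to a partner gene when Pearson |r| > 0.5 and
p < 0.01 (raw p, per the analysis protocol); the topology is a union of
driver stars — partner-partner correlations are not tested.
"""

from __future__ import annotations

import logging
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InestimableError, ValidationError

log = logging.getLogger(__name__)


def correlate(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with its two-sided p-value.

    p comes from t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom.
    Raises for fewer than 3 points or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("correlate needs equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InestimableError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _correlate_matrix(driver_values: np.ndarray, partner_matrix: np.ndarray):
    """Vectorized Pearson r and p of one driver against many partners."""
    n = driver_values.size
    x = driver_values - driver_values.mean()
    ym = partner_matrix - partner_matrix.mean(axis=1, keepdims=True)
    sx = np.sqrt((x**2).sum())
    sy = np.sqrt((ym**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ym @ x) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return r, p


def build_network(
    drivers: Sequence[str],
    expression: pd.DataFrame,
    p_cut: float = 0.01,
    r_cut: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, nx.Graph]:
    """Build the merged driver co-expression network.

    Returns (edge table, node table with degree, graph). Zero-variance
    partners are skipped; duplicate driver-driver edges are deduplicated;
    an edgeless network is a valid result. Hubs are the max-degree nodes
    (ties reported as a set, ordered lexicographically).
    """
    drivers = list(dict.fromkeys(drivers))
    missing = [g for g in drivers if g not in expression.index]
    if missing:
        raise ValidationError(f"drivers absent from expression matrix: {missing}")
    genes = list(expression.index)
    values = expression.values.astype(float)
    variable = values.std(axis=1) > 0
    gene_pos = {g: i for i, g in enumerate(genes)}
    driver_set = set(drivers)

    edges: dict[tuple[str, str], dict] = {}
    for d in drivers:
        di = gene_pos[d]
        if not variable[di]:
            log.info("driver %s has zero variance; skipped", d)
            continue
        r, p = _correlate_matrix(values[di], values)
        passing = np.where((np.abs(r) > r_cut) & (p < p_cut) & variable)[0]
        for j in passing:
            partner = genes[j]
            if partner == d:
                continue
            key = tuple(sorted((d, partner)))
            if key in edges:
                continue
            edges[key] = {
                "driver": d,
                "partner": partner,
                "r": float(r[j]),
                "p_value": float(p[j]),
                "sign": "positive" if r[j] > 0 else "negative",
            }
    edge_df = pd.DataFrame(
        sorted(edges.values(), key=lambda e: (e["driver"], e["partner"])),
        columns=["driver", "partner", "r", "p_value", "sign"],
    )
    graph = nx.Graph()
    graph.add_nodes_from(drivers)
    for e in edges.values():
        graph.add_edge(e["driver"], e["partner"], r=e["r"], p_value=e["p_value"])
    node_df = pd.DataFrame(
        {
            "gene": sorted(graph.nodes),
            "degree": [graph.degree[g] for g in sorted(graph.nodes)],
            "is_driver": [g in driver_set for g in sorted(graph.nodes)],
        }
    )
    return edge_df, node_df, graph


def hub_genes(node_table: pd.DataFrame) -> list[str]:
    """Max-degree node(s), lexicographically ordered tie set."""
    if node_table.empty:
        return []
    top = node_table["degree"].max()
    return sorted(node_table.loc[node_table["degree"] == top, "gene"])
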