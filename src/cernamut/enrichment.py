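"""Rank-based enrichment: preranked running-sum GSEA with a gene-set
resampling permutation null, and hypergeometric over-representation.

Two ranking schemes are supported, matching the analysis protocol:
-log10(p) weights from the driver tests, and correlation-coefficient
weights from the co-expression stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, InestimableError, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by descending rank weight."""

    genes: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self):
        if len(self.genes) != len(self.weights):
            raise ValidationError("genes and weights must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in ranked list")
        if np.any(np.diff(self.weights) > 0):
            raise ValidationError("weights must be non-increasing")


def make_ranked_list(genes, weights) -> RankedList:
    """Sort (gene, weight) pairs by descending weight, ties by gene id."""
    df = pd.DataFrame({"gene": list(genes), "w": np.asarray(weights, dtype=float)})
    df = df.sort_values(["w", "gene"], ascending=[False, True], kind="stable")
    return RankedList(tuple(df["gene"]), df["w"].to_numpy())


def rank_by_neglog_p(results: pd.DataFrame, gene_col: str = "gene",
                     p_col: str = "p_value") -> RankedList:
    """Rank genes by -log10(p); p = 0 is clamped to the smallest positive
    double with a warning."""
    p = results[p_col].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    if np.any(p == 0):
        log.warning("clamping %d zero p-values", int(np.sum(p == 0)))
        p = np.where(p == 0, np.finfo(float).tiny, p)
    return make_ranked_list(results[gene_col], -np.log10(p))


def rank_by_correlation(edges: pd.DataFrame, gene_col: str = "partner",
                        r_col: str = "r") -> RankedList:
    """Rank genes by their co-expression coefficient."""
    return make_ranked_list(edges[gene_col], edges[r_col].to_numpy(dtype=float))


def gsea_enrichment_score(
    ranked: RankedList, gene_set: set[str], p_exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov-Smirnov running sum and its signed extremum.

    Hits increment by |w|^p / sum_set |w|^p, misses decrement by
    1/(N - N_set); the enrichment score is the maximum-deviation value of
    the running sum. A set covering the whole list is degenerate (no
    misses) and flagged with a warning.
    """
    in_set = np.array([g in gene_set for g in ranked.genes])
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise InestimableError("gene set has no overlap with the ranked list")
    n = len(ranked.genes)
    w = np.abs(ranked.weights) ** p_exponent
    denom_hit = w[in_set].sum()
    if denom_hit == 0:  # all-zero weights: fall back to unweighted steps
        steps_hit = np.where(in_set, 1.0 / n_hit, 0.0)
    else:
        steps_hit = np.where(in_set, w / denom_hit, 0.0)
    if n == n_hit:
        log.warning("gene set covers the entire ranked list; ES degenerate at 1")
        miss_step = 0.0
    else:
        miss_step = 1.0 / (n - n_hit)
    running = np.cumsum(steps_hit - np.where(in_set, 0.0, miss_step))
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def gsea_pvalue(
    ranked: RankedList,
    gene_set: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    p_exponent: float = 1.0,
) -> tuple[float, float]:
    """Permutation p-value of |ES| against random same-size gene sets
    drawn from the ranked universe; p = (1 + #{|ES_null| >= |ES|}) / (1 + n_perm)."""
    if n_perm <= 0:
        raise ConfigError("n_perm must be positive")
    es, _ = gsea_enrichment_score(ranked, gene_set, p_exponent)
    rng = np.random.default_rng(seed)
    n = len(ranked.genes)
    k = sum(1 for g in ranked.genes if g in gene_set)
    w = np.abs(ranked.weights) ** p_exponent
    count = 0
    for _ in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        denom = w[mask].sum()
        steps = (w / denom if denom > 0 else np.full(n, 1.0 / k)) * mask
        miss = 0.0 if n == k else 1.0 / (n - k)
        running = np.cumsum(steps - np.where(mask, 0.0, miss))
        es_null = running[np.argmax(np.abs(running))]
        if abs(es_null) >= abs(es):
            count += 1
    return es, (1 + count) / (1 + n_perm)


def hypergeom_ora(
    query: set[str], gene_set: set[str], universe: set[str]
) -> tuple[int, float]:
    """Upper-tail hypergeometric p of the query/set overlap."""
    if not universe:
        raise ValidationError("empty universe")
    if not query <= universe:
        raise ValidationError("query genes must be a subset of the universe")
    members = gene_set & universe
    overlap = len(query & members)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(query)))
    return overlap, min(p, 1.0)


def ora_table(
    query: set[str], gene_sets: dict[str, set[str]], universe: set[str]
) -> pd.DataFrame:
    """Over-representation across many sets, with BH adjustment."""
    rows = []
    for name, members in sorted(gene_sets.items()):
        overlap, p = hypergeom_ora(query, members, universe)
        rows.append(
            {"set": name, "size": len(members & universe), "overlap": overlap, "p_value": p}
        )
    out = pd.DataFrame(rows, columns=["set", "size", "overlap", "p_value"])
    if not out.empty:
        out["p_adj"] = stats.false_discovery_control(out["p_value"], method="bh")
    return out


def gsea_table(
    ranked: RankedList,
    gene_sets: dict[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
    p_exponent: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA across many sets, with BH adjustment."""
    rows = []
    for i, (name, members) in enumerate(sorted(gene_sets.items())):
        try:
            es, p = gsea_pvalue(ranked, members, n_perm, seed + i, p_exponent)
        except InestimableError:
            log.info("set %s skipped: no overlap", name)
            continue
        rows.append(
            {
                "set": name,
                "size": sum(1 for g in ranked.genes if g in members),
                "es": es,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows, columns=["set", "size", "es", "p_value"])
    if not out.empty:
        out["p_adj"] = stats.false_discovery_control(out["p_value"], method="bh")
    return out
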