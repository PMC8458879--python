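"""Expression-driver testing: genes differentially expressed between
mutation-carrier and non-carrier samples.

The test runs on log2(x+1)-transformed values (Welch variant by default);
the fold change is reported on the linear scale with a pseudocount of 1,
and a gene is flagged as a driver when p < alpha and |log2 FC| exceeds
log2 of the fold-change cutoff (defaults 0.05 and 1.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InestimableError, ValidationError
from .landscape import MutationMatrix

log = logging.getLogger(__name__)

PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class DriverTestResult:
    gene: str
    n_mut: int
    n_wt: int
    mean_mut: float
    mean_wt: float
    fold_change: float
    log2fc: float
    p_value: float
    is_driver: bool


def align_cohorts(
    mutation_matrix: MutationMatrix, expression: pd.DataFrame
) -> tuple[list[str], MutationMatrix, pd.DataFrame]:
    """Restrict both cohorts to their shared samples.

    Sample order follows the expression matrix. Raises if the
    intersection is empty; logs how many samples were dropped.
    """
    shared = [s for s in expression.columns if s in set(mutation_matrix.samples)]
    if not shared:
        raise ValidationError("no samples shared between mutation and expression data")
    dropped = (len(expression.columns) - len(shared)) + (
        len(mutation_matrix.samples) - len(shared)
    )
    if dropped:
        log.info("align_cohorts: %d shared samples, %d dropped", len(shared), dropped)
    return (
        shared,
        MutationMatrix(mutation_matrix.counts[shared]),
        expression[shared],
    )


def test_driver(
    expr_mut: np.ndarray,
    expr_wt: np.ndarray,
    *,
    log_transform: bool = True,
    welch: bool = True,
) -> tuple[float, float]:
    """Two-sided t-test plus linear-scale fold change for one gene.

    Returns ``(p_value, fold_change)`` with
    ``fold_change = (mean_mut + 1) / (mean_wt + 1)``. Identical groups
    report p = 1. Groups with fewer than 2 samples are untestable.
    """
    expr_mut = np.asarray(expr_mut, dtype=float)
    expr_wt = np.asarray(expr_wt, dtype=float)
    if len(expr_mut) < 2 or len(expr_wt) < 2:
        raise InestimableError("each group needs >= 2 samples")
    fc = (expr_mut.mean() + PSEUDOCOUNT) / (expr_wt.mean() + PSEUDOCOUNT)
    a, b = (np.log2(expr_mut + 1), np.log2(expr_wt + 1)) if log_transform else (
        expr_mut,
        expr_wt,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, equal_var=not welch)
    if np.isnan(p):  # both groups constant: no evidence of a difference
        p = 1.0
    return float(p), float(fc)


def identify_drivers(
    mutation_matrix: MutationMatrix,
    expression: pd.DataFrame,
    alpha: float = 0.05,
    fc_cut: float = 1.5,
    *,
    log_transform: bool = True,
    welch: bool = True,
) -> pd.DataFrame:
    """Test every gene of the (carrier-filtered) mutation matrix.

    Returns one row per tested gene sorted by |log2 FC| descending, with
    BH-adjusted p reported alongside the raw p actually used for
    flagging.
    """
    shared, mm, expr = align_cohorts(mutation_matrix, expression)
    rows = []
    for gene in mm.genes:
        if gene not in expr.index:
            continue
        carriers = mm.carrier_mask.loc[gene].values
        values = expr.loc[gene].values.astype(float)
        try:
            p, fc = test_driver(
                values[carriers], values[~carriers],
                log_transform=log_transform, welch=welch,
            )
        except InestimableError:
            log.info("gene %s untestable (carrier group too small)", gene)
            continue
        rows.append(
            {
                "gene": gene,
                "n_mut": int(carriers.sum()),
                "n_wt": int((~carriers).sum()),
                "mean_mut": float(values[carriers].mean()),
                "mean_wt": float(values[~carriers].mean()),
                "fold_change": fc,
                "log2fc": float(np.log2(fc)),
                "p_value": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "gene", "n_mut", "n_wt", "mean_mut", "mean_wt",
                "fold_change", "log2fc", "p_value", "p_adj", "is_driver",
            ]
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = stats.false_discovery_control(out["p_value"], method="bh")
    out["is_driver"] = (out["p_value"] < alpha) & (
        out["log2fc"].abs() > np.log2(fc_cut)
    )
    return (
        out.reindex(out["log2fc"].abs().sort_values(ascending=False, kind="stable").index)
        .reset_index(drop=True)
    )
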