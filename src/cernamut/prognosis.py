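"""Survival branch: univariate Cox screen, L1-penalised selection,
multivariate Cox risk model, risk scoring, Kaplan-Meier / log-rank and
cumulative/dynamic time-dependent AUC.

Expression enters the survival models as log2(x+1); genes are
standardised before penalised fitting so the L1 path shrinks comparable
scales. The published pancreatic-adenocarcinoma 8-gene risk model ships
as a bundled fixture and is applied on the same scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .exceptions import ConfigError, InestimableError, ValidationError

log = logging.getLogger(__name__)

#: six ROC evaluation times: a uniform grid over the 6-18 month interval
DEFAULT_EVAL_TIMES = (180.0, 253.0, 326.0, 399.0, 472.0, 545.0)


def check_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table (index = sample, os_days > 0, event in {0,1})."""
    for col in ("os_days", "event"):
        if col not in clinical.columns:
            raise ValidationError(f"clinical table lacks column {col!r}")
    if (clinical["os_days"] <= 0).any():
        raise ValidationError("os_days must be positive")
    if not set(clinical["event"].unique()) <= {0, 1}:
        raise ValidationError("event must be binary")
    return clinical


def prepare_expression(expression: pd.DataFrame, *, standardize: bool = False) -> pd.DataFrame:
    """log2(x+1) transform (genes x samples), optionally z-scored per gene.

    Zero-variance genes are left centred at 0 rather than divided by 0.
    """
    out = np.log2(expression.astype(float) + 1.0)
    if standardize:
        mu = out.mean(axis=1)
        sd = out.std(axis=1, ddof=0).replace(0.0, 1.0)
        out = out.sub(mu, axis=0).div(sd, axis=0)
    return out


# ------------------------------------------------------------------ Cox


@dataclass(frozen=True)
class CoxResult:
    beta: float
    hr: float
    se: float
    p_value: float


def univariate_cox(values: np.ndarray, clinical: pd.DataFrame) -> CoxResult:
    """Cox proportional-hazards fit of survival on a single covariate.

    ``values`` must align with the clinical table's rows. Raises for
    fewer than 2 events or a constant covariate (zero information).
    """
    check_clinical(clinical)
    values = np.asarray(values, dtype=float)
    if len(values) != len(clinical):
        raise ValidationError("covariate length does not match clinical table")
    if clinical["event"].sum() < 2:
        raise InestimableError("need at least 2 events")
    if np.std(values) == 0:
        raise InestimableError("constant covariate: zero partial-likelihood information")
    df = pd.DataFrame(
        {"os_days": clinical["os_days"].values, "event": clinical["event"].values, "x": values}
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="os_days", event_col="event")
    except ConvergenceError as exc:
        raise InestimableError(f"Cox fit did not converge: {exc}") from exc
    row = cph.summary.loc["x"]
    return CoxResult(
        beta=float(row["coef"]),
        hr=float(np.exp(row["coef"])),
        se=float(row["se(coef)"]),
        p_value=float(row["p"]),
    )


def screen_univariate(
    expression: pd.DataFrame, clinical: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene univariate Cox screen on log2(x+1) expression.

    Returns a table (gene, beta, hr, se, p_value, selected) sorted by p.
    Inestimable genes are skipped with a log entry.
    """
    samples = [s for s in expression.columns if s in clinical.index]
    expr = prepare_expression(expression[samples])
    clin = clinical.loc[samples]
    rows = []
    for gene in expr.index:
        try:
            res = univariate_cox(expr.loc[gene].values, clin)
        except InestimableError as exc:
            log.info("gene %s skipped in Cox screen: %s", gene, exc)
            continue
        rows.append(
            {"gene": gene, "beta": res.beta, "hr": res.hr, "se": res.se, "p_value": res.p_value}
        )
    out = pd.DataFrame(rows, columns=["gene", "beta", "hr", "se", "p_value"])
    if not out.empty:
        out["selected"] = out["p_value"] < alpha
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    return out


def _breslow_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood at a fixed coefficient vector."""
    lp = X @ beta
    order = np.argsort(-time, kind="stable")  # descending time
    lp_o, t_o, e_o = lp[order], time[order], event[order]
    cum = np.logaddexp.accumulate(lp_o)  # log sum exp over risk set
    ll = 0.0
    i = 0
    n = len(t_o)
    while i < n:
        j = i
        while j < n and t_o[j] == t_o[i]:
            j += 1
        log_risk = cum[j - 1]  # everyone with time >= t_o[i]
        for k in range(i, j):
            if e_o[k]:
                ll += lp_o[k] - log_risk
        i = j
    return float(ll)


def lasso_cox_select(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    n_folds: int = 10,
    seed: int = 0,
    *,
    n_alphas: int = 50,
    alpha_min_ratio: float = 0.01,
) -> tuple[list[str], pd.DataFrame]:
    """L1-penalised Cox gene selection along a cross-validated lambda path.

    Expression (genes x samples) is log2(x+1) transformed and
    standardised; the coordinate-descent path comes from scikit-survival
    and lambda is chosen by the Verweij-van Houwelingen cross-validated
    partial-likelihood deviance. Returns the selected genes (non-zero
    coefficients at the chosen lambda; possibly empty) and the
    coefficient path.
    """
    from sklearn.model_selection import KFold
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    check_clinical(clinical)
    if expression.shape[0] < 1:
        raise ValidationError("no candidate genes")
    samples = [s for s in expression.columns if s in clinical.index]
    clin = clinical.loc[samples]
    n_events = int(clin["event"].sum())
    if n_events < n_folds:
        raise ValidationError(f"{n_events} events < {n_folds} folds")
    X = prepare_expression(expression[samples], standardize=True).T.values
    genes = list(expression.index)
    y = Surv.from_arrays(
        event=clin["event"].values.astype(bool), time=clin["os_days"].values.astype(float)
    )
    time = clin["os_days"].values.astype(float)
    event = clin["event"].values.astype(int)

    base = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio, fit_baseline_model=False
    )
    base.fit(X, y)
    alphas = np.asarray(base.alphas_)

    cv_pl = np.zeros((n_folds, len(alphas)))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for fi, (train_idx, _) in enumerate(kf.split(X)):
        fold = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas), fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold.fit(X[train_idx], y[train_idx])
        fold_alphas = list(fold.alphas_)
        for ai, a in enumerate(alphas):
            if a in fold_alphas:
                beta = fold.coef_[:, fold_alphas.index(a)]
            else:  # path truncated early in this fold: nearest computed alpha
                beta = fold.coef_[:, int(np.argmin(np.abs(np.asarray(fold_alphas) - a)))]
            full = _breslow_loglik(beta, X, time, event)
            train = _breslow_loglik(beta, X[train_idx], time[train_idx], event[train_idx])
            cv_pl[fi, ai] = full - train
    mean_cv = cv_pl.mean(axis=0)
    best_idx = int(np.argmax(mean_cv))
    # one-standard-error rule: the sparsest lambda whose CV likelihood is
    # within one fold-SE of the optimum (alphas are in decreasing order)
    se_best = float(cv_pl[:, best_idx].std(ddof=1) / np.sqrt(n_folds))
    chosen_idx = int(np.argmax(mean_cv >= mean_cv[best_idx] - se_best))
    best_alpha = float(alphas[chosen_idx])
    coefs = base.coef_[:, chosen_idx]
    selected = [g for g, c in zip(genes, coefs) if c != 0.0]
    if not selected:
        log.info("lasso selected no genes at lambda=%.4g", best_alpha)
    path = pd.DataFrame(base.coef_, index=genes, columns=[f"{a:.6g}" for a in alphas])
    path.attrs["chosen_alpha"] = best_alpha
    return selected, path


# ------------------------------------------------------------------ risk model


@dataclass(frozen=True)
class RiskModel:
    """Ordered gene list with signed Cox coefficients defining a linear
    risk score (no intercept)."""

    genes: tuple[str, ...]
    coefficients: tuple[float, ...]
    name: str = "risk_model"

    def __post_init__(self):
        if len(self.genes) != len(self.coefficients):
            raise ValidationError("genes and coefficients must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in risk model")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"gene": self.genes, "coefficient": self.coefficients}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "RiskModel":
        df = pd.read_csv(path, sep="\t")
        return cls(
            tuple(df["gene"].astype(str)),
            tuple(df["coefficient"].astype(float)),
            name or Path(path).stem,
        )


def load_published_model() -> RiskModel:
    """The published 8-gene pancreatic-adenocarcinoma risk model."""
    with resources.files("cernamut.data").joinpath("published_risk_model.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return RiskModel(
        tuple(df["gene"]), tuple(df["coefficient"].astype(float)), "published_8gene"
    )


def risk_score(expression_row: Mapping[str, float], model: RiskModel) -> float:
    """Linear risk score sum(coef_i * expr_i); every model gene must be present."""
    total = 0.0
    for gene, coef in zip(model.genes, model.coefficients):
        if gene not in expression_row:
            raise ValidationError(f"expression value missing for model gene {gene!r}")
        total += coef * float(expression_row[gene])
    return total


def score_samples(expression: pd.DataFrame, model: RiskModel) -> pd.Series:
    """Risk score per sample of a genes x samples matrix."""
    missing = [g for g in model.genes if g not in expression.index]
    if missing:
        raise ValidationError(f"expression matrix missing model genes: {missing}")
    sub = expression.loc[list(model.genes)].T.values
    return pd.Series(sub @ np.asarray(model.coefficients), index=expression.columns,
                     name="risk_score")


def multivariate_cox(
    expression: pd.DataFrame, clinical: pd.DataFrame, name: str = "fitted"
) -> tuple[RiskModel, pd.DataFrame]:
    """Joint Cox fit over the selected genes (rows of ``expression``).

    Values are used as given (the pipeline supplies the log2 scale).
    Collinear or separating predictors trigger a ridge-stabilised refit
    with a warning. Returns the RiskModel plus a per-gene table with HR,
    95% CI and Wald p.
    """
    check_clinical(clinical)
    if expression.empty:
        raise ValidationError("no genes to fit")
    samples = [s for s in expression.columns if s in clinical.index]
    if len(samples) <= expression.shape[0]:
        raise ValidationError("need more samples than genes")
    df = expression[samples].T.copy()
    df["os_days"] = clinical.loc[samples, "os_days"].values
    df["event"] = clinical.loc[samples, "event"].values
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="os_days", event_col="event")
    except ConvergenceError:
        log.warning("multivariate Cox unstable; refitting with ridge penalty 0.1")
        cph = CoxPHFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="os_days", event_col="event")
    summary = cph.summary
    table = pd.DataFrame(
        {
            "gene": summary.index,
            "beta": summary["coef"].values,
            "hr": summary["exp(coef)"].values,
            "hr_ci_low": summary["exp(coef) lower 95%"].values,
            "hr_ci_high": summary["exp(coef) upper 95%"].values,
            "p_value": summary["p"].values,
        }
    ).reset_index(drop=True)
    model = RiskModel(tuple(table["gene"]), tuple(table["beta"].astype(float)), name)
    return model, table


# ------------------------------------------------------------------ cohorts & curves


def split_cohort(
    samples: Sequence[str], train_fraction: float = 0.7, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Reproducible disjoint train/test split; train size = round(f * n)."""
    samples = list(samples)
    if len(samples) < 2:
        raise ValidationError("need at least 2 samples to split")
    if not 0 < train_fraction < 1:
        raise ConfigError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = int(round(train_fraction * len(samples)))
    train = sorted(samples[i] for i in order[:n_train])
    test = sorted(samples[i] for i in order[n_train:])
    return train, test


def median_risk_groups(scores: pd.Series) -> pd.Series:
    """Dichotomise at the within-cohort median: > median high, <= median low."""
    if len(scores) < 2:
        raise ValidationError("need at least 2 scores")
    med = float(scores.median())
    if scores.nunique() == 1:
        log.warning("all risk scores identical; single-group degenerate split")
    return pd.Series(
        np.where(scores.values > med, "high", "low"), index=scores.index, name="risk_group"
    )


def km_estimate(clinical: pd.DataFrame, groups: pd.Series) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group: (time, survival) steps."""
    check_clinical(clinical)
    out = {}
    for grp in sorted(groups.unique()):
        idx = groups.index[groups == grp]
        if len(idx) == 0:
            raise ValidationError(f"empty group {grp!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(clinical.loc[idx, "os_days"], clinical.loc[idx, "event"])
        df = kmf.survival_function_.reset_index()
        df.columns = ["time", "survival"]
        out[str(grp)] = df
    return out


def logrank_test(clinical: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and two-sided p."""
    check_clinical(clinical)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValidationError("log-rank test needs exactly 2 groups")
    a = groups.index[groups == labels[0]]
    b = groups.index[groups == labels[1]]
    if clinical.loc[a, "event"].sum() < 1 or clinical.loc[b, "event"].sum() < 1:
        raise InestimableError("each group needs at least one event")
    res = _ll_logrank(
        clinical.loc[a, "os_days"], clinical.loc[b, "os_days"],
        clinical.loc[a, "event"], clinical.loc[b, "event"],
    )
    return float(res.test_statistic), float(res.p_value)


def time_dependent_auc(
    scores: pd.Series, clinical: pd.DataFrame, eval_time: float
) -> float:
    """Cumulative/dynamic AUC at one evaluation time.

    Cases are samples with an event by ``eval_time``; controls are
    samples still under observation past it; samples censored before
    ``eval_time`` are excluded. The AUC is the Mann-Whitney probability
    that a case outscores a control, ties counting one half.
    """
    check_clinical(clinical)
    s = scores.loc[clinical.index].values.astype(float)
    t = clinical["os_days"].values.astype(float)
    e = clinical["event"].values.astype(int)
    case = (e == 1) & (t <= eval_time)
    control = t > eval_time
    if case.sum() == 0 or control.sum() == 0:
        raise InestimableError(f"no cases or no controls at t={eval_time}")
    cs, ct = s[case], s[control]
    wins = (cs[:, None] > ct[None, :]).sum() + 0.5 * (cs[:, None] == ct[None, :]).sum()
    return float(wins / (len(cs) * len(ct)))


def auc_over_grid(
    scores: pd.Series,
    clinical: pd.DataFrame,
    eval_times: Sequence[float] = DEFAULT_EVAL_TIMES,
) -> pd.DataFrame:
    """Time-dependent AUC over an evaluation grid; undefined times get NaN."""
    rows = []
    for t in eval_times:
        try:
            auc = time_dependent_auc(scores, clinical, t)
        except InestimableError:
            auc = np.nan
        rows.append({"time": float(t), "auc": auc})
    return pd.DataFrame(rows)
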