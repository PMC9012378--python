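"""Tertile risk stratification and per-tertile odds-ratio models.

Scores pooled over every cohort (both case groups plus the shared
controls) are cut at their empirical 1/3 and 2/3 quantiles into three
risk groups T1 < T2 < T3.  For each case cohort versus the shared
controls, per-tertile odds ratios against the T1 reference come from a
logistic regression on tertile indicators, optionally adjusted for
clinical covariates and genotype principal components; cumulative
sensitivity/specificity at each tertile threshold and the ordinal AUROC
complete a publication-style risk table.

Quantile convention: nearest rank — with n pooled scores the cut points
are the order statistics at 0-based indices floor(n/3) and floor(2n/3),
samples strictly below a cut point fall in the lower group and boundary
ties all go up.  With distinct scores this yields group sizes within one
of n/3 (exactly n/3 when 3 | n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin

from .metrics import auroc_from_ordinal, threshold_metrics

TERTILE_LABELS = ("T1", "T2", "T3")


# ---------------------------------------------------------------------------
# Tertile stratification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TertileAssignment:
    """Pooled-tertile cut points and per-sample group labels."""

    boundaries: tuple[float, float]
    groups: pd.Series  # sample_id -> 'T1'|'T2'|'T3'
    pooling: str = "all samples"

    def counts(self) -> pd.Series:
        return self.groups.value_counts().reindex(TERTILE_LABELS, fill_value=0)


class TertileStratifier(BaseEstimator, TransformerMixin):
    """Learn pooled tertile cut points; assign samples to T1/T2/T3.

    ``fit`` takes the pooled score vector that defines the boundaries
    (cases of every cohort plus shared controls); ``transform`` maps any
    score vector onto the learned groups.  Boundary ties go to the upper
    group, making the assignment deterministic and order-independent.

    Attributes: ``boundaries_`` (lower, upper cut points).
    """

    def fit(self, scores: np.ndarray, y=None) -> "TertileStratifier":
        s = np.asarray(scores, dtype=float)
        if s.ndim != 1:
            s = s.ravel()
        if s.size < 3:
            raise ValueError("need at least 3 scores to form tertiles")
        if not np.isfinite(s).all():
            raise ValueError("scores must be finite")
        if np.ptp(s) == 0:
            raise ValueError("degenerate stratification: all scores identical")
        srt = np.sort(s)
        n = s.size
        self.boundaries_ = (float(srt[n // 3]), float(srt[(2 * n) // 3]))
        if self.boundaries_[0] == self.boundaries_[1]:
            warnings.warn(
                "tertile boundaries coincide (heavy ties); middle group is empty",
                stacklevel=2,
            )
        return self

    def transform(self, scores: np.ndarray) -> np.ndarray:
        lo, hi = self.boundaries_
        s = np.asarray(scores, dtype=float)
        out = np.where(s < lo, "T1", np.where(s < hi, "T2", "T3"))
        return out


def tertile_stratify(scores: pd.Series | np.ndarray) -> TertileAssignment:
    """Stratify a pooled score vector into tertile risk groups."""
    if isinstance(scores, pd.Series):
        index = scores.index
        values = scores.to_numpy(float)
    else:
        values = np.asarray(scores, float)
        index = pd.RangeIndex(values.size)
    strat = TertileStratifier().fit(values)
    groups = pd.Series(strat.transform(values), index=index, name="tertile")
    return TertileAssignment(strat.boundaries_, groups)


# ---------------------------------------------------------------------------
# Logistic fits
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class LogisticFit:
    """Logistic regression summary: log-odds coefficients, ORs, Wald CIs."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    converged: bool
    separation: bool
    method: str  # 'mle' | 'firth'
    n_cases: int
    n_controls: int
    alpha: float = 0.05
    odds_ratios: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        z = norm.ppf(1.0 - self.alpha / 2.0)
        self.odds_ratios = pd.DataFrame(
            {
                "or": np.exp(self.params),
                "ci_low": np.exp(self.params - z * self.bse),
                "ci_high": np.exp(self.params + z * self.bse),
                "p": self.pvalues,
            }
        )


def _firth_logit(y: np.ndarray, X: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Bias-reduced logistic regression (Jeffreys-prior penalized score)."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XW = X * w[:, None]
        info = X.T @ XW
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise ValueError("rank-deficient design in Firth refit") from exc
        # leverages of the weighted hat matrix
        h = np.einsum("ij,jk,ik->i", X * np.sqrt(w)[:, None], info_inv, X * np.sqrt(w)[:, None])
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = X.T @ (X * w[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se


def fit_logistic(
    y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    firth: str | bool = "auto",
    alpha: float = 0.05,
) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald odds-ratio CIs.

    ``X`` must include an intercept column.  Separation or
    non-convergence is flagged; with ``firth='auto'`` (default) such fits
    are redone with a bias-reduced (Jeffreys-penalized) estimator whose
    finite estimates remain interpretable under separation.
    ``firth=True`` forces the penalized fit, ``firth=False`` never
    refits.
    """
    Xdf = pd.DataFrame(X).astype(float)
    y = np.asarray(y).astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("y must contain both classes")
    if len(y) <= Xdf.shape[1]:
        raise ValueError("need more observations than design columns")
    if np.linalg.matrix_rank(Xdf.to_numpy()) < Xdf.shape[1]:
        raise ValueError("rank-deficient design matrix")
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())

    def _finish(params, bse, pvals, converged, separation, method):
        return LogisticFit(
            params=pd.Series(params, index=Xdf.columns),
            bse=pd.Series(bse, index=Xdf.columns),
            pvalues=pd.Series(pvals, index=Xdf.columns),
            converged=converged,
            separation=separation,
            method=method,
            n_cases=n_cases,
            n_controls=n_controls,
            alpha=alpha,
        )

    if firth is not True:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, Xdf).fit(disp=0, maxiter=200)
                converged = bool(res.mle_retvals.get("converged", False))
            except Exception:
                res, converged = None, False
        if res is not None:
            # separation heuristic: runaway coefficients or exploded SEs
            separation = bool(
                (np.abs(res.params) > 15).any() or (res.bse > 200).any()
            )
            if converged and not separation:
                return _finish(res.params, res.bse, res.pvalues, True, False, "mle")
            if firth is False:
                warnings.warn(
                    "logistic fit did not converge cleanly (possible separation); "
                    "estimates may be unstable",
                    stacklevel=2,
                )
                return _finish(res.params, res.bse, res.pvalues, converged, separation, "mle")
        warnings.warn(
            "separation or non-convergence detected; using Firth bias-reduced refit",
            stacklevel=2,
        )
    beta, se = _firth_logit(y, Xdf.to_numpy())
    zstat = beta / se
    pvals = 2 * norm.sf(np.abs(zstat))
    return _finish(beta, se, pvals, True, False, "firth")


# ---------------------------------------------------------------------------
# Per-tertile risk table
# ---------------------------------------------------------------------------

def _tertile_design(groups: np.ndarray, covariates: pd.DataFrame | None) -> pd.DataFrame:
    X = pd.DataFrame(
        {
            "const": 1.0,
            "T2": (groups == "T2").astype(float),
            "T3": (groups == "T3").astype(float),
        }
    )
    if covariates is not None:
        X = pd.concat([X.reset_index(drop=True), covariates.reset_index(drop=True)], axis=1)
    return X


def tertile_risk_table(
    assignment: TertileAssignment,
    cohort: pd.DataFrame,
    adjust: list[str] | None = None,
    firth: str | bool = "auto",
) -> pd.DataFrame:
    """Per-tertile risk table for each case cohort vs the shared controls.

    ``assignment.groups`` must be indexed by sample_id; ``cohort`` needs
    ``sample_id``, ``label`` ('case'/'control'), ``cohort`` (cohort tag)
    and any adjustment covariate columns named in ``adjust``.

    Returns one row per (case cohort, tertile) with case/control counts
    and percentages, odds ratio vs T1 with Wald 95% CI and p-value
    (adjusted when ``adjust`` given), cumulative sensitivity/specificity
    at that tertile threshold, and the three-level ordinal AUROC (stored
    on the T3 row).
    """
    cohort = cohort.copy()
    cohort["sample_id"] = cohort["sample_id"].astype(str)
    groups = assignment.groups
    merged = cohort.set_index("sample_id")
    missing = [s for s in merged.index if s not in groups.index]
    if missing:
        raise ValueError(f"samples without tertile assignment: {missing[:5]}...")
    merged["tertile"] = groups.reindex(merged.index)

    controls = merged[merged["label"] == "control"]
    if controls.empty:
        raise ValueError("no control samples")
    control_counts = controls["tertile"].value_counts().reindex(TERTILE_LABELS, fill_value=0)
    if control_counts["T1"] == 0:
        raise ValueError("empty reference tertile (T1) among controls; ORs undefined")

    case_tags = sorted(merged.loc[merged["label"] == "case", "cohort"].unique())
    rows = []
    fits: dict[str, LogisticFit] = {}
    for tag in case_tags:
        cases = merged[(merged["label"] == "case") & (merged["cohort"] == tag)]
        case_counts = cases["tertile"].value_counts().reindex(TERTILE_LABELS, fill_value=0)
        if case_counts["T1"] == 0:
            raise ValueError(f"empty reference tertile (T1) among {tag} cases; ORs undefined")
        sub = pd.concat([cases, controls])
        y = (sub["label"] == "case").to_numpy(float)
        cov = sub[adjust].astype(float) if adjust else None
        X = _tertile_design(sub["tertile"].to_numpy(), cov)
        fit = fit_logistic(y, X, firth=firth)
        fits[tag] = fit
        roc = auroc_from_ordinal(case_counts.to_numpy(), control_counts.to_numpy())
        n_case, n_control = int(case_counts.sum()), int(control_counts.sum())
        for lvl, label in enumerate(TERTILE_LABELS):
            sens, spec, acc = threshold_metrics(
                case_counts.to_numpy(), control_counts.to_numpy(), lvl
            )
            row = {
                "cohort": tag,
                "tertile": label,
                "n_case": int(case_counts[label]),
                "pct_case": 100.0 * case_counts[label] / n_case,
                "n_control": int(control_counts[label]),
                "pct_control": 100.0 * control_counts[label] / n_control,
                "or": 1.0 if label == "T1" else fit.odds_ratios.loc[label, "or"],
                "ci_low": np.nan if label == "T1" else fit.odds_ratios.loc[label, "ci_low"],
                "ci_high": np.nan if label == "T1" else fit.odds_ratios.loc[label, "ci_high"],
                "p": np.nan if label == "T1" else fit.odds_ratios.loc[label, "p"],
                "sensitivity": sens,
                "specificity": spec,
                "accuracy": acc,
                "auroc": roc.auroc if label == "T3" else np.nan,
            }
            rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["boundaries"] = assignment.boundaries
    table.attrs["fits"] = fits
    return table


class TertileRiskModel(BaseEstimator):
    """End-to-end pooled-tertile risk model.

    ``fit`` pools the supplied scores to learn tertile boundaries, then
    builds the per-cohort risk table with (optionally adjusted) odds
    ratios against the lowest tertile.

    Parameters
    ----------
    adjust : covariate column names for the logistic adjustment, or None
    firth : separation policy passed to :func:`fit_logistic`

    Attributes
    ----------
    stratifier_ : fitted TertileStratifier
    assignment_ : TertileAssignment for the pooled samples
    table_ : risk table DataFrame (see :func:`tertile_risk_table`)
    """

    def __init__(self, adjust: list[str] | None = None, firth: str | bool = "auto") -> None:
        self.adjust = adjust
        self.firth = firth

    def fit(self, scores: pd.Series, cohort: pd.DataFrame) -> "TertileRiskModel":
        if not isinstance(scores, pd.Series):
            raise TypeError("scores must be a pandas Series indexed by sample_id")
        self.assignment_ = tertile_stratify(scores)
        self.stratifier_ = TertileStratifier().fit(scores.to_numpy(float))
        self.table_ = tertile_risk_table(
            self.assignment_, cohort, adjust=self.adjust, firth=self.firth
        )
        return self


__all__ = [
    "TERTILE_LABELS",
    "TertileAssignment",
    "TertileStratifier",
    "tertile_stratify",
    "LogisticFit",
    "fit_logistic",
    "tertile_risk_table",
    "TertileRiskModel",
]
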