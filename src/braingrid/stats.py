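"""Seizure-association statistics.

Effect measures and regression machinery for the cell-level seizure scan:

* closed-form 2×2 odds ratio and relative risk with log-scale Wald 95% CIs;
* maximum-likelihood logistic regression (via iteratively reweighted least
  squares) with explicit convergence and separation flags;
* a univariate per-cell logistic scan of seizure on cell involvement,
  reporting nominal p-values without multiplicity adjustment by default
  (Benjamini–Hochberg available behind a flag);
* forward stepwise selection with conditional removal: entry by Rao score
  test, removal re-check by likelihood-ratio test, with the conventional
  defaults p_enter = 0.05 and p_remove = 0.10;
* subgroup scans by diagnosis and/or grade.

Degenerate cells (involved in fewer than ``min_involved`` patients, or in
all but fewer than ``min_involved``) are excluded with a stated reason
rather than silently fitted; separated fits are flagged and their estimates
withheld rather than shrunk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

logger = logging.getLogger("braingrid")

__all__ = [
    "TwoByTwo",
    "EffectEstimate",
    "LogisticFit",
    "CellAssociation",
    "StepwiseResult",
    "odds_ratio",
    "relative_risk",
    "fit_logistic",
    "univariate_scan",
    "stepwise_multivariate",
    "subgroup_scan",
]

Z95 = sps.norm.ppf(0.975)

#: |coefficient| beyond which a logistic fit is treated as diverging
#: (odds ratios beyond e^15 ≈ 3×10^6 have no epidemiological meaning).
SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure × outcome contingency counts.

    ``a``: exposed with outcome, ``b``: exposed without,
    ``c``: unexposed with outcome, ``d``: unexposed without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @classmethod
    def from_vectors(cls, exposure, outcome) -> "TwoByTwo":
        e = np.asarray(exposure, bool)
        o = np.asarray(outcome, bool)
        return cls(
            int((e & o).sum()), int((e & ~o).sum()),
            int((~e & o).sum()), int((~e & ~o).sum()),
        )


@dataclass(frozen=True)
class EffectEstimate:
    measure: str  # "OR" or "RR"
    point: float
    ci_low: float
    ci_high: float
    p: float
    method: str
    estimable: bool = True

    def __post_init__(self) -> None:
        if self.estimable:
            if not (self.ci_low <= self.point <= self.ci_high):
                raise ValueError("confidence interval must contain the point estimate")
            if not (0.0 <= self.p <= 1.0):
                raise ValueError("p-value outside [0, 1]")


def _not_estimable(measure: str, method: str) -> EffectEstimate:
    return EffectEstimate(measure, np.nan, np.nan, np.nan, np.nan, method, estimable=False)


def odds_ratio(t: TwoByTwo) -> EffectEstimate:
    """Cross-product odds ratio with log-scale Wald 95% CI and Wald p.

    Any zero cell makes the OR (or its standard error) non-finite; such
    tables are flagged non-estimable — no continuity correction is applied
    by default.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return _not_estimable("OR", "2x2 cross-product")
    log_or = np.log(t.a) + np.log(t.d) - np.log(t.b) - np.log(t.c)
    se = np.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    z = log_or / se
    return EffectEstimate(
        "OR",
        float(np.exp(log_or)),
        float(np.exp(log_or - Z95 * se)),
        float(np.exp(log_or + Z95 * se)),
        float(2 * sps.norm.sf(abs(z))),
        "2x2 cross-product",
    )


def relative_risk(t: TwoByTwo) -> EffectEstimate:
    """Risk ratio [a/(a+b)] / [c/(c+d)] with log-scale Wald 95% CI."""
    n1, n0 = t.a + t.b, t.c + t.d
    if n1 == 0 or n0 == 0:
        raise ValueError("both exposure groups must be non-empty")
    if t.a == 0 or t.c == 0:
        return _not_estimable("RR", "risk ratio")
    log_rr = np.log(t.a / n1) - np.log(t.c / n0)
    se = np.sqrt(1 / t.a - 1 / n1 + 1 / t.c - 1 / n0)
    z = log_rr / se
    return EffectEstimate(
        "RR",
        float(np.exp(log_rr)),
        float(np.exp(log_rr - Z95 * se)),
        float(np.exp(log_rr + Z95 * se)),
        float(2 * sps.norm.sf(abs(z))),
        "risk ratio",
    )


# --------------------------------------------------------------------------
# logistic regression
# --------------------------------------------------------------------------


@dataclass
class LogisticFit:
    params: np.ndarray
    cov: np.ndarray
    llf: float
    converged: bool
    separated: bool
    names: list[str]
    n: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald_table(self) -> pd.DataFrame:
        se = self.se
        z = self.params / se
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": se,
                "OR": np.exp(self.params),
                "ci_low": np.exp(self.params - Z95 * se),
                "ci_high": np.exp(self.params + Z95 * se),
                "p": 2 * sps.norm.sf(np.abs(z)),
            },
            index=self.names,
        )


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: Optional[Sequence[str]] = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic fit (IRLS/Newton) with degeneracy flags.

    ``X`` must include the intercept column.  Complete or quasi-complete
    separation — a diverging coefficient (|coef| > 15) or an optimizer
    separation error — sets ``separated``; callers must not report such
    coefficients as estimates.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, p) aligned with y")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    sd = X.std(axis=0)
    const_cols = np.flatnonzero(sd == 0)
    if len(const_cols) > 1 or (len(const_cols) == 1 and not np.all(X[:, const_cols[0]] == 1)):
        raise ValueError("constant (zero-variance) predictor column")
    if names is None:
        names = [f"x{i}" for i in range(p)]
    separated = False
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", tol=tol, maxiter=maxiter)
            params = np.asarray(res.params, float)
            cov = np.asarray(res.cov_params(), float)
            llf = float(res.llf)
            converged = bool(res.mle_retvals.get("converged", False))
        except (PerfectSeparationError, PerfectSeparationWarning):
            return LogisticFit(
                np.full(p, np.nan), np.full((p, p), np.nan), np.nan,
                False, True, list(names), n,
            )
        except np.linalg.LinAlgError:
            # singular information matrix: fall back to BFGS to get a
            # diagnosis, then flag
            res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=maxiter)
            params = np.asarray(res.params, float)
            cov = np.full((p, p), np.nan)
            llf = float(res.llf)
            converged = False
    if np.max(np.abs(params)) > SEPARATION_BOUND:
        separated = True
    return LogisticFit(params, cov, llf, converged, separated, list(names), n)


# --------------------------------------------------------------------------
# per-cell univariate scan
# --------------------------------------------------------------------------


@dataclass
class CellAssociation:
    cell: str
    n_involved: int
    estimate: Optional[EffectEstimate]
    flag: str  # "ok" | "degenerate" | "separated"
    reason: str = ""


def univariate_scan(
    matrix,
    outcome: pd.Series,
    min_involved: int = 1,
    adjust: Optional[str] = None,
) -> list[CellAssociation]:
    """Univariate logistic regression of seizure on involvement, per cell.

    Cells with fewer than ``min_involved`` involved patients (or fewer than
    ``min_involved`` uninvolved) are excluded as degenerate with a stated
    reason.  p-values are nominal; ``adjust="bh"`` appends
    Benjamini–Hochberg adjusted p-values to the estimable cells' estimates
    via a parallel return through :func:`scan_frame`.
    """
    frame = matrix.frame
    outcome = outcome.reindex(frame.index)
    keep = outcome.notna()
    frame = frame.loc[keep]
    y = outcome.loc[keep].astype(bool).to_numpy()
    n = len(frame)
    results: list[CellAssociation] = []
    for label in frame.columns:
        x = frame[label].to_numpy()
        n_inv = int(x.sum())
        if n_inv < min_involved or (n - n_inv) < min_involved:
            results.append(
                CellAssociation(
                    label, n_inv, None, "degenerate",
                    f"involved={n_inv} of {n} (min_involved={min_involved})",
                )
            )
            continue
        t = TwoByTwo.from_vectors(x.astype(bool), y)
        if min(t.a, t.b, t.c, t.d) == 0:
            # a zero 2x2 cell is exact separation for the logistic fit
            results.append(
                CellAssociation(
                    label, n_inv, None, "separated",
                    f"zero contingency cell (a={t.a}, b={t.b}, c={t.c}, d={t.d})",
                )
            )
            continue
        X = np.column_stack([np.ones(n), x])
        fit = fit_logistic(X, y.astype(float), names=["const", label])
        if fit.separated or not fit.converged:
            results.append(
                CellAssociation(label, n_inv, None, "separated", "non-finite MLE")
            )
            continue
        tab = fit.wald_table().loc[label]
        est = EffectEstimate(
            "OR", float(tab["OR"]), float(tab["ci_low"]), float(tab["ci_high"]),
            float(tab["p"]), "univariate logistic",
        )
        results.append(CellAssociation(label, n_inv, est, "ok"))
    n_ok = sum(1 for r in results if r.flag == "ok")
    if n_ok == 0:
        logger.warning("univariate scan: all %d cells degenerate or separated", len(results))
    else:
        logger.info("univariate scan: %d of %d cells estimable", n_ok, len(results))
    if adjust is not None and adjust.lower() not in ("none", "bh", "fdr_bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    return results


def scan_frame(results: list[CellAssociation], adjust: Optional[str] = None) -> pd.DataFrame:
    """Tabulate a scan as a DataFrame (one row per cell), optionally adding
    Benjamini–Hochberg adjusted p-values for the estimable cells."""
    rows = []
    for r in results:
        e = r.estimate
        rows.append(
            {
                "cell": r.cell,
                "n_involved": r.n_involved,
                "OR": e.point if e else np.nan,
                "ci_low": e.ci_low if e else np.nan,
                "ci_high": e.ci_high if e else np.nan,
                "p": e.p if e else np.nan,
                "flag": r.flag,
                "reason": r.reason,
            }
        )
    df = pd.DataFrame(rows).set_index("cell")
    if adjust is not None and adjust.lower() in ("bh", "fdr_bh"):
        ok = df["flag"] == "ok"
        adj = np.full(len(df), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
        df["p_bh"] = adj
    return df


# --------------------------------------------------------------------------
# stepwise multivariate model
# --------------------------------------------------------------------------


@dataclass
class StepwiseResult:
    steps: list[dict]
    selected: list[str]
    confounders: list[str]
    fit: Optional[LogisticFit]
    table: Optional[pd.DataFrame]
    p_enter: float
    p_remove: float
    flag: str = "ok"  # "ok" | "empty"


def _score_test(X_base: np.ndarray, y: np.ndarray, fitted_p: np.ndarray, x_new: np.ndarray) -> float:
    """Rao score test p-value for adding one column to a fitted model.

    At the base MLE the score of the current coefficients vanishes, so the
    statistic reduces to U² · [I⁻¹]_new,new with U = x_newᵀ(y − p̂) and I the
    expanded-model information matrix.
    """
    Xf = np.column_stack([X_base, x_new])
    w = fitted_p * (1 - fitted_p)
    info = (Xf * w[:, None]).T @ Xf
    try:
        inv_last = np.linalg.inv(info)[-1, -1]
    except np.linalg.LinAlgError:
        return np.nan
    u = float(x_new @ (y - fitted_p))
    stat = u * u * inv_last
    return float(sps.chi2.sf(stat, 1))


def _is_collinear(X_base: np.ndarray, x_new: np.ndarray) -> bool:
    Xf = np.column_stack([X_base, x_new])
    return np.linalg.matrix_rank(Xf) < Xf.shape[1]


def stepwise_multivariate(
    data: pd.DataFrame,
    candidates: Sequence[str],
    outcome: str,
    confounders: Sequence[str] = (),
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 100,
) -> StepwiseResult:
    """Forward selection with conditional removal on a logistic model.

    Confounders are always retained in the design; candidate variables
    enter by the smallest score-test p-value below ``p_enter`` (ties broken
    lexicographically) and already-entered candidates are re-checked for
    removal by likelihood-ratio test against ``p_remove`` after every entry.
    The full step log is recorded, so the procedure is auditable and
    deterministic for a given input.
    """
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    if not (0 < p_enter <= p_remove < 1):
        raise ValueError("need 0 < p_enter <= p_remove < 1")
    y = data[outcome].astype(float).to_numpy()
    n = len(data)

    def design(variables: Sequence[str]) -> tuple[np.ndarray, list[str]]:
        names = ["const", *confounders, *variables]
        cols = [np.ones(n)] + [data[v].astype(float).to_numpy() for v in names[1:]]
        return np.column_stack(cols), names

    steps: list[dict] = []
    selected: list[str] = []
    remaining = list(candidates)
    X, names = design(selected)
    fit = fit_logistic(X, y, names=names)
    for _ in range(max_steps):
        p_hat = 1.0 / (1.0 + np.exp(-(X @ fit.params)))
        entry_p: dict[str, float] = {}
        for var in remaining:
            x_new = data[var].astype(float).to_numpy()
            if _is_collinear(X, x_new):
                steps.append({"action": "skip", "variable": var, "reason": "collinear"})
                continue
            entry_p[var] = _score_test(X, y, p_hat, x_new)
        viable = {v: p for v, p in entry_p.items() if np.isfinite(p) and p < p_enter}
        if not viable:
            break
        best = min(viable, key=lambda v: (viable[v], v))
        selected.append(best)
        remaining.remove(best)
        X, names = design(selected)
        fit = fit_logistic(X, y, names=names)
        steps.append({"action": "enter", "variable": best, "p": viable[best]})
        # conditional removal: LR-test each entered candidate, drop the worst
        changed = True
        while changed and selected:
            changed = False
            removal_p = {}
            for var in selected:
                reduced = [v for v in selected if v != var]
                Xr, nr = design(reduced)
                fr = fit_logistic(Xr, y, names=nr)
                lr = 2 * (fit.llf - fr.llf)
                removal_p[var] = float(sps.chi2.sf(max(lr, 0.0), 1))
            worst = max(removal_p, key=lambda v: (removal_p[v], v))
            if removal_p[worst] > p_remove:
                selected.remove(worst)
                remaining.append(worst)
                X, names = design(selected)
                fit = fit_logistic(X, y, names=names)
                steps.append({"action": "remove", "variable": worst, "p": removal_p[worst]})
                changed = True
    flag = "ok" if selected else "empty"
    table = fit.wald_table() if not fit.separated else None
    return StepwiseResult(
        steps, selected, list(confounders), fit, table, p_enter, p_remove, flag
    )


# --------------------------------------------------------------------------
# subgroup scans
# --------------------------------------------------------------------------

MIN_SUBGROUP = 10


def subgroup_scan(
    cohort,
    matrix,
    diagnosis: Optional[str] = None,
    grade: Optional[int] = None,
    min_involved: int = 1,
    min_subgroup: int = MIN_SUBGROUP,
    adjust: Optional[str] = None,
) -> list[CellAssociation]:
    """Univariate scan restricted to a diagnosis and/or grade stratum."""
    df = cohort.to_frame()
    keep = pd.Series(True, index=df.index)
    if diagnosis is not None:
        keep &= df["diagnosis"] == diagnosis
    if grade is not None:
        keep &= df["grade"] == grade
    ids = df.index[keep]
    ids = [i for i in ids if i in matrix.frame.index]
    if len(ids) < min_subgroup:
        raise ValueError(
            f"subgroup (diagnosis={diagnosis}, grade={grade}) has {len(ids)} "
            f"patients, below the minimum of {min_subgroup}"
        )
    logger.info("subgroup scan: diagnosis=%s grade=%s n=%d", diagnosis, grade, len(ids))
    sub_matrix = type(matrix)(matrix.frame.loc[ids], matrix.threshold_ml, {})
    outcome = df.loc[ids, "seizure"]
    return univariate_scan(sub_matrix, outcome, min_involved=min_involved, adjust=adjust)
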