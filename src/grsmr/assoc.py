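"""Self-contained association engine for case-control analyses.

Implements the statistics the score pipeline reports: logistic
regression fitted by Newton/IRLS with observed-information Wald
inference, crude 2x2 odds ratios with Woolf standard errors, Pearson
chi-square and Fisher exact tests for 2x2 tables, allelic odds ratios
from allele frequencies, and ordinal trend tests across exposure
categories. Only tail probabilities of reference distributions are
delegated to :mod:`scipy.stats`; every estimator and test statistic is
computed here so results are fully reproducible and auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .types import AssocResult, ContingencyTable

__all__ = [
    "SeparationError",
    "RankDeficiencyError",
    "LogisticFit",
    "fit_logistic",
    "wald_ci",
    "crude_or",
    "allelic_or_from_eaf",
    "chisq_2x2",
    "fisher_exact",
    "trend_test",
    "cochran_armitage_trend",
    "eaf",
    "exposure_result",
]

Z_975 = 1.959964  # Phi^-1(0.975)

# Newton/IRLS convergence constants; fixed so reruns are deterministic.
MAX_ITER = 50
SCORE_TOL = 1e-8
DEV_TOL = 1e-10
_SEP_PROB = 1e-9
_SEP_COEF = 30.0


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the aliased column."""


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit with observed-information covariance."""

    params: np.ndarray
    cov: np.ndarray
    names: tuple[str, ...]
    deviance: float
    n_iter: int
    converged: bool
    n: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald_p(self, index: int) -> float:
        z = self.params[index] / self.se[index]
        return float(2.0 * stats.norm.sf(abs(z)))

    def term(self, name: str) -> int:
        return self.names.index(name)

    def result(self, name: str, model: str = "") -> AssocResult:
        """Package one coefficient as an :class:`AssocResult`."""
        j = self.term(name)
        return AssocResult(
            estimate=float(self.params[j]),
            se=float(self.se[j]),
            p=self.wald_p(j),
            n=self.n,
            model=model or f"logistic({'+'.join(self.names)})",
        )


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    # QR with column pivoting localizes the aliased column on rank drop.
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[j] for j in piv[rank:]]
        raise RankDeficiencyError(f"design matrix rank deficient; aliased: {aliased}")


def fit_logistic(
    outcome: np.ndarray,
    design: np.ndarray,
    names: Sequence[str] | None = None,
    max_iter: int = MAX_ITER,
) -> LogisticFit:
    """Fit a binary logistic model by Newton-Raphson (IRLS).

    Parameters
    ----------
    outcome
        Binary 0/1 vector.
    design
        n x p covariate matrix including the intercept column.
    names
        Column names; defaults to ``x0..x{p-1}``.

    Convergence is declared when the largest score component falls
    below 1e-8 or the deviance change below 1e-10 (at most 50
    iterations). Standard errors come from the inverse observed
    information at the optimum. Raises :class:`SeparationError` when
    fitted probabilities pin at 0/1 with diverging coefficients, and
    :class:`RankDeficiencyError` for an aliased design column.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design must be n x p with n matching outcome")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    p = X.shape[1]
    names = tuple(names) if names is not None else tuple(f"x{j}" for j in range(p))
    if len(names) != p:
        raise ValueError("names length mismatch")
    _check_design(X, names)

    beta = np.zeros(p)
    dev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = _expit(eta)
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        # Separation: probabilities pinned at the data's labels while
        # coefficients run away -> likelihood has no interior maximum.
        pinned = ((mu < _SEP_PROB) | (mu > 1.0 - _SEP_PROB)).mean()
        if np.abs(beta).max() > _SEP_COEF and pinned > 0.5:
            raise SeparationError(
                "separation detected: fitted probabilities pinned at 0/1 "
                f"with max|coef| = {np.abs(beta).max():.1f}"
            )
        if np.abs(score).max() < SCORE_TOL:
            converged = True
            break
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        beta = beta + step
        new_dev = _deviance(y, _expit(X @ beta))
        if abs(dev - new_dev) < DEV_TOL:
            dev = new_dev
            converged = True
            break
        dev = new_dev
    mu = _expit(X @ beta)
    if not converged and np.abs(beta).max() > _SEP_COEF:
        raise SeparationError(
            f"no convergence in {max_iter} iterations with diverging coefficients"
        )
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    return LogisticFit(
        params=beta,
        cov=cov,
        names=names,
        deviance=_deviance(y, mu),
        n_iter=it,
        converged=converged,
        n=y.shape[0],
    )


def _expit(eta: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * eta))  # numerically symmetric expit


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    eps = 1e-300
    ll = y * np.log(mu + eps) + (1.0 - y) * np.log(1.0 - mu + eps)
    return float(-2.0 * ll.sum())


def wald_ci(estimate: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval on the odds-ratio scale, exp(b +/- z*se)."""
    if se <= 0:
        raise ValueError("se must be positive")
    z = Z_975 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2.0))
    return math.exp(estimate - z * se), math.exp(estimate + z * se)


def crude_or(table: ContingencyTable) -> AssocResult:
    """Unadjusted cross-product odds ratio ad/bc with the Woolf SE.

    A zero cell triggers the Haldane-Anscombe correction (0.5 added to
    every cell, flagged on the result); a zero margin leaves the odds
    ratio undefined and raises.
    """
    if 0 in table.margins():
        raise ValueError("zero margin: odds ratio undefined")
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    est = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = est / se
    return AssocResult(
        estimate=est,
        se=se,
        p=float(2.0 * stats.norm.sf(abs(z))),
        n=table.n,
        model="crude 2x2",
        corrected=corrected,
    )


def allelic_or_from_eaf(eaf_case: float, eaf_control: float) -> float:
    """Allelic odds ratio from effect-allele frequencies in each group."""
    for v in (eaf_case, eaf_control):
        if not 0.0 < v < 1.0:
            raise ValueError("allele frequency must lie strictly in (0, 1)")
    return (eaf_case / (1.0 - eaf_case)) / (eaf_control / (1.0 - eaf_control))


def chisq_2x2(
    table: ContingencyTable, continuity: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test for a 2x2 table, 1 df.

    ``continuity=True`` applies the Yates correction (off by default).
    Returns ``(statistic, p)``.
    """
    r1, r2, c1, c2 = table.margins()
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin")
    a, b, c, d = table.a, table.b, table.c, table.d
    num = abs(a * d - b * c)
    if continuity:
        num = max(num - table.n / 2.0, 0.0)
    statistic = float(num**2 * table.n / (r1 * r2 * c1 * c2))
    return statistic, float(stats.chi2.sf(statistic, 1))


def fisher_exact(table: ContingencyTable, max_total: int = 100_000) -> float:
    """Two-sided Fisher exact p by point-probability enumeration.

    With margins fixed, sums the hypergeometric probabilities of every
    table whose probability does not exceed the observed one (a small
    relative tolerance absorbs floating-point ties).
    """
    if table.n > max_total:
        raise ValueError(
            f"table total {table.n} exceeds enumeration cap {max_total}; "
            "use chisq_2x2"
        )
    r1, r2, c1, c2 = table.margins()
    # Degenerate margins collapse the support to one table and give p = 1.
    # Support of the (unexposed, control) cell a given fixed margins.
    lo = max(0, r1 - c2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, table.n, r1, c1)
    p_obs = stats.hypergeom.pmf(table.a, table.n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)


def trend_test(
    outcome: np.ndarray,
    category_index: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: Sequence[str] | None = None,
) -> AssocResult:
    """Dose-response trend across ordered exposure categories.

    Fits a logistic model with the 1..k category index entered as a
    single ordinal numeric term (plus any covariates) and reports the
    Wald test of that term. Requires k >= 3 distinct categories.
    """
    cat = np.asarray(category_index, dtype=float).ravel()
    if np.unique(cat).size < 3:
        raise ValueError("trend test needs at least 3 categories")
    n = cat.shape[0]
    cols = [np.ones(n), cat]
    names = ["intercept", "trend"]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.extend(cov.T)
        names.extend(
            covariate_names
            if covariate_names is not None
            else [f"c{j}" for j in range(cov.shape[1])]
        )
    X = np.column_stack(cols)
    fit = fit_logistic(outcome, X, names)
    return fit.result("trend", model="logistic ordinal trend")


def cochran_armitage_trend(
    counts_control: Sequence[int], counts_case: Sequence[int]
) -> tuple[float, float]:
    """Cochran-Armitage test for trend with scores 1..k.

    Alternative to the ordinal-logistic Wald trend test; covariate-free.
    Returns ``(z, p)`` two-sided.
    """
    r0 = np.asarray(counts_control, dtype=float)
    r1 = np.asarray(counts_case, dtype=float)
    if r0.shape != r1.shape or r0.size < 3:
        raise ValueError("need matching control/case counts over >= 3 categories")
    scores = np.arange(1, r0.size + 1, dtype=float)
    n_k = r0 + r1
    n = n_k.sum()
    p_case = r1.sum() / n
    t = float((scores * (r1 - p_case * n_k)).sum())
    s_mean = (scores * n_k).sum() / n
    var = p_case * (1 - p_case) * ((scores - s_mean) ** 2 * n_k).sum()
    z = t / math.sqrt(var)
    return z, float(2.0 * stats.norm.sf(abs(z)))


def eaf(dosages: np.ndarray, subset: np.ndarray | None = None) -> float:
    """Effect-allele frequency: mean long-allele dosage / 2 over a subset."""
    x = np.asarray(dosages, dtype=float)
    if subset is not None:
        x = x[np.asarray(subset, dtype=bool)]
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("empty subset")
    return float(x.mean() / 2.0)


def exposure_result(
    outcome: np.ndarray,
    exposure: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: Sequence[str] | None = None,
    exposure_name: str = "exposure",
) -> AssocResult:
    """Adjusted logistic odds ratio for a single exposure term.

    Convenience wrapper used by every pipeline stage: intercept +
    exposure + optional covariates, Wald inference on the exposure.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    n = y.shape[0]
    cols = [np.ones(n), np.asarray(exposure, dtype=float).ravel()]
    names = ["intercept", exposure_name]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.extend(cov.T)
        names.extend(
            covariate_names
            if covariate_names is not None
            else [f"c{j}" for j in range(cov.shape[1])]
        )
    fit = fit_logistic(y, np.column_stack(cols), names)
    return fit.result(exposure_name)
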