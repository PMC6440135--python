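"""Binomial logit transition regression for ED departures.

Each 30-minute interval contributes one binomial observation: out of
n(t) = Q(t) + A(t) patients who could leave, D(t) actually do, with

    D(t) ~ Bin(n(t), p(t | t-1)),
    logit p(t | t-1) = alpha + sum_j delta_j D(t-j) + sum_i beta_i x_i(t),

where the delta terms absorb the serial correlation of departures and the
beta terms are the pre-specified system-level predictors (arrivals, queue
terms, shift, weekend and the shift-by-weekend interaction). exp(beta) is
the odds ratio of a departure per unit covariate, and its reciprocal the
multiplicative change in expected waiting time.

The fitter is iteratively reweighted least squares (Newton scoring with the
canonical logit link, for which expected and observed information agree);
convergence is declared when the deviance changes by less than 1e-10
relative between iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import expit, xlogy

MAX_ITER = 100
DEVIANCE_RTOL = 1e-10

RESERVED_COLUMNS = ("start", "D", "n")


class RankDeficiencyError(ValueError):
    """The covariate matrix does not have full column rank."""


def binomial_deviance(d: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    """Deviance 2*(loglik_saturated - loglik_model), with 0*log(0) := 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = xlogy(d, d) - xlogy(d, n * p) + xlogy(n - d, n - d) - xlogy(n - d, n * (1 - p))
    return float(2.0 * term.sum())


def binomial_loglik(d: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    """Binomial log-likelihood without the combinatorial constant."""
    return float((xlogy(d, p) + xlogy(n - d, 1.0 - p)).sum())


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Name the columns a rank-revealing QR flags as linearly dependent."""
    _, r, piv = linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[j] for j in sorted(piv[rank:])]


@dataclass
class _IRLSFit:
    params: np.ndarray
    cov: np.ndarray
    deviance: float
    deviances: list[float]
    converged: bool
    iterations: int


def _irls(
    d: np.ndarray, n: np.ndarray, x: np.ndarray, max_iter: int = MAX_ITER
) -> _IRLSFit:
    nobs, k = x.shape
    beta = np.zeros(k)
    # start from the pooled departure probability on the intercept
    pbar = min(max(d.sum() / n.sum(), 1e-6), 1 - 1e-6)
    beta[0] = np.log(pbar / (1 - pbar)) if np.allclose(x[:, 0], 1.0) else 0.0
    eta = x @ beta
    p = expit(eta)
    dev = binomial_deviance(d, n, p)
    deviances = [dev]
    converged = False
    it = 0
    xtwx = np.eye(k)
    for it in range(1, max_iter + 1):
        w = n * p * (1.0 - p)
        w = np.maximum(w, 1e-12)
        z = eta + (d - n * p) / w
        xw = x * w[:, None]
        xtwx = x.T @ xw
        beta_new = np.linalg.solve(xtwx, xw.T @ z)
        eta = x @ beta_new
        p = expit(eta)
        dev_new = binomial_deviance(d, n, p)
        beta = beta_new
        deviances.append(dev_new)
        if abs(dev - dev_new) < DEVIANCE_RTOL * (abs(dev) + 0.1):
            converged = True
            dev = dev_new
            break
        dev = dev_new
    if np.max(np.abs(beta)) > 30.0:
        warnings.warn(
            "divergent coefficients: possible complete separation", RuntimeWarning
        )
    w = np.maximum(n * p * (1.0 - p), 1e-12)
    xtwx = x.T @ (x * w[:, None])
    cov = np.linalg.inv(xtwx)
    return _IRLSFit(beta, cov, dev, deviances, converged, it)


class DepartureModel:
    """Transition regression model for departures, built from a design table.

    Parameters
    ----------
    design : DataFrame
        Output of :func:`edtransit.census.build_design` (or a compatible
        frame): response column ``D``, trial column ``n``, one column per
        covariate. Any other columns besides ``start`` are treated as
        covariates.
    covariates : sequence of str, optional
        Restrict the model to a subset of covariate columns, e.g. to fit
        the no-interaction model for the likelihood-ratio test.
    """

    def __init__(self, design: pd.DataFrame, covariates: list[str] | None = None):
        for col in ("D", "n"):
            if col not in design.columns:
                raise ValueError(f"design table lacks required column {col!r}")
        if covariates is None:
            covariates = [c for c in design.columns if c not in RESERVED_COLUMNS]
        else:
            missing = [c for c in covariates if c not in design.columns]
            if missing:
                raise ValueError(f"unknown covariate columns {missing}")
        self.design = design
        self.covariate_names = list(covariates)
        self.param_names = ["intercept", *self.covariate_names]
        self.endog = design["D"].to_numpy(float)
        self.trials = design["n"].to_numpy(float)
        if np.any(self.endog > self.trials) or np.any(self.endog < 0):
            raise ValueError("response must satisfy 0 <= D <= n")
        x = design[self.covariate_names].to_numpy(float)
        self.exog = np.column_stack([np.ones(len(design)), x])
        if len(design) < 1:
            raise ValueError("design table has no rows")
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            bad = _collinear_columns(self.exog, self.param_names)
            raise RankDeficiencyError(f"collinear design columns: {bad}")

    @classmethod
    def from_census(cls, census: pd.DataFrame, n_lags: int = 3, **kwargs) -> "DepartureModel":
        """Build the model straight from a labelled census series."""
        from .census import build_design

        return cls(build_design(census, n_lags=n_lags), **kwargs)

    def loglike(self, params: np.ndarray) -> float:
        p = expit(self.exog @ np.asarray(params, float))
        return binomial_loglik(self.endog, self.trials, p)

    def fit(self, max_iter: int = MAX_ITER) -> "DepartureResults":
        """Maximise the binomial log-likelihood by IRLS."""
        res = _irls(self.endog, self.trials, self.exog, max_iter=max_iter)
        null = _irls(self.endog, self.trials, np.ones((len(self.endog), 1)), max_iter=max_iter)
        return DepartureResults(self, res, null.deviance)


@dataclass
class DepartureResults:
    """Fit of a :class:`DepartureModel`: estimates, uncertainty, deviances."""

    model: DepartureModel
    _fit: _IRLSFit
    null_deviance: float
    params: pd.Series = field(init=False)
    bse: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        names = self.model.param_names
        self.params = pd.Series(self._fit.params, index=names, name="coef")
        self.bse = pd.Series(np.sqrt(np.diag(self._fit.cov)), index=names, name="se")

    # -- basic accessors -------------------------------------------------
    @property
    def cov_params(self) -> pd.DataFrame:
        names = self.model.param_names
        return pd.DataFrame(self._fit.cov, index=names, columns=names)

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def iterations(self) -> int:
        return self._fit.iterations

    @property
    def deviance_path(self) -> list[float]:
        """Deviance at each IRLS iteration (monotone non-increasing)."""
        return list(self._fit.deviances)

    @property
    def residual_deviance(self) -> float:
        return self._fit.deviance

    @property
    def n_rows(self) -> int:
        return len(self.model.endog)

    @property
    def df_resid(self) -> int:
        return self.n_rows - len(self.params)

    @property
    def df_null(self) -> int:
        return self.n_rows - 1

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index, name="p")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"low": self.params - z * self.bse, "high": self.params + z * self.bse}
        )

    # -- predictions -----------------------------------------------------
    def predict(self, design: pd.DataFrame | None = None) -> np.ndarray:
        """One-step-ahead departure probabilities for a design table."""
        if design is None:
            exog = self.model.exog
        else:
            missing = [c for c in self.model.covariate_names if c not in design.columns]
            if missing:
                raise ValueError(f"design lacks covariate columns {missing}")
            x = design[self.model.covariate_names].to_numpy(float)
            exog = np.column_stack([np.ones(len(design)), x])
        return expit(exog @ self.params.to_numpy())

    # -- reporting -------------------------------------------------------
    def odds_ratio_table(self, z: float = 1.96) -> pd.DataFrame:
        """Odds ratios with Wald 95% CIs, p-values and relative waiting-time change.

        The last column is the percent change in expected waiting time per
        unit covariate, round(100 / OR): an OR below 1 lengthens the wait.
        """
        if not self.converged:
            raise RuntimeError("fit did not converge; odds ratios unreliable")
        rows = []
        for term in self.model.covariate_names:
            coef = self.params[term]
            se = self.bse[term]
            rows.append(
                {
                    "term": term,
                    "or": np.exp(coef),
                    "ci_low": np.exp(coef - z * se),
                    "ci_high": np.exp(coef + z * se),
                    "p_value": self.pvalues[term],
                    "wt_change_pct": int(round(100.0 / np.exp(coef))),
                }
            )
        return pd.DataFrame(rows)

    def combined_or(self, shift: str, weekend: bool) -> tuple[float, int]:
        """Departure odds ratio of a shift/weekend cell vs the weekday day shift.

        Sums the applicable shift, weekend and interaction coefficients and
        exponentiates; also returns the relative waiting-time percent.
        """
        return combined_or(self.params, shift, weekend)

    def summary(self) -> str:
        """Text summary in the style of a GLM fit report."""
        lines = [
            "Binomial logit transition model of ED departures",
            "=" * 56,
            f"rows: {self.n_rows}   converged: {self.converged} "
            f"({self.iterations} IRLS iterations)",
            f"null deviance:     {self.null_deviance:12.2f}  on {self.df_null} df",
            f"residual deviance: {self.residual_deviance:12.2f}  on {self.df_resid} df",
            "-" * 56,
            f"{'term':<18}{'coef':>9}{'se':>8}{'OR':>8}{'p':>10}{'WT%':>6}",
        ]
        ors = np.exp(self.params)
        for term in self.params.index:
            p = self.pvalues[term]
            pct = int(round(100.0 / ors[term]))
            lines.append(
                f"{term:<18}{self.params[term]:>9.4f}{self.bse[term]:>8.4f}"
                f"{ors[term]:>8.3f}{p:>10.2g}{pct:>5d}%"
            )
        return "\n".join(lines)


def combined_or(coefficients: pd.Series, shift: str, weekend: bool) -> tuple[float, int]:
    """Combined shift/weekend odds ratio relative to the weekday day shift.

    ``coefficients`` may be any mapping of coefficient names to values
    containing the shift, weekend and interaction terms that apply.
    Returns (odds ratio, relative waiting-time percent).
    """
    if shift not in ("day", "evening", "night"):
        raise ValueError(f"unknown shift level {shift!r}")
    total = 0.0
    if shift != "day":
        total += float(coefficients[f"shift_{shift}"])
    if weekend:
        total += float(coefficients["weekend"])
        if shift != "day":
            total += float(coefficients[f"{shift}_weekend"])
    ratio = float(np.exp(total))
    return ratio, int(round(100.0 / ratio))


def lr_interaction_test(
    fit_full: DepartureResults, fit_reduced: DepartureResults
) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square test of nested fits on the same rows.

    Returns (chi2, df, p) where chi2 is the deviance drop from the reduced
    to the full model and df the number of extra coefficients.
    """
    if fit_full.n_rows != fit_reduced.n_rows:
        raise ValueError("fits were not computed on the same design rows")
    extra = set(fit_reduced.params.index) - set(fit_full.params.index)
    if extra:
        raise ValueError(f"reduced model is not nested in the full model: {sorted(extra)}")
    chi2 = fit_reduced.residual_deviance - fit_full.residual_deviance
    df = len(fit_full.params) - len(fit_reduced.params)
    chi2 = max(chi2, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return chi2, df, p
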