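"""One-step-ahead predictions, residual diagnostics and held-out validation.

The fitted model yields for each interval the expected number of
departures E(t+1) = n(t+1) * p(t+1|t), where p uses only covariates that
encode past state, never the interval's own outcome. Standardised
(Pearson) residuals (D - E) / sqrt(n p (1-p)) should be mean-zero with
unit variance and approximately normal when the model is well specified;
goodness of fit is summarised by the null and residual deviance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import DepartureResults, binomial_deviance


def _coef_array(coefficients, covariate_names: list[str]) -> np.ndarray:
    missing = [c for c in ("intercept", *covariate_names) if c not in coefficients]
    if missing:
        raise ValueError(f"coefficients lack terms {missing}")
    return np.array([coefficients["intercept"], *(coefficients[c] for c in covariate_names)])


def one_step_ahead(
    fit: DepartureResults | pd.Series | dict,
    design: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Expected departures and Pearson residuals for each design row.

    ``fit`` may be a results object or a plain name -> coefficient mapping
    (with an ``intercept`` entry); in the latter case ``covariates`` defaults
    to every coefficient name present as a design column.
    """
    if isinstance(fit, DepartureResults):
        names = fit.model.covariate_names
        coefs = fit.params
    else:
        coefs = pd.Series(dict(fit))
        names = covariates or [c for c in coefs.index if c != "intercept"]
    missing = [c for c in names if c not in design.columns]
    if missing:
        raise ValueError(f"design lacks covariate columns {missing}")
    beta = _coef_array(coefs, names)
    x = np.column_stack(
        [np.ones(len(design)), design[list(names)].to_numpy(float)]
    )
    from scipy.special import expit

    p = expit(x @ beta)
    d = design["D"].to_numpy(float)
    n = design["n"].to_numpy(float)
    e = n * p
    var = n * p * (1.0 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = np.where(var > 0, (d - e) / np.sqrt(var), np.nan)
    out = pd.DataFrame(
        {"D": d.astype(int), "n": n.astype(int), "p": p, "E": e, "pearson_resid": resid}
    )
    if "start" in design.columns:
        out.insert(0, "start", design["start"].to_numpy())
    return out


@dataclass
class DiagnosticBundle:
    """Plot-ready residual tables (no rendering).

    ``resid_vs_fitted`` backs a residuals-against-fitted scatter;
    ``qq`` holds sorted residuals against standard-normal quantiles at
    plotting positions (i - 0.5) / m.
    """

    resid_vs_fitted: pd.DataFrame
    qq: pd.DataFrame
    n_dropped: int

    @property
    def residual_mean(self) -> float:
        return float(self.resid_vs_fitted["pearson_resid"].mean())

    @property
    def residual_var(self) -> float:
        return float(self.resid_vs_fitted["pearson_resid"].var(ddof=1))


def residual_diagnostics(rows: pd.DataFrame) -> DiagnosticBundle:
    """Assemble residual-vs-fitted and normal QQ tables from prediction rows.

    Rows with degenerate binomial variance (n p (1-p) = 0) carry no
    residual; they are dropped and counted in ``n_dropped``.
    """
    ok = rows["pearson_resid"].notna()
    kept = rows.loc[ok]
    if len(kept) < 2:
        raise ValueError("need at least 2 rows with non-degenerate variance")
    rvf = kept[["E", "pearson_resid"]].rename(columns={"E": "fitted"}).reset_index(drop=True)
    m = len(kept)
    sorted_resid = np.sort(kept["pearson_resid"].to_numpy())
    theo = stats.norm.ppf((np.arange(1, m + 1) - 0.5) / m)
    qq = pd.DataFrame({"theoretical": theo, "sample": sorted_resid})
    return DiagnosticBundle(rvf, qq, int((~ok).sum()))


def goodness_of_fit(fit: DepartureResults) -> tuple[float, float, int, int]:
    """(null deviance, residual deviance, df null, df residual) of a fit."""
    if not fit.converged:
        raise RuntimeError("goodness of fit requires a converged fit")
    return fit.null_deviance, fit.residual_deviance, fit.df_null, fit.df_resid


@dataclass
class ValidationReport:
    """Held-out scoring of fixed coefficients on a new design table."""

    rows: pd.DataFrame
    residual_mean: float
    residual_sd: float
    deviance: float
    n_rows: int

    def __str__(self) -> str:
        return (
            f"validation on {self.n_rows} rows: deviance {self.deviance:.2f}, "
            f"Pearson residual mean {self.residual_mean:.4f}, "
            f"SD {self.residual_sd:.4f}"
        )


def validate(
    coefficients: DepartureResults | pd.Series | dict,
    design: pd.DataFrame,
    covariates: list[str] | None = None,
) -> ValidationReport:
    """Score a new design table with coefficients fixed from training.

    Deterministic: identical inputs give identical reports. Validating on
    the training design itself reproduces the training residual deviance.
    """
    rows = one_step_ahead(coefficients, design, covariates=covariates)
    resid = rows["pearson_resid"].dropna()
    dev = binomial_deviance(
        rows["D"].to_numpy(float), rows["n"].to_numpy(float), rows["p"].to_numpy()
    )
    return ValidationReport(
        rows=rows,
        residual_mean=float(resid.mean()),
        residual_sd=float(resid.std(ddof=1)),
        deviance=dev,
        n_rows=len(rows),
    )
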