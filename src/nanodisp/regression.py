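"""Ordinary least squares with the QSPR statistics suite.

The central objects are :class:`DispersibilityMLR` (the model: a response
vector and a small set of named descriptor columns) and :class:`MLRResults`
(the fit: coefficients with uncertainty halfwidths, R², residual standard
error ``s``, the F statistic with its p-value, and leave-one-out
cross-validation statistics PRESS, Q², SPRESS and SDEP).

Conventions
-----------
* ``s = sqrt(RSS / (n - p - 1))`` with ``p`` predictors plus an intercept.
* ``F = (R²/p) / ((1-R²)/(n-p-1))``; its p-value comes from the F
  distribution.
* Leave-one-out predictions use the hat-matrix shortcut
  ``e_i / (1 - h_ii)`` (algebraically identical to n refits);
  ``PRESS = sum of squared LOO errors``, ``Q² = 1 - PRESS/TSS``,
  ``SPRESS = sqrt(PRESS/(n-p-1))`` and ``SDEP = sqrt(PRESS/(n-1))`` by
  default — the df convention calibrated on the packaged single-descriptor
  model, switchable via ``sdep_df``.
* Reported "(± …)" halfwidths are 95% confidence halfwidths
  (``t_{0.975, n-p-1} × SE``); plain standard errors are exposed alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DispersibilityMLR",
    "MLRResults",
    "LOOStatistics",
    "fit_ols",
    "loo_crossvalidate",
    "correlation_matrix",
    "predict",
]

_SDEP_DF = {"n-1", "n", "n-p-1"}


class LOOStatistics(NamedTuple):
    """Leave-one-out cross-validation summary."""

    press: float
    q2: float
    spress: float
    sdep: float


def _as_design(X, names: Sequence[str] | None):
    """Coerce X (DataFrame or 2-D array) to (array, column names)."""
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if names is None:
        names = [f"x{i + 1}" for i in range(arr.shape[1])]
    return arr, list(names)


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name columns implicated in rank deficiency (constant or |r|~1 pairs)."""
    bad = [n for j, n in enumerate(names) if np.ptp(X[:, j]) == 0]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    if corr.ndim == 2:
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                if abs(corr[a, b]) > 1 - 1e-10:
                    bad.extend([names[a], names[b]])
    return sorted(set(bad))


class DispersibilityMLR:
    """Multiple linear regression of an endpoint on named descriptors.

    Parameters
    ----------
    endog : 1-D array-like
        The response (here LogC, log10 of the dispersibility in mg/mL).
    exog : DataFrame or 2-D array
        Descriptor columns, WITHOUT a constant; an intercept is always added.
    descriptor_names : sequence of str, optional
        Column names when ``exog`` is a plain array.

    Examples
    --------
    >>> from nanodisp import corpus
    >>> df = corpus.study_frame()
    >>> train = df[df.split == "train"]
    >>> res = DispersibilityMLR.from_dataframe(train, "LogC", ["SRW09"]).fit()
    >>> round(res.rsquared, 3)
    0.547
    """

    def __init__(self, endog, exog, descriptor_names: Sequence[str] | None = None):
        X, names = _as_design(exog, descriptor_names)
        y = np.asarray(endog, dtype=float).ravel()
        n, p = X.shape
        if len(y) != n:
            raise ValueError(f"response length {len(y)} != {n} rows")
        if n <= p + 1:
            raise ValueError(f"need n > p+1 observations; got n={n}, p={p}")
        design = np.column_stack([X, np.ones(n)])
        if np.linalg.matrix_rank(design) < p + 1:
            bad = _collinear_columns(X, names)
            raise ValueError(
                "rank-deficient design; collinear or constant column(s): "
                + (", ".join(bad) if bad else "(undetermined)")
            )
        self.endog = y
        self.exog = X
        self.descriptor_names = names
        self.nobs = n
        self.k_vars = p

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, response: str, columns: Sequence[str]
    ) -> "DispersibilityMLR":
        missing = [c for c in [response, *columns] if c not in df.columns]
        if missing:
            raise KeyError(f"column(s) not in frame: {missing}")
        return cls(df[response], df[list(columns)])

    @classmethod
    def from_matrix(cls, matrix, y, columns: Sequence[str]) -> "DispersibilityMLR":
        """Build from a :class:`~nanodisp.corpus.DescriptorMatrix`."""
        return cls(y, matrix.data[list(columns)])

    def fit(self, sdep_df: str = "n-1") -> "MLRResults":
        if sdep_df not in _SDEP_DF:
            raise ValueError(f"sdep_df must be one of {sorted(_SDEP_DF)}")
        design = np.column_stack([self.exog, np.ones(self.nobs)])
        beta, _, _, _ = np.linalg.lstsq(design, self.endog, rcond=None)
        return MLRResults(self, beta, sdep_df)


class MLRResults:
    """Fitted model: estimates, uncertainties, diagnostics.

    Attributes of note: ``params`` (coefficients, ``"intercept"`` last),
    ``bse`` (standard errors), ``halfwidths`` (95% CI halfwidths, the
    conventional "(± …)" report), ``rsquared``, ``s``, ``fvalue``,
    ``f_pvalue`` and the lazy ``loo`` statistics.
    """

    def __init__(self, model: DispersibilityMLR, beta: np.ndarray, sdep_df: str):
        self.model = model
        self._beta = beta
        self.sdep_df = sdep_df
        self.index = [*model.descriptor_names, "intercept"]

    # -- point estimates ---------------------------------------------------

    @cached_property
    def params(self) -> pd.Series:
        return pd.Series(self._beta, index=self.index)

    @property
    def intercept(self) -> float:
        return float(self._beta[-1])

    @cached_property
    def fittedvalues(self) -> np.ndarray:
        design = np.column_stack([self.model.exog, np.ones(self.model.nobs)])
        return design @ self._beta

    @cached_property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    # -- goodness of fit ---------------------------------------------------

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def df_resid(self) -> int:
        return self.model.nobs - self.model.k_vars - 1

    @cached_property
    def rss(self) -> float:
        return float(self.resid @ self.resid)

    @cached_property
    def tss(self) -> float:
        y = self.model.endog
        return float(((y - y.mean()) ** 2).sum())

    @cached_property
    def rsquared(self) -> float:
        return 1.0 - self.rss / self.tss

    @cached_property
    def s(self) -> float:
        """Residual standard error, sqrt(RSS/(n-p-1))."""
        return float(np.sqrt(self.rss / self.df_resid))

    @cached_property
    def fvalue(self) -> float:
        r2, p = self.rsquared, self.model.k_vars
        return (r2 / p) / ((1.0 - r2) / self.df_resid)

    @cached_property
    def f_pvalue(self) -> float:
        return float(stats.f.sf(self.fvalue, self.model.k_vars, self.df_resid))

    # -- coefficient uncertainty -------------------------------------------

    @cached_property
    def bse(self) -> pd.Series:
        """Coefficient standard errors (intercept last)."""
        design = np.column_stack([self.model.exog, np.ones(self.model.nobs)])
        xtx_inv = np.linalg.inv(design.T @ design)
        se = np.sqrt(np.diag(xtx_inv) * self.rss / self.df_resid)
        return pd.Series(se, index=self.index)

    def conf_halfwidth(self, alpha: float = 0.05) -> pd.Series:
        """Two-sided (1-alpha) confidence halfwidths, t_{1-alpha/2} × SE."""
        t = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return t * self.bse

    @cached_property
    def halfwidths(self) -> pd.Series:
        """The conventional "(± …)" report: 95% confidence halfwidths."""
        return self.conf_halfwidth(0.05)

    # -- leave-one-out -----------------------------------------------------

    @cached_property
    def loo(self) -> LOOStatistics:
        X = pd.DataFrame(self.model.exog, columns=self.model.descriptor_names)
        return loo_crossvalidate(X, self.model.endog, sdep_df=self.sdep_df)

    # -- prediction --------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Predict the endpoint for new descriptor rows.

        ``X`` may be a DataFrame (matched to the model's descriptor names; a
        missing column raises), a 2-D array in model column order, or a
        :class:`~nanodisp.corpus.DescriptorMatrix`.
        """
        if hasattr(X, "data") and hasattr(X, "provenance"):  # DescriptorMatrix
            X = X.data
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.model.descriptor_names if c not in X.columns]
            if missing:
                raise KeyError(f"missing descriptor column(s): {missing}")
            arr = X[self.model.descriptor_names].to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim == 1:
                arr = arr[:, None]
            if arr.shape[1] != self.model.k_vars:
                raise ValueError(
                    f"expected {self.model.k_vars} columns, got {arr.shape[1]}"
                )
        return arr @ self._beta[:-1] + self._beta[-1]

    # -- presentation ------------------------------------------------------

    def equation(self, response: str = "LogC", digits: int = 4) -> str:
        """The fitted equation in the conventional '±' layout."""
        hw = self.halfwidths
        terms = []
        for name in self.model.descriptor_names:
            b = self.params[name]
            terms.append(f"{b:+.{digits}f} (±{hw[name]:.{digits}f}) {name}")
        terms.append(f"{self.intercept:+.{digits}f} (±{hw['intercept']:.{digits}f})")
        return f"{response} = " + " ".join(terms)

    def summary(self) -> str:
        loo = self.loo
        lines = [
            self.equation(),
            (
                f"n = {self.nobs}, R² = {self.rsquared:.3f}, s = {self.s:.3f}, "
                f"F = {self.fvalue:.3f}, p = {self.f_pvalue:.2e}"
            ),
            (
                f"LOO: PRESS = {loo.press:.3f}, Q² = {loo.q2:.3f}, "
                f"SPRESS = {loo.spress:.3f}, SDEP = {loo.sdep:.3f} "
                f"(df convention: {self.sdep_df})"
            ),
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed-vs-fitted scatter with the identity line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.endog, self.fittedvalues)
        lo = min(self.model.endog.min(), self.fittedvalues.min())
        hi = max(self.model.endog.max(), self.fittedvalues.max())
        ax.plot([lo, hi], [lo, hi], ls="--", color="grey")
        ax.set_xlabel("observed")
        ax.set_ylabel("fitted")
        return ax

    def __repr__(self) -> str:
        return (
            f"<MLRResults: {' + '.join(self.model.descriptor_names)}; "
            f"n={self.nobs}, R²={self.rsquared:.3f}>"
        )


def fit_ols(X, y, names: Sequence[str] | None = None, sdep_df: str = "n-1") -> MLRResults:
    """Functional entry point: fit ``y ~ X + 1`` and return :class:`MLRResults`."""
    return DispersibilityMLR(y, X, descriptor_names=names).fit(sdep_df=sdep_df)


def loo_crossvalidate(X, y, sdep_df: str = "n-1") -> LOOStatistics:
    """Leave-one-out statistics via the hat-matrix shortcut.

    Exact (not approximate): for OLS the prediction of the i-th point from
    the model refitted without it equals ``y_i - e_i/(1 - h_ii)``.

    Raises
    ------
    ValueError
        If a leave-one-out fit is singular (leverage 1), naming the index.
    """
    if sdep_df not in _SDEP_DF:
        raise ValueError(f"sdep_df must be one of {sorted(_SDEP_DF)}")
    Xa, names = _as_design(X, None)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xa.shape
    if n < p + 3:
        raise ValueError(f"need n >= p+3 for leave-one-out; got n={n}, p={p}")
    design = np.column_stack([Xa, np.ones(n)])
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    hat = np.einsum("ij,ji->i", design, np.linalg.pinv(design))
    near_singular = np.flatnonzero(1 - hat < 1e-10)
    if near_singular.size:
        raise ValueError(
            f"singular leave-one-out fit for left-out index {int(near_singular[0])}"
        )
    loo_err = resid / (1 - hat)
    press = float(loo_err @ loo_err)
    tss = float(((y - y.mean()) ** 2).sum())
    q2 = 1.0 - press / tss
    spress = float(np.sqrt(press / (n - p - 1)))
    denom = {"n-1": n - 1, "n": n, "n-p-1": n - p - 1}[sdep_df]
    sdep = float(np.sqrt(press / denom))
    return LOOStatistics(press, q2, spress, sdep)


def correlation_matrix(columns: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of named columns.

    Symmetric with unit diagonal; entries for zero-variance columns are NaN
    and the offending names are recorded in ``result.attrs["zero_variance"]``.

    Raises
    ------
    ValueError
        With fewer than 3 observations.
    """
    if len(columns) < 3:
        raise ValueError(f"need >= 3 observations, got {len(columns)}")
    corr = columns.corr(method="pearson")
    zero_var = [c for c in columns.columns if np.ptp(columns[c].to_numpy()) == 0]
    np.fill_diagonal(corr.values, 1.0)
    corr.attrs["zero_variance"] = zero_var
    return corr


def predict(results: MLRResults, X) -> np.ndarray:
    """Functional alias for :meth:`MLRResults.predict`."""
    return results.predict(X)
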