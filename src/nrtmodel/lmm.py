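"""Random-intercept linear mixed model estimated by REML.

The model for observation ``j`` of subject ``i`` is::

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_e^2)

Estimation profiles the restricted likelihood over the single variance ratio
``lambda = sigma_b^2 / sigma_e^2``.  For a given lambda the covariance of a
subject's observations is ``sigma_e^2 (I + lambda J)`` whose inverse has the
closed Woodbury form ``I - lambda/(1 + n_i lambda) J``; beta is then the GLS
solution, ``sigma_e^2`` has a closed-form profile estimate, and the REML
log-likelihood reduces to a smooth scalar function of ``log lambda`` that is
maximised with a derivative-free bounded optimiser.  The boundary estimate
``sigma_b^2 = 0`` (equivalent to OLS) is permitted and reported.

Design columns are rescaled internally to unit root-mean-square for numerical
conditioning (raw-Hz cubic spline columns span ~12 orders of magnitude);
estimates, standard errors and the covariance are reported on the original
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["RandomInterceptLMM", "RandomInterceptLMMResults", "WaldTestResult"]

_LOG_LAMBDA_BOUNDS = (-30.0, 30.0)
_LOG_LAMBDA_TOL = 1e-8


@dataclass(frozen=True)
class WaldTestResult:
    """Large-sample Wald test of a fixed effect (or a joint block)."""

    statistic: float
    pvalue: float
    df: int = 1

    @property
    def z(self) -> float:
        if self.df != 1:
            raise ValueError("z is defined only for single-coefficient tests")
        return self.statistic


class _GroupSuffStats:
    """Per-group cross-products needed by the profiled REML criterion."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        self.order = order
        Xs, ys, gs = X[order], y[order], groups[order]
        self.labels, starts = np.unique(gs, return_index=True)
        bounds = np.r_[starts, len(gs)]
        self.n_i = np.diff(bounds)
        self.XtX = Xs.T @ Xs
        self.Xty = Xs.T @ ys
        self.yty = float(ys @ ys)
        # per-group sums of rows of X and of y
        self.Sx = np.add.reduceat(Xs, bounds[:-1], axis=0)
        self.Sy = np.add.reduceat(ys, bounds[:-1])

    def gls_pieces(self, lam: float):
        """Return X'V^-1X, X'V^-1y, y'V^-1y for V = I + lam * J (blockwise)."""
        c = lam / (1.0 + self.n_i * lam)  # shape (m,)
        XtVX = self.XtX - (self.Sx * c[:, None]).T @ self.Sx
        XtVy = self.Xty - self.Sx.T @ (c * self.Sy)
        ytVy = self.yty - float(c @ self.Sy**2)
        return XtVX, XtVy, ytVy


class RandomInterceptLMM:
    """Linear mixed model with a subject-specific random intercept.

    Parameters
    ----------
    endog : array-like
        Response vector (NRT thresholds, in current-level units).
    exog : DataFrame
        Fixed-effect design matrix with named columns; include an
        ``intercept`` column explicitly if wanted.
    groups : array-like
        Subject labels, one per row of ``exog``.
    """

    def __init__(self, endog, exog: pd.DataFrame, groups):
        if not isinstance(exog, pd.DataFrame):
            exog = pd.DataFrame(np.asarray(exog))
            exog.columns = [f"x{i}" for i in range(exog.shape[1])]
        y = np.asarray(endog, dtype=float).ravel()
        g = np.asarray(groups)
        if len(y) != len(exog) or len(g) != len(exog):
            raise ValueError("endog, exog and groups must have equal length")
        if exog.columns.duplicated().any():
            raise ValueError("design-matrix column names must be unique")
        if exog.isna().any().any() or np.isnan(y).any():
            raise ValueError("missing values in the design or response")
        self.endog = y
        self.exog = exog
        self.groups = g
        self.exog_names = list(exog.columns)
        self._check_rank()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        covariates: list[str],
        group: str,
        add_intercept: bool = True,
    ) -> "RandomInterceptLMM":
        """Build the model from named numeric columns of a long-format table."""
        missing = [c for c in [response, group, *covariates] if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        X = data[covariates].astype(float).copy()
        if add_intercept:
            X.insert(0, "intercept", 1.0)
        return cls(data[response], X, data[group])

    def _check_rank(self) -> None:
        X = self.exog.to_numpy(dtype=float)
        scale = np.sqrt((X**2).mean(axis=0))
        if np.any(scale == 0):
            dead = [n for n, s in zip(self.exog_names, scale) if s == 0]
            raise ValueError(f"all-zero design columns: {dead}")
        Xs = X / scale
        rank = np.linalg.matrix_rank(Xs)
        if rank < Xs.shape[1]:
            aliased = []
            kept: list[int] = []
            for j in range(Xs.shape[1]):
                trial = Xs[:, kept + [j]]
                if np.linalg.matrix_rank(trial) > len(kept):
                    kept.append(j)
                else:
                    aliased.append(self.exog_names[j])
            raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
        self._scale = scale

    # -- REML machinery ----------------------------------------------------

    def _neg2_reml(self, lam: float, ss: _GroupSuffStats, n: int, p: int):
        XtVX, XtVy, ytVy = ss.gls_pieces(lam)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - float(beta @ XtVy)
        rss = max(rss, 1e-300)
        sigma2_e = rss / (n - p)
        logdet_v = float(np.sum(np.log1p(ss.n_i * lam)))
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf, beta, sigma2_e, XtVX
        neg2 = (
            (n - p) * np.log(sigma2_e)
            + logdet_v
            + logdet_xvx
            + (n - p) * (1.0 + np.log(2.0 * np.pi))
        )
        return neg2, beta, sigma2_e, XtVX

    def _neg2_ml(self, lam: float, ss: _GroupSuffStats, n: int):
        """Profiled -2 maximum-likelihood criterion (used for BIC; REML
        likelihoods are not comparable across fixed-effect structures)."""
        XtVX, XtVy, ytVy = ss.gls_pieces(lam)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = max(ytVy - float(beta @ XtVy), 1e-300)
        sigma2 = rss / n
        logdet_v = float(np.sum(np.log1p(ss.n_i * lam)))
        return n * np.log(sigma2) + logdet_v + n * (1.0 + np.log(2.0 * np.pi))

    def fit(self) -> "RandomInterceptLMMResults":
        """Maximise the restricted likelihood over the variance ratio and
        return a results object with estimates, uncertainties and fit stats."""
        y = self.endog
        Xs = self.exog.to_numpy(dtype=float) / self._scale
        n, p = Xs.shape
        ss = _GroupSuffStats(Xs, y, self.groups)
        m = len(ss.labels)

        if n - p <= 0:
            raise ValueError("more fixed effects than observations")

        if m < 2:
            raise ValueError("at least two groups are required to fit the model")
        singleton_groups = bool(np.all(ss.n_i == 1))
        if singleton_groups:
            warnings.warn(
                    "one observation per group: sigma_b^2 is not separable from "
                    "sigma_e^2; fitting OLS with sigma_b^2 = 0",
                    stacklevel=2,
                )
            lam_hat = 0.0
        else:
            def objective(u: float) -> float:
                return self._neg2_reml(np.exp(u), ss, n, p)[0]

            res = optimize.minimize_scalar(
                objective,
                bounds=_LOG_LAMBDA_BOUNDS,
                method="bounded",
                options={"xatol": _LOG_LAMBDA_TOL},
            )
            if not res.success:
                raise RuntimeError(
                    "REML optimisation failed to converge over "
                    f"log-lambda in {_LOG_LAMBDA_BOUNDS}: {res.message}"
                )
            lam_hat = float(np.exp(res.x))
            # check the sigma_b^2 = 0 boundary explicitly
            if self._neg2_reml(0.0, ss, n, p)[0] <= res.fun:
                lam_hat = 0.0

        neg2, beta_s, sigma2_e, XtVX_s = self._neg2_reml(lam_hat, ss, n, p)
        # report the loglik on the original column scale: the scaled design
        # shifts log|X'V^-1 X| by -2 sum(log scale)
        neg2 += 2.0 * float(np.sum(np.log(self._scale)))

        # separate profiled ML optimum, for information criteria
        if singleton_groups:
            lam_ml = 0.0
        else:
            res_ml = optimize.minimize_scalar(
                lambda u: self._neg2_ml(np.exp(u), ss, n),
                bounds=_LOG_LAMBDA_BOUNDS, method="bounded",
                options={"xatol": _LOG_LAMBDA_TOL},
            )
            lam_ml = float(np.exp(res_ml.x))
            if self._neg2_ml(0.0, ss, n) <= res_ml.fun:
                lam_ml = 0.0
        loglik_ml = -0.5 * self._neg2_ml(lam_ml, ss, n)
        cov_s = sigma2_e * np.linalg.inv(XtVX_s)
        # undo the internal column scaling
        beta = beta_s / self._scale
        cov = cov_s / np.outer(self._scale, self._scale)
        sigma2_b = lam_hat * sigma2_e

        return RandomInterceptLMMResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_params_=pd.DataFrame(cov, index=self.exog_names, columns=self.exog_names),
            sigma2_b=float(sigma2_b),
            sigma2_e=float(sigma2_e),
            lambda_=float(lam_hat),
            reml_loglik=float(-0.5 * neg2),
            loglik_ml=float(loglik_ml),
            group_labels=ss.labels,
            group_sizes=ss.n_i,
        )


class RandomInterceptLMMResults:
    """Fitted random-intercept mixed model.

    Exposes fixed-effect estimates (``params``), their standard errors
    (``bse``) and covariance, the two variance components, the restricted
    log-likelihood and BIC, shrunken per-subject intercepts (BLUPs), fitted
    values, marginal and conditional residuals, Wald tests, and population
    prediction with confidence bands.
    """

    def __init__(
        self,
        model: RandomInterceptLMM,
        params: pd.Series,
        cov_params_: pd.DataFrame,
        sigma2_b: float,
        sigma2_e: float,
        lambda_: float,
        reml_loglik: float,
        group_labels: np.ndarray,
        group_sizes: np.ndarray,
        loglik_ml: float | None = None,
    ):
        self.model = model
        self.params = params
        self._cov_params = cov_params_
        self.sigma2_b = sigma2_b
        self.sigma2_e = sigma2_e
        self.lambda_ = lambda_
        self.reml_loglik = reml_loglik
        self.loglik_ml = reml_loglik if loglik_ml is None else loglik_ml
        self.group_labels = group_labels
        self.group_sizes = group_sizes

    # -- basic accessors ---------------------------------------------------

    @property
    def nobs(self) -> int:
        return len(self.model.endog)

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def k_fe(self) -> int:
        return len(self.params)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self._cov_params)), index=self.params.index)

    def cov_params(self) -> pd.DataFrame:
        return self._cov_params.copy()

    @property
    def bic(self) -> float:
        """Schwarz criterion, smaller-is-better: -2 loglik + k ln N with k
        counting fixed effects plus the two variance components.

        Computed from the profiled *maximum-likelihood* log-likelihood:
        restricted likelihoods are not comparable between models with
        different fixed effects, and the criterion's purpose here is exactly
        that comparison (functional-form selection).
        """
        k = self.k_fe + 2
        return -2.0 * self.loglik_ml + k * np.log(self.nobs)

    # -- fitted values and residuals --------------------------------------

    @property
    def fittedvalues(self) -> np.ndarray:
        """Marginal (population-level) fitted values X beta-hat."""
        return self.model.exog.to_numpy(dtype=float) @ self.params.to_numpy()

    @property
    def resid_marginal(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    @property
    def random_effects(self) -> pd.Series:
        """BLUPs of the subject intercepts: the subject-mean marginal
        residual shrunk by ``n_i sigma_b^2 / (sigma_e^2 + n_i sigma_b^2)``."""
        r = self.resid_marginal
        df = pd.DataFrame({"g": self.model.groups, "r": r})
        means = df.groupby("g", sort=True)["r"].mean()
        n_i = df.groupby("g", sort=True)["r"].size().to_numpy()
        if self.sigma2_b == 0.0:
            return pd.Series(0.0, index=means.index)
        shrink = (self.sigma2_b * n_i) / (self.sigma2_e + n_i * self.sigma2_b)
        return means * shrink

    @property
    def resid_conditional(self) -> np.ndarray:
        """Residuals after removing both the fixed effects and the BLUP."""
        blup = self.random_effects
        return self.resid_marginal - blup.reindex(self.model.groups).to_numpy()

    # -- inference ---------------------------------------------------------

    def wald_test(self, name: str) -> WaldTestResult:
        """Two-sided large-sample Wald test of a single coefficient."""
        if name not in self.params.index:
            raise KeyError(f"unknown coefficient {name!r}; have {list(self.params.index)}")
        z = self.params[name] / self.bse[name]
        p = 2.0 * stats.norm.sf(abs(z))
        return WaldTestResult(statistic=float(z), pvalue=float(p), df=1)

    def wald_test_joint(self, names: list[str]) -> WaldTestResult:
        """Joint chi-square Wald test that a block of coefficients is zero."""
        missing = [n for n in names if n not in self.params.index]
        if missing:
            raise KeyError(f"unknown coefficients: {missing}")
        b = self.params[names].to_numpy()
        V = self._cov_params.loc[names, names].to_numpy()
        stat = float(b @ np.linalg.solve(V, b))
        p = float(stats.chi2.sf(stat, df=len(names)))
        return WaldTestResult(statistic=stat, pvalue=p, df=len(names))

    def predict(self, exog: pd.DataFrame, ci: bool = True, alpha: float = 0.05) -> pd.DataFrame:
        """Population-level prediction ``x' beta`` with a fixed-effects-only
        normal confidence band ``+- z_{1-alpha/2} sqrt(x' V x)``."""
        if list(exog.columns) != list(self.params.index):
            raise ValueError(
                "prediction design columns must match the fit: "
                f"expected {list(self.params.index)}, got {list(exog.columns)}"
            )
        X = exog.to_numpy(dtype=float)
        mean = X @ self.params.to_numpy()
        out = pd.DataFrame({"mean": mean}, index=exog.index)
        if ci:
            V = self._cov_params.to_numpy()
            var = np.einsum("ij,jk,ik->i", X, V, X)
            half = stats.norm.ppf(1.0 - alpha / 2.0) * np.sqrt(np.clip(var, 0.0, None))
            out["lower95"] = mean - half
            out["upper95"] = mean + half
        return out

    # -- reporting ---------------------------------------------------------

    def to_dict(self) -> dict:
        """JSON-serialisable fit artifact."""
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "sigma2_b": self.sigma2_b,
            "sigma2_e": self.sigma2_e,
            "reml_loglik": self.reml_loglik,
            "bic": self.bic,
            "n_obs": int(self.nobs),
            "n_groups": int(self.n_groups),
        }

    def summary(self) -> str:
        lines = [
            "Random-intercept linear mixed model (REML)",
            f"  observations: {self.nobs}   groups: {self.n_groups}   fixed effects: {self.k_fe}",
            f"  sigma_b^2 = {self.sigma2_b:.4f}   sigma_e^2 = {self.sigma2_e:.4f}",
            f"  REML loglik = {self.reml_loglik:.3f}   BIC = {self.bic:.3f}",
            "",
            f"  {'coefficient':<22}{'estimate':>12}{'SE':>12}{'z':>9}{'P>|z|':>9}",
        ]
        bse = self.bse
        for name in self.params.index:
            w = self.wald_test(name)
            lines.append(
                f"  {name:<22}{self.params[name]:>12.4f}{bse[name]:>12.4f}"
                f"{w.statistic:>9.2f}{w.pvalue:>9.3f}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<RandomInterceptLMMResults n={self.nobs} groups={self.n_groups} "
            f"k_fe={self.k_fe} bic={self.bic:.1f}>"
        )
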