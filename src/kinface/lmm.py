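"""Gaussian linear mixed models with crossed random intercepts.

Fits y = X beta + Z b + e by maximum likelihood, where the random
structure is a set of crossed intercept factors (participant, triad,
target/left/right image, ...) and optionally a per-group random slope on
one covariate, with or without an intercept-slope correlation.

The likelihood is profiled: for fixed variance *ratios* gamma_k =
sigma_k^2 / sigma^2 the GLS fixed effects and the residual variance have
closed forms via the Woodbury identity, so the optimizer only searches
the (few) log-scale ratio parameters, from multiple starts.  All linear
algebra works on q x q cross-product matrices (q = total random-effect
levels), never on n x n covariance matrices.

Uncertainty for fixed effects comes either from the profiled-ML
covariance (Wald) or from a seeded parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CrossedLMM",
    "LMMFit",
    "LRTResult",
    "lrt",
    "parametric_bootstrap",
]

#: bounds for relative standard deviations sigma_k / sigma_resid
_SD_BOUNDS = (0.0, 50.0)
_COR_BOUNDS = (-50.0, 50.0)


@dataclass
class LRTResult:
    chi_sq: float
    df: int
    p: float


@dataclass
class LMMFit:
    """Maximum-likelihood fit of a crossed random-effects model."""

    beta: pd.Series
    cov_beta: np.ndarray
    sigma2: float
    varcomps: dict[str, float]  # variances on the response scale
    loglik: float
    n_obs: int
    n_params: int  # fixed effects + variance parameters + residual
    converged: bool
    theta: np.ndarray  # optimizer parameters (log ratios / Cholesky)
    model: "CrossedLMM" = field(repr=False)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_beta)), index=self.beta.index)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2)
        se = self.se
        return pd.DataFrame(
            {"lower": self.beta - z * se, "upper": self.beta + z * se},
            index=self.beta.index,
        )

    def wald_p(self) -> pd.Series:
        z = self.beta / self.se
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.beta.index)


class CrossedLMM:
    """Model specification + profiled-ML machinery.

    Parameters
    ----------
    X:
        Fixed-effect design matrix ``(n, p)`` (include the intercept
        column yourself).
    y:
        Response vector ``(n,)``.
    factors:
        ``[(name, codes)]`` where codes are integer level indices for
        each observation; one random intercept per factor.
    slope:
        Optional ``(factor_name, covariate, correlated)``: adds a random
        slope on ``covariate`` for the named factor, with an
        intercept-slope correlation when ``correlated`` is True.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        factors: Sequence[tuple[str, np.ndarray]],
        fe_names: Sequence[str] | None = None,
        slope: tuple[str, np.ndarray, bool] | None = None,
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        n, p = self.X.shape
        if self.y.shape != (n,):
            raise ValueError("X and y lengths differ")
        self.fe_names = list(fe_names) if fe_names is not None else [
            f"x{i}" for i in range(p)
        ]
        self.factor_names = [name for name, _ in factors]
        self.slope = None
        self.slope_factor = None
        self.correlated = False

        blocks = []
        self.block_slices: dict[str, slice] = {}
        offset = 0
        self._codes: dict[str, np.ndarray] = {}
        for name, codes in factors:
            codes = np.asarray(codes, dtype=int)
            q_k = int(codes.max()) + 1
            Zk = np.zeros((n, q_k))
            Zk[np.arange(n), codes] = 1.0
            blocks.append(Zk)
            self.block_slices[name] = slice(offset, offset + q_k)
            self._codes[name] = codes
            offset += q_k
        if slope is not None:
            fac, covariate, correlated = slope
            if fac not in self.block_slices:
                raise ValueError(f"slope factor {fac!r} is not a random factor")
            covariate = np.asarray(covariate, dtype=float)
            codes = self._codes[fac]
            q_k = self.block_slices[fac].stop - self.block_slices[fac].start
            Zs = np.zeros((n, q_k))
            Zs[np.arange(n), codes] = covariate
            blocks.append(Zs)
            self.block_slices["__slope__"] = slice(offset, offset + q_k)
            self.slope = covariate
            self.slope_factor = fac
            self.correlated = bool(correlated)
            offset += q_k
        self.q = offset
        Z = np.concatenate(blocks, axis=1)

        self.n = n
        self.p = p
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ self.X
        self.XtX = self.X.T @ self.X
        self._set_y(self.y, Z_needed=Z)
        self._Z = Z  # kept for simulation / refits

    def _set_y(self, y: np.ndarray, Z_needed: np.ndarray | None = None) -> None:
        Z = Z_needed if Z_needed is not None else self._Z
        self.y = np.asarray(y, dtype=float)
        self.Zty = Z.T @ self.y
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    # -- parameter layout ---------------------------------------------------
    # one relative SD (sigma_k / sigma_resid, linear scale, bound 0) per
    # plain factor; the slope adds either one more (uncorrelated) or replaces
    # the slope factor's single parameter with a scaled Cholesky
    # (l11, l21, l22), where l21 carries the intercept-slope covariance.

    @property
    def n_theta(self) -> int:
        k = len(self.factor_names)
        if self.slope is None:
            return k
        return k + (2 if self.correlated else 1)

    def _scales(self, theta: np.ndarray):
        """Column scale vector and optional (l21) coupling for the mixing."""
        scale = np.empty(self.q)
        coupling = None
        i = 0
        for name in self.factor_names:
            sl = self.block_slices[name]
            if self.slope is not None and self.correlated and name == self.slope_factor:
                scale[sl] = max(theta[i], 0.0)  # l11
                coupling = theta[i + 1]  # l21
                scale[self.block_slices["__slope__"]] = max(theta[i + 2], 0.0)  # l22
                i += 3
            else:
                scale[sl] = max(theta[i], 0.0)
                i += 1
        if self.slope is not None and not self.correlated:
            scale[self.block_slices["__slope__"]] = max(theta[i], 0.0)
            i += 1
        return scale, coupling

    def _mix(self, M: np.ndarray, scale: np.ndarray, coupling, rows: bool):
        """Apply B (columns) or B' (rows) to cross-product matrices."""
        out = M * scale if not rows else M * scale[:, None]
        if coupling is not None:
            sl_int = self.block_slices[self.slope_factor]
            sl_slo = self.block_slices["__slope__"]
            if rows:
                out[sl_int] = out[sl_int] + coupling * M[sl_slo] * 1.0
            else:
                out[:, sl_int] = out[:, sl_int] + coupling * M[:, sl_slo]
        return out

    def _profile(self, theta: np.ndarray):
        scale, coupling = self._scales(theta)
        # A'A = B' ZtZ B ; note B acts on the right as columns, B' on rows
        C = self._mix(self.ZtZ, scale, coupling, rows=False)
        C = self._mix(C, scale, coupling, rows=True)
        M = C + np.eye(self.q)
        try:
            Lm = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            return None
        U = self._mix(self.ZtX, scale, coupling, rows=True)  # B' Z'X
        v = self._mix(self.Zty[:, None], scale, coupling, rows=True)[:, 0]
        Su = np.linalg.solve(Lm, U)
        sv = np.linalg.solve(Lm, v)
        XtWX = self.XtX - Su.T @ Su
        XtWy = self.Xty - Su.T @ sv
        yWy = self.yty - sv @ sv
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return None
        rss = yWy - beta @ XtWy
        if not np.isfinite(rss) or rss <= 0:
            return None
        sigma2 = rss / self.n
        logdet = 2.0 * float(np.sum(np.log(np.diag(Lm))))
        ll = -0.5 * (self.n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
        return beta, sigma2, ll, XtWX

    def _neg_ll(self, theta: np.ndarray) -> float:
        prof = self._profile(theta)
        if prof is None:
            return 1e12
        return -prof[2]

    def _correlation_index(self) -> int:
        """Position of the l21 parameter within theta (correlated slope)."""
        i = 0
        for name in self.factor_names:
            if name == self.slope_factor:
                return i + 1
            i += 3 if (self.correlated and name == self.slope_factor) else 1
        raise RuntimeError("slope factor not found")

    def default_starts(self) -> list[np.ndarray]:
        base = []
        for level in (0.3, 1.0):
            theta = np.full(self.n_theta, level)
            if self.slope is not None and self.correlated:
                theta[self._correlation_index()] = 0.0
            base.append(theta)
        return base

    def _bounds(self) -> list[tuple[float, float]]:
        bounds: list[tuple[float, float]] = []
        for name in self.factor_names:
            if self.slope is not None and self.correlated and name == self.slope_factor:
                bounds += [_SD_BOUNDS, _COR_BOUNDS, _SD_BOUNDS]
            else:
                bounds.append(_SD_BOUNDS)
        if self.slope is not None and not self.correlated:
            bounds.append(_SD_BOUNDS)
        return bounds

    def fit(
        self,
        starts: Sequence[np.ndarray] | None = None,
        tol: float = 1e-8,
    ) -> LMMFit:
        """Maximize the profiled ML log-likelihood from multiple starts.

        The search is derivative-free (Nelder-Mead with bounds) over the
        relative-SD parameters; boundary solutions (zero variances) are
        legal and common.
        """
        starts = list(starts) if starts is not None else self.default_starts()
        best = None
        converged = False
        bounds = self._bounds()
        for theta0 in starts:
            res = optimize.minimize(
                self._neg_ll,
                np.asarray(theta0, dtype=float),
                method="Nelder-Mead",
                bounds=bounds,
                options={"fatol": tol, "xatol": 1e-6, "maxiter": 4000,
                         "maxfev": 8000},
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
                converged = bool(res.success)
        theta = best.x
        prof = self._profile(theta)
        if prof is None:
            raise RuntimeError("mixed-model fit failed at the optimum")
        beta, sigma2, ll, XtWX = prof
        cov_beta = sigma2 * np.linalg.inv(XtWX)
        varcomps = self._varcomps(theta, sigma2)
        return LMMFit(
            beta=pd.Series(beta, index=self.fe_names),
            cov_beta=cov_beta,
            sigma2=sigma2,
            varcomps=varcomps,
            loglik=float(ll),
            n_obs=self.n,
            n_params=self.p + self.n_theta + 1,
            converged=converged,
            theta=np.asarray(theta, dtype=float),
            model=self,
        )

    def _varcomps(self, theta: np.ndarray, sigma2: float) -> dict[str, float]:
        out: dict[str, float] = {}
        i = 0
        for name in self.factor_names:
            if self.slope is not None and self.correlated and name == self.slope_factor:
                l11, l21, l22 = max(theta[i], 0.0), theta[i + 1], max(theta[i + 2], 0.0)
                out[name] = sigma2 * l11 * l11
                out[f"{name}_slope"] = sigma2 * (l21 * l21 + l22 * l22)
                out[f"{name}_int_slope_cov"] = sigma2 * l11 * l21
                i += 3
            else:
                out[name] = sigma2 * float(max(theta[i], 0.0)) ** 2
                i += 1
        if self.slope is not None and not self.correlated:
            out[f"{self.slope_factor}_slope"] = sigma2 * float(max(theta[i], 0.0)) ** 2
        out["residual"] = sigma2
        return out

    # -- simulation / bootstrap ---------------------------------------------

    def simulate(self, fit: LMMFit, rng: np.random.Generator) -> np.ndarray:
        """Draw a response vector from the fitted generative model."""
        mean = self.X @ fit.beta.to_numpy()
        y = mean + rng.normal(0.0, np.sqrt(fit.sigma2), size=self.n)
        vc = fit.varcomps
        for name in self.factor_names:
            codes = self._codes[name]
            q_k = int(codes.max()) + 1
            if (
                self.slope is not None
                and name == self.slope_factor
                and f"{name}_slope" in vc
            ):
                var_i = max(vc.get(name, 0.0), 0.0)
                var_s = max(vc.get(f"{name}_slope", 0.0), 0.0)
                cov = vc.get(f"{name}_int_slope_cov", 0.0)
                cov_mat = np.array([[var_i, cov], [cov, var_s]])
                # clip tiny negative eigenvalues from boundary fits
                w, V = np.linalg.eigh(cov_mat)
                cov_mat = (V * np.clip(w, 0.0, None)) @ V.T
                b = rng.multivariate_normal(np.zeros(2), cov_mat, size=q_k)
                y = y + b[codes, 0] + b[codes, 1] * self.slope
            else:
                b = rng.normal(0.0, np.sqrt(max(vc.get(name, 0.0), 0.0)), size=q_k)
                y = y + b[codes]
        return y

    def refit(
        self, y_new: np.ndarray, theta_start: np.ndarray, tol: float = 1e-6
    ) -> LMMFit:
        """Single-start warm refit on a new response (bootstrap replicate)."""
        old_y, old_Zty, old_Xty, old_yty = self.y, self.Zty, self.Xty, self.yty
        try:
            self._set_y(y_new)
            return self.fit(starts=[theta_start], tol=tol)
        finally:
            self.y, self.Zty, self.Xty, self.yty = old_y, old_Zty, old_Xty, old_yty


def lrt(full: LMMFit, reduced: LMMFit) -> LRTResult:
    """Likelihood-ratio test of nested ML fits on identical data."""
    if full.n_obs != reduced.n_obs:
        raise ValueError("fits are not on the same data (n differs)")
    df = full.n_params - reduced.n_params
    if df < 1:
        raise ValueError("reduced model is not nested in the full model")
    if not set(reduced.beta.index) <= set(full.beta.index):
        raise ValueError("reduced fixed effects are not a subset of the full model")
    chi_sq = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return LRTResult(chi_sq=chi_sq, df=df, p=float(stats.chi2.sf(chi_sq, df)))


def parametric_bootstrap(
    fit: LMMFit,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Percentile bootstrap intervals and sign-based p-values for the
    fixed effects, simulating from the fitted model.

    ``p`` is ``2 * min(P(beta* <= 0), P(beta* >= 0))`` with a 1/(B+1)
    floor; it plays the role of the MCMC-derived p-values that
    mixed-model software reports for Gaussian fits.
    """
    rng = np.random.default_rng(seed)
    model = fit.model
    draws = np.empty((n_boot, len(fit.beta)))
    for b in range(n_boot):
        y_star = model.simulate(fit, rng)
        draws[b] = model.refit(y_star, fit.theta).beta.to_numpy()
    alpha = 1.0 - level
    lower = np.quantile(draws, alpha / 2, axis=0)
    upper = np.quantile(draws, 1 - alpha / 2, axis=0)
    centered = draws - draws.mean(axis=0) + fit.beta.to_numpy()
    p = np.minimum(
        1.0,
        2.0
        * np.minimum(
            (centered <= 0).mean(axis=0), (centered >= 0).mean(axis=0)
        ),
    )
    p = np.maximum(p, 1.0 / (n_boot + 1))
    return pd.DataFrame(
        {"estimate": fit.beta.to_numpy(), "lower": lower, "upper": upper, "p": p},
        index=fit.beta.index,
    )
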