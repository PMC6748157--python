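"""Cumulative-link (proportional-odds) ordinal regression.

The model for an ordinal outcome :math:`Y` with observed levels
:math:`y_1 < y_2 < \\dots < y_J` and covariate row :math:`x` is

.. math::

    P(Y \\le y_j \\mid x) = F(\\theta_j - x \\cdot \\beta),
    \\qquad F(z) = 1 / (1 + e^{-z}),

with strictly increasing thresholds :math:`\\theta_1 < \\dots < \\theta_{J-1}`
shared slopes :math:`\\beta` (the proportional-odds assumption).  The sign
convention :math:`\\theta_j - x\\beta` means a positive coefficient shifts
probability mass toward *higher* (worse) outcome categories, so
:math:`e^{\\beta}` is the multiplicative change in the odds of a worse
outcome per unit increase of the predictor.

Fitting is full maximum likelihood by Newton iteration with step-halving,
on an unconstrained reparameterization of the thresholds
(:math:`\\theta_1` and the logs of successive differences) so monotonicity
holds at every iterate.  Standard errors come from the inverse observed
information evaluated in the natural parameterization at the optimum.

The public surface follows the statsmodels convention: a
:class:`CumulativeLinkModel` built from data whose :meth:`~CumulativeLinkModel.fit`
returns a :class:`CumulativeLinkResults` carrying estimates, covariance,
log-likelihood, AIC and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .exceptions import (
    ComparisonError,
    DegenerateOutcomeError,
    FitError,
    InputError,
)

__all__ = [
    "DesignSpec",
    "build_design",
    "CumulativeLinkModel",
    "CumulativeLinkResults",
    "ModelComparison",
    "lrt_compare",
]

_TINY = 1e-300


@dataclass(frozen=True)
class DesignSpec:
    """Declarative model formula: outcome, main effects and interactions.

    Interaction terms are pairs of column names encoded as elementwise
    products; an interaction does not require its components among the
    main effects.
    """

    outcome: str
    main_terms: tuple[str, ...]
    interaction_terms: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        names = self.term_names
        if len(set(names)) != len(names):
            raise InputError(f"duplicate terms in design: {names}")

    @property
    def term_names(self) -> list[str]:
        return list(self.main_terms) + [
            f"{a}:{b}" for a, b in self.interaction_terms
        ]

    @property
    def required_columns(self) -> set[str]:
        cols = set(self.main_terms) | {self.outcome}
        for a, b in self.interaction_terms:
            cols |= {a, b}
        return cols


def build_design(data: pd.DataFrame, spec: DesignSpec):
    """Build the model frame for a cumulative-link fit.

    Returns ``(y, X, levels, term_names)`` where ``y`` holds 0-based ordinal
    ranks over the sorted *observed* outcome levels (gaps in the nominal
    scale are collapsed), ``X`` is the predictor matrix with interaction
    columns as raw products, and ``levels`` are the observed outcome values
    in ascending order.
    """
    missing_cols = spec.required_columns - set(data.columns)
    if missing_cols:
        raise InputError(f"columns absent from data: {sorted(missing_cols)}")
    sub = data[sorted(spec.required_columns)]
    na_rows = sub.index[sub.isna().any(axis=1)]
    if len(na_rows):
        raise InputError(f"missing values in rows {list(na_rows[:20])}")

    outcome = np.asarray(data[spec.outcome])
    levels = np.unique(outcome)
    if levels.size < 2:
        raise DegenerateOutcomeError(
            f"outcome {spec.outcome!r} has a single observed level"
        )
    y = np.searchsorted(levels, outcome)

    cols = [np.asarray(data[t], dtype=float) for t in spec.main_terms]
    for a, b in spec.interaction_terms:
        cols.append(np.asarray(data[a], dtype=float) * np.asarray(data[b], dtype=float))
    X = np.column_stack(cols) if cols else np.empty((len(outcome), 0))
    return y, X, levels, spec.term_names


def _loglik_terms(y, X, beta, thresholds):
    """Per-observation category probabilities and cut densities.

    Returns (P, Fu, Fl, fu, fl) where the upper/lower cut arguments are
    theta_{y+1} - eta and theta_y - eta with the conventions
    theta_0 = -inf, theta_J = +inf.
    """
    eta = X @ beta if X.size else np.zeros(len(y))
    th = np.concatenate([[-np.inf], thresholds, [np.inf]])
    au = th[y + 1] - eta
    al = th[y] - eta
    Fu = expit(au)
    Fl = expit(al)
    fu = np.where(np.isfinite(au), Fu * (1.0 - Fu), 0.0)
    fl = np.where(np.isfinite(al), Fl * (1.0 - Fl), 0.0)
    P = Fu - Fl
    return P, Fu, Fl, fu, fl


class CumulativeLinkModel:
    """Proportional-odds logit model for an ordinal outcome.

    Parameters
    ----------
    endog : array-like
        Ordinal outcome values (any ordered numeric coding; only the
        observed levels define the threshold structure).
    exog : array-like, shape (n, p)
        Predictor matrix, raw units, no intercept column (the thresholds
        absorb the location).
    term_names : sequence of str, optional
        Labels for the predictor columns.
    """

    def __init__(self, endog, exog, term_names=None):
        endog = np.asarray(endog)
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        if len(endog) != len(exog):
            raise InputError("endog and exog lengths differ")
        self.levels = np.unique(endog)
        if self.levels.size < 2:
            raise DegenerateOutcomeError("outcome has a single observed level")
        self.y = np.searchsorted(self.levels, endog)
        self.X = exog
        self.nobs = len(endog)
        self.n_levels = self.levels.size
        p = exog.shape[1]
        self.term_names = (
            list(term_names) if term_names is not None
            else [f"x{i + 1}" for i in range(p)]
        )
        if len(self.term_names) != p:
            raise InputError("term_names length does not match exog columns")
        self.k_params = p + self.n_levels - 1

    @classmethod
    def from_spec(cls, data: pd.DataFrame, spec: DesignSpec) -> "CumulativeLinkModel":
        y, X, levels, names = build_design(data, spec)
        model = cls(np.asarray(data[spec.outcome]), X, names)
        return model

    @classmethod
    def from_dataframe(cls, data, outcome, main_terms, interaction_terms=()):
        spec = DesignSpec(
            outcome=outcome,
            main_terms=tuple(main_terms),
            interaction_terms=tuple(tuple(t) for t in interaction_terms),
        )
        return cls.from_spec(data, spec)

    # ------------------------------------------------------------------
    # likelihood and derivatives
    # ------------------------------------------------------------------

    def loglike(self, beta, thresholds) -> float:
        """Log-likelihood at (beta, thresholds) in natural parameters."""
        beta = np.asarray(beta, dtype=float)
        thresholds = np.asarray(thresholds, dtype=float)
        if thresholds.size != self.n_levels - 1:
            raise InputError(
                f"expected {self.n_levels - 1} thresholds, got {thresholds.size}"
            )
        if thresholds.size > 1 and np.any(np.diff(thresholds) <= 0):
            raise InputError("thresholds must be strictly increasing")
        P, *_ = _loglik_terms(self.y, self.X, beta, thresholds)
        return float(np.sum(np.log(np.maximum(P, _TINY))))

    def _score_hessian_natural(self, beta, thresholds):
        """Gradient and Hessian of the log-likelihood in (thresholds, beta)."""
        y, X = self.y, self.X
        J1 = self.n_levels - 1
        p = X.shape[1]
        P, Fu, Fl, fu, fl = _loglik_terms(y, X, beta, thresholds)
        P = np.maximum(P, _TINY)
        fpu = fu * (1.0 - 2.0 * Fu)  # f'(a_u)
        fpl = fl * (1.0 - 2.0 * Fl)

        g = np.zeros(J1 + p)
        H = np.zeros((J1 + p, J1 + p))

        A, B = fu, fl
        iu = y          # upper cut index into thresholds (valid when y <= J1-1)
        il = y - 1      # lower cut index (valid when y >= 1)
        has_u = y <= J1 - 1
        has_l = y >= 1

        # gradient
        np.add.at(g, iu[has_u], (A / P)[has_u])
        np.add.at(g, il[has_l], (-B / P)[has_l])
        gb = -(A - B) / P
        g[J1:] = X.T @ gb if p else 0.0

        # theta-theta block (ratios A/P etc. avoid underflow of P**2)
        d_uu = fpu / P - (A / P) ** 2
        d_ll = -fpl / P - (B / P) ** 2
        d_ul = (A / P) * (B / P)
        np.add.at(H, (iu[has_u], iu[has_u]), d_uu[has_u])
        np.add.at(H, (il[has_l], il[has_l]), d_ll[has_l])
        both = has_u & has_l
        np.add.at(H, (iu[both], il[both]), d_ul[both])
        np.add.at(H, (il[both], iu[both]), d_ul[both])

        # beta-beta block
        w = (fpu - fpl) / P - ((A - B) / P) ** 2
        if p:
            H[J1:, J1:] = X.T @ (w[:, None] * X)

            # theta-beta blocks
            c_u = (A / P) * ((A - B) / P) - fpu / P
            c_l = fpl / P - (B / P) * ((A - B) / P)
            M = np.zeros((J1, p))
            np.add.at(M, iu[has_u], (c_u[has_u][:, None] * X[has_u]))
            np.add.at(M, il[has_l], (c_l[has_l][:, None] * X[has_l]))
            H[:J1, J1:] = M
            H[J1:, :J1] = M.T
        return g, H

    # ------------------------------------------------------------------
    # threshold reparameterization: zeta -> theta
    # ------------------------------------------------------------------

    @staticmethod
    def _theta_from_zeta(zeta_th):
        th = np.empty_like(zeta_th)
        th[0] = zeta_th[0]
        if zeta_th.size > 1:
            with np.errstate(over="ignore"):
                # inf thresholds from an absurd trial step yield -inf
                # log-likelihood and are rejected by the line search
                th[1:] = zeta_th[0] + np.cumsum(np.exp(zeta_th[1:]))
        return th

    @staticmethod
    def _zeta_from_theta(theta):
        z = np.empty_like(theta)
        z[0] = theta[0]
        if theta.size > 1:
            z[1:] = np.log(np.diff(theta))
        return z

    def _score_hessian_zeta(self, zeta):
        J1 = self.n_levels - 1
        p = self.X.shape[1]
        theta = self._theta_from_zeta(zeta[:J1])
        beta = zeta[J1:]
        g_nat, H_nat = self._score_hessian_natural(beta, theta)

        # Jacobian of theta wrt zeta_theta: column 0 all ones; column k (>=1)
        # equals exp(zeta_k) for rows j >= k.
        Jm = np.zeros((J1, J1))
        Jm[:, 0] = 1.0
        for k in range(1, J1):
            Jm[k:, k] = np.exp(zeta[k])

        g = np.empty(J1 + p)
        g[:J1] = Jm.T @ g_nat[:J1]
        g[J1:] = g_nat[J1:]

        H = np.empty((J1 + p, J1 + p))
        H[:J1, :J1] = Jm.T @ H_nat[:J1, :J1] @ Jm
        # curvature of the reparameterization: d2 theta_j / d zeta_k^2 = e^{zeta_k}
        for k in range(1, J1):
            H[k, k] += np.exp(zeta[k]) * np.sum(g_nat[k:J1])
        H[:J1, J1:] = Jm.T @ H_nat[:J1, J1:]
        H[J1:, :J1] = H[:J1, J1:].T
        H[J1:, J1:] = H_nat[J1:, J1:]
        return g, H, theta, beta

    # ------------------------------------------------------------------
    # fitting
    # ------------------------------------------------------------------

    def _start_params(self):
        counts = np.bincount(self.y, minlength=self.n_levels)
        cum = np.cumsum(counts)[:-1] / self.nobs
        cum = np.clip(cum, 1.0 / (2 * self.nobs), 1 - 1.0 / (2 * self.nobs))
        theta0 = logit(cum)
        # strictly increasing by construction unless a level is empty
        eps = 1e-6
        for j in range(1, theta0.size):
            if theta0[j] <= theta0[j - 1]:
                theta0[j] = theta0[j - 1] + eps
        return theta0

    def fit(self, maxiter=200, gtol=1e-8, beta_cap=30.0) -> "CumulativeLinkResults":
        """Maximize the likelihood by Newton iteration with step-halving.

        Thresholds are initialized at the empirical cumulative logits and
        slopes at zero.  Divergent slopes (|beta| exceeding ``beta_cap``,
        the signature of complete separation) yield a warning and a result
        flagged not converged rather than an exception.
        """
        J1 = self.n_levels - 1
        p = self.X.shape[1]
        if self.nobs <= self.k_params:
            warnings.warn(
                f"n ({self.nobs}) <= number of parameters ({self.k_params}); "
                "estimates may be unstable",
                stacklevel=2,
            )
        zeta = np.concatenate([self._zeta_from_theta(self._start_params()), np.zeros(p)])

        def negll(z):
            th = self._theta_from_zeta(z[:J1])
            P, *_ = _loglik_terms(self.y, self.X, z[J1:], th)
            return -np.sum(np.log(np.maximum(P, _TINY)))

        ll = -negll(zeta)
        converged = False
        n_iter = 0
        for n_iter in range(1, maxiter + 1):
            g, H, theta, beta = self._score_hessian_zeta(zeta)
            gmax = np.max(np.abs(g))
            if gmax < gtol:
                converged = True
                break
            # Solve (-H + lam*I) step = g, damping the Hessian to positive
            # definiteness when the reparameterization makes it indefinite
            # away from the optimum (Levenberg-style safeguard).
            A = -H
            try:
                eigmin = float(np.linalg.eigvalsh(A).min())
            except np.linalg.LinAlgError:
                eigmin = -1.0
            if eigmin <= 1e-10:
                A = A + (abs(eigmin) + 1e-6 * (1.0 + abs(eigmin))) * np.eye(len(g))
            try:
                step = np.linalg.solve(A, g)
                if g @ step <= 0:  # numerical safeguard
                    step = g / (1.0 + np.linalg.norm(g))
            except np.linalg.LinAlgError:
                step = g / (1.0 + np.linalg.norm(g))
            # Newton decrement: predicted remaining log-likelihood gain.
            # With raw-unit covariates the information matrix is badly
            # scaled and the gradient norm can stagnate at the limit of
            # double precision while the optimum is already attained; the
            # final step below is still applied (quadratic convergence)
            # before declaring success.
            final_step = 0.5 * (g @ step) < 1e-12 * (1.0 + abs(ll))
            # step-halving line search
            t = 1.0
            improved = False
            for _ in range(60):
                cand = zeta + t * step
                ll_new = -negll(cand)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    # accept any non-decreasing step; strict improvement
                    # is guaranteed along an ascent direction for small t
                    if ll_new > ll or t < 1e-12:
                        zeta = cand
                        ll = ll_new
                        improved = True
                        break
                t *= 0.5
            if not improved:
                # line search exhausted machine precision; treat as
                # converged only if the score is already near zero
                converged = gmax < 1e-5
                break
            if final_step:
                converged = True
                break
            if np.any(np.abs(zeta[J1:]) > beta_cap):
                warnings.warn(
                    "slope estimate diverging (possible separation); "
                    "capping and flagging not converged",
                    stacklevel=2,
                )
                zeta[J1:] = np.clip(zeta[J1:], -beta_cap, beta_cap)
                ll = -negll(zeta)
                break

        theta = self._theta_from_zeta(zeta[:J1])
        beta = zeta[J1:]
        if ll > -1e-3 and p:
            # likelihood at its supremum of 0: the data are perfectly
            # separated and the slope estimates diverge
            warnings.warn(
                "perfect separation: slope estimates diverge; "
                "returning capped estimates flagged not converged",
                stacklevel=2,
            )
            beta = np.clip(beta, -beta_cap, beta_cap)
            converged = False
        if not converged and n_iter >= maxiter:
            g, _, _, _ = self._score_hessian_zeta(zeta)
            raise FitError(
                "Newton iteration did not converge",
                diagnostics={
                    "iterations": n_iter,
                    "loglik": ll,
                    "grad_max": float(np.max(np.abs(g))),
                },
            )

        # observed information in natural parameters
        _, H_nat = self._score_hessian_natural(beta, theta)
        try:
            vcov = np.linalg.inv(-H_nat)
        except np.linalg.LinAlgError:
            warnings.warn("observed information singular; using pseudo-inverse",
                          stacklevel=2)
            vcov = np.linalg.pinv(-H_nat)
        vcov = (vcov + vcov.T) / 2.0
        return CumulativeLinkResults(
            model=self,
            params=beta,
            thresholds=theta,
            vcov=vcov,
            llf=float(ll),
            converged=converged,
            iterations=n_iter,
        )


@dataclass
class CumulativeLinkResults:
    """Results of a cumulative-link fit.

    ``vcov`` is ordered (thresholds, slopes); ``bse`` exposes the slope
    standard errors and ``bse_thresholds`` the threshold standard errors.
    """

    model: CumulativeLinkModel
    params: np.ndarray
    thresholds: np.ndarray
    vcov: np.ndarray
    llf: float
    converged: bool
    iterations: int

    def __post_init__(self):
        self.term_names = self.model.term_names
        self.observed_levels = self.model.levels
        self.nobs = self.model.nobs
        self.k_params = self.model.k_params

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def bse(self) -> np.ndarray:
        J1 = self.thresholds.size
        return np.sqrt(np.maximum(np.diag(self.vcov)[J1:], 0.0))

    @property
    def bse_thresholds(self) -> np.ndarray:
        J1 = self.thresholds.size
        return np.sqrt(np.maximum(np.diag(self.vcov)[:J1], 0.0))

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.zvalues))

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """Exponentiate slopes into odds ratios with Wald confidence bounds.

        Returns a frame with columns ``term, or, ci_low, ci_high, p``;
        the interval is symmetric on the log scale.
        """
        if not self.converged:
            warnings.warn("odds ratios from a non-converged fit", stacklevel=2)
        z = norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {
                "term": self.term_names,
                "or": np.exp(self.params),
                "ci_low": np.exp(self.params - z * self.bse),
                "ci_high": np.exp(self.params + z * self.bse),
                "p": self.pvalues,
            }
        )

    def predict(self, exog) -> np.ndarray:
        """Category probabilities over the observed levels, rows sum to 1."""
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        eta = X @ self.params if X.shape[1] else np.zeros(X.shape[0])
        th = np.concatenate([[-np.inf], self.thresholds, [np.inf]])
        cdf = expit(th[None, :] - eta[:, None])
        probs = np.diff(cdf, axis=1)
        return probs

    def compare_lr_test(self, nested: "CumulativeLinkResults") -> "ModelComparison":
        return lrt_compare(nested, self)

    def summary(self) -> str:
        lines = [
            "Cumulative link model (logit), maximum likelihood",
            f"  n = {self.nobs}, levels = {self.observed_levels.size}, "
            f"k = {self.k_params}, converged = {self.converged} "
            f"({self.iterations} iterations)",
            f"  log-likelihood = {self.llf:.1f}, AIC = {self.aic:.1f}",
            "",
            f"  {'term':<16}{'coef':>10}{'se':>9}{'z':>8}{'p':>10}  ",
        ]
        for name, b, se, z, pv in zip(
            self.term_names, self.params, self.bse, self.zvalues, self.pvalues
        ):
            stars = _stars(pv)
            lines.append(f"  {name:<16}{b:>10.3f}{se:>9.3f}{z:>8.2f}{pv:>10.3g} {stars}")
        lines.append("")
        lines.append("  thresholds: " + ", ".join(f"{t:.3f}" for t in self.thresholds))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable record of the fit."""
        return {
            "term_names": list(self.term_names),
            "beta": self.params.tolist(),
            "se": self.bse.tolist(),
            "vcov": self.vcov.tolist(),
            "thresholds": self.thresholds.tolist(),
            "observed_levels": np.asarray(self.observed_levels).tolist(),
            "loglik": self.llf,
            "aic": self.aic,
            "n": int(self.nobs),
            "k": int(self.k_params),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
        }


def _stars(p: float) -> str:
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class ModelComparison:
    """Likelihood-ratio (ANOVA chi-square) comparison of nested fits."""

    chi2: float
    df: int
    p: float
    aic_a: float
    aic_b: float
    loglik_a: float
    loglik_b: float


def lrt_compare(fit_nested: CumulativeLinkResults,
                fit_full: CumulativeLinkResults) -> ModelComparison:
    """Likelihood-ratio test between nested cumulative-link fits.

    ``fit_nested`` must use a subset of the full model's terms, the same
    outcome levels, and the same number of observations.  The statistic is
    ``2 * (llf_full - llf_nested)`` on ``k_full - k_nested`` degrees of
    freedom.
    """
    if fit_nested.nobs != fit_full.nobs:
        raise ComparisonError("fits use different numbers of observations")
    if not np.array_equal(fit_nested.observed_levels, fit_full.observed_levels):
        raise ComparisonError("fits use different outcome level sets")
    if not set(fit_nested.term_names) <= set(fit_full.term_names):
        raise ComparisonError(
            "models are not nested: "
            f"{set(fit_nested.term_names) - set(fit_full.term_names)} "
            "missing from the full model"
        )
    df = fit_full.k_params - fit_nested.k_params
    chi2 = 2.0 * (fit_full.llf - fit_nested.llf)
    if df < 1 and chi2 > 1e-8:
        raise ComparisonError("full model has no extra parameters")
    if chi2 < -1e-6:
        raise FitError(
            "full-model likelihood below nested-model likelihood; "
            "at least one fit is at a poor optimum",
            diagnostics={"chi2": chi2},
        )
    chi2 = max(chi2, 0.0)
    p = float(chi2_dist.sf(chi2, df)) if df >= 1 else 1.0
    return ModelComparison(
        chi2=float(chi2),
        df=int(df),
        p=p,
        aic_a=fit_nested.aic,
        aic_b=fit_full.aic,
        loglik_a=fit_nested.llf,
        loglik_b=fit_full.llf,
    )
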