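"""Fractional-response, censored-normal and least-squares estimators.

Three model families for a bounded outcome y_i in [0, 1]:

* :class:`FractionalLogit` — quasi-likelihood estimation of the conditional
  mean E[y|x] = G(x'beta) with G the logistic function. The Bernoulli
  quasi-log-likelihood Q(beta) = sum_i y_i log G_i + (1-y_i) log(1-G_i) is
  maximised by Newton/IRLS; point masses at 0 and 1 are legal observations.
  Inference uses the sandwich (robust) covariance A^{-1} B A^{-1}.
* :class:`Tobit` — maximum likelihood for a two-limit censored normal:
  a latent y* = x'beta + eps, eps ~ N(0, sigma^2), observed clamped to
  [lower, upper]; interior points contribute a normal density, points at a
  limit contribute the tail mass.
* :class:`OLS` — closed-form least squares with heteroskedasticity-robust
  covariance, the conventional comparator (its predictions can leave [0,1]).

Each model's ``fit()`` returns a results object carrying coefficients,
robust covariance, log-(quasi-)likelihood and convergence metadata, with a
``summary()`` table and family-appropriate ``predict()``.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, special, stats

from .design import DesignMatrix
from .exceptions import ConvergenceWarning, IdentificationError

_MU_EPS = 1e-12


def inv_logit(eta):
    """Logistic function 1/(1+exp(-eta)); numerically stable for large |eta|."""
    return special.expit(eta)


def logit(p):
    return special.logit(p)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise naming the offending columns when X is rank deficient."""
    n, p = X.shape
    # QR with column pivoting: columns pivoted past the numerical rank are
    # linear combinations of earlier ones.
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(n, p) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < p:
        collinear = [names[i] for i in piv[rank:]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {collinear}"
        )


def _hc1_sandwich(A: np.ndarray, scores: np.ndarray, df_scale: float) -> np.ndarray:
    """A^{-1} B A^{-1} with B the outer product of per-observation scores and
    an HC1-style small-sample factor."""
    Ainv = linalg.pinvh(A)
    B = scores.T @ scores
    cov = Ainv @ B @ Ainv * df_scale
    return 0.5 * (cov + cov.T)


def _cluster_sandwich(A: np.ndarray, scores: np.ndarray, groups: np.ndarray) -> np.ndarray:
    Ainv = linalg.pinvh(A)
    labels = np.unique(groups)
    g = len(labels)
    B = np.zeros_like(A)
    for lab in labels:
        s = scores[groups == lab].sum(axis=0)
        B += np.outer(s, s)
    cov = Ainv @ B @ Ainv * g / max(g - 1, 1)
    return 0.5 * (cov + cov.T)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates and robust inference for one fitted model."""

    params: np.ndarray
    cov_robust: np.ndarray
    llf: float
    family: str
    column_names: list[str]
    n_obs: int
    converged: bool
    n_iter: int
    model: "object" = None
    sigma: float | None = None  # Tobit scale
    sigma_se: float | None = None

    @property
    def beta(self) -> np.ndarray:  # spec-facing alias
        return self.params

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_robust))

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.tvalues))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def predict(self, X_new: np.ndarray | None = None) -> np.ndarray:
        X = self.model.X if X_new is None else np.asarray(X_new, dtype=float)
        return self.model.mean_response(X, self)

    def param(self, name: str) -> float:
        return float(self.params[self.column_names.index(name)])

    def to_json(self) -> str:
        payload = {
            "family": self.family,
            "n_obs": self.n_obs,
            "loglik": self.llf,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "coefficients": dict(zip(self.column_names, self.params.tolist())),
            "robust_se": dict(zip(self.column_names, self.bse.tolist())),
        }
        if self.sigma is not None:
            payload["sigma"] = self.sigma
            payload["sigma_robust_se"] = self.sigma_se
        return json.dumps(payload, indent=2)

    def summary(self) -> str:
        """Coefficient table with robust SEs in parentheses and significance
        stars (*** p<0.01, ** p<0.05, * p<0.1)."""

        def star(p):
            return "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.1 else ""

        title = f"{self.family} regression" + (
            f": {self.model.response_name}" if getattr(self.model, "response_name", "") else ""
        )
        lines = [title, "=" * 58]
        lines.append(f"{'Variables':<28}{'Coefficients':>14}")
        lines.append("-" * 58)
        for name, b, se, p in zip(self.column_names, self.params, self.bse, self.pvalues):
            lines.append(f"{name:<28}{b:>11.4g}{star(p):<3}")
            lines.append(f"{'':<28}({se:.3g})")
        if self.sigma is not None:
            lines.append(f"{'sigma':<28}{self.sigma:>11.4g}")
        lines.append("-" * 58)
        lines.append(f"Log {'pseudo-' if self.family == 'fractional_logit' else ''}likelihood"
                     f"  {self.llf:.4g}")
        lines.append(f"Number of observations  {self.n_obs}")
        if not self.converged:
            lines.append("WARNING: optimiser did not converge")
        lines.append("*** p<0.01, ** p<0.05, * p<0.1")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model base
# ---------------------------------------------------------------------------

class _Model:
    family = ""

    def __init__(self, endog, exog, column_names=None, response_name=""):
        self.y = np.asarray(endog, dtype=float)
        self.X = np.asarray(exog, dtype=float)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValueError("endog/exog shapes are inconsistent")
        self.column_names = (
            list(column_names)
            if column_names is not None
            else [f"x{j}" for j in range(self.X.shape[1])]
        )
        self.response_name = response_name
        self.region_block: list[int] = []

    @classmethod
    def from_design(cls, dm: DesignMatrix, **kwargs):
        m = cls(dm.y, dm.X, column_names=dm.column_names,
                response_name=dm.response_name, **kwargs)
        m.region_block = list(dm.region_block)
        m.design = dm
        return m

    def _groups(self, cov_type, groups):
        if cov_type == "cluster" and groups is None:
            raise ValueError("cov_type='cluster' requires groups")
        return np.asarray(groups) if groups is not None else None


class FractionalLogit(_Model):
    """Quasi-likelihood fractional-response model with a logistic mean."""

    family = "fractional_logit"

    def __init__(self, endog, exog, column_names=None, response_name=""):
        super().__init__(endog, exog, column_names, response_name)
        if np.any((self.y < 0) | (self.y > 1)):
            raise ValueError("fractional logit requires y in [0, 1]")

    def loglike(self, beta: np.ndarray) -> float:
        mu = np.clip(inv_logit(self.X @ beta), _MU_EPS, 1 - _MU_EPS)
        return float(np.sum(special.xlogy(self.y, mu) + special.xlogy(1 - self.y, 1 - mu)))

    def score(self, beta: np.ndarray) -> np.ndarray:
        mu = inv_logit(self.X @ beta)
        return self.X.T @ (self.y - mu)

    def _start(self) -> np.ndarray:
        z = logit(np.clip(self.y, 0.01, 0.99))
        beta, *_ = np.linalg.lstsq(self.X, z, rcond=None)
        return beta

    def fit(
        self,
        start_params: np.ndarray | None = None,
        maxiter: int = 200,
        gtol: float = 1e-8,
        lltol: float = 1e-10,
        cov_type: str = "HC1",
        groups=None,
    ) -> FitResult:
        _check_full_rank(self.X, self.column_names)
        groups = self._groups(cov_type, groups)
        X, y = self.X, self.y
        n, p = X.shape
        beta = self._start() if start_params is None else np.asarray(start_params, float)
        ll = self.loglike(beta)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            mu = inv_logit(X @ beta)
            score = X.T @ (y - mu)
            if np.max(np.abs(score)) < gtol:
                converged = True
                break
            w = np.clip(mu * (1 - mu), _MU_EPS, None)
            H = X.T @ (X * w[:, None])
            try:
                step = linalg.solve(H, score, assume_a="pos")
            except linalg.LinAlgError:
                step = linalg.lstsq(H + 1e-8 * np.eye(p), score)[0]
            # halving line search: Newton on a concave quasi-likelihood almost
            # never needs it, but divergence toward separation does
            # tolerance relative to |ll|: absolute comparisons drown in
            # float noise once n is large
            ll_eps = 1e-13 * (abs(ll) + 1.0)
            scale = 1.0
            ll_new = self.loglike(beta + step)
            while ll_new < ll - ll_eps and scale > 1e-12:
                scale *= 0.5
                ll_new = self.loglike(beta + scale * step)
            if ll_new < ll - ll_eps:
                break  # stalled: no ascent direction left
            beta = beta + scale * step
            if scale < 1e-8 and abs(ll_new - ll) <= lltol * (abs(ll) + 1e-300):
                ll = ll_new
                break  # step collapsed without further likelihood gain
            ll = ll_new
        if not converged and np.max(np.abs(self.score(beta))) < 1e-6:
            converged = True  # score is numerically zero even if gtol unmet
        if not converged:
            warnings.warn(
                "fractional logit did not converge (possible quasi-separation); "
                "returning partial result",
                ConvergenceWarning,
            )
        mu = inv_logit(X @ beta)
        w = np.clip(mu * (1 - mu), _MU_EPS, None)
        A = X.T @ (X * w[:, None])
        scores = X * (y - mu)[:, None]
        if cov_type == "cluster":
            cov = _cluster_sandwich(A, scores, groups)
        else:
            cov = _hc1_sandwich(A, scores, n / max(n - p, 1))
        return FitResult(
            params=beta,
            cov_robust=cov,
            llf=self.loglike(beta),
            family=self.family,
            column_names=self.column_names,
            n_obs=n,
            converged=converged,
            n_iter=it,
            model=self,
        )

    def mean_response(self, X: np.ndarray, res: FitResult) -> np.ndarray:
        return inv_logit(X @ res.params)


class Tobit(_Model):
    """Two-limit censored-normal (Tobit) regression fitted by ML.

    ``lower``/``upper`` may be ``-inf``/``inf`` to drop a limit; with both
    infinite the likelihood is that of a normal linear model and the MLE
    coincides with OLS.
    """

    family = "tobit"

    def __init__(self, endog, exog, column_names=None, response_name="",
                 lower: float = 0.0, upper: float = 1.0):
        super().__init__(endog, exog, column_names, response_name)
        if lower >= upper:
            raise ValueError("lower limit must be below upper limit")
        self.lower, self.upper = float(lower), float(upper)
        self._at_lower = np.isfinite(lower) & (self.y <= lower)
        self._at_upper = np.isfinite(upper) & (self.y >= upper)
        self._interior = ~(self._at_lower | self._at_upper)
        if not self._interior.any():
            if self._at_lower.all() or self._at_upper.all():
                raise IdentificationError(
                    "all observations censored at one limit; Tobit not identified"
                )

    # theta = (beta, log sigma)
    def _unpack(self, theta):
        return theta[:-1], float(np.exp(theta[-1]))

    def loglike(self, theta: np.ndarray) -> float:
        return float(np.sum(self._loglike_obs(theta)))

    def _loglike_obs(self, theta: np.ndarray) -> np.ndarray:
        beta, sigma = self._unpack(theta)
        xb = self.X @ beta
        ll = np.empty(len(self.y))
        i = self._interior
        z = (self.y[i] - xb[i]) / sigma
        ll[i] = -0.5 * z**2 - 0.5 * np.log(2 * np.pi) - np.log(sigma)
        if self._at_lower.any():
            zl = (self.lower - xb[self._at_lower]) / sigma
            ll[self._at_lower] = special.log_ndtr(zl)
        if self._at_upper.any():
            zu = (self.upper - xb[self._at_upper]) / sigma
            ll[self._at_upper] = special.log_ndtr(-zu)
        return ll

    def _score_obs(self, theta: np.ndarray) -> np.ndarray:
        """Per-observation gradient in (beta, log sigma)."""
        beta, sigma = self._unpack(theta)
        xb = self.X @ beta
        n, p = self.X.shape
        g = np.zeros((n, p + 1))
        i = self._interior
        z = (self.y[i] - xb[i]) / sigma
        g[i, :p] = self.X[i] * (z / sigma)[:, None]
        g[i, p] = z**2 - 1.0
        if self._at_lower.any():
            m = self._at_lower
            zl = (self.lower - xb[m]) / sigma
            # d/dz log Phi(z) = phi/Phi = exp(log phi - log Phi)
            ratio = np.exp(stats.norm.logpdf(zl) - special.log_ndtr(zl))
            g[m, :p] = self.X[m] * (-ratio / sigma)[:, None]
            g[m, p] = -ratio * zl
        if self._at_upper.any():
            m = self._at_upper
            zu = (self.upper - xb[m]) / sigma
            ratio = np.exp(stats.norm.logpdf(zu) - special.log_ndtr(-zu))
            g[m, :p] = self.X[m] * (ratio / sigma)[:, None]
            g[m, p] = ratio * zu
        return g

    def score(self, theta: np.ndarray) -> np.ndarray:
        return self._score_obs(theta).sum(axis=0)

    def _start(self) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ beta
        sigma = max(float(np.std(resid)), 1e-3)
        return np.concatenate([beta, [np.log(sigma)]])

    def fit(self, start_params=None, maxiter: int = 500, gtol: float = 1e-10,
            cov_type: str = "HC1", groups=None) -> FitResult:
        _check_full_rank(self.X, self.column_names)
        groups = self._groups(cov_type, groups)
        n, p = self.X.shape
        theta0 = self._start() if start_params is None else np.asarray(start_params, float)
        res = optimize.minimize(
            lambda t: -self.loglike(t),
            theta0,
            jac=lambda t: -self.score(t),
            method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        theta = res.x
        # Newton polish: BFGS line searches often stall within ~1e-4 of the
        # optimum when censoring is heavy and sigma is small
        for _ in range(10):
            g = self.score(theta)
            if np.max(np.abs(g)) < 1e-9:
                break
            H = self._neg_hessian(theta)
            try:
                step = linalg.solve(H, g, assume_a="sym")
            except linalg.LinAlgError:
                break
            ll0 = self.loglike(theta)
            scale = 1.0
            while scale > 1e-10 and self.loglike(theta + scale * step) < ll0 - 1e-12:
                scale *= 0.5
            if scale <= 1e-10:
                break
            theta = theta + scale * step
        beta, sigma = self._unpack(theta)
        converged = bool(np.max(np.abs(self.score(theta))) < 1e-5 * max(1.0, n / 100))
        if sigma < 1e-8:
            converged = False
        if not converged:
            warnings.warn("Tobit optimiser did not fully converge", ConvergenceWarning)
        A = self._neg_hessian(theta)
        scores = self._score_obs(theta)
        if cov_type == "cluster":
            cov_theta = _cluster_sandwich(A, scores, groups)
        else:
            cov_theta = _hc1_sandwich(A, scores, n / max(n - p - 1, 1))
        sigma_se = float(np.sqrt(max(cov_theta[p, p], 0.0)) * sigma)  # delta: dsigma/dlogsigma
        return FitResult(
            params=beta,
            cov_robust=cov_theta[:p, :p],
            llf=self.loglike(theta),
            family=self.family,
            column_names=self.column_names,
            n_obs=n,
            converged=converged,
            n_iter=int(res.nit),
            model=self,
            sigma=sigma,
            sigma_se=sigma_se,
        )

    def _neg_hessian(self, theta: np.ndarray, h: float = 1e-6) -> np.ndarray:
        """Negative Hessian of the log-likelihood by central differences of the
        analytic gradient."""
        k = len(theta)
        H = np.zeros((k, k))
        for j in range(k):
            step = h * max(1.0, abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += step
            tm[j] -= step
            H[:, j] = -(self.score(tp) - self.score(tm)) / (2 * step)
        return 0.5 * (H + H.T)

    def mean_response(self, X: np.ndarray, res: FitResult) -> np.ndarray:
        """E[y] of the two-limit censored normal at the fitted parameters."""
        xb = X @ res.params
        s = res.sigma
        zl = (self.lower - xb) / s if np.isfinite(self.lower) else np.full_like(xb, -np.inf)
        zu = (self.upper - xb) / s if np.isfinite(self.upper) else np.full_like(xb, np.inf)
        Pl, Pu = stats.norm.cdf(zl), stats.norm.cdf(zu)
        out = (Pu - Pl) * xb + s * (stats.norm.pdf(zl) - stats.norm.pdf(zu))
        if np.isfinite(self.lower):
            out += self.lower * Pl
        if np.isfinite(self.upper):
            out += self.upper * (1.0 - Pu)
        return out


class OLS(_Model):
    """Ordinary least squares with heteroskedasticity-robust covariance."""

    family = "ols"

    def fit(self, cov_type: str = "HC1", groups=None) -> FitResult:
        _check_full_rank(self.X, self.column_names)
        groups = self._groups(cov_type, groups)
        X, y = self.X, self.y
        n, p = X.shape
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        A = X.T @ X
        scores = X * resid[:, None]
        if cov_type == "cluster":
            cov = _cluster_sandwich(A, scores, groups)
        else:
            cov = _hc1_sandwich(A, scores, n / max(n - p, 1))
        sigma2 = float(resid @ resid) / n
        llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        return FitResult(
            params=beta,
            cov_robust=cov,
            llf=llf,
            family=self.family,
            column_names=self.column_names,
            n_obs=n,
            converged=True,
            n_iter=0,
            model=self,
        )

    def mean_response(self, X: np.ndarray, res: FitResult) -> np.ndarray:
        pred = X @ res.params
        if np.any((pred < 0) | (pred > 1)):
            warnings.warn(
                "OLS predictions fall outside [0, 1]; the linear model does not "
                "respect the bounded outcome",
                UserWarning,
            )
        return pred


FAMILIES = {
    "fractional_logit": FractionalLogit,
    "tobit": Tobit,
    "ols": OLS,
}


def fit_fractional_logit(dm: DesignMatrix, **kwargs) -> FitResult:
    return FractionalLogit.from_design(dm).fit(**kwargs)


def fit_tobit(dm: DesignMatrix, lower: float = 0.0, upper: float = 1.0, **kwargs) -> FitResult:
    return Tobit.from_design(dm, lower=lower, upper=upper).fit(**kwargs)


def fit_ols(dm: DesignMatrix, **kwargs) -> FitResult:
    return OLS.from_design(dm).fit(**kwargs)


def fit_family(dm: DesignMatrix, family: str, **kwargs) -> FitResult:
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")
    if family == "tobit":
        return fit_tobit(dm, **kwargs)
    return FAMILIES[family].from_design(dm).fit(**kwargs)


def predict(fit: FitResult, X_new: np.ndarray | None = None) -> np.ndarray:
    """Family-appropriate mean prediction (fractions for the bounded families)."""
    return fit.predict(X_new)
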