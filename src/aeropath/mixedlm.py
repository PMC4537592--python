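"""Maximum-likelihood linear models with random intercepts.

All model comparison in this package is by AICc over maximum-likelihood
(never REML) fits, so fixed-effect structures remain comparable.  The
implementation profiles out the fixed effects and the residual variance and
optimizes the variance ratios of up to a few (possibly crossed) random
intercept factors numerically.  For zero factors it reduces to OLS.

Parameter counting convention: ``k`` = number of fixed-effect columns
(including the intercept) + one variance parameter per random-intercept
factor + one residual variance.  Declared random factors are always counted
even when their variance estimate lies on the zero boundary, so ``k`` is
constant across fixed-effect candidates sharing a random-effect structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

__all__ = ["LMMResult", "fit_lmm", "FitError"]

_TWO_PI = 2.0 * np.pi


class FitError(RuntimeError):
    """The model could not be fit (degenerate response or singular design)."""


@dataclass
class LMMResult:
    names: list[str]
    params: np.ndarray
    se: np.ndarray
    llf: float
    k: int
    n: int
    sigma2: float
    re_var: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    singular: tuple[str, ...] = ()

    @property
    def df_resid(self) -> int:
        return self.n - len(self.params)

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.se

    @property
    def pvalues(self) -> np.ndarray:
        t = np.abs(self.tvalues)
        return 2.0 * stats.t.sf(t, df=max(self.df_resid, 1))

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def coef_pvalue(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])


def _ols(y: np.ndarray, X: np.ndarray, names: list[str], n_re: int) -> LMMResult:
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise FitError("singular fixed-effect design")
    r = y - X @ beta
    sigma2 = float(r @ r) / n
    if sigma2 <= 0 or not np.isfinite(sigma2):
        raise FitError("degenerate fit: zero residual variance")
    llf = -0.5 * n * (np.log(_TWO_PI * sigma2) + 1.0)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return LMMResult(
        names=list(names), params=beta, se=se, llf=float(llf),
        k=p + 1 + n_re, n=n, sigma2=sigma2,
    )


def fit_lmm(y, X, names, groups: dict[str, np.ndarray] | None = None) -> LMMResult:
    """Fit ``y = X beta + sum_j b_j[group_j] + eps`` by maximum likelihood.

    ``groups`` maps a factor name to an array of group labels (one per row);
    each factor contributes an independent random intercept.  Factors whose
    variance estimate collapses to the boundary are reported in ``singular``
    but remain in the parameter count (see module docstring).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if len(y) != n:
        raise FitError("response/design length mismatch")
    if n <= p + 1:
        raise FitError(f"too few observations (n={n}) for {p} fixed effects")
    if np.ptp(y) == 0.0:
        raise FitError("degenerate fit: zero-variance response")
    groups = dict(groups or {})
    if not groups:
        return _ols(y, X, names, 0)

    factor_names = list(groups)
    A = []
    for g in factor_names:
        codes = np.unique(np.asarray(groups[g]), return_inverse=True)[1]
        A.append((codes[:, None] == codes[None, :]).astype(float))
    m = len(A)
    eye = np.eye(n)

    def profile(theta: np.ndarray):
        V = eye.copy()
        for th, Aj in zip(theta, A):
            V += th * Aj
        try:
            c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        ViX = linalg.cho_solve((c, low), X, check_finite=False)
        Viy = linalg.cho_solve((c, low), y, check_finite=False)
        XtViX = X.T @ ViX
        try:
            beta = linalg.solve(XtViX, X.T @ Viy, assume_a="pos")
        except linalg.LinAlgError:
            return None
        r = y - X @ beta
        Vir = Viy - ViX @ beta
        sigma2 = float(r @ Vir) / n
        if sigma2 <= 0 or not np.isfinite(sigma2):
            return None
        llf = -0.5 * (n * np.log(_TWO_PI * sigma2) + n + logdet)
        return llf, beta, sigma2, XtViX

    def neg(theta: np.ndarray) -> float:
        out = profile(theta)
        if out is None:
            return 1e12
        return -out[0]

    best = None
    for x0 in ([0.5] * m, [0.05] * m):
        res = optimize.minimize(
            neg, np.asarray(x0, dtype=float), method="L-BFGS-B",
            bounds=[(0.0, 1e6)] * m, options={"maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and res.fun < 1e11:
            break  # profiled likelihood is well-behaved; skip the restart
    theta = np.clip(best.x, 0.0, None)
    out = profile(theta)
    if out is None:
        raise FitError("mixed-model likelihood could not be evaluated at optimum")
    llf, beta, sigma2, XtViX = out
    try:
        cov = sigma2 * np.linalg.inv(XtViX)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - singular design
        raise FitError("singular fixed-effect design") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    singular = tuple(g for g, th in zip(factor_names, theta) if th < 1e-6)
    return LMMResult(
        names=list(names),
        params=beta,
        se=se,
        llf=float(llf),
        k=p + 1 + m,
        n=n,
        sigma2=sigma2,
        re_var={g: float(th * sigma2) for g, th in zip(factor_names, theta)},
        converged=bool(best.success),
        singular=singular,
    )
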