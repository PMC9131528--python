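"""Maximum-likelihood path analysis (observed-variable SEM).

Models are recursive linear systems over observed variables, e.g. regional
brain volumes predicting an anxiety score:

    HADS ~ PFC + AMG + HIP

With path matrix B (B[out, pred] = coefficient) and exogenous/residual
covariance Psi, the implied covariance is

    Sigma(theta) = (I - B)^-1 Psi (I - B)^-T.

Fitting minimizes the ML discrepancy

    F_ML(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p,

with chi^2 = (n - 1) F_min, df = p(p+1)/2 - #free. Fit indices follow the
usual conventions: RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1))) (0 for a
saturated model), AIC = chi^2 + 2 #free. Standardized coefficients use
model-implied standard deviations: s = b sd(pred) / sd(out).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import NumericalError, PreconditionError

__all__ = [
    "PathModel",
    "SEMData",
    "SEMFit",
    "implied_covariance",
    "fit_ml",
    "fit_indices",
    "standardize",
]


@dataclass(frozen=True)
class PathModel:
    """A recursive (acyclic) observed-variable path model.

    Free parameters, in order: path coefficients, exogenous variances,
    free exogenous covariances, endogenous residual variances. Exogenous
    covariances are free by default (saturated exogenous block) unless
    explicitly fixed to zero in the model text (``x ~~ 0*y``).
    """

    variables: tuple[str, ...]
    paths: tuple[tuple[str, str], ...]  # (outcome, predictor)
    fixed_zero_covs: tuple[tuple[str, str], ...] = ()

    @classmethod
    def from_text(cls, text: str) -> "PathModel":
        """Parse a lavaan-like edge list.

        One statement per line: ``y ~ x1 + x2`` declares paths,
        ``x1 ~~ 0*x2`` fixes an exogenous covariance to zero. Variables are
        collected in order of first appearance.
        """
        variables: list[str] = []
        paths: list[tuple[str, str]] = []
        fixed: list[tuple[str, str]] = []

        def add(v: str) -> None:
            if v not in variables:
                variables.append(v)

        for raw in text.splitlines():
            line = raw.split("#")[0].strip()
            if not line:
                continue
            if "~~" in line:
                lhs, rhs = (s.strip() for s in line.split("~~", 1))
                add(lhs)
                for term in rhs.split("+"):
                    term = term.strip()
                    if term.startswith("0*"):
                        other = term[2:].strip()
                        add(other)
                        fixed.append((lhs, other))
                    else:
                        add(term)  # free covariance: the default, nothing to record
            elif "~" in line:
                lhs, rhs = (s.strip() for s in line.split("~", 1))
                add(lhs)
                for term in rhs.split("+"):
                    term = term.strip()
                    if term:
                        add(term)
                        paths.append((lhs, term))
            else:
                raise PreconditionError(f"cannot parse model line: {raw!r}")
        model = cls(tuple(variables), tuple(paths), tuple(fixed))
        model.topological_order()  # validates acyclicity
        return model

    @property
    def endogenous(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(out for out, _ in self.paths))

    @property
    def exogenous(self) -> tuple[str, ...]:
        endo = set(self.endogenous)
        return tuple(v for v in self.variables if v not in endo)

    def topological_order(self) -> list[str]:
        """Kahn's algorithm over path edges; raises on cycles."""
        indeg = {v: 0 for v in self.variables}
        children: dict[str, list[str]] = {v: [] for v in self.variables}
        for out, pred in self.paths:
            indeg[out] += 1
            children[pred].append(out)
        queue = [v for v in self.variables if indeg[v] == 0]
        order: list[str] = []
        while queue:
            v = queue.pop(0)
            order.append(v)
            for ch in children[v]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        if len(order) != len(self.variables):
            raise PreconditionError("path model contains a cycle")
        return order

    def free_exo_covs(self) -> tuple[tuple[str, str], ...]:
        exo = self.exogenous
        fixed = {frozenset(p) for p in self.fixed_zero_covs}
        out = []
        for i in range(len(exo)):
            for j in range(i + 1, len(exo)):
                if frozenset((exo[i], exo[j])) not in fixed:
                    out.append((exo[i], exo[j]))
        return tuple(out)

    def parameter_names(self) -> tuple[str, ...]:
        names = [f"{out}~{pred}" for out, pred in self.paths]
        names += [f"var({v})" for v in self.exogenous]
        names += [f"cov({a},{b})" for a, b in self.free_exo_covs()]
        names += [f"resid({v})" for v in self.endogenous]
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.parameter_names())

    @property
    def df(self) -> int:
        p = len(self.variables)
        return p * (p + 1) // 2 - self.n_free


@dataclass
class SEMData:
    """Sample covariance matrix plus sample size, variable-aligned to a model."""

    cov: np.ndarray
    n: int
    variables: tuple[str, ...]

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        p = len(self.variables)
        if self.cov.shape != (p, p):
            raise PreconditionError("covariance shape does not match variables")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise PreconditionError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov).min() <= 0:
            raise PreconditionError("sample covariance must be positive definite")
        if self.n <= p:
            raise PreconditionError("need more observations than variables")

    @classmethod
    def from_table(cls, table: pd.DataFrame, variables: tuple[str, ...] | None = None) -> "SEMData":
        if variables is None:
            variables = tuple(table.columns)
        sub = table.loc[:, list(variables)].dropna()
        return cls(np.cov(sub.to_numpy(), rowvar=False, ddof=1), len(sub), tuple(variables))

    def aligned(self, model: PathModel) -> "SEMData":
        missing = set(model.variables) - set(self.variables)
        if missing:
            raise PreconditionError(f"data lacks model variables: {sorted(missing)}")
        idx = [self.variables.index(v) for v in model.variables]
        return SEMData(self.cov[np.ix_(idx, idx)], self.n, model.variables)


@dataclass
class SEMFit:
    model: PathModel
    theta: dict[str, float]
    f_min: float
    chi2: float
    df: int
    n: int
    converged: bool
    grad_norm: float
    rmsea: float = field(default=np.nan)
    aic: float = field(default=np.nan)
    standardized: dict[str, float] = field(default_factory=dict)
    implied: np.ndarray | None = None


def _split_theta(model: PathModel, theta: np.ndarray):
    n_path = len(model.paths)
    n_exo = len(model.exogenous)
    n_cov = len(model.free_exo_covs())
    b = theta[:n_path]
    ev = theta[n_path : n_path + n_exo]
    ec = theta[n_path + n_exo : n_path + n_exo + n_cov]
    rv = theta[n_path + n_exo + n_cov :]
    return b, ev, ec, rv


def implied_covariance(model: PathModel, theta: np.ndarray) -> np.ndarray:
    """Model-implied covariance Sigma(theta) = (I-B)^-1 Psi (I-B)^-T."""
    theta = np.asarray(theta, dtype=float)
    if theta.size != model.n_free:
        raise PreconditionError(
            f"theta has {theta.size} entries, model has {model.n_free} free parameters"
        )
    names = model.variables
    idx = {v: i for i, v in enumerate(names)}
    p = len(names)
    b, ev, ec, rv = _split_theta(model, theta)
    B = np.zeros((p, p))
    for (out, pred), coef in zip(model.paths, b):
        B[idx[out], idx[pred]] = coef
    psi = np.zeros((p, p))
    for v, var in zip(model.exogenous, ev):
        psi[idx[v], idx[v]] = var
    for (a, bb), cov in zip(model.free_exo_covs(), ec):
        psi[idx[a], idx[bb]] = psi[idx[bb], idx[a]] = cov
    for v, var in zip(model.endogenous, rv):
        psi[idx[v], idx[v]] = var
    inv = np.linalg.inv(np.eye(p) - B)
    return inv @ psi @ inv.T


def _f_ml(model: PathModel, theta: np.ndarray, S: np.ndarray, logdet_s: float) -> float:
    sigma = implied_covariance(model, theta)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e8 + float(np.sum(theta**2))  # infeasible: steer the optimizer back
    logdet = 2.0 * float(np.log(np.diag(chol)).sum())
    sinv_s = np.linalg.solve(sigma, S)
    return logdet + float(np.trace(sinv_s)) - logdet_s - len(S)


def _start_values(model: PathModel, S: np.ndarray) -> np.ndarray:
    """Recursive OLS start: near-exact for recursive models with saturated
    exogenous block, which makes the subsequent minimization a polish step."""
    idx = {v: i for i, v in enumerate(model.variables)}
    b0 = []
    resid0 = {}
    for out in model.endogenous:
        preds = [pred for o, pred in model.paths if o == out]
        pi = [idx[p] for p in preds]
        oi = idx[out]
        sxx = S[np.ix_(pi, pi)]
        sxy = S[pi, oi]
        try:
            beta = np.linalg.solve(sxx, sxy)
        except np.linalg.LinAlgError:
            beta = np.zeros(len(pi))
        resid = float(S[oi, oi] - beta @ sxy)
        resid0[out] = max(resid, 0.05 * S[oi, oi])
        for p_name, coef in zip(preds, beta):
            b0.append(((out, p_name), coef))
    coef_map = dict(b0)
    theta0 = [coef_map.get(path, 0.0) for path in model.paths]
    theta0 += [S[idx[v], idx[v]] for v in model.exogenous]
    theta0 += [S[idx[a], idx[b]] for a, b in model.free_exo_covs()]
    theta0 += [resid0[v] for v in model.endogenous]
    return np.array(theta0)


def fit_ml(model: PathModel, data: SEMData, n_restarts: int = 5, tol: float = 1e-8) -> SEMFit:
    """Fit the path model by maximum likelihood on the sample covariance.

    Quasi-Newton (L-BFGS-B) minimization of F_ML with variance parameters
    bounded away from zero, started from recursive-OLS values, with seeded
    random restarts if the gradient norm or discrepancy does not meet
    tolerance.
    """
    if model.df < 0:
        raise PreconditionError(
            f"model not identified: {model.n_free} free parameters exceed "
            f"{len(model.variables) * (len(model.variables) + 1) // 2} moments"
        )
    data = data.aligned(model)
    S = data.cov
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise PreconditionError("sample covariance must be positive definite")
    n_path = len(model.paths)
    n_exo = len(model.exogenous)
    n_cov = len(model.free_exo_covs())
    n_res = len(model.endogenous)
    bounds = (
        [(None, None)] * n_path
        + [(1e-8, None)] * n_exo
        + [(None, None)] * n_cov
        + [(1e-8, None)] * n_res
    )
    obj = lambda th: _f_ml(model, th, S, logdet_s)
    theta0 = _start_values(model, S)
    rng = np.random.default_rng(0)
    best = None
    for attempt in range(n_restarts + 1):
        x0 = theta0 if attempt == 0 else theta0 * rng.uniform(0.5, 1.5, theta0.size)
        res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 2000, "ftol": 1e-14, "gtol": tol})
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < 1e7 and np.linalg.norm(best.jac) < 1e-4:
            break
    if best is None or best.fun >= 1e7:
        raise NumericalError(f"SEM optimizer failed to find a feasible point: {best}")
    grad_norm = float(np.linalg.norm(best.jac))
    converged = bool(best.success or grad_norm < 1e-3)
    if not converged:
        warnings.warn(f"SEM fit convergence doubtful (|grad|={grad_norm:.2e})", stacklevel=2)
    f_min = max(float(best.fun), 0.0)
    chi2 = (data.n - 1) * f_min
    theta = dict(zip(model.parameter_names(), best.x))
    fit = SEMFit(
        model=model,
        theta=theta,
        f_min=f_min,
        chi2=chi2,
        df=model.df,
        n=data.n,
        converged=converged,
        grad_norm=grad_norm,
        implied=implied_covariance(model, best.x),
    )
    fit.rmsea, fit.aic = fit_indices(fit, data.n)
    fit.standardized = standardize(fit)
    return fit


def fit_indices(fit: SEMFit, n: int) -> tuple[float, float]:
    """RMSEA and AIC for a fitted model.

    RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1))); defined as 0 for a
    saturated model (df = 0), with a warning. AIC = chi2 + 2 #free (the
    chi-square-based convention used for comparing models on one dataset).
    """
    if fit.df == 0:
        warnings.warn("df = 0 (saturated model); RMSEA defined as 0", stacklevel=2)
        rmsea = 0.0
    else:
        rmsea = float(np.sqrt(max(fit.chi2 - fit.df, 0.0) / (fit.df * (n - 1))))
    aic = float(fit.chi2 + 2 * fit.model.n_free)
    return rmsea, aic


def standardize(fit: SEMFit, data: SEMData | None = None) -> dict[str, float]:
    """Standardized path coefficients s = b sd(pred)/sd(out), implied SDs."""
    sigma = fit.implied
    if sigma is None:
        raise PreconditionError("fit has no implied covariance")
    idx = {v: i for i, v in enumerate(fit.model.variables)}
    sds = np.sqrt(np.diag(sigma))
    if np.any(sds <= 0):
        raise NumericalError("zero implied standard deviation; cannot standardize")
    out = {}
    for outcome, pred in fit.model.paths:
        b = fit.theta[f"{outcome}~{pred}"]
        out[f"{outcome}~{pred}"] = float(b * sds[idx[pred]] / sds[idx[outcome]])
    return out
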