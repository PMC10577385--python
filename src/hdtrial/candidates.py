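"""The ten candidate height-diameter equations and their fitting routines.

Height-diameter (H-D) curves predict total height H (m) from stem diameter
at breast height D (cm).  The candidate set spans linear, reciprocal,
quadratic, and six asymptotic nonlinear families; models 4-8 honour the
biological constraint H -> 1.3 m (breast height) as D -> 0:

    (1)  H = a + bD
    (2)  1/H = a + b/D                     (fit on the reciprocal scale)
    (3)  H = a + bD + cD²
    (4)  H = 1.3 + a(1 − e^{−bD})^c        (Chapman-Richards)
    (5)  H = 1.3 + aD^b                    (power)
    (6)  H = 1.3 + exp(a + b/(D + 1))      (Wykoff)
    (7)  H = 1.3 + aD/(b + D)              (hyperbolic)
    (8)  H = 1.3 + a(1 − e^{−bD^c})        (Weibull)
    (9)  H = a(1 − e^{−bD})^c
    (10) H = a(1 − e^{−bD^c})

Models 1-3 are fit by exact ordinary least squares (model 2 on 1/H vs 1/D,
predictions back-transformed to the H scale); models 4-10 by bounded
trust-region nonlinear least squares from deterministic starting values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .gof import loglik_gaussian


@dataclass(frozen=True)
class HDModelSpec:
    """Static description of one candidate equation."""

    model_id: int
    parameter_names: tuple[str, ...]
    passes_through_breast_height: bool
    response_transform: str = "none"  # "reciprocal" only for model 2
    closed_form_ols: bool = False

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)


MODELS: dict[int, HDModelSpec] = {
    1: HDModelSpec(1, ("a", "b"), False, closed_form_ols=True),
    2: HDModelSpec(2, ("a", "b"), False, response_transform="reciprocal",
                   closed_form_ols=True),
    3: HDModelSpec(3, ("a", "b", "c"), False, closed_form_ols=True),
    4: HDModelSpec(4, ("a", "b", "c"), True),
    5: HDModelSpec(5, ("a", "b"), True),
    6: HDModelSpec(6, ("a", "b"), True),
    7: HDModelSpec(7, ("a", "b"), True),
    8: HDModelSpec(8, ("a", "b", "c"), True),
    9: HDModelSpec(9, ("a", "b", "c"), False),
    10: HDModelSpec(10, ("a", "b", "c"), False),
}


def predict(spec: HDModelSpec | int, params, dbh):
    """Evaluate a candidate model at DBH (cm), returning height (m).

    ``params`` is a sequence in the order of ``spec.parameter_names``.
    Model 2 returns H itself (back-transformed), never 1/H; DBH = 0 is a
    domain error there.
    """
    if isinstance(spec, int):
        spec = MODELS[spec]
    d = np.asarray(dbh, dtype=float)
    p = [float(v) for v in params]
    mid = spec.model_id
    if mid == 1:
        h = p[0] + p[1] * d
    elif mid == 2:
        if np.any(d == 0):
            raise ZeroDivisionError("model 2 is undefined at DBH = 0")
        h = 1.0 / (p[0] + p[1] / d)
    elif mid == 3:
        h = p[0] + p[1] * d + p[2] * d**2
    elif mid == 4:
        h = 1.3 + p[0] * (1.0 - np.exp(-p[1] * d)) ** p[2]
    elif mid == 5:
        h = 1.3 + p[0] * d ** p[1]
    elif mid == 6:
        h = 1.3 + np.exp(p[0] + p[1] / (d + 1.0))
    elif mid == 7:
        h = 1.3 + p[0] * d / (p[1] + d)
    elif mid == 8:
        h = 1.3 + p[0] * (1.0 - np.exp(-p[1] * d ** p[2]))
    elif mid == 9:
        h = p[0] * (1.0 - np.exp(-p[1] * d)) ** p[2]
    elif mid == 10:
        h = p[0] * (1.0 - np.exp(-p[1] * d ** p[2]))
    else:  # pragma: no cover
        raise ValueError(f"unknown model id {mid}")
    return h if np.ndim(dbh) else float(h)


class FlatDataError(ValueError):
    """All heights identical: starting values are undefined."""


def starting_values(spec: HDModelSpec | int, dbh, height) -> dict[str, float]:
    """Deterministic starting values for the nonlinear fits.

    Heuristics: asymptote-type parameters start at 1.1 × max(H); rate
    parameters solve the model through the median (DBH, H) point; shape
    parameters start at 1.  Model 6 starts from an exact log-scale OLS.
    """
    if isinstance(spec, int):
        spec = MODELS[spec]
    d = np.asarray(dbh, dtype=float)
    h = np.asarray(height, dtype=float)
    if np.ptp(h) == 0:
        raise FlatDataError("all heights are equal; cannot seed a fit")
    hmax = float(h.max())
    dm = float(np.median(d))
    hm = float(np.median(h))
    a0 = 1.1 * hmax
    mid = spec.model_id
    eps = 1e-6
    if mid in (1, 2, 3):
        # OLS path does not need starts; provide something sane anyway
        return dict(zip(spec.parameter_names, [hm, 0.1, 0.0][: spec.n_params]))
    if mid == 4:
        frac = min(max((hm - 1.3) / a0, eps), 1 - eps)
        return {"a": a0, "b": -np.log(1 - frac) / dm, "c": 1.0}
    if mid == 5:
        b0 = 0.8
        return {"a": max((hm - 1.3) / dm**b0, eps), "b": b0}
    if mid == 6:
        y = np.log(np.clip(h - 1.3, eps, None))
        x = 1.0 / (d + 1.0)
        b0, a0 = np.polyfit(x, y, 1)
        return {"a": float(a0), "b": float(b0)}
    if mid == 7:
        b0 = max(a0 * dm / max(hm - 1.3, eps) - dm, eps)
        return {"a": a0, "b": b0}
    if mid == 8:
        frac = min(max((hm - 1.3) / a0, eps), 1 - eps)
        return {"a": a0, "b": -np.log(1 - frac) / dm, "c": 1.0}
    if mid in (9, 10):
        frac = min(max(hm / a0, eps), 1 - eps)
        return {"a": a0, "b": -np.log(1 - frac) / dm, "c": 1.0}
    raise ValueError(f"unknown model id {mid}")  # pragma: no cover


@dataclass
class FitResult:
    """A fitted candidate model with parameter and fit statistics."""

    model_id: int
    params: dict[str, float]
    std_errors: dict[str, float]
    n: int
    sse: float
    loglik: float
    converged: bool
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def spec(self) -> HDModelSpec:
        return MODELS[self.model_id]

    def predict(self, dbh):
        return predict(self.spec, [self.params[p] for p in
                                   self.spec.parameter_names], dbh)


def _std_errors_from_jacobian(jac: np.ndarray, sse: float, n: int,
                              k: int) -> np.ndarray:
    dof = max(n - k, 1)
    s2 = sse / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return se


def fit(spec: HDModelSpec | int, dbh, height,
        max_nfev: int = 2000) -> FitResult:
    """Fit one candidate model to per-tree (DBH, H) data.

    Linear models 1-3 use exact OLS (model 2 after reciprocal transform,
    with all fit statistics — SSE, log-likelihood — computed on the
    back-transformed H scale).  Models 4-10 use bounded trust-region
    nonlinear least squares (parameters constrained positive) with
    tolerances ftol=1e-10 on relative SSE change and gtol=1e-8 on the
    gradient norm.  Non-convergence is reported via ``converged=False``,
    never an exception.
    """
    if isinstance(spec, int):
        spec = MODELS[spec]
    d = np.asarray(dbh, dtype=float)
    h = np.asarray(height, dtype=float)
    n = len(d)
    if n < spec.n_params + 1:
        raise ValueError(f"need at least {spec.n_params + 1} trees")

    names = spec.parameter_names
    if spec.closed_form_ols:
        if spec.model_id == 1:
            X = np.column_stack([np.ones(n), d])
            y = h
        elif spec.model_id == 2:
            X = np.column_stack([np.ones(n), 1.0 / d])
            y = 1.0 / h
        else:  # model 3
            X = np.column_stack([np.ones(n), d, d**2])
            y = h
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = predict(spec, beta, d)
        resid = h - fitted
        sse = float(resid @ resid)
        # SEs on the estimation scale (the scale the parameters live on)
        r_est = y - X @ beta
        se = _std_errors_from_jacobian(X, float(r_est @ r_est), n, len(beta))
        return FitResult(
            model_id=spec.model_id,
            params=dict(zip(names, map(float, beta))),
            std_errors=dict(zip(names, map(float, se))),
            n=n, sse=sse, loglik=loglik_gaussian(h, fitted),
            converged=True, fitted=fitted,
        )

    x0_map = starting_values(spec, d, h)
    x0 = np.array([x0_map[p] for p in names])

    def residuals(theta):
        return predict(spec, theta, d) - h

    # positivity keeps the asymptotic forms on their increasing branch;
    # Wykoff's log-scale parameters (model 6) are naturally unbounded
    bounds = ((-np.inf, np.inf) if spec.model_id == 6
              else (1e-12, np.inf))
    res = least_squares(residuals, x0, bounds=bounds,
                        ftol=1e-10, gtol=1e-8, xtol=1e-12, max_nfev=max_nfev)
    fitted = predict(spec, res.x, d)
    resid = h - fitted
    sse = float(resid @ resid)
    se = _std_errors_from_jacobian(res.jac, sse, n, len(names))
    return FitResult(
        model_id=spec.model_id,
        params=dict(zip(names, map(float, res.x))),
        std_errors=dict(zip(names, map(float, se))),
        n=n, sse=sse, loglik=loglik_gaussian(h, fitted),
        converged=bool(res.success), fitted=fitted,
    )


def fit_all(dbh, height, model_ids=None) -> dict[int, FitResult]:
    """Fit every candidate model (or a subset) to the same data."""
    ids = list(model_ids) if model_ids is not None else sorted(MODELS)
    return {mid: fit(MODELS[mid], dbh, height) for mid in ids}
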