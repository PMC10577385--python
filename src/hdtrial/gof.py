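"""Goodness-of-fit statistics and base-model ranking.

All candidate fits are compared on the observed height scale using the
profile Gaussian log-likelihood

    LL = −n/2 · (ln 2π + ln(SSE/n) + 1),

mean absolute error, (adjusted) R², AIC = 2k − 2·LL, and a paired t-test of
predicted vs observed heights as a systematic-bias screen.  Models whose
paired t-test rejects at 5% are excluded from the ranking; the remainder
are ordered by AIC (ascending), with MAE and then R² breaking ties.

``aic`` counts only mean-function parameters (σ is profiled out).  The
``fixed_k3`` option fixes k = 3 for every model, a convention some
published comparison tables use; the default is the true per-model count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


def loglik_gaussian(observed, fitted) -> float:
    """Profile Gaussian log-likelihood of a fitted curve.

    The residual variance is profiled at its MLE SSE/n, giving
    LL = −n/2 (ln 2π + ln(SSE/n) + 1).  SSE = 0 is an overflow error.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape:
        raise ValueError("observed and fitted must have equal length")
    n = len(obs)
    if n < 2:
        raise ValueError("need at least two observations")
    sse = float(np.sum((obs - fit) ** 2))
    if sse == 0:
        raise OverflowError("zero residual sum of squares: likelihood diverges")
    return -n / 2.0 * (np.log(2 * np.pi) + np.log(sse / n) + 1.0)


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k − 2·LL, k ≥ 1 mean parameters."""
    if k < 1:
        raise ValueError("k must be at least 1")
    return 2.0 * k - 2.0 * loglik


def mae(observed, fitted) -> float:
    """Mean absolute error in metres."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape:
        raise ValueError("observed and fitted must have equal length")
    return float(np.mean(np.abs(obs - fit)))


def r2(observed, fitted, k: int) -> tuple[float, float]:
    """Coefficient of determination and its small-sample adjustment.

    R² = 1 − SSE/SST; R²adj = 1 − (1 − R²)(n − 1)/(n − k − 1).
    A constant observed vector (SST = 0) is an error.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape:
        raise ValueError("observed and fitted must have equal length")
    n = len(obs)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ZeroDivisionError("constant observed vector: R² undefined")
    sse = float(np.sum((obs - fit) ** 2))
    plain = 1.0 - sse / sst
    adj = 1.0 - (1.0 - plain) * (n - 1) / (n - k - 1)
    return plain, adj


def paired_t(observed, predicted) -> tuple[float, float, float, float]:
    """Two-sided paired t-test on differences (predicted − observed).

    Returns (mean difference, its standard error, t, p).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    n = len(obs)
    if n < 3:
        raise ValueError("need at least three pairs")
    diff = pred - obs
    sd = float(np.std(diff, ddof=1))
    if sd == 0:
        if np.all(diff == 0):  # perfect agreement: no bias by construction
            return 0.0, 0.0, 0.0, 1.0
        raise ZeroDivisionError("zero-variance non-zero differences: t undefined")
    se = sd / np.sqrt(n)
    mean_diff = float(diff.mean())
    t = mean_diff / se
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return mean_diff, se, float(t), float(p)


@dataclass
class FitStats:
    """Model-comparison statistics for one candidate fit."""

    model_id: int
    mae: float
    r2: float
    r2_adj: float
    aic: float
    loglik: float
    mean_diff: float
    se_diff: float
    t: float
    p: float

    @property
    def bias_flag(self) -> bool:
        """Significant systematic bias in the paired t-test at 5%."""
        return self.p < 0.05


def fit_stats(fit_result, observed, fixed_k3: bool = False) -> FitStats:
    """Compute the full comparison row for one fitted candidate model."""
    obs = np.asarray(observed, dtype=float)
    fitted = np.asarray(fit_result.fitted, dtype=float)
    k = 3 if fixed_k3 else fit_result.spec.n_params
    plain, adj = r2(obs, fitted, fit_result.spec.n_params)
    md, se, t, p = paired_t(obs, fitted)
    return FitStats(
        model_id=fit_result.model_id,
        mae=mae(obs, fitted), r2=plain, r2_adj=adj,
        aic=aic(fit_result.loglik, k), loglik=fit_result.loglik,
        mean_diff=md, se_diff=se, t=t, p=p,
    )


@dataclass
class ModelRanking:
    """Ordered model comparison with the base-model choice."""

    ranked_ids: list[int]
    excluded_ids: list[int]
    base_model_id: int
    base_passes_through_breast_height: bool


def rank_models(stats_list, specs) -> ModelRanking:
    """Rank candidate models and pick the base model.

    Bias-flagged models (paired t-test p < 0.05) are excluded; the rest are
    ordered by AIC ascending, ties broken by MAE then by higher R², then by
    model id.  If every model is flagged, the full ranking is returned with
    a warning rather than failing.  The result records whether the winner
    satisfies the biological breast-height constraint (H = 1.3 m at D = 0).
    """
    if len(stats_list) < 2:
        raise ValueError("need at least two models to rank")
    spec_by_id = {s.model_id: s for s in specs}
    eligible = [s for s in stats_list if not s.bias_flag]
    excluded = [s.model_id for s in stats_list if s.bias_flag]
    if not eligible:
        warnings.warn("every candidate model shows significant prediction bias; "
                      "ranking all models regardless")
        eligible = list(stats_list)
        excluded = []
    key = lambda s: (s.aic, s.mae, -s.r2, s.model_id)
    ranked = [s.model_id for s in sorted(eligible, key=key)]
    base = ranked[0]
    return ModelRanking(
        ranked_ids=ranked, excluded_ids=excluded, base_model_id=base,
        base_passes_through_breast_height=
        spec_by_id[base].passes_through_breast_height,
    )
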