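"""Posterior summaries and model-evaluation statistics.

Implements the quantities used to report the fitted models: the split-chain
potential scale reduction factor (R-hat), probability of direction (pd),
draw-wise conditional/marginal Bayesian R-squared, ROC AUC by the
Mann-Whitney rank statistic with tie correction, a posterior-predictive
summary table, and a lag-k autocorrelation report for date-ordered Pearson
residuals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "probability_of_direction",
    "rhat",
    "effective_sample_size",
    "bayes_r2",
    "roc_auc",
    "residual_acf",
    "ppc_table",
]

_LATENT_LOGISTIC_VAR = np.pi**2 / 3.0


def probability_of_direction(draws) -> float:
    """pd = max(P(theta > 0), P(theta < 0)) estimated from posterior draws.

    Draws exactly at zero are counted toward the majority side; the result
    lies in [0.5, 1].
    """
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 2:
        raise DataError("probability of direction needs at least 2 draws")
    pos = np.mean(x > 0)
    neg = np.mean(x < 0)
    zero = np.mean(x == 0)
    return float(max(pos, neg) + zero)


def rhat(chains) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` is (n_chains, n_draws).  Each chain is split in half, and
    R-hat = sqrt(((n-1)/n * W + B/n) / W) over the split halves.  Constant
    chains are a degenerate case and return 1.0 (with zero variance there
    is nothing to diagnose).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise DataError("rhat needs a (n_chains >= 2, n_draws) draw matrix")
    if x.shape[1] < 4:
        raise DataError("rhat needs at least 4 draws per chain")
    half = x.shape[1] // 2
    splits = np.vstack([x[:, :half], x[:, half : 2 * half]])
    m, n = splits.shape
    means = splits.mean(axis=1)
    w = splits.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    b = n * means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def effective_sample_size(chains) -> float:
    """Bulk effective sample size (delegates to arviz)."""
    import arviz as az

    x = np.asarray(chains, dtype=float)
    return float(az.ess(az.convert_to_dataset(x[None] if x.ndim == 1 else x)).x)


def bayes_r2(
    fitted: np.ndarray,
    mode: str = "conditional",
    scale: str = "probability",
) -> tuple[np.ndarray, dict]:
    """Draw-wise Bayesian R-squared from fitted values.

    Parameters
    ----------
    fitted : (S, n) array
        Per-draw fitted values: success probabilities for a Bernoulli
        model (``scale="probability"``), or linear predictors for the
        latent-scale variant used for ordinal models
        (``scale="latent"``).
    mode : str
        Label recorded in the summary ("conditional" fitted values include
        random intercepts, "marginal" set them to zero); the caller chooses
        which fitted values to pass.
    scale : str
        "probability": R2_s = Var(p_s) / (Var(p_s) + mean(p_s (1 - p_s))).
        "latent": R2_s = Var(eta_s) / (Var(eta_s) + pi^2 / 3), the
        cumulative-logit latent-variance convention.

    Returns the per-draw R2 vector and a summary dict (mean, 2.5 %, 97.5 %).
    """
    f = np.asarray(fitted, dtype=float)
    if f.ndim != 2:
        raise DataError("fitted values must be (draws, rows)")
    var_fit = f.var(axis=1)
    if scale == "probability":
        resid = (f * (1.0 - f)).mean(axis=1)
    elif scale == "latent":
        resid = np.full(f.shape[0], _LATENT_LOGISTIC_VAR)
    else:
        raise DataError(f"unknown R2 scale {scale!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(var_fit + resid > 0, var_fit / (var_fit + resid), 0.0)
    lo, hi = np.percentile(r2, [2.5, 97.5])
    summary = {"mode": mode, "scale": scale, "mean": float(r2.mean()),
               "ci_low": float(lo), "ci_high": float(hi)}
    return r2, summary


def roc_auc(scores, outcomes) -> float:
    """Area under the ROC curve via the tie-corrected rank statistic.

    AUC = (sum of positive-class ranks - n_pos (n_pos + 1) / 2) /
    (n_pos * n_neg), with midranks for ties, i.e. the Mann-Whitney
    U-statistic normalized to [0, 1].
    """
    from scipy.stats import rankdata

    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if s.shape != y.shape:
        raise DataError("scores and outcomes differ in length")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC undefined: outcomes contain a single class")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def residual_acf(
    residuals: np.ndarray,
    dates: np.ndarray,
    ids: np.ndarray,
    max_lag: int = 5,
) -> pd.DataFrame:
    """Lag-1..max_lag autocorrelation of date-ordered residuals per individual.

    Residuals are ordered by date within each individual; autocorrelations
    are computed per individual (lags exceeding an individual's series
    length are dropped) and averaged across individuals.  Returns a table
    (lag, acf, n_individuals).
    """
    if max_lag < 1:
        return pd.DataFrame(columns=["lag", "acf", "n_individuals"])
    df = pd.DataFrame({"r": residuals, "date": dates, "id": ids})
    per_lag: dict[int, list[float]] = {k: [] for k in range(1, max_lag + 1)}
    for _, sub in df.groupby("id"):
        x = sub.sort_values("date")["r"].to_numpy(dtype=float)
        x = x - x.mean()
        denom = float(x @ x)
        if denom == 0:
            continue
        for k in range(1, min(max_lag, len(x) - 1) + 1):
            per_lag[k].append(float(x[:-k] @ x[k:]) / denom)
    rows = [
        {"lag": k, "acf": float(np.mean(v)) if v else np.nan, "n_individuals": len(v)}
        for k, v in per_lag.items()
        if v
    ]
    return pd.DataFrame(rows)


def ppc_table(observed: np.ndarray, replicated: np.ndarray, levels=None) -> pd.DataFrame:
    """Observed vs posterior-replicated share of each outcome level.

    ``replicated`` is (S, n): S posterior-predictive datasets.  Returns one
    row per level with the observed share and the mean and 95 % interval of
    the replicated shares — a tabular posterior-predictive check.
    """
    obs = np.asarray(observed)
    rep = np.asarray(replicated)
    if levels is None:
        levels = np.unique(obs)
    rows = []
    for lev in levels:
        obs_share = float(np.mean(obs == lev))
        rep_share = (rep == lev).mean(axis=1)
        lo, hi = np.percentile(rep_share, [2.5, 97.5])
        rows.append(
            {"level": lev, "observed": obs_share, "replicated_mean": float(rep_share.mean()),
             "replicated_low": float(lo), "replicated_high": float(hi)}
        )
    return pd.DataFrame(rows)
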