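"""Bayesian hierarchical GLMMs: Bernoulli and cumulative-ordinal responses.

The model for row :math:`i` is

.. math::

    \\eta_i = \\mathbf{x}_i^\\top \\beta
             + \\sum_m \\beta^{mo}_m \\, \\mathrm{mo}(x_{im}; \\zeta_m)
             + \\sum_g b_{g[i]}, \\qquad b_g \\sim \\mathcal N(0, \\sigma_g^2)

with a logit link.  A Bernoulli response models participation-type yes/no
outcomes; a cumulative-ordinal response with :math:`K` categories and
ordered thresholds :math:`\\tau_1 < \\dots < \\tau_{K-1}` models the 1-4
aggression-intensity scale.  Monotonic terms encode an ordinal covariate
(e.g. maternal aggression level 0-4) through

.. math::

    \\mathrm{mo}(x; \\zeta) = D \\sum_{j=1}^{x} \\zeta_j,

where :math:`\\zeta` is a simplex of per-step increments, so the effect is
constrained to be monotone in the level and :math:`\\beta^{mo}` is the
average per-step effect.

Priors: fixed effects and monotonic coefficients normal(0, 1) on the
standardized-covariate scale, random-intercept SDs half-normal(0, 1),
simplexes Dirichlet(1, ..., 1), thresholds normal(0, 5).  Sampling is by
the package's NUTS backend on the unconstrained scale (log SDs,
non-centered random effects, anchored-softmax simplexes, log threshold
increments).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError, DataError
from .results import PosteriorResult
from .sampler import sample_nuts

__all__ = [
    "ModelSpec",
    "BernoulliGLMM",
    "OrdinalGLMM",
    "monotonic_transform",
    "ordinal_likelihood",
    "bernoulli_loglik",
]


def monotonic_transform(level, zeta) -> np.ndarray | float:
    """mo(x; zeta) = D * sum_{j<=x} zeta_j for x in 0..D.

    ``zeta`` must be a simplex of length D; mo(0) = 0 and mo(D) = D for any
    simplex, so the coefficient multiplying the transform is the average
    effect of one step up the ordinal scale.
    """
    zeta = np.asarray(zeta, dtype=float)
    if np.any(zeta < 0):
        raise DataError("monotonic simplex has a negative entry")
    if abs(zeta.sum() - 1.0) > 1e-10:
        raise DataError("monotonic simplex does not sum to 1")
    d = len(zeta)
    cum = np.concatenate([[0.0], np.cumsum(zeta)])
    x = np.asarray(level, dtype=int)
    if np.any((x < 0) | (x > d)):
        raise DataError(f"monotonic level outside 0..{d}")
    out = d * cum[x]
    return float(out) if np.isscalar(level) else out


def ordinal_likelihood(k, eta, thresholds) -> np.ndarray | float:
    """P(Y = k) under the cumulative-logit model, k in 1..K.

    ``thresholds`` are the K-1 strictly increasing cut points; boundary
    thresholds are -inf and +inf, so the K probabilities telescope to 1.
    """
    tau = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(tau) <= 0):
        raise DataError("ordinal thresholds must be strictly increasing")
    pad = np.concatenate([[-np.inf], tau, [np.inf]])
    k = np.asarray(k, dtype=int)
    if np.any((k < 1) | (k > len(tau) + 1)):
        raise DataError(f"ordinal category outside 1..{len(tau) + 1}")
    upper = expit(pad[k] - eta)
    lower = expit(pad[k - 1] - eta)
    out = upper - lower
    return float(out) if np.isscalar(eta) and out.ndim == 0 else out


def bernoulli_loglik(y, eta) -> float:
    """Sum of Bernoulli-logit log likelihoods: y*eta - log(1 + e^eta)."""
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass
class ModelSpec:
    """Declarative model specification against panel columns.

    ``random_intercepts`` entries may be plain column names or
    colon-composites such as ``"focal_group:individual"``, which build the
    interaction factor and hence express nesting (id within group).
    """

    response: str = "bernoulli"  # "bernoulli" | "ordinal"
    fixed: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    monotonic: tuple[tuple[str, int], ...] = ()  # (column, D)
    random_intercepts: tuple[str, ...] = ()
    n_categories: int | None = None  # ordinal K
    intercept: bool = True  # ignored (absorbed by thresholds) for ordinal
    prior_scale_fixed: float = 1.0
    prior_scale_threshold: float = 5.0
    chains: int = 4
    iterations: int = 1000  # per chain, including warmup
    warmup: int | None = None  # default: iterations // 2
    target_accept: float = 0.9

    def __post_init__(self):
        if self.response not in ("bernoulli", "ordinal"):
            raise ConfigError("response", f"unknown response {self.response!r}")
        if self.response == "ordinal" and (self.n_categories is None or self.n_categories < 2):
            raise ConfigError("n_categories", "ordinal response needs K >= 2")
        for col, d in self.monotonic:
            if d < 1:
                raise ConfigError("monotonic", f"term {col!r} needs D >= 1")


class _Design:
    """Numeric design assembled once from the panel for a ModelSpec."""

    def __init__(self, panel: pd.DataFrame, spec: ModelSpec, response_col: str):
        self.spec = spec
        n = len(panel)
        if n == 0:
            raise DataError("empty panel")
        cols, names = [], []
        if spec.response == "bernoulli" and spec.intercept:
            cols.append(np.ones(n))
            names.append("Intercept")
        for c in spec.fixed:
            x = panel[c].to_numpy(dtype=float)
            if np.std(x) == 0.0:
                warnings.warn(f"dropping constant covariate column {c!r}", stacklevel=3)
                continue
            cols.append(x)
            names.append(c)
        for a, b in spec.interactions:
            x = panel[a].to_numpy(dtype=float) * panel[b].to_numpy(dtype=float)
            if np.std(x) == 0.0:
                warnings.warn(f"dropping constant interaction {a}:{b}", stacklevel=3)
                continue
            cols.append(x)
            names.append(f"{a}:{b}")
        self.X = np.column_stack(cols) if cols else np.empty((n, 0))
        self.xnames = names

        self.mono = []
        for c, d in spec.monotonic:
            lev = panel[c].to_numpy(dtype=int)
            if lev.min() < 0 or lev.max() > d:
                raise DataError(f"monotonic column {c!r} has levels outside 0..{d}")
            self.mono.append((c, lev, d))

        self.re = []
        for factor in spec.random_intercepts:
            parts = factor.split(":")
            key = panel[parts[0]].astype(str)
            for p in parts[1:]:
                key = key + ":" + panel[p].astype(str)
            codes, labels = pd.factorize(key)
            self.re.append((factor, codes.astype(int), len(labels), list(labels)))

        y = panel[response_col].to_numpy()
        if spec.response == "bernoulli":
            if not np.isin(y, [0, 1]).all():
                raise DataError(f"response column {response_col!r} is not 0/1")
            self.y = y.astype(float)
        else:
            k = spec.n_categories
            yi = y.astype(int)
            if yi.min() < 1 or yi.max() > k:
                raise DataError(f"ordinal response outside 1..{k}")
            self.y = yi - 1  # 0-based category index
        self.n = n

    # -- parameter vector layout ------------------------------------------
    @property
    def n_fixed(self):
        return self.X.shape[1]

    @property
    def n_thresh(self):
        return (self.spec.n_categories - 1) if self.spec.response == "ordinal" else 0

    def layout(self):
        """Slices of the unconstrained parameter vector."""
        idx = 0
        lay = {}
        lay["beta"] = slice(idx, idx + self.n_fixed)
        idx += self.n_fixed
        lay["beta_mo"] = slice(idx, idx + len(self.mono))
        idx += len(self.mono)
        lay["thresh"] = slice(idx, idx + self.n_thresh)  # (t1, log-increments)
        idx += self.n_thresh
        for name, _, _, _ in self.re:
            lay[f"logsd_{name}"] = slice(idx, idx + 1)
            idx += 1
        for name, _, nlev, _ in self.re:
            lay[f"z_{name}"] = slice(idx, idx + nlev)
            idx += nlev
        for name, _, d in self.mono:
            lay[f"u_{name}"] = slice(idx, idx + d - 1)
            idx += d - 1
        lay["_dim"] = idx
        return lay


def _softmax_anchor(u: np.ndarray) -> np.ndarray:
    """Anchored softmax: map R^{D-1} to the D-simplex (last logit fixed at 0)."""
    logits = np.concatenate([u, [0.0]])
    logits -= logits.max()
    e = np.exp(logits)
    return e / e.sum()


class _LogDensity:
    """Unnormalized log posterior and gradient on the unconstrained scale."""

    def __init__(self, design: _Design):
        self.d = design
        self.lay = design.layout()
        self.dim = self.lay["_dim"]

    def initial_point(self) -> np.ndarray:
        d = self.d
        theta = np.zeros(self.dim)
        theta[self.lay["thresh"]] = self._init_thresholds()
        for name, _, _, _ in d.re:
            theta[self.lay[f"logsd_{name}"]] = np.log(0.3)
        return theta

    def _init_thresholds(self):
        d = self.d
        if d.spec.response != "ordinal":
            return np.empty(0)
        k = d.spec.n_categories
        freq = np.bincount(d.y, minlength=k).astype(float) + 0.5
        cum = np.cumsum(freq)[:-1] / freq.sum()
        tau = np.log(cum / (1 - cum))
        out = np.empty(k - 1)
        out[0] = tau[0]
        if k > 2:
            out[1:] = np.log(np.maximum(np.diff(tau), 1e-3))
        return out

    def unpack_thresholds(self, t_params: np.ndarray) -> np.ndarray:
        if t_params.size == 0:
            return t_params
        tau = np.empty_like(t_params)
        tau[0] = t_params[0]
        if t_params.size > 1:
            tau[1:] = t_params[0] + np.cumsum(np.exp(t_params[1:]))
        return tau

    def __call__(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        d, lay = self.d, self.lay
        spec = d.spec
        grad = np.zeros_like(theta)
        logp = 0.0

        beta = theta[lay["beta"]]
        beta_mo = theta[lay["beta_mo"]]
        sc = spec.prior_scale_fixed
        logp += -0.5 * float(beta @ beta) / sc**2 - 0.5 * float(beta_mo @ beta_mo) / sc**2
        grad[lay["beta"]] = -beta / sc**2
        grad[lay["beta_mo"]] = -beta_mo / sc**2

        eta = d.X @ beta if d.n_fixed else np.zeros(d.n)

        # monotonic terms
        zetas, movals = [], []
        for m, (name, lev, dm) in enumerate(d.mono):
            u = theta[lay[f"u_{name}"]]
            zeta = _softmax_anchor(u)
            zetas.append(zeta)
            cum = np.concatenate([[0.0], np.cumsum(zeta)])
            moval = dm * cum[lev]
            movals.append(moval)
            eta += beta_mo[m] * moval
            logp += float(np.sum(np.log(zeta)))  # Dirichlet(1) + softmax Jacobian

        # random intercepts (non-centered)
        sigmas, zs = [], []
        for name, codes, nlev, _ in d.re:
            u = theta[lay[f"logsd_{name}"]][0]
            sigma = np.exp(u)
            z = theta[lay[f"z_{name}"]]
            sigmas.append(sigma)
            zs.append(z)
            eta += sigma * z[codes]
            logp += -0.5 * sigma**2 + u  # half-normal(0,1) prior + log Jacobian
            grad[lay[f"logsd_{name}"]] = -(sigma**2) + 1.0
            logp += -0.5 * float(z @ z)
            grad[lay[f"z_{name}"]] = -z

        # likelihood and d loglik / d eta
        if spec.response == "bernoulli":
            logp += bernoulli_loglik(d.y, eta)
            r = d.y - expit(eta)
        else:
            k = spec.n_categories
            t_params = theta[lay["thresh"]]
            tau = self.unpack_thresholds(t_params)
            pad = np.concatenate([[-np.inf], tau, [np.inf]])
            fu = expit(pad[d.y + 1] - eta)
            fl = expit(pad[d.y] - eta)
            p = np.maximum(fu - fl, 1e-300)
            logp += float(np.sum(np.log(p)))
            du = np.where(np.isfinite(pad[d.y + 1]), fu * (1 - fu), 0.0)
            dl = np.where(np.isfinite(pad[d.y]), fl * (1 - fl), 0.0)
            r = (dl - du) / p
            # gradient wrt thresholds tau_j (0-based j = 0..K-2)
            g_tau = np.zeros(k - 1)
            np.add.at(g_tau, np.clip(d.y, 0, k - 2), np.where(d.y <= k - 2, du / p, 0.0))
            np.subtract.at(g_tau, np.clip(d.y - 1, 0, k - 2), np.where(d.y >= 1, dl / p, 0.0))
            # threshold prior normal(0, s)
            s2 = spec.prior_scale_threshold**2
            logp += -0.5 * float(tau @ tau) / s2
            g_tau += -tau / s2
            gt = np.zeros_like(t_params)
            gt[0] = g_tau.sum()
            if t_params.size > 1:
                inc = np.exp(t_params[1:])
                rev = np.cumsum(g_tau[::-1])[::-1]
                gt[1:] = inc * rev[1:]
                logp += float(np.sum(t_params[1:]))  # Jacobian of log-increments
                gt[1:] += 1.0
            grad[lay["thresh"]] = gt

        # chain rule: d loglik / d eta = r
        if d.n_fixed:
            grad[lay["beta"]] += d.X.T @ r
        for m, (name, lev, dm) in enumerate(d.mono):
            zeta = zetas[m]
            grad[lay["beta_mo"]][m] += float(r @ movals[m])
            s = np.bincount(lev, weights=r, minlength=dm + 1)
            c = np.cumsum(s[::-1])[::-1][1:]  # c_j = sum_{x >= j} r
            gz = beta_mo[m] * dm * c + 1.0 / zeta
            dmn = dm
            gu_full = zeta * gz - zeta * float(gz @ zeta)
            grad[lay[f"u_{name}"]] += gu_full[: dmn - 1]
        for g_i, (name, codes, nlev, _) in enumerate(d.re):
            sigma, z = sigmas[g_i], zs[g_i]
            rsum = np.bincount(codes, weights=r, minlength=nlev)
            grad[lay[f"z_{name}"]] += sigma * rsum
            grad[lay[f"logsd_{name}"]] += sigma * float(z @ rsum)
        return logp, grad


class BayesGLMM:
    """Bernoulli / cumulative-ordinal mixed model fitted by NUTS.

    Parameters
    ----------
    panel : DataFrame
        Model-ready event panel, one row per non-adult x IGC.
    spec : ModelSpec
        Declarative term structure and sampler settings.
    response_col : str
        Column holding the response (0/1 or 1..K).
    """

    def __init__(self, panel: pd.DataFrame, spec: ModelSpec, response_col: str):
        self.panel = panel.reset_index(drop=True)
        self.spec = spec
        self.response_col = response_col
        self.design = _Design(self.panel, spec, response_col)
        self.logdensity = _LogDensity(self.design)

    @classmethod
    def from_dataframe(cls, panel, response, fixed=(), interactions=(), monotonic=(),
                       random_intercepts=(), **kw):
        resp_type = kw.pop("response_type", "bernoulli")
        n_cat = kw.pop("n_categories", None)
        spec = ModelSpec(
            response=resp_type,
            fixed=tuple(fixed),
            interactions=tuple(interactions),
            monotonic=tuple(monotonic),
            random_intercepts=tuple(random_intercepts),
            n_categories=n_cat,
            **kw,
        )
        return cls(panel, spec, response)

    def loglik(self, theta: np.ndarray) -> float:
        """Log likelihood only (no priors) at an unconstrained point."""
        d = self.design
        lay = self.logdensity.lay
        beta = theta[lay["beta"]]
        eta = d.X @ beta if d.n_fixed else np.zeros(d.n)
        for m, (name, lev, dm) in enumerate(d.mono):
            zeta = _softmax_anchor(theta[lay[f"u_{name}"]])
            eta += theta[lay["beta_mo"]][m] * monotonic_transform(lev, zeta)
        for name, codes, nlev, _ in d.re:
            sigma = np.exp(theta[lay[f"logsd_{name}"]][0])
            eta += sigma * theta[lay[f"z_{name}"]][codes]
        if self.spec.response == "bernoulli":
            return bernoulli_loglik(d.y, eta)
        tau = self.logdensity.unpack_thresholds(theta[lay["thresh"]])
        p = ordinal_likelihood(d.y + 1, eta, tau)
        return float(np.sum(np.log(np.maximum(p, 1e-300))))

    def fit(self, seed: int = 0, chains: int | None = None, iterations: int | None = None,
            warmup: int | None = None, target_accept: float | None = None) -> PosteriorResult:
        """Run NUTS and return a :class:`PosteriorResult`.

        ``iterations`` is per chain and includes warmup (default: half),
        mirroring the convention of the common R fitting packages.
        """
        spec = self.spec
        chains = chains or spec.chains
        iterations = iterations or spec.iterations
        warmup = warmup if warmup is not None else (spec.warmup or iterations // 2)
        n_draws = iterations - warmup
        if n_draws < 1:
            raise ConfigError("iterations", "must exceed warmup")
        draws, diag = sample_nuts(
            self.logdensity,
            self.logdensity.initial_point(),
            n_warmup=warmup,
            n_draws=n_draws,
            n_chains=chains,
            seed=seed,
            target_accept=target_accept or spec.target_accept,
        )
        return PosteriorResult(model=self, raw_draws=draws, sampler_diagnostics=diag)


class BernoulliGLMM(BayesGLMM):
    """Bernoulli-logit mixed model (participation / grooming yes-no)."""

    def __init__(self, panel, response, fixed=(), interactions=(), monotonic=(),
                 random_intercepts=(), **kw):
        spec = ModelSpec(
            response="bernoulli", fixed=tuple(fixed), interactions=tuple(interactions),
            monotonic=tuple(monotonic), random_intercepts=tuple(random_intercepts), **kw,
        )
        super().__init__(panel, spec, response)


class OrdinalGLMM(BayesGLMM):
    """Cumulative-logit ordinal mixed model (aggression level 1..K)."""

    def __init__(self, panel, response, n_categories, fixed=(), interactions=(),
                 monotonic=(), random_intercepts=(), **kw):
        spec = ModelSpec(
            response="ordinal", n_categories=n_categories, fixed=tuple(fixed),
            interactions=tuple(interactions), monotonic=tuple(monotonic),
            random_intercepts=tuple(random_intercepts), **kw,
        )
        super().__init__(panel, spec, response)
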