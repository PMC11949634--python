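"""Posterior results container shared by all fitted models.

Holds raw unconstrained NUTS draws plus the model's design, and exposes the
natural-scale parameters (coefficients, random-intercept SDs, thresholds,
monotonic simplexes), per-parameter summaries with 95 % credible intervals,
probability of direction, R-hat and effective sample size, and fitted
probabilities with random effects included (conditional) or zeroed
(marginal).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import expit

from . import diagnostics as dg
from .errors import DataError

__all__ = ["PosteriorResult"]


class PosteriorResult:
    """Draws and summaries for one fitted GLMM.

    Parameters
    ----------
    model : BayesGLMM
        The fitted model (provides design matrices and parameter layout).
    raw_draws : (n_chains, n_draws, dim) array
        Post-warmup draws on the unconstrained scale.
    sampler_diagnostics : SamplerDiagnostics
    """

    def __init__(self, model, raw_draws: np.ndarray, sampler_diagnostics=None):
        self.model = model
        self.raw_draws = raw_draws
        self.sampler_diagnostics = sampler_diagnostics
        self.n_chains, self.n_draws, self.dim = raw_draws.shape
        self._lay = model.logdensity.lay
        self._natural: dict[str, np.ndarray] | None = None

    # ------------------------------------------------------------------
    def _compute_natural(self) -> dict[str, np.ndarray]:
        """Map raw draws to named natural-scale scalar parameters (C, S)."""
        if self._natural is not None:
            return self._natural
        d = self.model.design
        lay = self._lay
        raw = self.raw_draws
        nat: dict[str, np.ndarray] = {}
        beta = raw[:, :, lay["beta"]]
        for j, name in enumerate(d.xnames):
            nat[f"b_{name}"] = beta[:, :, j]
        for m, (name, _, _) in enumerate(d.mono):
            nat[f"bmo_{name}"] = raw[:, :, lay["beta_mo"]][:, :, m]
        if d.n_thresh:
            t = raw[:, :, lay["thresh"]]
            tau = np.empty_like(t)
            tau[:, :, 0] = t[:, :, 0]
            if d.n_thresh > 1:
                tau[:, :, 1:] = t[:, :, [0]] + np.cumsum(np.exp(t[:, :, 1:]), axis=2)
            for k in range(d.n_thresh):
                nat[f"tau[{k + 1}]"] = tau[:, :, k]
        for name, _, _, _ in d.re:
            nat[f"sd_{name}"] = np.exp(raw[:, :, lay[f"logsd_{name}"]][:, :, 0])
        for name, _, dm in d.mono:
            u = raw[:, :, lay[f"u_{name}"]]
            logits = np.concatenate([u, np.zeros(u.shape[:2] + (1,))], axis=2)
            e = np.exp(logits - logits.max(axis=2, keepdims=True))
            zeta = e / e.sum(axis=2, keepdims=True)
            for j in range(dm):
                nat[f"zeta_{name}[{j + 1}]"] = zeta[:, :, j]
        self._natural = nat
        return nat

    @property
    def parameter_names(self) -> list[str]:
        return list(self._compute_natural())

    def get(self, name: str) -> np.ndarray:
        """Natural-scale draws for one parameter, shape (chains, draws)."""
        nat = self._compute_natural()
        if name not in nat:
            raise KeyError(f"unknown parameter {name!r}; have {list(nat)}")
        return nat[name]

    def draws_flat(self, name: str) -> np.ndarray:
        return self.get(name).ravel()

    # ------------------------------------------------------------------
    def summary(self, parameters=None, ess: bool = True) -> pd.DataFrame:
        """Posterior summary table: mean, sd, median, 95 % CI, pd, R-hat, ESS."""
        nat = self._compute_natural()
        names = parameters if parameters is not None else list(nat)
        rows = []
        for name in names:
            x = nat[name]
            flat = x.ravel()
            lo, hi = np.percentile(flat, [2.5, 97.5])
            row = {
                "parameter": name,
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)),
                "median": float(np.median(flat)),
                "ci_2.5": float(lo),
                "ci_97.5": float(hi),
                "pd": dg.probability_of_direction(flat),
                "rhat": dg.rhat(x) if self.n_chains >= 2 else np.nan,
            }
            if ess:
                row["ess"] = dg.effective_sample_size(x)
            rows.append(row)
        return pd.DataFrame(rows).set_index("parameter")

    def check_convergence(self, threshold: float = 1.01, warn: bool = True) -> list[str]:
        """Names of parameters whose split R-hat exceeds ``threshold``."""
        if self.n_chains < 2:
            return []
        nat = self._compute_natural()
        bad = [n for n, x in nat.items() if dg.rhat(x) > threshold]
        if bad and warn:
            warnings.warn(
                f"R-hat > {threshold} for {len(bad)} parameter(s): {bad[:8]}", stacklevel=2
            )
        return bad

    # ------------------------------------------------------------------
    def _design_arrays_for(self, panel):
        """(X, mono levels, re codes) for the fitted panel or a new one."""
        d = self.model.design
        if panel is None:
            return d.X, [lev for _, lev, _ in d.mono], [codes for _, codes, _, _ in d.re]
        cols = []
        for name in d.xnames:
            if name == "Intercept":
                cols.append(np.ones(len(panel)))
            elif ":" in name and name not in panel.columns:
                a, b = name.split(":", 1)
                cols.append(panel[a].to_numpy(float) * panel[b].to_numpy(float))
            else:
                cols.append(panel[name].to_numpy(float))
        x = np.column_stack(cols) if cols else np.empty((len(panel), 0))
        mono_levels = [panel[name].to_numpy(int) for name, _, _ in d.mono]
        re_codes = []
        for factor, _, _, labels in d.re:
            parts = factor.split(":")
            key = panel[parts[0]].astype(str)
            for p in parts[1:]:
                key = key + ":" + panel[p].astype(str)
            lookup = {lab: i for i, lab in enumerate(labels)}
            codes = np.array([lookup.get(k, -1) for k in key], dtype=int)
            if (codes == -1).any():
                warnings.warn(
                    f"{int((codes == -1).sum())} unseen level(s) of {factor!r}; "
                    "their random intercept is set to 0",
                    stacklevel=3,
                )
            re_codes.append(codes)
        return x, mono_levels, re_codes

    def linear_predictor(self, mode: str = "conditional", panel=None) -> np.ndarray:
        """Per-draw linear predictor eta, shape (total draws, n rows).

        ``mode="conditional"`` includes the sampled random intercepts;
        ``mode="marginal"`` sets every random effect to zero.  Unseen factor
        levels in a new ``panel`` also contribute zero.
        """
        if mode not in ("conditional", "marginal"):
            raise DataError(f"unknown mode {mode!r}")
        d = self.model.design
        lay = self._lay
        s_total = self.n_chains * self.n_draws
        flat = self.raw_draws.reshape(s_total, self.dim)
        x, mono_levels, re_codes = self._design_arrays_for(panel)
        eta = flat[:, lay["beta"]] @ x.T if d.n_fixed else np.zeros((s_total, x.shape[0]))
        for m, (name, _, dm) in enumerate(d.mono):
            u = flat[:, lay[f"u_{name}"]]
            logits = np.concatenate([u, np.zeros((s_total, 1))], axis=1)
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            zeta = e / e.sum(axis=1, keepdims=True)
            cum = np.concatenate([np.zeros((s_total, 1)), np.cumsum(zeta, axis=1)], axis=1)
            moval = dm * cum[:, mono_levels[m]]  # (S, n)
            eta += flat[:, lay["beta_mo"]][:, [m]] * moval
        if mode == "conditional":
            for g, (name, _, nlev, _) in enumerate(d.re):
                sigma = np.exp(flat[:, lay[f"logsd_{name}"]])  # (S, 1)
                z = flat[:, lay[f"z_{name}"]]
                codes = re_codes[g]
                contrib = sigma * np.where(codes >= 0, z[:, np.clip(codes, 0, nlev - 1)], 0.0)
                eta += contrib
        return eta

    def fitted_probability(self, mode: str = "conditional", panel=None) -> np.ndarray:
        """Per-draw success probabilities (Bernoulli models), (S, n)."""
        if self.model.spec.response != "bernoulli":
            raise DataError("fitted_probability is for Bernoulli models; "
                            "use category_probabilities / linear_predictor")
        return expit(self.linear_predictor(mode, panel))

    def category_probabilities(self, mode: str = "conditional", panel=None) -> np.ndarray:
        """Per-draw ordinal category probabilities, (S, n, K)."""
        if self.model.spec.response != "ordinal":
            raise DataError("category_probabilities is for ordinal models")
        eta = self.linear_predictor(mode, panel)
        s_total = eta.shape[0]
        flat = self.raw_draws.reshape(s_total, self.dim)
        t = flat[:, self._lay["thresh"]]
        tau = np.empty_like(t)
        tau[:, 0] = t[:, 0]
        if t.shape[1] > 1:
            tau[:, 1:] = t[:, [0]] + np.cumsum(np.exp(t[:, 1:]), axis=1)
        k = self.model.spec.n_categories
        cdf = expit(tau[:, None, :] - eta[:, :, None])  # (S, n, K-1)
        probs = np.empty((s_total, eta.shape[1], k))
        probs[:, :, 0] = cdf[:, :, 0]
        probs[:, :, 1:-1] = np.diff(cdf, axis=2)
        probs[:, :, -1] = 1.0 - cdf[:, :, -1]
        return probs

    def posterior_predictive(self, seed: int = 0, mode: str = "conditional",
                             max_draws: int = 200) -> np.ndarray:
        """Replicated response datasets (S, n) for posterior-predictive checks."""
        rng = np.random.default_rng(seed)
        if self.model.spec.response == "bernoulli":
            p = self.fitted_probability(mode)
            if p.shape[0] > max_draws:
                p = p[rng.choice(p.shape[0], max_draws, replace=False)]
            return rng.binomial(1, p)
        probs = self.category_probabilities(mode)
        if probs.shape[0] > max_draws:
            probs = probs[rng.choice(probs.shape[0], max_draws, replace=False)]
        cum = np.cumsum(probs, axis=2)
        u = rng.random(cum.shape[:2])[:, :, None]
        return 1 + (u > cum[:, :, :-1]).sum(axis=2)  # categories 1..K

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Tidy (chain, draw, parameter, value) table of natural draws."""
        nat = self._compute_natural()
        frames = []
        for name, x in nat.items():
            c, s = np.meshgrid(np.arange(self.n_chains), np.arange(self.n_draws), indexing="ij")
            frames.append(pd.DataFrame({
                "chain": c.ravel(), "draw": s.ravel(), "parameter": name, "value": x.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)

    def to_inference_data(self):
        """Natural-scale draws as an arviz InferenceData object."""
        import arviz as az

        nat = self._compute_natural()
        return az.from_dict(posterior={k: v for k, v in nat.items()})

    def plot_intervals(self, parameters=None, ax=None):
        """Forest plot of posterior means with 95 % credible intervals.

        Defaults to the fixed-effect coefficients (``b_*`` and ``bmo_*``).
        Returns the matplotlib axes.
        """
        import matplotlib.pyplot as plt

        if parameters is None:
            parameters = [p for p in self.parameter_names
                          if p.startswith(("b_", "bmo_"))]
        summ = self.summary(parameters=parameters, ess=False)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.4 * len(summ) + 1))
        y = np.arange(len(summ))[::-1]
        ax.hlines(y, summ["ci_2.5"], summ["ci_97.5"], color="steelblue", lw=2)
        ax.plot(summ["mean"], y, "o", color="steelblue")
        ax.axvline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_yticks(y)
        ax.set_yticklabels(summ.index)
        ax.set_xlabel("posterior mean and 95% CI (logit scale)")
        return ax
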