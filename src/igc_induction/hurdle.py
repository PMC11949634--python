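"""Nested double-hurdle model of within-IGC grooming.

For each participant x IGC row the outcome is a pair ``(y1, y2)``: hurdle 1
asks whether the non-adult was groomed during the conflict; hurdle 2,
defined only when ``y1 = 1``, asks whether the groomer was the mother.  The
log likelihood of one row with grooming probability ``p1`` and
mother-groomer probability ``p2`` is

    log L = (1 - y1) log(1 - p1) + y1 [log p1 + y2 log p2 + (1 - y2) log(1 - p2)]

so the three legal outcomes {not groomed, groomed by other, groomed by
mother} have probabilities (1 - p1), p1 (1 - p2), p1 p2 summing to one.

Both hurdles share the same covariates (sex, age, rank) but carry separate
coefficient vectors and separate random-intercept SDs for individual
nested in mother nested in focal group; the joint likelihood therefore
factorizes, and the two hurdles are sampled as independent Bernoulli
sub-posteriors and reported as a result pair.  Model performance is
summarized by in-sample ROC AUC of each hurdle (rank statistic with tie
correction), with random effects included ("full") or zeroed
("main_only").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diagnostics import roc_auc
from .errors import DataError
from .glmm import BernoulliGLMM
from .results import PosteriorResult

__all__ = ["hurdle_loglik", "DoubleHurdleModel", "DoubleHurdleResults", "hurdle_auc"]

DEFAULT_HURDLE_COVARIATES = ("sex_male", "age", "rank")
DEFAULT_HURDLE_RE = ("focal_group", "focal_group:mother", "focal_group:mother:individual")


def hurdle_loglik(y1: int, y2, p1: float, p2: float) -> float:
    """Log likelihood of one double-hurdle outcome.

    ``y2`` must be None (undefined) when ``y1 = 0``; passing a defined
    ``y2`` with ``y1 = 0`` is a data error.  ``p1, p2`` in (0, 1).
    """
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise DataError("hurdle probabilities must lie in (0, 1)")
    if y1 == 0:
        if y2 is not None and not (isinstance(y2, float) and np.isnan(y2)):
            raise DataError("y2 is defined although y1 = 0")
        return float(np.log1p(-p1))
    y2 = int(y2)
    return float(np.log(p1) + (np.log(p2) if y2 else np.log1p(-p2)))


class DoubleHurdleResults:
    """Posterior pair for the two hurdles plus AUC machinery."""

    def __init__(self, model: "DoubleHurdleModel",
                 hurdle1: PosteriorResult, hurdle2: PosteriorResult):
        self.model = model
        self.hurdle1 = hurdle1
        self.hurdle2 = hurdle2

    def summary(self, ess: bool = True) -> pd.DataFrame:
        s1 = self.hurdle1.summary(ess=ess)
        s2 = self.hurdle2.summary(ess=ess)
        s1.index = ["h1_" + i for i in s1.index]
        s2.index = ["h2_" + i for i in s2.index]
        return pd.concat([s1, s2])

    def auc(self, which_hurdle: int, effects: str = "full") -> float:
        """In-sample ROC AUC of one hurdle's posterior-mean probabilities.

        ``effects="full"`` includes the fitted random intercepts,
        ``"main_only"`` uses fixed effects alone (marginal probabilities).
        """
        if which_hurdle not in (1, 2):
            raise DataError("which_hurdle must be 1 or 2")
        if effects not in ("full", "main_only"):
            raise DataError(f"unknown effects mode {effects!r}")
        mode = "conditional" if effects == "full" else "marginal"
        res = self.hurdle1 if which_hurdle == 1 else self.hurdle2
        y = res.model.design.y.astype(int)
        p = res.fitted_probability(mode).mean(axis=0)
        return roc_auc(p, y)

    def auc_table(self) -> pd.DataFrame:
        rows = [
            {"hurdle": h, "effects": e, "auc": self.auc(h, e)}
            for h in (1, 2)
            for e in ("full", "main_only")
        ]
        return pd.DataFrame(rows)


class DoubleHurdleModel:
    """Model 4: grooming receipt and the groomer's identity, participants only.

    Parameters
    ----------
    panel : DataFrame
        Participant rows (participation = 1) with ``groomed`` (0/1) and
        ``groomed_by_mother`` (0/1, NaN when not groomed).
    covariates : sequence of str
        Shared fixed effects for both hurdles (default sex, age, rank).
    random_intercepts : sequence of str
        Grouping factors; the default expresses id within mother within
        focal group.
    """

    def __init__(self, panel: pd.DataFrame, covariates=DEFAULT_HURDLE_COVARIATES,
                 random_intercepts=DEFAULT_HURDLE_RE,
                 chains: int = 8, iterations: int = 500):
        panel = panel.reset_index(drop=True)
        if (panel["participation"] != 1).any():
            raise DataError("double-hurdle panel must contain participant rows only")
        defined = panel["groomed_by_mother"].notna()
        if ((panel["groomed"] == 1) != defined).any():
            raise DataError("groomed_by_mother must be defined exactly when groomed = 1")
        if int(panel["groomed"].sum()) == 0:
            raise DataError("no hurdle-1 successes: hurdle 2 is unidentifiable")
        sub = panel[panel["groomed"] == 1].reset_index(drop=True)
        if sub["groomed_by_mother"].nunique() < 2:
            raise DataError("hurdle-2 outcome is single-class on the groomed subset")
        self.panel = panel
        self.panel2 = sub.assign(groomed_by_mother=sub["groomed_by_mother"].astype(int))
        self.covariates = tuple(covariates)
        self.random_intercepts = tuple(random_intercepts)
        self.chains = chains
        self.iterations = iterations
        self._m1 = BernoulliGLMM(
            self.panel, "groomed", fixed=self.covariates,
            random_intercepts=self.random_intercepts,
            chains=chains, iterations=iterations)
        self._m2 = BernoulliGLMM(
            self.panel2, "groomed_by_mother", fixed=self.covariates,
            random_intercepts=self.random_intercepts,
            chains=chains, iterations=iterations)

    def loglik(self, p1: np.ndarray, p2_full: np.ndarray) -> float:
        """Joint log likelihood given per-row probabilities on the full panel."""
        y1 = self.panel["groomed"].to_numpy(int)
        y2 = self.panel["groomed_by_mother"].to_numpy(float)
        ll = (1 - y1) * np.log1p(-p1) + y1 * np.log(p1)
        ll = ll + np.where(y1 == 1, np.where(y2 == 1, np.log(p2_full),
                                             np.log1p(-p2_full)), 0.0)
        return float(ll.sum())

    def fit(self, seed: int = 0, chains: int | None = None,
            iterations: int | None = None, warmup: int | None = None,
            target_accept: float = 0.9) -> DoubleHurdleResults:
        """Sample both hurdles and return the result pair.

        The hurdles share no parameters, so their posteriors are sampled
        independently (the joint likelihood factorizes exactly).
        """
        r1 = self._m1.fit(seed=seed, chains=chains, iterations=iterations,
                          warmup=warmup, target_accept=target_accept)
        r2 = self._m2.fit(seed=seed + 1, chains=chains, iterations=iterations,
                          warmup=warmup, target_accept=target_accept)
        return DoubleHurdleResults(self, r1, r2)


def hurdle_auc(result: DoubleHurdleResults, which_hurdle: int,
               effects: str = "full") -> float:
    """Functional form of :meth:`DoubleHurdleResults.auc`."""
    return result.auc(which_hurdle, effects)
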