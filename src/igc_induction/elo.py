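"""Sequential Elo ratings from dyadic agonistic outcomes.

Each decided contest moves the winner's rating up and the loser's down by
``k * (1 - E)``, where ``E`` is the winner's expected score given the
pre-contest rating difference.  Two expectation curves are supported:

``logistic``
    ``E = 1 / (1 + 10 ** ((r_loser - r_winner) / 400))`` — the classic
    chess formulation.
``normal``
    ``E = Phi((r_winner - r_loser) / (200 * sqrt(2)))`` — the default of
    the R reference implementation widely used for animal dominance data,
    and the default here.

Draws credit both parties a score of 0.5, so at equal ratings a draw
changes nothing.  ``unknown`` outcomes are skipped (and counted).  Ratings
are piecewise constant between contests, which supports rank lookup on an
arbitrary date, e.g. the day of an intergroup encounter.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError, IntegrityError, LookupError_

__all__ = ["elo_update", "EloSeries", "run_elo"]

_SQRT2_200 = 200.0 * math.sqrt(2.0)


def expected_score(r_a: float, r_b: float, curve: str = "normal") -> float:
    """Expected score of the first party given ratings ``r_a`` vs ``r_b``."""
    if curve == "logistic":
        return 1.0 / (1.0 + 10.0 ** ((r_b - r_a) / 400.0))
    if curve == "normal":
        return float(norm.cdf((r_a - r_b) / _SQRT2_200))
    raise ConfigError("expectation_curve", f"unknown curve {curve!r}")


def elo_update(
    r_winner: float,
    r_loser: float,
    k: float = 100.0,
    curve: str = "normal",
    draw: bool = False,
) -> tuple[float, float]:
    """One rating update; returns the post-contest ``(winner, loser)`` ratings.

    For a draw the "winner"/"loser" labels are arbitrary: both receive
    score 0.5, so the transfer is ``k * (0.5 - E)`` toward the first party.
    Rating is conserved: the first party's gain equals the second's loss.
    """
    if k <= 0:
        raise ConfigError("k", "must be > 0")
    e = expected_score(r_winner, r_loser, curve)
    score = 0.5 if draw else 1.0
    delta = k * (score - e)
    return r_winner + delta, r_loser - delta


@dataclass
class EloSeries:
    """Piecewise-constant rating trajectories for the members of one group."""

    group_id: str
    k: float = 100.0
    start_value: float = 1000.0
    curve: str = "normal"
    #: id -> (list of event days, list of post-event ratings); parallel arrays
    _traj: dict[str, tuple[list[int], list[float]]] = field(default_factory=dict)
    n_skipped_unknown: int = 0

    def register(self, ids) -> None:
        for i in ids:
            self._traj.setdefault(str(i), ([], []))

    @property
    def ids(self) -> list[str]:
        return list(self._traj)

    def rating(self, id_: str, date: int) -> float:
        """Rating of ``id_`` at the end of ``date``."""
        if id_ not in self._traj:
            raise LookupError_(f"id {id_!r} not registered in Elo series for group {self.group_id}")
        days, ratings = self._traj[id_]
        pos = bisect_right(days, date)
        if pos == 0:
            return self.start_value
        return ratings[pos - 1]

    def _append(self, id_: str, date: int, rating: float) -> None:
        days, ratings = self._traj[id_]
        days.append(date)
        ratings.append(rating)

    def ratings_on_date(self, date: int, ids=None) -> pd.Series:
        ids = self.ids if ids is None else list(ids)
        return pd.Series({i: self.rating(i, date) for i in ids}, name="rating")

    def rank_on_date(self, id_: str, date: int, standardize: bool = True, ids=None) -> float:
        """Rating (raw or z-scored across group members) of ``id_`` on ``date``.

        Standardization is over the members alive on the date (``ids``
        restricts the reference set); with fewer than two members, or zero
        spread, the standardized rank is 0.
        """
        if not standardize:
            return self.rating(id_, date)
        r = self.ratings_on_date(date, ids)
        if id_ not in r.index:
            raise LookupError_(f"id {id_!r} not in reference set on date {date}")
        sd = r.std(ddof=0)
        if len(r) < 2 or sd == 0:
            return 0.0
        return float((r[id_] - r.mean()) / sd)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (date, id, rating) table of every rating change."""
        rows = [
            (d, i, v)
            for i, (days, ratings) in self._traj.items()
            for d, v in zip(days, ratings)
        ]
        return pd.DataFrame(rows, columns=["date", "id", "rating"]).sort_values(
            ["date", "id"], kind="stable", ignore_index=True
        )


def run_elo(
    events: pd.DataFrame,
    roster: pd.DataFrame,
    k: float = 100.0,
    start_value: float = 1000.0,
    curve: str = "normal",
) -> dict[str, EloSeries]:
    """Run sequential Elo per group over a date-sorted agonistic event table.

    ``events`` needs columns ``date, aggressor_id, victim_id, outcome`` with
    outcome in {win, loss, draw, unknown} from the aggressor's perspective;
    ``roster`` needs ``id, group_id``.  Same-day events are applied in table
    order.  Returns one :class:`EloSeries` per group.
    """
    if k <= 0:
        raise ConfigError("k", "must be > 0")
    group_of = dict(zip(roster["id"].astype(str), roster["group_id"].astype(str)))
    series: dict[str, EloSeries] = {}
    for gid, sub in roster.groupby("group_id"):
        s = EloSeries(group_id=str(gid), k=k, start_value=start_value, curve=curve)
        s.register(sub["id"].astype(str))
        series[str(gid)] = s

    ev = events.sort_values("date", kind="stable")
    for row in ev.itertuples(index=False):
        agg, vic, outcome = str(row.aggressor_id), str(row.victim_id), str(row.outcome)
        date = int(row.date)
        if outcome == "unknown":
            g = group_of.get(agg)
            if g is not None:
                series[g].n_skipped_unknown += 1
            continue
        if agg not in group_of or vic not in group_of:
            missing = agg if agg not in group_of else vic
            raise IntegrityError(f"agonistic event on day {date} involves unregistered id {missing!r}")
        g = group_of[agg]
        if group_of[vic] != g:
            # between-group aggression carries no within-group rank information
            continue
        s = series[g]
        ra, rv = s.rating(agg, date), s.rating(vic, date)
        if outcome == "win":
            new_a, new_v = elo_update(ra, rv, k, curve)
        elif outcome == "loss":
            new_v, new_a = elo_update(rv, ra, k, curve)
        elif outcome == "draw":
            new_a, new_v = elo_update(ra, rv, k, curve, draw=True)
        else:
            raise IntegrityError(f"unknown outcome code {outcome!r} on day {date}")
        s._append(agg, date, new_a)
        s._append(vic, date, new_v)
    return series
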