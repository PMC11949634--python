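"""Ingest, validation and panel construction for the five observation tables.

``load_tables`` reads and type-checks the scan, agonism, IGC, roster and
neophilia tables (real or synthetic; CSV with header rows, dates as integer
day indices) and enforces the data model's invariants: legal activity and
outcome alphabets, grooming records carrying a partner and role, aggression
levels in 1..4, no self-partners, and referential integrity against the
roster.  ``build_event_panel`` then joins the covariate stages (Elo ranks,
annual network centralities, neophilia, maternal participation) into the
model-ready panel with one row per non-adult x IGC of its group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .elo import run_elo
from .errors import CoverageError, DataError, IntegrityError
from .networks import build_networks, centrality_table

__all__ = ["Dataset", "load_tables", "build_event_panel", "CONTINUOUS_COLUMNS"]

log = logging.getLogger("igc_induction")

ACTIVITY_SET = {"foraging", "resting", "grooming", "moving", "playing"}
OUTCOME_SET = {"win", "loss", "draw", "unknown"}
LEVEL_LABELS = {0: "non-participant", 1: "non-aggressive", 2: "stationary",
                3: "active", 4: "physical"}

#: panel columns scaled and mean-centred before modelling
CONTINUOUS_COLUMNS = [
    "age", "rank", "neophilia", "grooming_EC", "spatial_EC",
    "n_focal_participants", "n_opposing_participants",
    "focal_group_size", "opposing_group_size",
]

TABLE_NAMES = ("roster", "neophilia", "scans", "agonism", "igc")


@dataclass
class Dataset:
    """Typed bundle of the five validated observation tables."""

    roster: pd.DataFrame
    neophilia: pd.DataFrame
    scans: pd.DataFrame
    agonism: pd.DataFrame
    igc: pd.DataFrame
    #: event_id -> {individual: level} parsed from the participants field
    participants: dict[str, dict[str, int]] = field(default_factory=dict)
    #: event_id -> list of (groomer, groomee)
    grooming: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def row_counts(self) -> dict[str, int]:
        return {name: len(getattr(self, name)) for name in TABLE_NAMES}

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in TABLE_NAMES:
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)


def _parse_participants(s, event_id: str, line: int) -> dict[str, int]:
    if not isinstance(s, str) or not s:
        return {}
    out = {}
    for tok in s.split(";"):
        if ":" not in tok:
            raise DataError(f"malformed participant token {tok!r} in event {event_id}",
                            file="igc.csv", line=line)
        id_, lev = tok.rsplit(":", 1)
        try:
            lev = int(lev)
        except ValueError:
            raise DataError(f"non-integer level {lev!r} in event {event_id}",
                            file="igc.csv", line=line) from None
        if not 1 <= lev <= 4:
            raise DataError(
                f"participation level {lev} outside 1..4 for {id_} in event {event_id}",
                file="igc.csv", line=line)
        out[id_] = lev
    return out


def _parse_grooming(s, event_id: str, line: int) -> list[tuple[str, str]]:
    if not isinstance(s, str) or not s:
        return []
    out = []
    for tok in s.split(";"):
        if ">" not in tok:
            raise DataError(f"malformed grooming dyad {tok!r} in event {event_id}",
                            file="igc.csv", line=line)
        a, b = tok.split(">", 1)
        out.append((a, b))
    return out


def load_tables(source: str | Path | dict, schema_version: str = "1") -> Dataset:
    """Load and validate the five tables from a directory (or path mapping).

    Raises :class:`DataError` with file and line number on the first
    invariant violation, and :class:`IntegrityError` on orphan ids.  Logs a
    row-count summary at INFO level.
    """
    if isinstance(source, (str, Path)):
        paths = {name: Path(source) / f"{name}.csv" for name in TABLE_NAMES}
    else:
        paths = {k: Path(v) for k, v in source.items()}
    for name in TABLE_NAMES:
        if not paths[name].exists():
            raise DataError(f"missing table file", file=str(paths[name]))
    roster = pd.read_csv(paths["roster"], dtype={"id": str, "mother_id": str,
                                                 "group_id": str, "sex": str},
                         keep_default_na=False)
    roster["birth_date"] = roster["birth_date"].astype(int)
    if "is_adult" in roster.columns:
        roster["is_adult"] = roster["is_adult"].astype(str).isin(("True", "true", "1"))
    else:
        roster["is_adult"] = roster["mother_id"] == ""
    known = set(roster["id"])
    for i, row in enumerate(roster.itertuples(index=False)):
        if row.sex not in ("F", "M"):
            raise DataError(f"sex {row.sex!r} not in {{F, M}}", file="roster.csv", line=i + 2)
        if row.mother_id and row.mother_id not in known:
            raise IntegrityError(f"mother {row.mother_id!r} of {row.id!r} not in roster",
                                 file="roster.csv", line=i + 2)
    mother_group = dict(zip(roster["id"], roster["group_id"]))
    for i, row in enumerate(roster.itertuples(index=False)):
        if row.mother_id and mother_group[row.mother_id] != row.group_id:
            raise IntegrityError(f"mother of {row.id!r} is in a different group",
                                 file="roster.csv", line=i + 2)

    neophilia = pd.read_csv(paths["neophilia"], dtype={"id": str})
    bad = ~neophilia["neophilia"].between(0, 1)
    if bad.any():
        raise DataError("neophilia outside [0, 1]", file="neophilia.csv",
                        line=int(np.flatnonzero(bad)[0]) + 2)

    scans = pd.read_csv(paths["scans"], dtype={"group_id": str, "individual_id": str,
                                               "partner_id": str, "partner_role": str,
                                               "activity": str, "neighbours_3m": str},
                        keep_default_na=False)
    scans["day"] = scans["day"].astype(int)
    bad_act = ~scans["activity"].isin(ACTIVITY_SET)
    if bad_act.any():
        i = int(np.flatnonzero(bad_act)[0])
        raise DataError(f"unknown activity {scans['activity'].iloc[i]!r}",
                        file="scans.csv", line=i + 2)
    grooming_rows = scans["activity"] == "grooming"
    missing_partner = grooming_rows & (
        (scans["partner_id"] == "") | ~scans["partner_role"].isin(("groomer", "groomee")))
    if missing_partner.any():
        i = int(np.flatnonzero(missing_partner)[0])
        raise DataError("grooming scan without partner id/role",
                        file="scans.csv", line=i + 2)
    self_partner = grooming_rows & (scans["partner_id"] == scans["individual_id"])
    if self_partner.any():
        i = int(np.flatnonzero(self_partner)[0])
        raise DataError("self-partner in grooming scan", file="scans.csv", line=i + 2)
    orphan = ~scans["individual_id"].isin(known)
    if orphan.any():
        i = int(np.flatnonzero(orphan)[0])
        raise IntegrityError(f"scan id {scans['individual_id'].iloc[i]!r} not in roster",
                             file="scans.csv", line=i + 2)

    agonism = pd.read_csv(paths["agonism"], dtype={"aggressor_id": str, "victim_id": str,
                                                   "outcome": str})
    agonism["date"] = agonism["date"].astype(int)
    bad_out = ~agonism["outcome"].isin(OUTCOME_SET)
    if bad_out.any():
        i = int(np.flatnonzero(bad_out)[0])
        raise DataError(f"unknown outcome {agonism['outcome'].iloc[i]!r}",
                        file="agonism.csv", line=i + 2)
    self_ag = agonism["aggressor_id"] == agonism["victim_id"]
    if self_ag.any():
        i = int(np.flatnonzero(self_ag)[0])
        raise DataError("aggressor equals victim", file="agonism.csv", line=i + 2)
    for col in ("aggressor_id", "victim_id"):
        orphan = ~agonism[col].isin(known)
        if orphan.any():
            i = int(np.flatnonzero(orphan)[0])
            raise IntegrityError(f"agonism id {agonism[col].iloc[i]!r} not in roster",
                                 file="agonism.csv", line=i + 2)

    igc = pd.read_csv(paths["igc"], dtype={"event_id": str, "focal_group": str,
                                           "opposing_group": str, "participants": str,
                                           "igc_grooming": str}, keep_default_na=False)
    igc["date"] = igc["date"].astype(int)
    participants: dict[str, dict[str, int]] = {}
    grooming: dict[str, list[tuple[str, str]]] = {}
    group_of = dict(zip(roster["id"], roster["group_id"]))
    for i, row in enumerate(igc.itertuples(index=False)):
        line = i + 2
        if row.focal_group == row.opposing_group:
            raise DataError(f"event {row.event_id}: focal equals opposing group",
                            file="igc.csv", line=line)
        pmap = _parse_participants(row.participants, row.event_id, line)
        for id_ in pmap:
            if id_ not in known:
                raise IntegrityError(f"participant {id_!r} not in roster",
                                     file="igc.csv", line=line)
        dyads = _parse_grooming(row.igc_grooming, row.event_id, line)
        for a, b in dyads:
            for x in (a, b):
                if x not in known:
                    raise IntegrityError(f"grooming id {x!r} not in roster",
                                         file="igc.csv", line=line)
                if group_of[x] != row.focal_group:
                    raise DataError(
                        f"grooming id {x!r} not in focal group {row.focal_group}",
                        file="igc.csv", line=line)
        participants[row.event_id] = pmap
        grooming[row.event_id] = dyads

    ds = Dataset(roster=roster, neophilia=neophilia, scans=scans, agonism=agonism,
                 igc=igc, participants=participants, grooming=grooming)
    log.info("loaded tables: %s", ds.row_counts())
    return ds


def _standardize(panel: pd.DataFrame, columns=CONTINUOUS_COLUMNS) -> pd.DataFrame:
    for c in columns:
        x = panel[c].to_numpy(dtype=float)
        panel[c + "_raw"] = x
        sd = x.std()
        panel[c] = (x - x.mean()) / sd if sd > 0 else 0.0
    return panel


def build_event_panel(
    dataset: Dataset,
    reference: str = "all_nonadults",
    weaning_age_days: int = 365,
    days_per_year: int = 365,
    elo_k: float = 100.0,
    elo_start: float = 1000.0,
    elo_curve: str = "normal",
    standardize: bool = True,
) -> pd.DataFrame:
    """Model-ready panel: one row per non-adult x IGC of its group.

    Covariates: age in days, sex dummy, Elo rank on the event date
    (standardized within group-date), neophilia (population-mean imputed
    and flagged when missing), year-matched grooming and spatial
    eigenvector centralities, maternal participation (0/1) and level
    (0..4), participant counts and group sizes from the event record.
    Responses: participation (0/1), aggression level (0..4), groomed
    (0/1), groomed-by-mother (0/1; NaN unless groomed).  Continuous
    covariates are scaled and mean-centred (originals kept as ``*_raw``).

    ``reference`` selects the row set: ``all_nonadults`` (default),
    ``juveniles`` (age at event >= weaning threshold), or
    ``participants_only``.
    """
    if reference not in ("all_nonadults", "juveniles", "participants_only"):
        raise DataError(f"unknown reference set {reference!r}")
    roster = dataset.roster
    elo = run_elo(dataset.agonism[dataset.agonism["outcome"] != "unknown"], roster,
                  k=elo_k, start_value=elo_start, curve=elo_curve)
    scan_years = {(g, int(d) // days_per_year)
                  for g, d in zip(dataset.scans["group_id"], dataset.scans["day"])}
    years_by_group: dict[str, set[int]] = {}
    for g, y in scan_years:
        years_by_group.setdefault(g, set()).add(y)
    pairs = []
    for g, years in years_by_group.items():
        for y in sorted(years):
            pairs.append(build_networks(dataset.scans, roster, y, g,
                                        days_per_year=days_per_year))
    cent = centrality_table(pairs)
    cent_map = {(r.individual_id, r.year): (r.grooming_EC, r.spatial_EC)
                for r in cent.itertuples(index=False)}
    neo = dict(zip(dataset.neophilia["id"], dataset.neophilia["neophilia"]))
    neo_mean = float(dataset.neophilia["neophilia"].mean())

    by_group = {g: sub for g, sub in roster.groupby("group_id")}
    mother_of = dict(zip(roster["id"], roster["mother_id"]))
    rank_cache: dict[tuple[str, int], dict[str, float]] = {}
    rows = []
    n_dropped = 0
    for row in dataset.igc.itertuples(index=False):
        g = row.focal_group
        date = int(row.date)
        year = date // days_per_year
        if g not in years_by_group:
            raise CoverageError(f"no scan coverage for group {g}: cannot build networks")
        if year not in years_by_group[g]:
            raise CoverageError(
                f"no year-{year} network for group {g} (event {row.event_id})")
        sub = by_group[g]
        alive = sub[sub["birth_date"] <= date]
        key = (g, date)
        if key not in rank_cache:
            r = elo[g].ratings_on_date(date, ids=list(alive["id"]))
            sd = r.std(ddof=0)
            rank_cache[key] = dict((r - r.mean()) / sd if (len(r) > 1 and sd > 0) else r * 0)
        ranks = rank_cache[key]
        pmap = dataset.participants.get(row.event_id, {})
        dyads = dataset.grooming.get(row.event_id, [])
        groomees = {b for _, b in dyads}
        by_mother = {b for a, b in dyads if mother_of.get(b, "") == a}
        kids = alive[~alive["is_adult"].astype(bool)]
        for kid in kids.itertuples(index=False):
            if (kid.id, year) not in cent_map:
                n_dropped += 1
                log.info("dropping %s at event %s: no year-%d network entry",
                         kid.id, row.event_id, year)
                continue
            gec, sec = cent_map[(kid.id, year)]
            mother_level = pmap.get(kid.mother_id, 0)
            level = pmap.get(kid.id, 0)
            groomed = 1 if kid.id in groomees else 0
            rows.append({
                "event_id": row.event_id, "date": date, "year": year,
                "individual": kid.id, "mother": kid.mother_id,
                "focal_group": g, "opposing_group": row.opposing_group,
                "sex_male": 1.0 if kid.sex == "M" else 0.0,
                "age": float(date - kid.birth_date),
                "rank": ranks.get(kid.id, 0.0),
                "neophilia": neo.get(kid.id, neo_mean),
                "neophilia_imputed": kid.id not in neo,
                "grooming_EC": gec, "spatial_EC": sec,
                "mother_participated": 1.0 if mother_level > 0 else 0.0,
                "mother_level": int(mother_level),
                "n_focal_participants": float(row.n_focal_participants),
                "n_opposing_participants": float(row.n_opposing_participants),
                "focal_group_size": float(row.focal_group_size),
                "opposing_group_size": float(row.opposing_group_size),
                "participation": 1 if level > 0 else 0,
                "level": int(level),
                "groomed": groomed,
                "groomed_by_mother": (1 if kid.id in by_mother else 0) if groomed else np.nan,
            })
    panel = pd.DataFrame(rows)
    if len(panel) == 0:
        raise DataError("event panel is empty")
    if reference == "juveniles":
        panel = panel[panel["age"] >= weaning_age_days].reset_index(drop=True)
    elif reference == "participants_only":
        panel = panel[panel["participation"] == 1].reset_index(drop=True)
    if standardize:
        panel = _standardize(panel)
    panel.attrs["n_dropped"] = n_dropped
    panel.attrs["reference"] = reference
    log.info("panel: %d rows (%d dropped)", len(panel), n_dropped)
    return panel
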