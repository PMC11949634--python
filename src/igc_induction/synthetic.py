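"""Synthetic cohort generator with fully known ground truth.

Generates the five observation tables of the study design — scan records,
ad-libitum agonistic events, intergroup-conflict (IGC) events, a
life-history roster, and per-individual neophilia scores — from an explicit
generative model whose every parameter sits in :class:`GeneratorConfig`.
The non-adult outcome variables (participation yes/no, aggression level
1-4, being groomed during the IGC, being groomed by the mother) are drawn
from exactly the model families the pipeline fits, so the configured
coefficient vectors are recoverable ground truth.

Covariate realism: ranks and network centralities entering the outcome
models are not drawn independently but computed by running the package's
own Elo and network stages on the synthetic agonism and scan streams,
preserving the pipeline's dependency structure.  Maternal participation is
drawn first from an adult-propensity model; offspring outcomes condition
on it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import GeneratorConfig
from .elo import run_elo
from .errors import ConfigError, DataError
from .glmm import monotonic_transform
from .networks import build_networks, centrality_table

__all__ = [
    "generate_population",
    "generate_neophilia",
    "generate_scans",
    "generate_agonism",
    "generate_igc",
    "generate_dataset",
    "CovariateProvider",
]

ACTIVITIES = ("foraging", "resting", "grooming", "moving", "playing")
_COHORT_SPREAD_DAYS = 30  # SD of birth dates around each seasonal cohort peak


def _group_name(g: int) -> str:
    return f"G{g + 1}"


def generate_population(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Roster of individuals: non-adult cohorts plus the adult group cores.

    Non-adults are assigned to three seasonal birth cohorts (one year
    apart, the earliest preceding the study start) and to a mother in the
    same group; mothers carry one or two offspring.  Returns a table with
    columns ``id, sex, birth_date, mother_id, group_id, is_adult``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    rows = []
    for g in range(cfg.n_groups):
        gname = _group_name(g)
        cohort = cfg.cohort_sizes[g]
        n_mothers = max(1, int(np.ceil(cohort / cfg.offspring_per_mother)))
        n_adults = max(n_mothers + 2, int(round(cohort * cfg.adults_per_nonadult)))
        n_females = max(n_mothers, (n_adults + 1) // 2)
        for j in range(n_adults):
            rows.append({
                "id": f"{gname}A{j + 1:02d}",
                "sex": "F" if j < n_females else "M",
                "birth_date": int(rng.integers(-3650, -1825)),
                "mother_id": "",
                "group_id": gname,
                "is_adult": True,
            })
        mother_ids = [f"{gname}A{j + 1:02d}" for j in range(n_mothers)]
        for i in range(cohort):
            cohort_year = i % 3
            birth = int(cfg.cohort_anchor_day + 365 * cohort_year
                        + round(rng.normal(0, _COHORT_SPREAD_DAYS)))
            rows.append({
                "id": f"{gname}N{i + 1:02d}",
                "sex": "M" if rng.random() < 0.5 else "F",
                "birth_date": birth,
                "mother_id": mother_ids[i % n_mothers],
                "group_id": gname,
                "is_adult": False,
            })
    return pd.DataFrame(rows)


def generate_neophilia(roster: pd.DataFrame, cfg: GeneratorConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Per-individual neophilia index in [0, 1] (taken as given downstream)."""
    vals = rng.beta(2.0, 2.0, size=len(roster))
    return pd.DataFrame({"id": roster["id"].to_numpy(), "neophilia": vals})


def _latent_strengths(roster, cfg, rng) -> dict[str, float]:
    if cfg.latent_strengths is not None:
        missing = set(roster["id"]) - set(cfg.latent_strengths)
        if missing:
            raise ConfigError("latent_strengths", f"missing ids: {sorted(missing)[:5]}")
        return dict(cfg.latent_strengths)
    out = {}
    for row in roster.itertuples(index=False):
        base = cfg.adult_strength_mean if row.is_adult else 0.0
        out[row.id] = float(base + rng.normal(0, 1))
    return out


def generate_scans(roster: pd.DataFrame, cfg: GeneratorConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Scan-sampling records: one row per visible individual per window.

    Grooming bouts are drawn from a dyadic kernel in which mother-offspring
    dyads are up-weighted by ``mother_groom_multiplier``; 3-m neighbours
    come from a spatial affinity kernel concentrated within the non-adult
    age class.
    """
    if len(roster) == 0:
        raise DataError("empty roster")
    act_names = [a for a in cfg.activity_probs]
    act_p = np.array([cfg.activity_probs[a] for a in act_names])
    act_p = act_p / act_p.sum()
    n_windows = cfg.n_scan_windows_per_day
    frames = []
    for gname, sub in roster.groupby("group_id", sort=True):
        ids = sub["id"].to_numpy()
        birth = sub["birth_date"].to_numpy()
        nonadult = (~sub["is_adult"].to_numpy(bool)).astype(float)
        n = len(ids)
        mother_idx = {i: np.flatnonzero(ids == m)[0]
                      for i, m in enumerate(sub["mother_id"]) if m}
        # grooming kernel
        wg = np.ones((n, n))
        np.fill_diagonal(wg, 0.0)
        for kid, mom in mother_idx.items():
            wg[kid, mom] = wg[mom, kid] = cfg.mother_groom_multiplier
        # spatial affinity kernel (non-adults cluster with non-adults)
        wn = np.ones((n, n)) + np.outer(nonadult, nonadult) * (cfg.ageclass_affinity - 1.0)
        np.fill_diagonal(wn, 0.0)

        obs_days = [d for d in range(cfg.n_days) if d % 7 < cfg.obs_days_per_week]
        for day in obs_days:
            alive = np.flatnonzero(birth <= day)
            if alive.size == 0:
                continue
            na = alive.size
            vis = rng.random((n_windows, na)) >= cfg.missingness
            w_idx, a_idx = np.nonzero(vis)
            n_rows = w_idx.size
            if n_rows == 0:
                continue
            ind = alive[a_idx]
            groom = np.zeros(n_rows, dtype=bool)
            partner = np.full(n_rows, -1)
            if na >= 2 and cfg.scan_groom_prob > 0:
                groom = rng.random(n_rows) < cfg.scan_groom_prob
                gi = np.flatnonzero(groom)
                if gi.size:
                    with np.errstate(divide="ignore"):
                        logw = np.log(wg[np.ix_(ind[gi], alive)])
                    gumb = rng.gumbel(size=logw.shape)
                    partner[gi] = alive[np.argmax(logw + gumb, axis=1)]
            activity = np.where(
                groom, "grooming", rng.choice(act_names, size=n_rows, p=act_p)
            )
            is_groomer = rng.random(n_rows) < 0.5
            # neighbours within 3 m
            k = rng.binomial(3, min(cfg.neighbour_rate / 3.0, 1.0), size=n_rows)
            k = np.minimum(k, na - 1)
            with np.errstate(divide="ignore"):
                logwn = np.log(wn[np.ix_(ind, alive)])
            order = np.argsort(-(logwn + rng.gumbel(size=logwn.shape)), axis=1)
            id_alive = ids[alive]
            nbr_strings = []
            for r in range(n_rows):
                if k[r] == 0:
                    nbr_strings.append("")
                    continue
                sel = [id_alive[c] for c in order[r] if alive[c] != ind[r]][: k[r]]
                nbr_strings.append(";".join(sel))
            frames.append(pd.DataFrame({
                "day": day,
                "window": w_idx,
                "group_id": gname,
                "individual_id": ids[ind],
                "activity": activity,
                "partner_id": np.where(partner >= 0, ids[np.maximum(partner, 0)], ""),
                "partner_role": np.where(
                    groom, np.where(is_groomer, "groomee", "groomer"), "none"
                ),
                "neighbours_3m": nbr_strings,
            }))
    if not frames:
        return pd.DataFrame(columns=["day", "window", "group_id", "individual_id",
                                     "activity", "partner_id", "partner_role", "neighbours_3m"])
    return pd.concat(frames, ignore_index=True)


def generate_agonism(roster: pd.DataFrame, cfg: GeneratorConfig,
                     rng: np.random.Generator,
                     strengths: dict[str, float] | None = None) -> pd.DataFrame:
    """Dyadic within-group agonistic events with latent-strength outcomes.

    The aggressor wins with probability ``logistic(s_agg - s_vict)``; a
    configured fraction of outcomes are draws or unknown.  Event dates are
    uniform over study days.
    """
    strengths = strengths or _latent_strengths(roster, cfg, rng)
    frames = []
    for gname, sub in roster.groupby("group_id", sort=True):
        ids = sub["id"].to_numpy()
        birth = sub["birth_date"].to_numpy()
        s = np.array([strengths[i] for i in ids])
        n_events = rng.poisson(cfg.agonism_rate * cfg.n_days)
        if n_events == 0:
            continue
        dates = np.sort(rng.integers(0, cfg.n_days, n_events))
        agg = np.empty(n_events, dtype=int)
        vic = np.empty(n_events, dtype=int)
        for date in np.unique(dates):
            mask = dates == date
            m = int(mask.sum())
            alive = np.flatnonzero(birth <= date)
            if alive.size < 2:
                agg[mask] = vic[mask] = -1
                continue
            a = rng.integers(0, alive.size, m)
            v = rng.integers(0, alive.size - 1, m)
            v = v + (v >= a)
            agg[mask] = alive[a]
            vic[mask] = alive[v]
        keep = agg >= 0
        agg, vic, dates = agg[keep], vic[keep], dates[keep]
        u = rng.random(agg.size)
        p_win = expit(s[agg] - s[vic])
        win = rng.random(agg.size) < p_win
        outcome = np.where(
            u < cfg.draw_prob, "draw",
            np.where(u < cfg.draw_prob + cfg.unknown_prob, "unknown",
                     np.where(win, "win", "loss")),
        )
        frames.append(pd.DataFrame({
            "date": dates, "aggressor_id": ids[agg], "victim_id": ids[vic],
            "outcome": outcome,
        }))
    if not frames:
        return pd.DataFrame(columns=["date", "aggressor_id", "victim_id", "outcome"])
    return pd.concat(frames, ignore_index=True).sort_values(
        "date", kind="stable", ignore_index=True)


class CovariateProvider:
    """Rank, centrality and neophilia lookups built from the raw streams."""

    def __init__(self, roster, scans, agonism, neophilia, cfg: GeneratorConfig):
        self.roster = roster
        self.cfg = cfg
        self.elo = run_elo(agonism[agonism["outcome"] != "unknown"], roster,
                           k=cfg.elo_k, start_value=cfg.elo_start, curve=cfg.elo_curve)
        years = sorted(set(int(d) // cfg.days_per_year for d in scans["day"].unique())) or [0]
        pairs = []
        for gname in roster["group_id"].unique():
            for year in years:
                pairs.append(build_networks(scans, roster, year, gname,
                                            days_per_year=cfg.days_per_year))
        cent = centrality_table(pairs)
        self._cent = {(r.individual_id, r.year): (r.grooming_EC, r.spatial_EC)
                      for r in cent.itertuples(index=False)}
        self.centrality = cent
        self.neophilia = dict(zip(neophilia["id"], neophilia["neophilia"]))
        self._rank_cache: dict[tuple[str, int], dict[str, float]] = {}

    def ranks(self, group_id: str, date: int, alive_ids) -> dict[str, float]:
        """Standardized Elo ranks for all alive members of a group-date."""
        key = (group_id, int(date))
        if key not in self._rank_cache:
            series = self.elo[group_id]
            r = series.ratings_on_date(int(date), ids=alive_ids)
            sd = r.std(ddof=0)
            z = (r - r.mean()) / sd if (len(r) > 1 and sd > 0) else r * 0.0
            self._rank_cache[key] = dict(z)
        return self._rank_cache[key]

    def centrality_of(self, id_: str, year: int) -> tuple[float, float]:
        return self._cent.get((id_, year), (0.0, 0.0))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_igc(roster: pd.DataFrame, covariates: CovariateProvider,
                 cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """IGC event table with participant levels and within-IGC grooming.

    Per event: the opposing group is sampled uniformly among the other
    groups; maternal/adult participation is drawn from the adult propensity
    model; each alive non-adult's participation comes from the
    participation logistic with the configured coefficients and random
    effects; participant aggression levels from the cumulative-ordinal
    model (maternal level through the monotonic transform); within-IGC
    grooming from hurdle 1 and groomer-is-mother from hurdle 2.
    """
    c1 = cfg.true_coefficients["participation"]
    c2 = cfg.true_coefficients["aggression"]
    c3 = cfg.true_coefficients["grooming"]
    c4 = cfg.true_coefficients["mother_groomer"]
    sds = cfg.random_effect_sds
    zeta = np.asarray(c2["zeta"], dtype=float)
    thresholds = np.asarray(c2["thresholds"], dtype=float)

    groups = sorted(roster["group_id"].unique())
    by_group = {g: roster[roster["group_id"] == g] for g in groups}
    nonadults = roster[~roster["is_adult"].astype(bool)]
    mothers = sorted(set(nonadults["mother_id"]))

    # independent random-intercept draws per model family
    def re_draw(keys, sd):
        return dict(zip(keys, rng.normal(0, sd, len(keys))))

    na_ids = list(nonadults["id"])
    re_ = {
        "m1_id": re_draw(na_ids, sds["individual"]),
        "m1_fg": re_draw(groups, sds["focal_group"]),
        "m1_og": re_draw(groups, sds["opposing_group"]),
        "m2_id": re_draw(na_ids, sds["individual"]),
        "m2_fg": re_draw(groups, sds["focal_group"]),
        "m2_og": re_draw(groups, sds["opposing_group"]),
        "m3_id": re_draw(na_ids, sds["individual"]),
        "m3_mo": re_draw(mothers, sds["mother"]),
        "m3_fg": re_draw(groups, sds["focal_group"]),
        "m4_id": re_draw(na_ids, sds["individual"]),
        "m4_mo": re_draw(mothers, sds["mother"]),
        "m4_fg": re_draw(groups, sds["focal_group"]),
    }

    # --- event skeleton ---------------------------------------------------
    events = []
    for g in groups:
        counts = rng.poisson(cfg.igc_rate, cfg.n_days)
        for day in np.flatnonzero(counts):
            for _ in range(int(counts[day])):
                events.append((int(day), g))
    events.sort()
    if not events:
        return pd.DataFrame(columns=[
            "event_id", "date", "focal_group", "opposing_group", "focal_group_size",
            "opposing_group_size", "n_focal_participants", "n_opposing_participants",
            "participants", "igc_grooming"])

    rows = []  # per (non-adult, event) covariate rows
    meta = []  # per event metadata
    for e_idx, (date, focal) in enumerate(events):
        others = [g for g in groups if g != focal]
        opposing = others[int(rng.integers(len(others)))]
        sub_f = by_group[focal]
        sub_o = by_group[opposing]
        alive_f = sub_f[sub_f["birth_date"] <= date]
        alive_o = sub_o[sub_o["birth_date"] <= date]
        adults_f = alive_f[alive_f["is_adult"].astype(bool)]
        mother_set = set(nonadults["mother_id"])
        part_adults = {}
        for a in adults_f.itertuples(index=False):
            p = (cfg.maternal_participation_prob if a.id in mother_set
                 else cfg.adult_participation_prob)
            if rng.random() < p:
                part_adults[a.id] = 1 + int(rng.choice(4, p=cfg.adult_level_probs))
        n_opp_adults = int(alive_o["is_adult"].astype(bool).sum())
        n_opposing_part = int(rng.binomial(n_opp_adults, cfg.adult_participation_prob))
        ranks = covariates.ranks(focal, date, list(alive_f["id"]))
        year = date // cfg.days_per_year
        kids = alive_f[~alive_f["is_adult"].astype(bool)]
        for kid in kids.itertuples(index=False):
            gec, sec = covariates.centrality_of(kid.id, year)
            mother_level = part_adults.get(kid.mother_id, 0)
            rows.append({
                "event_idx": e_idx, "individual": kid.id, "mother": kid.mother_id,
                "sex_male": 1.0 if kid.sex == "M" else 0.0,
                "age": float(date - kid.birth_date),
                "rank": ranks.get(kid.id, 0.0),
                "neophilia": covariates.neophilia.get(kid.id, 0.5),
                "grooming_EC": gec, "spatial_EC": sec,
                "mother_participated": 1.0 if mother_level > 0 else 0.0,
                "mother_level": mother_level,
                "n_focal_participants": float(len(part_adults)),
                "n_opposing_participants": float(n_opposing_part),
                "focal_group_size": float(len(alive_f)),
                "opposing_group_size": float(len(alive_o)),
            })
        meta.append({
            "event_id": f"E{e_idx + 1:05d}", "date": date, "focal_group": focal,
            "opposing_group": opposing, "focal_group_size": len(alive_f),
            "opposing_group_size": len(alive_o),
            "n_focal_participants": len(part_adults),
            "n_opposing_participants": n_opposing_part,
            "part_adults": part_adults,
        })

    cov = pd.DataFrame(rows)
    continuous = ["age", "rank", "neophilia", "grooming_EC", "spatial_EC",
                  "n_focal_participants", "n_opposing_participants",
                  "focal_group_size", "opposing_group_size"]
    z = {c: _zscore(cov[c].to_numpy(float)) for c in continuous}
    z["sex_male"] = cov["sex_male"].to_numpy(float)
    z["mother_participated"] = cov["mother_participated"].to_numpy(float)
    n = len(cov)

    def eta_of(coeffs, extra=0.0):
        eta = np.full(n, float(coeffs.get("intercept", 0.0)))
        for name, beta in coeffs.items():
            if name in ("intercept", "zeta", "thresholds", "mo_mother_level",
                        "participants_interaction", "participation"):
                continue
            if name in z:
                eta += beta * z[name]
        if "participants_interaction" in coeffs:
            eta += coeffs["participants_interaction"] * z["n_focal_participants"] * \
                z["n_opposing_participants"]
        return eta + extra

    ind = cov["individual"].to_numpy()
    mom = cov["mother"].to_numpy()
    fg = np.array([meta[i]["focal_group"] for i in cov["event_idx"]])
    og = np.array([meta[i]["opposing_group"] for i in cov["event_idx"]])

    def re_vec(tag_id, tag_g1, keys1, tag_g2=None, keys2=None):
        v = np.array([re_[tag_id][i] for i in ind])
        v += np.array([re_[tag_g1][k] for k in keys1])
        if tag_g2 is not None:
            v += np.array([re_[tag_g2][k] for k in keys2])
        return v

    # participation (Model 1 analogue)
    eta1 = eta_of(c1, re_vec("m1_id", "m1_fg", fg, "m1_og", og))
    y_part = (rng.random(n) < expit(eta1)).astype(int)

    # aggression level of participants (Model 2 analogue)
    eta2 = eta_of(c2, re_vec("m2_id", "m2_fg", fg, "m2_og", og))
    eta2 = eta2 + c2["mo_mother_level"] * monotonic_transform(
        cov["mother_level"].to_numpy(int), zeta)
    cdf = expit(thresholds[None, :] - eta2[:, None])
    u = rng.random(n)
    level = 1 + (u[:, None] > cdf).sum(axis=1)
    level = np.where(y_part == 1, level, 0)

    # within-IGC grooming (hurdle 1 / Model 3 analogue)
    eta3 = eta_of(c3, re_vec("m3_id", "m3_fg", fg))
    eta3 = eta3 + np.array([re_["m3_mo"][m] for m in mom])
    eta3 = eta3 + c3.get("participation", 0.0) * y_part
    y_groomed = (rng.random(n) < expit(eta3)).astype(int)

    # groomer-is-mother (hurdle 2 analogue)
    eta4 = eta_of(c4, re_vec("m4_id", "m4_fg", fg))
    eta4 = eta4 + np.array([re_["m4_mo"][m] for m in mom])
    y_by_mother = ((rng.random(n) < expit(eta4)) & (y_groomed == 1)).astype(int)

    # --- assemble the event table ----------------------------------------
    adults_female = {g: list(sub[(sub["is_adult"].astype(bool)) & (sub["sex"] == "F")]["id"])
                     for g, sub in by_group.items()}
    part_strings = ["" for _ in meta]
    groom_strings = [[] for _ in meta]
    for i, m in enumerate(meta):
        parts = dict(m["part_adults"])
        mask = (cov["event_idx"] == i).to_numpy()
        for j in np.flatnonzero(mask):
            if y_part[j]:
                parts[ind[j]] = int(level[j])
            if y_groomed[j]:
                if y_by_mother[j]:
                    groomer = mom[j]
                else:
                    cands = [a for a in adults_female[m["focal_group"]] if a != mom[j]]
                    groomer = cands[int(rng.integers(len(cands)))] if cands else mom[j]
                groom_strings[i].append(f"{groomer}>{ind[j]}")
        part_strings[i] = ";".join(f"{k}:{v}" for k, v in parts.items())
    out = pd.DataFrame([{
        "event_id": m["event_id"], "date": m["date"], "focal_group": m["focal_group"],
        "opposing_group": m["opposing_group"], "focal_group_size": m["focal_group_size"],
        "opposing_group_size": m["opposing_group_size"],
        "n_focal_participants": m["n_focal_participants"],
        "n_opposing_participants": m["n_opposing_participants"],
        "participants": part_strings[i], "igc_grooming": ";".join(groom_strings[i]),
    } for i, m in enumerate(meta)])
    return out


def generate_dataset(cfg: GeneratorConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full generative model; optionally write the five CSVs + truth.

    Returns a dict with keys ``roster, neophilia, scans, agonism, igc``
    (DataFrames) and ``truth`` (the generating parameters).  Output is a
    deterministic function of ``cfg`` including its seed.
    """
    rng = np.random.default_rng(cfg.seed)
    roster = generate_population(cfg, rng)
    neophilia = generate_neophilia(roster, cfg, rng)
    strengths = _latent_strengths(roster, cfg, rng)
    scans = generate_scans(roster, cfg, rng)
    agonism = generate_agonism(roster, cfg, rng, strengths=strengths)
    cov = CovariateProvider(roster, scans, agonism, neophilia, cfg)
    igc = generate_igc(roster, cov, cfg, rng)
    truth = {
        "config": cfg.to_dict(),
        "latent_strengths": strengths,
    }
    data = {"roster": roster, "neophilia": neophilia, "scans": scans,
            "agonism": agonism, "igc": igc, "truth": truth}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("roster", "neophilia", "scans", "agonism", "igc"):
            data[name].to_csv(out / f"{name}.csv", index=False)
        (out / "truth.json").write_text(json.dumps(truth, indent=1, default=float))
    return data
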