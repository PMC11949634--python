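"""Generative model: determinism, configured probabilities, kernels."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import chi2_contingency

from igc_induction import GeneratorConfig, generate_dataset, generate_population
from igc_induction.errors import ConfigError
from igc_induction.synthetic import (
    ACTIVITIES,
    CovariateProvider,
    generate_agonism,
    generate_igc,
    generate_neophilia,
    generate_scans,
)

from conftest import SMALL_CFG, toy_roster


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("cohort_sizes", (0, 5, 5)),
        ("igc_rate", -0.1),
        ("draw_prob", 1.5),
        ("scan_interval", 5),  # <= scan_window
        ("n_groups", 1),
        ("adult_level_probs", (0.5, 0.5, 0.0, 0.1)),
    ])
    def test_invalid_field_raises_named_config_error(self, field, value):
        with pytest.raises(ConfigError) as exc:
            GeneratorConfig(**{field: value})
        assert exc.value.field in (field, "cohort_sizes", "scan_interval",
                                   "adult_level_probs")


class TestPopulation:
    def test_group_and_cohort_counts_match_config(self):
        cfg = GeneratorConfig(cohort_sizes=(10, 10, 10), seed=1)
        roster = generate_population(cfg)
        nonadults = roster[~roster["is_adult"]]
        assert roster["group_id"].nunique() == 3
        assert len(nonadults) == 30
        assert nonadults.groupby("group_id").size().tolist() == [10, 10, 10]

    def test_every_nonadult_has_a_mother_in_its_group(self):
        roster = generate_population(GeneratorConfig(seed=2))
        group = dict(zip(roster["id"], roster["group_id"]))
        for row in roster[~roster["is_adult"]].itertuples(index=False):
            assert row.mother_id
            assert group[row.mother_id] == row.group_id

    def test_same_seed_identical_rosters(self):
        cfg = GeneratorConfig(seed=7)
        r1 = generate_population(cfg)
        r2 = generate_population(GeneratorConfig(seed=7))
        pd.testing.assert_frame_equal(r1, r2)


class TestDeterminism:
    def test_full_dataset_byte_identical_under_same_seed(self, tmp_path):
        cfg = GeneratorConfig(**SMALL_CFG)
        generate_dataset(cfg, out_dir=tmp_path / "a")
        generate_dataset(GeneratorConfig(**SMALL_CFG), out_dir=tmp_path / "b")
        for name in ("roster", "neophilia", "scans", "agonism", "igc"):
            assert (tmp_path / "a" / f"{name}.csv").read_bytes() == \
                (tmp_path / "b" / f"{name}.csv").read_bytes()

    def test_different_seed_differs(self, tmp_path):
        cfg1 = dict(SMALL_CFG)
        cfg2 = dict(SMALL_CFG, seed=43)
        generate_dataset(GeneratorConfig(**cfg1), out_dir=tmp_path / "a")
        generate_dataset(GeneratorConfig(**cfg2), out_dir=tmp_path / "b")
        assert (tmp_path / "a" / "igc.csv").read_bytes() != \
            (tmp_path / "b" / "igc.csv").read_bytes()

    def test_truth_file_carries_generating_parameters(self, small_dir):
        truth = json.loads((small_dir / "truth.json").read_text())
        coeffs = truth["config"]["true_coefficients"]
        assert "participation" in coeffs and "aggression" in coeffs
        assert truth["config"]["seed"] == SMALL_CFG["seed"]
        assert "latent_strengths" in truth


class TestScans:
    def test_window_count_per_day(self):
        """10 h observed at 30-min intervals -> 20 scan windows."""
        cfg = GeneratorConfig(cohort_sizes=(3, 3, 3), n_days=1, seed=0)
        scans = generate_scans(generate_population(cfg), cfg, np.random.default_rng(0))
        assert cfg.n_scan_windows_per_day == 20
        assert sorted(scans["window"].unique()) == list(range(20))

    def test_activities_from_legal_alphabet(self, small_dataset):
        assert set(small_dataset.scans["activity"]) <= set(ACTIVITIES)

    def test_unit_mother_multiplier_mixes_partners_at_baseline_rate(self):
        """With multiplier 1 mother-offspring grooming is at chance level."""
        cfg = GeneratorConfig(cohort_sizes=(8, 8, 8), n_days=40, seed=3,
                              mother_groom_multiplier=1.0, scan_groom_prob=0.3)
        roster = generate_population(cfg)
        scans = generate_scans(roster, cfg, np.random.default_rng(3))
        mother = dict(zip(roster["id"], roster["mother_id"]))
        groom = scans[(scans["activity"] == "grooming")
                      & scans["individual_id"].isin(mother)
                      & (scans["individual_id"].str.contains("N"))]
        is_mom = (groom["partner_id"].to_numpy()
                  == np.array([mother[i] for i in groom["individual_id"]]))
        # chance share: the mother is one of the n_alive - 1 possible partners
        group_of = dict(zip(roster["id"], roster["group_id"]))
        alive_per_day = {
            (g, d): int((sub["birth_date"] <= d).sum())
            for g, sub in roster.groupby("group_id")
            for d in groom["day"].unique()
        }
        expected = float(np.mean([
            1.0 / (alive_per_day[(group_of[i], d)] - 1)
            for i, d in zip(groom["individual_id"], groom["day"])
        ]))
        observed = is_mom.mean()
        table = np.array([[is_mom.sum(), len(is_mom) - is_mom.sum()],
                          [expected * len(is_mom), (1 - expected) * len(is_mom)]])
        assert chi2_contingency(table).pvalue > 0.01
        assert observed == pytest.approx(expected, abs=0.03)

    def test_large_multiplier_makes_mother_the_modal_partner(self, small_dataset):
        roster = small_dataset.roster
        scans = small_dataset.scans
        mother = dict(zip(roster["id"], roster["mother_id"]))
        kids = roster.loc[~roster["is_adult"], "id"]
        modal_is_mother = 0
        n_observed = 0
        for kid in kids:
            partners = scans[(scans["individual_id"] == kid)
                             & (scans["activity"] == "grooming")]["partner_id"]
            if len(partners) < 10:  # born after the observation window
                continue
            n_observed += 1
            if partners.mode().iloc[0] == mother[kid]:
                modal_is_mother += 1
        assert n_observed >= 10
        assert modal_is_mother >= 0.8 * n_observed

    def test_missingness_thins_records(self):
        base = GeneratorConfig(cohort_sizes=(5, 5, 5), n_days=10, seed=1)
        holey = GeneratorConfig(cohort_sizes=(5, 5, 5), n_days=10, seed=1,
                                missingness=0.5)
        s1 = generate_scans(generate_population(base), base, np.random.default_rng(1))
        s2 = generate_scans(generate_population(holey), holey, np.random.default_rng(1))
        assert len(s2) < 0.6 * len(s1)


class TestAgonism:
    def test_equal_strengths_win_rate_half(self):
        roster = toy_roster(10)
        cfg = GeneratorConfig(cohort_sizes=(10, 1, 1), n_days=100, agonism_rate=20.0,
                              draw_prob=0.0, unknown_prob=0.0, seed=5)
        ev = generate_agonism(roster, cfg, np.random.default_rng(5),
                              strengths={i: 0.0 for i in roster["id"]})
        assert (ev["outcome"] == "win").mean() == pytest.approx(0.5, abs=0.02)

    def test_four_point_strength_gap_wins_at_logistic_rate(self):
        roster = toy_roster(2)
        cfg = GeneratorConfig(cohort_sizes=(2, 1, 1), n_days=200, agonism_rate=20.0,
                              draw_prob=0.0, unknown_prob=0.0, seed=6)
        strengths = {"G1N00": 4.0, "G1N01": 0.0}
        ev = generate_agonism(roster, cfg, np.random.default_rng(6), strengths=strengths)
        strong_aggressor = ev["aggressor_id"] == "G1N00"
        wins_strong = (ev.loc[strong_aggressor, "outcome"] == "win").mean()
        losses_weak = (ev.loc[~strong_aggressor, "outcome"] == "loss").mean()
        p_strong = (wins_strong + losses_weak) / 2
        assert p_strong == pytest.approx(expit(4.0), abs=0.01)  # 0.982

    def test_draw_prob_one_gives_only_draws(self):
        roster = toy_roster(5)
        cfg = GeneratorConfig(cohort_sizes=(5, 1, 1), n_days=20, agonism_rate=5.0,
                              draw_prob=1.0, unknown_prob=0.0, seed=7)
        ev = generate_agonism(roster, cfg, np.random.default_rng(7))
        assert (ev["outcome"] == "draw").all()

    def test_outcomes_from_legal_alphabet(self, small_dataset):
        assert set(small_dataset.agonism["outcome"]) <= {"win", "loss", "draw", "unknown"}


def _igc_with_coeffs(coeff_updates, seed=8, **cfg_kw):
    defaults = dict(cohort_sizes=(8, 8, 8), n_days=50, igc_rate=0.8,
                    agonism_rate=2.0, seed=seed)
    defaults.update(cfg_kw)
    cfg = GeneratorConfig(**defaults)
    for model, upd in coeff_updates.items():
        cfg.true_coefficients[model].update(upd)
    rng = np.random.default_rng(cfg.seed)
    roster = generate_population(cfg, rng)
    neo = generate_neophilia(roster, cfg, rng)
    scans = generate_scans(roster, cfg, rng)
    ag = generate_agonism(roster, cfg, rng)
    cov = CovariateProvider(roster, scans, ag, neo, cfg)
    return generate_igc(roster, cov, cfg, rng), roster, cfg


class TestIGC:
    def test_null_model_participation_rate_half(self):
        zero1 = {k: 0.0 for k in GeneratorConfig().true_coefficients["participation"]}
        igc, roster, cfg = _igc_with_coeffs(
            {"participation": zero1}, n_days=80, igc_rate=1.2,
            random_effect_sds={"individual": 0.0, "focal_group": 0.0,
                               "opposing_group": 0.0, "mother": 0.0})
        nonadults = set(roster.loc[~roster["is_adult"], "id"])
        n_part = n_rows = 0
        for row in igc.itertuples(index=False):
            present = roster[(roster["group_id"] == row.focal_group)
                             & (~roster["is_adult"])
                             & (roster["birth_date"] <= row.date)]
            ids = {p.split(":")[0] for p in row.participants.split(";") if p}
            n_part += len(ids & nonadults)
            n_rows += len(present)
        assert n_rows > 1200
        se = 0.5 / np.sqrt(n_rows)
        assert n_part / n_rows == pytest.approx(0.5, abs=3 * se)

    def test_age_effect_makes_participation_monotone_across_age_quintiles(self):
        igc, roster, cfg = _igc_with_coeffs({"participation": {"age": 2.0}})
        birth = dict(zip(roster["id"], roster["birth_date"]))
        nonadults = set(roster.loc[~roster["is_adult"], "id"])
        ages, outcomes = [], []
        for row in igc.itertuples(index=False):
            members = roster[(roster["group_id"] == row.focal_group)
                             & (~roster["is_adult"])
                             & (roster["birth_date"] <= row.date)]
            ids = {p.split(":")[0] for p in row.participants.split(";") if p}
            for kid in members["id"]:
                ages.append(row.date - birth[kid])
                outcomes.append(1 if kid in ids else 0)
        df = pd.DataFrame({"age": ages, "y": outcomes})
        df["q"] = pd.qcut(df["age"], 5, labels=False, duplicates="drop")
        means = df.groupby("q")["y"].mean()
        assert (means.diff().dropna() > -0.02).all()
        assert means.iloc[-1] > means.iloc[0] + 0.2

    def test_impossible_grooming_hurdle_yields_no_grooming_records(self):
        igc, _, _ = _igc_with_coeffs({"grooming": {"intercept": -40.0,
                                                   "participation": 0.0}})
        assert (igc["igc_grooming"] == "").all()

    def test_participant_levels_in_legal_range(self, small_dataset):
        for pmap in small_dataset.participants.values():
            assert all(1 <= lev <= 4 for lev in pmap.values())
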