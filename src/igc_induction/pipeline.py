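"""Pipeline orchestration: generate -> ingest -> covariates -> fit -> report.

The four canonical models are registered here with the term structures and
default sampler settings used for the study system:

m1  participation (yes/no), Bernoulli; age, sex, rank, neophilia, grooming
    and spatial EC, maternal participation, participant counts of both
    sides with their interaction, both group sizes; random intercepts for
    individual nested in focal group, crossed with opposing group;
    4 chains x 2500 iterations.
m2  aggression level (1-4) of participants, cumulative ordinal; as m1 but
    maternal aggression level (0-4) enters as a monotonic predictor;
    4 chains x 4000 iterations.
m3  groomed during the IGC (yes/no), Bernoulli, all non-adults;
    participation plus sex, age, rank, neophilia, ECs, focal group size
    and participant counts; id nested in focal group; 4 chains x 3500.
m4  nested double hurdle on participants (groomed; groomed by mother);
    sex, age, rank; id in mother in focal group; 8 chains x 500.

Test-scale sampler settings are passed through ``sampler_overrides``; the
registry holds the full-scale defaults.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .diagnostics import bayes_r2, residual_acf
from .errors import ConfigError, DataError
from .glmm import BernoulliGLMM, OrdinalGLMM
from .hurdle import DoubleHurdleModel, DoubleHurdleResults
from .observations import build_event_panel, load_tables
from .results import PosteriorResult
from .synthetic import generate_dataset

__all__ = ["RunConfig", "run_pipeline", "describe_dataset", "build_model",
           "model_r2", "model_residual_acf", "MODEL_IDS"]

log = logging.getLogger("igc_induction")

MODEL_IDS = ("m1", "m2", "m3", "m4")

_M1_FIXED = ("age", "sex_male", "rank", "neophilia", "grooming_EC", "spatial_EC",
             "mother_participated", "n_focal_participants", "n_opposing_participants",
             "focal_group_size", "opposing_group_size")
_M2_FIXED = tuple(t for t in _M1_FIXED if t != "mother_participated")
_M3_FIXED = ("participation", "sex_male", "age", "rank", "neophilia", "grooming_EC",
             "spatial_EC", "focal_group_size", "n_focal_participants",
             "n_opposing_participants")
_INTERACTION = (("n_focal_participants", "n_opposing_participants"),)
_M1_RE = ("focal_group", "focal_group:individual", "opposing_group")
_M3_RE = ("focal_group", "focal_group:individual")

_DEFAULT_SAMPLER = {
    "m1": {"chains": 4, "iterations": 2500},
    "m2": {"chains": 4, "iterations": 4000},
    "m3": {"chains": 4, "iterations": 3500},
    "m4": {"chains": 8, "iterations": 500},
}


def build_model(model_id: str, panel: pd.DataFrame, **sampler_kw):
    """Construct the registered model ``m1..m4`` against a full event panel.

    m2 and m4 are fitted on the participant subset of the panel without
    re-standardizing, so coefficients share the full panel's covariate
    scale across models.
    """
    kw = dict(_DEFAULT_SAMPLER.get(model_id, {}))
    kw.update(sampler_kw)
    if model_id == "m1":
        return BernoulliGLMM(panel, "participation", fixed=_M1_FIXED,
                             interactions=_INTERACTION, random_intercepts=_M1_RE, **kw)
    if model_id == "m2":
        sub = panel[panel["participation"] == 1].reset_index(drop=True)
        if len(sub) == 0:
            raise DataError("no participant rows for the aggression-level model")
        return OrdinalGLMM(sub, "level", n_categories=4, fixed=_M2_FIXED,
                           interactions=_INTERACTION, monotonic=(("mother_level", 4),),
                           random_intercepts=_M1_RE, **kw)
    if model_id == "m3":
        return BernoulliGLMM(panel, "groomed", fixed=_M3_FIXED,
                             interactions=(), random_intercepts=_M3_RE, **kw)
    if model_id == "m4":
        sub = panel[panel["participation"] == 1].reset_index(drop=True)
        return DoubleHurdleModel(sub, **kw)
    raise ConfigError("models", f"unknown model id {model_id!r}")


def model_r2(result: PosteriorResult, mode: str = "conditional"):
    """Draw-wise Bayesian R2 for a fitted GLMM.

    Bernoulli models use the fitted-probability variance decomposition;
    ordinal models use the latent-logit convention (residual variance
    pi^2/3) and are labelled as such in the summary.
    """
    if result.model.spec.response == "bernoulli":
        fitted = result.fitted_probability(mode)
        return bayes_r2(fitted, mode=mode, scale="probability")
    eta = result.linear_predictor(mode)
    return bayes_r2(eta, mode=mode, scale="latent")


def model_residual_acf(result: PosteriorResult, panel: pd.DataFrame,
                       max_lag: int = 5) -> pd.DataFrame:
    """Lag-k autocorrelation of posterior-mean Pearson residuals by individual."""
    if result.model.spec.response == "bernoulli":
        y = result.model.design.y
        p = result.fitted_probability("conditional").mean(axis=0)
        resid = (y - p) / np.sqrt(np.maximum(p * (1 - p), 1e-12))
    else:
        y = result.model.design.y + 1
        probs = result.category_probabilities("conditional").mean(axis=0)
        k = np.arange(1, probs.shape[1] + 1)
        mean = probs @ k
        var = probs @ (k**2) - mean**2
        resid = (y - mean) / np.sqrt(np.maximum(var, 1e-12))
    mp = result.model.panel
    return residual_acf(resid, mp["date"].to_numpy(), mp["individual"].to_numpy(),
                        max_lag=max_lag)


def describe_dataset(panel: pd.DataFrame) -> dict:
    """Headline descriptive statistics of the event panel.

    Percentages are on the 0-100 scale: share of IGCs with at least one
    non-adult participant; distribution of aggression levels among
    participant rows; maternal co-participation among participant rows;
    participant sex split; mean participant age in years.
    """
    if len(panel) == 0:
        raise DataError("empty panel")
    n_igcs = int(panel["event_id"].nunique())
    by_event = panel.groupby("event_id")["participation"].max()
    part = panel[panel["participation"] == 1]
    out = {
        "n_igcs": n_igcs,
        "pct_igcs_with_nonadult_participation": float(100 * by_event.mean()),
        "n_participant_rows": int(len(part)),
    }
    level_names = {1: "non_aggressive", 2: "stationary", 3: "active", 4: "physical"}
    for lev, name in level_names.items():
        out[f"pct_level_{name}"] = (
            float(100 * (part["level"] == lev).mean()) if len(part) else np.nan)
    out["pct_mother_coparticipation"] = (
        float(100 * part["mother_participated"].mean()) if len(part) else np.nan)
    out["pct_participants_male"] = (
        float(100 * part["sex_male"].mean()) if len(part) else np.nan)
    out["pct_participants_female"] = (
        float(100 - out["pct_participants_male"]) if len(part) else np.nan)
    age = part["age_raw"] if "age_raw" in part.columns else part["age"]
    out["mean_participant_age_years"] = float(age.mean() / 365.0) if len(part) else np.nan
    return out


@dataclass
class RunConfig:
    """Configuration of one pipeline run (synthetic or on-disk data)."""

    generator: GeneratorConfig | None = None
    data_dir: str | None = None
    reference: str = "all_nonadults"
    models: tuple[str, ...] = MODEL_IDS
    sampler_overrides: dict = field(default_factory=dict)  # model_id -> kwargs
    out_dir: str = "igc_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = set(self.models) - set(MODEL_IDS)
        if unknown:
            raise ConfigError("models", f"unknown model id(s) {sorted(unknown)}")
        if self.generator is None and self.data_dir is None:
            raise ConfigError("data_dir", "need either a generator config or a data dir")
        if self.reference not in ("all_nonadults", "juveniles"):
            raise ConfigError("reference", f"unknown reference {self.reference!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages in dependency order; returns the manifest.

    Writes per-stage outputs (tables, posterior summaries, diagnostics,
    descriptives) under ``cfg.out_dir`` and a ``manifest.json`` recording
    input hashes, seeds, row counts and output paths.  A stage failure
    marks the stage failed in the manifest and skips downstream stages.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "outputs": {}}
    t_start = time.time()

    def stage(name):
        def deco(fn):
            def run(*a, **k):
                t0 = time.time()
                try:
                    res = fn(*a, **k)
                    manifest["stages"][name] = {"status": "ok",
                                                "seconds": round(time.time() - t0, 2)}
                    return res
                except Exception as e:  # noqa: BLE001 - recorded and re-raised
                    manifest["stages"][name] = {"status": "failed", "error": str(e)}
                    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
                    raise
            return run
        return deco

    @stage("data")
    def _data():
        if cfg.generator is not None:
            data_dir = out / "data"
            generate_dataset(cfg.generator, out_dir=data_dir)
        else:
            data_dir = Path(cfg.data_dir)
        manifest["inputs"] = {p.name: _sha256(p) for p in sorted(data_dir.glob("*.csv"))}
        return load_tables(data_dir)

    @stage("panel")
    def _panel(ds):
        panel = build_event_panel(ds, reference=cfg.reference)
        path = out / "panel.csv"
        panel.to_csv(path, index=False)
        manifest["outputs"]["panel"] = str(path)
        manifest["panel_rows"] = len(panel)
        return panel

    @stage("describe")
    def _describe(panel):
        desc = describe_dataset(panel)
        path = out / "descriptives.json"
        path.write_text(json.dumps(desc, indent=1))
        manifest["outputs"]["descriptives"] = str(path)
        return desc

    ds = _data()
    panel = _panel(ds)
    _describe(panel)

    results: dict = {}
    for mid in cfg.models:
        @stage(f"fit_{mid}")
        def _fit(mid=mid):
            model = build_model(mid, panel, **cfg.sampler_overrides.get(mid, {}))
            res = model.fit(seed=cfg.seed + int(mid[1]))
            summ = res.summary(ess=False)
            path = out / f"{mid}_summary.csv"
            summ.to_csv(path)
            manifest["outputs"][f"{mid}_summary"] = str(path)
            if isinstance(res, DoubleHurdleResults):
                auc_path = out / f"{mid}_auc.csv"
                res.auc_table().to_csv(auc_path, index=False)
                manifest["outputs"][f"{mid}_auc"] = str(auc_path)
            else:
                _, r2c = model_r2(res, "conditional")
                _, r2m = model_r2(res, "marginal")
                diag_path = out / f"{mid}_r2.json"
                diag_path.write_text(json.dumps({"conditional": r2c, "marginal": r2m},
                                                indent=1))
                manifest["outputs"][f"{mid}_r2"] = str(diag_path)
            return res
        results[mid] = _fit()

    manifest["total_seconds"] = round(time.time() - t_start, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    manifest["results"] = results
    return manifest
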