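"""End-to-end orchestration: simulate/load -> sleep -> FA -> univariate -> PLS-C.

A single :class:`PipelineConfig` (YAML-loadable) drives the whole analysis:
data come either from the synthetic cohort generator or from a directory of
delimited-text tables; sleep indices and actigraphy summaries are computed
per subject; ROI FA is aggregated into global and callosal FA; the
covariate-adjusted univariate battery and the group-wise PLS-C are run; and a
machine-readable :class:`RunReport` (JSON + TSV tables) is written with full
provenance (config hash, seed, iteration counts) and per-rule exclusion
accounting.  Identical config + seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .sleep import (
    ActigraphyRecording,
    KarolinskaResponse,
    RestInterval,
    compute_awi,
    compute_dsi,
    score_epochs,
    summarize_sleep,
)
from .synthetic import SLEEP_MEASURES, SyntheticCohort, SyntheticCohortConfig, generate_cohort
from .univariate import correlation_family, glm_group_test
from .wm import derive_fa
from .plsc import groupwise_plsc, PLSC

logger = logging.getLogger("uhrsleepwm")

BASE_COVARIATES = ["age", "sex", "abs_motion", "rel_motion"]

# Post-hoc confounder sets, each rerun separately on top of the base set.
DEFAULT_CONFOUNDER_SETS = {
    "none": [],
    "antipsychotics": ["antipsychotics"],
    "sleep_medication": ["sleep_med"],
    "substance_composite": ["substance_use"],
    "depressive_total": ["madrs"],
    "uhr_composite": ["caarms"],
}

REQUIRED_COVARIATE_COLUMNS = ["group"] + BASE_COVARIATES
KSQ_COLUMNS = ["subject_id", "period"] + list("abcdefg")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    outdir: str = "pipeline_out"
    seed: int = 0
    input_dir: Optional[str] = None          # load data instead of simulating
    simulate: dict = field(default_factory=dict)  # SyntheticCohortConfig overrides
    period: str = "last_4_weeks"
    n_perm: int = 1000
    n_boot: int = 1000
    bootstrap_B: int = 1000
    confounder_sets: dict = field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDER_SETS))
    confounder_sweep_plsc: bool = False
    antipsychotic_free: bool = False         # sensitivity filter on patients

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir")  # analysis-irrelevant: same config elsewhere = same run
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CohortData:
    """In-memory cohort: covariate table, ROI FA, questionnaires, actigraphy."""

    covariates: pd.DataFrame
    roi_fa: pd.DataFrame
    responses: list
    actigraphy: dict


def _require_columns(df: pd.DataFrame, cols, fname: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{fname}: missing required column(s) {missing}")


def load_cohort_dir(path) -> CohortData:
    """Load a delimited-text cohort directory (as written by ``to_dir``)."""
    p = Path(path)
    cov = pd.read_csv(p / "covariates.csv")
    _require_columns(cov, ["subject_id"] + REQUIRED_COVARIATE_COLUMNS, "covariates.csv")
    cov = cov.set_index("subject_id")
    roi = pd.read_csv(p / "roi_fa.csv")
    _require_columns(roi, ["subject_id"], "roi_fa.csv")
    roi = roi.set_index("subject_id")
    ksq = pd.read_csv(p / "ksq.csv")
    _require_columns(ksq, KSQ_COLUMNS, "ksq.csv")
    responses = []
    for i, row in ksq.iterrows():
        items = {}
        for k in "abcdefg":
            v = row[k]
            items[k] = None if pd.isna(v) else int(v)
        try:
            responses.append(KarolinskaResponse(
                subject_id=str(row["subject_id"]), period=str(row["period"]),
                items=items))
        except ValueError as exc:
            raise ValueError(f"ksq.csv row {i}: {exc}") from exc
    diary = pd.read_csv(p / "diary.csv", parse_dates=["bed_time", "rise_time"])
    _require_columns(diary, ["subject_id", "bed_time", "rise_time"], "diary.csv")
    acti = pd.read_csv(p / "actigraphy.csv", parse_dates=["timestamp"])
    _require_columns(acti, ["subject_id", "timestamp", "counts"], "actigraphy.csv")
    recordings = {}
    diary_map = diary.set_index("subject_id")
    for sid, sub in acti.groupby("subject_id", sort=False):
        if sid not in diary_map.index:
            raise ValueError(f"diary.csv: no rest interval for subject {sid!r}")
        rest = RestInterval(bed_time=diary_map.loc[sid, "bed_time"],
                            rise_time=diary_map.loc[sid, "rise_time"])
        recordings[str(sid)] = ActigraphyRecording(
            epochs=pd.DatetimeIndex(sub["timestamp"]),
            counts=sub["counts"].to_numpy(float), rest=rest)
    return CohortData(covariates=cov, roi_fa=roi, responses=responses,
                      actigraphy=recordings)


def sleep_table(data: CohortData, period: str = "last_4_weeks"):
    """Per-subject sleep measures plus named exclusions.

    Returns (summary frame indexed by subject, exclusions frame).  DSI/AWI
    come from the questionnaire of the requested recall period; the
    actigraphy measures from Cole-Kripke scoring of the diary rest interval.
    A subject with a missing questionnaire item has a missing index
    (excluded listwise downstream); a night scored with no sleep at all is
    flagged and its actigraphy measures set missing.
    """
    by_subject = {r.subject_id: r for r in data.responses if r.period == period}
    rows, exclusions = [], []
    for sid in data.covariates.index:
        sid = str(sid)
        row = {"subject_id": sid, "dsi": np.nan, "awi": np.nan,
               "tst": np.nan, "waso": np.nan, "se": np.nan, "sfi": np.nan,
               "no_sleep_flag": False}
        resp = by_subject.get(sid)
        if resp is None:
            exclusions.append({"subject_id": sid, "rule": "missing_questionnaire"})
        else:
            dsi, awi = compute_dsi(resp), compute_awi(resp)
            if dsi is None:
                exclusions.append({"subject_id": sid, "rule": "missing_dsi_item"})
            else:
                row["dsi"] = dsi
            if awi is None:
                exclusions.append({"subject_id": sid, "rule": "missing_awi_item"})
            else:
                row["awi"] = awi
        rec = data.actigraphy.get(sid)
        if rec is None:
            exclusions.append({"subject_id": sid, "rule": "missing_actigraphy"})
        else:
            summ = summarize_sleep(score_epochs(rec), rec.rest)
            if summ.no_sleep:
                row["no_sleep_flag"] = True
                exclusions.append({"subject_id": sid, "rule": "no_sleep_scored"})
            else:
                row.update({"tst": summ.tst, "waso": summ.waso,
                            "se": summ.se, "sfi": summ.sfi})
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("subject_id")
    excl = pd.DataFrame(exclusions, columns=["subject_id", "rule"])
    return summary, excl


def build_analysis_table(data: CohortData, period: str = "last_4_weeks"):
    """Merged covariates + derived FA + sleep measures, with exclusions."""
    summary, excl = sleep_table(data, period=period)
    roi = data.roi_fa.copy()
    roi.index = roi.index.astype(str)
    derived = derive_fa(roi)
    cov = data.covariates.copy()
    cov.index = cov.index.astype(str)
    merged = cov.join(derived).join(roi).join(summary)
    return merged, excl


def _analysis_complete(merged: pd.DataFrame, cols) -> pd.DataFrame:
    return merged.dropna(subset=list(cols))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written to disk)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "n_boot": cfg.n_boot,
        "stages": {},
    }
    rng_seeds = np.random.SeedSequence(cfg.seed).generate_state(8)

    # --- stage 1: data -----------------------------------------------------
    if cfg.input_dir:
        data = load_cohort_dir(cfg.input_dir)
        report["stages"]["data"] = {"source": str(cfg.input_dir)}
    else:
        sim_cfg = SyntheticCohortConfig(**{**cfg.simulate, "seed": cfg.seed})
        cohort = generate_cohort(sim_cfg)
        cohort.to_dir(out / "cohort")
        data = CohortData(covariates=cohort.covariates, roi_fa=cohort.roi_fa,
                          responses=cohort.responses, actigraphy=cohort.actigraphy)
        report["stages"]["data"] = {
            "source": "simulated",
            "n_patients": sim_cfg.n_patients, "n_controls": sim_cfg.n_controls,
        }
    n_cohort = len(data.covariates)

    # --- stage 2+3: sleep + FA + merge ------------------------------------
    merged, excl = build_analysis_table(data, period=cfg.period)
    merged.to_csv(out / "merged.csv")
    excl.to_csv(out / "exclusions.tsv", sep="\t", index=False)
    report["stages"]["sleep_fa"] = {
        "n_cohort": n_cohort,
        "n_excluded_rules": excl["rule"].value_counts().to_dict(),
    }

    if cfg.antipsychotic_free and "antipsychotics" in merged.columns:
        drop = (merged["group"] == "patient") & (merged["antipsychotics"] == 1)
        merged = merged[~drop]
        report["stages"]["sleep_fa"]["antipsychotic_free_dropped"] = int(drop.sum())

    merged["group_code"] = (merged["group"] == "patient").astype(int)
    analysis_cols = ["global_fa", "callosal_fa", *SLEEP_MEASURES, *BASE_COVARIATES]
    complete = _analysis_complete(merged, analysis_cols)
    report["stages"]["sleep_fa"]["n_complete"] = int(len(complete))
    # accounting identity: every dropped subject is attributed to a rule
    report["stages"]["sleep_fa"]["n_dropped_listwise"] = int(
        len(merged) - len(complete))

    # --- stage 4: univariate -----------------------------------------------
    glm_rows = []
    for var in ("global_fa", "callosal_fa"):
        res = glm_group_test(complete[var], complete["group_code"],
                             complete[BASE_COVARIATES])
        glm_rows.append({"analysis": "glm_group", "y": var, "F": res.f_stat,
                         "df_num": res.df_num, "df_den": res.df_den,
                         "p": res.p_value})
    glm_frame = pd.DataFrame(glm_rows)

    fam_frames = []
    subsets = {"ALL": complete, "UHR": complete[complete["group"] == "patient"],
               "HC": complete[complete["group"] == "control"]}
    fam_seed = int(rng_seeds[0])
    for name, sub in subsets.items():
        fam = correlation_family(
            sub, x_cols=("global_fa", "callosal_fa"), y_cols=SLEEP_MEASURES,
            cov_cols=BASE_COVARIATES, B=cfg.bootstrap_B, seed=fam_seed)
        fam.insert(0, "analysis", name)
        fam.insert(1, "covariate_set", "none")
        fam_frames.append(fam)

    # post-hoc confounder sweep: each extra covariate set separately,
    # uncorrected beyond its own family
    for set_name, extra in cfg.confounder_sets.items():
        if set_name == "none" or not extra:
            continue
        cols_ok = [c for c in extra if c in complete.columns]
        if len(cols_ok) != len(extra):
            logger.warning("confounder set %s: missing columns", set_name)
            continue
        sub = _analysis_complete(complete, extra)
        sub = sub[sub["group"] == "patient"]
        if len(sub) < len(BASE_COVARIATES) + len(extra) + 4:
            continue
        fam = correlation_family(
            sub, x_cols=("global_fa", "callosal_fa"), y_cols=SLEEP_MEASURES,
            cov_cols=BASE_COVARIATES + extra, B=cfg.bootstrap_B, seed=fam_seed)
        fam.insert(0, "analysis", "UHR")
        fam.insert(1, "covariate_set", set_name)
        fam_frames.append(fam)

    univariate = pd.concat([glm_frame, pd.concat(fam_frames, ignore_index=True)],
                           ignore_index=True)
    univariate.to_csv(out / "univariate_results.tsv", sep="\t", index=False)
    report["stages"]["univariate"] = {"n_tests": int(len(univariate))}

    # --- stage 5: PLS-C ----------------------------------------------------
    roi_cols = [c for c in data.roi_fa.columns]
    plsc_input = complete
    gw = groupwise_plsc(
        plsc_input[roi_cols], plsc_input[list(SLEEP_MEASURES)],
        plsc_input["group"].to_numpy(), cov=plsc_input[BASE_COVARIATES],
        n_perm=cfg.n_perm, n_boot=cfg.n_boot, seed=int(rng_seeds[1]),
        x_names=roi_cols, y_names=list(SLEEP_MEASURES))
    pooled = PLSC.from_dataframe(plsc_input, x_cols=roi_cols,
                                 y_cols=list(SLEEP_MEASURES),
                                 cov_cols=BASE_COVARIATES)
    pooled_res = pooled.fit(n_perm=cfg.n_perm, n_boot=cfg.n_boot,
                            seed=int(rng_seeds[2]))
    plsc_payload = {
        "pooled": pooled_res.to_dict(),
        "contrast_p": gw.contrast_p,
        "contrast_inertia": gw.contrast_inertia,
        "within": {str(g): r.to_dict() for g, r in gw.within.items()},
    }
    (out / "plsc_result.json").write_text(
        json.dumps(plsc_payload, indent=1, sort_keys=True))
    tables = []
    for g, r in gw.within.items():
        t = r.salience_table()
        t.insert(0, "analysis", str(g))
        tables.append(t)
    pd.concat(tables, ignore_index=True).to_csv(
        out / "salience_table.tsv", sep="\t", index=False)
    report["stages"]["plsc"] = {
        "pooled_p_omnibus": pooled_res.p_omnibus,
        "contrast_p": gw.contrast_p,
        "within_p_omnibus": {str(g): r.p_omnibus for g, r in gw.within.items()},
    }

    if cfg.confounder_sweep_plsc:
        sweep = {}
        for set_name, extra in cfg.confounder_sets.items():
            if set_name == "none" or not extra:
                continue
            if any(c not in complete.columns for c in extra):
                continue
            sub = _analysis_complete(complete, extra)
            model = PLSC.from_dataframe(
                sub, x_cols=roi_cols, y_cols=list(SLEEP_MEASURES),
                cov_cols=BASE_COVARIATES + extra)
            res = model.fit(n_perm=cfg.n_perm, n_boot=cfg.n_boot,
                            seed=int(rng_seeds[3]))
            sweep[set_name] = {"p_omnibus": res.p_omnibus,
                               "p_lv": np.asarray(res.p_lv).tolist()}
        report["stages"]["plsc_confounder_sweep"] = sweep

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
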