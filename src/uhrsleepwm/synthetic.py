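"""Synthetic two-group cohort with planted brain-sleep covariance.

Generates complete datasets with the statistical structure the analysis
pipeline assumes: a patient/control cohort with covariates (age, sex, scanner
motion), a 48-ROI FA table with a group deficit and covariate effects, a
per-subject latent sleep-disturbance score z ~ N(0, latent_sd) that loads
sparsely onto a chosen ROI subset (FA units per latent s.d.) and onto the six
sleep-wake measures (each on its natural scale), Karolinska questionnaire
items produced by a latent-Gaussian ordinal (probit-style) model, and 24-h
1-min-epoch actigraphy produced by a two-state (sleep/wake) bout process
modulating Poisson activity counts.

Setting both loadings vectors to zero yields a null cohort: the latent score
then influences nothing, so FA and the sleep measures are conditionally
independent given group and covariates.  The planted latent score of every
subject is recorded for recovery tests.

Reproducibility: each subject owns an independent random stream spawned from
the master seed, so regenerating with the same config and seed reproduces the
dataset bit-for-bit regardless of generation order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import CALLOSAL_LABELS, JHU_LABELS
from .sleep import ActigraphyRecording, KarolinskaResponse, RestInterval

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_questionnaire",
    "generate_actigraphy",
    "DEFAULT_FA_BASELINE",
    "DEFAULT_LATENT_LOADINGS_X",
    "DEFAULT_LATENT_LOADINGS_Y",
    "SLEEP_MEASURES",
]

SLEEP_MEASURES = ("dsi", "awi", "tst", "se", "sfi", "waso")

# Per-ROI FA baselines drawn once from U(0.4, 0.8) with a fixed stream and
# frozen here as the package default (plausible tract-level FA magnitudes).
DEFAULT_FA_BASELINE = np.round(
    np.random.default_rng(1822).uniform(0.4, 0.8, size=len(JHU_LABELS)), 4
)

# Sparse planted X-loadings (FA units per latent s.d.): higher latent sleep
# disturbance goes with lower FA in five tracts and higher FA in the fornix,
# echoing the kind of sparse regional pattern such analyses report.
_PLANTED_X = {
    "Fornix (column and body of fornix)": +0.012,
    "Corticospinal tract R": -0.012,
    "Corticospinal tract L": -0.012,
    "Cerebral peduncle L": -0.012,
    "Medial lemniscus L": -0.012,
    "Cingulum (hippocampus) L": -0.012,
}
DEFAULT_LATENT_LOADINGS_X = np.array(
    [_PLANTED_X.get(label, 0.0) for label in JHU_LABELS]
)

# Y-loadings on each measure's natural scale per latent s.d.
# (DSI points, AWI points, TST minutes, SE %, SFI points, WASO minutes).
# TST/SE/SFI are realized through the bout process: the latency slope is
# derived from the TST and WASO entries (TST = TIB - latency - WASO), SE is
# emergent, and the SFI entry modulates sleep-bout fragmentation.
DEFAULT_LATENT_LOADINGS_Y = np.array([1.5, 1.2, -15.0, -3.1, 6.0, 14.0])

DEFAULT_ITEM_THRESHOLDS = np.array([-1.5, -0.5, 0.5, 1.5])


@dataclass
class SyntheticCohortConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the two-group design the pipeline targets: 64 patients
    and 35 controls; age ~ N(23.6, 3.9); female probability 0.42 (patients)
    and 0.60 (controls); absolute / relative scanner motion ~ N(1.26, 0.35) /
    N(0.18, 0.08) truncated positive; a patient FA deficit of 0.013 FA units;
    and the planted latent loadings above.
    """

    n_patients: int = 64
    n_controls: int = 35
    roi_labels: Sequence[str] = field(default_factory=lambda: list(JHU_LABELS))
    group_fa_deficit: float = 0.013
    covariate_betas: dict = field(default_factory=lambda: {
        "age": -0.0003, "sex": 0.004, "abs_motion": -0.002, "rel_motion": -0.010,
    })
    latent_loadings_x: np.ndarray = field(
        default_factory=lambda: DEFAULT_LATENT_LOADINGS_X.copy())
    latent_loadings_y: np.ndarray = field(
        default_factory=lambda: DEFAULT_LATENT_LOADINGS_Y.copy())
    latent_sd: float = 1.0
    noise_sd_fa: float = 0.01
    subject_fa_sd: float = 0.012  # shared per-subject FA offset across all ROIs
    seed: int = 0
    # distribution details
    fa_baseline: np.ndarray = field(default_factory=lambda: DEFAULT_FA_BASELINE.copy())
    age_mean: float = 23.6
    age_sd: float = 3.9
    p_female: dict = field(default_factory=lambda: {"patient": 0.42, "control": 0.60})
    abs_motion_mean: float = 1.26
    abs_motion_sd: float = 0.35
    rel_motion_mean: float = 0.18
    rel_motion_sd: float = 0.08
    group_sleep_shift: float = 0.8   # latent-units shift of questionnaire items in patients
    dsi_baseline_shift: float = -0.9   # latent-units item baseline, sleep items (a)-(d)
    awi_baseline_shift: float = -0.35  # latent-units item baseline, awakening items (e)-(g)
    item_thresholds: np.ndarray = field(
        default_factory=lambda: DEFAULT_ITEM_THRESHOLDS.copy())
    night_noise_sd: float = 0.3      # extra latent noise for the last-night recall
    base_date: str = "2024-03-01"
    time_in_bed_mean: float = 480.0  # minutes
    time_in_bed_sd: float = 40.0
    baseline_latency_mean: float = 12.0   # minutes of wake before sleep onset at z = 0
    baseline_waso_mean: float = 48.0      # underlying minutes awake after onset at z = 0
    mean_sleep_bout: float = 13.0         # minutes, at z = 0
    sfi_reference: float = 26.0           # SFI scale used to convert the SFI loading
    lam_wake: float = 80.0                # Poisson count rate in wake epochs
    lam_sleep: float = 0.3                # Poisson count rate in sleep epochs at z = 0
    lam_day: float = 250.0                # Poisson count rate out of bed

    def __post_init__(self):
        self.latent_loadings_x = np.asarray(self.latent_loadings_x, dtype=float)
        self.latent_loadings_y = np.asarray(self.latent_loadings_y, dtype=float)
        self.fa_baseline = np.asarray(self.fa_baseline, dtype=float)
        self.item_thresholds = np.asarray(self.item_thresholds, dtype=float)
        self.validate()

    def validate(self):
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("each group needs at least 2 subjects")
        labels = list(self.roi_labels)
        if len(labels) != 48 or len(set(labels)) != 48:
            raise ValueError("roi_labels must hold exactly 48 unique labels")
        for c in CALLOSAL_LABELS:
            if c not in labels:
                raise ValueError(f"roi_labels must contain {c!r}")
        if self.latent_loadings_x.shape != (48,):
            raise ValueError("latent_loadings_x must have length 48")
        if self.latent_loadings_y.shape != (len(SLEEP_MEASURES),):
            raise ValueError(
                f"latent_loadings_y must have length {len(SLEEP_MEASURES)}")
        if self.fa_baseline.shape != (48,):
            raise ValueError("fa_baseline must have length 48")
        if self.item_thresholds.shape != (4,) or np.any(
            np.diff(self.item_thresholds) <= 0
        ):
            raise ValueError("item_thresholds must be 4 strictly increasing cut-points")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
            elif isinstance(v, (list, tuple)):
                d[k] = list(v)
        return d


def _ordinal_slope(thresholds: np.ndarray) -> float:
    """d E[item] / d shift at shift = 0 for the latent-Gaussian ordinal model."""
    return float(stats.norm.pdf(thresholds).sum())


def generate_questionnaire(
    latent_score: float,
    item_thresholds: np.ndarray,
    rng: np.random.Generator,
    subject_id: str = "",
    period: str = "last_4_weeks",
    item_loadings: Optional[np.ndarray] = None,
    baseline_shift=0.0,
) -> KarolinskaResponse:
    """Draw the seven ordinal items from the latent-Gaussian threshold model.

    Item i is 1 + #{cut-points below t_i}, where
    t_i = baseline_shift + item_loadings[i] * latent_score + N(0, 1).
    With the default unit loadings the expected item score is monotone in
    latent_score and saturates at 1 / 5 for extreme scores.
    """
    thresholds = np.asarray(item_thresholds, dtype=float)
    if thresholds.shape != (4,) or np.any(np.diff(thresholds) <= 0):
        raise ValueError("item_thresholds must be 4 strictly increasing cut-points")
    loadings = (np.ones(7) if item_loadings is None
                else np.asarray(item_loadings, dtype=float))
    baseline = np.broadcast_to(np.asarray(baseline_shift, dtype=float), (7,))
    latents = baseline + loadings * latent_score + rng.standard_normal(7)
    scores = 1 + (latents[:, None] > thresholds[None, :]).sum(axis=1)
    items = dict(zip("abcdefg", (int(s) for s in scores)))
    return KarolinskaResponse(subject_id=subject_id, period=period, items=items)


def generate_actigraphy(
    latent_score: float,
    diary: RestInterval,
    rng: np.random.Generator,
    config: Optional[SyntheticCohortConfig] = None,
) -> ActigraphyRecording:
    """Simulate a 24-h, 1-min-epoch activity-count recording.

    Out-of-bed epochs are active (Poisson(lam_day)).  In bed, a two-state
    semi-Markov sleep/wake bout process runs: an initial wake latency, then
    alternating geometric sleep and wake bouts whose stationary wake fraction
    and sleep-bout length are modulated by the latent score through the
    configured Y-loadings.  Wake epochs carry Poisson(lam_wake) counts; sleep
    epochs carry Poisson(lam_sleep * e^{z/2}) counts, which vanish (all in-bed
    counts zero) as the latent score goes to minus infinity.
    """
    cfg = config or SyntheticCohortConfig()
    z = float(latent_score)
    # device-style grid: whole-minute epochs, independent of diary seconds
    start = (diary.bed_time - pd.Timedelta(hours=8)).floor("min")
    epochs = pd.date_range(start, periods=1440, freq="1min")
    in_bed = (epochs >= diary.bed_time) & (epochs < diary.rise_time)
    n_bed = int(in_bed.sum())
    if n_bed == 0:
        raise ValueError("empty rest interval within the recording window")

    l_dsi, l_awi, l_tst, l_se, l_sfi, l_waso = cfg.latent_loadings_y
    latency_slope = -(l_tst + l_waso)  # from TST = TIB - latency - WASO
    latency_mean = max(cfg.baseline_latency_mean + latency_slope * z, 0.0)
    latency = min(int(rng.poisson(latency_mean)), n_bed)

    n_after = n_bed - latency
    waso_target = max(cfg.baseline_waso_mean + l_waso * z, 0.0)
    wake_frac = min(waso_target / max(n_after, 1), 0.9)
    mean_sleep_bout = float(np.clip(
        cfg.mean_sleep_bout * np.exp(-(l_sfi / max(cfg.sfi_reference, 1e-9)) * z),
        1.5, 120.0,
    ))

    state = np.zeros(n_bed, dtype=bool)  # True = sleep
    pos = latency
    asleep = True
    if wake_frac <= 0:
        state[pos:] = True
        pos = n_bed
    while pos < n_bed:
        if asleep:
            bout = rng.geometric(1.0 / mean_sleep_bout)
        else:
            mean_wake_bout = max(wake_frac * mean_sleep_bout / (1 - wake_frac), 1.0)
            bout = rng.geometric(min(1.0 / mean_wake_bout, 1.0))
        state[pos:pos + bout] = asleep
        pos += bout
        asleep = not asleep

    counts = rng.poisson(cfg.lam_day, size=1440).astype(float)
    lam_sleep = cfg.lam_sleep * np.exp(0.5 * z)
    bed_idx = np.where(in_bed)[0]
    sleep_counts = rng.poisson(lam_sleep, size=n_bed)
    wake_counts = rng.poisson(cfg.lam_wake, size=n_bed)
    counts[bed_idx] = np.where(state, sleep_counts, wake_counts)
    return ActigraphyRecording(epochs=epochs, counts=counts, rest=diary)


@dataclass
class SyntheticCohort:
    """One generated dataset plus the planted ground truth."""

    config: SyntheticCohortConfig
    covariates: pd.DataFrame          # indexed by subject_id
    roi_fa: pd.DataFrame              # subjects x 48, atlas-labelled columns
    responses: list                   # KarolinskaResponse, both recall periods
    actigraphy: dict                  # subject_id -> ActigraphyRecording
    latent: pd.Series                 # planted z per subject

    def ksq_frame(self) -> pd.DataFrame:
        rows = []
        for resp in self.responses:
            row = {"subject_id": resp.subject_id, "period": resp.period}
            row.update({k: resp.item(k) for k in "abcdefg"})
            rows.append(row)
        return pd.DataFrame(rows)

    def diary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"subject_id": sid, "bed_time": rec.rest.bed_time,
                 "rise_time": rec.rest.rise_time}
                for sid, rec in self.actigraphy.items()
            ]
        )

    def actigraphy_frame(self) -> pd.DataFrame:
        frames = []
        for sid, rec in self.actigraphy.items():
            frames.append(pd.DataFrame({
                "subject_id": sid,
                "timestamp": rec.epochs,
                "counts": rec.counts.astype(int),
            }))
        return pd.concat(frames, ignore_index=True)

    def to_dir(self, outdir) -> None:
        """Write the delimited-text dataset (plus truth.json) to a directory."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.covariates.to_csv(out / "covariates.csv")
        self.roi_fa.to_csv(out / "roi_fa.csv")
        self.ksq_frame().to_csv(out / "ksq.csv", index=False)
        self.actigraphy_frame().to_csv(out / "actigraphy.csv", index=False)
        self.diary_frame().to_csv(out / "diary.csv", index=False)
        truth = {
            "config": self.config.to_jsonable(),
            "latent": {k: float(v) for k, v in self.latent.items()},
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))


def _draw_covariates(rng, cfg: SyntheticCohortConfig, group: str) -> dict:
    age = cfg.age_mean + cfg.age_sd * rng.standard_normal()
    sex = int(rng.random() < cfg.p_female[group])  # 1 = female
    abs_motion = -1.0
    while abs_motion <= 0:
        abs_motion = cfg.abs_motion_mean + cfg.abs_motion_sd * rng.standard_normal()
    rel_motion = -1.0
    while rel_motion <= 0:
        rel_motion = cfg.rel_motion_mean + cfg.rel_motion_sd * rng.standard_normal()
    return {"age": age, "sex": sex, "abs_motion": abs_motion,
            "rel_motion": rel_motion}


def _draw_clinical(rng, group: str, z: float) -> dict:
    if group == "patient":
        madrs = max(15.86 + 7.31 * rng.standard_normal() + 1.5 * z, 0.0)
        caarms = max(49.91 + 15.71 * rng.standard_normal() + 3.0 * z, 0.0)
        antipsychotics = int(rng.random() < 0.297)
        sleep_med = int(rng.random() < 0.11)
        substance = float(rng.poisson(3.0))
    else:
        madrs = max(2.5 + 2.0 * rng.standard_normal(), 0.0)
        caarms = 0.0
        antipsychotics = 0
        sleep_med = int(rng.random() < 0.02)
        substance = float(rng.poisson(2.0))
    return {"madrs": madrs, "caarms": caarms, "antipsychotics": antipsychotics,
            "sleep_med": sleep_med, "substance_use": substance}


def generate_cohort(config: Optional[SyntheticCohortConfig] = None) -> SyntheticCohort:
    """Generate a full synthetic cohort from the configuration."""
    cfg = config or SyntheticCohortConfig()
    cfg.validate()
    labels = list(cfg.roi_labels)
    n_total = cfg.n_patients + cfg.n_controls
    subject_ids = [f"P{i + 1:03d}" for i in range(cfg.n_patients)] + [
        f"C{i + 1:03d}" for i in range(cfg.n_controls)
    ]
    groups = ["patient"] * cfg.n_patients + ["control"] * cfg.n_controls
    streams = np.random.SeedSequence(cfg.seed).spawn(n_total)

    slope0 = _ordinal_slope(cfg.item_thresholds)
    l_dsi, l_awi = cfg.latent_loadings_y[0], cfg.latent_loadings_y[1]
    # per-item latent shifts chosen so the index-level effect matches the
    # natural-scale loading at first order (linearized threshold model)
    item_loadings = np.concatenate([
        np.full(4, l_dsi / (4 * slope0)),
        np.full(3, l_awi / (3 * slope0)),
    ])

    cov_rows, fa_rows, responses, acti, zs = [], [], [], {}, []
    base = pd.Timestamp(cfg.base_date)
    for sid, group, ss in zip(subject_ids, groups, streams):
        rng = np.random.default_rng(ss)
        cov = _draw_covariates(rng, cfg, group)
        z = cfg.latent_sd * rng.standard_normal()
        clin = _draw_clinical(rng, group, z)

        deficit = cfg.group_fa_deficit if group == "patient" else 0.0
        cov_effect = (
            cfg.covariate_betas.get("age", 0.0) * (cov["age"] - cfg.age_mean)
            + cfg.covariate_betas.get("sex", 0.0) * (cov["sex"] - 0.5)
            + cfg.covariate_betas.get("abs_motion", 0.0)
            * (cov["abs_motion"] - cfg.abs_motion_mean)
            + cfg.covariate_betas.get("rel_motion", 0.0)
            * (cov["rel_motion"] - cfg.rel_motion_mean)
        )
        subject_offset = cfg.subject_fa_sd * rng.standard_normal()
        mean_fa = (cfg.fa_baseline - deficit + cov_effect + subject_offset
                   + cfg.latent_loadings_x * z)
        fa = None
        for _ in range(100):  # reject-and-resample keeps FA inside (0, 1)
            candidate = mean_fa + cfg.noise_sd_fa * rng.standard_normal(48)
            if np.all((candidate > 0) & (candidate < 1)):
                fa = candidate
                break
        if fa is None:
            raise RuntimeError(f"could not draw FA in (0,1) for {sid}")

        gshift = cfg.group_sleep_shift if group == "patient" else 0.0
        item_baseline = gshift + np.concatenate([
            np.full(4, cfg.dsi_baseline_shift), np.full(3, cfg.awi_baseline_shift)])
        responses.append(generate_questionnaire(
            z, cfg.item_thresholds, rng, subject_id=sid, period="last_4_weeks",
            item_loadings=item_loadings, baseline_shift=item_baseline,
        ))
        z_night = z + cfg.night_noise_sd * rng.standard_normal()
        responses.append(generate_questionnaire(
            z_night, cfg.item_thresholds, rng, subject_id=sid, period="last_night",
            item_loadings=item_loadings, baseline_shift=item_baseline,
        ))

        bed = (base + pd.Timedelta(hours=22, minutes=30)
               + pd.Timedelta(minutes=int(round(30 * rng.standard_normal()))))
        tib = max(int(round(cfg.time_in_bed_mean
                            + cfg.time_in_bed_sd * rng.standard_normal())), 120)
        diary = RestInterval(bed_time=bed, rise_time=bed + pd.Timedelta(minutes=tib))
        acti[sid] = generate_actigraphy(z, diary, rng, config=cfg)

        cov_rows.append({"subject_id": sid, "group": group, **cov, **clin})
        fa_rows.append(fa)
        zs.append(z)

    covariates = pd.DataFrame(cov_rows).set_index("subject_id")
    roi_fa = pd.DataFrame(np.asarray(fa_rows), index=pd.Index(subject_ids,
                          name="subject_id"), columns=labels)
    latent = pd.Series(zs, index=pd.Index(subject_ids, name="subject_id"), name="z")
    return SyntheticCohort(config=cfg, covariates=covariates, roi_fa=roi_fa,
                           responses=responses, actigraphy=acti, latent=latent)
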