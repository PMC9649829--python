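"""Subjective and objective sleep-wake measures.

Subjective side: the modified Karolinska Sleep Questionnaire covers seven
ordinal items, each scored 1 ("never") to 5 ("always"), higher = worse sleep:

    (a) difficulty falling asleep      (e) difficulty waking up
    (b) disturbed/restless sleep       (f) non-refreshing sleep
    (c) repeated awakenings            (g) exhaustion at awakening
    (d) premature awakening

Two indices are derived: the Disturbed Sleep Index, DSI = a+b+c+d (range
4–20), and the Disturbed Awakening Index, AWI = e+f+g (range 3–15).  A
respondent missing any contributing item gets a missing index and is excluded
listwise downstream.

Objective side: wrist actigraphy at 1-min epochs within a diary-defined rest
interval.  Epochs are scored sleep/wake with the published Cole–Kripke
one-minute weighted-sum classifier, and the scored labels are summarized into
total sleep time (TST), wake after sleep onset (WASO), sleep efficiency (SE),
and the sleep fragmentation index SFI = movement index (MI) + fragmentation
index (FI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DSI_ITEMS",
    "AWI_ITEMS",
    "KarolinskaResponse",
    "SleepIndices",
    "RestInterval",
    "ActigraphyRecording",
    "SleepSummary",
    "compute_dsi",
    "compute_awi",
    "score_epochs",
    "summarize_sleep",
    "sleep_summary",
    "COLE_KRIPKE_WEIGHTS",
    "COLE_KRIPKE_SCALE",
]

DSI_ITEMS = ("a", "b", "c", "d")
AWI_ITEMS = ("e", "f", "g")
ALL_ITEMS = DSI_ITEMS + AWI_ITEMS

# Cole-Kripke (1992) one-minute epoch weights over the window A[-4..+2];
# an epoch is scored sleep iff SCALE * sum(w_i * count_i) < 1.
COLE_KRIPKE_WEIGHTS = np.array([404.0, 598.0, 326.0, 441.0, 1408.0, 508.0, 350.0])
COLE_KRIPKE_SCALE = 0.00001


@dataclass(frozen=True)
class KarolinskaResponse:
    """One questionnaire administration (one subject, one recall period)."""

    subject_id: str
    period: str  # "last_night" or "last_4_weeks"
    items: Mapping[str, Optional[int]]

    def __post_init__(self):
        for key, value in self.items.items():
            if key not in ALL_ITEMS:
                raise ValueError(f"unknown questionnaire item {key!r}")
            if value is not None and value not in (1, 2, 3, 4, 5):
                raise ValueError(
                    f"item {key!r} = {value!r} outside the 1-5 response scale"
                )

    def item(self, key: str) -> Optional[int]:
        return self.items.get(key)


@dataclass(frozen=True)
class SleepIndices:
    dsi: Optional[int]
    awi: Optional[int]

    def __post_init__(self):
        if self.dsi is not None and not 4 <= self.dsi <= 20:
            raise ValueError(f"DSI {self.dsi} outside [4, 20]")
        if self.awi is not None and not 3 <= self.awi <= 15:
            raise ValueError(f"AWI {self.awi} outside [3, 15]")


def _sum_items(resp: KarolinskaResponse, keys: Sequence[str]) -> Optional[int]:
    values = [resp.item(k) for k in keys]
    if any(v is None for v in values):
        return None
    return int(sum(values))


def compute_dsi(resp: KarolinskaResponse) -> Optional[int]:
    """Disturbed Sleep Index: sum of items (a)-(d); None if any is missing."""
    return _sum_items(resp, DSI_ITEMS)


def compute_awi(resp: KarolinskaResponse) -> Optional[int]:
    """Disturbed Awakening Index: sum of items (e)-(g); None if any is missing."""
    return _sum_items(resp, AWI_ITEMS)


@dataclass(frozen=True)
class RestInterval:
    """Diary-reported in-bed interval; the diary is taken as authoritative."""

    bed_time: pd.Timestamp
    rise_time: pd.Timestamp

    def __post_init__(self):
        object.__setattr__(self, "bed_time", pd.Timestamp(self.bed_time))
        object.__setattr__(self, "rise_time", pd.Timestamp(self.rise_time))
        if not self.rise_time > self.bed_time:
            raise ValueError("rise_time must be after bed_time")


@dataclass
class ActigraphyRecording:
    """Activity counts on a strict 1-min epoch grid plus the rest interval.

    Epochs are half-open ``[t, t + 60 s)``; an epoch is in bed iff its start
    time lies in ``[bed_time, rise_time)``.
    """

    epochs: pd.DatetimeIndex
    counts: np.ndarray
    rest: RestInterval

    def __post_init__(self):
        self.epochs = pd.DatetimeIndex(self.epochs)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.epochs) != len(self.counts):
            raise ValueError("epochs and counts differ in length")
        if len(self.epochs) < 2:
            raise ValueError("recording needs at least two epochs")
        deltas = np.diff(self.epochs.asi8)
        if not np.all(deltas == 60 * 10**9):
            raise ValueError("epochs must be strictly increasing with 60 s spacing")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("activity counts must be finite and non-negative")

    def in_bed_mask(self) -> np.ndarray:
        return (self.epochs >= self.rest.bed_time) & (self.epochs < self.rest.rise_time)


def _cole_kripke_scores(counts: np.ndarray) -> np.ndarray:
    """Weighted-sum score per epoch; zero-padded at the recording edges."""
    padded = np.concatenate([np.zeros(4), counts, np.zeros(2)])
    # window for epoch i: padded[i : i+7] aligned with weights A-4..A+2
    windows = np.lib.stride_tricks.sliding_window_view(padded, 7)
    return COLE_KRIPKE_SCALE * windows @ COLE_KRIPKE_WEIGHTS


def score_epochs(rec: ActigraphyRecording, algorithm: str = "cole_kripke") -> np.ndarray:
    """Score each in-bed epoch sleep (True) / wake (False).

    Uses the Cole-Kripke one-minute weighted-sum rule on the full recording
    (so neighbours outside the rest interval inform edge epochs), then
    restricts to the in-bed epochs.  Raises if the recording does not cover
    the rest interval.
    """
    if algorithm != "cole_kripke":
        raise ValueError(f"unknown scoring algorithm {algorithm!r}")
    mask = rec.in_bed_mask()
    if not mask.any():
        raise ValueError("recording contains no epochs inside the rest interval")
    covered_start = rec.epochs[0] <= rec.rest.bed_time
    covered_end = rec.epochs[-1] + pd.Timedelta(minutes=1) >= rec.rest.rise_time
    if not (covered_start and covered_end):
        raise ValueError("recording does not cover the rest interval")
    scores = _cole_kripke_scores(rec.counts)
    return (scores < 1.0)[mask]


@dataclass(frozen=True)
class SleepSummary:
    """Epoch-count summary of one scored night (all durations in minutes)."""

    tst: float
    waso: float
    se: float
    sfi: float
    mi: float
    fi: float
    sleep_onset: Optional[pd.Timestamp]
    time_in_bed: float
    no_sleep: bool = field(default=False)

    def __post_init__(self):
        if not 0.0 <= self.se <= 100.0:
            raise ValueError("sleep efficiency outside [0, 100]")
        if self.tst > self.time_in_bed:
            raise ValueError("TST exceeds time in bed")
        if self.waso < 0:
            raise ValueError("negative WASO")


def _sleep_bout_lengths(labels: np.ndarray) -> list[int]:
    lengths: list[int] = []
    run = 0
    for is_sleep in labels:
        if is_sleep:
            run += 1
        elif run:
            lengths.append(run)
            run = 0
    if run:
        lengths.append(run)
    return lengths


def summarize_sleep(labels: Sequence[bool], rest: RestInterval) -> SleepSummary:
    """Summarize per-epoch sleep/wake labels over the rest interval.

    TST counts sleep epochs; sleep onset is the first sleep epoch; WASO counts
    wake epochs after onset; SE = 100*TST/time-in-bed; MI = 100*wake/time-in-bed;
    FI = 100 * (# sleep bouts of length 1) / (# sleep bouts); SFI = MI + FI.
    With no sleep epoch at all the summary is flagged and TST = SE = WASO = 0.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.size == 0:
        raise ValueError("empty label vector")
    tib = float(labels.size)
    tst = float(labels.sum())
    wake = tib - tst
    mi = 100.0 * wake / tib
    if tst == 0:
        return SleepSummary(
            tst=0.0, waso=0.0, se=0.0, sfi=mi, mi=mi, fi=0.0,
            sleep_onset=None, time_in_bed=tib, no_sleep=True,
        )
    onset_idx = int(np.argmax(labels))
    waso = float((~labels[onset_idx:]).sum())
    se = 100.0 * tst / tib
    bouts = _sleep_bout_lengths(labels)
    fi = 100.0 * sum(1 for b in bouts if b == 1) / len(bouts)
    sfi = mi + fi
    onset = rest.bed_time + pd.Timedelta(minutes=onset_idx)
    return SleepSummary(
        tst=tst, waso=waso, se=se, sfi=sfi, mi=mi, fi=fi,
        sleep_onset=onset, time_in_bed=tib, no_sleep=False,
    )


def sleep_summary(rec: ActigraphyRecording) -> SleepSummary:
    """Score a recording and summarize it in one step."""
    return summarize_sleep(score_epochs(rec), rec.rest)
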