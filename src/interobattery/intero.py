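"""Interoceptive scoring: heartbeat-task accuracies, confidence, awareness,
and MAIA/BPQ questionnaire subscales.

Accuracy scores
---------------
*Heartbeat detection* (tapping along with one's heartbeat): taps are matched
one-to-one to R-peaks within an HR-category-specific latency window, the
matched counts are pooled over trials, and

    acc_d = 1 - |recorded - matched| / recorded            (clipped to [0, 1])

*Heartbeat counting* (silent counting over fixed intervals):

    acc_c = mean over trials of 1 - |recorded - counted| / recorded

which is deliberately left unclipped — over-counting beyond twice the recorded
beats drives the per-trial score negative, exactly as the formula reads.

Awareness
---------
The discrepancy between objective accuracy and subjective confidence, both
min-max normalised across the analysed cohort:
``aw_i = |acc_norm_i - conf_norm_i|``, always in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from math import isnan

import numpy as np
import yaml

__all__ = [
    "TappingTrial",
    "CountingTrial",
    "InteroScores",
    "QuestionnaireMap",
    "DEFAULT_TAP_WINDOWS",
    "HR_SLOW_BOUND",
    "HR_FAST_BOUND",
    "categorize_hr",
    "detection_accuracy",
    "counting_accuracy",
    "mean_confidence",
    "awareness_discrepancy",
    "score_questionnaire",
    "load_questionnaire_map",
]

# HR category boundaries (beats/min).  The printed inequalities are strict on
# both sides; the boundary values themselves are assigned to the mid category.
HR_SLOW_BOUND = 69.75
HR_FAST_BOUND = 94.25

#: Post-R-peak latency windows (s) per HR category within which a tap counts
#: as correct.  The scoring tradition uses HR-dependent windows but does not
#: fix them; these defaults are configurable and the accuracy formula itself
#: is window-agnostic.
DEFAULT_TAP_WINDOWS: dict[str, tuple[float, float]] = {
    "slow": (0.100, 0.500),
    "mid": (0.100, 0.400),
    "fast": (0.050, 0.300),
}


@dataclass(frozen=True)
class TappingTrial:
    tap_times: tuple
    r_peak_times: tuple
    trial_duration: float

    def __post_init__(self):
        for name, seq in (("tap_times", self.tap_times), ("r_peak_times", self.r_peak_times)):
            arr = np.asarray(seq, dtype=float)
            if arr.size and (np.any(np.diff(arr) < 0)):
                raise ValueError(f"{name} must be non-decreasing")
            if arr.size and (arr[0] < 0 or arr[-1] > self.trial_duration):
                raise ValueError(f"{name} must lie within [0, trial_duration]")


@dataclass(frozen=True)
class CountingTrial:
    recorded_beats: int
    counted_beats: int
    confidence: int

    def __post_init__(self):
        if self.recorded_beats < 1:
            raise ValueError("recorded_beats must be >= 1")
        if self.counted_beats < 0:
            raise ValueError("counted_beats must be >= 0")
        if not 1 <= self.confidence <= 9:
            raise ValueError("confidence must be an integer in 1..9")


@dataclass(frozen=True)
class InteroScores:
    acc_d: float
    acc_c: float
    con_d: float
    con_c: float
    aw_d: float = float("nan")
    aw_c: float = float("nan")


def categorize_hr(mean_hr: float) -> str:
    """HR category: 'slow' (< 69.75), 'fast' (> 94.25), else 'mid'."""
    if mean_hr <= 0:
        raise ValueError("mean HR must be positive")
    if mean_hr < HR_SLOW_BOUND:
        return "slow"
    if mean_hr > HR_FAST_BOUND:
        return "fast"
    return "mid"


def _trial_mean_hr(r_peaks: np.ndarray, duration: float) -> float:
    if r_peaks.size >= 2 and r_peaks[-1] > r_peaks[0]:
        return 60.0 * (r_peaks.size - 1) / (r_peaks[-1] - r_peaks[0])
    return 60.0 * r_peaks.size / duration


def _match_taps(taps: np.ndarray, beats: np.ndarray, window: tuple[float, float]) -> int:
    """One-to-one greedy matching of taps to preceding beats by smallest latency."""
    lo, hi = window
    pairs = []
    for ti, t in enumerate(taps):
        for bi, b in enumerate(beats):
            lat = t - b
            if lo <= lat <= hi:
                pairs.append((lat, ti, bi))
    pairs.sort()
    used_t: set[int] = set()
    used_b: set[int] = set()
    n = 0
    for _, ti, bi in pairs:
        if ti in used_t or bi in used_b:
            continue
        used_t.add(ti)
        used_b.add(bi)
        n += 1
    return n


def detection_accuracy(
    trials,
    windows: dict[str, tuple[float, float]] | None = None,
) -> float:
    """Heartbeat-detection accuracy from tapping trials.

    Each trial is assigned an HR category from its own mean HR; taps landing
    within that category's post-R-peak window are matched one-to-one to beats
    (greedy, smallest latency first).  Matched counts are pooled across trials
    and the accuracy formula is applied with the total recorded beat count.
    """
    if windows is None:
        windows = DEFAULT_TAP_WINDOWS
    trials = list(trials)
    if not trials:
        raise ValueError("need at least one tapping trial")
    recorded = 0
    correct = 0
    for trial in trials:
        beats = np.asarray(trial.r_peak_times, dtype=float)
        taps = np.asarray(trial.tap_times, dtype=float)
        if beats.size == 0:
            raise ValueError("a tapping trial has zero recorded heartbeats")
        cat = categorize_hr(_trial_mean_hr(beats, trial.trial_duration))
        recorded += beats.size
        correct += _match_taps(taps, beats, windows[cat])
    acc = 1.0 - abs(recorded - correct) / recorded
    return float(np.clip(acc, 0.0, 1.0))


def counting_accuracy(trials, n_trials: int = 4) -> float:
    """Heartbeat-counting accuracy, averaged over (by default exactly 4) trials."""
    trials = list(trials)
    if len(trials) != n_trials:
        raise ValueError(f"expected exactly {n_trials} counting trials, got {len(trials)}")
    scores = [
        1.0 - abs(t.recorded_beats - t.counted_beats) / t.recorded_beats for t in trials
    ]
    return float(np.mean(scores))


def mean_confidence(ratings) -> float:
    """Mean of 1-9 confidence ratings (2 for detection, 4 for counting)."""
    ratings = list(ratings)
    if not ratings:
        raise ValueError("no confidence ratings given")
    for r in ratings:
        if not 1 <= r <= 9:
            raise ValueError(f"confidence rating {r} outside 1..9")
    return float(np.mean(ratings))


def awareness_discrepancy(accuracies, confidences) -> np.ndarray:
    """Cohort-wise awareness: |min-max-normalised accuracy - confidence|.

    Both vectors are normalised to [0, 1] across the analysed cohort, so the
    result is invariant to any affine rescaling of either raw measure.
    """
    acc = np.asarray(accuracies, dtype=float)
    conf = np.asarray(confidences, dtype=float)
    if acc.shape != conf.shape or acc.size < 2:
        raise ValueError("accuracy and confidence vectors must have equal length >= 2")
    out = []
    for name, v in (("accuracy", acc), ("confidence", conf)):
        rng = v.max() - v.min()
        if rng == 0:
            raise ValueError(f"{name} vector has zero range; cannot min-max normalise")
        out.append((v - v.min()) / rng)
    return np.abs(out[0] - out[1])


# --------------------------------------------------------------------------- #
# Questionnaires
# --------------------------------------------------------------------------- #

@dataclass
class QuestionnaireMap:
    """Item->subscale map with reverse-coded items and an aggregation rule."""

    instrument: str
    items: dict  # item id -> subscale name
    reverse: set = field(default_factory=set)
    response_range: tuple = (0, 5)
    aggregation: str = "mean"  # "mean" | "sum"

    def __post_init__(self):
        self.reverse = set(self.reverse)
        unknown = self.reverse - set(self.items)
        if unknown:
            raise ValueError(f"reverse-coded items not in map: {sorted(unknown)}")
        if self.aggregation not in ("mean", "sum"):
            raise ValueError("aggregation must be 'mean' or 'sum'")

    @property
    def subscales(self) -> list[str]:
        seen: list[str] = []
        for s in self.items.values():
            if s not in seen:
                seen.append(s)
        return seen


def load_questionnaire_map(instrument: str) -> QuestionnaireMap:
    """Load a shipped default map ('maia' or 'bpq'); the YAML files are editable."""
    path = resources.files("interobattery").joinpath(f"data/{instrument.lower()}_map.yaml")
    raw = yaml.safe_load(path.read_text())
    return QuestionnaireMap(
        instrument=raw["instrument"],
        items={int(k): v for k, v in raw["items"].items()},
        reverse=set(raw.get("reverse", [])),
        response_range=tuple(raw["response_range"]),
        aggregation=raw["aggregation"],
    )


def score_questionnaire(
    responses: dict,
    qmap: QuestionnaireMap,
    *,
    max_missing_fraction: float = 0.20,
) -> dict[str, float]:
    """Subscale scores from item responses.

    Reverse-coded items are flipped within the response range.  A subscale with
    more than ``max_missing_fraction`` of its items missing scores NaN; with
    fewer missing, the mean of the available items is used (prorated to the
    item count for sum aggregation).  Unknown items raise.
    """
    lo, hi = qmap.response_range
    unknown = set(responses) - set(qmap.items)
    if unknown:
        raise KeyError(f"unknown questionnaire items: {sorted(unknown)}")
    values: dict[int, float] = {}
    for item, v in responses.items():
        if v is None or (isinstance(v, float) and isnan(v)):
            continue
        if not lo <= v <= hi:
            raise ValueError(f"response {v} for item {item} outside range [{lo}, {hi}]")
        values[item] = (lo + hi - v) if item in qmap.reverse else float(v)

    scores: dict[str, float] = {}
    for sub in qmap.subscales:
        items = [i for i, s in qmap.items.items() if s == sub]
        avail = [values[i] for i in items if i in values]
        if len(items) - len(avail) > max_missing_fraction * len(items):
            scores[sub] = float("nan")
            continue
        m = float(np.mean(avail))
        scores[sub] = m if qmap.aggregation == "mean" else m * len(items)
    return scores
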