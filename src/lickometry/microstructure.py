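"""Meal/burst segmentation of 23-h lick streams and microstructure variables.

The segmentation hierarchy has three timescales:

* within-burst inter-lick intervals (ILIs), ~100-160 ms in rodents;
* **bursts** — runs of licks with no internal pause exceeding 1 s;
* **meals** — bouts initiated by 5 licks within 1 s and terminated by a
  pause of at least 600 s.

Whole-meal measures (lick count, duration) index total consumption, which is
shaped by post-ingestive feedback; intra-meal measures (burst size and
duration, pause duration) and initial-rate measures (licks in the first
minute, licks in the first burst) index orosensory, taste-driven drive.

Averaging convention: each variable is computed per meal and then averaged
across meals **unweighted** ("the average of each variable per meal,
averaged across all meals").  Meals with a single burst contribute no pause
observation (excluded from the pause mean, not counted as zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ValidationError

MS = 1000.0


@dataclass(frozen=True)
class Burst:
    """A run of licks with every internal ILI <= the burst pause threshold."""

    licks: np.ndarray  # ms

    @property
    def start(self) -> int:
        return int(self.licks[0])

    @property
    def end(self) -> int:
        return int(self.licks[-1])

    @property
    def n_licks(self) -> int:
        return int(self.licks.size)

    @property
    def duration_s(self) -> float:
        # single-lick burst has zero duration
        return (self.end - self.start) / MS


@dataclass
class Meal:
    """A meal: ordered licks from the initiating run to the last pre-pause lick."""

    licks: np.ndarray  # ms
    bursts: list[Burst] = field(default_factory=list)

    @property
    def onset(self) -> int:
        return int(self.licks[0])

    @property
    def offset(self) -> int:
        return int(self.licks[-1])

    @property
    def n_licks(self) -> int:
        return int(self.licks.size)

    @property
    def duration_s(self) -> float:
        return (self.offset - self.onset) / MS


@dataclass(frozen=True)
class MicrostructureSummary:
    """Session-level microstructure variables (per-meal means, unweighted).

    All meal-derived fields are NaN when the session contains no meals;
    ``mean_pause_duration_s`` is NaN when no meal has two or more bursts.
    ``licks_first_minute`` is anchored at the session's first lick;
    ``licks_first_minute_meal`` is the per-meal mean of licks within 60 s of
    each meal onset (both conventions are reported).
    """

    session_licks: int
    n_meals: int
    mean_meal_licks: float
    mean_meal_duration_s: float
    mean_n_bursts: float
    mean_burst_size: float
    mean_burst_duration_s: float
    mean_pause_duration_s: float
    licks_first_minute: float
    licks_first_minute_meal: float
    licks_first_burst: float


def _as_ms_array(licks: Sequence[int] | np.ndarray) -> np.ndarray:
    arr = np.asarray(licks, dtype=np.int64)
    if arr.ndim != 1:
        raise ValidationError("licks must be a 1-D timestamp array")
    if arr.size > 1 and np.any(np.diff(arr) <= 0):
        raise ValidationError("lick timestamps must be strictly increasing")
    return arr


def segment_meals(
    licks: Sequence[int] | np.ndarray,
    init_count: int = 5,
    init_window_s: float = 1.0,
    termination_pause_s: float = 600.0,
) -> list[Meal]:
    """Segment a lick stream (ms timestamps) into meals.

    Scanning forward from the end of the previous meal, a meal opens at the
    EARLIEST lick ``i`` such that ``t[i + init_count - 1] - t[i]`` is within
    the initiation window; it closes at the last lick followed by a gap of at
    least ``termination_pause_s`` (threshold-inclusive), or at the end of the
    stream.  Licks that never head a qualifying initiation run belong to no
    meal (orphans).
    """
    t = _as_ms_array(licks)
    window_ms = init_window_s * MS
    gap_ms = termination_pause_s * MS
    meals: list[Meal] = []
    n = t.size
    j = 0
    while j <= n - init_count:
        # earliest qualifying onset at or after j
        span = t[j + init_count - 1 :] - t[j : n - init_count + 1]
        hits = np.nonzero(span <= window_ms)[0]
        if hits.size == 0:
            break
        i = j + int(hits[0])
        # meal ends at first gap >= threshold after onset
        gaps = np.diff(t[i:])
        stops = np.nonzero(gaps >= gap_ms)[0]
        k = i + int(stops[0]) if stops.size else n - 1
        meal = Meal(licks=t[i : k + 1])
        meal.bursts = segment_bursts(meal)
        meals.append(meal)
        j = k + 1
    return meals


def segment_bursts(
    meal: Meal | Sequence[int] | np.ndarray, pause_s: float = 1.0
) -> list[Burst]:
    """Split a meal's licks into bursts at every ILI strictly greater than ``pause_s``.

    An ILI exactly equal to the threshold stays within the burst.  Every meal
    lick lands in exactly one burst and burst order is preserved.
    """
    t = meal.licks if isinstance(meal, Meal) else _as_ms_array(meal)
    if t.size == 0:
        return []
    cuts = np.nonzero(np.diff(t) > pause_s * MS)[0] + 1
    return [Burst(licks=seg) for seg in np.split(t, cuts)]


def burst_pauses_s(bursts: Sequence[Burst]) -> list[float]:
    """Pauses between consecutive bursts within a meal (end of one to start of next)."""
    return [
        (nxt.start - cur.end) / MS for cur, nxt in zip(bursts[:-1], bursts[1:])
    ]


def summarize_session(
    licks: Sequence[int] | np.ndarray,
    meals: Sequence[Meal] | None = None,
    pause_s: float = 1.0,
    first_minute_s: float = 60.0,
) -> MicrostructureSummary:
    """Compute session-level microstructure variables.

    ``session_licks`` counts ALL licks, including orphans outside any meal.
    Per-meal variables are averaged across meals with equal weight.
    """
    t = _as_ms_array(licks)
    if meals is None:
        meals = segment_meals(t)

    nan = float("nan")
    if len(meals) == 0:
        fm = nan
        if t.size:
            fm = float(np.count_nonzero(t < t[0] + first_minute_s * MS))
        return MicrostructureSummary(
            session_licks=int(t.size),
            n_meals=0,
            mean_meal_licks=nan,
            mean_meal_duration_s=nan,
            mean_n_bursts=nan,
            mean_burst_size=nan,
            mean_burst_duration_s=nan,
            mean_pause_duration_s=nan,
            licks_first_minute=fm,
            licks_first_minute_meal=nan,
            licks_first_burst=nan,
        )

    per_meal_licks = []
    per_meal_dur = []
    per_meal_nbursts = []
    per_meal_burst_size = []
    per_meal_burst_dur = []
    per_meal_pause = []
    per_meal_first_min = []
    for meal in meals:
        bursts = meal.bursts or segment_bursts(meal, pause_s=pause_s)
        per_meal_licks.append(meal.n_licks)
        per_meal_dur.append(meal.duration_s)
        per_meal_nbursts.append(len(bursts))
        # mean burst size = meal licks / number of bursts
        per_meal_burst_size.append(meal.n_licks / len(bursts))
        per_meal_burst_dur.append(float(np.mean([b.duration_s for b in bursts])))
        pauses = burst_pauses_s(bursts)
        if pauses:
            per_meal_pause.append(float(np.mean(pauses)))
        per_meal_first_min.append(
            float(np.count_nonzero(
                (meal.licks >= meal.onset)
                & (meal.licks < meal.onset + first_minute_s * MS)
            ))
        )

    first_burst = meals[0].bursts or segment_bursts(meals[0], pause_s=pause_s)
    window_start = int(t[0])
    licks_first_minute = float(
        np.count_nonzero(t < window_start + first_minute_s * MS)
    )

    return MicrostructureSummary(
        session_licks=int(t.size),
        n_meals=len(meals),
        mean_meal_licks=float(np.mean(per_meal_licks)),
        mean_meal_duration_s=float(np.mean(per_meal_dur)),
        mean_n_bursts=float(np.mean(per_meal_nbursts)),
        mean_burst_size=float(np.mean(per_meal_burst_size)),
        mean_burst_duration_s=float(np.mean(per_meal_burst_dur)),
        mean_pause_duration_s=float(np.mean(per_meal_pause))
        if per_meal_pause
        else math.nan,
        licks_first_minute=licks_first_minute,
        licks_first_minute_meal=float(np.mean(per_meal_first_min)),
        licks_first_burst=float(first_burst[0].n_licks),
    )


def meal_table(meals: Sequence[Meal]) -> pd.DataFrame:
    """Per-meal table (one row per meal) for CSV export."""
    rows = []
    for i, meal in enumerate(meals):
        bursts = meal.bursts or segment_bursts(meal)
        pauses = burst_pauses_s(bursts)
        rows.append(
            {
                "meal_id": i,
                "onset_ms": meal.onset,
                "offset_ms": meal.offset,
                "n_licks": meal.n_licks,
                "duration_s": meal.duration_s,
                "n_bursts": len(bursts),
                "mean_burst_size": meal.n_licks / len(bursts),
                "mean_burst_duration_s": float(
                    np.mean([b.duration_s for b in bursts])
                ),
                "mean_pause_duration_s": float(np.mean(pauses))
                if pauses
                else math.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "meal_id",
            "onset_ms",
            "offset_ms",
            "n_licks",
            "duration_s",
            "n_bursts",
            "mean_burst_size",
            "mean_burst_duration_s",
            "mean_pause_duration_s",
        ],
    )


def summary_table(summary: MicrostructureSummary) -> pd.DataFrame:
    """One-row DataFrame view of a session summary."""
    return pd.DataFrame([summary.__dict__])
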