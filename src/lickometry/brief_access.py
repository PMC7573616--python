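"""Standardized lick ratios (SLR) for brief-access gustometry.

Brief-access tests present seconds-scale stimulus trials so that licking
reflects orosensory (taste) evaluation rather than post-ingestive feedback.
Raw trial lick counts are normalized per subject:

    SLR = mean licks per trial / maximum potential licks,
    maximum potential licks = trial duration / mean valid ILI,

where the mean valid inter-lick interval (ILI) comes from water-training
sessions, keeping only ILIs strictly between 50 and 200 ms (the local,
within-burst lick rhythm).  The SLR therefore removes individual differences
in baseline lick rate: 1.0 means the subject licked the stimulus at its own
maximal sustained rate for the whole trial.

Non-initiated trials are treated as missing, not zero, and excluded from the
per-stimulus average; ``n_trials_used`` records how many presentations
contributed.  SLR values above 1 are possible (stimulus licking faster than
the water-training rhythm) and are kept, not clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import LickSession, assemble_trials

logger = logging.getLogger(__name__)

ILI_VALID_LOW_S = 0.050
ILI_VALID_HIGH_S = 0.200


class BaselineError(ValueError):
    """Water-training data cannot support a baseline (no valid ILIs)."""


@dataclass(frozen=True)
class SubjectBaseline:
    """Per-subject baseline lick rhythm from water training."""

    subject_id: str
    mean_valid_ili: float  # seconds
    n_valid_ilis: int
    max_potential_licks: float  # per trial duration


def filter_valid_ilis(ilis: Sequence[float]) -> list[float]:
    """Keep ILIs strictly inside the (50 ms, 200 ms) window, order preserved.

    Both boundaries are excluded.  Raises :class:`BaselineError` if nothing
    survives, since the training session is then unusable for a baseline.
    """
    kept = [x for x in ilis if ILI_VALID_LOW_S < x < ILI_VALID_HIGH_S]
    if not kept:
        raise BaselineError(
            "no ILIs inside (0.050, 0.200) s; training session unusable"
        )
    return kept


def max_potential_lick_rate(trial_duration_s: float, mean_valid_ili_s: float) -> float:
    """Maximum potential licks in one trial: duration / mean valid ILI (unrounded)."""
    if trial_duration_s <= 0:
        raise ValueError("trial_duration_s must be positive")
    if mean_valid_ili_s <= 0:
        raise ValueError("mean_valid_ili_s must be positive")
    return trial_duration_s / mean_valid_ili_s


def standardized_lick_ratio(mean_licks: float, max_potential: float) -> float:
    """Mean trial licks divided by the subject's maximum potential licks."""
    if max_potential <= 0:
        raise ValueError("max_potential must be positive")
    if mean_licks < 0:
        raise ValueError("mean_licks must be non-negative")
    slr = mean_licks / max_potential
    if slr > 1:
        logger.info("SLR %.3f exceeds 1: licking outpaced the training rhythm", slr)
    return slr


def compute_baseline(
    training_sessions: Iterable[LickSession],
    subject_id: str,
    trial_duration_s: float = 15.0,
) -> SubjectBaseline:
    """Pool all of a subject's water-training sessions into one ILI baseline."""
    ilis_s: list[float] = []
    for s in training_sessions:
        if s.subject_id != subject_id:
            continue
        ilis_s.extend(s.ilis_ms() / 1000.0)
    if not ilis_s:
        raise BaselineError(f"no water-training ILIs for subject {subject_id!r}")
    valid = filter_valid_ilis(ilis_s)
    mean_ili = float(np.mean(valid))
    return SubjectBaseline(
        subject_id=subject_id,
        mean_valid_ili=mean_ili,
        n_valid_ilis=len(valid),
        max_potential_licks=max_potential_lick_rate(trial_duration_s, mean_ili),
    )


def compute_baselines(
    training_sessions: Sequence[LickSession], trial_duration_s: float = 15.0
) -> dict[str, SubjectBaseline]:
    subjects = sorted({s.subject_id for s in training_sessions})
    return {
        sid: compute_baseline(training_sessions, sid, trial_duration_s)
        for sid in subjects
    }


def summarize_brief_access(
    sessions: Sequence[LickSession],
    baselines: Mapping[str, SubjectBaseline],
    trial_duration_s: float = 15.0,
    initiation_limit_s: float = 30.0,
    average_over_sessions: bool = True,
) -> pd.DataFrame:
    """SLR table per (subject, tastant, concentration).

    Lick counts from the block presentations of each stimulus are averaged
    (non-initiated trials excluded, recorded in ``n_trials_used``), then
    divided by the subject's maximum potential licks.  With
    ``average_over_sessions=True`` (default) counts are pooled across test
    days before averaging; set it to False for a per-session table (a
    ``session_id`` column is then included).
    """
    missing = sorted(
        {s.subject_id for s in sessions if s.subject_id not in baselines}
    )
    if missing:
        raise BaselineError(f"no baseline for subjects: {', '.join(missing)}")

    rows = []
    for s in sessions:
        for tr in assemble_trials(s, trial_duration_s, initiation_limit_s):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "session_id": s.session_id,
                    "tastant": tr.tastant,
                    "concentration": tr.concentration,
                    "initiated": tr.initiated,
                    "n_licks": tr.n_licks,
                }
            )
    trials = pd.DataFrame(rows)
    keys = ["subject_id", "group", "tastant", "concentration"]
    if not average_over_sessions:
        keys = keys[:3] + ["session_id"] + keys[3:]

    out = []
    for key_vals, grp in trials.groupby(keys, sort=True, dropna=False):
        initiated = grp[grp["initiated"]]
        n_used = int(initiated.shape[0])
        rec = dict(zip(keys, key_vals))
        baseline = baselines[rec["subject_id"]]
        mean_licks = float(initiated["n_licks"].mean()) if n_used else float("nan")
        rec.update(
            mean_licks=mean_licks,
            n_trials_used=n_used,
            slr=standardized_lick_ratio(mean_licks, baseline.max_potential_licks)
            if n_used
            else float("nan"),
        )
        out.append(rec)
    return pd.DataFrame(out)
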