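"""Reading, validating and writing lick-event tables.

The atomic behavioral record is a :class:`LickSession`: an ordered train of
lick timestamps (integer milliseconds from session start, matching the 1-ms
resolution of contact lickometers) together with subject/group/session
metadata.  Brief-access sessions additionally carry a list of
:class:`TrialWindow` records describing when each stimulus tube was offered.

The on-disk format is a tidy CSV with one lick per row:

    subject_id, group, session_id, session_type, trial_id, tastant,
    concentration_value, concentration_unit, timestamp_ms

``trial_id`` is empty for long-term (23-h) and water-training sessions.
Trial access windows are stored in a companion CSV
(``trial_id, tastant, concentration, access_start_ms``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SESSION_TYPES = ("water_training", "brief_access", "long_term")

LICK_COLUMNS = [
    "subject_id",
    "group",
    "session_id",
    "session_type",
    "trial_id",
    "tastant",
    "concentration_value",
    "concentration_unit",
    "timestamp_ms",
]

TRIAL_COLUMNS = [
    "subject_id",
    "session_id",
    "trial_id",
    "tastant",
    "concentration",
    "access_start_ms",
]


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class ValidationError(ValueError):
    """Row-level data violates an invariant (ordering, duplicates, ...)."""


@dataclass(frozen=True)
class TrialWindow:
    """Access window for one brief-access trial.

    ``first_lick`` and ``window_end`` are filled in by
    :func:`assemble_trials`; on input only ``access_start`` is required.
    """

    trial_id: str
    tastant: str
    concentration: float
    access_start: int  # ms
    first_lick: int | None = None  # ms, None if never initiated
    window_end: int | None = None  # ms, first_lick + trial duration


@dataclass(frozen=True)
class TrialResult:
    """Per-trial outcome of a brief-access presentation.

    Non-initiated trials carry ``initiated=False`` and ``n_licks=None``
    (missing, not zero): the animal never sampled the stimulus, so a zero
    count would conflate motivation with taste-driven avoidance.
    """

    trial_id: str
    tastant: str
    concentration: float
    initiated: bool
    latency_ms: int | None
    n_licks: int | None
    ilis_ms: tuple[int, ...] = ()


@dataclass
class LickSession:
    """An ordered lick train for one subject in one session."""

    subject_id: str
    group: str
    session_type: str
    session_id: str
    licks: np.ndarray  # int64 ms, strictly increasing
    tastant: str = ""
    concentration: float = float("nan")
    concentration_unit: str = ""
    trials: list[TrialWindow] | None = None
    # generator ground truth (meal/burst boundaries etc.); never serialized
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.licks = np.asarray(self.licks, dtype=np.int64)
        if self.session_type not in SESSION_TYPES:
            raise ValidationError(
                f"unknown session_type {self.session_type!r}; "
                f"expected one of {SESSION_TYPES}"
            )
        if self.licks.ndim != 1:
            raise ValidationError("licks must be a 1-D timestamp array")
        if self.licks.size > 1:
            diffs = np.diff(self.licks)
            bad = np.nonzero(diffs <= 0)[0]
            if bad.size:
                raise ValidationError(
                    f"timestamps not strictly increasing at lick index {bad[0] + 1}"
                )
        if self.session_type == "brief_access" and not self.trials:
            raise ValidationError("brief_access session requires trial windows")

    @property
    def n_licks(self) -> int:
        return int(self.licks.size)

    def ilis_ms(self) -> np.ndarray:
        """Inter-lick intervals in milliseconds."""
        return np.diff(self.licks)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: Path) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def read_lick_events(
    path: str | Path, trials_path: str | Path | None = None
) -> list[LickSession]:
    """Read a lick-event CSV into validated sessions.

    Rows are grouped by (subject_id, session_id).  Timestamps must be integer
    milliseconds; sub-millisecond values are rejected rather than rounded.
    Duplicate timestamps within a subject-session are a validation error.

    If ``trials_path`` is given, its trial windows are attached to every
    brief-access session.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "session_id": str, "trial_id": str})
    _require_columns(df, LICK_COLUMNS, path)

    ts = df["timestamp_ms"]
    if not np.issubdtype(ts.dtype, np.integer):
        frac = np.mod(ts.to_numpy(dtype=float), 1.0)
        if np.any(frac != 0):
            row = int(np.nonzero(frac != 0)[0][0])
            raise ValidationError(
                f"{path}: non-integer timestamp_ms at row {row} "
                "(timestamps are 1-ms resolution; refusing to round)"
            )
        df["timestamp_ms"] = ts.astype(np.int64)

    trials_by_session: dict[tuple[str, str], list[TrialWindow]] = {}
    if trials_path is not None:
        trials_by_session = read_trials(trials_path)

    sessions: list[LickSession] = []
    for (subject, session_id), grp in df.groupby(["subject_id", "session_id"], sort=True):
        t = grp["timestamp_ms"].to_numpy()
        order = np.argsort(t, kind="stable")
        t_sorted = t[order]
        dup = np.nonzero(np.diff(t_sorted) == 0)[0]
        if dup.size:
            row = int(grp.index[order[dup[0] + 1]])
            raise ValidationError(
                f"{path}: duplicated timestamp for subject {subject!r} "
                f"session {session_id!r} at row {row}"
            )
        first = grp.iloc[0]
        session_type = str(first["session_type"])
        trials = (
            trials_by_session.get((str(subject), str(session_id)))
            if session_type == "brief_access"
            else None
        )
        if session_type == "brief_access" and not trials:
            raise ValidationError(
                f"{path}: no trial windows for brief_access session "
                f"{subject!r}/{session_id!r}"
            )
        sessions.append(
            LickSession(
                subject_id=str(subject),
                group=str(first["group"]),
                session_type=session_type,
                session_id=str(session_id),
                licks=t_sorted,
                tastant="" if pd.isna(first["tastant"]) else str(first["tastant"]),
                concentration=float(first["concentration_value"])
                if pd.notna(first["concentration_value"])
                else float("nan"),
                concentration_unit=""
                if pd.isna(first["concentration_unit"])
                else str(first["concentration_unit"]),
                trials=list(trials) if trials else None,
            )
        )
    return sessions


def write_lick_events(sessions: Iterable[LickSession], path: str | Path) -> None:
    """Write sessions to the canonical lick-event CSV (one lick per row)."""
    rows = []
    for s in sessions:
        trial_for_lick = _trial_ids_per_lick(s)
        for ts, trial_id in zip(s.licks, trial_for_lick):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "session_id": s.session_id,
                    "session_type": s.session_type,
                    "trial_id": trial_id,
                    "tastant": s.tastant,
                    "concentration_value": s.concentration,
                    "concentration_unit": s.concentration_unit,
                    "timestamp_ms": int(ts),
                }
            )
    pd.DataFrame(rows, columns=LICK_COLUMNS).to_csv(path, index=False)


def _trial_ids_per_lick(session: LickSession) -> list[str]:
    if not session.trials:
        return [""] * session.n_licks
    out = [""] * session.n_licks
    starts = [w.access_start for w in session.trials]
    bounds = starts[1:] + [np.iinfo(np.int64).max]
    for i, ts in enumerate(session.licks):
        for w, nxt in zip(session.trials, bounds):
            if w.access_start <= ts < nxt:
                out[i] = w.trial_id
                break
    return out


def read_trials(path: str | Path) -> dict[tuple[str, str], list[TrialWindow]]:
    """Read a trial-window CSV, keyed by (subject_id, session_id).

    Trial orders are pseudorandomized per subject, so windows must be keyed
    to the session they describe.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "session_id": str, "trial_id": str})
    _require_columns(df, TRIAL_COLUMNS, path)
    out: dict[tuple[str, str], list[TrialWindow]] = {}
    for r in df.itertuples():
        out.setdefault((str(r.subject_id), str(r.session_id)), []).append(
            TrialWindow(
                trial_id=str(r.trial_id),
                tastant=str(r.tastant),
                concentration=float(r.concentration),
                access_start=int(r.access_start_ms),
            )
        )
    return out


def write_trials(sessions: Iterable[LickSession], path: str | Path) -> None:
    """Write the trial windows of brief-access sessions, keyed per session."""
    rows = []
    for s in sessions:
        for w in s.trials or ():
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "session_id": s.session_id,
                    "trial_id": w.trial_id,
                    "tastant": w.tastant,
                    "concentration": w.concentration,
                    "access_start_ms": w.access_start,
                }
            )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def assemble_trials(
    session: LickSession,
    trial_duration_s: float = 15.0,
    initiation_limit_s: float = 30.0,
) -> list[TrialResult]:
    """Assemble per-trial lick counts, latencies and ILIs for a brief-access session.

    The trial window opens at the first lick after stimulus access and is
    half-open, ``[first_lick, first_lick + trial_duration)``: a lick landing
    exactly on the closing boundary is excluded.  Trials with no lick within
    the initiation limit are flagged non-initiated with a missing (None) count.
    Licks falling outside every trial window trigger a warning and are ignored.
    """
    if session.session_type != "brief_access":
        raise ValidationError("assemble_trials requires a brief_access session")
    if not session.trials:
        raise ValidationError("session has no trial windows")

    dur_ms = int(round(trial_duration_s * 1000))
    limit_ms = int(round(initiation_limit_s * 1000))
    licks = session.licks
    results: list[TrialResult] = []
    used = np.zeros(licks.size, dtype=bool)

    for window in session.trials:
        start = window.access_start
        idx = np.searchsorted(licks, start, side="left")
        if idx >= licks.size or licks[idx] - start > limit_ms:
            results.append(
                TrialResult(
                    trial_id=window.trial_id,
                    tastant=window.tastant,
                    concentration=window.concentration,
                    initiated=False,
                    latency_ms=None,
                    n_licks=None,
                )
            )
            continue
        first = int(licks[idx])
        end = first + dur_ms  # half-open [first, end)
        j = np.searchsorted(licks, end, side="left")
        in_window = licks[idx:j]
        used[idx:j] = True
        results.append(
            TrialResult(
                trial_id=window.trial_id,
                tastant=window.tastant,
                concentration=window.concentration,
                initiated=True,
                latency_ms=first - start,
                n_licks=int(in_window.size),
                ilis_ms=tuple(int(d) for d in np.diff(in_window)),
            )
        )

    n_orphan = int((~used).sum())
    if n_orphan:
        warnings.warn(
            f"{n_orphan} licks fall outside every trial window and were ignored",
            stacklevel=2,
        )
    return results
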