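"""Chorda tympani (CT) whole-nerve response quantification.

Raw multiunit activity is full-wave rectified and passed through a
first-order leaky integrator (default time constant 1.5 s), emulating the
analog integrator of a nerve-recording rig.  A response magnitude is the
height of the integrated trace at a fixed latency after stimulus onset
(default 20 s) minus the mean pre-stimulus baseline.  Test magnitudes are
expressed relative to the mean of the bracketing reference-stimulus
(500 mM NH4Cl) responses; a stimulus series passes quality control only if
the two bracketing reference magnitudes deviate from each other by at most
10% of their mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter


class TraceError(ValueError):
    """Trace or event table violates an invariant."""


@dataclass(frozen=True)
class StimulusEvent:
    label: str
    onset_s: float
    rinse_s: float
    is_reference: bool

    def __post_init__(self) -> None:
        if self.rinse_s <= self.onset_s:
            raise TraceError(f"event {self.label!r}: rinse must follow onset")


@dataclass
class CTTrace:
    """Uniformly sampled nerve signal plus its stimulus-event table."""

    time_s: np.ndarray
    signal: np.ndarray
    events: list[StimulusEvent]

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_s.shape != self.signal.shape or self.time_s.ndim != 1:
            raise TraceError("time and signal must be 1-D arrays of equal length")
        if self.time_s.size < 2:
            raise TraceError("trace needs at least two samples")
        dt = np.diff(self.time_s)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise TraceError("sampling grid is not uniform")
        prev_rinse = -np.inf
        for ev in self.events:
            if ev.onset_s < prev_rinse:
                raise TraceError(f"event {ev.label!r} overlaps the previous event")
            prev_rinse = ev.rinse_s
            if ev.onset_s < self.time_s[0] or ev.rinse_s > self.time_s[-1]:
                raise TraceError(f"event {ev.label!r} outside trace extent")
        refs = [ev for ev in self.events if ev.is_reference]
        if len(refs) < 2:
            raise TraceError("need at least two reference applications")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])


@dataclass(frozen=True)
class CTResponse:
    """One stimulus response with its bracket and quality-control outcome.

    ``normalized`` is computed even when QC fails; ``excluded`` mirrors
    ``not qc_pass`` so failing series stay visible but flagged.
    """

    label: str
    onset_s: float
    is_reference: bool
    raw: float
    pre_ref: float
    post_ref: float
    normalized: float
    bracket_deviation: float
    qc_pass: bool

    @property
    def excluded(self) -> bool:
        return not self.qc_pass


def integrate_trace(
    raw: np.ndarray, sampling_rate: float, tau_s: float = 1.5
) -> np.ndarray:
    """Full-wave rectification followed by first-order leaky integration.

    Exact exponential update: ``y[n] = y[n-1] + (1 - exp(-dt/tau)) *
    (|x[n]| - y[n-1])`` with ``y[0] = |x[0]|``.  The output tracks the local
    mean of the rectified signal; for constant input c it converges to c, and
    a unit step reaches 1 - 1/e after one time constant.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    x = np.abs(np.asarray(raw, dtype=float))
    a = 1.0 - np.exp(-1.0 / (sampling_rate * tau_s))
    # y[0] = |x[0]| corresponds to lfilter initial condition (1-a)*|x[0]|
    y, _ = lfilter([a], [1.0, -(1.0 - a)], x, zi=[(1.0 - a) * x[0]])
    return y


def response_magnitude(
    time_s: np.ndarray,
    integrated: np.ndarray,
    onset_s: float,
    measure_at_s: float = 20.0,
    baseline_window_s: float = 5.0,
) -> float:
    """Baseline-subtracted height of the integrated trace at onset + ``measure_at_s``.

    The height is the instantaneous value at the sample nearest the
    measurement time; the baseline is the mean over
    ``[onset - baseline_window, onset)``.  Negative magnitudes are returned
    as-is (the caller may flag them).
    """
    time_s = np.asarray(time_s, dtype=float)
    t_meas = onset_s + measure_at_s
    if t_meas > time_s[-1] + 1e-9:
        raise TraceError("measurement time beyond trace end")
    if onset_s - baseline_window_s < time_s[0] - 1e-9:
        raise TraceError("baseline window precedes trace start")
    idx = int(np.argmin(np.abs(time_s - t_meas)))
    base_mask = (time_s >= onset_s - baseline_window_s) & (time_s < onset_s)
    if not np.any(base_mask):
        raise TraceError("empty baseline window")
    return float(integrated[idx] - integrated[base_mask].mean())


def bracket_qc(pre_ref: float, post_ref: float, tol: float = 0.10) -> tuple[bool, float]:
    """QC on bracketing reference magnitudes.

    deviation = |pre - post| / mean(pre, post); passes iff deviation <= tol
    (inclusive).  Symmetric in its arguments.
    """
    if pre_ref <= 0 or post_ref <= 0:
        raise TraceError("non-positive reference magnitude; series unusable")
    mean = 0.5 * (pre_ref + post_ref)
    deviation = abs(pre_ref - post_ref) / mean
    return deviation <= tol, deviation


def normalize_series(
    trace: CTTrace,
    tau_s: float = 1.5,
    measure_at_s: float = 20.0,
    baseline_window_s: float = 5.0,
    qc_tol: float = 0.10,
) -> list[CTResponse]:
    """Normalize every test response to its bracketing reference magnitudes.

    Each test stimulus is divided by the mean of the nearest reference
    magnitude before and after it; one reference application may close one
    series and open the next.  Series whose bracket deviates by more than
    ``qc_tol`` are computed but flagged ``qc_pass=False``.
    """
    integ = integrate_trace(trace.signal, trace.sampling_rate, tau_s=tau_s)
    magnitudes = [
        response_magnitude(
            trace.time_s, integ, ev.onset_s, measure_at_s, baseline_window_s
        )
        for ev in trace.events
    ]
    ref_idx = [i for i, ev in enumerate(trace.events) if ev.is_reference]

    # resolve every event's bracket before computing QC, so a structurally
    # missing bracket is reported ahead of any magnitude problem
    brackets: list[tuple[int, int]] = []
    for i, ev in enumerate(trace.events):
        if ev.is_reference:
            # a reference brackets itself together with its nearest partner
            others = [j for j in ref_idx if j != i]
            if not others:
                raise TraceError(f"no bracketing partner for reference {ev.label!r}")
            partner = min(others, key=lambda j: abs(j - i))
            brackets.append(tuple(sorted((i, partner))))
        else:
            pre = [j for j in ref_idx if j < i]
            post = [j for j in ref_idx if j > i]
            if not pre or not post:
                raise TraceError(f"stimulus {ev.label!r} lacks a reference bracket")
            brackets.append((pre[-1], post[0]))

    out: list[CTResponse] = []
    for (ev, raw), (pre_i, post_i) in zip(
        zip(trace.events, magnitudes), brackets
    ):
        pre_ref, post_ref = magnitudes[pre_i], magnitudes[post_i]
        qc_pass, deviation = bracket_qc(pre_ref, post_ref, tol=qc_tol)
        out.append(
            CTResponse(
                label=ev.label,
                onset_s=ev.onset_s,
                is_reference=ev.is_reference,
                raw=raw,
                pre_ref=pre_ref,
                post_ref=post_ref,
                normalized=raw / (0.5 * (pre_ref + post_ref)),
                bracket_deviation=deviation,
                qc_pass=qc_pass,
            )
        )
    return out


def responses_table(responses: Sequence[CTResponse]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "onset_s": r.onset_s,
                "is_reference": r.is_reference,
                "raw": r.raw,
                "pre_ref": r.pre_ref,
                "post_ref": r.post_ref,
                "normalized": r.normalized,
                "bracket_deviation": r.bracket_deviation,
                "qc_pass": r.qc_pass,
            }
            for r in responses
        ]
    )


def read_trace(trace_path: str | Path, events_path: str | Path) -> CTTrace:
    """Read a trace CSV (time_s, signal) and events CSV (label, onset_s, rinse_s, is_reference)."""
    tdf = pd.read_csv(trace_path)
    for col in ("time_s", "signal"):
        if col not in tdf.columns:
            raise TraceError(f"{trace_path}: missing column {col!r}")
    edf = pd.read_csv(events_path)
    for col in ("label", "onset_s", "rinse_s", "is_reference"):
        if col not in edf.columns:
            raise TraceError(f"{events_path}: missing column {col!r}")
    events = [
        StimulusEvent(
            label=str(r.label),
            onset_s=float(r.onset_s),
            rinse_s=float(r.rinse_s),
            is_reference=bool(r.is_reference),
        )
        for r in edf.itertuples()
    ]
    return CTTrace(
        time_s=tdf["time_s"].to_numpy(),
        signal=tdf["signal"].to_numpy(),
        events=events,
    )


def write_trace(trace: CTTrace, trace_path: str | Path, events_path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "signal": trace.signal}).to_csv(
        trace_path, index=False
    )
    pd.DataFrame(
        [
            {
                "label": ev.label,
                "onset_s": ev.onset_s,
                "rinse_s": ev.rinse_s,
                "is_reference": ev.is_reference,
            }
            for ev in trace.events
        ]
    ).to_csv(events_path, index=False)
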