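"""Synthetic gustometer/lickometer event streams and nerve traces.

Every downstream stage of the pipeline is testable against this generator's
known ground truth.  Lick generation is hierarchical, reproducing the three
timescales the segmentation rules target:

* meals arrive as a renewal process whose inter-meal pauses are heavy-tailed
  (lognormal) with a mean well above the 600-s meal-termination threshold;
* each meal contains a geometric number of bursts separated by intra-meal
  pauses between the burst threshold (1 s) and the meal threshold;
* each burst contains a geometric number of licks with truncated-normal
  within-burst ILIs (default mean 120 ms, sd 20 ms, truncated to
  (50, 300) ms — the rodent "local" lick rhythm).

Appetitive drive maps concentration to a value in (0, 1] through a Hill-type
saturating curve (decreasing for aversive tastants); treated groups apply a
multiplicative suppression factor to the drive for sweet and salt stimuli.
All randomness flows from one seed through per-(subject, session, purpose)
keyed generators, so adding subjects never perturbs existing streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ct_nerve import CTTrace, StimulusEvent
from .io import LickSession, TrialWindow

HOURS_23_MS = 23 * 3600 * 1000


class ConfigurationError(ValueError):
    """A simulation parameter violates its constraints."""


@dataclass(frozen=True)
class TastantParams:
    """Concentration-response parameters for one tastant.

    ``half_max`` is the concentration producing half-maximal drive (same
    units as the concentrations passed in); ``slope`` is the Hill exponent.
    ``appetitive`` selects an increasing (True) or decreasing (False) curve;
    ``suppressed`` marks tastants whose drive the group suppression factor
    multiplies (sweet and salt).
    """

    half_max: float
    slope: float = 2.0
    appetitive: bool = True
    suppressed: bool = False

    def drive(self, concentration: float) -> float:
        """Lick drive in (0, 1]: Hill curve of concentration."""
        if concentration <= 0:  # water
            return 1.0 if not self.appetitive else 0.35
        h = concentration**self.slope / (
            concentration**self.slope + self.half_max**self.slope
        )
        if self.appetitive:
            # water-level drive rising toward 1 with concentration
            return 0.35 + 0.65 * h
        return max(1.0 - 0.9 * h, 0.05)


DEFAULT_TASTANTS: dict[str, TastantParams] = {
    "water": TastantParams(half_max=1.0, appetitive=False),
    "sucrose": TastantParams(half_max=75.0, slope=1.5, suppressed=True),
    "saccharin": TastantParams(half_max=4.0, slope=1.5, suppressed=True),
    "nacl": TastantParams(half_max=150.0, slope=2.0, appetitive=False, suppressed=True),
    "quinine": TastantParams(half_max=0.05, slope=1.5, appetitive=False),
    "msg": TastantParams(half_max=100.0, slope=1.5),
}


@dataclass(frozen=True)
class BehaviorSimConfig:
    """Ground-truth parameters for behavioral stream generation."""

    seed: int = 0
    n_subjects_per_group: int = 8
    groups: tuple[str, ...] = ("control", "acute_lps", "chronic_lps")
    within_burst_ili_mean: float = 0.12  # s
    within_burst_ili_sd: float = 0.02  # s
    within_burst_ili_bounds: tuple[float, float] = (0.05, 0.3)  # s
    burst_length_mean: float = 37.0  # licks, geometric law (~4.4-s bursts)
    intra_meal_pause_mean: float = 55.0  # s
    intra_meal_pause_dispersion: float = 0.6  # lognormal sigma
    inter_meal_pause_mean: float = 4000.0  # s, must exceed 600
    meals_per_session_mean: float = 8.0
    bursts_per_meal_mean: float = 45.0
    tastants: Mapping[str, TastantParams] = field(
        default_factory=lambda: dict(DEFAULT_TASTANTS)
    )
    group_effect: Mapping[str, float] = field(
        default_factory=lambda: {"control": 1.0, "acute_lps": 0.7, "chronic_lps": 0.5}
    )

    def __post_init__(self) -> None:
        positive = {
            "within_burst_ili_mean": self.within_burst_ili_mean,
            "within_burst_ili_sd": self.within_burst_ili_sd,
            "burst_length_mean": self.burst_length_mean,
            "intra_meal_pause_mean": self.intra_meal_pause_mean,
            "inter_meal_pause_mean": self.inter_meal_pause_mean,
            "meals_per_session_mean": self.meals_per_session_mean,
            "bursts_per_meal_mean": self.bursts_per_meal_mean,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.inter_meal_pause_mean <= 600:
            raise ConfigurationError(
                "inter_meal_pause_mean must exceed the 600-s meal threshold"
            )
        lo, hi = self.within_burst_ili_bounds
        if not (0 < lo < hi):
            raise ConfigurationError("ILI truncation bounds must satisfy 0 < lo < hi")
        for group, f in self.group_effect.items():
            if not (0 < f <= 1):
                raise ConfigurationError(
                    f"suppression factor for {group!r} must be in (0, 1]"
                )
        if self.n_subjects_per_group < 1:
            raise ConfigurationError("n_subjects_per_group must be >= 1")


@dataclass(frozen=True)
class CTSimConfig:
    """Ground-truth parameters for nerve-trace generation.

    ``stimulus_events`` holds (label, onset_s, rinse_s, true_amplitude)
    tuples; the first and last must be reference applications (label
    ``reference_label``).  ``tau_s`` is the integrator time constant the
    downstream analysis is expected to use.
    """

    seed: int = 0
    sampling_rate: float = 1000.0  # Hz
    baseline_noise_sd: float = 0.01
    stimulus_events: tuple[tuple[str, float, float, float], ...] = ()
    reference_amplitude: float = 1.0
    reference_label: str = "NH4Cl"
    tau_s: float = 1.5
    ramp_tau_s: float = 0.4
    decay_tau_s: float = 2.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if not self.stimulus_events:
            raise ConfigurationError("stimulus_events must be non-empty")
        prev_rinse = -np.inf
        for label, onset, rinse, _amp in self.stimulus_events:
            if rinse <= onset:
                raise ConfigurationError(f"event {label!r}: rinse must follow onset")
            if onset < prev_rinse:
                raise ConfigurationError(
                    f"event {label!r} overlaps the previous event"
                )
            prev_rinse = rinse
        first, last = self.stimulus_events[0], self.stimulus_events[-1]
        if first[0] != self.reference_label or last[0] != self.reference_label:
            raise ConfigurationError(
                "first and last stimulus events must be reference applications"
            )


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode())


def stream_rng(seed: int, *keys) -> np.random.Generator:
    """Named random generator keyed by (seed, *keys).

    Each (subject, session, purpose) tuple gets an independent stream, so
    enlarging a cohort never perturbs streams already generated.
    """
    entropy = [int(seed) & 0xFFFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _truncnorm_ilis(rng: np.random.Generator, n: int, cfg: BehaviorSimConfig) -> np.ndarray:
    lo, hi = cfg.within_burst_ili_bounds
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(cfg.within_burst_ili_mean, cfg.within_burst_ili_sd, size=n - filled)
        ok = draw[(draw > lo) & (draw < hi)]
        out[filled : filled + ok.size] = ok
        filled += ok.size
    return out


def _geometric_count(rng: np.random.Generator, mean: float, minimum: int = 1) -> int:
    # geometric on {minimum, minimum+1, ...} with the requested mean
    excess = max(mean - minimum, 1e-9)
    return minimum + rng.geometric(1.0 / (1.0 + excess)) - 1


def _burst_licks(
    rng: np.random.Generator,
    start_s: float,
    n_licks: int,
    cfg: BehaviorSimConfig,
    cap_span_s: float | None = None,
) -> np.ndarray:
    """Lick times for one burst; optionally resample the head so the first
    5 licks span <= cap_span_s (guarantees the meal-initiation rule)."""
    ilis = _truncnorm_ilis(rng, max(n_licks - 1, 0), cfg)
    if cap_span_s is not None and n_licks >= 5:
        while ilis[:4].sum() > cap_span_s:
            ilis[:4] = _truncnorm_ilis(rng, 4, cfg)
    return start_s + np.concatenate(([0.0], np.cumsum(ilis)))


def gen_longterm_session(
    config: BehaviorSimConfig,
    subject: str,
    tastant: str,
    concentration: float,
    group: str = "control",
    session_id: str = "longterm-1",
    n_meals: int | None = None,
    duration_h: float = 23.0,
) -> LickSession:
    """Simulate a 23-h single-bottle session for one subject.

    Ground-truth meal and burst boundaries are attached under
    ``session.annotations`` (``meal_slices``: (start, stop) lick-index pairs;
    ``burst_sizes``: per-meal lists) for recovery tests.  The suppression
    factor for treated groups multiplies the expected number of bursts per
    meal for suppressed (sweet/salt) tastants, scaling session licks.
    """
    if tastant not in config.tastants:
        raise ConfigurationError(f"unknown tastant {tastant!r}")
    params = config.tastants[tastant]
    factor = config.group_effect.get(group, 1.0)
    drive = params.drive(concentration)
    if params.suppressed:
        drive *= factor

    rng = stream_rng(config.seed, subject, session_id, "longterm", tastant)
    duration_s = duration_h * 3600.0

    target_meals = (
        n_meals
        if n_meals is not None
        else max(1, int(rng.poisson(config.meals_per_session_mean)))
    )
    # heavy-tailed inter-meal pauses: lognormal with the configured mean,
    # clipped above the termination threshold so ground truth stays exact
    sigma = 0.5
    mu = np.log(config.inter_meal_pause_mean) - 0.5 * sigma**2

    licks: list[np.ndarray] = []
    meal_slices: list[tuple[int, int]] = []
    burst_sizes: list[list[int]] = []
    t = float(np.clip(rng.lognormal(mu, sigma), 650.0, None))
    n_so_far = 0
    for _ in range(target_meals):
        if t >= duration_s - 4000.0:
            break  # not enough room left for a whole meal
        meal_start_idx = n_so_far
        # Poisson burst count per meal (min 1); drive scales meal size
        n_bursts = max(
            1, int(rng.poisson(max(config.bursts_per_meal_mean * drive, 1.0)))
        )
        sizes: list[int] = []
        for b in range(n_bursts):
            n_in_burst = _geometric_count(rng, config.burst_length_mean)
            if b == 0:
                n_in_burst = max(n_in_burst, 5)
            burst = _burst_licks(
                rng, t, n_in_burst, config, cap_span_s=0.95 if b == 0 else None
            )
            licks.append(burst)
            sizes.append(n_in_burst)
            n_so_far += n_in_burst
            t = float(burst[-1])
            if b < n_bursts - 1:
                pause = float(
                    np.clip(
                        rng.lognormal(
                            np.log(config.intra_meal_pause_mean)
                            - 0.5 * config.intra_meal_pause_dispersion**2,
                            config.intra_meal_pause_dispersion,
                        ),
                        1.05,
                        550.0,
                    )
                )
                t += pause
        meal_slices.append((meal_start_idx, n_so_far))
        burst_sizes.append(sizes)
        t += float(np.clip(rng.lognormal(mu, sigma), 650.0, None))

    ts = np.concatenate(licks) if licks else np.empty(0)
    ts_ms = np.round(ts * 1000.0).astype(np.int64)
    ts_ms = ts_ms[ts_ms <= HOURS_23_MS]
    return LickSession(
        subject_id=subject,
        group=group,
        session_type="long_term",
        session_id=session_id,
        licks=ts_ms,
        tastant=tastant,
        concentration=concentration,
        concentration_unit="mM",
        annotations={
            "meal_slices": meal_slices,
            "burst_sizes": burst_sizes,
            "drive": drive,
            "n_meals": len(meal_slices),
        },
    )


def _lick_train(
    rng: np.random.Generator,
    start_s: float,
    end_s: float,
    drive: float,
    cfg: BehaviorSimConfig,
) -> np.ndarray:
    """Bout-structured lick train in [start, end): with probability ``drive``
    the next lick follows at a within-burst ILI, otherwise after a 1-4 s pause."""
    horizon = end_s - start_s
    offsets = [np.zeros(1)]
    total = 0.0
    chunk = 128
    while True:
        keep = rng.random(chunk) < drive
        gaps = np.where(
            keep, _truncnorm_ilis(rng, chunk, cfg), rng.uniform(1.0, 4.0, chunk)
        )
        cum = total + np.cumsum(gaps)
        stop = int(np.searchsorted(cum, horizon))
        offsets.append(cum[:stop])
        if stop < chunk:
            break
        total = float(cum[-1])
    return start_s + np.concatenate(offsets)


def gen_water_training_session(
    config: BehaviorSimConfig,
    subject: str,
    group: str = "control",
    session_id: str = "training-1",
    duration_s: float = 180.0,
) -> LickSession:
    """Steady licking to water under restriction: near-maximal drive."""
    rng = stream_rng(config.seed, subject, session_id, "training")
    ts = _lick_train(rng, 0.5, duration_s, drive=0.97, cfg=config)
    return LickSession(
        subject_id=subject,
        group=group,
        session_type="water_training",
        session_id=session_id,
        licks=np.round(ts * 1000.0).astype(np.int64),
        tastant="water",
        concentration=0.0,
        concentration_unit="",
    )


def gen_brief_access_session(
    config: BehaviorSimConfig,
    subject: str,
    stimulus_array: Sequence[tuple[str, float]],
    group: str = "control",
    session_id: str = "brief-1",
    n_blocks: int = 3,
    trial_duration_s: float = 15.0,
    initiation_limit_s: float = 30.0,
    intertrial_s: float = 10.0,
) -> LickSession:
    """Simulate one brief-access session: the stimulus array presented once
    per block in pseudorandom order, ``n_blocks`` blocks.

    Each trial offers ``initiation_limit_s`` to initiate; initiated trials
    get a bout-structured lick train for ``trial_duration_s`` after the
    first lick.  Trial windows are attached; the pseudorandom block order is
    reproducible from the seed.
    """
    if not stimulus_array:
        raise ConfigurationError("stimulus array must be non-empty")
    rng = stream_rng(config.seed, subject, session_id, "brief_access")

    trials: list[TrialWindow] = []
    licks: list[np.ndarray] = []
    t = 0.0
    trial_no = 0
    for block in range(n_blocks):
        order = rng.permutation(len(stimulus_array))
        for idx in order:
            tastant, conc = stimulus_array[idx]
            if tastant not in config.tastants:
                raise ConfigurationError(f"unknown tastant {tastant!r}")
            params = config.tastants[tastant]
            drive = params.drive(conc)
            if params.suppressed:
                drive *= config.group_effect.get(group, 1.0)
            access = t
            trial_no += 1
            trial_id = f"{block + 1}-{trial_no:02d}"
            p_initiate = min(1.0, 0.85 + 0.15 * drive)
            if rng.random() < p_initiate:
                latency = float(np.clip(rng.exponential(2.0) + 0.3, 0.3, initiation_limit_s - 0.5))
                first = access + latency
                # 2-ms guard keeps ms-rounded licks inside the half-open window
                train = _lick_train(
                    rng, first, first + trial_duration_s - 0.002, drive, config
                )
                licks.append(train)
                t = first + trial_duration_s + intertrial_s
            else:
                t = access + initiation_limit_s + intertrial_s
            trials.append(
                TrialWindow(
                    trial_id=trial_id,
                    tastant=tastant,
                    concentration=conc,
                    access_start=int(round(access * 1000)),
                )
            )
    ts = np.concatenate(licks) if licks else np.empty(0)
    return LickSession(
        subject_id=subject,
        group=group,
        session_type="brief_access",
        session_id=session_id,
        licks=np.round(ts * 1000.0).astype(np.int64),
        trials=trials,
    )


def gen_ct_trace(config: CTSimConfig) -> CTTrace:
    """Simulate a raw nerve trace from the configured stimulus series.

    The raw signal is zero-mean: Gaussian baseline noise plus stimulus-locked
    Gaussian activity whose rectified mean equals the event's true amplitude
    times an envelope (exponential ramp to plateau after onset, exponential
    decay after rinse).  Rectify-and-integrate downstream therefore recovers
    the true amplitudes.  Ground truth is attached as ``trace.annotations``
    is not used here; the config itself carries the true amplitudes.
    """
    last_rinse = config.stimulus_events[-1][2]
    total = last_rinse + 30.0
    n = int(round(total * config.sampling_rate)) + 1
    time = np.arange(n) / config.sampling_rate
    rng = stream_rng(config.seed, "ct_trace")

    envelope = np.zeros(n)
    for label, onset, rinse, amp in config.stimulus_events:
        if label == config.reference_label and amp is None:
            amp = config.reference_amplitude
        e = np.zeros(n)
        during = (time >= onset) & (time < rinse)
        e[during] = 1.0 - np.exp(-(time[during] - onset) / config.ramp_tau_s)
        after = time >= rinse
        plateau = 1.0 - np.exp(-(rinse - onset) / config.ramp_tau_s)
        e[after] = plateau * np.exp(-(time[after] - rinse) / config.decay_tau_s)
        envelope += amp * e

    # zero-mean carrier whose rectified mean equals the envelope
    carrier = rng.standard_normal(n) / np.sqrt(2.0 / np.pi)
    signal = envelope * carrier + rng.normal(0.0, config.baseline_noise_sd, size=n)

    events = [
        StimulusEvent(
            label=label,
            onset_s=onset,
            rinse_s=rinse,
            is_reference=(label == config.reference_label),
        )
        for label, onset, rinse, _ in config.stimulus_events
    ]
    return CTTrace(time_s=time, signal=signal, events=events)


def standard_ct_series(
    test_amplitudes: Sequence[tuple[str, float]],
    reference_amplitude: float = 1.0,
    stimulus_s: float = 25.0,
    rinse_gap_s: float = 35.0,
    start_s: float = 10.0,
    reference_label: str = "NH4Cl",
) -> tuple[tuple[str, float, float, float], ...]:
    """Build a bracketed stimulus-event tuple: reference, tests, reference.

    Each application lasts ``stimulus_s`` (matching the ~25-s applications
    followed by a water rinse) with ``rinse_gap_s`` between applications.
    """
    events = []
    t = start_s
    seq = (
        [(reference_label, reference_amplitude)]
        + list(test_amplitudes)
        + [(reference_label, reference_amplitude)]
    )
    for label, amp in seq:
        events.append((label, t, t + stimulus_s, amp))
        t += stimulus_s + rinse_gap_s
    return tuple(events)
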