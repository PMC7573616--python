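import numpy as np
import pytest

from lickometry import BehaviorSimConfig, CTSimConfig, standard_ct_series

SUCROSE_ARRAY = [
    ("water", 0.0),
    ("sucrose", 10.0),
    ("sucrose", 50.0),
    ("sucrose", 100.0),
    ("sucrose", 150.0),
]


@pytest.fixture
def behavior_config() -> BehaviorSimConfig:
    return BehaviorSimConfig(seed=42)


@pytest.fixture
def small_longterm_config() -> BehaviorSimConfig:
    """Small meals for fast segmentation tests."""
    return BehaviorSimConfig(
        seed=42,
        burst_length_mean=8.0,
        bursts_per_meal_mean=6.0,
        intra_meal_pause_mean=5.0,
        inter_meal_pause_mean=1200.0,
        meals_per_session_mean=5.0,
    )


@pytest.fixture
def ct_config() -> CTSimConfig:
    events = standard_ct_series(
        [("sucrose_100", 0.4), ("sucrose_500", 0.7), ("sucrose_1000", 0.9)],
        reference_amplitude=1.0,
    )
    return CTSimConfig(seed=7, stimulus_events=events, sampling_rate=1000.0)


def oracle_segment_meals(t_ms, init_count=5, window_ms=1000, gap_ms=600_000):
    """Literal, exhaustive reference: scan every index for the initiation run,
    extend until the first terminating gap.  Returns (onset, last) index pairs."""
    t = list(t_ms)
    n = len(t)
    meals = []
    j = 0
    while j <= n - init_count:
        onset = None
        for i in range(j, n - init_count + 1):
            if t[i + init_count - 1] - t[i] <= window_ms:
                onset = i
                break
        if onset is None:
            break
        k = onset
        while k < n - 1 and t[k + 1] - t[k] < gap_ms:
            k += 1
        meals.append((onset, k))
        j = k + 1
    return meals


def oracle_segment_bursts(t_ms, pause_ms=1000):
    """Reference burst split: cut at every ILI strictly above the pause."""
    bursts = []
    current = [t_ms[0]]
    for prev, cur in zip(t_ms[:-1], t_ms[1:]):
        if cur - prev > pause_ms:
            bursts.append(current)
            current = []
        current.append(cur)
    bursts.append(current)
    return bursts


def random_lick_stream(rng: np.random.Generator, max_licks=200) -> np.ndarray:
    """Adversarial stream mixing within-burst ILIs, pauses, meal-scale gaps and
    exact threshold boundaries (1 s ILIs, 600 s gaps, 1 s initiation spans)."""
    n = int(rng.integers(0, max_licks + 1))
    if n == 0:
        return np.empty(0, dtype=np.int64)
    kinds = rng.random(n - 1) if n > 1 else np.empty(0)
    gaps = np.empty(n - 1, dtype=np.int64)
    for i, u in enumerate(kinds):
        if u < 0.55:
            gaps[i] = rng.integers(60, 400)  # within-burst
        elif u < 0.75:
            gaps[i] = rng.integers(1001, 30_000)  # intra-meal pause
        elif u < 0.85:
            gaps[i] = rng.integers(550_000, 900_000)  # near/over meal gap
        elif u < 0.92:
            gaps[i] = 1000  # exact burst boundary (stays within burst)
        elif u < 0.96:
            gaps[i] = 600_000  # exact meal-termination boundary
        else:
            gaps[i] = 250  # makes 5-lick/1-s runs exactly borderline
    return np.concatenate(([0], np.cumsum(gaps)))
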