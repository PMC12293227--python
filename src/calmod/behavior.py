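"""Behavioral state segmentation from wheel speed and whisker motion energy.

Each session is partitioned exhaustively into three states:

* ``Locomotion`` — forward wheel speed above 1 cm/s; interruptions shorter
  than 0.5 s are merged and bouts must last strictly longer than 0.5 s.
* ``StillWhisking`` — still periods with concurrent whisker movement,
  detected from the smoothed motion-energy trace against a 1st-percentile
  baseline W0 (whisking is assessed only during still periods, since mice
  whisk continuously while running).
* ``Still`` — everything else.

Intervals are half-open ``[start, end)`` in seconds; sample ``i`` covers
``[i/fs, (i+1)/fs)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ContractError

STILL = "Still"
STILL_WHISKING = "StillWhisking"
LOCOMOTION = "Locomotion"
STATES = (STILL, STILL_WHISKING, LOCOMOTION)

SPEED_THRESHOLD_CMPS = 1.0      # locomotion speed threshold
LOC_MERGE_GAP_S = 0.5           # merge locomotion interruptions shorter than this
LOC_MIN_BOUT_S = 0.5            # locomotion bouts must strictly exceed this
WHISK_SMOOTH_S = 0.33           # moving-average window on motion energy
WHISK_BASELINE_PERCENTILE = 1.0  # percentile defining the baseline W0
WHISK_THRESHOLD_FACTOR = 1.5    # whisking when smoothed energy > factor * W0
WHISK_MERGE_GAP_S = 0.3         # merge whisk-bout gaps shorter than this
WHISK_MIN_BOUT_S = 0.4          # drop whisk bouts shorter than this

_EPS = 1e-9


@dataclass(frozen=True)
class BehaviorTrace:
    """Wheel speed (cm/s) and whisker motion energy (a.u.) on one clock."""

    speed: np.ndarray
    whisk_energy: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        speed = np.asarray(self.speed, dtype=float)
        whisk = np.asarray(self.whisk_energy, dtype=float)
        if speed.ndim != 1 or whisk.ndim != 1:
            raise ContractError("behavior channels must be one-dimensional")
        if len(speed) == 0:
            raise ContractError("behavior trace is empty")
        if len(speed) != len(whisk):
            raise ContractError(
                f"speed length {len(speed)} != whisk_energy length {len(whisk)}"
            )
        if not (np.all(np.isfinite(speed)) and np.all(np.isfinite(whisk))):
            raise ContractError("behavior channels contain non-finite samples")
        if np.any(speed < 0):
            raise ContractError("speed must be nonnegative")
        if self.sampling_rate <= 0:
            raise ContractError("sampling_rate must be positive")
        object.__setattr__(self, "speed", speed)
        object.__setattr__(self, "whisk_energy", whisk)

    @property
    def n_samples(self) -> int:
        return len(self.speed)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class StateSegmentation:
    """Exhaustive, sorted, disjoint partition of a session into the three states."""

    intervals: tuple[tuple[float, float, str], ...]
    sampling_rate: float

    def __post_init__(self):
        ivs = tuple((float(s), float(e), str(lab)) for s, e, lab in self.intervals)
        if not ivs:
            raise ContractError("segmentation must contain at least one interval")
        if abs(ivs[0][0]) > _EPS:
            raise ContractError("segmentation must start at 0")
        for (s, e, lab) in ivs:
            if lab not in STATES:
                raise ContractError(f"unknown state label {lab!r}; allowed: {STATES}")
            if e <= s:
                raise ContractError(f"empty or inverted interval ({s}, {e})")
        for (_, e0, _), (s1, _, _) in zip(ivs, ivs[1:]):
            if abs(e0 - s1) > _EPS:
                raise ContractError("intervals must be contiguous and sorted")
        object.__setattr__(self, "intervals", ivs)

    @property
    def duration(self) -> float:
        return self.intervals[-1][1]

    def intervals_for(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, lab in self.intervals if lab == label]

    def total_time(self, label: str) -> float:
        return float(sum(e - s for s, e, lab in self.intervals if lab == label))

    def labels_present(self, all_labels: bool = False) -> tuple[str, ...]:
        if all_labels:
            return STATES
        present = {lab for _, _, lab in self.intervals}
        return tuple(s for s in STATES if s in present)

    def label_at(self, t: float) -> str:
        """State containing time t (half-open intervals)."""
        if t < -_EPS or t > self.duration + _EPS:
            raise ContractError(f"time {t} outside session [0, {self.duration})")
        for _, e, lab in self.intervals:
            if t < e - _EPS:
                return lab
        return self.intervals[-1][2]

    def sample_labels(self, n_samples: int) -> np.ndarray:
        """Per-sample state labels (sample i labeled by the interval holding i/fs)."""
        fs = self.sampling_rate
        labels = np.empty(n_samples, dtype=object)
        for s, e, lab in self.intervals:
            a = int(round(s * fs))
            b = int(round(e * fs))
            labels[a:min(b, n_samples)] = lab
        return labels


# ---------------------------------------------------------------------------
# Run-length helpers (half-open sample-index runs)
# ---------------------------------------------------------------------------

def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    d = np.diff(np.concatenate(([False], mask, [False])).astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_short_gaps(runs: list[tuple[int, int]], max_gap_n: float) -> list[tuple[int, int]]:
    """Merge runs separated by gaps strictly shorter than max_gap_n samples."""
    if not runs:
        return []
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] < max_gap_n - _EPS:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _runs_to_intervals(runs: list[tuple[int, int]], fs: float) -> list[tuple[float, float]]:
    return [(a / fs, b / fs) for a, b in runs]


def _intervals_to_mask(intervals, fs: float, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, e in intervals:
        mask[int(round(s * fs)):min(int(round(e * fs)), n)] = True
    return mask


def moving_average(x: np.ndarray, window_s: float, fs: float) -> np.ndarray:
    """Centered moving average over the odd sample window nearest window_s."""
    w = int(round(window_s * fs))
    if w % 2 == 0:
        w += 1
    w = max(w, 1)
    if w == 1:
        return np.asarray(x, dtype=float)
    return np.convolve(x, np.ones(w) / w, mode="same")


# ---------------------------------------------------------------------------
# Segmentation operations
# ---------------------------------------------------------------------------

def segment_locomotion(
    behavior: BehaviorTrace,
    speed_threshold: float = SPEED_THRESHOLD_CMPS,
    merge_gap_s: float = LOC_MERGE_GAP_S,
    min_bout_s: float = LOC_MIN_BOUT_S,
) -> list[tuple[float, float]]:
    """Locomotion intervals from the speed trace.

    Thresholds speed > ``speed_threshold``, merges interruptions shorter
    than ``merge_gap_s`` into locomotion, then reclassifies bouts not
    strictly longer than ``min_bout_s`` as still (which also merges the
    sub-threshold interruptions of the remaining still time).
    """
    fs = behavior.sampling_rate
    runs = _true_runs(behavior.speed > speed_threshold)
    runs = _merge_short_gaps(runs, merge_gap_s * fs)
    runs = [(a, b) for a, b in runs if (b - a) > min_bout_s * fs + _EPS]
    return _runs_to_intervals(runs, fs)


def detect_whisking(
    behavior: BehaviorTrace,
    still_intervals: list[tuple[float, float]],
    smooth_s: float = WHISK_SMOOTH_S,
    baseline_percentile: float = WHISK_BASELINE_PERCENTILE,
    threshold_factor: float = WHISK_THRESHOLD_FACTOR,
    merge_gap_s: float = WHISK_MERGE_GAP_S,
    min_bout_s: float = WHISK_MIN_BOUT_S,
    threshold_mode: str = "multiplicative",
    order: str = "merge_first",
) -> list[tuple[float, float]]:
    """Whisk bouts from the motion-energy trace, restricted to still periods.

    The energy trace is smoothed with a ``smooth_s`` moving average; the
    baseline W0 is its ``baseline_percentile``-th percentile, and samples
    are whisking when the smoothed energy exceeds ``threshold_factor × W0``
    (multiplicative reading; ``threshold_mode='additive'`` uses
    ``W0 + threshold_factor`` instead). Gaps shorter than ``merge_gap_s``
    are merged and bouts shorter than ``min_bout_s`` dropped —
    ``order='merge_first'`` (default) merges before dropping so merging
    cannot resurrect dropped fragments; ``order='drop_first'`` follows the
    opposite reading. Bouts are finally intersected with still intervals;
    residual fragments shorter than ``min_bout_s`` (e.g. smoothing spillover
    at locomotion edges) are dropped so no whisk bout undercuts the minimum.

    If W0 ≤ 0 the multiplicative threshold is degenerate; an additive
    threshold of W0 + 1.5 × MAD is used with a warning.
    """
    if threshold_mode not in ("multiplicative", "additive"):
        raise ContractError(f"unknown threshold_mode {threshold_mode!r}")
    if order not in ("merge_first", "drop_first"):
        raise ContractError(f"unknown order {order!r}")
    fs = behavior.sampling_rate
    n = behavior.n_samples
    smoothed = moving_average(behavior.whisk_energy, smooth_s, fs)
    w0 = float(np.percentile(smoothed, baseline_percentile))
    if threshold_mode == "additive":
        threshold = w0 + threshold_factor
    elif w0 <= 0:
        mad = float(np.median(np.abs(smoothed - np.median(smoothed))))
        threshold = w0 + threshold_factor * mad
        warnings.warn(
            f"whisk baseline W0 = {w0:.4g} is not positive; using additive "
            f"threshold W0 + {threshold_factor}*MAD = {threshold:.4g}",
            RuntimeWarning,
            stacklevel=2,
        )
    else:
        threshold = threshold_factor * w0
    runs = _true_runs(smoothed > threshold)
    if order == "merge_first":
        runs = _merge_short_gaps(runs, merge_gap_s * fs)
        runs = [(a, b) for a, b in runs if (b - a) >= min_bout_s * fs - _EPS]
    else:
        runs = [(a, b) for a, b in runs if (b - a) >= min_bout_s * fs - _EPS]
        runs = _merge_short_gaps(runs, merge_gap_s * fs)
    whisk_mask = _intervals_to_mask(_runs_to_intervals(runs, fs), fs, n)
    still_mask = _intervals_to_mask(still_intervals, fs, n)
    final = _true_runs(whisk_mask & still_mask)
    final = [(a, b) for a, b in final if (b - a) >= min_bout_s * fs - _EPS]
    return _runs_to_intervals(final, fs)


def complement_intervals(
    intervals: list[tuple[float, float]], duration: float, fs: float
) -> list[tuple[float, float]]:
    """Still time: the session minus the given (locomotion) intervals."""
    n = int(round(duration * fs))
    mask = ~_intervals_to_mask(intervals, fs, n)
    return _runs_to_intervals(_true_runs(mask), fs)


def compose_segmentation(
    locomotion_intervals: list[tuple[float, float]],
    whisk_bouts: list[tuple[float, float]],
    duration: float,
    sampling_rate: float,
) -> StateSegmentation:
    """Combine locomotion intervals and whisk bouts into a full partition.

    Priority Locomotion > StillWhisking > Still; still periods coinciding
    with whisker movement become StillWhisking.
    """
    fs = sampling_rate
    n = int(round(duration * fs))
    if n <= 0:
        raise ContractError("session duration must be positive")
    loc = sorted(locomotion_intervals)
    for (s0, e0), (s1, e1) in zip(loc, loc[1:]):
        if s1 < e0 - _EPS:
            raise ContractError(
                f"overlapping locomotion intervals ({s0}, {e0}) and ({s1}, {e1})"
            )
    labels = np.full(n, STILL, dtype=object)
    labels[_intervals_to_mask(whisk_bouts, fs, n)] = STILL_WHISKING
    labels[_intervals_to_mask(loc, fs, n)] = LOCOMOTION
    intervals = []
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            end_t = duration if i == n else i / fs
            intervals.append((start / fs, end_t, labels[start]))
            start = i
    return StateSegmentation(intervals=tuple(intervals), sampling_rate=fs)


def segment_session(
    behavior: BehaviorTrace,
    speed_threshold: float = SPEED_THRESHOLD_CMPS,
    loc_merge_gap_s: float = LOC_MERGE_GAP_S,
    loc_min_bout_s: float = LOC_MIN_BOUT_S,
    whisk_smooth_s: float = WHISK_SMOOTH_S,
    whisk_baseline_percentile: float = WHISK_BASELINE_PERCENTILE,
    whisk_threshold_factor: float = WHISK_THRESHOLD_FACTOR,
    whisk_merge_gap_s: float = WHISK_MERGE_GAP_S,
    whisk_min_bout_s: float = WHISK_MIN_BOUT_S,
    whisk_threshold_mode: str = "multiplicative",
    whisk_order: str = "merge_first",
) -> StateSegmentation:
    """Full behavioral segmentation of one session."""
    loc = segment_locomotion(behavior, speed_threshold, loc_merge_gap_s, loc_min_bout_s)
    still = complement_intervals(loc, behavior.duration, behavior.sampling_rate)
    whisk = detect_whisking(
        behavior,
        still,
        smooth_s=whisk_smooth_s,
        baseline_percentile=whisk_baseline_percentile,
        threshold_factor=whisk_threshold_factor,
        merge_gap_s=whisk_merge_gap_s,
        min_bout_s=whisk_min_bout_s,
        threshold_mode=whisk_threshold_mode,
        order=whisk_order,
    )
    return compose_segmentation(loc, whisk, behavior.duration, behavior.sampling_rate)
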