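"""ΔF/F extraction and Ca²⁺ event detection for ROI fluorescence traces.

The processing chain mirrors standard two-photon trace analysis of
astrocytic microcompartments (soma AS, processes AP, gliopil Gp, endfeet
AE) and neuronal somata:

1. linear detrending of the raw trace (photobleaching correction),
2. neuropil subtraction for neuronal somata, ``F − α·F_np`` with α = 0.7,
3. ΔF/F0 = (F − F0)/F0 with F0 the 10th percentile of the trace smoothed
   by a first-order Savitzky–Golay filter over a 5 s window,
4. baseline noise σ = SD of ΔF/F during the least noisy 5 s period,
5. event detection at a threshold of k·σ (k = 2 for astrocytic
   compartments, 2.5 for neurons), with event extent given by the
   surrounding zero crossings of ΔF/F, amplitude the peak within that
   extent, and onset the first suprathreshold sample.

Time convention: sample ``i`` covers ``[i/fs, (i+1)/fs)`` seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import savgol_filter

from .errors import ContractError, MissingNeuropilError, NonPositiveBaselineError

COMPARTMENTS = ("AS", "AP", "Gp", "AE", "Neuron")
ASTRO_COMPARTMENTS = ("AS", "AP", "Gp", "AE")

# ΔF/F processing defaults
SMOOTH_WINDOW_S = 5.0          # Savitzky-Golay window for the F0 baseline
BASELINE_PERCENTILE = 10.0     # percentile of the smoothed trace taken as F0
SIGMA_WINDOW_S = 5.0           # least-noisy-period window for sigma
NEUROPIL_ALPHA = 0.7           # neuropil contamination ratio for neurons

# Event detection defaults
K_ASTRO = 2.0                  # threshold multiple of sigma, astrocytes
K_NEURON = 2.5                 # threshold multiple of sigma, neurons
# Absolute amplitude floor (ΔF/F units) applied as max(k·sigma, floor).
# The adaptive minimum-window sigma makes a bare k·sigma threshold fire on
# stationary noise of any scale; the floor keeps noise-only traces silent
# while staying well below physiological transient amplitudes. Set to 0 to
# recover the bare threshold rule.
MIN_EVENT_AMPLITUDE = 0.1


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ContractError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ContractError(f"{name} contains non-finite samples")
    return arr


@dataclass(frozen=True)
class RoiTrace:
    """One ROI's raw fluorescence trace with compartment label and metadata."""

    roi_id: str
    compartment: str
    F: np.ndarray
    sampling_rate: float
    F_np: np.ndarray | None = None
    session_id: str = ""
    mouse_id: str = ""
    group: str = ""

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ContractError(
                f"unknown compartment {self.compartment!r}; allowed: {COMPARTMENTS}"
            )
        if self.sampling_rate <= 0:
            raise ContractError("sampling_rate must be positive")
        object.__setattr__(self, "F", _as_float_array(self.F, "F"))
        if self.F_np is not None:
            fnp = _as_float_array(self.F_np, "F_np")
            if len(fnp) != len(self.F):
                raise ContractError(
                    f"F_np length {len(fnp)} != F length {len(self.F)}"
                )
            object.__setattr__(self, "F_np", fnp)

    @property
    def n_samples(self) -> int:
        return len(self.F)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def is_neuron(self) -> bool:
        return self.compartment == "Neuron"

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class DffTrace:
    """ΔF/F trace with its baseline, noise estimate, and provenance."""

    roi_id: str
    compartment: str
    dff: np.ndarray
    f0: float
    sampling_rate: float
    sigma: float | None = None
    session_id: str = ""
    mouse_id: str = ""
    group: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "dff", _as_float_array(self.dff, "dff"))
        if self.f0 <= 0:
            raise NonPositiveBaselineError(f"F0 must be positive, got {self.f0}")
        if self.sigma is not None and self.sigma < 0:
            raise ContractError("sigma must be nonnegative")

    @property
    def n_samples(self) -> int:
        return len(self.dff)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class CalciumEvent:
    """A detected Ca²⁺ transient.

    ``start_time``/``end_time`` bracket the zero crossings of ΔF/F (trace
    ends act as crossings), ``onset_time`` is the first suprathreshold
    sample, and ``amplitude`` is the peak ΔF/F within the extent.
    """

    roi_id: str
    onset_time: float
    start_time: float
    end_time: float
    amplitude: float

    def __post_init__(self):
        if not (self.start_time <= self.onset_time <= self.end_time):
            raise ContractError("event requires start <= onset <= end")
        if self.end_time <= self.start_time:
            raise ContractError("event duration must be positive")

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


# ---------------------------------------------------------------------------
# Trace preprocessing
# ---------------------------------------------------------------------------

DETREND_BIN_S = 30.0   # bin width for the baseline-percentile trend fit


def detrend_linear(trace: RoiTrace, method: str = "baseline") -> RoiTrace:
    """Remove the linear trend from F, preserving the mean level.

    Corrects slow monotone drifts such as photobleaching. The fitted line is
    subtracted and its mean added back, so the output mean equals the input
    mean and the subsequent baseline stays positive.

    ``method='ols'`` fits the textbook least-squares line to F. With long,
    high-amplitude Ca²⁺ transients the transient mass biases that slope and
    tilts the baseline, so the default ``method='baseline'`` estimates the
    drift slope from the 10th percentile of F within ~30 s bins — tracking
    the fluorescence floor rather than the signal mass. Both remove an
    exact line exactly.
    """
    if trace.n_samples < 2:
        raise ContractError("detrend_linear requires at least 2 samples")
    t = np.arange(trace.n_samples, dtype=float)
    if method == "ols":
        slope = np.polyfit(t, trace.F, 1)[0]
    elif method == "baseline":
        n_bins = int(trace.duration // DETREND_BIN_S)
        if n_bins < 4:
            slope = np.polyfit(t, trace.F, 1)[0]
        else:
            edges = np.linspace(0, trace.n_samples, n_bins + 1).astype(int)
            centers = (edges[:-1] + edges[1:]) / 2.0
            floors = [
                np.percentile(trace.F[a:b], BASELINE_PERCENTILE)
                for a, b in zip(edges[:-1], edges[1:])
            ]
            slope = np.polyfit(centers, floors, 1)[0]
    else:
        raise ContractError(f"unknown detrend method {method!r}")
    detrended = trace.F - slope * (t - t.mean())
    return replace(trace, F=detrended)


def subtract_neuropil(trace: RoiTrace, alpha: float = NEUROPIL_ALPHA) -> RoiTrace:
    """Subtract the contaminating neuropil signal from a neuronal soma trace.

    Computes ``F − α·F_np`` samplewise. Astrocytic traces are returned
    unchanged (they carry no paired neuropil signal by construction).
    """
    if not trace.is_neuron:
        return trace
    if trace.F_np is None:
        raise MissingNeuropilError(
            f"neuron ROI {trace.roi_id!r} has no paired neuropil trace"
        )
    return replace(trace, F=trace.F - alpha * trace.F_np)


def _odd_window_samples(window_s: float, fs: float, n: int, minimum: int = 3) -> int:
    w = int(round(window_s * fs))
    if w % 2 == 0:
        w += 1
    w = max(w, minimum)
    if w > n:
        raise ContractError(
            f"trace of {n} samples is shorter than the {window_s} s window ({w} samples)"
        )
    return w


def compute_dff(
    trace: RoiTrace,
    smooth_window_s: float = SMOOTH_WINDOW_S,
    percentile: float = BASELINE_PERCENTILE,
) -> DffTrace:
    """Convert a fluorescence trace to ΔF/F0 with a percentile baseline.

    F is smoothed with a first-order Savitzky–Golay filter over the odd
    sample window nearest ``smooth_window_s`` (51 samples at 10 Hz); F0 is
    the given percentile of the smoothed trace, taken as a single scalar,
    and ΔF/F0 = (F − F0)/F0. ΔF/F is invariant to positive rescaling of F.
    """
    w = _odd_window_samples(smooth_window_s, trace.sampling_rate, trace.n_samples)
    smoothed = savgol_filter(trace.F, window_length=w, polyorder=1)
    f0 = float(np.percentile(smoothed, percentile))
    if f0 <= 0:
        raise NonPositiveBaselineError(
            f"baseline F0 = {f0:.4g} is not positive for ROI {trace.roi_id!r}; "
            "check input units/offsets"
        )
    dff = (trace.F - f0) / f0
    return DffTrace(
        roi_id=trace.roi_id,
        compartment=trace.compartment,
        dff=dff,
        f0=f0,
        sampling_rate=trace.sampling_rate,
        session_id=trace.session_id,
        mouse_id=trace.mouse_id,
        group=trace.group,
        params={"smooth_window_s": smooth_window_s, "percentile": percentile},
    )


def estimate_sigma(dff: DffTrace | np.ndarray, fs: float | None = None,
                   window_s: float = SIGMA_WINDOW_S) -> float:
    """Baseline noise σ: the SD of ΔF/F during the least noisy window.

    Slides a ``window_s`` window one sample at a time and returns the
    minimum sample standard deviation. Invariant to adding a constant.
    """
    if isinstance(dff, DffTrace):
        x, fs = dff.dff, dff.sampling_rate
    else:
        if fs is None:
            raise ContractError("sampling rate required for a bare array")
        x = _as_float_array(dff, "dff")
    w = int(round(window_s * fs))
    if w < 2 or w > len(x):
        raise ContractError(
            f"sigma window of {w} samples invalid for trace of {len(x)} samples"
        )
    sds = sliding_window_view(x, w).std(axis=1, ddof=1)
    return float(sds.min())


def with_sigma(dff: DffTrace, window_s: float = SIGMA_WINDOW_S) -> DffTrace:
    """Return a copy of the trace with σ estimated and attached."""
    return replace(dff, sigma=estimate_sigma(dff, window_s=window_s))


def preprocess_trace(
    trace: RoiTrace,
    alpha: float = NEUROPIL_ALPHA,
    smooth_window_s: float = SMOOTH_WINDOW_S,
    percentile: float = BASELINE_PERCENTILE,
    sigma_window_s: float = SIGMA_WINDOW_S,
    detrend_method: str = "baseline",
) -> DffTrace:
    """Full preprocessing: detrend → neuropil subtraction → ΔF/F → σ."""
    t = detrend_linear(trace, method=detrend_method)
    t = subtract_neuropil(t, alpha=alpha)
    d = compute_dff(t, smooth_window_s=smooth_window_s, percentile=percentile)
    return with_sigma(d, window_s=sigma_window_s)


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def default_k(compartment: str) -> float:
    """Per-class threshold multiple: 2 σ for astrocytes, 2.5 σ for neurons."""
    return K_NEURON if compartment == "Neuron" else K_ASTRO


def _positive_runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs where x > 0."""
    pos = x > 0
    d = np.diff(np.concatenate(([False], pos, [False])).astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def detect_events(
    dff: DffTrace,
    k: float | None = None,
    min_amplitude: float = MIN_EVENT_AMPLITUDE,
    max_duration_s: float | None = None,
) -> list[CalciumEvent]:
    """Detect Ca²⁺ events as suprathreshold positive lobes of ΔF/F.

    A candidate exists wherever ΔF/F exceeds ``max(k·σ, min_amplitude)``;
    its extent is the contiguous positive lobe (zero crossings on either
    side; trace ends act as crossings), so suprathreshold excursions
    sharing one positive lobe merge into one event. Amplitude is the
    maximum ΔF/F within the lobe, onset the first suprathreshold sample.

    If σ = 0 with a nonzero trace, a degenerate-threshold warning is
    issued and the absolute floor alone is used. ``max_duration_s``, when
    set, truncates event extents measured from their start.
    """
    if dff.sigma is None:
        raise ContractError("detect_events requires sigma; call with_sigma first")
    if k is None:
        k = default_k(dff.compartment)
    x = dff.dff
    fs = dff.sampling_rate
    if dff.sigma == 0 and np.any(x != 0):
        warnings.warn(
            f"ROI {dff.roi_id!r}: sigma is 0 on a nonzero trace; "
            f"falling back to the absolute amplitude floor {min_amplitude}",
            RuntimeWarning,
            stacklevel=2,
        )
    threshold = max(k * dff.sigma, min_amplitude)
    events: list[CalciumEvent] = []
    for a, b in _positive_runs(x):
        lobe = x[a:b]
        peak = float(lobe.max())
        if peak <= threshold:
            continue
        onset_idx = a + int(np.argmax(lobe > threshold))
        start_t = a / fs
        end_t = b / fs
        if max_duration_s is not None and end_t - start_t > max_duration_s:
            end_t = start_t + max_duration_s
            cut = min(b, a + max(int(round(max_duration_s * fs)), 1))
            peak = float(x[a:cut].max())
            if peak <= threshold:
                continue
            onset_idx = a + int(np.argmax(x[a:cut] > threshold))
        events.append(
            CalciumEvent(
                roi_id=dff.roi_id,
                onset_time=onset_idx / fs,
                start_time=start_t,
                end_time=end_t,
                amplitude=peak,
            )
        )
    return events


# ---------------------------------------------------------------------------
# Per-state event summaries
# ---------------------------------------------------------------------------

def summarize_events_by_state(
    events_by_roi: dict[str, list[CalciumEvent]],
    segmentation,
    traces: list[RoiTrace] | list[DffTrace],
) -> pd.DataFrame:
    """Tidy per-ROI × state table of event frequency, amplitude, duration.

    Each event is assigned to the behavioral state containing its onset.
    Frequency is events per minute of total state time; a state with zero
    total time yields a missing frequency. A state visited but without
    events yields frequency 0 with missing amplitude/duration. Rows carry
    ROI, compartment, group and mouse identifiers for mixed-model export.
    """
    state_minutes = {
        label: segmentation.total_time(label) / 60.0 for label in segmentation.labels_present(all_labels=True)
    }
    rows = []
    for trace in traces:
        events = events_by_roi.get(trace.roi_id, [])
        by_state: dict[str, list[CalciumEvent]] = {s: [] for s in state_minutes}
        for ev in events:
            by_state[segmentation.label_at(ev.onset_time)].append(ev)
        for state, minutes in state_minutes.items():
            evs = by_state[state]
            freq = len(evs) / minutes if minutes > 0 else np.nan
            rows.append(
                {
                    "roi_id": trace.roi_id,
                    "compartment": trace.compartment,
                    "group": trace.group,
                    "mouse_id": trace.mouse_id,
                    "session_id": trace.session_id,
                    "state": state,
                    "n_events": len(evs),
                    "frequency_per_min": freq,
                    "amplitude_mean": float(np.mean([e.amplitude for e in evs])) if evs else np.nan,
                    "duration_mean_s": float(np.mean([e.duration for e in evs])) if evs else np.nan,
                }
            )
    return pd.DataFrame(rows)


def events_to_frame(events_by_roi: dict[str, list[CalciumEvent]]) -> pd.DataFrame:
    """Flatten detected events into a tidy table."""
    rows = [
        {
            "roi_id": roi,
            "start_s": ev.start_time,
            "onset_s": ev.onset_time,
            "end_s": ev.end_time,
            "duration_s": ev.duration,
            "amplitude": ev.amplitude,
        }
        for roi, evs in events_by_roi.items()
        for ev in evs
    ]
    cols = ["roi_id", "start_s", "onset_s", "end_s", "duration_s", "amplitude"]
    return pd.DataFrame(rows, columns=cols)
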