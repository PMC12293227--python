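"""Synthetic session generator with known ground truth.

Emulates simultaneous astrocytic/neuronal Ca²⁺ imaging during behavior:
a wheel-speed and whisker motion-energy trace following a latent
Still/Locomotion/Still-Whisking schedule, and per-ROI fluorescence traces
built as baseline + bleaching drift + state-switched Poisson event trains
(fast rise, single-exponential decay) + i.i.d. Gaussian noise. Neuronal
somata receive an additive shared neuropil component mixed with weight
``alpha_true`` and carry the paired neuropil trace; astrocytic ROIs within
one synthetic field of view share a common drive scaled by the configured
correlation level.

Two presets parameterize the event model per compartment × state:
``wildtype_config()`` and ``knockout_config()``, patterned on reported
per-state event frequencies, amplitudes and durations for wild-type and
IP3R2-knockout-like recordings. They are defaults emulating the two
regimes, not claims of exact reproduction; neuronal amplitudes/durations
(not reported per state) are typical somatic indicator values, and the
knockout preset uses state-flat neuronal rates so its generative neuronal
locomotion modulation is ≈ 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .behavior import (
    LOCOMOTION,
    STATES,
    STILL,
    STILL_WHISKING,
    BehaviorTrace,
    StateSegmentation,
    compose_segmentation,
)
from .errors import ContractError, InvalidConfigError
from .fluor import ASTRO_COMPARTMENTS, COMPARTMENTS, RoiTrace

WILD_TYPE = "wild-type"
KNOCKOUT = "knockout"


@dataclass(frozen=True)
class EventStats:
    """Event model for one compartment × state: rate, amplitude, duration."""

    rate_per_min: float
    amp_mean: float     # ΔF/F units
    dur_mean_s: float

    def validate(self, where: str) -> None:
        if self.rate_per_min < 0 or self.amp_mean < 0 or self.dur_mean_s < 0:
            raise InvalidConfigError(f"negative event parameter in {where}: {self}")


@dataclass(frozen=True)
class OnsetLocked:
    """Optional event injection at a fixed lag after each locomotion onset."""

    prob: float = 1.0
    lag_s: float = 1.5
    jitter_s: float = 0.0
    compartments: tuple[str, ...] = ASTRO_COMPARTMENTS


# Event model tables: compartment -> state -> (rate /min, amplitude ΔF/F,
# duration s). Astrocytic entries follow the reported wild-type and
# IP3R2-knockout per-state statistics; neuronal amplitude/duration are
# chosen typical values (see module docstring).
_WT_EVENT_MODEL = {
    "AS": {STILL: EventStats(0.69, 0.95, 10.14), STILL_WHISKING: EventStats(1.92, 1.02, 11.05), LOCOMOTION: EventStats(2.91, 2.12, 17.28)},
    "AP": {STILL: EventStats(0.87, 0.72, 9.63), STILL_WHISKING: EventStats(2.56, 0.74, 10.16), LOCOMOTION: EventStats(2.66, 1.39, 16.18)},
    "Gp": {STILL: EventStats(0.86, 0.55, 9.19), STILL_WHISKING: EventStats(2.28, 0.56, 9.72), LOCOMOTION: EventStats(2.62, 1.00, 15.80)},
    "AE": {STILL: EventStats(1.20, 0.80, 7.51), STILL_WHISKING: EventStats(2.68, 1.04, 8.56), LOCOMOTION: EventStats(3.83, 2.65, 17.12)},
    "Neuron": {STILL: EventStats(1.19, 0.40, 2.0), STILL_WHISKING: EventStats(0.80, 0.40, 2.0), LOCOMOTION: EventStats(1.62, 0.55, 2.5)},
}

_KO_EVENT_MODEL = {
    "AS": {STILL: EventStats(0.06, 0.24, 7.56), STILL_WHISKING: EventStats(0.03, 0.29, 10.26), LOCOMOTION: EventStats(0.34, 0.29, 10.59)},
    "AP": {STILL: EventStats(0.01, 0.34, 7.8), STILL_WHISKING: EventStats(0.001, 0.26, 9.19), LOCOMOTION: EventStats(0.13, 0.26, 8.12)},
    "Gp": {STILL: EventStats(0.03, 0.25, 7.50), STILL_WHISKING: EventStats(0.014, 0.26, 6.44), LOCOMOTION: EventStats(0.14, 0.27, 7.27)},
    "AE": {STILL: EventStats(0.0, 0.0, 0.0), STILL_WHISKING: EventStats(0.0, 0.0, 0.0), LOCOMOTION: EventStats(0.23, 0.36, 13.05)},
    "Neuron": {STILL: EventStats(1.0, 0.40, 2.0), STILL_WHISKING: EventStats(1.0, 0.40, 2.0), LOCOMOTION: EventStats(1.0, 0.40, 2.0)},
}

_DEFAULT_ROIS = {"AS": 3, "AP": 5, "Gp": 6, "AE": 1, "Neuron": 5}


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one synthetic genotype regime."""

    seed: int = 0
    group: str = WILD_TYPE
    sampling_rate: float = 10.0     # Hz
    duration_s: float = 300.0
    n_mice: int = 6
    sessions_per_mouse: int = 2
    rois_per_compartment: dict = field(default_factory=lambda: dict(_DEFAULT_ROIS))

    # state schedule
    mean_still_bout_s: float = 20.0
    mean_loc_bout_s: float = 8.0
    min_still_bout_s: float = 2.0
    min_loc_bout_s: float = 1.5
    loc_bout_prob: float = 1.0      # probability a locomotion bout follows a still bout
    whisk_rate_per_min: float = 4.0  # whisk bouts per minute of stillness
    mean_whisk_bout_s: float = 1.5
    min_whisk_bout_s: float = 0.6

    # fluorescence model
    event_model: dict = field(default_factory=lambda: dict(_WT_EVENT_MODEL))
    amp_cv: float = 0.25            # coefficient of variation of drawn amplitudes
    dur_cv: float = 0.25
    f0_level: float = 100.0         # baseline fluorescence, a.u.
    noise_sd: float = 2.0           # i.i.d. Gaussian noise, a.u. (0.02 ΔF/F at default F0)
    bleach_slope: float = -0.02     # linear drift, a.u./s
    alpha_true: float = 0.7         # neuropil contamination mixed into neuron traces
    neuropil_level: float = 80.0    # neuropil baseline, a.u.
    neuropil_fluct_sd: float = 0.05  # relative slow fluctuation of the neuropil
    corr_level: float = 0.3         # target noise-floor correlation of astro ROI pairs
    onset_locked: OnsetLocked | None = None

    # behavior trace synthesis
    loc_speed_cmps: float = 3.0     # typical running speed
    still_speed_jitter: float = 0.15  # still-speed noise scale (kept < 1 cm/s)
    whisk_base_energy: float = 1.0
    whisk_active_energy: float = 4.0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise InvalidConfigError("sampling_rate must be positive")
        if self.duration_s <= 0:
            raise InvalidConfigError("duration_s must be positive")
        if self.n_mice < 1 or self.sessions_per_mouse < 1:
            raise InvalidConfigError("need at least one mouse and one session")
        if not 0.0 <= self.alpha_true <= 1.0:
            raise InvalidConfigError("alpha_true must lie in [0, 1]")
        if not 0.0 <= self.loc_bout_prob <= 1.0:
            raise InvalidConfigError("loc_bout_prob must lie in [0, 1]")
        for v in (
            self.mean_still_bout_s, self.mean_loc_bout_s, self.whisk_rate_per_min,
            self.mean_whisk_bout_s, self.noise_sd, self.corr_level,
        ):
            if v < 0:
                raise InvalidConfigError(f"negative schedule/noise parameter: {v}")
        for comp, states in self.event_model.items():
            if comp not in COMPARTMENTS:
                raise InvalidConfigError(f"unknown compartment {comp!r} in event model")
            for state, stats in states.items():
                if state not in STATES:
                    raise InvalidConfigError(f"unknown state {state!r} in event model")
                stats.validate(f"{comp}/{state}")


def wildtype_config(**overrides) -> SimConfig:
    """Wild-type-like preset."""
    return replace(SimConfig(), group=WILD_TYPE, **overrides)


def knockout_config(**overrides) -> SimConfig:
    """IP3R2-knockout-like preset: astrocytic event rates/amplitudes strongly
    reduced, weaker inter-ROI coupling, state-flat neuronal rates."""
    base = SimConfig(
        group=KNOCKOUT,
        n_mice=5,
        event_model=dict(_KO_EVENT_MODEL),
        corr_level=0.1,
    )
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueEvent:
    onset_s: float
    amplitude: float
    duration_s: float


@dataclass
class SyntheticGroundTruth:
    """Everything the analysis is supposed to recover."""

    schedule: StateSegmentation
    alpha_true: float
    events: dict[str, list[TrueEvent]]
    state_mean_dff: dict[str, dict[str, float]]   # analytic event-driven mean ΔF/F
    locmi_true: dict[str, float]
    whiskmi_true: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "schedule": [list(iv) for iv in self.schedule.intervals],
            "sampling_rate": self.schedule.sampling_rate,
            "alpha_true": self.alpha_true,
            "events": {
                roi: [[e.onset_s, e.amplitude, e.duration_s] for e in evs]
                for roi, evs in self.events.items()
            },
            "state_mean_dff": self.state_mean_dff,
            "locmi_true": self.locmi_true,
            "whiskmi_true": self.whiskmi_true,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticGroundTruth":
        schedule = StateSegmentation(
            intervals=tuple((s, e, lab) for s, e, lab in d["schedule"]),
            sampling_rate=d["sampling_rate"],
        )
        return cls(
            schedule=schedule,
            alpha_true=d["alpha_true"],
            events={
                roi: [TrueEvent(*row) for row in rows]
                for roi, rows in d["events"].items()
            },
            state_mean_dff=d["state_mean_dff"],
            locmi_true=d["locmi_true"],
            whiskmi_true=d["whiskmi_true"],
        )


def _analytic_state_means(states: dict[str, EventStats]) -> dict[str, float]:
    # Stationary mean of a Poisson train of exponential-decay kernels:
    # rate * amplitude * tau, with tau = duration/3 (kernel ~5% at `duration`).
    return {
        state: st.rate_per_min / 60.0 * st.amp_mean * (st.dur_mean_s / 3.0)
        for state, st in states.items()
    }


def _mi(active: float, still: float) -> float:
    denom = active + still
    return float("nan") if denom == 0 else (active - still) / denom


# ---------------------------------------------------------------------------
# Behavior generation
# ---------------------------------------------------------------------------

def _smooth_unit_noise(n: int, rng: np.random.Generator, sigma: float = 2.0) -> np.ndarray:
    x = gaussian_filter1d(rng.standard_normal(n), sigma)
    sd = x.std()
    return x / sd if sd > 0 else x


def _draw_schedule(config: SimConfig, rng: np.random.Generator) -> list[tuple[int, int, str]]:
    """Alternating Still/Locomotion bouts in sample units."""
    fs = config.sampling_rate
    n_total = int(round(config.duration_s * fs))
    bouts: list[tuple[int, int, str]] = []
    pos = 0
    while pos < n_total:
        still_n = max(
            int(round(max(config.min_still_bout_s, rng.exponential(config.mean_still_bout_s)) * fs)),
            1,
        )
        end = min(pos + still_n, n_total)
        bouts.append((pos, end, STILL))
        pos = end
        if pos >= n_total:
            break
        if config.mean_loc_bout_s > 0 and rng.random() < config.loc_bout_prob:
            loc_n = max(
                int(round(max(config.min_loc_bout_s, rng.exponential(config.mean_loc_bout_s)) * fs)),
                1,
            )
            end = min(pos + loc_n, n_total)
            bouts.append((pos, end, LOCOMOTION))
            pos = end
    return bouts


def _draw_whisk_bouts(
    config: SimConfig,
    still_bouts: list[tuple[int, int]],
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Whisk bouts inside still periods, kept clear of bout/interval edges."""
    if config.whisk_rate_per_min <= 0:
        return []
    fs = config.sampling_rate
    margin = max(int(round(0.5 * fs)), 1)   # separation from edges and other bouts
    bouts = []
    for a, b in still_bouts:
        n_bouts = rng.poisson(config.whisk_rate_per_min / 60.0 * (b - a) / fs)
        last_end = a
        for start in np.sort(rng.integers(a, b, size=n_bouts)):
            dur_n = max(
                int(round(max(config.min_whisk_bout_s, rng.exponential(config.mean_whisk_bout_s)) * fs)),
                1,
            )
            if start < last_end + margin or start + dur_n + margin > b:
                continue   # drop candidates colliding with edges or earlier bouts
            bouts.append((int(start), int(start) + dur_n))
            last_end = int(start) + dur_n
    return bouts


def generate_behavior(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[BehaviorTrace, StateSegmentation]:
    """Speed and whisker motion-energy traces plus the true state schedule.

    Still speed stays below 1 cm/s (small jitter); locomotion bouts run
    well above it. Whisker energy is elevated during whisk bouts inside
    still periods and continuously elevated during locomotion.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = int(round(config.duration_s * fs))
    bouts = _draw_schedule(config, rng)
    still_bouts = [(a, b) for a, b, lab in bouts if lab == STILL]
    loc_bouts = [(a, b) for a, b, lab in bouts if lab == LOCOMOTION]
    whisk_bouts = _draw_whisk_bouts(config, still_bouts, rng)

    speed = np.abs(config.still_speed_jitter * rng.standard_normal(n))
    np.clip(speed, 0.0, 0.9, out=speed)
    for a, b in loc_bouts:
        seg = config.loc_speed_cmps + 0.8 * _smooth_unit_noise(b - a, rng)
        speed[a:b] = np.clip(seg, 1.5, 2.0 * config.loc_speed_cmps)

    energy = config.whisk_base_energy + 0.05 * np.abs(rng.standard_normal(n))
    active = np.zeros(n, dtype=bool)
    for a, b in whisk_bouts:
        active[a:b] = True
    for a, b in loc_bouts:
        active[a:b] = True
    elevated = config.whisk_active_energy + 0.3 * rng.standard_normal(n)
    energy[active] = np.clip(elevated, 0.6 * config.whisk_active_energy, None)[active]

    behavior = BehaviorTrace(speed=speed, whisk_energy=energy, sampling_rate=fs)
    schedule = compose_segmentation(
        [(a / fs, b / fs) for a, b in loc_bouts],
        [(a / fs, b / fs) for a, b in whisk_bouts],
        duration=n / fs,
        sampling_rate=fs,
    )
    return behavior, schedule


# ---------------------------------------------------------------------------
# Fluorescence generation
# ---------------------------------------------------------------------------

def _draw_events(
    stats_by_state: dict[str, EventStats],
    schedule: StateSegmentation,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[TrueEvent]:
    events: list[TrueEvent] = []
    for s, e, label in schedule.intervals:
        st = stats_by_state[label]
        if st.rate_per_min <= 0:
            continue
        lam = st.rate_per_min / 60.0 * (e - s)
        for _ in range(rng.poisson(lam)):
            onset = rng.uniform(s, e)
            amp = max(0.02, rng.normal(st.amp_mean, config.amp_cv * st.amp_mean))
            dur = max(0.5, rng.normal(st.dur_mean_s, config.dur_cv * st.dur_mean_s))
            events.append(TrueEvent(onset_s=onset, amplitude=amp, duration_s=dur))
    events.sort(key=lambda ev: ev.onset_s)
    return events


def _locked_events(
    compartment: str,
    stats_by_state: dict[str, EventStats],
    schedule: StateSegmentation,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[TrueEvent]:
    lock = config.onset_locked
    if lock is None or compartment not in lock.compartments:
        return []
    st = stats_by_state[LOCOMOTION]
    events = []
    for s, e in schedule.intervals_for(LOCOMOTION):
        if rng.random() >= lock.prob:
            continue
        lag = lock.lag_s + (lock.jitter_s * rng.standard_normal() if lock.jitter_s else 0.0)
        onset = s + max(lag, 0.0)
        if onset >= e or onset >= schedule.duration:
            continue
        amp = max(0.02, st.amp_mean if st.amp_mean > 0 else 0.5)
        dur = max(0.5, st.dur_mean_s if st.dur_mean_s > 0 else 2.0)
        events.append(TrueEvent(onset_s=onset, amplitude=amp, duration_s=dur))
    return events


def events_to_dff(
    events: list[TrueEvent], n: int, fs: float
) -> np.ndarray:
    """Sum of event kernels: instantaneous rise, exponential decay (τ = dur/3)."""
    sig = np.zeros(n)
    for ev in events:
        i0 = int(round(ev.onset_s * fs))
        if i0 >= n:
            continue
        tau = max(ev.duration_s / 3.0, 1.0 / fs)
        support = min(n - i0, int(math.ceil(5.0 * tau * fs)) + 1)
        t = np.arange(support) / fs
        sig[i0:i0 + support] += ev.amplitude * np.exp(-t / tau)
    return sig


def generate_fluorescence(
    config: SimConfig,
    schedule: StateSegmentation,
    rng: np.random.Generator | None = None,
    session_id: str = "sim",
    mouse_id: str = "m0",
) -> tuple[list[RoiTrace], SyntheticGroundTruth]:
    """Multi-ROI fluorescence traces for one session plus full ground truth."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = int(round(schedule.duration * fs))
    noise_dff = config.noise_sd / config.f0_level
    # shared astro drive scaled so the noise-floor pair correlation is corr_level
    if 0 < config.corr_level < 1 and noise_dff > 0:
        shared_sd = noise_dff * math.sqrt(config.corr_level / (1.0 - config.corr_level))
        shared = shared_sd * _smooth_unit_noise(n, rng, sigma=3.0)
    else:
        shared = np.zeros(n)
    np_fluct = config.neuropil_fluct_sd * _smooth_unit_noise(n, rng, sigma=10.0)
    neuropil = config.neuropil_level * (1.0 + np_fluct)

    t_s = np.arange(n) / fs
    traces: list[RoiTrace] = []
    events: dict[str, list[TrueEvent]] = {}
    state_means: dict[str, dict[str, float]] = {}
    locmi_true: dict[str, float] = {}
    whiskmi_true: dict[str, float] = {}
    for comp in COMPARTMENTS:
        n_rois = config.rois_per_compartment.get(comp, 0)
        stats_by_state = config.event_model[comp]
        means = _analytic_state_means(stats_by_state)
        for i in range(n_rois):
            roi_id = f"{session_id}-{comp}{i}"
            evs = _draw_events(stats_by_state, schedule, config, rng)
            evs += _locked_events(comp, stats_by_state, schedule, config, rng)
            evs.sort(key=lambda ev: ev.onset_s)
            dff_sig = events_to_dff(evs, n, fs)
            noise = rng.normal(0.0, config.noise_sd, n)
            if comp == "Neuron":
                intrinsic = config.f0_level * (1.0 + dff_sig)
                f_np = neuropil + rng.normal(0.0, 0.2, n)
                f = intrinsic + config.alpha_true * f_np + config.bleach_slope * t_s + noise
                trace = RoiTrace(
                    roi_id=roi_id, compartment=comp, F=f, F_np=f_np,
                    sampling_rate=fs, session_id=session_id,
                    mouse_id=mouse_id, group=config.group,
                )
            else:
                f = config.f0_level * (1.0 + dff_sig + shared) + config.bleach_slope * t_s + noise
                trace = RoiTrace(
                    roi_id=roi_id, compartment=comp, F=f,
                    sampling_rate=fs, session_id=session_id,
                    mouse_id=mouse_id, group=config.group,
                )
            traces.append(trace)
            events[roi_id] = evs
            state_means[roi_id] = dict(means)
            locmi_true[roi_id] = _mi(means[LOCOMOTION], means[STILL])
            whiskmi_true[roi_id] = _mi(means[STILL_WHISKING], means[STILL])

    truth = SyntheticGroundTruth(
        schedule=schedule,
        alpha_true=config.alpha_true,
        events=events,
        state_mean_dff=state_means,
        locmi_true=locmi_true,
        whiskmi_true=whiskmi_true,
    )
    return traces, truth


def generate_state_mean_dff(
    schedule: StateSegmentation,
    means: dict[str, float],
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """ΔF/F trace with an exactly configured mean per behavioral state.

    Used to probe modulation-index recovery against the analytic value
    (m_active − m_still)/(m_active + m_still) without the baseline-
    estimation step in between.
    """
    n = int(round(schedule.duration * schedule.sampling_rate))
    labels = schedule.sample_labels(n)
    dff = np.fromiter((means[lab] for lab in labels), dtype=float, count=n)
    return dff + rng.normal(0.0, noise_sd, n)


# ---------------------------------------------------------------------------
# Sessions and cohorts
# ---------------------------------------------------------------------------

def generate_session(
    config: SimConfig,
    session_id: str = "sim-s0",
    mouse_id: str = "m0",
    rng: np.random.Generator | None = None,
):
    """One complete synthetic session (behavior + traces + ground truth)."""
    from .session_io import Session

    if rng is None:
        rng = np.random.default_rng(config.seed)
    behavior, schedule = generate_behavior(config, rng)
    traces, truth = generate_fluorescence(
        config, schedule, rng, session_id=session_id, mouse_id=mouse_id
    )
    return Session(
        session_id=session_id,
        mouse_id=mouse_id,
        group=config.group,
        sampling_rate=config.sampling_rate,
        traces=traces,
        behavior=behavior,
        ground_truth=truth,
    )


def generate_cohort(config: SimConfig) -> list:
    """All sessions of one genotype group: ``n_mice × sessions_per_mouse``.

    Deterministic in ``config.seed``: per-session generators are spawned
    from a single root sequence.
    """
    config.validate()
    root = np.random.default_rng(config.seed)
    sessions = []
    for m in range(config.n_mice):
        mouse_id = f"{config.group}-m{m}"
        for s in range(config.sessions_per_mouse):
            session_id = f"{mouse_id}-s{s}"
            rng = np.random.default_rng(root.integers(0, 2**31 - 1))
            sessions.append(
                generate_session(config, session_id=session_id, mouse_id=mouse_id, rng=rng)
            )
    return sessions
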