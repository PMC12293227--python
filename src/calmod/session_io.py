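"""Session data model, file I/O, pipeline configuration and orchestration.

A :class:`Session` bundles all ROI traces, the behavior trace and optional
synthetic ground truth for one recording. Sessions round-trip through a
CSV bundle (``traces.csv``, ``behavior.csv``, ``session.json``, optional
``ground_truth.json``) or a single HDF5 file. :func:`run_pipeline` executes
the full analysis — detrend → neuropil subtraction → ΔF/F → σ → event
detection → behavior segmentation → modulation indices → transition
metrics → correlation table — writing every output plus a manifest that
records the configuration hash and seed needed to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import fluor, modulation, stats, transition
from .behavior import BehaviorTrace, StateSegmentation
from .errors import LoadError, PipelineError
from .fluor import COMPARTMENTS, DffTrace, RoiTrace

logger = logging.getLogger("calmod")

_EPS = 1e-9


@dataclass
class Session:
    """One recording: ROI traces + behavior on a shared clock."""

    session_id: str
    mouse_id: str
    group: str
    sampling_rate: float
    traces: list[RoiTrace]
    behavior: BehaviorTrace
    ground_truth: object | None = None

    def __post_init__(self):
        ids = [t.roi_id for t in self.traces]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise LoadError(f"duplicate roi_ids in session {self.session_id!r}: {dupes}")
        n = self.behavior.n_samples
        for t in self.traces:
            if t.n_samples != n:
                raise LoadError(
                    f"trace {t.roi_id!r} has {t.n_samples} samples but behavior "
                    f"has {n}"
                )
            if abs(t.sampling_rate - self.sampling_rate) > _EPS:
                raise LoadError(
                    f"trace {t.roi_id!r} sampling rate {t.sampling_rate} != "
                    f"session rate {self.sampling_rate}"
                )
        if abs(self.behavior.sampling_rate - self.sampling_rate) > _EPS:
            raise LoadError("behavior sampling rate differs from session rate")

    @property
    def duration(self) -> float:
        return self.behavior.duration


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class FluorConfig:
    smooth_window_s: float = fluor.SMOOTH_WINDOW_S
    baseline_percentile: float = fluor.BASELINE_PERCENTILE
    sigma_window_s: float = fluor.SIGMA_WINDOW_S
    neuropil_alpha: float = fluor.NEUROPIL_ALPHA
    k_astro: float = fluor.K_ASTRO
    k_neuron: float = fluor.K_NEURON
    min_event_amplitude: float = fluor.MIN_EVENT_AMPLITUDE
    max_event_duration_s: float | None = None
    detrend_method: str = "baseline"


@dataclass
class BehaviorConfig:
    speed_threshold_cmps: float = bh.SPEED_THRESHOLD_CMPS
    loc_merge_gap_s: float = bh.LOC_MERGE_GAP_S
    loc_min_bout_s: float = bh.LOC_MIN_BOUT_S
    whisk_smooth_s: float = bh.WHISK_SMOOTH_S
    whisk_baseline_percentile: float = bh.WHISK_BASELINE_PERCENTILE
    whisk_threshold_factor: float = bh.WHISK_THRESHOLD_FACTOR
    whisk_merge_gap_s: float = bh.WHISK_MERGE_GAP_S
    whisk_min_bout_s: float = bh.WHISK_MIN_BOUT_S
    whisk_threshold_mode: str = "multiplicative"
    whisk_order: str = "merge_first"


@dataclass
class ModulationConfig:
    min_loc_s: float = modulation.MIN_LOC_BOUT_S
    still_guard_s: float = modulation.STILL_GUARD_S
    min_still_s: float = modulation.MIN_STILL_SEGMENT_S
    min_whisk_s: float = modulation.MIN_WHISK_SEGMENT_S
    include_whisking_in_still: bool = True
    denom_eps: float = modulation.DENOM_EPS


@dataclass
class TransitionConfig:
    pre_s: float = transition.PRE_WINDOW_S
    post_s: float = transition.POST_WINDOW_S
    min_loc_s: float = transition.MIN_LOC_FOR_TRANSITION_S
    min_transitions: int = transition.MIN_TRANSITIONS
    baseline_return_s: float = transition.BASELINE_RETURN_S
    count_excluded: bool = False


@dataclass
class StatsConfig:
    n_boot: int = stats.N_BOOT
    alpha: float = stats.ALPHA
    sided: str = "two"


@dataclass
class PipelineConfig:
    """All tunable analysis parameters, one section per stage."""

    seed: int = 0
    fluor: FluorConfig = field(default_factory=FluorConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    modulation: ModulationConfig = field(default_factory=ModulationConfig)
    transition: TransitionConfig = field(default_factory=TransitionConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            seed=d.get("seed", 0),
            fluor=FluorConfig(**d.get("fluor", {})),
            behavior=BehaviorConfig(**d.get("behavior", {})),
            modulation=ModulationConfig(**d.get("modulation", {})),
            transition=TransitionConfig(**d.get("transition", {})),
            stats=StatsConfig(**d.get("stats", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def save_session(session: Session, path, format: str = "csv") -> Path:
    """Write a session as a CSV bundle directory or a single HDF5 file."""
    path = Path(path)
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        rows = []
        for t in session.traces:
            for i in range(t.n_samples):
                rows.append(
                    (i / t.sampling_rate, t.roi_id, t.compartment, t.F[i],
                     t.F_np[i] if t.F_np is not None else np.nan)
                )
        pd.DataFrame(
            rows, columns=["time_s", "roi_id", "compartment", "F", "F_np"]
        ).to_csv(path / "traces.csv", index=False)
        pd.DataFrame(
            {
                "time_s": session.behavior.times(),
                "speed_cmps": session.behavior.speed,
                "whisk_energy": session.behavior.whisk_energy,
            }
        ).to_csv(path / "behavior.csv", index=False)
        meta = {
            "session_id": session.session_id,
            "mouse_id": session.mouse_id,
            "group": session.group,
            "sampling_rate": session.sampling_rate,
        }
        (path / "session.json").write_text(json.dumps(meta, indent=1))
        if session.ground_truth is not None:
            (path / "ground_truth.json").write_text(
                json.dumps(session.ground_truth.to_dict())
            )
        return path
    if format == "hdf5":
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as fh:
            fh.attrs.update(
                session_id=session.session_id,
                mouse_id=session.mouse_id,
                group=session.group,
                sampling_rate=session.sampling_rate,
            )
            beh = fh.create_group("behavior")
            beh.create_dataset("speed_cmps", data=session.behavior.speed)
            beh.create_dataset("whisk_energy", data=session.behavior.whisk_energy)
            grp = fh.create_group("traces")
            for t in session.traces:
                g = grp.create_group(t.roi_id)
                g.attrs["compartment"] = t.compartment
                g.create_dataset("F", data=t.F)
                if t.F_np is not None:
                    g.create_dataset("F_np", data=t.F_np)
            if session.ground_truth is not None:
                fh.create_dataset(
                    "ground_truth_json",
                    data=json.dumps(session.ground_truth.to_dict()),
                )
        return path
    raise LoadError(f"unknown format {format!r}; use 'csv' or 'hdf5'")


def _load_ground_truth(payload: str):
    from .synthgen import SyntheticGroundTruth

    return SyntheticGroundTruth.from_dict(json.loads(payload))


def load_session(path, format: str = "csv") -> Session:
    """Read a session written by :func:`save_session`, with schema checks."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such session path: {path}")
    if format == "csv":
        meta = json.loads((path / "session.json").read_text())
        fs = float(meta["sampling_rate"])
        beh_df = pd.read_csv(path / "behavior.csv")
        for col in ("speed_cmps", "whisk_energy"):
            if col not in beh_df.columns:
                raise LoadError(f"behavior.csv is missing channel {col!r}")
        behavior = BehaviorTrace(
            speed=beh_df["speed_cmps"].to_numpy(),
            whisk_energy=beh_df["whisk_energy"].to_numpy(),
            sampling_rate=fs,
        )
        traces_df = pd.read_csv(path / "traces.csv")
        traces = []
        for roi_id, g in traces_df.groupby("roi_id", sort=False):
            comp = g["compartment"].iloc[0]
            if comp not in COMPARTMENTS:
                raise LoadError(
                    f"roi {roi_id!r}: unknown compartment {comp!r}; "
                    f"allowed: {COMPARTMENTS}"
                )
            f_np = g["F_np"].to_numpy()
            traces.append(
                RoiTrace(
                    roi_id=str(roi_id),
                    compartment=comp,
                    F=g["F"].to_numpy(),
                    F_np=None if np.isnan(f_np).all() else f_np,
                    sampling_rate=fs,
                    session_id=meta["session_id"],
                    mouse_id=meta["mouse_id"],
                    group=meta["group"],
                )
            )
        truth = None
        gt_path = path / "ground_truth.json"
        if gt_path.exists():
            truth = _load_ground_truth(gt_path.read_text())
        return Session(
            session_id=meta["session_id"],
            mouse_id=meta["mouse_id"],
            group=meta["group"],
            sampling_rate=fs,
            traces=traces,
            behavior=behavior,
            ground_truth=truth,
        )
    if format == "hdf5":
        with h5py.File(path, "r") as fh:
            fs = float(fh.attrs["sampling_rate"])
            meta = {k: fh.attrs[k] for k in ("session_id", "mouse_id", "group")}
            behavior = BehaviorTrace(
                speed=fh["behavior/speed_cmps"][:],
                whisk_energy=fh["behavior/whisk_energy"][:],
                sampling_rate=fs,
            )
            traces = []
            for roi_id in fh["traces"]:
                g = fh["traces"][roi_id]
                comp = g.attrs["compartment"]
                if comp not in COMPARTMENTS:
                    raise LoadError(
                        f"roi {roi_id!r}: unknown compartment {comp!r}; "
                        f"allowed: {COMPARTMENTS}"
                    )
                traces.append(
                    RoiTrace(
                        roi_id=roi_id,
                        compartment=comp,
                        F=g["F"][:],
                        F_np=g["F_np"][:] if "F_np" in g else None,
                        sampling_rate=fs,
                        session_id=str(meta["session_id"]),
                        mouse_id=str(meta["mouse_id"]),
                        group=str(meta["group"]),
                    )
                )
            truth = None
            if "ground_truth_json" in fh:
                truth = _load_ground_truth(fh["ground_truth_json"][()].decode())
        return Session(
            session_id=str(meta["session_id"]),
            mouse_id=str(meta["mouse_id"]),
            group=str(meta["group"]),
            sampling_rate=fs,
            traces=traces,
            behavior=behavior,
            ground_truth=truth,
        )
    raise LoadError(f"unknown format {format!r}; use 'csv' or 'hdf5'")


def segmentation_to_frame(seg: StateSegmentation) -> pd.DataFrame:
    return pd.DataFrame(
        [(s, e, lab) for s, e, lab in seg.intervals],
        columns=["start_s", "end_s", "label"],
    )


def segmentation_from_frame(df: pd.DataFrame, sampling_rate: float) -> StateSegmentation:
    return StateSegmentation(
        intervals=tuple(
            (row.start_s, row.end_s, row.label) for row in df.itertuples()
        ),
        sampling_rate=sampling_rate,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class SessionResult:
    """All per-session pipeline outputs as tidy tables."""

    session_id: str
    dff_traces: list[DffTrace]
    segmentation: StateSegmentation
    events_by_roi: dict[str, list]
    events: pd.DataFrame
    state_summary: pd.DataFrame
    modulation: pd.DataFrame
    transitions: pd.DataFrame
    activation: pd.DataFrame
    reliability: pd.DataFrame
    lags: pd.DataFrame
    correlations: pd.DataFrame


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(
    session: Session,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> SessionResult:
    """Execute the full trace-level analysis on one session.

    When ``out_dir`` is given, all tables are written there along with a
    ``manifest.json`` recording the stage outputs, configuration hash and
    seed. A failing stage raises :class:`PipelineError` naming the stage;
    outputs of earlier stages already written are retained.
    """
    cfg = config or PipelineConfig()
    fc, bc, mc, tc = cfg.fluor, cfg.behavior, cfg.modulation, cfg.transition

    preprocess = _stage("preprocess")(
        lambda t: fluor.preprocess_trace(
            t,
            alpha=fc.neuropil_alpha,
            smooth_window_s=fc.smooth_window_s,
            percentile=fc.baseline_percentile,
            sigma_window_s=fc.sigma_window_s,
            detrend_method=fc.detrend_method,
        )
    )
    dff_traces = [preprocess(t) for t in session.traces]

    detect = _stage("events")(
        lambda d: fluor.detect_events(
            d,
            k=fc.k_neuron if d.compartment == "Neuron" else fc.k_astro,
            min_amplitude=fc.min_event_amplitude,
            max_duration_s=fc.max_event_duration_s,
        )
    )
    events_by_roi = {d.roi_id: detect(d) for d in dff_traces}

    segmentation = _stage("segmentation")(bh.segment_session)(
        session.behavior,
        speed_threshold=bc.speed_threshold_cmps,
        loc_merge_gap_s=bc.loc_merge_gap_s,
        loc_min_bout_s=bc.loc_min_bout_s,
        whisk_smooth_s=bc.whisk_smooth_s,
        whisk_baseline_percentile=bc.whisk_baseline_percentile,
        whisk_threshold_factor=bc.whisk_threshold_factor,
        whisk_merge_gap_s=bc.whisk_merge_gap_s,
        whisk_min_bout_s=bc.whisk_min_bout_s,
        whisk_threshold_mode=bc.whisk_threshold_mode,
        whisk_order=bc.whisk_order,
    )

    state_summary = _stage("state_summary")(fluor.summarize_events_by_state)(
        events_by_roi, segmentation, dff_traces
    )
    mod_table = _stage("modulation")(modulation.modulation_table)(
        dff_traces,
        segmentation,
        min_loc_s=mc.min_loc_s,
        min_whisk_s=mc.min_whisk_s,
        guard_s=mc.still_guard_s,
        min_still_s=mc.min_still_s,
        include_whisking_in_still=mc.include_whisking_in_still,
        denom_eps=mc.denom_eps,
    )

    windows = _stage("transitions")(transition.extract_transitions)(
        segmentation, pre_s=tc.pre_s, post_s=tc.post_s, min_loc_s=tc.min_loc_s
    )
    trans_table = transition.transition_table(
        windows, events_by_roi, baseline_return_s=tc.baseline_return_s
    )
    activation = transition.activation_rate(trans_table, count_excluded=tc.count_excluded)
    reliability = transition.response_reliability(
        trans_table, min_transitions=tc.min_transitions
    )
    lags = transition.onset_lags(trans_table)

    n_astro = sum(1 for d in dff_traces if d.compartment != "Neuron")
    correlations = (
        stats.pairwise_roi_correlation(dff_traces)
        if n_astro >= 2
        else pd.DataFrame(columns=["roi_a", "roi_b", "compartment_a", "compartment_b", "r"])
    )

    result = SessionResult(
        session_id=session.session_id,
        dff_traces=dff_traces,
        segmentation=segmentation,
        events_by_roi=events_by_roi,
        events=fluor.events_to_frame(events_by_roi),
        state_summary=state_summary,
        modulation=mod_table,
        transitions=trans_table,
        activation=activation,
        reliability=reliability,
        lags=lags,
        correlations=correlations,
    )
    if out_dir is not None:
        write_result(result, session, cfg, out_dir)
    return result


def write_result(result: SessionResult, session: Session,
                 config: PipelineConfig, out_dir) -> Path:
    """Write all result tables, per-ROI baselines, and the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = {}

    segmentation_to_frame(result.segmentation).to_csv(
        out / "segmentation.tsv", sep="\t", index=False
    )
    outputs["segmentation"] = "segmentation.tsv"
    for name, df in [
        ("events", result.events),
        ("state_summary", result.state_summary),
        ("modulation", result.modulation),
        ("transitions", result.transitions),
        ("activation", result.activation),
        ("reliability", result.reliability),
        ("lags", result.lags),
        ("correlations", result.correlations),
    ]:
        df.to_csv(out / f"{name}.csv", index=False)
        outputs[name] = f"{name}.csv"
    baselines = {
        d.roi_id: {"f0": d.f0, "sigma": d.sigma} for d in result.dff_traces
    }
    (out / "baselines.json").write_text(json.dumps(baselines, indent=1))
    outputs["baselines"] = "baselines.json"

    manifest = {
        "session_id": session.session_id,
        "mouse_id": session.mouse_id,
        "group": session.group,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def run_cohort(sessions: list[Session], config: PipelineConfig | None = None) -> dict[str, pd.DataFrame]:
    """Run the pipeline over many sessions and pool the tidy tables.

    Returns pooled ``state_summary``, ``modulation``, ``reliability``,
    ``lags``, ``activation`` and ``correlations`` tables with session,
    mouse and group columns, ready for group comparison or mixed-model
    export.
    """
    pooled: dict[str, list[pd.DataFrame]] = {
        k: [] for k in ("state_summary", "modulation", "reliability", "lags",
                        "activation", "correlations")
    }
    for session in sessions:
        res = run_pipeline(session, config)
        meta = {
            "session_id": session.session_id,
            "mouse_id": session.mouse_id,
            "group": session.group,
        }
        roi_comp = {d.roi_id: d.compartment for d in res.dff_traces}
        for key in pooled:
            df = getattr(res, key).copy()
            for col, val in meta.items():
                if col not in df.columns:
                    df[col] = val
            if "roi_id" in df.columns and "compartment" not in df.columns:
                df["compartment"] = df["roi_id"].map(roi_comp)
            pooled[key].append(df)
    return {k: pd.concat(v, ignore_index=True) for k, v in pooled.items()}
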