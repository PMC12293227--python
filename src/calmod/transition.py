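"""Ca²⁺ responses around still→locomotion transitions.

For every locomotion onset whose bout lasts at least 3 s, a peri-transition
window spanning 2 s before to 7 s after the onset is analyzed. Per window,
ROIs are excluded when an event is already ongoing before the onset or when
an event's offset falls within 1 s before it (activity not yet returned to
baseline). From the included ROI-window pairs the module computes:

* activation rate — the fraction of ROIs with at least one post-onset
  event per transition;
* response reliability RR = RA/n — the fraction of a ROI's transitions
  with a post-onset event, for ROIs seen in at least 3 transitions;
* onset lag — the delay from locomotion onset to the first post-onset
  event onset, summarized at group level by a hierarchical bootstrap over
  mice and ROIs (see :mod:`calmod.stats`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import LOCOMOTION, StateSegmentation
from .fluor import CalciumEvent

PRE_WINDOW_S = 2.0        # pre-onset context
POST_WINDOW_S = 7.0       # post-onset window for responses
MIN_LOC_FOR_TRANSITION_S = 3.0   # locomotion bouts entering the analysis
MIN_TRANSITIONS = 3       # ROIs need at least this many transitions for RR
BASELINE_RETURN_S = 1.0   # event offsets within this pre-onset span exclude the ROI

INCLUDED = "included"

_EPS = 1e-9


@dataclass(frozen=True)
class TransitionWindow:
    """One qualifying still→locomotion transition."""

    transition_time: float
    loc_duration: float
    pre_s: float = PRE_WINDOW_S
    post_s: float = POST_WINDOW_S
    partial: bool = False   # clipped at session bounds or short pre-context

    @property
    def start(self) -> float:
        return self.transition_time - self.pre_s

    @property
    def end(self) -> float:
        return self.transition_time + self.post_s


def extract_transitions(
    segmentation: StateSegmentation,
    pre_s: float = PRE_WINDOW_S,
    post_s: float = POST_WINDOW_S,
    min_loc_s: float = MIN_LOC_FOR_TRANSITION_S,
) -> list[TransitionWindow]:
    """Peri-transition windows for locomotion bouts of at least ``min_loc_s``.

    A window is marked partial when fewer than ``pre_s`` seconds of
    non-locomotion precede the onset (including session-start clipping) or
    when the post window runs past the session end.
    """
    loc = segmentation.intervals_for(LOCOMOTION)
    windows = []
    prev_loc_end = None
    for s, e in loc:
        if e - s < min_loc_s - _EPS:
            prev_loc_end = e
            continue
        pre_context = s if prev_loc_end is None else s - prev_loc_end
        partial = (
            pre_context < pre_s - _EPS
            or s + post_s > segmentation.duration + _EPS
        )
        windows.append(
            TransitionWindow(
                transition_time=s,
                loc_duration=e - s,
                pre_s=pre_s,
                post_s=post_s,
                partial=partial,
            )
        )
        prev_loc_end = e
    return windows


def roi_inclusion(
    events: list[CalciumEvent],
    window: TransitionWindow,
    baseline_return_s: float = BASELINE_RETURN_S,
) -> tuple[bool, str]:
    """Whether a ROI enters the analysis of one transition window.

    Excluded when an event spans the onset (ongoing), when an event ends
    within ``baseline_return_s`` before the onset (signal not yet back at
    baseline), or when any event overlaps the remaining pre-onset context.
    Returns ``(included, reason)``.
    """
    t = window.transition_time
    for ev in events:
        if ev.start_time < t - _EPS and ev.end_time > t + _EPS:
            return False, "ongoing-event"
    for ev in events:
        if t - baseline_return_s - _EPS <= ev.end_time < t - _EPS:
            return False, "recent-offset"
    for ev in events:
        if ev.start_time < t - _EPS and ev.end_time > window.start + _EPS:
            return False, "pre-window-event"
    return True, INCLUDED


def _first_post_onset(events: list[CalciumEvent], window: TransitionWindow) -> float | None:
    """Relative onset of the first event starting in (0, post_s], or None."""
    t = window.transition_time
    lags = [
        ev.onset_time - t
        for ev in events
        if t + _EPS < ev.onset_time <= t + window.post_s + _EPS
    ]
    return min(lags) if lags else None


def transition_table(
    windows: list[TransitionWindow],
    events_by_roi: dict[str, list[CalciumEvent]],
    baseline_return_s: float = BASELINE_RETURN_S,
) -> pd.DataFrame:
    """Long table of ROI × transition outcomes.

    Columns: transition index and time, ROI, inclusion flag and reason,
    whether the ROI responded (post-onset event), and the first-event lag.
    """
    rows = []
    for i, w in enumerate(windows):
        for roi_id, events in events_by_roi.items():
            included, reason = roi_inclusion(events, w, baseline_return_s)
            lag = _first_post_onset(events, w)
            rows.append(
                {
                    "transition": i,
                    "transition_time_s": w.transition_time,
                    "loc_duration_s": w.loc_duration,
                    "partial": w.partial,
                    "roi_id": roi_id,
                    "included": included,
                    "exclusion_reason": reason,
                    "responded": lag is not None,
                    "first_onset_lag_s": np.nan if lag is None else lag,
                }
            )
    cols = [
        "transition", "transition_time_s", "loc_duration_s", "partial",
        "roi_id", "included", "exclusion_reason", "responded",
        "first_onset_lag_s",
    ]
    return pd.DataFrame(rows, columns=cols)


def activation_rate(
    table: pd.DataFrame,
    count_excluded: bool = False,
) -> pd.DataFrame:
    """Fraction of ROIs activated per transition.

    By default excluded ROIs leave both numerator and denominator;
    ``count_excluded`` keeps them in the denominator. Transitions with an
    empty denominator yield a missing rate.
    """
    rows = []
    for trans, sub in table.groupby("transition"):
        denom = sub if count_excluded else sub[sub["included"]]
        resp = int((denom["included"] & denom["responded"]).sum())
        n = len(denom)
        rows.append(
            {
                "transition": trans,
                "transition_time_s": sub["transition_time_s"].iloc[0],
                "n_rois": n,
                "n_active": resp,
                "activation_rate": resp / n if n > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def response_reliability(
    table: pd.DataFrame,
    min_transitions: int = MIN_TRANSITIONS,
) -> pd.DataFrame:
    """RR = RA/n per ROI over all qualifying transitions of its session.

    RA counts transitions with a post-onset event; n counts all qualifying
    transitions the ROI was present for. ROIs with fewer than
    ``min_transitions`` transitions are emitted with a missing RR.
    """
    rows = []
    for roi_id, sub in table.groupby("roi_id"):
        n = len(sub)
        ra = int(sub["responded"].sum())
        rows.append(
            {
                "roi_id": roi_id,
                "n_transitions": n,
                "n_responded": ra,
                "rr": ra / n if n >= min_transitions else np.nan,
            }
        )
    return pd.DataFrame(rows)


def onset_lags(table: pd.DataFrame) -> pd.DataFrame:
    """Per-ROI mean first-event onset lag over included, responding windows."""
    sub = table[table["included"] & table["responded"]]
    rows = [
        {
            "roi_id": roi_id,
            "n_windows": len(g),
            "mean_lag_s": float(g["first_onset_lag_s"].mean()),
        }
        for roi_id, g in sub.groupby("roi_id")
    ]
    return pd.DataFrame(rows, columns=["roi_id", "n_windows", "mean_lag_s"])
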