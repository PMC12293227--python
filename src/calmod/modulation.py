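"""Locomotion and whisking modulation indices from ΔF/F and the segmentation.

Both indices contrast mean ΔF/F between an active behavioral state and
qualifying stillness::

    LocMI   = (S_loc − S_s) / (S_loc + S_s)
    WhiskMI = (S_w  − S_s) / (S_w  + S_s)

where S_loc averages ΔF/F over locomotion bouts longer than 3 s, S_w over
still-whisking bouts of at least 0.4 s, and S_s over still time after
removing a ±2 s guard around every locomotion bout and keeping only
residual segments of at least 2 s. For nonnegative means the indices lie
in [−1, 1]; they are invariant to positive rescaling of ΔF/F. Because
ΔF/F can dip below zero, results whose denominator magnitude falls below a
small epsilon are flagged invalid rather than clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import LOCOMOTION, STILL_WHISKING, StateSegmentation
from .errors import ContractError
from .fluor import DffTrace

MIN_LOC_BOUT_S = 3.0       # locomotion bouts must exceed this to enter S_loc
STILL_GUARD_S = 2.0        # still time removed around each locomotion bout
MIN_STILL_SEGMENT_S = 2.0  # minimum residual still segment entering S_s
MIN_WHISK_SEGMENT_S = 0.4  # minimum still-whisking bout entering S_w
DENOM_EPS = 1e-3           # |S_active + S_s| below this marks the index invalid

_EPS = 1e-9

LOCMI = "LocMI"
WHISKMI = "WhiskMI"


@dataclass(frozen=True)
class ModulationResult:
    """One ROI's modulation index with its component means."""

    roi_id: str
    index_kind: str
    value: float            # NaN when invalid
    s_active: float
    s_still: float
    n_active_segments: int
    n_still_segments: int
    valid: bool
    compartment: str = ""
    mouse_id: str = ""
    session_id: str = ""
    group: str = ""


def _check_clock(dff: DffTrace, segmentation: StateSegmentation) -> None:
    if abs(dff.sampling_rate - segmentation.sampling_rate) > _EPS:
        raise ContractError(
            f"dff sampling rate {dff.sampling_rate} != segmentation rate "
            f"{segmentation.sampling_rate}"
        )
    if abs(dff.duration - segmentation.duration) > 1.0 / dff.sampling_rate + _EPS:
        raise ContractError(
            f"dff duration {dff.duration} != segmentation duration "
            f"{segmentation.duration}"
        )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    d = np.diff(np.concatenate(([False], mask, [False])).astype(np.int8))
    return list(zip(np.nonzero(d == 1)[0].tolist(), np.nonzero(d == -1)[0].tolist()))


def qualifying_still_mask(
    segmentation: StateSegmentation,
    n_samples: int,
    guard_s: float = STILL_GUARD_S,
    min_len_s: float = MIN_STILL_SEGMENT_S,
    include_whisking: bool = True,
) -> np.ndarray:
    """Boolean sample mask of still time entering S_s.

    Starts from Still (plus StillWhisking when ``include_whisking``),
    removes a ±``guard_s`` guard around every locomotion interval, and
    keeps only residual contiguous segments of at least ``min_len_s``.
    """
    fs = segmentation.sampling_rate
    labels = segmentation.sample_labels(n_samples)
    if include_whisking:
        mask = labels != LOCOMOTION
    else:
        mask = (labels != LOCOMOTION) & (labels != STILL_WHISKING)
    for s, e in segmentation.intervals_for(LOCOMOTION):
        a = int(round((s - guard_s) * fs))
        b = int(round((e + guard_s) * fs))
        mask[max(a, 0):min(b, n_samples)] = False
    keep = np.zeros(n_samples, dtype=bool)
    for a, b in _runs(mask):
        if (b - a) >= min_len_s * fs - _EPS:
            keep[a:b] = True
    return keep


def _interval_mask(intervals, fs: float, n: int, min_len_s: float, strict: bool) -> tuple[np.ndarray, int]:
    mask = np.zeros(n, dtype=bool)
    count = 0
    for s, e in intervals:
        length = e - s
        ok = length > min_len_s + _EPS if strict else length >= min_len_s - _EPS
        if ok:
            mask[int(round(s * fs)):min(int(round(e * fs)), n)] = True
            count += 1
    return mask, count


def _build_result(dff: DffTrace, kind: str, active_mask, still_mask,
                  n_active: int, n_still: int, denom_eps: float) -> ModulationResult:
    meta = dict(
        roi_id=dff.roi_id,
        compartment=dff.compartment,
        mouse_id=dff.mouse_id,
        session_id=dff.session_id,
        group=dff.group,
    )
    s_active = float(dff.dff[active_mask].mean()) if active_mask.any() else np.nan
    s_still = float(dff.dff[still_mask].mean()) if still_mask.any() else np.nan
    valid = (
        active_mask.any()
        and still_mask.any()
        and abs(s_active + s_still) >= denom_eps
    )
    value = (s_active - s_still) / (s_active + s_still) if valid else np.nan
    return ModulationResult(
        index_kind=kind,
        value=value,
        s_active=s_active,
        s_still=s_still,
        n_active_segments=n_active,
        n_still_segments=n_still,
        valid=bool(valid),
        **meta,
    )


def compute_locmi(
    dff: DffTrace,
    segmentation: StateSegmentation,
    min_loc_s: float = MIN_LOC_BOUT_S,
    guard_s: float = STILL_GUARD_S,
    min_still_s: float = MIN_STILL_SEGMENT_S,
    include_whisking_in_still: bool = True,
    denom_eps: float = DENOM_EPS,
) -> ModulationResult:
    """Locomotion modulation index for one ROI."""
    _check_clock(dff, segmentation)
    n = dff.n_samples
    fs = dff.sampling_rate
    loc_mask, n_loc = _interval_mask(
        segmentation.intervals_for(LOCOMOTION), fs, n, min_loc_s, strict=True
    )
    still_mask = qualifying_still_mask(
        segmentation, n, guard_s, min_still_s, include_whisking=include_whisking_in_still
    )
    n_still = len(_runs(still_mask))
    return _build_result(dff, LOCMI, loc_mask, still_mask, n_loc, n_still, denom_eps)


def compute_whiskmi(
    dff: DffTrace,
    segmentation: StateSegmentation,
    min_whisk_s: float = MIN_WHISK_SEGMENT_S,
    guard_s: float = STILL_GUARD_S,
    min_still_s: float = MIN_STILL_SEGMENT_S,
    denom_eps: float = DENOM_EPS,
) -> ModulationResult:
    """Whisking modulation index for one ROI.

    S_w averages over still-whisking bouts of at least ``min_whisk_s``;
    whisking during locomotion never contributes (running and free whisking
    cannot be separated). S_s uses the same qualifying still time as LocMI
    with the whisk bouts themselves excluded.
    """
    _check_clock(dff, segmentation)
    n = dff.n_samples
    fs = dff.sampling_rate
    whisk_mask, n_whisk = _interval_mask(
        segmentation.intervals_for(STILL_WHISKING), fs, n, min_whisk_s, strict=False
    )
    base_still = qualifying_still_mask(
        segmentation, n, guard_s, min_still_s, include_whisking=True
    )
    labels = segmentation.sample_labels(n)
    still_mask = base_still & (labels != STILL_WHISKING)
    n_still = len(_runs(still_mask))
    return _build_result(dff, WHISKMI, whisk_mask, still_mask, n_whisk, n_still, denom_eps)


def modulation_table(
    dff_traces: list[DffTrace],
    segmentation: StateSegmentation,
    min_loc_s: float = MIN_LOC_BOUT_S,
    min_whisk_s: float = MIN_WHISK_SEGMENT_S,
    guard_s: float = STILL_GUARD_S,
    min_still_s: float = MIN_STILL_SEGMENT_S,
    include_whisking_in_still: bool = True,
    denom_eps: float = DENOM_EPS,
) -> pd.DataFrame:
    """Tidy per-ROI table of both indices for a session."""
    rows = []
    for dff in dff_traces:
        for res in (
            compute_locmi(
                dff, segmentation, min_loc_s, guard_s, min_still_s,
                include_whisking_in_still, denom_eps,
            ),
            compute_whiskmi(
                dff, segmentation, min_whisk_s, guard_s, min_still_s, denom_eps
            ),
        ):
            rows.append(
                {
                    "roi_id": res.roi_id,
                    "compartment": res.compartment,
                    "group": res.group,
                    "mouse_id": res.mouse_id,
                    "session_id": res.session_id,
                    "index_kind": res.index_kind,
                    "value": res.value,
                    "s_active": res.s_active,
                    "s_still": res.s_still,
                    "n_active_segments": res.n_active_segments,
                    "n_still_segments": res.n_still_segments,
                    "valid": res.valid,
                }
            )
    return pd.DataFrame(rows)
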