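"""Independent brute-force reference implementations used as test oracles.

Everything here recomputes quantities with literal per-sample loops and
run-length encoding, sharing no code with the package implementation.
"""

import numpy as np

SPEED_THRESHOLD = 1.0
LOC_MERGE_GAP_S = 0.5
LOC_MIN_BOUT_S = 0.5
WHISK_SMOOTH_S = 0.33
WHISK_PCTL = 1.0
WHISK_FACTOR = 1.5
WHISK_MERGE_GAP_S = 0.3
WHISK_MIN_BOUT_S = 0.4


def rle_true(flags):
    """Half-open index runs where flags is True."""
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(flags)))
    return runs


def merge_gaps(runs, max_gap_samples):
    merged = []
    for a, b in runs:
        if merged and a - merged[-1][1] < max_gap_samples:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return merged


def moving_average_zeropad(x, w):
    """Centered moving average with zero padding, odd window w."""
    h = w // 2
    out = np.zeros(len(x))
    for i in range(len(x)):
        total = 0.0
        for j in range(i - h, i + h + 1):
            if 0 <= j < len(x):
                total += x[j]
        out[i] = total / w
    return out


def oracle_segmentation(speed, whisk, fs):
    """Per-sample labeler applying the segmentation rules literally.

    Returns a list of (start_s, end_s, label) intervals partitioning the
    session, with labels Still / StillWhisking / Locomotion.
    """
    n = len(speed)
    loc_runs = rle_true([s > SPEED_THRESHOLD for s in speed])
    loc_runs = merge_gaps(loc_runs, LOC_MERGE_GAP_S * fs)
    loc_runs = [(a, b) for a, b in loc_runs if (b - a) / fs > LOC_MIN_BOUT_S]
    loc_mask = np.zeros(n, dtype=bool)
    for a, b in loc_runs:
        loc_mask[a:b] = True

    w = int(round(WHISK_SMOOTH_S * fs))
    if w % 2 == 0:
        w += 1
    smoothed = moving_average_zeropad(np.asarray(whisk, dtype=float), w)
    w0 = np.percentile(smoothed, WHISK_PCTL)
    thr = WHISK_FACTOR * w0
    wruns = rle_true([v > thr for v in smoothed])
    wruns = merge_gaps(wruns, WHISK_MERGE_GAP_S * fs)
    wruns = [(a, b) for a, b in wruns if (b - a) / fs >= WHISK_MIN_BOUT_S]
    whisk_mask = np.zeros(n, dtype=bool)
    for a, b in wruns:
        whisk_mask[a:b] = True

    # whisking only counts within still time, and residual fragments below
    # the minimum bout length are relabeled still
    sw_mask = whisk_mask & ~loc_mask
    for a, b in rle_true(sw_mask):
        if (b - a) / fs < WHISK_MIN_BOUT_S:
            sw_mask[a:b] = False
    labels = []
    for i in range(n):
        if loc_mask[i]:
            labels.append("Locomotion")
        elif sw_mask[i]:
            labels.append("StillWhisking")
        else:
            labels.append("Still")
    intervals = []
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            intervals.append((start / fs, i / fs, labels[start]))
            start = i
    return intervals


def oracle_events(x, fs, k, sigma, min_amplitude=0.1):
    """Naive scan for suprathreshold positive lobes.

    Returns (start_s, onset_s, end_s, amplitude) tuples.
    """
    thr = max(k * sigma, min_amplitude)
    n = len(x)
    out = []
    i = 0
    while i < n:
        if x[i] > thr:
            j = i
            while j > 0 and x[j - 1] > 0:
                j -= 1
            e = i
            while e < n and x[e] > 0:
                e += 1
            onset = j
            while x[onset] <= thr:
                onset += 1
            out.append((j / fs, onset / fs, e / fs, max(x[j:e])))
            i = e
        else:
            i += 1
    return out


def oracle_sigma(x, fs, window_s=5.0):
    """Minimum over all sliding windows of the sample SD, by direct loops."""
    w = int(round(window_s * fs))
    best = np.inf
    for i in range(len(x) - w + 1):
        sd = np.std(x[i:i + w], ddof=1)
        best = min(best, sd)
    return best


def oracle_transition_counts(events, windows, post_s=7.0):
    """Per-ROI RA, n and first-onset lags recomputed by literal loops.

    ``events`` maps roi_id -> list of (onset_s, start_s, end_s); ``windows``
    is a list of transition times.
    """
    result = {}
    for roi, evs in events.items():
        ra = 0
        lags = []
        for t in windows:
            post = [o for o, _, _ in evs if t < o <= t + post_s]
            if post:
                ra += 1
                lags.append(min(post) - t)
        result[roi] = {"ra": ra, "n": len(windows), "lags": lags}
    return result
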