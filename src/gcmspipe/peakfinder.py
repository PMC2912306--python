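"""Slope-based EIC peak detection (the *PeakFinder* stage).

A chromatographic peak is admitted when the smoothed first derivative of the
trace exceeds a minimum slope for two consecutive scan intervals (peak start),
subsequently drops below the negative of that slope (falling phase), and the
trace then either reaches a local minimum or the descending slope decays back
above ``-min_slope`` for two consecutive intervals (peak end).  The apex is
the raw-intensity maximum between the boundaries (earliest scan on plateau
ties).  Candidate peaks are then screened by five thresholds: minimum slope,
height, width, area and peak-purity factor.

The purity factor of a window is the ratio of the area lying above the
horizontal line through the window's minimum intensity to the area below that
line; a peak rising from a true zero baseline has infinite purity (clamped to
``PURITY_SENTINEL``), while a flat rectangle has purity 0.

Areas are baseline-corrected by default: the trapezoidal integral of the raw
trace between the boundaries minus the area under the chord joining the
boundary intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, InputError
from .msdata import Trace

#: Finite stand-in for infinite purity on zero-minimum windows.
PURITY_SENTINEL = 1e9


@dataclass(frozen=True)
class PeakParams:
    """The five PeakFinder thresholds plus smoothing and baseline options.

    Attributes
    ----------
    min_slope:
        Minimum sustained slope (intensity units / s) that opens a peak.
    min_height:
        Minimum apex intensity.
    min_width:
        Minimum ``rt_end - rt_start`` in seconds.
    min_area:
        Minimum (baseline-corrected) peak area, intensity·seconds.
    min_purity:
        Minimum peak-purity factor.
    smoothing_window:
        Odd moving-average window (scans) applied before differentiation.
    baseline_correct:
        Subtract the chord under the peak from the trapezoidal area.
    """

    min_slope: float = 50.0
    min_height: float = 500.0
    min_width: float = 1.0
    min_area: float = 1000.0
    min_purity: float = 2.0
    smoothing_window: int = 3
    baseline_correct: bool = True

    def __post_init__(self):
        if self.min_slope <= 0:
            raise InputError("min_slope must be > 0")
        for name in ("min_height", "min_width", "min_area", "min_purity"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise InputError("smoothing_window must be an odd integer >= 1")


@dataclass
class EicPeak:
    """One detected extracted-ion-chromatogram peak."""

    mz: int
    rt_start: float
    rt_apex: float
    rt_end: float
    height: float
    area: float
    purity: float
    apex_ri: float | None = None

    def __post_init__(self):
        if not (self.rt_start < self.rt_apex < self.rt_end):
            raise InputError("peak must satisfy rt_start < rt_apex < rt_end")
        if self.height <= 0 or self.area <= 0 or self.purity < 0:
            raise InputError("peak must have positive height/area and purity >= 0")


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    pad = window // 2
    padded = np.pad(np.asarray(y, float), pad, mode="edge")
    return np.convolve(padded, np.full(window, 1.0 / window), mode="valid")


def peak_purity(trace: Trace, rt_start: float, rt_end: float) -> float:
    """Peak-purity factor of the window ``[rt_start, rt_end]``.

    Returns ``(area above the horizontal line through the window minimum) /
    (area below that line)``; ``math.inf`` when the minimum is exactly 0.
    """
    if rt_start >= rt_end:
        raise InputError("rt_start must be < rt_end")
    lo = int(np.searchsorted(trace.rts, rt_start, side="left"))
    hi = int(np.searchsorted(trace.rts, rt_end, side="right"))
    if hi - lo < 2:
        raise InputError("purity window contains fewer than 2 scans")
    t = trace.rts[lo:hi]
    y = trace.intensities[lo:hi]
    total = float(np.trapezoid(y, t))
    floor = float(y.min())
    below = floor * (t[-1] - t[0])
    above = total - below
    if below <= 0:
        return float("inf")
    return above / below


def detect_peaks(trace: Trace, params: PeakParams) -> list[EicPeak]:
    """Detect peaks on one EIC, ordered by apex retention time.

    Returned peaks are non-overlapping and each satisfies all five thresholds.
    """
    n = len(trace)
    if n < 2 * params.smoothing_window:
        raise InputError(
            f"trace has {n} points; needs >= {2 * params.smoothing_window}")
    t = trace.rts
    y = trace.intensities
    s = _smooth(y, params.smoothing_window)
    dt = np.diff(t)
    slope = np.diff(s) / dt                      # len n-1, slope[i] over [i, i+1]
    rising = slope >= params.min_slope
    sustained = rising[:-1] & rising[1:]         # len n-2; start candidates
    starts = np.flatnonzero(sustained)
    if starts.size == 0:
        return []

    falling = slope <= -params.min_slope
    local_min = s[1:] >= s[:-1]                  # len n-1; True at i: s[i+1]>=s[i]
    flat = slope > -params.min_slope
    decayed = flat[:-1] & flat[1:]               # len n-2
    end_cond = local_min[: n - 2] | decayed      # len n-2

    peaks: list[EicPeak] = []
    last_end = -1
    for st in starts:
        st = int(st)
        if st <= last_end:
            continue
        fall_rel = np.flatnonzero(falling[st + 1:])
        if fall_rel.size == 0:
            break
        f = st + 1 + int(fall_rel[0])
        end_rel = np.flatnonzero(end_cond[f + 1:])
        e = f + 1 + int(end_rel[0]) if end_rel.size else n - 1
        e = min(e, n - 1)
        ap = st + int(np.argmax(y[st:e + 1]))    # earliest scan wins on ties
        last_end = e
        if not (st < ap < e):
            continue
        height = float(y[ap])
        width = float(t[e] - t[st])
        raw_area = float(np.trapezoid(y[st:e + 1], t[st:e + 1]))
        chord = 0.5 * (y[st] + y[e]) * width
        area = raw_area - chord if params.baseline_correct else raw_area
        if area <= 0 or height <= 0:
            continue
        floor = float(y[st:e + 1].min())
        below = floor * width
        purity = min((raw_area - below) / below, PURITY_SENTINEL) \
            if below > 0 else PURITY_SENTINEL
        if (height >= params.min_height and width >= params.min_width
                and area >= params.min_area and purity >= params.min_purity):
            peaks.append(EicPeak(trace.channel, float(t[st]), float(t[ap]),
                                 float(t[e]), height, area, purity))
    return peaks


def detect_peaks_run(run, params: PeakParams,
                     mzs: list[int] | None = None) -> list[EicPeak]:
    """Run :func:`detect_peaks` over every EIC of a run (or a channel subset).

    Peaks are returned sorted by (rt_apex, mz).
    """
    from .msdata import extract_eic

    channels = [int(m) for m in (mzs if mzs is not None else run.mzs)]
    peaks: list[EicPeak] = []
    for mz in channels:
        peaks.extend(detect_peaks(extract_eic(run, mz), params))
    peaks.sort(key=lambda p: (p.rt_apex, p.mz))
    return peaks


# ---------------------------------------------------------------------------
# peak-list TSV
# ---------------------------------------------------------------------------

PEAKLIST_COLUMNS = ["mz", "rt_start_s", "rt_apex_s", "rt_end_s",
                    "height", "area", "purity", "apex_ri"]


def write_peaklist(peaks: list[EicPeak], path) -> None:
    """Write the tab-delimited peak list report file."""
    rows = [{
        "mz": p.mz,
        "rt_start_s": p.rt_start,
        "rt_apex_s": p.rt_apex,
        "rt_end_s": p.rt_end,
        "height": p.height,
        "area": p.area,
        "purity": min(p.purity, PURITY_SENTINEL),
        "apex_ri": "" if p.apex_ri is None else p.apex_ri,
    } for p in peaks]
    df = pd.DataFrame(rows, columns=PEAKLIST_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_peaklist(path) -> list[EicPeak]:
    """Read a peak list TSV back into :class:`EicPeak` objects."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: unreadable peak list ({exc})") from exc
    if list(df.columns) != PEAKLIST_COLUMNS:
        raise FormatError(f"{path}: unexpected peak list columns {list(df.columns)}")
    peaks = []
    for i, row in df.iterrows():
        try:
            ri = row["apex_ri"]
            peaks.append(EicPeak(
                mz=int(row["mz"]), rt_start=float(row["rt_start_s"]),
                rt_apex=float(row["rt_apex_s"]), rt_end=float(row["rt_end_s"]),
                height=float(row["height"]), area=float(row["area"]),
                purity=float(row["purity"]),
                apex_ri=None if pd.isna(ri) else float(ri)))
        except (ValueError, InputError) as exc:
            raise FormatError(f"{path}: malformed peak at line {i + 2}: {exc}") from exc
    return peaks
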