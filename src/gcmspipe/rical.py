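"""Retention-time → retention-index calibration.

Retention indices (RI) normalise retention times against a homologous series
of standards (classically *n*-alkanes, C10 → 1000) so that peak positions are
comparable across instruments and over column drift.  A calibration is a bare
table of (retention time, retention index) anchors; conversion is
piecewise-linear interpolation between bracketing anchors, with linear
extrapolation along the terminal segment outside the anchor range (flagged).

Two usage modes are supported: *external* calibration (one calibration file
from a dedicated standards run, shared by all samples) and *internal*
calibration (standards spiked into each sample and located per run with
:func:`find_calibration_peaks`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, DataError, FormatError
from .msdata import RawRun, extract_eic
from .peakfinder import PeakParams, detect_peaks


@dataclass(frozen=True)
class RiAnchor:
    """One calibration anchor: a standard's retention time and index."""

    rt: float
    ri: float

    def __post_init__(self):
        if self.ri <= 0:
            raise DataError(f"retention index must be > 0, got {self.ri}")


class RiCalibration:
    """Ordered RI anchors with strictly increasing rt and ri."""

    def __init__(self, anchors: Sequence[RiAnchor]):
        anchors = sorted(anchors, key=lambda a: a.rt)
        if len(anchors) < 2:
            raise CalibrationError("calibration needs at least 2 anchors")
        rts = np.array([a.rt for a in anchors], dtype=float)
        ris = np.array([a.ri for a in anchors], dtype=float)
        if np.any(np.diff(rts) <= 0):
            raise CalibrationError("anchor retention times must be strictly increasing")
        if np.any(np.diff(ris) <= 0):
            raise CalibrationError(
                "anchor retention indices must be strictly increasing with rt")
        self.anchors = list(anchors)
        self._rts = rts
        self._ris = ris

    @property
    def rt_range(self) -> tuple[float, float]:
        return float(self._rts[0]), float(self._rts[-1])


def _piecewise(x, xs, ys):
    """np.interp with terminal-segment linear extrapolation."""
    x = np.asarray(x, dtype=float)
    y = np.interp(x, xs, ys)
    lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
    hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    y = np.where(x < xs[0], ys[0] + (x - xs[0]) * lo_slope, y)
    y = np.where(x > xs[-1], ys[-1] + (x - xs[-1]) * hi_slope, y)
    return y


def rt_to_ri(cal: RiCalibration, rt, with_flag: bool = False):
    """Convert retention time(s) in seconds to retention index.

    With ``with_flag=True`` also returns whether the value(s) required
    extrapolation beyond the anchor range.
    """
    ri = _piecewise(rt, cal._rts, cal._ris)
    scalar = np.ndim(rt) == 0
    flag = (np.asarray(rt, dtype=float) < cal._rts[0]) | \
           (np.asarray(rt, dtype=float) > cal._rts[-1])
    if scalar:
        ri = float(ri)
        flag = bool(flag)
    if with_flag:
        return ri, flag
    return ri


def ri_to_rt(cal: RiCalibration, ri, with_flag: bool = False):
    """Numeric inverse of :func:`rt_to_ri` (exact for piecewise-linear maps)."""
    rt = _piecewise(ri, cal._ris, cal._rts)
    scalar = np.ndim(ri) == 0
    flag = (np.asarray(ri, dtype=float) < cal._ris[0]) | \
           (np.asarray(ri, dtype=float) > cal._ris[-1])
    if scalar:
        rt = float(rt)
        flag = bool(flag)
    if with_flag:
        return rt, flag
    return rt


def find_calibration_peaks(run: RawRun,
                           standards: Sequence[tuple[int, tuple[float, float], float]],
                           params: PeakParams | None = None) -> RiCalibration:
    """Internal calibration: locate each spiked standard in its rt window.

    ``standards`` is a sequence of ``(target m/z, (rt_lo, rt_hi), ri)``.  The
    anchor rt is the apex of the largest detected peak on the target channel
    inside the window.  A window with no peak above the detection thresholds
    raises :class:`CalibrationError` naming the missing standard.
    """
    params = params or PeakParams()
    anchors = []
    for mz, (rt_lo, rt_hi), ri in standards:
        trace = extract_eic(run, mz)
        candidates = [p for p in detect_peaks(trace, params)
                      if rt_lo <= p.rt_apex <= rt_hi]
        if not candidates:
            raise CalibrationError(
                f"run {run.run_id}: no peak for RI standard ri={ri:g} "
                f"(m/z {mz}, window {rt_lo:g}-{rt_hi:g} s)")
        best = max(candidates, key=lambda p: p.area)
        anchors.append(RiAnchor(best.rt_apex, ri))
    return RiCalibration(anchors)


# ---------------------------------------------------------------------------
# calibration TSV (columns rt_s, ri)
# ---------------------------------------------------------------------------

def read_calibration(path) -> RiCalibration:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: unreadable calibration TSV ({exc})") from exc
    if list(df.columns) != ["rt_s", "ri"]:
        raise FormatError(f"{path}: expected columns ['rt_s', 'ri']")
    return RiCalibration([RiAnchor(float(r.rt_s), float(r.ri))
                          for r in df.itertuples()])


def write_calibration(cal: RiCalibration, path) -> None:
    pd.DataFrame({"rt_s": [a.rt for a in cal.anchors],
                  "ri": [a.ri for a in cal.anchors]}) \
        .to_csv(path, sep="\t", index=False, float_format="%.10g")
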