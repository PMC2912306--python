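"""MSRI library matching: RI binning, tolerance search and quantifier/qualifier
ion scoring.

The matcher works on RI-calibrated EIC peak lists.  Peaks whose area falls
below ``min_peak_area`` are dropped at import; the rest are grouped by apex
retention index into fixed 0.1 RI-unit bins ("preliminary spectra").  Each bin
is searched against every library entry whose RI lies within ``ri_tolerance``
of the bin midpoint; for each of the entry's quantifier ions a separate match
attempt is made:

1. the quantifier ion must be present in the bin, otherwise the attempt is
   aborted;
2. the quantifier peak's area and the library spectrum predict the expected
   intensity of every qualifier ion:
   ``E_q = A_quantifier * S(q) / S(quantifier)``;
3. because qualifier EICs can apex a fraction of a scan away from the
   quantifier, peaks within ``gather_window`` RI units of the quantifier apex
   are gathered from the full peak list to augment the bin;
4. a qualifier is *found* when its relative deviation
   ``|A_q - E_q| / E_q`` is within twice ``max_avg_deviation``;
5. the match passes when enough qualifiers are found (an absolute minimum and
   a minimum fraction of the expected qualifiers, both configurable) and the
   mean deviation over all qualifiers present is below
   ``max_avg_deviation``.  A passed match reports the quantifier peak area as
   the analyte's signal intensity.

Per analyte per run the *winner* is the passed attempt with the lowest mean
qualifier deviation (ties: larger quantifier area, then earlier bin), so that
"best quantifier ion" selection is resolved by the data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InputError, LibraryValidationError
from .msrilib import LibraryEntry, MsriLibrary
from .peakfinder import EicPeak

log = logging.getLogger(__name__)

#: Fixed preliminary-spectrum bin width in RI units.
BIN_WIDTH = 0.1

#: Library relative-intensity floor below which an ion is not used as a
#: qualifier (tiny ions are noise-dominated).
QUALIFIER_INTENSITY_FLOOR = 20.0

PASSED = "passed"
ABORTED_NO_QUANTIFIER = "aborted_no_quantifier"
FAILED_QUALIFIERS = "failed_qualifiers"
BELOW_MIN_AREA = "below_min_area"
NO_RI_MATCH = "no_ri_match"


@dataclass(frozen=True)
class MatchParams:
    """Matching criteria.

    ``min_peak_area`` is the import filter applied before binning; the
    default 25,000 is the low-sensitivity (LS) preset and 5,000 the
    high-sensitivity (HS) preset.
    """

    ri_tolerance: float = 2.0
    gather_window: float = 1.0
    min_peak_area: float = 25_000.0
    min_qualifier_fraction: float = 0.6
    max_avg_deviation: float = 0.35
    min_qualifiers_absolute: int = 2
    qualifier_intensity_floor: float = QUALIFIER_INTENSITY_FLOOR

    def __post_init__(self):
        if self.ri_tolerance <= 0 or self.gather_window <= 0:
            raise InputError("ri_tolerance and gather_window must be > 0")
        if not (0 < self.min_qualifier_fraction <= 1):
            raise InputError("min_qualifier_fraction must be in (0, 1]")
        if self.max_avg_deviation <= 0 or self.min_peak_area < 0:
            raise InputError("bad matching thresholds")

    @classmethod
    def preset(cls, name: str, **overrides) -> "MatchParams":
        """``LS`` (min_peak_area 25,000) or ``HS`` (5,000)."""
        areas = {"LS": 25_000.0, "HS": 5_000.0}
        if name.upper() not in areas:
            raise InputError(f"unknown preset {name!r}; expected LS or HS")
        overrides.setdefault("min_peak_area", areas[name.upper()])
        return cls(**overrides)


@dataclass
class RiBin:
    """Peaks whose apex RI falls inside one half-open 0.1-RI bin."""

    bin_index: int
    peaks: dict[int, EicPeak]

    @property
    def ri_lo(self) -> float:
        return self.bin_index * BIN_WIDTH

    @property
    def ri_hi(self) -> float:
        return (self.bin_index + 1) * BIN_WIDTH

    @property
    def ri_mid(self) -> float:
        return (self.bin_index + 0.5) * BIN_WIDTH


def ri_bin_index(ri: float) -> int:
    """floor(ri / 0.1) with a guard against float representation of x.1."""
    return int(math.floor(ri * 10 + 1e-9))


def bin_peaks(peaks: list[EicPeak], params: MatchParams) -> list[RiBin]:
    """Group area-filtered peaks into 0.1 RI-unit bins by apex RI.

    If two peaks of the same m/z land in one bin the larger-area peak wins
    and the conflict is logged.
    """
    bins: dict[int, dict[int, EicPeak]] = {}
    for p in peaks:
        if p.apex_ri is None:
            raise InputError(f"peak at rt {p.rt_apex:g} s has no retention index")
        if p.area < params.min_peak_area:
            continue
        idx = ri_bin_index(p.apex_ri)
        slot = bins.setdefault(idx, {})
        old = slot.get(p.mz)
        if old is None or p.area > old.area:
            if old is not None:
                log.info("bin %d: m/z %d conflict, keeping area %.4g over %.4g",
                         idx, p.mz, p.area, old.area)
            slot[p.mz] = p
        else:
            log.info("bin %d: m/z %d conflict, keeping area %.4g over %.4g",
                     idx, p.mz, old.area, p.area)
    return [RiBin(i, bins[i]) for i in sorted(bins)]


@dataclass
class MatchResult:
    entry_name: str
    quantifier_mz: int
    bin_index: int
    bin_ri: float
    status: str
    reported_intensity: float | None = None
    qualifiers_expected: int = 0
    qualifiers_found: int = 0
    avg_deviation: float | None = None
    winner: bool = False
    quantifier_peak: EicPeak | None = field(default=None, repr=False)

    @property
    def passed(self) -> bool:
        return self.status == PASSED


def _qualifier_ions(entry: LibraryEntry, quantifier_mz: int,
                    params: MatchParams) -> list[int]:
    return sorted(m for m, s in entry.spectrum.items()
                  if m != quantifier_mz and s >= params.qualifier_intensity_floor)


def match_bin(bin: RiBin, all_peaks: list[EicPeak], entry: LibraryEntry,
              quantifier_mz: int, params: MatchParams) -> MatchResult:
    """One match attempt: (bin, library entry, quantifier ion)."""
    if quantifier_mz not in entry.spectrum or entry.spectrum[quantifier_mz] <= 0:
        raise LibraryValidationError(
            f"entry {entry.name!r}: quantifier m/z {quantifier_mz} "
            "missing from spectrum")
    result = MatchResult(entry.name, quantifier_mz, bin.bin_index, bin.ri_mid,
                         status=NO_RI_MATCH)
    if entry.ri is None or abs(entry.ri - bin.ri_mid) > params.ri_tolerance:
        return result
    qpeak = bin.peaks.get(quantifier_mz)
    if qpeak is None:
        result.status = ABORTED_NO_QUANTIFIER
        return result
    if qpeak.area < params.min_peak_area:
        result.status = BELOW_MIN_AREA
        return result

    qualifiers = _qualifier_ions(entry, quantifier_mz, params)
    result.qualifiers_expected = len(qualifiers)
    result.quantifier_peak = qpeak

    # gather same-analyte ions that apex a hair away from the quantifier
    augmented = dict(bin.peaks)
    for p in all_peaks:
        if p.area < params.min_peak_area or p.apex_ri is None:
            continue
        if abs(p.apex_ri - qpeak.apex_ri) <= params.gather_window:
            old = augmented.get(p.mz)
            if old is None or (p.area > old.area and p.mz != quantifier_mz):
                augmented[p.mz] = p

    s_quant = entry.spectrum[quantifier_mz]
    deviations = []
    found = 0
    for q in qualifiers:
        peak = augmented.get(q)
        if peak is None:
            continue  # absent: counts against the found fraction only
        expected = qpeak.area * entry.spectrum[q] / s_quant
        dev = abs(peak.area - expected) / expected
        deviations.append(dev)
        if dev <= 2.0 * params.max_avg_deviation:
            found += 1
    result.qualifiers_found = found
    result.avg_deviation = float(np.mean(deviations)) if deviations else math.inf

    required = max(params.min_qualifiers_absolute,
                   math.ceil(params.min_qualifier_fraction * len(qualifiers)))
    if found >= required and result.avg_deviation <= params.max_avg_deviation:
        result.status = PASSED
        result.reported_intensity = qpeak.area
    else:
        result.status = FAILED_QUALIFIERS
    return result


class MatchReport:
    """All match attempts for one run plus the per-analyte winners."""

    def __init__(self, results: list[MatchResult], run_id: str = ""):
        self.results = results
        self.run_id = run_id
        self.winners: dict[str, MatchResult] = {}
        by_name: dict[str, list[MatchResult]] = {}
        for r in results:
            if r.passed:
                by_name.setdefault(r.entry_name, []).append(r)
        for name, cands in by_name.items():
            cands.sort(key=lambda r: (r.avg_deviation,
                                      -(r.reported_intensity or 0.0),
                                      r.bin_index))
            cands[0].winner = True
            self.winners[name] = cands[0]

    def __len__(self) -> int:
        return len(self.results)


def match_run(peaks: list[EicPeak], library: MsriLibrary,
              params: MatchParams | None = None, run_id: str = "") -> MatchReport:
    """Match one run's RI-calibrated peak list against a library.

    Every (bin, RI-eligible entry, quantifier ion) triple yields one
    :class:`MatchResult`; entries without an RI are skipped.
    """
    params = params or MatchParams()
    bins = bin_peaks(peaks, params)
    filtered = [p for p in peaks
                if p.area >= params.min_peak_area and p.apex_ri is not None]
    entries = [e for e in library if e.ri is not None]
    entries.sort(key=lambda e: e.ri)
    entry_ris = np.array([e.ri for e in entries], dtype=float)

    results: list[MatchResult] = []
    for b in bins:
        lo = np.searchsorted(entry_ris, b.ri_mid - params.ri_tolerance, "left")
        hi = np.searchsorted(entry_ris, b.ri_mid + params.ri_tolerance, "right")
        for e in entries[lo:hi]:
            for q in e.quantifier_mzs:
                results.append(match_bin(b, filtered, e, q, params))
    return MatchReport(results, run_id=run_id)


# ---------------------------------------------------------------------------
# report TSV
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["entry_name", "quantifier_mz", "bin_ri", "status",
                  "reported_intensity", "qualifiers_expected",
                  "qualifiers_found", "avg_deviation", "winner"]


def write_report(report: MatchReport, path) -> None:
    rows = [{
        "entry_name": r.entry_name,
        "quantifier_mz": r.quantifier_mz,
        "bin_ri": r.bin_ri,
        "status": r.status,
        "reported_intensity": "" if r.reported_intensity is None
        else f"{r.reported_intensity:.10g}",
        "qualifiers_expected": r.qualifiers_expected,
        "qualifiers_found": r.qualifiers_found,
        "avg_deviation": "" if r.avg_deviation is None or
        not math.isfinite(r.avg_deviation) else f"{r.avg_deviation:.10g}",
        "winner": int(r.winner),
    } for r in report.results]
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_report(path, run_id: str = "") -> MatchReport:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: unreadable match report ({exc})") from exc
    if list(df.columns) != REPORT_COLUMNS:
        raise FormatError(f"{path}: unexpected report columns")
    results = []
    for rec in df.to_dict("records"):
        results.append(MatchResult(
            entry_name=rec["entry_name"],
            quantifier_mz=int(rec["quantifier_mz"]),
            bin_index=ri_bin_index(float(rec["bin_ri"]) - BIN_WIDTH / 2),
            bin_ri=float(rec["bin_ri"]),
            status=rec["status"],
            reported_intensity=None if pd.isna(rec["reported_intensity"])
            else float(rec["reported_intensity"]),
            qualifiers_expected=int(rec["qualifiers_expected"]),
            qualifiers_found=int(rec["qualifiers_found"]),
            avg_deviation=None if pd.isna(rec["avg_deviation"])
            else float(rec["avg_deviation"])))
    report = MatchReport.__new__(MatchReport)
    report.results = results
    report.run_id = run_id or path.stem
    report.winners = {}
    for r, flag in zip(results, df["winner"].tolist()):
        r.winner = bool(flag)
        if r.winner:
            report.winners[r.entry_name] = r
    return report


# ---------------------------------------------------------------------------
# benchmark scoring against generator truth
# ---------------------------------------------------------------------------

def classify_calls(report: MatchReport, truth_present: set[str],
                   library: MsriLibrary) -> dict[str, int]:
    """Score one run's winners against ground truth.

    Vocabulary: a winner for an analyte truly present is a *true positive*
    unless its winning quantifier peak is claimed by another winner, in which
    case both are *ambiguous*; a winner for an absent analyte is a *false
    positive*; a present analyte without a winner is a *false negative*; an
    absent analyte without a winner is a *true negative*.
    """
    claims: dict[int, list[str]] = {}
    for name, r in report.winners.items():
        if r.quantifier_peak is not None:
            claims.setdefault(id(r.quantifier_peak), []).append(name)
    shared = {n for names in claims.values() if len(names) > 1 for n in names}

    counts = dict(true_positive=0, false_positive=0, false_negative=0,
                  true_negative=0, ambiguous=0)
    for name in library.names:
        present = name in truth_present
        won = name in report.winners
        if won and name in shared:
            counts["ambiguous"] += 1
        elif won and present:
            counts["true_positive"] += 1
        elif won and not present:
            counts["false_positive"] += 1
        elif not won and present:
            counts["false_negative"] += 1
        else:
            counts["true_negative"] += 1
    return counts
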