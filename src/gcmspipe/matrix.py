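"""Analyte × sample data-matrix construction, internal-standard normalization
and raw-data-assisted missing-value replacement.

The matrix cell for (analyte, run) is the winning match's reported quantifier
peak area; cells without a winner are missing.  Missing cells can be filled by
re-integrating the raw data: the mean integration start and end retention
indices of the winner peaks from runs where the analyte *was* matched are
mapped into each missing run's retention-time axis through that run's RI
calibration, and the raw (baseline-uncorrected) EIC signal on the winning
quantifier channel is summed between those bounds.  Imputation therefore
precedes internal-standard normalization.

Normalization divides every cell by the sample's internal-standard value; the
standard's own row is retained at 1.0.
"""

from __future__ import annotations

import logging
import statistics
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError
from .matcher import MatchReport
from .msdata import RawRun, extract_eic
from .msrilib import MsriLibrary
from .rical import RiCalibration, ri_to_rt, rt_to_ri

log = logging.getLogger(__name__)

RAW = "raw"
IS_NORMALIZED = "is_normalized"

MATCHED = "matched"
IMPUTED = "imputed_from_raw"
MISSING = "missing"


class DataMatrix:
    """Analyte × sample intensity table with provenance.

    ``values`` is a pandas DataFrame (rows = analytes, columns = run ids,
    NaN = missing); ``provenance`` is a same-shaped DataFrame of
    ``{"matched", "imputed_from_raw", "missing"}``.
    """

    def __init__(self, values: pd.DataFrame, provenance: pd.DataFrame,
                 normalization_state: str = RAW):
        if values.shape != provenance.shape:
            raise InputError("values and provenance shapes differ")
        if normalization_state not in (RAW, IS_NORMALIZED):
            raise InputError(f"bad normalization state {normalization_state!r}")
        self.values = values
        self.provenance = provenance
        self.normalization_state = normalization_state

    @property
    def analytes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def copy(self) -> "DataMatrix":
        return DataMatrix(self.values.copy(), self.provenance.copy(),
                          self.normalization_state)

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path, provenance_path=None) -> None:
        out = self.values.copy()
        out.index.name = "analyte"
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")
        if provenance_path is not None:
            prov = self.provenance.copy()
            prov.index.name = "analyte"
            prov.to_csv(provenance_path, sep="\t")

    @classmethod
    def read_tsv(cls, path, provenance_path=None,
                 normalization_state: str = RAW) -> "DataMatrix":
        values = pd.read_csv(path, sep="\t", index_col="analyte",
                             na_values=["NA"]).astype(float)
        values.index.name = None
        if provenance_path is not None:
            prov = pd.read_csv(provenance_path, sep="\t", index_col="analyte")
            prov.index.name = None
        else:
            prov = values.where(values.isna(), MATCHED).where(~values.isna(),
                                                              MISSING)
        return cls(values, prov, normalization_state)


def build_matrix(reports: Mapping[str, MatchReport] | list[MatchReport],
                 library: MsriLibrary) -> DataMatrix:
    """Assemble the matrix of winning reported intensities, one column per run."""
    if not isinstance(reports, Mapping):
        ids = [r.run_id for r in reports]
        if len(set(ids)) != len(ids):
            raise InputError(f"duplicate run ids in reports: {ids}")
        reports = {r.run_id: r for r in reports}
    analytes = library.names
    samples = list(reports)
    values = pd.DataFrame(np.nan, index=analytes, columns=samples)
    prov = pd.DataFrame(MISSING, index=analytes, columns=samples)
    for run_id, report in reports.items():
        for name, res in report.winners.items():
            if name in values.index:
                values.loc[name, run_id] = res.reported_intensity
                prov.loc[name, run_id] = MATCHED
    return DataMatrix(values, prov, RAW)


def normalize_is(matrix: DataMatrix, standard_name: str) -> DataMatrix:
    """Divide every sample's cells by its internal-standard value.

    Idempotent; the standard row is retained with value 1.0.
    """
    if standard_name not in matrix.values.index:
        raise InputError(f"internal standard {standard_name!r} not in matrix")
    std = matrix.values.loc[standard_name]
    bad = [s for s in matrix.samples if pd.isna(std[s]) or std[s] <= 0]
    if bad:
        raise InputError(
            f"internal standard {standard_name!r} missing or non-positive "
            f"in runs: {bad}")
    values = matrix.values.div(std, axis=1)
    return DataMatrix(values, matrix.provenance.copy(), IS_NORMALIZED)


def apply_sample_factors(matrix: DataMatrix,
                         factors: Mapping[str, float]) -> DataMatrix:
    """Optional per-sample scalar normalization (mass/volume/amount)."""
    missing = [s for s in matrix.samples if s not in factors]
    if missing:
        raise InputError(f"no normalization factor for runs: {missing}")
    fac = pd.Series({s: float(factors[s]) for s in matrix.samples})
    if (fac <= 0).any():
        raise InputError("sample factors must be positive")
    return DataMatrix(matrix.values.div(fac, axis=1), matrix.provenance.copy(),
                      matrix.normalization_state)


def integration_consensus(reports: Mapping[str, MatchReport],
                          calibrations: Mapping[str, RiCalibration],
                          analyte: str) -> tuple[float, float, int] | None:
    """Consensus integration window for one analyte across matched runs.

    Returns (mean start RI, mean end RI, modal winning quantifier m/z) over
    the runs where the analyte was matched, or None if it never was.  The
    modal quantifier breaks ties toward the smaller m/z.
    """
    start_ris, end_ris, quant_mzs = [], [], []
    for run_id, report in reports.items():
        res = report.winners.get(analyte)
        if res is None or res.quantifier_peak is None:
            continue
        cal = calibrations[run_id]
        peak = res.quantifier_peak
        start_ris.append(rt_to_ri(cal, peak.rt_start))
        end_ris.append(rt_to_ri(cal, peak.rt_end))
        quant_mzs.append(res.quantifier_mz)
    if not start_ris:
        return None
    return (float(np.mean(start_ris)), float(np.mean(end_ris)),
            statistics.mode(sorted(quant_mzs)))


def impute_from_raw(matrix: DataMatrix,
                    runs: Mapping[str, RawRun],
                    reports: Mapping[str, MatchReport],
                    calibrations: Mapping[str, RiCalibration]) -> DataMatrix:
    """Replace missing cells with raw EIC sums over the mean integration window.

    For each missing (analyte, run): average the winner peaks' integration
    start/end RIs over the runs where the analyte was matched, map both back
    to retention times in the missing run via its calibration, and sum the
    raw quantifier-channel EIC between them (trapezoidal, uncorrected).
    Analytes never matched in any run are left missing with a warning.
    """
    if matrix.normalization_state != RAW:
        raise InputError("imputation must precede normalization")
    out = matrix.copy()
    for analyte in out.analytes:
        row = out.values.loc[analyte]
        missing_runs = [s for s in out.samples if pd.isna(row[s])]
        if not missing_runs:
            continue
        consensus = integration_consensus(reports, calibrations, analyte)
        if consensus is None:
            log.warning("analyte %r matched in no run; cells left missing",
                        analyte)
            continue
        mean_start, mean_end, quant_mz = consensus
        for run_id in missing_runs:
            if run_id not in runs:
                continue
            cal = calibrations[run_id]
            rt_lo = ri_to_rt(cal, mean_start)
            rt_hi = ri_to_rt(cal, mean_end)
            eic = extract_eic(runs[run_id], quant_mz)
            lo = int(np.searchsorted(eic.rts, rt_lo, side="left"))
            hi = int(np.searchsorted(eic.rts, rt_hi, side="right"))
            if hi - lo < 2:
                continue
            value = float(np.trapezoid(eic.intensities[lo:hi], eic.rts[lo:hi]))
            out.values.loc[analyte, run_id] = value
            out.provenance.loc[analyte, run_id] = IMPUTED
    return out
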