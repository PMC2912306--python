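"""Pipeline orchestration: detect → calibrate → match → matrix →
normalize/impute, in memory or against an on-disk artifact set.

:func:`process_runs` is the library entry point used by the CLI, the examples
and the validation scripts; :func:`run_pipeline` wraps it with file loading,
artifact writing and a manifest so that re-running an identical configuration
reproduces identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .errors import PipelineError
from .matcher import MatchParams, MatchReport, match_run, write_report
from .matrix import DataMatrix, build_matrix, impute_from_raw, normalize_is
from .msdata import RawRun, load_run
from .msrilib import MsriLibrary, parse_library
from .peakfinder import EicPeak, PeakParams, detect_peaks_run, write_peaklist
from .rical import RiCalibration, read_calibration, rt_to_ri

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    peaklists: dict[str, list[EicPeak]]
    reports: dict[str, MatchReport]
    raw_matrix: DataMatrix
    matrix: DataMatrix                 # imputed and/or normalized per config
    calibrations: dict[str, RiCalibration]


def assign_retention_indices(peaks: Sequence[EicPeak], cal: RiCalibration,
                             allow_extrapolated: bool = True) -> list[EicPeak]:
    """Fill ``apex_ri`` on every peak; optionally drop extrapolated ones."""
    out = []
    for p in peaks:
        ri, flagged = rt_to_ri(cal, p.rt_apex, with_flag=True)
        if flagged and not allow_extrapolated:
            continue
        p.apex_ri = ri
        out.append(p)
    return out


def process_runs(runs: Sequence[RawRun],
                 library: MsriLibrary,
                 calibrations: RiCalibration | Mapping[str, RiCalibration],
                 peak_params: PeakParams | None = None,
                 match_params: MatchParams | None = None,
                 internal_standard: str | None = None,
                 impute: bool = True,
                 normalize: bool = True,
                 allow_extrapolated_ri: bool = True) -> PipelineResult:
    """Run detection, RI assignment, matching and matrix construction.

    ``calibrations`` is either one external calibration shared by all runs or
    a per-run mapping (internal calibration).  Missing values are imputed
    from raw data before normalization when ``impute`` is set; the matrix is
    normalized to ``internal_standard`` when ``normalize`` is set.
    """
    peak_params = peak_params or PeakParams()
    match_params = match_params or MatchParams()
    if isinstance(calibrations, RiCalibration):
        cal_map = {r.run_id: calibrations for r in runs}
    else:
        cal_map = dict(calibrations)

    peaklists: dict[str, list[EicPeak]] = {}
    reports: dict[str, MatchReport] = {}
    for run in runs:
        t0 = time.perf_counter()
        peaks = detect_peaks_run(run, peak_params)
        peaks = assign_retention_indices(peaks, cal_map[run.run_id],
                                         allow_extrapolated_ri)
        peaklists[run.run_id] = peaks
        reports[run.run_id] = match_run(peaks, library, match_params,
                                        run_id=run.run_id)
        log.info("run %s: %d peaks, %d winners (%.2f s)", run.run_id,
                 len(peaks), len(reports[run.run_id].winners),
                 time.perf_counter() - t0)

    raw_matrix = build_matrix(reports, library)
    matrix = raw_matrix
    if impute:
        matrix = impute_from_raw(matrix, {r.run_id: r for r in runs},
                                 reports, cal_map)
    if normalize and internal_standard is not None:
        matrix = normalize_is(matrix, internal_standard)
    return PipelineResult(peaklists, reports, raw_matrix, matrix, cal_map)


# ---------------------------------------------------------------------------
# file-based configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """On-disk pipeline configuration.

    ``ri_mode`` is ``external`` (one shared calibration file) — internal
    calibration requires per-run standards and is driven from the API.
    """

    input_paths: list[str]
    library_path: str
    calibration_path: str
    output_dir: str
    input_format: str | None = None
    internal_standard: str | None = None
    preset: str = "LS"
    peak_params: PeakParams = field(default_factory=PeakParams)
    match_params: MatchParams | None = None
    impute: bool = True
    normalize: bool = True
    seed: int = 0

    def validate(self) -> None:
        for p in [self.library_path, self.calibration_path, *self.input_paths]:
            if not Path(p).exists():
                raise PipelineError("validate", f"missing input file: {p}")

    def resolved_match_params(self) -> MatchParams:
        return self.match_params or MatchParams.preset(self.preset)


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    text = json.dumps(dataclasses.asdict(config), sort_keys=True,
                      default=default)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline from files and write all artifacts.

    Outputs per run a peak list and match report TSV, plus raw and final
    matrices and a ``manifest.json`` recording inputs, parameter hash and
    package version.  Identical configurations produce identical artifacts.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        runs = [load_run(p, config.input_format) for p in config.input_paths]
        library = parse_library(config.library_path)
        cal = read_calibration(config.calibration_path)
        stage = "process"
        result = process_runs(runs, library, cal,
                              peak_params=config.peak_params,
                              match_params=config.resolved_match_params(),
                              internal_standard=config.internal_standard,
                              impute=config.impute,
                              normalize=config.normalize)
        stage = "write"
        for run_id, peaks in result.peaklists.items():
            write_peaklist(peaks, out / f"{run_id}.peaks.tsv")
        for run_id, report in result.reports.items():
            write_report(report, out / f"{run_id}.matches.tsv")
        result.raw_matrix.to_tsv(out / "matrix_raw.tsv")
        result.matrix.to_tsv(out / "matrix.tsv",
                             provenance_path=out / "matrix_provenance.tsv")
        manifest = {
            "inputs": [str(p) for p in config.input_paths],
            "library": config.library_path,
            "calibration": config.calibration_path,
            "parameter_hash": _config_hash(config),
            "version": __version__,
            "n_runs": len(runs),
            "n_analytes": len(library),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    return result
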