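"""Data-matrix construction, normalization and raw-data imputation."""

import numpy as np
import pandas as pd
import pytest

from gcmspipe.errors import InputError
from gcmspipe.matcher import MatchReport, MatchResult, PASSED
from gcmspipe.matrix import (IMPUTED, MATCHED, MISSING, DataMatrix,
                             build_matrix, impute_from_raw, normalize_is)
from gcmspipe.msrilib import LibraryEntry, MsriLibrary
from gcmspipe.peakfinder import EicPeak


def passed_result(name, intensity, quantifier=73, winner=True):
    peak = EicPeak(quantifier, 10.0, 12.0, 14.0, intensity / 4.0, intensity,
                   10.0, apex_ri=1200.0)
    return MatchResult(name, quantifier, 12000, 1200.05, PASSED,
                       reported_intensity=intensity, qualifiers_expected=3,
                       qualifiers_found=3, avg_deviation=0.0, winner=winner,
                       quantifier_peak=peak)


def report_for(run_id, values: dict[str, float]):
    results = [passed_result(name, v) for name, v in values.items()]
    return MatchReport(results, run_id=run_id)


@pytest.fixture
def library():
    return MsriLibrary([
        LibraryEntry("A", 1200.0, {73: 999.0, 147: 300.0}, [73]),
        LibraryEntry("B", 1300.0, {205: 999.0, 73: 400.0}, [205]),
    ])


class TestBuild:
    def test_dense_matrix(self, library):
        reports = [report_for(f"r{i}", {"A": 1e5 * (i + 1), "B": 2e5})
                   for i in range(3)]
        m = build_matrix(reports, library)
        assert m.analytes == ["A", "B"]
        assert m.samples == ["r0", "r1", "r2"]
        assert not m.missing_mask.any().any()
        assert (m.provenance == MATCHED).all().all()

    def test_cells_equal_winner_rows(self, library):
        reports = [report_for("r0", {"A": 123456.0, "B": 777.0})]
        m = build_matrix(reports, library)
        assert m.values.loc["A", "r0"] == 123456.0
        assert m.values.loc["B", "r0"] == 777.0

    def test_unmatched_cell_flagged_missing(self, library):
        reports = [report_for("r0", {"A": 1e5, "B": 1e5}),
                   report_for("r1", {"A": 1e5}),
                   report_for("r2", {"A": 1e5, "B": 1e5})]
        m = build_matrix(reports, library)
        assert m.missing_mask.loc["B", "r1"]
        assert m.provenance.loc["B", "r1"] == MISSING

    def test_duplicate_run_ids_rejected(self, library):
        reports = [report_for("r0", {"A": 1.0}), report_for("r0", {"A": 2.0})]
        with pytest.raises(InputError):
            build_matrix(reports, library)


class TestNormalize:
    def build(self, library):
        reports = [report_for("r0", {"A": 2e6, "B": 1e6}),
                   report_for("r1", {"A": 3e6, "B": 2e6})]
        return build_matrix(reports, library)

    def test_hand_division(self, library):
        m = normalize_is(self.build(library), "B")
        assert m.values.loc["A", "r0"] == pytest.approx(2.0)
        assert m.values.loc["A", "r1"] == pytest.approx(1.5)

    def test_standard_row_becomes_one(self, library):
        m = normalize_is(self.build(library), "B")
        assert np.allclose(m.values.loc["B"], 1.0, atol=1e-9)

    def test_idempotence(self, library):
        once = normalize_is(self.build(library), "B")
        twice = normalize_is(once, "B")
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_missing_standard_names_runs(self, library):
        reports = [report_for("r0", {"A": 2e6, "B": 1e6}),
                   report_for("bad_run", {"A": 3e6})]
        m = build_matrix(reports, library)
        with pytest.raises(InputError, match="bad_run"):
            normalize_is(m, "B")


class TestImputation:
    def strip_analyte(self, reports, analyte, run_ids):
        """Rebuild reports with one analyte's results removed from some runs."""
        out = {}
        for run_id, report in reports.items():
            if run_id in run_ids:
                kept = [r for r in report.results if r.entry_name != analyte]
                out[run_id] = MatchReport(kept, run_id=run_id)
            else:
                out[run_id] = report
        return out

    def pick_analyte(self, pipeline, experiment):
        """The analyte matched in the most runs (skip internal standard),
        plus the ids of the runs where it was matched."""
        from gcmspipe.simgen import INTERNAL_STANDARD

        best, best_runs = None, []
        for name in experiment.library.names:
            if name == INTERNAL_STANDARD:
                continue
            matched = [rid for rid, r in pipeline.reports.items()
                       if name in r.winners]
            if len(matched) > len(best_runs):
                best, best_runs = name, matched
        assert best is not None and len(best_runs) >= 4
        return best, best_runs

    def test_deletion_restoration_within_five_percent(self, small_experiment,
                                                      small_pipeline):
        from gcmspipe.matrix import integration_consensus

        analyte, matched_runs = self.pick_analyte(small_pipeline,
                                                  small_experiment)
        victims = matched_runs[:3]
        reports = self.strip_analyte(small_pipeline.reports, analyte, victims)
        runs = {r.run_id: r for r in small_experiment.runs}
        m = build_matrix(reports, small_experiment.library)
        assert m.missing_mask.loc[analyte, victims].all()
        imputed = impute_from_raw(m, runs, reports,
                                  small_pipeline.calibrations)
        # like-for-like reference: what matching reported on the same
        # quantifier channel the imputation re-integrates
        _, _, quant = integration_consensus(reports,
                                            small_pipeline.calibrations,
                                            analyte)
        compared = 0
        for run_id in victims:
            refs = [r.reported_intensity
                    for r in small_pipeline.reports[run_id].results
                    if r.entry_name == analyte and r.passed
                    and r.quantifier_mz == quant]
            value = imputed.values.loc[analyte, run_id]
            assert imputed.provenance.loc[analyte, run_id] == IMPUTED
            if refs:
                assert value == pytest.approx(max(refs), rel=0.05)
                compared += 1
        assert compared >= 2

    def test_never_matched_analyte_stays_missing(self, small_experiment,
                                                 small_pipeline):
        analyte, _ = self.pick_analyte(small_pipeline, small_experiment)
        all_runs = list(small_pipeline.reports)
        reports = self.strip_analyte(small_pipeline.reports, analyte, all_runs)
        runs = {r.run_id: r for r in small_experiment.runs}
        m = build_matrix(reports, small_experiment.library)
        imputed = impute_from_raw(m, runs, reports,
                                  small_pipeline.calibrations)
        assert imputed.missing_mask.loc[analyte].all()

    def test_imputation_preserves_matched_cells(self, small_experiment,
                                                small_pipeline):
        analyte, matched_runs = self.pick_analyte(small_pipeline,
                                                  small_experiment)
        victims = matched_runs[:2]
        reports = self.strip_analyte(small_pipeline.reports, analyte, victims)
        runs = {r.run_id: r for r in small_experiment.runs}
        m = build_matrix(reports, small_experiment.library)
        before = m.values.copy()
        imputed = impute_from_raw(m, runs, reports,
                                  small_pipeline.calibrations)
        mask = before.notna()
        pd.testing.assert_frame_equal(imputed.values[mask], before[mask])

    def test_absent_analyte_imputes_near_baseline(self, small_experiment,
                                                  small_pipeline):
        """Re-integrating a run where the analyte signal is genuinely tiny
        yields roughly the baseline integral, far below a real peak."""
        analyte, _ = self.pick_analyte(small_pipeline, small_experiment)
        runs = {r.run_id: r for r in small_experiment.runs}
        # fabricate a 'blank' run: clone a run and zero the analyte channels
        import copy

        from gcmspipe.simgen import INTERNAL_STANDARD

        donor_id = small_experiment.sample_ids[0]
        blank = copy.deepcopy(runs[donor_id])
        blank.run_id = "blank"
        a = small_experiment.panel.get(analyte)
        lo = np.searchsorted(blank.rts, a.rt_true - 8 * a.peak_sigma)
        hi = np.searchsorted(blank.rts, a.rt_true + 8 * a.peak_sigma)
        for mz in a.spectrum:
            j = blank._mz_index.get(int(mz))
            if j is not None:
                blank.matrix[lo:hi, j] = 30.0  # baseline only
        reports = dict(small_pipeline.reports)
        reports["blank"] = MatchReport([], run_id="blank")
        runs["blank"] = blank
        cals = dict(small_pipeline.calibrations)
        cals["blank"] = small_experiment.calibration
        m = build_matrix(reports, small_experiment.library)
        imputed = impute_from_raw(m, runs, reports, cals)
        value = imputed.values.loc[analyte, "blank"]
        typical = small_pipeline.raw_matrix.values.loc[analyte].min()
        assert value < 0.05 * typical

    def test_imputation_requires_unnormalized_matrix(self, library):
        reports = [report_for("r0", {"A": 2e6, "B": 1e6}),
                   report_for("r1", {"A": 3e6, "B": 2e6})]
        m = normalize_is(build_matrix(reports, library), "B")
        with pytest.raises(InputError):
            impute_from_raw(m, {}, {}, {})


def test_tsv_round_trip_with_missing(tmp_path, library):
    reports = [report_for("r0", {"A": 1e5, "B": 1e5}),
               report_for("r1", {"A": 1e5})]
    m = build_matrix(reports, library)
    vpath, ppath = tmp_path / "m.tsv", tmp_path / "prov.tsv"
    m.to_tsv(vpath, provenance_path=ppath)
    assert "NA" in vpath.read_text()
    back = DataMatrix.read_tsv(vpath, ppath)
    pd.testing.assert_frame_equal(back.values, m.values)
    pd.testing.assert_frame_equal(back.provenance, m.provenance)
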