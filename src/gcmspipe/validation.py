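"""Quantitative benchmark re-creations on synthetic ground-truthed data.

These helpers run the full pipeline on the simulated combinatorial mixing
experiment and measure how faithfully known analyte concentrations are
recovered as reported signal intensities:

* per-analyte coefficient of determination (R²) between known concentration
  and internal-standard-normalized reported intensity;
* correlation clustering of the resulting data matrix, which should resolve
  the three sub-mixtures of the design.

The default processing parameters below are the benchmark's study conditions
for the synthetic instrument model (baseline ~30 counts, additive detector
noise sd 10, 5 % multiplicative CV): peak detection thresholds sit well below
the smallest quantifier peaks of the dilution series, and matching uses the
default low-sensitivity preset (minimum peak area 25,000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .matcher import MatchParams
from .matrix import DataMatrix
from .peakfinder import PeakParams
from .pipeline import PipelineResult, process_runs
from .simgen import (INTERNAL_STANDARD, MixingExperiment, NoiseParams,
                     generate_mixing_experiment, make_panel)
from .stats import ClusterResult, correlation_cluster

#: Detection thresholds used for the synthetic benchmark chromatograms.
BENCHMARK_PEAK_PARAMS = PeakParams(min_slope=100.0, min_height=1000.0,
                                   min_width=1.0, min_area=1000.0,
                                   min_purity=2.0)


def concentration_signal_r2(matrix: DataMatrix, design: pd.DataFrame,
                            exclude: tuple[str, ...] = (INTERNAL_STANDARD,)
                            ) -> pd.Series:
    """Per-analyte R² between known concentration and reported intensity.

    Analytes with fewer than 3 reported values are scored 0 (no usable
    standard curve).  ``design`` is the samples × analytes truth table.
    """
    r2 = {}
    for analyte in matrix.analytes:
        if analyte in exclude:
            continue
        y = matrix.values.loc[analyte]
        x = design[analyte].reindex(y.index)
        ok = y.notna() & x.notna()
        if ok.sum() < 3 or np.ptp(x[ok].to_numpy()) == 0:
            r2[analyte] = 0.0
            continue
        fit = linregress(x[ok].to_numpy(float), y[ok].to_numpy(float))
        r2[analyte] = float(fit.rvalue ** 2)
    return pd.Series(r2, name="r2")


@dataclass
class MixingBenchmark:
    experiment: MixingExperiment
    pipeline: PipelineResult
    r2: pd.Series
    clusters: ClusterResult

    @property
    def mean_r2(self) -> float:
        return float(self.r2.mean())

    def fraction_above(self, threshold: float = 0.8) -> float:
        return float((self.r2 > threshold).mean())

    def percent_above(self, threshold: float = 0.8) -> float:
        return self.fraction_above(threshold) * 100.0


def run_mixing_benchmark(seed: int = 0,
                         noise: NoiseParams | None = None,
                         peak_params: PeakParams | None = None,
                         match_params: MatchParams | None = None
                         ) -> MixingBenchmark:
    """Simulate the 40-run mixing experiment and process it end to end.

    Returns the experiment, the pipeline result (imputed, IS-normalized
    matrix), the per-analyte concentration:signal R² series and the analyte
    correlation clustering (internal standard excluded).
    """
    rng = np.random.default_rng(seed)
    panel = make_panel(seed=int(rng.integers(2 ** 31)))
    experiment = generate_mixing_experiment(
        panel, seed=int(rng.integers(2 ** 31)), noise=noise or NoiseParams())
    result = process_runs(experiment.runs, experiment.library,
                          experiment.calibration,
                          peak_params=peak_params or BENCHMARK_PEAK_PARAMS,
                          match_params=match_params,
                          internal_standard=INTERNAL_STANDARD)
    r2 = concentration_signal_r2(result.matrix, experiment.design)
    clusters = correlation_cluster(result.matrix, exclude=["*(IS)*"])
    return MixingBenchmark(experiment, result, r2, clusters)
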