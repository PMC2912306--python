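"""Shared fixtures: small synthetic panels, runs and traces."""

from __future__ import annotations

import numpy as np
import pytest

from gcmspipe.msdata import RawRun, Trace
from gcmspipe.msrilib import LibraryEntry, MsriLibrary
from gcmspipe.rical import rt_to_ri
from gcmspipe.simgen import (NoiseParams, SyntheticAnalyte, SyntheticPanel,
                             default_alkane_calibration,
                             generate_mixing_experiment, make_panel)


def gaussian_trace(center: float, height: float, sigma: float,
                   baseline: float = 0.0, t_lo: float = 0.0,
                   t_hi: float = 120.0, dt: float = 0.25,
                   channel: int = 73) -> Trace:
    t = np.arange(t_lo, t_hi, dt)
    y = baseline + height * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return Trace(channel, t, y)


@pytest.fixture
def permissive_params():
    from gcmspipe.peakfinder import PeakParams

    return PeakParams(min_slope=5.0, min_height=1.0, min_width=0.5,
                      min_area=10.0, min_purity=0.0)


def build_panel(specs, rt_range=None, rf=5e5, sigma=2.0):
    """Hand-built panel from (name, rt, spectrum dict) tuples."""
    rts = [rt for _, rt, _ in specs]
    rt_range = rt_range or (min(rts) - 10, max(rts) + 10)
    cal = default_alkane_calibration(rt_range)
    analytes, entries, submix = [], [], {}
    for i, (name, rt, spec) in enumerate(specs):
        quantifiers = sorted(spec, key=lambda m: (-spec[m], m))[:2]
        analytes.append(SyntheticAnalyte(name, rt, sigma, dict(spec), rf,
                                         quantifiers))
        entries.append(LibraryEntry(name, rt_to_ri(cal, rt), dict(spec),
                                    list(quantifiers)))
        submix[name] = i % 3 + 1
    return SyntheticPanel(analytes, MsriLibrary(entries), cal, submix)


@pytest.fixture(scope="session")
def small_experiment():
    """A 9-analyte, 2-repetition mixing experiment with mild noise.

    Small enough to process in a few seconds; used by matcher/matrix/
    pipeline tests that need an end-to-end dataset.
    """
    panel = make_panel(n_analytes=9, rt_range=(300.0, 420.0), seed=5)
    return generate_mixing_experiment(
        panel, seed=5, noise=NoiseParams(baseline=30, cv=0.02, additive_sd=5),
        repetitions=2)


@pytest.fixture(scope="session")
def small_pipeline(small_experiment):
    from gcmspipe.pipeline import process_runs
    from gcmspipe.simgen import INTERNAL_STANDARD
    from gcmspipe.validation import BENCHMARK_PEAK_PARAMS

    return process_runs(small_experiment.runs, small_experiment.library,
                        small_experiment.calibration,
                        peak_params=BENCHMARK_PEAK_PARAMS,
                        internal_standard=INTERNAL_STANDARD)
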