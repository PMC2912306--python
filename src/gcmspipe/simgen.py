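"""Ground-truthed synthetic GC/MS data.

Emulates unit-resolution GC-quadrupole chromatograms of derivatized metabolite
standard mixtures: each synthetic analyte has a true retention time, a
Gaussian (optionally exponentially-modified Gaussian) peak shape, a random
unit-mass spectrum scaled to base peak 999, and a linear detector response
factor.  An always-present internal standard (a ribitol surrogate) is spiked
at fixed concentration.

The combinatorial mixing experiment generator reproduces the validation
design for quantitative benchmarking: the panel is partitioned into three
sub-mixtures of chromatographically non-co-eluting standards (co-elution is
allowed, and likely, *between* sub-mixtures), an 8-point two-fold dilution
series is prepared from each sub-mixture, the level order of each series is
independently randomised, and the randomised mixing is repeated 5 times to
give 5 sets of 8 complex samples (40 runs), every one containing the full
set of 85 standards plus the internal standard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, InputError
from .msdata import RawRun
from .msrilib import BASE_PEAK, LibraryEntry, MsriLibrary
from .rical import RiAnchor, RiCalibration, rt_to_ri

INTERNAL_STANDARD = "Ribitol (IS)"

#: Default panel size: the number of metabolite standards in the mixing design.
DEFAULT_N_ANALYTES = 85

#: Minimum rt separation, in multiples of sigma, between same-submix analytes.
MIN_SUBMIX_SEPARATION_SIGMA = 4.0

_MIN_GAP_S = 3.0          # minimum rt gap between any two consecutive analytes
_SIGMA_RANGE = (1.2, 2.0)  # peak sigma, seconds
_MZ_RANGE = (70, 600)      # nominal fragment masses of TMS/methoxime spectra
_N_IONS = (5, 20)
_RF_RANGE = (4e5, 9e5)     # response factor: area counts per concentration unit


@dataclass
class SyntheticAnalyte:
    name: str
    rt_true: float
    peak_sigma: float
    spectrum: dict[int, float]            # base peak = 999
    response_factor: float
    quantifier_mzs: list[int]

    def __post_init__(self):
        if not self.spectrum:
            raise InputError(f"{self.name}: empty spectrum")
        if self.response_factor <= 0:
            raise InputError(f"{self.name}: response factor must be > 0")


@dataclass
class NoiseParams:
    """Per-point noise model: baseline offset, multiplicative CV on the
    analyte signal, additive Gaussian detector noise."""

    baseline: float = 30.0
    cv: float = 0.05
    additive_sd: float = 10.0


@dataclass
class SyntheticPanel:
    """A panel of analytes plus its paired library and RI calibration."""

    analytes: list[SyntheticAnalyte]
    library: MsriLibrary
    calibration: RiCalibration
    submix: dict[str, int | None]         # analyte → 1..3, IS → None

    @property
    def internal_standard(self) -> SyntheticAnalyte:
        for a in self.analytes:
            if self.submix[a.name] is None:
                return a
        raise KeyError("no internal standard in panel")

    def get(self, name: str) -> SyntheticAnalyte:
        for a in self.analytes:
            if a.name == name:
                return a
        raise KeyError(name)


def default_alkane_calibration(rt_range: tuple[float, float]) -> RiCalibration:
    """Synthetic n-alkane ladder: one anchor every 60 s, 100 RI units apart,
    extended one rung beyond each end of the analyte rt range."""
    lo, hi = rt_range
    start = lo - 60.0
    n = int(math.ceil((hi + 60.0 - start) / 60.0)) + 1
    return RiCalibration([RiAnchor(start + 60.0 * k, 800.0 + 100.0 * k)
                          for k in range(n)])


def make_panel(n_analytes: int = DEFAULT_N_ANALYTES,
               rt_range: tuple[float, float] = (300.0, 960.0),
               seed: int = 0,
               n_submixes: int = 3) -> SyntheticPanel:
    """Build a reproducible analyte panel with its MSRI library.

    Analytes are laid down along the rt axis with random gaps of at least
    ``_MIN_GAP_S`` seconds and assigned to sub-mixtures round-robin, which
    guarantees >4 sigma separation within a sub-mixture while allowing close
    neighbours (and hence co-elution) across sub-mixtures.  Library RIs come
    from the panel's fixed synthetic alkane calibration.
    """
    if n_analytes < 1:
        raise DesignError("n_analytes must be >= 1")
    rng = np.random.default_rng(seed)
    n_slots = n_analytes + 1               # + internal standard
    lo, hi = rt_range
    span = hi - lo
    budget = span - _MIN_GAP_S * n_slots
    if budget <= 0:
        raise DesignError(
            f"rt_range {rt_range} too small for {n_slots} analytes at "
            f"{_MIN_GAP_S} s minimum spacing")
    extras = rng.random(n_slots)
    extras *= budget / extras.sum()
    rts = lo + np.cumsum(_MIN_GAP_S + extras)

    cal = default_alkane_calibration(rt_range)
    is_slot = n_slots // 2                 # internal standard mid-run

    analytes: list[SyntheticAnalyte] = []
    submix: dict[str, int | None] = {}
    entries: list[LibraryEntry] = []
    mix_counter = 0
    for slot in range(n_slots):
        if slot == is_slot:
            name = INTERNAL_STANDARD
            mix: int | None = None
        else:
            name = f"Analyte_{mix_counter + 1:03d}"
            mix = (mix_counter % n_submixes) + 1
            mix_counter += 1
        n_ions = int(rng.integers(_N_IONS[0], _N_IONS[1] + 1))
        mzs = rng.choice(np.arange(_MZ_RANGE[0], _MZ_RANGE[1] + 1),
                         size=n_ions, replace=False)
        intens = rng.uniform(50.0, 950.0, size=n_ions)
        intens[0] = BASE_PEAK
        spectrum = {int(m): float(v) for m, v in zip(mzs, intens)}
        by_intensity = sorted(spectrum, key=lambda m: (-spectrum[m], m))
        quantifiers = by_intensity[:2]
        analyte = SyntheticAnalyte(
            name=name,
            rt_true=float(rts[slot]),
            peak_sigma=float(rng.uniform(*_SIGMA_RANGE)),
            spectrum=spectrum,
            response_factor=float(rng.uniform(*_RF_RANGE)),
            quantifier_mzs=quantifiers)
        analytes.append(analyte)
        submix[name] = mix
        entries.append(LibraryEntry(
            name=name,
            ri=rt_to_ri(cal, analyte.rt_true),
            spectrum=dict(spectrum),
            quantifier_mzs=list(quantifiers),
            annotations={"class": "internal standard" if mix is None
                         else f"submix {mix}"}))
    panel = SyntheticPanel(analytes, MsriLibrary(entries, "synthetic panel"),
                           cal, submix)
    _check_spacing(panel, n_submixes)
    return panel


def _check_spacing(panel: SyntheticPanel, n_submixes: int) -> None:
    by_mix: dict[int, list[SyntheticAnalyte]] = {}
    for a in panel.analytes:
        mix = panel.submix[a.name]
        if mix is not None:
            by_mix.setdefault(mix, []).append(a)
    for mix, members in by_mix.items():
        members.sort(key=lambda a: a.rt_true)
        for a, b in zip(members, members[1:]):
            sep = b.rt_true - a.rt_true
            limit = MIN_SUBMIX_SEPARATION_SIGMA * max(a.peak_sigma, b.peak_sigma)
            if sep <= limit:
                raise DesignError(
                    f"submix {mix}: {a.name} and {b.name} co-elute "
                    f"({sep:.2f} s apart, need > {limit:.2f} s)")


def simulate_run(panel: SyntheticPanel,
                 composition: dict[str, float],
                 noise: NoiseParams | None = None,
                 seed: int = 0,
                 run_id: str = "synthetic_run",
                 scan_interval: float = 0.25,
                 rt_pad: float = 30.0,
                 peak_shape: str = "gaussian",
                 emg_tau: float = 1.0) -> tuple[RawRun, pd.DataFrame]:
    """Simulate one GC/MS run of the panel at the given composition.

    Channel intensity at scan time t is
    ``sum_a conc_a * rf_a * (S_a(m)/999) * shape(t; rt_a, sigma_a)``
    plus baseline and noise.  Returns the run and a ground-truth peak table
    with one row per injected (analyte, ion) peak: channel, rt bounds
    (apex ± 4 sigma), noiseless area, concentration and quantifier flag.
    """
    noise = noise or NoiseParams()
    unknown = set(composition) - {a.name for a in panel.analytes}
    if unknown:
        raise InputError(f"composition names not in panel: {sorted(unknown)}")
    for name, conc in composition.items():
        if conc < 0:
            raise InputError(f"negative concentration for {name}")
    if peak_shape not in ("gaussian", "emg"):
        raise InputError(f"unknown peak shape {peak_shape!r}")
    rng = np.random.default_rng(seed)

    active = [a for a in panel.analytes if composition.get(a.name, 0.0) > 0]
    if not active:
        raise InputError("composition contains no analyte at > 0 concentration")
    t_lo = min(a.rt_true for a in active) - rt_pad
    t_hi = max(a.rt_true for a in active) + rt_pad
    rts = np.arange(t_lo, t_hi + scan_interval / 2, scan_interval)
    channels = np.array(sorted({m for a in panel.analytes for m in a.spectrum}),
                        dtype=int)
    col = {int(m): j for j, m in enumerate(channels)}
    signal = np.zeros((rts.size, channels.size))

    truth_rows = []
    for a in active:
        conc = composition[a.name]
        amp = conc * a.response_factor          # total peak area on base channel
        lo_i = int(np.searchsorted(rts, a.rt_true - 8.5 * a.peak_sigma))
        hi_i = int(np.searchsorted(rts, a.rt_true + 8.5 * a.peak_sigma
                                   + (8 * emg_tau if peak_shape == "emg" else 0)))
        tt = rts[lo_i:hi_i]
        if peak_shape == "gaussian":
            shape = np.exp(-0.5 * ((tt - a.rt_true) / a.peak_sigma) ** 2) \
                / (a.peak_sigma * math.sqrt(2 * math.pi))
        else:  # exponentially-modified Gaussian, unit area
            from scipy.stats import exponnorm
            shape = exponnorm.pdf(tt, K=emg_tau / a.peak_sigma,
                                  loc=a.rt_true, scale=a.peak_sigma)
        for m, s in a.spectrum.items():
            frac = s / BASE_PEAK
            signal[lo_i:hi_i, col[m]] += amp * frac * shape
            truth_rows.append(dict(
                analyte=a.name, mz=int(m),
                rt_lo=a.rt_true - 4 * a.peak_sigma,
                rt_apex=a.rt_true,
                rt_hi=a.rt_true + 4 * a.peak_sigma,
                area=amp * frac,
                concentration=conc,
                is_quantifier=int(m) in a.quantifier_mzs))

    if noise.cv > 0:
        signal *= np.clip(1.0 + noise.cv * rng.standard_normal(signal.shape),
                          0.0, None)
    observed = signal + noise.baseline
    if noise.additive_sd > 0:
        observed += noise.additive_sd * rng.standard_normal(signal.shape)
    observed = np.clip(observed, 0.0, None)

    run = RawRun(run_id, rts, channels, observed,
                 metadata={"seed": seed, "scan_interval_s": scan_interval})
    truth = pd.DataFrame(truth_rows)
    return run, truth


@dataclass
class MixingExperiment:
    """The combinatorial mixing experiment: design, simulated runs, truth."""

    panel: SyntheticPanel
    design: pd.DataFrame                  # samples × analytes, concentration
    runs: list[RawRun]
    truths: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.design.index)

    @property
    def library(self) -> MsriLibrary:
        return self.panel.library

    @property
    def calibration(self) -> RiCalibration:
        return self.panel.calibration


def generate_mixing_experiment(panel: SyntheticPanel | None = None,
                               seed: int = 0,
                               noise: NoiseParams | None = None,
                               repetitions: int = 5,
                               n_levels: int = 8,
                               dilution_factor: float = 2.0,
                               stock_concentration: float = 1.0,
                               is_concentration: float = 0.5,
                               simulate: bool = True) -> MixingExperiment:
    """Generate the randomised combinatorial mixing experiment.

    Each repetition draws an independent random ordering of the 8-point
    two-fold dilution series of each of the three sub-mixtures; the j-th
    sample of the repetition combines the j-th element of each reordered
    series, so all analytes are present in every sample but sub-mixture
    concentrations vary independently.  With the defaults this yields
    5 × 8 = 40 samples of 85 standards plus the internal standard.
    """
    rng = np.random.default_rng(seed)
    if panel is None:
        panel = make_panel(seed=int(rng.integers(2 ** 31)))
    noise = noise or NoiseParams()
    mixes = sorted({m for m in panel.submix.values() if m is not None})
    if len(mixes) < 3:
        raise DesignError("panel must partition into at least 3 sub-mixtures")

    rows = []
    index = []
    for rep in range(repetitions):
        orders = {m: rng.permutation(n_levels) for m in mixes}
        for j in range(n_levels):
            conc = {}
            for a in panel.analytes:
                mix = panel.submix[a.name]
                if mix is None:
                    conc[a.name] = is_concentration
                else:
                    conc[a.name] = stock_concentration * \
                        dilution_factor ** (-float(orders[mix][j]))
            rows.append(conc)
            index.append(f"run_{rep + 1:02d}_{j + 1:02d}")
    design = pd.DataFrame(rows, index=index,
                          columns=[a.name for a in panel.analytes])

    runs: list[RawRun] = []
    truths: dict[str, pd.DataFrame] = {}
    if simulate:
        for sample_id in index:
            run_seed = int(rng.integers(2 ** 31))
            run, truth = simulate_run(panel, design.loc[sample_id].to_dict(),
                                      noise=noise, seed=run_seed,
                                      run_id=sample_id)
            runs.append(run)
            truths[sample_id] = truth
    return MixingExperiment(panel, design, runs, truths)
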