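"""Statistics and exploratory analysis on metabolite data matrices, plus the
chromatographic statistical-scan comparator on raw runs.

Implements Welch's unequal-variance t-test (two-sided, Welch–Satterthwaite
degrees of freedom), per-analyte treatment:control tables, PCA (SVD of the
centered, optionally unit-variance-scaled sample × analyte matrix),
average-linkage hierarchical clustering on 1 − Pearson correlation distance,
and a scan-by-scan Welch comparison of two chromatogram sets that reports the
retention-time regions that are both statistically significant and beyond a
fold-change threshold.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

from .errors import InputError
from .matrix import DataMatrix
from .msdata import RawRun, extract_tic

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Welch's t-test
# ---------------------------------------------------------------------------

def welch(a, b) -> tuple[float, float, float]:
    """Welch's two-sided t-test.

    Returns ``(t, df, p)`` with
    ``t = (mean(a) - mean(b)) / sqrt(s2_a/n_a + s2_b/n_b)`` and
    Welch–Satterthwaite degrees of freedom.  Zero variance in both groups with
    equal means yields ``t = 0, p = 1`` by convention; with unequal means
    ``t = ±inf, p = 0``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InputError("non-finite values in input")
    va = a.var(ddof=1) / a.size
    vb = b.var(ddof=1) / b.size
    diff = a.mean() - b.mean()
    if va + vb == 0:
        if diff == 0:
            return 0.0, float(a.size + b.size - 2), 1.0
        return float(np.sign(diff) * np.inf), float(a.size + b.size - 2), 0.0
    t = diff / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass
class GroupDesign:
    """run_id → group label; ``control``/``treatment`` for testing ops."""

    groups: dict[str, str]
    control: str = "control"
    treatment: str = "treatment"

    def runs(self, label: str) -> list[str]:
        return [r for r, g in self.groups.items() if g == label]


@dataclass
class TTestRow:
    analyte: str
    mean_control: float
    mean_treatment: float
    ratio: float
    t: float
    df: float
    p: float
    n_control: int
    n_treatment: int
    testable: bool = True


def ttest_table(matrix: DataMatrix, design: GroupDesign,
                sort_by: str | None = None,
                bh_qvalues: bool = False) -> pd.DataFrame:
    """Per-analyte Welch's t-test and treatment/control ratio table.

    Rows with fewer than 2 non-missing replicates in either group are flagged
    untestable (``p`` = NaN).  Sorting is stable (mergesort).  Benjamini–
    Hochberg q-values are appended only on request; raw p-values are the
    default report.
    """
    ctrl_runs = [r for r in design.runs(design.control) if r in matrix.samples]
    trt_runs = [r for r in design.runs(design.treatment) if r in matrix.samples]
    if len(ctrl_runs) < 2 or len(trt_runs) < 2:
        raise InputError("each group needs at least 2 runs in the matrix")
    rows = []
    for analyte in matrix.analytes:
        a = matrix.values.loc[analyte, trt_runs].dropna().to_numpy(float)
        b = matrix.values.loc[analyte, ctrl_runs].dropna().to_numpy(float)
        mean_t = float(a.mean()) if a.size else np.nan
        mean_c = float(b.mean()) if b.size else np.nan
        ratio = mean_t / mean_c if (a.size and b.size and mean_c > 0) else np.nan
        if a.size >= 2 and b.size >= 2:
            t, df, p = welch(a, b)
            rows.append(dict(analyte=analyte, mean_control=mean_c,
                             mean_treatment=mean_t, ratio=ratio, t=t, df=df,
                             p=p, n_control=b.size, n_treatment=a.size,
                             testable=True))
        else:
            rows.append(dict(analyte=analyte, mean_control=mean_c,
                             mean_treatment=mean_t, ratio=ratio, t=np.nan,
                             df=np.nan, p=np.nan, n_control=b.size,
                             n_treatment=a.size, testable=False))
    table = pd.DataFrame(rows)
    if bh_qvalues:
        p = table["p"].to_numpy(float)
        ok = np.isfinite(p)
        q = np.full_like(p, np.nan)
        if ok.any():
            m = ok.sum()
            order = np.argsort(p[ok])
            ranked = p[ok][order] * m / (np.arange(m) + 1)
            q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
            qq = np.empty(m)
            qq[order] = np.minimum(q_sorted, 1.0)
            q[ok] = qq
        table["q"] = q
    if sort_by is not None:
        if sort_by not in table.columns:
            raise InputError(f"cannot sort by {sort_by!r}")
        table = table.sort_values(sort_by, kind="mergesort").reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame          # samples × components
    loadings: pd.DataFrame        # analytes × components
    explained: np.ndarray         # variance fractions, sums to 1


def pca(matrix: DataMatrix, scaling: str = "none") -> PcaResult:
    """PCA of the sample × analyte matrix via SVD of centered data.

    Analytes missing in more samples than they are present are dropped with a
    warning; remaining missing cells are filled with the analyte mean before
    centering.  ``scaling`` is ``none`` or ``unit_variance``.
    """
    if scaling not in ("none", "unit_variance"):
        raise InputError(f"unknown scaling {scaling!r}")
    values = matrix.values
    n_samples = len(matrix.samples)
    keep = [a for a in matrix.analytes
            if values.loc[a].notna().sum() * 2 >= n_samples]
    dropped = set(matrix.analytes) - set(keep)
    if dropped:
        log.warning("pca: dropping %d analytes with majority-missing values",
                    len(dropped))
    X = values.loc[keep].T  # samples × analytes
    X = X.fillna(X.mean(axis=0))
    Xc = X - X.mean(axis=0)
    if scaling == "unit_variance":
        sd = Xc.std(axis=0, ddof=1).replace(0.0, 1.0)
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc.to_numpy(float), full_matrices=False)
    comps = [f"PC{i + 1}" for i in range(s.size)]
    scores = pd.DataFrame(U * s, index=X.index, columns=comps)
    loadings = pd.DataFrame(Vt.T, index=keep, columns=comps)
    total = (s ** 2).sum()
    explained = (s ** 2) / total if total > 0 else np.zeros_like(s)
    return PcaResult(scores, loadings, explained)


# ---------------------------------------------------------------------------
# correlation clustering (HCA)
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    correlation: pd.DataFrame       # analyte × analyte Pearson r, leaf order
    linkage: np.ndarray             # scipy linkage matrix (average linkage)
    leaves: list[str]
    clusters: dict[str, int]        # analyte → flat cluster id (1-based)
    n_clusters: int


def correlation_cluster(matrix: DataMatrix,
                        exclude: list[str] | None = None,
                        n_clusters: int | None = None) -> ClusterResult:
    """Hierarchical clustering of analytes on 1 − Pearson-r distance.

    ``exclude`` is a list of glob patterns (e.g. internal standards, unknown
    analytes) removed before the correlation matrix is formed; zero-variance
    analytes are excluded with a warning.  Flat clusters are cut at the
    largest merge-height gap unless ``n_clusters`` is given.
    """
    names = matrix.analytes
    for pattern in exclude or []:
        names = [n for n in names if not fnmatch.fnmatch(n, pattern)]
    data = matrix.values.loc[names]
    variances = data.var(axis=1, ddof=0)
    flat = [n for n in names if not (variances[n] > 0)]
    if flat:
        log.warning("correlation_cluster: excluding zero-variance analytes %s",
                    flat)
        names = [n for n in names if n not in set(flat)]
    if len(names) < 3:
        raise InputError("need at least 3 analytes after exclusion")
    corr = matrix.values.loc[names].T.corr(method="pearson")
    dist = 1.0 - corr.to_numpy(float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaf_idx = hierarchy.leaves_list(Z)
    leaves = [names[i] for i in leaf_idx]

    heights = Z[:, 2]
    if n_clusters is None:
        if len(heights) < 2:
            n_clusters = len(names)
        else:
            gaps = np.diff(heights)
            cut_after = int(np.argmax(gaps))           # largest height gap
            n_clusters = len(names) - (cut_after + 1)
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    clusters = {name: int(lab) for name, lab in zip(names, labels)}
    ordered_corr = corr.loc[leaves, leaves]
    return ClusterResult(ordered_corr, Z, leaves, clusters, int(n_clusters))


# ---------------------------------------------------------------------------
# chromatographic statistical scan
# ---------------------------------------------------------------------------

@dataclass
class ScanRegion:
    rt_lo: float
    rt_hi: float
    min_p: float
    mean_ratio: float

    def __post_init__(self):
        if not self.rt_lo < self.rt_hi:
            raise InputError("region must have rt_lo < rt_hi")


def statistical_scan(runs_a: list[RawRun], runs_b: list[RawRun],
                     alpha: float = 0.05,
                     min_ratio: float = 2.0,
                     channel: int | None = None) -> list[ScanRegion]:
    """Locate rt regions where two chromatogram sets differ.

    TICs (or one EIC when ``channel`` is given) are resampled onto a common
    grid (union rt range, median scan interval) by linear interpolation; per
    grid point a Welch test and the mean intensity ratio are computed, and
    points with ``p < alpha`` and a fold change beyond ``min_ratio`` (in
    either direction) are merged into maximal contiguous regions.
    """
    if len(runs_a) < 2 or len(runs_b) < 2:
        raise InputError("need at least 2 runs per side")
    if channel is None:
        tics_a = [extract_tic(r) for r in runs_a]
        tics_b = [extract_tic(r) for r in runs_b]
    else:
        from .msdata import extract_eic

        tics_a = [extract_eic(r, channel) for r in runs_a]
        tics_b = [extract_eic(r, channel) for r in runs_b]
    all_tics = tics_a + tics_b
    lo = min(t.rts[0] for t in all_tics)
    hi = max(t.rts[-1] for t in all_tics)
    overlap_lo = max(t.rts[0] for t in all_tics)
    overlap_hi = min(t.rts[-1] for t in all_tics)
    if overlap_lo >= overlap_hi:
        log.warning("statistical_scan: runs do not overlap in rt; no regions")
        return []
    step = float(np.median(np.concatenate([np.diff(t.rts) for t in all_tics])))
    grid = np.arange(lo, hi + step / 2, step)
    A = np.vstack([np.interp(grid, t.rts, t.intensities) for t in tics_a])
    B = np.vstack([np.interp(grid, t.rts, t.intensities) for t in tics_b])

    na, nb = A.shape[0], B.shape[0]
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    va = A.var(axis=0, ddof=1) / na
    vb = B.var(axis=0, ddof=1) / nb
    denom = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(denom > 0, (ma - mb) / np.where(denom > 0, denom, 1), 0.0)
        df = np.where(va + vb > 0,
                      (va + vb) ** 2 /
                      np.where(va + vb > 0,
                               va ** 2 / (na - 1) + vb ** 2 / (nb - 1), 1), 1.0)
        p = np.where(denom > 0, 2.0 * t_dist.sf(np.abs(t_stat), df), 1.0)
        ratio = np.where(mb > 0, ma / np.where(mb > 0, mb, 1), np.inf)
        ratio = np.where((ma == 0) & (mb == 0), 1.0, ratio)
        fold = np.where(ratio >= 1, ratio,
                        np.where(ratio > 0, 1.0 / ratio, np.inf))
    hits = (p < alpha) & (fold > min_ratio)

    regions: list[ScanRegion] = []
    idx = np.flatnonzero(hits)
    if idx.size == 0:
        return regions
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        i0, i1 = int(idx[s]), int(idx[e])
        rt_lo = float(grid[i0] - step / 2)
        rt_hi = float(grid[i1] + step / 2)
        regions.append(ScanRegion(rt_lo, rt_hi,
                                  float(p[i0:i1 + 1].min()),
                                  float(np.mean(ratio[i0:i1 + 1]))))
    return regions
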