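"""Welch's t-test, t-test tables, PCA, correlation clustering, statistical scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gcmspipe.errors import InputError
from gcmspipe.matrix import DataMatrix
from gcmspipe.stats import (GroupDesign, correlation_cluster, pca,
                            statistical_scan, ttest_table, welch)


def matrix_from(values: np.ndarray, analytes=None, samples=None):
    analytes = analytes or [f"a{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=analytes, columns=samples)
    prov = pd.DataFrame("matched", index=analytes, columns=samples)
    return DataMatrix(df, prov)


class TestWelch:
    def test_hand_case(self):
        t, df, p = welch([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.2879, abs=1e-4)

    def test_identical_vectors(self):
        t, _df, p = welch([5, 5, 5], [5, 5, 5])
        assert t == 0.0 and p == 1.0

    def test_antisymmetry(self):
        a, b = [1.0, 2.5, 3.1], [0.4, 0.9, 2.2, 1.1]
        assert welch(a, b)[0] == pytest.approx(-welch(b, a)[0], rel=1e-12)

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3),
                           rng.integers(2, 12))
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3),
                           rng.integers(2, 12))
            t, df, p = welch(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)
            assert df == pytest.approx(ref.df, abs=1e-9)

    def test_short_vectors_rejected(self):
        with pytest.raises(InputError):
            welch([1.0], [1.0, 2.0])


class TestTTestTable:
    def design(self, n=3):
        groups = {f"c{i}": "control" for i in range(n)}
        groups.update({f"t{i}": "treatment" for i in range(n)})
        return GroupDesign(groups)

    def test_identical_groups_ratio_one_p_one(self):
        values = np.tile([[5.0, 5.0, 5.0, 5.0, 5.0, 5.0]], (2, 1))
        m = matrix_from(values, samples=["c0", "c1", "c2", "t0", "t1", "t2"])
        table = ttest_table(m, self.design())
        assert len(table) == 2
        assert np.allclose(table["ratio"], 1.0)
        assert np.allclose(table["p"], 1.0)

    def test_row_count_equals_analytes(self):
        rng = np.random.default_rng(0)
        m = matrix_from(rng.uniform(1, 2, (7, 6)),
                        samples=["c0", "c1", "c2", "t0", "t1", "t2"])
        assert len(ttest_table(m, self.design())) == 7

    def test_untestable_row_flagged(self):
        values = np.array([[1.0, np.nan, np.nan, 2.0, 2.1, 1.9]])
        m = matrix_from(values, samples=["c0", "c1", "c2", "t0", "t1", "t2"])
        table = ttest_table(m, self.design())
        assert not table.loc[0, "testable"]
        assert np.isnan(table.loc[0, "p"])

    def test_twofold_spike_detected_reliably(self):
        """2-fold change at n=5, CV 5%: ratio near 2, p < 0.01 in >=95% of
        200 seeded repetitions."""
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(200):
            ctrl = 1.0 * (1 + 0.05 * rng.standard_normal(5))
            trt = 2.0 * (1 + 0.05 * rng.standard_normal(5))
            samples = [f"c{i}" for i in range(5)] + [f"t{i}" for i in range(5)]
            m = matrix_from(np.concatenate([ctrl, trt])[None, :],
                            samples=samples)
            table = ttest_table(m, GroupDesign(
                {s: ("control" if s.startswith("c") else "treatment")
                 for s in samples}))
            row = table.iloc[0]
            if 1.8 <= row["ratio"] <= 2.2 and row["p"] < 0.01:
                hits += 1
        assert hits >= 190

    def test_bh_qvalues_monotone_in_p(self):
        rng = np.random.default_rng(5)
        m = matrix_from(rng.uniform(1, 4, (20, 6)),
                        samples=["c0", "c1", "c2", "t0", "t1", "t2"])
        table = ttest_table(m, self.design(), bh_qvalues=True, sort_by="p")
        q = table["q"].to_numpy()
        assert np.all(np.diff(q) >= -1e-12)
        assert np.all(q >= table["p"].to_numpy() - 1e-12)


class TestPca:
    def random_matrix(self, seed=0, n_analytes=8, n_samples=10):
        rng = np.random.default_rng(seed)
        return matrix_from(rng.normal(10, 3, (n_analytes, n_samples)))

    def test_variance_fractions_sum_to_one(self):
        res = pca(self.random_matrix())
        assert res.explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rank_one_matrix_loads_on_pc1(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([2.0, 1.0, 5.0, 3.0, 4.0])
        m = matrix_from(np.outer(u, v))
        res = pca(m)
        assert res.explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_reconstruction_identity(self):
        m = self.random_matrix(seed=3)
        res = pca(m)
        X = m.values.T.to_numpy()
        Xc = X - X.mean(axis=0)
        approx = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(approx, Xc, atol=1e-9)

    def test_sample_reorder_invariance_up_to_sign(self):
        m = self.random_matrix(seed=4)
        res1 = pca(m)
        perm = np.random.default_rng(1).permutation(len(m.samples))
        shuffled = DataMatrix(m.values.iloc[:, perm],
                              m.provenance.iloc[:, perm])
        res2 = pca(shuffled)
        for k in range(3):
            a = res1.scores.iloc[perm, k].to_numpy()
            b = res2.scores.iloc[:, k].to_numpy()
            assert np.allclose(a, b, atol=1e-8) or \
                np.allclose(a, -b, atol=1e-8)

    def test_majority_missing_analyte_dropped(self):
        values = np.random.default_rng(0).normal(10, 1, (4, 6))
        values[2, :4] = np.nan
        res = pca(matrix_from(values))
        assert "a2" not in res.loadings.index


class TestCorrelationCluster:
    def block_matrix(self, seed=0):
        """Three independent blocks of perfectly correlated analytes."""
        rng = np.random.default_rng(seed)
        base = rng.uniform(1, 5, (3, 12))
        rows, names = [], []
        for b in range(3):
            for i in range(4):
                rows.append(base[b] * (i + 1))
                names.append(f"block{b}_{i}")
        return matrix_from(np.array(rows), analytes=names)

    def test_three_blocks_three_clusters(self):
        res = correlation_cluster(self.block_matrix())
        assert res.n_clusters == 3
        labels = {}
        for name, lab in res.clusters.items():
            labels.setdefault(name.split("_")[0], set()).add(lab)
        assert all(len(v) == 1 for v in labels.values())
        assert len({next(iter(v)) for v in labels.values()}) == 3

    def test_merge_heights_non_decreasing(self):
        res = correlation_cluster(self.block_matrix(seed=2))
        heights = res.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_permutation_equivariance(self):
        m = self.block_matrix()
        res1 = correlation_cluster(m)
        perm = np.random.default_rng(3).permutation(len(m.analytes))
        shuffled = DataMatrix(m.values.iloc[perm], m.provenance.iloc[perm])
        res2 = correlation_cluster(shuffled)
        groups1 = {}
        groups2 = {}
        for name in m.analytes:
            groups1.setdefault(res1.clusters[name], set()).add(name)
            groups2.setdefault(res2.clusters[name], set()).add(name)
        assert {frozenset(v) for v in groups1.values()} == \
            {frozenset(v) for v in groups2.values()}

    def test_exclusion_and_zero_variance(self):
        m = self.block_matrix()
        flat = matrix_from(np.vstack([m.values.to_numpy(),
                                      np.full((1, 12), 7.0)]),
                           analytes=m.analytes + ["constant"])
        res = correlation_cluster(flat, exclude=["block2_*"])
        assert all(not n.startswith("block2") for n in res.leaves)
        assert "constant" not in res.leaves

    def test_too_few_analytes_rejected(self):
        m = self.block_matrix()
        with pytest.raises(InputError):
            correlation_cluster(m, exclude=["block*"])


class TestStatisticalScan:
    def runs(self, spike=1.0, n=3, seed=0):
        from gcmspipe.msdata import RawRun

        rng = np.random.default_rng(seed)
        out = []
        t = np.arange(560.0, 640.0, 0.25)
        for k in range(n):
            y = 200.0 + spike * 5e4 * np.exp(-0.5 * ((t - 600.0) / 2.0) ** 2)
            y = y * (1 + 0.05 * rng.standard_normal(t.size))
            out.append(RawRun(f"r{seed}_{k}", t, np.array([73]),
                              np.clip(y, 0, None)[:, None]))
        return out

    def test_identical_sets_give_no_regions(self):
        runs = self.runs(seed=1)
        assert statistical_scan(runs, runs) == []

    def test_spike_found_and_sides_symmetric(self):
        a = self.runs(spike=5.0, seed=2)
        b = self.runs(spike=1.0, seed=3)
        fwd = statistical_scan(a, b)
        rev = statistical_scan(b, a)
        assert len(fwd) == 1
        assert fwd[0].rt_lo <= 600.0 <= fwd[0].rt_hi
        assert [(r.rt_lo, r.rt_hi) for r in fwd] == \
            [(r.rt_lo, r.rt_hi) for r in rev]

    def test_non_overlapping_ranges_warn_empty(self):
        from gcmspipe.msdata import RawRun

        t1 = np.arange(0.0, 10.0, 0.5)
        t2 = np.arange(100.0, 110.0, 0.5)
        mk = lambda t, rid: RawRun(rid, t, np.array([73]),
                                   np.ones((t.size, 1)))
        assert statistical_scan([mk(t1, "a1"), mk(t1, "a2")],
                                [mk(t2, "b1"), mk(t2, "b2")]) == []

    def test_needs_two_runs_per_side(self):
        runs = self.runs()
        with pytest.raises(InputError):
            statistical_scan(runs[:1], runs)
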