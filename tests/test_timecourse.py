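"""Normalization, polynomial time-course fitting, and profile clustering."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from chromdyn import (BinGrid, BinnedTrack, cluster_profiles,
                      fit_polynomial_timecourse, fpkm, select_dynamic,
                      timecourse_analysis, tmm_factors, window_rpm)


def _meta(n_tp=5, n_rep=3, weeks=(0, 2, 4, 7, 10)):
    rows = []
    for t in range(n_tp):
        for r in range(n_rep):
            rows.append({"sample": f"t{t}_r{r}", "timepoint": f"t{t}",
                         "week": float(weeks[t]), "replicate": r + 1})
    return pd.DataFrame(rows)


class TestTMM:
    def test_reference_sample_gets_factor_one_before_rescale(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, size=(200, 4)) + 1,
                              columns=list("ABCD"))
        f = tmm_factors(counts, ref="A")
        # rescaling to geometric mean 1 shifts all factors equally
        np.testing.assert_allclose(np.exp(np.log(f).mean()), 1.0, atol=1e-12)

    def test_pure_depth_change_gives_factor_one(self):
        a = pd.Series([100, 200, 300, 400, 500])
        counts = pd.DataFrame({"A": a, "B": 2 * a})
        f = tmm_factors(counts, ref="A")
        np.testing.assert_allclose(f, 1.0, atol=1e-12)

    def test_outlier_gene_trimmed_hand_oracle(self):
        """One 8-fold outlier is trimmed; every kept gene has the same
        M-value, so the factor ratio is exactly 2*5500/18000 = 11/18."""
        a = pd.Series([100, 200, 300, 400, 500, 600, 700, 800, 900, 1000])
        b = 2 * a
        b.iloc[4] = 8000
        counts = pd.DataFrame({"A": a, "B": b})
        f = tmm_factors(counts, ref="A")
        assert f["B"] / f["A"] == pytest.approx(11 / 18, abs=1e-12)

    def test_all_zero_sample_is_error(self):
        counts = pd.DataFrame({"A": [1, 2], "B": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(counts)

    def test_matches_edger_calcnormfactors(self, tmp_path):
        """Dual-route check against edgeR's reference implementation."""
        rng = np.random.default_rng(42)
        base = rng.lognormal(4, 1, size=300)
        counts = pd.DataFrame(
            {f"s{j}": rng.poisson(base * rng.uniform(0.5, 2.0))
             for j in range(5)})
        counts += 1   # avoid zeros so both routes keep identical gene sets
        cpath = tmp_path / "counts.tsv"
        counts.to_csv(cpath, sep="\t", index=False)
        script = tmp_path / "tmm.R"
        script.write_text(
            'x <- as.matrix(read.delim("%s"))\n'
            'suppressMessages(library(edgeR))\n'
            'f <- calcNormFactors(x, method="TMM")\n'
            'cat(sprintf("%%.12f", f), sep="\\n")\n' % cpath)
        res = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        expected = np.array([float(v) for v in res.stdout.split()])
        ours = tmm_factors(counts).to_numpy()
        np.testing.assert_allclose(ours, expected, atol=1e-6)


class TestFPKM:
    def test_formula(self):
        counts = pd.DataFrame({"s": [10]}, index=["g"])
        out = fpkm(counts, pd.Series({"g": 2000}), pd.Series({"s": 1e6}))
        assert out.loc["g", "s"] == pytest.approx(5.0)

    def test_zero_count_and_library_scaling(self):
        counts = pd.DataFrame({"s1": [0, 50], "s2": [0, 50]},
                              index=["g0", "g1"])
        libs = pd.Series({"s1": 1e6, "s2": 2e6})
        out = fpkm(counts, pd.Series({"g0": 1000, "g1": 1000}), libs)
        assert out.loc["g0"].eq(0).all()
        assert out.loc["g1", "s2"] == pytest.approx(out.loc["g1", "s1"] / 2)

    def test_zero_length_names_gene(self):
        counts = pd.DataFrame({"s": [1]}, index=["broken"])
        with pytest.raises(ValueError, match="broken"):
            fpkm(counts, pd.Series({"broken": 0}), pd.Series({"s": 1e6}))


class TestWindowRPM:
    def _setup(self, values):
        grid = BinGrid([("chr1", 20_000)], 200)
        return BinnedTrack(grid, np.asarray(values, float), None)

    def test_rpm_formula(self):
        track = self._setup(np.zeros(100))
        track.values[50:55] = 20.0        # 100 counts
        track.library_size = 1e7
        genes = pd.DataFrame([("chr1", 10_000, 11_000, "g", 0, "+")],
                             columns=["chrom", "start", "end", "name",
                                      "score", "strand"])
        rpm = window_rpm(track, genes, "tss_1.5kb")
        assert rpm["g"] == pytest.approx(10.0)

    def test_annulus_excludes_core(self):
        track = self._setup(np.zeros(100))
        genes = pd.DataFrame([("chr1", 8_000, 10_000, "g", 0, "+")],
                             columns=["chrom", "start", "end", "name",
                                      "score", "strand"])
        # all signal within gene body +/- 1.5 kb: annular scheme sees nothing
        lo, hi = 8_000 - 1_500, 10_000 + 1_500
        track.values[lo // 200:(hi - 1) // 200 + 1] = 5.0
        track.library_size = 1e6
        assert window_rpm(track, genes, "genebody_1.5-10kb")["g"] == 0.0
        assert window_rpm(track, genes, "genebody_2kb")["g"] > 0

    def test_hand_summed_counts(self):
        track = self._setup(np.arange(100, dtype=float))
        track.library_size = 1e6
        genes = pd.DataFrame([
            ("chr1", 10_000, 10_200, "gp", 0, "+"),
            ("chr1", 10_000, 10_200, "gm", 0, "-"),
            ("chr1", 400, 600, "edge", 0, "+"),
        ], columns=["chrom", "start", "end", "name", "score", "strand"])
        rpm = window_rpm(track, genes, "tss_1.5kb")
        # + strand TSS 10000: bins of [8500,11500) -> 42..57
        assert rpm["gp"] == pytest.approx(sum(range(42, 58)))
        # - strand TSS 10200: bins of [8700,11700) -> 43..58
        assert rpm["gm"] == pytest.approx(sum(range(43, 59)))
        # window truncated at chromosome start: bins of [0,1900) -> 0..9
        assert rpm["edge"] == pytest.approx(sum(range(10)))

    def test_unknown_scheme(self):
        track = self._setup(np.zeros(100))
        with pytest.raises(ValueError, match="unknown scheme"):
            window_rpm(track, pd.DataFrame(), "nope")


class TestPolynomialFit:
    def test_exact_quartic_has_r2_one(self):
        meta = _meta()
        t = meta["week"].to_numpy()
        y = 1 + 2 * t - 0.3 * t ** 2 + 0.01 * t ** 4
        values = pd.DataFrame([y], index=["g"], columns=meta["sample"])
        res = fit_polynomial_timecourse(values, meta)
        assert res.table.loc["g", "r2"] == pytest.approx(1.0)

    def test_constant_feature_r2_zero(self):
        meta = _meta()
        values = pd.DataFrame([[3.0] * len(meta)], index=["flat"],
                              columns=meta["sample"])
        res = fit_polynomial_timecourse(values, meta)
        assert res.table.loc["flat", "r2"] == 0.0

    def test_matches_normal_equations_oracle(self):
        meta = _meta()
        rng = np.random.default_rng(5)
        values = pd.DataFrame(rng.normal(size=(7, len(meta))),
                              index=[f"g{i}" for i in range(7)],
                              columns=meta["sample"])
        res = fit_polynomial_timecourse(values, meta, degree=4)
        t = meta["week"].to_numpy()
        ts = (t - t.mean()) / t.std()
        X = np.vander(ts, 5, increasing=True)
        XtX, Xt = X.T @ X, X.T
        for g in values.index:
            y = values.loc[g].to_numpy()
            beta = np.linalg.solve(XtX, Xt @ y)
            np.testing.assert_allclose(
                res.table.loc[g, [f"coef_{i}" for i in range(5)]].astype(float),
                beta, atol=1e-8)
            r2 = 1 - ((y - X @ beta) ** 2).sum() / ((y - y.mean()) ** 2).sum()
            assert res.table.loc[g, "r2"] == pytest.approx(r2, abs=1e-8)

    def test_r2_invariant_to_affine_rescaling(self):
        meta = _meta()
        rng = np.random.default_rng(6)
        y = rng.normal(size=len(meta))
        values = pd.DataFrame([y, 5 * y + 2], index=["a", "b"],
                              columns=meta["sample"])
        res = fit_polynomial_timecourse(values, meta)
        assert res.table.loc["a", "r2"] == pytest.approx(
            res.table.loc["b", "r2"], abs=1e-12)

    def test_too_few_timepoints(self):
        meta = _meta(n_tp=3, weeks=(0, 2, 4))
        values = pd.DataFrame(np.zeros((1, len(meta))), index=["g"],
                              columns=meta["sample"])
        with pytest.raises(ValueError, match="degree"):
            fit_polynomial_timecourse(values, meta, degree=4)


class TestSelectDynamic:
    def test_boundary_is_strict(self):
        meta = _meta()
        res = fit_polynomial_timecourse(
            pd.DataFrame(np.zeros((2, len(meta))), index=["a", "b"],
                         columns=meta["sample"]), meta)
        res.table.loc["a", "r2"] = 0.7
        res.table.loc["b", "r2"] = 0.7000001
        dyn = select_dynamic(res, r2_cutoff=0.7)
        assert list(dyn) == ["b"]

    def test_null_simulation_false_positive_rate(self):
        meta = _meta()
        rng = np.random.default_rng(7)
        values = pd.DataFrame(rng.normal(size=(1000, len(meta))),
                              columns=meta["sample"])
        res = fit_polynomial_timecourse(values, meta)
        select_dynamic(res)
        assert res.table["dynamic"].mean() < 0.05

    def test_planted_trends_detected(self):
        meta = _meta()
        rng = np.random.default_rng(8)
        t = meta["week"].to_numpy()
        ts = (t - t.mean()) / t.std()
        rows = []
        for _ in range(200):
            beta = rng.normal(size=5)
            signal = np.vander(ts, 5, increasing=True) @ beta
            signal *= np.sqrt(10) / signal.std()       # SNR 10 vs unit noise
            rows.append(signal + rng.normal(size=len(t)))
        values = pd.DataFrame(rows, columns=meta["sample"])
        res = fit_polynomial_timecourse(values, meta)
        select_dynamic(res)
        assert res.table["dynamic"].mean() >= 0.95


class TestClusterProfiles:
    def _two_archetypes(self, n=60, noise=0.1, seed=9):
        meta = _meta()
        rng = np.random.default_rng(seed)
        up = np.array([0, 1, 2, 3, 4.0])
        down = up[::-1]
        rows, truth = [], []
        for i in range(n):
            mu = up if i % 2 else down
            truth.append(i % 2)
            rows.append(np.repeat(mu, 3) + rng.normal(0, noise, 15))
        values = pd.DataFrame(rows, columns=meta["sample"])
        return values, meta, np.array(truth)

    def test_two_planted_archetypes_perfectly_recovered(self):
        values, meta, truth = self._two_archetypes()
        labels, k, _ = cluster_profiles(values, meta, k=2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_duplication_invariance(self):
        values, meta, _ = self._two_archetypes(n=20)
        doubled = pd.concat([values, values.set_axis(
            [i + 100 for i in values.index])])
        l1, _, _ = cluster_profiles(values, meta, k=2, seed=0)
        l2, _, _ = cluster_profiles(doubled, meta, k=2, seed=0)
        a = (l2.iloc[:20].to_numpy() == l2.iloc[20:].to_numpy()).all()
        assert a   # each duplicate lands with its twin

    def test_seed_determinism_and_silhouette_selection(self):
        values, meta, _ = self._two_archetypes()
        l1, k1, sil = cluster_profiles(values, meta, k=None,
                                       k_range=range(2, 6), seed=1)
        l2, k2, _ = cluster_profiles(values, meta, k=None,
                                     k_range=range(2, 6), seed=1)
        assert k1 == k2 == 2 and l1.equals(l2)
        assert sil.loc[sil["silhouette"].idxmax(), "k"] == 2

    def test_k_larger_than_features_is_error(self):
        values, meta, _ = self._two_archetypes(n=4)
        with pytest.raises(ValueError):
            cluster_profiles(values, meta, k=10, seed=0)


class TestEndToEndArchetypes:
    def test_four_planted_archetypes_recovered(self, desk_config,
                                               desk_dataset):
        """log2-FPKM profiles of the four planted temporal archetypes are
        flagged dynamic and clustered back to truth with ARI > 0.9."""
        truth, _, expr = desk_dataset
        log_expr = np.log2(expr.fpkm)
        res = timecourse_analysis(log_expr, expr.meta, k=4, seed=0)
        dyn = res.dynamic_features
        assert len(dyn) > 0.9 * len(log_expr)
        labels = res.table.loc[dyn, "cluster"].astype(int)
        ari = adjusted_rand_score(truth.cluster_truth.loc[dyn], labels)
        assert ari > 0.9
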