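import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisrange import decay_inference as di
from cisrange.genome_io import Gene, GenomeLayout, Tad
from cisrange.rp_model import DecaySpec

from .conftest import make_peakset


class TestDefaultGrid:
    def test_endpoints(self):
        g = di.default_grid(2)
        assert g[0] == pytest.approx(100)
        assert g[-1] == pytest.approx(4_000_000)

    def test_geometric_spacing(self):
        g = di.default_grid(33)
        ratios = g[1:] / g[:-1]
        assert np.allclose(ratios, ratios[0], rtol=1e-9)
        assert np.all((g >= 100 - 1e-9) & (g <= 4_000_000 + 1e-3))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            di.default_grid(1)


class TestDeriveDeGenes:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2FC", "p"])

    def test_thresholds_strict(self):
        t = self._table([("a", 1.5, 0.001), ("b", 1.0, 0.001), ("c", -2.0, 0.005),
                         ("d", 3.0, 0.01)])
        de = di.derive_de_genes(t, "TF1")
        assert de.genes == {"a", "c"}  # b fails |lfc|>1 strictly, d fails p<0.01

    def test_direction_filter(self):
        t = self._table([("a", 1.5, 0.001), ("b", -2.0, 0.005)])
        assert di.derive_de_genes(t, "TF1", direction="down").genes == {"b"}
        assert di.derive_de_genes(t, "TF1", direction="up").genes == {"a"}

    def test_empty_result_advises(self):
        t = self._table([("a", 0.2, 0.5)])
        with pytest.raises(ValueError, match="threshold"):
            di.derive_de_genes(t, "TF1")


class TestKsSeparation:
    def test_identical_distributions_zero(self):
        scores = pd.Series(np.tile([1.0, 2.0, 3.0], 10),
                           index=[f"g{i}" for i in range(30)])
        de = di.DEGeneSet("TF1", frozenset(f"g{i}" for i in range(0, 30, 2)))
        # DE and non-DE contain the same multiset of values
        stat, _ = di.ks_separation(scores, de)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_one(self):
        scores = pd.Series(
            list(range(10)) + list(range(100, 110)),
            index=[f"g{i}" for i in range(20)], dtype=float,
        )
        de = di.DEGeneSet("TF1", frozenset(f"g{i}" for i in range(10, 20)))
        stat, p = di.ks_separation(scores, de)
        assert stat == pytest.approx(1.0)
        assert p < 1e-4

    def test_matches_brute_force_ecdf(self, rng):
        de_vals = rng.random(50)
        other_vals = rng.random(500)
        scores = pd.Series(
            np.concatenate([de_vals, other_vals]),
            index=[f"d{i}" for i in range(50)] + [f"o{i}" for i in range(500)],
        )
        de = di.DEGeneSet("TF1", frozenset(f"d{i}" for i in range(50)))
        stat, _ = di.ks_separation(scores, de)
        # brute-force sup over pooled points of |ECDF difference|
        pooled = np.concatenate([de_vals, other_vals])
        sup = max(
            abs((de_vals <= x).mean() - (other_vals <= x).mean()) for x in pooled
        )
        assert stat == pytest.approx(sup, abs=1e-12)

    def test_empty_group_rejected(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            di.ks_separation(scores, di.DEGeneSet("TF1", frozenset(["a", "b"])))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=-1000, max_value=1000),
                    min_size=6, max_size=40, unique=True))
    def test_invariant_under_monotone_transform(self, values):
        # the KS statistic depends only on score ranks
        scores = pd.Series([float(v) for v in values],
                           index=[f"g{i}" for i in range(len(values))])
        de = di.DEGeneSet("TF1", frozenset(scores.index[: len(values) // 2]))
        s1, _ = di.ks_separation(scores, de)
        s2, _ = di.ks_separation(np.exp(scores / 250.0), de)
        assert s1 == pytest.approx(s2, abs=1e-12)


class TestNormalizeExpression:
    def test_rows_centered(self, rng):
        raw = pd.DataFrame(rng.random((40, 5)) * 50)
        norm = di.normalize_expression(raw)
        assert np.abs(norm.mean(axis=1)).max() < 1e-10

    def test_constant_gene_row_becomes_zero(self, rng):
        # columns are permutations of one another, so the constant row keeps
        # the same within-column rank everywhere and centering zeroes it
        base = np.sort(rng.random(9) * 10)
        cols = {f"s{j}": rng.permutation(base) for j in range(4)}
        raw = pd.DataFrame(cols)
        raw.loc[9] = 7.0
        norm = di.normalize_expression(raw)
        assert np.allclose(norm.loc[9], 0.0, atol=1e-12)

    def test_quantile_step_equalizes_distributions(self, rng):
        raw = pd.DataFrame(rng.lognormal(1, 1, size=(60, 3)))
        logged = np.log2(raw.to_numpy() + 1)
        ref = np.sort(logged, axis=0).mean(axis=1)
        norm = di.normalize_expression(raw)
        recentered = norm.to_numpy() + (norm.to_numpy() * 0)
        # undo gene centering by reconstructing: each column's sorted values
        # must equal the pooled reference before centering
        from scipy import stats as sps
        for j in range(3):
            ranks = sps.rankdata(logged[:, j], method="average")
            expect = np.interp(ranks, np.arange(1, 61), ref)
            row_means = np.empty(60)
            # recompute what the implementation centered away
            full = np.empty((60, 3))
            for jj in range(3):
                r = sps.rankdata(logged[:, jj], method="average")
                full[:, jj] = np.interp(r, np.arange(1, 61), ref)
            assert np.allclose(norm.to_numpy()[:, j],
                               expect - full.mean(axis=1))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            di.normalize_expression(pd.DataFrame({"s1": [1.0, 2.0]}))


class TestCorrelationProfile:
    def _expr(self, rows):
        return pd.DataFrame(rows, columns=[f"s{i}" for i in range(len(next(iter(rows.values()))))])

    def test_self_and_anti_correlation(self):
        tf = np.array([1.0, 2.0, 3.0, 4.0])
        expr = pd.DataFrame(
            {"s0": [1, 1, -1], "s1": [2, 2, -2], "s2": [3, 3, -3], "s3": [4, 4, -4]},
            index=["TF", "same", "anti"], dtype=float,
        )
        prof = di.correlation_profile(expr, "TF")
        assert prof.corr["same"] == pytest.approx(1.0)
        assert prof.corr["anti"] == pytest.approx(-1.0)

    def test_pearson_equals_standardized_ols_slope(self, rng):
        # the correlation is the MLE slope of the standardized regression
        for _ in range(100):
            n = int(rng.integers(5, 40))
            tf = rng.normal(size=n)
            gene = rng.normal(size=n)
            expr = pd.DataFrame([tf, gene], index=["TF", "g"],
                                columns=[f"s{i}" for i in range(n)])
            prof = di.correlation_profile(expr, "TF")
            zt = (tf - tf.mean()) / tf.std()
            zg = (gene - gene.mean()) / gene.std()
            slope = float(np.linalg.lstsq(
                np.vstack([np.ones(n), zt]).T, zg, rcond=None)[0][1])
            assert prof.corr["g"] == pytest.approx(slope, abs=1e-12)

    def test_zero_variance_gene_absent(self):
        expr = pd.DataFrame(
            {"s0": [1, 5], "s1": [2, 5], "s2": [3, 5]}, index=["TF", "flat"],
            dtype=float,
        )
        prof = di.correlation_profile(expr, "TF")
        assert np.isnan(prof.corr["flat"])

    def test_constant_tf_rejected(self):
        expr = pd.DataFrame(
            {"s0": [1, 1], "s1": [1, 2], "s2": [1, 3]}, index=["TF", "g"],
            dtype=float,
        )
        with pytest.raises(ValueError, match="constant"):
            di.correlation_profile(expr, "TF")


class TestConcordance:
    def test_exact_linear_relation(self, rng):
        rp = rng.random(50)
        gamma = 0.3 + 0.2 * rp
        fit = di.concordance_linear(gamma, rp)
        assert fit.rho == pytest.approx(1.0)
        assert fit.beta == pytest.approx(0.2)
        assert fit.alpha == pytest.approx(0.3)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_independent_vectors_small_rho(self, rng):
        rho = di.concordance_linear(rng.normal(size=500), rng.normal(size=500)).rho
        assert abs(rho) < 0.15

    def test_brute_force_covariance_oracle(self, rng):
        gamma = rng.normal(size=100)
        rp = rng.normal(size=100)
        fit = di.concordance_linear(gamma, rp)
        n = 100
        mg, mr = gamma.mean(), rp.mean()
        sxy = sum((gamma[i] - mg) * (rp[i] - mr) for i in range(n))
        sxx = sum((rp[i] - mr) ** 2 for i in range(n))
        syy = sum((gamma[i] - mg) ** 2 for i in range(n))
        assert fit.rho == pytest.approx(sxy / np.sqrt(sxx * syy), abs=1e-12)
        assert fit.beta == pytest.approx(sxy / sxx, abs=1e-12)
        alpha = mg - (sxy / sxx) * mr
        assert fit.alpha == pytest.approx(alpha, abs=1e-12)
        resid = gamma - alpha - (sxy / sxx) * rp
        assert fit.sigma2 == pytest.approx(np.mean(resid**2), abs=1e-12)

    def test_dcor_perfect_dependence(self, rng):
        x = rng.normal(size=40)
        assert di.concordance_dcor(x, x) == pytest.approx(1.0)

    def test_dcor_independent_near_zero(self, rng):
        vals = [di.distance_correlation(rng.normal(size=30), rng.normal(size=30))
                for _ in range(10)]
        assert np.mean(vals) < 0.4

    def test_dcor_brute_force_oracle(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        got = di.distance_correlation(x, y)
        n = 20
        a = np.array([[abs(x[i] - x[j]) for j in range(n)] for i in range(n)])
        b = np.array([[abs(y[i] - y[j]) for j in range(n)] for i in range(n)])
        A = np.empty((n, n))
        B = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                A[i, j] = a[i, j] - a[i].mean() - a[:, j].mean() + a.mean()
                B[i, j] = b[i, j] - b[i].mean() - b[:, j].mean() + b.mean()
        dcov2 = (A * B).mean()
        expect = np.sqrt(dcov2 / np.sqrt((A * A).mean() * (B * B).mean()))
        assert got == pytest.approx(expect, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            di.concordance_linear(np.ones(10), np.arange(10.0))


def _grid_search_setup(rng, n_genes=120):
    tads = [Tad(f"t{i}", "chr1", i * 200_000, (i + 1) * 200_000) for i in range(10)]
    genes = [Gene(f"g{i}", "chr1", int(rng.integers(0, 2_000_000)), "+")
             for i in range(n_genes)]
    layout = GenomeLayout(genes=genes, tads=tads)
    rows = []
    for g in genes:
        for d in rng.laplace(0, 10_000 / np.log(2), size=3):
            c = int(g.tss + d)
            if c >= 100:
                rows.append(("chr1", c - 100, c + 100, 1.0))
    return layout, make_peakset(rows)


class TestDeltaGridSearch:
    def test_sign_invariance_repressor(self, rng):
        layout, ps = _grid_search_setup(rng)
        grid = di.default_grid(17)
        from cisrange.rp_model import gene_peak_distances
        gpd = gene_peak_distances(ps, layout)
        rp_true = gpd.rp(DecaySpec("exponential", delta=10_000))
        corr = pd.Series(0.05 * rp_true + rng.normal(0, 0.02, len(rp_true)),
                         index=gpd.gene_ids)
        up = di.delta_grid_search(ps, layout,
                                  di.CorrelationProfile("TFX", corr, 100), grid)
        down = di.delta_grid_search(ps, layout,
                                    di.CorrelationProfile("TFX", -corr, 100), grid)
        assert up.delta_star == down.delta_star
        np.testing.assert_allclose(up.statistic, down.statistic, atol=1e-12)

    def test_statistic_invariant_to_gene_order(self, rng):
        layout, ps = _grid_search_setup(rng)
        grid = di.default_grid(9)
        from cisrange.rp_model import gene_peak_distances
        gpd = gene_peak_distances(ps, layout)
        corr = pd.Series(rng.normal(0, 0.1, len(gpd.gene_ids)), index=gpd.gene_ids)
        prof = di.CorrelationProfile("TFX", corr, 100)
        prof_shuffled = di.CorrelationProfile(
            "TFX", corr.sample(frac=1.0, random_state=1), 100
        )
        c1 = di.delta_grid_search(ps, layout, prof, grid)
        c2 = di.delta_grid_search(ps, layout, prof_shuffled, grid)
        np.testing.assert_allclose(c1.statistic, c2.statistic, atol=1e-12)

    def test_tf_own_gene_excluded(self, rng):
        layout, ps = _grid_search_setup(rng)
        grid = di.default_grid(5)
        from cisrange.rp_model import gene_peak_distances
        gpd = gene_peak_distances(ps, layout)
        corr = pd.Series(rng.normal(0, 0.1, len(gpd.gene_ids)), index=gpd.gene_ids)
        tf_gene = gpd.gene_ids[0]
        corr[tf_gene] = 1.0  # would dominate if not excluded
        prof = di.CorrelationProfile(tf_gene, corr, 100)
        curve = di.delta_grid_search(ps, layout, prof, grid)
        corr2 = corr.copy()
        corr2[tf_gene] = -1.0
        curve2 = di.delta_grid_search(
            ps, layout, di.CorrelationProfile(tf_gene, corr2, 100), grid
        )
        np.testing.assert_allclose(curve.statistic, curve2.statistic, atol=1e-12)


class TestTieBreakAndPerturbRoute:
    def test_constant_curve_ties_to_smallest_delta(self):
        # one equidistant peak per gene: RP ordering identical at every delta,
        # so the KS statistic is constant and the argmax must be the smallest
        tads = [Tad(f"t{i}", "chr1", i * 100_000, (i + 1) * 100_000) for i in range(4)]
        genes = [Gene(f"g{i}", "chr1", i * 100_000 + 50_000, "+") for i in range(4)]
        layout = GenomeLayout(genes=genes, tads=tads)
        rows = [("chr1", g.tss + 900, g.tss + 1_100, 1.0) for g in genes]
        ps = make_peakset(rows)
        de = di.DEGeneSet("TF1", frozenset(["g0", "g1"]))
        grid = di.default_grid(9)
        curve = di.infer_delta_perturbation(ps, layout, de, grid)
        assert np.allclose(curve.statistic, curve.statistic[0])
        assert curve.delta_star == grid[0]

    def test_planted_short_range_argmax_small(self, rng):
        # DE genes have a peak at 500 bp; non-DE genes are peak-free
        tads = [Tad(f"t{i}", "chr1", i * 100_000, (i + 1) * 100_000) for i in range(30)]
        genes = [Gene(f"g{i}", "chr1", i * 100_000 + 50_000, "+") for i in range(30)]
        layout = GenomeLayout(genes=genes, tads=tads)
        de_ids = [f"g{i}" for i in range(10)]
        rows = [("chr1", layout.genes[i].tss + 400, layout.genes[i].tss + 600, 1.0)
                for i in range(10)]
        # distant background peaks for the others
        rows += [("chr1", layout.genes[i].tss + 40_000, layout.genes[i].tss + 40_200, 1.0)
                 for i in range(10, 30)]
        ps = make_peakset(rows)
        grid = di.default_grid(17)
        curve = di.infer_delta_perturbation(
            ps, layout, di.DEGeneSet("TF1", frozenset(de_ids)), grid
        )
        assert curve.delta_star <= 3_000

    def test_planted_long_range_argmax_large(self, rng):
        # every gene has one promoter-proximal peak from the same distance
        # distribution; DE genes additionally carry a peak ~50 kb away, so
        # only large delta separates the two groups
        tads = [Tad(f"t{i}", "chr1", i * 200_000, (i + 1) * 200_000) for i in range(60)]
        genes = [Gene(f"g{i}", "chr1", i * 200_000 + 100_000, "+") for i in range(60)]
        layout = GenomeLayout(genes=genes, tads=tads)
        de_ids = [f"g{i}" for i in range(20)]
        rows = []
        for i, g in enumerate(genes):
            close = int(rng.integers(200, 2_000))
            rows.append(("chr1", g.tss + close - 100, g.tss + close + 100, 1.0))
            if i < 20:
                rows.append(("chr1", g.tss + 49_900, g.tss + 50_100, 1.0))
        ps = make_peakset(rows)
        grid = di.default_grid(17)
        curve = di.infer_delta_perturbation(
            ps, layout, di.DEGeneSet("TF1", frozenset(de_ids)), grid
        )
        assert curve.delta_star >= 10_000


class TestAggregation:
    def _curve(self, stats, grid=None):
        grid = di.default_grid(len(stats)) if grid is None else grid
        return di.DecayCurve(grid, np.asarray(stats, dtype=float), "expr-linear",
                             sample_id="s")

    def test_unqualified_sample_yields_no_estimate(self):
        est = di.aggregate_tf_delta([self._curve([0.02, 0.05, 0.03])], "TF1",
                                    min_qualified=1)
        assert est.delta_star is None

    def test_mean_curve_argmax(self):
        c1 = self._curve([0.1, 0.3, 0.2, 0.05])
        c2 = self._curve([0.1, 0.2, 0.35, 0.05])
        est = di.aggregate_tf_delta([c1, c2], "TF1")
        mean_stat = (c1.statistic + c2.statistic) / 2
        assert est.delta_star == pytest.approx(c1.grid[int(np.argmax(mean_stat))])

    def test_idempotent_for_identical_curves(self):
        c = self._curve([0.05, 0.4, 0.1, 0.02])
        est = di.aggregate_tf_delta([c, c, c], "TF1")
        assert est.delta_star == c.delta_star

    def test_one_qualified_of_required_two_refuses(self):
        c1 = self._curve([0.02, 0.05, 0.03])
        c2 = self._curve([0.1, 0.4, 0.2])
        est = di.aggregate_tf_delta([c1, c2], "TF1", min_qualified=2)
        assert est.delta_star is None
        assert est.qualified_samples == ["s"]


@pytest.mark.parametrize(
    "delta,expected",
    [(1_000, "short-range"), (47_000, "long-range"), (3_000, "short-range"),
     (3_001, "long-range")],
)
def test_classify_range(delta, expected):
    assert di.classify_range(delta) == expected


class TestDeltaBySubset:
    def test_small_subset_refused(self, rng):
        layout, ps = _grid_search_setup(rng)
        from cisrange.rp_model import gene_peak_distances
        gpd = gene_peak_distances(ps, layout)
        corr = pd.Series(rng.normal(0, 0.1, len(gpd.gene_ids)), index=gpd.gene_ids)
        prof = di.CorrelationProfile("TFX", corr, 100)
        est = di.delta_by_subset(ps, layout, prof, di.default_grid(5),
                                 gpd.gene_ids[:5], "tiny")
        assert est is None

    def test_full_subset_equals_unrestricted(self, rng):
        layout, ps = _grid_search_setup(rng)
        from cisrange.rp_model import gene_peak_distances
        gpd = gene_peak_distances(ps, layout)
        corr = pd.Series(rng.normal(0, 0.1, len(gpd.gene_ids)), index=gpd.gene_ids)
        prof = di.CorrelationProfile("TFX", corr, 100)
        grid = di.default_grid(9)
        est = di.delta_by_subset(ps, layout, prof, grid, gpd.gene_ids, "all")
        unrestricted = di.delta_grid_search(ps, layout, prof, grid)
        assert est.delta_star == di.aggregate_tf_delta(
            [unrestricted], "TFX", min_qualified=1).delta_star

    def test_locality_of_disjoint_subsets(self, rng):
        # perturbing correlations outside the subset must not change the estimate
        layout, ps = _grid_search_setup(rng)
        from cisrange.rp_model import gene_peak_distances
        gpd = gene_peak_distances(ps, layout)
        ids = gpd.gene_ids
        half = ids[: len(ids) // 2]
        other = ids[len(ids) // 2:]
        corr = pd.Series(rng.normal(0, 0.1, len(ids)), index=ids)
        corr2 = corr.copy()
        corr2[other] = rng.normal(0, 0.1, len(other))
        grid = di.default_grid(9)
        c1 = di.delta_grid_search(ps, layout,
                                  di.CorrelationProfile("TFX", corr, 100),
                                  grid, gene_subset=half)
        c2 = di.delta_grid_search(ps, layout,
                                  di.CorrelationProfile("TFX", corr2, 100),
                                  grid, gene_subset=half)
        np.testing.assert_allclose(c1.statistic, c2.statistic, atol=1e-12)
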