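import numpy as np
import pandas as pd
import pytest

from cisrange import synthetic as syn
from cisrange.rp_model import DecaySpec, gene_peak_distances


@pytest.fixture(scope="module")
def genome():
    return syn.make_genome(syn.SimConfig(seed=42))


class TestMakeGenome:
    def test_deterministic(self):
        l1, ab1 = syn.make_genome(syn.SimConfig(seed=5))
        l2, ab2 = syn.make_genome(syn.SimConfig(seed=5))
        assert ab1 == ab2
        assert [(g.gene_id, g.tss) for g in l1.genes] == [
            (g.gene_id, g.tss) for g in l2.genes
        ]
        assert [(t.tad_id, t.start, t.end) for t in l1.tads] == [
            (t.tad_id, t.start, t.end) for t in l2.tads
        ]

    def test_all_genes_inside_their_tads(self, genome):
        layout, _ = genome
        assert not layout.unmapped_genes
        for g in layout.genes:
            t = layout.tad_by_id(layout.gene_to_tad[g.gene_id])
            assert t.start <= g.tss < t.end

    def test_planted_density_ratio(self):
        # B-class TADs are gene-sparse at roughly the planted A:B ratio
        ratios = []
        for seed in range(10):
            layout, ab = syn.make_genome(syn.SimConfig(seed=seed))
            per_class = {"A": [0.0, 0.0], "B": [0.0, 0.0]}  # [genes, Mb]
            for t in layout.tads:
                per_class[ab[t.tad_id]][1] += t.length / 1e6
            for g in layout.genes:
                per_class[ab[layout.gene_to_tad[g.gene_id]]][0] += 1
            ratios.append(
                (per_class["A"][0] / per_class["A"][1])
                / (per_class["B"][0] / per_class["B"][1])
            )
        planted = syn.SimConfig(seed=0).gene_density_a / syn.SimConfig(seed=0).gene_density_b
        assert planted * 0.8 <= np.mean(ratios) <= planted * 1.2

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            syn.SimConfig(seed=1, gene_density_a=0.0)


class TestMakePeaks:
    def test_deterministic(self, genome):
        layout, _ = genome
        cfg = [syn.TfSimConfig("TF1", delta_true=5_000)]
        p1 = syn.make_peaks(layout, cfg, seed=9)[0]
        p2 = syn.make_peaks(layout, cfg, seed=9)[0]
        pd.testing.assert_frame_equal(p1.peaks, p2.peaks)

    def test_displacement_scale_tracks_delta(self, genome):
        # median |peak - nearest TSS| is on the order of delta_true while
        # delta stays below the typical TSS spacing, and grows with delta
        layout, _ = genome
        tss = np.array([g.tss for g in layout.genes])
        medians = {}
        for dt in (1_000, 10_000):
            ps = syn.make_peaks(
                layout,
                [syn.TfSimConfig("TF1", delta_true=dt, n_background=0)],
                seed=3,
            )[0]
            mids = ps.representative_points()
            nearest = np.array([np.abs(tss - m).min() for m in mids])
            medians[dt] = np.median(nearest)
        assert 300 <= medians[1_000] <= 3_000
        assert medians[10_000] > medians[1_000]

    def test_concentration_factor_enriches_targets(self, genome):
        layout, _ = genome
        targets = tuple(layout.tad_ids[:5])
        ps = syn.make_peaks(
            layout,
            [syn.TfSimConfig("TF1", bound_gene_frac=0.0, n_background=20_000,
                             target_tads=targets, concentration=10.0)],
            seed=4,
        )[0]
        from cisrange.tad_occupancy import peak_density
        dens = peak_density(ps, layout)
        enriched = dens[list(targets)].mean()
        rest = dens[[t for t in layout.tad_ids if t not in targets]].mean()
        assert 7.0 <= enriched / rest <= 13.0  # ~10x within 30%


class TestMakeExpression:
    def test_planted_coupling_recovered_in_correlations(self, genome):
        from cisrange import decay_inference as di
        layout, _ = genome
        ps = syn.make_peaks(layout, [syn.TfSimConfig("TF1", delta_true=10_000)],
                            seed=5)[0]
        # tiny noise, many samples: per-gene correlations track beta*R
        expr, tf_row = syn.make_expression(
            layout, ps, 10_000, beta=0.05, sigma=0.05, n_samples=400, seed=6
        )
        norm = di.normalize_expression(expr)
        prof = di.correlation_profile(norm, tf_row)
        gpd = gene_peak_distances(ps, layout)
        rp = pd.Series(gpd.rp(DecaySpec("exponential", delta=10_000)),
                       index=gpd.gene_ids)
        joined = pd.concat([prof.corr.rename("c"), rp.rename("r")], axis=1).dropna()
        joined = joined.drop(index=tf_row, errors="ignore")
        assert joined["c"].corr(joined["r"]) > 0.9

    def test_zero_effect_gives_no_qualified_curve(self, genome):
        from cisrange import decay_inference as di
        layout, _ = genome
        ps = syn.make_peaks(layout, [syn.TfSimConfig("TF1")], seed=7)[0]
        expr, tf_row = syn.make_expression(layout, ps, 10_000, beta=0.0, seed=8)
        norm = di.normalize_expression(expr)
        prof = di.correlation_profile(norm, tf_row)
        curve = di.delta_grid_search(ps, layout, prof, di.default_grid(9))
        assert curve.stat_max < 0.1

    def test_invalid_sigma_rejected(self, genome):
        layout, _ = genome
        ps = syn.make_peaks(layout, [syn.TfSimConfig("TF1")], seed=7)[0]
        with pytest.raises(ValueError):
            syn.make_expression(layout, ps, 10_000, sigma=0.0)


class TestMakePerturbation:
    def test_table_consistent_with_thresholds(self, genome):
        from cisrange.decay_inference import derive_de_genes
        layout, _ = genome
        ps = syn.make_peaks(layout, [syn.TfSimConfig("TF1")], seed=10)[0]
        de, table = syn.make_perturbation(layout, ps, 10_000, n_de=80, seed=11)
        recovered = derive_de_genes(table, "TF1")
        assert recovered.genes == de.genes
        assert len(de.genes) == 80

    def test_de_genes_have_higher_mean_rp(self, genome):
        layout, _ = genome
        ps = syn.make_peaks(layout, [syn.TfSimConfig("TF1")], seed=10)[0]
        de, _ = syn.make_perturbation(layout, ps, 10_000, n_de=80, seed=11)
        gpd = gene_peak_distances(ps, layout)
        rp = pd.Series(gpd.rp(DecaySpec("exponential", delta=10_000)),
                       index=gpd.gene_ids)
        in_de = rp.index.isin(de.genes)
        assert rp[in_de].mean() > rp[~in_de].mean()

    def test_zero_de_rejected(self, genome):
        layout, _ = genome
        ps = syn.make_peaks(layout, [syn.TfSimConfig("TF1")], seed=10)[0]
        with pytest.raises(ValueError):
            syn.make_perturbation(layout, ps, 10_000, n_de=0)


class TestOtherGenerators:
    def test_h3k27ac_block_structure_and_determinism(self, genome):
        layout, ab = genome
        m1 = syn.make_h3k27ac(layout, ab, seed=12)
        m2 = syn.make_h3k27ac(layout, ab, seed=12)
        pd.testing.assert_frame_equal(m1, m2)
        a_mean = m1.loc[[t for t in m1.index if ab[t] == "A"]].mean().mean()
        b_mean = m1.loc[[t for t in m1.index if ab[t] == "B"]].mean().mean()
        assert a_mean > b_mean

    def test_eqtl_distances_nonnegative_and_pass_filter(self, genome):
        layout, ab = genome
        eq = syn.make_eqtls(layout, ab, seed=13)
        assert (eq["p"] <= 1e-5).all()
        assert ((eq["pos"] - eq["tss"]).abs() >= 0).all()

    def test_contacts_deterministic(self, genome):
        layout, ab = genome
        small = syn.SimConfig(seed=2, n_tads=5)
        lay, labels = syn.make_genome(small)
        c1 = syn.make_contacts(lay, labels, seed=14)
        c2 = syn.make_contacts(lay, labels, seed=14)
        pd.testing.assert_frame_equal(c1, c2)

    def test_positive_exponent_rejected(self, genome):
        layout, ab = genome
        with pytest.raises(ValueError):
            syn.make_contacts(layout, ab, exponents={"A": 0.5, "B": -0.3})

    def test_snp_count_exact_and_null_uniformish(self, genome):
        layout, ab = genome
        snps = syn.make_snps(layout, layout.tad_ids[:3], factor=10.0,
                             n_snps=137, seed=15)
        assert len(snps) == 137
        # factor 0: placement uniform over TADs (chi-square sanity check)
        null = syn.make_snps(layout, layout.tad_ids[:3], factor=0.0,
                             n_snps=5_000, seed=16)
        from cisrange.gwas_tad import snp_counts_per_tad
        counts = snp_counts_per_tad(null, layout)
        from scipy import stats
        chi, p = stats.chisquare(counts)
        assert p > 0.001

    def test_ground_truth_round_trip(self, genome):
        layout, ab = genome
        gt = syn.GroundTruth(
            syn.SimConfig(seed=42), ab_labels=ab,
            delta_true={"TF1": 10_000.0},
            target_tads={"TF1": tuple(layout.tad_ids[:2])},
        )
        frame = gt.to_frame()
        assert (frame["field"] == "ab_label").sum() == len(ab)
        assert frame.loc[frame["field"] == "delta_true", "value"].iloc[0] == 10_000.0
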