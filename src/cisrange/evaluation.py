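"""Recovery benchmarks on synthetic data with planted ground truth.

Each function simulates fresh data under the standard study conditions
(50 TADs, ~600 genes, 200 expression samples, σ = 0.5, coupling calibrated to
a peak concordance of ~0.4, 33-point geometric Δ grid), runs the inference it
exercises, and reports a recovery summary.  The functions are shared between
the test suite and the reproduction script so both measure the same thing.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import (
    decay_inference as di,
    eqtl_hic,
    gwas_tad,
    synthetic as syn,
    tad_chromatin as tc,
    tad_occupancy as to,
)
from .rp_model import DecaySpec, gene_peak_distances

GRID_POINTS = 33


def _seed(base: int, i: int) -> int:
    return int((base * 100_003 + i * 7_919) % (2**31 - 1))


def _grid_index(grid: np.ndarray, delta: float) -> int:
    return int(np.argmin(np.abs(np.log(grid) - np.log(delta))))


def _expression_curve(delta_true: float, seed: int, method: str = "linear"):
    layout, _ = syn.make_genome(syn.SimConfig(seed=seed))
    ps = syn.make_peaks(
        layout, [syn.TfSimConfig("TF1", delta_true=delta_true)], seed=_seed(seed, 1)
    )[0]
    beta = syn.calibrate_beta(layout, ps, delta_true)
    expr, tf_row = syn.make_expression(
        layout, ps, delta_true, beta=beta, n_samples=200, seed=_seed(seed, 2)
    )
    norm = di.normalize_expression(expr)
    profile = di.correlation_profile(norm, tf_row)
    grid = di.default_grid(GRID_POINTS)
    return di.delta_grid_search(ps, layout, profile, grid, method=method), grid


def delta_recovery_expression(
    delta_true: float, n_seeds: int = 20, base_seed: int = 0
) -> dict:
    """Fraction of seeds whose expression-route Δ̂ lands within one grid step."""
    grid = di.default_grid(GRID_POINTS)
    target = _grid_index(grid, delta_true)
    hits = 0
    stats_max = []
    for i in range(n_seeds):
        curve, _ = _expression_curve(delta_true, _seed(base_seed, 100 + i))
        hits += abs(curve.argmax_index - target) <= 1
        stats_max.append(curve.stat_max)
    return {
        "rate": hits / n_seeds,
        "n": n_seeds,
        "mean_max_stat": float(np.mean(stats_max)),
    }


def delta_recovery_perturbation(
    delta_true: float, n_seeds: int = 20, base_seed: int = 0, n_de: int = 100
) -> dict:
    """Fraction of seeds whose KS-argmax Δ̂ lands within one grid step."""
    grid = di.default_grid(GRID_POINTS)
    target = _grid_index(grid, delta_true)
    hits = 0
    for i in range(n_seeds):
        seed = _seed(base_seed, 200 + i)
        layout, _ = syn.make_genome(syn.SimConfig(seed=seed))
        ps = syn.make_peaks(
            layout, [syn.TfSimConfig("TF1", delta_true=delta_true)],
            seed=_seed(seed, 1),
        )[0]
        de, table = syn.make_perturbation(
            layout, ps, delta_true, n_de=n_de, seed=_seed(seed, 2)
        )
        de = di.derive_de_genes(table, "TF1")
        curve = di.infer_delta_perturbation(ps, layout, de, grid)
        hits += abs(curve.argmax_index - target) <= 1
    return {"rate": hits / n_seeds, "n": n_seeds}


def pearson_mle_identity_error(n_fixtures: int = 100, base_seed: int = 0) -> dict:
    """Max |Pearson ρ − standardized-OLS slope| over random fixtures."""
    rng = np.random.default_rng(_seed(base_seed, 300))
    worst = 0.0
    for _ in range(n_fixtures):
        n = int(rng.integers(5, 60))
        tf = rng.normal(size=n)
        gene = rng.normal(size=n)
        expr = pd.DataFrame(
            [tf, gene], index=["TF", "g"], columns=[f"s{i}" for i in range(n)]
        )
        rho = di.correlation_profile(expr, "TF").corr["g"]
        zt = (tf - tf.mean()) / tf.std()
        zg = (gene - gene.mean()) / gene.std()
        slope = float(
            np.linalg.lstsq(np.vstack([np.ones(n), zt]).T, zg, rcond=None)[0][1]
        )
        worst = max(worst, abs(rho - slope))
    return {"max_abs_error": worst, "n": n_fixtures}


def method_agreement_rate(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Linear-|ρ| and dCor Δ* agreement within one grid step."""
    agree = 0
    for i in range(n_seeds):
        seed = _seed(base_seed, 400 + i)
        c_lin, _ = _expression_curve(10_000, seed, method="linear")
        c_dcor, _ = _expression_curve(10_000, seed, method="dcor")
        agree += abs(c_lin.argmax_index - c_dcor.argmax_index) <= 1
    return {"rate": agree / n_seeds, "n": n_seeds}


def tad_type_delta_ordering_rate(
    n_seeds: int = 20, base_seed: int = 0,
    delta_a: float = 10_000.0, delta_b: float = 50_000.0,
) -> dict:
    """Recovery of Δ̂^B > Δ̂^A with class-specific planted decay distances."""
    grid = di.default_grid(GRID_POINTS)
    dbc = {"A": delta_a, "B": delta_b}
    ok = 0
    for i in range(n_seeds):
        seed = _seed(base_seed, 500 + i)
        layout, ab = syn.make_genome(syn.SimConfig(seed=seed))
        ps = syn.make_peaks(
            layout, [syn.TfSimConfig("TF1")], seed=_seed(seed, 1),
            ab_labels=ab, delta_by_class=dbc,
        )[0]
        expr, tf_row = syn.make_expression(
            layout, ps, 0.0, seed=_seed(seed, 2), ab_labels=ab, delta_by_class=dbc
        )
        norm = di.normalize_expression(expr)
        profile = di.correlation_profile(norm, tf_row)
        est = {}
        for cls in ("A", "B"):
            genes = [g for g, t in layout.gene_to_tad.items() if ab[t] == cls]
            sub = di.delta_by_subset(ps, layout, profile, grid, genes, cls)
            est[cls] = None if sub is None else sub.delta_star
        ok += est["A"] is not None and est["B"] is not None and est["B"] > est["A"]
    return {"rate": ok / n_seeds, "n": n_seeds}


def ab_recovery_ari(
    n_seeds: int = 10, base_seed: int = 0, separation: float = 5.0
) -> dict:
    """ARI of A/B-type calls (k=2 biclustering) against planted classes."""
    aris = []
    for i in range(n_seeds):
        seed = _seed(base_seed, 600 + i)
        layout, ab = syn.make_genome(syn.SimConfig(seed=seed))
        sig = syn.make_h3k27ac(
            layout, ab, n_samples=20, separation=separation, seed=_seed(seed, 1)
        )
        z = tc.sample_z_transform(sig)
        clustering = tc.bicluster(z, k=2)
        a_type, b_type = tc.call_ab_types(clustering)
        pred = ["A" if t in a_type else "B" for t in z.index]
        truth = [ab[t] for t in z.index]
        aris.append(adjusted_rand_score(truth, pred))
    return {"mean_ari": float(np.mean(aris)), "min_ari": float(np.min(aris)),
            "n": n_seeds}


def _occupancy_setup(seed: int, n_tfs: int = 20):
    layout, _ = syn.make_genome(syn.SimConfig(seed=seed))
    tf_ids = [f"TF{i:02d}" for i in range(n_tfs)]
    targets = syn.partition_target_tads(layout, tf_ids, seed=_seed(seed, 1))
    cfgs = [
        syn.TfSimConfig(tf, bound_gene_frac=0.0, n_background=1_000,
                        target_tads=targets[tf], concentration=10.0)
        for tf in tf_ids
    ]
    peaksets = syn.make_peaks(layout, cfgs, seed=_seed(seed, 2))
    return layout, tf_ids, targets, peaksets


def target_tad_precision_recall(base_seed: int = 0, n_seeds: int = 5) -> dict:
    """Precision/recall of z ≥ 1 target-TAD calls on 10×-concentrated TADs."""
    precs, recs = [], []
    for i in range(n_seeds):
        seed = _seed(base_seed, 700 + i)
        layout, tf_ids, targets, peaksets = _occupancy_setup(seed)
        z = to.tad_zscores(to.density_matrix(peaksets, layout))
        for ps in peaksets:
            called = to.call_target_tads(z, ps.sample_id)
            true = set(targets[ps.tf_id])
            tp = len(called & true)
            precs.append(tp / len(called) if called else 0.0)
            recs.append(tp / len(true))
    return {"precision": float(np.mean(precs)), "recall": float(np.mean(recs)),
            "n": n_seeds * 20}


def eqtl_contrast_rates(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Detection of the planted A/B distance shift and null rejection rate."""
    detected = 0
    for i in range(n_seeds):
        seed = _seed(base_seed, 800 + i)
        layout, ab = syn.make_genome(syn.SimConfig(seed=seed))
        eq = eqtl_hic.filter_eqtls(syn.make_eqtls(layout, ab, seed=_seed(seed, 1)))
        res = eqtl_hic.compare_distances_ab(
            eq, layout.gene_to_tad,
            [t for t, v in ab.items() if v == "A"],
            [t for t, v in ab.items() if v == "B"],
        )
        detected += (res.p < 0.01) and (res.median1 > res.median2)
    null_rejected = 0
    n_null = 2 * n_seeds
    for i in range(n_null):
        seed = _seed(base_seed, 850 + i)
        layout, ab = syn.make_genome(syn.SimConfig(seed=seed))
        eq = eqtl_hic.filter_eqtls(
            syn.make_eqtls(layout, ab, mu_by_class={"A": 4.0, "B": 4.0},
                           seed=_seed(seed, 1))
        )
        res = eqtl_hic.compare_distances_ab(
            eq, layout.gene_to_tad,
            [t for t, v in ab.items() if v == "A"],
            [t for t, v in ab.items() if v == "B"],
        )
        null_rejected += res.p < 0.05
    return {
        "detection_rate": detected / n_seeds,
        "null_rejection_rate": null_rejected / n_null,
        "n": n_seeds,
    }


def hic_exponent_recovery(
    n_seeds: int = 20, base_seed: int = 0,
    exponents: Mapping[str, float] = {"A": -0.45, "B": -0.35},
) -> dict:
    """Power-law exponent error and planted A/B ordering recovery."""
    errors = []
    ordered = 0
    for i in range(n_seeds):
        seed = _seed(base_seed, 900 + i)
        layout, ab = syn.make_genome(syn.SimConfig(seed=seed, n_tads=20))
        contacts = syn.make_contacts(layout, ab, exponents=dict(exponents),
                                     seed=_seed(seed, 1))
        lam = {}
        for cls in ("A", "B"):
            curve = eqtl_hic.contact_curve(
                contacts, layout.tads, bin_size=10_000,
                tad_set=[t for t, v in ab.items() if v == cls], label=cls,
            )
            lam[cls], _ = eqtl_hic.fit_powerlaw(curve, d_range=(10_000, 300_000))
        errors.append(abs(lam["A"] - exponents["A"]))
        errors.append(abs(lam["B"] - exponents["B"]))
        ordered += lam["A"] < lam["B"]
    return {
        "max_abs_error": float(np.max(errors)),
        "mean_abs_error": float(np.mean(errors)),
        "ordering_rate": ordered / n_seeds,
        "n": n_seeds,
    }


def gwas_prioritization(
    n_seeds: int = 20, base_seed: int = 0, n_perm: int = 10_000
) -> dict:
    """Rank and permutation significance of the SNP-enriched TF, plus a
    null-calibration KS check of p-value uniformity."""
    top_rank = 0
    significant = 0
    null_ps: list[float] = []
    for i in range(n_seeds):
        seed = _seed(base_seed, 1_000 + i)
        layout, tf_ids, targets, peaksets = _occupancy_setup(seed)
        abundance = gwas_tad.abundance_matrix(peaksets, layout)
        snps = syn.make_snps(layout, targets[tf_ids[0]], factor=10.0,
                             n_snps=200, seed=_seed(seed, 3))
        counts = gwas_tad.snp_counts_per_tad(snps, layout)
        res = gwas_tad.permutation_significance(
            counts, abundance, n_perm=n_perm, seed=_seed(seed, 4)
        )
        top_rank += res.table["cosine"].idxmax() == tf_ids[0]
        significant += res.table.loc[tf_ids[0], "p"] < 0.001
        # null: SNPs placed uniformly
        null_snps = syn.make_snps(layout, targets[tf_ids[0]], factor=0.0,
                                  n_snps=200, seed=_seed(seed, 5))
        null_counts = gwas_tad.snp_counts_per_tad(null_snps, layout)
        null_res = gwas_tad.permutation_significance(
            null_counts, abundance, n_perm=max(500, n_perm // 10),
            seed=_seed(seed, 6),
        )
        null_ps.extend(null_res.table["p"].tolist())
    ks_p = float(stats.kstest(null_ps, "uniform").pvalue)
    return {
        "top_rank_rate": top_rank / n_seeds,
        "significant_rate": significant / n_seeds,
        "null_uniform_ks_p": ks_p,
        "null_mean_p": float(np.mean(null_ps)),
        "n": n_seeds,
    }


def oracle_equivalence(base_seed: int = 0) -> dict:
    """Max discrepancy between vectorized implementations and brute-force
    references (RP matrix, cosine score, KS statistic, dCor, contact curve)."""
    rng = np.random.default_rng(_seed(base_seed, 1_100))
    out = {}

    # RP matrix vs double loop
    layout, _ = syn.make_genome(syn.SimConfig(seed=_seed(base_seed, 1_101), n_tads=10))
    ps = syn.make_peaks(layout, [syn.TfSimConfig("TF1")], seed=_seed(base_seed, 1_102))[0]
    gpd = gene_peak_distances(ps, layout)
    rp = gpd.rp(DecaySpec("exponential", delta=25_000))
    mids = ps.representative_points()
    chroms = ps.peaks["chrom"].to_numpy()
    worst = 0.0
    for gi, g in enumerate(layout.mapped_genes()):
        expect = 0.0
        g_tad = layout.gene_to_tad[g.gene_id]
        for pos, chrom in zip(mids, chroms):
            if layout.tad_of_point(chrom, int(pos)) == g_tad:
                expect += 2.0 ** (-abs(int(pos) - g.tss) / 25_000)
        worst = max(worst, abs(rp[gi] - expect))
    out["rp_max_abs_diff"] = worst

    # cosine vs explicit summation
    s = rng.integers(0, 20, size=50).astype(float)
    a = rng.random(50) + 0.01
    _, cos = gwas_tad.trait_tf_score(s, a)
    num = sum(s[i] * a[i] for i in range(50))
    den = np.sqrt(sum(v * v for v in s)) * np.sqrt(sum(v * v for v in a))
    out["cosine_abs_diff"] = abs(cos - num / den)

    # KS vs brute-force ECDF sup
    de_vals = rng.random(50)
    other = rng.random(500)
    scores = pd.Series(
        np.concatenate([de_vals, other]),
        index=[f"d{i}" for i in range(50)] + [f"o{i}" for i in range(500)],
    )
    de = di.DEGeneSet("TF1", frozenset(f"d{i}" for i in range(50)))
    ks, _ = di.ks_separation(scores, de)
    pooled = np.concatenate([de_vals, other])
    sup = max(abs((de_vals <= x).mean() - (other <= x).mean()) for x in pooled)
    out["ks_abs_diff"] = abs(ks - sup)

    # dCor vs explicit double centering
    x = rng.normal(size=20)
    y = 0.5 * x + rng.normal(size=20)
    got = di.distance_correlation(x, y)
    n = 20
    amat = np.abs(x[:, None] - x[None, :])
    bmat = np.abs(y[:, None] - y[None, :])
    A = np.empty((n, n))
    B = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = amat[i, j] - amat[i].mean() - amat[:, j].mean() + amat.mean()
            B[i, j] = bmat[i, j] - bmat[i].mean() - bmat[:, j].mean() + bmat.mean()
    expect = np.sqrt((A * B).mean() / np.sqrt((A * A).mean() * (B * B).mean()))
    out["dcor_abs_diff"] = abs(got - expect)

    # contact curve vs pair enumeration
    small, labels = syn.make_genome(syn.SimConfig(seed=_seed(base_seed, 1_103), n_tads=4))
    contacts = syn.make_contacts(small, labels, seed=_seed(base_seed, 1_104))
    curve = eqtl_hic.contact_curve(contacts, small.tads, bin_size=10_000)
    obs = {
        (r.bin1_start, r.bin2_start): r.count for r in contacts.itertuples(index=False)
    }
    worst = 0.0
    for d, f in zip(curve.distances, curve.frequency):
        sep = int(d) // 10_000
        num = 0.0
        den = 0
        for t in small.tads:
            nb = t.length // 10_000
            for i in range(nb - sep):
                den += 1
                num += obs.get((t.start + 10_000 * i, t.start + 10_000 * (i + sep)), 0)
        worst = max(worst, abs(f - num / den))
    out["contact_curve_abs_diff"] = worst
    return out
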