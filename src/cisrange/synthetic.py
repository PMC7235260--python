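"""Synthetic-data generators with planted ground truth.

Every generator is a pure function of its arguments and a seed, emitting the
same in-memory containers (and, through ``genome_io`` writers, the same file
formats) the analysis consumes.  The planted structure mirrors the signals
the method is designed to detect:

* a genome of non-overlapping TADs carrying A-type (gene-dense, active) and
  B-type (gene-sparse, repressed) classes;
* TF peak sets whose TSS displacements follow a two-sided exponential with
  scale Δ_true/ln 2, so the planted kernel matches the exponential RP kernel
  2^(−x/Δ) exactly; background peaks can be concentrated k-fold in designated
  target TADs;
* expression cohorts where each gene's coupling to the TF equals
  β·R(Δ_true), the linear structure the cohort route assumes;
* perturbation DE sets sampled with probability proportional to R(Δ_true);
* H3K27ac with planted A/B block structure, lognormal eQTL–TSS distances
  with class-specific scale, power-law Hi-C contacts with class-specific
  exponents, and trait SNP sets enriched in one TF's target TADs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .decay_inference import DEGeneSet
from .genome_io import Gene, GenomeLayout, PeakSet, Tad
from .rp_model import DecaySpec, gene_peak_distances

LN2 = math.log(2.0)


@dataclass
class SimConfig:
    """Genome-level simulation parameters (study-condition defaults)."""

    seed: int
    n_tads: int = 50
    tad_length_median: int = 700_000
    tad_length_log_sd: float = 0.25
    tad_gap: int = 100_000
    frac_a: float = 0.5
    gene_density_a: float = 25.0  # genes / Mb in A-type TADs
    gene_density_b: float = 10.0  # genes / Mb in B-type TADs

    def __post_init__(self) -> None:
        if self.n_tads <= 0 or self.gene_density_a <= 0 or self.gene_density_b <= 0:
            raise ValueError("counts and densities must be positive")


@dataclass
class TfSimConfig:
    """Per-TF peak-placement parameters."""

    tf_id: str
    delta_true: float = 10_000.0
    sample_id: str | None = None
    bound_gene_frac: float = 0.7
    peaks_per_gene_mean: float = 2.0  # 1 + Poisson(mean) peaks per bound gene
    n_background: int = 500
    target_tads: tuple[str, ...] = ()
    concentration: float = 1.0


@dataclass
class GroundTruth:
    """Planted parameters recorded alongside every synthetic dataset."""

    config: SimConfig
    ab_labels: dict[str, str] = field(default_factory=dict)
    delta_true: dict[str, float] = field(default_factory=dict)
    target_tads: dict[str, tuple[str, ...]] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("seed", "", self.config.seed)]
        rows += [("ab_label", k, v) for k, v in self.ab_labels.items()]
        rows += [("delta_true", k, v) for k, v in self.delta_true.items()]
        rows += [("target_tads", k, ";".join(v)) for k, v in self.target_tads.items()]
        rows += [("extra", k, v) for k, v in self.extras.items()]
        return pd.DataFrame(rows, columns=["field", "key", "value"])


def make_genome(config: SimConfig) -> tuple[GenomeLayout, dict[str, str]]:
    """Synthetic chromosome of non-overlapping TADs with planted A/B classes.

    Gene counts per TAD are Poisson at the class density; gene positions are
    uniform within the TAD.  Deterministic given the config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    tads: list[Tad] = []
    ab: dict[str, str] = {}
    genes: list[Gene] = []
    pos = 0
    mu = math.log(config.tad_length_median)
    for i in range(config.n_tads):
        length = int(rng.lognormal(mu, config.tad_length_log_sd))
        length = max(length, 100_000)
        tad_id = f"tad{i:03d}"
        tads.append(Tad(tad_id, "chr1", pos, pos + length))
        label = "A" if rng.random() < config.frac_a else "B"
        ab[tad_id] = label
        density = config.gene_density_a if label == "A" else config.gene_density_b
        n_genes = rng.poisson(density * length / 1e6)
        for j in range(n_genes):
            tss = int(rng.integers(pos, pos + length))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(f"g_{i:03d}_{j:03d}", "chr1", tss, strand))
        pos += length + config.tad_gap
    if not genes:
        raise ValueError("gene densities too low: simulated genome has no genes")
    genes.sort(key=lambda g: g.tss)
    return GenomeLayout(genes=genes, tads=tads), ab


def make_peaks(
    layout: GenomeLayout,
    tf_configs: Sequence[TfSimConfig],
    seed: int,
    ab_labels: Mapping[str, str] | None = None,
    delta_by_class: Mapping[str, float] | None = None,
) -> list[PeakSet]:
    """TF peak sets: TSS-anchored peaks with two-sided-exponential
    displacement of scale Δ_true/ln 2 plus uniform background peaks,
    optionally concentrated ``concentration``-fold in target TADs.

    With ``delta_by_class`` (and the TAD class labels), the displacement
    scale around a gene follows the Δ planted for that gene's TAD class —
    the construction behind TAD-type-specific decay distances.
    """
    rng = np.random.default_rng(seed)
    out: list[PeakSet] = []
    tad_list = layout.tads
    lengths = np.array([t.length for t in tad_list], dtype=float)
    for cfg in tf_configs:
        rows: list[tuple[str, int, int, float]] = []
        # signal peaks around TSSs
        for g in layout.mapped_genes():
            if rng.random() > cfg.bound_gene_frac:
                continue
            if delta_by_class is not None:
                if ab_labels is None:
                    raise ValueError("delta_by_class requires ab_labels")
                delta_g = delta_by_class[ab_labels[layout.gene_to_tad[g.gene_id]]]
            else:
                delta_g = cfg.delta_true
            n_k = 1 + rng.poisson(cfg.peaks_per_gene_mean)
            disp = rng.laplace(0.0, delta_g / LN2, size=n_k)
            for d in disp:
                center = int(g.tss + d)
                if center < 0:
                    continue
                rows.append(("chr1", center - 100, center + 100, float(rng.gamma(2.0, 2.0))))
        # background peaks, weighted by TAD length and target concentration
        weights = lengths.copy()
        target = set(cfg.target_tads)
        for i, t in enumerate(tad_list):
            if t.tad_id in target:
                weights[i] *= cfg.concentration
        weights /= weights.sum()
        choices = rng.choice(len(tad_list), size=cfg.n_background, p=weights)
        for idx in choices:
            t = tad_list[idx]
            center = int(rng.integers(t.start, t.end))
            rows.append(("chr1", center - 100, center + 100, float(rng.gamma(2.0, 2.0))))
        peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "intensity"])
        peaks["start"] = peaks["start"].clip(lower=0)
        sample = cfg.sample_id or f"{cfg.tf_id}_s1"
        out.append(PeakSet(cfg.tf_id, sample, peaks))
    return out


def _rp_at_truth(
    layout: GenomeLayout, peakset: PeakSet, delta_true: float
) -> pd.Series:
    gpd = gene_peak_distances(peakset, layout)
    return pd.Series(
        gpd.rp(DecaySpec("exponential", delta=delta_true)), index=gpd.gene_ids
    )

# Default effect size: at the default cohort scale (50 TADs, ~600 genes,
# 200 samples, sigma=0.5, delta_true=10 kb) the planted concordance curve
# peaks near |rho|=0.4, the moderate coupling the study conditions assume.
DEFAULT_BETA = 0.009
DEFAULT_SIGMA = 0.5
EXPR_LOG_OFFSET = 5.0
TARGET_CONCORDANCE = 0.4


def calibrate_beta(
    layout: GenomeLayout,
    peakset: PeakSet,
    delta_true: float,
    target_rho: float = TARGET_CONCORDANCE,
    sigma: float = DEFAULT_SIGMA,
    n_samples: int = 200,
) -> float:
    """Effect size β giving a planted concordance peak of ≈ ``target_rho``.

    The peak concordance between estimated correlations γ̂ and R(Δ_true) is
    approximately s/√(s² + σ_e²), where s = (β/σ)·sd(R) is the spread of
    true correlations across genes and σ_e ≈ 1/√(n−1) is the sampling noise
    of a per-gene correlation.  Inverting gives the β whose concordance
    ceiling is the target.  Deterministic given the inputs — no simulation.
    """
    if not (0 < target_rho < 1):
        raise ValueError("target_rho must lie in (0, 1)")
    rp = _rp_at_truth(layout, peakset, delta_true)
    sd_r = float(rp.to_numpy().std())
    if sd_r == 0:
        raise ValueError("RP scores are constant; cannot plant a coupling")
    sigma_e = 1.0 / math.sqrt(n_samples - 1)
    s_needed = sigma_e * target_rho / math.sqrt(1.0 - target_rho**2)
    return s_needed * sigma / sd_r


def make_expression(
    layout: GenomeLayout,
    peakset: PeakSet,
    delta_true: float,
    beta: float = DEFAULT_BETA,
    sigma: float = DEFAULT_SIGMA,
    n_samples: int = 200,
    seed: int = 0,
    ab_labels: Mapping[str, str] | None = None,
    delta_by_class: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, str]:
    """Expression cohort with planted coupling γ_j = β·R_j(Δ_true).

    Latent standardized expression of gene j in sample k is
    γ_j·E_k + ε, ε ~ N(0, σ²), with TF expression E ~ N(0,1).  The matrix is
    emitted on a positive RPKM-like scale via the fixed monotone transform
    x = 2^(z + offset) − 1 so the log-quantile-center normalization path is
    exercised end to end.  With ``delta_by_class`` the planted coupling of a
    gene uses the Δ of its TAD class.  Returns (matrix, tf row name).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    if delta_by_class is not None:
        if ab_labels is None:
            raise ValueError("delta_by_class requires ab_labels")
        rp_by_class = {
            cls: _rp_at_truth(layout, peakset, d) for cls, d in delta_by_class.items()
        }
        any_rp = next(iter(rp_by_class.values()))
        cls_of = pd.Series(
            [ab_labels[layout.gene_to_tad[g]] for g in any_rp.index],
            index=any_rp.index,
        )
        rp = pd.Series(
            [rp_by_class[cls_of[g]][g] for g in any_rp.index], index=any_rp.index
        )
    else:
        rp = _rp_at_truth(layout, peakset, delta_true)
    gamma = beta * rp.to_numpy()
    e_tf = rng.standard_normal(n_samples)
    noise = rng.normal(0.0, sigma, size=(len(gamma), n_samples))
    z = gamma[:, None] * e_tf[None, :] + noise
    tf_row_name = f"TF_{peakset.tf_id}"
    z_full = np.vstack([e_tf[None, :], z])
    index = [tf_row_name] + list(rp.index)
    raw = np.exp2(z_full + EXPR_LOG_OFFSET) - 1.0
    cols = [f"s{k:03d}" for k in range(n_samples)]
    return pd.DataFrame(raw, index=index, columns=cols), tf_row_name


DE_RESPONSE_NOISE_SD = 0.5


def make_perturbation(
    layout: GenomeLayout,
    peakset: PeakSet,
    delta_true: float,
    n_de: int = 100,
    seed: int = 0,
    mode: str = "threshold",
    response_noise_sd: float = DE_RESPONSE_NOISE_SD,
) -> tuple[DEGeneSet, pd.DataFrame]:
    """Perturbation experiment with planted DE genes driven by R(Δ_true).

    ``mode="threshold"`` (default) models what a knockdown experiment
    realizes: each gene's response magnitude is R(Δ_true) times a
    multiplicative lognormal measurement/biology noise term, and the DE set
    is the ``n_de`` strongest responders — the genes that would clear a fold
    change threshold.  ``mode="proportional"`` instead samples the DE set
    with probability proportional to R(Δ_true), a softer construction.

    Emits a (gene, log2FC, p) table consistent with the DE thresholds
    |log2FC| > 1, p < 0.01 for the planted DE genes and sub-threshold values
    for the rest.
    """
    if n_de <= 0:
        raise ValueError("n_de must be positive")
    rng = np.random.default_rng(seed)
    rp = _rp_at_truth(layout, peakset, delta_true)
    weights = rp.to_numpy(dtype=float)
    positive = weights > 0
    if n_de > positive.sum():
        raise ValueError("n_de exceeds the number of genes with positive RP")
    if mode == "threshold":
        response = weights * rng.lognormal(0.0, response_noise_sd, size=len(weights))
        de_idx = np.argsort(response)[-n_de:]
    elif mode == "proportional":
        p_sel = weights / weights.sum()
        de_idx = rng.choice(len(weights), size=n_de, replace=False, p=p_sel)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    de_genes = frozenset(rp.index[de_idx])
    rows = []
    for g in rp.index:
        if g in de_genes:
            lfc = (1.2 + rng.exponential(0.8)) * (1 if rng.random() < 0.5 else -1)
            p = 10.0 ** (-rng.uniform(3.0, 8.0))
        else:
            lfc = float(np.clip(rng.normal(0.0, 0.3), -0.95, 0.95))
            p = float(rng.uniform(0.02, 1.0))
        rows.append((g, lfc, p))
    table = pd.DataFrame(rows, columns=["gene", "log2FC", "p"])
    return DEGeneSet(peakset.tf_id, de_genes), table


def make_h3k27ac(
    layout: GenomeLayout,
    ab_labels: Mapping[str, str],
    n_samples: int = 20,
    separation: float = 5.0,
    noise_sd: float = 1.0,
    sample_effect_sd: float = 0.3,
    baseline: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """TAD × sample H3K27ac signal with planted A/B block structure.

    signal = baseline + class effect + sample effect + noise, with the A−B
    class-mean separation equal to ``separation`` noise standard deviations.
    """
    rng = np.random.default_rng(seed)
    tad_ids = layout.tad_ids
    class_shift = np.array(
        [separation * noise_sd / 2 * (1 if ab_labels[t] == "A" else -1) for t in tad_ids]
    )
    sample_effect = rng.normal(0.0, sample_effect_sd, size=n_samples)
    noise = rng.normal(0.0, noise_sd, size=(len(tad_ids), n_samples))
    x = baseline + class_shift[:, None] + sample_effect[None, :] + noise
    cols = [f"h3k27ac_{k:03d}" for k in range(n_samples)]
    return pd.DataFrame(x, index=tad_ids, columns=cols)


def make_eqtls(
    layout: GenomeLayout,
    ab_labels: Mapping[str, str],
    mu_by_class: Mapping[str, float] = {"A": 4.0, "B": 4.5},
    sigma_log10: float = 1.0,
    n_per_class: int = 500,
    tissue: str = "tissue1",
    seed: int = 0,
) -> pd.DataFrame:
    """eQTL table with class-specific log10-normal variant–TSS distances.

    All emitted p-values pass the p ≤ 1e−5 filter.
    """
    rng = np.random.default_rng(seed)
    genes_by_class: dict[str, list[Gene]] = {"A": [], "B": []}
    for g in layout.mapped_genes():
        genes_by_class[ab_labels[layout.gene_to_tad[g.gene_id]]].append(g)
    rows = []
    for cls, mu in mu_by_class.items():
        pool = genes_by_class[cls]
        if not pool:
            raise ValueError(f"no mapped genes in class {cls}")
        idx = rng.integers(0, len(pool), size=n_per_class)
        dist = 10.0 ** rng.normal(mu, sigma_log10, size=n_per_class)
        signs = rng.choice([-1, 1], size=n_per_class)
        for i, d, s in zip(idx, dist, signs):
            g = pool[i]
            pos = max(0, int(g.tss + s * d))
            rows.append(
                (g.chrom, pos, g.gene_id, g.tss, 10.0 ** (-rng.uniform(5.0, 12.0)), tissue)
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "gene_id", "tss", "p", "tissue"]
    )


def make_contacts(
    layout: GenomeLayout,
    ab_labels: Mapping[str, str],
    exponents: Mapping[str, float] = {"A": -0.45, "B": -0.35},
    bin_size: int = 10_000,
    depth: float = 100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Intra-TAD binned contacts with Poisson counts of mean depth·sep^λ,
    λ class-specific.  Zero-count pairs are omitted from the table (they
    still count in the contact-curve denominator)."""
    for lam in exponents.values():
        if lam >= 0:
            raise ValueError("contact exponents must be negative")
    rng = np.random.default_rng(seed)
    rows = []
    for t in layout.tads:
        lam = exponents[ab_labels[t.tad_id]]
        n_bins = t.length // bin_size
        starts = t.start + bin_size * np.arange(n_bins)
        for sep in range(1, n_bins):
            mean = depth * sep**lam
            counts = rng.poisson(mean, size=n_bins - sep)
            for i, c in enumerate(counts):
                if c > 0:
                    rows.append((t.chrom, int(starts[i]), int(starts[i + sep]), int(c)))
    return pd.DataFrame(rows, columns=["chrom", "bin1_start", "bin2_start", "count"])


def make_snps(
    layout: GenomeLayout,
    target_tads: Sequence[str],
    factor: float = 10.0,
    n_snps: int = 200,
    trait: str = "trait1",
    seed: int = 0,
) -> pd.DataFrame:
    """Trait SNPs placed in TADs with probability ∝ (1 + factor·1[target])."""
    rng = np.random.default_rng(seed)
    target = set(target_tads)
    weights = np.array(
        [1.0 + (factor if t.tad_id in target else 0.0) for t in layout.tads]
    )
    weights /= weights.sum()
    choices = rng.choice(len(layout.tads), size=n_snps, p=weights)
    rows = []
    for idx in choices:
        t = layout.tads[idx]
        rows.append((trait, t.chrom, int(rng.integers(t.start, t.end))))
    return pd.DataFrame(rows, columns=["trait", "chrom", "pos"])


def partition_target_tads(
    layout: GenomeLayout, tf_ids: Sequence[str], seed: int
) -> dict[str, tuple[str, ...]]:
    """Assign every TAD to exactly one TF as a target (random partition).

    Mirrors the observed structure in which most TADs are preferentially
    occupied by some TF, which keeps per-TAD z-scores interpretable.
    """
    rng = np.random.default_rng(seed)
    tad_ids = list(layout.tad_ids)
    rng.shuffle(tad_ids)
    out: dict[str, list[str]] = {tf: [] for tf in tf_ids}
    for i, tid in enumerate(tad_ids):
        out[tf_ids[i % len(tf_ids)]].append(tid)
    return {tf: tuple(sorted(v)) for tf, v in out.items()}
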