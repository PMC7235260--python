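"""Inference of TF-specific regulatory decay distances Δ*.

Two routes estimate how far a TF's binding sites act:

* **Perturbation route** — genes differentially expressed (DE) after
  perturbing the TF are taken as direct targets.  For each candidate Δ the
  two-sample Kolmogorov–Smirnov statistic measures how well RP(Δ) separates
  DE genes from the rest; Δ* is the grid argmax.

* **Expression-cohort route** — the Pearson correlation γ̂_ij between TF and
  gene expression across samples estimates the TF's regulatory effect on each
  gene (it is the MLE of the slope in a standardized linear model).  For each
  Δ, the concordance between γ̂_i· and the RP column R_i·(Δ) is scored either
  by |Pearson ρ| (equivalent to maximizing the profile likelihood / ρ²) or by
  distance correlation (dCor), and Δ* is the grid argmax.

Multi-sample aggregation follows a qualification rule: a ChIP-seq sample
qualifies if its concordance curve exceeds 0.1 anywhere; with at least two
qualified samples the curves are averaged pointwise and Δ* is the argmax of
the mean curve, provided the mean maximum also exceeds 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomeLayout, PeakSet
from .rp_model import DecaySpec, GenePeakDistances, gene_peak_distances

logger = logging.getLogger(__name__)

GRID_MIN_BP = 100
GRID_MAX_BP = 4_000_000
DEFAULT_GRID_POINTS = 33
SHORT_RANGE_MAX_BP = 3_000
QUALIFICATION_THRESHOLD = 0.1
MIN_QUALIFIED_SAMPLES = 2
DE_LFC_THRESHOLD = 1.0
DE_P_THRESHOLD = 0.01
SUBSET_GENE_FLOOR = 30


def default_grid(n_points: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    """Geometric Δ grid from 100 bp to 4000 kb inclusive."""
    if n_points < 2:
        raise ValueError("grid needs at least 2 points")
    return np.geomspace(GRID_MIN_BP, GRID_MAX_BP, n_points)


@dataclass
class DEGeneSet:
    tf_id: str
    genes: frozenset[str]
    direction: str | None = None
    lfc_threshold: float = DE_LFC_THRESHOLD
    p_threshold: float = DE_P_THRESHOLD


def derive_de_genes(
    table: pd.DataFrame,
    tf_id: str,
    lfc_threshold: float = DE_LFC_THRESHOLD,
    p_threshold: float = DE_P_THRESHOLD,
    direction: Literal["up", "down"] | None = None,
) -> DEGeneSet:
    """DE genes from a perturbation table (gene, log2FC, p).

    Strict inequalities: |log2FC| > 1 and p < 0.01 by default; an optional
    direction filter keeps only up- or down-regulated genes.
    """
    required = {"gene", "log2FC", "p"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"perturbation table missing columns: {sorted(missing)}")
    mask = (table["log2FC"].abs() > lfc_threshold) & (table["p"] < p_threshold)
    if direction == "up":
        mask &= table["log2FC"] > 0
    elif direction == "down":
        mask &= table["log2FC"] < 0
    genes = frozenset(table.loc[mask, "gene"].astype(str))
    if not genes:
        raise ValueError(
            "no genes pass the DE thresholds; review |log2FC| and p cutoffs"
        )
    return DEGeneSet(tf_id, genes, direction, lfc_threshold, p_threshold)


def ks_separation(
    rp_scores: pd.Series, de: DEGeneSet, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Two-sample KS statistic between DE genes' RP scores and all others'."""
    de_mask = rp_scores.index.isin(de.genes)
    de_scores = rp_scores[de_mask].to_numpy()
    other = rp_scores[~de_mask].to_numpy()
    if len(de_scores) == 0 or len(other) == 0:
        raise ValueError("both DE and non-DE groups must be non-empty")
    res = stats.ks_2samp(de_scores, other, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DecayCurve:
    """Concordance (or separation) statistic as a function of Δ over a grid."""

    grid: np.ndarray
    statistic: np.ndarray
    method: str
    sample_id: str | None = None
    pvalues: np.ndarray | None = None
    fits: pd.DataFrame | None = None  # per-Δ alpha/beta/sigma2 for the linear model
    signs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.statistic):
            raise ValueError("grid and statistic length mismatch")
        if not np.all(np.isfinite(self.statistic)):
            raise ValueError("statistic must be finite at every grid point")

    @property
    def argmax_index(self) -> int:
        # first maximum → smallest Δ on an ascending grid (tie-break)
        return int(np.argmax(self.statistic))

    @property
    def delta_star(self) -> float:
        return float(self.grid[self.argmax_index])

    @property
    def stat_max(self) -> float:
        return float(self.statistic[self.argmax_index])


def infer_delta_perturbation(
    peakset: PeakSet,
    layout: GenomeLayout,
    de: DEGeneSet,
    grid: np.ndarray,
) -> DecayCurve:
    """Δ* as the grid argmax of the KS separation of DE genes by RP(Δ)."""
    if len(grid) < 2:
        raise ValueError("grid needs at least 2 points")
    gpd = gene_peak_distances(peakset, layout)
    scored = pd.Index(gpd.gene_ids)
    ks_stats = np.empty(len(grid))
    ks_ps = np.empty(len(grid))
    for i, delta in enumerate(grid):
        rp = pd.Series(gpd.rp(DecaySpec("exponential", delta=delta)), index=scored)
        ks_stats[i], ks_ps[i] = ks_separation(rp, de)
    return DecayCurve(
        np.asarray(grid, dtype=float), ks_stats, "perturb-ks",
        sample_id=peakset.sample_id, pvalues=ks_ps,
    )


# --- expression-cohort route -------------------------------------------------


def normalize_expression(raw: pd.DataFrame) -> pd.DataFrame:
    """log2(x+1) → quantile normalization across samples → gene-wise centering.

    Quantile normalization maps every sample onto the pooled reference of
    column-wise sorted means, so all samples share one value distribution.
    """
    if raw.shape[1] < 2:
        raise ValueError("need at least 2 samples to normalize")
    if (raw.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative (RPKM-like)")
    logged = np.log2(raw.to_numpy(dtype=float) + 1.0)
    n = logged.shape[0]
    reference = np.sort(logged, axis=0).mean(axis=1)
    out = np.empty_like(logged)
    positions = np.arange(1, n + 1)
    for j in range(logged.shape[1]):
        ranks = stats.rankdata(logged[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    out -= out.mean(axis=1, keepdims=True)
    df = pd.DataFrame(out, index=raw.index, columns=raw.columns)
    df.attrs["normalization"] = "log-quantile-centered"
    return df


@dataclass
class CorrelationProfile:
    """Per-gene γ̂_ij: Pearson correlation of TF expression with each gene."""

    tf_gene: str
    corr: pd.Series  # NaN where a gene row has zero variance
    n_samples: int


def correlation_profile(expr: pd.DataFrame, tf_gene: str) -> CorrelationProfile:
    if tf_gene not in expr.index:
        raise KeyError(f"TF gene {tf_gene!r} not in expression matrix")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = expr.to_numpy(dtype=float)
    tf_row = x[expr.index.get_loc(tf_gene)]
    tf_c = tf_row - tf_row.mean()
    tf_ss = float(tf_c @ tf_c)
    if tf_ss == 0.0:
        raise ValueError(f"TF row {tf_gene!r} is constant")
    centered = x - x.mean(axis=1, keepdims=True)
    gene_ss = (centered**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centered @ tf_c) / np.sqrt(gene_ss * tf_ss)
    corr[gene_ss == 0.0] = np.nan
    return CorrelationProfile(
        tf_gene, pd.Series(corr, index=expr.index), expr.shape[1]
    )


@dataclass(frozen=True)
class LinearConcordance:
    rho: float
    alpha: float
    beta: float
    sigma2: float
    n: int


def concordance_linear(gamma: np.ndarray, rp: np.ndarray) -> LinearConcordance:
    """Pearson ρ between γ̂ and R(Δ) plus the closed-form OLS/MLE fit
    γ̂ = α + β·R + ε (σ̂² is the 1/n maximum-likelihood residual variance)."""
    gamma = np.asarray(gamma, dtype=float)
    rp = np.asarray(rp, dtype=float)
    ok = np.isfinite(gamma) & np.isfinite(rp)
    gamma, rp = gamma[ok], rp[ok]
    n = len(gamma)
    if n < 3:
        raise ValueError("need at least 3 genes with both values present")
    gc = gamma - gamma.mean()
    rc = rp - rp.mean()
    sgg = float(gc @ gc)
    srr = float(rc @ rc)
    if sgg == 0.0 or srr == 0.0:
        raise ValueError("zero variance in gamma or RP vector")
    sgr = float(gc @ rc)
    rho = sgr / np.sqrt(sgg * srr)
    beta = sgr / srr
    alpha = float(gamma.mean() - beta * rp.mean())
    resid = gamma - alpha - beta * rp
    sigma2 = float(resid @ resid) / n
    return LinearConcordance(float(rho), alpha, float(beta), sigma2, n)


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample distance correlation (dCor) of two 1-D samples.

    Zero iff the variables are independent (in the population version);
    computed from double-centered pairwise-distance matrices.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("length mismatch")
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    dcov2 = (A * B).mean()
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    denom = np.sqrt(dvar_x * dvar_y)
    if denom == 0.0:
        raise ValueError("zero distance variance")
    return float(np.sqrt(max(dcov2, 0.0) / denom))


def concordance_dcor(gamma: np.ndarray, rp: np.ndarray) -> float:
    gamma = np.asarray(gamma, dtype=float)
    rp = np.asarray(rp, dtype=float)
    ok = np.isfinite(gamma) & np.isfinite(rp)
    if ok.sum() < 3:
        raise ValueError("need at least 3 genes with both values present")
    return distance_correlation(gamma[ok], rp[ok])


def delta_grid_search(
    peakset: PeakSet,
    layout: GenomeLayout,
    profile: CorrelationProfile,
    grid: np.ndarray,
    method: Literal["linear", "dcor"] = "linear",
    gene_subset: Sequence[str] | None = None,
) -> DecayCurve:
    """Concordance curve over a Δ grid and its argmax.

    The linear method maximizes |ρ| between γ̂ and R(Δ) (equivalent to ρ²,
    the profile-likelihood criterion); dcor maximizes distance correlation.
    The TF's own gene is excluded to avoid trivial self-correlation.  Ties
    break toward the smallest Δ.
    """
    if len(grid) < 2:
        raise ValueError("grid needs at least 2 points")
    if gene_subset is not None:
        genes = [
            g for g in layout.mapped_genes()
            if g.gene_id in set(gene_subset) and g.gene_id != profile.tf_gene
        ]
    else:
        genes = [g for g in layout.mapped_genes() if g.gene_id != profile.tf_gene]
    if not genes:
        raise ValueError("no usable genes after subsetting")
    gpd = gene_peak_distances(peakset, layout, genes=genes)
    gamma = profile.corr.reindex([g.gene_id for g in genes]).to_numpy(dtype=float)

    n = len(grid)
    stat = np.zeros(n)
    signs = np.zeros(n)
    fit_rows = []
    for i, delta in enumerate(grid):
        rp = gpd.rp(DecaySpec("exponential", delta=float(delta)))
        if method == "linear":
            try:
                fit = concordance_linear(gamma, rp)
            except ValueError:
                fit_rows.append((np.nan, np.nan, np.nan))
                continue
            stat[i] = abs(fit.rho)
            signs[i] = np.sign(fit.rho)
            fit_rows.append((fit.alpha, fit.beta, fit.sigma2))
        elif method == "dcor":
            try:
                stat[i] = concordance_dcor(gamma, rp)
            except ValueError:
                stat[i] = 0.0
        else:
            raise ValueError(f"unknown method {method!r}")
    fits = (
        pd.DataFrame(fit_rows, columns=["alpha", "beta", "sigma2"])
        if method == "linear"
        else None
    )
    return DecayCurve(
        np.asarray(grid, dtype=float), stat, f"expr-{method}",
        sample_id=peakset.sample_id, fits=fits, signs=signs if method == "linear" else None,
    )


# --- aggregation and classification ------------------------------------------


@dataclass
class TfDeltaEstimate:
    tf_id: str
    delta_star: float | None
    qualified_samples: list[str] = field(default_factory=list)
    curves: list[DecayCurve] = field(default_factory=list)
    mean_curve: DecayCurve | None = None
    cohort: str | None = None
    subset: str | None = None

    @property
    def range_class(self) -> str | None:
        if self.delta_star is None:
            return None
        return classify_range(self.delta_star)


def classify_range(delta_star: float) -> str:
    """Short-range (Δ* ≤ 3 kb) vs long-range (Δ* > 3 kb); boundary is short."""
    return "long-range" if delta_star > SHORT_RANGE_MAX_BP else "short-range"


def aggregate_tf_delta(
    curves: Sequence[DecayCurve],
    tf_id: str,
    threshold: float = QUALIFICATION_THRESHOLD,
    min_qualified: int = MIN_QUALIFIED_SAMPLES,
    cohort: str | None = None,
    subset: str | None = None,
) -> TfDeltaEstimate:
    """Aggregate per-sample concordance curves into one TF-level estimate.

    A sample qualifies if its curve exceeds ``threshold`` anywhere.  With at
    least ``min_qualified`` qualified samples, curves are averaged pointwise;
    if the averaged maximum also exceeds ``threshold``, Δ* is the argmax of
    the mean curve.  Absence of an estimate is a valid outcome.
    """
    if not curves:
        raise ValueError("need at least one curve")
    grid = curves[0].grid
    for c in curves[1:]:
        if not np.allclose(c.grid, grid):
            raise ValueError("curves use different grids")
    qualified = [c for c in curves if c.stat_max > threshold]
    est = TfDeltaEstimate(
        tf_id, None,
        qualified_samples=[c.sample_id for c in qualified if c.sample_id],
        curves=list(curves), cohort=cohort, subset=subset,
    )
    if len(qualified) < min_qualified:
        return est
    mean_stat = np.mean([c.statistic for c in qualified], axis=0)
    mean_curve = DecayCurve(grid, mean_stat, curves[0].method + "-mean")
    est.mean_curve = mean_curve
    if mean_curve.stat_max > threshold:
        est.delta_star = mean_curve.delta_star
    return est


def delta_by_subset(
    peakset: PeakSet,
    layout: GenomeLayout,
    profile: CorrelationProfile,
    grid: np.ndarray,
    subset_genes: Sequence[str],
    subset_label: str,
    method: Literal["linear", "dcor"] = "linear",
    threshold: float = QUALIFICATION_THRESHOLD,
    min_qualified: int = 1,
    gene_floor: int = SUBSET_GENE_FLOOR,
) -> TfDeltaEstimate | None:
    """Δ* with genes restricted to one TAD type or tissue-specific TAD set.

    Returns None (with a warning) when fewer than ``gene_floor`` subset genes
    remain — too few for a stable concordance.
    """
    usable = [g for g in subset_genes if g in layout.gene_to_tad and g != profile.tf_gene]
    if len(usable) < gene_floor:
        logger.warning(
            "subset %r has only %d usable genes (< %d); refusing to estimate",
            subset_label, len(usable), gene_floor,
        )
        return None
    curve = delta_grid_search(peakset, layout, profile, grid, method, usable)
    return aggregate_tf_delta(
        [curve], profile.tf_gene, threshold=threshold,
        min_qualified=min_qualified, subset=subset_label,
    )
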