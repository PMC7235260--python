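"""Trait–TF prioritization from TAD-wise SNP counts.

Trait-associated SNPs are counted per TAD; each TF's occupancy is summarized
as its relative TAD-wise abundance (per-TAD peak count divided by the TF's
mean per-TAD count).  The match between a trait and a TF is

    TFscore = Σ_TADs  #SNPs · relative abundance        (a dot product)

whose normalized form is the cosine similarity of the two vectors.
Significance comes from a one-sided permutation test that shuffles the SNP
count vector across TADs, with Benjamini–Hochberg correction across TFs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genome_io import GenomeLayout, PeakSet
from .tad_occupancy import peak_counts

GWAS_P_FLAG = 0.001
MIN_TRAIT_SNPS = 20


def relative_abundance(counts: np.ndarray | pd.Series) -> np.ndarray:
    """Per-TAD peak count divided by the TF's mean per-TAD count.

    The output averages to exactly 1 by construction.
    """
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total == 0:
        raise ValueError("TF has no peaks in any TAD")
    return arr / arr.mean()


def abundance_matrix(
    peaksets: Sequence[PeakSet], layout: GenomeLayout
) -> pd.DataFrame:
    """TADs × TFs relative-abundance matrix.

    Multiple samples of one TF are averaged (raw counts) before normalizing.
    """
    by_tf: dict[str, list[pd.Series]] = {}
    for ps in peaksets:
        by_tf.setdefault(ps.tf_id, []).append(peak_counts(ps, layout))
    cols = {}
    for tf, series_list in by_tf.items():
        mean_counts = pd.concat(series_list, axis=1).mean(axis=1)
        cols[tf] = relative_abundance(mean_counts.to_numpy())
    return pd.DataFrame(cols, index=series_list[0].index)


def snp_counts_per_tad(
    snps: pd.DataFrame, layout: GenomeLayout
) -> pd.Series:
    """Count SNPs (chrom, pos) per TAD; SNPs outside all TADs are ignored."""
    counts = {t.tad_id: 0 for t in layout.tads}
    for row in snps.itertuples(index=False):
        tid = layout.tad_of_point(str(row.chrom), int(row.pos))
        if tid is not None:
            counts[tid] += 1
    return pd.Series(counts, dtype=float)


def trait_tf_score(
    snp_counts: np.ndarray | pd.Series, abundance: np.ndarray | pd.Series
) -> tuple[float, float]:
    """(TFscore, cosine similarity) between SNP counts and TF abundance."""
    s = np.asarray(snp_counts, dtype=float)
    a = np.asarray(abundance, dtype=float)
    if len(s) != len(a):
        raise ValueError("vector length mismatch")
    ns, na = np.linalg.norm(s), np.linalg.norm(a)
    if ns == 0 or na == 0:
        raise ValueError("zero-norm vector")
    score = float(s @ a)
    return score, score / (ns * na)


@dataclass
class TraitTfResult:
    trait: str
    table: pd.DataFrame  # per TF: tfscore, cosine, p, p_adj, significant


def permutation_significance(
    snp_counts: pd.Series,
    abundance: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    trait: str = "trait",
    p_flag: float = GWAS_P_FLAG,
) -> TraitTfResult:
    """One-sided permutation test of trait–TF cosine similarity.

    The null permutes the SNP-count vector across TADs; p = (1 + #null ≥
    observed) / (1 + n_perm), BH-adjusted across TFs.  Flags mark TFs with
    adjusted one-sided p below ``p_flag`` (positive tail).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if seed is None:
        raise ValueError("seed is required for reproducible permutations")
    rng = np.random.default_rng(seed)
    s = snp_counts.reindex(abundance.index).to_numpy(dtype=float)
    A = abundance.to_numpy(dtype=float)  # TADs × TFs
    norms_a = np.linalg.norm(A, axis=0)
    norm_s = np.linalg.norm(s)
    if norm_s == 0 or (norms_a == 0).any():
        raise ValueError("zero-norm vector")
    observed_score = s @ A
    observed_cos = observed_score / (norm_s * norms_a)

    perms = np.empty((n_perm, len(s)))
    for i in range(n_perm):
        perms[i] = rng.permutation(s)
    null_cos = (perms @ A) / (norm_s * norms_a)  # permutation preserves |s|
    exceed = (null_cos >= observed_cos[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    p_adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "tfscore": observed_score,
            "cosine": observed_cos,
            "p": p,
            "p_adj": p_adj,
            "significant": p < p_flag,
        },
        index=abundance.columns,
    )
    return TraitTfResult(trait, table)
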