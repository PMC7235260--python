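"""TAD chromatin-state classification from H3K27ac signal.

Mean H3K27ac signal per TAD is z-transformed within each sample, TADs and
samples are hierarchically biclustered, and the TAD clusters with the
strongest and weakest mean signal become A-type (active) and B-type
(repressed) TADs.  Tissue-predominant TADs are those with significantly
higher signal in one sample group than another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .genome_io import GenomeLayout, Tad

logger = logging.getLogger(__name__)

DIFFERENTIAL_P_CUT = 1e-10
DEFAULT_K = 10


def tad_mean_signal(
    coverage: pd.DataFrame, tads: Sequence[Tad]
) -> pd.Series:
    """Base-pair-weighted mean coverage over each TAD.

    ``coverage`` is a bedGraph-like table (chrom, start, end, value) with
    non-overlapping intervals; uncovered bases count as 0.
    """
    known_chroms = {t.chrom for t in tads}
    extra = set(coverage["chrom"].unique()) - known_chroms
    if extra:
        logger.info("coverage chromosomes absent from TADs ignored: %s", sorted(extra))
    by_chrom = {c: g for c, g in coverage.groupby("chrom")}
    out = {}
    for tad in tads:
        sub = by_chrom.get(tad.chrom)
        if sub is None:
            out[tad.tad_id] = 0.0
            continue
        starts = np.maximum(sub["start"].to_numpy(), tad.start)
        ends = np.minimum(sub["end"].to_numpy(), tad.end)
        widths = np.clip(ends - starts, 0, None)
        total = float(widths @ sub["value"].to_numpy(dtype=float))
        out[tad.tad_id] = total / tad.length
    return pd.Series(out, name="mean_signal")


def sample_z_transform(matrix: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Standardize each sample column to mean 0, sd 1 (population sd default)."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 TADs")
    x = matrix.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    zero = sd <= 1e-12 * (np.abs(mu) + 1.0)
    if zero.any():
        bad = matrix.columns[zero][0]
        raise ValueError(f"sample {bad!r} has constant signal; cannot z-transform")
    return pd.DataFrame((x - mu) / sd, index=matrix.index, columns=matrix.columns)


@dataclass
class TadClustering:
    tad_labels: pd.Series  # tad_id -> cluster (1..k), ordered by ascending mean signal
    sample_labels: pd.Series
    cluster_means: pd.Series  # cluster -> mean signal
    k: int
    a_type: frozenset[str] = field(default_factory=frozenset)
    b_type: frozenset[str] = field(default_factory=frozenset)


def bicluster(
    matrix: pd.DataFrame,
    k: int = DEFAULT_K,
    method: str = "average",
    metric: str = "euclidean",
) -> TadClustering:
    """Hierarchical biclustering of the TAD × sample z-score matrix.

    Rows (TADs) and columns (samples) are each clustered and cut into k
    groups; TAD cluster labels are renumbered by ascending cluster-mean
    signal so that cluster 1 is the weakest and cluster k the strongest.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > min(matrix.shape):
        raise ValueError("k exceeds matrix dimensions")
    x = matrix.to_numpy(dtype=float)
    row_link = linkage(x, method=method, metric=metric)
    col_link = linkage(x.T, method=method, metric=metric)
    row_raw = fcluster(row_link, t=k, criterion="maxclust")
    col_raw = fcluster(col_link, t=k, criterion="maxclust")

    raw_means = pd.Series(x.mean(axis=1)).groupby(row_raw).mean()
    # renumber by ascending mean; ties by cluster size then raw label
    sizes = pd.Series(row_raw).value_counts()
    order = sorted(raw_means.index, key=lambda c: (raw_means[c], sizes[c], c))
    relabel = {old: new for new, old in enumerate(order, start=1)}
    tad_labels = pd.Series([relabel[c] for c in row_raw], index=matrix.index)
    cluster_means = pd.Series(
        {relabel[c]: raw_means[c] for c in raw_means.index}
    ).sort_index()
    sample_labels = pd.Series(col_raw, index=matrix.columns)
    return TadClustering(tad_labels, sample_labels, cluster_means, k)


def call_ab_types(clustering: TadClustering) -> tuple[frozenset[str], frozenset[str]]:
    """A-type = TADs of the strongest-mean cluster, B-type = weakest cluster.

    Middle clusters stay untyped.  After ``bicluster`` renumbering, weakest
    is cluster 1 and strongest is cluster k, so ties are already resolved
    deterministically (by size, then label).
    """
    weakest = clustering.cluster_means.index[0]
    strongest = clustering.cluster_means.index[-1]
    b_type = frozenset(clustering.tad_labels.index[clustering.tad_labels == weakest])
    a_type = frozenset(clustering.tad_labels.index[clustering.tad_labels == strongest])
    clustering.a_type = a_type
    clustering.b_type = b_type
    return a_type, b_type


def differential_tads(
    matrix: pd.DataFrame,
    group1: Sequence[str],
    group2: Sequence[str],
    p_cut: float = DIFFERENTIAL_P_CUT,
) -> tuple[frozenset[str], frozenset[str], pd.DataFrame]:
    """Per-TAD Welch t-test between two sample groups.

    Returns (group1-predominant TADs, group2-predominant TADs, full table).
    A TAD is group1-predominant when its group1 mean is higher and the
    two-sided p-value is below ``p_cut``.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("both groups need at least 2 samples")
    x1 = matrix[list(group1)].to_numpy(dtype=float)
    x2 = matrix[list(group2)].to_numpy(dtype=float)
    t, p = stats.ttest_ind(x1, x2, axis=1, equal_var=False)
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    table = pd.DataFrame(
        {"mean1": m1, "mean2": m2, "t": t, "p": p}, index=matrix.index
    )
    p = np.nan_to_num(p, nan=1.0)
    g1 = frozenset(matrix.index[(m1 > m2) & (p < p_cut)])
    g2 = frozenset(matrix.index[(m2 > m1) & (p < p_cut)])
    return g1, g2, table


def genes_in_tad_set(layout: GenomeLayout, tad_set: Sequence[str]) -> list[str]:
    """Gene ids whose TSS lies in one of the given TADs."""
    wanted = set(tad_set)
    return [g for g, t in layout.gene_to_tad.items() if t in wanted]
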