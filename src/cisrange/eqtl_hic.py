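"""eQTL–TSS distance comparisons and Hi-C contact-frequency decay.

Significant eQTLs (p ≤ 1e−5) are assigned to TAD classes by the TAD holding
the target gene's TSS; log-transformed variant–TSS distances are compared
between classes (or between tissues within tissue-predominant TAD sets) with
Student's t-tests.  Hi-C decay is quantified as the average contact frequency
F(d) over intra-TAD bin pairs at each separation d, with a power-law exponent
fitted by OLS on log F vs log d.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomeLayout, Tad

logger = logging.getLogger(__name__)

EQTL_P_MAX = 1e-5


def filter_eqtls(table: pd.DataFrame, p_max: float = EQTL_P_MAX) -> pd.DataFrame:
    """Keep eQTL–TSS pairs with p ≤ p_max (boundary inclusive) and attach the
    variant–TSS distance column."""
    if "p" not in table.columns:
        raise ValueError("eQTL table needs a 'p' column")
    kept = table[table["p"] <= p_max].copy()
    if kept.empty:
        logger.warning("no eQTL pairs pass p <= %g", p_max)
    kept["distance"] = (kept["pos"] - kept["tss"]).abs()
    return kept


def _log_distances(distances: np.ndarray) -> np.ndarray:
    # +1 offset admits zero distances; the base cancels in t statistics
    return np.log10(np.asarray(distances, dtype=float) + 1.0)


@dataclass
class DistanceComparison:
    t: float
    p: float
    median1: float
    median2: float
    n1: int
    n2: int


def compare_distances_ab(
    eqtls: pd.DataFrame,
    gene_to_tad: Mapping[str, str],
    a_type: Sequence[str],
    b_type: Sequence[str],
) -> DistanceComparison:
    """t-test of log10 eQTL–TSS distances, B-type vs A-type TAD genes.

    Group 1 is B-type, group 2 A-type; a positive t means longer distances in
    B-type TADs.  Medians are reported on the bp scale.
    """
    a_set, b_set = set(a_type), set(b_type)
    tads = eqtls["gene_id"].map(gene_to_tad)
    d_b = eqtls.loc[tads.isin(b_set), "distance"].to_numpy(dtype=float)
    d_a = eqtls.loc[tads.isin(a_set), "distance"].to_numpy(dtype=float)
    if len(d_a) < 2 or len(d_b) < 2:
        raise ValueError("each TAD class needs at least 2 eQTL pairs")
    t, p = stats.ttest_ind(_log_distances(d_b), _log_distances(d_a))
    return DistanceComparison(
        float(t), float(p), float(np.median(d_b)), float(np.median(d_a)),
        len(d_b), len(d_a),
    )


def compare_distances_tissue_pair(
    eqtls_t1: pd.DataFrame,
    eqtls_t2: pd.DataFrame,
    predominant_sets: Mapping[str, Sequence[str]],
    gene_to_tad: Mapping[str, str],
) -> dict[str, DistanceComparison]:
    """Within each tissue-predominant TAD set, compare log distances between
    the two tissues' eQTLs (tissue 1 minus tissue 2 in the t sign).

    Sets with fewer than 2 pairs in either tissue are excluded with a warning.
    """
    out: dict[str, DistanceComparison] = {}
    for label, tad_set in predominant_sets.items():
        wanted = set(tad_set)
        d1 = eqtls_t1.loc[
            eqtls_t1["gene_id"].map(gene_to_tad).isin(wanted), "distance"
        ].to_numpy(dtype=float)
        d2 = eqtls_t2.loc[
            eqtls_t2["gene_id"].map(gene_to_tad).isin(wanted), "distance"
        ].to_numpy(dtype=float)
        if len(d1) < 2 or len(d2) < 2:
            logger.warning("TAD set %r has <2 pairs in a tissue; excluded", label)
            continue
        t, p = stats.ttest_ind(_log_distances(d1), _log_distances(d2))
        out[label] = DistanceComparison(
            float(t), float(p), float(np.median(d1)), float(np.median(d2)),
            len(d1), len(d2),
        )
    return out


@dataclass
class ContactCurve:
    """Average contact frequency per genomic separation over intra-TAD pairs."""

    distances: np.ndarray  # bp, bin-midpoint separations
    frequency: np.ndarray  # F(d)
    tad_set_label: str = ""
    n_possible: np.ndarray | None = None


def contact_curve(
    contacts: pd.DataFrame,
    tads: Sequence[Tad],
    bin_size: int,
    tad_set: Sequence[str] | None = None,
    label: str = "",
) -> ContactCurve:
    """F(d) = Σ observed counts / number of possible intra-TAD pairs at d.

    ``contacts`` has columns chrom, bin1_start, bin2_start, count; both bins
    of a counted pair must fall inside a single TAD of the set.  Zero-count
    pairs still enter the denominator.
    """
    if tad_set is not None:
        wanted = set(tad_set)
        tads = [t for t in tads if t.tad_id in wanted]
    if not tads:
        raise ValueError("empty TAD set")

    # denominator: possible same-TAD bin pairs at each separation
    possible: dict[int, int] = {}
    for t in tads:
        n_bins = (t.end - t.start) // bin_size
        for sep in range(1, n_bins):
            possible[sep] = possible.get(sep, 0) + (n_bins - sep)

    observed: dict[int, float] = {}
    layout_trees = GenomeLayout(genes=[], tads=list(tads))
    for row in contacts.itertuples(index=False):
        b1, b2 = int(row.bin1_start), int(row.bin2_start)
        if b1 == b2:
            continue
        t1 = layout_trees.tad_of_point(str(row.chrom), b1 + bin_size // 2)
        t2 = layout_trees.tad_of_point(str(row.chrom), b2 + bin_size // 2)
        if t1 is None or t1 != t2:
            continue
        sep = abs(b2 - b1) // bin_size
        observed[sep] = observed.get(sep, 0.0) + float(row.count)

    seps = np.array(sorted(possible), dtype=int)
    freq = np.array([observed.get(int(s), 0.0) / possible[int(s)] for s in seps])
    n_poss = np.array([possible[int(s)] for s in seps])
    return ContactCurve(seps * float(bin_size), freq, label, n_poss)


def fit_powerlaw(
    curve: ContactCurve, d_range: tuple[float, float] | None = None
) -> tuple[float, float]:
    """OLS of log F on log d: returns (exponent λ̂, intercept).

    Only bins with F > 0 inside ``d_range`` enter the fit; fewer than 3 such
    bins is an error.
    """
    d = curve.distances.astype(float)
    f = curve.frequency.astype(float)
    mask = f > 0
    if d_range is not None:
        mask &= (d >= d_range[0]) & (d <= d_range[1])
    if mask.sum() < 3:
        raise ValueError("need at least 3 bins with positive frequency in range")
    slope, intercept = np.polyfit(np.log(d[mask]), np.log(f[mask]), 1)
    return float(slope), float(intercept)
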