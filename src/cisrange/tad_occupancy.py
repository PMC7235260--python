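"""TF occupancy of TADs: binding density, relative-occupancy z-scores,
target-TAD calls, and descriptive statistics over target TADs.

Binding density is peaks/kb per TAD.  Standardizing each TAD's densities
across TFs gives the relative occupancy of a TF in that TAD compared with
other TFs; TADs where a TF's z-score is at least 1 are that TF's target TADs.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomeLayout, PeakSet

logger = logging.getLogger(__name__)

TARGET_Z_THRESHOLD = 1.0


def peak_density(peakset: PeakSet, layout: GenomeLayout) -> pd.Series:
    """Peaks/kb per TAD, counting peak representative points."""
    counts = peak_counts(peakset, layout)
    lengths_kb = pd.Series(
        {t.tad_id: t.length / 1000.0 for t in layout.tads}
    )
    return (counts / lengths_kb).rename(peakset.sample_id)


def peak_counts(peakset: PeakSet, layout: GenomeLayout) -> pd.Series:
    """Number of peak representative points inside each TAD."""
    counts = {t.tad_id: 0 for t in layout.tads}
    points = peakset.representative_points()
    chroms = peakset.peaks["chrom"].to_numpy()
    for pos, chrom in zip(points, chroms):
        tid = layout.tad_of_point(chrom, int(pos))
        if tid is not None:
            counts[tid] += 1
    return pd.Series(counts, dtype=float)


def density_matrix(
    peaksets: Sequence[PeakSet], layout: GenomeLayout
) -> pd.DataFrame:
    """TADs × TF-samples matrix of binding densities."""
    return pd.DataFrame({ps.sample_id: peak_density(ps, layout) for ps in peaksets})


def tad_zscores(densities: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Standardize each TAD row across TFs: z = (density − mean) / sd.

    Rows with zero sd across TFs (every TF equally dense) are set to NaN with
    a warning — no relative occupancy is defined there.
    """
    if densities.shape[1] < 3:
        raise ValueError("need at least 3 TF samples")
    x = densities.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    # relative tolerance: a row of identical values can carry sd ~ 1e-16
    degenerate = (sd <= 1e-12 * (np.abs(mu) + 1.0)).ravel()
    if degenerate.any():
        logger.warning(
            "%d TADs have zero density sd across TFs; z-scores set absent",
            int(degenerate.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    z[degenerate, :] = np.nan
    return pd.DataFrame(z, index=densities.index, columns=densities.columns)


def call_target_tads(
    z: pd.DataFrame, sample_id: str, threshold: float = TARGET_Z_THRESHOLD
) -> frozenset[str]:
    """TADs where the TF's relative occupancy is >= threshold (inclusive)."""
    col = z[sample_id]
    return frozenset(col.index[col >= threshold])


def target_tad_trend(
    tf_expression: Mapping[str, float],
    tad_values: pd.DataFrame,
    target_tads: Sequence[str],
) -> tuple[float, float]:
    """Correlation of TF expression with mean target-TAD activity across
    cell lines.

    ``tad_values`` is TADs × cell lines (H3K27ac or mean gene expression);
    the across-target-TAD mean per cell line is correlated with the TF's
    expression in the same cell lines.
    """
    lines = [c for c in tad_values.columns if c in tf_expression]
    if len(lines) < 3:
        raise ValueError("need at least 3 cell lines with both quantities")
    targets = [t for t in target_tads if t in tad_values.index]
    if not targets:
        raise ValueError("no target TADs present in the value matrix")
    mean_val = tad_values.loc[targets, lines].mean(axis=0).to_numpy(dtype=float)
    expr = np.array([tf_expression[c] for c in lines], dtype=float)
    if np.std(expr) == 0 or np.std(mean_val) == 0:
        raise ValueError("constant vector; correlation undefined")
    r, p = stats.pearsonr(expr, mean_val)
    return float(r), float(p)


def autoregulation_index(
    tf_gene_id: str,
    layout: GenomeLayout,
    z: pd.DataFrame,
    sample_id: str,
    threshold: float = TARGET_Z_THRESHOLD,
) -> tuple[float | None, bool]:
    """The TF's relative occupancy in the TAD harboring its own gene.

    Returns (z-score or None, auto-regulatory flag).  Absent when the TF's
    gene maps to no TAD or the TAD's z-row is degenerate.
    """
    tad_id = layout.gene_to_tad.get(tf_gene_id)
    if tad_id is None or tad_id not in z.index:
        return None, False
    value = z.loc[tad_id, sample_id]
    if not np.isfinite(value):
        return None, False
    return float(value), bool(value >= threshold)


def tissue_cv(values: Sequence[float], ddof: int = 0) -> float | None:
    """Coefficient of variation (sd/mean) of a gene's per-tissue expression;
    None when the mean is non-positive."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        raise ValueError("need at least 2 tissues")
    mean = arr.mean()
    if mean <= 0:
        return None
    return float(arr.std(ddof=ddof) / mean)
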