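"""Pioneer-factor-like test.

A pioneer factor opens closed chromatin and thereby promotes binding of other
TFs near its own motif.  The signature tested here: the focal TF's motif
enrichment within *other* TFs' ChIP-seq peaks should rise with the focal TF's
expression across cell lines.  The procedure: summarize enrichment per cell
line (average duplicates, then median across non-focal TFs), binarize at the
grand mean, and fit a logistic regression of the binary summary on focal-TF
expression; a slope Wald p-value below 0.05 flags the TF pioneer-like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

PIONEER_ALPHA = 0.05


def summarize_enrichment(table: pd.DataFrame, focal_tf: str) -> pd.Series:
    """Per-cell-line enrichment summary y_i.

    Rows of the focal TF itself are excluded; enrichment of redundant
    (tf, cell_line) duplicates is averaged; y_i is the median across the
    remaining TFs in each cell line.
    """
    required = {"tf_id", "cell_line", "enrichment"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"enrichment table missing columns: {sorted(missing)}")
    if (table["enrichment"] <= 0).any():
        raise ValueError("enrichment ratios must be positive")
    non_focal = table[table["tf_id"] != focal_tf]
    if non_focal.empty:
        raise ValueError("no non-focal rows in enrichment table")
    dedup = (
        non_focal.groupby(["cell_line", "tf_id"], sort=True)["enrichment"]
        .mean()
        .reset_index()
    )
    y = dedup.groupby("cell_line")["enrichment"].median()
    return y.rename("y")


@dataclass
class PioneerResult:
    focal_tf: str
    y: pd.Series
    y_binary: pd.Series
    x: pd.Series
    slope: float | None
    pvalue: float | None
    pioneer_like: bool
    status: str  # "ok" | "separated"
    separation_sign: int | None = None


def pioneer_test(
    y: pd.Series, x: Mapping[str, float], focal_tf: str = "",
    alpha: float = PIONEER_ALPHA,
) -> PioneerResult:
    """Binarize y at its mean and fit logistic y* ~ intercept + x.

    Complete separation is detected and reported as status "separated" with
    the slope sign instead of a spurious p-value.
    """
    lines = [c for c in y.index if c in x]
    if len(lines) < 6:
        raise ValueError("need at least 6 cell lines")
    yv = y.loc[lines]
    xv = pd.Series({c: float(x[c]) for c in lines})
    if xv.nunique() < 2:
        raise ValueError("focal TF expression must vary across cell lines")
    ybin = (yv >= yv.mean()).astype(int)
    if ybin.nunique() < 2:
        raise ValueError("degenerate response: all binarized values identical")

    lo = ybin == 1
    if xv[lo].min() > xv[~lo].max():
        return PioneerResult(focal_tf, yv, ybin, xv, None, None, False,
                             "separated", separation_sign=1)
    if xv[lo].max() < xv[~lo].min():
        return PioneerResult(focal_tf, yv, ybin, xv, None, None, False,
                             "separated", separation_sign=-1)

    exog = sm.add_constant(xv.to_numpy(dtype=float))
    try:
        fit = sm.Logit(ybin.to_numpy(), exog).fit(disp=0, maxiter=200)
    except PerfectSeparationError:
        sign = 1 if np.corrcoef(xv, ybin)[0, 1] >= 0 else -1
        return PioneerResult(focal_tf, yv, ybin, xv, None, None, False,
                             "separated", separation_sign=sign)
    slope = float(fit.params[1])
    pvalue = float(fit.pvalues[1])
    return PioneerResult(
        focal_tf, yv, ybin, xv, slope, pvalue, bool(pvalue < alpha), "ok"
    )
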