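"""Selection of genes whose treatment response tracks retinoid sensitivity.

For each gene, the per-cell-line log2 fold-change (treated over vehicle) is
regressed on the per-line ATRA-score; genes whose response is linearly
correlated with sensitivity across the cohort are selected through a
transparent filter chain: a minimum number of lines with usable fold-changes,
a floor on |Pearson r|, and a BH-FDR cut on the two-sided correlation-test
p-value. Selected genes split into up- and downregulated sets by the sign of
the regression slope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .counts_de import bh_adjust

__all__ = [
    "correlate_with_score",
    "split_by_direction",
    "ScoreAssociation",
    "export_direction_gmt",
]


def correlate_with_score(
    logfc: pd.DataFrame,
    scores: pd.Series,
    fdr: float = 0.05,
    r_min: float = 0.5,
    min_lines: int = 8,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of log2FC against the sensitivity score.

    Parameters
    ----------
    logfc : DataFrame, genes x cell lines
        Per-line treatment log2 fold-changes; NaN entries mark lines where a
        gene is not usable (not expressed).
    scores : Series indexed by cell line
        Rescaled sensitivity scores; must align with ``logfc`` columns and
        have nonzero variance.
    fdr, r_min, min_lines
        Selection filters: BH-adjusted p < ``fdr``, |r| >= ``r_min`` and at
        least ``min_lines`` usable lines.

    Returns one row per gene: pearson_r, slope, intercept, n_lines, p_value,
    adj_p, direction and selected.
    """
    missing = set(logfc.columns) - set(scores.index)
    if missing:
        raise ValueError(f"scores missing for lines: {sorted(missing)}")
    s = scores.loc[logfc.columns].to_numpy(dtype=float)
    if logfc.shape[1] < 3:
        raise ValueError("need >= 3 cell lines")
    if np.ptp(s) == 0:
        raise ValueError("score vector has zero variance")

    L = logfc.to_numpy(dtype=float)
    mask = np.isfinite(L)
    Lz = np.where(mask, L, 0.0)
    n = mask.sum(axis=1)

    sx = mask @ s
    sxx = mask @ (s * s)
    sy = Lz.sum(axis=1)
    syy = (Lz * Lz).sum(axis=1)
    sxy = Lz @ s
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        var_x = sxx - sx * sx / n
        var_y = syy - sy * sy / n
        r = cov / np.sqrt(var_x * var_y)
        slope = cov / var_x
        intercept = sy / n - slope * sx / n
    bad = (n < 3) | ~np.isfinite(r) | (var_y <= 0) | (var_x <= 0)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    slope = np.where(bad, np.nan, slope)

    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r * r, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n - 2, 1))
    p = np.where(np.isfinite(r), p, np.nan)

    adj = np.full(p.size, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        adj[ok] = bh_adjust(p[ok])

    selected = ok & (adj < fdr) & (np.abs(r) >= r_min) & (n >= min_lines)
    direction = np.where(slope > 0, "up", np.where(slope < 0, "down", "none"))
    selected &= direction != "none"
    return pd.DataFrame(
        {
            "pearson_r": r,
            "slope": slope,
            "intercept": intercept,
            "n_lines": n,
            "p_value": p,
            "adj_p": adj,
            "direction": direction,
            "selected": selected,
        },
        index=logfc.index,
    )


def split_by_direction(results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition the selected genes by slope sign (zero slope excluded)."""
    sel = results[results["selected"]]
    return sel[sel["direction"] == "up"], sel[sel["direction"] == "down"]


class ScoreAssociation(BaseEstimator):
    """Estimator form of the sensitivity-association screen.

    Parameters mirror :func:`correlate_with_score`; after ``fit(logfc,
    scores)`` the full association table is in ``results_`` and the selected
    up/down gene lists in ``up_genes_`` / ``down_genes_``.
    """

    def __init__(self, fdr: float = 0.05, r_min: float = 0.5, min_lines: int = 8) -> None:
        self.fdr = fdr
        self.r_min = r_min
        self.min_lines = min_lines

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "ScoreAssociation":
        self.results_ = correlate_with_score(
            X, y, fdr=self.fdr, r_min=self.r_min, min_lines=self.min_lines
        )
        up, down = split_by_direction(self.results_)
        self.up_genes_ = list(up.index)
        self.down_genes_ = list(down.index)
        return self


def export_direction_gmt(results: pd.DataFrame, path, prefix: str = "SCORE_ASSOCIATED") -> None:
    """Write the selected up/down gene sets as a two-line GMT file."""
    up, down = split_by_direction(results)
    with open(path, "w") as fh:
        fh.write("\t".join([f"{prefix}_UP", "score-correlated upregulated", *up.index]) + "\n")
        fh.write("\t".join([f"{prefix}_DOWN", "score-correlated downregulated", *down.index]) + "\n")
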