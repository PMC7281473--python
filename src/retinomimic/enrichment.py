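"""Gene-set layer: pre-ranked competitive testing and single-sample scoring.

Two complementary summaries of pathway behaviour:

* :func:`preranked_test` — a competitive rank test of a gene set against the
  rest of the ranked universe (two-sided Wilcoxon rank-sum of in-set versus
  out-of-set statistics), the pathway-level readout for differential-
  expression statistics. Inter-gene correlation is deliberately not modelled;
  the test answers "do set members sit unusually high or low in the
  ranking", with BH-FDR across the collection.
* :func:`ssgsea` — single-sample gene-set enrichment: within one expression
  profile, genes are ranked by decreasing expression and the score is the
  summed difference between the weighted in-set ECDF and the unweighted
  out-of-set ECDF, with weights |expression|^alpha (alpha 0.25 by default;
  alpha 0 makes the score purely rank-based).

ssGSEA scores of sensitivity-split cohorts are compared per set with a
two-sided Welch t-test, BH-corrected across the sets tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .counts_de import bh_adjust

__all__ = [
    "GeneSet",
    "read_gmt",
    "write_gmt",
    "preranked_test",
    "PrerankedEnrichment",
    "ssgsea",
    "SSGSEA",
    "compare_groups",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    members: frozenset
    collection: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gmt(path, collection: str = "") -> list[GeneSet]:
    """Parse a GMT file (name, description, members...).

    Duplicate members within a set are deduplicated with a warning.
    """
    sets = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {i}: need name, description and >= 1 member")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if len(set(members)) != len(members):
                warnings.warn(f"gene set {name!r} has duplicate members; deduplicated")
            sets.append(GeneSet(name, frozenset(members), collection))
    return sets


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.collection or "na", *sorted(gs.members)]) + "\n")


def preranked_test(
    statistics: pd.Series,
    gene_sets: Sequence[GeneSet],
    min_set_size: int = 2,
    method: str = "auto",
) -> pd.DataFrame:
    """Competitive rank test of each set against the rest of the universe.

    For every set, the ranking statistics of member genes present in
    ``statistics`` are compared with those of all remaining genes by a
    two-sided Wilcoxon rank-sum (Mann-Whitney) test; the direction is up
    when the mean in-set rank exceeds the mean out-of-set rank. FDR is BH
    across the sets tested. ``method`` is 'exact', 'asymptotic' or 'auto'
    (exact when the universe is tie-free and holds at most 200 genes).
    """
    stats_clean = statistics.dropna()
    universe = set(stats_clean.index)
    rows = []
    for gs in gene_sets:
        members = gs.members & universe
        if len(members) < min_set_size:
            raise ValueError(
                f"gene set {gs.name!r}: fewer than {min_set_size} members in the ranking"
            )
        if len(members) == len(universe):
            raise ValueError(f"gene set {gs.name!r} covers the whole universe")
        in_mask = stats_clean.index.isin(members)
        x = stats_clean.to_numpy(float)[in_mask]
        y = stats_clean.to_numpy(float)[~in_mask]
        ranks = stats.rankdata(stats_clean.to_numpy(float))
        if np.ptp(ranks) == 0:
            p, direction = 1.0, "up"
        else:
            if method == "auto":
                values = stats_clean.to_numpy(float)
                tie_free = np.unique(values).size == values.size
                use = "exact" if tie_free and values.size <= 200 else "asymptotic"
            else:
                use = method
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=use)
            p = float(res.pvalue)
            direction = "up" if ranks[in_mask].mean() >= ranks[~in_mask].mean() else "down"
        rows.append(
            {
                "set_name": gs.name,
                "direction": direction,
                "p_value": p,
                "n_in_set_tested": len(members),
            }
        )
    out = pd.DataFrame(rows).set_index("set_name")
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    return out


class PrerankedEnrichment(BaseEstimator):
    """Estimator form of the pre-ranked competitive test.

    ``fit(statistics)`` stores the per-set table in ``results_``.
    """

    def __init__(self, gene_sets: Sequence[GeneSet], min_set_size: int = 2) -> None:
        self.gene_sets = gene_sets
        self.min_set_size = min_set_size

    def fit(self, X: pd.Series, y=None) -> "PrerankedEnrichment":
        self.results_ = preranked_test(X, self.gene_sets, self.min_set_size)
        return self


def _ssgsea_one(values: np.ndarray, gene_ids: np.ndarray, member_mask: np.ndarray, alpha: float) -> float:
    # descending by value; ties broken by stable (ascending) gene-id order
    order = np.lexsort((gene_ids, -values))
    v = values[order]
    inset = member_mask[order]
    n = v.size
    n_in = int(inset.sum())
    if n_in == 0:
        raise ValueError("no gene of the set is present in the profile")
    if n_in == n:
        raise ValueError("gene set covers the entire profile")
    w = np.abs(v) ** alpha if alpha != 0 else np.ones(n)
    w_in = np.where(inset, w, 0.0)
    denom_in = w_in.sum()
    if denom_in == 0:
        raise ValueError("in-set weights sum to zero")
    p_in = np.cumsum(w_in) / denom_in
    p_out = np.cumsum(~inset) / (n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea(
    expression: pd.DataFrame | pd.Series,
    gene_sets: Sequence[GeneSet],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Single-sample enrichment scores, samples x sets.

    ``expression`` is genes x samples (a Series is one sample). Within each
    sample, genes are ordered by decreasing expression (stable gene-id
    tie-break) and the score is sum over ranks of the weighted in-set ECDF
    minus the out-of-set ECDF; weights are |expression|^alpha. With
    ``normalize``, scores are divided by the range of all computed scores
    (off by default — raw scores are comparable within a run).
    """
    if isinstance(expression, pd.Series):
        expression = expression.to_frame()
    gene_ids = expression.index.to_numpy(str)
    out = pd.DataFrame(
        index=expression.columns, columns=[gs.name for gs in gene_sets], dtype=float
    )
    masks = {gs.name: expression.index.isin(gs.members) for gs in gene_sets}
    for sample in expression.columns:
        values = expression[sample].to_numpy(float)
        for gs in gene_sets:
            out.at[sample, gs.name] = _ssgsea_one(values, gene_ids, masks[gs.name], alpha)
    if normalize:
        rng = out.to_numpy().max() - out.to_numpy().min()
        if rng > 0:
            out = out / rng
    return out


class SSGSEA(TransformerMixin, BaseEstimator):
    """Transformer: expression (genes x samples) -> scores (samples x sets).

    Parameters
    ----------
    gene_sets : sequence of GeneSet
    alpha : float, default 0.25
        Rank weighting exponent; 0 gives a purely rank-based score.
    normalize : bool, default False
        Divide scores by their overall range after computation.
    """

    def __init__(
        self,
        gene_sets: Sequence[GeneSet],
        alpha: float = 0.25,
        normalize: bool = False,
    ) -> None:
        self.gene_sets = gene_sets
        self.alpha = alpha
        self.normalize = normalize

    def fit(self, X=None, y=None) -> "SSGSEA":
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return ssgsea(X, self.gene_sets, alpha=self.alpha, normalize=self.normalize)


def compare_groups(
    scores: pd.DataFrame,
    labels: pd.Series,
    group_a: str = "HIGH",
    group_b: str = "LOW",
) -> pd.DataFrame:
    """Welch t-test of ssGSEA scores between two sensitivity groups, per set.

    ``scores`` is samples x sets; ``labels`` assigns each sample to a group.
    BH adjustment runs across the sets tested (e.g. n = 3 when three
    pathways are compared). Each group needs >= 2 samples.
    """
    common = scores.index.intersection(labels.index)
    lab = labels.loc[common]
    a_idx = common[lab == group_a]
    b_idx = common[lab == group_b]
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise ValueError("each group needs >= 2 samples")
    rows = []
    for set_name in scores.columns:
        a = scores.loc[a_idx, set_name].to_numpy(float)
        b = scores.loc[b_idx, set_name].to_numpy(float)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "set_name": set_name,
                "t_stat": float(t),
                "p_value": float(p),
                "mean_" + group_a.lower(): float(a.mean()),
                "mean_" + group_b.lower(): float(b.mean()),
            }
        )
    out = pd.DataFrame(rows).set_index("set_name")
    out["adj_p"] = bh_adjust(out["p_value"].to_numpy())
    return out
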