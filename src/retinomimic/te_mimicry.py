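"""Viral-mimicry quantification from transposable-element counts.

Endogenous retrovirus (ENV) expression is summarized at three levels:

* family induction — instance counts are summed into family-level features
  (plus one all-member meta-gene) and the per-line treatment log2
  fold-change of each family is computed, with an NB test of the meta-gene
  providing the per-line significance call;
* median ENV induction — per line, the median across families of the linear
  (2^log2FC) fold-change, the single-number viral-mimicry readout;
* score correlation — ordinary least squares of the per-line median
  induction on the ATRA-score, reported as R^2 per subtype group, which is
  how score-coupled (basal) and score-independent (luminal) ENV activation
  patterns are told apart.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import META_GENE, TEFamily
from .counts_de import CountMatrix, nb_wald_test, bh_adjust, per_line_logfc, size_factors

__all__ = [
    "aggregate_families",
    "family_induction",
    "median_env_induction",
    "env_score_correlation",
]


def aggregate_families(
    te_counts: CountMatrix,
    families: list[TEFamily] | Mapping[str, str],
    include_metagene: bool = True,
) -> CountMatrix:
    """Sum instance-level counts into family-level features.

    ``families`` is either a list of :class:`TEFamily` or a mapping
    instance_id -> family name. Family counts are member sums (count
    additivity is what makes the meta-gene construction valid); the
    meta-gene row is the sum over every family member.
    """
    if isinstance(families, Mapping):
        instance_to_family = dict(families)
    else:
        instance_to_family = {
            iid: fam.name for fam in families for iid in fam.member_ids
        }
    known = te_counts.counts.index.intersection(instance_to_family)
    sub = te_counts.counts.loc[known]
    fam_labels = pd.Series({i: instance_to_family[i] for i in known})
    agg = sub.groupby(fam_labels).sum().sort_index()
    if include_metagene:
        agg.loc[META_GENE] = sub.sum(axis=0)
    return CountMatrix(agg.astype(sub.dtypes.iloc[0] if len(sub) else int), te_counts.samples)


def family_induction(
    family_counts: CountMatrix,
    pseudocount: float = 0.5,
    test: bool = True,
    sf: np.ndarray | pd.Series | None = None,
) -> pd.DataFrame:
    """Per-(line, family) treatment log2 fold-change with meta-gene p-values.

    Fold-changes come from :func:`per_line_logfc` on the family-aggregated
    matrix. When ``test`` is set, each line's six samples (3 vehicle + 3
    treated) are run through the NB Wald test, giving a per-family p-value
    and a BH adjustment across families within the line; the meta-gene row
    is tested as one additional aggregate feature and is the per-line
    significance call for ENV induction as a whole.

    ``sf`` supplies per-sample size factors estimated from a stable
    reference (the canonical-gene matrix). Repeat families respond to
    treatment broadly, so median-of-ratios on the repeat matrix alone would
    absorb the very induction being measured; when ``sf`` is omitted it is
    still estimated from ``family_counts`` as a fallback.
    """
    if sf is None:
        sf_arr = size_factors(family_counts.counts)
    else:
        sf_arr = (
            sf.loc[family_counts.sample_ids].to_numpy(float)
            if isinstance(sf, pd.Series)
            else np.asarray(sf, dtype=float)
        )
    sf_series = pd.Series(sf_arr, index=family_counts.sample_ids)
    lfc = per_line_logfc(family_counts, pseudocount=pseudocount, sf=sf_arr)
    rows = []
    for line in lfc.columns:
        meta = family_counts.samples[family_counts.samples["cell_line"] == line]
        pvals = {}
        if test:
            sub = CountMatrix(family_counts.counts[meta.index], meta)
            res = nb_wald_test(
                sub.counts,
                meta["condition"].to_numpy(),
                sf=sf_series.loc[meta.index].to_numpy(),
            )
            p = res["p_value"].to_numpy()
            adj = np.full(p.size, np.nan)
            ok = np.isfinite(p)
            if ok.any():
                adj[ok] = bh_adjust(p[ok])
            pvals = {f: (p[i], adj[i]) for i, f in enumerate(res.index)}
        subtype = meta["subtype"].iloc[0]
        for fam in lfc.index:
            p_f, adj_f = pvals.get(fam, (np.nan, np.nan))
            rows.append(
                {
                    "cell_line": line,
                    "subtype": subtype,
                    "family": fam,
                    "log2_fold_change": lfc.at[fam, line],
                    "p_value": p_f,
                    "adj_p": adj_f,
                }
            )
    return pd.DataFrame(rows)


def median_env_induction(
    induction: pd.DataFrame,
    mode: str = "median_of_fc",
    family_counts: CountMatrix | None = None,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-line median ENV induction on the linear fold-change scale.

    The default ``median_of_fc`` takes, per line, the median over families
    of 2^log2FC (the meta-gene row is excluded — it is a test feature, not
    a family). The alternative reading, ``fc_of_medians``, computes the
    ratio of the median family expression under treatment to the median
    under vehicle and requires ``family_counts``.
    """
    fam_rows = induction[induction["family"] != META_GENE]
    if fam_rows.empty:
        raise ValueError("no family-level induction values")
    if mode == "median_of_fc":
        return (
            fam_rows.assign(fc=lambda d: 2.0 ** d["log2_fold_change"])
            .groupby("cell_line")["fc"]
            .median()
            .rename("median_env_induction")
        )
    if mode == "fc_of_medians":
        if family_counts is None:
            raise ValueError("fc_of_medians mode needs the family count matrix")
        sf = size_factors(family_counts.counts)
        norm = family_counts.counts / sf
        norm = norm.drop(index=META_GENE, errors="ignore")
        out = {}
        for line, meta in family_counts.samples.groupby("cell_line", sort=True):
            is_atra = meta["condition"] == "ATRA"
            med_a = norm[meta.index[is_atra]].mean(axis=1).median()
            med_d = norm[meta.index[~is_atra]].mean(axis=1).median()
            out[line] = (med_a + pseudocount) / (med_d + pseudocount)
        return pd.Series(out, name="median_env_induction")
    raise ValueError(f"unknown mode {mode!r}")


def env_score_correlation(
    medians: pd.Series,
    scores: pd.Series,
    subtypes: pd.Series | None = None,
) -> pd.DataFrame:
    """OLS of median ENV induction on the ATRA-score, per subtype group.

    Returns one row per group (all, plus each subtype when ``subtypes`` is
    given) with r_squared, slope, intercept, n_lines and a degenerate flag
    (constant response — R^2 reported as 0).
    """
    lines = medians.index.intersection(scores.index)
    if subtypes is not None:
        lines = lines.intersection(subtypes.index)
    groups: dict[str, pd.Index] = {"all": lines}
    if subtypes is not None:
        for name in sorted(subtypes.loc[lines].unique()):
            groups[name] = lines[subtypes.loc[lines] == name]
    rows = []
    for name, idx in groups.items():
        if len(idx) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 lines")
        x = scores.loc[idx].to_numpy(float)
        y = medians.loc[idx].to_numpy(float)
        degenerate = np.ptp(y) == 0 or np.ptp(x) == 0
        if degenerate:
            slope, intercept, r2 = 0.0, float(np.mean(y)), 0.0
        else:
            fit = stats.linregress(x, y)
            slope, intercept, r2 = fit.slope, fit.intercept, fit.rvalue ** 2
        rows.append(
            {
                "group": name,
                "r_squared": float(r2),
                "slope": float(slope),
                "intercept": float(intercept),
                "n_lines": len(idx),
                "degenerate": bool(degenerate),
            }
        )
    return pd.DataFrame(rows).set_index("group")
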