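"""Dose-response scoring of retinoid (ATRA) sensitivity.

A cell line's sensitivity to the anti-proliferative action of all-trans
retinoic acid is summarized by the *ATRA-score*: viability fractions measured
over a log-spaced concentration grid are converted to inhibition curves, the
area under the inhibition curve (AUC, on the log10-concentration axis,
normalized to [0, 1]) is multiplied by the maximal inhibition (Amax), the
product is log2-transformed, and the resulting values are min-max rescaled
across the cohort so that 0 marks total resistance and 1 maximal sensitivity.
Lines are then split into HIGH/LOW (binary, default threshold 0.17) or
HIGH/INTERMEDIATE/LOW (ternary) sensitivity groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "DoseResponseAssay",
    "ScoreConfig",
    "AtraScore",
    "AtraScorer",
    "inhibition_curve",
    "atra_score_raw",
    "rescale_scores",
    "classify_sensitivity",
    "assays_from_frame",
    "read_curves",
    "write_scores",
]


@dataclass(frozen=True)
class DoseResponseAssay:
    """Replicate viability fractions for one cell line over a dose grid.

    Parameters
    ----------
    cell_line_id : str
        Identifier of the assayed line.
    concentrations : array-like of float
        Strictly increasing, positive drug concentrations in µM
        (log-spaced by assay design).
    viability : array-like, shape (n_concentrations, n_replicates)
        Fractions of the vehicle-control signal; non-negative and finite.
    """

    cell_line_id: str
    concentrations: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        viab = np.atleast_2d(np.asarray(self.viability, dtype=float))
        if conc.ndim != 1 or conc.size < 2:
            raise ValueError("assay needs >= 2 concentrations")
        if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")
        if viab.shape[0] != conc.size:
            raise ValueError(
                f"viability has {viab.shape[0]} rows for {conc.size} concentrations"
            )
        if viab.shape[1] < 1:
            raise ValueError("assay needs >= 1 replicate")
        if not np.all(np.isfinite(viab)) or np.any(viab < 0):
            raise ValueError("viability values must be finite and non-negative")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "viability", viab)

    @property
    def n_replicates(self) -> int:
        return self.viability.shape[1]


@dataclass(frozen=True)
class ScoreConfig:
    """Scoring thresholds.

    ``high_low_threshold`` splits the cohort into binary HIGH/LOW groups
    (score strictly above the threshold is HIGH; a tie is the conservative
    LOW call). ``class_boundaries`` are the ternary LOW/INTERMEDIATE and
    INTERMEDIATE/HIGH cut points. ``epsilon_product`` floors AUC * Amax
    before the log2 so totally resistant lines map to a finite cohort floor.
    """

    high_low_threshold: float = 0.17
    class_boundaries: tuple[float, float] = (0.17, 0.5)
    epsilon_product: float = 2.0 ** -20

    def __post_init__(self) -> None:
        if not 0.0 < self.high_low_threshold < 1.0:
            raise ValueError("high_low_threshold must be in (0, 1)")
        lo, hi = self.class_boundaries
        if not lo < hi:
            raise ValueError("class_boundaries must be ordered")
        if self.epsilon_product <= 0:
            raise ValueError("epsilon_product must be positive")


@dataclass
class AtraScore:
    """Per-line sensitivity statistic and cohort-rescaled score."""

    cell_line_id: str
    auc: float
    amax: float
    log2_product: float
    score: float = float("nan")
    sensitivity_class: str | None = None


def inhibition_curve(assay: DoseResponseAssay) -> np.ndarray:
    """Per-concentration mean growth inhibition, 1 - mean(viability), in [0, 1]."""
    return np.clip(1.0 - assay.viability.mean(axis=1), 0.0, 1.0)


def atra_score_raw(
    assay: DoseResponseAssay, config: ScoreConfig = ScoreConfig()
) -> AtraScore:
    """AUC, Amax and their log2 product for one line.

    AUC is the trapezoid of mean inhibition over log10(concentration),
    divided by the log10 range, hence a dimensionless mean inhibition in
    [0, 1]. Amax is the maximal per-concentration mean inhibition.
    """
    inh = inhibition_curve(assay)
    x = np.log10(assay.concentrations)
    auc = float(np.trapezoid(inh, x) / (x[-1] - x[0]))
    amax = float(inh.max())
    log2_product = float(np.log2(max(auc * amax, config.epsilon_product)))
    return AtraScore(assay.cell_line_id, auc=auc, amax=amax, log2_product=log2_product)


def rescale_scores(
    raw_scores: Sequence[AtraScore], config: ScoreConfig = ScoreConfig()
) -> list[AtraScore]:
    """Min-max rescale log2(AUC * Amax) across the cohort to [0, 1].

    The least sensitive line maps to 0, the most sensitive to 1; ordering is
    preserved. A degenerate cohort (all raw values identical) is an error —
    the rescaling is undefined.
    """
    if len(raw_scores) < 2:
        raise ValueError("rescaling needs a cohort of >= 2 cell lines")
    vals = np.array([s.log2_product for s in raw_scores], dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise ValueError("degenerate cohort: all log2(AUC*Amax) values identical")
    scaled = (vals - lo) / (hi - lo)
    out = []
    for s, sc in zip(raw_scores, scaled):
        s = replace(s, score=float(sc))
        s.sensitivity_class = classify_sensitivity(s.score, config, binary=False)
        out.append(s)
    return out


def classify_sensitivity(
    score: float | AtraScore,
    config: ScoreConfig = ScoreConfig(),
    binary: bool = True,
) -> str:
    """Sensitivity call for a rescaled score.

    Binary: HIGH iff score > threshold, else LOW (tie -> LOW). Ternary:
    LOW below the first boundary, HIGH above the second, INTERMEDIATE
    between (boundaries themselves fall in the lower class).
    """
    s = score.score if isinstance(score, AtraScore) else float(score)
    if not 0.0 <= s <= 1.0:
        raise ValueError("score must lie in [0, 1]")
    if binary:
        return "HIGH" if s > config.high_low_threshold else "LOW"
    lo, hi = config.class_boundaries
    if s <= lo:
        return "LOW"
    if s <= hi:
        return "INTERMEDIATE"
    return "HIGH"


class AtraScorer(BaseEstimator):
    """Cohort-level ATRA-score estimator.

    Fit on a collection of dose-response assays (or a long-format table);
    exposes the per-line AUC, Amax, log2 product, rescaled score and
    sensitivity calls as a tidy table.

    Parameters
    ----------
    threshold : float, default 0.17
        Binary HIGH/LOW split point on the rescaled score.
    class_boundaries : (float, float), default (0.17, 0.5)
        Ternary LOW/INTERMEDIATE/HIGH boundaries.
    epsilon_product : float, default 2**-20
        Floor on AUC * Amax before the log2 transform.

    Attributes
    ----------
    raw_ : list of AtraScore
        Per-line statistics before cohort rescaling.
    scores_ : pandas.DataFrame
        One row per line: auc, amax, log2_product, atra_score,
        binary_class, sensitivity_class; indexed by cell_line.
    """

    def __init__(
        self,
        threshold: float = 0.17,
        class_boundaries: tuple[float, float] = (0.17, 0.5),
        epsilon_product: float = 2.0 ** -20,
    ) -> None:
        self.threshold = threshold
        self.class_boundaries = class_boundaries
        self.epsilon_product = epsilon_product

    def _config(self) -> ScoreConfig:
        return ScoreConfig(
            high_low_threshold=self.threshold,
            class_boundaries=tuple(self.class_boundaries),
            epsilon_product=self.epsilon_product,
        )

    def fit(self, X: Iterable[DoseResponseAssay] | pd.DataFrame, y=None) -> "AtraScorer":
        if isinstance(X, pd.DataFrame):
            assays = assays_from_frame(X)
        else:
            assays = list(X)
        if not assays:
            raise ValueError("no assays provided")
        cfg = self._config()
        self.raw_ = [atra_score_raw(a, cfg) for a in assays]
        rescaled = rescale_scores(self.raw_, cfg)
        rows = []
        for s in rescaled:
            rows.append(
                {
                    "cell_line": s.cell_line_id,
                    "auc": s.auc,
                    "amax": s.amax,
                    "log2_product": s.log2_product,
                    "atra_score": s.score,
                    "binary_class": classify_sensitivity(s.score, cfg, binary=True),
                    "sensitivity_class": s.sensitivity_class,
                }
            )
        self.scores_ = pd.DataFrame(rows).set_index("cell_line")
        return self

    def fit_predict(self, X, y=None) -> pd.Series:
        """Fit and return the binary HIGH/LOW call per line."""
        self.fit(X)
        return self.scores_["binary_class"]

    @property
    def score_series(self) -> pd.Series:
        return self.scores_["atra_score"]


def assays_from_frame(frame: pd.DataFrame) -> list[DoseResponseAssay]:
    """Build assays from a long table.

    Expected columns: cell_line, concentration_uM, replicate,
    viability_fraction.
    """
    required = {"cell_line", "concentration_uM", "replicate", "viability_fraction"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"curve table missing columns: {sorted(missing)}")
    assays = []
    for line, grp in frame.groupby("cell_line", sort=True):
        wide = grp.pivot_table(
            index="concentration_uM",
            columns="replicate",
            values="viability_fraction",
        ).sort_index()
        if wide.isna().any().any():
            raise ValueError(f"incomplete dose/replicate grid for line {line!r}")
        assays.append(
            DoseResponseAssay(str(line), wide.index.to_numpy(float), wide.to_numpy(float))
        )
    return assays


def read_curves(path) -> list[DoseResponseAssay]:
    """Read a TSV of viability curves (see :func:`assays_from_frame`)."""
    return assays_from_frame(pd.read_csv(path, sep="\t"))


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", float_format="%.10g")
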