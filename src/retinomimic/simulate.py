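"""Synthetic study generator with known ground truth.

Emulates the structure of a 16-line breast-cancer retinoid study — 8 luminal
and 8 basal cell lines, each profiled under vehicle (DMSO) and treatment
(ATRA) in 3 replicates, plus 5-point log-spaced dose-response viability
curves with 6 replicates per point — so every pipeline stage can be
exercised, and its recovery measured, without any deposited data:

* dose-response curves are Hill-shaped with line-specific EC50/Emax driven
  by a single latent sensitivity in [0, 1] (the true potency ordering);
* gene counts are negative-binomial with log-normal baseline means and a
  mean-dispersion trend; a planted subset of genes responds to treatment
  with a log2 fold-change linear in the line's sensitivity;
* transposable-element instances inherit family-level induction that is
  sensitivity-proportional in basal lines and sensitivity-independent in
  luminal lines (the viral-mimicry contrast), and a set of decoy instances
  is planted inside exons so the annotation filter has something to catch;
* a toy two-chromosome gene/exon annotation, a repeat table, a family map
  and demonstration gene sets (planted up / planted down / random control)
  are emitted alongside.

Every random draw descends from one seed through named substreams, so a
given (config, seed) pair reproduces byte-identical outputs and each stage
can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import GenomicInterval, TEInstance, write_gtf, write_repeat_table
from .counts_de import CountMatrix
from .dose_response import DoseResponseAssay
from .enrichment import GeneSet, write_gmt

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SyntheticStudy",
    "simulate_dose_response",
    "simulate_counts",
    "simulate_study",
]

_STREAMS = ("dose", "genes", "te", "annotation", "sets")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shape and effect-size parameters (defaults mirror the design
    the pipeline targets: 16 lines, 8/8 subtype split, 5-dose curves with 6
    replicates, triplicate paired count samples)."""

    n_lines: int = 16
    n_luminal: int = 8
    doses: tuple = (0.001, 0.01, 0.1, 1.0, 10.0)
    n_viability_replicates: int = 6
    viability_noise_sd: float = 0.05
    n_replicates: int = 3
    n_genes: int = 2000
    n_planted_genes: int = 200
    planted_slope_min: float = 1.0
    planted_slope_max: float = 2.5
    planted_noise_sd: float = 0.25
    gene_log_mean: float = float(np.log(100.0))
    gene_log_sd: float = 1.0
    dispersion_intercept: float = 0.05
    dispersion_slope: float = 5.0
    library_size_sd: float = 0.1
    n_te_instances: int = 240
    n_te_families: int = 8
    n_decoys: int = 24
    te_log_mean: float = float(np.log(50.0))
    te_log_sd: float = 0.6
    basal_env_slope_min: float = 1.5
    basal_env_slope_max: float = 2.5
    luminal_env_lfc_min: float = 0.5
    luminal_env_lfc_max: float = 1.5
    luminal_env_line_sd: float = 0.4
    env_noise_sd: float = 0.1
    n_annotation_genes: int = 30

    def __post_init__(self) -> None:
        if self.n_lines < 2 or not 0 <= self.n_luminal <= self.n_lines:
            raise ValueError("invalid cohort shape")
        if self.n_te_families < 1:
            raise ValueError("family list must be non-empty")
        if self.n_planted_genes > self.n_genes:
            raise ValueError("more planted genes than genes")

    def line_table(self) -> pd.DataFrame:
        """Line names, subtypes and latent sensitivities (the ground truth).

        Sensitivities are evenly spread over [0.05, 0.95] within each
        subtype, so both subtypes span resistant-to-sensitive."""
        names, subtypes, sens = [], [], []
        n_basal = self.n_lines - self.n_luminal
        for prefix, n in (("LUM", self.n_luminal), ("BAS", n_basal)):
            grid = np.linspace(0.05, 0.95, n) if n > 1 else np.array([0.5] * n)
            for i in range(n):
                names.append(f"{prefix}{i + 1:02d}")
                subtypes.append("luminal" if prefix == "LUM" else "basal")
                sens.append(float(grid[i]))
        return pd.DataFrame(
            {"subtype": subtypes, "sensitivity": sens},
            index=pd.Index(names, name="cell_line"),
        )


@dataclass
class SimulationTruth:
    """Everything needed to check recovery, serializable to JSON."""

    seed: int
    line_sensitivity: dict
    line_subtype: dict
    planted_gene_slopes: dict
    te_family_basal_slope: dict
    te_family_luminal_lfc: dict
    luminal_line_env_deviation: dict
    instance_family: dict
    decoy_instances: list
    config: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _hill_inhibition(dose: np.ndarray, emax: float, ec50: float, hill: float = 1.2) -> np.ndarray:
    return emax * dose ** hill / (dose ** hill + ec50 ** hill)


def simulate_dose_response(
    config: SimulationConfig = SimulationConfig(),
    seed: int = 0,
    noise_sd: float | None = None,
) -> tuple[list[DoseResponseAssay], pd.DataFrame]:
    """Hill-shaped viability curves plus the true potency table.

    Each line's latent sensitivity s sets Emax = 0.15 + 0.8 s and
    EC50 = 10^(1.5 - 3 s) µM, so potency ordering follows s. Replicate noise
    is Gaussian, truncated at zero viability.
    """
    lines = config.line_table()
    sd = config.viability_noise_sd if noise_sd is None else noise_sd
    rng = _rngs(seed)["dose"]
    doses = np.asarray(config.doses, dtype=float)
    assays = []
    for name, row in lines.iterrows():
        s = row["sensitivity"]
        inh = _hill_inhibition(doses, emax=0.15 + 0.8 * s, ec50=10.0 ** (1.5 - 3.0 * s))
        viab = 1.0 - inh[:, None] + rng.normal(
            0.0, sd, size=(doses.size, config.n_viability_replicates)
        )
        assays.append(DoseResponseAssay(name, doses, np.clip(viab, 0.0, None)))
    return assays, lines


def _sample_sheet(lines: pd.DataFrame, n_replicates: int) -> pd.DataFrame:
    rows = []
    for name, row in lines.iterrows():
        for cond in ("DMSO", "ATRA"):
            for r in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample": f"{name}_{cond}_R{r}",
                        "cell_line": name,
                        "condition": cond,
                        "replicate": r,
                        "subtype": row["subtype"],
                    }
                )
    return pd.DataFrame(rows).set_index("sample")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, alpha) with Var = mu + alpha mu^2, vectorized."""
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_counts(
    config: SimulationConfig = SimulationConfig(),
    seed: int = 0,
    lines: pd.DataFrame | None = None,
) -> tuple[CountMatrix, CountMatrix, dict, SimulationTruth]:
    """Gene and TE count matrices, toy annotation and the ground truth.

    Returns ``(gene_counts, te_counts, annotation, truth)`` where
    ``annotation`` is a dict with genes, exons, repeats (decoys included),
    the instance -> family map and the demonstration gene sets.
    """
    rngs = _rngs(seed)
    if lines is None:
        lines = config.line_table()
    samples = _sample_sheet(lines, config.n_replicates)
    sens = lines["sensitivity"]
    is_atra = (samples["condition"] == "ATRA").to_numpy()
    sample_lines = samples["cell_line"].to_numpy()

    # --- genes ----------------------------------------------------------
    g = rngs["genes"]
    gene_ids = np.array([f"GENE{i:05d}" for i in range(config.n_genes)])
    base_mean = g.lognormal(config.gene_log_mean, config.gene_log_sd, config.n_genes)
    base_mean = np.maximum(base_mean, 1.0)
    alpha = config.dispersion_intercept + config.dispersion_slope / base_mean
    planted_idx = g.choice(config.n_genes, size=config.n_planted_genes, replace=False)
    slopes = g.uniform(config.planted_slope_min, config.planted_slope_max, config.n_planted_genes)
    slopes *= g.choice([-1.0, 1.0], size=config.n_planted_genes)
    slope_vec = np.zeros(config.n_genes)
    slope_vec[planted_idx] = slopes

    lib = np.exp(g.normal(0.0, config.library_size_sd, len(samples)))
    lfc = np.zeros((config.n_genes, len(samples)))
    for j, (line, treated) in enumerate(zip(sample_lines, is_atra)):
        if treated:
            noise = g.normal(0.0, config.planted_noise_sd, config.n_genes)
            lfc[:, j] = np.where(slope_vec != 0, slope_vec * sens[line] + noise, 0.0)
    mu = base_mean[:, None] * 2.0 ** lfc * lib[None, :]
    gene_counts = _nb_draw(g, mu, alpha[:, None])
    gene_cm = CountMatrix(pd.DataFrame(gene_counts, index=gene_ids, columns=samples.index), samples)

    # --- transposable elements -----------------------------------------
    t = rngs["te"]
    fam_names = [f"ENV_FAM{f + 1}" for f in range(config.n_te_families)]
    basal_slope = dict(
        zip(fam_names, t.uniform(config.basal_env_slope_min, config.basal_env_slope_max, config.n_te_families))
    )
    luminal_lfc = dict(
        zip(fam_names, t.uniform(config.luminal_env_lfc_min, config.luminal_env_lfc_max, config.n_te_families))
    )
    n_all_te = config.n_te_instances + config.n_decoys
    te_ids, te_fams = [], []
    for i in range(config.n_te_instances):
        te_ids.append(f"TE{i:05d}")
        te_fams.append(fam_names[i % config.n_te_families])
    decoy_ids = []
    for d in range(config.n_decoys):
        iid = f"TE_DECOY{d:04d}"
        decoy_ids.append(iid)
        te_ids.append(iid)
        te_fams.append(fam_names[d % config.n_te_families])
    te_mean = np.maximum(t.lognormal(config.te_log_mean, config.te_log_sd, n_all_te), 1.0)
    te_alpha = config.dispersion_intercept + config.dispersion_slope / te_mean

    subtype_by_line = lines["subtype"]
    # Luminal lines vary in ENV induction from line to line, but the truth is
    # exactly score-independent: the per-line deviations are sampled and then
    # projected orthogonal to the (centered) sensitivity vector within the
    # luminal group, planting an exact null for the score correlation.
    lum_lines = lines.index[lines["subtype"] == "luminal"]
    lum_dev = pd.Series(0.0, index=lines.index)
    if len(lum_lines) >= 3 and config.luminal_env_line_sd > 0:
        d = t.normal(0.0, 1.0, len(lum_lines))
        s_c = sens[lum_lines].to_numpy() - sens[lum_lines].mean()
        d = d - d.mean()
        if np.dot(s_c, s_c) > 0:
            d = d - np.dot(d, s_c) / np.dot(s_c, s_c) * s_c
        sd = d.std()
        if sd > 0:
            lum_dev[lum_lines] = d / sd * config.luminal_env_line_sd

    te_lfc = np.zeros((n_all_te, len(samples)))
    fam_arr = np.array(te_fams)
    for j, (line, treated) in enumerate(zip(sample_lines, is_atra)):
        if not treated:
            continue
        if subtype_by_line[line] == "basal":
            fam_effect = np.array([basal_slope[f] * sens[line] for f in fam_arr])
        else:
            fam_effect = np.array([luminal_lfc[f] + lum_dev[line] for f in fam_arr])
        te_lfc[:, j] = fam_effect + t.normal(0.0, config.env_noise_sd, n_all_te)
    te_mu = te_mean[:, None] * 2.0 ** te_lfc * lib[None, :]
    te_counts = _nb_draw(t, te_mu, te_alpha[:, None])
    te_cm = CountMatrix(pd.DataFrame(te_counts, index=te_ids, columns=samples.index), samples)

    # --- toy annotation --------------------------------------------------
    genes, exons, repeats = _toy_annotation(config, te_ids, te_fams, decoy_ids)

    # --- demonstration gene sets ----------------------------------------
    srng = rngs["sets"]
    up = [gene_ids[i] for i in planted_idx[slope_vec[planted_idx] > 0]]
    down = [gene_ids[i] for i in planted_idx[slope_vec[planted_idx] < 0]]
    unplanted = np.setdiff1d(np.arange(config.n_genes), planted_idx)
    control = list(gene_ids[srng.choice(unplanted, size=min(50, unplanted.size), replace=False)])
    gene_sets = [
        GeneSet(name, frozenset(members), "synthetic")
        for name, members in (
            ("PLANTED_UP", up),
            ("PLANTED_DOWN", down),
            ("RANDOM_CONTROL", control),
        )
        if members
    ]

    truth = SimulationTruth(
        seed=seed,
        line_sensitivity={k: float(v) for k, v in sens.items()},
        line_subtype=dict(lines["subtype"]),
        planted_gene_slopes={gene_ids[i]: float(slope_vec[i]) for i in sorted(planted_idx)},
        te_family_basal_slope={k: float(v) for k, v in basal_slope.items()},
        te_family_luminal_lfc={k: float(v) for k, v in luminal_lfc.items()},
        luminal_line_env_deviation={k: float(v) for k, v in lum_dev[lum_lines].items()},
        instance_family=dict(zip(te_ids, te_fams)),
        decoy_instances=decoy_ids,
        config=asdict(config),
    )
    annotation = {
        "genes": genes,
        "exons": exons,
        "repeats": repeats,
        "instance_family": dict(zip(te_ids, te_fams)),
        "gene_sets": gene_sets,
    }
    return gene_cm, te_cm, annotation, truth


def _toy_annotation(
    config: SimulationConfig,
    te_ids: list[str],
    te_fams: list[str],
    decoy_ids: list[str],
) -> tuple[list[GenomicInterval], list[GenomicInterval], list[TEInstance]]:
    """Two-chromosome toy layout: genes with two exons each, repeats in the
    intergenic gaps, decoy repeats inside first exons."""
    genes, exons = [], []
    spans = []  # (chrom, gene_start) per annotation gene
    for k in range(config.n_annotation_genes):
        chrom = f"chr{1 + (k % 2)}"
        start = 1001 + (k // 2) * 20000
        gid = f"AGENE{k:03d}"
        spans.append((chrom, start))
        genes.append(GenomicInterval(chrom, start, start + 4999, "+", "gene", {"gene_id": gid}))
        exons.append(GenomicInterval(chrom, start, start + 999, "+", "exon", {"gene_id": gid, "exon_number": "1"}))
        exons.append(
            GenomicInterval(chrom, start + 3000, start + 3999, "+", "exon", {"gene_id": gid, "exon_number": "2"})
        )
    decoy_set = set(decoy_ids)
    repeats = []
    n_gaps = len(spans)
    gap_slot = 0
    for iid, fam in zip(te_ids, te_fams):
        rep_name = f"{fam}_REP"
        if iid in decoy_set:
            chrom, gstart = spans[len(repeats) % n_gaps]
            start = gstart + 100  # inside exon 1
            iv = GenomicInterval(chrom, start, start + 199, "-", "repeat")
        else:
            chrom, gstart = spans[gap_slot % n_gaps]
            offset = 6000 + (gap_slot // n_gaps) * 400
            start = gstart + offset
            iv = GenomicInterval(chrom, start, start + 299, "+", "repeat")
            gap_slot += 1
        repeats.append(TEInstance(iv, repeat_name=rep_name, family=fam, instance_id=iid))
    return genes, exons, repeats


@dataclass
class SyntheticStudy:
    """Full generated study bundle."""

    assays: list
    lines: pd.DataFrame
    gene_counts: CountMatrix
    te_counts: CountMatrix
    annotation: dict
    truth: SimulationTruth

    def write(self, outdir) -> dict:
        """Write every artifact as plain text; returns the path map."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        curves = []
        for a in self.assays:
            for ci, conc in enumerate(a.concentrations):
                for ri in range(a.n_replicates):
                    curves.append(
                        {
                            "cell_line": a.cell_line_id,
                            "concentration_uM": conc,
                            "replicate": ri + 1,
                            "viability_fraction": a.viability[ci, ri],
                        }
                    )
        paths = {
            "curves": out / "curves.tsv",
            "gene_counts": out / "gene_counts.tsv",
            "te_counts": out / "te_counts.tsv",
            "samples": out / "samples.tsv",
            "genes_gtf": out / "genes.gtf",
            "repeats": out / "repeats.tsv",
            "families": out / "families.tsv",
            "gene_sets": out / "sets.gmt",
            "truth": out / "truth.json",
        }
        pd.DataFrame(curves).to_csv(paths["curves"], sep="\t", index=False, float_format="%.10g")
        self.gene_counts.to_tsv(paths["gene_counts"], paths["samples"])
        self.te_counts.counts.to_csv(paths["te_counts"], sep="\t")
        write_gtf(self.annotation["genes"] + self.annotation["exons"], paths["genes_gtf"])
        write_repeat_table(self.annotation["repeats"], paths["repeats"])
        fam_rows = sorted({(t.repeat_name, t.family) for t in self.annotation["repeats"]})
        pd.DataFrame(fam_rows, columns=["repeat_name", "family"]).to_csv(
            paths["families"], sep="\t", index=False
        )
        write_gmt(self.annotation["gene_sets"], paths["gene_sets"])
        self.truth.to_json(paths["truth"])
        return {k: str(v) for k, v in paths.items()}


def simulate_study(
    config: SimulationConfig = SimulationConfig(), seed: int = 0
) -> SyntheticStudy:
    """Generate the complete study (curves + counts + annotation + truth)."""
    assays, lines = simulate_dose_response(config, seed)
    gene_cm, te_cm, annotation, truth = simulate_counts(config, seed, lines)
    return SyntheticStudy(assays, lines, gene_cm, te_cm, annotation, truth)
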