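"""Synthetic data with known ground truth for every pipeline stage.

The peptide generator emulates a paired knockdown experiment: four
patient-derived cell lines, each measured under a control (scrambled
siRNA) and a treatment (targeting siRNA) condition.  On the log2 scale a
peptide intensity is

    baseline(protein) + cell-line effect (shared by the pair's two
    conditions) + peptide ionization offset + condition effect (treatment
    samples of differential proteins only) + technical noise,

exponentiated to the linear scale.  Each cell then goes missing
independently with probability ``logistic((mnar_tau - log2 x) / mnar_slope)``
— the left-censored, abundance-dependent (MNAR) mechanism that motivates
noise-floor imputation.  Differential proteins are a ``pi_de`` fraction
with down-skewed signs (``p_down`` defaults to 0.72, matching the roughly
132-down / 52-up split such knockdown proteomes show).

One master seed governs all draws through numpy ``SeedSequence`` spawning
in a fixed stream order (truth, structure, intensities, missingness), so
stages are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .assay import StainingCount, StressTestTrace
from .containers import CONTROL, TREATMENT, PeptideMatrix


@dataclass
class SimParams:
    """Generator settings; defaults are the emulated study conditions."""

    n_proteins: int = 2000
    mean_extra_peptides: float = 2.0  # peptides/protein = 1 + Poisson(mean)
    n_pairs: int = 4
    pi_de: float = 0.10
    effect_low: float = 0.5  # |log2FC| ~ Uniform(low, high); set equal to fix
    effect_high: float = 2.0
    p_down: float = 0.72
    baseline_log2_mean: float = 23.0
    baseline_log2_sd: float = 2.0
    cellline_sd: float = 0.5
    peptide_offset_sd: float = 1.0
    tech_sd: float = 0.25
    mnar_tau: float = 19.0
    mnar_slope: float = 1.0
    p_unique: float = 0.70
    p_razor: float = 0.25  # remainder is class "other"
    seed: int = 0

    def __post_init__(self):
        for name in ("baseline_log2_sd", "cellline_sd", "peptide_offset_sd", "tech_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.pi_de <= 1 or not 0 <= self.p_down <= 1:
            raise ValueError("pi_de and p_down must be in [0, 1]")
        if self.effect_low > self.effect_high or self.effect_low < 0:
            raise ValueError("need 0 <= effect_low <= effect_high")
        if self.n_pairs < 2:
            raise ValueError("the paired design needs at least 2 cell lines")
        if self.mnar_slope <= 0:
            raise ValueError("mnar_slope must be > 0")


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def missing_probability(log2_intensity, p: SimParams):
    """Logistic MNAR dropout probability at a given log2 intensity."""
    z = (p.mnar_tau - np.asarray(log2_intensity, dtype=float)) / p.mnar_slope
    return special.expit(z)


def simulate_truth(p: SimParams, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"G{i:04d}" for i in range(1, p.n_proteins + 1)]
    is_de = rng.random(p.n_proteins) < p.pi_de
    magnitude = rng.uniform(p.effect_low, p.effect_high, p.n_proteins)
    sign = np.where(rng.random(p.n_proteins) < p.p_down, -1.0, 1.0)
    true_log2fc = np.where(is_de, sign * magnitude, 0.0)
    direction = np.select([true_log2fc > 0, true_log2fc < 0], ["up", "down"], "none")
    return pd.DataFrame(
        {"protein_id": ids, "is_de": is_de, "true_log2fc": true_log2fc,
         "direction": direction}
    )


def simulate_peptides(p: SimParams) -> tuple[PeptideMatrix, pd.DataFrame]:
    """Generate a peptide matrix and its ground-truth table."""
    rng_truth, rng_struct, rng_intens, rng_miss = _streams(p.seed, 4)
    truth = simulate_truth(p, rng_truth)

    n_pep_per_prot = 1 + rng_struct.poisson(p.mean_extra_peptides, p.n_proteins)
    protein_of = np.repeat(np.arange(p.n_proteins), n_pep_per_prot)
    n_pep = len(protein_of)
    classes = rng_struct.choice(
        ["unique", "razor", "other"],
        size=n_pep,
        p=[p.p_unique, p.p_razor, 1.0 - p.p_unique - p.p_razor],
    )
    peptide_ids = [f"PEP{i:05d}" for i in range(1, n_pep + 1)]

    lines = [f"L{j + 1}" for j in range(p.n_pairs)]
    samples = [f"{ln}_{cond}" for ln in lines for cond in ("ctrl", "kd")]
    condition_of = {s: (CONTROL if s.endswith("_ctrl") else TREATMENT) for s in samples}
    pair_of = {s: s.split("_")[0] for s in samples}

    baseline = rng_intens.normal(p.baseline_log2_mean, p.baseline_log2_sd, p.n_proteins)
    cl_effect = rng_intens.normal(0.0, p.cellline_sd, (p.n_proteins, p.n_pairs))
    pep_offset = rng_intens.normal(0.0, p.peptide_offset_sd, n_pep)
    effect = truth["true_log2fc"].to_numpy()

    log2 = np.empty((n_pep, len(samples)))
    for j, s in enumerate(samples):
        line_idx = lines.index(pair_of[s])
        mu = (
            baseline[protein_of]
            + cl_effect[protein_of, line_idx]
            + pep_offset
        )
        if condition_of[s] == TREATMENT:
            mu = mu + effect[protein_of]
        log2[:, j] = mu + rng_intens.normal(0.0, p.tech_sd, n_pep)

    linear = 2.0 ** log2
    dropped = rng_miss.random(log2.shape) < missing_probability(log2, p)
    linear[dropped] = np.nan

    intens = pd.DataFrame(linear, index=pd.Index(peptide_ids, name="peptide_id"),
                          columns=samples)
    leading = pd.Series(
        truth["protein_id"].to_numpy()[protein_of], index=intens.index
    )
    pclass = pd.Series(classes, index=intens.index)
    matrix = PeptideMatrix(
        intensities=intens,
        leading_protein=leading,
        peptide_class=pclass,
        condition_of=condition_of,
        pair_of=pair_of,
    )
    return matrix, truth


def simulate_deg_table(
    truth: pd.DataFrame,
    seed: int,
    shared_fraction: float = 1.0,
    transcript_noise_sd: float = 0.3,
    null_log2fc_sd: float = 0.15,
) -> pd.DataFrame:
    """Transcriptome table sharing a fraction of the proteomic DE truth.

    Shared differential genes get a noisy copy of the protein-level effect
    and a small fdr; everything else is null (log2fc near 0, fdr well
    above threshold).  Deterministic given the seed.
    """
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(truth)
    de = truth["is_de"].to_numpy()
    shared = de & (rng.random(n) < shared_fraction)
    log2fc = np.where(
        shared,
        truth["true_log2fc"].to_numpy() + rng.normal(0, transcript_noise_sd, n),
        rng.normal(0, null_log2fc_sd, n),
    )
    fdr = np.where(shared, 10.0 ** rng.uniform(-8, -2, n), rng.uniform(0.1, 1.0, n))
    return pd.DataFrame(
        {"gene": truth["protein_id"], "log2fc": log2fc, "fdr": fdr,
         "true_de": shared}
    )


def simulate_gene_sets(
    truth: pd.DataFrame,
    seed: int,
    n_random_sets: int = 20,
    set_size: tuple[int, int] = (15, 60),
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Random gene sets plus one set enriched for down-regulated truth."""
    rng = np.random.default_rng(seed)
    ids = truth["protein_id"].to_numpy()
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    for i in range(1, n_random_sets + 1):
        size = min(int(rng.integers(set_size[0], set_size[1] + 1)), len(ids) - 1)
        sets[f"RANDOM_{i:02d}"] = set(rng.choice(ids, size, replace=False))
        desc[f"RANDOM_{i:02d}"] = "random member draw"
    down = truth.loc[truth["direction"] == "down", "protein_id"].to_numpy()
    if len(down):
        take = min(len(down), set_size[1])
        members = set(rng.choice(down, take, replace=False))
        pad = rng.choice(ids, min(max(set_size[0] - take, 5), len(ids)), replace=False)
        sets["TRUE_DOWN_SET"] = members | set(pad)
        desc["TRUE_DOWN_SET"] = "enriched for truly downregulated proteins"
    return sets, desc


def simulate_trace(
    seed: int,
    cell_count: int = 35_000,
    basal_ocr: float = 100.0,
    post_oligo_ocr: float = 40.0,
    post_fccp_ocr: float = 180.0,
    post_rotenone_ocr: float = 10.0,
    basal_ecar: float = 30.0,
    post_oligo_ecar: float = 60.0,
    noise_sd: float = 2.0,
    cycles_per_segment: int = 3,
    cycle_minutes: float = 6.5,
) -> StressTestTrace:
    """Flux trace built from segment means plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    n = 4 * cycles_per_segment
    timepoints = cycle_minutes * np.arange(1, n + 1)
    seg = np.repeat([0, 1, 2, 3], cycles_per_segment)
    ocr_means = np.array([basal_ocr, post_oligo_ocr, post_fccp_ocr, post_rotenone_ocr])
    ecar_means = np.array(
        [basal_ecar, post_oligo_ecar, post_oligo_ecar * 0.9, post_oligo_ecar * 0.8]
    )
    ocr = ocr_means[seg] + rng.normal(0, noise_sd, n)
    ecar = ecar_means[seg] + rng.normal(0, noise_sd / 2, n)
    half = cycle_minutes / 2
    injections = [
        (timepoints[cycles_per_segment - 1] + half, "oligomycin"),
        (timepoints[2 * cycles_per_segment - 1] + half, "fccp"),
        (timepoints[3 * cycles_per_segment - 1] + half, "rotenone"),
    ]
    return StressTestTrace(
        timepoints=timepoints, ocr=ocr, ecar=ecar,
        injections=injections, cell_count=cell_count,
    )


def simulate_counts(
    seed: int, n_total: int = 600, p_positive: float = 0.3
) -> StainingCount:
    """Binomial staining count at a given positivity rate."""
    rng = np.random.default_rng(seed)
    return StainingCount(
        positive=int(rng.binomial(n_total, p_positive)), total_dapi=n_total
    )
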