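"""Peptide-to-protein label-free quantification chain.

The treatment chain runs in a fixed order:

1. **normalize** — rescale each sample (column) so its non-missing median
   equals the median of all per-sample medians;
2. **filter** — keep unique/razor peptides observed at least
   ``min_values_per_condition`` times in the control group *or* in the
   treatment group ("quantified" peptides);
3. **impute** — replace remaining missing values by a per-sample noise
   floor, the first centile of the sample's observed intensities (missing
   values in label-free MS are left-censored: low-abundance ions fall under
   the detection limit, so a low-quantile noise value is the natural fill);
4. **aggregate** — sum peptide intensities per leading razor protein and
   keep proteins with at least ``min_peptides_per_protein`` quantified
   peptides.

The order matters (imputed values participate in protein sums) and is
frozen; :func:`run_lfq` composes the four stages and reports survivor
counts per stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CONTROL, TREATMENT, PeptideMatrix, ProteinMatrix

logger = logging.getLogger(__name__)


@dataclass
class LfqParams:
    """Tunable parameters of the quantification chain.

    noise_centile is a percentage in (0, 100); quantile_rule is any
    interpolation method accepted by :func:`numpy.percentile` (the default
    linear interpolation between order statistics).
    """

    noise_centile: float = 1.0
    min_values_per_condition: int = 2
    min_peptides_per_protein: int = 2
    include_classes: frozenset[str] = frozenset({"unique", "razor"})
    quantile_rule: str = "linear"

    def __post_init__(self):
        if not 0 < self.noise_centile < 100:
            raise ValueError("noise_centile must be in (0, 100)")
        if self.min_values_per_condition < 1 or self.min_peptides_per_protein < 1:
            raise ValueError("minimum counts must be >= 1")


def normalize_by_sample_median(m: PeptideMatrix) -> PeptideMatrix:
    """Equalize per-sample medians (normalization by column).

    Each value becomes ``x * T / m_j`` where ``m_j`` is the median of
    sample j's non-missing intensities and ``T`` is the median of the
    ``m_j``.  The target T is a convention only: any positive constant
    yields identical downstream ratios and log-scale tests.
    """
    medians = m.intensities.median(axis=0, skipna=True)
    empty = medians.index[medians.isna()].tolist()
    if empty:
        raise ValueError(f"samples with no observed intensities: {empty}")
    target = float(np.median(medians.to_numpy()))
    scaled = m.intensities * (target / medians)
    return m.replace_intensities(scaled)


def filter_quantifiable(m: PeptideMatrix, p: LfqParams) -> PeptideMatrix:
    """Keep quantified peptides of the included classes, order preserved.

    A peptide is quantified when it has at least
    ``min_values_per_condition`` observed values in the control group or
    in the treatment group.
    """
    class_ok = m.peptide_class.isin(p.include_classes)
    n_ctrl = m.intensities[m.samples_in(CONTROL)].notna().sum(axis=1)
    n_trt = m.intensities[m.samples_in(TREATMENT)].notna().sum(axis=1)
    quantified = (n_ctrl >= p.min_values_per_condition) | (
        n_trt >= p.min_values_per_condition
    )
    keep = m.intensities.index[class_ok & quantified]
    if len(keep) == 0:
        logger.warning("no peptide passed the quantifiability filter")
    return m.subset(keep)


def impute_noise_floor(m: PeptideMatrix, p: LfqParams) -> PeptideMatrix:
    """Fill missing cells with the per-sample noise_centile-th percentile.

    Observed cells are bit-identical to the input; the output has no
    missing values.
    """
    filled = m.intensities.copy()
    for s in m.sample_ids:
        col = filled[s]
        observed = col.dropna().to_numpy()
        if observed.size == 0:
            raise ValueError(f"sample {s!r} has no observed values to impute from")
        noise = float(np.percentile(observed, p.noise_centile, method=p.quantile_rule))
        filled[s] = col.fillna(noise)
    return m.replace_intensities(filled)


def aggregate_to_proteins(m: PeptideMatrix, p: LfqParams) -> ProteinMatrix:
    """Sum peptide intensities by leading razor protein.

    Proteins with fewer than ``min_peptides_per_protein`` contributing
    peptides are dropped.  Requires a fully imputed matrix.
    """
    if m.intensities.isna().any().any():
        raise ValueError("aggregate_to_proteins requires an imputed matrix")
    groups = m.intensities.groupby(m.leading_protein, sort=True)
    sums = groups.sum()
    sums.index.name = "protein_id"
    counts = groups.size().rename("n_quantified_peptides")
    keep = counts.index[counts >= p.min_peptides_per_protein]
    return ProteinMatrix(
        intensities=sums.loc[keep],
        n_quantified_peptides=counts.loc[keep],
        condition_of=dict(m.condition_of),
        pair_of=dict(m.pair_of),
    )


def run_lfq(m: PeptideMatrix, p: LfqParams | None = None) -> tuple[ProteinMatrix, pd.DataFrame]:
    """Run the full chain; returns (protein matrix, stage report).

    The report has one row per stage with the surviving peptide and
    protein counts; counts are monotone nonincreasing because the stages
    only rescale, fill, or remove.
    """
    p = p or LfqParams()
    stages = []

    def log_stage(name, pm: PeptideMatrix | None, prot: ProteinMatrix | None = None):
        n_pep = len(pm.peptide_ids) if pm is not None else int(prot.n_quantified_peptides.sum())
        n_prot = (
            pm.leading_protein.nunique() if pm is not None else len(prot.protein_ids)
        )
        stages.append({"stage": name, "peptides": n_pep, "proteins": n_prot})

    log_stage("input", m)
    normed = normalize_by_sample_median(m)
    log_stage("normalized", normed)
    filtered = filter_quantifiable(normed, p)
    log_stage("quantifiable", filtered)
    if len(filtered.peptide_ids) == 0:
        report = pd.DataFrame(stages + [{"stage": "proteins", "peptides": 0, "proteins": 0}])
        empty = ProteinMatrix(
            intensities=pd.DataFrame(
                np.empty((0, len(m.sample_ids))), columns=m.sample_ids, dtype=float
            ),
            n_quantified_peptides=pd.Series(dtype=int),
            condition_of=dict(m.condition_of),
            pair_of=dict(m.pair_of),
        )
        return empty, report
    imputed = impute_noise_floor(filtered, p)
    log_stage("imputed", imputed)
    proteins = aggregate_to_proteins(imputed, p)
    log_stage("proteins", None, proteins)
    report = pd.DataFrame(stages)
    logger.info("lfq chain: %s", report.to_dict("records"))
    return proteins, report
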