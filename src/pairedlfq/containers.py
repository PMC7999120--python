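"""In-memory containers for the peptide→protein quantification pipeline.

Intensities are kept on the linear scale in pandas DataFrames whose rows are
features (peptides or proteins) and whose columns are samples.  Missing
observations are NaN; a stored zero is never a valid intensity and is
converted to NaN on read.  Each matrix carries the experimental design as two
maps: ``condition_of`` (sample → ``control``/``treatment``) and ``pair_of``
(sample → cell-line label).  The design is *paired* when every cell line
appears in both conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
TREATMENT = "treatment"
CONDITIONS = (CONTROL, TREATMENT)

PEPTIDE_CLASSES = ("unique", "razor", "other")


class DesignError(ValueError):
    """The sample annotation does not describe a valid two-condition design."""


def _check_design(sample_ids, condition_of, pair_of):
    for s in sample_ids:
        if s not in condition_of:
            raise DesignError(f"sample {s!r} has no condition label")
        if condition_of[s] not in CONDITIONS:
            raise DesignError(
                f"sample {s!r}: condition {condition_of[s]!r} is not one of {CONDITIONS}"
            )
        if s not in pair_of:
            raise DesignError(f"sample {s!r} has no cell-line (pair) label")


def _is_paired(sample_ids, condition_of, pair_of) -> bool:
    lines: dict[str, set[str]] = {}
    for s in sample_ids:
        lines.setdefault(pair_of[s], set()).add(condition_of[s])
    return all(conds == set(CONDITIONS) for conds in lines.values())


@dataclass
class PeptideMatrix:
    """Peptide rows × sample columns of linear-scale intensities.

    Parameters
    ----------
    intensities
        DataFrame indexed by peptide id; NaN marks missing, all stored
        values must be strictly positive.
    leading_protein
        Per-peptide leading razor protein accession (aligned to the index).
    peptide_class
        Per-peptide class, one of ``unique``/``razor``/``other``.
    condition_of, pair_of
        Sample → condition / cell-line maps covering every column.
    """

    intensities: pd.DataFrame
    leading_protein: pd.Series
    peptide_class: pd.Series
    condition_of: dict[str, str]
    pair_of: dict[str, str]
    paired: bool = field(init=False)

    def __post_init__(self):
        _check_design(self.sample_ids, self.condition_of, self.pair_of)
        self.leading_protein = self.leading_protein.reindex(self.intensities.index)
        self.peptide_class = self.peptide_class.reindex(self.intensities.index)
        if self.leading_protein.isna().any():
            bad = self.intensities.index[self.leading_protein.isna()][:5].tolist()
            raise ValueError(f"peptides without a leading protein: {bad}")
        unknown = set(self.peptide_class.dropna()) - set(PEPTIDE_CLASSES)
        if unknown:
            raise ValueError(f"unknown peptide classes: {sorted(unknown)}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("intensities must be > 0 or NaN (zeros become NaN on read)")
        self.paired = _is_paired(self.sample_ids, self.condition_of, self.pair_of)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.intensities.index)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition_of[s] == condition]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.intensities.isna()

    def replace_intensities(self, values: pd.DataFrame) -> "PeptideMatrix":
        """New matrix with the same annotation but different values."""
        return PeptideMatrix(
            intensities=values,
            leading_protein=self.leading_protein.loc[values.index],
            peptide_class=self.peptide_class.loc[values.index],
            condition_of=dict(self.condition_of),
            pair_of=dict(self.pair_of),
        )

    def subset(self, peptide_ids) -> "PeptideMatrix":
        return self.replace_intensities(self.intensities.loc[peptide_ids])


@dataclass
class ProteinMatrix:
    """Aggregated per-protein intensities; strictly positive, no missing."""

    intensities: pd.DataFrame
    n_quantified_peptides: pd.Series
    condition_of: dict[str, str]
    pair_of: dict[str, str]
    paired: bool = field(init=False)

    def __post_init__(self):
        _check_design(self.sample_ids, self.condition_of, self.pair_of)
        self.n_quantified_peptides = self.n_quantified_peptides.reindex(
            self.intensities.index
        )
        vals = self.intensities.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("ProteinMatrix must not contain missing values")
        if np.any(vals <= 0):
            raise ValueError("protein intensities must be strictly positive")
        self.paired = _is_paired(self.sample_ids, self.condition_of, self.pair_of)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensities.index)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition_of[s] == condition]
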