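import numpy as np
import pandas as pd
import pytest

from pairedlfq.containers import PeptideMatrix
from pairedlfq.simulate import SimParams, simulate_peptides


def build_matrix(values, proteins=None, classes=None, n_pairs=None):
    """Construct a small PeptideMatrix from a {sample: column} dict.

    Samples named ``c1..cK`` are control, ``t1..tK`` treatment, with cell
    line ``Lk`` shared by ``ck``/``tk``.  None marks missing.
    """
    df = pd.DataFrame(values, dtype=float)
    df.index = [f"pep{i}" for i in range(len(df))]
    proteins = proteins or [f"prot{i}" for i in range(len(df))]
    classes = classes or ["unique"] * len(df)
    condition_of = {
        s: ("control" if s.startswith("c") else "treatment") for s in df.columns
    }
    pair_of = {s: "L" + s[1:] for s in df.columns}
    return PeptideMatrix(
        intensities=df,
        leading_protein=pd.Series(proteins, index=df.index),
        peptide_class=pd.Series(classes, index=df.index),
        condition_of=condition_of,
        pair_of=pair_of,
    )


@pytest.fixture(scope="session")
def small_simulation():
    """~500-peptide paired simulation shared by the chain-correctness tests."""
    params = SimParams(n_proteins=170, seed=42)
    matrix, truth = simulate_peptides(params)
    return params, matrix, truth


def matrix_as_rows(m: PeptideMatrix):
    """Loop-friendly view used by the brute-force oracles."""
    rows = {}
    for pep in m.peptide_ids:
        vals = {}
        for s in m.sample_ids:
            v = m.intensities.at[pep, s]
            vals[s] = None if pd.isna(v) else float(v)
        rows[pep] = {
            "protein": m.leading_protein[pep],
            "class": m.peptide_class[pep],
            "values": vals,
        }
    return rows


def matrix_as_columns(m: PeptideMatrix):
    return {
        s: [
            None if pd.isna(v) else float(v)
            for v in m.intensities[s].tolist()
        ]
        for s in m.sample_ids
    }
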