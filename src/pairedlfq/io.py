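"""Readers and writers for the tabular formats the pipeline touches.

Supported formats
-----------------
* peptide tables in the MaxQuant ``peptides.txt`` tab-separated dialect:
  one row per peptide, a sequence column, a leading-razor-protein column, a
  peptide-class column, and one ``Intensity <sample>`` column per sample;
* differential-expression tables (``gene``, ``log2fc``, ``fdr``) as TSV;
* gene-set collections in GMT (``name<TAB>description<TAB>member...``);
* generic result tables as TSV with an optional ``#``-prefixed header line.

Parsing is strict: UTF-8, ``.`` decimal point, no thousands separators.
Zeros and blank intensity cells become NaN (missing).  Readers never drop a
row silently — rejected rows are reported through ``logging`` with reasons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import PeptideMatrix

logger = logging.getLogger(__name__)

INTENSITY_PREFIX = "Intensity "


class FormatError(ValueError):
    """The file does not conform to the declared tabular dialect."""


@dataclass
class PeptideColumns:
    """Column-name map for the peptides table; defaults follow MaxQuant."""

    sequence: str = "Sequence"
    leading_protein: str = "Leading razor protein"
    peptide_class: str = "Peptide class"
    #: explicit sample → intensity-column map; empty means discover
    #: columns named ``Intensity <sample_id>`` (case-sensitive, one space).
    intensity_of: dict[str, str] = field(default_factory=dict)


def _classify(raw: str) -> str:
    """Map a free-text peptide-class cell onto unique/razor/other.

    MaxQuant wording varies across versions, so any value *containing*
    "unique" or "razor" (case-insensitive) is accepted; unique wins when
    both appear, anything else is "other".
    """
    low = str(raw).lower()
    if "unique" in low:
        return "unique"
    if "razor" in low:
        return "razor"
    return "other"


def read_peptides(
    path,
    design: dict[str, tuple[str, str]],
    columns: PeptideColumns | None = None,
) -> PeptideMatrix:
    """Read a MaxQuant-dialect peptides TSV into a :class:`PeptideMatrix`.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    design
        ``sample_id -> (condition, cell_line)``; every declared sample must
        have an intensity column, extra intensity columns are ignored with
        a warning.
    columns
        Optional column-name overrides (see :class:`PeptideColumns`).
    """
    cols = columns or PeptideColumns()
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    for required in (cols.sequence, cols.leading_protein, cols.peptide_class):
        if required not in df.columns:
            raise FormatError(f"required column {required!r} missing from {path}")

    if cols.intensity_of:
        sample_col = dict(cols.intensity_of)
    else:
        sample_col = {s: INTENSITY_PREFIX + s for s in design}
    absent = [s for s, c in sample_col.items() if c not in df.columns]
    if absent:
        raise FormatError(
            f"design samples with no intensity column in {path}: {sorted(absent)}"
        )
    extra = [
        c
        for c in df.columns
        if c.startswith(INTENSITY_PREFIX) and c not in sample_col.values()
    ]
    if extra:
        logger.warning("ignoring %d intensity columns not in the design: %s", len(extra), extra)

    intens = {}
    for s, c in sample_col.items():
        raw = df[c].replace("", np.nan)
        try:
            vals = pd.to_numeric(raw, errors="raise").astype(float)
        except (ValueError, TypeError):
            numeric = pd.to_numeric(raw, errors="coerce")
            bad = raw.notna() & numeric.isna()
            row = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"non-numeric intensity {raw.iloc[row]!r} at row {row + 2}, column {c!r}"
            ) from None
        vals[vals == 0] = np.nan  # MaxQuant writes 0 for not-detected
        intens[s] = vals

    matrix = pd.DataFrame(intens, columns=list(design))
    matrix.index = df[cols.sequence].astype(str)
    matrix.index.name = "peptide_id"
    dup = matrix.index.duplicated()
    if dup.any():
        raise FormatError(
            f"duplicate peptide ids in {path}: {sorted(set(matrix.index[dup]))[:5]}"
        )
    return PeptideMatrix(
        intensities=matrix,
        leading_protein=pd.Series(
            df[cols.leading_protein].astype(str).values, index=matrix.index
        ),
        peptide_class=pd.Series(
            [_classify(v) for v in df[cols.peptide_class]], index=matrix.index
        ),
        condition_of={s: design[s][0] for s in design},
        pair_of={s: design[s][1] for s in design},
    )


def write_peptides(m: PeptideMatrix, path, columns: PeptideColumns | None = None) -> None:
    """Write a matrix back to the peptides dialect (round-trip exact)."""
    cols = columns or PeptideColumns()
    out = pd.DataFrame(
        {
            cols.sequence: m.peptide_ids,
            cols.leading_protein: m.leading_protein.values,
            cols.peptide_class: m.peptide_class.values,
        }
    )
    for s in m.sample_ids:
        # missing is stored as 0, the MaxQuant convention
        out[INTENSITY_PREFIX + s] = m.intensities[s].fillna(0.0).values
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_deg_table(path) -> pd.DataFrame:
    """Read a differential-expression TSV with columns gene, log2fc, fdr.

    Duplicate gene rows keep the smallest-fdr row (deterministic
    de-duplication, logged); fdr outside [0, 1] is a validation error.
    """
    df = pd.read_csv(path, sep="\t", encoding="utf-8", comment="#")
    missing = {"gene", "log2fc", "fdr"} - set(df.columns)
    if missing:
        raise FormatError(f"DEG table {path} lacks columns: {sorted(missing)}")
    df = df[["gene", "log2fc", "fdr"]].copy()
    df["gene"] = df["gene"].astype(str)
    df["log2fc"] = pd.to_numeric(df["log2fc"], errors="raise")
    df["fdr"] = pd.to_numeric(df["fdr"], errors="raise")
    bad = df[(df["fdr"] < 0) | (df["fdr"] > 1)]
    if len(bad):
        raise FormatError(
            f"fdr outside [0,1] for genes {bad['gene'].head().tolist()} in {path}"
        )
    n_in = len(df)
    df = df.sort_values("fdr", kind="stable").drop_duplicates("gene").sort_index()
    if len(df) < n_in:
        logger.info("dropped %d duplicate gene rows (kept smallest fdr)", n_in - len(df))
    return df.reset_index(drop=True)


def read_gmt(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a GMT file into (sets, descriptions).

    Empty sets are dropped with a warning; duplicate set names are an error.
    """
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: GMT line needs name<TAB>description")
            name, description = parts[0], parts[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = {p for p in parts[2:] if p.strip()}
            if not members:
                logger.warning("%s:%d: dropping empty set %r", path, lineno, name)
                continue
            sets[name] = members
            desc[name] = description
    return sets, desc


def write_gmt(sets: dict[str, set[str]], desc: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fields = [name, desc.get(name, "")] + sorted(members)
            fh.write("\t".join(fields) + "\n")


def read_design(path) -> dict[str, tuple[str, str]]:
    """Read a design TSV (sample, condition, cell_line) into a map."""
    df = pd.read_csv(path, sep="\t", encoding="utf-8", comment="#")
    missing = {"sample", "condition", "cell_line"} - set(df.columns)
    if missing:
        raise FormatError(f"design table {path} lacks columns: {sorted(missing)}")
    return {
        str(r.sample): (str(r.condition), str(r.cell_line)) for r in df.itertuples()
    }


def write_design(m, path) -> None:
    df = pd.DataFrame(
        {
            "sample": m.sample_ids,
            "condition": [m.condition_of[s] for s in m.sample_ids],
            "cell_line": [m.pair_of[s] for s in m.sample_ids],
        }
    )
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def write_proteins(pm: "ProteinMatrix", path, header_comment: str | None = None) -> None:
    out = pm.intensities.copy()
    out.insert(0, "n_quantified_peptides", pm.n_quantified_peptides)
    out.insert(0, "protein_id", pm.protein_ids)
    write_table(out, path, header_comment)


def read_proteins(path, design: dict[str, tuple[str, str]]) -> "ProteinMatrix":
    from .containers import ProteinMatrix

    df = pd.read_csv(path, sep="\t", encoding="utf-8", comment="#")
    for required in ("protein_id", "n_quantified_peptides"):
        if required not in df.columns:
            raise FormatError(f"protein table {path} lacks column {required!r}")
    absent = [s for s in design if s not in df.columns]
    if absent:
        raise FormatError(f"design samples missing from {path}: {absent}")
    df = df.set_index("protein_id")
    return ProteinMatrix(
        intensities=df[list(design)].astype(float),
        n_quantified_peptides=df["n_quantified_peptides"].astype(int),
        condition_of={s: design[s][0] for s in design},
        pair_of={s: design[s][1] for s in design},
    )


def write_trace(trace, path) -> None:
    """Write a flux trace as TSV with injection/cell-count header comments."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# cell_count\t{trace.cell_count}\n")
        for t, agent in trace.injections:
            fh.write(f"# injection\t{t}\t{agent}\n")
        pd.DataFrame(
            {"time_min": trace.timepoints, "ocr": trace.ocr, "ecar": trace.ecar}
        ).to_csv(fh, sep="\t", index=False)


def read_trace(path):
    from .assay import StressTestTrace

    cell_count = None
    injections: list[tuple[float, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].strip().split("\t")
            if parts[0] == "cell_count":
                cell_count = int(parts[1])
            elif parts[0] == "injection":
                injections.append((float(parts[1]), parts[2]))
    if cell_count is None:
        raise FormatError(f"trace {path} lacks a '# cell_count' header line")
    df = pd.read_csv(path, sep="\t", encoding="utf-8", comment="#")
    return StressTestTrace(
        timepoints=df["time_min"].to_numpy(),
        ocr=df["ocr"].to_numpy(),
        ecar=df["ecar"].to_numpy(),
        injections=injections,
        cell_count=cell_count,
    )


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a result table as TSV, optionally with a ``#`` header line."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write("# " + header_comment + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8", comment="#")
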