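"""Small quantitative assay formulas: staining indices, ΔΔCt, flux metrics.

* Staining index: positive cells / DAPI-positive cells × 100, with a
  validity flag when fewer than 500 cells were counted.
* ΔΔCt relative expression: target Ct normalized to a housekeeping gene
  (18S) within each sample, differenced between treated and control,
  fold = 2^(−ΔΔCt).
* Extracellular-flux stress test: OCR (pmol O2/min) and ECAR (mpH/min)
  traces segmented at the injections oligomycin → FCCP → rotenone.
  Basal respiration is the pre-oligomycin OCR mean, ATP-linked the
  basal-minus-post-oligomycin drop, maximal respiration the post-FCCP
  (pre-rotenone) OCR, spare capacity maximal − basal; maximal glycolytic
  capacity is the post-oligomycin ECAR.  All metrics are normalized to
  cell number and reported per 10^4 cells (raw per-well values kept too).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MIN_CELLS_FOR_VALID_INDEX = 500
INJECTION_ORDER = ("oligomycin", "fccp", "rotenone")


@dataclass
class StainingCount:
    positive: int
    total_dapi: int

    def __post_init__(self):
        if self.total_dapi < 0 or self.positive < 0:
            raise ValueError("counts must be nonnegative")
        if self.positive > self.total_dapi:
            raise ValueError("positive cells cannot exceed DAPI-positive cells")


def staining_index(c: StainingCount) -> tuple[float, bool]:
    """Percentage of positive-staining cells; returns (index, valid).

    ``valid`` is False when fewer than 500 cells were counted for the
    condition.
    """
    index = 100.0 * c.positive / c.total_dapi
    return index, c.total_dapi >= MIN_CELLS_FOR_VALID_INDEX


@dataclass
class CtRecord:
    """qPCR Ct triplicates for a target and the 18S housekeeping reference."""

    sample: str
    target_ct: tuple[float, ...]
    ref_ct: tuple[float, ...]
    group: str = "control"

    def __post_init__(self):
        if not self.target_ct or not self.ref_ct:
            raise ValueError("Ct triplicates must be nonempty")
        if any(ct <= 0 for ct in (*self.target_ct, *self.ref_ct)):
            raise ValueError("Ct values must be positive")

    @property
    def delta_ct(self) -> float:
        return float(np.mean(self.target_ct) - np.mean(self.ref_ct))


def ddct_fold_change(treated: CtRecord, control: CtRecord) -> float:
    """Relative expression by the ΔΔCt method: 2^-(ΔCt_treated - ΔCt_control)."""
    return float(2.0 ** -(treated.delta_ct - control.delta_ct))


@dataclass
class StressTestTrace:
    """Time-ordered OCR/ECAR measurements with injection annotations."""

    timepoints: np.ndarray  # minutes
    ocr: np.ndarray  # pmol O2 / min, per well
    ecar: np.ndarray  # mpH / min, per well
    injections: list[tuple[float, str]]  # (time, agent), in protocol order
    cell_count: int

    def __post_init__(self):
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        self.ecar = np.asarray(self.ecar, dtype=float)
        n = len(self.timepoints)
        if len(self.ocr) != n or len(self.ecar) != n:
            raise ValueError("OCR/ECAR traces must match the timepoints")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        agents = tuple(a for _, a in self.injections)
        if agents != INJECTION_ORDER:
            raise ValueError(
                f"injections must be {INJECTION_ORDER} in order, got {agents}"
            )
        if any(t2 <= t1 for (t1, _), (t2, _) in zip(self.injections, self.injections[1:])):
            raise ValueError("injection times must increase")
        if self.cell_count <= 0:
            raise ValueError("cell_count must be positive")

    def segment(self, start: float | None, end: float | None) -> np.ndarray:
        """Measurement indices with start < t < end (None = open end)."""
        mask = np.ones_like(self.timepoints, dtype=bool)
        if start is not None:
            mask &= self.timepoints > start
        if end is not None:
            mask &= self.timepoints < end
        return np.flatnonzero(mask)


def stress_test_metrics(
    trace: StressTestTrace,
    segment_stat: str = "mean",
    subtract_non_mito: bool = False,
    per_cells: float = 1e4,
) -> dict[str, float]:
    """Mitochondrial/glycolytic stress-test metrics from one well's trace.

    ``segment_stat`` chooses mean (default) or max as the per-segment
    summary.  ``subtract_non_mito`` subtracts the post-rotenone OCR from
    the respiration metrics (off by default).  Metrics come in two units:
    per well (``*_per_well``) and per ``per_cells`` cells.
    """
    if segment_stat not in ("mean", "max"):
        raise ValueError("segment_stat must be 'mean' or 'max'")
    stat = np.mean if segment_stat == "mean" else np.max
    t_oligo, t_fccp, t_rot = (t for t, _ in trace.injections)
    segments = {
        "basal": trace.segment(None, t_oligo),
        "post_oligomycin": trace.segment(t_oligo, t_fccp),
        "post_fccp": trace.segment(t_fccp, t_rot),
        "post_rotenone": trace.segment(t_rot, None),
    }
    for name, idx in segments.items():
        if idx.size == 0:
            raise ValueError(f"trace has no measurement cycle in segment {name!r}")

    ocr = {name: float(stat(trace.ocr[idx])) for name, idx in segments.items()}
    ecar = {name: float(stat(trace.ecar[idx])) for name, idx in segments.items()}
    non_mito = ocr["post_rotenone"] if subtract_non_mito else 0.0

    per_well = {
        "basal_ocr": ocr["basal"] - non_mito,
        "atp_linked_ocr": ocr["basal"] - ocr["post_oligomycin"],
        "maximal_ocr": ocr["post_fccp"] - non_mito,
        "spare_capacity_ocr": ocr["post_fccp"] - ocr["basal"],
        "basal_ecar": ecar["basal"],
        "glycolytic_capacity_ecar": ecar["post_oligomycin"],
    }
    scale = per_cells / trace.cell_count
    out = {f"{k}_per_well": v for k, v in per_well.items()}
    out.update({k: v * scale for k, v in per_well.items()})
    return out
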