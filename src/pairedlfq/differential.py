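"""Per-protein fold changes and paired significance testing.

For each protein the effect size is the ratio of arithmetic group means
(treatment / control, linear scale) and the test is a paired two-sided
Student's t-test on within-cell-line differences — each cell line is
measured under both conditions, so the test is the one-sample t of the
per-line differences (of log2 intensities by default) against zero.

A protein is called significant when p < alpha and the two-sided fold
change max(ratio, 1/ratio) exceeds fc_threshold, both strict.  No
multiplicity correction is applied at the protein level by default;
Benjamini–Hochberg adjustment is available and, when enabled, replaces
the raw p in the significance rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CONTROL, TREATMENT, ProteinMatrix


@dataclass
class DiffParams:
    alpha: float = 0.05
    fc_threshold: float = 1.2
    test_scale: str = "log2"  # "log2" or "linear"
    adjust: str = "none"  # "none" or "benjamini_hochberg"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if self.test_scale not in ("log2", "linear"):
            raise ValueError("test_scale must be 'log2' or 'linear'")
        if self.adjust not in ("none", "benjamini_hochberg"):
            raise ValueError("adjust must be 'none' or 'benjamini_hochberg'")


def group_ratio(pm: ProteinMatrix) -> pd.Series:
    """Treatment-mean / control-mean per protein, linear scale."""
    ctrl = pm.samples_in(CONTROL)
    trt = pm.samples_in(TREATMENT)
    if not ctrl or not trt:
        raise ValueError("both conditions need at least one sample")
    return pm.intensities[trt].mean(axis=1) / pm.intensities[ctrl].mean(axis=1)


def _paired_differences(pm: ProteinMatrix, scale: str) -> pd.DataFrame:
    """Per-protein treatment-minus-control differences, one column per line."""
    if not pm.paired:
        raise ValueError("paired test requires every cell line in both conditions")
    lines: dict[str, dict[str, str]] = {}
    for s in pm.sample_ids:
        lines.setdefault(pm.pair_of[s], {})[pm.condition_of[s]] = s
    if len(lines) < 2:
        raise ValueError("paired test needs at least 2 cell lines")
    vals = pm.intensities
    if scale == "log2":
        vals = np.log2(vals)
    diffs = {
        line: vals[cols[TREATMENT]] - vals[cols[CONTROL]] for line, cols in lines.items()
    }
    return pd.DataFrame(diffs)


def paired_t_test(pm: ProteinMatrix, params: DiffParams | None = None) -> pd.DataFrame:
    """Two-sided paired t-test per protein.

    Returns a frame with columns ``p_value`` and ``degenerate``.  When all
    per-line differences of a protein are identical the t statistic is
    undefined; such proteins get p = NaN and ``degenerate = True`` rather
    than a fabricated 0 or 1.
    """
    params = params or DiffParams()
    diffs = _paired_differences(pm, params.test_scale).to_numpy()
    degenerate = np.ptp(diffs, axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant-difference rows are flagged below; scipy's precision
        # warning for them is expected noise
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_1samp(diffs, popmean=0.0, axis=1)
        p = np.asarray(res.pvalue, dtype=float)
    p[degenerate] = np.nan
    return pd.DataFrame(
        {"p_value": p, "degenerate": degenerate}, index=pm.intensities.index
    )


def benjamini_hochberg(p) -> np.ndarray:
    """Step-up Benjamini–Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_significance(
    ratio: pd.Series, p_value: pd.Series, params: DiffParams | None = None
) -> pd.DataFrame:
    """Apply the fold-change + significance rule to per-feature results.

    Output columns: feature_id, ratio, log2fc, p_value, p_adjusted,
    significant, direction (up iff ratio > 1, down iff ratio < 1).
    """
    params = params or DiffParams()
    ratio = ratio.astype(float)
    p_value = p_value.reindex(ratio.index).astype(float)
    out = pd.DataFrame(
        {
            "feature_id": ratio.index.astype(str),
            "ratio": ratio.values,
            "log2fc": np.log2(ratio.values),
            "p_value": p_value.values,
        }
    )
    if params.adjust == "benjamini_hochberg":
        adjusted = np.full(len(out), np.nan)
        ok = out["p_value"].notna().to_numpy()
        adjusted[ok] = benjamini_hochberg(out.loc[ok, "p_value"].to_numpy())
        out["p_adjusted"] = adjusted
        p_for_rule = out["p_adjusted"]
    else:
        out["p_adjusted"] = np.nan
        p_for_rule = out["p_value"]
    two_sided_fc = np.maximum(out["ratio"], 1.0 / out["ratio"])
    out["significant"] = (p_for_rule < params.alpha) & (two_sided_fc > params.fc_threshold)
    out["significant"] = out["significant"].fillna(False).astype(bool)
    out["direction"] = np.select(
        [out["ratio"] > 1, out["ratio"] < 1], ["up", "down"], default="none"
    )
    return out


def differential_proteins(
    pm: ProteinMatrix, params: DiffParams | None = None
) -> pd.DataFrame:
    """Ratio + paired t + significance call in one step."""
    params = params or DiffParams()
    ratio = group_ratio(pm)
    tested = paired_t_test(pm, params)
    res = call_significance(ratio, tested["p_value"], params)
    res["degenerate"] = tested["degenerate"].to_numpy()
    return res
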