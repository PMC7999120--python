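"""Transcript–protein concordance: threshold both layers, intersect, score.

Identifiers are harmonized by exact match after uppercasing and trimming
whitespace (an optional protein→gene map can be supplied); unmatched
features are counted and reported, never silently dropped.  The overlap
p-value is the hypergeometric upper tail on the shared *measured*
universe — features quantified in both layers — not on the called sets,
to avoid inflating the universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ConcordanceReport:
    n_deg: int
    n_dep: int
    n_common: int
    n_concordant: int
    quadrants: dict[str, int]  # up_up, down_down, up_down, down_up
    unmatched: list[str] = field(default_factory=list)
    overlap_p: float = float("nan")
    universe_size: int = 0

    def as_frame(self) -> pd.DataFrame:
        row = {
            "n_deg": self.n_deg,
            "n_dep": self.n_dep,
            "n_common": self.n_common,
            "n_concordant": self.n_concordant,
            **self.quadrants,
            "n_unmatched": len(self.unmatched),
            "overlap_p": self.overlap_p,
            "universe_size": self.universe_size,
        }
        return pd.DataFrame([row])


def threshold_deg(
    deg: pd.DataFrame, fc_threshold: float = 1.5, fdr_alpha: float = 0.05
) -> pd.DataFrame:
    """Call differentially expressed genes at |fold| > threshold, fdr < alpha.

    The fold-change rule is two-sided on the linear scale:
    max(2**log2fc, 2**-log2fc) > fc_threshold, strict.  Returns the called
    rows with a ``direction`` column from the sign of log2fc.
    """
    fold = np.maximum(2.0 ** deg["log2fc"], 2.0 ** (-deg["log2fc"]))
    called = deg[(deg["fdr"] < fdr_alpha) & (fold > fc_threshold)].copy()
    called["direction"] = np.where(called["log2fc"] > 0, "up", "down")
    return called.reset_index(drop=True)


def _canon(identifier: str) -> str:
    return str(identifier).strip().upper()


def concordance(
    deg_calls: pd.DataFrame,
    dep_calls: pd.DataFrame,
    deg_universe: set[str] | None = None,
    dep_universe: set[str] | None = None,
    id_map: dict[str, str] | None = None,
) -> ConcordanceReport:
    """Compare called gene and protein sets and score direction agreement.

    Parameters
    ----------
    deg_calls
        Frame with ``gene`` and ``direction`` columns (from
        :func:`threshold_deg`).
    dep_calls
        Frame with ``feature_id`` and ``direction`` columns restricted to
        significant proteins (e.g. ``differential_proteins`` rows with
        ``significant``).
    deg_universe, dep_universe
        All *measured* identifiers per layer; default to the calls when
        absent (degrading the hypergeometric p to the called sets only).
    id_map
        Optional protein accession → gene symbol map applied before
        harmonization.
    """
    id_map = {_canon(k): _canon(v) for k, v in (id_map or {}).items()}

    def map_protein(i: str) -> str:
        c = _canon(i)
        return id_map.get(c, c)

    deg_dir = {_canon(g): d for g, d in zip(deg_calls["gene"], deg_calls["direction"])}
    dep_dir = {
        map_protein(i): d
        for i, d in zip(dep_calls["feature_id"], dep_calls["direction"])
    }
    deg_uni = (
        {_canon(g) for g in deg_universe} if deg_universe is not None else set(deg_dir)
    )
    dep_uni = (
        {map_protein(i) for i in dep_universe}
        if dep_universe is not None
        else set(dep_dir)
    )
    shared = deg_uni & dep_uni
    if not shared:
        raise ValueError("no shared measured universe between the two layers")

    common = set(deg_dir) & set(dep_dir)
    quadrants = {"up_up": 0, "down_down": 0, "up_down": 0, "down_up": 0}
    for g in common:
        quadrants[f"{deg_dir[g]}_{dep_dir[g]}"] += 1
    n_concordant = quadrants["up_up"] + quadrants["down_down"]
    unmatched = sorted((set(deg_dir) | set(dep_dir)) - shared)

    # hypergeometric tail on the shared universe: draw the DEP calls in the
    # universe, count how many land on DEG calls in the universe
    deg_in = set(deg_dir) & shared
    dep_in = set(dep_dir) & shared
    k = len(deg_in & dep_in)
    overlap_p = float(
        stats.hypergeom.sf(k - 1, len(shared), len(deg_in), len(dep_in))
    )
    return ConcordanceReport(
        n_deg=len(deg_dir),
        n_dep=len(dep_dir),
        n_common=len(common),
        n_concordant=n_concordant,
        quadrants=quadrants,
        unmatched=unmatched,
        overlap_p=overlap_p,
        universe_size=len(shared),
    )
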