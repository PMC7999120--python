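"""Gene-set enrichment: preranked walk statistic and over-representation.

Two procedures:

* :func:`enrichment_score` / :func:`permutation_null` — a preranked
  (GSEA-style) enrichment score: walk down a list of features ranked by a
  score (here, fold change), incrementing the running sum at set members
  ("hits") in proportion to |score|^weight and decrementing it uniformly at
  non-members; the ES is the signed maximal deviation from zero.
  Significance comes from a gene-permutation null: random same-size sets
  drawn from the ranked ids, an add-one permutation p-value against nulls
  of the same sign, and a normalized ES (NES) rescaled by the mean |null
  ES| of that sign.

* :func:`overrepresentation` — a hypergeometric upper-tail test of a hit
  list against each set within a stated universe, Benjamini–Hochberg
  adjusted across sets, selected at adjusted p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import benjamini_hochberg


@dataclass
class GeneSetCollection:
    """Named sets of feature identifiers; no empty sets, unique names."""

    sets: dict[str, set[str]]
    description: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self):
        return len(self.sets)


@dataclass
class RankedList:
    """Identifiers ordered by nonincreasing score (ties keep input order)."""

    ids: list[str]
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.ids) != len(self.scores):
            raise ValueError("ids and scores differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ranked ids must be unique")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be nonincreasing")

    @classmethod
    def from_scores(cls, ids, scores) -> "RankedList":
        """Build by stable descending sort on the scores."""
        scores = np.asarray(scores, dtype=float)
        order = np.argsort(-scores, kind="stable")
        return cls([ids[i] for i in order], scores[order])


def enrichment_score(
    ranked: RankedList, members: set[str], weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted Kolmogorov–Smirnov-like running-sum enrichment score.

    Returns ``(es, running_sum, leading_edge)``.  Hits step up by
    |score|^weight normalized over hits; misses step down by 1/(N - K).
    The leading edge contains the hit members at or before the extremum
    (at or after it when the ES is negative).
    """
    n = len(ranked.ids)
    hit = np.array([i in members for i in ranked.ids], dtype=bool)
    k = int(hit.sum())
    if k == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if k == n:
        raise ValueError("gene set covers the entire ranked list")
    w = np.abs(ranked.scores) ** weight
    hit_weight = np.where(hit, w, 0.0)
    total = hit_weight.sum()
    if total == 0:  # all hit scores are exactly 0: fall back to equal steps
        hit_weight = hit.astype(float)
        total = float(k)
    steps = np.where(hit, hit_weight / total, -1.0 / (n - k))
    running = np.cumsum(steps)
    extremum = int(np.argmax(np.abs(running)))
    es = float(running[extremum])
    if es >= 0:
        edge_mask = hit[: extremum + 1]
        edge = [ranked.ids[i] for i in range(extremum + 1) if hit[i]]
    else:
        edge = [ranked.ids[i] for i in range(extremum, n) if hit[i]]
    return es, running, edge


def permutation_null(
    ranked: RankedList,
    members: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> tuple[float, float, bool]:
    """Gene-permutation NES and p-value for one set.

    Draws ``n_perm`` random same-size sets without replacement from the
    ranked ids, computes their ES, and reports

    * ``p = (1 + #{|null| >= |es|, same sign}) / (1 + #same-sign nulls)``
      (the add-one convention keeps p > 0),
    * ``nes = es / mean(|null es| of the same sign)``.

    Deterministic given the seed.  When no null realization shares the
    observed sign, p is reported at the 1/(1 + n_perm) floor and the
    returned flag is True.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    present = [m for m in members if m in set(ranked.ids)]
    k = len(present)
    es, _, _ = enrichment_score(ranked, set(present), weight)
    ids = np.asarray(ranked.ids)
    null = np.empty(n_perm)
    for j in range(n_perm):
        perm = set(rng.choice(ids, size=k, replace=False).tolist())
        null[j], _, _ = enrichment_score(ranked, perm, weight)
    if es == 0:
        return 0.0, 1.0, False
    same_sign = null > 0 if es > 0 else null < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        return np.nan, 1.0 / (1.0 + n_perm), True
    extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
    p = (1.0 + extreme) / (1.0 + n_same)
    nes = es / float(np.mean(np.abs(null[same_sign])))
    return nes, p, False


def preranked(
    ranked: RankedList,
    gsc: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 1,
    max_size: int | None = None,
) -> pd.DataFrame:
    """Preranked enrichment over a collection; BH across tested sets."""
    universe = set(ranked.ids)
    rows = []
    for name, members in gsc.sets.items():
        overlap = members & universe
        if len(overlap) < min_size or (max_size and len(overlap) > max_size):
            continue
        if len(overlap) == 0 or len(overlap) == len(ranked.ids):
            rows.append(
                {"set_name": name, "size": len(overlap), "es": np.nan, "nes": np.nan,
                 "p_value": np.nan, "leading_edge": "", "at_floor": False}
            )
            continue
        es, _, edge = enrichment_score(ranked, overlap, weight)
        nes, p, floored = permutation_null(ranked, overlap, n_perm, seed, weight)
        rows.append(
            {"set_name": name, "size": len(overlap), "es": es, "nes": nes,
             "p_value": p, "leading_edge": ",".join(edge), "at_floor": floored}
        )
    out = pd.DataFrame(rows)
    if len(out):
        adj = np.full(len(out), np.nan)
        ok = out["p_value"].notna().to_numpy()
        if ok.any():
            adj[ok] = benjamini_hochberg(out.loc[ok, "p_value"].to_numpy())
        out["p_adjusted"] = adj
    return out


def overrepresentation(
    hits: set[str],
    universe: set[str],
    gsc: GeneSetCollection,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a hit list in each set.

    Every set is intersected with the universe before testing; p is the
    one-sided upper tail P(overlap >= observed), equal to the one-sided
    Fisher exact p of the corresponding 2x2 table.  Sets are selected at
    BH-adjusted p < ``alpha``.
    """
    stray = hits - universe
    if stray:
        raise ValueError(f"hits outside the universe: {sorted(stray)[:5]}")
    M, N = len(universe), len(hits)
    rows = []
    for name, members in gsc.sets.items():
        in_universe = members & universe
        n = len(in_universe)
        k = len(in_universe & hits)
        expected = N * n / M if M else 0.0
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append(
            {"set_name": name, "set_size": n, "overlap_count": k,
             "expected_count": expected, "p_value": p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = benjamini_hochberg(out["p_value"].to_numpy())
        out["selected"] = out["p_adjusted"] < alpha
    return out
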