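"""Independent brute-force reimplementations used as test oracles.

Everything here is deliberately written with plain Python loops and
``statistics``/closed forms, independent of the package's vectorized
code paths, so the two routes can disagree when either is wrong.
"""

from __future__ import annotations

import math
import statistics

from scipy import stats as scipy_stats


def brute_normalize(columns: dict[str, list]) -> dict[str, list]:
    """Median normalization by column; None marks missing."""
    medians = {
        s: statistics.median([v for v in vals if v is not None])
        for s, vals in columns.items()
    }
    target = statistics.median(medians.values())
    return {
        s: [None if v is None else v * target / medians[s] for v in vals]
        for s, vals in columns.items()
    }


def brute_filter(
    rows: dict[str, dict],
    condition_of: dict[str, str],
    min_per_condition: int = 2,
    include_classes=("unique", "razor"),
) -> list[str]:
    """Peptide ids surviving the class + >=k-in-one-condition rules."""
    kept = []
    for pep, row in rows.items():
        if row["class"] not in include_classes:
            continue
        counts = {"control": 0, "treatment": 0}
        for s, v in row["values"].items():
            if v is not None:
                counts[condition_of[s]] += 1
        if counts["control"] >= min_per_condition or counts["treatment"] >= min_per_condition:
            kept.append(pep)
    return kept


def brute_percentile(values: list, centile: float) -> float:
    """Linear interpolation between order statistics (inclusive)."""
    ordered = sorted(values)
    rank = centile / 100.0 * (len(ordered) - 1)
    lo = math.floor(rank)
    hi = math.ceil(rank)
    if lo == hi:
        return float(ordered[lo])
    frac = rank - lo
    return float(ordered[lo] * (1 - frac) + ordered[hi] * frac)


def brute_impute(columns: dict[str, list], centile: float = 1.0) -> dict[str, list]:
    out = {}
    for s, vals in columns.items():
        observed = [v for v in vals if v is not None]
        noise = brute_percentile(observed, centile)
        out[s] = [noise if v is None else v for v in vals]
    return out


def brute_aggregate(
    rows: dict[str, dict], samples: list[str], min_peptides: int = 2
) -> dict[str, dict]:
    """Sum by leading protein, keep proteins with >= min_peptides peptides."""
    sums: dict[str, dict] = {}
    counts: dict[str, int] = {}
    for row in rows.values():
        prot = row["protein"]
        counts[prot] = counts.get(prot, 0) + 1
        acc = sums.setdefault(prot, {s: 0.0 for s in samples})
        for s in samples:
            acc[s] += row["values"][s]
    return {
        p: {"values": sums[p], "n_peptides": counts[p]}
        for p in sums
        if counts[p] >= min_peptides
    }


def paired_t_closed_form(diffs: list) -> float:
    """Two-sided p of the textbook paired t statistic on the differences."""
    n = len(diffs)
    mean = sum(diffs) / n
    var = sum((d - mean) ** 2 for d in diffs) / (n - 1)
    t = mean / math.sqrt(var / n)
    return 2.0 * scipy_stats.t.sf(abs(t), n - 1)


def bh_step_up(pvalues: list) -> list:
    """Hand-applied Benjamini-Hochberg step-up adjustment."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(pvalues[i] * m / rank_from_top, 1.0)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def brute_enrichment_score(ids: list, scores: list, members: set, weight: float = 1.0):
    """O(N*K) cumulative walk: returns (es, running_sum list)."""
    n = len(ids)
    hits = [i for i in ids if i in members]
    k = len(hits)
    denom_hit = sum(abs(scores[i]) ** weight for i in range(n) if ids[i] in members)
    running = []
    total = 0.0
    for i in range(n):
        if ids[i] in members:
            if denom_hit > 0:
                total += abs(scores[i]) ** weight / denom_hit
            else:
                total += 1.0 / k
        else:
            total -= 1.0 / (n - k)
        running.append(total)
    es = max(running, key=abs)
    return es, running


def fisher_upper_tail(k: int, big_m: int, n: int, big_n: int) -> float:
    """One-sided Fisher exact p of the 2x2 table matching hypergeom sf."""
    table = [[k, n - k], [big_n - k, big_m - n - big_n + k]]
    return float(scipy_stats.fisher_exact(table, alternative="greater")[1])
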