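"""Independent brute-force re-implementation of the pipeline rules.

Plain dict/loop arithmetic, no pandas, no shared code with the package:
used as the ground truth for equivalence testing on small random inputs.
"""

from __future__ import annotations

import math


def oracle_nsc(counts: dict[str, dict[str, int]]) -> dict[str, dict[str, float]]:
    """counts[protein][replicate] -> nsc[protein][replicate]."""
    reps = sorted({r for row in counts.values() for r in row})
    totals = {r: sum(counts[p].get(r, 0) for p in counts) for r in reps}
    return {
        p: {r: counts[p].get(r, 0) / totals[r] for r in reps} for p in counts
    }


def oracle_group_means(nsc, group_of) -> dict[str, dict[str, float]]:
    groups = sorted(set(group_of.values()))
    out = {}
    for p, row in nsc.items():
        out[p] = {}
        for g in groups:
            vals = [v for r, v in row.items() if group_of[r] == g]
            out[p][g] = sum(vals) / len(vals)
    return out


def oracle_ratios(means, baseline="NN"):
    """Per protein per test group: (ratio or None, discordant, baseline_zero)."""
    positive = [v for row in means.values() for v in row.values() if v > 0]
    eps = min(positive) / 2 if positive else math.nan
    groups = sorted({g for row in means.values() for g in row} - {baseline})
    out = {}
    for p, row in means.items():
        out[p] = {}
        for g in groups:
            t, b = row[g], row[baseline]
            if t == 0 and b == 0:
                out[p][g] = (None, False, False)
            elif t > 0 and b > 0:
                out[p][g] = (t / b, False, False)
            elif b == 0:
                out[p][g] = (t / eps, True, True)
            else:
                out[p][g] = (eps / b, True, False)
    return out


def oracle_abundance(
    counts, group_of, sc_threshold=10, presence_fraction=0.5, rounding="floor"
):
    """Per protein: (significant_groups, low_groups, global_low)."""
    groups = sorted(set(group_of.values()))
    out = {}
    for p, row in counts.items():
        sig, low = set(), set()
        for g in groups:
            vals = [row.get(r, 0) for r in group_of if group_of[r] == g]
            detected = sum(1 for v in vals if v >= 1)
            quota = presence_fraction * len(vals)
            quota = max(1, math.ceil(quota) if rounding == "ceil" else math.floor(quota))
            if max(vals) >= sc_threshold and detected >= quota:
                sig.add(g)
            elif detected >= 1 and max(vals) <= sc_threshold:
                low.add(g)
        all_vals = list(row.values())
        detected_any = any(v >= 1 for v in all_vals)
        global_low = detected_any and max(all_vals, default=0) <= sc_threshold and not sig
        out[p] = (sig, low, global_low)
    return out


def oracle_calls(
    ratios, abundance, over=2.0, under=0.5, policy="test-significant"
) -> dict[str, dict[str, str]]:
    """Per protein per comparison: direction ('up'/'down'/'none')."""
    out = {}
    for p, row in ratios.items():
        out[p] = {}
        for g, (ratio, discordant, baseline_zero) in row.items():
            if ratio is None:
                continue
            d = "up" if ratio > over else "down" if ratio < under else "none"
            if discordant:
                if policy == "never":
                    d = "none"
                elif policy == "test-significant":
                    if baseline_zero:
                        if g not in abundance[p][0]:
                            d = "none"
                    else:
                        d = "none"
            out[p][g] = d
    return out


def oracle_venn(calls: dict[str, dict[str, str]]) -> dict[frozenset, int]:
    cells: dict[frozenset, int] = {}
    for p, row in calls.items():
        subset = frozenset(g for g, d in row.items() if d != "none")
        if subset:
            cells[subset] = cells.get(subset, 0) + 1
    return cells
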