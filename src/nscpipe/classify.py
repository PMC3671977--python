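"""Abundance, presence and differential-expression rules.

A protein is *significant* in a group when its spectral count reaches the
SC threshold (default 10) in at least one of the group's replicates and it
is detected in at least the presence quota (default 50%) of them.  It is
*low-abundant* in a group when detected there but never above the
threshold, and globally low-abundant when that holds across every
replicate and it is significant nowhere (significance dominates the shared
SC = 10 boundary).  Differential expression against the baseline group is
called on the NSC ratio with strict cutoffs (> 2 over-expressed, < 0.5
under-expressed by default).

Comparisons in which exactly one side is undetected need a convention
because a fold ratio against zero is not measurable.  The default policy
("test-significant") never assigns a direction from absence alone: a
protein undetected in the test group gets no call, and a protein detected
only in the test group is called (via the ε-floored ratio, hence upward)
only when the test-group evidence itself clears the significance bar.
Alternatives: "epsilon-sign" (always call on the ε-floored ratio) and
"never" (discordant comparisons are never called).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import (
    AbundanceClassification,
    CategorySummary,
    DepCall,
    SpectralCountMatrix,
    ValidationError,
)
from .quantify import ConfigurationError, RatioTable

DISCORDANT_POLICIES = ("test-significant", "epsilon-sign", "never")


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds of the classification rules.

    sc_threshold: SC level separating significant from low-abundant (10).
    presence_fraction: fraction of a group's replicates that must detect
        the protein for significance (0.5).
    presence_rounding: how the quota ``presence_fraction * n`` is turned
        into a replicate count; "floor" (default, minimum 1) reproduces the
        reference annotations, "ceil" is the strict at-least-50% reading.
    over_threshold / under_threshold: strict NSC-ratio cutoffs (2, 0.5).
    detection_floor: SC needed to count a protein as present (1).
    discordant_policy: handling of one-sided-zero comparisons (see module
        docstring).
    """

    sc_threshold: int = 10
    presence_fraction: float = 0.5
    over_threshold: float = 2.0
    under_threshold: float = 0.5
    detection_floor: int = 1
    presence_rounding: str = "floor"
    discordant_policy: str = "test-significant"

    def __post_init__(self):
        if self.sc_threshold < 1:
            raise ConfigurationError("sc_threshold must be >= 1")
        if not (0 < self.presence_fraction <= 1):
            raise ConfigurationError("presence_fraction must lie in (0, 1]")
        if not (self.under_threshold < 1 < self.over_threshold):
            raise ConfigurationError("need under_threshold < 1 < over_threshold")
        if self.presence_rounding not in ("floor", "ceil"):
            raise ConfigurationError(
                f"unknown presence_rounding {self.presence_rounding!r}"
            )
        if self.discordant_policy not in DISCORDANT_POLICIES:
            raise ConfigurationError(
                f"unknown discordant_policy {self.discordant_policy!r}"
            )

    def presence_quota(self, n_replicates: int) -> int:
        """Detected-replicate count required for significance in a group."""
        q = self.presence_fraction * n_replicates
        if self.presence_rounding == "ceil":
            return max(1, math.ceil(q))
        return max(1, math.floor(q))

    def with_(self, **kwargs) -> "RuleConfig":
        return replace(self, **kwargs)


def classify_abundance(
    matrix: SpectralCountMatrix, config: RuleConfig = RuleConfig()
) -> AbundanceClassification:
    """Apply the significance / low-abundance rules per protein per group."""
    design = matrix.design
    present = matrix.group_presence_counts(config.detection_floor)
    sig_cols, low_cols, max_cols = {}, {}, {}
    for g in design.groups:
        reps = design.replicates_of(g)
        gmax = matrix.counts[reps].max(axis=1)
        quota = config.presence_quota(len(reps))
        sig_cols[g] = (gmax >= config.sc_threshold) & (present[g] >= quota)
        low_cols[g] = (present[g] >= 1) & (gmax <= config.sc_threshold) & ~sig_cols[g]
        max_cols[g] = gmax
    significant_in = pd.DataFrame(sig_cols)
    low_in = pd.DataFrame(low_cols)
    overall_max = matrix.counts.max(axis=1)
    detected_anywhere = present.sum(axis=1) >= 1
    global_low = (
        detected_anywhere
        & (overall_max <= config.sc_threshold)
        & ~significant_in.any(axis=1)
    )
    return AbundanceClassification(
        present_in=present,
        significant_in=significant_in,
        low_in=low_in,
        global_low_abundant=global_low,
        detected_anywhere=detected_anywhere,
    )


def _direction(ratio: float, config: RuleConfig) -> str:
    if np.isnan(ratio):
        return "none"
    if ratio > config.over_threshold:
        return "up"
    if ratio < config.under_threshold:
        return "down"
    return "none"


def call_dep(
    ratios: RatioTable,
    config: RuleConfig = RuleConfig(),
    classification: AbundanceClassification | None = None,
) -> list[DepCall]:
    """Turn the ratio table into differential-expression calls.

    Strict inequalities: a ratio exactly at a threshold is not a call.
    Undefined ratios (both sides zero) yield no call.  One-sided zeros are
    resolved by ``config.discordant_policy``; the default needs the
    abundance classification to gate baseline-absent calls on test-group
    significance.
    """
    if config.discordant_policy == "test-significant" and classification is None:
        raise ConfigurationError(
            "discordant_policy='test-significant' requires the abundance "
            "classification"
        )
    calls: list[DepCall] = []
    for g in ratios.comparisons:
        r_col = ratios.ratio[g]
        d_col = ratios.discordant[g]
        bz_col = ratios.baseline_zero[g]
        for protein in ratios.proteins:
            r = float(r_col[protein])
            if np.isnan(r):
                continue
            discordant = bool(d_col[protein])
            direction = _direction(r, config)
            if discordant:
                if config.discordant_policy == "never":
                    direction = "none"
                elif config.discordant_policy == "test-significant":
                    if bool(bz_col[protein]):
                        # detected only in the test group: call iff the
                        # test-group evidence is itself significant
                        if not bool(classification.significant_in.loc[protein, g]):
                            direction = "none"
                    else:
                        # undetected in the test group: absence is not a
                        # measured fold change
                        direction = "none"
            calls.append(
                DepCall(
                    protein=protein,
                    comparison=g,
                    ratio=r,
                    direction=direction,
                    presence_discordant=discordant,
                )
            )
    return calls


def dep_proteins(calls: list[DepCall]) -> set[str]:
    """Proteins with at least one up/down call in any comparison."""
    return {c.protein for c in calls if c.direction != "none"}


def venn_partition(calls: list[DepCall]) -> dict[frozenset, int]:
    """Partition DEP proteins by the subset of comparisons they are called in.

    Cells are keyed by frozensets of comparison labels; counts over all
    cells sum to the number of DEP proteins.  Duplicate (protein,
    comparison) calls are deduplicated; conflicting duplicates are an
    error.
    """
    seen: dict[tuple[str, str], str] = {}
    for c in calls:
        key = (c.protein, c.comparison)
        if key in seen and seen[key] != c.direction:
            raise ValidationError(f"conflicting duplicate call for {key}")
        seen[key] = c.direction
    membership: dict[str, set[str]] = {}
    for (protein, comparison), direction in seen.items():
        if direction != "none":
            membership.setdefault(protein, set()).add(comparison)
    cells: dict[frozenset, int] = {}
    for subset in membership.values():
        key = frozenset(subset)
        cells[key] = cells.get(key, 0) + 1
    return cells


def categorize(
    matrix: SpectralCountMatrix,
    classification: AbundanceClassification,
    calls: list[DepCall],
    config: RuleConfig = RuleConfig(),
) -> tuple[pd.DataFrame, CategorySummary]:
    """Per-protein category flags plus the headline summary.

    Flags are non-exclusive: a protein may be common and differentially
    expressed at the same time.  ``is_common`` means detected in every
    replicate of every group; ``is_unique`` means detected in at least one
    group and completely undetected in at least one other.
    """
    if list(matrix.proteins) != list(classification.proteins):
        raise ValidationError("matrix and classification cover different proteins")
    called = {p for p in dep_proteins(calls)}
    unknown = called - set(matrix.proteins)
    if unknown:
        raise ValidationError(f"calls refer to unknown proteins: {sorted(unknown)}")
    design = matrix.design
    sizes = design.group_sizes()
    present = classification.present_in
    is_common = pd.Series(True, index=present.index)
    for g, n in sizes.items():
        is_common &= present[g] == n
    undetected_somewhere = (present == 0).any(axis=1)
    is_unique = classification.detected_anywhere & undetected_somewhere

    directions = {
        g: pd.Series("", index=present.index, dtype=object) for g in design.test_groups
    }
    for c in calls:
        if c.direction != "none" and c.comparison in directions:
            directions[c.comparison][c.protein] = c.direction
    flags = pd.DataFrame(
        {
            "is_common": is_common,
            "is_unique": is_unique,
            "is_significant": classification.significant_in.any(axis=1),
            "is_low_abundant": classification.global_low_abundant,
            "is_dep": pd.Series(
                [p in called for p in present.index], index=present.index
            ),
        }
    )
    flags["significant_groups"] = classification.significant_in.apply(
        lambda row: ",".join(g for g in design.groups if row.get(g, False)), axis=1
    )
    flags["low_groups"] = classification.low_in.apply(
        lambda row: ",".join(g for g in design.groups if row.get(g, False)), axis=1
    )
    for g in design.test_groups:
        flags[f"dep_{g}"] = directions[g]
    for g in design.groups:
        flags[f"present_{g}"] = present[g]

    venn = venn_partition(calls)
    summary = CategorySummary(
        n_total=len(matrix.proteins),
        n_low_abundant=int(classification.global_low_abundant.sum()),
        n_significant=int(classification.significant_in.any(axis=1).sum()),
        n_significant_by_group={
            g: int(classification.significant_in[g].sum()) for g in design.groups
        },
        n_common=int(is_common.sum()),
        n_unique=int(is_unique.sum()),
        n_dep=len(called),
        venn=venn,
    )
    return flags, summary


def select_set(
    classification: AbundanceClassification,
    calls: list[DepCall],
    selector: str,
    design=None,
    exclusive: bool = False,
) -> list[str]:
    """Deterministic, order-stable protein sets for profiling.

    Selectors: ``common``, ``unique``, ``dep``, ``low_abundant``,
    ``significant:<group>``, ``dep:<group>:<direction>``.  ``common`` needs
    the study ``design`` (group sizes).  With ``exclusive=True`` a ``dep:``
    selector keeps only proteins whose sole up/down call is the requested
    one.
    """
    order = list(classification.present_in.index)
    present = classification.present_in

    def ordered(members) -> list[str]:
        members = set(members)
        return [p for p in order if p in members]

    if selector == "common":
        if design is None:
            raise ConfigurationError("selector 'common' requires the study design")
        mask = pd.Series(True, index=present.index)
        for g, n in design.group_sizes().items():
            mask &= present[g] == n
        return ordered(present.index[mask])
    if selector == "unique":
        mask = classification.detected_anywhere & (present == 0).any(axis=1)
        return ordered(present.index[mask])
    if selector == "low_abundant":
        return ordered(present.index[classification.global_low_abundant])
    if selector == "dep":
        return ordered(dep_proteins(calls))
    if selector.startswith("significant:"):
        group = selector.split(":", 1)[1]
        if group not in classification.significant_in.columns:
            raise ConfigurationError(f"unknown group {group!r} in selector")
        return ordered(present.index[classification.significant_in[group]])
    if selector.startswith("dep:"):
        parts = selector.split(":")
        if len(parts) != 3:
            raise ConfigurationError(f"malformed selector {selector!r}")
        _, group, direction = parts
        if direction not in ("up", "down"):
            raise ConfigurationError(f"unknown direction {direction!r} in selector")
        known = set(classification.present_in.columns) | {
            c.comparison for c in calls
        }
        if group not in known:
            raise ConfigurationError(f"unknown group {group!r} in selector")
        hits = {
            c.protein
            for c in calls
            if c.comparison == group and c.direction == direction
        }
        if exclusive:
            n_calls: dict[str, int] = {}
            for c in calls:
                if c.direction != "none":
                    n_calls[c.protein] = n_calls.get(c.protein, 0) + 1
            hits = {p for p in hits if n_calls.get(p, 0) == 1}
        return ordered(hits)
    raise ConfigurationError(f"unknown selector {selector!r}")
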