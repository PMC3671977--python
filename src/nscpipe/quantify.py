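"""Normalized spectral counting and group-vs-baseline fold ratios.

The normalized spectral count (NSC) of a protein in a replicate is its
spectral count divided by the replicate's total spectral count, so NSC
columns sum to 1 and the statistic is invariant to sequencing/acquisition
depth.  Differential expression is assessed on the ratio of group-level
NSC summaries against the baseline group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import NscMatrix, SpectralCountMatrix, StudyDesign, ValidationError


class DegenerateReplicateError(ValidationError):
    """A replicate column has zero total spectral counts."""


class ConfigurationError(ValueError):
    pass


def compute_nsc(matrix: SpectralCountMatrix) -> NscMatrix:
    """Divide each count by its replicate's total SC.

    Raises :class:`DegenerateReplicateError` naming any all-zero replicate.
    """
    totals = matrix.replicate_totals()
    dead = list(totals.index[totals == 0])
    if dead:
        raise DegenerateReplicateError(
            f"replicate(s) with zero total spectral counts: {dead}"
        )
    values = matrix.counts / totals
    return NscMatrix(values, matrix.design)


@dataclass
class GroupNscSummary:
    """Group-level NSC summaries (proteins x groups).

    ``mean_nsc`` is the arithmetic mean of the group's replicate NSC values,
    zeros included, so each replicate carries equal weight regardless of its
    library size.  ``pooled_nsc`` (sum of group counts / sum of group
    totals) is kept alongside as the alternative aggregation.
    """

    mean_nsc: pd.DataFrame
    pooled_nsc: pd.DataFrame
    detected_fraction: pd.DataFrame
    detected_counts: pd.DataFrame
    design: StudyDesign

    @property
    def proteins(self) -> list[str]:
        return list(self.mean_nsc.index)


def summarize_groups(
    nsc: NscMatrix, matrix: SpectralCountMatrix, detection_floor: int = 1
) -> GroupNscSummary:
    """Per-protein, per-group mean NSC and detection fractions."""
    design = nsc.design
    mean_cols, pooled_cols, frac_cols, det_cols = {}, {}, {}, {}
    totals = matrix.replicate_totals()
    for g in design.groups:
        reps = design.replicates_of(g)
        mean_cols[g] = nsc.values[reps].mean(axis=1)
        pooled_cols[g] = matrix.counts[reps].sum(axis=1) / totals[reps].sum()
        det = (matrix.counts[reps] >= detection_floor).sum(axis=1)
        det_cols[g] = det
        frac_cols[g] = det / len(reps)
    return GroupNscSummary(
        mean_nsc=pd.DataFrame(mean_cols),
        pooled_nsc=pd.DataFrame(pooled_cols),
        detected_fraction=pd.DataFrame(frac_cols),
        detected_counts=pd.DataFrame(det_cols),
        design=design,
    )


@dataclass(frozen=True)
class EpsilonPolicy:
    """Pseudo-NSC floor used when exactly one side of a ratio is zero.

    mode "half-min-positive" (default): ε is half the smallest positive
    group-mean NSC in the whole summary.  mode "fixed": ε is ``value``.
    """

    mode: str = "half-min-positive"
    value: float = float("nan")

    def __post_init__(self):
        if self.mode not in ("half-min-positive", "fixed"):
            raise ConfigurationError(f"unknown epsilon policy {self.mode!r}")
        if self.mode == "fixed" and not self.value > 0:
            raise ConfigurationError("fixed epsilon must be positive")

    @classmethod
    def parse(cls, text: str) -> "EpsilonPolicy":
        """Parse 'half-min-positive' or 'fixed:<value>'."""
        if text.startswith("fixed:"):
            return cls("fixed", float(text.split(":", 1)[1]))
        return cls(text)

    def epsilon_for(self, summary_values: pd.DataFrame) -> float:
        if self.mode == "fixed":
            return self.value
        positive = summary_values.to_numpy()
        positive = positive[positive > 0]
        if positive.size == 0:
            return np.nan
        return float(positive.min()) / 2.0


@dataclass
class RatioTable:
    """Group-vs-baseline NSC ratios.

    ``ratio`` holds NaN where both sides are zero (undefined: no downstream
    call may be made).  ``discordant`` marks cells where exactly one side
    was zero and the ε floor was substituted; for those, ``baseline_zero``
    tells which side was absent.  ``epsilon_used`` is the floor applied.
    """

    ratio: pd.DataFrame  # proteins x test groups
    discordant: pd.DataFrame
    baseline_zero: pd.DataFrame
    epsilon_used: float
    baseline_group: str

    @property
    def proteins(self) -> list[str]:
        return list(self.ratio.index)

    @property
    def comparisons(self) -> list[str]:
        return list(self.ratio.columns)


def nsc_ratio(
    summary: GroupNscSummary,
    test_groups=None,
    baseline_group: str | None = None,
    epsilon_policy: EpsilonPolicy | str = EpsilonPolicy(),
    aggregation: str = "mean",
) -> RatioTable:
    """NSC ratio of each test group against the baseline.

    ratio = summary(test) / summary(baseline) when both sides are positive;
    a one-sided zero is floored at ε (``epsilon_policy``) and flagged
    discordant; a two-sided zero yields NaN.  Ratios are never rounded:
    thresholding downstream uses strict inequalities.
    """
    if isinstance(epsilon_policy, str):
        epsilon_policy = EpsilonPolicy.parse(epsilon_policy)
    if aggregation not in ("mean", "pooled"):
        raise ConfigurationError(f"unknown aggregation {aggregation!r}")
    values = summary.mean_nsc if aggregation == "mean" else summary.pooled_nsc
    baseline = baseline_group or summary.design.baseline_group
    if baseline not in values.columns:
        raise ConfigurationError(f"baseline group {baseline!r} not in summary")
    if test_groups is None:
        test_groups = [g for g in values.columns if g != baseline]
    eps = epsilon_policy.epsilon_for(values)

    base = values[baseline].to_numpy()
    ratios, disc, bzero = {}, {}, {}
    for g in test_groups:
        if g not in values.columns:
            raise ConfigurationError(f"test group {g!r} not in summary")
        test = values[g].to_numpy()
        num = test.copy()
        den = base.copy()
        one_zero = (test > 0) != (base > 0)
        num[one_zero & (test == 0)] = eps
        den[one_zero & (base == 0)] = eps
        with np.errstate(divide="ignore", invalid="ignore"):
            r = num / den
        r[(test == 0) & (base == 0)] = np.nan
        ratios[g] = r
        disc[g] = one_zero
        bzero[g] = one_zero & (base == 0)
    idx = values.index
    return RatioTable(
        ratio=pd.DataFrame(ratios, index=idx),
        discordant=pd.DataFrame(disc, index=idx),
        baseline_zero=pd.DataFrame(bzero, index=idx),
        epsilon_used=eps,
        baseline_group=baseline,
    )
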