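"""Synthetic spectral-count matrices with planted differential effects.

Counts are drawn from a negative-binomial noise model, the standard
overdispersed model for spectral counts: a count has mean
``baseline_mean_sc x fold(protein, group) x library factor(replicate)``
and variance ``mean + dispersion * mean^2``; dispersion 0 is the Poisson
limit.  Planted fold multipliers are recorded as truth labels so that the
operating characteristics (recall, false-positive rate) of the
differential-expression caller can be measured.

Because the pipeline normalizes within each replicate (NSC is a closed
composition), planting effects in one direction only shifts every other
protein's NSC in the opposite direction.  :func:`balanced_fold_effects`
builds effect maps whose expected library size is unchanged, isolating the
caller's behaviour from that composition artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DepCall, SpectralCountMatrix, StudyDesign, ValidationError
from .quantify import ConfigurationError


@dataclass
class SimulationParams:
    """Parameters of one simulated experiment.

    planted_effects maps ``(protein, group)`` to a positive fold
    multiplier; unmapped pairs have fold 1.  library_size_jitter is the
    half-width of the uniform per-replicate depth factor around 1.
    """

    n_proteins: int
    design: StudyDesign
    baseline_mean_sc: float = 50.0
    dispersion: float = 0.0
    planted_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    library_size_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        if self.baseline_mean_sc <= 0:
            raise ConfigurationError("baseline_mean_sc must be positive")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if not (0 <= self.library_size_jitter < 1):
            raise ConfigurationError("library_size_jitter must lie in [0, 1)")
        for (p, g), fold in self.planted_effects.items():
            if fold <= 0:
                raise ConfigurationError(f"fold for ({p}, {g}) must be positive")

    def protein_names(self) -> list[str]:
        width = len(str(self.n_proteins))
        return [f"P{i + 1:0{width}d}" for i in range(self.n_proteins)]


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    params: SimulationParams,
) -> tuple[SpectralCountMatrix, pd.DataFrame]:
    """Draw a count matrix; return it with per-comparison truth labels.

    Truth labels are "up"/"down"/"none" per (protein, test group) from the
    planted fold (fold > 1 up, < 1 down).  Reproducible given
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    design = params.design
    proteins = params.protein_names()
    baseline = params.baseline_mean_sc

    jitter = params.library_size_jitter
    lib = {
        r: 1.0 + (jitter * rng.uniform(-1.0, 1.0) if jitter > 0 else 0.0)
        for r in design.replicate_ids
    }
    cols = {}
    for r in design.replicate_ids:
        g = design.group_of[r]
        means = np.array(
            [baseline * params.planted_effects.get((p, g), 1.0) * lib[r] for p in proteins]
        )
        cols[r] = _draw_counts(rng, means, params.dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(proteins, name="accession"))
    matrix = SpectralCountMatrix(counts, design)

    truth_cols = {}
    for g in design.test_groups:
        labels = []
        for p in proteins:
            fold = params.planted_effects.get((p, g), 1.0)
            labels.append("up" if fold > 1 else "down" if fold < 1 else "none")
        truth_cols[g] = labels
    truth = pd.DataFrame(truth_cols, index=pd.Index(proteins, name="accession"))
    return matrix, truth


def balanced_fold_effects(
    proteins: list[str], group: str, fold: float, n_effects: int
) -> dict[tuple[str, str], float]:
    """Plant ``n_effects`` fold-``fold`` effects without shifting library size.

    The first proteins in the list receive the effects: ``n_up`` of them at
    ``fold`` and the rest at ``1/fold``, with ``n_up`` chosen so the
    expected total count of the affected group is unchanged
    (``n_up (fold - 1) = n_down (1 - 1/fold)``, i.e. n_down = fold x n_up).
    This keeps the closed NSC composition of null proteins at ratio 1.
    """
    if fold <= 1:
        raise ConfigurationError("fold must exceed 1")
    if n_effects > len(proteins):
        raise ConfigurationError("more effects than proteins")
    n_up = round(n_effects / (1.0 + fold))
    effects: dict[tuple[str, str], float] = {}
    for i, p in enumerate(proteins[:n_effects]):
        effects[(p, group)] = fold if i < n_up else 1.0 / fold
    return effects


@dataclass
class RecoveryStats:
    """Operating characteristics of the caller against planted truth."""

    recall: float
    false_positive_rate: float
    confusion: pd.DataFrame  # per comparison: tp, fn, fp, tn, wrong_direction

    def to_dict(self) -> dict:
        return {
            "recall": self.recall,
            "false_positive_rate": self.false_positive_rate,
            "confusion": self.confusion.to_dict(orient="index"),
        }


def evaluate_recovery(calls: list[DepCall], truth: pd.DataFrame) -> RecoveryStats:
    """Recall and false-positive rate of DEP calls against planted truth.

    A planted effect counts as recovered only when the called direction
    matches; a call of either direction on a null (protein, comparison)
    pair is a false positive.  Uncalled pairs count as direction "none".
    """
    called: dict[tuple[str, str], str] = {}
    for c in calls:
        key = (c.protein, c.comparison)
        if key not in called or c.direction != "none":
            called[key] = c.direction
    call_proteins = {p for p, _ in called}
    if not call_proteins <= set(truth.index):
        raise ValidationError("calls refer to proteins absent from the truth table")

    rows = {}
    tp = fn = fp = tn = 0
    for g in truth.columns:
        g_tp = g_fn = g_fp = g_tn = g_wrong = 0
        for p in truth.index:
            want = truth.loc[p, g]
            got = called.get((p, g), "none")
            if want == "none":
                if got == "none":
                    g_tn += 1
                else:
                    g_fp += 1
            else:
                if got == want:
                    g_tp += 1
                else:
                    g_fn += 1
                    if got != "none":
                        g_wrong += 1
        rows[g] = {
            "tp": g_tp, "fn": g_fn, "fp": g_fp, "tn": g_tn,
            "wrong_direction": g_wrong,
        }
        tp += g_tp
        fn += g_fn
        fp += g_fp
        tn += g_tn
    n_planted = tp + fn
    n_null = fp + tn
    return RecoveryStats(
        recall=tp / n_planted if n_planted else float("nan"),
        false_positive_rate=fp / n_null if n_null else float("nan"),
        confusion=pd.DataFrame.from_dict(rows, orient="index"),
    )
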