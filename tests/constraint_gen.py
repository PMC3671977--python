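"""Random satisfiable constraint sets for round-trip testing."""

from __future__ import annotations

import numpy as np

from nscpipe.classify import RuleConfig
from nscpipe.fixtures import paper_design
from nscpipe.model import StudyDesign
from nscpipe.reconstruct import (
    ConstraintSet,
    ProteinConstraint,
    _solve_levels,
    _structural_check,
)


def _random_protein(
    rng: np.random.Generator, acc: str, design: StudyDesign, cs_probe: ConstraintSet,
    config: RuleConfig,
) -> ProteinConstraint:
    sizes = design.group_sizes()
    b = design.baseline_group
    for _ in range(60):
        presence, abundance = {}, {}
        for g in design.groups:
            if rng.random() < 0.25:
                presence[g], abundance[g] = 0, "absent"
                continue
            p = int(rng.integers(1, sizes[g] + 1))
            presence[g] = p
            if p >= config.presence_quota(sizes[g]) and rng.random() < 0.5:
                abundance[g] = "significant"
            else:
                abundance[g] = rng.choice(["low", "detected"])
        if all(v == 0 for v in presence.values()):
            continue
        dep = {}
        for g in design.test_groups:
            if presence.get(g, 0) == 0 or presence.get(b, 0) == 0:
                # discordant / undefined comparisons resolve themselves;
                # leave the outcome to the calling policy
                dep[g] = "any"
            else:
                dep[g] = rng.choice(["up", "down", "none", "any"])
        cand = ProteinConstraint(acc, presence, abundance, dep)
        probe = ConstraintSet([cand], design, margin=cs_probe.margin)
        if _structural_check(cand, probe, config):
            continue
        solved = _solve_levels(cand, probe, config)
        if isinstance(solved, dict):
            return cand
    # fall back to an unconstrained detected-everywhere protein
    presence = {g: sizes[g] for g in design.groups}
    abundance = {g: "significant" for g in design.groups}
    return ProteinConstraint(acc, presence, abundance,
                             {g: "any" for g in design.test_groups})


def random_constraint_set(
    rng: np.random.Generator,
    design: StudyDesign | None = None,
    max_proteins: int = 8,
    config: RuleConfig = RuleConfig(),
) -> ConstraintSet:
    """A satisfiable ConstraintSet with a housekeeping filler protein."""
    design = design or paper_design()
    sizes = design.group_sizes()
    filler = ProteinConstraint(
        "FILLER",
        presence={g: sizes[g] for g in design.groups},
        abundance={g: "significant" for g in design.groups},
        dep={g: "any" for g in design.test_groups},
        filler=True,
    )
    probe = ConstraintSet([filler], design)
    n = int(rng.integers(1, max_proteins))
    constraints = [filler] + [
        _random_protein(rng, f"P{i}", design, probe, config) for i in range(n)
    ]
    return ConstraintSet(constraints, design)
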