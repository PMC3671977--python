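import numpy as np
import pandas as pd
import pytest

from nscpipe.classify import RuleConfig, call_dep, classify_abundance
from nscpipe.fixtures import load_reference_annotations, paper_design
from nscpipe.quantify import compute_nsc, nsc_ratio, summarize_groups
from nscpipe.reconstruct import (
    ConstraintSet,
    ProteinConstraint,
    UnsatisfiableConstraintError,
    check_satisfiable,
    reconstruct_from_constraints,
    reconstruct_reference_matrix,
    reference_constraints,
)

from constraint_gen import random_constraint_set


def classify_result(matrix, config=RuleConfig()):
    classification = classify_abundance(matrix, config)
    ratios = nsc_ratio(summarize_groups(compute_nsc(matrix), matrix))
    calls = call_dep(ratios, config, classification)
    directions = {(c.protein, c.comparison): c.direction for c in calls}
    return classification, directions


def assert_satisfies(matrix, cs, config=RuleConfig()):
    classification, directions = classify_result(matrix, config)
    present = classification.present_in
    for c in cs.constraints:
        for g in cs.design.groups:
            want = c.presence.get(g, 0)
            assert int(present.loc[c.accession, g]) == want, (c.accession, g)
            a = c.abundance.get(g, "absent" if want == 0 else "detected")
            sig = bool(classification.significant_in.loc[c.accession, g])
            assert sig == (a == "significant"), (c.accession, g, a)
            if a == "low":
                assert bool(classification.low_in.loc[c.accession, g])
        for g, target in c.dep.items():
            if target == "any":
                continue
            got = directions.get((c.accession, g), "none")
            assert got == target, (c.accession, g, got, target)


class TestSingleProtein:
    def test_constant_presence_no_dep(self):
        design = paper_design()
        sizes = design.group_sizes()
        cs = ConstraintSet(
            [
                ProteinConstraint(
                    "X",
                    presence={g: sizes[g] for g in design.groups},
                    abundance={g: "significant" for g in design.groups},
                    dep={g: "none" for g in design.test_groups},
                )
            ],
            design,
        )
        m = reconstruct_from_constraints(cs, seed=1)
        assert_satisfies(m, cs)

    def test_down_call_clears_threshold_with_margin(self):
        design = paper_design()
        sizes = design.group_sizes()
        filler = ProteinConstraint(
            "F", {g: sizes[g] for g in design.groups},
            {g: "significant" for g in design.groups},
            {g: "any" for g in design.test_groups}, filler=True,
        )
        target = ProteinConstraint(
            "X",
            presence={"NN": 4, "NA": 3, "ON": 1, "OA": 2},
            abundance={"NN": "significant", "NA": "significant",
                       "ON": "detected", "OA": "detected"},
            dep={"NA": "down", "ON": "any", "OA": "any"},
        )
        cs = ConstraintSet([filler, target], design, margin=0.25)
        m = reconstruct_from_constraints(cs, seed=2)
        _, directions = classify_result(m)
        assert directions[("X", "NA")] == "down"
        summary = summarize_groups(compute_nsc(m), m)
        ratio = summary.mean_nsc.loc["X", "NA"] / summary.mean_nsc.loc["X", "NN"]
        assert ratio < 0.5 * (1 - 0.05)  # clears the cutoff, not grazing it

    def test_same_seed_identical_output(self):
        rng = np.random.default_rng(3)
        cs = random_constraint_set(rng)
        a = reconstruct_from_constraints(cs, seed=11)
        b = reconstruct_from_constraints(cs, seed=11)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestSatisfiability:
    def test_down_call_with_absent_test_group_rejected(self):
        design = paper_design()
        cs = ConstraintSet(
            [
                ProteinConstraint(
                    "X",
                    presence={"NN": 5, "NA": 0, "ON": 1, "OA": 2},
                    abundance={"NN": "significant", "NA": "absent",
                               "ON": "detected", "OA": "detected"},
                    dep={"NA": "down"},
                )
            ],
            design,
        )
        with pytest.raises(UnsatisfiableConstraintError, match="absence"):
            check_satisfiable(cs)

    def test_baseline_absent_up_call_needs_test_significance(self):
        design = paper_design()
        cs = ConstraintSet(
            [
                ProteinConstraint(
                    "X",
                    presence={"NN": 0, "NA": 2, "ON": 0, "OA": 0},
                    abundance={"NN": "absent", "NA": "low",
                               "ON": "absent", "OA": "absent"},
                    dep={"NA": "up"},
                )
            ],
            design,
        )
        with pytest.raises(UnsatisfiableConstraintError, match="significance"):
            check_satisfiable(cs)

    def test_conflicting_fold_and_abundance_caps_rejected(self):
        design = paper_design()
        # NN capped low but a significant NA group must sit 2.25x lower still
        cs = ConstraintSet(
            [
                ProteinConstraint(
                    "X",
                    presence={"NN": 2, "NA": 4, "ON": 0, "OA": 0},
                    abundance={"NN": "low", "NA": "significant",
                               "ON": "absent", "OA": "absent"},
                    dep={"NA": "down"},
                )
            ],
            design,
        )
        with pytest.raises(UnsatisfiableConstraintError):
            check_satisfiable(cs)


class TestRoundTrip:
    N_SETS = 200

    def test_random_satisfiable_sets_round_trip_exactly(self):
        rng = np.random.default_rng(31)
        for i in range(self.N_SETS):
            cs = random_constraint_set(rng)
            m = reconstruct_from_constraints(cs, seed=1000 + i)
            assert_satisfies(m, cs)

    def test_reference_constraints_round_trip(self):
        cs, relaxations = reference_constraints()
        assert len(relaxations) == 2
        m = reconstruct_from_constraints(cs, seed=42)
        assert_satisfies(m, cs)


class TestReferenceReconstruction:
    def test_matches_reference_annotations_row_for_row(self):
        matrix, relaxations = reconstruct_reference_matrix(seed=42)
        classification, directions = classify_result(matrix)
        annotations = load_reference_annotations()
        relaxed_accessions = {"56676397", "50363217"}
        for acc, ann in annotations.items():
            got_presence = {
                g: int(classification.present_in.loc[acc, g])
                for g in matrix.design.groups
            }
            assert got_presence == ann.presence, ann.name
            assert bool(classification.global_low_abundant[acc]) == ann.low_global
            got_dep = {
                g: d
                for (p, g), d in directions.items()
                if p == acc and d != "none"
            }
            got_sig = classification.significant_groups(acc)
            if acc in relaxed_accessions:
                continue  # documented relaxations, asserted below
            assert got_dep == ann.dep, ann.name
            assert got_sig == ann.significant_groups, ann.name

    def test_documented_relaxations_behave_as_logged(self):
        matrix, relaxations = reconstruct_reference_matrix(seed=42)
        classification, directions = classify_result(matrix)
        # ankyrin: up in OA only (baseline absent, OA significant)
        ank = {
            g: d for (p, g), d in directions.items()
            if p == "56676397" and d != "none"
        }
        assert ank == {"OA": "up"}
        # serpin A1: printed directions kept, NN significance emerges
        ser = {
            g: d for (p, g), d in directions.items()
            if p == "50363217" and d != "none"
        }
        assert ser == {"NA": "up", "OA": "down", "ON": "up"}
        assert classification.significant_groups("50363217") == {
            "NN", "NA", "OA", "ON",
        }

    def test_library_sizes_hit_target_exactly(self):
        matrix, _ = reconstruct_reference_matrix(seed=42, target_library_size=500)
        assert (matrix.replicate_totals() == 500).all()

    def test_classified_outcome_invariant_to_seed_and_library_size(self):
        baseline = None
        for seed, lib in [(42, 500), (7, 500), (42, 900)]:
            matrix, _ = reconstruct_reference_matrix(
                seed=seed, target_library_size=lib
            )
            classification, directions = classify_result(matrix)
            snapshot = (
                classification.significant_in.to_numpy().tolist(),
                classification.global_low_abundant.to_numpy().tolist(),
                sorted((p, g, d) for (p, g), d in directions.items() if d != "none"),
            )
            if baseline is None:
                baseline = snapshot
            else:
                assert snapshot == baseline
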