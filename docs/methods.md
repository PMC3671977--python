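# Methods

## Quantification model

Spectral counting treats the number of MS/MS spectra matched to a protein
as a semiquantitative abundance proxy. Because acquisition depth varies
between runs, each count is normalized by its replicate's total
(`NSC(i, r) = SC(i, r) / Σ_j SC(j, r)`), making every replicate a closed
composition that sums to 1. NSC is scale-invariant per replicate:
multiplying one replicate's counts by any positive factor leaves its NSC
column unchanged (property-tested).

Group abundance is summarized as the **arithmetic mean of the replicate
NSC values, zeros included**, rather than pooling counts and
renormalizing. Pooling would weight replicates by their library sizes;
the mean keeps each biological replicate equally weighted. The pooled
alternative is retained behind `aggregation="pooled"` for sensitivity
checks; defaults and all packaged results use the mean.

Differential expression of group *g* against the baseline *B* is the
ratio of the two group summaries, with strict, never-rounded cutoffs:
up-regulated when R > `over_threshold` (2), down-regulated when
R < `under_threshold` (0.5). The thresholds form a reciprocal pair, so
swapping numerator and denominator maps calls onto their mirror image.

## Abundance classes

Per group, a protein is **significant** when (a) SC reaches
`sc_threshold` (10) in at least one of the group's replicates and (b) it
is detected (SC ≥ `detection_floor`, default 1) in at least the presence
quota of them; **low-abundant** in a group when detected but never above
the threshold there; **globally low-abundant** when its SC never exceeds
the threshold in any replicate and it is significant nowhere. A count of
exactly 10 satisfies both written rules; the classes are kept disjoint by
letting significance dominate, which matches how the reference study's
table partitions its rows.

The presence quota is `max(1, floor(presence_fraction x n_g))` detected
replicates — for the packaged design, 2 of 5 in NN, 2 of 4 in NA, 1 of 2
in OA and 1 of 1 in ON. The strict at-least-50% reading (ceiling) is
available via `presence_rounding="ceil"`, but it is demonstrably not what
the reference annotations encode: two proteins there are significant in
NN while detected in only 2 of its 5 replicates. The floor convention
reproduces the printed classification; the choice only matters for
odd-sized groups.

## Presence-discordant comparisons

When a protein is detected on exactly one side of a comparison the fold
ratio is not measurable. The ratio table still reports a finite value by
flooring the zero side at ε (default: half the smallest positive group
mean in the whole summary, configurable as a fixed value) and flags the
cell `presence_discordant`; a two-sided zero is undefined and can never
produce a call.

Whether a discordant cell yields a *direction* is a separate policy
(`discordant_policy`):

* `"test-significant"` (default): a protein undetected in the test group
  receives no call — absence at low sampling depth is not evidence of
  down-regulation — and a protein detected only in the test group is
  called up only when the test-group evidence independently clears the
  significance bar.
* `"epsilon-sign"`: every one-sided zero is called on the ε-floored
  ratio.
* `"never"`: discordant cells are never called.

The default is the only convention consistent with the reference
annotations: an ε-sign rule would call nearly every presence-discordant
row (inflating the DEP count from 20 to ~25), while a blanket "never"
rule would miss the one baseline-absent protein the study did call.

Two reference rows remain irreproducible under any convention and are
carried as *documented relaxations*, surfaced by the fixture builder and
`reproduce_paper`:

* **ankyrin repeat domain 11** — printed "down in OA, ON" despite being
  undetected in the NN baseline. A fold against an absent baseline can
  only point up; the reconstruction calls it up in OA (where it is
  significant) and leaves NA/ON uncalled (evidence below the bar).
* **serpin A1** — printed down in OA, significant in OA, yet not
  significant in NN. The down-call forces NN means above twice the OA
  significance floor, which puts NN counts over the threshold in several
  replicates: NN significance follows arithmetically. (The study's own
  prose counts 24 NN-significant proteins, consistent with this.)

## Constraint-guided reconstruction

The raw count matrix behind the packaged study was never published, so it
is rebuilt from the printed per-protein annotations. The generator is
constructive, not rejection sampling — the single-replicate ON group and
35 x 12 joint constraints make rejection hopeless:

1. **Level solving.** Per protein, every abundance class maps to a
   feasible interval of group mean counts (significance floor
   `sc_threshold + 2` in one replicate keeps integer rounding clear of
   the boundary; low-abundance caps counts at `sc_threshold − 1` so a
   met presence quota cannot flip the class). Fold targets are imposed
   with a margin (default 0.25: up-targets ≥ 2.25, down-targets ≤ 1/2.25,
   no-call band [1/1.75, 1.75]); interval propagation on the baseline
   mean either yields target levels or a precise infeasibility reason
   (`check_satisfiable`).
2. **Integerization.** Group totals are rounded and distributed over a
   seeded choice of detected replicates, honoring floors and caps.
3. **Library-size padding.** A designated abundant filler protein
   (albumin in the packaged fixture) absorbs each replicate's residual so
   every column totals exactly `target_library_size` (500 by default) —
   NSC ratios then reduce to pure count ratios and per-protein
   constraints decouple.
4. **Verification.** The real quantification + classification pipeline
   runs on the result; any violated constraint triggers a bounded repair
   loop (nudge the offending group level, re-integerize), and failure to
   converge raises with the violation list.

Because constraints are verified post hoc, the *classified outcome* is
invariant to the seed and to the target library size (tested for several
seeds and sizes 400–2000); the seed only moves which replicates within a
group carry the detections and how totals are split.

## Simulation model

`simulate_counts` draws each count from a negative binomial with mean
`baseline_mean_sc x fold(protein, group) x library factor(replicate)` and
variance `mean + dispersion x mean²`; dispersion 0 is the exact Poisson
limit (variance/mean ratio ≈ 1, tested at three standard errors). The
library factor is uniform in `1 ± library_size_jitter`. Defaults —
baseline mean SC 50, dispersion 0.1 — sit in the range typical of
moderately abundant seminal-plasma proteins and give per-replicate
coefficients of variation around 35%.

Because NSC is a closed composition, planting effects in one direction
only is self-defeating: 100 four-fold up-effects among 200 proteins
inflate the affected group's library ~2.5x, compressing every planted
ratio to ~1.6 and pushing every null to ~0.4 — the caller would recover
nothing and flag every null. `balanced_fold_effects` therefore plants
effects with the expected library size held fixed (for fold 4: one up
per four downs), isolating threshold behaviour from compositional
distortion. The packaged operating-characteristic experiment — 200
proteins, 100 planted four-fold effects, NN = 5 vs NA = 4, dispersion
0.1, seed 1 — yields recall 0.98 and false-positive rate 0.01 under the
default thresholds.

What the simulator does *not* emulate: peptide-level detectability and
shared-peptide inference, intensity-dependent missingness (absence here
is purely sampling zeros), and between-protein count correlations beyond
the compositional constraint. Passing recovery tests therefore show that
the thresholds behave as designed under clean overdispersed sampling,
not that real seminal-plasma data would be called with these error
rates.

## Functional profiling

Annotation tables are pre-slimmed, opaque term strings per protein and
aspect (cellular component, biological process); no GO DAG traversal
happens in the package, matching the external-tool workflow the profiles
mirror. A profile reports `100 x (members with term) / set size`:
unannotated members dilute every term, the conservative reading of
per-set share bar charts; values are multi-label and need not sum to 100.
The packaged GO-slim table is a synthetic reconstruction (so labelled)
consistent with the study narrative — e.g. 10 of the 11 common proteins
extracellular (90.9%) — and supports mechanics tests only; exact figure
percentages are not reproduction targets because the original slimming
tool versions are unknown.

## Numerical choices and edge cases

* Ratios are compared to thresholds strictly and never rounded; a ratio
  of exactly 2.0 or 0.5 is not a call.
* An all-zero replicate column is a hard error naming the replicate (an
  NSC denominator of zero has no interpretation).
* Duplicate accessions, negative or fractional counts, unknown group
  labels, and matrix/design mismatches are rejected at parse time with
  line-level messages; alias merging conserves every replicate total and
  warns (without dropping data) on accessions missing from the catalog.
* TSV dialect: tab-separated, UTF-8, `#` comments, no quoting; "NA" is
  always a group label, never a missing value. A missing count cell
  means "not identified" and reads as 0.
* Problem sizes in the test suite (1000 random ≤ 8 x ≤ 6 oracle
  matrices, 200 random constraint sets, one 200-protein recovery
  simulation) were chosen to exercise every rule branch while keeping
  the full suite around a minute on one core.

## Known limitations

* The per-group low-abundance notes in the reference table are not
  exhaustive (e.g. a detected-but-capped baseline group may derive a low
  flag the table omits); round-trip checks assert the flags the table
  states, plus the global class, exactly.
* The reference table's printed per-group significant tallies disagree
  with its own rows in two groups (NN, ON); the package reproduces the
  rows, and the tallies that follow from them, not the printed totals.
* With `presence_rounding="ceil"` the packaged fixture is intentionally
  not reproducible (two reference rows violate the strict quota); the
  satisfiability checker reports exactly which rows fail and why.
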