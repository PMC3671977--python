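"""Multi-label functional-distribution profiling of protein sets.

Proteins carry sets of GO-slim terms (cellular component and biological
process aspects); a profile reports, for a chosen protein set, the
percentage of the set annotated with each term.  Terms are opaque strings:
the annotation table is expected to be pre-slimmed, so no ontology
traversal happens here.  Percentages are taken over the full set size —
unannotated members dilute every term — and need not sum to 100 because a
protein may carry several terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import ParseError, _read_tsv
from .quantify import ConfigurationError

ASPECTS = ("cellular_component", "biological_process")


class EmptySetError(ValueError):
    pass


@dataclass
class AnnotationTable:
    """Per-protein term sets, one set per aspect."""

    cc_terms: dict[str, set[str]] = field(default_factory=dict)
    bp_terms: dict[str, set[str]] = field(default_factory=dict)

    def terms_for(self, protein: str, aspect: str) -> set[str]:
        table = self._table(aspect)
        return set(table.get(protein, set()))

    def _table(self, aspect: str) -> dict[str, set[str]]:
        if aspect == "cellular_component":
            return self.cc_terms
        if aspect == "biological_process":
            return self.bp_terms
        raise ConfigurationError(f"unknown aspect {aspect!r}")

    def add(self, protein: str, aspect: str, term: str) -> None:
        if not term:
            raise ParseError("empty annotation term")
        self._table(aspect).setdefault(protein, set()).add(term)

    @property
    def proteins(self) -> set[str]:
        return set(self.cc_terms) | set(self.bp_terms)


def load_annotations(path) -> AnnotationTable:
    """Read an annotations TSV with columns accession, aspect, term.

    Duplicate rows are deduplicated (set semantics); an aspect outside
    {cellular_component, biological_process} is a parse error.
    """
    df = _read_tsv(path)
    for col in ("accession", "aspect", "term"):
        if col not in df.columns:
            raise ParseError(f"{path}: annotation file lacks column {col!r}")
    table = AnnotationTable()
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        if row.aspect not in ASPECTS:
            raise ParseError(f"{path}: line {lineno}: unknown aspect {row.aspect!r}")
        table.add(row.accession, row.aspect, row.term)
    return table


@dataclass
class DistributionProfile:
    """Percentage of a protein set annotated with each term."""

    set_name: str
    aspect: str
    set_size: int
    percent_of: dict[str, float]

    def to_series(self) -> pd.Series:
        return pd.Series(self.percent_of, name=self.set_name, dtype=float)


def profile(
    proteins: list[str],
    annotations: AnnotationTable,
    aspect: str,
    set_name: str = "set",
) -> DistributionProfile:
    """Percentage of ``proteins`` carrying each term of ``aspect``.

    percent(term) = 100 * (#members annotated with term) / set size.
    Terms absent from every member are omitted.  Duplicated input
    accessions are counted once; an empty set is an error.
    """
    members = list(dict.fromkeys(proteins))
    if not members:
        raise EmptySetError("cannot profile an empty protein set")
    counts: dict[str, int] = {}
    for p in members:
        for t in annotations.terms_for(p, aspect):
            counts[t] = counts.get(t, 0) + 1
    n = len(members)
    percent = {t: 100.0 * c / n for t, c in sorted(counts.items())}
    return DistributionProfile(set_name, aspect, n, percent)


def compare_profiles(profiles: list[DistributionProfile]) -> pd.DataFrame:
    """Term x set matrix of percentages, zero-filled, ranked by max percent.

    All profiles must share the same aspect; the result is the column-wise
    concatenation of the individual profiles (no recomputation).
    """
    if not profiles:
        raise ConfigurationError("need at least one profile")
    aspects = {p.aspect for p in profiles}
    if len(aspects) > 1:
        raise ConfigurationError(f"mixed aspects: {sorted(aspects)}")
    table = pd.concat([p.to_series() for p in profiles], axis=1).fillna(0.0)
    order = table.max(axis=1).sort_values(ascending=False, kind="stable").index
    return table.loc[order]
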