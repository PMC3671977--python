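"""Domain types for spectral-count proteomics data.

A label-free LC-MS/MS experiment is summarized as a matrix of spectral
counts (SC): the number of MS/MS spectra assigned to peptides of each
protein in each replicate run.  Replicates belong to study groups (here
semen-quality groups NN, NA, ON, OA), one of which serves as the baseline
for fold-ratio comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical ordering of the study groups used throughout reports
GROUP_ORDER = ("NN", "NA", "ON", "OA")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


class DesignError(ValidationError):
    """Raised when a study design is inconsistent with a count matrix."""


def _order_groups(groups) -> list[str]:
    """Sort group labels canonically (known groups first, then lexical)."""
    known = [g for g in GROUP_ORDER if g in groups]
    extra = sorted(g for g in groups if g not in GROUP_ORDER)
    return known + extra


@dataclass(frozen=True)
class ProteinRecord:
    """One protein in the catalog, keyed by its NCBI accession.

    ``aliases`` holds alternate accessions (e.g. other isoforms reported
    separately during database search) whose counts are merged into this
    record by :func:`nscpipe.io.resolve_aliases`.
    """

    accession: str
    name: str
    uniprot: str = ""
    mw_kda: float = float("nan")
    pi: float = float("nan")
    aliases: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.accession:
            raise ValidationError("protein accession must be non-empty")
        if not np.isnan(self.mw_kda) and self.mw_kda <= 0:
            raise ValidationError(f"{self.accession}: mw_kda must be > 0")
        if not np.isnan(self.pi) and not (0 < self.pi < 14):
            raise ValidationError(f"{self.accession}: pI must lie in (0, 14)")
        if self.accession in self.aliases:
            raise ValidationError(f"{self.accession}: accession may not alias itself")


def validate_catalog(catalog: list[ProteinRecord]) -> dict[str, str]:
    """Check catalog invariants; return the alias -> primary accession map.

    Primary accessions must be unique, alias sets disjoint, and no alias may
    collide with a primary accession.
    """
    primaries: set[str] = set()
    alias_map: dict[str, str] = {}
    for rec in catalog:
        if rec.accession in primaries:
            raise ValidationError(f"duplicate primary accession {rec.accession}")
        primaries.add(rec.accession)
        for a in rec.aliases:
            if a in alias_map:
                raise ValidationError(f"alias {a} mapped to more than one record")
            alias_map[a] = rec.accession
    clash = primaries & set(alias_map)
    if clash:
        raise ValidationError(f"accessions both primary and alias: {sorted(clash)}")
    return alias_map


@dataclass(frozen=True)
class StudyDesign:
    """Mapping of replicate ids to study groups, with a baseline group."""

    replicate_ids: tuple[str, ...]
    group_of: dict[str, str]
    baseline_group: str = "NN"

    def __post_init__(self):
        if len(set(self.replicate_ids)) != len(self.replicate_ids):
            raise DesignError("replicate ids must be unique")
        missing = [r for r in self.replicate_ids if r not in self.group_of]
        if missing:
            raise DesignError(f"replicates missing from design: {missing}")
        if self.baseline_group not in set(self.group_of.values()):
            raise DesignError(
                f"baseline group {self.baseline_group!r} has no replicates"
            )

    @property
    def groups(self) -> list[str]:
        return _order_groups(set(self.group_of.values()))

    @property
    def test_groups(self) -> list[str]:
        return [g for g in self.groups if g != self.baseline_group]

    def replicates_of(self, group: str) -> list[str]:
        reps = [r for r in self.replicate_ids if self.group_of[r] == group]
        if not reps:
            raise DesignError(f"group {group!r} has no replicates")
        return reps

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.replicates_of(g)) for g in self.groups}

    @classmethod
    def from_groups(cls, sizes: dict[str, int], baseline: str = "NN") -> "StudyDesign":
        """Build a design with auto-named replicates, e.g. NN1..NN5."""
        reps, mapping = [], {}
        for g, n in sizes.items():
            for i in range(1, n + 1):
                rid = f"{g}{i}" if n > 1 else g
                reps.append(rid)
                mapping[rid] = g
        return cls(tuple(reps), mapping, baseline)


@dataclass
class SpectralCountMatrix:
    """Integer spectral counts, proteins (rows) x replicates (columns)."""

    counts: pd.DataFrame
    design: StudyDesign

    def __post_init__(self):
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein accessions: {dups}")
        if list(df.columns) != list(self.design.replicate_ids):
            raise DesignError(
                "count matrix columns do not match design replicate ids: "
                f"{list(df.columns)} vs {list(self.design.replicate_ids)}"
            )
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("spectral counts must be integers")
            self.counts = df.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("spectral counts must be non-negative")

    @property
    def proteins(self) -> list[str]:
        return list(self.counts.index)

    def replicate_totals(self) -> pd.Series:
        """Library size (total SC) of each replicate."""
        return self.counts.sum(axis=0)

    def presence(self, detection_floor: int = 1) -> pd.DataFrame:
        """Boolean detection matrix at the given SC floor."""
        return self.counts >= detection_floor

    def group_presence_counts(self, detection_floor: int = 1) -> pd.DataFrame:
        """Detected-replicate counts per protein per group."""
        det = self.presence(detection_floor)
        cols = {
            g: det[self.design.replicates_of(g)].sum(axis=1)
            for g in self.design.groups
        }
        return pd.DataFrame(cols)

    def subset(self, proteins: list[str]) -> "SpectralCountMatrix":
        return SpectralCountMatrix(self.counts.loc[proteins].copy(), self.design)


@dataclass
class NscMatrix:
    """Normalized spectral counts: each SC divided by its replicate's total.

    Columns of a valid matrix sum to 1; a value is 0 exactly where the raw
    count is 0.
    """

    values: pd.DataFrame
    design: StudyDesign

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)


@dataclass
class AbundanceClassification:
    """Per-protein presence / significance / low-abundance flags.

    significant_in and low_in are boolean frames (proteins x groups);
    a protein is globally low-abundant when it is detected somewhere, its
    maximum SC never exceeds the threshold, and it is significant nowhere.
    """

    present_in: pd.DataFrame
    significant_in: pd.DataFrame
    low_in: pd.DataFrame
    global_low_abundant: pd.Series
    detected_anywhere: pd.Series

    @property
    def proteins(self) -> list[str]:
        return list(self.present_in.index)

    def significant_groups(self, protein: str) -> set[str]:
        row = self.significant_in.loc[protein]
        return set(row.index[row])

    def low_groups(self, protein: str) -> set[str]:
        row = self.low_in.loc[protein]
        return set(row.index[row])


@dataclass(frozen=True)
class DepCall:
    """A differential-expression verdict for one protein in one comparison."""

    protein: str
    comparison: str
    ratio: float
    direction: str  # "up" | "down" | "none"
    presence_discordant: bool = False

    def __post_init__(self):
        if self.direction not in ("up", "down", "none"):
            raise ValidationError(f"bad direction {self.direction!r}")


@dataclass
class CategorySummary:
    """Headline category counts of a classified study (Figure-1 style)."""

    n_total: int
    n_low_abundant: int
    n_significant: int
    n_significant_by_group: dict[str, int]
    n_common: int
    n_unique: int
    n_dep: int
    venn: dict[frozenset, int] = field(default_factory=dict)

    def venn_as_strings(self) -> dict[str, int]:
        """Venn cells keyed by '+'-joined canonically ordered group names."""
        return {
            "+".join(_order_groups(k)): v
            for k, v in sorted(self.venn.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
        }

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_low_abundant": self.n_low_abundant,
            "n_significant": self.n_significant,
            "n_significant_by_group": dict(self.n_significant_by_group),
            "n_common": self.n_common,
            "n_unique": self.n_unique,
            "n_dep": self.n_dep,
            "venn": self.venn_as_strings(),
        }
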