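"""Packaged study fixture: catalog, reference annotations, GO-slim table.

The study pooled seminal plasma into 12 replicates — NN = 5, NA = 4,
ON = 1, OA = 2 — and identified 35 proteins.  Raw spectral counts were
never deposited; what is packaged here is the transcription of the printed
protein metadata and per-protein classification annotations (presence,
abundance class, differential-expression calls), from which
:mod:`nscpipe.reconstruct` rebuilds a consistent count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .io import read_catalog, _read_tsv
from .model import ProteinRecord, SpectralCountMatrix, StudyDesign
from .profiling import AnnotationTable, load_annotations

GROUPS = ("NN", "NA", "ON", "OA")
REPLICATES_PER_GROUP = {"NN": 5, "NA": 4, "ON": 1, "OA": 2}


def _data_path(name: str):
    return resources.files("nscpipe").joinpath("data", name)


def paper_design() -> StudyDesign:
    """The study's replicate design: NN=5, NA=4, ON=1, OA=2 (baseline NN)."""
    return StudyDesign.from_groups(dict(REPLICATES_PER_GROUP), baseline="NN")


def load_catalog() -> list[ProteinRecord]:
    """The 35-protein catalog (NCBI accession keyed, with alias merges)."""
    with resources.as_file(_data_path("catalog.tsv")) as p:
        return read_catalog(p)


@dataclass
class ReferenceAnnotation:
    """Expected classification of one fixture protein.

    ``dep`` maps comparison group -> printed direction; ``low_groups`` are
    the per-group low-abundance notes; ``significant_groups`` the groups in
    which the protein met the significance rule.
    """

    accession: str
    name: str
    n_samples_printed: int
    presence: dict[str, int]
    low_global: bool
    low_groups: set[str] = field(default_factory=set)
    dep: dict[str, str] = field(default_factory=dict)
    significant_groups: set[str] = field(default_factory=set)
    notes: str = ""

    @property
    def n_samples(self) -> int:
        return sum(self.presence.values())

    @property
    def is_dep(self) -> bool:
        return bool(self.dep)


def load_reference_annotations() -> dict[str, ReferenceAnnotation]:
    """Per-protein expected classification, keyed by accession."""
    with resources.as_file(_data_path("reference_annotations.tsv")) as p:
        df = _read_tsv(p)
    out: dict[str, ReferenceAnnotation] = {}
    for row in df.itertuples(index=False):
        dep = {}
        if row.dep:
            for item in row.dep.split(","):
                comp, direction = item.split(":")
                dep[comp] = direction
        out[row.accession] = ReferenceAnnotation(
            accession=row.accession,
            name=row.name,
            n_samples_printed=int(row.n_samples_printed),
            presence={g: int(getattr(row, f"present_{g}")) for g in GROUPS},
            low_global=row.low_global == "1",
            low_groups=set(filter(None, row.low_groups.split(","))),
            dep=dep,
            significant_groups=set(filter(None, row.significant_groups.split(","))),
            notes=row.notes,
        )
    return out


def load_paper_fixture() -> tuple[list[ProteinRecord], dict[str, ReferenceAnnotation]]:
    """The packaged fixture: protein catalog + expected classifications."""
    return load_catalog(), load_reference_annotations()


def load_goslim_annotations() -> AnnotationTable:
    """Synthetic GO-slim reconstruction for the 35 fixture proteins.

    Assembled for testing the profiling mechanics (it reproduces the
    narrative features such as 10/11 common proteins extracellular); not
    authoritative GO data.
    """
    with resources.as_file(_data_path("goslim_synthetic.tsv")) as p:
        return load_annotations(p)


def annotation_lookup_by_name() -> dict[str, ReferenceAnnotation]:
    """Reference annotations keyed by protein display name."""
    return {a.name: a for a in load_reference_annotations().values()}


# ---------------------------------------------------------------------------
# Per-sample identification lists (accessions reported in each replicate,
# as originally listed BEFORE alias merging).  These carry presence only —
# spectral counts were not published — and exercise alias resolution:
# e.g. prostate specific antigen appears as isoform 1 (4502173) in ten
# replicates and as isoform 4 (71834855) in the other two.  Three
# accessions (4502247, 26051231, 4505185) have no catalog record at all.

SAMPLE_IDENTIFICATIONS: dict[str, tuple[str, ...]] = {
    "NN1": ("4506885", "4505821", "4502027", "5453678", "11386147", "151301154",
            "71834855", "4502247", "4503143", "4502337", "4503109", "4506713",
            "42716297"),
    "NN2": ("4505821", "4506885", "38049014", "4502027", "4502173", "54607120",
            "4502337", "4503109", "11386147", "5453678", "50363217", "151301154",
            "221316614", "4503107", "4507509", "16933542", "4503143", "6382064",
            "4503009", "42716297"),
    "NN3": ("4505821", "4506885", "38049014", "4502027", "4502173", "54607120",
            "4502337", "5453678", "4507509", "11386147", "221316614", "4503109",
            "4757826", "16933542", "167857790", "4503107", "151301154", "4503143",
            "4503009", "25121982", "5031863", "42716297", "6382064", "32171249"),
    "NN4": ("4505821", "4506885", "38049014", "54607120", "4502027", "4502173",
            "4502337", "151301154", "5453678", "6382064", "42716297", "167857790",
            "4505529", "11386147", "221316614", "4507509", "4757826", "16933542",
            "4503107", "4503009", "5031863", "4557871", "25121982", "4503109",
            "50363217", "4503143", "32171249"),
    "NN5": ("4505821", "4506885", "4502027", "5453678", "4502173", "4503109",
            "4502337", "11386147", "6382064", "54607120", "42716297", "5031863",
            "4758236"),
    "NA1": ("4505821", "4502027", "4506885", "38049014", "4502173", "54607120",
            "4502337", "5453678", "221316614", "50363217", "4507509", "11386147",
            "4757826", "16933542", "4503107", "4503109", "89033736", "32171249",
            "6382064", "104487006", "4557871", "42716297", "4503143", "5031863"),
    "NA2": ("4505821", "4506885", "38049014", "4502027", "4502173", "4502337",
            "54607120", "5453678", "11386147", "4507509", "50363217", "4758236",
            "4503107", "4757826", "6382064", "4503143", "42716297", "31543380",
            "4503009", "5031863", "4503109", "110735433", "89033736", "16933542",
            "4507065", "4503139"),
    "NA3": ("4505821", "4506885", "4502027", "11386147", "89033736", "5453678",
            "4502337", "4502173", "42716297"),
    "NA4": ("4505821", "4506885", "38049014", "4502173", "4502337", "54607120",
            "11386147", "5453678", "50363217", "4758236", "4757826", "4507509",
            "4503109", "4503107", "4503143", "4503139", "4503009"),
    "ON": ("4505821", "4506885", "38049014", "4502027", "4502173", "4502337",
           "54607120", "50363217", "11386147", "5453678", "4507509", "221316614",
           "4757826", "151301154", "16933542", "4503143", "4503107", "4503009",
           "42716297", "6382064", "4507065", "104487006"),
    "OA1": ("4505821", "4506885", "38049014", "4502027", "54607120", "4502173",
            "4502337", "56676397", "89033736", "5453678", "42716297", "47132551",
            "4758236", "11386147", "6382064", "4507509", "4757826", "50363217",
            "4557871", "4503143", "4503107", "4503109", "4507065", "4503009",
            "5031863", "4503139", "19923082", "4505185", "32171249"),
    "OA2": ("4505821", "4506885", "4502027", "4503109", "71834855", "11386147",
            "42716297", "89033736", "4502337", "5453678", "56676397", "4503009",
            "54607120", "4758236", "5031863", "4503143", "26051231", "6382064"),
}


def sample_identification_matrix() -> SpectralCountMatrix:
    """0/1 presence matrix over the original (pre-merge) accessions.

    Row order follows first appearance across replicates; counts are 1
    where the protein was reported identified in the replicate.
    """
    design = paper_design()
    order: list[str] = []
    for rid in design.replicate_ids:
        for acc in SAMPLE_IDENTIFICATIONS[rid]:
            if acc not in order:
                order.append(acc)
    data = {
        rid: [1 if acc in SAMPLE_IDENTIFICATIONS[rid] else 0 for acc in order]
        for rid in design.replicate_ids
    }
    counts = pd.DataFrame(data, index=pd.Index(order, name="accession"))
    return SpectralCountMatrix(counts, design)
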