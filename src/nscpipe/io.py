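"""Readers and writers for the pipeline's plain-text formats.

Dialect: tab-separated, UTF-8, ``#`` comment lines ignored, no quoting.
Missing cells in a count matrix mean "protein not identified in that
replicate" and are read as 0.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    CategorySummary,
    DesignError,
    ProteinRecord,
    SpectralCountMatrix,
    StudyDesign,
    ValidationError,
    validate_catalog,
)


class ParseError(ValueError):
    """Raised for malformed TSV input; message names the offending line."""


class UnmappedAccessionWarning(UserWarning):
    """A matrix row's accession is absent from the catalog (kept verbatim)."""


def _read_tsv(path) -> pd.DataFrame:
    try:
        # na_filter off: "NA" is a study group label, never a missing value
        return pd.read_csv(
            path, sep="\t", comment="#", dtype=str, na_filter=False
        ).fillna("")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse TSV ({exc})") from exc


def read_design(path) -> StudyDesign:
    """Read a design TSV with columns replicate_id, group."""
    df = _read_tsv(path)
    for col in ("replicate_id", "group"):
        if col not in df.columns:
            raise ParseError(f"{path}: design file lacks column {col!r}")
    reps = tuple(df["replicate_id"])
    mapping = dict(zip(df["replicate_id"], df["group"]))
    return StudyDesign(reps, mapping)


def read_count_matrix(path, design_path, allowed_groups=None) -> SpectralCountMatrix:
    """Read a counts TSV (first column ``accession``) plus its design file.

    Counts must be non-negative integers; replicates present in the matrix
    but missing from the design raise :class:`~nscpipe.model.DesignError`;
    group labels outside ``allowed_groups`` (when given) are rejected.
    """
    design = read_design(design_path)
    if allowed_groups is not None:
        bad = sorted(set(design.group_of.values()) - set(allowed_groups))
        if bad:
            raise DesignError(f"{design_path}: unknown group labels {bad}")
    df = _read_tsv(path)
    if df.columns[0] != "accession":
        raise ParseError(f"{path}: first column must be 'accession'")
    df = df.set_index("accession")
    missing = [c for c in df.columns if c not in design.group_of]
    if missing:
        raise DesignError(f"{path}: replicates missing from design: {missing}")
    df = df.replace("", "0")
    for lineno, (acc, row) in enumerate(df.iterrows(), start=2):
        for cell in row:
            try:
                v = int(cell)
            except ValueError:
                raise ValidationError(
                    f"{path}: line {lineno} ({acc}): non-integer count {cell!r}"
                ) from None
            if v < 0:
                raise ValidationError(
                    f"{path}: line {lineno} ({acc}): negative count {v}"
                )
    counts = df.astype(np.int64)
    # keep design order for columns, matrix order for rows
    counts = counts.reindex(columns=list(design.replicate_ids), fill_value=0)
    return SpectralCountMatrix(counts, design)


def write_count_matrix(matrix: SpectralCountMatrix, path, design_path=None) -> None:
    df = matrix.counts.copy()
    df.index.name = "accession"
    df.to_csv(path, sep="\t")
    if design_path is not None:
        write_design(matrix.design, design_path)


def write_design(design: StudyDesign, path) -> None:
    pd.DataFrame(
        {
            "replicate_id": list(design.replicate_ids),
            "group": [design.group_of[r] for r in design.replicate_ids],
        }
    ).to_csv(path, sep="\t", index=False)


def read_catalog(path) -> list[ProteinRecord]:
    """Read a catalog TSV: accession, uniprot, name, mw_kda, pi, aliases."""
    df = _read_tsv(path)
    records = []
    for _, row in df.iterrows():
        aliases = frozenset(a for a in str(row.get("aliases", "")).split(",") if a)
        records.append(
            ProteinRecord(
                accession=row["accession"],
                uniprot=row.get("uniprot", ""),
                name=row["name"],
                mw_kda=float(row["mw_kda"]) if row.get("mw_kda") else float("nan"),
                pi=float(row["pi"]) if row.get("pi") else float("nan"),
                aliases=aliases,
            )
        )
    validate_catalog(records)
    return records


def write_catalog(catalog: list[ProteinRecord], path) -> None:
    rows = [
        {
            "accession": r.accession,
            "uniprot": r.uniprot,
            "name": r.name,
            "mw_kda": r.mw_kda,
            "pi": r.pi,
            "aliases": ",".join(sorted(r.aliases)),
        }
        for r in catalog
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def resolve_aliases(
    matrix: SpectralCountMatrix, catalog: list[ProteinRecord]
) -> SpectralCountMatrix:
    """Merge rows whose accession is an alias into their primary record's row.

    Counts are summed, so every replicate's total SC is conserved.  Rows
    with accessions unknown to the catalog are kept verbatim and flagged
    with :class:`UnmappedAccessionWarning`.
    """
    alias_map = validate_catalog(catalog)
    primaries = {r.accession for r in catalog}
    target = []
    for acc in matrix.proteins:
        if acc in alias_map:
            target.append(alias_map[acc])
        else:
            if acc not in primaries:
                warnings.warn(
                    f"accession {acc} not in catalog; row kept verbatim",
                    UnmappedAccessionWarning,
                    stacklevel=2,
                )
            target.append(acc)
    merged = matrix.counts.groupby(pd.Index(target, name="accession"), sort=False).sum()
    return SpectralCountMatrix(merged, matrix.design)


# ---------------------------------------------------------------------------
# reports


def write_report(summary: CategorySummary, per_protein: pd.DataFrame, outdir) -> dict:
    """Write report.json (summary) and report.tsv (per-protein table).

    Column order of the TSV is stable; returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "report.json"
    tsv_path = outdir / "report.tsv"
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=False)
        fh.write("\n")
    df = per_protein.copy()
    df.index.name = "accession"
    df.to_csv(tsv_path, sep="\t")
    return {"json": json_path, "tsv": tsv_path}


def read_report(outdir) -> tuple[dict, pd.DataFrame]:
    outdir = Path(outdir)
    with open(outdir / "report.json", encoding="utf-8") as fh:
        summary = json.load(fh)
    table = pd.read_csv(outdir / "report.tsv", sep="\t", index_col="accession").fillna("")
    return summary, table
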