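"""Readers and writers for the eight tabular source types.

Each source kind is one long-format, UTF-8, RFC 4180 CSV with a fixed header.
Booleans serialize as ``true``/``false``; the empty string means missing;
multi-valued fields (``names``, set-valued status columns) join on ``|``.

Loading validates every row against its type's invariants and returns the kept
rows together with a :class:`LoadReport`. In strict mode (the pipeline
default), any schema or row error raises; in lenient mode offending rows are
dropped but counted, so exploratory use never silently loses data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .chem_registry import (
    CasNumber,
    CasParseError,
    ChemicalRecord,
    IdentifierSet,
    normalize_cas,
)

__all__ = [
    "PROGRAMS",
    "METABOLOME_DATABASES",
    "HMDB_STATUSES",
    "METABOLOME_STATUSES",
    "SAMPLE_TYPES",
    "METHODS",
    "ANALYTE_FORMS",
    "HAZARD_SOURCES",
    "HAZARD_CLASSES",
    "HAZARD_CATEGORIES",
    "SOURCE_KINDS",
    "SchemaError",
    "RowError",
    "LoadReport",
    "FccMigexEntry",
    "BiomonitoringAnalyte",
    "MetabolomeListing",
    "EvidenceMapRecord",
    "HazardRecord",
    "GroupAnnotation",
    "FcchumonRecord",
    "read_source",
    "write_source",
    "write_fcchumon",
    "apply_cas_patch",
]

# ---------------------------------------------------------------------------
# Controlled vocabularies

PROGRAMS = ("NHANES", "CHMS", "HBM4EU", "KoNEHS", "BiomonitoringCalifornia")
METABOLOME_DATABASES = ("HMDB", "BloodExposome", "ExposomeExplorer")
HMDB_STATUSES = ("detected_quantified", "detected_not_quantified", "expected_not_quantified")
METABOLOME_STATUSES = HMDB_STATUSES + ("listed",)
BIOMON_STATUSES = ("detected", "not_detected")
SAMPLE_TYPES = ("urine", "serum", "blood", "plasma", "breast_milk",
                "umbilical_cord", "placenta", "other")
METHODS = ("targeted", "nontargeted", "both")
ANALYTE_FORMS = ("parent", "specific_metabolite", "unspecific_metabolite")
HAZARD_SOURCES = ("ECHA_CLP", "Japan_GHS")
HAZARD_CLASSES = ("carcinogenicity", "mutagenicity", "reproductive_toxicity",
                  "stot_re", "other")
HAZARD_CATEGORIES = ("cat_1A", "cat_1B", "cat_1", "cat_2", "other", "none")
EVIDENCE_CATEGORIES = ("detected", "monitored_not_detected", "no_evidence")
EVIDENCE_SOURCES = ("biomonitoring", "metabolome", "literature")
STEPS = ("step1", "step2", "none")


class SchemaError(ValueError):
    """The file-level header or structure does not match the declared kind."""


class RowError(ValueError):
    """One or more rows violated their type's invariants (strict mode)."""


@dataclass
class LoadReport:
    """Counts and row-level errors from one read; read = kept + rejected."""

    path: str
    kind: str
    n_read: int = 0
    n_kept: int = 0
    n_rejected: int = 0
    errors: list[tuple[int, str]] = field(default_factory=list)  # (row number, message)


# ---------------------------------------------------------------------------
# Row types

@dataclass(frozen=True)
class FccMigexEntry:
    """One chemical x study observation of an FCC in an FCM migrate/extract."""

    entry_id: str
    identifiers: IdentifierSet
    fca_type: str
    fcm_material: str
    detected: bool
    reference_id: str


@dataclass(frozen=True)
class BiomonitoringAnalyte:
    """A program-specific analyte, optionally linked to its parent compound."""

    program: str
    analyte_identifiers: IdentifierSet
    parent_cas: CasNumber | None
    status: str
    analyte_name: str = ""

    def __post_init__(self) -> None:
        if self.program not in PROGRAMS:
            raise ValueError(f"unknown biomonitoring program: {self.program!r}")
        if self.status not in BIOMON_STATUSES:
            raise ValueError(f"invalid biomonitoring status: {self.status!r}")


@dataclass(frozen=True)
class MetabolomeListing:
    """One chemical listed in a metabolome/exposome database."""

    database: str
    identifiers: IdentifierSet
    status: str

    def __post_init__(self) -> None:
        if self.database not in METABOLOME_DATABASES:
            raise ValueError(f"unknown metabolome database: {self.database!r}")
        if self.database == "HMDB":
            if self.status not in HMDB_STATUSES:
                raise ValueError(f"HMDB rows require an HMDB metabolite status, "
                                 f"got {self.status!r}")
        elif self.status != "listed":
            raise ValueError(f"{self.database} rows must carry status 'listed', "
                             f"got {self.status!r}")


@dataclass(frozen=True)
class EvidenceMapRecord:
    """One study x FCC extraction row from the systematic evidence map."""

    study_id: str
    fcc_cas: CasNumber
    sample_type: str
    method: str
    analyte_form: str
    detected: bool

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"invalid sample type: {self.sample_type!r}")
        if self.method not in METHODS:
            raise ValueError(f"invalid method: {self.method!r}")
        if self.analyte_form not in ANALYTE_FORMS:
            raise ValueError(f"invalid analyte form: {self.analyte_form!r}")


@dataclass(frozen=True)
class HazardRecord:
    """One GHS-style classification row from a hazard inventory.

    ``category='none'`` asserts that data exist for the chemical without any
    classification, which separates 'not classified' from 'no hazard data';
    such rows must carry ``has_data=True``.
    """

    identifiers: IdentifierSet
    source: str
    hazard_class: str
    category: str
    has_data: bool

    def __post_init__(self) -> None:
        if self.source not in HAZARD_SOURCES:
            raise ValueError(f"unknown hazard source: {self.source!r}")
        if self.hazard_class not in HAZARD_CLASSES:
            raise ValueError(f"unknown hazard class: {self.hazard_class!r}")
        if self.category not in HAZARD_CATEGORIES:
            raise ValueError(f"unknown hazard category: {self.category!r}")
        if not self.has_data:
            raise ValueError("hazard rows assert data existence; has_data must be true")


@dataclass(frozen=True)
class GroupAnnotation:
    """Curated chemical-group label for one CAS."""

    cas: CasNumber
    group_label: str


@dataclass(frozen=True)
class FcchumonRecord:
    """Consolidated per-FCC output row of the whole pipeline."""

    chem_id: str
    identifiers: IdentifierSet
    overall_status: str
    evidence_sources: frozenset[str]
    step: str
    tier: str | None
    group_label: str | None
    migex_detect_entries: int

    def __post_init__(self) -> None:
        if self.overall_status not in EVIDENCE_CATEGORIES:
            raise ValueError(f"invalid overall_status: {self.overall_status!r}")
        if self.step not in STEPS:
            raise ValueError(f"invalid step: {self.step!r}")
        if self.step == "step2" and self.overall_status == "detected" \
                and "literature" not in self.evidence_sources:
            raise ValueError(f"{self.chem_id}: step-2 detection requires literature evidence")
        if self.overall_status == "detected" and not self.evidence_sources:
            raise ValueError(f"{self.chem_id}: detected status requires evidence sources")


# ---------------------------------------------------------------------------
# Parsing helpers

def _parse_bool(s: str, column: str) -> bool:
    if s == "true":
        return True
    if s == "false":
        return False
    raise ValueError(f"{column}: expected true/false, got {s!r}")


def _opt(s: str) -> str | None:
    return s if s != "" else None


def _ids_from_row(row: dict, cas_col: str = "cas", name_col: str = "name") -> IdentifierSet:
    names = [row[name_col]] if row.get(name_col) else []
    return IdentifierSet.from_strings(
        cas=_opt(row.get(cas_col, "")),
        inchikey=_opt(row.get("inchikey", "")),
        smiles=_opt(row.get("smiles", "")),
        names=names,
    )


def _parse_registry(row: dict) -> ChemicalRecord:
    names = tuple(n for n in row["names"].split("|") if n)
    ids = IdentifierSet.from_strings(
        cas=_opt(row["cas"]), inchikey=_opt(row["inchikey"]),
        smiles=_opt(row["smiles"]), names=names,
    )
    return ChemicalRecord(
        chem_id=row["chem_id"],
        identifiers=ids,
        is_mixture=_parse_bool(row["is_mixture"], "is_mixture"),
        in_fccdb=_parse_bool(row["in_fccdb"], "in_fccdb"),
        in_fccmigex=_parse_bool(row["in_fccmigex"], "in_fccmigex"),
    )


def _parse_biomonitoring(row: dict) -> BiomonitoringAnalyte:
    parent = normalize_cas(row["parent_cas"]) if row["parent_cas"] else None
    ids = IdentifierSet.from_strings(
        cas=_opt(row["analyte_cas"]),
        names=[row["analyte_name"]] if row["analyte_name"] else [],
    )
    return BiomonitoringAnalyte(
        program=row["program"], analyte_identifiers=ids,
        parent_cas=parent, status=row["status"],
        analyte_name=row["analyte_name"],
    )


def _parse_metabolome(row: dict) -> MetabolomeListing:
    return MetabolomeListing(
        database=row["database"], identifiers=_ids_from_row(row), status=row["status"],
    )


def _parse_fccmigex(row: dict) -> FccMigexEntry:
    return FccMigexEntry(
        entry_id=row["entry_id"],
        identifiers=_ids_from_row(row),
        fca_type=row["fca_type"],
        fcm_material=row["fcm_material"],
        detected=_parse_bool(row["detected"], "detected"),
        reference_id=row["reference_id"],
    )


def _parse_hazard(row: dict) -> HazardRecord:
    return HazardRecord(
        identifiers=IdentifierSet.from_strings(cas=row["cas"]),
        source=row["source"],
        hazard_class=row["hazard_class"],
        category=row["category"],
        has_data=_parse_bool(row["has_data"], "has_data"),
    )


def _parse_evidence_map(row: dict) -> EvidenceMapRecord:
    return EvidenceMapRecord(
        study_id=row["study_id"],
        fcc_cas=normalize_cas(row["fcc_cas"]),
        sample_type=row["sample_type"],
        method=row["method"],
        analyte_form=row["analyte_form"],
        detected=_parse_bool(row["detected"], "detected"),
    )


def _parse_groups(row: dict) -> GroupAnnotation:
    return GroupAnnotation(cas=normalize_cas(row["cas"]), group_label=row["group_label"])


def _parse_fcchumon(row: dict) -> FcchumonRecord:
    names = tuple(n for n in row["names"].split("|") if n)
    ids = IdentifierSet.from_strings(
        cas=_opt(row["cas"]), inchikey=_opt(row["inchikey"]),
        smiles=_opt(row["smiles"]), names=names,
    )
    return FcchumonRecord(
        chem_id=row["chem_id"],
        identifiers=ids,
        overall_status=row["overall_status"],
        evidence_sources=frozenset(s for s in row["evidence_sources"].split("|") if s),
        step=row["step"],
        tier=_opt(row["tier"]),
        group_label=_opt(row["group_label"]),
        migex_detect_entries=int(row["migex_detect_entries"]),
    )


# ---------------------------------------------------------------------------
# Serialization helpers (inverse of the parsers)

def _fmt_bool(b: bool) -> str:
    return "true" if b else "false"


def _fmt_cas(cas: CasNumber | None) -> str:
    return cas.normalized if cas is not None else ""


def _ids_cols(ids: IdentifierSet) -> dict:
    return {
        "cas": _fmt_cas(ids.cas),
        "inchikey": ids.inchikey or "",
        "smiles": ids.smiles or "",
    }


def _dump_registry(rec: ChemicalRecord) -> dict:
    return {
        "chem_id": rec.chem_id,
        **_ids_cols(rec.identifiers),
        "names": "|".join(rec.identifiers.names),
        "is_mixture": _fmt_bool(rec.is_mixture),
        "in_fccdb": _fmt_bool(rec.in_fccdb),
        "in_fccmigex": _fmt_bool(rec.in_fccmigex),
    }


def _dump_biomonitoring(a: BiomonitoringAnalyte) -> dict:
    return {
        "program": a.program,
        "analyte_cas": _fmt_cas(a.analyte_identifiers.cas),
        "analyte_name": a.analyte_name,
        "parent_cas": _fmt_cas(a.parent_cas),
        "status": a.status,
    }


def _dump_metabolome(m: MetabolomeListing) -> dict:
    return {
        "database": m.database,
        **_ids_cols(m.identifiers),
        "name": m.identifiers.names[0] if m.identifiers.names else "",
        "status": m.status,
    }


def _dump_fccmigex(e: FccMigexEntry) -> dict:
    return {
        "entry_id": e.entry_id,
        **_ids_cols(e.identifiers),
        "name": e.identifiers.names[0] if e.identifiers.names else "",
        "fca_type": e.fca_type,
        "fcm_material": e.fcm_material,
        "detected": _fmt_bool(e.detected),
        "reference_id": e.reference_id,
    }


def _dump_hazard(h: HazardRecord) -> dict:
    return {
        "cas": _fmt_cas(h.identifiers.cas),
        "source": h.source,
        "hazard_class": h.hazard_class,
        "category": h.category,
        "has_data": _fmt_bool(h.has_data),
    }


def _dump_evidence_map(r: EvidenceMapRecord) -> dict:
    return {
        "study_id": r.study_id,
        "fcc_cas": r.fcc_cas.normalized,
        "sample_type": r.sample_type,
        "method": r.method,
        "analyte_form": r.analyte_form,
        "detected": _fmt_bool(r.detected),
    }


def _dump_groups(g: GroupAnnotation) -> dict:
    return {"cas": g.cas.normalized, "group_label": g.group_label}


def _dump_fcchumon(r: FcchumonRecord) -> dict:
    return {
        "chem_id": r.chem_id,
        **_ids_cols(r.identifiers),
        "names": "|".join(r.identifiers.names),
        "overall_status": r.overall_status,
        "evidence_sources": "|".join(sorted(r.evidence_sources)),
        "step": r.step,
        "tier": r.tier or "",
        "group_label": r.group_label or "",
        "migex_detect_entries": str(r.migex_detect_entries),
    }


# ---------------------------------------------------------------------------
# Kind dispatch

_KindSpec = tuple[Sequence[str], Callable[[dict], object], Callable[[object], dict]]

SOURCE_KINDS: dict[str, _KindSpec] = {
    "registry": (
        ["chem_id", "cas", "inchikey", "smiles", "names",
         "is_mixture", "in_fccdb", "in_fccmigex"],
        _parse_registry, _dump_registry,
    ),
    "biomonitoring": (
        ["program", "analyte_cas", "analyte_name", "parent_cas", "status"],
        _parse_biomonitoring, _dump_biomonitoring,
    ),
    "metabolome": (
        ["database", "cas", "inchikey", "smiles", "name", "status"],
        _parse_metabolome, _dump_metabolome,
    ),
    "fccmigex": (
        ["entry_id", "cas", "inchikey", "smiles", "name",
         "fca_type", "fcm_material", "detected", "reference_id"],
        _parse_fccmigex, _dump_fccmigex,
    ),
    "hazard": (
        ["cas", "source", "hazard_class", "category", "has_data"],
        _parse_hazard, _dump_hazard,
    ),
    "evidence_map": (
        ["study_id", "fcc_cas", "sample_type", "method", "analyte_form", "detected"],
        _parse_evidence_map, _dump_evidence_map,
    ),
    "groups": (
        ["cas", "group_label"],
        _parse_groups, _dump_groups,
    ),
    "fcchumon": (
        ["chem_id", "cas", "inchikey", "smiles", "names", "overall_status",
         "evidence_sources", "step", "tier", "group_label", "migex_detect_entries"],
        _parse_fcchumon, _dump_fcchumon,
    ),
}


def read_source(path: str | Path, kind: str, strict: bool = True):
    """Read and validate one source CSV.

    Returns ``(rows, report)``. Uniqueness invariants that span rows
    (``entry_id``, evidence-map keys) are enforced here as well.
    """
    if kind not in SOURCE_KINDS:
        raise KeyError(f"unknown source kind: {kind!r}")
    header, parse, _ = SOURCE_KINDS[kind]
    path = Path(path)
    report = LoadReport(path=str(path), kind=kind)
    rows: list = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            got = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, expected header {header}")
        if got != list(header):
            raise SchemaError(f"{path}: header {got} does not match {list(header)} "
                              f"for kind {kind!r}")
        for lineno, values in enumerate(reader, start=2):
            report.n_read += 1
            if len(values) != len(header):
                report.errors.append((lineno, f"expected {len(header)} fields, "
                                              f"got {len(values)}"))
                report.n_rejected += 1
                continue
            row = dict(zip(header, values))
            try:
                rows.append(parse(row))
            except (ValueError, CasParseError) as exc:
                report.errors.append((lineno, str(exc)))
                report.n_rejected += 1
                continue
            report.n_kept += 1

    _check_uniqueness(rows, kind, report)
    if strict and report.errors:
        first = "; ".join(f"row {n}: {m}" for n, m in report.errors[:5])
        raise RowError(f"{path}: {report.n_rejected} invalid rows ({first} ...)")
    return rows, report


def _check_uniqueness(rows: list, kind: str, report: LoadReport) -> None:
    keys = None
    if kind == "fccmigex":
        keys = [e.entry_id for e in rows]
        label = "entry_id"
    elif kind == "evidence_map":
        keys = [(r.study_id, r.fcc_cas.normalized, r.sample_type, r.analyte_form)
                for r in rows]
        label = "(study_id, fcc_cas, sample_type, analyte_form)"
    elif kind in ("registry", "fcchumon"):
        keys = [r.chem_id for r in rows]
        label = "chem_id"
    if keys is not None and len(set(keys)) != len(keys):
        seen, dup = set(), None
        for k in keys:
            if k in seen:
                dup = k
                break
            seen.add(k)
        report.errors.append((0, f"duplicate {label}: {dup!r}"))


def write_source(rows: Iterable, path: str | Path, kind: str) -> None:
    """Write rows of one source kind; inverse of :func:`read_source`."""
    if kind not in SOURCE_KINDS:
        raise KeyError(f"unknown source kind: {kind!r}")
    header, _, dump = SOURCE_KINDS[kind]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(header))
        writer.writeheader()
        for row in rows:
            writer.writerow(dump(row))


def write_fcchumon(records: Iterable[FcchumonRecord], path: str | Path) -> None:
    """Write the consolidated table, deterministically sorted by chem_id."""
    write_source(sorted(records, key=lambda r: r.chem_id), path, "fcchumon")


def apply_cas_patch(
    analytes: Iterable[BiomonitoringAnalyte],
    patch: dict[str, str],
) -> list[BiomonitoringAnalyte]:
    """Fill manually-assigned CAS numbers for analytes that lack one.

    ``patch`` maps analyte name -> CAS string, emulating the manual curation
    step that makes name-only analytes comparable to the FCC universe.
    """
    out = []
    for a in analytes:
        if a.analyte_identifiers.cas is None and a.analyte_name in patch:
            ids = IdentifierSet.from_strings(
                cas=patch[a.analyte_name],
                inchikey=a.analyte_identifiers.inchikey,
                smiles=a.analyte_identifiers.smiles,
                names=a.analyte_identifiers.names,
            )
            a = BiomonitoringAnalyte(
                program=a.program, analyte_identifiers=ids,
                parent_cas=a.parent_cas, status=a.status, analyte_name=a.analyte_name,
            )
        out.append(a)
    return out
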