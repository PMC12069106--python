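"""Step 1: match the known-FCC universe to biomonitoring and metabolome sources.

Biomonitoring analytes are first expanded along metabolite-parent links, so an
FCC counts as monitored (or detected) whether the program measured the parent
compound itself or one of its metabolites. Each FCC then receives exactly one
step-1 evidence category:

* ``detected`` — detected in at least one biomonitoring program, or listed in
  at least one metabolome/exposome database (a listing alone is treated as
  evidence of presence in humans);
* ``monitored_not_detected`` — monitored in one or more programs, never
  detected, and absent from every metabolome/exposome database;
* ``no_evidence`` — neither monitored nor listed.

Detection in any single program dominates non-detection everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .chem_registry import (
    CasParseError,
    ChemicalRegistry,
    IdentifierSet,
    match_chemicals,
)
from .source_io import (
    PROGRAMS,
    BiomonitoringAnalyte,
    MetabolomeListing,
)

__all__ = [
    "Step1Status",
    "Step1Partition",
    "ProgramOverlap",
    "expand_metabolite_links",
    "resolve_step1",
    "count_step1_partition",
    "cross_program_overlap",
]


@dataclass(frozen=True)
class Step1Status:
    """Per-FCC outcome of the step-1 comparisons."""

    chem_id: str
    biomon_detected_in: frozenset[str]
    biomon_monitored_in: frozenset[str]
    metabolome_listed_in: frozenset[str]
    category: str

    def __post_init__(self) -> None:
        if not self.biomon_detected_in <= self.biomon_monitored_in:
            raise ValueError(f"{self.chem_id}: detected programs must be monitored")
        expected = _category(self.biomon_detected_in, self.biomon_monitored_in,
                             self.metabolome_listed_in)
        if self.category != expected:
            raise ValueError(f"{self.chem_id}: category {self.category!r} "
                             f"inconsistent with memberships (expected {expected!r})")


def _category(detected: frozenset, monitored: frozenset, listed: frozenset) -> str:
    if detected or listed:
        return "detected"
    if monitored:
        return "monitored_not_detected"
    return "no_evidence"


def expand_metabolite_links(
    analytes: Iterable[BiomonitoringAnalyte],
) -> tuple[list[BiomonitoringAnalyte], list[str]]:
    """Emit an additional parent-CAS row for every metabolite analyte.

    The parent row carries the same program and status as the metabolite row,
    so downstream matching sees the parent compound directly. Original rows
    are preserved. Returns ``(expanded rows, error messages)``; a parent link
    whose CAS cannot be parsed is reported, not silently dropped.
    """
    out: list[BiomonitoringAnalyte] = []
    errors: list[str] = []
    for a in analytes:
        out.append(a)
        if a.parent_cas is None:
            continue
        try:
            ids = IdentifierSet(cas=a.parent_cas)
        except (ValueError, CasParseError) as exc:  # pragma: no cover - defensive
            errors.append(f"{a.analyte_name or a.program}: bad parent CAS: {exc}")
            continue
        out.append(BiomonitoringAnalyte(
            program=a.program,
            analyte_identifiers=ids,
            parent_cas=None,
            status=a.status,
            analyte_name=f"{a.analyte_name} (parent)" if a.analyte_name else "",
        ))
    return out, errors


def resolve_step1(
    registry: ChemicalRegistry,
    analytes: Iterable[BiomonitoringAnalyte],
    listings: Iterable[MetabolomeListing],
) -> dict[str, Step1Status]:
    """Assign every registry FCC its step-1 status.

    ``analytes`` should already be metabolite-expanded (see
    :func:`expand_metabolite_links`). Matching uses any agreeing identifier
    kind with CAS > InChIKey > SMILES precedence.
    """
    analytes = list(analytes)
    listings = list(listings)

    monitored: dict[str, set[str]] = {}
    detected: dict[str, set[str]] = {}
    listed: dict[str, set[str]] = {}

    biomon_right = [(str(i), a.analyte_identifiers) for i, a in enumerate(analytes)]
    for m in match_chemicals(registry.records, biomon_right).matches:
        a = analytes[int(m.right_id)]
        monitored.setdefault(m.left_id, set()).add(a.program)
        if a.status == "detected":
            detected.setdefault(m.left_id, set()).add(a.program)

    metab_right = [(str(i), l.identifiers) for i, l in enumerate(listings)]
    for m in match_chemicals(registry.records, metab_right).matches:
        listed.setdefault(m.left_id, set()).add(listings[int(m.right_id)].database)

    statuses: dict[str, Step1Status] = {}
    for rec in registry:
        det = frozenset(detected.get(rec.chem_id, ()))
        mon = frozenset(monitored.get(rec.chem_id, ()))
        lst = frozenset(listed.get(rec.chem_id, ()))
        statuses[rec.chem_id] = Step1Status(
            chem_id=rec.chem_id,
            biomon_detected_in=det,
            biomon_monitored_in=mon,
            metabolome_listed_in=lst,
            category=_category(det, mon, lst),
        )
    return statuses


@dataclass(frozen=True)
class Step1Partition:
    """Step-1 detected FCCs split by source inventory, plus the remainder."""

    fccdb_only: int
    fccmigex_only: int
    both: int
    monitored_not_detected: int
    no_evidence: int

    @property
    def n_detected(self) -> int:
        return self.fccdb_only + self.fccmigex_only + self.both


def count_step1_partition(
    statuses: Mapping[str, Step1Status],
    registry: ChemicalRegistry,
) -> Step1Partition:
    """Tally the detected set by FCCdb/FCCmigex membership flags."""
    db_only = migex_only = both = mnd = none = 0
    for rec in registry:
        cat = statuses[rec.chem_id].category
        if cat == "detected":
            if rec.in_fccdb and rec.in_fccmigex:
                both += 1
            elif rec.in_fccdb:
                db_only += 1
            else:
                migex_only += 1
        elif cat == "monitored_not_detected":
            mnd += 1
        else:
            none += 1
    return Step1Partition(db_only, migex_only, both, mnd, none)


@dataclass(frozen=True)
class ProgramOverlap:
    """Cross-program monitoring/detection coverage over the five programs."""

    monitored_in_at_least: dict[int, int]  # k -> FCCs monitored in >= k programs
    monitored_in_exactly: dict[int, int]
    all_five_monitored: int
    all_five_detected: int  # detected status in every one of the five programs
    detected_in_all_monitored: int


def cross_program_overlap(statuses: Mapping[str, Step1Status]) -> ProgramOverlap:
    """Coverage counts across the five biomonitoring programs."""
    n_programs = len(PROGRAMS)
    at_least = {k: 0 for k in range(1, n_programs + 1)}
    exactly = {k: 0 for k in range(1, n_programs + 1)}
    all_mon = all_det = det_all_mon = 0
    for st in statuses.values():
        n = len(st.biomon_monitored_in)
        if n == 0:
            continue
        exactly[n] += 1
        for k in range(1, n + 1):
            at_least[k] += 1
        if n == n_programs:
            all_mon += 1
            if len(st.biomon_detected_in) == n_programs:
                all_det += 1
        if st.biomon_detected_in == st.biomon_monitored_in:
            det_all_mon += 1
    return ProgramOverlap(
        monitored_in_at_least=at_least,
        monitored_in_exactly=exactly,
        all_five_monitored=all_mon,
        all_five_detected=all_det,
        detected_in_all_monitored=det_all_mon,
    )
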