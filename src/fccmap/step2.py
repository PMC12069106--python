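"""Step 2: prioritization and literature-evidence classification.

FCCs absent from every step-1 source are candidates for systematic evidence
mapping. Candidates are prioritized when the FCM migration/extraction database
reports their detection in at least ``threshold`` entries (default 5; only
entries with ``detected=true`` count). Post-screening literature extraction
records then determine each prioritized FCC's human-evidence status, with
per-sample-type, per-method, and per-analyte-form aggregations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .chem_registry import ChemicalRegistry, match_chemicals
from .source_io import (
    ANALYTE_FORMS,
    METHODS,
    SAMPLE_TYPES,
    EvidenceMapRecord,
    FccMigexEntry,
)
from .step1 import Step1Status

__all__ = [
    "PrioritizedFcc",
    "Step2Status",
    "Step2Summary",
    "count_migex_detect_entries",
    "prioritize",
    "classify_step2",
    "aggregate_step2",
]

DEFAULT_THRESHOLD = 5


@dataclass(frozen=True)
class PrioritizedFcc:
    """An FCC selected for the systematic evidence map."""

    chem_id: str
    cas: str | None
    migex_detect_entries: int


@dataclass(frozen=True)
class Step2Status:
    """Literature-evidence outcome for one prioritized FCC."""

    chem_id: str
    n_studies: int
    category: str
    sample_types_detected: frozenset[str]
    methods_used: tuple[tuple[str, int], ...]  # sorted (method, n_studies) pairs
    analyte_forms: frozenset[str]
    unspecific_metabolite_flag: bool = False

    def __post_init__(self) -> None:
        if self.category == "no_evidence" and self.n_studies != 0:
            raise ValueError(f"{self.chem_id}: no_evidence requires zero studies")
        if self.category != "no_evidence" and self.n_studies == 0:
            raise ValueError(f"{self.chem_id}: {self.category} requires >=1 study")
        if self.category == "detected" and not self.sample_types_detected \
                and self.n_studies > 0:
            raise ValueError(f"{self.chem_id}: detected without any sample type")


def count_migex_detect_entries(
    registry: ChemicalRegistry,
    entries: Iterable[FccMigexEntry],
) -> dict[str, int]:
    """Per-FCC number of FCM database entries reporting detection.

    Entries with ``detected=false`` (targeted in FCMs but never found) are
    excluded. Every registry FCC appears in the result, with zero if unmatched.
    """
    entries = [e for e in entries if e.detected]
    counts = {rec.chem_id: 0 for rec in registry}
    right = [(str(i), e.identifiers) for i, e in enumerate(entries)]
    for m in match_chemicals(registry.records, right).matches:
        counts[m.left_id] += 1
    return counts


def prioritize(
    registry: ChemicalRegistry,
    step1_statuses: Mapping[str, Step1Status],
    migex_entries: Iterable[FccMigexEntry],
    threshold: int = DEFAULT_THRESHOLD,
) -> list[PrioritizedFcc]:
    """Select FCCs absent from all step-1 sources with enough FCM detections.

    Absence means never monitored in any biomonitoring program *and* never
    listed in any metabolome/exposome database. Output is deterministically
    ordered by (detect-entry count descending, chem_id).
    """
    if threshold < 1:
        raise ValueError("prioritization threshold must be >= 1")
    counts = count_migex_detect_entries(registry, migex_entries)
    out = []
    for rec in registry:
        st = step1_statuses[rec.chem_id]
        if st.biomon_monitored_in or st.metabolome_listed_in:
            continue
        if counts[rec.chem_id] >= threshold:
            cas = rec.identifiers.cas.normalized if rec.identifiers.cas else None
            out.append(PrioritizedFcc(rec.chem_id, cas, counts[rec.chem_id]))
    out.sort(key=lambda p: (-p.migex_detect_entries, p.chem_id))
    return out


def classify_step2(
    records: Iterable[EvidenceMapRecord],
    prioritized: Sequence[PrioritizedFcc],
) -> tuple[dict[str, Step2Status], list[EvidenceMapRecord]]:
    """One status per prioritized FCC from literature extraction records.

    Any detection dominates: one positive record makes the FCC ``detected``;
    only-negative records yield ``monitored_not_detected``; no records yield
    ``no_evidence``. ``n_studies`` counts distinct study identifiers. Records
    whose CAS is not among the prioritized FCCs are returned as rejects.
    Classification is invariant to record order and duplication.
    """
    cas_to_chem = {p.cas: p.chem_id for p in prioritized if p.cas is not None}
    by_chem: dict[str, set[EvidenceMapRecord]] = {p.chem_id: set() for p in prioritized}
    rejects: list[EvidenceMapRecord] = []
    for r in records:
        chem = cas_to_chem.get(r.fcc_cas.normalized)
        if chem is None:
            rejects.append(r)
        else:
            by_chem[chem].add(r)

    statuses: dict[str, Step2Status] = {}
    for p in prioritized:
        recs = sorted(by_chem[p.chem_id],
                      key=lambda r: (r.study_id, r.sample_type, r.analyte_form))
        studies = {r.study_id for r in recs}
        any_detected = any(r.detected for r in recs)
        if not recs:
            cat = "no_evidence"
        elif any_detected:
            cat = "detected"
        else:
            cat = "monitored_not_detected"
        method_studies: dict[str, set[str]] = {}
        for r in recs:
            method_studies.setdefault(r.method, set()).add(r.study_id)
        statuses[p.chem_id] = Step2Status(
            chem_id=p.chem_id,
            n_studies=len(studies),
            category=cat,
            sample_types_detected=frozenset(r.sample_type for r in recs if r.detected),
            methods_used=tuple(sorted((m, len(s)) for m, s in method_studies.items())),
            analyte_forms=frozenset(r.analyte_form for r in recs),
            unspecific_metabolite_flag=any(
                r.detected and r.analyte_form == "unspecific_metabolite" for r in recs
            ),
        )
    return statuses, rejects


@dataclass
class Step2Summary:
    """Aggregations over the evidence map (multiple sample types per FCC allowed)."""

    sample_type_fcc_counts: dict[str, int] = field(default_factory=dict)
    method_study_counts: dict[str, int] = field(default_factory=dict)
    method_fcc_counts: dict[str, int] = field(default_factory=dict)
    analyte_form_fcc_counts: dict[str, int] = field(default_factory=dict)
    n_detected: int = 0
    n_monitored_not_detected: int = 0
    n_no_evidence: int = 0


def aggregate_step2(
    statuses: Mapping[str, Step2Status],
    records: Iterable[EvidenceMapRecord],
) -> Step2Summary:
    """Summarize detections by sample type, analytical method, and analyte form.

    Sample-type counts are distinct FCCs with at least one detection in that
    sample type. Method counts tally distinct studies per method (a study using
    both approaches counts once, under ``both``) and distinct detected FCCs per
    method. Analyte-form counts are distinct FCCs with any record of that form.
    """
    records = list(records)
    summary = Step2Summary(
        sample_type_fcc_counts={t: 0 for t in SAMPLE_TYPES},
        method_study_counts={m: 0 for m in METHODS},
        method_fcc_counts={m: 0 for m in METHODS},
        analyte_form_fcc_counts={f: 0 for f in ANALYTE_FORMS},
    )
    for st in statuses.values():
        if st.category == "detected":
            summary.n_detected += 1
        elif st.category == "monitored_not_detected":
            summary.n_monitored_not_detected += 1
        else:
            summary.n_no_evidence += 1
        for t in st.sample_types_detected:
            summary.sample_type_fcc_counts[t] += 1
        for f in st.analyte_forms:
            summary.analyte_form_fcc_counts[f] += 1

    method_studies: dict[str, set[str]] = {m: set() for m in METHODS}
    method_fccs: dict[str, set[str]] = {m: set() for m in METHODS}
    cas_detected = {r.fcc_cas.normalized for r in records if r.detected}
    for r in records:
        method_studies[r.method].add(r.study_id)
        if r.detected and r.fcc_cas.normalized in cas_detected:
            method_fccs[r.method].add(r.fcc_cas.normalized)
    summary.method_study_counts = {m: len(s) for m, s in method_studies.items()}
    summary.method_fcc_counts = {m: len(s) for m, s in method_fccs.items()}
    return summary
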