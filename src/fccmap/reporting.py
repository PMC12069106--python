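"""Consolidation of step-1, step-2, hazard, and group inputs into one table.

The consolidated table (one row per known FCC) carries the overall evidence
status, contributing evidence sources, which pipeline step produced the
evidence, the GHS concern tier where the FCC belongs to a hazard-mapped
subset, and the curated group label. On every run the three statuses
partition the universe: detected + monitored_not_detected + no_evidence
equals the registry size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .chem_registry import ChemicalRegistry
from .hazard import merge_other_tiers
from .source_io import EvidenceMapRecord, FcchumonRecord, GroupAnnotation
from .step1 import Step1Status
from .step2 import Step2Status

__all__ = [
    "ConsistencyError",
    "UNGROUPED_LABEL",
    "consolidate",
    "EvidenceSummary",
    "evidence_summary",
    "GroupSummary",
    "group_summaries",
    "sankey_export",
    "biomonitored_fcm_subset",
]

#: Reserved label aggregating FCCs without a curated group annotation.
UNGROUPED_LABEL = "ungrouped"


class ConsistencyError(ValueError):
    """Cross-input contradiction, e.g. a step-2 status for a step-1 FCC."""


def biomonitored_fcm_subset(
    step1_statuses: Mapping[str, Step1Status],
    migex_detect_counts: Mapping[str, int],
) -> list[str]:
    """FCCs present in FCMs that were included in biomonitoring programs.

    Computed as (monitored in >=1 program) intersected with (>=1 FCM database
    entry reporting detection); this is the step-1A subset carried into hazard
    mapping and group summaries. Override with an explicit subset file if a
    different definition is needed.
    """
    return [
        chem_id
        for chem_id, st in step1_statuses.items()
        if st.biomon_monitored_in and migex_detect_counts.get(chem_id, 0) >= 1
    ]


def consolidate(
    step1_statuses: Mapping[str, Step1Status],
    step2_statuses: Mapping[str, Step2Status],
    tiers: Mapping[str, str],
    groups: Iterable[GroupAnnotation],
    registry: ChemicalRegistry,
    migex_detect_counts: Mapping[str, int] | None = None,
) -> list[FcchumonRecord]:
    """Build the consolidated per-FCC table.

    Overall status: detected if detected in step 1 or step 2;
    monitored_not_detected if monitored anywhere but never detected;
    no_evidence otherwise. A step-2 status for an FCC with any step-1
    source presence raises :class:`ConsistencyError`.
    """
    migex_detect_counts = migex_detect_counts or {}
    group_by_cas = {g.cas.normalized: g.group_label for g in groups}

    records: list[FcchumonRecord] = []
    for rec in registry:
        s1 = step1_statuses[rec.chem_id]
        s2 = step2_statuses.get(rec.chem_id)
        if s2 is not None and (s1.biomon_monitored_in or s1.metabolome_listed_in):
            raise ConsistencyError(
                f"{rec.chem_id}: has a step-2 status but is present in step-1 sources"
            )

        sources = set()
        if s1.biomon_detected_in:
            sources.add("biomonitoring")
        if s1.metabolome_listed_in:
            sources.add("metabolome")
        if s2 is not None and s2.category == "detected":
            sources.add("literature")

        if s1.category == "detected" or (s2 is not None and s2.category == "detected"):
            status = "detected"
        elif s1.category == "monitored_not_detected" or (
            s2 is not None and s2.category == "monitored_not_detected"
        ):
            status = "monitored_not_detected"
        else:
            status = "no_evidence"

        if s1.category != "no_evidence" or s1.biomon_monitored_in:
            step = "step1"
        elif s2 is not None:
            step = "step2"
        else:
            step = "none"

        cas = rec.identifiers.cas.normalized if rec.identifiers.cas else None
        records.append(FcchumonRecord(
            chem_id=rec.chem_id,
            identifiers=rec.identifiers,
            overall_status=status,
            evidence_sources=frozenset(sources),
            step=step,
            tier=tiers.get(rec.chem_id),
            group_label=group_by_cas.get(cas) if cas else None,
            migex_detect_entries=migex_detect_counts.get(rec.chem_id, 0),
        ))
    return records


@dataclass
class EvidenceSummary:
    """Headline counts over the consolidated table (the summary.json payload)."""

    n_universe: int
    n_evidence: int
    pct_evidence: int  # nearest integer percent of the universe with evidence
    n_biomon_detected: int
    n_metabolome_listed: int
    n_overlap: int  # FCCs with both biomonitoring and metabolome evidence
    n_step2_detected: int
    n_monitored_not_detected: int
    n_no_evidence: int
    n_by_step: dict[str, int] = field(default_factory=dict)
    tier_counts: dict[str, int] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "n_universe": self.n_universe,
            "n_evidence": self.n_evidence,
            "pct_evidence": self.pct_evidence,
            "n_biomon_detected": self.n_biomon_detected,
            "n_metabolome_listed": self.n_metabolome_listed,
            "n_overlap": self.n_overlap,
            "n_step2_detected": self.n_step2_detected,
            "n_monitored_not_detected": self.n_monitored_not_detected,
            "n_no_evidence": self.n_no_evidence,
            "tier_counts": dict(self.tier_counts),
        }


def evidence_summary(records: Sequence[FcchumonRecord]) -> EvidenceSummary:
    """Totals by status and source over the consolidated table.

    The biomonitoring/metabolome overlap is counted once (set semantics), so
    source totals never double-count FCCs present in both kinds of sources.
    """
    n = len(records)
    n_detected = sum(r.overall_status == "detected" for r in records)
    n_mnd = sum(r.overall_status == "monitored_not_detected" for r in records)
    n_none = n - n_detected - n_mnd
    by_step: dict[str, int] = {"step1": 0, "step2": 0, "none": 0}
    tier_raw: dict[str, int] = {}
    for r in records:
        by_step[r.step] += 1
        if r.tier is not None:
            tier_raw[r.tier] = tier_raw.get(r.tier, 0) + 1
    return EvidenceSummary(
        n_universe=n,
        n_evidence=n_detected,
        pct_evidence=round(100 * n_detected / n) if n else 0,
        n_biomon_detected=sum("biomonitoring" in r.evidence_sources for r in records),
        n_metabolome_listed=sum("metabolome" in r.evidence_sources for r in records),
        n_overlap=sum(
            {"biomonitoring", "metabolome"} <= r.evidence_sources for r in records
        ),
        n_step2_detected=sum("literature" in r.evidence_sources for r in records),
        n_monitored_not_detected=n_mnd,
        n_no_evidence=n_none,
        n_by_step=by_step,
        tier_counts=merge_other_tiers(tier_raw),
    )


@dataclass(frozen=True)
class GroupSummary:
    """Per-group evidence summary (one bar/pie of the group figure)."""

    group_label: str
    n_fccs: int
    migex_detect_entry_sum: int
    human_evidence_weight: int
    n_detected: int
    n_monitored_not_detected: int
    n_no_evidence: int

    def __post_init__(self) -> None:
        if self.n_detected + self.n_monitored_not_detected + self.n_no_evidence \
                != self.n_fccs:
            raise ValueError(f"{self.group_label}: status split must sum to n_fccs")


def group_summaries(
    records: Sequence[FcchumonRecord],
    step1_statuses: Mapping[str, Step1Status] | None = None,
    step2_records: Sequence[EvidenceMapRecord] | None = None,
) -> list[GroupSummary]:
    """Summarize a subset of the consolidated table by curated group.

    The FCM-evidence weight per group is the sum of its members' FCM
    detect-entry counts. The human-evidence weight depends on the subset kind:
    with ``step1_statuses`` it is the summed number of programs monitoring each
    member; with ``step2_records`` it is the number of distinct studies that
    monitored at least one member. FCCs without a label aggregate under
    ``ungrouped``.
    """
    if (step1_statuses is None) == (step2_records is None):
        raise ValueError("provide exactly one of step1_statuses or step2_records")

    members: dict[str, list[FcchumonRecord]] = {}
    for r in records:
        members.setdefault(r.group_label or UNGROUPED_LABEL, []).append(r)

    out = []
    for label in sorted(members):
        recs = members[label]
        if step1_statuses is not None:
            weight = sum(
                len(step1_statuses[r.chem_id].biomon_monitored_in) for r in recs
            )
        else:
            cas_set = {r.identifiers.cas.normalized for r in recs
                       if r.identifiers.cas is not None}
            weight = len({
                er.study_id for er in step2_records
                if er.fcc_cas.normalized in cas_set
            })
        out.append(GroupSummary(
            group_label=label,
            n_fccs=len(recs),
            migex_detect_entry_sum=sum(r.migex_detect_entries for r in recs),
            human_evidence_weight=weight,
            n_detected=sum(r.overall_status == "detected" for r in recs),
            n_monitored_not_detected=sum(
                r.overall_status == "monitored_not_detected" for r in recs
            ),
            n_no_evidence=sum(r.overall_status == "no_evidence" for r in recs),
        ))
    return out


def sankey_export(records: Sequence[FcchumonRecord]) -> list[tuple[str, str, int]]:
    """Evidence-status x concern-tier flow table for one hazard-mapped subset.

    Tiers other_concern and not_classified merge into one band, matching the
    reporting convention. Every record must carry a tier; flows sum to the
    subset size.
    """
    flows: dict[tuple[str, str], int] = {}
    for r in records:
        if r.tier is None:
            raise ValueError(f"{r.chem_id}: sankey export requires a tier for "
                             f"every record in the subset")
        band = ("other_or_not_classified"
                if r.tier in ("other_concern", "not_classified") else r.tier)
        key = (r.overall_status, band)
        flows[key] = flows.get(key, 0) + 1
    return sorted((s, t, n) for (s, t), n in flows.items())
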