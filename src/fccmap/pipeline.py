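"""End-to-end driver: step 1, step 2, hazard tiering, and consolidation."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .chem_registry import ChemicalRegistry
from .hazard import TierTable, tier_table
from .reporting import (
    EvidenceSummary,
    biomonitored_fcm_subset,
    consolidate,
    evidence_summary,
)
from .source_io import (
    BiomonitoringAnalyte,
    EvidenceMapRecord,
    FccMigexEntry,
    FcchumonRecord,
    GroupAnnotation,
    HazardRecord,
    MetabolomeListing,
    read_source,
)
from .step1 import (
    ProgramOverlap,
    Step1Partition,
    Step1Status,
    count_step1_partition,
    cross_program_overlap,
    expand_metabolite_links,
    resolve_step1,
)
from .step2 import (
    DEFAULT_THRESHOLD,
    PrioritizedFcc,
    Step2Status,
    Step2Summary,
    aggregate_step2,
    classify_step2,
    count_migex_detect_entries,
    prioritize,
)
from .synthetic import SourceBundle

__all__ = ["PipelineResult", "run_pipeline", "run_pipeline_on_bundle",
           "run_pipeline_from_dir"]


@dataclass
class PipelineResult:
    """Everything the pipeline computes, for reporting and export."""

    step1_statuses: dict[str, Step1Status]
    partition: Step1Partition
    program_overlap: ProgramOverlap
    migex_detect_counts: dict[str, int]
    prioritized: list[PrioritizedFcc]
    step2_statuses: dict[str, Step2Status]
    step2_rejects: list[EvidenceMapRecord]
    step2_summary: Step2Summary
    biomonitored_subset: list[str]
    biomonitored_tiers: TierTable
    prioritized_tiers: TierTable
    records: list[FcchumonRecord]
    summary: EvidenceSummary
    hmdb_listed: int = 0
    n_biomon_monitored: int = 0

    def records_for_subset(self, subset: Iterable[str]) -> list[FcchumonRecord]:
        wanted = set(subset)
        return [r for r in self.records if r.chem_id in wanted]


def run_pipeline(
    registry: ChemicalRegistry,
    biomonitoring: Sequence[BiomonitoringAnalyte],
    metabolome: Sequence[MetabolomeListing],
    fccmigex: Sequence[FccMigexEntry],
    evidence_map: Sequence[EvidenceMapRecord],
    hazard: Sequence[HazardRecord],
    groups: Sequence[GroupAnnotation] = (),
    threshold: int = DEFAULT_THRESHOLD,
) -> PipelineResult:
    """Run both steps, tier the two hazard-mapped subsets, and consolidate."""
    expanded, _ = expand_metabolite_links(biomonitoring)
    step1_statuses = resolve_step1(registry, expanded, metabolome)
    partition = count_step1_partition(step1_statuses, registry)
    overlap = cross_program_overlap(step1_statuses)

    migex_counts = count_migex_detect_entries(registry, fccmigex)
    prioritized = prioritize(registry, step1_statuses, fccmigex, threshold)
    step2_statuses, rejects = classify_step2(evidence_map, prioritized)
    step2_summary = aggregate_step2(step2_statuses, evidence_map)

    hazard_by_chem: dict[str, list[HazardRecord]] = {}
    for rec in hazard:
        if rec.identifiers.cas is None:
            continue
        chem = registry.lookup_cas(rec.identifiers.cas.normalized)
        if chem is not None:
            hazard_by_chem.setdefault(chem, []).append(rec)

    bio_subset = biomonitored_fcm_subset(step1_statuses, migex_counts)
    bio_tiers = tier_table(bio_subset, hazard_by_chem)
    pri_tiers = tier_table([p.chem_id for p in prioritized], hazard_by_chem)

    tiers = {**bio_tiers.assignments, **pri_tiers.assignments}
    records = consolidate(step1_statuses, step2_statuses, tiers, groups, registry,
                          migex_counts)
    return PipelineResult(
        step1_statuses=step1_statuses,
        partition=partition,
        program_overlap=overlap,
        migex_detect_counts=migex_counts,
        prioritized=prioritized,
        step2_statuses=step2_statuses,
        step2_rejects=rejects,
        step2_summary=step2_summary,
        biomonitored_subset=bio_subset,
        biomonitored_tiers=bio_tiers,
        prioritized_tiers=pri_tiers,
        records=records,
        summary=evidence_summary(records),
        hmdb_listed=sum(
            "HMDB" in s.metabolome_listed_in for s in step1_statuses.values()
        ),
        n_biomon_monitored=sum(
            bool(s.biomon_monitored_in) for s in step1_statuses.values()
        ),
    )


def run_pipeline_on_bundle(bundle: SourceBundle,
                           threshold: int | None = None) -> PipelineResult:
    """Convenience wrapper for synthetic bundles."""
    return run_pipeline(
        bundle.registry,
        bundle.biomonitoring,
        bundle.metabolome,
        bundle.fccmigex,
        bundle.evidence_map,
        bundle.hazard,
        bundle.groups,
        threshold=threshold if threshold is not None
        else bundle.spec.prioritization_threshold,
    )


def run_pipeline_from_dir(src_dir: str | Path,
                          threshold: int = DEFAULT_THRESHOLD) -> PipelineResult:
    """Load a source bundle directory (as written by the generator) and run."""
    src = Path(src_dir)
    registry_rows, _ = read_source(src / "registry.csv", "registry")
    biomon, _ = read_source(src / "biomonitoring.csv", "biomonitoring")
    metab, _ = read_source(src / "metabolome.csv", "metabolome")
    migex, _ = read_source(src / "fccmigex.csv", "fccmigex")
    hazard, _ = read_source(src / "hazard.csv", "hazard")
    evidence, _ = read_source(src / "evidence_map.csv", "evidence_map")
    groups_path = src / "groups.csv"
    groups, _ = read_source(groups_path, "groups") if groups_path.exists() else ([], None)
    return run_pipeline(ChemicalRegistry(registry_rows), biomon, metab, migex,
                        evidence, hazard, groups, threshold=threshold)
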