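"""Seeded generator of coherent multi-source synthetic universes.

The external sources behind the real analysis (FCC inventories, five
biomonitoring programs, three metabolome/exposome databases, GHS inventories,
and the literature evidence map) are proprietary or living databases. This
module builds synthetic stand-ins with the same *marginal structure*: a
:class:`UniverseSpec` fixes the counts and overlaps (how many FCCs are
biomonitoring-detected, metabolome-listed, in both, prioritized, and so on)
and :func:`generate_universe` constructs memberships that satisfy every quota
exactly. Free attributes (program assignments, FCM materials, study layouts)
are drawn from a seeded RNG, so identical specs produce byte-identical
bundles. :func:`paper_marginals` is the preset whose quotas reproduce the
published marginal counts of the real analysis.

Synthetic CAS numbers are drawn from a reserved high-numbered block (first
block 9,000,000+; metabolites 8,500,000+) so they cannot collide with real
registry numbers, and all carry valid check digits.
"""

from __future__ import annotations

import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .chem_registry import (
    CasNumber,
    ChemicalRecord,
    ChemicalRegistry,
    IdentifierSet,
    cas_check_digit,
)
from .source_io import (
    HAZARD_SOURCES,
    HMDB_STATUSES,
    PROGRAMS,
    SAMPLE_TYPES,
    BiomonitoringAnalyte,
    EvidenceMapRecord,
    FccMigexEntry,
    GroupAnnotation,
    HazardRecord,
    MetabolomeListing,
    write_source,
)

__all__ = [
    "InfeasibleSpecError",
    "UniverseSpec",
    "SourceBundle",
    "generate_universe",
    "paper_marginals",
    "synthetic_cas",
]

TIER_QUOTA_KEYS = ("high", "medium", "other_or_not_classified", "no_hazard_data")

_FCA_TYPES = ("packaging", "tableware", "processing_equipment")
_FCM_MATERIALS = ("plastic", "paper_board", "coated_metal", "silicone", "glass")
_STEP1_GROUPS = ("VOCs", "PFAS", "pesticides", "metals", "dioxin_like",
                 "flame_retardants", "phthalates_and_alternatives")
_STEP2_GROUPS = ("oligomers", "antioxidants", "photoinitiators", "plasticizers",
                 "other_step2")


class InfeasibleSpecError(ValueError):
    """The requested quotas cannot be satisfied simultaneously."""


def synthetic_cas(index: int, base: int = 9_000_000) -> CasNumber:
    """Deterministic, checksum-valid CAS from a reserved high-numbered block."""
    first = base + index // 100
    second = index % 100
    body = f"{first}{second:02d}"
    check = cas_check_digit(body)
    return CasNumber(raw=f"{first}-{second:02d}-{check}",
                     normalized=f"{first}-{second:02d}-{check}",
                     checksum_valid=True)


def _synthetic_inchikey(index: int) -> str:
    letters, n = [], index
    for _ in range(14):
        letters.append(chr(65 + n % 26))
        n //= 26
    return f"{''.join(reversed(letters))}-SYNTHETICA-N"


@dataclass
class UniverseSpec:
    """Marginal counts and overlaps of one synthetic universe.

    Counts are constructed, not sampled: the pipeline run on the generated
    bundle recovers each quota exactly. Fields left at zero simply produce no
    rows of that kind.
    """

    n_universe: int
    seed: int = 0
    # step-1 detected set, partitioned by source-inventory flags
    n_fccdb_only: int = 0
    n_migex_only: int = 0
    n_both: int = 0
    # biomonitoring margins
    n_biomon_detected: int = 0
    n_biomon_monitored_only: int = 0
    all_five_monitored: int = 0
    all_five_detected: int = 0
    # metabolome/exposome margins
    n_metabolome_listed: int = 0
    n_overlap_biomon_metabolome: int = 0
    n_notdetected_in_metabolome: int = 0
    hmdb_status_counts: tuple[int, int, int] = (0, 0, 0)
    # step-2 margins
    n_prioritized: int = 0
    prioritization_threshold: int = 5
    n_step2_with_studies: int = 0
    n_step2_all_negative: int = 0
    sample_type_quota: dict[str, int] = field(default_factory=dict)
    # hazard margins: subset name -> tier band -> count
    hazard_tier_quota: dict[str, dict[str, int]] = field(default_factory=dict)
    #: of the prioritized-set no_hazard_data quota, how many fall on FCCs
    #: without any step-2 study (None: as many as fit, from the tail)
    hazard_no_data_no_evidence: int | None = None
    # generator behaviour
    metabolite_link_fraction: float = 0.10
    n_migex_below_threshold: int = 0

    # ----- derived quantities -------------------------------------------------

    @property
    def n_step1_detected(self) -> int:
        """Union of biomonitoring-detected and metabolome-listed FCCs."""
        return (self.n_biomon_detected + self.n_metabolome_listed
                - self.n_overlap_biomon_metabolome)

    @property
    def n_step2_detected(self) -> int:
        return self.n_step2_with_studies - self.n_step2_all_negative

    @property
    def n_biomon_subset(self) -> int:
        """Size of the biomonitored-and-in-FCM hazard-mapped subset."""
        return sum(self.hazard_tier_quota.get("biomonitored", {}).values())

    def validate(self) -> None:
        """Raise :class:`InfeasibleSpecError` with an explanation if quotas clash."""
        def fail(msg: str):
            raise InfeasibleSpecError(msg)

        ints = {k: v for k, v in asdict(self).items()
                if isinstance(v, int) and k != "seed"}
        for k, v in ints.items():
            if v < 0:
                fail(f"{k} must be non-negative, got {v}")
        if any(c < 0 for c in self.hmdb_status_counts):
            fail("hmdb_status_counts must be non-negative")

        if self.n_overlap_biomon_metabolome > min(self.n_biomon_detected,
                                                  self.n_metabolome_listed):
            fail("biomonitoring/metabolome overlap exceeds a source margin")
        part = self.n_fccdb_only + self.n_migex_only + self.n_both
        if part > self.n_universe:
            fail("inventory partition exceeds the universe size")
        if part != self.n_step1_detected:
            fail(f"inventory partition ({part}) must equal the implied step-1 "
                 f"detected count ({self.n_step1_detected})")
        if self.n_notdetected_in_metabolome > self.n_biomon_monitored_only:
            fail("metabolome-listed non-detections exceed the monitored-only count")
        if (self.n_overlap_biomon_metabolome + self.n_notdetected_in_metabolome
                > self.n_metabolome_listed):
            fail("metabolome overlaps exceed the metabolome-listed total")
        if sum(self.hmdb_status_counts) > self.n_metabolome_listed:
            fail("HMDB rows exceed the metabolome-listed total")
        if not (self.n_step2_all_negative <= self.n_step2_with_studies
                <= self.n_prioritized):
            fail("step-2 study counts must nest: all_negative <= with_studies "
                 "<= prioritized")
        if not (self.all_five_detected <= self.all_five_monitored
                <= self.n_biomon_detected):
            fail("all-five-program counts must nest within the detected set")
        if self.prioritization_threshold < 1:
            fail("prioritization threshold must be >= 1")
        if self.n_migex_below_threshold and self.prioritization_threshold < 2:
            fail("below-threshold candidates require a threshold >= 2")

        n_step1 = (self.n_biomon_detected + self.n_biomon_monitored_only
                   + self.n_metabolome_listed - self.n_overlap_biomon_metabolome
                   - self.n_notdetected_in_metabolome)
        used = n_step1 + self.n_prioritized + self.n_migex_below_threshold
        if used > self.n_universe:
            fail(f"quotas require {used} FCCs but the universe has {self.n_universe}")

        for subset, quota in self.hazard_tier_quota.items():
            if subset not in ("biomonitored", "prioritized"):
                fail(f"unknown hazard subset: {subset!r}")
            for k in quota:
                if k not in TIER_QUOTA_KEYS:
                    fail(f"unknown tier band in hazard quota: {k!r}")
            if any(v < 0 for v in quota.values()):
                fail("hazard tier quotas must be non-negative")
        nsub = self.n_biomon_subset
        if nsub > self.n_biomon_detected + self.n_notdetected_in_metabolome:
            fail("biomonitored hazard subset exceeds the monitored, "
                 "step-1-detected FCCs available")
        if nsub > self.n_migex_only + self.n_both:
            fail("biomonitored hazard subset exceeds the FCCs carrying an "
                 "FCCmigex inventory flag")
        pq = self.hazard_tier_quota.get("prioritized", {})
        if pq and sum(pq.values()) != self.n_prioritized:
            fail("prioritized hazard quota must sum to n_prioritized")
        if self.hazard_no_data_no_evidence is not None:
            x = self.hazard_no_data_no_evidence
            nd = pq.get("no_hazard_data", 0)
            n_none = self.n_prioritized - self.n_step2_with_studies
            if x > nd or x > n_none or nd - x > self.n_step2_with_studies:
                fail("hazard_no_data_no_evidence is inconsistent with the "
                     "prioritized quotas")

        n_det2 = self.n_step2_detected
        quota = {k: v for k, v in self.sample_type_quota.items() if v}
        if quota:
            for t, v in quota.items():
                if t not in SAMPLE_TYPES:
                    fail(f"unknown sample type in quota: {t!r}")
                if v > n_det2:
                    fail(f"sample-type quota {t}={v} exceeds the {n_det2} "
                         f"step-2 detected FCCs")
            if sum(quota.values()) < n_det2:
                fail("sample-type quotas cannot cover every detected FCC")
        if not 0.0 <= self.metabolite_link_fraction <= 1.0:
            fail("metabolite_link_fraction must be within [0, 1]")


@dataclass
class SourceBundle:
    """All generated source tables for one universe."""

    spec: UniverseSpec
    registry: ChemicalRegistry
    biomonitoring: list[BiomonitoringAnalyte]
    metabolome: list[MetabolomeListing]
    fccmigex: list[FccMigexEntry]
    hazard: list[HazardRecord]
    evidence_map: list[EvidenceMapRecord]
    groups: list[GroupAnnotation]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        write_source(self.registry.records, out / "registry.csv", "registry")
        write_source(self.biomonitoring, out / "biomonitoring.csv", "biomonitoring")
        write_source(self.metabolome, out / "metabolome.csv", "metabolome")
        write_source(self.fccmigex, out / "fccmigex.csv", "fccmigex")
        write_source(self.hazard, out / "hazard.csv", "hazard")
        write_source(self.evidence_map, out / "evidence_map.csv", "evidence_map")
        write_source(self.groups, out / "groups.csv", "groups")


def paper_marginals(seed: int = 0) -> UniverseSpec:
    """Preset reproducing the published marginal structure of the analysis.

    14,402 known FCCs; 194 biomonitoring-detected and 71 monitored-only over
    five programs (13 monitored in all five, 8 detected in all five); 3528
    metabolome-listed with a 184-FCC overlap with the detected set and 61 of
    the 71 non-detections listed; HMDB statuses 367/1072/772; 175 prioritized
    FCCs at threshold 5, of which 68 have eligible studies and 5 only
    non-detections; per-sample-type detection counts for the evidence map; and
    GHS tier quotas for the 235-FCC biomonitored and 175-FCC prioritized
    hazard-mapped subsets.
    """
    return UniverseSpec(
        n_universe=14402,
        seed=seed,
        n_fccdb_only=1883,
        n_migex_only=863,
        n_both=792,
        n_biomon_detected=194,
        n_biomon_monitored_only=71,
        all_five_monitored=13,
        all_five_detected=8,
        n_metabolome_listed=3528,
        n_overlap_biomon_metabolome=184,
        n_notdetected_in_metabolome=61,
        hmdb_status_counts=(367, 1072, 772),
        n_prioritized=175,
        prioritization_threshold=5,
        n_step2_with_studies=68,
        n_step2_all_negative=5,
        sample_type_quota={
            "urine": 28, "serum": 20, "blood": 13, "plasma": 12,
            "breast_milk": 13, "umbilical_cord": 18, "placenta": 6,
        },
        hazard_tier_quota={
            "biomonitored": {"high": 100, "medium": 44,
                             "other_or_not_classified": 77, "no_hazard_data": 14},
            "prioritized": {"high": 5, "medium": 13,
                            "other_or_not_classified": 98, "no_hazard_data": 59},
        },
        hazard_no_data_no_evidence=49,
        n_migex_below_threshold=40,
    )


# ---------------------------------------------------------------------------
# Generation


def _make_registry(spec: UniverseSpec, layout: dict, rng: random.Random) -> ChemicalRegistry:
    n = spec.n_universe
    detected: list[int] = layout["detected"]
    subset: set[int] = set(layout["biomon_subset"])
    migex_flagged: set[int] = set(layout["prioritized"]) | set(layout["below_threshold"])

    flags: dict[int, tuple[bool, bool]] = {}
    pools = {"db": spec.n_fccdb_only, "mi": spec.n_migex_only, "bo": spec.n_both}
    # subset members must carry an FCCmigex flag; feasibility was validated
    for idx in detected:
        if idx in subset:
            if pools["bo"] > 0:
                pools["bo"] -= 1
                flags[idx] = (True, True)
            else:
                pools["mi"] -= 1
                flags[idx] = (False, True)
    for idx in detected:
        if idx in flags:
            continue
        if pools["db"] > 0:
            pools["db"] -= 1
            flags[idx] = (True, False)
        elif pools["bo"] > 0:
            pools["bo"] -= 1
            flags[idx] = (True, True)
        else:
            pools["mi"] -= 1
            flags[idx] = (False, True)

    records = []
    for i in range(n):
        cas = synthetic_cas(i)
        is_mixture = i % 250 == 137
        inchikey = None if is_mixture or i % 5 == 0 else _synthetic_inchikey(i)
        smiles = None if is_mixture or i % 3 == 0 else f"[Syn{i}]"
        ids = IdentifierSet(cas=cas, inchikey=inchikey, smiles=smiles,
                            names=(f"chem-{i:05d}",))
        if i in flags:
            in_db, in_mi = flags[i]
        elif i in migex_flagged:
            in_db, in_mi = rng.random() < 0.5, True
        else:
            in_db, in_mi = True, rng.random() < 0.1
        records.append(ChemicalRecord(
            chem_id=f"FCC{i:05d}", identifiers=ids, is_mixture=is_mixture,
            in_fccdb=in_db, in_fccmigex=in_mi,
        ))
    return ChemicalRegistry(records)


def _make_biomonitoring(spec: UniverseSpec, layout: dict, registry: ChemicalRegistry,
                        rng: random.Random) -> list[BiomonitoringAnalyte]:
    rows: list[BiomonitoringAnalyte] = []
    programs = list(PROGRAMS)

    def emit(idx: int, program_status: list[tuple[str, str]]) -> None:
        rec = registry.records[idx]
        cas = rec.identifiers.cas
        via_metabolite = rng.random() < spec.metabolite_link_fraction
        if via_metabolite:
            met_cas = synthetic_cas(idx, base=8_500_000)
            ids = IdentifierSet(cas=met_cas, names=(f"metabolite-of-{idx:05d}",))
            parent = cas
            name = f"metabolite-of-{idx:05d}"
        else:
            ids = IdentifierSet(cas=cas, names=(f"analyte-{idx:05d}",))
            parent = None
            name = f"analyte-{idx:05d}"
        for program, status in program_status:
            rows.append(BiomonitoringAnalyte(
                program=program, analyte_identifiers=ids,
                parent_cas=parent, status=status, analyte_name=name,
            ))

    biomon_detected: list[int] = layout["biomon_detected"]
    for pos, idx in enumerate(biomon_detected):
        if pos < spec.all_five_detected:
            plan = [(p, "detected") for p in programs]
        elif pos < spec.all_five_monitored:
            plan = [(p, "detected") for p in programs[:-1]]
            plan.append((programs[-1], "not_detected"))
        else:
            k = rng.randint(1, 3)
            chosen = rng.sample(programs, k)
            plan = [(p, "detected") for p in chosen]
            if pos % 10 == 3 and k <= 3:
                extra = next(p for p in programs if p not in chosen)
                plan.append((extra, "not_detected"))
        emit(idx, plan)

    for idx in layout["monitored_only"]:
        chosen = rng.sample(programs, rng.randint(1, 2))
        emit(idx, [(p, "not_detected") for p in chosen])
    return rows


def _make_metabolome(spec: UniverseSpec, layout: dict,
                     registry: ChemicalRegistry) -> list[MetabolomeListing]:
    rows: list[MetabolomeListing] = []
    listed: list[int] = layout["metabolome_listed"]
    hmdb_n = sum(spec.hmdb_status_counts)
    status_seq: list[str] = []
    for s, c in zip(HMDB_STATUSES, spec.hmdb_status_counts):
        status_seq.extend([s] * c)

    for pos, idx in enumerate(listed):
        rec = registry.records[idx]
        if pos % 37 == 5 and rec.identifiers.inchikey is not None:
            ids = IdentifierSet(inchikey=rec.identifiers.inchikey)
        else:
            ids = IdentifierSet(cas=rec.identifiers.cas)
        if pos < hmdb_n:
            rows.append(MetabolomeListing("HMDB", ids, status_seq[pos]))
        else:
            rows.append(MetabolomeListing("BloodExposome", ids, "listed"))
        if pos % 50 == 7:
            rows.append(MetabolomeListing(
                "ExposomeExplorer", IdentifierSet(cas=rec.identifiers.cas), "listed"))
    return rows


def _make_fccmigex(spec: UniverseSpec, layout: dict, registry: ChemicalRegistry,
                   rng: random.Random) -> list[FccMigexEntry]:
    rows: list[FccMigexEntry] = []
    counter = 0

    def emit(idx: int, n_detected: int, n_not: int = 0) -> None:
        nonlocal counter
        rec = registry.records[idx]
        ids = IdentifierSet(cas=rec.identifiers.cas)
        for flag, count in ((True, n_detected), (False, n_not)):
            for _ in range(count):
                counter += 1
                rows.append(FccMigexEntry(
                    entry_id=f"E{counter:06d}",
                    identifiers=ids,
                    fca_type=rng.choice(_FCA_TYPES),
                    fcm_material=rng.choice(_FCM_MATERIALS),
                    detected=flag,
                    reference_id=f"ref{rng.randint(1, 3000):04d}",
                ))

    thr = spec.prioritization_threshold
    for pos, idx in enumerate(layout["prioritized"]):
        # one heavy-tail chemical mirrors the most frequently detected FCC
        n_det = 99 if pos == 0 and thr <= 99 else thr + rng.randint(0, 4)
        emit(idx, n_det, n_not=1 if pos % 20 == 11 else 0)
    for pos, idx in enumerate(layout["biomon_subset"]):
        emit(idx, rng.randint(1, 8), n_not=1 if pos % 10 == 4 else 0)
    for idx in layout["below_threshold"]:
        emit(idx, rng.randint(1, thr - 1))
    return rows


def _assign_sample_types(detected: list[int], quota: Mapping[str, int],
                         rng: random.Random) -> dict[int, list[str]]:
    """Give every detected FCC >=1 sample type while hitting each quota exactly."""
    assigned: dict[int, list[str]] = {f: [] for f in detected}
    quota = {t: quota.get(t, 0) for t in SAMPLE_TYPES if quota.get(t, 0) > 0}
    if not quota:
        for f in detected:
            assigned[f].append(rng.choice(SAMPLE_TYPES[:4]))
        return assigned
    in_type: dict[str, set[int]] = {t: set() for t in quota}
    i = 0
    for t in quota:  # primary pass: one type per FCC until everyone is covered
        while len(in_type[t]) < quota[t] and i < len(detected):
            in_type[t].add(detected[i])
            assigned[detected[i]].append(t)
            i += 1
    for off, t in enumerate(quota):  # fill pass: multi-membership
        need = quota[t] - len(in_type[t])
        if need <= 0:
            continue
        candidates = [f for f in detected if f not in in_type[t]]
        rot = (off * 7) % len(candidates)
        candidates = candidates[rot:] + candidates[:rot]
        for f in candidates[:need]:
            in_type[t].add(f)
            assigned[f].append(t)
    return assigned


def _make_evidence_map(spec: UniverseSpec, layout: dict, registry: ChemicalRegistry,
                       rng: random.Random) -> list[EvidenceMapRecord]:
    rows: list[EvidenceMapRecord] = []
    prioritized: list[int] = layout["prioritized"]
    n_det = spec.n_step2_detected
    detected = prioritized[:n_det]
    all_negative = prioritized[n_det:spec.n_step2_with_studies]
    sample_types = _assign_sample_types(detected, spec.sample_type_quota, rng)

    study_counter = 0

    def new_study() -> tuple[str, str]:
        nonlocal study_counter
        study_counter += 1
        # exactly one study applies both approaches; the rest split by RNG
        method = "both" if study_counter == 1 else (
            "targeted" if rng.random() < 0.7 else "nontargeted")
        return f"S{study_counter:04d}", method

    for pos, idx in enumerate(detected):
        cas = registry.records[idx].identifiers.cas
        if pos < 2:
            form = "unspecific_metabolite"
        elif pos % 9 == 4:
            form = "specific_metabolite"
        else:
            form = "parent"
        studies = [new_study() for _ in range(1 + (rng.random() < 0.4))]
        types = sample_types[idx]
        for j, st in enumerate(types):
            study_id, method = studies[j % len(studies)]
            rows.append(EvidenceMapRecord(study_id, cas, st, method, form, True))
        if pos % 7 == 2:
            unused = [t for t in SAMPLE_TYPES if t not in types]
            if unused:
                study_id, method = studies[0]
                rows.append(EvidenceMapRecord(study_id, cas, unused[0], method,
                                              form, False))

    for idx in all_negative:
        cas = registry.records[idx].identifiers.cas
        for st in rng.sample(SAMPLE_TYPES[:5], rng.randint(1, 3)):
            study_id, method = new_study()
            rows.append(EvidenceMapRecord(study_id, cas, st, method, "parent", False))
    return rows


_HIGH_VARIANTS = (("carcinogenicity", "cat_1A"), ("reproductive_toxicity", "cat_1B"),
                  ("mutagenicity", "cat_1B"), ("stot_re", "cat_1"))
_MEDIUM_CLASSES = ("carcinogenicity", "mutagenicity", "reproductive_toxicity", "stot_re")


def _tier_sequence(quota: Mapping[str, int]) -> list[str]:
    seq: list[str] = []
    seq.extend(["high"] * quota.get("high", 0))
    seq.extend(["medium"] * quota.get("medium", 0))
    n_other = quota.get("other_or_not_classified", 0)
    # split the merged band between the two internal tiers
    seq.extend(["other_concern" if i % 2 == 0 else "not_classified"
                for i in range(n_other)])
    seq.extend(["no_hazard_data"] * quota.get("no_hazard_data", 0))
    return seq


def _hazard_rows_for(idx: int, tier: str, registry: ChemicalRegistry,
                     rng: random.Random, pos: int) -> list[HazardRecord]:
    ids = IdentifierSet(cas=registry.records[idx].identifiers.cas)
    src = rng.choice(HAZARD_SOURCES)
    other_src = HAZARD_SOURCES[1 - HAZARD_SOURCES.index(src)]
    if tier == "no_hazard_data":
        return []
    if tier == "high":
        cls, cat = _HIGH_VARIANTS[pos % len(_HIGH_VARIANTS)]
        rows = [HazardRecord(ids, src, cls, cat, True)]
        if pos % 6 == 1:  # pooled second source with a weaker classification
            rows.append(HazardRecord(ids, other_src, cls, "cat_2", True))
        return rows
    if tier == "medium":
        cls = _MEDIUM_CLASSES[pos % len(_MEDIUM_CLASSES)]
        return [HazardRecord(ids, src, cls, "cat_2", True)]
    if tier == "other_concern":
        return [HazardRecord(ids, src, "other", "other", True)]
    return [HazardRecord(ids, src, "other", "none", True)]  # not_classified


def _make_hazard(spec: UniverseSpec, layout: dict, registry: ChemicalRegistry,
                 rng: random.Random) -> list[HazardRecord]:
    rows: list[HazardRecord] = []
    bio_quota = spec.hazard_tier_quota.get("biomonitored", {})
    for pos, (idx, tier) in enumerate(
            zip(layout["biomon_subset"], _tier_sequence(bio_quota))):
        rows.extend(_hazard_rows_for(idx, tier, registry, rng, pos))

    pq = spec.hazard_tier_quota.get("prioritized", {})
    if pq:
        prioritized: list[int] = layout["prioritized"]
        n_studied = spec.n_step2_with_studies
        n_none = spec.n_prioritized - n_studied
        nd = pq.get("no_hazard_data", 0)
        x = spec.hazard_no_data_no_evidence
        if x is None:
            x = min(nd, n_none)
        no_data = set(prioritized[len(prioritized) - x:]) if x else set()
        head_nd = nd - x  # no-data quota falling on FCCs with studies
        if head_nd:
            no_data |= set(prioritized[n_studied - head_nd:n_studied])
        remaining = [i for i in prioritized if i not in no_data]
        seq = _tier_sequence({k: v for k, v in pq.items() if k != "no_hazard_data"})
        for pos, (idx, tier) in enumerate(zip(remaining, seq)):
            rows.extend(_hazard_rows_for(idx, tier, registry, rng, pos))
    return rows


def _make_groups(spec: UniverseSpec, layout: dict, registry: ChemicalRegistry,
                 rng: random.Random) -> list[GroupAnnotation]:
    rows = []
    for idx in layout["biomon_subset"]:
        rows.append(GroupAnnotation(registry.records[idx].identifiers.cas,
                                    rng.choice(_STEP1_GROUPS)))
    for idx in layout["prioritized"]:
        rows.append(GroupAnnotation(registry.records[idx].identifiers.cas,
                                    rng.choice(_STEP2_GROUPS)))
    return rows


def _layout(spec: UniverseSpec) -> dict:
    """Deterministic index blocks for every membership role."""
    i = 0

    def take(n: int) -> list[int]:
        nonlocal i
        block = list(range(i, i + n))
        i += n
        return block

    biomon_detected = take(spec.n_biomon_detected)
    notdet_listed = take(spec.n_notdetected_in_metabolome)
    monitored_unlisted = take(spec.n_biomon_monitored_only
                              - spec.n_notdetected_in_metabolome)
    metabolome_only = take(spec.n_metabolome_listed
                           - spec.n_overlap_biomon_metabolome
                           - spec.n_notdetected_in_metabolome)
    prioritized = take(spec.n_prioritized)
    below = take(spec.n_migex_below_threshold)

    overlap = biomon_detected[:spec.n_overlap_biomon_metabolome]
    listed = overlap + notdet_listed + metabolome_only
    detected = biomon_detected + notdet_listed + metabolome_only

    nsub = spec.n_biomon_subset
    a = min(spec.n_biomon_detected, nsub)
    subset = biomon_detected[:a] + notdet_listed[:nsub - a]

    return {
        "biomon_detected": biomon_detected,
        "monitored_only": notdet_listed + monitored_unlisted,
        "metabolome_listed": listed,
        "detected": detected,
        "prioritized": prioritized,
        "below_threshold": below,
        "biomon_subset": subset,
    }


def generate_universe(spec: UniverseSpec) -> SourceBundle:
    """Construct the full source bundle for one spec.

    Deterministic given the spec (including its seed); every quota in the spec
    is satisfied exactly, all synthetic CAS numbers are checksum-valid, and no
    two chemicals share an identifier.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    layout = _layout(spec)
    registry = _make_registry(spec, layout, rng)
    return SourceBundle(
        spec=spec,
        registry=registry,
        biomonitoring=_make_biomonitoring(spec, layout, registry, rng),
        metabolome=_make_metabolome(spec, layout, registry),
        fccmigex=_make_fccmigex(spec, layout, registry, rng),
        hazard=_make_hazard(spec, layout, registry, rng),
        evidence_map=_make_evidence_map(spec, layout, registry, rng),
        groups=_make_groups(spec, layout, registry, rng),
    )
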