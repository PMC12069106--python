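"""Metabolite expansion, step-1 status resolution, and partition counting."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_chem, make_ids
from fccmap.chem_registry import ChemicalRegistry, normalize_cas
from fccmap.source_io import PROGRAMS, BiomonitoringAnalyte, MetabolomeListing
from fccmap.step1 import (
    Step1Status,
    count_step1_partition,
    cross_program_overlap,
    expand_metabolite_links,
    resolve_step1,
)

CAS_POOL = ["84-66-2", "100-42-5", "7440-43-9", "50-00-0", "71-43-2",
            "119-61-9", "1709-70-2", "128-39-2", "65447-77-0", "96-76-4"]


def analyte(cas, program="NHANES", status="detected", parent=None, name=""):
    return BiomonitoringAnalyte(
        program=program,
        analyte_identifiers=make_ids(cas=cas, names=[name] if name else []),
        parent_cas=normalize_cas(parent) if parent else None,
        status=status,
        analyte_name=name,
    )


def listing(cas, database="BloodExposome", status="listed"):
    return MetabolomeListing(database, make_ids(cas=cas), status)


class TestExpandMetaboliteLinks:
    def test_metabolite_row_emits_parent_row_with_same_program_and_status(self):
        rows, errors = expand_metabolite_links(
            [analyte("863029-89-4", parent="84-66-2", name="mono-ethyl phthalate")])
        assert errors == []
        assert len(rows) == 2
        assert rows[0].analyte_identifiers.cas.normalized == "863029-89-4"
        assert rows[1].analyte_identifiers.cas.normalized == "84-66-2"
        assert rows[1].program == "NHANES" and rows[1].status == "detected"
        assert rows[1].parent_cas is None

    def test_row_without_parent_passes_through_unchanged(self):
        a = analyte("84-66-2")
        rows, _ = expand_metabolite_links([a])
        assert rows == [a]

    def test_mixed_status_metabolites_of_one_parent_yield_detection(self):
        registry = ChemicalRegistry([make_chem("P", cas="84-66-2")])
        rows, _ = expand_metabolite_links([
            analyte("863029-89-4", parent="84-66-2", status="detected"),
            analyte("4376-20-9", parent="84-66-2", status="not_detected"),
        ])
        status = resolve_step1(registry, rows, [])["P"]
        assert status.category == "detected"
        assert status.biomon_detected_in == {"NHANES"}

    def test_expansion_never_reduces_the_matched_fcc_set(self):
        registry = ChemicalRegistry([make_chem("P", cas="84-66-2"),
                                     make_chem("Q", cas="100-42-5")])
        raw = [analyte("863029-89-4", parent="84-66-2"), analyte("100-42-5")]
        before = resolve_step1(registry, raw, [])
        after = resolve_step1(registry, expand_metabolite_links(raw)[0], [])
        for chem_id in registry.by_id:
            assert before[chem_id].biomon_monitored_in \
                <= after[chem_id].biomon_monitored_in


class TestResolveStep1:
    def test_single_detected_analyte(self):
        registry = ChemicalRegistry([make_chem("X", cas="84-66-2")])
        st1 = resolve_step1(registry, [analyte("84-66-2")], [])["X"]
        assert st1.category == "detected"
        assert st1.biomon_detected_in == {"NHANES"}

    def test_metabolome_listing_rescues_a_non_detection(self):
        registry = ChemicalRegistry([make_chem("X", cas="84-66-2")])
        st1 = resolve_step1(
            registry,
            [analyte("84-66-2", status="not_detected")],
            [listing("84-66-2")],
        )["X"]
        assert st1.category == "detected"
        assert st1.biomon_detected_in == frozenset()
        assert st1.metabolome_listed_in == {"BloodExposome"}

    def test_monitored_only_without_listing(self):
        registry = ChemicalRegistry([make_chem("X", cas="84-66-2")])
        st1 = resolve_step1(registry,
                            [analyte("84-66-2", status="not_detected")], [])["X"]
        assert st1.category == "monitored_not_detected"

    def test_five_chemical_universe_union(self):
        # 2 detected via biomonitoring, 3 listed, 1 in both -> 4 detected
        registry = ChemicalRegistry(
            [make_chem(f"C{i}", cas=CAS_POOL[i]) for i in range(5)])
        analytes = [analyte(CAS_POOL[0]), analyte(CAS_POOL[1])]
        listings = [listing(CAS_POOL[1]), listing(CAS_POOL[2]), listing(CAS_POOL[3])]
        statuses = resolve_step1(registry, analytes, listings)
        detected = {c for c, s in statuses.items() if s.category == "detected"}
        assert detected == {"C0", "C1", "C2", "C3"}
        assert statuses["C4"].category == "no_evidence"

    def test_inconsistent_status_construction_rejected(self):
        with pytest.raises(ValueError):
            Step1Status("X", frozenset({"NHANES"}), frozenset(), frozenset(),
                        "detected")
        with pytest.raises(ValueError):
            Step1Status("X", frozenset(), frozenset(), frozenset({"HMDB"}),
                        "no_evidence")

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.data())
    def test_agrees_with_brute_force_oracle_on_small_universes(self, data):
        n = data.draw(st.integers(1, 10))
        registry = ChemicalRegistry(
            [make_chem(f"C{i}", cas=CAS_POOL[i]) for i in range(n)])
        analytes = [
            analyte(data.draw(st.sampled_from(CAS_POOL)),
                    program=data.draw(st.sampled_from(PROGRAMS)),
                    status=data.draw(st.sampled_from(["detected", "not_detected"])))
            for _ in range(data.draw(st.integers(0, 8)))
        ]
        listings = [listing(data.draw(st.sampled_from(CAS_POOL)))
                    for _ in range(data.draw(st.integers(0, 8)))]
        statuses = resolve_step1(registry, analytes, listings)

        for rec in registry:  # nested-loop oracle over FCCs x source rows
            cas = rec.identifiers.cas.normalized
            mon = {a.program for a in analytes
                   if a.analyte_identifiers.cas.normalized == cas}
            det = {a.program for a in analytes
                   if a.analyte_identifiers.cas.normalized == cas
                   and a.status == "detected"}
            lst = {l.database for l in listings
                   if l.identifiers.cas.normalized == cas}
            s = statuses[rec.chem_id]
            assert set(s.biomon_monitored_in) == mon
            assert set(s.biomon_detected_in) == det
            assert set(s.metabolome_listed_in) == lst
            expected = ("detected" if det or lst else
                        "monitored_not_detected" if mon else "no_evidence")
            assert s.category == expected

        # partition law holds on every input
        counts = {c: 0 for c in ("detected", "monitored_not_detected", "no_evidence")}
        for s in statuses.values():
            counts[s.category] += 1
        assert sum(counts.values()) == len(registry)

    def test_adding_a_listing_never_leaves_detected(self):
        registry = ChemicalRegistry([make_chem("X", cas="84-66-2")])
        base = resolve_step1(registry, [analyte("84-66-2")], [])["X"]
        more = resolve_step1(registry, [analyte("84-66-2")],
                             [listing("84-66-2")])["X"]
        assert base.category == more.category == "detected"


class TestPartitionAndOverlap:
    def test_partition_tallies_inventory_flags(self):
        registry = ChemicalRegistry([
            make_chem("A", cas=CAS_POOL[0], in_fccdb=True, in_fccmigex=False),
            make_chem("B", cas=CAS_POOL[1], in_fccdb=True, in_fccmigex=False),
            make_chem("C", cas=CAS_POOL[2], in_fccdb=False, in_fccmigex=True),
            make_chem("D", cas=CAS_POOL[3], in_fccdb=True, in_fccmigex=True),
            make_chem("E", cas=CAS_POOL[4]),
        ])
        statuses = resolve_step1(
            registry, [analyte(CAS_POOL[i]) for i in range(4)], [])
        part = count_step1_partition(statuses, registry)
        assert (part.fccdb_only, part.fccmigex_only, part.both) == (2, 1, 1)
        assert part.n_detected == 4
        assert part.no_evidence == 1

    def test_empty_detected_set(self):
        registry = ChemicalRegistry([make_chem("A", cas=CAS_POOL[0])])
        statuses = resolve_step1(registry, [], [])
        part = count_step1_partition(statuses, registry)
        assert (part.fccdb_only, part.fccmigex_only, part.both) == (0, 0, 0)

    def test_all_five_detection_is_strict(self):
        registry = ChemicalRegistry([make_chem("X", cas="84-66-2"),
                                     make_chem("Y", cas="100-42-5")])
        analytes = [analyte("84-66-2", program=p) for p in PROGRAMS]
        analytes += [analyte("100-42-5", program=p) for p in PROGRAMS[:4]]
        analytes.append(analyte("100-42-5", program=PROGRAMS[4],
                                status="not_detected"))
        overlap = cross_program_overlap(resolve_step1(registry, analytes, []))
        assert overlap.all_five_monitored == 2
        assert overlap.all_five_detected == 1
        assert overlap.monitored_in_at_least[1] == 2
        assert overlap.monitored_in_at_least[5] == 2
        assert overlap.monitored_in_exactly[5] == 2
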