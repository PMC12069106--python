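"""Generator feasibility checks, determinism, and quota round-trip recovery."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fccmap.chem_registry import normalize_cas
from fccmap.pipeline import run_pipeline_on_bundle
from fccmap.synthetic import (
    InfeasibleSpecError,
    UniverseSpec,
    generate_universe,
    paper_marginals,
    synthetic_cas,
)


def small_spec(**overrides):
    base = dict(
        n_universe=80, seed=3,
        n_fccdb_only=7, n_migex_only=1, n_both=2,
        n_biomon_detected=4, n_biomon_monitored_only=2,
        all_five_monitored=1, all_five_detected=1,
        n_metabolome_listed=7, n_overlap_biomon_metabolome=1,
        n_notdetected_in_metabolome=1, hmdb_status_counts=(1, 2, 1),
        n_prioritized=4, n_step2_with_studies=3, n_step2_all_negative=1,
        sample_type_quota={"urine": 2, "serum": 1},
        hazard_tier_quota={
            "biomonitored": {"high": 1, "medium": 1,
                             "other_or_not_classified": 0, "no_hazard_data": 1},
            "prioritized": {"high": 1, "medium": 0,
                            "other_or_not_classified": 2, "no_hazard_data": 1},
        },
        n_migex_below_threshold=2,
    )
    base.update(overrides)
    return UniverseSpec(**base)


class TestSpecValidation:
    def test_small_spec_is_feasible(self):
        small_spec().validate()

    def test_paper_preset_is_feasible(self):
        paper_marginals().validate()

    @pytest.mark.parametrize("overrides, match", [
        (dict(n_overlap_biomon_metabolome=5), "overlap exceeds"),
        (dict(n_fccdb_only=6), "partition .* must equal"),
        (dict(n_step2_all_negative=4), "step-2 study counts"),
        (dict(all_five_monitored=5), "all-five-program"),
        (dict(n_universe=10), "universe has"),
        (dict(hmdb_status_counts=(5, 5, 5)), "HMDB rows exceed"),
        (dict(sample_type_quota={"urine": 1}), "sample-type quotas cannot cover"),
        (dict(sample_type_quota={"saliva": 2}), "unknown sample type"),
        (dict(prioritization_threshold=0), "threshold"),
        (dict(n_notdetected_in_metabolome=3), "non-detections exceed"),
    ])
    def test_infeasible_specs_fail_before_generation(self, overrides, match):
        with pytest.raises(InfeasibleSpecError, match=match):
            generate_universe(small_spec(**overrides))

    def test_prioritized_quota_must_cover_the_whole_set(self):
        quota = {"biomonitored": {"high": 3},
                 "prioritized": {"high": 1, "no_hazard_data": 1}}
        with pytest.raises(InfeasibleSpecError, match="must sum"):
            small_spec(hazard_tier_quota=quota).validate()


class TestGeneration:
    def test_all_quotas_zero_yields_registry_only(self):
        bundle = generate_universe(UniverseSpec(n_universe=10, seed=1))
        assert len(bundle.registry) == 10
        assert bundle.biomonitoring == []
        assert bundle.metabolome == []
        assert bundle.fccmigex == []
        assert bundle.hazard == []
        assert bundle.evidence_map == []

    def test_same_spec_and_seed_give_byte_identical_bundles(self, tmp_path):
        for i, d in enumerate(("a", "b")):
            generate_universe(small_spec(seed=11)).write(tmp_path / d)
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files
        for name in files:
            assert (tmp_path / "a" / name).read_bytes() \
                == (tmp_path / "b" / name).read_bytes()

    def test_different_seed_changes_free_attributes_not_quotas(self):
        r1 = run_pipeline_on_bundle(generate_universe(small_spec(seed=1)))
        r2 = run_pipeline_on_bundle(generate_universe(small_spec(seed=2)))
        assert r1.summary.n_evidence == r2.summary.n_evidence
        assert r1.partition == r2.partition

    def test_generated_cas_are_checksum_valid_and_unique(self):
        bundle = generate_universe(small_spec())
        seen_cas, seen_keys = set(), set()
        for rec in bundle.registry:
            cas = rec.identifiers.cas
            assert normalize_cas(cas.normalized).checksum_valid
            assert cas.normalized not in seen_cas
            seen_cas.add(cas.normalized)
            if rec.identifiers.inchikey:
                assert rec.identifiers.inchikey not in seen_keys
                seen_keys.add(rec.identifiers.inchikey)
        # metabolite analyte CAS live in a reserved block, disjoint from FCCs
        for a in bundle.biomonitoring:
            if a.parent_cas is not None:
                assert a.analyte_identifiers.cas.normalized not in seen_cas
                assert normalize_cas(
                    a.analyte_identifiers.cas.normalized).checksum_valid

    def test_reserved_block_helper(self):
        cas = synthetic_cas(0)
        assert cas.normalized.startswith("9000000-")
        assert normalize_cas(cas.normalized).checksum_valid


@st.composite
def feasible_specs(draw):
    d = draw(st.integers(0, 8))            # biomonitoring-detected FCCs
    m = draw(st.integers(0, 4))            # monitored, never detected
    notdet_listed = draw(st.integers(0, m))
    overlap = draw(st.integers(0, d))
    extra = draw(st.integers(0, 10))       # metabolome-only FCCs
    listed = overlap + notdet_listed + extra
    detected_total = d + listed - overlap

    h1 = draw(st.integers(0, listed))
    h2 = draw(st.integers(0, listed - h1))
    h3 = draw(st.integers(0, listed - h1 - h2))

    nsub = draw(st.integers(0, d + notdet_listed))
    five_mon = draw(st.integers(0, min(2, d)))
    five_det = draw(st.integers(0, five_mon))

    p = draw(st.integers(0, 6))
    ws = draw(st.integers(0, p))
    an = draw(st.integers(0, ws))
    n_det2 = ws - an
    quota = {"urine": n_det2, "blood": min(1, n_det2)} if n_det2 else {}

    def split4(n):
        a = draw(st.integers(0, n))
        b = draw(st.integers(0, n - a))
        c = draw(st.integers(0, n - a - b))
        return {"high": a, "medium": b, "other_or_not_classified": c,
                "no_hazard_data": n - a - b - c}

    below = draw(st.integers(0, 2))
    used = d + m + extra + p + below
    return UniverseSpec(
        n_universe=used + draw(st.integers(0, 15)),
        seed=draw(st.integers(0, 2**16)),
        n_fccdb_only=detected_total - nsub, n_migex_only=0, n_both=nsub,
        n_biomon_detected=d, n_biomon_monitored_only=m,
        all_five_monitored=five_mon, all_five_detected=five_det,
        n_metabolome_listed=listed, n_overlap_biomon_metabolome=overlap,
        n_notdetected_in_metabolome=notdet_listed,
        hmdb_status_counts=(h1, h2, h3),
        n_prioritized=p, n_step2_with_studies=ws, n_step2_all_negative=an,
        sample_type_quota=quota,
        hazard_tier_quota={"biomonitored": split4(nsub),
                           "prioritized": split4(p)},
        n_migex_below_threshold=below,
    )


class TestRoundTripRecovery:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(spec=feasible_specs())
    def test_pipeline_recovers_every_quota(self, spec):
        bundle = generate_universe(spec)
        res = run_pipeline_on_bundle(bundle)

        assert res.partition.fccdb_only == spec.n_fccdb_only
        assert res.partition.fccmigex_only == spec.n_migex_only
        assert res.partition.both == spec.n_both
        assert res.partition.n_detected == spec.n_step1_detected
        assert res.n_biomon_monitored == (spec.n_biomon_detected
                                          + spec.n_biomon_monitored_only)
        assert res.partition.monitored_not_detected == (
            spec.n_biomon_monitored_only - spec.n_notdetected_in_metabolome)
        assert res.hmdb_listed == sum(spec.hmdb_status_counts)
        assert sum(bool(s.metabolome_listed_in)
                   for s in res.step1_statuses.values()) == spec.n_metabolome_listed
        assert res.program_overlap.all_five_monitored == spec.all_five_monitored
        assert res.program_overlap.all_five_detected == spec.all_five_detected

        assert len(res.prioritized) == spec.n_prioritized
        assert res.step2_summary.n_detected == spec.n_step2_detected
        assert res.step2_summary.n_monitored_not_detected \
            == spec.n_step2_all_negative
        for t, v in spec.sample_type_quota.items():
            assert res.step2_summary.sample_type_fcc_counts[t] == v

        assert len(res.biomonitored_subset) == spec.n_biomon_subset
        bio_quota = spec.hazard_tier_quota["biomonitored"]
        pri_quota = spec.hazard_tier_quota["prioritized"]
        from fccmap.hazard import merge_other_tiers
        assert merge_other_tiers(res.biomonitored_tiers.counts) == bio_quota
        assert merge_other_tiers(res.prioritized_tiers.counts) == pri_quota

        s = res.summary
        assert s.n_evidence == spec.n_step1_detected + spec.n_step2_detected
        assert s.n_overlap == spec.n_overlap_biomon_metabolome
        assert s.n_monitored_not_detected == (
            spec.n_biomon_monitored_only - spec.n_notdetected_in_metabolome
            + spec.n_step2_all_negative)
        assert (s.n_evidence + s.n_monitored_not_detected + s.n_no_evidence
                == spec.n_universe)
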