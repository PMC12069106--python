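"""GHS-based concern tiering of FCCs.

Tier rules follow the human-health criteria of the EU Chemicals Strategy for
Sustainability, applied to pooled GHS classification records from the two
hazard inventories:

* ``high`` — any carcinogenicity/mutagenicity/reproductive-toxicity (CMR)
  classification in category 1A or 1B, or STOT repeated-exposure category 1;
* ``medium`` — suspected CMR and/or STOT RE, i.e. category 2;
* ``other_concern`` — classified, but only for other hazards (e.g. aquatic
  toxicity, skin sensitization);
* ``not_classified`` — data exist in at least one hazard category, but no
  classification;
* ``no_hazard_data`` — not listed in the inventories, or no data in any
  hazard category (no records at all).

The tier order is total (high > medium > other_concern > not_classified >
no_hazard_data), the assignment is the maximum over records, and therefore
adding a record can never lower a chemical's tier. Endocrine disruption,
persistence, bioaccumulation, and mobility are outside the tiering; records
for them may still assert data existence (``category='none'``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .source_io import HazardRecord

__all__ = [
    "TIERS",
    "CMR_CLASSES",
    "assign_tier",
    "tier_table",
    "TierTable",
    "merge_other_tiers",
]

#: Concern tiers in ascending precedence.
TIERS = ("no_hazard_data", "not_classified", "other_concern", "medium", "high")
_RANK = {t: i for i, t in enumerate(TIERS)}

CMR_CLASSES = frozenset({"carcinogenicity", "mutagenicity", "reproductive_toxicity"})


def _record_tier(rec: HazardRecord) -> str:
    if rec.hazard_class in CMR_CLASSES and rec.category in ("cat_1A", "cat_1B"):
        return "high"
    if rec.hazard_class == "stot_re" and rec.category == "cat_1":
        return "high"
    if (rec.hazard_class in CMR_CLASSES or rec.hazard_class == "stot_re") \
            and rec.category == "cat_2":
        return "medium"
    if rec.category != "none":
        return "other_concern"
    return "not_classified"  # has_data=True, no classification


def assign_tier(records: Iterable[HazardRecord]) -> str:
    """Concern tier for one chemical from its pooled inventory records.

    An empty record set means the chemical is absent from the inventories and
    yields ``no_hazard_data``. The result is the precedence maximum over
    records, hence independent of record order and source inventory.
    """
    tier = "no_hazard_data"
    for rec in records:
        t = _record_tier(rec)
        if _RANK[t] > _RANK[tier]:
            tier = t
    return tier


@dataclass
class TierTable:
    """Per-chemical tier assignments over one subset, with tallies."""

    assignments: dict[str, str]
    counts: dict[str, int]
    #: chemicals whose two inventories would assign different tiers on their own
    source_disagreements: frozenset[str]

    @property
    def n(self) -> int:
        return sum(self.counts.values())


def tier_table(
    subset: Sequence[str],
    records_by_chem: Mapping[str, Sequence[HazardRecord]],
) -> TierTable:
    """Assign one tier to every chemical in ``subset``.

    ``records_by_chem`` maps a chemical key (chem_id or CAS, caller's choice)
    to its pooled hazard records; keys absent from the mapping have no hazard
    data. Counts cover all five tiers and sum to ``len(subset)``. Chemicals
    where the per-source tiers disagree (pooled-max still applies) are flagged.
    """
    assignments: dict[str, str] = {}
    counts = {t: 0 for t in TIERS}
    disagreements = set()
    for key in subset:
        recs = list(records_by_chem.get(key, ()))
        tier = assign_tier(recs)
        assignments[key] = tier
        counts[tier] += 1
        per_source = {s: [r for r in recs if r.source == s]
                      for s in {r.source for r in recs}}
        if len({assign_tier(rs) for rs in per_source.values()}) > 1:
            disagreements.add(key)
    return TierTable(assignments=assignments, counts=counts,
                     source_disagreements=frozenset(disagreements))


def merge_other_tiers(counts: Mapping[str, int]) -> dict[str, int]:
    """Collapse other_concern + not_classified into one reporting band."""
    return {
        "high": counts.get("high", 0),
        "medium": counts.get("medium", 0),
        "other_or_not_classified": counts.get("other_concern", 0)
        + counts.get("not_classified", 0),
        "no_hazard_data": counts.get("no_hazard_data", 0),
    }
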