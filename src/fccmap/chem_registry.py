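"""Chemical identity model: CAS numbers, identifier sets, and cross-list matching.

Every comparison in the pipeline runs through this module. Chemicals are keyed
by up to three machine identifiers — CAS Registry Number, InChIKey, and SMILES —
and two lists match when *any* shared identifier kind agrees exactly after
normalization (union semantics). Chemical names are deliberately excluded from
automated matching; they are kept only for human-facing lookup.

CAS Registry Numbers carry a check digit: with the digits of the two leading
blocks numbered 1, 2, 3, ... from the rightmost digit leftward, the weighted sum
``sum(digit * position) mod 10`` must equal the final digit. Numbers that fail
the check are flagged but *retained and matchable*, because registry numbers in
real source lists must be reproducible verbatim.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "CasParseError",
    "CasNumber",
    "IdentifierSet",
    "ChemicalRecord",
    "MatchResult",
    "MatchReport",
    "normalize_cas",
    "cas_check_digit",
    "validate_inchikey",
    "canonicalize_smiles",
    "match_chemicals",
    "ChemicalRegistry",
]

_CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")
_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

#: Identifier kinds usable for automated matching, in default precedence order.
MATCH_KINDS = ("cas", "inchikey", "smiles")


class CasParseError(ValueError):
    """Raised when a string cannot be interpreted as a CAS Registry Number."""


def cas_check_digit(body_digits: str) -> int:
    """Check digit for the concatenated non-check digits of a CAS number.

    Positions count 1, 2, 3, ... from the rightmost non-check digit leftward.
    """
    return sum((i + 1) * int(d) for i, d in enumerate(reversed(body_digits))) % 10


@dataclass(frozen=True)
class CasNumber:
    """A parsed CAS Registry Number.

    ``normalized`` always matches ``^\\d{2,7}-\\d{2}-\\d$``; ``checksum_valid``
    records whether the final digit satisfies the registry checksum.
    """

    raw: str
    normalized: str
    checksum_valid: bool

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.normalized


def normalize_cas(raw: str) -> CasNumber:
    """Parse and normalize a CAS Registry Number.

    Whitespace is stripped, leading zeros in the first block are removed, and
    hyphens are inserted for all-digit input. Malformed input raises
    :class:`CasParseError` naming the offending value — never a silent
    pass-through.
    """
    if raw is None:
        raise CasParseError("CAS number is missing")
    s = "".join(str(raw).split())
    if not s:
        raise CasParseError("CAS number is empty")
    if "-" not in s:
        if not s.isdigit() or len(s) < 5:
            raise CasParseError(f"not a CAS number: {raw!r}")
        s = f"{s[:-3]}-{s[-3:-1]}-{s[-1]}"
    blocks = s.split("-")
    if len(blocks) != 3:
        raise CasParseError(f"CAS number must have three blocks: {raw!r}")
    first = blocks[0].lstrip("0") or "0"
    normalized = f"{first}-{blocks[1]}-{blocks[2]}"
    m = _CAS_RE.match(normalized)
    if m is None:
        raise CasParseError(f"malformed CAS number: {raw!r}")
    check = int(m.group(3))
    valid = cas_check_digit(m.group(1) + m.group(2)) == check
    return CasNumber(raw=str(raw), normalized=normalized, checksum_valid=valid)


def validate_inchikey(raw: str) -> bool:
    """True iff the trimmed, uppercased input matches the 14-10-1 pattern.

    Validation never throws; any non-conforming input (including ``None`` and
    the empty string) returns ``False``.
    """
    if raw is None:
        return False
    return _INCHIKEY_RE.match(str(raw).strip().upper()) is not None


def canonicalize_smiles(smiles: str) -> str:
    """Canonical SMILES via RDKit; raises ValueError on unparsable input.

    Only used when matching is explicitly switched to structure-level SMILES
    comparison; default matching compares SMILES as exact trimmed strings.
    """
    from rdkit import Chem  # local import: optional dependency path

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class IdentifierSet:
    """Normalized identifiers for one chemical.

    At least one of CAS / InChIKey / SMILES / names must be present. InChIKeys
    are stored trimmed and uppercased and must match the 14-10-1 pattern;
    SMILES are stored trimmed, otherwise verbatim.
    """

    cas: CasNumber | None = None
    inchikey: str | None = None
    smiles: str | None = None
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.cas is None and not self.inchikey and not self.smiles and not self.names:
            raise ValueError("IdentifierSet requires at least one identifier")
        if self.inchikey is not None and not validate_inchikey(self.inchikey):
            raise ValueError(f"invalid InChIKey: {self.inchikey!r}")

    @classmethod
    def from_strings(
        cls,
        cas: str | None = None,
        inchikey: str | None = None,
        smiles: str | None = None,
        names: Sequence[str] = (),
    ) -> "IdentifierSet":
        """Build from raw strings; empty strings count as missing."""
        cas_obj = normalize_cas(cas) if cas not in (None, "") else None
        key = str(inchikey).strip().upper() if inchikey not in (None, "") else None
        smi = str(smiles).strip() if smiles not in (None, "") else None
        return cls(cas=cas_obj, inchikey=key, smiles=smi or None,
                   names=tuple(n for n in names if n))

    def match_value(self, kind: str) -> str | None:
        """The comparison value for one identifier kind, or None if absent."""
        if kind == "cas":
            return self.cas.normalized if self.cas is not None else None
        if kind == "inchikey":
            return self.inchikey
        if kind == "smiles":
            return self.smiles
        raise KeyError(kind)

    @property
    def matchable(self) -> bool:
        return any(self.match_value(k) is not None for k in MATCH_KINDS)


@dataclass(frozen=True)
class ChemicalRecord:
    """One known food contact chemical in the registry."""

    chem_id: str
    identifiers: IdentifierSet
    is_mixture: bool = False
    in_fccdb: bool = True
    in_fccmigex: bool = False

    def __post_init__(self) -> None:
        if not (self.in_fccdb or self.in_fccmigex):
            raise ValueError(
                f"{self.chem_id}: registry records must belong to at least one inventory"
            )


@dataclass(frozen=True)
class MatchResult:
    """A single left-record x right-row identifier match.

    ``matched_on`` is the highest-precedence identifier kind that agreed.
    """

    left_id: str
    right_id: str
    matched_on: str


@dataclass
class MatchReport:
    """Matches plus bookkeeping from one matching run."""

    matches: list[MatchResult] = field(default_factory=list)
    n_left_skipped: int = 0
    n_right_skipped: int = 0
    #: (left_id, right_id, detail) rows where another shared identifier kind disagreed
    warnings: list[tuple[str, str, str]] = field(default_factory=list)

    def pairs(self) -> set[tuple[str, str]]:
        return {(m.left_id, m.right_id) for m in self.matches}


def match_chemicals(
    left: Iterable[ChemicalRecord],
    right: Iterable[tuple[str, IdentifierSet]],
    precedence: Sequence[str] = MATCH_KINDS,
    smiles_mode: str = "exact",
) -> MatchReport:
    """Match registry records against external rows on any shared identifier.

    A pair matches if any identifier kind agrees exactly after normalization;
    ``matched_on`` records the first agreeing kind in ``precedence``. Records
    carrying only names are skipped and counted. Pairs whose remaining shared
    identifier kinds disagree still match, but generate a warning row so the
    conflict can be audited. ``smiles_mode='canonical'`` compares RDKit
    canonical SMILES instead of exact strings.
    """
    if smiles_mode not in ("exact", "canonical"):
        raise ValueError(f"unknown smiles_mode: {smiles_mode!r}")

    def value(ids: IdentifierSet, kind: str) -> str | None:
        v = ids.match_value(kind)
        if v is not None and kind == "smiles" and smiles_mode == "canonical":
            v = canonicalize_smiles(v)
        return v

    report = MatchReport()
    left = list(left)
    right = list(right)

    index: dict[str, dict[str, list[str]]] = {k: {} for k in precedence}
    right_ids_map: dict[str, IdentifierSet] = {}
    for rid, ids in right:
        right_ids_map[rid] = ids
        if not ids.matchable:
            report.n_right_skipped += 1
            continue
        for kind in precedence:
            v = value(ids, kind)
            if v is not None:
                index[kind].setdefault(v, []).append(rid)

    seen: set[tuple[str, str]] = set()
    for rec in left:
        if not rec.identifiers.matchable:
            report.n_left_skipped += 1
            continue
        for kind in precedence:
            v = value(rec.identifiers, kind)
            if v is None:
                continue
            for rid in index[kind].get(v, ()):
                if (rec.chem_id, rid) in seen:
                    continue
                seen.add((rec.chem_id, rid))
                report.matches.append(MatchResult(rec.chem_id, rid, kind))
                rids = right_ids_map[rid]
                for other in precedence:
                    if other == kind:
                        continue
                    lv, rv = value(rec.identifiers, other), value(rids, other)
                    if lv is not None and rv is not None and lv != rv:
                        report.warnings.append(
                            (rec.chem_id, rid, f"{other} disagrees: {lv!r} != {rv!r}")
                        )
    return report


class ChemicalRegistry:
    """Container for the known-FCC universe with identifier lookups."""

    def __init__(self, records: Iterable[ChemicalRecord]):
        self.records: list[ChemicalRecord] = list(records)
        self.by_id: dict[str, ChemicalRecord] = {}
        for rec in self.records:
            if rec.chem_id in self.by_id:
                raise ValueError(f"duplicate chem_id: {rec.chem_id}")
            self.by_id[rec.chem_id] = rec
        self._by_cas: dict[str, str] = {}
        for rec in self.records:
            if rec.identifiers.cas is not None:
                self._by_cas.setdefault(rec.identifiers.cas.normalized, rec.chem_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def chem_ids(self) -> list[str]:
        return [rec.chem_id for rec in self.records]

    def lookup_cas(self, cas: str) -> str | None:
        """chem_id carrying this (raw or normalized) CAS, or None."""
        try:
            return self._by_cas.get(normalize_cas(cas).normalized)
        except CasParseError:
            return None

    def lookup_name(self, name: str) -> list[str]:
        """Case-insensitive name lookup helper (never used in automated matching)."""
        needle = name.strip().lower()
        return [
            rec.chem_id
            for rec in self.records
            if any(n.lower() == needle for n in rec.identifiers.names)
        ]
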