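"""Family networks at a reference time, under two temporal semantics.

A child's family network at time ``T`` is the set of individuals linked to
the child by relationship rows, with membership decided by one of:

* **recorded** — any relationship row (any type, either direction) whose
  ``recorded_date`` is strictly before ``T``.  This is what the registry
  actually knew at ``T``; because services often only map a family after a
  serious event, these networks are sparse at early notifications.
* **whole_life** — only whole-life-type rows (parent/child, sibling,
  half-sibling), backdated to the date of birth of the younger of the two
  individuals: the member belongs iff that effective date is ``<= T``,
  regardless of when the row was recorded.  This simulates linkage with a
  birth registry.  A sibling born after ``T`` is therefore never a member.

Only membership is backdated; member *attributes* (their events, their
recorded abusive rows) are evaluated downstream against ``T`` with no
backdating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger("kinrisk")


@dataclass(frozen=True)
class FamilyNetwork:
    """Membership of one child's network at one time point.

    ``membership_basis`` maps each member to the indices (in
    ``db.relationships``) of the rows supporting their membership.
    """

    child_id: str
    as_of: pd.Timestamp
    semantics: str  # "recorded" | "whole_life"
    members: frozenset[str]
    membership_basis: dict[str, tuple[int, ...]] = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.members)


def _touching(db, child_id: str) -> pd.DataFrame:
    rel = db.relationships
    mask = (rel["subject_id"] == child_id) | (rel["object_id"] == child_id)
    rows = rel[mask].copy()
    rows["other"] = rows["object_id"].where(rows["subject_id"] == child_id, rows["subject_id"])
    return rows


def _build(child_id, as_of, semantics, rows) -> FamilyNetwork:
    basis: dict[str, list[int]] = {}
    for idx, other in zip(rows.index, rows["other"]):
        basis.setdefault(other, []).append(int(idx))
    return FamilyNetwork(
        child_id=child_id,
        as_of=pd.Timestamp(as_of),
        semantics=semantics,
        members=frozenset(basis),
        membership_basis={k: tuple(v) for k, v in basis.items()},
    )


def recorded_network(db, child_id: str, as_of) -> FamilyNetwork:
    """Members = persons linked to the child by any relationship row (either
    direction) with ``recorded_date`` strictly before ``as_of``."""
    _require_person(db, child_id)
    as_of = pd.Timestamp(as_of)
    rows = _touching(db, child_id)
    rows = rows[rows["recorded_date"] < as_of]
    return _build(child_id, as_of, "recorded", rows)


def whole_life_network(db, child_id: str, as_of) -> FamilyNetwork:
    """Members = persons linked to the child by a whole-life-type row whose
    effective date — the dob of the younger of the two — is ``<= as_of``.
    ``recorded_date`` is ignored; non-whole-life types never contribute.
    Counterparts with no recorded dob cannot be backdated and are excluded
    (with a log message).
    """
    _require_person(db, child_id)
    as_of = pd.Timestamp(as_of)
    rows = _touching(db, child_id)
    rows = rows[rows["type_code"].isin(db.taxonomy.whole_life_codes)]
    if rows.empty:
        return _build(child_id, as_of, "whole_life", rows)
    dob = db.persons.set_index("person_id")["dob"]
    child_dob = dob.get(child_id)
    other_dob = rows["other"].map(dob)
    missing = other_dob.isna() | pd.isna(child_dob)
    if missing.any():
        logger.warning(
            "whole_life_network(%s): %d row(s) dropped, counterpart dob missing",
            child_id,
            int(missing.sum()),
        )
        rows = rows[~missing]
        other_dob = other_dob[~missing]
    if pd.isna(child_dob):
        rows = rows.iloc[0:0]
        effective = other_dob.iloc[0:0]
    else:
        effective = other_dob.where(other_dob > child_dob, child_dob)
    rows = rows[effective <= as_of]
    return _build(child_id, as_of, "whole_life", rows)


def _require_person(db, person_id: str) -> None:
    if not (db.persons["person_id"] == person_id).any():
        raise KeyError(f"unknown person {person_id!r}")
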