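"""Domain model and CSV I/O for child-protection registry extracts.

A registry extract is three delimited tables plus a relationship taxonomy:

* ``persons.csv`` — one row per individual: ``person_id,dob,gender,ethnicity_group``.
  ``gender`` and ``ethnicity_group`` are audit-only attributes; they are never
  used as model predictors.
* ``relationships.csv`` — directed relationship rows
  ``subject_id,object_id,type_code,recorded_date``.  The timestamp is the date
  the relationship was *entered into the registry*, not the date it began,
  which for family ties may be many years earlier.
* ``events.csv`` — per-person event stream ``person_id,event_type,date``
  (notifications, referral decisions, substantiated findings, family group
  conferences/agreements, interventions).

The taxonomy maps each relationship ``type_code`` to its semantics: whether it
is a *whole-life* relationship (parent/child, sibling, half-sibling — ties that
exist from the birth of the younger member and can be backdated as if linked
from a birth registry), whether it records abuse, and if so which role
(subject or object) is the instigator.

All dates are ISO-8601 calendar dates; registry timestamps carry no
time-of-day.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("kinrisk")

# ---------------------------------------------------------------------------
# Constants and schemas
# ---------------------------------------------------------------------------

EVENT_TYPES = frozenset(
    {
        "notification",
        "referral_decision",
        "substantiated_finding",
        "family_group_conference",
        "family_agreement",
        "intervention",
    }
)

#: Event types that constitute a "target event": a serious intervention by
#: child protection services or a substantiated finding of maltreatment.
TARGET_EVENT_TYPES = frozenset({"intervention", "substantiated_finding"})

PERSON_COLUMNS = ["person_id", "dob", "gender", "ethnicity_group"]
RELATIONSHIP_COLUMNS = ["subject_id", "object_id", "type_code", "recorded_date"]
EVENT_COLUMNS = ["person_id", "event_type", "date"]
TAXONOMY_COLUMNS = [
    "type_code",
    "is_whole_life",
    "is_abusive",
    "abuse_instigator_role",
    "description",
]

#: Default registry collection window (start, end), configurable at load time.
DEFAULT_COLLECTION_WINDOW = (pd.Timestamp("1996-01-01"), pd.Timestamp("2016-12-31"))


class DatabaseError(ValueError):
    """Base class for registry validation failures."""


class SchemaError(DatabaseError):
    """A table is missing a required column or has a malformed header."""


class TaxonomyError(DatabaseError):
    """A relationship row references an unknown or ill-defined type code."""


class IntegrityError(DatabaseError):
    """Referential-integrity or value-domain violation, with row locations."""


class DateParseError(DatabaseError):
    """A date field failed ISO-8601 parsing, with row locations."""


# ---------------------------------------------------------------------------
# Row-level domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Person:
    """One individual.  ``dob`` is required wherever whole-life backdating
    needs it; ``gender``/``ethnicity_group`` exist only for the fairness
    audit and are never model inputs."""

    person_id: str
    dob: pd.Timestamp | None = None
    gender: str | None = None
    ethnicity_group: str | None = None


@dataclass(frozen=True)
class Relationship:
    """A directed relationship row as recorded: ``subject`` relates to
    ``object`` (e.g. A is mother of C; B physically abused C)."""

    subject_id: str
    object_id: str
    type_code: str
    recorded_date: pd.Timestamp


@dataclass(frozen=True)
class Event:
    person_id: str
    event_type: str
    date: pd.Timestamp

    @property
    def is_target(self) -> bool:
        return self.event_type in TARGET_EVENT_TYPES


@dataclass(frozen=True)
class TaxonomyEntry:
    type_code: str
    is_whole_life: bool
    is_abusive: bool
    abuse_instigator_role: str  # "subject" | "object" | "none"
    description: str = ""


@dataclass(frozen=True)
class RelationshipTaxonomy:
    """Mapping from relationship type codes to their semantics.

    The full 134-type operational taxonomy is not public; this object is a
    configurable stand-in preserving the three semantic categories the
    analysis needs: whole-life family ties, abusive relationships (with the
    instigating role identified), and everything else.
    """

    entries: Mapping[str, TaxonomyEntry]

    def __post_init__(self) -> None:
        for code, e in self.entries.items():
            if code != e.type_code:
                raise TaxonomyError(f"taxonomy key {code!r} != entry code {e.type_code!r}")
            if e.abuse_instigator_role not in ("subject", "object", "none"):
                raise TaxonomyError(
                    f"type {code!r}: invalid abuse_instigator_role "
                    f"{e.abuse_instigator_role!r}"
                )
            if e.is_abusive and e.abuse_instigator_role == "none":
                raise TaxonomyError(f"abusive type {code!r} must name an instigator role")
            if not e.is_abusive and e.abuse_instigator_role != "none":
                raise TaxonomyError(f"non-abusive type {code!r} cannot name an instigator")

    @property
    def whole_life_codes(self) -> frozenset[str]:
        return frozenset(c for c, e in self.entries.items() if e.is_whole_life)

    @property
    def abusive_codes(self) -> frozenset[str]:
        return frozenset(c for c, e in self.entries.items() if e.is_abusive)

    def instigator_role(self, type_code: str) -> str:
        return self.entries[type_code].abuse_instigator_role

    def __contains__(self, type_code: str) -> bool:
        return type_code in self.entries

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "type_code": e.type_code,
                "is_whole_life": e.is_whole_life,
                "is_abusive": e.is_abusive,
                "abuse_instigator_role": e.abuse_instigator_role,
                "description": e.description,
            }
            for e in self.entries.values()
        ]
        return pd.DataFrame(rows, columns=TAXONOMY_COLUMNS).sort_values("type_code").reset_index(
            drop=True
        )


def default_taxonomy() -> RelationshipTaxonomy:
    """A ~12-type synthetic taxonomy covering the semantic categories used by
    the analysis: whole-life family ties, directed abusive relationships with
    the subject as instigator, and miscellaneous other relationships."""

    def t(code, wl, ab, role, desc):
        return TaxonomyEntry(code, wl, ab, role, desc)

    entries = [
        t("parent_child", True, False, "none", "subject is parent of object"),
        t("sibling", True, False, "none", "full siblings"),
        t("half_sibling", True, False, "none", "half siblings"),
        t("step_parent_of", False, False, "none", "subject is step-parent of object"),
        t("partner_of", False, False, "none", "domestic partners"),
        t("caregiver_of", False, False, "none", "subject cares for object"),
        t("grandparent_of", False, False, "none", "subject is grandparent of object"),
        t("cousin_of", False, False, "none", "cousins"),
        t("household_member", False, False, "none", "shares a household"),
        t("neighbour_of", False, False, "none", "neighbours"),
        t("physically_abused", False, True, "subject", "subject physically abused object"),
        t("emotionally_abused", False, True, "subject", "subject emotionally abused object"),
    ]
    return RelationshipTaxonomy({e.type_code: e for e in entries})


# ---------------------------------------------------------------------------
# Database container
# ---------------------------------------------------------------------------


@dataclass
class CPSDatabase:
    """A validated child-protection registry: persons, timestamped directed
    relationships, timestamped per-person events, and the taxonomy giving
    the relationship codes their semantics.

    Tables are pandas DataFrames in canonical (sorted) row order; all date
    columns are ``datetime64[ns]`` at midnight.
    """

    persons: pd.DataFrame
    relationships: pd.DataFrame
    events: pd.DataFrame
    collection_window: tuple[pd.Timestamp, pd.Timestamp]
    taxonomy: RelationshipTaxonomy = field(default_factory=default_taxonomy)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frames(
        cls,
        persons: pd.DataFrame,
        relationships: pd.DataFrame,
        events: pd.DataFrame,
        taxonomy: RelationshipTaxonomy | None = None,
        collection_window: tuple | None = None,
    ) -> "CPSDatabase":
        """Validate raw frames and return a canonicalised database.

        Raises :class:`SchemaError`, :class:`TaxonomyError`,
        :class:`IntegrityError` or :class:`DateParseError` describing the
        offending rows.  Exact duplicate relationship rows are dropped with a
        logged count.
        """
        taxonomy = taxonomy if taxonomy is not None else default_taxonomy()
        window = _coerce_window(collection_window)
        persons = _check_columns(persons.copy(), PERSON_COLUMNS, "persons")
        relationships = _check_columns(relationships.copy(), RELATIONSHIP_COLUMNS, "relationships")
        events = _check_columns(events.copy(), EVENT_COLUMNS, "events")

        persons["dob"] = _parse_dates(persons["dob"], "persons.dob", allow_missing=True)
        relationships["recorded_date"] = _parse_dates(
            relationships["recorded_date"], "relationships.recorded_date"
        )
        events["date"] = _parse_dates(events["date"], "events.date")
        for col in ("gender", "ethnicity_group"):
            persons[col] = persons[col].replace("", pd.NA)

        dup_ids = persons["person_id"][persons["person_id"].duplicated()]
        if len(dup_ids):
            raise IntegrityError(f"duplicate person_id values: {sorted(set(dup_ids))[:10]}")

        known = set(persons["person_id"])
        _check_ids(relationships["subject_id"], known, "relationships.subject_id")
        _check_ids(relationships["object_id"], known, "relationships.object_id")
        _check_ids(events["person_id"], known, "events.person_id")

        self_loops = relationships.index[
            relationships["subject_id"] == relationships["object_id"]
        ]
        if len(self_loops):
            raise IntegrityError(
                f"relationship rows with subject_id == object_id at rows {list(self_loops[:10])}"
            )

        unknown_codes = set(relationships["type_code"]) - set(taxonomy.entries)
        if unknown_codes:
            raise TaxonomyError(f"unknown relationship type codes: {sorted(unknown_codes)[:10]}")

        bad_types = events.index[~events["event_type"].isin(EVENT_TYPES)]
        if len(bad_types):
            raise IntegrityError(
                f"unknown event_type at rows {list(bad_types[:10])}: "
                f"{sorted(set(events.loc[bad_types, 'event_type']))[:10]}"
            )

        _check_in_window(relationships["recorded_date"], window, "relationships.recorded_date")
        _check_in_window(events["date"], window, "events.date")

        wl_codes = taxonomy.whole_life_codes
        wl = relationships[relationships["type_code"].isin(wl_codes)]
        wl_people = set(wl["subject_id"]) | set(wl["object_id"])
        no_dob = persons[persons["person_id"].isin(wl_people) & persons["dob"].isna()]
        if len(no_dob):
            raise IntegrityError(
                "persons referenced by whole-life relationships lack a dob "
                f"(backdating needs it): {sorted(no_dob['person_id'])[:10]}"
            )

        n_before = len(relationships)
        relationships = relationships.drop_duplicates(subset=RELATIONSHIP_COLUMNS)
        n_dup = n_before - len(relationships)
        if n_dup:
            logger.info("dropped %d exact duplicate relationship row(s)", n_dup)

        persons = persons.sort_values("person_id", kind="mergesort").reset_index(drop=True)
        relationships = relationships.sort_values(
            RELATIONSHIP_COLUMNS, kind="mergesort"
        ).reset_index(drop=True)
        events = events.sort_values(EVENT_COLUMNS, kind="mergesort").reset_index(drop=True)
        return cls(persons, relationships, events, window, taxonomy)

    @classmethod
    def from_records(
        cls,
        persons: Iterable[Person] = (),
        relationships: Iterable[Relationship] = (),
        events: Iterable[Event] = (),
        taxonomy: RelationshipTaxonomy | None = None,
        collection_window: tuple | None = None,
    ) -> "CPSDatabase":
        """Build a validated database from row objects (fixture helper)."""
        pf = pd.DataFrame(
            [
                {
                    "person_id": p.person_id,
                    "dob": "" if p.dob is None else pd.Timestamp(p.dob).date().isoformat(),
                    "gender": p.gender or "",
                    "ethnicity_group": p.ethnicity_group or "",
                }
                for p in persons
            ],
            columns=PERSON_COLUMNS,
        )
        rf = pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "object_id": r.object_id,
                    "type_code": r.type_code,
                    "recorded_date": pd.Timestamp(r.recorded_date).date().isoformat(),
                }
                for r in relationships
            ],
            columns=RELATIONSHIP_COLUMNS,
        )
        ef = pd.DataFrame(
            [
                {
                    "person_id": e.person_id,
                    "event_type": e.event_type,
                    "date": pd.Timestamp(e.date).date().isoformat(),
                }
                for e in events
            ],
            columns=EVENT_COLUMNS,
        )
        return cls.from_frames(pf, rf, ef, taxonomy, collection_window)

    # -- queries -----------------------------------------------------------

    def person_dob(self, person_id: str) -> pd.Timestamp | None:
        row = self.persons.loc[self.persons["person_id"] == person_id, "dob"]
        if row.empty:
            raise KeyError(person_id)
        v = row.iloc[0]
        return None if pd.isna(v) else v

    def events_for(self, person_id: str) -> pd.DataFrame:
        return self.events[self.events["person_id"] == person_id]

    def target_events(self) -> pd.DataFrame:
        return self.events[self.events["event_type"].isin(TARGET_EVENT_TYPES)]

    def equals(self, other: "CPSDatabase") -> bool:
        return (
            self.persons.equals(other.persons)
            and self.relationships.equals(other.relationships)
            and self.events.equals(other.events)
            and self.collection_window == other.collection_window
            and self.taxonomy.to_frame().equals(other.taxonomy.to_frame())
        )

    def summary(self) -> dict:
        return {
            "n_persons": int(len(self.persons)),
            "n_relationships": int(len(self.relationships)),
            "n_events": int(len(self.events)),
            "collection_window": [
                self.collection_window[0].date().isoformat(),
                self.collection_window[1].date().isoformat(),
            ],
        }


# ---------------------------------------------------------------------------
# Loading / writing
# ---------------------------------------------------------------------------


def load_taxonomy(path: str | Path) -> RelationshipTaxonomy:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = _check_columns(df, TAXONOMY_COLUMNS, "taxonomy")
    entries = {}
    for i, row in df.iterrows():
        entries[row["type_code"]] = TaxonomyEntry(
            type_code=row["type_code"],
            is_whole_life=_parse_bool(row["is_whole_life"], f"taxonomy row {i + 2}"),
            is_abusive=_parse_bool(row["is_abusive"], f"taxonomy row {i + 2}"),
            abuse_instigator_role=row["abuse_instigator_role"] or "none",
            description=row["description"],
        )
    return RelationshipTaxonomy(entries)


def load_database(
    persons_path: str | Path,
    relationships_path: str | Path,
    events_path: str | Path,
    taxonomy_path: str | Path,
    collection_window: tuple | None = None,
) -> CPSDatabase:
    """Read and validate the three-table CSV database plus taxonomy.

    Rows violating referential integrity are rejected with their CSV line
    numbers; exact duplicate relationship rows are dropped with a logged
    count.  See :meth:`CPSDatabase.from_frames` for the validation rules.
    """
    taxonomy = load_taxonomy(taxonomy_path)
    persons = pd.read_csv(persons_path, dtype=str, keep_default_na=False)
    relationships = pd.read_csv(relationships_path, dtype=str, keep_default_na=False)
    events = pd.read_csv(events_path, dtype=str, keep_default_na=False)
    return CPSDatabase.from_frames(persons, relationships, events, taxonomy, collection_window)


def load_dir(directory: str | Path, collection_window: tuple | None = None) -> CPSDatabase:
    """Load a database written by :func:`write_database` from one directory.

    If ``meta.json`` is present its collection window is used unless an
    explicit ``collection_window`` overrides it.
    """
    d = Path(directory)
    if collection_window is None and (d / "meta.json").exists():
        meta = json.loads((d / "meta.json").read_text())
        collection_window = tuple(meta["collection_window"])
    return load_database(
        d / "persons.csv",
        d / "relationships.csv",
        d / "events.csv",
        d / "taxonomy.csv",
        collection_window,
    )


def write_database(db: CPSDatabase, directory: str | Path) -> dict[str, Path]:
    """Write the database as four UTF-8 CSV files plus ``meta.json``.

    Round-trip contract: ``load_dir(write_database(db))`` equals ``db``
    field-for-field.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "persons": d / "persons.csv",
        "relationships": d / "relationships.csv",
        "events": d / "events.csv",
        "taxonomy": d / "taxonomy.csv",
        "meta": d / "meta.json",
    }
    p = db.persons.copy()
    p["dob"] = p["dob"].dt.strftime("%Y-%m-%d")
    p.to_csv(paths["persons"], index=False, encoding="utf-8")
    r = db.relationships.copy()
    r["recorded_date"] = r["recorded_date"].dt.strftime("%Y-%m-%d")
    r.to_csv(paths["relationships"], index=False, encoding="utf-8")
    e = db.events.copy()
    e["date"] = e["date"].dt.strftime("%Y-%m-%d")
    e.to_csv(paths["events"], index=False, encoding="utf-8")
    db.taxonomy.to_frame().to_csv(paths["taxonomy"], index=False, encoding="utf-8")
    paths["meta"].write_text(
        json.dumps(
            {
                "collection_window": [
                    db.collection_window[0].date().isoformat(),
                    db.collection_window[1].date().isoformat(),
                ]
            },
            indent=0,
        )
        + "\n"
    )
    return paths


# ---------------------------------------------------------------------------
# Internal helpers
# ---------------------------------------------------------------------------


def _coerce_window(window: tuple | None) -> tuple[pd.Timestamp, pd.Timestamp]:
    if window is None:
        return DEFAULT_COLLECTION_WINDOW
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if start > end:
        raise DatabaseError(f"collection window start {start.date()} after end {end.date()}")
    return (start, end)


def _check_columns(df: pd.DataFrame, required: list[str], table: str) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing}")
    return df[required]


def _parse_dates(col: pd.Series, name: str, allow_missing: bool = False) -> pd.Series:
    raw = col.replace("", pd.NA)
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    bad = raw.notna() & parsed.isna()
    if bad.any():
        lines = [int(i) + 2 for i in col.index[bad][:10]]
        raise DateParseError(f"{name}: unparseable ISO dates at line(s) {lines}")
    if not allow_missing and raw.isna().any():
        lines = [int(i) + 2 for i in col.index[raw.isna()][:10]]
        raise DateParseError(f"{name}: missing required dates at line(s) {lines}")
    return parsed


def _check_ids(col: pd.Series, known: set, name: str) -> None:
    bad = ~col.isin(known)
    if bad.any():
        lines = [int(i) + 2 for i in col.index[bad][:10]]
        raise IntegrityError(
            f"{name}: unknown person id(s) {sorted(set(col[bad]))[:10]} at line(s) {lines}"
        )


def _check_in_window(col: pd.Series, window: tuple, name: str) -> None:
    bad = (col < window[0]) | (col > window[1])
    if bad.any():
        lines = [int(i) + 2 for i in col.index[bad][:10]]
        raise IntegrityError(
            f"{name}: dates outside collection window "
            f"{window[0].date()}..{window[1].date()} at line(s) {lines}"
        )


def _parse_bool(v: str, where: str) -> bool:
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise TaxonomyError(f"{where}: cannot parse boolean {v!r}")
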