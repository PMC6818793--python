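"""The twelve predictor variables computed for each notification.

Four event-based variables use only the focal child's own event history
strictly before the notification date ``T`` (the "recent" variants restrict
to the last two calendar years).  Network variables count members of the
child's family network under recorded (``*R``) and whole-life (``*W``)
semantics:

* ``nNeighsR`` — recorded network size (adults and children).  The
  whole-life network *size* is deliberately never emitted: it reflects who
  happens to be in the registry rather than family structure, a known data
  collection bias.
* ``nWithNotes*`` / ``nWithTarget*`` — members who are themselves children
  (under 16 completed years at ``T``) with at least one notification /
  target event strictly before ``T``.
* ``nAbusers*`` — members (adults or children) recorded as the instigator of
  at least one abusive relationship — with anyone — before ``T``.

Membership may be backdated (whole-life semantics) but member attributes
never are: events after ``T`` and abusive rows recorded after ``T`` are
invisible, under both semantics.  Counts of prior referral decisions, and
gender/ethnicity, are excluded as predictors by design.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import Notification, add_years, completed_years
from .data_model import TARGET_EVENT_TYPES
from .networks import FamilyNetwork, recorded_network, whole_life_network

logger = logging.getLogger("kinrisk")

EVENT_FEATURES = ["nNotes", "nTargets", "nNotesRecent", "nTargetsRecent"]
RECORDED_FEATURES = ["nNeighsR", "nWithNotesR", "nWithTargetR", "nAbusersR"]
WHOLE_LIFE_FEATURES = ["nWithNotesW", "nWithTargetW", "nAbusersW"]

#: All twelve predictors, in canonical column order.
FEATURE_NAMES = ["age"] + EVENT_FEATURES + RECORDED_FEATURES + WHOLE_LIFE_FEATURES

ID_COLUMNS = ["child_id", "seq", "date", "ec"]

#: Completed-years cutoff below which a network member counts as a child for
#: the nWithNotes*/nWithTarget* variables; matches the sample's age filter.
CHILD_AGE_LIMIT = 16


def event_features(db, notification: Notification, recent_years: int = 2) -> dict[str, int]:
    """The four event-based counts for one notification (child's own events
    strictly before ``T``; the index notification itself is excluded)."""
    t = pd.Timestamp(notification.date)
    t_recent = add_years(t, -recent_years)
    ev = db.events_for(notification.child_id)
    notes = ev[(ev["event_type"] == "notification") & (ev["date"] < t)]
    targets = ev[ev["event_type"].isin(TARGET_EVENT_TYPES) & (ev["date"] < t)]
    return {
        "nNotes": int(len(notes)),
        "nTargets": int(len(targets)),
        "nNotesRecent": int((notes["date"] >= t_recent).sum()),
        "nTargetsRecent": int((targets["date"] >= t_recent).sum()),
    }


def network_features(
    db,
    notification: Notification,
    recorded: FamilyNetwork,
    whole_life: FamilyNetwork,
) -> dict[str, int]:
    """The seven network counts for one notification, given the two networks
    computed at the notification's date."""
    t = pd.Timestamp(notification.date)
    if pd.Timestamp(recorded.as_of) != t or pd.Timestamp(whole_life.as_of) != t:
        raise ValueError("networks must be computed at the notification date")

    def attrs(member: str) -> tuple[bool, bool, bool]:
        """(is child with prior note, is child with prior target, is abuser)."""
        dob = db.person_dob(member)
        is_child = dob is not None and _age_at(t, dob) < CHILD_AGE_LIMIT
        ev = db.events_for(member)
        ev = ev[ev["date"] < t]
        has_note = bool((ev["event_type"] == "notification").any())
        has_target = bool(ev["event_type"].isin(TARGET_EVENT_TYPES).any())
        rel = db.relationships
        abusive = rel[rel["type_code"].isin(db.taxonomy.abusive_codes)]
        inst_subject = abusive["type_code"].map(db.taxonomy.instigator_role) == "subject"
        instigator = abusive["subject_id"].where(inst_subject, abusive["object_id"])
        is_abuser = bool(
            ((instigator == member) & (abusive["recorded_date"] < t)).any()
        )
        return is_child and has_note, is_child and has_target, is_abuser

    out = {k: 0 for k in RECORDED_FEATURES + WHOLE_LIFE_FEATURES}
    out["nNeighsR"] = len(recorded)
    for m in recorded.members:
        note, target, abuser = attrs(m)
        out["nWithNotesR"] += note
        out["nWithTargetR"] += target
        out["nAbusersR"] += abuser
    for m in whole_life.members:
        note, target, abuser = attrs(m)
        out["nWithNotesW"] += note
        out["nWithTargetW"] += target
        out["nAbusersW"] += abuser
    return {k: int(v) for k, v in out.items()}


def case_features(db, notification: Notification) -> dict[str, int]:
    """All twelve predictors for one notification (reference path; the bulk
    path is :func:`feature_matrix`)."""
    rec = recorded_network(db, notification.child_id, notification.date)
    wl = whole_life_network(db, notification.child_id, notification.date)
    out = {"age": int(notification.age_years)}
    out.update(event_features(db, notification))
    out.update(network_features(db, notification, rec, wl))
    return out


# ---------------------------------------------------------------------------
# Bulk path
# ---------------------------------------------------------------------------


def feature_matrix(db, cases: pd.DataFrame, recent_years: int = 2) -> pd.DataFrame:
    """One row per eligible labelled case: identifiers, the twelve
    predictors, and ``ec``; rows ordered by (child_id, seq); counts default
    to 0 (no missing values).  Pure function of its inputs.

    Vectorised equivalent of calling :func:`case_features` per row.
    """
    cases = cases[cases["eligible"]] if "eligible" in cases.columns else cases
    if cases.empty:
        return pd.DataFrame(columns=ID_COLUMNS + FEATURE_NAMES)
    cases = cases.sort_values(["child_id", "seq"], kind="mergesort").reset_index(drop=True)
    key = pd.RangeIndex(len(cases))
    base = pd.DataFrame(
        {
            "_key": key,
            "child_id": cases["child_id"].to_numpy(),
            "date": cases["date"].to_numpy(),
        }
    )
    base["_t_recent"] = add_years(base["date"], -recent_years)

    out = pd.DataFrame(index=key)
    out["age"] = cases["age_years"].astype(int).to_numpy()

    # --- event features: child's own prior events -------------------------
    ev = db.events[["person_id", "event_type", "date"]]
    own = base.merge(ev, left_on="child_id", right_on="person_id", suffixes=("", "_ev"))
    prior = own[own["date_ev"] < own["date"]]
    is_note = prior["event_type"] == "notification"
    is_target = prior["event_type"].isin(TARGET_EVENT_TYPES)
    recent = prior["date_ev"] >= prior["_t_recent"]
    for name, mask in [
        ("nNotes", is_note),
        ("nTargets", is_target),
        ("nNotesRecent", is_note & recent),
        ("nTargetsRecent", is_target & recent),
    ]:
        out[name] = prior.loc[mask].groupby("_key").size().reindex(key, fill_value=0)

    # --- network membership ----------------------------------------------
    rel = db.relationships
    fwd = rel[["subject_id", "object_id", "type_code", "recorded_date"]].rename(
        columns={"subject_id": "pid", "object_id": "other"}
    )
    bwd = rel[["subject_id", "object_id", "type_code", "recorded_date"]].rename(
        columns={"object_id": "pid", "subject_id": "other"}
    )
    edges = pd.concat([fwd, bwd], ignore_index=True)
    touch = base.merge(edges, left_on="child_id", right_on="pid")

    dob = db.persons.set_index("person_id")["dob"]
    members_r = touch[touch["recorded_date"] < touch["date"]].drop_duplicates(
        ["_key", "other"]
    )

    wl = touch[touch["type_code"].isin(db.taxonomy.whole_life_codes)].copy()
    child_dob = wl["child_id"].map(dob)
    other_dob = wl["other"].map(dob)
    effective = other_dob.where(other_dob > child_dob, child_dob)
    ok = child_dob.notna() & other_dob.notna() & (effective <= wl["date"])
    members_w = wl[ok].drop_duplicates(["_key", "other"])

    attr = _member_attributes(db)

    for members, neigh_col, cols in [
        (members_r, "nNeighsR", ("nWithNotesR", "nWithTargetR", "nAbusersR")),
        (members_w, None, ("nWithNotesW", "nWithTargetW", "nAbusersW")),
    ]:
        m = members.merge(attr, how="left", left_on="other", right_index=True)
        if neigh_col:
            out[neigh_col] = m.groupby("_key").size().reindex(key, fill_value=0)
        age_m = completed_years(m["date"], m["member_dob"])
        is_child = age_m.notna() & (age_m < CHILD_AGE_LIMIT)
        with_note = is_child & (m["first_note"] < m["date"])
        with_target = is_child & (m["first_target"] < m["date"])
        abuser = m["first_abuse_recorded"] < m["date"]
        for name, mask in zip(cols, (with_note, with_target, abuser)):
            out[name] = m.loc[mask].groupby("_key").size().reindex(key, fill_value=0)

    for name in FEATURE_NAMES:
        out[name] = out[name].astype(int)

    result = pd.concat(
        [cases[["child_id", "seq", "date", "ec"]].reset_index(drop=True), out[FEATURE_NAMES]],
        axis=1,
    )
    return result


def _member_attributes(db) -> pd.DataFrame:
    """Per-person attribute dates: dob, first notification, first target
    event, and first recorded abusive-instigation row."""
    ev = db.events
    first_note = (
        ev[ev["event_type"] == "notification"].groupby("person_id")["date"].min()
    )
    first_target = (
        ev[ev["event_type"].isin(TARGET_EVENT_TYPES)].groupby("person_id")["date"].min()
    )
    rel = db.relationships
    abusive = rel[rel["type_code"].isin(db.taxonomy.abusive_codes)]
    if len(abusive):
        role = abusive["type_code"].map(db.taxonomy.instigator_role)
        instigator = abusive["subject_id"].where(role == "subject", abusive["object_id"])
        first_abuse = abusive.groupby(instigator)["recorded_date"].min()
    else:
        first_abuse = pd.Series(dtype="datetime64[ns]")
    attr = pd.DataFrame(
        {
            "member_dob": db.persons.set_index("person_id")["dob"],
            "first_note": first_note,
            "first_target": first_target,
            "first_abuse_recorded": first_abuse,
        }
    )
    return attr


def _age_at(t: pd.Timestamp, dob: pd.Timestamp) -> int:
    return t.year - dob.year - ((t.month, t.day) < (dob.month, dob.day))
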