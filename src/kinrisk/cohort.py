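"""Notification-level analysis table: sample filters and outcome labelling.

The unit of analysis is a *notification* — a report to child protection
services about one child.  Each notification row is indexed (child ``i``,
lifetime sequence ``j``, date ``T``).  The binary response, *estimated
concern* (``EC``), is 1 iff any of the following occurs in the two years
after the notification: (i) a substantiated finding of maltreatment; (ii) a
family group conference or family agreement; (iii) a referral decision at a
subsequent notification.

Window conventions (applied identically by the feature module, mirrored
backwards): "prior to T" means strictly before ``T``; the follow-up window is
``(T, T + followup_years calendar years]`` — right-closed, so the index
notification's own same-day records fall in neither past nor future.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger("kinrisk")

#: Default event-inclusion window for the analysis sample.
DEFAULT_EVENT_WINDOW = (pd.Timestamp("2006-01-01"), pd.Timestamp("2013-12-31"))

#: Event types that can flip estimated concern to 1, with rule priority used
#: only to break same-day ties when reporting which rule fired first.
QUALIFYING_RULES = {
    "substantiated_finding": (1, "substantiated finding"),
    "family_group_conference": (2, "family group conference/agreement"),
    "family_agreement": (2, "family group conference/agreement"),
    "referral_decision": (3, "referral decision at subsequent notification"),
}

NOTIFICATION_COLUMNS = ["child_id", "seq", "date", "age_years", "eligible", "reason"]


@dataclass(frozen=True)
class Notification:
    """One analysis row: child ``i`` at their ``seq``-th lifetime
    notification, dated ``T``."""

    child_id: str
    seq: int
    date: pd.Timestamp
    age_years: int | None
    eligible: bool
    reason: str | None = None


@dataclass(frozen=True)
class LabelledCase:
    notification: Notification
    ec: int
    qualifying_event: str | None = None


def add_years(ts, years: int):
    """Calendar-year offset (Feb 29 anniversaries land on Feb 28)."""
    return ts + pd.DateOffset(years=years)


def completed_years(t: pd.Series, dob: pd.Series) -> pd.Series:
    """Completed (floored) years of age at ``t`` for vector inputs; NA where
    dob is missing."""
    age = t.dt.year - dob.dt.year - (
        (t.dt.month < dob.dt.month)
        | ((t.dt.month == dob.dt.month) & (t.dt.day < dob.dt.day))
    ).astype(int)
    return age.where(dob.notna())


def assemble_notifications(
    db,
    event_window: tuple | None = None,
    max_age_years: int = 16,
    followup_years: int = 2,
) -> pd.DataFrame:
    """One row per notification event, with lifetime sequence and eligibility.

    ``seq`` is assigned over *all* of a child's notifications, eligible or
    not, ordered by date (same-day ties broken by event-table row order), so
    that ``j`` counts lifetime notifications.  A notification is eligible iff
    the child's dob is known, the date falls inside ``event_window``, the
    child is under ``max_age_years`` completed years at the date, and the
    follow-up window ends within the registry's collection window.
    Ineligible rows carry the first failing reason.
    """
    if event_window is None:
        event_window = DEFAULT_EVENT_WINDOW
    w0, w1 = pd.Timestamp(event_window[0]), pd.Timestamp(event_window[1])
    notes = db.events[db.events["event_type"] == "notification"].copy()
    if notes.empty:
        return pd.DataFrame(columns=NOTIFICATION_COLUMNS)
    notes = notes.rename(columns={"person_id": "child_id"})
    notes["_row"] = notes.index
    notes = notes.sort_values(["child_id", "date", "_row"], kind="mergesort")
    ties = notes.duplicated(subset=["child_id", "date"], keep=False)
    if ties.any():
        logger.info(
            "%d same-child same-day notification(s); ordered by event-table row order",
            int(ties.sum()),
        )
    notes["seq"] = notes.groupby("child_id").cumcount() + 1

    dob = db.persons.set_index("person_id")["dob"]
    d = notes["child_id"].map(dob)
    t = notes["date"]
    age = completed_years(t, d)

    followup_end = add_years(t, followup_years)
    reason = pd.Series(None, index=notes.index, dtype=object)
    ok = pd.Series(True, index=notes.index)

    def fail(mask, label):
        nonlocal ok
        m = mask & ok
        reason[m] = label
        ok &= ~mask

    fail(d.isna(), "missing dob")
    fail((t < w0) | (t > w1), "window")
    fail(age.notna() & (age >= max_age_years), "age")
    fail(followup_end > db.collection_window[1], "incomplete follow-up")

    out = pd.DataFrame(
        {
            "child_id": notes["child_id"].to_numpy(),
            "seq": notes["seq"].to_numpy(),
            "date": notes["date"].to_numpy(),
            "age_years": age.astype("Int64").to_numpy(),
            "eligible": ok.to_numpy(),
            "reason": reason.to_numpy(),
        }
    )
    logger.info(
        "assembled %d notifications for %d children (%d eligible)",
        len(out),
        out["child_id"].nunique(),
        int(out["eligible"].sum()),
    )
    return out.reset_index(drop=True)


def estimated_concern(db, notification: Notification, followup_years: int = 2) -> LabelledCase:
    """Label one eligible notification by scanning the child's events.

    ``ec = 1`` iff a qualifying event (see :data:`QUALIFYING_RULES`) falls in
    ``(T, T + followup_years]``; ``qualifying_event`` names the earliest
    firing rule.
    """
    if not notification.eligible:
        raise ValueError(
            f"notification {notification.child_id} seq={notification.seq} is ineligible "
            f"({notification.reason}); estimated concern is defined for eligible rows"
        )
    t = pd.Timestamp(notification.date)
    t_end = add_years(t, followup_years)
    ev = db.events_for(notification.child_id)
    ev = ev[ev["event_type"].isin(QUALIFYING_RULES) & (ev["date"] > t) & (ev["date"] <= t_end)]
    if ev.empty:
        return LabelledCase(notification, 0, None)
    ranks = ev["event_type"].map(lambda k: QUALIFYING_RULES[k][0])
    ev = ev.assign(_rank=ranks).sort_values(["date", "_rank"], kind="mergesort")
    first = ev.iloc[0]
    desc = (
        f"{QUALIFYING_RULES[first['event_type']][1]} "
        f"({first['event_type']}@{first['date'].date().isoformat()})"
    )
    return LabelledCase(notification, 1, desc)


def label_notifications(db, notifications: pd.DataFrame, followup_years: int = 2) -> pd.DataFrame:
    """Vectorised labelling of all eligible notifications.

    Returns the eligible rows of ``notifications`` with ``ec`` and
    ``qualifying_event`` columns appended; agrees row-for-row with
    :func:`estimated_concern`.
    """
    cases = notifications[notifications["eligible"]].copy()
    if cases.empty:
        out = notifications.head(0).copy()
        out["ec"] = pd.Series(dtype=int)
        out["qualifying_event"] = pd.Series(dtype=object)
        return out
    cases["_key"] = range(len(cases))
    cases["_t_end"] = add_years(cases["date"], followup_years)

    q = db.events[db.events["event_type"].isin(QUALIFYING_RULES)].copy()
    q["_rank"] = q["event_type"].map(lambda k: QUALIFYING_RULES[k][0])
    merged = cases[["_key", "child_id", "date", "_t_end"]].merge(
        q, left_on="child_id", right_on="person_id", suffixes=("", "_ev")
    )
    inside = merged[(merged["date_ev"] > merged["date"]) & (merged["date_ev"] <= merged["_t_end"])]
    inside = inside.sort_values(["_key", "date_ev", "_rank"], kind="mergesort")
    firing = inside.drop_duplicates("_key", keep="first").set_index("_key")

    ec = cases["_key"].isin(firing.index).astype(int)
    desc = cases["_key"].map(
        firing.apply(
            lambda r: (
                f"{QUALIFYING_RULES[r['event_type']][1]} "
                f"({r['event_type']}@{r['date_ev'].date().isoformat()})"
            ),
            axis=1,
        )
        if len(firing)
        else pd.Series(dtype=object)
    )
    out = cases.drop(columns=["_key", "_t_end"])
    out["ec"] = ec.to_numpy()
    out["qualifying_event"] = desc.to_numpy()
    logger.info("labelled %d cases; EC=1 rate %.3f", len(out), out["ec"].mean())
    return out.reset_index(drop=True)


def split_subsamples(cases: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """The three analysis subsamples: all notifications, first notifications
    (j = 1) and subsequent notifications (j > 1)."""
    return {
        "all": cases,
        "first": cases[cases["seq"] == 1].reset_index(drop=True),
        "subsequent": cases[cases["seq"] > 1].reset_index(drop=True),
    }


def notification_from_row(row) -> Notification:
    """Build a :class:`Notification` from one assembled table row."""
    age = row["age_years"]
    return Notification(
        child_id=row["child_id"],
        seq=int(row["seq"]),
        date=pd.Timestamp(row["date"]),
        age_years=None if pd.isna(age) else int(age),
        eligible=bool(row["eligible"]),
        reason=row["reason"] if isinstance(row["reason"], str) else None,
    )
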