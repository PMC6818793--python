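"""Shared fixtures and independent oracles.

The oracles here are deliberately naive (plain-Python scans and pair
enumeration) so they stay independent of the vectorised implementation
paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import kinrisk as kr
from kinrisk.synthetic_data import override


# ---------------------------------------------------------------------------
# Random adversarial databases (unstructured, unlike the generator's output)
# ---------------------------------------------------------------------------

WINDOW = (pd.Timestamp("1996-01-01"), pd.Timestamp("2016-12-31"))


def random_database(seed: int, n_persons: int = 120, n_rel: int = 600, n_events: int = 400):
    """A random registry with arbitrary relationship structure: whole-life,
    abusive and other rows thrown between random person pairs, some persons
    without dobs (never linked by whole-life rows)."""
    rng = np.random.default_rng(seed)
    tax = kr.default_taxonomy()
    codes = sorted(tax.entries)
    ids = [f"R{i:04d}" for i in range(n_persons)]
    dob_days = rng.integers(0, 365 * 40, size=n_persons)  # born 1970..2010
    dobs = pd.Timestamp("1970-01-01") + pd.to_timedelta(dob_days, unit="D")
    no_dob = set(rng.choice(n_persons, size=n_persons // 10, replace=False))

    wl_codes = tax.whole_life_codes
    rel_rows = []
    seen = set()
    while len(rel_rows) < n_rel:
        a, b = rng.integers(0, n_persons, size=2)
        if a == b:
            continue
        code = codes[rng.integers(0, len(codes))]
        if code in wl_codes and (a in no_dob or b in no_dob):
            code = "household_member"
        rec = WINDOW[0] + pd.Timedelta(days=int(rng.integers(0, 7665)))
        key = (ids[a], ids[b], code, rec)
        if key in seen:
            continue
        seen.add(key)
        rel_rows.append(
            kr.Relationship(subject_id=ids[a], object_id=ids[b], type_code=code, recorded_date=rec)
        )

    etypes = sorted(kr.data_model.EVENT_TYPES)
    ev_rows = [
        kr.Event(
            person_id=ids[int(rng.integers(0, n_persons))],
            event_type=etypes[int(rng.integers(0, len(etypes)))],
            date=WINDOW[0] + pd.Timedelta(days=int(rng.integers(0, 7665))),
        )
        for _ in range(n_events)
    ]
    persons = [
        kr.Person(
            person_id=ids[i],
            dob=None if i in no_dob else dobs[i],
            gender="F" if rng.random() < 0.5 else "M",
            ethnicity_group=f"group_{'abc'[int(rng.integers(0, 3))]}",
        )
        for i in range(n_persons)
    ]
    return kr.CPSDatabase.from_records(persons, rel_rows, ev_rows, collection_window=WINDOW)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def oracle_recorded_members(db, child_id, as_of) -> set:
    """Linear scan over all relationship rows with a date filter."""
    out = set()
    as_of = pd.Timestamp(as_of)
    for row in db.relationships.itertuples(index=False):
        if row.recorded_date < as_of:
            if row.subject_id == child_id:
                out.add(row.object_id)
            elif row.object_id == child_id:
                out.add(row.subject_id)
    return out


def oracle_whole_life_members(db, child_id, as_of) -> set:
    """Brute-force enumeration over whole-life rows with dob comparison."""
    out = set()
    as_of = pd.Timestamp(as_of)
    wl = db.taxonomy.whole_life_codes
    dob = {p.person_id: p.dob for p in db.persons.itertuples(index=False)}
    for row in db.relationships.itertuples(index=False):
        if row.type_code not in wl:
            continue
        if row.subject_id == child_id:
            other = row.object_id
        elif row.object_id == child_id:
            other = row.subject_id
        else:
            continue
        d1, d2 = dob.get(child_id), dob.get(other)
        if pd.isna(d1) or pd.isna(d2):
            continue
        if max(d1, d2) <= as_of:
            out.add(other)
    return out


def oracle_auc(labels, scores) -> float:
    """Exhaustive pair counting: P(random positive outscores random
    negative), ties counting half."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_bernoulli_loglik(X, y, beta) -> float:
    """Independently coded likelihood evaluation (per-case loop)."""
    import math

    total = 0.0
    for xi, yi in zip(np.atleast_2d(X), y):
        eta = beta[0] + float(np.dot(xi, beta[1:]))
        p = 1.0 / (1.0 + math.exp(-eta))
        total += math.log(p) if yi == 1 else math.log(1.0 - p)
    return total


def oracle_gini_threshold(x, y):
    """Exhaustive midpoint enumeration scored by Gini gain (plain loops)."""
    xs = sorted(set(x))
    n = len(x)

    def gini(labels):
        if not labels:
            return 0.0
        p = sum(labels) / len(labels)
        return 2.0 * p * (1.0 - p)

    parent = gini(list(y))
    best_t, best_dec = None, -1.0
    for a, b in zip(xs[:-1], xs[1:]):
        c = (a + b) / 2.0
        left = [yi for xi, yi in zip(x, y) if xi <= c]
        right = [yi for xi, yi in zip(x, y) if xi > c]
        dec = parent - (len(left) * gini(left) + len(right) * gini(right)) / n
        if dec > best_dec + 1e-12:  # strict improvement: ties keep smaller c
            best_t, best_dec = c, dec
    return best_t, best_dec


def oracle_estimated_concern(db, child_id, t, followup_years=2):
    """Direct window scan over every event row."""
    from dateutil.relativedelta import relativedelta

    t = pd.Timestamp(t)
    t_end = t + relativedelta(years=followup_years)
    qualifying = {
        "substantiated_finding",
        "family_group_conference",
        "family_agreement",
        "referral_decision",
    }
    for row in db.events.itertuples(index=False):
        if row.person_id != child_id or row.event_type not in qualifying:
            continue
        if t < row.date <= pd.Timestamp(t_end):
            return 1
    return 0


# ---------------------------------------------------------------------------
# Session fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_scenario_db():
    """A moderate censored-recording registry shared across tests."""
    cfg = override(kr.scenario("censored_recording", seed=7), n_families=400)
    db, truth = kr.generate_with_truth(cfg)
    return db, truth


@pytest.fixture(scope="session")
def small_feature_table(small_scenario_db):
    db, _ = small_scenario_db
    notes = kr.assemble_notifications(db)
    cases = kr.label_notifications(db, notes)
    return db, kr.feature_matrix(db, cases)


@pytest.fixture()
def tiny_db():
    """Hand-built family: mother M1, father F1, children C1 (b. 2000) and
    C2 (b. 2010), abusive row F1→M1, events on C1."""
    persons = [
        kr.Person("C1", pd.Timestamp("2000-06-15")),
        kr.Person("C2", pd.Timestamp("2010-03-01")),
        kr.Person("F1", pd.Timestamp("1975-01-01"), gender="M"),
        kr.Person("M1", pd.Timestamp("1978-05-20"), gender="F"),
    ]
    rels = [
        kr.Relationship("M1", "C1", "parent_child", pd.Timestamp("2007-01-10")),
        kr.Relationship("F1", "C1", "parent_child", pd.Timestamp("2007-01-10")),
        kr.Relationship("M1", "C2", "parent_child", pd.Timestamp("2012-08-01")),
        kr.Relationship("C1", "C2", "sibling", pd.Timestamp("2012-08-01")),
        kr.Relationship("F1", "M1", "physically_abused", pd.Timestamp("2005-03-03")),
    ]
    events = [
        kr.Event("C1", "notification", pd.Timestamp("2006-09-01")),
        kr.Event("C1", "referral_decision", pd.Timestamp("2006-09-05")),
        kr.Event("C1", "substantiated_finding", pd.Timestamp("2006-12-01")),
        kr.Event("C1", "notification", pd.Timestamp("2008-02-20")),
        kr.Event("C2", "notification", pd.Timestamp("2011-07-01")),
    ]
    return kr.CPSDatabase.from_records(persons, rels, events, collection_window=WINDOW)
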