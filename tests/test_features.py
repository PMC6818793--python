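"""The twelve per-notification predictors: boundary conventions, member
attribute rules, exclusions, and bulk/per-case agreement."""

import pandas as pd

import kinrisk as kr
from kinrisk.features import case_features

from conftest import WINDOW


def _note(child, date, seq=1, age=6):
    return kr.Notification(child, seq, pd.Timestamp(date), age, True)


class TestEventFeatures:
    def test_first_notification_has_all_zero_event_features(self, tiny_db):
        f = kr.event_features(tiny_db, _note("C1", "2006-09-01"))
        assert f == {"nNotes": 0, "nTargets": 0, "nNotesRecent": 0, "nTargetsRecent": 0}

    def test_recent_window_is_two_calendar_years_left_closed(self):
        db = kr.CPSDatabase.from_records(
            [kr.Person("C1", pd.Timestamp("2000-06-15"))],
            [],
            [
                kr.Event("C1", "notification", pd.Timestamp("2007-09-10")),  # T - 30 months
                kr.Event("C1", "notification", pd.Timestamp("2010-03-01")),  # T - 10 days
                kr.Event("C1", "notification", pd.Timestamp("2008-03-11")),  # exactly T - 2y
            ],
            collection_window=WINDOW,
        )
        f = kr.event_features(db, _note("C1", "2010-03-11"))
        assert f["nNotes"] == 3
        assert f["nNotesRecent"] == 2  # boundary day T-2y is inside [T-2y, T)

    def test_event_exactly_at_t_is_excluded(self):
        db = kr.CPSDatabase.from_records(
            [kr.Person("C1", pd.Timestamp("2000-06-15"))],
            [],
            [kr.Event("C1", "intervention", pd.Timestamp("2010-03-11"))],
            collection_window=WINDOW,
        )
        f = kr.event_features(db, _note("C1", "2010-03-11"))
        assert f["nTargets"] == 0 and f["nTargetsRecent"] == 0

    def test_event_features_ignore_relationship_table(self, tiny_db):
        stripped = kr.CPSDatabase(
            tiny_db.persons,
            tiny_db.relationships.iloc[0:0],
            tiny_db.events,
            tiny_db.collection_window,
            tiny_db.taxonomy,
        )
        note = _note("C1", "2009-01-01")
        assert kr.event_features(tiny_db, note) == kr.event_features(stripped, note)


class TestNetworkFeatures:
    def test_empty_networks_give_zero_counts(self, tiny_db):
        t = "2006-01-01"  # before anything is recorded
        rec = kr.recorded_network(tiny_db, "C1", t)
        f = kr.network_features(
            tiny_db,
            _note("C1", t),
            rec,
            kr.FamilyNetwork("C1", pd.Timestamp(t), "whole_life", frozenset()),
        )
        assert all(v == 0 for v in f.values())

    def test_mixed_membership_example(self):
        """An adult abuser and a child with a prior notification in the
        recorded network: network size counts both, note counts only the
        child, abuser counts only the adult."""
        persons = [
            kr.Person("C1", pd.Timestamp("2004-01-01")),
            kr.Person("K1", pd.Timestamp("2006-01-01")),  # child member
            kr.Person("A1", pd.Timestamp("1980-01-01")),  # adult abuser
            kr.Person("V1", pd.Timestamp("1982-01-01")),
        ]
        t = pd.Timestamp("2010-01-01")
        rels = [
            kr.Relationship("A1", "C1", "household_member", pd.Timestamp("2008-01-01")),
            kr.Relationship("K1", "C1", "household_member", pd.Timestamp("2008-01-01")),
            kr.Relationship("A1", "V1", "physically_abused", pd.Timestamp("2009-01-01")),
        ]
        events = [kr.Event("K1", "notification", pd.Timestamp("2009-07-01"))]
        db = kr.CPSDatabase.from_records(persons, rels, events, collection_window=WINDOW)
        rec = kr.recorded_network(db, "C1", t)
        wl = kr.whole_life_network(db, "C1", t)
        f = kr.network_features(db, _note("C1", t), rec, wl)
        assert f["nNeighsR"] == 2
        assert f["nWithNotesR"] == 1
        assert f["nAbusersR"] == 1
        assert f["nWithTargetR"] == 0

    def test_member_events_after_t_are_invisible(self, tiny_db):
        """C1's substantiated finding happens 2006-12-01; at an earlier T the
        whole-life member C1 contributes nothing to C2's counts — events are
        never backdated."""
        t = pd.Timestamp("2010-06-01")  # C2 born, C1 finding already happened
        wl = kr.whole_life_network(tiny_db, "C2", t)
        assert "C1" in wl.members
        f_before = kr.network_features(
            tiny_db,
            _note("C2", "2010-06-01", age=0),
            kr.recorded_network(tiny_db, "C2", t),
            wl,
        )
        assert f_before["nWithTargetW"] == 1  # finding was 2006, before T
        # same structure but the finding happens only after T
        t2 = pd.Timestamp("2010-06-01")
        shifted = kr.CPSDatabase.from_records(
            [kr.Person(r.person_id, r.dob) for r in tiny_db.persons.itertuples(index=False)],
            [],
            [kr.Event("C1", "substantiated_finding", pd.Timestamp("2011-01-01"))],
            collection_window=WINDOW,
        )
        wl2 = kr.FamilyNetwork("C2", t2, "whole_life", frozenset({"C1"}))
        rec2 = kr.FamilyNetwork("C2", t2, "recorded", frozenset())
        f_after = kr.network_features(shifted, _note("C2", t2, age=0), rec2, wl2)
        assert f_after["nWithTargetW"] == 0

    def test_abuser_status_uses_recording_date_not_backdating(self):
        """A parent's abusive row recorded after T does not count, even
        though the parent is a whole-life member from the child's birth."""
        persons = [
            kr.Person("C1", pd.Timestamp("2005-01-01")),
            kr.Person("P1", pd.Timestamp("1980-01-01")),
            kr.Person("V1", pd.Timestamp("1981-01-01")),
        ]
        rels = [
            kr.Relationship("P1", "C1", "parent_child", pd.Timestamp("2012-01-01")),
            kr.Relationship("P1", "V1", "emotionally_abused", pd.Timestamp("2011-06-01")),
        ]
        db = kr.CPSDatabase.from_records(persons, rels, [], collection_window=WINDOW)
        before = pd.Timestamp("2010-01-01")
        after = pd.Timestamp("2012-06-01")
        wl_b = kr.whole_life_network(db, "C1", before)
        assert "P1" in wl_b.members
        f_b = kr.network_features(db, _note("C1", before), kr.recorded_network(db, "C1", before), wl_b)
        assert f_b["nAbusersW"] == 0  # abuse row recorded 2011, after this T
        wl_a = kr.whole_life_network(db, "C1", after)
        f_a = kr.network_features(db, _note("C1", after), kr.recorded_network(db, "C1", after), wl_a)
        assert f_a["nAbusersW"] == 1

    def test_adult_members_never_count_toward_notes_or_targets(self):
        persons = [
            kr.Person("C1", pd.Timestamp("2004-01-01")),
            kr.Person("P1", pd.Timestamp("1980-01-01")),
        ]
        rels = [kr.Relationship("P1", "C1", "parent_child", pd.Timestamp("2006-01-01"))]
        events = [
            kr.Event("P1", "notification", pd.Timestamp("2007-01-01")),
            kr.Event("P1", "intervention", pd.Timestamp("2007-06-01")),
        ]
        db = kr.CPSDatabase.from_records(persons, rels, events, collection_window=WINDOW)
        t = pd.Timestamp("2010-01-01")
        f = kr.network_features(
            db, _note("C1", t), kr.recorded_network(db, "C1", t), kr.whole_life_network(db, "C1", t)
        )
        assert f["nNeighsR"] == 1  # the adult is in the network
        assert f["nWithNotesR"] == 0 and f["nWithTargetW"] == 0  # but is not a child


class TestFeatureMatrix:
    def test_empty_cohort_yields_full_header(self, tiny_db):
        out = kr.feature_matrix(tiny_db, pd.DataFrame(columns=["child_id", "seq", "date",
                                                               "age_years", "eligible", "ec"]))
        assert list(out.columns) == ["child_id", "seq", "date", "ec"] + kr.FEATURE_NAMES
        assert len(out) == 0

    def test_row_count_and_determinism(self, small_feature_table):
        db, table = small_feature_table
        notes = kr.assemble_notifications(db)
        cases = kr.label_notifications(db, notes)
        assert len(table) == len(cases)
        again = kr.feature_matrix(db, cases)
        pd.testing.assert_frame_equal(table, again)

    def test_bulk_path_agrees_with_per_case_functions(self, small_feature_table):
        db, table = small_feature_table
        sample = table.sample(n=min(40, len(table)), random_state=3)
        for _, row in sample.iterrows():
            note = kr.Notification(row["child_id"], int(row["seq"]), pd.Timestamp(row["date"]),
                                   int(row["age"]), True)
            expected = case_features(db, note)
            for name in kr.FEATURE_NAMES:
                assert row[name] == expected[name], (name, note)

    def test_excluded_predictors_never_appear(self, small_feature_table):
        _, table = small_feature_table
        banned = {"gender", "ethnicity_group", "nNeighsW", "nReferrals", "nWithContactW"}
        assert banned.isdisjoint(table.columns)
        assert len(kr.FEATURE_NAMES) == 12

    def test_invariants_hold_on_generated_cohort(self, small_feature_table):
        _, t = small_feature_table
        assert (t[kr.FEATURE_NAMES] >= 0).all().all()
        assert (t["nNotesRecent"] <= t["nNotes"]).all()
        assert (t["nTargetsRecent"] <= t["nTargets"]).all()
        for c in ("nWithNotesR", "nWithTargetR", "nAbusersR"):
            assert (t[c] <= t["nNeighsR"]).all()
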