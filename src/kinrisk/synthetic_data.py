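"""Synthetic child-protection registries with known ground truth.

Real child-protection registries are confidential, so every downstream stage
of the pipeline is exercised on simulated databases that reproduce the
*statistical structure* the analysis depends on:

* two-generation family pedigrees (parents, step-parents, siblings,
  half-siblings) plus non-family adult ties;
* a latent per-family risk score entering all event hazards log-linearly, so
  that children whose family members have prior events carry elevated
  outcome rates — the signal the network features are meant to recover;
* per-child event streams on a discrete daily grid: notifications arrive as
  daily Bernoulli draws, and referral decisions, substantiated findings,
  family group conferences/agreements and interventions follow individual
  notifications with risk-dependent probabilities and short delays.  The
  family's first event of any kind is therefore always a notification;
* a recording-censorship process: each family relationship row is *real*
  from the birth of its younger member, but its ``recorded_date`` — the only
  timestamp the registry keeps — tends to postdate the family's first target
  event, emulating services that only map a family after a serious event.
  Whole-life backdating exists to undo exactly this censoring;
* optional uniform date-of-birth jitter (up to 7 days) emulating
  anonymisation noise.

The generator also emits ground-truth side tables (latent risks, the true
pedigree with effective dates) for test oracles only; the analysis pipeline
never reads them.

Defaults are chosen for statistical power at roughly 20,000 children, not for
demographic realism of any particular jurisdiction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    CPSDatabase,
    DEFAULT_COLLECTION_WINDOW,
    TARGET_EVENT_TYPES,
    default_taxonomy,
)

class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic registry, with power-oriented defaults.

    Rates are per child-year unless stated; the latent family risk ``z`` is
    Normal(0, ``latent_risk_sd``) and multiplies hazards by
    ``exp(effect * z)`` and per-notification response probabilities on the
    log-odds scale.
    """

    n_families: int = 7000
    mean_children_per_family: float = 2.8
    max_children_per_family: int = 8
    two_parent_prob: float = 0.75
    step_parent_prob: float = 0.2
    half_sibling_prob: float = 0.25
    birth_window: tuple = ("1996-01-01", "2013-12-31")
    collection_window: tuple = DEFAULT_COLLECTION_WINDOW
    # latent risk and its effects
    latent_risk_sd: float = 1.0
    risk_effect_notification: float = 0.8
    risk_effect_response: float = 0.8
    # event process
    notification_rate_per_year: float = 0.15
    age_rate_decay: float = 0.04
    referral_prob: float = 0.30
    substantiation_prob: float = 0.12
    conference_prob: float = 0.06
    agreement_prob: float = 0.06
    intervention_prob: float = 0.08
    max_event_age_years: int = 17
    # abusive relationships (adult instigators)
    abusive_edge_base_prob: float = 0.04
    abusive_edge_risk_effect: float = 1.0
    # recording model
    p_record_before_target: float = 0.2
    record_delay_mean_days: float = 365.0
    ethnicity_censoring: dict | None = None
    # demography / anonymisation
    ethnicity_probs: tuple = (("group_a", 0.5), ("group_b", 0.3), ("group_c", 0.2))
    dob_jitter_days: int = 0
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "two_parent_prob": self.two_parent_prob,
            "step_parent_prob": self.step_parent_prob,
            "half_sibling_prob": self.half_sibling_prob,
            "referral_prob": self.referral_prob,
            "substantiation_prob": self.substantiation_prob,
            "conference_prob": self.conference_prob,
            "agreement_prob": self.agreement_prob,
            "intervention_prob": self.intervention_prob,
            "abusive_edge_base_prob": self.abusive_edge_base_prob,
            "p_record_before_target": self.p_record_before_target,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        for name in ("notification_rate_per_year", "record_delay_mean_days", "latent_risk_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_families < 0:
            raise ConfigError("n_families must be >= 0")
        if not 0 <= self.dob_jitter_days <= 7:
            raise ConfigError("dob_jitter_days must be in 0..7")
        b0, b1 = (pd.Timestamp(self.birth_window[0]), pd.Timestamp(self.birth_window[1]))
        c0, c1 = (pd.Timestamp(self.collection_window[0]), pd.Timestamp(self.collection_window[1]))
        if b0 > b1:
            raise ConfigError("birth_window start after end")
        if b0 < c0 or b1 > c1:
            raise ConfigError(
                f"birth_window {b0.date()}..{b1.date()} outside collection window "
                f"{c0.date()}..{c1.date()}"
            )
        if self.ethnicity_censoring:
            for k, v in self.ethnicity_censoring.items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"ethnicity_censoring[{k!r}]={v} outside [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["birth_window"] = [str(pd.Timestamp(x).date()) for x in self.birth_window]
        d["collection_window"] = [str(pd.Timestamp(x).date()) for x in self.collection_window]
        d["ethnicity_probs"] = [list(t) for t in self.ethnicity_probs]
        return d


@dataclass
class GroundTruth:
    """Oracle-only side tables: never read by the analysis pipeline."""

    members: pd.DataFrame  # person_id, family_id, role, latent_risk
    pedigree: pd.DataFrame  # subject_id, object_id, type_code, effective_date

    def write(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        m = self.members.copy()
        m.to_csv(d / "members.csv", index=False)
        p = self.pedigree.copy()
        p["effective_date"] = p["effective_date"].dt.strftime("%Y-%m-%d")
        p.to_csv(d / "pedigree.csv", index=False)


SCENARIOS = ("null_risk", "planted_risk", "censored_recording")


def scenario(name: str, seed: int = 0) -> GeneratorConfig:
    """Versioned preset configurations.

    * ``null_risk`` — all latent-risk effects zero: no predictor should carry
      signal and downstream ROC scores sit at 0.5.
    * ``planted_risk`` — positive risk effects with mostly-early recording.
    * ``censored_recording`` — positive risk effects and relationship
      recording almost always deferred until after the family's first target
      event (probability of early recording 0.05), the regime under which
      whole-life backdating pays off.
    """
    if name == "null_risk":
        return GeneratorConfig(
            risk_effect_notification=0.0,
            risk_effect_response=0.0,
            abusive_edge_risk_effect=0.0,
            seed=seed,
        )
    if name == "planted_risk":
        return GeneratorConfig(p_record_before_target=0.9, seed=seed)
    if name == "censored_recording":
        return GeneratorConfig(p_record_before_target=0.05, seed=seed)
    raise ConfigError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate(config: GeneratorConfig) -> CPSDatabase:
    """Generate a validated synthetic registry; see :func:`generate_with_truth`."""
    db, _ = generate_with_truth(config)
    return db


def generate_with_truth(config: GeneratorConfig) -> tuple[CPSDatabase, GroundTruth]:
    """Generate a synthetic registry plus its ground-truth side tables.

    The whole output is a deterministic function of the config (including its
    seed): two runs with equal configs produce equal databases.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    win0, win1 = (
        pd.Timestamp(config.collection_window[0]),
        pd.Timestamp(config.collection_window[1]),
    )
    b0, b1 = pd.Timestamp(config.birth_window[0]), pd.Timestamp(config.birth_window[1])
    taxonomy = default_taxonomy()

    if config.n_families == 0:
        empty_persons = pd.DataFrame(columns=["person_id", "dob", "gender", "ethnicity_group"])
        empty_rel = pd.DataFrame(
            columns=["subject_id", "object_id", "type_code", "recorded_date"]
        )
        empty_ev = pd.DataFrame(columns=["person_id", "event_type", "date"])
        db = CPSDatabase.from_frames(
            empty_persons.astype(str),
            empty_rel.astype(str),
            empty_ev.astype(str),
            taxonomy,
            (win0, win1),
        )
        truth = GroundTruth(
            members=pd.DataFrame(columns=["person_id", "family_id", "role", "latent_risk"]),
            pedigree=pd.DataFrame(
                {
                    "subject_id": pd.Series(dtype=str),
                    "object_id": pd.Series(dtype=str),
                    "type_code": pd.Series(dtype=str),
                    "effective_date": pd.Series(dtype="datetime64[ns]"),
                }
            ),
        )
        return db, truth

    fam = _draw_families(config, rng, b0, b1)
    persons = fam["persons"]
    children = fam["children"]
    rel_rows = fam["relationships"]  # family relationship rows, pre-recording
    z_by_family = fam["latent_risk"]

    events = _draw_events(config, rng, children, z_by_family, win0, win1)
    abusive = _draw_abusive_edges(config, rng, fam, win0, win1)
    recorded = _assign_recorded_dates(
        config, rng, rel_rows, events, fam, win0, win1
    )

    relationships = pd.concat([recorded, abusive], ignore_index=True)

    if config.dob_jitter_days > 0:
        jitter = rng.integers(
            -config.dob_jitter_days, config.dob_jitter_days + 1, size=len(persons)
        )
        persons = persons.copy()
        persons["dob"] = persons["dob"] + pd.to_timedelta(jitter, unit="D")

    persons_out = persons[["person_id", "dob", "gender", "ethnicity_group"]].copy()
    persons_out["dob"] = persons_out["dob"].dt.strftime("%Y-%m-%d")
    rel_out = relationships[["subject_id", "object_id", "type_code", "recorded_date"]].copy()
    rel_out["recorded_date"] = rel_out["recorded_date"].dt.strftime("%Y-%m-%d")
    ev_out = events[["person_id", "event_type", "date"]].copy()
    ev_out["date"] = ev_out["date"].dt.strftime("%Y-%m-%d")

    db = CPSDatabase.from_frames(persons_out, rel_out, ev_out, taxonomy, (win0, win1))
    truth = GroundTruth(
        members=persons[["person_id", "family_id", "role"]]
        .assign(latent_risk=persons["family_id"].map(z_by_family))
        .reset_index(drop=True),
        pedigree=rel_rows[["subject_id", "object_id", "type_code", "effective_date"]]
        .reset_index(drop=True),
    )
    return db, truth


# -- pedigree ---------------------------------------------------------------


def _draw_families(config: GeneratorConfig, rng, b0, b1) -> dict:
    nf = config.n_families
    fam_ids = np.array([f"F{i:05d}" for i in range(nf)])
    z = rng.normal(0.0, config.latent_risk_sd, size=nf)
    n_children = 1 + rng.poisson(max(config.mean_children_per_family - 1.0, 0.0), size=nf)
    n_children = np.minimum(n_children, config.max_children_per_family)
    has_father = rng.random(nf) < config.two_parent_prob
    has_step = rng.random(nf) < config.step_parent_prob
    eth_labels = np.array([e[0] for e in config.ethnicity_probs])
    eth_p = np.array([float(e[1]) for e in config.ethnicity_probs])
    eth_p = eth_p / eth_p.sum()
    fam_eth = eth_labels[rng.choice(len(eth_labels), size=nf, p=eth_p)]

    birth_span = (b1 - b0).days
    person_rows: list[dict] = []
    rel_rows: list[dict] = []
    counter = 0

    def new_id():
        nonlocal counter
        counter += 1
        return f"P{counter:07d}"

    # vectorised child dobs: per family, n_children uniform days, sorted
    for i in range(nf):
        fid = fam_ids[i]
        k = int(n_children[i])
        child_days = np.sort(rng.integers(0, birth_span + 1, size=k))
        child_dobs = [b0 + pd.Timedelta(days=int(d)) for d in child_days]
        first_dob = child_dobs[0]
        mother_age = 20 + 15 * rng.random()
        mother_dob = first_dob - pd.Timedelta(days=int(mother_age * 365.25))
        mother = new_id()
        person_rows.append(
            dict(person_id=mother, dob=mother_dob, gender="F",
                 ethnicity_group=fam_eth[i], family_id=fid, role="mother")
        )
        father = None
        if has_father[i]:
            father = new_id()
            father_dob = first_dob - pd.Timedelta(days=int((20 + 18 * rng.random()) * 365.25))
            person_rows.append(
                dict(person_id=father, dob=father_dob, gender="M",
                     ethnicity_group=fam_eth[i], family_id=fid, role="father")
            )
            rel_rows.append(
                dict(subject_id=mother, object_id=father, type_code="partner_of",
                     effective_date=max(mother_dob, father_dob), family_id=fid)
            )
        step = None
        if has_step[i]:
            step = new_id()
            step_dob = first_dob - pd.Timedelta(days=int((18 + 20 * rng.random()) * 365.25))
            person_rows.append(
                dict(person_id=step, dob=step_dob, gender="M" if rng.random() < 0.5 else "F",
                     ethnicity_group=fam_eth[i], family_id=fid, role="step_parent")
            )

        ids, half_flags = [], []
        for c in range(k):
            cid = new_id()
            dob = child_dobs[c]
            half = c > 0 and rng.random() < config.half_sibling_prob
            person_rows.append(
                dict(person_id=cid, dob=dob, gender="F" if rng.random() < 0.5 else "M",
                     ethnicity_group=fam_eth[i], family_id=fid, role="child")
            )
            rel_rows.append(
                dict(subject_id=mother, object_id=cid, type_code="parent_child",
                     effective_date=dob, family_id=fid)
            )
            if father is not None and not half:
                rel_rows.append(
                    dict(subject_id=father, object_id=cid, type_code="parent_child",
                         effective_date=dob, family_id=fid)
                )
            if step is not None:
                rel_rows.append(
                    dict(subject_id=step, object_id=cid, type_code="step_parent_of",
                         effective_date=dob, family_id=fid)
                )
            for prev, prev_half in zip(ids, half_flags):
                code = "half_sibling" if (half or prev_half) else "sibling"
                rel_rows.append(
                    dict(subject_id=prev, object_id=cid, type_code=code,
                         effective_date=dob, family_id=fid)
                )
            ids.append(cid)
            half_flags.append(half)

    persons = pd.DataFrame(person_rows)
    relationships = pd.DataFrame(rel_rows)
    children = persons[persons["role"] == "child"].reset_index(drop=True)
    return dict(
        persons=persons,
        children=children,
        relationships=relationships,
        latent_risk=pd.Series(z, index=fam_ids),
    )


# -- events -----------------------------------------------------------------


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p / (1.0 - p))


def _draw_events(config, rng, children, z_by_family, win0, win1) -> pd.DataFrame:
    """Daily-grid notification draws per (child, year-of-age) segment, then
    risk-dependent follow-up events hanging off individual notifications."""
    z = children["family_id"].map(z_by_family).to_numpy()
    ids = children["person_id"].to_numpy()
    n = len(children)
    dob_d = children["dob"].to_numpy().astype("datetime64[D]").astype(np.int64)
    w0 = np.int64(win0.to_datetime64().astype("datetime64[D]").astype(np.int64))
    w1 = np.int64(win1.to_datetime64().astype("datetime64[D]").astype(np.int64))

    base = config.notification_rate_per_year / 365.25
    rate_mult = np.exp(config.risk_effect_notification * z)

    # (child, age-year) segments, flattened; each a run of Bernoulli days
    ages = np.arange(config.max_event_age_years)
    seg_s = dob_d[:, None] + np.round(ages * 365.25).astype(np.int64)[None, :]
    seg_e = dob_d[:, None] + np.round((ages + 1) * 365.25).astype(np.int64)[None, :] - 1
    seg_s = np.maximum(seg_s, w0)
    seg_e = np.minimum(seg_e, w1)
    seg_len = seg_e - seg_s + 1
    seg_p = np.minimum(base * np.exp(-config.age_rate_decay * ages)[None, :] * rate_mult[:, None], 0.5)
    valid = seg_len > 0
    child_idx_f = np.repeat(np.arange(n), config.max_event_age_years)[valid.ravel()]
    seg_s_f = seg_s.ravel()[valid.ravel()]
    seg_len_f = seg_len.ravel()[valid.ravel()]
    seg_p_f = seg_p.ravel()[valid.ravel()]

    counts = rng.binomial(seg_len_f, seg_p_f) if len(seg_p_f) else np.array([], dtype=int)

    note_child_parts, note_day_parts = [], []
    singles = counts == 1
    if singles.any():
        offs = rng.integers(0, seg_len_f[singles])
        note_child_parts.append(child_idx_f[singles])
        note_day_parts.append(seg_s_f[singles] + offs)
    for j in np.nonzero(counts >= 2)[0]:
        k = int(counts[j])
        offs = np.sort(rng.choice(seg_len_f[j], size=k, replace=False))
        note_child_parts.append(np.full(k, child_idx_f[j]))
        note_day_parts.append(seg_s_f[j] + offs)

    if note_child_parts:
        note_child_idx = np.concatenate(note_child_parts)
        note_days = np.concatenate(note_day_parts)
        order = np.lexsort((note_days, note_child_idx))
        note_child_idx = note_child_idx[order]
        note_days = note_days[order]
    else:
        note_child_idx = np.array([], dtype=int)
        note_days = np.array([], dtype=np.int64)

    note_dt = pd.to_datetime(note_days.astype("datetime64[D]"))
    events = [
        pd.DataFrame(
            {
                "person_id": ids[note_child_idx],
                "event_type": "notification",
                "date": note_dt,
            }
        )
        if len(note_child_idx)
        else pd.DataFrame(columns=["person_id", "event_type", "date"])
    ]

    n_notes = len(note_child_idx)
    if n_notes:
        zn = z[note_child_idx]
        followups = [
            ("referral_decision", config.referral_prob, 1, 14),
            ("substantiated_finding", config.substantiation_prob, 30, 210),
            ("family_group_conference", config.conference_prob, 30, 210),
            ("family_agreement", config.agreement_prob, 30, 210),
            ("intervention", config.intervention_prob, 30, 270),
        ]
        for etype, p0, dmin, dmax in followups:
            if p0 <= 0.0:
                continue
            p = _sigmoid(_logit(p0) + config.risk_effect_response * zn)
            hit = rng.random(n_notes) < p
            delays = dmin + rng.integers(0, dmax - dmin + 1, size=n_notes)
            dts = note_dt + pd.to_timedelta(delays, unit="D")
            keep = hit & (dts <= win1)
            if keep.any():
                events.append(
                    pd.DataFrame(
                        {
                            "person_id": ids[note_child_idx[keep]],
                            "event_type": etype,
                            "date": dts[keep],
                        }
                    )
                )

    out = pd.concat(events, ignore_index=True)
    return out


# -- abusive relationships --------------------------------------------------


def _draw_abusive_edges(config, rng, fam, win0, win1) -> pd.DataFrame:
    """Adults with elevated latent risk acquire a recorded abusive
    relationship row (instigator = subject).  Targets are other adults, so
    abusive rows never confer recorded-network membership on children; they
    feed the known-abuser features through adult network members."""
    persons = fam["persons"]
    z_by_family = fam["latent_risk"]
    adults = persons[persons["role"] != "child"].reset_index(drop=True)
    if adults.empty or config.abusive_edge_base_prob <= 0.0:
        return pd.DataFrame(columns=["subject_id", "object_id", "type_code", "recorded_date"])
    z = adults["family_id"].map(z_by_family).to_numpy()
    p = _sigmoid(_logit(config.abusive_edge_base_prob) + config.abusive_edge_risk_effect * z)
    hit = rng.random(len(adults)) < p

    by_family: dict[str, list[int]] = {}
    for i, f in enumerate(adults["family_id"]):
        by_family.setdefault(f, []).append(i)

    span = (win1 - win0).days
    rows = []
    for i in np.nonzero(hit)[0]:
        mates = [j for j in by_family[adults.at[i, "family_id"]] if j != i]
        if mates:
            obj = adults.at[int(rng.choice(mates)), "person_id"]
        else:
            j = int(rng.integers(0, len(adults)))
            if j == i:
                j = (j + 1) % len(adults)
            if len(adults) == 1:
                continue
            obj = adults.at[j, "person_id"]
        code = "physically_abused" if rng.random() < 0.5 else "emotionally_abused"
        rec = win0 + pd.Timedelta(days=int(rng.integers(0, span + 1)))
        rows.append(
            dict(
                subject_id=adults.at[int(i), "person_id"],
                object_id=obj,
                type_code=code,
                recorded_date=rec,
            )
        )
    if not rows:
        return pd.DataFrame(columns=["subject_id", "object_id", "type_code", "recorded_date"])
    return pd.DataFrame(rows)


# -- recording model --------------------------------------------------------


def _assign_recorded_dates(config, rng, rel_rows, events, fam, win0, win1) -> pd.DataFrame:
    """Each family relationship row is recorded either shortly after its
    effective date (probability ``p_record_before_target``, per family,
    optionally overridden per ethnicity group) or only after the family's
    first target event; families with no target event have their rows
    recorded at the end of the collection window."""
    persons = fam["persons"]
    fam_of = persons.set_index("person_id")["family_id"]
    targets = events[events["event_type"].isin(TARGET_EVENT_TYPES)]
    first_target = (
        targets.assign(family_id=targets["person_id"].map(fam_of))
        .groupby("family_id")["date"]
        .min()
    )

    eth_of_family = (
        persons.drop_duplicates("family_id").set_index("family_id")["ethnicity_group"]
    )
    p_before = pd.Series(config.p_record_before_target, index=eth_of_family.index)
    if config.ethnicity_censoring:
        for label, pval in config.ethnicity_censoring.items():
            p_before[eth_of_family == label] = pval

    rel = rel_rows.copy()
    p_row = rel["family_id"].map(p_before).to_numpy()
    early = rng.random(len(rel)) < p_row
    delays = pd.to_timedelta(
        np.round(rng.exponential(config.record_delay_mean_days, size=len(rel))).astype(int),
        unit="D",
    )
    trigger = rel["family_id"].map(first_target)
    effective = rel["effective_date"]

    recorded = pd.Series(pd.NaT, index=rel.index, dtype="datetime64[ns]")
    recorded[early] = effective[early] + delays[early]
    late = ~early
    has_trigger = late & trigger.notna()
    base = pd.concat([effective[has_trigger], trigger[has_trigger]], axis=1).max(axis=1)
    recorded[has_trigger] = base + delays[has_trigger]
    recorded[late & trigger.isna()] = win1
    recorded = recorded.clip(lower=win0, upper=win1)

    out = rel[["subject_id", "object_id", "type_code"]].copy()
    out["recorded_date"] = recorded
    return out


# -- convenience ------------------------------------------------------------


def write_scenario(name: str, seed: int, out_dir: str | Path) -> CPSDatabase:
    """Generate a preset scenario and write it (with ground truth) to disk."""
    from .data_model import write_database

    cfg = scenario(name, seed=seed)
    db, truth = generate_with_truth(cfg)
    write_database(db, out_dir)
    truth.write(Path(out_dir) / "truth")
    return db


def config_from_dict(d: dict) -> GeneratorConfig:
    """Build a config from a plain dict (e.g. parsed YAML/JSON overrides)."""
    allowed = {f.name for f in GeneratorConfig.__dataclass_fields__.values()}
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown generator config keys: {sorted(unknown)}")
    cfg = GeneratorConfig(**d)
    cfg.validate()
    return cfg


def override(config: GeneratorConfig, **kwargs) -> GeneratorConfig:
    cfg = replace(config, **kwargs)
    cfg.validate()
    return cfg
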