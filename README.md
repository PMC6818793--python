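# kinrisk

Family-network predictors for child-protection risk models.

Child protection services receive *notifications* — reports that a child may
be at risk — and must decide which to refer for investigation. Most
predictive risk models score these decisions from the child's own event
history. `kinrisk` implements and evaluates an alternative source of signal:
the child's **family network**, built from the relationship rows that
registries record, under two temporal semantics:

* **recorded** — a person belongs to the network at time `T` if some
  relationship row linking them to the child was entered in the registry
  before `T`. Registries typically map a family only *after* a serious
  event, so these networks are nearly empty at a child's first notification.
* **whole-life** — parent/child, sibling and half-sibling ties are backdated
  to the date of birth of the younger member, simulating linkage with a
  birth registry: the tie is visible from the day it truly begins,
  regardless of when a social worker recorded it. Events are never
  backdated — only membership is.

The package is aimed at researchers in administrative-registry epidemiology
and predictive risk modelling who want a tested, reproducible pipeline for
this class of analysis, exercised end-to-end on synthetic registries with
known ground truth (real child-protection data are confidential).

## The analysis

The unit of analysis is the notification (child *i*, lifetime index *j*,
date *T*). The binary response, **estimated concern**, is

> EC<sub>ij</sub> = 1 iff, within two years after the notification, the child
> has (i) a substantiated finding of maltreatment, (ii) a family group
> conference or family agreement, or (iii) a referral decision at a
> subsequent notification.

Twelve predictors are computed per notification: age; four event counts from
the child's own history (`nNotes`, `nTargets`, `nNotesRecent`,
`nTargetsRecent`); four recorded-network counts (`nNeighsR`, `nWithNotesR`,
`nWithTargetR`, `nAbusersR`); and three whole-life-network counts
(`nWithNotesW`, `nWithTargetW`, `nAbusersW` — the whole-life network *size*
is deliberately excluded as a registry-coverage artefact). Models are plain
maximum-likelihood logistic regressions

    logit EC_ij = α₀ + Σ_k α_k x_kij

compared by the ROC score (area under the ROC curve, on pooled out-of-fold
predictions from K = 10 cross-validation) and by AIC = 2k − 2 ln L. An
exhaustive best-subset search ranks all {age + 3 other predictors} models,
on three subsamples: all notifications, first notifications (j = 1, where
event-based predictors are identically zero and are excluded), and
subsequent notifications (j > 1). Depth-1 classification trees
(Gini-optimal single thresholds) give per-predictor positive predictive
values and false omission rates by age bracket, and a fairness audit checks
statistical calibration and error-rate parity across gender and ethnicity
groups — which are never model inputs.

The synthetic generator plants a latent per-family risk that raises both a
family's prior event rates and a child's future outcome rates, and censors
relationship recording until after the family's first serious event. Under
that regime the pipeline reproduces the qualitative headline: models with
whole-life features beat models without them, most clearly at the first
notification.

## Worked example

```python
import kinrisk as kr
from kinrisk.models import whole_life_comparison

cfg = kr.scenario("censored_recording", seed=1)   # ~20,000 children
db = kr.generate(cfg)
cases = kr.label_notifications(db, kr.assemble_notifications(db))
table = kr.feature_matrix(db, cases)

comp = whole_life_comparison(table, "first", K=10, seed=1)
for name, res in comp.items():
    print(name, list(res.spec.predictor_names), round(res.roc_score, 4))
```

prints

```
best_whole_life ['age', 'nAbusersW', 'nWithNotesW', 'nWithTargetW'] 0.6496
best_without_whole_life ['age', 'nAbusersR', 'nWithNotesR', 'nWithTargetR'] 0.6343
full ['age', 'nAbusersR', 'nAbusersW', 'nNeighsR', 'nWithNotesR', 'nWithNotesW', 'nWithTargetR', 'nWithTargetW'] 0.649
```

The best four-variable model at the first notification uses whole-life
features and outscores the best recorded-only model by ROC 0.015 — at the
screening moment where the registry itself knows the least, backdated birth
ties recover family history that recording censorship hides. The same seed's
depth-1 tree on `nWithTargetW` flags 35% of first notifications as high risk
(PPV 0.71, false omission rate 0.52) versus 26% flagged by its recorded
counterpart (PPV 0.70, FOR 0.55): the whole-life split finds a larger
high-risk group with a cleaner separation.

The same pipeline runs from the shell:

```
kinrisk run --scenario censored_recording --seed 42 --out out/
```

writing `cases.csv`, `features.csv`, `results.json`, `stumps.json`,
`audit.json` and a deterministic `manifest.json`.

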