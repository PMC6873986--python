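# metasurv

Decentralized training of multigene linear survival signatures across
multiple gene-expression cohorts. Instead of merging studies into one
dataset, the model minimizes a per-cohort hinge-approximated survival
discordance loss and sums it over cohorts — no patient is ever compared to a
patient from another study, so incomparable follow-up scales and platform
effects cannot corrupt training.

Core ingredients:

- **Percentile-rank features** — each sample's expression profile is
  replaced by within-sample ranks divided by the gene count, making features
  invariant to any strictly monotone platform distortion.
- **Meta-z gene prioritization** — per-gene concordance z-scores per cohort,
  combined by Stouffer's method and filtered by Benjamini-Hochberg at
  α = 0.05.
- **Hinge discordance loss** — a convex surrogate for survival discordance
  over comparable pairs, with an O(m + nd) loss/subgradient evaluation and
  quasi-Newton (L-BFGS) minimization.
- **Ridge penalty with leave-one-dataset-out selection** — λ is chosen by
  holding out whole cohorts, cumulating the unpenalized held-out loss, and
  taking the minimizer.
- **Synthetic multi-cohort generator** — known sparse ground truth,
  cohort-specific baseline hazards spanning 10×, per-cohort monotone
  distortions, and calibrated independent censoring, for end-to-end testing.

## CLI

```sh
# generate a synthetic 4-cohort collection with ground truth
metasurv simulate --out data/ --seed 7

# rank-transform expression matrices
metasurv transform --expression data/cohort1_expression.tsv --out ranks/

# prioritize genes across cohorts
metasurv prioritize \
  --cohort data/cohort1_expression.tsv data/cohort1_clinical.tsv \
  --cohort data/cohort2_expression.tsv data/cohort2_clinical.tsv \
  --out priority.tsv

# train end to end (signature + priority table + CV report)
metasurv train \
  --cohort data/cohort1_expression.tsv data/cohort1_clinical.tsv \
  --cohort data/cohort2_expression.tsv data/cohort2_clinical.tsv \
  --cohort data/cohort3_expression.tsv data/cohort3_clinical.tsv \
  --out run/

# evaluate a signature on cohorts (c-index + univariable Cox)
metasurv evaluate --signature run/signature.json \
  --cohort data/cohort4_expression.tsv data/cohort4_clinical.tsv \
  --out eval.tsv
```

Expression matrices are TSV/CSV, features × samples, with a header row of
sample ids and the first column holding feature ids. Clinical tables need
columns `sample_id`, `time`, `event` (1 = event observed, 0 = censored).
An optional two-column probeset→gene map collapses probeset-level matrices
(largest mean expression wins). Signatures are JSON.

Sign convention: the fitted `w·x` is a *survival* (protective) score; all
reported risk scores are its negation, so higher risk ⇒ shorter predicted
survival.

## Library

```python
import metasurv as ms

collection, truth = ms.simulate_collection()          # default scenario
result = ms.train_signature(collection.cohorts)       # full pipeline
risk = ms.score(result.signature, some_cohort)        # per-sample risk
ms.cindex_ztest(risk, times, events)                  # evaluation
```

## Tests and acceptance report

```sh
python -m pytest -q                                   # full suite (~2.5 min)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the acceptance criteria: exact equivalence
of the fast subgradient with a naive double-loop oracle, finite-difference
and convexity checks, the decentralization invariances (cohort order,
per-cohort time rescaling, monotone expression distortions — and the
demonstration that a naively merged loss violates them), exact single-cohort
reduction, statistical unit checks with Monte-Carlo null calibration, ground
truth recovery on the default synthetic collection, and a 10-seed contrast
against a naively merged training pipeline. `scripts/acceptance.py` runs an
end-to-end synthetic self-check; it emits an empty JSON target object since
all acceptance targets here are property-based rather than numeric
reproductions (the published benchmark numbers require external clinical
datasets).
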