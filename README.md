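# tcmrec

Knowledge-guided recommendation of **evidence elements** for Traditional
Chinese Medicine (TCM) consultations.

In TCM syndrome differentiation, a physician reads a patient's symptom
presentation and distils it into a set of atomic diagnostic units —
evidence elements such as *xu* (deficiency) or *re* (heat) — grouped into
five categories: **a** disease site, **b** essential substance, **c**
disease evil, **d** pathological state, **e** connecting word.  `tcmrec`
is a clinical-decision-support library for researchers and engineers
building such recommenders: given a corpus of consultation records
(tokenized symptoms, demographics, dates, diagnoses, element labels) it
engineers association-rule and domain-knowledge features, trains a
scene-conditioned multi-task neural ranker, and evaluates the ranked
element recommendations.

## What is inside

**Feature engineering** — per-corpus association statistics

```
P(b|a)            = count(a,b) / count(a,B)            co-occurrence
confidence(A⇒B)   = count(A∩B) / count(A)
support(A⇒B)      = count(A∩B) / count(T)
TF                = n_ij / Σ_k n_kj ,   IDF = ln N/(n_i+1)
```

plus TCM domain knowledge: sexagenary (Heavenly-Stem/Earthly-Branch) year
features with five-element correspondences, female-seven/male-eight age
staging codes, acute/chronic diagnosis labels, and per-symptom common
element priors.

**Model** — a multi-task *meta-attention* network.  Symptom tokens pass
through multi-head self-attention `softmax(QKᵀ/√d)V` and a feed-forward
block `ReLU((xW1+b1)W2)+b2`; the result is fused with patient, scene and
dense statistical feature blocks by a squeeze-and-excitation gate
(`s = σ(MLP(z))`, `x_{l+1} = x_l + s`).  A group of S shared and K
per-task unique experts is gated per task by **meta attention**
`α_i = Vᵀ·Meta([E_i])`, softmax-normalised over the S+K experts, where
every **meta unit** `y = ReLU(W_meta x + b_meta)`,
`W_meta = Reshape(W·e_scene + b)` generates its weights from a scene
embedding, so effective parameters differ per scene (task identity,
department, or season).  Per-task meta towers produce element scores for
the five category tasks; each head also carries a wide path with the
case's per-candidate association-evidence score.  MLP and MMoE baselines
share the identical input pipeline.  Everything runs on numpy via an
in-package reverse-mode autodiff engine — no deep-learning framework
required.

**Evaluation** — AUC, Hits@10 (per-sample label recall in the top ten),
mean rank, MRR, and the positional **unit hit rate**
`Hits_k = (1/N) Σ_i 1[pred_ik ∈ label_i]` — the fraction of test samples
whose k-th ranked prediction is a true element — with `hits_avg` the mean
of positions 1–3.  All metrics are verified against brute-force oracles.

**Synthetic corpora** — a generator with planted per-scene conditional
tables `P(element | symptom, scene)` and a reference ranking oracle
computed from the ground truth, so feature recovery, learnability and
scene-awareness are testable without access to private clinical data.

## Worked example

Train the meta model on a scene-heterogeneous synthetic corpus (2,000
train / 600 test cases, 50 symptoms, 30 elements, 5 departments whose
symptom→element conditionals differ completely):

```python
import tcmrec as tr

spec = tr.SyntheticSpec.random(n_symptoms=50, n_elements=30, n_scenes=5,
                               scene_heterogeneity=1.0, seed=9)
corpus = tr.generate_corpus(spec, 2600, seed=10)
train, test = corpus.cases[:2000], corpus.cases[2000:]

model = tr.EvidenceElementModel(train, kind="meta",
                                config=tr.ModelConfig(seed=0, scene_field="department"))
results = model.fit(eval_cases=test,
                    train_config=tr.TrainConfig(epochs=12, batch_size=256,
                                                learning_rate=3e-3, seed=0))
print(results.summary())
```

```
Evidence-element recommendation results
=======================================================
model kind:          meta
scene conditioning:  department
tasks (categories):  [6, 4, 7, 9, 4] elements per a-e
parameters:          526363
training steps:      96
final train loss:    13.9183
-------------------------------------------------------
held-out samples:    600
Hits@10:             0.5458
mean rank:           10.9854
MRR:                 0.2132
AUC:                 0.6957
unit hit rate 1-3:   0.5017, 0.4400, 0.3917
hits_avg (1-3):      0.4444
=======================================================
```

Hits@10 = 0.546 means that on average 54.6 % of each held-out case's true
elements appear in its top-ten recommendations; unit hit rate 0.50 at
position 1 means half the cases have a correct element ranked first.
Individual predictions:

```python
pred = results.predict(test[:1])[0]
pred.ranked_elements[:5]   # ['e004', 'e022', 'e015', 'e001', 'e017']
sorted(pred.label_set)     # ['e001', 'e004', 'e012', 'e015', 'e017', 'e019', 'e022', 'e023']
```

— all five top-ranked elements are true labels of this case.  Under the
same protocol the MLP baseline reaches mean Hits@10 ≈ 0.513 over five
seeds versus ≈ 0.537 for the meta model: conditioning the generated
weights on the department is what lets the model track per-scene
conditionals.

A CLI covers the same workflow from the shell:
`tcmrec simulate|featurize|train|evaluate|score|compare-baselines`.

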