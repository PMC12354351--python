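# Methods

`tcmrec` recommends *evidence elements* — the atomic diagnostic units of
Traditional Chinese Medicine syndrome differentiation — for a consultation
record, from its symptom tokens, demographics and contextual fields.
Elements are grouped into five categories (a = disease site, b = essential
substance, c = disease evil, d = pathological state, e = connecting word),
and prediction is phrased as five multi-label classification tasks, one
per category, whose score vectors are merged into a single global ranking
per case.

## Feature engineering

**Association statistics.** From a training corpus the package computes
per-case presence counts and derives, for symptom *a* and element *b*:

* co-occurrence probability `P(b|a) = count(a,b) / count(a,B)`, where
  `count(a,B)` counts cases containing *a* and at least one element;
* rule confidence `confidence(A⇒B) = count(A∩B)/count(A)` and support
  `support(A⇒B) = count(A∩B)/count(T)` over item sets;
* TF `n_ij / Σ_k n_kj` over a case's element list (raw multiplicity), and
  IDF `ln(N/(n_i+1))` with the natural logarithm.  Any fixed log base
  preserves ordering; a token present in every document yields the small
  negative value `ln(N/(N+1))`, kept as computed.

Counts for the probability-like statistics are presence-based (a token
counted once per case); only TF uses within-case multiplicity.  TF/IDF
documents default to element lists (configurable to symptom lists).

**Domain knowledge.** Demographic and calendar features: the sexagenary
year cycle (anchored at 1984 = jiǎ-zǐ, Gregorian year boundary — a
documented simplification that ignores the lunar new-year offset), the
stem→five-element correspondence (jiǎ/yǐ→wood … rén/guǐ→water,
overridable by config), year-fortune polarity (yang stem = excess), the
female-seven/male-eight age codes (stages end at multiples of 7/8 with
age 0 folded into stage 1; code = sex prefix + zero-padded stage, capped
at stage 13), configurable acute/chronic and disease-list labels (unknown
names are `unlabeled`, never guessed), and an innate-constitution label
implemented as a configurable lookup keyed by (year stem, birth month) —
the doctrine gives no algorithm, so the table is data, not a claim.
Per-symptom priors (top-m co-occurring elements, count-descending with
lexicographic tie-break) are available as inspection features.

**Category alignment.** When a record's element and category lists have
equal length they align positionally; mismatched rows (the packaged
sample corpus deliberately contains one) are flagged and excluded from
alignment, and their elements inherit categories from consistent rows
where possible.  Elements whose category remains unknown are assigned to
category c (disease evil) for task placement only.

## Network

Pipeline per case: symptom-token embeddings → multi-head self-attention
(scaled dot-product per head, scale `1/√d_head`) → position-wise
feed-forward `ReLU((xW1+b1)W2)+b2` (the rectifier sits outside the second
product, matching the definition used here) → masked mean-pool.  The
pooled high-order block is fused with the patient-profile embedding
block, the scene embedding and a projected dense-statistics block by a
squeeze-and-excitation gate: squeeze = per-group means, excitation = a
small MLP with sigmoid output `s`, fusion `x + s` by default
(`senet_mode="multiplicative"` selects canonical reweighting `x⊙s`).
The fused vector feeds S shared + K-per-task unique two-layer ReLU
experts.  Per task, a *meta attention* gate scores each visible expert
through a *meta unit* — a dense ReLU layer whose weights and bias are
reshaped from an affine map of the scene embedding — followed by a
projection vector and a softmax over the S+K experts; the gated mixture
passes through a *meta tower* (a cascade of meta units) and a linear head
sized to the category's element vocabulary.

The conditioning scene defaults to the task identity (a learned per-task
embedding); `scene_field="department"` or `"season"` conditions on the
per-case categorical instead, in which case generated weights are batched
per sample.  Zeroing every generator weight collapses all meta units to
the fixed dense layers stored in their generator biases, making the model
exactly invariant to the conditioning scene — an MMoE-like degenerate
model that an independently written plain-numpy pipeline reproduces, and
that the tests assert.

**Wide path.**  Each task head also receives, per candidate element, an
*association evidence* score computed from the training statistics: with
`conf(s,e)` the rule confidence and `base_e` the element's marginal
frequency, the score is the Naive-Bayes-corrected noisy-or log-survival

    w_e = −[ ln(1−base_e) + Σ_{s∈case} ( ln(1−conf(s,e)) − ln(1−base_e) ) ]

added to the logits through one learned scalar per task.  Purely deep
variants must reconstruct per-candidate statistics through pooled
embedding bottlenecks, which underfits badly at desk scale; the wide path
is the classical wide-and-deep remedy and carries exactly the package's
low-order association features.  Deep heads initialize at 0.1× fan-in
scale so optimization starts from the associative prior and learns deep
(notably scene-dependent) corrections.  `wide_path=False` disables it.

**Baselines.**  An MLP (same encoded inputs, stacked dense ReLU, five
heads) and an MMoE (shared experts, plain per-task softmax gates, dense
towers), both with the identical input pipeline including the wide path,
so comparisons isolate the meta-attention machinery.

**Training.**  Multi-label sigmoid cross-entropy per task (stable
`max(z,0) − zy + ln(1+e^{−|z|})` form), summed over the five tasks with
optional weights; Adam, default learning rate 1e-3, batch 128 — package
defaults, since no reference values exist for them.  Epoch feeding
shuffles deterministically per (seed, epoch) and touches every record
exactly once; held-out evaluation runs each epoch; the best held-out
Hits@10 parameters are checkpointed and restored; non-finite loss aborts.
A repeated-run harness trains R times (default 5) and reports mean ± sd.

**Autodiff.**  The network runs on an in-package reverse-mode automatic
differentiation engine over numpy float64 arrays (broadcast arithmetic,
batched matmul, softmax, reductions, embedding scatter-gather).  Gradient
correctness is verified against central finite differences on the
largest-magnitude entries of every parameter group, evaluating two step
sizes per entry (1e-3 and 1e-4) and keeping the better agreement, since
large steps suffer truncation error and small steps floating-point
cancellation; agreement is required within 1e-4 relative error.

## Ranking and evaluation

Per-task logits are mapped to per-element sigmoid probabilities and
concatenated into one global candidate ranking (ties broken by element
id).  A per-task-softmax merge is available (`merge="softmax"`) but not
the default: with a multi-label objective it forces each category to sum
to one regardless of how many of a case's labels fall in it, which
measurably degrades cross-category ranking.

Metrics: pairwise AUC (ties ½, Mann-Whitney rank implementation), Hits@k
as per-sample label recall in the top k, mean rank and MRR over one
evaluation unit per (sample, true label) by default (`unit="best"`
selects the best-ranked label per sample), and the positional *unit hit
rate* — at each rank position k, the fraction of samples whose k-th
ranked prediction is a true label — with `hits_avg` the mean of positions
1–3.  A label absent from a ranking receives rank `vocab+1`, flagged.
All metrics are tested against brute-force double-loop oracles.

## Synthetic corpora

The generator plants per-scene conditional tables `P(element | symptom,
scene)` (sparse Dirichlet rows concentrated on ~4 elements per symptom),
partitions elements over the five categories (weights skewed toward c/d,
matching the look of real element lists), and draws per case: a scene
(department), demographics, 3–9 symptoms, then one element from each
case symptom's conditional row plus mixture-distributed padding without
replacement to a 3–8 target.  Because every symptom contributes a draw, a
planted deterministic rule `P(e|s)=1` fires in every case containing `s`,
and the inclusion probability of element e is dominated by
`1 − Π_{s∈case}(1 − P(e|s,scene))` — the score used by the *reference
ranking oracle* that upper-bounds trained models (it ignores the small
padding and without-replacement corrections, so it is near- rather than
exactly Bayes-optimal).  A `scene_heterogeneity` knob interpolates
between one shared table (0) and independent per-scene tables (1).

What the generator does *not* emulate: real Chinese clinical text,
correlated symptom co-occurrence, demographic–element dependence (off by
default), label noise, and physician effects.  Passing tests therefore
demonstrate mechanism correctness and statistical recovery on the planted
process, not clinical performance.

## Study sizes and verification artifacts

The packaged six-case sample corpus reproduces published example
consultations (symptoms, syndromes, elements, categories, diseases) with
synthetic demographic placeholders; association statistics on it are
asserted against hand counts exactly.  The planted-corpus learnability
check uses 50 symptoms, 30 elements over 5 categories, 5 scenes, 5,000
training and 1,000 test cases, homogeneous scenes, 40 epochs at learning
rate 3e-3: the trained meta model must reach ≥0.8× the oracle's Hits@1
and ≥0.95× its Hits@10.  The ordering check uses maximally heterogeneous
scenes (heterogeneity 1.0), 2,000/600 cases, five seeds, the meta model
conditioned on the department scene versus the MLP baseline, reported as
mean ± sd; these sizes are the package's desk-scale choices.

## Known limitations

* The Gregorian-year sexagenary assignment misdates births in the weeks
  before lunar new year.
* The constitution projection is a lookup, not a derivation.
* Statistics are corpus-global; scene-sliced statistics would sharpen the
  wide path under strong heterogeneity but are deliberately left to the
  deep path, which is the component under study.
* The softmax-merge mode remains for comparison but is dominated by the
  sigmoid merge under the multi-label objective.
* CPU-only, float64; desk-scale corpora (≤ a few hundred thousand cases).
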