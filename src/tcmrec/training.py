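"""Automated training: case encoding, batch feeding, loss, session loop.

The loop mirrors a conventional session workflow: copy/shuffle/sequential
batch retrieval, per-step loss, periodic held-out evaluation with the full
ranking-metric suite, best-metric checkpointing (held-out Hits@10) with
optional early stopping, and a repeated-run harness that trains R times
and reports mean ± sd per metric.

The multi-task loss is sigmoid cross-entropy per element, summed over the
task's element vocabulary and over the five tasks, averaged over the
batch; per-task weights are optional.  Defaults (Adam, learning rate
1e-3, batch 128) are package choices and documented as such.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .corpus import CaseRecord, VocabSet, season_of
from .features import AssociationStats
from .knowledge import age_gender_code, stem_branch_features
from .metrics import MetricReport, RankedPrediction, build_report
from .network import (TASK_CODES, merge_task_scores, save_checkpoint)

log = logging.getLogger(__name__)


# -- case encoding --------------------------------------------------------

class CaseEncoder:
    """Turns case records into the dense/index arrays the networks consume.

    Profile tokens combine sex, the female-seven/male-eight age code, the
    birth-year stem element and polarity, and the consultation season.
    Dense statistics per case: for each of the five element categories the
    max and mean confidence of (case symptom => category element) rules,
    plus log(1 + number of symptoms): 11 values.

    The encoder also emits a per-candidate *association evidence* score —
    a Naive-Bayes-corrected noisy-or of rule confidences,
    ``w_e = -[ln(1-base_e) + Σ_{s∈case}(ln(1-conf(s,e)) - ln(1-base_e))]``
    with ``base_e`` the element's marginal document frequency — the
    wide-path input added to each task head's logits.
    """

    N_PROFILE_SLOTS = 5
    DENSE_DIM = 11
    CONF_CAP = 0.995

    def __init__(self, vocabs: VocabSet, stats: AssociationStats,
                 scene_field: str = "department", max_symptoms: int = 12):
        self.vocabs = vocabs
        self.stats = stats
        self.scene_field = scene_field if scene_field != "task" else "department"
        self.max_symptoms = max_symptoms
        self.profile_vocab: dict[str, int] = {}
        # disjoint task partition of the element vocabulary (ids > 0);
        # elements with no recorded category default to "c" (disease evil)
        self.task_element_ids: list[list[int]] = [[] for _ in TASK_CODES]
        for eid in range(1, len(vocabs.element_vocab)):
            code = vocabs.category_of_id(eid) or "c"
            self.task_element_ids[TASK_CODES.index(code)].append(eid)
        self._task_col: dict[int, tuple[int, int]] = {}
        for t, ids in enumerate(self.task_element_ids):
            for col, eid in enumerate(ids):
                self._task_col[eid] = (t, col)
        # per-symptom confidence lists for the dense block
        self._sym_conf: dict[str, list[tuple[int, float]]] = {}
        for (a, b), n in stats.pair_count.items():
            eid = vocabs.element_vocab[b]
            if eid == 0:
                continue
            conf = n / stats.symptom_any_count[a]
            self._sym_conf.setdefault(a, []).append((eid, conf))
        self._build_wide_tables()

    def _build_wide_tables(self) -> None:
        """Log-survival tables for the association-evidence wide feature."""
        n_elem = sum(self.task_vocab_sizes)
        self._wide_col: dict[int, int] = {}
        off = 0
        for ids in self.task_element_ids:
            for j, eid in enumerate(ids):
                self._wide_col[eid] = off + j
            off += len(ids)
        base = np.zeros(n_elem)
        n_cases = max(self.stats.n_cases, 1)
        for eid, col in self._wide_col.items():
            tok = self.vocabs.element_vocab.token(eid)
            base[col] = min(self.stats.doc_freq.get(tok, 0) / n_cases, self.CONF_CAP)
        self._log1m_base = np.log1p(-base)
        n_sym = len(self.vocabs.symptom_vocab)
        self._log_ratio = np.zeros((n_sym, n_elem))
        for a, pairs in self._sym_conf.items():
            sid = self.vocabs.symptom_vocab[a]
            if sid == 0:
                continue
            for eid, conf in pairs:
                col = self._wide_col[eid]
                self._log_ratio[sid, col] = (math.log1p(-min(conf, self.CONF_CAP))
                                             - self._log1m_base[col])

    def _wide_features(self, sym_row: np.ndarray) -> np.ndarray:
        ids = np.unique(sym_row[sym_row > 0])
        w = -(self._log1m_base + self._log_ratio[ids].sum(axis=0))
        return w

    @property
    def task_vocab_sizes(self) -> list[int]:
        return [len(ids) for ids in self.task_element_ids]

    def fit(self, cases: list[CaseRecord]) -> "CaseEncoder":
        tokens = sorted({t for rec in cases for t in self._profile_tokens(rec) if t})
        self.profile_vocab = {tok: i + 1 for i, tok in enumerate(tokens)}
        return self

    def _profile_tokens(self, rec: CaseRecord) -> list[str | None]:
        toks: list[str | None] = [None] * self.N_PROFILE_SLOTS
        if rec.patient_sex:
            toks[0] = f"sex:{rec.patient_sex}"
            if rec.age_years is not None:
                toks[1] = f"age:{age_gender_code(rec.patient_sex, rec.age_years).code}"
        profile = stem_branch_features(rec.birth_date) if rec.birth_date else None
        if profile is not None:
            toks[2] = f"stem:{profile.stem_element}"
            toks[3] = f"polarity:{profile.fortune_polarity}"
        season = rec.consult_season or (season_of(rec.consult_date)
                                        if rec.consult_date else None)
        if season:
            toks[4] = f"season:{season}"
        return toks

    def sizes(self) -> dict:
        return {
            "n_symptom_ids": len(self.vocabs.symptom_vocab),
            "n_profile_ids": len(self.profile_vocab) + 1,
            "n_scene_ids": len(self.vocabs.scene_vocab),
            "dense_dim": self.DENSE_DIM,
            "task_vocab_sizes": self.task_vocab_sizes,
        }

    def encode(self, cases: list[CaseRecord], with_labels: bool = True) -> dict:
        B, T = len(cases), self.max_symptoms
        sym_ids = np.zeros((B, T), dtype=np.intp)
        prof_ids = np.zeros((B, self.N_PROFILE_SLOTS), dtype=np.intp)
        scene_ids = np.zeros(B, dtype=np.intp)
        dense = np.zeros((B, self.DENSE_DIM))
        wide_all = np.zeros((B, sum(self.task_vocab_sizes)))
        labels = [np.zeros((B, v)) for v in self.task_vocab_sizes]
        label_sets: list[set[str]] = []
        for i, rec in enumerate(cases):
            ids = [self.vocabs.symptom_vocab[s] for s in rec.symptoms][:T]
            sym_ids[i, :len(ids)] = ids
            for j, tok in enumerate(self._profile_tokens(rec)):
                prof_ids[i, j] = self.profile_vocab.get(tok, 0) if tok else 0
            scene = getattr(rec, self.scene_field, None)
            scene_ids[i] = self.vocabs.scene_vocab[str(scene)] if scene else 0
            dense[i] = self._dense_features(rec)
            wide_all[i] = self._wide_features(sym_ids[i])
            if with_labels:
                known: set[str] = set()
                for el in rec.elements:
                    eid = self.vocabs.element_vocab[el]
                    if eid == 0:
                        log.warning("case %s: element %r outside vocabulary; skipped",
                                    rec.case_id, el)
                        continue
                    t, col = self._task_col[eid]
                    labels[t][i, col] = 1.0
                    known.add(el)
                if not known:
                    raise ValueError(f"case {rec.case_id}: no in-vocabulary labels")
                label_sets.append(known)
        splits = np.cumsum(self.task_vocab_sizes)[:-1]
        out = {"sym_ids": sym_ids, "prof_ids": prof_ids, "scene_ids": scene_ids,
               "dense": dense, "wide": np.split(wide_all, splits, axis=1),
               "case_ids": [r.case_id for r in cases]}
        if with_labels:
            out["labels"] = labels
            out["label_sets"] = label_sets
        return out

    def _dense_features(self, rec: CaseRecord) -> np.ndarray:
        per_task: list[list[float]] = [[] for _ in TASK_CODES]
        for s in set(rec.symptoms):
            for eid, conf in self._sym_conf.get(s, ()):
                per_task[self._task_col[eid][0]].append(conf)
        out = np.zeros(self.DENSE_DIM)
        for t, vals in enumerate(per_task):
            if vals:
                out[2 * t] = max(vals)
                out[2 * t + 1] = sum(vals) / len(vals)
        out[10] = math.log1p(len(rec.symptoms))
        return out


def batch_size_of(batch: dict) -> int:
    return batch["sym_ids"].shape[0]


def slice_batch(batch: dict, idx: np.ndarray) -> dict:
    out = {}
    for key, val in batch.items():
        if key in ("labels", "wide"):
            out[key] = [arr[idx] for arr in val]
        elif key in ("label_sets", "case_ids"):
            out[key] = [val[i] for i in idx]
        else:
            out[key] = val[idx]
    return out


def batch_feeder(dataset, batch_size: int, shuffle: bool = True,
                 seed: int = 0):
    """Yield index arrays covering one epoch; every record exactly once.

    ``dataset`` may be a record count, a list, or an encoded batch dict.
    The final partial batch is emitted.  Shuffle order is a deterministic
    function of ``seed``.
    """
    if isinstance(dataset, int):
        n = dataset
    elif isinstance(dataset, dict):
        n = batch_size_of(dataset)
    else:
        n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if batch_size > n:
        log.warning("batch_size %d > dataset size %d; single batch", batch_size, n)
    order = (np.random.default_rng(seed).permutation(n) if shuffle
             else np.arange(n))
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


# -- loss -----------------------------------------------------------------

def multi_task_loss(score_vectors: list[Tensor], label_sets: list[np.ndarray],
                    task_weights: list[float] | None = None
                    ) -> tuple[Tensor, list[float]]:
    """Multi-label sigmoid cross-entropy summed over the five tasks.

    Per task: elementwise ``max(z,0) - z·y + ln(1 + e^{-|z|})`` summed over
    the task vocabulary, averaged over the batch.  Returns the weighted
    total and the per-task values for logging.
    """
    if task_weights is None:
        task_weights = [1.0] * len(score_vectors)
    if len(score_vectors) != len(label_sets):
        raise ValueError("score/label task count mismatch")
    total: Tensor | None = None
    per_task: list[float] = []
    for z, y, w in zip(score_vectors, label_sets, task_weights):
        y = np.asarray(y, dtype=float)
        if z.shape != y.shape:
            raise ValueError(f"labels shape {y.shape} != scores shape {z.shape}")
        if ((y != 0) & (y != 1)).any():
            raise ValueError("labels must be 0/1 within the task vocabulary")
        absz = z.relu() + (-z).relu()
        per_el = z.relu() - z * Tensor(y) + ((-absz).exp() + 1.0).log()
        task_loss = per_el.sum(axis=1).mean()
        per_task.append(float(task_loss.data))
        term = task_loss * w
        total = term if total is None else total + term
    return total, per_task


# -- optimizer ------------------------------------------------------------

class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def make_optimizer(name: str, params: dict[str, Tensor], lr: float):
    if name == "adam":
        return Adam(params, lr=lr)
    if name == "sgd":
        class _SGD:
            def step(_self):
                for p in params.values():
                    if p.grad is not None:
                        p.data -= lr * p.grad
        return _SGD()
    raise ValueError(f"unknown optimizer {name!r}")


# -- config, log, loop ----------------------------------------------------

@dataclass
class TrainConfig:
    batch_size: int = 128
    epochs: int = 5
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    eval_every_n_steps: int | None = None  # None -> end of each epoch
    checkpoint_dir: str | None = None
    seed: int = 0
    early_stop_patience: int | None = None
    task_weights: list[float] | None = None

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainLog:
    losses: list[tuple[int, float]] = field(default_factory=list)
    evals: list[tuple[int, dict]] = field(default_factory=list)
    checkpoints: list[str] = field(default_factory=list)
    best_step: int = -1
    best_hits10: float = float("-inf")


def predict_task_scores(model, batch: dict, chunk: int = 1024) -> list[np.ndarray]:
    """Forward passes without gradients; per-task logit arrays."""
    n = batch_size_of(batch)
    pieces: list[list[np.ndarray]] = [[] for _ in range(model.config.n_tasks)]
    for start in range(0, n, chunk):
        idx = np.arange(start, min(start + chunk, n))
        logits = model.forward(slice_batch(batch, idx))
        for t, z in enumerate(logits):
            pieces[t].append(z.data)
    return [np.concatenate(p, axis=0) for p in pieces]


def rank_predictions(model, batch: dict, encoder: CaseEncoder,
                     merge: str | None = None) -> list[RankedPrediction]:
    """Global per-case candidate rankings over the whole element vocabulary."""
    merge = merge or model.config.merge
    scores, ids = merge_task_scores(predict_task_scores(model, batch),
                                    encoder.task_element_ids, merge=merge)
    vocab = encoder.vocabs.element_vocab
    preds = []
    label_sets = batch.get("label_sets")
    for i in range(scores.shape[0]):
        order = np.lexsort((ids, -scores[i]))
        preds.append(RankedPrediction(
            sample_id=batch["case_ids"][i],
            ranked_elements=[vocab.token(int(ids[j])) for j in order],
            scores=[float(scores[i, j]) for j in order],
            label_set=set(label_sets[i]) if label_sets is not None else set(),
        ))
    return preds


def evaluate_ranking(model, batch: dict, encoder: CaseEncoder,
                     merge: str | None = None, k_max: int = 10) -> MetricReport:
    """Score every case, build global rankings and compute all metrics."""
    preds = rank_predictions(model, batch, encoder, merge=merge)
    n_elements = sum(encoder.task_vocab_sizes)
    return build_report(preds, vocab_size=n_elements, k_max=min(k_max, n_elements))


def train_model(model, train_batch: dict, config: TrainConfig,
                eval_batch: dict | None = None,
                encoder: CaseEncoder | None = None) -> TrainLog:
    """Session loop: shuffled epochs, Adam steps, periodic held-out evaluation.

    Keeps (and restores) the parameters of the best held-out Hits@10
    evaluation; raises on divergence (non-finite loss).
    """
    opt = make_optimizer(config.optimizer, model.params(), config.learning_rate)
    tlog = TrainLog()
    step = 0
    best_params: dict[str, np.ndarray] | None = None
    stale = 0

    def run_eval():
        nonlocal best_params, stale
        report = evaluate_ranking(model, eval_batch, encoder)
        tlog.evals.append((step, report.to_dict()))
        if report.hits_at_10 > tlog.best_hits10:
            tlog.best_hits10 = report.hits_at_10
            tlog.best_step = step
            best_params = {k: p.data.copy() for k, p in model.params().items()}
            stale = 0
            if config.checkpoint_dir:
                save_checkpoint(model, config.checkpoint_dir)
                tlog.checkpoints.append(str(config.checkpoint_dir))
        else:
            stale += 1
        return report

    for epoch in range(config.epochs):
        for idx in batch_feeder(train_batch, config.batch_size, shuffle=True,
                                seed=config.seed + epoch):
            mini = slice_batch(train_batch, idx)
            logits = model.forward(mini)
            loss, _ = multi_task_loss(logits, mini["labels"], config.task_weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at step {step}: loss={float(loss.data)}")
            model.zero_grad()
            loss.backward()
            opt.step()
            tlog.losses.append((step, float(loss.data)))
            step += 1
            if (eval_batch is not None and config.eval_every_n_steps
                    and step % config.eval_every_n_steps == 0):
                run_eval()
        if eval_batch is not None and not config.eval_every_n_steps:
            run_eval()
        if (config.early_stop_patience is not None
                and stale >= config.early_stop_patience):
            log.info("early stop at epoch %d (patience %d)", epoch,
                     config.early_stop_patience)
            break
    if best_params is not None:
        for k, p in model.params().items():
            p.data[:] = best_params[k]
    return tlog


def repeated_runs(run_fn, n_runs: int = 5, base_seed: int = 0) -> dict:
    """Train/evaluate ``n_runs`` times; report per-metric mean and sd.

    ``run_fn(seed)`` must return a flat dict of metric values.  Mirrors the
    averaged five-run evaluation protocol.
    """
    rows = [run_fn(base_seed + r) for r in range(n_runs)]
    keys = rows[0].keys()
    out = {}
    for key in keys:
        vals = np.array([row[key] for row in rows], dtype=float)
        out[key] = {"mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if n_runs > 1 else 0.0,
                    "runs": vals.tolist()}
    return out


# -- gradient verification -------------------------------------------------

def gradient_check(model, batch: dict, n_entries: int = 2,
                   eps: tuple[float, ...] = (1e-3, 1e-4)) -> dict[str, float]:
    """Central finite differences vs backprop, per parameter group.

    Checks the ``n_entries`` largest-magnitude gradient entries of each
    group (tiny entries are dominated by floating-point cancellation in
    the difference quotient, not by backprop error) at each step size in
    ``eps``, keeping the better agreement per entry — large steps suffer
    truncation error, small steps roundoff.  Returns max relative error
    per group with denominator ``max(|analytic|, |numeric|, 1e-8)``.
    """

    def loss_value() -> float:
        logits = model.forward(batch)
        loss, _ = multi_task_loss(logits, batch["labels"])
        return float(loss.data)

    logits = model.forward(batch)
    loss, _ = multi_task_loss(logits, batch["labels"])
    model.zero_grad()
    loss.backward()
    errors: dict[str, float] = {}
    for name, p in model.params().items():
        g = p.grad if p.grad is not None else np.zeros_like(p.data)
        flat = p.data.reshape(-1)
        gflat = g.reshape(-1)
        picks = np.argsort(-np.abs(gflat))[:min(n_entries, flat.size)]
        worst = 0.0
        for j in picks:
            orig = flat[j]
            ana = gflat[j]
            best = np.inf
            for h in eps:
                flat[j] = orig + h
                up = loss_value()
                flat[j] = orig - h
                down = loss_value()
                flat[j] = orig
                num = (up - down) / (2 * h)
                best = min(best, abs(num - ana) / max(abs(num), abs(ana), 1e-8))
            worst = max(worst, best)
        errors[name] = worst
    return errors
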