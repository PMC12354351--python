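"""High-level modelling API: build from case records, fit, inspect results.

`EvidenceElementModel` owns the whole pipeline — vocabularies, association
statistics, the case encoder and one of the three network kinds — and its
``fit`` returns an `EvidenceElementResults` carrying the trained network,
the training log and held-out ranking metrics, with a ``summary()`` table.

    >>> model = EvidenceElementModel(train_cases, kind="meta")
    >>> res = model.fit(eval_cases=test_cases)
    >>> print(res.summary())
    >>> res.predict(new_cases)[0].ranked_elements[:10]
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

from .corpus import CaseRecord, VocabSet, build_vocabularies, split_dataset
from .features import AssociationStats, build_association_stats
from .metrics import MetricReport, RankedPrediction
from .network import ModelConfig, build_model, load_checkpoint, save_checkpoint
from .training import (CaseEncoder, TrainConfig, TrainLog, evaluate_ranking,
                       rank_predictions, repeated_runs, train_model)


class EvidenceElementModel:
    """Evidence-element recommender over TCM consultation records.

    Parameters
    ----------
    train_cases
        Labeled consultations used for vocabularies, statistics and fitting.
    kind
        ``"meta"`` (scene-conditioned multi-task meta-attention model),
        ``"mlp"`` or ``"mmoe"`` baselines.
    config
        Network hyperparameters; defaults are desk-scale.
    min_count
        Vocabulary frequency floor; rarer tokens map to the unknown id.
    """

    def __init__(self, train_cases: list[CaseRecord], kind: str = "meta",
                 config: ModelConfig | None = None, min_count: int = 1,
                 vocabs: VocabSet | None = None,
                 stats: AssociationStats | None = None):
        if not train_cases:
            raise ValueError("train_cases must be nonempty")
        self.kind = kind
        self.config = config or ModelConfig()
        scene_field = ("department" if self.config.scene_field == "task"
                       else self.config.scene_field)
        self.train_cases = train_cases
        self.vocabs = vocabs or build_vocabularies(train_cases, min_count=min_count,
                                                   scene_field=scene_field)
        self.stats = stats or build_association_stats(train_cases)
        self.encoder = CaseEncoder(self.vocabs, self.stats,
                                   scene_field=self.config.scene_field).fit(train_cases)
        self.network = build_model(kind, self.config, self.encoder.sizes())

    @classmethod
    def from_corpus(cls, cases: list[CaseRecord], test_fraction: float = 0.2,
                    split_seed: int = 0, **kwargs
                    ) -> tuple["EvidenceElementModel", list[CaseRecord]]:
        """Split a corpus and return (model over train, held-out test cases)."""
        split = split_dataset(cases, test_fraction, split_seed)
        return cls(split.train, **kwargs), split.test

    def fit(self, eval_cases: list[CaseRecord] | None = None,
            train_config: TrainConfig | None = None) -> "EvidenceElementResults":
        tc = train_config or TrainConfig()
        train_batch = self.encoder.encode(self.train_cases)
        eval_batch = self.encoder.encode(eval_cases) if eval_cases else None
        tlog = train_model(self.network, train_batch, tc,
                           eval_batch=eval_batch, encoder=self.encoder)
        report = (evaluate_ranking(self.network, eval_batch, self.encoder)
                  if eval_batch is not None else None)
        return EvidenceElementResults(self, tlog, report, tc)


class EvidenceElementResults:
    """Fit artifacts: trained network, training log, held-out metrics."""

    def __init__(self, model: EvidenceElementModel, train_log: TrainLog,
                 report: MetricReport | None, train_config: TrainConfig):
        self.model = model
        self.train_log = train_log
        self.report = report
        self.train_config = train_config

    @property
    def params(self):
        return self.model.network.params()

    def predict(self, cases: list[CaseRecord]) -> list[RankedPrediction]:
        with_labels = all(c.elements for c in cases)
        batch = self.model.encoder.encode(cases, with_labels=with_labels)
        return rank_predictions(self.model.network, batch, self.model.encoder)

    def evaluate(self, cases: list[CaseRecord]) -> MetricReport:
        batch = self.model.encoder.encode(cases)
        return evaluate_ranking(self.model.network, batch, self.model.encoder)

    def save(self, path: str | Path) -> None:
        save_checkpoint(self.model.network, path)

    def load_network(self, path: str | Path) -> None:
        self.model.network = load_checkpoint(path)

    def summary(self) -> str:
        cfg, enc = self.model.config, self.model.encoder
        n_params = sum(p.data.size for p in self.params.values())
        lines = [
            "Evidence-element recommendation results",
            "=" * 55,
            f"model kind:          {self.model.kind}",
            f"scene conditioning:  {cfg.scene_field}",
            f"tasks (categories):  {enc.task_vocab_sizes} elements per a-e",
            f"parameters:          {n_params}",
            f"training steps:      {len(self.train_log.losses)}",
        ]
        if self.train_log.losses:
            lines.append(f"final train loss:    {self.train_log.losses[-1][1]:.4f}")
        if self.report is not None:
            r = self.report
            lines += [
                "-" * 55,
                f"held-out samples:    {r.n_samples}",
                f"Hits@10:             {r.hits_at_10:.4f}",
                f"mean rank:           {r.mean_rank:.4f}",
                f"MRR:                 {r.mrr:.4f}",
                f"AUC:                 {r.auc:.4f}",
                f"unit hit rate 1-3:   "
                + ", ".join(f"{v:.4f}" for v in r.unit_hit_rate[:3]),
                f"hits_avg (1-3):      {r.hits_avg:.4f}",
            ]
        lines.append("=" * 55)
        return "\n".join(lines)


def compare_models(train_cases: list[CaseRecord], eval_cases: list[CaseRecord],
                   kinds: tuple[str, ...] = ("meta", "mlp", "mmoe"),
                   n_runs: int = 5, base_seed: int = 0,
                   config: ModelConfig | None = None,
                   train_config: TrainConfig | None = None) -> dict:
    """Repeated-run comparison harness: per kind, metric mean ± sd over seeds."""
    config = config or ModelConfig()
    tc = train_config or TrainConfig()
    out = {}
    for kind in kinds:
        def run(seed, kind=kind):
            m = EvidenceElementModel(train_cases, kind=kind,
                                     config=replace(config, seed=seed))
            res = m.fit(eval_cases=eval_cases,
                        train_config=replace(tc, seed=seed))
            r = res.report
            return {"hits_at_10": r.hits_at_10, "mean_rank": r.mean_rank,
                    "mrr": r.mrr, "auc": r.auc, "hits_avg": r.hits_avg,
                    "hits_at_1": r.unit_hit_rate[0]}
        out[kind] = repeated_runs(run, n_runs=n_runs, base_seed=base_seed)
    return out
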