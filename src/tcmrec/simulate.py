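"""Synthetic consultation corpora with planted symptom→element structure.

The generator emulates the shape of a real TCM case corpus: per case it
draws a scene (department), demographics, a symptom set of 3–9 tokens,
and an evidence-element set of 3–8 tokens from planted per-scene
conditional distributions, with elements partitioned over the five
category codes a–e.  Because every symptom in a case contributes one
element draw from its own conditional row, a planted deterministic rule
P(e|s) = 1 guarantees e appears in every case containing s, and the
inclusion probability of element e given symptoms S and scene c is
dominated by ``1 - Π_{s∈S} (1 - P(e|s,c))`` — the quantity the reference
ranking oracle uses.  Ground truth is retained so recovery and ceiling
tests are possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import yaml

from .corpus import CATEGORY_CODES, CaseRecord, season_of
from .metrics import RankedPrediction

log = logging.getLogger(__name__)

#: default category-partition weights — skewed toward disease evil (c) and
#: pathological state (d), the dominant codes in real element lists
DEFAULT_CATEGORY_WEIGHTS = {"a": 0.2, "b": 0.15, "c": 0.25, "d": 0.3, "e": 0.1}


@dataclass
class SyntheticSpec:
    """Planted generative parameters for a synthetic corpus."""

    n_symptoms: int = 500
    n_elements: int = 150
    n_diseases: int = 20
    n_scenes: int = 4
    conditional: np.ndarray = None  # (n_scenes, n_symptoms, n_elements), rows sum to 1
    element_category: list[str] = field(default_factory=list)  # len n_elements
    symptoms_per_case: tuple[int, int] = (3, 9)
    elements_per_case: tuple[int, int] = (3, 8)
    birth_year_range: tuple[int, int] = (1940, 2015)
    consult_year_range: tuple[int, int] = (2020, 2023)
    seed: int = 0

    def validate(self) -> None:
        if self.conditional is None:
            raise ValueError("spec.conditional is unset; use SyntheticSpec.random()")
        c = np.asarray(self.conditional, dtype=float)
        if c.shape != (self.n_scenes, self.n_symptoms, self.n_elements):
            raise ValueError(f"conditional shape {c.shape} inconsistent with spec")
        if not np.allclose(c.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("conditional rows must sum to 1")
        if (c < 0).any():
            raise ValueError("conditional has negative entries")
        if len(self.element_category) != self.n_elements:
            raise ValueError("element_category must cover every element")
        if set(self.element_category) - set(CATEGORY_CODES):
            raise ValueError("element_category codes outside a-e")
        lo, hi = self.symptoms_per_case
        if not (1 <= lo <= hi <= self.n_symptoms):
            raise ValueError("bad symptoms_per_case range")
        lo, hi = self.elements_per_case
        if not (1 <= lo <= hi):
            raise ValueError("bad elements_per_case range")

    # -- token naming ------------------------------------------------------
    def symptom_token(self, i: int) -> str:
        return f"s{i:03d}"

    def element_token(self, j: int) -> str:
        return f"e{j:03d}"

    def scene_token(self, c: int) -> str:
        return f"dept{c}"

    @classmethod
    def random(cls, n_symptoms: int = 50, n_elements: int = 30,
               n_diseases: int = 8, n_scenes: int = 5,
               elements_per_symptom: int = 4,
               scene_heterogeneity: float = 0.0, seed: int = 0,
               **kwargs) -> "SyntheticSpec":
        """Random spec with sparse, peaked conditional rows.

        Each symptom concentrates its conditional mass on about
        ``elements_per_symptom`` elements (Dirichlet weights on a random
        support).  ``scene_heterogeneity`` in [0, 1] interpolates between
        one shared table (0) and fully independent per-scene tables (1).
        """
        rng = np.random.default_rng(seed)

        def one_table() -> np.ndarray:
            tbl = np.zeros((n_symptoms, n_elements))
            for s in range(n_symptoms):
                k = min(elements_per_symptom, n_elements)
                supp = rng.choice(n_elements, size=k, replace=False)
                tbl[s, supp] = rng.dirichlet(np.full(k, 0.6))
            return tbl

        base = one_table()
        cond = np.empty((n_scenes, n_symptoms, n_elements))
        for c in range(n_scenes):
            cond[c] = (1.0 - scene_heterogeneity) * base + scene_heterogeneity * one_table()
        cond /= cond.sum(axis=2, keepdims=True)

        codes, weights = zip(*DEFAULT_CATEGORY_WEIGHTS.items())
        counts = np.floor(np.asarray(weights) * n_elements).astype(int)
        counts[-1] = n_elements - counts[:-1].sum()
        categories = [code for code, n in zip(codes, counts) for _ in range(n)]

        spec = cls(n_symptoms=n_symptoms, n_elements=n_elements,
                   n_diseases=n_diseases, n_scenes=n_scenes,
                   conditional=cond, element_category=categories,
                   seed=seed, **kwargs)
        spec.validate()
        return spec

    def plant_rule(self, symptom: int, element: int, prob: float = 1.0,
                   scene: int | None = None) -> None:
        """Overwrite a conditional row to place mass ``prob`` on one element."""
        scenes = range(self.n_scenes) if scene is None else [scene]
        for c in scenes:
            row = self.conditional[c, symptom].copy()
            row[element] = 0.0
            rest = row.sum()
            if rest > 0:
                row *= (1.0 - prob) / rest
            else:
                row[:] = (1.0 - prob) / (self.n_elements - 1)
                row[element] = 0.0
            row[element] = prob
            self.conditional[c, symptom] = row / row.sum()

    # -- (de)serialization -------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "n_symptoms": self.n_symptoms, "n_elements": self.n_elements,
            "n_diseases": self.n_diseases, "n_scenes": self.n_scenes,
            "symptoms_per_case": list(self.symptoms_per_case),
            "elements_per_case": list(self.elements_per_case),
            "birth_year_range": list(self.birth_year_range),
            "consult_year_range": list(self.consult_year_range),
            "seed": self.seed,
            "element_category": list(self.element_category),
            "conditional": np.asarray(self.conditional).tolist(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def load(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["conditional"] = np.asarray(payload["conditional"])
        for key in ("symptoms_per_case", "elements_per_case",
                    "birth_year_range", "consult_year_range"):
            payload[key] = tuple(payload[key])
        spec = cls(**payload)
        spec.validate()
        return spec


@dataclass
class GeneratedCorpus:
    cases: list[CaseRecord]
    spec: SyntheticSpec


def _draw_elements(rng: np.random.Generator, spec: SyntheticSpec,
                   scene: int, symptoms: np.ndarray) -> list[int]:
    """One element draw per symptom, then mixture padding to the target count."""
    chosen: list[int] = []
    chosen_set: set[int] = set()
    for s in symptoms:
        j = int(rng.choice(spec.n_elements, p=spec.conditional[scene, s]))
        if j not in chosen_set:
            chosen.append(j)
            chosen_set.add(j)
    lo, hi = spec.elements_per_case
    target = int(rng.integers(lo, hi + 1))
    mixture = spec.conditional[scene, symptoms].mean(axis=0)
    while len(chosen) < min(target, spec.n_elements):
        p = mixture.copy()
        p[list(chosen_set)] = 0.0
        total = p.sum()
        if total <= 0:
            p = np.ones(spec.n_elements)
            p[list(chosen_set)] = 0.0
            total = p.sum()
        j = int(rng.choice(spec.n_elements, p=p / total))
        chosen.append(j)
        chosen_set.add(j)
    # present the set ordered by mixture probability, most typical first
    chosen.sort(key=lambda j: (-mixture[j], j))
    return chosen


def generate_corpus(spec: SyntheticSpec, n_cases: int,
                    seed: int | None = None) -> GeneratedCorpus:
    """Draw ``n_cases`` consultations from the planted process; deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cases: list[CaseRecord] = []
    lo_s, hi_s = spec.symptoms_per_case
    for i in range(n_cases):
        scene = int(rng.integers(spec.n_scenes))
        sex = "female" if rng.random() < 0.5 else "male"
        birth_year = int(rng.integers(*spec.birth_year_range))
        birth = date(birth_year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
        consult = date(int(rng.integers(spec.consult_year_range[0],
                                        spec.consult_year_range[1] + 1)), 1, 1)
        consult += timedelta(days=int(rng.integers(0, 365)))
        r = int(rng.integers(lo_s, hi_s + 1))
        symptoms = rng.choice(spec.n_symptoms, size=min(r, spec.n_symptoms),
                              replace=False)
        symptoms.sort()
        elements = _draw_elements(rng, spec, scene, symptoms)
        disease = int(rng.integers(spec.n_diseases))
        cases.append(CaseRecord(
            case_id=f"syn-{i:06d}",
            physician=f"dr{int(rng.integers(10)):02d}",
            department=spec.scene_token(scene),
            patient_sex=sex,
            birth_date=birth,
            age_years=max(consult.year - birth.year, 0),
            consult_date=consult,
            consult_season=season_of(consult),
            symptoms=[spec.symptom_token(s) for s in symptoms],
            syndrome=None,
            elements=[spec.element_token(j) for j in elements],
            element_categories=[spec.element_category[j] for j in elements],
            disease_name=f"dz{disease:02d}",
        ))
    return GeneratedCorpus(cases=cases, spec=spec)


def bayes_optimal_ranking(spec: SyntheticSpec, symptom_tokens: list[str],
                          scene_token: str) -> RankedPrediction:
    """Reference ranking by planted inclusion probability.

    Elements are scored by ``1 - Π_{s∈case}(1 - P(e|s, scene))`` — the
    probability that at least one of the case's per-symptom draws produces
    the element — with the symptom-mixture probability as tie-break.  A
    symptom token outside the spec contributes uniformly and is flagged.
    This is the ceiling ranking trained models are compared against.
    """
    scene = int(scene_token.removeprefix("dept"))
    rows = []
    for tok in symptom_tokens:
        try:
            s = int(tok.removeprefix("s"))
            rows.append(spec.conditional[scene, s])
        except (ValueError, IndexError):
            log.warning("bayes_optimal_ranking: unknown symptom %r", tok)
            rows.append(np.full(spec.n_elements, 1.0 / spec.n_elements))
    rows = np.asarray(rows)
    inclusion = 1.0 - np.prod(1.0 - rows, axis=0)
    mixture = rows.mean(axis=0)
    order = sorted(range(spec.n_elements),
                   key=lambda j: (-inclusion[j], -mixture[j], j))
    return RankedPrediction(
        sample_id="oracle",
        ranked_elements=[spec.element_token(j) for j in order],
        scores=[float(inclusion[j]) for j in order],
        label_set=set(),
    )


def oracle_predictions(corpus: GeneratedCorpus) -> list[RankedPrediction]:
    """Reference ranking for every case, carrying the case's true labels."""
    preds = []
    for rec in corpus.cases:
        p = bayes_optimal_ranking(corpus.spec, rec.symptoms, rec.department)
        preds.append(RankedPrediction(
            sample_id=rec.case_id,
            ranked_elements=p.ranked_elements,
            scores=p.scores,
            label_set=set(rec.elements),
        ))
    return preds
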