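"""Case-record ingestion, vocabularies, dataset splitting and the feature store.

A consultation record ("case") is one row of a delimited (CSV, UTF-8,
header row) or JSON-lines file with the columns/keys::

    case_id, physician, department, patient_sex, birth_date, age_years,
    consult_date, consult_season, symptoms, syndrome, elements,
    element_categories, disease_name

Multi-token fields (``symptoms``, ``elements``, ``element_categories``)
are separated by an ASCII comma or the Chinese enumeration comma; tokens
are trimmed and lower-cased.  Missing optional values are carried as
``None`` — never dropped.  The feature store is a schema-versioned
directory of JSON-lines files with a manifest; loading a store written
under a different schema version raises instead of reinterpreting.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

CATEGORY_CODES = ("a", "b", "c", "d", "e")
#: category semantics: a = disease site, b = essential substance,
#: c = disease evil, d = pathological state, e = connecting word
SEASONS = ("spring", "summer", "autumn", "winter")
SEPARATORS = (",", "、", "，")  # comma, 、 , fullwidth comma
FEATURE_STORE_SCHEMA = "tcmrec-feature-store/1"

FIELDS = (
    "case_id", "physician", "department", "patient_sex", "birth_date",
    "age_years", "consult_date", "consult_season", "symptoms", "syndrome",
    "elements", "element_categories", "disease_name",
)


class CorpusError(ValueError):
    """Malformed corpus input (names the offending row and field)."""


def tokenize_field(raw: str | None) -> list[str]:
    """Split a multi-token field on comma / enumeration comma, trim, lowercase."""
    if raw is None or raw == "":
        return []
    text = raw
    for sep in SEPARATORS[1:]:
        text = text.replace(sep, ",")
    return [t.strip().lower() for t in text.split(",") if t.strip()]


def _parse_date(raw: str | None, row: int, fieldname: str) -> date | None:
    if raw in (None, "", "null", "NA"):
        return None
    try:
        return datetime.strptime(raw, "%Y-%m-%d").date()
    except ValueError as exc:
        raise CorpusError(f"row {row}: field {fieldname!r}: bad date {raw!r}") from exc


@dataclass
class CaseRecord:
    """One consultation: demographics, symptom tokens and evidence elements."""

    case_id: str
    symptoms: list[str]
    elements: list[str]
    element_categories: list[str] = field(default_factory=list)
    syndrome: str | None = None
    disease_name: str | None = None
    physician: str | None = None
    department: str | None = None
    patient_sex: str | None = None  # "female" | "male"
    birth_date: date | None = None
    age_years: int | None = None
    consult_date: date | None = None
    consult_season: str | None = None

    def validate(self, row: int | None = None, require_elements: bool = True) -> None:
        where = f"row {row}: " if row is not None else ""
        if not self.symptoms:
            raise CorpusError(f"{where}field 'symptoms': empty")
        if require_elements and not self.elements:
            raise CorpusError(f"{where}field 'elements': empty")
        for code in self.element_categories:
            if code not in CATEGORY_CODES:
                raise CorpusError(
                    f"{where}field 'element_categories': invalid code {code!r}")
        if self.patient_sex not in (None, "female", "male"):
            raise CorpusError(f"{where}field 'patient_sex': {self.patient_sex!r}")
        if self.consult_season not in (None, *SEASONS):
            raise CorpusError(f"{where}field 'consult_season': {self.consult_season!r}")
        if (self.age_years is not None and self.birth_date is not None
                and self.consult_date is not None):
            derived = (self.consult_date.year - self.birth_date.year)
            if abs(derived - self.age_years) > 1:
                raise CorpusError(
                    f"{where}field 'age_years': {self.age_years} inconsistent with "
                    f"birth/consult dates (derived {derived})")

    def to_row(self) -> dict[str, str]:
        return {
            "case_id": self.case_id,
            "physician": self.physician or "",
            "department": self.department or "",
            "patient_sex": self.patient_sex or "",
            "birth_date": self.birth_date.isoformat() if self.birth_date else "",
            "age_years": "" if self.age_years is None else str(self.age_years),
            "consult_date": self.consult_date.isoformat() if self.consult_date else "",
            "consult_season": self.consult_season or "",
            "symptoms": ", ".join(self.symptoms),
            "syndrome": self.syndrome or "",
            "elements": ", ".join(self.elements),
            "element_categories": ", ".join(self.element_categories),
            "disease_name": self.disease_name or "",
        }


def _record_from_row(row: dict, rownum: int, require_elements: bool) -> CaseRecord:
    def get(key):
        v = row.get(key)
        if isinstance(v, str):
            v = v.strip()
        return None if v in ("", None, "null", "NA") else v

    age = get("age_years")
    if age is not None:
        try:
            age = int(age)
        except (TypeError, ValueError) as exc:
            raise CorpusError(f"row {rownum}: field 'age_years': {age!r}") from exc
        if age < 0:
            raise CorpusError(f"row {rownum}: field 'age_years': negative")
    symptoms = row.get("symptoms")
    elements = row.get("elements")
    cats = row.get("element_categories")
    rec = CaseRecord(
        case_id=str(get("case_id") or f"case-{rownum}"),
        physician=get("physician"),
        department=get("department"),
        patient_sex=(get("patient_sex") or "").lower() or None,
        birth_date=_parse_date(get("birth_date"), rownum, "birth_date"),
        age_years=age,
        consult_date=_parse_date(get("consult_date"), rownum, "consult_date"),
        consult_season=(get("consult_season") or "").lower() or None,
        symptoms=symptoms if isinstance(symptoms, list) else tokenize_field(symptoms),
        syndrome=get("syndrome"),
        elements=elements if isinstance(elements, list) else tokenize_field(elements),
        element_categories=(cats if isinstance(cats, list)
                            else tokenize_field(cats)),
        disease_name=get("disease_name"),
    )
    rec.validate(row=rownum, require_elements=require_elements)
    return rec


def read_cases(path: str | Path, dialect: str = "delimited",
               require_elements: bool = True) -> list[CaseRecord]:
    """Read a case file; ``dialect`` is ``"delimited"`` (CSV) or ``"json_lines"``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[CaseRecord] = []
    if dialect == "delimited":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise CorpusError(f"{path}: empty file")
            unknown = set(reader.fieldnames) - set(FIELDS)
            if unknown:
                raise CorpusError(f"{path}: unknown columns {sorted(unknown)}")
            for i, row in enumerate(reader, start=2):
                records.append(_record_from_row(row, i, require_elements))
    elif dialect == "json_lines":
        with path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusError(f"row {i}: invalid JSON") from exc
                records.append(_record_from_row(row, i, require_elements))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not records:
        raise CorpusError(f"{path}: empty file")
    return records


def write_cases(cases: list[CaseRecord], path: str | Path,
                dialect: str = "delimited") -> None:
    path = Path(path)
    if dialect == "delimited":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(FIELDS))
            writer.writeheader()
            for rec in cases:
                writer.writerow(rec.to_row())
    elif dialect == "json_lines":
        with path.open("w", encoding="utf-8") as fh:
            for rec in cases:
                row = rec.to_row()
                row["symptoms"] = rec.symptoms
                row["elements"] = rec.elements
                row["element_categories"] = rec.element_categories
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# -- vocabularies ---------------------------------------------------------

UNK = "<unk>"


@dataclass
class Vocab:
    """Bijection token <-> dense integer id; id 0 is the padding/unknown slot."""

    token_to_id: dict[str, int]
    id_to_token: list[str]

    @classmethod
    def from_counts(cls, counts: Counter, min_count: int = 1) -> "Vocab":
        kept = [(t, c) for t, c in counts.items() if c >= min_count]
        kept.sort(key=lambda tc: (-tc[1], tc[0]))  # frequency desc, then lexicographic
        id_to_token = [UNK] + [t for t, _ in kept]
        return cls({t: i for i, t in enumerate(id_to_token)}, id_to_token)

    def __len__(self):
        return len(self.id_to_token)

    def __getitem__(self, token: str) -> int:
        return self.token_to_id.get(token, 0)

    def token(self, idx: int) -> str:
        return self.id_to_token[idx]


@dataclass
class VocabSet:
    symptom_vocab: Vocab
    element_vocab: Vocab
    disease_vocab: Vocab
    scene_vocab: Vocab
    element_category_of: dict[str, str]  # element token -> category code

    def category_of_id(self, element_id: int) -> str | None:
        return self.element_category_of.get(self.element_vocab.token(element_id))


def align_categories(cases: list[CaseRecord]) -> dict[str, str]:
    """Element -> category map.

    Per-position alignment is used when a case's element and category lists
    have equal length; rows where the lengths disagree are logged and only
    consulted through the consistent-row dictionary.  Conflicting
    assignments resolve by majority, ties by lexicographically smaller code.
    """
    votes: dict[str, Counter] = {}
    n_flagged = 0
    for rec in cases:
        if len(rec.elements) == len(rec.element_categories) and rec.elements:
            for el, code in zip(rec.elements, rec.element_categories):
                votes.setdefault(el, Counter())[code] += 1
        elif rec.element_categories:
            n_flagged += 1
            log.warning("case %s: %d elements but %d category codes; "
                        "skipped for category alignment", rec.case_id,
                        len(rec.elements), len(rec.element_categories))
    if n_flagged:
        log.info("category alignment: %d inconsistent rows flagged", n_flagged)
    out: dict[str, str] = {}
    for el, ctr in votes.items():
        top = max(ctr.values())
        out[el] = min(code for code, n in ctr.items() if n == top)
    return out


def build_vocabularies(cases: list[CaseRecord], min_count: int = 1,
                       scene_field: str = "department") -> VocabSet:
    """Build all vocabularies; tokens rarer than ``min_count`` map to id 0."""
    if not cases:
        raise CorpusError("no cases")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    sym, elem, dis, scene = Counter(), Counter(), Counter(), Counter()
    for rec in cases:
        sym.update(set(rec.symptoms))
        elem.update(set(rec.elements))
        if rec.disease_name:
            dis[rec.disease_name] += 1
        val = getattr(rec, scene_field, None)
        if val:
            scene[str(val)] += 1
    vocabs = VocabSet(
        symptom_vocab=Vocab.from_counts(sym, min_count),
        element_vocab=Vocab.from_counts(elem, min_count),
        disease_vocab=Vocab.from_counts(dis, min_count),
        scene_vocab=Vocab.from_counts(scene, 1),
        element_category_of=align_categories(cases),
    )
    if len(vocabs.symptom_vocab) == 1 and len(vocabs.element_vocab) == 1:
        raise CorpusError(f"min_count={min_count} removes every token")
    return vocabs


# -- splitting ------------------------------------------------------------

@dataclass
class DatasetSplit:
    train: list[CaseRecord]
    test: list[CaseRecord]
    split_seed: int


def split_dataset(cases: list[CaseRecord], test_fraction: float,
                  seed: int) -> DatasetSplit:
    """Deterministic shuffled split; test size = round(n * test_fraction)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(cases)
    if n < 2:
        raise CorpusError("need at least 2 records to split")
    n_test = int(round(n * test_fraction))
    n_test = min(max(n_test, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    test_idx = set(order[:n_test].tolist())
    return DatasetSplit(
        train=[cases[i] for i in range(n) if i not in test_idx],
        test=[cases[i] for i in range(n) if i in test_idx],
        split_seed=seed,
    )


# -- feature store --------------------------------------------------------

def corpus_hash(cases: list[CaseRecord]) -> str:
    h = hashlib.sha256()
    for rec in cases:
        h.update(json.dumps(rec.to_row(), sort_keys=True, ensure_ascii=False)
                 .encode("utf-8"))
    return h.hexdigest()[:16]


def serialize_feature_store(features, path: str | Path,
                            corpus_digest: str = "") -> None:
    """Write any object exposing ``to_records()`` to a versioned store directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    records = features.to_records()
    with (path / "features.jsonl").open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")
    manifest = {
        "schema_version": FEATURE_STORE_SCHEMA,
        "feature_class": type(features).__name__,
        "corpus_hash": corpus_digest,
        "created": datetime.now().isoformat(timespec="seconds"),
        "n_records": len(records),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_feature_store(path: str | Path, cls):
    """Load a store written by :func:`serialize_feature_store` as ``cls``."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise CorpusError(f"{path}: not a feature store (no manifest)")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise CorpusError(f"{path}: corrupted manifest") from exc
    if manifest.get("schema_version") != FEATURE_STORE_SCHEMA:
        raise CorpusError(
            f"{path}: schema version {manifest.get('schema_version')!r} "
            f"!= expected {FEATURE_STORE_SCHEMA!r}")
    if manifest.get("feature_class") != cls.__name__:
        raise CorpusError(f"{path}: store holds {manifest.get('feature_class')!r}, "
                          f"requested {cls.__name__}")
    records = []
    try:
        with (path / "features.jsonl").open(encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if line.strip():
                    records.append(json.loads(line))
    except (OSError, json.JSONDecodeError) as exc:
        raise CorpusError(f"{path}: corrupted feature rows") from exc
    if len(records) != manifest["n_records"]:
        raise CorpusError(f"{path}: truncated store "
                          f"({len(records)} != {manifest['n_records']} rows)")
    return cls.from_records(records)


def season_of(d: date) -> str:
    return ("winter", "spring", "summer", "autumn")[(d.month % 12) // 3]


def records_equal(a: CaseRecord, b: CaseRecord) -> bool:
    return dataclasses.asdict(a) == dataclasses.asdict(b)
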