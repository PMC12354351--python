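"""Packaged six-case sample corpus and default knowledge configuration.

The six consultations reproduce published example rows (symptom, syndrome,
element, category and disease fields); the demographic columns are
synthetic placeholders added so every record exercises the full schema.
One row deliberately carries four elements but only three category codes,
exercising the category-alignment fallback.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .corpus import CaseRecord, read_cases


def sample_corpus_path():
    return resources.files("tcmrec.data") / "sample_cases.csv"


def load_sample_corpus() -> list[CaseRecord]:
    with resources.as_file(sample_corpus_path()) as path:
        return read_cases(path, dialect="delimited")


def load_knowledge_config() -> dict:
    ref = resources.files("tcmrec.data") / "knowledge_config.yaml"
    with resources.as_file(ref) as path, open(path) as fh:
        return yaml.safe_load(fh)
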