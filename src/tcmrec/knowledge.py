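"""TCM domain-knowledge features derived from demographics, dates and diagnoses.

Covers the sexagenary (Heavenly-Stem / Earthly-Branch) year cycle and its
five-element correspondences, the female-seven / male-eight age staging
codes, configurable acute/chronic and disease-list labels, a config-driven
constitution lookup keyed by (year stem, birth month), and per-symptom
common-element priors drawn from the association statistics.

The Gregorian calendar year is used for the sexagenary assignment (the
cycle is anchored at 1984 = jia-zi); no lunar new-year correction is
applied — a documented simplification of a few weeks per year boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

from .features import AssociationStats

log = logging.getLogger(__name__)

HEAVENLY_STEMS = ("jia", "yi", "bing", "ding", "wu", "ji",
                  "geng", "xin", "ren", "gui")
EARTHLY_BRANCHES = ("zi", "chou", "yin", "mao", "chen", "si",
                    "wu", "wei", "shen", "you", "xu", "hai")

#: canonical stem -> five-element table (pairs of stems share an element)
STEM_ELEMENT = {
    "jia": "wood", "yi": "wood",
    "bing": "fire", "ding": "fire",
    "wu": "earth", "ji": "earth",
    "geng": "metal", "xin": "metal",
    "ren": "water", "gui": "water",
}

BRANCH_ELEMENT = {
    "zi": "water", "hai": "water",
    "yin": "wood", "mao": "wood",
    "si": "fire", "wu": "fire",
    "shen": "metal", "you": "metal",
    "chen": "earth", "xu": "earth", "chou": "earth", "wei": "earth",
}

#: six-qi sequence used by the default constitution lookup
SIX_QI = ("wind-wood", "sovereign-fire", "ministerial-fire",
          "damp-earth", "dry-metal", "cold-water")

MAX_STAGE = 13


@dataclass
class StemBranchProfile:
    year_stem: str
    year_branch: str
    stem_element: str
    branch_element: str
    fortune_polarity: str  # "excess" (yang stem) | "deficit" (yin stem)
    birth_month: int


def stem_branch_features(birth_date: date | None,
                         stem_element_table: dict[str, str] | None = None
                         ) -> StemBranchProfile | None:
    """Sexagenary profile of the birth year; ``None`` (flagged) when date missing."""
    if birth_date is None:
        log.warning("stem_branch_features: missing birth date")
        return None
    year = birth_date.year
    if year < 1850:
        raise ValueError(f"birth year {year} out of supported range (>= 1850)")
    table = stem_element_table or STEM_ELEMENT
    stem_idx = (year - 4) % 10
    branch_idx = (year - 4) % 12
    stem = HEAVENLY_STEMS[stem_idx]
    branch = EARTHLY_BRANCHES[branch_idx]
    return StemBranchProfile(
        year_stem=stem,
        year_branch=branch,
        stem_element=table[stem],
        branch_element=BRANCH_ELEMENT[branch],
        fortune_polarity="excess" if stem_idx % 2 == 0 else "deficit",
        birth_month=birth_date.month,
    )


@dataclass
class AgeGenderCode:
    code: str
    sex_prefix: int  # 0 female, 1 male
    stage: int


def age_gender_code(sex: str, age_years: int) -> AgeGenderCode:
    """Female-seven / male-eight staging code.

    Stages end at multiples of 7 (female) or 8 (male); age 0 folds into
    stage 1, so female stage 1 = ages 0-7, stage 2 = 8-14, male stage 1 =
    ages 0-8, stage 2 = 9-16, and so on.  The code string is the sex
    prefix (0 female / 1 male) followed by the zero-padded stage.
    """
    if age_years < 0:
        raise ValueError("age_years must be non-negative")
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    width = 7 if sex == "female" else 8
    stage = 1 if age_years == 0 else (age_years - 1) // width + 1
    if stage > MAX_STAGE:
        log.info("age_gender_code: stage %d capped at %d", stage, MAX_STAGE)
        stage = MAX_STAGE
    prefix = 0 if sex == "female" else 1
    return AgeGenderCode(code=f"{prefix}{stage:02d}", sex_prefix=prefix, stage=stage)


def constitution_lookup(profile: StemBranchProfile,
                        table: dict[str, str] | None = None) -> str:
    """Innate-constitution label keyed by (year stem, birth month).

    The doctrine behind this projection is not algorithmic; the default
    table combines the stem's five-element with the birth month's seasonal
    qi from the six-qi sequence.  A config-supplied ``table`` mapping
    ``"<stem>-<month>"`` to labels overrides it.
    """
    key = f"{profile.year_stem}-{profile.birth_month}"
    if table and key in table:
        return table[key]
    qi = SIX_QI[(profile.birth_month - 1) // 2]
    return f"{profile.stem_element}/{qi}"


def diagnosis_labels(tcm_diagnosis: str | None, western_diagnosis: str | None,
                     config: dict) -> dict[str, object]:
    """Acute/chronic flag and disease-list memberships from configured tables.

    ``config`` keys: ``acute`` and ``chronic`` (name lists), ``tcm_diseases``
    (known TCM disease names) and ``western_classes`` (name -> bucket).
    Unknown names map to ``"unlabeled"`` — never guessed.
    """
    acute = {s.lower() for s in config.get("acute", [])}
    chronic = {s.lower() for s in config.get("chronic", [])}
    tcm_list = {s.lower() for s in config.get("tcm_diseases", [])}
    west = {k.lower(): v for k, v in config.get("western_classes", {}).items()}

    tcm = (tcm_diagnosis or "").strip().lower()
    wst = (western_diagnosis or "").strip().lower()
    if tcm in chronic or wst in chronic:
        flag: object = 1
    elif tcm in acute or wst in acute:
        flag = 0
    else:
        flag = "unlabeled"
    return {
        "acute_chronic": flag,
        "tcm_listed": tcm in tcm_list,
        "western_class": west.get(wst, "unlabeled"),
    }


@dataclass
class SymptomPrior:
    """Per-symptom ranked common elements with counts and category codes."""

    common_elements: dict[str, list[str]] = field(default_factory=dict)
    common_element_freq: dict[str, list[int]] = field(default_factory=dict)
    common_element_category: dict[str, str] = field(default_factory=dict)


def symptom_prior_features(symptoms: list[str], stats: AssociationStats,
                           top_m: int = 3,
                           categories: dict[str, str] | None = None) -> SymptomPrior:
    """Top-``top_m`` co-occurring elements per symptom (count desc, then lexicographic)."""
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    prior = SymptomPrior()
    categories = categories or {}
    for sym in symptoms:
        pairs = [(b, n) for (a, b), n in stats.pair_count.items() if a == sym]
        if not pairs:
            log.warning("symptom_prior_features: %r unseen in statistics", sym)
            prior.common_elements[sym] = []
            prior.common_element_freq[sym] = []
            continue
        pairs.sort(key=lambda bn: (-bn[1], bn[0]))
        top = pairs[:top_m]
        prior.common_elements[sym] = [b for b, _ in top]
        prior.common_element_freq[sym] = [n for _, n in top]
        for b, _ in top:
            if b in categories:
                prior.common_element_category[b] = categories[b]
    return prior
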