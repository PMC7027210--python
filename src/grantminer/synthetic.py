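"""Synthetic World RePORT-style corpora with known ground truth.

The generator emits a grants table, a collaborations table and a
ground-truth table whose joint distributions mirror the 2016 portfolio
of the ten funders reporting to World RePORT: funder weights and
per-funder mean durations follow the observed per-funder grant counts,
the health-category mixture follows the observed four-way split, income
groups follow the observed recipient distribution, about 10% of direct
grants spawn collaborations, and collaborating institutions prefer
partners in their own income group (with a high-income pull otherwise).

Titles and abstracts are template sentences with the chosen disease
synonym embedded so that it is the earliest lexicon hit in its
designated field; distractor clauses are verified at build time to
contain no lexicon synonym, so earliest-match logic is genuinely
exercised. Unclassifiable grants are verified to contain no synonym at
all. Generation is fully deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from ._text import normalize_text
from .data_model import (
    CollaborationRecord,
    CountryTable,
    GrantRecord,
    write_collaborations,
    write_grants,
)
from .lexicon import CATEGORIES, Lexicon, TypeLexicon
from .type_classifier import _best_type_hit
from . import resources

#: Observed 2016 grant counts per funder; the default funder weights.
FUNDER_GRANT_COUNTS: dict[str, int] = {
    "NIH": 52928,
    "CIHR": 5567,
    "Wellcome Trust": 5273,
    "MRC": 2649,
    "EC": 1076,
    "SRC": 999,
    "BMGF": 783,
    "Institut Pasteur": 99,
    "Sida": 25,
    "EDCTP": 21,
}

#: Observed mean grant durations per funder, in months.
FUNDER_MEAN_DURATION_MONTHS: dict[str, float] = {
    "NIH": 82.0,
    "CIHR": 52.0,
    "Wellcome Trust": 44.0,
    "MRC": 55.0,
    "EC": 35.0,
    "SRC": 43.0,
    "BMGF": 43.0,
    "Institut Pasteur": 18.0,
    "Sida": 35.0,
    "EDCTP": 33.0,
}

#: Observed 2016 health-category counts (classified grants).
CATEGORY_COUNTS: dict[str, int] = {
    CATEGORIES[0]: 40035,
    CATEGORIES[1]: 11123,
    CATEGORIES[2]: 3056,
    CATEGORIES[3]: 1127,
}

#: Observed 2016 recipient counts per income group.
INCOME_COUNTS: dict[str, int] = {
    "high": 68660,
    "upper_middle": 309,
    "lower_middle": 285,
    "low": 165,
    "unspecified": 1,
}

#: Observed 2016 grant-type shares (research is the remainder's complement
#: split over the three minor matched types).
TYPE_SHARES: dict[str, float] = {
    "research": 0.704,
    "training": 0.187,
    "meetings": 0.042,
    "capacity_strengthening": 0.030,
    "core_funding": 0.020,
    "networking": 0.017,
}

_TERRA_INCOGNITA = "Terra Incognita"  # synthetic unlisted territory

_PRE_PHRASES = (
    "mechanistic studies of",
    "longitudinal cohort analysis of",
    "randomised evaluation of interventions for",
    "molecular determinants of",
    "community surveillance of",
    "novel biomarkers for",
    "host immune responses in",
    "comparative epidemiology of",
    "therapeutic targeting of",
    "implementation strategies for",
)

_POST_PHRASES = (
    "in urban populations",
    "in a multicentre setting",
    "using single-cell profiling",
    "across diverse age groups",
    "with integrated data platforms",
    "in low-resource settings",
    "through advanced imaging",
    "via computational modelling",
    "in primary care",
    "among older adults",
)

_NEUTRAL_TITLES = (
    "advanced methods in quantitative cell biology",
    "statistical approaches to population genomics",
    "improving laboratory measurement standards",
    "computational modelling of biomolecular systems",
    "innovations in biomedical engineering",
    "data infrastructure for clinical registries",
    "proteomic profiling of tissue microenvironments",
    "imaging technologies for translational science",
    "methods development for causal inference",
    "high-throughput screening platform development",
)

_ABSTRACT_FILLERS = (
    "This project will develop new experimental and analytical tools.",
    "The team combines laboratory assays with population-scale data.",
    "Findings will be disseminated through open-access publications.",
    "The work builds on an established multidisciplinary collaboration.",
    "Rigorous quality control procedures will be applied throughout.",
    "The study design includes prospective and retrospective components.",
)

_TYPE_PHRASES: dict[str, str] = {
    "core_funding": "core funding for",
    "training": "doctoral training programme:",
    "capacity_strengthening": "fellowship award:",
    "meetings": "international conference:",
    "networking": "research networking initiative:",
}

_INSTITUTIONS = (
    "University of Northbridge",
    "Easthaven Institute of Health Sciences",
    "Marlow Research Centre",
    "Westfield Medical College",
    "Kingsport School of Public Health",
    "Ravenhill University",
    "Claremont Biomedical Institute",
    "Harrowgate Centre for Clinical Studies",
)


def _normalised(weights: Mapping[str, float], name: str) -> dict[str, float]:
    vals = np.asarray(list(weights.values()), dtype=float)
    if (vals < 0).any() or vals.sum() <= 0:
        raise ValueError(f"{name}: weights must be nonnegative with positive sum")
    vals = vals / vals.sum()
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name}: weights do not normalise")
    return dict(zip(weights.keys(), vals))


@dataclass
class SynthConfig:
    """Study conditions for a synthetic corpus.

    Weight mappings are normalised on construction; the defaults are the
    observed 2016 portfolio proportions described in the module docstring.
    """

    n_grants: int = 1000
    seed: int = 0
    year: int = 2016
    funder_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(FUNDER_GRANT_COUNTS)
    )
    category_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(CATEGORY_COUNTS)
    )
    income_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(INCOME_COUNTS)
    )
    type_mix: Mapping[str, float] = field(default_factory=lambda: dict(TYPE_SHARES))
    p_abstract: float = 0.8
    p_unclassifiable: float = 0.2
    p_title_mention: float = 0.5
    p_collab: float = 0.10
    collab_count_law: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.28, 2: 0.24, 3: 0.18, 4: 0.12, 5: 0.10, 6: 0.08}
    )
    collab_same_group: float = 0.6
    p_second_mention: float = 0.0
    duration_mean_months: Mapping[str, float] = field(
        default_factory=lambda: dict(FUNDER_MEAN_DURATION_MONTHS)
    )
    duration_sd_months: float = 9.0

    def __post_init__(self):
        if self.n_grants < 0:
            raise ValueError("n_grants must be >= 0")
        for p_name in ("p_abstract", "p_unclassifiable", "p_title_mention",
                       "p_collab", "collab_same_group", "p_second_mention"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{p_name} must be a probability, got {p}")
        self.funder_weights = _normalised(self.funder_weights, "funder_weights")
        self.category_mix = _normalised(self.category_mix, "category_mix")
        self.income_mix = _normalised(self.income_mix, "income_mix")
        self.type_mix = _normalised(self.type_mix, "type_mix")
        self.collab_count_law = _normalised(self.collab_count_law, "collab_count_law")


class SyntheticCorpus(NamedTuple):
    grants: list[GrantRecord]
    collaborations: list[CollaborationRecord]
    truth: pd.DataFrame


def _pick(rng: np.random.Generator, weights: Mapping) -> object:
    keys = list(weights.keys())
    return keys[int(rng.choice(len(keys), p=list(weights.values())))]


def _clean_phrases(phrases, lexicon: Lexicon, type_lexicon: TypeLexicon):
    """Drop template phrases that collide with either synonym list."""
    out = []
    for ph in phrases:
        norm = normalize_text(ph)
        if lexicon.first_match(norm) is None and _best_type_hit(norm, type_lexicon) is None:
            out.append(ph)
    if not out:
        raise ValueError("no template phrase survives the supplied lexicons")
    return out


class _TextBuilder:
    def __init__(self, rng, lexicon, type_lexicon):
        self.rng = rng
        self.lexicon = lexicon
        self.type_lexicon = type_lexicon
        self.pre = _clean_phrases(_PRE_PHRASES, lexicon, type_lexicon)
        self.post = _clean_phrases(_POST_PHRASES, lexicon, type_lexicon)
        self.neutral = _clean_phrases(_NEUTRAL_TITLES, lexicon, type_lexicon)
        self.abstract_fillers = _clean_phrases(_ABSTRACT_FILLERS, lexicon, type_lexicon)

    def _choice(self, seq):
        return seq[int(self.rng.integers(len(seq)))]

    def title_with(self, synonym: str, type_phrase: str | None) -> str:
        parts = []
        if type_phrase:
            parts.append(type_phrase)
        parts.append(self._choice(self.pre))
        parts.append(synonym)
        parts.append(self._choice(self.post))
        return " ".join(parts)

    def neutral_title(self, type_phrase: str | None) -> str:
        body = self._choice(self.neutral)
        return f"{type_phrase} {body}" if type_phrase else body

    def abstract_with(self, synonym: str | None, second: str | None = None) -> str:
        sentences = [self._choice(self.abstract_fillers)]
        if synonym is not None:
            sentences.append(
                f"The central focus of this work is {synonym} and its broader determinants."
            )
        if second is not None:
            sentences.append(f"Comorbidity with {second} will also be examined.")
        sentences.append(self._choice(self.abstract_fillers))
        return " ".join(sentences)


def _verify_grant(
    grant: GrantRecord,
    true_disease: str | None,
    true_field: str,
    true_type: str,
    lexicon: Lexicon,
    type_lexicon: TypeLexicon,
) -> bool:
    t_norm = normalize_text(grant.title)
    a_norm = normalize_text(grant.abstract)
    t_hit = lexicon.first_match(t_norm)
    a_hit = lexicon.first_match(a_norm)
    if true_disease is None:
        if t_hit is not None or a_hit is not None:
            return False
    elif true_field == "title":
        if t_hit is None or t_hit.entry.disease != true_disease:
            return False
    else:
        if t_hit is not None:
            return False
        if a_hit is None or a_hit.entry.disease != true_disease:
            return False
    type_hit = _best_type_hit(t_norm, type_lexicon) or _best_type_hit(a_norm, type_lexicon)
    if true_type == "research":
        return type_hit is None
    return type_hit is not None and type_hit[4] == true_type


def generate_corpus(
    config: SynthConfig,
    lexicon: Lexicon | None = None,
    type_lexicon: TypeLexicon | None = None,
    country_table: CountryTable | None = None,
) -> SyntheticCorpus:
    """Generate (grants, collaborations, ground truth) under ``config``.

    Every grant is verified post-hoc against the lexicons: the true
    synonym is the earliest hit in its designated field, unclassifiable
    grants contain no synonym, and the planted type synonym (or its
    absence, for research) is recoverable. Identical (config, seed)
    yields an identical corpus.
    """
    lexicon = lexicon if lexicon is not None else resources.demo_lexicon()
    type_lexicon = (
        type_lexicon if type_lexicon is not None else resources.demo_type_lexicon()
    )
    country_table = (
        country_table if country_table is not None else resources.demo_country_table()
    )
    by_cat = lexicon.diseases_by_category()
    for cat in config.category_mix:
        if config.category_mix[cat] > 0 and not by_cat.get(cat):
            raise ValueError(f"lexicon has no disease in requested category {cat!r}")
    countries_by_group = country_table.countries_by_income_group()
    for grp in config.income_mix:
        if grp == "unspecified":
            continue
        if config.income_mix[grp] > 0 and not countries_by_group.get(grp):
            raise ValueError(f"country table has no country in income group {grp!r}")

    rng = np.random.default_rng(config.seed)
    builder = _TextBuilder(rng, lexicon, type_lexicon)
    grants: list[GrantRecord] = []
    collaborations: list[CollaborationRecord] = []
    truth_rows = []

    for i in range(config.n_grants):
        gid = f"G{config.year}-{i:06d}"
        funder = _pick(rng, config.funder_weights)
        income_group = _pick(rng, config.income_mix)
        if income_group == "unspecified":
            country, region = _TERRA_INCOGNITA, "unspecified"
        else:
            country = builder._choice(countries_by_group[income_group])
            region = country_table.get(country).who_region
        true_type = _pick(rng, config.type_mix)
        type_phrase = _TYPE_PHRASES.get(true_type)

        classifiable = rng.random() >= config.p_unclassifiable
        if classifiable:
            category = _pick(rng, config.category_mix)
            disease = builder._choice(by_cat[category])
            synonym = builder._choice(lexicon.synonyms_for_disease(disease))
            true_field = "title" if rng.random() < config.p_title_mention else "abstract"
        else:
            category = disease = synonym = None
            true_field = "none"

        second = None
        if classifiable and rng.random() < config.p_second_mention:
            other = [d for ds in by_cat.values() for d in ds if d != disease]
            if other:
                second = builder._choice(lexicon.synonyms_for_disease(builder._choice(other)))

        has_abstract = true_field == "abstract" or rng.random() < config.p_abstract

        for _attempt in range(20):
            if true_field == "title":
                title = builder.title_with(synonym, type_phrase)
                if second is not None:
                    title = f"{title} and comorbid {second}"
                abstract = builder.abstract_with(None) if has_abstract else None
            elif true_field == "abstract":
                title = builder.neutral_title(type_phrase)
                abstract = builder.abstract_with(synonym, second)
            else:
                title = builder.neutral_title(type_phrase)
                abstract = builder.abstract_with(None) if has_abstract else None

            mean = config.duration_mean_months.get(funder, 48.0)
            months = max(6, int(round(rng.normal(mean, config.duration_sd_months))))
            start = date(config.year, 1, 1) + timedelta(days=int(rng.integers(365)))
            end = start + timedelta(days=int(round(months * 30.4375)))
            grant = GrantRecord(
                grant_id=gid,
                funder=funder,
                title=title,
                year=config.year,
                abstract=abstract,
                recipient_institution=builder._choice(_INSTITUTIONS),
                recipient_country=country,
                start_date=start,
                end_date=end,
            )
            if _verify_grant(grant, disease, true_field, true_type, lexicon, type_lexicon):
                break
        else:
            raise RuntimeError(f"could not build a verifiable grant for {gid}")

        grants.append(grant)
        truth_rows.append(
            {
                "grant_id": gid,
                "true_disease": disease,
                "true_category": category,
                "true_field": true_field,
                "true_type": true_type,
                "true_income_group": income_group,
                "true_region": region,
            }
        )

        if rng.random() < config.p_collab:
            k = int(_pick(rng, config.collab_count_law))
            for _ in range(k):
                if rng.random() < config.collab_same_group:
                    partner_group = income_group
                elif income_group != "high" and rng.random() < 0.7:
                    partner_group = "high"
                else:
                    others = [g for g in config.income_mix if g != income_group]
                    partner_group = builder._choice(others)
                if partner_group == "unspecified":
                    partner_country = _TERRA_INCOGNITA
                else:
                    partner_country = builder._choice(countries_by_group[partner_group])
                collaborations.append(
                    CollaborationRecord(
                        direct_grant_id=gid,
                        collab_institution=builder._choice(_INSTITUTIONS),
                        collab_country=partner_country,
                    )
                )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "grant_id",
            "true_disease",
            "true_category",
            "true_field",
            "true_type",
            "true_income_group",
            "true_region",
        ],
    )
    return SyntheticCorpus(grants, collaborations, truth)


def corpus_report(grants, truth: pd.DataFrame) -> dict[str, dict[str, tuple[int, float]]]:
    """Realised category/type/income mixes: key -> (count, proportion)."""
    grants = list(grants)
    n = len(grants)
    report: dict[str, dict[str, tuple[int, float]]] = {}
    if n == 0:
        return report
    for col, name in (
        ("true_category", "category"),
        ("true_type", "type"),
        ("true_income_group", "income_group"),
    ):
        counts = truth[col].value_counts(dropna=True)
        report[name] = {str(k): (int(v), v / n) for k, v in counts.items()}
    return report


def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> dict[str, Path]:
    """Write grants/collaborations/truth CSVs in the standard dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "grants": out_dir / "grants.csv",
        "collaborations": out_dir / "collaborations.csv",
        "truth": out_dir / "truth.csv",
    }
    write_grants(corpus.grants, paths["grants"])
    write_collaborations(corpus.collaborations, paths["collaborations"])
    corpus.truth.to_csv(paths["truth"], index=False)
    return paths
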