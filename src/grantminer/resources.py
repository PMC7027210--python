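"""Bundled demonstration resources.

The package ships a small demonstration disease lexicon (every top-level
health category and subcategory represented, with neglected-tropical-
disease and blueprint-pathogen exemplars), a reconstructed grant-type
synonym list, and a country-metadata table. They are illustrative: a
production analysis would substitute the full, maintained synonym list
and the complete country classification in the same file formats.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

from .data_model import CountryTable, load_country_table
from .lexicon import Lexicon, TypeLexicon, load_lexicon, load_type_lexicon


def _data_path(name: str) -> Path:
    return Path(str(files("grantminer").joinpath("data", name)))


def demo_lexicon_path() -> Path:
    return _data_path("demo_lexicon.csv")


def demo_type_lexicon_path() -> Path:
    return _data_path("type_lexicon.json")


def demo_country_table_path() -> Path:
    return _data_path("countries.csv")


def demo_lexicon() -> Lexicon:
    return load_lexicon(demo_lexicon_path())


def demo_type_lexicon() -> TypeLexicon:
    return load_type_lexicon(demo_type_lexicon_path())


def demo_country_table() -> CountryTable:
    return load_country_table(demo_country_table_path())
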