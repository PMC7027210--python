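"""Core record types and table readers/writers.

The grants table follows a World RePORT-export-like schema: one row per
direct (primary) grant with funder, free-text title/abstract, recipient
institution and country, and start/end dates. A companion collaborations
table lists the institutions a direct grant collaborated with, keyed by
the direct grant's id. Column headers are configuration, not hard-coded:
a default mapping ships with the package, but any export dialect can be
described with :class:`TableDialect`.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

#: The closed six-value set of WHO regions.
WHO_REGIONS = (
    "Africa",
    "Americas",
    "Eastern Mediterranean",
    "Europe",
    "South-East Asia",
    "Western Pacific",
)

#: World Bank income groups plus the explicit "unspecified" bucket.
INCOME_GROUPS = ("high", "upper_middle", "lower_middle", "low", "unspecified")

_FIELDS = (
    "grant_id",
    "funder",
    "year",
    "title",
    "abstract",
    "recipient_institution",
    "recipient_country",
    "start_date",
    "end_date",
)
_MANDATORY_COLUMNS = ("grant_id", "funder", "title")
_YEAR_ONLY = re.compile(r"^\d{4}$")


@dataclass(frozen=True)
class TableDialect:
    """How to read a grants export: delimiter, column names, date format."""

    delimiter: str = ","
    columns: Mapping[str, str] = field(
        default_factory=lambda: {f: f for f in _FIELDS}
    )
    date_format: str = "%Y-%m-%d"
    encoding: str = "utf-8"


DEFAULT_DIALECT = TableDialect()


@dataclass(frozen=True)
class GrantRecord:
    """One direct grant."""

    grant_id: str
    funder: str
    title: str
    year: int | None = None
    abstract: str | None = None
    recipient_institution: str = ""
    recipient_country: str = ""
    start_date: date | None = None
    end_date: date | None = None

    def __post_init__(self):
        if not self.grant_id:
            raise ValueError("grant_id must be nonempty")
        if (
            self.start_date is not None
            and self.end_date is not None
            and self.end_date < self.start_date
        ):
            raise ValueError(
                f"grant {self.grant_id}: end_date {self.end_date} precedes "
                f"start_date {self.start_date}"
            )


@dataclass(frozen=True)
class CollaborationRecord:
    """One collaboration spawned by a direct grant."""

    direct_grant_id: str
    collab_institution: str
    collab_country: str
    resolved: bool = True


@dataclass(frozen=True)
class CountryInfo:
    country: str
    who_region: str
    income_group: str = "unspecified"
    gdp_per_capita: float | None = None


@dataclass
class LoadResult:
    """Outcome of loading a grants table: nothing is dropped silently."""

    records: list[GrantRecord]
    n_rejected: int = 0
    rejected_rows: list[int] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def n_in(self) -> int:
        return len(self.records) + self.n_rejected


def canonical_country(name: str) -> str:
    """Trim, collapse whitespace and case-fold a country name for lookup."""
    return re.sub(r"\s+", " ", str(name).strip()).casefold()


def _parse_date(raw: str, fmt: str, grant_id: str, flags: list[str]) -> date | None:
    raw = raw.strip()
    if not raw:
        return None
    if _YEAR_ONLY.match(raw):
        flags.append(f"grant {grant_id}: partial date {raw!r} resolved to {raw}-01-01")
        return date(int(raw), 1, 1)
    return datetime.strptime(raw, fmt).date()


def _read_rows(path: Path, dialect: TableDialect) -> list[dict[str, str]]:
    try:
        with open(path, newline="", encoding=dialect.encoding) as fh:
            return list(csv.DictReader(fh, delimiter=dialect.delimiter))
    except UnicodeDecodeError:
        log.warning("%s: %s decode failed, falling back to latin-1", path, dialect.encoding)
        with open(path, newline="", encoding="latin-1") as fh:
            return list(csv.DictReader(fh, delimiter=dialect.delimiter))


def load_grants(path: str | Path, dialect: TableDialect = DEFAULT_DIALECT) -> LoadResult:
    """Load a grants table.

    Rows with a missing grant_id are rejected and counted (never silently
    dropped); duplicate grant_ids raise :class:`ValueError` listing the
    offenders; an unmapped mandatory column raises :class:`KeyError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = _read_rows(path, dialect)
    header = set(rows[0]) if rows else _probe_header(path, dialect)
    for fld in _MANDATORY_COLUMNS:
        col = dialect.columns.get(fld, fld)
        if col not in header:
            raise KeyError(f"mandatory column {col!r} (field {fld}) not in header")

    col = {f: dialect.columns.get(f, f) for f in _FIELDS}
    result = LoadResult(records=[])
    for i, row in enumerate(rows, start=2):
        gid = (row.get(col["grant_id"]) or "").strip()
        if not gid:
            result.n_rejected += 1
            result.rejected_rows.append(i)
            continue
        year_raw = (row.get(col["year"]) or "").strip()
        result.records.append(
            GrantRecord(
                grant_id=gid,
                funder=(row.get(col["funder"]) or "").strip(),
                title=row.get(col["title"]) or "",
                year=int(year_raw) if year_raw else None,
                abstract=(row.get(col["abstract"]) or None),
                recipient_institution=(row.get(col["recipient_institution"]) or "").strip(),
                recipient_country=(row.get(col["recipient_country"]) or "").strip(),
                start_date=_parse_date(
                    row.get(col["start_date"]) or "", dialect.date_format, gid, result.flags
                ),
                end_date=_parse_date(
                    row.get(col["end_date"]) or "", dialect.date_format, gid, result.flags
                ),
            )
        )
    ids: dict[str, int] = {}
    for r in result.records:
        ids[r.grant_id] = ids.get(r.grant_id, 0) + 1
    dupes = sorted(g for g, n in ids.items() if n > 1)
    if dupes:
        raise ValueError(f"duplicate grant_ids: {dupes}")
    if result.n_rejected:
        log.warning(
            "%s: rejected %d row(s) with missing grant_id (rows %s)",
            path, result.n_rejected, result.rejected_rows,
        )
    return result


def _probe_header(path: Path, dialect: TableDialect) -> set[str]:
    with open(path, newline="", encoding=dialect.encoding) as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        try:
            return set(next(reader))
        except StopIteration:
            return set()


def write_grants(
    records: Iterable[GrantRecord],
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> None:
    """Write grants back to CSV; inverse of :func:`load_grants`."""
    col = {f: dialect.columns.get(f, f) for f in _FIELDS}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow([col[f] for f in _FIELDS])
        for r in records:
            writer.writerow(
                [
                    r.grant_id,
                    r.funder,
                    "" if r.year is None else r.year,
                    r.title,
                    "" if r.abstract is None else r.abstract,
                    r.recipient_institution,
                    r.recipient_country,
                    "" if r.start_date is None else r.start_date.strftime(dialect.date_format),
                    "" if r.end_date is None else r.end_date.strftime(dialect.date_format),
                ]
            )


def load_collaborations(
    path: str | Path,
    known_grant_ids: set[str] | None = None,
) -> list[CollaborationRecord]:
    """Load the collaborations table.

    Rows whose direct_grant_id does not resolve against ``known_grant_ids``
    are kept but flagged ``resolved=False`` — funders are not always able
    to account for every collaboration, and dropping them would hide that.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            gid = (row.get("direct_grant_id") or "").strip()
            resolved = known_grant_ids is None or gid in known_grant_ids
            if not resolved:
                log.warning("collaboration references unknown grant %r", gid)
            out.append(
                CollaborationRecord(
                    direct_grant_id=gid,
                    collab_institution=(row.get("collab_institution") or "").strip(),
                    collab_country=(row.get("collab_country") or "").strip(),
                    resolved=resolved,
                )
            )
    return out


def write_collaborations(records: Iterable[CollaborationRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["direct_grant_id", "collab_institution", "collab_country"])
        for r in records:
            writer.writerow([r.direct_grant_id, r.collab_institution, r.collab_country])


class CountryTable:
    """Case-insensitive country -> :class:`CountryInfo` lookup."""

    def __init__(self, infos: Iterable[CountryInfo]):
        self._by_canon: dict[str, CountryInfo] = {}
        for info in infos:
            self._by_canon[canonical_country(info.country)] = info

    def get(self, country: str) -> CountryInfo | None:
        return self._by_canon.get(canonical_country(country))

    def __contains__(self, country: str) -> bool:
        return canonical_country(country) in self._by_canon

    def __len__(self) -> int:
        return len(self._by_canon)

    def __iter__(self):
        return iter(self._by_canon.values())

    def countries_by_income_group(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for info in self._by_canon.values():
            out.setdefault(info.income_group, []).append(info.country)
        return out


def load_country_table(path: str | Path) -> CountryTable:
    """Load country metadata (WHO region, income group, optional GDP pc)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    infos = []
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            region = row["who_region"].strip()
            if region not in WHO_REGIONS:
                raise ValueError(f"row {i}: unknown WHO region {region!r}")
            group = (row.get("income_group") or "unspecified").strip() or "unspecified"
            if group not in INCOME_GROUPS:
                raise ValueError(f"row {i}: unknown income group {group!r}")
            gdp_raw = (row.get("gdp_per_capita") or "").strip()
            infos.append(
                CountryInfo(
                    country=row["country"].strip(),
                    who_region=region,
                    income_group=group,
                    gdp_per_capita=float(gdp_raw) if gdp_raw else None,
                )
            )
    return CountryTable(infos)


def with_abstract(record: GrantRecord, abstract: str | None) -> GrantRecord:
    """Convenience copy-with-update used when mapping in scraped abstracts."""
    return replace(record, abstract=abstract)
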