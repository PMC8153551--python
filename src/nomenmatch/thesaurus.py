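"""The parsed reference checklist (accepted names + synonyms) and its indexes.

The checklist arrives as a delimited text file with one name per row, a
status column (``accepted`` or ``synonym``) and, for synonyms, the verbatim
full name of the accepted entry they point to.  Building the thesaurus
parses every name once and indexes entries by normalized full name (for the
exact-match pre-processing step) and by genus phonetic key (for candidate
generation), so matching never re-parses the reference side.

Unparseable rows are quarantined — collected in a report — rather than
aborting a 24k-name build; duplicate accepted full names keep the first
occurrence with a warning.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .nameparse import InfraPart, ParsedName, ParseError, Rank, parse_name
from .options import MatchOptions
from .textnorm import normalize_string

__all__ = [
    "ReferenceEntry",
    "Thesaurus",
    "ChecklistError",
    "load_checklist",
    "build_thesaurus",
    "save_thesaurus",
    "load_thesaurus",
]

STATUS_ACCEPTED = "accepted"
STATUS_SYNONYM = "synonym"


class ChecklistError(ValueError):
    """Raised when a checklist file cannot be loaded."""


@dataclass(frozen=True)
class ReferenceEntry:
    entry_id: str
    full_name: str
    status: str  # accepted | synonym
    accepted_id: str  # self for accepted entries
    parsed: ParsedName

    @property
    def is_accepted(self) -> bool:
        return self.status == STATUS_ACCEPTED


@dataclass
class Thesaurus:
    entries: dict[str, ReferenceEntry] = field(default_factory=dict)
    #: genus phonetic key -> entry ids
    genus_index: dict[str, list[str]] = field(default_factory=dict)
    #: normalized full name -> entry ids (plus a case-folded shadow index)
    name_index: dict[str, list[str]] = field(default_factory=dict)
    _name_index_ci: dict[str, list[str]] = field(default_factory=dict)
    quarantine: list[tuple[int, str, str]] = field(default_factory=list)  # (row, name, reason)

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, entry: ReferenceEntry) -> None:
        self.entries[entry.entry_id] = entry
        self.genus_index.setdefault(entry.parsed.genus_phonetic, []).append(entry.entry_id)
        key = normalize_string(entry.full_name)
        self.name_index.setdefault(key, []).append(entry.entry_id)
        self._name_index_ci.setdefault(key.casefold(), []).append(entry.entry_id)

    def lookup_exact(self, normalized: str, *, case_insensitive: bool = False) -> list[str]:
        """Entry ids whose normalized full name equals ``normalized``."""
        if case_insensitive:
            return list(self._name_index_ci.get(normalized.casefold(), []))
        return list(self.name_index.get(normalized, []))

    def accepted_entry(self, entry_id: str) -> ReferenceEntry:
        """Resolve any entry to its accepted entry in one hop."""
        entry = self.entries[entry_id]
        return self.entries[entry.accepted_id]


def load_checklist(
    path: str | Path,
    *,
    delimiter: str = ",",
    name_column: str = "name",
    status_column: str = "status",
    accepted_column: str = "accepted_name",
) -> list[tuple[str, str, str]]:
    """Read (full_name, status, accepted_ref) triples from a delimited file.

    ``status`` is case-folded to ``accepted``/``synonym``; a synonym row with
    an empty accepted reference is a :class:`ChecklistError` naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise ChecklistError(f"checklist file not found: {path}")
    rows: list[tuple[str, str, str]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in (name_column, status_column, accepted_column):
            if col not in header:
                raise ChecklistError(f"missing column {col!r} in {path} (header: {header})")
        for lineno, row in enumerate(reader, start=2):
            name = (row[name_column] or "").strip()
            status = (row[status_column] or "").strip().casefold()
            accepted_ref = (row[accepted_column] or "").strip()
            if not name:
                continue
            if status not in (STATUS_ACCEPTED, STATUS_SYNONYM):
                raise ChecklistError(f"row {lineno}: unknown status {row[status_column]!r}")
            if status == STATUS_SYNONYM and not accepted_ref:
                raise ChecklistError(f"row {lineno}: synonym {name!r} has no accepted reference")
            rows.append((name, status, accepted_ref))
    return rows


def build_thesaurus(rows: Iterable[tuple[str, str, str]], options: MatchOptions | None = None) -> Thesaurus:
    """Parse and index checklist rows into a :class:`Thesaurus`.

    Accepted entries are inserted first so synonyms can resolve their target
    by verbatim name; rows that fail to parse, and synonyms whose accepted
    target is missing, land in ``thesaurus.quarantine``.
    """
    options = options or MatchOptions()
    thesaurus = Thesaurus()
    rows = list(rows)
    by_name: dict[str, str] = {}  # accepted full_name -> entry_id

    parsed_rows: list[tuple[int, str, str, str, ParsedName]] = []
    for i, (name, status, accepted_ref) in enumerate(rows):
        normalized = normalize_string(name, treat_cfr_as_uncertain=options.treat_cfr_as_uncertain)
        try:
            parsed = parse_name(normalized, options)
        except ParseError as exc:
            thesaurus.quarantine.append((i, name, str(exc)))
            continue
        parsed_rows.append((i, name, status, accepted_ref, parsed))

    for i, name, status, accepted_ref, parsed in parsed_rows:
        if status != STATUS_ACCEPTED:
            continue
        if name in by_name:
            warnings.warn(f"duplicate accepted name {name!r} (row {i}); keeping the first", stacklevel=2)
            continue
        entry_id = f"e{i:06d}"
        by_name[name] = entry_id
        thesaurus.add(ReferenceEntry(entry_id, name, STATUS_ACCEPTED, entry_id, parsed))

    for i, name, status, accepted_ref, parsed in parsed_rows:
        if status != STATUS_SYNONYM:
            continue
        target = by_name.get(accepted_ref)
        if target is None:
            thesaurus.quarantine.append((i, name, f"accepted target {accepted_ref!r} not found"))
            continue
        entry_id = f"e{i:06d}"
        thesaurus.add(ReferenceEntry(entry_id, name, STATUS_SYNONYM, target, parsed))

    return thesaurus


# --- persistence: one flat TSV row per entry, one column per parsed field ---

_COLUMNS = [
    "entry_id", "full_name", "status", "accepted_id",
    "genus", "genus_phonetic", "species", "species_phonetic", "species_authority",
    "parse_flag", "ambiguous_token", "case_insensitive", "tail",
]
for _n in (1, 2):
    _COLUMNS += [f"infra{_n}_rank", f"infra{_n}_token", f"infra{_n}_epithet",
                 f"infra{_n}_phonetic", f"infra{_n}_authority"]


def save_thesaurus(thesaurus: Thesaurus, path: str | Path) -> None:
    """Persist the parsed form as a diffable TSV (one column per field)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for entry_id in sorted(thesaurus.entries):
            e = thesaurus.entries[entry_id]
            p = e.parsed
            row = [
                e.entry_id, e.full_name, e.status, e.accepted_id,
                p.genus, p.genus_phonetic, p.species_epithet, p.species_phonetic,
                p.species_authority, p.parse_flag, p.ambiguous_token,
                "1" if p.case_insensitive else "0", " ".join(p.tail_tokens),
            ]
            for n in range(2):
                if n < len(p.infra):
                    part = p.infra[n]
                    row += [part.rank.value, part.rank_token, part.epithet,
                            part.epithet_phonetic, part.authority]
                else:
                    row += ["", "", "", "", ""]
            writer.writerow(row)


def load_thesaurus(path: str | Path) -> Thesaurus:
    """Rebuild a :class:`Thesaurus` from :func:`save_thesaurus` output."""
    thesaurus = Thesaurus()
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _COLUMNS:
            raise ChecklistError(f"{path} is not a thesaurus file (bad header)")
        for row in reader:
            infra = []
            for n in (1, 2):
                if row[f"infra{n}_epithet"]:
                    infra.append(
                        InfraPart(
                            rank=Rank(row[f"infra{n}_rank"]),
                            rank_token=row[f"infra{n}_token"],
                            epithet=row[f"infra{n}_epithet"],
                            epithet_phonetic=row[f"infra{n}_phonetic"],
                            authority=row[f"infra{n}_authority"],
                        )
                    )
            parsed = ParsedName(
                genus=row["genus"],
                genus_phonetic=row["genus_phonetic"],
                species_epithet=row["species"],
                species_phonetic=row["species_phonetic"],
                species_authority=row["species_authority"],
                infra=tuple(infra),
                parse_flag=row["parse_flag"],
                ambiguous_token=row["ambiguous_token"],
                tail_tokens=tuple(row["tail"].split()) if row["tail"] else (),
                case_insensitive=row["case_insensitive"] == "1",
            )
            thesaurus.add(
                ReferenceEntry(row["entry_id"], row["full_name"], row["status"], row["accepted_id"], parsed)
            )
    return thesaurus
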