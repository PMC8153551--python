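"""Batch list matching: read a names list, dedupe, match, report, export.

The batch tool reads names from plain text (one per line) or CSV (user
picks the separator and the name column), removes duplicates, runs each
name through the four-stage pipeline (normalize, exact pre-process, parse,
match) and produces a summary report plus a four-column CSV: original
name, accepted name, synonym (filled when the match hit a synonym rather
than an accepted name) and score.  Ambiguous rows carry the top candidate
with an asterisk on the score so batch users still get a best guess.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .matching import (
    STATUS_AMBIGUOUS,
    STATUS_EXACT,
    STATUS_NONE,
    STATUS_UNAMBIGUOUS,
    MatchResult,
    match_name,
)
from .options import MatchOptions
from .textnorm import normalize_string
from .thesaurus import Thesaurus

__all__ = ["MatchOptions", "ListMatchReport", "ListSizeError", "read_name_list",
           "run_list_match", "write_results_csv"]

logger = logging.getLogger(__name__)


class ListSizeError(ValueError):
    """Raised when a list exceeds the distinct-name cap."""


@dataclass(frozen=True)
class ListMatchReport:
    total_names: int
    distinct_names: int
    n_exact: int
    n_unambiguous: int
    n_ambiguous: int
    n_none: int
    elapsed: float

    def __post_init__(self) -> None:
        if self.n_exact + self.n_unambiguous + self.n_ambiguous + self.n_none != self.distinct_names:
            raise ValueError("status tallies do not sum to the number of distinct names")

    def as_dict(self) -> dict:
        return {
            "total_names": self.total_names,
            "distinct_names": self.distinct_names,
            "exact": self.n_exact,
            "unambiguous": self.n_unambiguous,
            "ambiguous": self.n_ambiguous,
            "none": self.n_none,
            "elapsed_seconds": round(self.elapsed, 3),
        }


def read_name_list(
    path: str | Path,
    options: MatchOptions | None = None,
    *,
    fmt: str | None = None,
) -> tuple[list[str], int]:
    """Read a name list and deduplicate it.

    ``fmt`` is ``"text"`` or ``"csv"``; when omitted it is inferred from the
    file extension.  Deduplication keys on the normalized name (case-folded
    when case-insensitive matching is forced), keeping first occurrences in
    order.  Returns (distinct names, total raw count); more distinct names
    than ``options.max_names`` raises :class:`ListSizeError`.
    """
    options = options or MatchOptions()
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "text"

    if fmt == "csv":
        if options.name_column is None:
            raise ValueError("CSV input requires options.name_column")
        df = pd.read_csv(path, sep=options.separator_char, dtype=str, keep_default_na=False)
        if isinstance(options.name_column, int):
            if options.name_column >= df.shape[1]:
                raise ValueError(f"column index {options.name_column} out of range")
            series = df.iloc[:, options.name_column]
        else:
            if options.name_column not in df.columns:
                raise ValueError(f"column {options.name_column!r} not in {list(df.columns)}")
            series = df[options.name_column]
        raw = [str(v) for v in series.tolist()]
    else:
        raw = path.read_text(encoding="utf-8").splitlines()

    raw = [r.strip() for r in raw if r.strip()]
    seen: set[str] = set()
    distinct: list[str] = []
    for name in raw:
        key = normalize_string(name, treat_cfr_as_uncertain=options.treat_cfr_as_uncertain)
        if options.force_case_insensitive:
            key = key.casefold()
        if key and key not in seen:
            seen.add(key)
            distinct.append(name)
    if len(distinct) > options.max_names:
        raise ListSizeError(
            f"{len(distinct)} distinct names exceed the {options.max_names}-name cap"
        )
    return distinct, len(raw)


def run_list_match(
    names: list[str],
    thesaurus: Thesaurus,
    options: MatchOptions | None = None,
    *,
    total_names: int | None = None,
) -> tuple[list[MatchResult], ListMatchReport]:
    """Match every (distinct) name and tally the outcome statuses.

    ``total_names`` is the raw row count before deduplication (defaults to
    the distinct count).  Individual failures (unparseable names) become
    no-match results with a note; they never abort the batch.
    """
    if not names:
        raise ValueError("empty name list")
    options = options or MatchOptions()
    t0 = time.perf_counter()
    results: list[MatchResult] = []
    tallies = {STATUS_EXACT: 0, STATUS_UNAMBIGUOUS: 0, STATUS_AMBIGUOUS: 0, STATUS_NONE: 0}
    for name in names:
        result = match_name(name, thesaurus, options)
        tallies[result.status] += 1
        logger.info(
            "matched %r: status=%s score=%s candidates=%d",
            name, result.status,
            f"{result.candidates[0].score:.2f}" if result.candidates else "-",
            len(result.candidates),
        )
        results.append(result)
    report = ListMatchReport(
        total_names=total_names if total_names is not None else len(names),
        distinct_names=len(names),
        n_exact=tallies[STATUS_EXACT],
        n_unambiguous=tallies[STATUS_UNAMBIGUOUS],
        n_ambiguous=tallies[STATUS_AMBIGUOUS],
        n_none=tallies[STATUS_NONE],
        elapsed=time.perf_counter() - t0,
    )
    return results, report


def _format_score(result: MatchResult) -> str:
    if result.status == STATUS_NONE:
        return "0"
    score = result.candidates[0].score
    text = f"{score:.2f}".rstrip("0").rstrip(".")
    if result.status == STATUS_AMBIGUOUS:
        text += "*"
    return text


def write_results_csv(results: list[MatchResult], path: str | Path) -> None:
    """Write the four-column result CSV: original_name, accepted_name,
    synonym, score.  Ambiguous rows carry the top candidate with an
    asterisked score; no-match rows leave the name cells empty."""
    if not results:
        raise ValueError("no results to write")
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["original_name", "accepted_name", "synonym", "score"])
        for r in results:
            writer.writerow([r.raw_input, r.accepted_name, r.synonym_name, _format_score(r)])
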