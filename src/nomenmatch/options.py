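"""User-tunable settings shared by the parser, matcher and batch tool."""

from __future__ import annotations

from dataclasses import dataclass, field


#: Named separators accepted on the command line, mapped to characters.
SEPARATORS = {"comma": ",", "semicolon": ";", "colon": ":", "tab": "\t"}


@dataclass
class MatchOptions:
    """All knobs of the list matcher in one place.

    Parameters
    ----------
    separator:
        Column separator for CSV input: one of ``comma``, ``semicolon``,
        ``colon``, ``tab`` (or the literal character).
    name_column:
        Header name or 0-based index of the column holding taxon names
        (CSV input only).
    rank_aliases:
        Extra infraspecific rank indicators supplied by the user, e.g.
        ``{"subspecies": {"s"}}`` when a dataset uses "s." for subspecies.
        Consulted before the built-in alias tables.
    phonetic_enabled:
        Whether the phonetic test may admit candidates that fail the
        orthographic (edit-distance) test.
    threshold:
        Returned-score cutoff in [1, 100]; candidates below it are dropped.
        At 100 only exact matches survive.
    force_case_insensitive:
        Parse without using capitalization as a signal even when the input
        is mixed-case.
    max_names:
        Cap on the number of distinct names per input list.
    ambiguity_margin:
        A result is unambiguous when the top candidate leads the runner-up
        by at least this many returned-score points.
    mdld_block_limit:
        Maximum length of each block in an MDLD block transposition.
    query_edit_cap:
        Maximum total edits the interactive query corrector may spend.
    genus_ed_cap / epithet_ed_cap:
        MDLD caps for the orthographic candidate filters at the genus and
        (infra)species stages.
    seed:
        Seed for synthetic-data driven runs; irrelevant to matching itself.
    """

    separator: str = "comma"
    name_column: str | int | None = None
    rank_aliases: dict[str, set[str]] = field(default_factory=dict)
    phonetic_enabled: bool = True
    threshold: int = 70
    force_case_insensitive: bool = False
    max_names: int = 5000
    ambiguity_margin: float = 5.0
    mdld_block_limit: int = 2
    query_edit_cap: int = 2
    genus_ed_cap: int = 2
    epithet_ed_cap: int = 3
    treat_cfr_as_uncertain: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.threshold <= 100:
            raise ValueError(f"threshold must be in [1, 100], got {self.threshold}")
        if self.max_names < 1:
            raise ValueError("max_names must be >= 1")
        if self.mdld_block_limit < 1:
            raise ValueError("mdld_block_limit must be >= 1")
        known = {"subspecies", "variety", "form", "cultivar"}
        unknown = set(self.rank_aliases) - known
        if unknown:
            raise ValueError(f"unknown rank(s) in rank_aliases: {sorted(unknown)}")

    @property
    def separator_char(self) -> str:
        return SEPARATORS.get(self.separator, self.separator)
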