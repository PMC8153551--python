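"""Score aggregation for candidate matches.

Each Latin component (genus, species epithet, infraspecific epithets) gets a
ComponentScore of ``1 - ED/maxED`` where ED is the modified
Damerau–Levenshtein distance and maxED the length of the longer string.  An
infraspecific component loses 0.3 when its rank indicator disagrees with the
reference (subsp. vs var., say), floored at 0.  The TaxonScore is the plain
mean of the component scores; the author citation contributes through a
separate n-gram similarity, and the final score returned to the user is

    ReturnedScore = (TaxonScore * 0.9 + AuthorScore * 0.1) * 100

so a perfect name with a wrong or missing authority still reaches 90.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .nameparse import Rank

__all__ = [
    "ComponentRecord",
    "ScoreBreakdown",
    "component_score",
    "apply_rank_penalty",
    "taxon_score",
    "returned_score",
    "RANK_PENALTY",
    "TAXON_WEIGHT",
    "AUTHOR_WEIGHT",
]

RANK_PENALTY = 0.3
TAXON_WEIGHT = 0.9
AUTHOR_WEIGHT = 0.1


@dataclass(frozen=True)
class ComponentRecord:
    """Bookkeeping for one scored name component."""

    component: str  # "genus", "species", "infra1", "infra2"
    ed: int
    max_ed: int
    component_score: float
    phonetic_hit: bool = False
    rank_penalty_applied: bool = False


@dataclass(frozen=True)
class ScoreBreakdown:
    components: tuple[ComponentRecord, ...]
    taxon_score: float
    author_score: float
    returned_score: float

    def __post_init__(self) -> None:
        for rec in self.components:
            if not 0.0 <= rec.component_score <= 1.0:
                raise ValueError(f"component score out of range: {rec}")
        if not 0.0 <= self.taxon_score <= 1.0 or not 0.0 <= self.author_score <= 1.0:
            raise ValueError("taxon/author scores must lie in [0, 1]")
        expected = returned_score(self.taxon_score, self.author_score)
        if abs(self.returned_score - expected) > 1e-9:
            raise ValueError(
                f"returned_score {self.returned_score} inconsistent with "
                f"taxon {self.taxon_score} / author {self.author_score}"
            )


def component_score(ed: int, len_input: int, len_reference: int) -> float:
    """``1 - ED/maxED`` with maxED the length of the longer string."""
    if len_input < 0 or len_reference < 0:
        raise ValueError("lengths must be non-negative")
    max_ed = max(len_input, len_reference)
    if max_ed == 0:
        raise ValueError("cannot score two empty components")
    if ed < 0 or ed > max_ed:
        raise ValueError(f"ED {ed} outside [0, {max_ed}]")
    return 1.0 - ed / max_ed


def apply_rank_penalty(score: float, input_rank: Rank, reference_rank: Rank) -> float:
    """Deduct 0.3 from an infraspecific component with the wrong rank indicator.

    No penalty when the ranks agree or the input rank is unknown (the input
    simply did not say); the result is floored at 0 so component scores stay
    in [0, 1].
    """
    if input_rank == reference_rank or input_rank == Rank.UNKNOWN:
        return score
    return max(score - RANK_PENALTY, 0.0)


def taxon_score(components: list[float] | tuple[float, ...]) -> float:
    """Arithmetic mean of the component scores present."""
    if not components:
        raise ValueError("taxon_score needs at least one component")
    return sum(components) / len(components)


def returned_score(taxon: float, author: float) -> float:
    """Final 0–100 score combining taxon (weight 0.9) and author (0.1)."""
    return (taxon * TAXON_WEIGHT + author * AUTHOR_WEIGHT) * 100.0
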