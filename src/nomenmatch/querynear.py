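"""Near-match correction for interactive query strings.

A query box accepts any fragment of a scientific name ("officinalis",
"lanthus alt"); a typo in the fragment would silently return an empty
result list.  The corrector finds the closest substring of any reference
full name, under two constraints inherited from the interactive setting:
the corrected string may be at most one character longer or shorter than
the query, and blank spaces in the query are never inserted or replaced —
word boundaries the user typed are trusted.

"officialis" → "officinalis" (one insertion, matching both Calendula and
Galega entries); "lantus alt" → "lanthus alt" (one insertion inside the
first word, matching Ailanthus altissima).
"""

from __future__ import annotations

from dataclasses import dataclass

from .textnorm import normalize_string
from .thesaurus import Thesaurus

__all__ = ["QueryCorrection", "nearest_query_match", "blank_locked_distance"]

_INF = 10**9


@dataclass(frozen=True)
class QueryCorrection:
    query: str
    corrected: str
    edit_cost: int
    matched_entries: tuple[str, ...]
    was_corrected: bool


def blank_locked_distance(query: str, window: str, cap: int) -> int:
    """Edit distance from ``query`` to ``window`` where blanks are immovable.

    Blanks may only align to blanks: substituting a blank for a non-blank
    (either direction), inserting a blank, or deleting a blank is forbidden.
    Returns ``cap + 1`` as soon as the distance provably exceeds ``cap``.
    """
    n, m = len(query), len(window)
    if abs(n - m) > cap:
        return cap + 1
    # first row: inserting the first j window chars (forbidden past a blank)
    prev: list[int] = []
    acc = 0
    for j in range(m + 1):
        prev.append(acc)
        if j < m:
            acc = _INF if window[j] == " " else acc + 1
    for i in range(1, n + 1):
        qc = query[i - 1]
        cur = [prev[0] + (1 if qc != " " else _INF)]
        for j in range(1, m + 1):
            wc = window[j - 1]
            if qc == wc:
                best = prev[j - 1]
            elif qc == " " or wc == " ":
                best = _INF  # blank never substituted
            else:
                best = prev[j - 1] + 1
            if qc != " ":  # deletion of a query char
                best = min(best, prev[j] + 1)
            if wc != " ":  # insertion of a window char
                best = min(best, cur[j - 1] + 1)
            cur.append(best)
        prev = cur
        if min(prev) > cap:
            return cap + 1
    return min(prev[-1], cap + 1)


def nearest_query_match(
    query: str, thesaurus: Thesaurus, *, edit_cap: int = 2
) -> QueryCorrection:
    """Correct a free-text query to the closest substring of a reference name.

    An exact substring hit returns the query unchanged.  Otherwise every
    window of length ``len(query) ± 1`` of every reference full name is
    scored with :func:`blank_locked_distance`; the cheapest correction wins,
    ties resolved by number of matching entries, then lexicographically.
    When nothing lies within ``edit_cap`` edits, ``corrected`` is empty.
    """
    q = " ".join(normalize_string(query).split()).casefold()
    if not q:
        raise ValueError("empty query")

    names = {eid: e.full_name for eid, e in thesaurus.entries.items()}

    exact = tuple(sorted(eid for eid, name in names.items() if q in name.casefold()))
    if exact:
        return QueryCorrection(q, q, 0, exact, was_corrected=False)

    n = len(q)
    # candidate corrected strings -> minimal cost
    costs: dict[str, int] = {}
    for name in names.values():
        folded = name.casefold()
        for length in (n - 1, n, n + 1):
            if length < 1 or length > len(folded):
                continue
            for start in range(len(folded) - length + 1):
                window = folded[start : start + length]
                if window in costs and costs[window] <= 1:
                    continue
                cost = blank_locked_distance(q, window, edit_cap)
                if cost <= edit_cap:
                    prev = costs.get(window)
                    if prev is None or cost < prev:
                        costs[window] = cost
    if not costs:
        return QueryCorrection(q, "", edit_cap + 1, (), was_corrected=True)

    best_cost = min(costs.values())
    finalists = [w for w, c in costs.items() if c == best_cost]
    scored = []
    for w in finalists:
        hits = tuple(sorted(eid for eid, name in names.items() if w in name.casefold()))
        scored.append((-len(hits), w, hits))
    scored.sort()
    _, corrected, hits = scored[0]
    return QueryCorrection(q, corrected, best_cost, hits, was_corrected=True)
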