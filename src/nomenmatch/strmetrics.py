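"""String comparators used by the name matcher.

Four primitives: the classic Levenshtein edit distance, a modified
Damerau–Levenshtein distance (MDLD) that charges a swap of two adjacent
character blocks the length of the longer block, an n-gram (bigram Dice)
similarity for author strings, and the phonetic encoder that collapses the
common mis-hearings of Latin epithets (vowel confusion, z/s, k/c, silent h,
doubled letters) onto a shared key.

The MDLD is the workhorse: "canadsiens" vs "canadensis" costs 2 here (swap
of the adjacent blocks "si" and "en") where plain Levenshtein charges 4.
Transposed blocks are consumed whole — they cannot be re-edited afterwards —
which keeps the recurrence a strict generalisation of the optimal string
alignment variant of Damerau–Levenshtein.
"""

from __future__ import annotations

__all__ = ["levenshtein", "mdld", "ngram_similarity", "phonetic_key"]


def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character insertions, deletions or
    substitutions transforming ``a`` into ``b``."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):  # keep the rolling row short
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def mdld(a: str, b: str, block_limit: int = 2) -> int:
    """Modified Damerau–Levenshtein distance with adjacent block transpositions.

    Extends :func:`levenshtein` with a swap of two adjacent blocks of up to
    ``block_limit`` characters each; swapping blocks of lengths ``k1`` and
    ``k2`` costs ``max(k1, k2)``.  With ``block_limit=1`` this is the classic
    (optimal string alignment) Damerau–Levenshtein distance.  Never exceeds
    the plain Levenshtein distance.
    """
    if block_limit < 1:
        raise ValueError("block_limit must be >= 1")
    if a == b:
        return 0
    n, m = len(a), len(b)
    # d[i][j]: distance between a[:i] and b[:j]
    d = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        d[i][0] = i
    for j in range(m + 1):
        d[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = min(
                d[i - 1][j] + 1,
                d[i][j - 1] + 1,
                d[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
            # Swap of adjacent blocks: a ends ...XY, b ends ...YX with
            # |X| = k1, |Y| = k2.
            for k1 in range(1, block_limit + 1):
                for k2 in range(1, block_limit + 1):
                    if i >= k1 + k2 and j >= k1 + k2:
                        ax = a[i - k1 - k2 : i - k2]
                        ay = a[i - k2 : i]
                        bx = b[j - k1 : j]
                        by = b[j - k1 - k2 : j - k1]
                        if ax == bx and ay == by:
                            cand = d[i - k1 - k2][j - k1 - k2] + max(k1, k2)
                            if cand < best:
                                best = cand
            d[i][j] = best
    return d[n][m]


def _author_bigrams(text: str) -> list[str]:
    """Bigrams of the case-folded, letters-only, blank-collapsed string."""
    kept = "".join(c if c.isalpha() else " " for c in text.casefold())
    collapsed = " ".join(kept.split())
    return [collapsed[i : i + 2] for i in range(len(collapsed) - 1)]


def ngram_similarity(a: str, b: str) -> float:
    """Dice coefficient over character-bigram multisets of two author strings.

    Returns a similarity in [0, 1]; 1.0 iff the (case-folded, blank-collapsed)
    inputs are equal and non-empty, 0.0 when they share no bigram.
    """
    fa = " ".join(a.casefold().split())
    fb = " ".join(b.casefold().split())
    if fa == fb:
        return 1.0 if fa else 0.0
    ba = _author_bigrams(a)
    bb = _author_bigrams(b)
    if not ba or not bb:
        return 0.0
    from collections import Counter

    ca, cb = Counter(ba), Counter(bb)
    shared = sum((ca & cb).values())
    return 2.0 * shared / (len(ba) + len(bb))


# Phonetic folding rules, applied in order to everything after the first
# letter, repeatedly until a fixed point is reached.  Digraphs collapse
# before single vowels so that e.g. the terminal "-ia" of "Huperzia"
# becomes A (not IA -> II).
_DIGRAPHS = (("AE", "I"), ("IA", "A"), ("OE", "I"), ("OI", "A"))
_SINGLES = (("E", "I"), ("O", "A"), ("U", "I"), ("Z", "S"), ("K", "C"))


def phonetic_key(word: str) -> str:
    """Uppercase phonetic key of a single Latin word.

    The first letter is preserved; the remainder is folded so that common
    misspellings collide: AE/OE -> I, IA/OI -> A, E -> I, O -> A, U -> I,
    Z -> S, K -> C, H dropped after the first position, and runs of a letter
    collapsed.  Idempotent: ``phonetic_key(phonetic_key(w)) == phonetic_key(w)``.
    """
    if not word or not word.isalpha():
        raise ValueError(f"phonetic_key expects a single alphabetic word, got {word!r}")
    upper = word.upper()
    head, rest = upper[0], upper[1:]
    while True:
        new = rest.replace("H", "")
        for src, dst in _DIGRAPHS:
            new = new.replace(src, dst)
        for src, dst in _SINGLES:
            new = new.replace(src, dst)
        # collapse runs (also across the head boundary: "LLOYDIA" -> L + "L...")
        out: list[str] = []
        prev = head
        for c in new:
            if c != prev:
                out.append(c)
            prev = c
        new = "".join(out)
        if new == rest:
            return head + rest
        rest = new
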