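"""Independent brute-force oracles, kept deliberately naive.

These re-derive expected values from first principles and share no code
with the package paths they check.
"""

from __future__ import annotations

from functools import lru_cache


def scs_length(s1: tuple, s2: tuple) -> int:
    """Shortest common supersequence length for plain (singleton) sequences.

    Textbook recursion on suffixes with equality matching; exponential
    memoised form rather than the package's tabulated alignment.
    """

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == len(s1):
            return len(s2) - j
        if j == len(s2):
            return len(s1) - i
        if s1[i] == s2[j]:
            return 1 + rec(i + 1, j + 1)
        return 1 + min(rec(i + 1, j), rec(i, j + 1))

    return rec(0, 0)


def is_supersequence(sup: tuple, sub: tuple) -> bool:
    """Plain subsequence test by exhaustive recursion."""
    if not sub:
        return True
    if not sup:
        return False
    if sup[0] == sub[0] and is_supersequence(sup[1:], sub[1:]):
        return True
    return is_supersequence(sup[1:], sub)
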