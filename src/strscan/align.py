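"""Banded edit distance, fitting alignments, and an exact partition-distance oracle.

All alignments in the scanner are component-wise: one pattern component
(a unit copy, a spacer+unit block, or a flank) is fitted against the
start or end of the remaining read context.  Distances are unit-cost
Levenshtein (substitution = insertion = deletion = 1) restricted to a
diagonal band |i - j| <= band, which bounds the number of indels any
single component alignment may contain.

``brute_force_distance`` is an exhaustive dynamic program over all
partitions of a query string into flank / run / spacer segments and all
admissible copy numbers.  It is deliberately independent of the greedy
extension engine and is intended as a small-scale exactness oracle, not
a production path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .patterns import STRPattern

__all__ = [
    "INF",
    "FitResult",
    "banded_edit_distance",
    "fit_prefix",
    "fit_suffix",
    "brute_force_distance",
]

INF = float("inf")


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting a pattern component against read context.

    ``distance`` is the banded edit distance of the best fit and
    ``consumed`` the number of read bases it spans (counted from the
    start of the context for prefix fits, from the end for suffix fits).
    """

    distance: int
    consumed: int


def _banded_rows(s: str, t: str, band: int, max_cols: int | None = None):
    """Yield (row_index, col_lo, values) for the banded DP of s vs t.

    ``values[c - col_lo]`` is the edit distance between ``s[:row_index]``
    and ``t[:c]`` over alignments staying within the diagonal band.
    Cells outside the band are implicitly INF.
    """
    lt = len(t) if max_cols is None else min(len(t), max_cols)
    lo = 0
    hi = min(lt, band)
    row = [float(c) for c in range(lo, hi + 1)]
    yield 0, lo, row
    for r in range(1, len(s) + 1):
        nlo = max(0, r - band)
        nhi = min(lt, r + band)
        if nlo > nhi:
            return
        nrow = [INF] * (nhi - nlo + 1)
        sc = s[r - 1]
        for c in range(nlo, nhi + 1):
            best = INF
            # deletion of s[r-1] (vertical move)
            if lo <= c <= hi:
                v = row[c - lo] + 1
                if v < best:
                    best = v
            if c > 0:
                # diagonal (match/substitution)
                if lo <= c - 1 <= hi:
                    v = row[c - 1 - lo] + (0 if sc == t[c - 1] else 1)
                    if v < best:
                        best = v
                # insertion of t[c-1] (horizontal move)
                if nlo <= c - 1:
                    v = nrow[c - 1 - nlo] + 1
                    if v < best:
                        best = v
            nrow[c - nlo] = best
        lo, hi, row = nlo, nhi, nrow
        yield r, lo, row


def banded_edit_distance(a: str, b: str, band: int) -> int | float:
    """Minimum edit distance between ``a`` and ``b`` using at most ``band`` indels.

    Returns :data:`INF` when no alignment exists within the band (in
    particular whenever ``abs(len(a) - len(b)) > band``).
    """
    if abs(len(a) - len(b)) > band:
        return INF
    result: int | float = INF
    for r, lo, row in _banded_rows(a, b, band):
        if r == len(a) and lo <= len(b) <= lo + len(row) - 1:
            result = row[len(b) - lo]
    if result is INF:
        return INF
    return int(result)


def fit_prefix(
    s: str, t: str, band: int, delta_remaining: int | float
) -> FitResult | None:
    """Fit component ``s`` against a prefix of context ``t``.

    Considers every prefix ``p`` of ``t`` with ``abs(len(p) - len(s)) <=
    band`` and returns the minimum banded edit distance together with
    the prefix length consumed.  Ties prefer the longest prefix (consume
    the full component length when possible).  Returns ``None`` when the
    best distance exceeds ``delta_remaining``.
    """
    ls = len(s)
    best_d: int | float = INF
    best_c = -1
    for r, lo, row in _banded_rows(s, t, band, max_cols=ls + band):
        if r != ls:
            continue
        for off, d in enumerate(row):
            c = lo + off
            if d < best_d or (d == best_d and c > best_c):
                best_d, best_c = d, c
    if best_d is INF or best_d > delta_remaining:
        return None
    return FitResult(distance=int(best_d), consumed=best_c)


def fit_suffix(
    s: str, t: str, band: int, delta_remaining: int | float
) -> FitResult | None:
    """Fit component ``s`` against a suffix of context ``t``.

    Equivalent to ``fit_prefix(s[::-1], t[::-1], ...)``; ``consumed``
    counts bases from the end of ``t``.
    """
    return fit_prefix(s[::-1], t[::-1], band, delta_remaining)


def _component_costs(comp: str, t: str, band: int) -> list[tuple[int, int | float]]:
    """All (consumed, distance) pairs for aligning ``comp`` to prefixes of ``t``."""
    out: list[tuple[int, int | float]] = []
    for r, lo, row in _banded_rows(comp, t, band, max_cols=len(comp) + band):
        if r != len(comp):
            continue
        for off, d in enumerate(row):
            if d is not INF and d < INF:
                out.append((lo + off, d))
    return out


def brute_force_distance(
    Q: str, P: "STRPattern", epsilon: int, band: int
) -> int | float:
    """Exact minimum partition distance between query ``Q`` and pattern ``P``.

    Minimises, over every partition of ``Q`` into
    ``(q_L, q_1, p_1, ..., q_n, p_n, q_R)`` and every per-unit copy
    number ``m_i`` with ``|m_i - c_i| <= epsilon``, the sum of banded
    edit distances between each segment and its pattern component
    (flanks ``s_L``/``s_R``, tandem runs ``s_i^{m_i}``, spacers ``t_i``).

    Exhaustive oracle for testing only; guarded to ``len(Q) <= 300`` and
    at most 3 units.
    """
    if len(Q) > 300 or P.n_units > 3:
        raise ValueError("brute_force_distance is a test-scale oracle: |Q| <= 300, n <= 3")

    lq = len(Q)
    # dp[j] = min distance aligning the components consumed so far to Q[:j]
    dp: list[int | float] = [INF] * (lq + 1)
    dp[0] = 0

    def apply_fixed(dp_in: list[int | float], comp: str) -> list[int | float]:
        if comp == "":
            return list(dp_in)
        ndp: list[int | float] = [INF] * (lq + 1)
        for j1 in range(lq + 1):
            if dp_in[j1] is INF:
                continue
            for consumed, d in _component_costs(comp, Q[j1:], band):
                j2 = j1 + consumed
                v = dp_in[j1] + d
                if v < ndp[j2]:
                    ndp[j2] = v
        return ndp

    def apply_unit(dp_in: list[int | float], unit: str, c: int) -> list[int | float]:
        m_lo = max(0, c - epsilon)
        m_hi = c + epsilon
        full = unit * m_hi
        lu = len(unit)
        ndp: list[int | float] = [INF] * (lq + 1)
        for j1 in range(lq + 1):
            if dp_in[j1] is INF:
                continue
            base = dp_in[j1]
            if m_lo == 0 and base < ndp[j1]:
                ndp[j1] = base  # m = 0: empty run
            # one banded DP against unit^m_hi; read off each m's row
            for r, lo, row in _banded_rows(full, Q[j1:], band, max_cols=len(full) + band):
                if r == 0 or r % lu or r // lu < max(1, m_lo):
                    continue
                for off, d in enumerate(row):
                    j2 = j1 + lo + off
                    v = base + d
                    if v < ndp[j2]:
                        ndp[j2] = v
        return ndp

    dp = apply_fixed(dp, P.left_flank)
    for i, (unit, c) in enumerate(P.units):
        dp = apply_unit(dp, unit, c)
        dp = apply_fixed(dp, P.spacers[i])
    dp = apply_fixed(dp, P.right_flank)
    res = dp[lq]
    return res if res is INF else int(res)
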