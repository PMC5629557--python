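"""Greedy bidirectional extension of seed alignments.

Starting from an exact tandem-repeat seed, the engine first completes a
truncated unit copy by gap-free extension, then repeatedly applies the
locally cheapest extension at the 3' end — another copy of the current
unit (admissible while m_i < c_i + epsilon), the spacer plus the next
unit (while more units remain), or the right flank (at the last unit) —
and symmetrically at the 5' end towards the left flank.  Extension
stops when both flanks are anchored (accepted call), when a side runs
out of admissible candidates before reaching its flank, or when the
cumulative edit distance exceeds delta (rejected).

Ties in the candidate minimum are broken in the order listed above
(continue the run, then cross to the next unit, then terminate at the
flank), which deterministically maximises the recovered copy number.
Flanks truncated by the read end are accepted with a clipped anchor as
long as at least ``min_flank_anchor`` bases align.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import fit_prefix, fit_suffix
from .patterns import ScanParams, STRPattern
from .seeding import SeedMatch, reverse_complement

__all__ = [
    "ExtensionState",
    "STRCall",
    "STOP",
    "complete_truncated_unit",
    "extend_3prime_step",
    "extend_5prime_step",
    "extend_alignment",
    "count_copies",
]


class _Stop:
    """Sentinel: a side has no admissible extension left."""

    def __repr__(self) -> str:  # pragma: no cover
        return "STOP"


STOP = _Stop()


@dataclass
class ExtensionState:
    """Mutable state of one bidirectional extension (in pattern orientation)."""

    pattern_id: int
    i3: int  # current unit index at the 3' frontier (0-based)
    i5: int  # current unit index at the 5' frontier (0-based)
    j3: int  # read cursor: position after the rightmost aligned base
    j5: int  # read cursor: position of the leftmost aligned base
    distance: int = 0
    copies: list[int] = field(default_factory=list)  # observed m_i per unit
    reached_s_R: bool = False
    reached_s_L: bool = False
    anchor3: int = 0  # right-flank bases aligned
    anchor5: int = 0  # left-flank bases aligned


@dataclass(frozen=True)
class STRCall:
    """One read's accepted alignment to one locus."""

    pattern_id: int
    marker: str
    read_id: str
    strand: str
    start: int  # forward-read coordinates, 0-based half-open
    end: int
    unit_seqs: tuple[str, ...]
    copies: tuple[int, ...]
    distance: int
    anchor5: int
    anchor3: int

    @property
    def total_copies(self) -> int:
        return sum(self.copies)


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def complete_truncated_unit(
    seed: SeedMatch, read: str, pattern: STRPattern
) -> ExtensionState:
    """Initialise extension state, completing partially covered unit copies.

    ``seed`` coordinates must refer to ``read`` directly (the caller
    orients minus-strand seeds first).  If the seed ends mid-copy the
    remaining bases of that copy are compared gap-free against the read
    (each mismatch costs 1); symmetrically for a seed starting mid-copy.
    A completion clipped by the read end is discarded and the partial
    copy is not counted.
    """
    unit = pattern.units[seed.unit_index][0]
    lu = len(unit)
    k = seed.end - seed.start
    state = ExtensionState(
        pattern_id=seed.pattern_id,
        i3=seed.unit_index,
        i5=seed.unit_index,
        j3=seed.end,
        j5=seed.start,
        copies=[0] * pattern.n_units,
    )
    m = seed.whole_copies

    # 3' side: the seed covers q leading bases of a trailing truncated copy
    q = (seed.phase + k) % lu
    if q:
        rest = unit[q:]
        if state.j3 + len(rest) <= len(read):
            state.distance += _mismatches(read[state.j3 : state.j3 + len(rest)], rest)
            state.j3 += len(rest)
            m += 1

    # 5' side: a seed starting at phase p covers the last lu - p bases of a copy
    p = seed.phase
    if p:
        head = unit[:p]
        if state.j5 - p >= 0:
            state.distance += _mismatches(read[state.j5 - p : state.j5], head)
            state.j5 -= p
            m += 1

    state.copies[seed.unit_index] = m
    return state


def _clip_flank_3(flank: str, avail: int) -> str:
    return flank if avail >= len(flank) else flank[:avail]


def _clip_flank_5(flank: str, avail: int) -> str:
    return flank if avail >= len(flank) else flank[len(flank) - avail :]


def extend_3prime_step(
    state: ExtensionState, read: str, pattern: STRPattern, params: ScanParams
) -> ExtensionState | _Stop:
    """One greedy step at the 3' end; returns STOP when no candidate fits."""
    if state.reached_s_R or state.distance > params.delta:
        return STOP
    budget = params.delta - state.distance
    context = read[state.j3 :]
    i = state.i3
    unit, ref_copies = pattern.units[i]

    cand_a = (
        fit_prefix(unit, context, params.band, budget)
        if state.copies[i] < ref_copies + params.epsilon
        else None
    )
    cand_b = (
        fit_prefix(pattern.spacers[i] + pattern.units[i + 1][0], context, params.band, budget)
        if i < pattern.n_units - 1
        else None
    )
    cand_c = None
    flank_eff = ""
    if i == pattern.n_units - 1:
        flank_eff = _clip_flank_3(pattern.right_flank, len(context))
        if len(flank_eff) >= params.min_flank_anchor:
            cand_c = fit_prefix(flank_eff, context, params.band, budget)

    best = None
    for tag, cand in (("a", cand_a), ("b", cand_b), ("c", cand_c)):
        if cand is not None and (best is None or cand.distance < best[1].distance):
            best = (tag, cand)
    if best is None:
        return STOP

    tag, fit = best
    state.distance += fit.distance
    state.j3 += fit.consumed
    if tag == "a":
        state.copies[i] += 1
    elif tag == "b":
        state.i3 = i + 1
        state.copies[i + 1] += 1
    else:
        state.reached_s_R = True
        state.anchor3 = len(flank_eff)
    return state


def extend_5prime_step(
    state: ExtensionState, read: str, pattern: STRPattern, params: ScanParams
) -> ExtensionState | _Stop:
    """One greedy step at the 5' end; mirror of :func:`extend_3prime_step`."""
    if state.reached_s_L or state.distance > params.delta:
        return STOP
    budget = params.delta - state.distance
    context = read[: state.j5]
    i = state.i5
    unit, ref_copies = pattern.units[i]

    cand_a = (
        fit_suffix(unit, context, params.band, budget)
        if state.copies[i] < ref_copies + params.epsilon
        else None
    )
    cand_b = (
        fit_suffix(pattern.units[i - 1][0] + pattern.spacers[i - 1], context, params.band, budget)
        if i > 0
        else None
    )
    cand_c = None
    flank_eff = ""
    if i == 0:
        flank_eff = _clip_flank_5(pattern.left_flank, len(context))
        if len(flank_eff) >= params.min_flank_anchor:
            cand_c = fit_suffix(flank_eff, context, params.band, budget)

    best = None
    for tag, cand in (("a", cand_a), ("b", cand_b), ("c", cand_c)):
        if cand is not None and (best is None or cand.distance < best[1].distance):
            best = (tag, cand)
    if best is None:
        return STOP

    tag, fit = best
    state.distance += fit.distance
    state.j5 -= fit.consumed
    if tag == "a":
        state.copies[i] += 1
    elif tag == "b":
        state.i5 = i - 1
        state.copies[i - 1] += 1
    else:
        state.reached_s_L = True
        state.anchor5 = len(flank_eff)
    return state


def extend_alignment(
    seed: SeedMatch,
    read: str,
    pattern: STRPattern,
    params: ScanParams,
    read_id: str = "",
) -> STRCall | None:
    """Run the full bidirectional extension of one seed.

    Alternates 3' and 5' steps (3' first) until both flanks are
    anchored; returns ``None`` when either side stops short of its
    flank, the budget delta is exceeded, or an observed copy number
    deviates from the reference by more than epsilon.
    """
    read = read.upper()
    if seed.strand == "-":
        oread = reverse_complement(read)
        ostart = len(read) - seed.end
        oend = len(read) - seed.start
    else:
        oread = read
        ostart, oend = seed.start, seed.end
    oseed = SeedMatch(
        pattern_id=seed.pattern_id,
        unit_index=seed.unit_index,
        start=ostart,
        end=oend,
        phase=seed.phase,
        strand="+",
        whole_copies=seed.whole_copies,
    )

    state = complete_truncated_unit(oseed, oread, pattern)
    if state.distance > params.delta:
        return None

    while not (state.reached_s_R and state.reached_s_L):
        progressed = False
        if not state.reached_s_R:
            if extend_3prime_step(state, oread, pattern, params) is STOP:
                return None
            progressed = True
        if not state.reached_s_L:
            if extend_5prime_step(state, oread, pattern, params) is STOP:
                return None
            progressed = True
        if not progressed:  # pragma: no cover - loop condition already exits
            break

    if state.distance > params.delta:
        return None
    for (unit, c), m in zip(pattern.units, state.copies):
        if abs(m - c) > params.epsilon:
            return None

    if seed.strand == "-":
        start = len(read) - state.j3
        end = len(read) - state.j5
    else:
        start, end = state.j5, state.j3
    return STRCall(
        pattern_id=seed.pattern_id,
        marker=pattern.marker,
        read_id=read_id,
        strand=seed.strand,
        start=start,
        end=end,
        unit_seqs=pattern.unit_seqs,
        copies=tuple(state.copies),
        distance=state.distance,
        anchor5=state.anchor5,
        anchor3=state.anchor3,
    )


def count_copies(call: STRCall) -> list[tuple[str, int]]:
    """Observed whole-copy count per repetitive unit, in pattern order."""
    return list(zip(call.unit_seqs, call.copies))
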