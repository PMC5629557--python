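"""Tandem-repeat k-mer seeds: construction, panel indexing, and read lookup.

A seed is the length-k prefix of the infinite tandem repetition of a
repetitive unit; when k is not a multiple of the unit length the last
copy is truncated.  Every rotation (phase) of each unit is indexed so
that reads entering a tandem run mid-unit still seed.  Lookup is exact
match; overlapping hits along one tandem run are collapsed to the
single hit covering the most whole unit copies (ties: leftmost).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .patterns import ScanParams, STRPattern

__all__ = [
    "SeedIndex",
    "SeedMatch",
    "build_seed",
    "seed_phases",
    "index_patterns",
    "find_seeds",
    "reverse_complement",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def build_seed(unit: str, k: int) -> str:
    """Length-k prefix of the infinite tandem repetition of ``unit``."""
    if k < len(unit):
        raise ValueError(
            f"seed length k={k} shorter than unit {unit!r}: seed cannot "
            "contain one full copy"
        )
    reps = -(-k // len(unit))  # ceil
    return (unit * reps)[:k]


def seed_phases(unit: str, k: int) -> list[str]:
    """Seeds for every distinct rotation of ``unit``, duplicates removed."""
    seen: dict[str, None] = {}
    for p in range(len(unit)):
        rot = unit[p:] + unit[:p]
        seed = build_seed(rot, k)
        seen.setdefault(seed, None)
    return list(seen)


@dataclass(frozen=True)
class SeedMatch:
    """An exact k-mer hit linking a read interval to a pattern's tandem run.

    ``start``/``end`` are 0-based half-open on the forward read even for
    minus-strand hits; ``phase`` is the 0-based offset within the unit at
    which the seed starts (in pattern orientation); ``whole_copies`` is
    the number of complete unit copies the seed covers.
    """

    pattern_id: int
    unit_index: int
    start: int
    end: int
    phase: int
    strand: str
    whole_copies: int


class SeedIndex:
    """Exact-match index from k-mer seeds to (pattern, unit, phase) entries."""

    def __init__(self, k: int, patterns: Sequence[STRPattern]):
        self.k = k
        self.patterns = list(patterns)
        self._table: dict[str, list[tuple[int, int, int]]] = {}

    def add(self, seed: str, pattern_id: int, unit_index: int, phase: int) -> None:
        if len(seed) != self.k:
            raise ValueError(f"seed {seed!r} is not length k={self.k}")
        self._table.setdefault(seed, []).append((pattern_id, unit_index, phase))

    def lookup(self, kmer: str) -> list[tuple[int, int, int]]:
        return self._table.get(kmer, [])

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self._table

    def keys(self):
        return self._table.keys()


def index_patterns(patterns: Sequence[STRPattern], params: ScanParams) -> SeedIndex:
    """Index every phase seed of every indexable unit of the panel.

    A unit whose maximum admissible tandem run ``(c_i + epsilon) * |s_i|``
    is shorter than k can never contain a length-k exact seed; such
    units are skipped with a warning.  Duplicate marker names and empty
    panels are errors.
    """
    patterns = list(patterns)
    if not patterns:
        raise ValueError("empty panel: nothing to index")
    names = [p.marker for p in patterns]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate marker name(s) in panel: {', '.join(dupes)}")

    index = SeedIndex(params.k, patterns)
    for pid, pattern in enumerate(patterns):
        for ui, (unit, copies) in enumerate(pattern.units):
            if len(unit) > params.k:
                logger.warning(
                    "skipping unit %d (%s) of %s: unit longer than k=%d",
                    ui + 1,
                    unit,
                    pattern.marker,
                    params.k,
                )
                continue
            if (copies + params.epsilon) * len(unit) < params.k:
                logger.warning(
                    "skipping unit %d (%s) of %s: max run length %d < k=%d",
                    ui + 1,
                    unit,
                    pattern.marker,
                    (copies + params.epsilon) * len(unit),
                    params.k,
                )
                continue
            for phase in range(len(unit)):
                rot = unit[phase:] + unit[:phase]
                seed = build_seed(rot, params.k)
                # periodic units repeat rotations; keep one entry per (pattern, unit)
                if (pid, ui) in {(e[0], e[1]) for e in index.lookup(seed)}:
                    continue
                index.add(seed, pid, ui, phase)
    return index


def _whole_copies(phase: int, k: int, unit_len: int) -> int:
    leading_partial = (unit_len - phase) % unit_len
    return (k - leading_partial) // unit_len


def _raw_hits(seq: str, index: SeedIndex) -> list[tuple[int, int, int, int]]:
    """(pattern_id, unit_index, pos, phase) for every exact k-mer hit in seq."""
    k = index.k
    hits: list[tuple[int, int, int, int]] = []
    for pos in range(len(seq) - k + 1):
        for pid, ui, phase in index.lookup(seq[pos : pos + k]):
            hits.append((pid, ui, pos, phase))
    return hits


def find_seeds(read: str, index: SeedIndex, params: ScanParams) -> list[SeedMatch]:
    """All collapsed exact seed hits of ``read`` against the index.

    Scans the forward read and, when ``params.both_strands``, the
    reverse complement; minus-strand hits are reported with coordinates
    mapped back onto the forward read.  Hits to the same (pattern, unit,
    strand) whose intervals overlap are collapsed to one hit per seed
    phase — the one covering the most whole copies (ties: leftmost on
    the scanned orientation).  One hit is kept per phase rather than one
    per run because a flank base that coincidentally continues the
    repeat's periodicity creates an exact but mis-phased boundary seed,
    indistinguishable from an interior seed until extension.
    """
    read = read.upper()
    k = index.k
    if len(read) < k:
        return []

    out: list[SeedMatch] = []
    scans: list[tuple[str, str]] = [("+", read)]
    if params.both_strands:
        scans.append(("-", reverse_complement(read)))

    for strand, seq in scans:
        groups: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for pid, ui, pos, phase in _raw_hits(seq, index):
            groups.setdefault((pid, ui), []).append((pos, phase))
        for (pid, ui), hits in groups.items():
            unit_len = len(index.patterns[pid].units[ui][0])
            hits.sort()
            # chain overlapping hits into runs, keep best hit per run
            run: list[tuple[int, int]] = []
            run_end = -1
            runs: list[list[tuple[int, int]]] = []
            for pos, phase in hits:
                if run and pos >= run_end:
                    runs.append(run)
                    run = []
                run.append((pos, phase))
                run_end = pos + k
            if run:
                runs.append(run)
            for r in runs:
                by_phase: dict[int, tuple[int, int]] = {}
                for pos, phase in r:
                    cur = by_phase.get(phase)
                    if cur is None or (
                        _whole_copies(phase, k, unit_len),
                        -pos,
                    ) > (_whole_copies(cur[1], k, unit_len), -cur[0]):
                        by_phase[phase] = (pos, phase)
                for pos, phase in sorted(by_phase.values()):
                    if strand == "+":
                        start, end = pos, pos + k
                    else:
                        start, end = len(read) - pos - k, len(read) - pos
                    out.append(
                        SeedMatch(
                            pattern_id=pid,
                            unit_index=ui,
                            start=start,
                            end=end,
                            phase=phase,
                            strand=strand,
                            whole_copies=_whole_copies(phase, k, unit_len),
                        )
                    )
    out.sort(key=lambda s: (s.pattern_id, s.unit_index, s.strand, s.start))
    return out
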