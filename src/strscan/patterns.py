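"""STR locus patterns and scan parameters.

An STR (short tandem repeat) locus is modelled as a pattern

    s_L  (s_1)_{c_1}  t_1  (s_2)_{c_2}  t_2  ...  (s_n)_{c_n}  s_R

where ``s_i`` is the i-th repetitive unit (1-6 bp motif) with reference
copy number ``c_i``, ``t_i`` is the spacer between consecutive repeat
runs (``t_n`` is always empty), and ``s_L`` / ``s_R`` are the unique
flanking sequences that anchor the locus.  Most forensic markers have
n = 1; compound markers such as YCAII have n = 2.

Panels are stored as a tab-separated table with one locus per row
(columns: marker, chrom, start, end, left_flank, units, copies,
spacers, right_flank; multi-unit fields are ';'-joined).  Coordinates
in the file are 1-based inclusive; all in-memory read coordinates in
this package are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

__all__ = [
    "DNA_ALPHABET",
    "PanelError",
    "PatternValidationError",
    "STRPattern",
    "ScanParams",
    "build_pattern",
    "parse_pattern_table",
    "write_pattern_table",
]

DNA_ALPHABET = frozenset("ACGT")

_TABLE_COLUMNS = (
    "marker",
    "chrom",
    "start",
    "end",
    "left_flank",
    "units",
    "copies",
    "spacers",
    "right_flank",
)


class PanelError(ValueError):
    """Malformed panel file or invalid panel contents."""


class PatternValidationError(PanelError):
    """An STR pattern violates a structural invariant."""


def _check_dna(seq: str, what: str, allow_empty: bool = False) -> None:
    if not seq and not allow_empty:
        raise PatternValidationError(f"{what} must be non-empty")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise PatternValidationError(
            f"{what} contains non-ACGT symbol(s): {','.join(sorted(bad))}"
        )


@dataclass(frozen=True)
class STRPattern:
    """One STR locus of a panel.

    ``units`` is an ordered tuple of ``(unit, ref_copies)`` pairs and
    ``spacers`` holds one spacer per unit with the last entry forced
    empty.  ``chrom`` / ``ref_start`` / ``ref_end`` are informational
    (1-based inclusive reference coordinates).
    """

    marker: str
    left_flank: str
    units: tuple[tuple[str, int], ...]
    spacers: tuple[str, ...]
    right_flank: str
    chrom: str = "."
    ref_start: int = 0
    ref_end: int = 0

    def __post_init__(self) -> None:
        if not self.marker:
            raise PatternValidationError("marker name must be non-empty")
        if len(self.units) < 1:
            raise PatternValidationError(f"{self.marker}: needs at least one repetitive unit")
        if len(self.spacers) != len(self.units):
            raise PatternValidationError(
                f"{self.marker}: {len(self.units)} unit(s) require {len(self.units)} "
                f"spacer(s) (last empty), got {len(self.spacers)}"
            )
        if self.spacers[-1] != "":
            raise PatternValidationError(f"{self.marker}: last spacer must be empty")
        _check_dna(self.left_flank, f"{self.marker}: left_flank")
        _check_dna(self.right_flank, f"{self.marker}: right_flank")
        for idx, (unit, copies) in enumerate(self.units, start=1):
            _check_dna(unit, f"{self.marker}: unit {idx}")
            if len(unit) > 6:
                raise PatternValidationError(
                    f"{self.marker}: unit {idx} longer than 6 bp ({unit!r})"
                )
            if copies < 1:
                raise PatternValidationError(
                    f"{self.marker}: unit {idx} reference copy number must be >= 1"
                )
        for idx, spacer in enumerate(self.spacers, start=1):
            _check_dna(spacer, f"{self.marker}: spacer {idx}", allow_empty=True)

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def ref_copies(self) -> tuple[int, ...]:
        return tuple(c for _, c in self.units)

    @property
    def unit_seqs(self) -> tuple[str, ...]:
        return tuple(u for u, _ in self.units)


@dataclass(frozen=True)
class ScanParams:
    """Tuning knobs of the seed-and-extend scan.

    k
        seed length in bases; a read must contain an exact k-mer of some
        unit's tandem run to be considered.
    delta
        maximum total edit distance of an accepted occurrence.
    epsilon
        maximum per-unit deviation |m_i - c_i| between observed and
        reference copy numbers.  The default is deliberately loose:
        real alleles routinely sit far from the reference copy number.
    band
        maximum number of indels allowed inside any single component
        alignment (diagonal half-width of the banded DP).
    min_flank_anchor
        minimum number of flank bases that must align on each side for
        a call to count as anchored (reads may truncate flanks).
    both_strands
        scan the reverse complement as well as the forward read.
    """

    k: int = 18
    delta: int = 4
    epsilon: int = 30
    band: int = 3
    min_flank_anchor: int = 8
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.band < 0:
            raise ValueError("band must be >= 0")
        if self.min_flank_anchor < 1:
            raise ValueError("min_flank_anchor must be >= 1")


def build_pattern(
    marker_name: str,
    left_flank: str,
    units: Sequence[tuple[str, int]],
    spacers: Sequence[str] | None = None,
    right_flank: str = "",
    coords: tuple[str, int, int] | None = None,
) -> STRPattern:
    """Construct a validated :class:`STRPattern` from explicit components.

    Lowercase sequences are uppercased; the last spacer may be omitted.
    Raises :class:`PatternValidationError` on any invariant violation,
    naming the offending field.
    """
    units_norm = tuple((str(u).upper(), int(c)) for u, c in units)
    if spacers is None:
        spacers = [""] * len(units_norm)
    spacers_norm = [str(s).upper() for s in spacers]
    if len(spacers_norm) == len(units_norm) - 1:
        spacers_norm.append("")
    if len(spacers_norm) != len(units_norm):
        raise PatternValidationError(
            f"{marker_name}: got {len(units_norm)} unit(s) but {len(spacers)} spacer(s)"
        )
    chrom, start, end = coords if coords is not None else (".", 0, 0)
    return STRPattern(
        marker=str(marker_name),
        left_flank=str(left_flank).upper(),
        units=units_norm,
        spacers=tuple(spacers_norm),
        right_flank=str(right_flank).upper(),
        chrom=str(chrom),
        ref_start=int(start),
        ref_end=int(end),
    )


def parse_pattern_table(source: IO[str] | Iterable[str]) -> list[STRPattern]:
    """Parse a panel TSV into a list of patterns (file order preserved).

    Lines starting with '#' are comments.  Any malformed row raises
    :class:`PanelError` carrying the 1-based line number.
    """
    patterns: list[STRPattern] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != len(_TABLE_COLUMNS):
            raise PanelError(
                f"line {lineno}: expected {len(_TABLE_COLUMNS)} tab-separated "
                f"columns, got {len(fields)}"
            )
        marker, chrom, start, end, left, units_f, copies_f, spacers_f, right = fields
        unit_seqs = units_f.split(";")
        copy_strs = copies_f.split(";")
        if len(copy_strs) != len(unit_seqs):
            raise PanelError(
                f"line {lineno}: {len(unit_seqs)} unit(s) but {len(copy_strs)} copy number(s)"
            )
        try:
            copies = [int(c) for c in copy_strs]
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise PanelError(f"line {lineno}: {exc}") from None
        if spacers_f == "":
            spacers: list[str] = [""] * len(unit_seqs)
        else:
            spacers = spacers_f.split(";")
            if len(spacers) == len(unit_seqs) - 1:
                spacers.append("")
            if len(spacers) != len(unit_seqs):
                raise PanelError(
                    f"line {lineno}: {len(unit_seqs)} unit(s) but "
                    f"{len(spacers)} spacer(s)"
                )
        try:
            patterns.append(
                build_pattern(
                    marker,
                    left,
                    list(zip(unit_seqs, copies)),
                    spacers,
                    right,
                    coords=(chrom, start_i, end_i),
                )
            )
        except PatternValidationError as exc:
            raise PanelError(f"line {lineno}: {exc}") from None
    return patterns


def write_pattern_table(patterns: Iterable[STRPattern], sink: IO[str]) -> None:
    """Write patterns as a panel TSV; inverse of :func:`parse_pattern_table`."""
    sink.write("#" + "\t".join(_TABLE_COLUMNS) + "\n")
    for p in patterns:
        row = (
            p.marker,
            p.chrom,
            str(p.ref_start),
            str(p.ref_end),
            p.left_flank,
            ";".join(u for u, _ in p.units),
            ";".join(str(c) for _, c in p.units),
            ";".join(p.spacers),
            p.right_flank,
        )
        sink.write("\t".join(row) + "\n")
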