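"""Synthetic panels and reads with planted STR alleles and ground truth.

The generator emulates the two sequencing regimes the scanner targets:
long (~1000 bp) capillary-style reads that contain a whole STR locus
with room to spare, and short (~100 bp) reads that usually truncate
it.  Each simulated read embeds one rendered locus allele inside
random padding, applies i.i.d. base substitutions (SNPs or sequencing
errors are indistinguishable to the scanner), reverse-complements
about half of the reads, and records a truth table so recall and
copy-number accuracy are measurable exactly.

Padding is screened against the panel's seed k-mers, so a seed hit in
a fixture can only come from a planted locus.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import IO, Mapping, Sequence

from .patterns import STRPattern, build_pattern
from .seeding import reverse_complement, seed_phases

__all__ = [
    "TruthRecord",
    "make_panel",
    "render_locus",
    "simulate_reads",
    "write_fastq",
    "write_truth",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read."""

    read_id: str
    marker: str
    copies: tuple[int, ...]  # planted per-unit copy numbers
    n_errors: int
    error_positions: tuple[int, ...]  # positions on the final (oriented) read
    strand: str
    locus_start: int  # interval of the locus on the final read, half-open
    locus_end: int
    fully_contained: bool


def _min_period(s: str) -> int:
    for p in range(1, len(s)):
        if len(s) % p == 0 and s == s[:p] * (len(s) // p):
            return p
    return len(s)


def _random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _random_unit(rng: random.Random, length: int) -> str:
    # reject periodic motifs ("ATAT", "AAA") so the phase of a seed hit
    # is unambiguous; length-1 units are unavoidably homopolymeric
    while True:
        u = _random_dna(rng, length)
        if length == 1 or _min_period(u) == length:
            return u


def _random_boundary_seq(
    rng: random.Random,
    length: int,
    forbid_prefix: str | None = None,
    forbid_suffix: str | None = None,
) -> str:
    # tandem runs are maximal by definition: the sequence right of a run
    # must not start with another whole unit copy, nor the sequence left
    # of a run end with one, or that copy would belong to the run
    while True:
        s = _random_dna(rng, length)
        if forbid_prefix and s.startswith(forbid_prefix):
            continue
        if forbid_suffix and s.endswith(forbid_suffix):
            continue
        return s


def make_panel(
    n_loci: int,
    unit_lengths: Sequence[int] = (2, 3, 4, 5, 6),
    copy_range: tuple[int, int] = (8, 20),
    flank_length: int = 60,
    seed: int = 0,
    two_unit_fraction: float = 0.15,
    spacer_length: int = 6,
    min_run_length: int = 24,
) -> list[STRPattern]:
    """Random panel of ``n_loci`` STR patterns; deterministic given ``seed``.

    A ``two_unit_fraction`` share of loci get two units separated by a
    spacer (compound markers); all other loci have a single unit.
    Reference copy numbers are drawn from ``copy_range`` but floored so
    every reference tandem run spans at least ``min_run_length`` bases
    (short-unit markers carry proportionally more copies, as real
    panels do); this keeps every locus seedable at typical seed lengths.
    """
    if not unit_lengths or copy_range[0] > copy_range[1]:
        raise ValueError("unit_lengths and copy_range must be non-empty")
    rng = random.Random(seed)
    panel: list[STRPattern] = []
    for i in range(n_loci):
        two_units = rng.random() < two_unit_fraction
        units = []
        for _ in range(2 if two_units else 1):
            unit = _random_unit(rng, rng.choice(list(unit_lengths)))
            lo = max(copy_range[0], -(-min_run_length // len(unit)))
            units.append((unit, rng.randint(lo, max(copy_range[1], lo))))
        if two_units:
            spacers = [
                _random_boundary_seq(
                    rng,
                    spacer_length,
                    forbid_prefix=units[0][0],
                    forbid_suffix=units[1][0],
                ),
                "",
            ]
        else:
            spacers = [""]
        left = _random_boundary_seq(rng, flank_length, forbid_suffix=units[0][0])
        right = _random_boundary_seq(rng, flank_length, forbid_prefix=units[-1][0])
        panel.append(
            build_pattern(
                f"SIM{i:03d}",
                left,
                units,
                spacers,
                right,
                coords=("chrS", 1 + 1000 * i, 1000 * i + 500),
            )
        )
    return panel


def render_locus(
    pattern: STRPattern, copies_override: Sequence[int] | None = None
) -> str:
    """Exact sequence ``s_L · s_1^{m_1} · t_1 · ... · s_n^{m_n} · s_R``."""
    copies = (
        tuple(copies_override) if copies_override is not None else pattern.ref_copies
    )
    if len(copies) != pattern.n_units or any(m < 1 for m in copies):
        raise ValueError("copies_override must give one positive count per unit")
    parts = [pattern.left_flank]
    for (unit, _), spacer, m in zip(pattern.units, pattern.spacers, copies):
        parts.append(unit * m)
        parts.append(spacer)
    parts.append(pattern.right_flank)
    return "".join(parts)


def _forbidden_kmers(patterns: Sequence[STRPattern], k: int) -> set[str]:
    kmers: set[str] = set()
    for p in patterns:
        for unit, _ in p.units:
            if k >= len(unit):
                for s in seed_phases(unit, k):
                    kmers.add(s)
                    kmers.add(reverse_complement(s))
    return kmers


def _screened_padding(
    rng: random.Random, length: int, context: str, at_start: bool,
    forbidden: set[str], k: int,
) -> str:
    """Random padding whose junction with ``context`` creates no seed k-mer."""
    for _ in range(200):
        pad = _random_dna(rng, length)
        joined = pad + context[: k - 1] if at_start else context[-(k - 1):] + pad
        if not any(
            joined[i : i + k] in forbidden for i in range(max(0, len(joined) - k + 1))
        ):
            return pad
    raise RuntimeError("could not generate seed-free padding")  # pragma: no cover


def simulate_reads(
    patterns: Sequence[STRPattern],
    allele_model: Mapping[str, Sequence[Sequence[int]]] | None = None,
    read_length: int = 1000,
    n_reads_per_locus: int = 10,
    error_rate: float = 0.0,
    seed: int = 0,
    k: int = 18,
    rc_fraction: float = 0.5,
) -> tuple[list[tuple[str, str]], list[TruthRecord]]:
    """Simulate reads with planted STR alleles.

    ``allele_model`` maps marker name to the allele set to draw from
    (each allele a per-unit copy-number list); markers absent from the
    model are simulated at their reference copy numbers.  Reads longer
    than the rendered locus contain it fully inside screened random
    padding; shorter reads are windows over the locus rendering.
    Returns ``(reads, truth)`` with reads as ``(read_id, sequence)``
    pairs; deterministic given ``seed``.
    """
    rng = random.Random(seed)
    forbidden = _forbidden_kmers(patterns, k)
    reads: list[tuple[str, str]] = []
    truth: list[TruthRecord] = []

    for pattern in patterns:
        alleles: Sequence[Sequence[int]]
        if allele_model is not None and pattern.marker in allele_model:
            alleles = allele_model[pattern.marker]
        else:
            alleles = [pattern.ref_copies]
        for ridx in range(n_reads_per_locus):
            allele = tuple(int(m) for m in rng.choice(list(alleles)))
            core = render_locus(pattern, allele)
            if read_length >= len(core):
                left = rng.randint(0, read_length - len(core))
                right = read_length - len(core) - left
                lpad = (
                    _screened_padding(rng, left, core, True, forbidden, k)
                    if left
                    else ""
                )
                rpad = (
                    _screened_padding(rng, right, core, False, forbidden, k)
                    if right
                    else ""
                )
                seq = lpad + core + rpad
                locus_start, locus_end = left, left + len(core)
                contained = True
            else:
                w = rng.randint(0, len(core) - read_length)
                seq = core[w : w + read_length]
                locus_start, locus_end = 0, read_length
                contained = False

            bases = list(seq)
            errors: list[int] = []
            for pos in range(len(bases)):
                if rng.random() < error_rate:
                    bases[pos] = rng.choice([b for b in _BASES if b != bases[pos]])
                    errors.append(pos)
            seq = "".join(bases)

            strand = "-" if rng.random() < rc_fraction else "+"
            if strand == "-":
                seq = reverse_complement(seq)
                n = len(seq)
                errors = sorted(n - 1 - e for e in errors)
                locus_start, locus_end = n - locus_end, n - locus_start

            read_id = f"{pattern.marker}_r{ridx:04d}"
            reads.append((read_id, seq))
            truth.append(
                TruthRecord(
                    read_id=read_id,
                    marker=pattern.marker,
                    copies=allele,
                    n_errors=len(errors),
                    error_positions=tuple(errors),
                    strand=strand,
                    locus_start=locus_start,
                    locus_end=locus_end,
                    fully_contained=contained,
                )
            )
    return reads, truth


def write_fastq(reads: Sequence[tuple[str, str]], sink: IO[str]) -> None:
    """Write reads as FASTQ with a constant placeholder quality."""
    for read_id, seq in reads:
        sink.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth(truth: Sequence[TruthRecord], sink: IO[str]) -> None:
    """Write the truth table as a TSV."""
    sink.write(
        "#read_id\tmarker\tcopies\tn_errors\terror_positions\tstrand\t"
        "locus_start\tlocus_end\tfully_contained\n"
    )
    for t in truth:
        sink.write(
            "\t".join(
                (
                    t.read_id,
                    t.marker,
                    ";".join(str(m) for m in t.copies),
                    str(t.n_errors),
                    ",".join(str(p) for p in t.error_positions),
                    t.strand,
                    str(t.locus_start),
                    str(t.locus_end),
                    "true" if t.fully_contained else "false",
                )
            )
            + "\n"
        )
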