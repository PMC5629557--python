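"""End-to-end profiling pipeline: stream reads, scan, aggregate, report.

Each read is scanned independently against the panel; a read supports
at most one allele (copy-number signature) per marker — the accepted
call with the smallest edit distance wins — but may support several
distinct markers.  Per-locus profiles map each observed signature to
its supporting reads; a locus with two or more observed signatures is
classified multi-allelic (heterozygosity on autosomes, multi-copy loci
on the Y chromosome).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio import SeqIO

from .extension import STRCall, extend_alignment
from .patterns import ScanParams, STRPattern
from .seeding import SeedIndex, find_seeds, index_patterns

__all__ = [
    "LocusProfile",
    "read_sequences",
    "scan_read",
    "profile_reads",
    "write_report",
    "write_calls",
    "format_signature",
    "parse_allele_cell",
]


@dataclass
class LocusProfile:
    """Aggregated support for one panel locus.

    ``alleles`` maps a per-unit copy-number signature, e.g. ``(13,)`` or
    ``(19, 23)``, to the ids of the reads supporting it.
    """

    marker: str
    pattern: STRPattern
    alleles: dict[tuple[int, ...], list[str]] = field(default_factory=dict)

    @property
    def multi_allelic(self) -> bool:
        return sum(1 for reads in self.alleles.values() if reads) >= 2

    @property
    def n_supporting_reads(self) -> int:
        return sum(len(r) for r in self.alleles.values())


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_sequences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream ``(read_id, sequence)`` from a FASTA or FASTQ file.

    gzip compression and the record format are auto-detected from the
    file content; FASTQ qualities are read and discarded.  Malformed
    records raise ``ValueError`` carrying the record index.
    """
    handle = _open_text(path)
    try:
        first = handle.read(1)
        if not first:
            return
        handle.seek(0)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ (starts with {first!r})")
        idx = 0
        try:
            for record in SeqIO.parse(handle, fmt):
                yield record.id, str(record.seq).upper()
                idx += 1
        except ValueError as exc:
            raise ValueError(f"{path}: malformed record #{idx + 1}: {exc}") from exc
    finally:
        handle.close()


def scan_read(
    read_id: str,
    read: str,
    index: SeedIndex,
    patterns: Sequence[STRPattern],
    params: ScanParams,
) -> list[STRCall]:
    """Scan one read against the panel; best accepted call per marker.

    Every collapsed seed is extended; among multiple accepted calls for
    the same pattern the one with minimal distance is kept (ties: most
    total copies, then leftmost on the read).
    """
    best: dict[int, STRCall] = {}
    for seed in find_seeds(read, index, params):
        call = extend_alignment(seed, read, patterns[seed.pattern_id], params, read_id)
        if call is None:
            continue
        cur = best.get(call.pattern_id)
        if cur is None or (
            (call.distance, -call.total_copies, call.start)
            < (cur.distance, -cur.total_copies, cur.start)
        ):
            best[call.pattern_id] = call
    return [best[pid] for pid in sorted(best)]


def profile_reads(
    reads: Iterable[tuple[str, str]],
    patterns: Sequence[STRPattern],
    params: ScanParams,
    calls_out: list[STRCall] | None = None,
) -> list[LocusProfile]:
    """Profile a stream of reads against the panel.

    Returns one :class:`LocusProfile` per panel locus in panel order;
    loci without support have an empty allele table.  If ``calls_out``
    is given, every accepted per-read call is appended to it.
    """
    patterns = list(patterns)
    index = index_patterns(patterns, params)
    profiles = [LocusProfile(marker=p.marker, pattern=p) for p in patterns]
    for read_id, seq in reads:
        for call in scan_read(read_id, seq, index, patterns, params):
            profiles[call.pattern_id].alleles.setdefault(call.copies, []).append(read_id)
            if calls_out is not None:
                calls_out.append(call)
    return profiles


def format_signature(sig: tuple[int, ...]) -> str:
    return ";".join(str(m) for m in sig)


def _allele_cell(profile: LocusProfile) -> str:
    entries = sorted(
        ((sig, len(reads)) for sig, reads in profile.alleles.items() if reads),
        key=lambda e: (-e[1], e[0]),
    )
    return ",".join(f"{format_signature(sig)}({count})" for sig, count in entries)


def parse_allele_cell(cell: str) -> dict[tuple[int, ...], int]:
    """Inverse of the report's allele cell formatting (used for round-trips)."""
    out: dict[tuple[int, ...], int] = {}
    if not cell:
        return out
    for entry in cell.split(","):
        sig_s, _, count_s = entry.rstrip(")").partition("(")
        out[tuple(int(x) for x in sig_s.split(";"))] = int(count_s)
    return out


def _params_header(params: ScanParams) -> str:
    return (
        f"# params: k={params.k} delta={params.delta} epsilon={params.epsilon} "
        f"band={params.band} min_flank_anchor={params.min_flank_anchor} "
        f"both_strands={params.both_strands}"
    )


def write_report(
    profiles: Sequence[LocusProfile],
    sink: IO[str],
    params: ScanParams | None = None,
) -> None:
    """Write the locus-level TSV: one row per panel locus.

    The allele cell lists observed signatures as ``copies(count)``
    entries in descending support order; per-unit copies inside one
    signature are ';'-joined.
    """
    if params is not None:
        sink.write(_params_header(params) + "\n")
    sink.write(
        "#marker\tchrom\tstart\tend\tunits\tref_copies\talleles\t"
        "n_supporting_reads\tmulti_allelic\n"
    )
    for prof in profiles:
        p = prof.pattern
        sink.write(
            "\t".join(
                (
                    p.marker,
                    p.chrom,
                    str(p.ref_start),
                    str(p.ref_end),
                    ";".join(p.unit_seqs),
                    format_signature(p.ref_copies),
                    _allele_cell(prof),
                    str(prof.n_supporting_reads),
                    "true" if prof.multi_allelic else "false",
                )
            )
            + "\n"
        )


def write_calls(
    calls: Sequence[STRCall],
    sink: IO[str],
    params: ScanParams | None = None,
) -> None:
    """Write the per-read calls TSV."""
    if params is not None:
        sink.write(_params_header(params) + "\n")
    sink.write("#read_id\tmarker\tstrand\tstart\tend\tcopies\tdistance\n")
    for c in calls:
        sink.write(
            "\t".join(
                (
                    c.read_id,
                    c.marker,
                    c.strand,
                    str(c.start),
                    str(c.end),
                    format_signature(c.copies),
                    str(c.distance),
                )
            )
            + "\n"
        )
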