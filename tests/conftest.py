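import random

import pytest

from strscan import ScanParams, build_pattern


@pytest.fixture
def params():
    return ScanParams()


@pytest.fixture
def atcc_pattern():
    """Single-unit locus with an ATCC tetranucleotide run of 8 copies."""
    return build_pattern(
        "ATCC8",
        "TTACGGTTCAACCTGGTAAG",
        [("ATCC", 8)],
        [""],
        "GTAACCTTGGAACGTGATCA",
        coords=("chr1", 101, 180),
    )


@pytest.fixture
def two_unit_pattern():
    """Compound locus with two runs and a spacer (YCAII-style layout)."""
    return build_pattern(
        "DUO",
        "TTACGGTTCAACCTGGTAAG",
        [("TAGA", 6), ("CAGT", 7)],
        ["GGTTCC", ""],
        "GTAACCTTGGAACGTGATCA",
    )


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def random_pattern(rng: random.Random, *, max_units: int = 2, max_copies: int = 12,
                   flank: int = 12, min_run: int = 14):
    """Small random locus for oracle comparisons, honouring run maximality."""
    n_units = 1 + (rng.random() < 0.3 and max_units > 1)
    units = []
    for _ in range(n_units):
        length = rng.choice([2, 3, 4])
        while True:
            u = random_dna(rng, length)
            if len(set(u)) > 1 and all(
                u != u[i:] + u[:i] for i in range(1, length)
            ):
                break
        lo = max(4, -(-min_run // length))
        units.append((u, rng.randint(lo, max(max_copies, lo))))

    def boundary(length, fp=None, fs=None):
        while True:
            s = random_dna(rng, length)
            if fp and s.startswith(fp):
                continue
            if fs and s.endswith(fs):
                continue
            return s

    if n_units == 2:
        spacers = [boundary(5, fp=units[0][0], fs=units[1][0]), ""]
    else:
        spacers = [""]
    return build_pattern(
        f"R{rng.randrange(10**6)}",
        boundary(flank, fs=units[0][0]),
        units,
        spacers,
        boundary(flank, fp=units[-1][0]),
    )


def plant_substitutions(rng: random.Random, seq: str, n: int) -> str:
    bases = list(seq)
    for pos in rng.sample(range(len(bases)), n):
        bases[pos] = rng.choice([b for b in "ACGT" if b != bases[pos]])
    return "".join(bases)
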