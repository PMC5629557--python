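# Methods

## Locus model and distance

An STR locus is a pattern `P = s_L (s_1)_{c_1} t_1 … (s_n)_{c_n} s_R`:
unique flanks `s_L`/`s_R`, repetitive units `s_i` (1–6 bp, non-empty)
at reference copy numbers `c_i ≥ 1`, and spacers `t_i` between runs
with `t_n` empty. The distance between a query string `Q` and `P` is
the minimum, over all partitions of `Q` into flank / run / spacer
segments and all per-unit copy numbers `m_i` with `|m_i − c_i| ≤ ε`,
of the summed per-component edit distances, each component aligned by
unit-cost Levenshtein DP restricted to a diagonal band `|i − j| ≤ ω`.
The band implements the constraint that any single component alignment
contains at most ω indels; copy-number change is modelled by `m_i`,
not by indels, which is why ω can stay small.

`align.brute_force_distance` computes this minimum exactly by chaining
banded prefix tables across the component sequence (min over `m_i` per
run). It is exponential-free but still quadratic per component and is
guarded to `|Q| ≤ 300`, `n ≤ 3`: it exists as an independent oracle
for the greedy engine, not as a production path.

## Seeding

A seed is the length-k prefix of the infinite repetition of a unit;
`k mod |s_i| ≠ 0` truncates the last copy. Every rotation of every
unit is indexed, since a read may enter a run at any phase. Units
whose maximum admissible run `(c_i + ε)·|s_i|` is shorter than k are
skipped with a warning — they can never contain an exact seed.

Lookup is exact k-mer matching on the forward read and (by default) its
reverse complement, with minus-strand coordinates mapped back to the
forward read. Along a clean tandem run every k-mer position hits, so
overlapping hits to the same (pattern, unit, strand) are collapsed:
one hit is kept per seed phase — the hit covering the most whole
copies, ties to the leftmost. Collapsing per phase rather than to a
single hit per run matters at run boundaries: a flank base that
coincidentally continues the unit's periodicity produces an exact but
mis-phased seed protruding into the flank, locally indistinguishable
from an interior seed; extending one candidate per phase (≤ 6 per run)
and keeping the best resulting call makes error-free recovery exact.

## Greedy bidirectional extension

A seed initialises the cursor pair and copy count; a truncated copy at
either seed end is first completed gap-free (mismatches cost 1; a
completion clipped by the read end is discarded). Then, strictly
alternating 3′ before 5′, each step fits up to three candidates against
the remaining context with the residual budget `δ − D`:

* another copy of the current unit, admissible while `m_i < c_i + ε`;
* the spacer concatenated with the next unit (3′ side; mirrored on 5′),
  admissible while more units remain;
* the terminal flank, admissible at the last (first) unit.

The candidate with minimum added distance is applied; ties are broken
in the order listed, preferring run continuation, which
deterministically maximises the recovered copy number. Extension stops
with an accepted call when both flanks are anchored, or rejects when a
side runs out of candidates or `D` would exceed δ. Fitting alignments
(`fit_prefix`/`fit_suffix`) minimise distance over prefixes (suffixes)
of the context within the band; distance ties prefer the longest fit,
so a component consumes its full length when it can.

Flanks truncated by the read end are accepted with a clipped anchor as
long as ≥ `min_flank_anchor` bases align; the distance is computed over
the overlap only. Both flanks are required — an unanchored run gives
no call, because the copy number of a run not bracketed by flanks is
not measurable. On acceptance each `|m_i − c_i| ≤ ε` is re-checked
(the greedy bounds `m_i` from above during extension; the lower bound
is validated at the end).

Accepted calls report per-unit copy counts (whole copies only — STR
nomenclature uses integer alleles), total distance, strand, and the
aligned read interval in forward-read coordinates.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| k | 18 | seed length (bases); multiple of unit lengths 2, 3, 6; fits 100 bp reads |
| δ | 4 | max total edit distance of an accepted occurrence |
| ε | 30 | max per-unit deviation of observed from reference copies; effectively unconstrained upward, since real alleles sit up to ~11 copies from the reference |
| ω | 3 | max indels per component alignment; larger run-length changes are copy-number changes, handled by ε |
| min_flank_anchor | 8 | min aligned flank bases per side; 8 bp gives a ~6·10⁻⁵ chance of a random anchor match |
| both_strands | on | shotgun reads sample both strands; calls are reported in pattern orientation |

## Synthetic data

`simulate.make_panel` draws random loci: units are uniform non-periodic
motifs (periodic motifs like `ATAT` are rejected so seed phase is
unambiguous), 15% of loci get two units with a spacer (compound-marker
style), flanks default to 60 bp. Reference copies are drawn from
`copy_range` (default 8–20) but floored so every reference run spans
≥ `min_run_length` = 24 bases — short-unit markers carry
proportionally more copies, as real dinucleotide markers do, and every
locus stays seedable at k = 18. Flanks and spacers honour tandem-run
maximality: the sequence right of a run never starts with a whole copy
of that run's unit, nor the sequence left of it end with one. This is
part of what defines a locus boundary (such a copy would belong to the
run); without it the reference copy number itself would be ill-defined.

`simulate_reads` embeds a rendered allele inside i.i.d. random padding
(reads longer than the locus) or windows over the rendering (shorter
reads), applies i.i.d. substitutions at `error_rate`, reverse-
complements about half the reads, and emits a truth record per read.
Padding is screened against the panel's seed k-mers on both strands,
so seeds in fixtures can only arise from planted loci. Defaults (18
loci, 10 reads per locus, 1000 bp or 100 bp reads, 0 or 0.5%
substitution error) emulate long-read and short-read whole-genome
regimes at desk scale.

What the simulator does **not** model: PCR stutter (the dominant real
STR artifact), indel sequencing errors by default, coverage variation,
quality scores (constant placeholder), and real genomic repeat
structure around loci. Passing tests therefore demonstrate the
correctness of the seeding/extension machinery and its robustness to
substitution noise — not calling accuracy on stutter-affected
amplicon data.

## Numerical and design choices

* Unit costs 1/1/1 for substitution/insertion/deletion (plain
  Levenshtein).
* Infeasible banded alignments return an `INF` sentinel rather than
  raising, so candidate minima skip infeasible branches uniformly.
* All tie-breaks are fixed (candidate order; longest fit; leftmost
  seed), so identical inputs give byte-identical reports.
* Paired-end mates are scanned as independent reads.
* A read supports at most one allele per marker (its best call) but may
  support several markers, including overlapping panel loci.
* Reads shorter than k, or containing non-ACGT characters in the
  seeded region, simply produce no hits.

## Known limitations

* The extension is strictly greedy with one-component lookahead: a
  sequencing error in a flank can tie with a spurious run continuation,
  which the mandated tie order resolves toward the run; the cursor may
  then drift past the run boundary until the band makes the flank
  infeasible, losing that read. At 0.5% error this costs ~20% of
  individual 1000 bp reads while locus-level recovery (any supporting
  read) stays at 100%; δ is the controlling parameter.
* Homopolymer and periodic units share rotations, so their seeds
  collapse; phase within such runs is intrinsically ambiguous.
* Copy numbers are integers; partial-repeat alleles (e.g. 9.3 at TH01)
  are reported at their whole-copy count.
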