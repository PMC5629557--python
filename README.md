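# strscan

Targeted profiling of short tandem repeats (STRs) in sequencing reads.

STRs — microsatellites of 2–30 tandem copies of a 1–6 bp unit — are the
workhorse markers of forensic identity testing (CODIS, Y-STR panels) and
of genetic testing for repeat-expansion disorders. Given a user-defined
panel of STR loci and whole-genome or amplicon sequencing reads, this
package finds the reads containing each locus and reports the repeat
copy number observed in every supporting read, without mapping reads to
a reference genome.

## Model

Each locus is a pattern

```
P = s_L (s_1)_{c_1} t_1 (s_2)_{c_2} t_2 … (s_n)_{c_n} s_R
```

with repetitive units `s_i` at reference copy numbers `c_i`, spacers
`t_i` between runs (`t_n = ∅`), and unique flanks `s_L`, `s_R`. A read
`T` supports `P` if some substring of `T` aligns to `P` with edit
distance ≤ δ, where the alignment decomposes into per-component fits:
flank vs flank, each tandem run vs `s_i` repeated `m_i` times with
`|m_i − c_i| ≤ ε`, spacer vs spacer. Component alignments use banded
dynamic programming with at most ω indels each.

The scan is greedy seed-and-extend:

1. **Index** — every rotation of every unit is turned into a length-k
   tandem seed (e.g. `ATCC`, k=18 → `ATCCATCCATCCATCCAT`) and indexed.
2. **Seed** — exact k-mer hits in each read (both strands) become seed
   alignments; overlapping hits along one run are collapsed.
3. **Extend** — after gap-free completion of a truncated seed copy, the
   engine repeatedly applies the locally cheapest extension at the 3′
   end — another copy of `s_i` (while `m_i < c_i + ε`), spacer + next
   unit, or the right flank — and symmetrically at the 5′ end, until
   both flanks are anchored or the distance budget δ is spent.

Per locus, the supporting reads' copy-number signatures are aggregated;
a locus with ≥ 2 observed signatures is classified **multi-allelic**
(heterozygosity on autosomes, multi-copy loci on chrY).

## Worked example

Simulate a panel with planted alleles and profile it:

```bash
strscan simulate --panel-out panel.tsv --reads-out reads.fq \
    --truth-out truth.tsv --n-loci 4 --reads-per-locus 5 --seed 1
strscan scan --panel panel.tsv --reads reads.fq --out demo --per-read-calls
head -3 demo.profile.tsv
```

prints (after the parameter header):

```
# params: k=18 delta=4 epsilon=30 band=3 min_flank_anchor=8 both_strands=True
#marker	chrom	start	end	units	ref_copies	alleles	n_supporting_reads	multi_allelic
SIM000	chrS	1	500	GA;TTCAT	19;8	19;8(5)	5	false
```

Reading the `SIM000` row: the locus has two repetitive units (`GA` and
`TTCAT`) with reference copies 19 and 8; all 5 simulated reads support
the allele with 19 and 8 observed copies (`19;8(5)` = signature,
supporting-read count in parentheses); one observed signature, so not
multi-allelic. `demo.calls.tsv` lists each supporting read with its
strand, aligned interval, per-unit copies and edit distance.

The same pipeline is available as a library:

```python
from strscan import ScanParams, make_panel, simulate_reads, profile_reads

panel = make_panel(18, seed=1)
reads, truth = simulate_reads(panel, read_length=1000, seed=2)
profiles = profile_reads(reads, panel, ScanParams())
```

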