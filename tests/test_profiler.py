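import gzip
import io
import random

import pytest
from click.testing import CliRunner

from strscan import (
    ScanParams,
    index_patterns,
    make_panel,
    parse_allele_cell,
    profile_reads,
    read_sequences,
    render_locus,
    reverse_complement,
    scan_read,
    simulate_reads,
    write_calls,
    write_fastq,
    write_report,
    write_pattern_table,
)
from strscan.cli import main as cli_main


class TestReadSequences:
    def test_fasta_order_preserved(self, tmp_path):
        fa = tmp_path / "r.fa"
        fa.write_text(">a\nACGT\n>b\nGGTTAA\n>c\nTTTT\n")
        assert list(read_sequences(fa)) == [("a", "ACGT"), ("b", "GGTTAA"), ("c", "TTTT")]

    def test_gzipped_fastq_qualities_dropped(self, tmp_path):
        fq = tmp_path / "r.fq.gz"
        records = "".join(f"@r{i}\nACGTACGT\n+\nIIIIIIII\n" for i in range(10))
        with gzip.open(fq, "wt") as fh:
            fh.write(records)
        out = list(read_sequences(fq))
        assert len(out) == 10
        assert out[0] == ("r0", "ACGTACGT")

    def test_empty_sequence_record_yields_empty_string(self, tmp_path):
        fa = tmp_path / "r.fa"
        fa.write_text(">a\n\n>b\nACGT\n")
        assert list(read_sequences(fa)) == [("a", ""), ("b", "ACGT")]

    def test_garbage_rejected(self, tmp_path):
        bad = tmp_path / "r.txt"
        bad.write_text("not a sequence file\n")
        with pytest.raises(ValueError, match="not FASTA or FASTQ"):
            list(read_sequences(bad))


class TestScanRead:
    def test_read_with_no_seeds_is_empty(self, atcc_pattern, params):
        idx = index_patterns([atcc_pattern], params)
        assert scan_read("r", "GATC" * 30, idx, [atcc_pattern], params) == []

    def test_read_spanning_two_loci_yields_two_calls(
        self, atcc_pattern, two_unit_pattern, params
    ):
        panel = [atcc_pattern, two_unit_pattern]
        idx = index_patterns(panel, params)
        read = render_locus(atcc_pattern) + render_locus(two_unit_pattern)
        calls = scan_read("r", read, idx, panel, params)
        assert [(c.marker, c.copies) for c in calls] == [("ATCC8", (8,)), ("DUO", (6, 7))]
        assert all(c.distance == 0 for c in calls)

    def test_best_call_per_marker(self, atcc_pattern, params):
        # two renderings of the same locus on one read: one exact, one mutated;
        # the read supports a single allele, the exact one
        clean = render_locus(atcc_pattern)
        noisy = list(render_locus(atcc_pattern, [9]))
        noisy[len(atcc_pattern.left_flank) + 3] = "G"
        read = clean + "TTGACTGATC" + "".join(noisy)
        idx = index_patterns([atcc_pattern], params)
        calls = scan_read("r", read, idx, [atcc_pattern], params)
        assert len(calls) == 1
        assert calls[0].copies == (8,) and calls[0].distance == 0


class TestProfileReads:
    def test_haploid_counts(self, params):
        panel = make_panel(6, seed=4)
        reads, _ = simulate_reads(panel, n_reads_per_locus=10, seed=5)
        profiles = profile_reads(reads, panel, params)
        assert [p.marker for p in profiles] == [q.marker for q in panel]
        for prof, pat in zip(profiles, panel):
            assert prof.alleles == {pat.ref_copies: prof.alleles[pat.ref_copies]}
            assert len(prof.alleles[pat.ref_copies]) == 10
            assert prof.multi_allelic is False

    def test_heterozygous_locus_is_multi_allelic(self, params):
        panel = make_panel(4, seed=6)
        model = {
            p.marker: [p.ref_copies, tuple(c + 3 for c in p.ref_copies)]
            for p in panel
        }
        reads, truth = simulate_reads(
            panel, allele_model=model, n_reads_per_locus=20, seed=7
        )
        profiles = profile_reads(reads, panel, params)
        for prof in profiles:
            observed = {s for s, r in prof.alleles.items() if r}
            assert len(observed) == 2
            assert prof.multi_allelic is True

    def test_empty_stream_keeps_all_loci(self, params):
        panel = make_panel(5, seed=8)
        profiles = profile_reads([], panel, params)
        assert len(profiles) == 5
        assert all(p.alleles == {} and not p.multi_allelic for p in profiles)

    def test_support_bounded_by_input_reads(self, params):
        panel = make_panel(4, seed=9)
        reads, _ = simulate_reads(panel, n_reads_per_locus=5, seed=10)
        profiles = profile_reads(reads, panel, params)
        for prof in profiles:
            assert prof.n_supporting_reads <= len(reads)

    def test_counts_invariant_under_read_order(self, params):
        panel = make_panel(4, seed=12)
        reads, _ = simulate_reads(panel, n_reads_per_locus=6, seed=13)
        shuffled = list(reads)
        random.Random(0).shuffle(shuffled)
        a = profile_reads(reads, panel, params)
        b = profile_reads(shuffled, panel, params)
        for pa, pb in zip(a, b):
            assert {s: len(r) for s, r in pa.alleles.items()} == {
                s: len(r) for s, r in pb.alleles.items()
            }


class TestReports:
    def test_report_round_trips_allele_multiset(self, params):
        panel = make_panel(4, seed=6)
        model = {
            p.marker: [p.ref_copies, tuple(c + 3 for c in p.ref_copies)]
            for p in panel
        }
        reads, _ = simulate_reads(panel, allele_model=model,
                                  n_reads_per_locus=12, seed=7)
        profiles = profile_reads(reads, panel, params)
        buf = io.StringIO()
        write_report(profiles, buf, params=params)
        rows = [l.split("\t") for l in buf.getvalue().splitlines()
                if not l.startswith("#")]
        assert len(rows) == len(panel)
        for row, prof in zip(rows, profiles):
            assert row[0] == prof.marker
            assert parse_allele_cell(row[6]) == {
                s: len(r) for s, r in prof.alleles.items() if r
            }
            assert row[8] == ("true" if prof.multi_allelic else "false")

    def test_empty_profile_row(self, params):
        panel = make_panel(1, seed=3)
        profiles = profile_reads([], panel, params)
        buf = io.StringIO()
        write_report(profiles, buf)
        row = [l for l in buf.getvalue().splitlines() if not l.startswith("#")][0]
        assert row.split("\t")[6] == ""

    def test_calls_table_columns(self, atcc_pattern, params):
        idx = index_patterns([atcc_pattern], params)
        calls = scan_read("r1", render_locus(atcc_pattern), idx, [atcc_pattern], params)
        buf = io.StringIO()
        write_calls(calls, buf)
        row = [l for l in buf.getvalue().splitlines() if not l.startswith("#")][0]
        rid, marker, strand, start, end, copies, dist = row.split("\t")
        assert (rid, marker, copies, dist) == ("r1", "ATCC8", "8", "0")


class TestCli:
    def _write_inputs(self, tmp_path, rc_fraction=0.5):
        panel = make_panel(4, seed=20)
        reads, _ = simulate_reads(panel, n_reads_per_locus=4, seed=21,
                                  rc_fraction=rc_fraction)
        panel_path = tmp_path / "panel.tsv"
        reads_path = tmp_path / "reads.fq"
        with open(panel_path, "w") as fh:
            write_pattern_table(panel, fh)
        with open(reads_path, "w") as fh:
            write_fastq(reads, fh)
        return panel_path, reads_path

    def test_scan_writes_reports(self, tmp_path):
        panel_path, reads_path = self._write_inputs(tmp_path)
        out = tmp_path / "out"
        result = CliRunner().invoke(
            cli_main,
            ["scan", "--panel", str(panel_path), "--reads", str(reads_path),
             "--out", str(out), "--per-read-calls"],
        )
        assert result.exit_code == 0, result.output
        profile = (tmp_path / "out.profile.tsv").read_text()
        assert profile.count("\n") >= 5
        assert (tmp_path / "out.calls.tsv").exists()

    def test_byte_stable_reruns(self, tmp_path):
        panel_path, reads_path = self._write_inputs(tmp_path)
        outputs = []
        for name in ("a", "b"):
            out = tmp_path / name
            result = CliRunner().invoke(
                cli_main,
                ["scan", "--panel", str(panel_path), "--reads", str(reads_path),
                 "--out", str(out)],
            )
            assert result.exit_code == 0
            outputs.append((tmp_path / f"{name}.profile.tsv").read_bytes())
        assert outputs[0] == outputs[1]

    def test_missing_panel_is_usage_error(self, tmp_path):
        result = CliRunner().invoke(
            cli_main,
            ["scan", "--panel", str(tmp_path / "nope.tsv"),
             "--reads", str(tmp_path / "nope.fq"), "--out", str(tmp_path / "o")],
        )
        assert result.exit_code == 2
        assert not (tmp_path / "o.profile.tsv").exists()

    def test_no_reverse_complement_flag(self, tmp_path):
        # all reads reverse-complemented: default recovers, forward-only finds none
        panel_path, reads_path = self._write_inputs(tmp_path, rc_fraction=1.0)
        runner = CliRunner()
        out_def = tmp_path / "def"
        out_fwd = tmp_path / "fwd"
        assert runner.invoke(
            cli_main, ["scan", "--panel", str(panel_path), "--reads",
                       str(reads_path), "--out", str(out_def)]
        ).exit_code == 0
        assert runner.invoke(
            cli_main, ["scan", "--panel", str(panel_path), "--reads",
                       str(reads_path), "--out", str(out_fwd),
                       "--no-reverse-complement"]
        ).exit_code == 0

        def total_support(path):
            rows = [l.split("\t") for l in path.read_text().splitlines()
                    if not l.startswith("#")]
            return sum(int(r[7]) for r in rows)

        assert total_support(tmp_path / "def.profile.tsv") == 16
        assert total_support(tmp_path / "fwd.profile.tsv") == 0

    def test_simulate_subcommand(self, tmp_path):
        result = CliRunner().invoke(
            cli_main,
            ["simulate", "--panel-out", str(tmp_path / "p.tsv"),
             "--reads-out", str(tmp_path / "r.fq"),
             "--truth-out", str(tmp_path / "t.tsv"),
             "--n-loci", "3", "--reads-per-locus", "2", "--seed", "1"],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "p.tsv").exists()
        assert (tmp_path / "r.fq").read_text().count("@") >= 6
        assert (tmp_path / "t.tsv").exists()
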