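"""FASTA parsing, batch scanning, curves, and output round-trips."""

import io
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from parse2.batch import (
    ScanConfig,
    build_reference_table,
    cumulative_curve,
    read_fasta,
    recall_auc,
    scan_fasta,
    summarize_sequence,
)
from parse2.potential import ps_potential
from parse2.synthetic import (
    ArchitectureSpec,
    generate_architecture,
    generate_class_sequence,
)
from parse2.windows import window_table


def fasta_io(text: str) -> io.StringIO:
    return io.StringIO(text)


UNIPROT_HEADER = (
    ">sp|P0DMV8|HS71A_HUMAN Heat shock 70 kDa protein 1A "
    "OS=Homo sapiens OX=9606 GN=HSPA1A PE=1 SV=1"
)


class TestReadFasta:
    def test_uniprot_dialect_parsed(self):
        records = read_fasta(fasta_io(UNIPROT_HEADER + "\nGGGG\n"))
        rec = records[0]
        assert rec.accession == "P0DMV8"
        assert rec.gene == "HSPA1A"
        assert rec.protein_name == "Heat shock 70 kDa protein 1A"
        assert rec.raw_header.startswith("sp|P0DMV8|")
        assert rec.id == "P0DMV8"

    def test_plain_header_keeps_raw_text(self):
        records = read_fasta(fasta_io(">seq1\n" + "G" * 30 + "\n"))
        rec = records[0]
        assert rec.accession == "" and rec.gene == ""
        assert rec.id == "seq1"

    def test_multiline_and_lowercase_sequences(self):
        text = ">a\nggg\nAAA\n>b\nCCCC\n"
        records = read_fasta(fasta_io(text))
        assert records[0].sequence == "GGGAAA"
        assert records[1].sequence == "CCCC"

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="empty FASTA"):
            read_fasta(fasta_io(""))


class TestSummaries:
    def test_uniform_p_sequence_has_single_psid_region(self):
        seq = generate_class_sequence("P", 100, seed=5)
        records = read_fasta(fasta_io(f">p_fix\n{seq}\n"))
        row = summarize_sequence(records[0])
        assert row.longest_ps_idr == 100
        assert row.longest_idr == 0 and row.longest_folded == 0
        assert row.length == 100

    def test_two_block_fixture_matches_layout(self):
        fixture = generate_architecture(
            ArchitectureSpec((("P", 60), ("F", 60)), seed=6)
        )
        records = read_fasta(fasta_io(f">fix\n{fixture.sequence}\n"))
        row = summarize_sequence(records[0])
        for klass, start, end in fixture.expected:
            nominal = end - start + 1
            got = {"PS_ID": row.longest_ps_idr, "FOLDED": row.longest_folded}[
                klass
            ]
            assert abs(got - nominal) <= fixture.tolerance

    def test_potential_matches_module_value(self):
        seq = generate_class_sequence("P", 80, seed=7)
        records = read_fasta(fasta_io(f">x\n{seq}\n"))
        row = summarize_sequence(records[0])
        assert row.ps_potential == pytest.approx(
            ps_potential(window_table(seq))
        )


class TestScan:
    @pytest.fixture
    def small_fasta(self, tmp_path):
        entries = []
        for i, (klass, length) in enumerate(
            [("P", 100), ("F", 80), ("D", 90)]
        ):
            seq = generate_class_sequence(klass, length, seed=10 + i)
            entries.append(f">seq{i}_{klass}\n{seq}")
        entries.append(">tiny\n" + "G" * 25)  # skipped: too short
        entries.append(">badchar\n" + "G" * 20 + "X" + "G" * 20)  # skipped
        path = tmp_path / "input.fasta"
        path.write_text("\n".join(entries) + "\n")
        return path

    def test_row_plus_skip_counts_match_input(self, small_fasta):
        result = scan_fasta(small_fasta)
        skipped = [line for line in result.log if line.startswith("skipped")]
        assert len(result.summary) + len(skipped) == 5
        assert any("too short" in line for line in skipped)
        assert any("non-canonical" in line for line in skipped)

    def test_psidr_fasta_round_trips_coordinates(self, small_fasta):
        result = scan_fasta(small_fasta)
        records = {
            r.id: r for r in read_fasta(small_fasta)
        }
        assert result.ps_idrs  # the P sequence exports a >=50 region
        for rec_id, start, end, subseq in result.ps_idrs:
            parent = records[rec_id].sequence
            assert parent[start - 1 : end] == subseq

    def test_outputs_are_deterministic(self, small_fasta, tmp_path):
        out1, out2 = tmp_path / "run1", tmp_path / "run2"
        scan_fasta(small_fasta, output_dir=out1)
        scan_fasta(small_fasta, output_dir=out2)
        for name in (
            "summary.tsv",
            "ps_idrs.fasta",
            "curve_psidr_length.tsv",
            "curve_ps_potential.tsv",
            "scan_log.txt",
        ):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_no_psidr_input_gives_empty_fasta_full_summary(self, tmp_path):
        seq = generate_class_sequence("F", 120, seed=3)
        path = tmp_path / "folded.fasta"
        path.write_text(f">f1\n{seq}\n")
        result = scan_fasta(path, output_dir=tmp_path / "out")
        assert (tmp_path / "out" / "ps_idrs.fasta").read_text() == ""
        assert len(result.summary) == 1

    def test_reference_enrichment_auc_above_half(self, small_fasta, tmp_path):
        # reference: mostly folded/disordered; query: the scan input with a
        # strong PS sequence
        ref_entries = []
        for i in range(6):
            klass = "F" if i % 2 else "D"
            seq = generate_class_sequence(klass, 90, seed=40 + i)
            ref_entries.append(f">ref{i}\n{seq}")
        ref_path = tmp_path / "ref.fasta"
        ref_path.write_text("\n".join(ref_entries) + "\n")
        reference = build_reference_table(ref_path)
        result = scan_fasta(small_fasta, reference=reference)
        assert result.potential_recall is not None
        assert result.potential_recall.auc > 0.5
        assert 0.0 <= result.length_recall.auc <= 1.0


class TestCurves:
    def test_cumulative_fraction_counting(self):
        curve = cumulative_curve([10, 50, 100], thresholds=[50])
        assert curve["fraction"].tolist() == [pytest.approx(2 / 3)]

    def test_cumulative_endpoints(self):
        curve = cumulative_curve([10, 50, 100], thresholds=[10, 101])
        assert curve["fraction"].tolist() == [1.0, 0.0]

    def test_cumulative_default_grid_non_increasing(self, rng):
        values = rng.integers(0, 50, size=100)
        curve = cumulative_curve(values)
        assert (np.diff(curve["fraction"]) <= 0).all()
        assert curve["fraction"].iloc[0] == 1.0

    def test_empty_values_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cumulative_curve([])

    def test_self_recall_is_diagonal(self, rng):
        values = rng.normal(size=500)
        curve = recall_auc(values, values)
        assert curve.auc == pytest.approx(0.5, abs=0.01)
        np.testing.assert_allclose(
            curve.query_fraction, curve.reference_fraction
        )

    def test_dominant_query_saturates_auc(self):
        curve = recall_auc([100, 101, 102], [1, 2, 3])
        assert curve.auc == pytest.approx(1.0, abs=1e-12)

    def test_matched_distributions_near_half(self, rng):
        q = rng.normal(size=4000)
        r = rng.normal(size=4000)
        assert recall_auc(q, r).auc == pytest.approx(0.5, abs=0.03)

    def test_fractions_monotone_in_threshold(self, rng):
        curve = recall_auc(rng.normal(size=50), rng.normal(size=70))
        assert (np.diff(curve.query_fraction) <= 1e-12).all()
        assert (np.diff(curve.reference_fraction) <= 1e-12).all()
        assert 0.0 <= curve.auc <= 1.0
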