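"""Coordinate frame, variant grammar, and table round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirmut.reference_io import (
    FLANK_LEN,
    MirnaGeneAnnotation,
    ParsedVariant,
    VariantParseError,
    format_n_position,
    parse_n_position,
    position_index,
    read_annotations,
    read_isomir_tables,
    read_mutation_table,
    span_length,
    write_annotations,
    write_isomir_tables,
    write_mutation_table,
)


class TestCoordinateFrame:
    def test_skip_zero_numbering(self):
        assert position_index(-25) == 0
        assert position_index(-1) == 24
        assert position_index(1) == 25  # n.1 is the 26th letter (1-based 26)
        assert position_index(60) == 84

    def test_position_zero_rejected(self):
        with pytest.raises(VariantParseError):
            position_index(0)

    def test_span_length_across_zero(self):
        assert span_length(-2, 1) == 3  # -2, -1, 1
        assert span_length(5, 7) == 3


class TestVariantGrammar:
    @pytest.mark.parametrize(
        "token, L, expected",
        [
            ("n.35C>T", 87, ParsedVariant("substitution", 35, 35, "C", "T")),
            ("n.-6C>G", 72, ParsedVariant("substitution", -6, -6, "C", "G")),
            ("n.5-7delAGC", 122, ParsedVariant("deletion", 5, 7, "AGC", "")),
            ("n.97_98dupGG", 110, ParsedVariant("duplication", 97, 98, "GG", "GGGG")),
            ("n.21-22delTA", 110, ParsedVariant("deletion", 21, 22, "TA", "")),
            ("n.10_11insAC", 60, ParsedVariant("insertion", 10, 11, "", "AC")),
        ],
    )
    def test_parses_paper_style_tokens(self, token, L, expected):
        assert parse_n_position(token, L) == expected

    @pytest.mark.parametrize(
        "token, L, code",
        [
            ("n.1-5delAAAAA", 60, "long_indel"),
            ("n.0A>C", 60, "out_of_range"),
            ("n.90C>T", 60, "out_of_range"),
            ("n.-30G>A", 60, "out_of_range"),
            ("garbage", 60, "bad_token"),
            ("n.5-7delAG", 60, "bad_token"),  # span/sequence length mismatch
        ],
    )
    def test_error_codes(self, token, L, code):
        with pytest.raises(VariantParseError) as err:
            parse_n_position(token, L)
        assert err.value.code == code

    def test_ref_checked_against_sequence(self, toy_annotation):
        base = toy_annotation.base_at(10)
        other = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
        ok = parse_n_position(f"n.10{base}>A" if base != "A" else "n.10A>C",
                              toy_annotation.length, toy_annotation.extended_seq)
        assert ok.ref == base
        with pytest.raises(VariantParseError) as err:
            parse_n_position(f"n.10{other}>A", toy_annotation.length,
                             toy_annotation.extended_seq)
        assert err.value.code == "ref_mismatch"

    @given(
        kind=st.sampled_from(["substitution", "deletion", "duplication"]),
        start=st.integers(min_value=-25, max_value=80).filter(lambda x: x != 0),
        length=st.integers(min_value=1, max_value=4),
        seq=st.text(alphabet="ACGT", min_size=4, max_size=4),
    )
    @settings(max_examples=200, deadline=None)
    def test_parse_format_bijection(self, kind, start, length, seq):
        """format then parse is the identity on in-range variants."""
        L = 80
        if kind == "substitution":
            variant = ParsedVariant(kind, start, start, seq[0], seq[1])
        else:
            end = position_index(start) + length - 1
            end_pos = end - FLANK_LEN if end < FLANK_LEN else end - FLANK_LEN + 1
            if end_pos > L + FLANK_LEN:
                return
            s = seq[:length]
            variant = ParsedVariant(kind, start, end_pos, s, "" if kind == "deletion" else s + s)
        assert parse_n_position(format_n_position(variant), L) == variant


class TestSubregions:
    def test_partition_covers_every_position(self, toy_annotation):
        """Every coordinate in [-25, L+25]\\{0} maps to exactly one subregion."""
        L = toy_annotation.length
        seen = {}
        for pos in range(-FLANK_LEN, L + FLANK_LEN + 1):
            if pos == 0:
                continue
            seen[pos] = toy_annotation.subregion(pos)
        assert len(seen) == L + 2 * FLANK_LEN
        # ordered blocks: flank5 < (duplex5p/seed5p) < loop < (duplex3p/seed3p) < flank3
        assert seen[-25] == seen[5] == "flank5"
        assert seen[6] == "duplex5p" and seen[7] == "seed5p" and seen[13] == "seed5p"
        assert seen[14] == "duplex5p"
        assert seen[28] == "loop" and seen[33] == "loop"
        assert seen[34] == "duplex3p" and seen[35] == "seed3p"
        assert seen[56] == seen[85] == "flank3"

    def test_positions_beyond_arm_count_as_flank_even_inside_hairpin(self, toy_annotation):
        # subregion labels follow the arm spans, not the hairpin boundary
        assert 56 <= toy_annotation.length  # inside the precursor...
        assert toy_annotation.subregion(56) == "flank3"  # ...but 3' of the mature arm


class TestAnnotationIO:
    def _write_reference(self, tmp_path, rows, seqs):
        fasta = tmp_path / "ref.fasta"
        coords = tmp_path / "ref.tsv"
        fasta.write_text("".join(f">{g}\n{s}\n" for g, s in seqs.items()))
        pd.DataFrame(
            rows,
            columns=["gene_id", "precursor_id", "L", "mature5p_span", "mature3p_span",
                     "redundant_group"],
        ).to_csv(coords, sep="\t", index=False)
        return fasta, coords

    def test_round_trip_single_gene(self, tmp_path, toy_annotation):
        write_annotations({"MIRTOY": toy_annotation}, tmp_path / "a.fasta", tmp_path / "a.tsv")
        loaded, rejects = read_annotations(tmp_path / "a.fasta", tmp_path / "a.tsv")
        assert rejects == []
        assert loaded["MIRTOY"] == toy_annotation
        assert loaded["MIRTOY"].length == 60

    def test_missing_arm_rejected(self, tmp_path, toy_annotation):
        fasta, coords = self._write_reference(
            tmp_path,
            [["G1", "G1-pre", 60, "6-27", ".", "."]],
            {"G1": toy_annotation.extended_seq},
        )
        loaded, rejects = read_annotations(fasta, coords)
        assert loaded == {}
        assert [(r.item_id, r.reason) for r in rejects] == [("G1", "arm_undefined")]

    def test_bad_flank_rejected(self, tmp_path, toy_annotation):
        fasta, coords = self._write_reference(
            tmp_path,
            [["G1", "G1-pre", 60, "6-27", "34-55", "."]],
            {"G1": toy_annotation.extended_seq[:-3]},
        )
        loaded, rejects = read_annotations(fasta, coords)
        assert loaded == {} and rejects[0].reason == "bad_flank"

    def test_redundant_group_loaded_and_flagged(self, tmp_path, toy_annotation):
        fasta, coords = self._write_reference(
            tmp_path,
            [["MIR1-1", "p1", 60, "6-27", "34-55", "MIR1"],
             ["MIR1-2", "p2", 60, "6-27", "34-55", "MIR1"]],
            {"MIR1-1": toy_annotation.extended_seq, "MIR1-2": toy_annotation.extended_seq},
        )
        loaded, rejects = read_annotations(fasta, coords)
        assert rejects == [] and len(loaded) == 2
        assert {a.redundant_group for a in loaded.values()} == {"MIR1"}


class TestIsomirIO:
    def test_native_round_trip_byte_identical(self, tmp_path, record_factory):
        df = record_factory([(0, 0, 0, 30), (0, -1, 0, 10), (1, 0, 1, 5)])
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_isomir_tables(df, p1)
        loaded, rejects = read_isomir_tables(p1)
        assert rejects == []
        write_isomir_tables(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_unknown_column_hard_error(self, tmp_path, record_factory):
        df = record_factory([(0, 0, 0, 30)])
        df["mystery"] = 1
        df.to_csv(tmp_path / "x.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="unknown columns"):
            read_isomir_tables(tmp_path / "x.tsv")

    def test_negative_count_hard_error(self, tmp_path, record_factory):
        df = record_factory([(0, 0, 0, -3)])
        df.to_csv(tmp_path / "x.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="negative"):
            read_isomir_tables(tmp_path / "x.tsv")

    def test_shift_out_of_range_rejected(self, tmp_path, record_factory):
        df = record_factory([(12, 0, 0, 5), (0, 0, 0, 7)])
        df.to_csv(tmp_path / "x.tsv", sep="\t", index=False)
        loaded, rejects = read_isomir_tables(tmp_path / "x.tsv")
        assert len(loaded) == 1 and loaded["shift5"].iloc[0] == 0
        assert rejects[0].reason == "shift_out_of_range"

    def test_isomirmap_dialect_assigns_source_and_allele(self, tmp_path, record_factory):
        base = record_factory([(0, 0, 0, 10)]).drop(columns=["allele", "source"])
        paths = {}
        for source in ("exclusive", "ambiguous", "snps"):
            p = tmp_path / f"{source}.tsv"
            base.to_csv(p, sep="\t", index=False)
            paths[source] = p
        loaded, _ = read_isomir_tables(paths, dialect="isomirmap")
        pairs = set(zip(loaded["source"], loaded["allele"]))
        assert pairs == {("exclusive", "WT"), ("ambiguous", "AMBIG"), ("snps", "MUT")}


class TestMutationIO:
    def test_round_trip_and_rejections(self, tmp_path, toy_annotation):
        base10 = toy_annotation.base_at(10)
        alt = "A" if base10 != "A" else "C"
        rows = pd.DataFrame(
            [
                {"mutation_id": "M1", "gene_id": "MIRTOY", "sample_id": "S1",
                 "cancer_type": "LUAD", "hgvs_n": f"n.10{base10}>{alt}",
                 "dna_ref_reads": 60, "dna_alt_reads": 40, "homozygous": 0},
                {"mutation_id": "M2", "gene_id": "MIRTOY", "sample_id": "S2",
                 "cancer_type": "LUAD", "hgvs_n": "n.1-5delAAAAA",
                 "dna_ref_reads": 50, "dna_alt_reads": 50, "homozygous": 1},
            ]
        )
        path = tmp_path / "muts.tsv"
        rows.to_csv(path, sep="\t", index=False)
        muts, rejects = read_mutation_table(path, {"MIRTOY": toy_annotation})
        assert [m.mutation_id for m in muts] == ["M1"]
        assert muts[0].subregion == "seed5p"
        assert [(r.item_id, r.reason) for r in rejects] == [("M2", "long_indel")]
        out = tmp_path / "muts_out.tsv"
        write_mutation_table(muts, out)
        reloaded, _ = read_mutation_table(out, {"MIRTOY": toy_annotation})
        assert reloaded == muts
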