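"""Annotation model: parsing, circular coordinate arithmetic, gaps."""

import pytest

from mitochar.annotation import (
    FeatureKind,
    GeneFeature,
    MitogenomeAnnotation,
    extract_feature_sequence,
    feature_length,
    gap_summary,
    intergenic_gaps,
    parse_feature_table,
    serialize_feature_table,
    validate_annotation,
    write_gff3,
)


def _toy_ann(features, length, circular=True):
    return MitogenomeAnnotation(features, length, circular)


class TestParsing:
    def test_thousands_separators_and_dashes(self, ref_ann):
        at_rich = ref_ann.feature("AT-rich region")
        assert (at_rich.start, at_rich.end) == (13380, 14151)
        assert at_rich.kind is FeatureKind.CONTROL

    def test_nd_rows_become_unlocated_placeholders(self, ref_ann):
        ile = ref_ann.feature("tRNA-Ile")
        assert not ile.located
        gaps = intergenic_gaps(ref_ann)
        names = {g.upstream for g in gaps} | {g.downstream for g in gaps}
        assert "tRNA-Ile" not in names

    def test_kinds_inferred_from_names(self, ref_ann):
        assert len(ref_ann.by_kind(FeatureKind.PCG)) == 13
        assert len(ref_ann.by_kind(FeatureKind.RRNA)) == 2
        assert len(ref_ann.by_kind(FeatureKind.TRNA)) == 22

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            parse_feature_table("Gene/Region\tCoordinates\n")

    def test_malformed_coordinates_name_the_row(self):
        with pytest.raises(ValueError, match="COI"):
            parse_feature_table("Gene/Region\tCoordinates\tStrand\nCOI\t12..34x\tJ\n")

    def test_duplicate_names_rejected(self):
        text = "Gene/Region\tCoordinates\tStrand\nCOI\t1-9\tJ\nCOI\t10-20\tJ\n"
        with pytest.raises(ValueError, match="duplicate"):
            parse_feature_table(text)

    def test_serialize_parse_round_trip(self, ref_ann):
        text = serialize_feature_table(ref_ann)
        again = parse_feature_table(text, genome_length=ref_ann.genome_length)
        for f, g in zip(ref_ann.features, again.features):
            assert (f.name, f.start, f.end, f.strand) == (g.name, g.start, g.end, g.strand)
            if f.located:
                assert feature_length(f, ref_ann) == feature_length(g, again)


class TestFeatureLength:
    @pytest.mark.parametrize(
        "name,expected", [("AT-rich region", 772), ("ND5", 1719), ("COI", 1540)]
    )
    def test_published_sizes(self, ref_ann, name, expected):
        assert feature_length(ref_ann.feature(name), ref_ann) == expected

    def test_printed_sizes_recomputed_from_coordinates(self, ref_ann):
        """Sizes are recomputed from coordinates, never read off the table;
        the published table is internally inconsistent for tRNA-Asp
        (2378-2448 spans 71 bp, printed 66) and tRNA-Tyr (15442-15497
        spans 56 bp, printed 64)."""
        mismatches = {
            f.name
            for f in ref_ann.located_features
            if f.printed_size is not None
            and feature_length(f, ref_ann) != f.printed_size
        }
        assert mismatches == {"tRNA-Asp", "tRNA-Tyr"}
        assert feature_length(ref_ann.feature("tRNA-Asp"), ref_ann) == 71

    def test_whole_genome_feature(self):
        f = GeneFeature("all", FeatureKind.CONTROL, 1, 50, None)
        assert feature_length(f, _toy_ann([f], 50)) == 50

    def test_wrapping_feature(self):
        f = GeneFeature("wrap", FeatureKind.CONTROL, 9, 2, None)
        assert feature_length(f, _toy_ann([f], 10)) == 4

    def test_unlocated_raises(self, ref_ann):
        with pytest.raises(ValueError):
            feature_length(ref_ann.feature("tRNA-Ile"), ref_ann)


class TestIntergenicGaps:
    def test_largest_gap_is_between_ser2_and_nd1(self, ref_ann):
        summary = gap_summary(intergenic_gaps(ref_ann))
        assert summary["largest_gap_bp"] == 70
        assert summary["largest_gap_between"] == ("tRNA-Ser2", "ND1")

    def test_adjacent_overlap_reported_negative(self, ref_ann):
        gaps = {(g.upstream, g.downstream): g.gap_bp for g in intergenic_gaps(ref_ann)}
        assert gaps[("tRNA-Lys", "tRNA-Asp")] == -1

    def test_abutting_features_gap_zero(self):
        a = GeneFeature("a", FeatureKind.PCG, 1, 10, "J", start_codon="ATG", stop_codon="TAA")
        b = GeneFeature("b", FeatureKind.PCG, 11, 20, "J", start_codon="ATG", stop_codon="TAA")
        gaps = intergenic_gaps(_toy_ann([a, b], 20))
        assert [(g.gap_bp, g.closing) for g in gaps] == [(0, False), (0, True)]

    def test_linear_mode_skips_closing_pair(self):
        a = GeneFeature("a", FeatureKind.PCG, 1, 10, "J")
        b = GeneFeature("b", FeatureKind.PCG, 15, 20, "J")
        assert len(intergenic_gaps(_toy_ann([a, b], 25, circular=False))) == 1

    def test_matches_occupancy_scan_oracle(self):
        """On non-overlapping toy annotations, each adjacent gap equals the
        number of unoccupied positions between the two features, and the
        total of positive gaps equals the total of unoccupied positions."""
        import random

        rng = random.Random(7)
        for _ in range(25):
            length = rng.randint(20, 100)
            pos, feats = 1, []
            while pos + 3 < length:
                fl = rng.randint(2, 8)
                if pos + fl - 1 > length:
                    break
                feats.append(
                    GeneFeature(f"g{len(feats)}", FeatureKind.TRNA, pos, pos + fl - 1, "J",
                                anticodon="AAA")
                )
                pos += fl + rng.randint(0, 6)
            if len(feats) < 2:
                continue
            ann = _toy_ann(feats, length)
            occupied = [False] * (length + 1)
            for f in feats:
                for i in range(f.start, f.end + 1):
                    occupied[i] = True
            gaps = intergenic_gaps(ann)
            for g in gaps:
                up = ann.feature(g.upstream)
                down = ann.feature(g.downstream)
                if g.closing:
                    free = sum(not occupied[i] for i in range(up.end + 1, length + 1))
                    free += sum(not occupied[i] for i in range(1, down.start))
                else:
                    free = sum(not occupied[i] for i in range(up.end + 1, down.start))
                assert g.gap_bp == free
            assert sum(g.gap_bp for g in gaps if g.gap_bp > 0) == occupied.count(False) - 1

    def test_length_conservation(self):
        """Feature lengths plus signed gaps tile the circular genome."""
        feats = [
            GeneFeature("a", FeatureKind.PCG, 3, 12, "J"),
            GeneFeature("b", FeatureKind.PCG, 12, 20, "N"),  # 1 bp overlap
            GeneFeature("c", FeatureKind.PCG, 25, 30, "J"),
        ]
        ann = _toy_ann(feats, 33)
        total = sum(feature_length(f, ann) for f in feats)
        total += sum(g.gap_bp for g in intergenic_gaps(ann))
        assert total == ann.genome_length


class TestSequenceExtraction:
    def test_j_strand_is_verbatim_slice(self):
        f = GeneFeature("x", FeatureKind.PCG, 1, 3, "J")
        assert extract_feature_sequence("ATGCC", f) == "ATG"

    def test_n_strand_is_reverse_complement(self):
        f = GeneFeature("x", FeatureKind.PCG, 1, 3, "N")
        assert extract_feature_sequence("ATGCC", f) == "CAT"

    def test_wrapping_feature_spans_origin(self):
        genome = "AACCGGTTAC"  # 10 bp toy
        f = GeneFeature("x", FeatureKind.CONTROL, 9, 2, None)
        # brute force: tail (positions 9-10) + head (1-2)
        assert extract_feature_sequence(genome, f) == genome[8:] + genome[:2] == "ACAA"

    def test_out_of_range_raises(self):
        f = GeneFeature("x", FeatureKind.PCG, 2, 9, "J")
        with pytest.raises(ValueError):
            extract_feature_sequence("ACGT", f)


class TestValidation:
    def test_declared_codons_matching_sequence_yield_no_findings(self):
        genome = "ATGAAATAA"
        f = GeneFeature("g", FeatureKind.PCG, 1, 9, "J", start_codon="ATG", stop_codon="TAA")
        findings = validate_annotation(_toy_ann([f], 9), genome)
        assert findings == []

    def test_incomplete_stop_reported_as_info(self, ref_ann):
        findings = validate_annotation(ref_ann)
        coi = [f for f in findings if f.feature == "COI" and "incomplete stop" in f.message]
        assert coi and coi[0].severity == "info"

    def test_start_codon_mismatch_detected(self):
        genome = "TTTAAATAA"
        f = GeneFeature("g", FeatureKind.PCG, 1, 9, "J", start_codon="ATG", stop_codon="TAA")
        findings = validate_annotation(_toy_ann([f], 9), genome)
        assert any(f.severity == "mismatch" and "start" in f.message for f in findings)

    def test_reference_pcg_declared_codons_are_canonical(self, ref_ann):
        findings = validate_annotation(ref_ann)
        assert not any(f.severity == "warning" for f in findings)


def test_gff3_export_maps_strands(ref_ann):
    gff = write_gff3(ref_ann, seqid="ON859837")
    lines = [l.split("\t") for l in gff.splitlines() if not l.startswith("#")]
    nd1 = next(l for l in lines if "ND1" in l[8] and "Name=ND1" in l[8])
    assert (nd1[3], nd1[4], nd1[6]) == ("10218", "11168", "-")
    coi = next(l for l in lines if "Name=COI" in l[8])
    assert coi[6] == "+"
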