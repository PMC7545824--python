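"""Coding-change parsing, protein consequences, and genomic projection.

The dual-route oracle: a genomic variant projected into CDS coordinates
and applied codon-wise must agree with brute-force translation of the
whole mutated gene.
"""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from tetramap.genome import extract_cds, transcription_order_positions
from tetramap.hgvs import (
    CodingChange,
    HGVSParseError,
    ReferenceMismatchError,
    UnsupportedHGVSError,
    apply_coding_change,
    format_hgvs_c,
    genomic_to_coding,
    parse_hgvs_c,
    to_mature,
)
from tetramap.variants import VariantCall

_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _cds_with_codon(codon: str, codon_index: int, n_codons: int) -> str:
    """A CDS of GCA filler with ``codon`` planted at 1-based codon_index."""
    codons = ["GCA"] * n_codons
    codons[codon_index - 1] = codon
    return "".join(codons)


class TestParse:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("c.479C>T", CodingChange(479, 479, "C", "T")),
            ("c.302C>A", CodingChange(302, 302, "C", "A")),
            ("c.2044_2045delCCinsTT", CodingChange(2044, 2045, "CC", "TT")),
        ],
    )
    def test_published_descriptors(self, text, expected):
        assert parse_hgvs_c(text) == expected

    def test_round_trips_through_format(self):
        for text in ("c.479C>T", "c.2044_2045delCCinsTT", "c.1A>G"):
            assert format_hgvs_c(parse_hgvs_c(text)) == text

    @pytest.mark.parametrize("text", ["c.479+2T>A", "c.-12G>A", "c.*5A>T"])
    def test_offset_and_utr_classes_unsupported(self, text):
        with pytest.raises(UnsupportedHGVSError):
            parse_hgvs_c(text)

    @pytest.mark.parametrize(
        "text", ["p.Pro160Leu", "c.10_12delCCinsTT", "479C>T", "c.C>T"]
    )
    def test_malformed_descriptors_rejected(self, text):
        with pytest.raises(HGVSParseError):
            parse_hgvs_c(text)

    @settings(derandomize=True, max_examples=200)
    @given(
        start=st.integers(1, 100_000),
        ref=st.text("ACGT", min_size=1, max_size=6),
        data=st.data(),
    )
    def test_parse_format_round_trip_property(self, start, ref, data):
        """parse and format are inverse on every supported descriptor."""
        alt = data.draw(
            st.text("ACGT", min_size=len(ref), max_size=len(ref)).filter(
                lambda a: a != ref
            )
        )
        change = CodingChange(start, start + len(ref) - 1, ref, alt)
        assert parse_hgvs_c(format_hgvs_c(change)) == change


class TestApply:
    @pytest.mark.parametrize(
        "text,codon_index,label",
        [
            ("c.2044_2045delCCinsTT", 682, "Pro682Phe"),
            ("c.479C>T", 160, "Pro160Leu"),
            ("c.302C>A", 101, "Pro101His"),
        ],
    )
    def test_published_proline_changes(self, text, codon_index, label):
        change = parse_hgvs_c(text)
        cds = _cds_with_codon("CCT", codon_index, codon_index + 3)
        pc = apply_coding_change(cds, change)
        assert pc.position == codon_index
        assert pc.label == label
        assert pc.consequence == "missense"

    def test_synonymous_and_nonsense_classified(self):
        cds = _cds_with_codon("CCT", 4, 8)
        syn = apply_coding_change(cds, parse_hgvs_c("c.12T>C"))  # CCT -> CCC
        assert syn.consequence == "synonymous"
        cds2 = _cds_with_codon("TAC", 4, 8)
        non = apply_coding_change(cds2, parse_hgvs_c("c.12C>A"))  # TAC -> TAA
        assert non.consequence == "nonsense"

    def test_reference_mismatch_signals_wrong_transcript(self):
        cds = _cds_with_codon("CCT", 4, 8)
        with pytest.raises(ReferenceMismatchError):
            apply_coding_change(cds, parse_hgvs_c("c.12A>G"))

    def test_cds_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            apply_coding_change("GCAA", parse_hgvs_c("c.1G>T"))


class TestToMature:
    def test_transit_peptide_shift(self):
        """Precursor Pro160Leu is Pro129Leu after a 31-residue transit
        peptide is cleaved."""
        pc = apply_coding_change(
            _cds_with_codon("CCT", 160, 163), parse_hgvs_c("c.479C>T")
        )
        mature = to_mature(pc, 31)
        assert mature.mature_position == 129
        assert mature.mature_label == "Pro129Leu"

    def test_zero_transit_is_identity(self):
        pc = apply_coding_change(
            _cds_with_codon("CCT", 4, 8), parse_hgvs_c("c.11C>T")
        )
        assert to_mature(pc, 0).mature_position == pc.position

    def test_change_inside_transit_peptide_rejected(self):
        pc = apply_coding_change(
            _cds_with_codon("CCT", 20, 40), parse_hgvs_c("c.59C>T")
        )
        with pytest.raises(ValueError):
            to_mature(pc, 31)


class TestGenomicToCoding:
    def _gene(self, small_model, strand):
        for g in small_model.genes:
            if g.strand == strand:
                return g
        raise AssertionError

    def test_minus_strand_alleles_reverse_complemented(self, small_model,
                                                       small_reference):
        gene = self._gene(small_model, "-")
        positions = transcription_order_positions(gene)
        cds_pos = 10
        genomic_pos = positions[cds_pos - 1]
        ref_base = small_reference[gene.chromosome][genomic_pos - 1]
        alt_base = "ACGT".replace(ref_base, "")[0]
        v = VariantCall(gene.chromosome, genomic_pos, ref_base, alt_base, 100.0)
        change = genomic_to_coding(v, gene, small_reference)
        assert change.cds_start == cds_pos
        assert change.ref_nt == _COMPL[ref_base]
        assert change.alt_nt == _COMPL[alt_base]

    def test_plus_strand_alleles_pass_through(self, small_model,
                                              small_reference):
        gene = self._gene(small_model, "+")
        genomic_pos = gene.cds_intervals[0][0] + 5
        ref_base = small_reference[gene.chromosome][genomic_pos - 1]
        alt_base = "ACGT".replace(ref_base, "")[0]
        v = VariantCall(gene.chromosome, genomic_pos, ref_base, alt_base, 100.0)
        change = genomic_to_coding(v, gene, small_reference)
        assert (change.ref_nt, change.alt_nt) == (ref_base, alt_base)
        assert change.cds_start == 6

    def test_intronic_position_has_no_coding_effect(self, small_model,
                                                    small_reference):
        gene = small_model.genes[0]
        pos = gene.cds_intervals[0][1] + 10
        ref_base = small_reference[gene.chromosome][pos - 1]
        v = VariantCall(gene.chromosome, pos, ref_base,
                        "ACGT".replace(ref_base, "")[0], 100.0)
        assert genomic_to_coding(v, gene, small_reference) is None

    def test_reference_mismatch_rejected(self, small_model, small_reference):
        gene = small_model.genes[0]
        pos = gene.cds_intervals[0][0]
        ref_base = small_reference[gene.chromosome][pos - 1]
        wrong = "ACGT".replace(ref_base, "")[0]
        other = "ACGT".replace(ref_base, "").replace(wrong, "")[0]
        v = VariantCall(gene.chromosome, pos, wrong, other, 100.0)
        with pytest.raises(ReferenceMismatchError):
            genomic_to_coding(v, gene, small_reference)

    def test_agrees_with_whole_protein_translation(self, small_model,
                                                   small_reference):
        """Route A (project + apply codon-wise) equals route B (mutate the
        chromosome, re-extract the CDS, translate everything, diff)."""
        rng = np.random.default_rng(42)
        genes = list(small_model.genes)
        for _ in range(300):
            gene = genes[rng.integers(len(genes))]
            positions = transcription_order_positions(gene)
            # draw a 1- or 2-nt substitution fully inside the CDS
            width = int(rng.integers(1, 3))
            cds_pos = int(rng.integers(1, gene.cds_length - width + 1))
            genomic = sorted(positions[cds_pos - 1 : cds_pos - 1 + width])
            if genomic[-1] - genomic[0] != width - 1:
                continue  # straddles an intron; projection refuses these
            chrom_seq = small_reference[gene.chromosome]
            ref = "".join(chrom_seq[p - 1] for p in
                          range(genomic[0], genomic[0] + width))
            alt = "".join(
                str(b) for b in rng.choice(list("ACGT"), size=width)
            )
            if alt == ref:
                continue
            v = VariantCall(gene.chromosome, genomic[0], ref, alt, 100.0)
            change = genomic_to_coding(v, gene, small_reference)
            cds = extract_cds(gene, small_reference)
            pc = apply_coding_change(cds, change)
            # independent route: splice the chromosome and re-translate
            mutated_chrom = (
                chrom_seq[: genomic[0] - 1] + alt + chrom_seq[genomic[0] - 1 + width :]
            )
            mutated_ref = dict(small_reference)
            mutated_ref[gene.chromosome] = mutated_chrom
            before = str(Seq(cds).translate())
            after = str(Seq(extract_cds(gene, mutated_ref)).translate())
            diffs = [i for i, (x, y) in enumerate(zip(before, after), start=1)
                     if x != y]
            if pc.consequence == "synonymous":
                assert before == after
            else:
                assert diffs
                assert diffs[0] >= pc.position
                assert diffs[-1] <= pc.position + len(pc.ref_aa) - 1
                assert before[pc.position - 1 : pc.position - 1 + len(pc.ref_aa)] \
                    == pc.ref_aa
                assert after[pc.position - 1 : pc.position - 1 + len(pc.alt_aa)] \
                    == pc.alt_aa
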