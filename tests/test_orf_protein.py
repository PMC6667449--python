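import numpy as np
import pytest
from Bio.Seq import Seq

from splicecat import orf_protein, synthetic
from splicecat.core_io import DomainAnnotation, GenomeSequence, GenomicInterval
from splicecat.orf_protein import (
    ArchitectureSignature,
    OrfRecord,
    architecture_signature,
    build_orf,
    classify_product,
    domain_content,
    longest_orf,
    map_orf_to_genome,
    spliced_sequence,
)

from conftest import make_transcript


class TestSplicedSequence:
    def test_plus_concatenation(self):
        genome = GenomeSequence({"chr1": "NNATGNNAAANN"})
        tx = make_transcript("t", [(2, 5), (7, 10)])
        spliced = spliced_sequence(genome, tx)
        assert spliced.mrna == "ATGAAA"
        assert spliced.genomic_positions == [2, 3, 4, 7, 8, 9]

    def test_minus_revcomp(self):
        genome = GenomeSequence({"chr1": "NNATGNNAAANN"})
        tx = make_transcript("t", [(2, 5), (7, 10)], strand="-")
        spliced = spliced_sequence(genome, tx)
        assert spliced.mrna == "TTTCAT"
        assert spliced.genomic_positions == [9, 8, 7, 4, 3, 2]

    def test_single_exon(self):
        genome = GenomeSequence({"chr1": "ACGTACGT"})
        tx = make_transcript("t", [(2, 6)])
        assert spliced_sequence(genome, tx).mrna == "GTAC"

    def test_out_of_bounds_error(self):
        genome = GenomeSequence({"chr1": "ACGT"})
        tx = make_transcript("t", [(2, 6)])
        with pytest.raises(IndexError):
            spliced_sequence(genome, tx)


class TestLongestOrf:
    def test_hand_translation(self):
        orf = longest_orf("ATGAAATGA", min_codons=1)
        assert orf.protein == "MK"
        assert orf.has_stop is True
        assert (orf.start, orf.end) == (0, 9)

    def test_no_atg(self):
        assert longest_orf("CCCCCCCCC", min_codons=1) is None

    def test_min_codons_gate(self):
        assert longest_orf("ATGAAATGA", min_codons=3) is None

    def test_tie_five_prime_most(self):
        # two ATGs, same protein length (no stops): 5'-most wins
        seq = "ATGAAACCCATGAAACCC"
        orf = longest_orf(seq, min_codons=1)
        assert orf.start == 0

    def test_incomplete_orf_kept(self):
        orf = longest_orf("ATGAAAAA", min_codons=1)
        assert orf.has_stop is False
        assert orf.protein == "MK"
        assert (orf.end - orf.start) % 3 == 0

    @staticmethod
    def _oracle(mrna):
        best = None
        for i in range(len(mrna) - 2):
            if mrna[i : i + 3] != "ATG":
                continue
            protein = []
            has_stop = False
            for j in range(i, len(mrna) - 2, 3):
                codon = mrna[j : j + 3]
                aa = str(Seq(codon).translate())
                if aa == "*":
                    has_stop = True
                    break
                protein.append(aa)
            candidate = ("".join(protein), i, has_stop)
            if best is None or len(candidate[0]) > len(best[0]):
                best = candidate
        return best

    def test_equals_bruteforce_on_1000_seeded_sequences(self):
        rng = np.random.default_rng(1234)
        bases = "ACGT"
        for _ in range(1000):
            n = int(rng.integers(3, 61))
            seq = "".join(bases[i] for i in rng.integers(0, 4, size=n))
            expected = self._oracle(seq)
            got = longest_orf(seq, min_codons=1)
            if expected is None or len(expected[0]) < 1:
                assert got is None
            else:
                assert got is not None
                assert (got.protein, got.start, got.has_stop) == expected


class TestMapOrfToGenome:
    def test_single_exon_single_interval(self):
        genome = GenomeSequence({"chr1": "NNATGAAATGANN"})
        tx = make_transcript("t", [(2, 11)])
        spliced, orf = build_orf(genome, tx, min_codons=1)
        assert orf.footprint == [GenomicInterval("chr1", 2, 11, "+")]

    def test_junction_split_lengths_sum(self):
        genome = GenomeSequence({"chr1": "NNATGAANNNNATGANN"})
        tx = make_transcript("t", [(2, 7), (11, 15)])
        spliced, orf = build_orf(genome, tx, min_codons=1)
        assert len(orf.footprint) == 2
        assert sum(len(i) for i in orf.footprint) == orf.end - orf.start

    def test_bijection_round_trip(self):
        genome = GenomeSequence({"chr1": "NNATGAANNNNATGANN"})
        tx = make_transcript("t", [(2, 7), (11, 15)])
        spliced, orf = build_orf(genome, tx, min_codons=1)
        footprint_positions = set()
        for ival in orf.footprint:
            footprint_positions |= set(range(ival.start, ival.end))
        mapped = set(spliced.genomic_positions[orf.start : orf.end])
        assert mapped == footprint_positions

    def test_out_of_bounds_orf(self):
        genome = GenomeSequence({"chr1": "ATGAAATGA"})
        tx = make_transcript("t", [(0, 9)])
        spliced = spliced_sequence(genome, tx)
        bad = OrfRecord(start=0, end=12, protein="MKX", has_stop=False, footprint=[])
        with pytest.raises(ValueError):
            map_orf_to_genome(spliced, bad)

    def test_footprint_reextraction_translates_identically(self, locus, planted_variants):
        # splice-map consistency on realistic multi-exon CDS
        for variant in planted_variants:
            tx = variant.to_transcript("s1", 1.0, locus.gene_id)
            spliced, orf = build_orf(locus.genome, tx)
            cds = "".join(
                locus.genome.fetch(i.chrom, i.start, i.end) for i in orf.footprint
            )
            protein = str(Seq(cds).translate()).rstrip("*")
            assert protein == orf.protein


def _domain(name, start, end, instance=1, strand="+"):
    return DomainAnnotation(
        gene_id="G",
        domain_name=name,
        instance_index=instance,
        intervals=[GenomicInterval("chr1", start, end, strand)],
    )


class TestDomainContent:
    domains = [
        _domain("SP", 0, 60),
        _domain("Ig", 100, 190),
        _domain("TM1", 300, 360),
        _domain("TM2", 400, 460),
    ]

    def test_full_coverage_vs_absent(self):
        footprint = [GenomicInterval("chr1", 0, 200, "+")]
        content = domain_content(footprint, self.domains)
        assert content.is_present("SP") and content.is_present("Ig")
        assert not content.is_present("TM1") and not content.is_present("TM2")
        assert content.tm_count == 0

    def test_partial_below_threshold_absent(self):
        gain = _domain("GAIN", 0, 100)
        footprint = [GenomicInterval("chr1", 0, 50, "+")]
        content = domain_content(footprint, [gain], presence_threshold=0.9)
        assert content.coverage("GAIN") == pytest.approx(0.5)
        assert not content.is_present("GAIN")

    def test_empty_footprint_all_absent(self):
        content = domain_content([], self.domains)
        assert content.present_keys == []

    def test_coverage_at_threshold_present(self):
        gain = _domain("GAIN", 0, 100)
        footprint = [GenomicInterval("chr1", 0, 90, "+")]
        assert domain_content(footprint, [gain]).is_present("GAIN")


class TestClassifyProduct:
    def _content(self, covered, domains):
        footprint = [GenomicInterval("chr1", s, e, "+") for s, e in covered]
        return domain_content(footprint, domains)

    domains = [
        _domain("SP", 0, 30),
        _domain("SEA", 40, 100),
        _domain("Ig", 110, 170),
        _domain("GAIN", 180, 300),
        _domain("GPS", 300, 330),
    ] + [_domain(f"TM{i}", 340 + 40 * (i - 1), 340 + 40 * i) for i in range(1, 8)]

    def test_soluble_ntf(self):
        cls = classify_product(self._content([(0, 300)], self.domains))
        assert cls.product_class == "SOLUBLE_NTF"
        assert cls.tm_count == 0

    def test_ctf_gps_and_tms_only(self):
        cls = classify_product(self._content([(300, 620)], self.domains))
        assert cls.product_class == "CTF"
        assert cls.has_gps and not cls.has_sp

    def test_anchored_ntf_tm1_only(self):
        cls = classify_product(self._content([(0, 380)], self.domains))
        assert cls.product_class == "ANCHORED_NTF"
        assert cls.tm_count == 1

    def test_full_receptor(self):
        cls = classify_product(self._content([(0, 620)], self.domains))
        assert cls.product_class == "FULL_RECEPTOR"
        assert cls.tm_count == 7

    def test_other_when_nothing_fits(self):
        cls = classify_product(self._content([], self.domains))
        assert cls.product_class == "OTHER"

    def test_planted_classes_recovered(self, locus, planted_variants):
        for variant in planted_variants:
            tx = variant.to_transcript("s1", 1.0, locus.gene_id)
            _, orf = build_orf(locus.genome, tx)
            content = domain_content(orf.footprint, locus.domains)
            assert classify_product(content).product_class == variant.product_class


class TestStrandSymmetry:
    def test_mirrored_locus_same_proteins(self, locus, planted_variants):
        length = locus.genome.length(locus.contig)
        mirrored_genome = synthetic.mirror_genome(locus.genome, locus.contig)
        for variant in planted_variants:
            tx = variant.to_transcript("s1", 1.0, locus.gene_id)
            _, orf_fwd = build_orf(locus.genome, tx)
            tx_rev = synthetic.mirror_transcript(tx, length)
            _, orf_rev = build_orf(mirrored_genome, tx_rev)
            assert orf_rev.protein == orf_fwd.protein
            mirrored_domains = [
                synthetic.mirror_domain(d, length) for d in locus.domains
            ]
            cls_fwd = classify_product(domain_content(orf_fwd.footprint, locus.domains))
            cls_rev = classify_product(domain_content(orf_rev.footprint, mirrored_domains))
            assert cls_rev.product_class == cls_fwd.product_class


class TestVariabilityFlags:
    def _results(self, locus, variants):
        orfs, contents, classifications = {}, {}, {}
        for v in variants:
            tx = v.to_transcript("s1", 1.0, locus.gene_id)
            _, orf = build_orf(locus.genome, tx)
            orfs[v.name] = orf
            contents[v.name] = domain_content(orf.footprint, locus.domains)
            classifications[v.name] = classify_product(contents[v.name])
        return orfs, contents, classifications

    def test_single_full_variant_all_false(self, locus):
        variants = synthetic.simulate_variants(locus, {"FULL_RECEPTOR": 1.0}, 1)
        orfs, contents, classifications = self._results(locus, variants)
        flags = orf_protein.gene_variability_flags(
            [variants[0].name], classifications, contents, orfs, locus.domains
        )
        assert flags.as_tuple() == (False,) * 6

    def test_icl3_insertion_sets_tm7_flag(self, locus):
        variants = synthetic.simulate_variants(
            locus, {"FULL_RECEPTOR": 1.0}, 1, include_icl3_insertion=True
        )
        orfs, contents, classifications = self._results(locus, variants)
        flags = orf_protein.gene_variability_flags(
            [v.name for v in variants], classifications, contents, orfs, locus.domains
        )
        assert flags.tm7_variability is True
        assert flags.cterm_variability is False

    def test_alt_cterm_sets_cterm_flag(self, locus):
        variants = synthetic.simulate_variants(
            locus, {"FULL_RECEPTOR": 1.0}, 1, include_alt_cterm=True
        )
        orfs, contents, classifications = self._results(locus, variants)
        flags = orf_protein.gene_variability_flags(
            [v.name for v in variants], classifications, contents, orfs, locus.domains
        )
        assert flags.cterm_variability is True
        assert flags.tm7_variability is False

    def test_ig_skip_sets_ntf_domain_flag(self, locus):
        variants = synthetic.simulate_variants(
            locus, {"FULL_RECEPTOR": 1.0}, 1, include_ig2_skip=True
        )
        orfs, contents, classifications = self._results(locus, variants)
        flags = orf_protein.gene_variability_flags(
            [v.name for v in variants], classifications, contents, orfs, locus.domains
        )
        assert flags.ntf_domain_variability is True

    def test_class_flags(self, locus):
        mix = {"FULL_RECEPTOR": 0.25, "SOLUBLE_NTF": 0.25,
               "ANCHORED_NTF": 0.25, "CTF": 0.25}
        variants = synthetic.simulate_variants(locus, mix, 4)
        orfs, contents, classifications = self._results(locus, variants)
        flags = orf_protein.gene_variability_flags(
            [v.name for v in variants], classifications, contents, orfs, locus.domains
        )
        assert flags.soluble_ntf and flags.anchored_ntf and flags.ctf


class TestArchitectureSignature:
    def _region(self, locus):
        gps = next(d for d in locus.domains if d.domain_name == "GPS")
        tm7 = next(d for d in locus.domains if d.domain_name == "TM7")
        return (gps.intervals[0].start, tm7.intervals[-1].end)

    def test_adgrf_single_exon_region_empty(self, adgrf_locus):
        variants = synthetic.simulate_variants(adgrf_locus, {"FULL_RECEPTOR": 1.0}, 1)
        tx = variants[0].to_transcript("s1", 1.0, adgrf_locus.gene_id)
        _, orf = build_orf(adgrf_locus.genome, tx)
        sig = architecture_signature(orf, self._region(adgrf_locus))
        assert sig.introns == ()

    def test_multi_exon_region_not_empty_and_self_equal(self, locus):
        variants = synthetic.simulate_variants(locus, {"FULL_RECEPTOR": 1.0}, 1)
        tx = variants[0].to_transcript("s1", 1.0, locus.gene_id)
        _, orf = build_orf(locus.genome, tx)
        region = self._region(locus)
        sig_a = architecture_signature(orf, region)
        sig_b = architecture_signature(orf, region)
        assert sig_a == sig_b
        # GPS..TM7 spans codons 165..320 with splits every 20 codons inside
        assert sig_a.introns == tuple(
            (offset, 0) for offset in (15, 35, 55, 75, 95, 115, 135)
        )

    def test_phase_computation(self):
        # hand-built: CDS split mid-codon -> phase 1 intron
        genome = GenomeSequence({"chr1": "ATGAAAG" + "N" * 5 + "AAAAATAA" + "N" * 3})
        tx = make_transcript("t", [(0, 7), (12, 20)])
        _, orf = build_orf(genome, tx, min_codons=1)
        sig = architecture_signature(orf, (0, 20), region_name="cds")
        assert sig.introns == ((2, 1),)  # after 7 coding bases: codon 2, phase 1

    def test_region_not_covered_error(self, locus):
        variants = synthetic.simulate_variants(locus, {"CTF": 1.0}, 1)
        tx = variants[0].to_transcript("s1", 1.0, locus.gene_id)
        _, orf = build_orf(locus.genome, tx)
        sp = next(d for d in locus.domains if d.domain_name == "SP")
        with pytest.raises(ValueError, match="not covered"):
            architecture_signature(orf, (sp.intervals[0].start, sp.intervals[0].end))
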