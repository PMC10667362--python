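import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import (
    flank_homology,
    leftmost_equivalent_deletion,
    leftmost_equivalent_insertion,
    reverse_complement,
    run_length_at,
    tandem_copies_at,
)

from nerdcall.catalog import (
    NormalizedIndel,
    ReferenceGenome,
    assign_channel,
    build_catalog,
    classify_variant,
    homopolymer_length,
    microhomology_length,
    normalize_indel,
    repeat_unit_count,
)
from nerdcall.channels import ID83_CHANNELS, ChannelId
from nerdcall.errors import DataError, UnclassifiableIndelError
from nerdcall.simulate import SimulationConfig, generate_reference, realize_variant
from nerdcall.variants import VariantRecord


def rec(chrom, pos, ref, alt):
    return VariantRecord(sample_id="S", chrom=chrom, pos=pos, ref=ref, alt=alt)


def genome_of(**contigs):
    return ReferenceGenome(contigs)


class TestNormalizeIndel:
    def test_simple_deletion_strips_anchor(self):
        g = genome_of(c="GGGGATTG")
        n = normalize_indel(rec("c", 5, "AT", "A"), g)
        assert (n.start, n.seq, n.kind) == (5, "T", "deletion")

    def test_deletion_already_left_aligned_in_run(self):
        g = genome_of(c="CCCGAAAT")
        n = normalize_indel(rec("c", 4, "GA", "G"), g)
        assert (n.start, n.seq, n.kind) == (4, "A", "deletion")

    def test_insertion_after_anchor(self):
        g = genome_of(c="GCTGG")
        n = normalize_indel(rec("c", 3, "T", "TCA"), g)
        assert (n.start, n.seq, n.kind) == (3, "CA", "insertion")

    def test_right_shifted_representation_is_left_aligned(self):
        # CAG tract: deleting the third CAG must normalize to the first
        g = genome_of(c="TT" + "CAG" * 3 + "TT")
        n = normalize_indel(rec("c", 8, "GCAG", "G"), g)
        assert (n.start, n.seq) == (2, "CAG")

    def test_ref_mismatch_is_data_error(self):
        g = genome_of(c="GGGGATTG")
        with pytest.raises(DataError):
            normalize_indel(rec("c", 5, "AC", "A"), g)

    def test_complex_substitution_unclassifiable(self):
        g = genome_of(c="GGGGATTG")
        with pytest.raises(UnclassifiableIndelError):
            normalize_indel(rec("c", 5, "ATT", "AGC"), g)

    def test_unknown_contig_is_data_error(self):
        g = genome_of(c="GGGGATTG")
        with pytest.raises(DataError):
            normalize_indel(rec("missing", 2, "GA", "G"), g)

    @given(st.data())
    def test_left_alignment_matches_brute_force(self, data):
        """Normalization lands on the brute-force minimal equivalent start."""
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        # make repeats likely
        unit = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(1, 4))))
        ins_at = int(rng.integers(20, 80))
        seq = seq[:ins_at] + unit * int(rng.integers(2, 5)) + seq[ins_at:]
        g = genome_of(c=seq)
        size = int(rng.integers(1, 5))
        start = int(rng.integers(10, len(seq) - 20))
        if data.draw(st.booleans()):
            n = normalize_indel(
                rec("c", start, seq[start - 1 : start - 1 + 1 + size], seq[start - 1]), g
            )
            assert n.start == leftmost_equivalent_deletion(seq, start, size)
        else:
            ins = seq[start : start + size]  # guaranteed ACGT
            n = normalize_indel(rec("c", start, seq[start - 1], seq[start - 1] + ins), g)
            exp_start, exp_seq = leftmost_equivalent_insertion(seq, start, ins)
            assert (n.start, n.seq) == (exp_start, exp_seq)


class TestContextCounts:
    def test_deleting_one_base_of_homopolymer_counts_whole_run(self):
        g = genome_of(c="GGTTTTGG")
        n = normalize_indel(rec("c", 2, "GT", "G"), g)
        assert homopolymer_length(n, g) == 4 == run_length_at("GGTTTTGG", 2)

    def test_insertion_with_no_identical_neighbor_has_run_zero(self):
        g = genome_of(c="AGGA")
        n = NormalizedIndel("c", 1, "C", "insertion")
        assert homopolymer_length(n, g) == 0

    def test_insertion_adjacent_to_run_counts_existing_bases(self):
        g = genome_of(c="GATTC")
        n = NormalizedIndel("c", 2, "T", "insertion")
        assert homopolymer_length(n, g) == 2 == run_length_at("GATTC", 2)

    def test_deleting_one_repeat_copy_counts_all_copies(self):
        seq = "TTACAGCAGCAGTT"
        g = genome_of(c=seq)
        n = normalize_indel(rec("c", 3, "ACAG", "A"), g)
        assert (n.start, n.seq) == (3, "CAG")
        assert repeat_unit_count(n, g) == 3 == tandem_copies_at(seq, 3, "CAG")

    def test_insertion_with_no_adjacent_copy_counts_zero(self):
        g = genome_of(c="GGCCGG")
        n = NormalizedIndel("c", 2, "AT", "insertion")
        assert repeat_unit_count(n, g) == 0

    def test_two_copy_dinucleotide_deletion(self):
        seq = "GGATATGG"
        g = genome_of(c=seq)
        n = normalize_indel(rec("c", 2, "GAT", "G"), g)
        assert repeat_unit_count(n, g) == 2 == tandem_copies_at(seq, 2, "AT")

    def test_right_flank_microhomology(self):
        #          0123456789
        seq = "GG" + "TAGC" + "TATT" + "GG"  # deleted TAGC, flank starts TA
        g = genome_of(c=seq)
        n = NormalizedIndel("c", 2, "TAGC", "deletion")
        assert microhomology_length(n, g) == 2 == flank_homology(seq, 2, "TAGC")

    def test_no_flank_homology(self):
        seq = "GG" + "ACGT" + "GGGG"
        g = genome_of(c=seq)
        n = NormalizedIndel("c", 2, "ACGT", "deletion")
        assert microhomology_length(n, g) == 0

    def test_partial_prefix_match_stops_at_mismatch(self):
        seq = "GG" + "AAC" + "AAT" + "GG"  # deleted AAC followed by AA then T
        g = genome_of(c=seq)
        n = NormalizedIndel("c", 2, "AAC", "deletion")
        assert microhomology_length(n, g) == 2 == flank_homology(seq, 2, "AAC")


class TestAssignChannel:
    def test_long_deletion_with_microhomology_is_id8_dominant_class(self):
        deleted = "TACCGAG"
        seq = "GT" + deleted + "TAG" + "GG"  # flank shares exactly "TA"
        g = genome_of(c=seq)
        n = NormalizedIndel("c", 2, deleted, "deletion")
        chan = assign_channel(n, g)
        assert chan == ChannelId("Del", "5+", "microhomology", "2")
        assert chan.label == "5:Del:M:2"

    def test_one_base_deletion_in_long_a_run_uses_pyrimidine_strand(self):
        g = genome_of(c="GG" + "A" * 6 + "GG")
        n = normalize_indel(rec("c", 2, "GA", "G"), g)
        chan = assign_channel(n, g)
        assert chan == ChannelId("Del", "1", "homopolymer_T", "6+")

    def test_single_copy_deletion_without_homology_gets_repeat_bin_one(self):
        g = genome_of(c="GG" + "ACT" + "GGA")
        n = NormalizedIndel("c", 2, "ACT", "deletion")
        assert assign_channel(n, g) == ChannelId("Del", "3", "repeat", "1")

    def test_insertion_channels(self):
        g = genome_of(c="GGATATCC")
        # inserting AT before the existing two copies
        n = NormalizedIndel("c", 2, "AT", "insertion")
        assert assign_channel(n, g) == ChannelId("Ins", "2", "repeat", "2")

    @pytest.mark.parametrize("chan", ID83_CHANNELS, ids=lambda c: c.label)
    def test_realized_channel_roundtrips(self, chan, engineered, rng):
        """realize -> normalize -> classify recovers every channel."""
        genome, registry = engineered
        for _ in range(5):
            v = realize_variant(chan, genome, rng, registry)
            assert classify_variant(v, genome) == chan

    def test_strand_symmetry(self, engineered, rng):
        """Classification is invariant under reverse-complementing everything."""
        genome, registry = engineered
        for chan in rng.choice(len(ID83_CHANNELS), size=25, replace=False):
            chan = ID83_CHANNELS[int(chan)]
            v = realize_variant(chan, genome, rng, registry)
            n = normalize_indel(v, genome)
            contig = genome.seq(v.chrom, 0, genome.length(v.chrom))
            rc = reverse_complement(contig)
            size = len(n.seq)
            if n.kind == "deletion":
                rc_start = len(contig) - (n.start + size)
                rc_n = NormalizedIndel("rc", rc_start, reverse_complement(n.seq), "deletion")
                rc_rec = VariantRecord(
                    sample_id="S",
                    chrom="rc",
                    pos=rc_start,  # anchor base at rc_start-1 (0-based)
                    ref=rc[rc_start - 1 : rc_start + size],
                    alt=rc[rc_start - 1],
                )
            else:
                rc_start = len(contig) - n.start
                rc_rec = VariantRecord(
                    sample_id="S",
                    chrom="rc",
                    pos=rc_start,
                    ref=rc[rc_start - 1],
                    alt=rc[rc_start - 1] + reverse_complement(n.seq),
                )
            g2 = genome_of(rc=rc)
            assert classify_variant(rc_rec, g2) == chan


class TestBuildCatalog:
    def test_empty_sample_yields_zero_vector(self):
        g = genome_of(c="GGGGATTG")
        cat = build_catalog({"S1": []}, g)
        assert cat.shape == (1, 83)
        assert cat.loc["S1"].sum() == 0

    def test_snvs_ignored_and_conservation_holds(self, engineered, rng):
        genome, registry = engineered
        chans = [ID83_CHANNELS[int(i)] for i in rng.integers(0, 83, 30)]
        recs = [realize_variant(c, genome, rng, registry) for c in chans]
        ref_base = genome.base(genome.contigs[0], 24)
        snv = VariantRecord(
            sample_id="S", chrom=genome.contigs[0], pos=25,
            ref=ref_base, alt="A" if ref_base != "A" else "C",
        )
        cat = build_catalog({"S": recs + [snv]}, genome)
        assert cat.loc["S"].sum() == 30

    def test_order_independence(self, engineered, rng):
        genome, registry = engineered
        chans = [ID83_CHANNELS[int(i)] for i in rng.integers(0, 83, 20)]
        recs = [realize_variant(c, genome, rng, registry) for c in chans]
        a = build_catalog({"S": recs}, genome)
        b = build_catalog({"S": recs[::-1]}, genome)
        assert (a.values == b.values).all()

    def test_complex_indels_counted_not_classified(self):
        g = genome_of(c="GGGGATTGAA")
        from nerdcall.catalog import IndelCatalogEncoder

        enc = IndelCatalogEncoder(reference=g).fit()
        bad = rec("c", 5, "ATT", "AG")  # complex: deletion plus substitution
        good = rec("c", 5, "AT", "A")
        cat = enc.transform({"S": [bad, good]})
        assert cat.loc["S"].sum() == 1
        assert enc.unclassified_counts_["S"] == 1
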