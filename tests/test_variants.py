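import textwrap
from dataclasses import replace

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nerdcall.errors import ConfigurationError, DataError
from nerdcall.variants import (
    FilterThresholds,
    SampleMetadata,
    VariantFilter,
    VariantRecord,
    ercc_mutation_status,
    evaluate_filters,
    is_deleterious,
    pass_variant_filters,
    read_somatic_vcf,
    select_cohort,
)

VCF_TEXT = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##tumor_sample=TUMOR
    ##normal_sample=NORMAL
    ##contig=<ID=chr1,length=10000>
    ##FILTER=<ID=germline,Description="x">
    ##INFO=<ID=TLOD,Number=A,Type=Float,Description="x">
    ##INFO=<ID=NLOD,Number=1,Type=Float,Description="x">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">
    ##FORMAT=<ID=AF,Number=A,Type=Float,Description="x">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL
    chr1\t100\t.\tA\tT\t.\tPASS\tTLOD=31.5;NLOD=10.1\tGT:AD:AF:DP\t0/1:40,20:0.3333:60\t0/0:30,0:0.0:30
    chr1\t200\t.\tAT\tA\t.\tPASS\tTLOD=12.0;NLOD=8.0\tGT:AD:AF:DP\t0/1:50,10:0.1667:60\t0/0:25,0:0.0:25
    chr1\t300\t.\tG\tGCA\t.\tPASS\tTLOD=9.0;NLOD=6.0\tGT:AD:AF:DP\t0/1:44,11:0.2:55\t0/0:28,0:0.0:28
    chr1\t400\t.\tC\tA,G\t.\tPASS\tTLOD=7.5,5.5;NLOD=4.0\tGT:AD:AF:DP\t0/1:30,9,6:0.2,0.1333:45\t0/0:22,0,0:0.0,0.0:22
    chr1\t500\t.\tT\tC\t.\tgermline\tTLOD=8.0;NLOD=1.0\tGT:AD:AF:DP\t0/1:35,15:0.3:50\t0/0:18,2:0.1:20
    """
)


@pytest.fixture()
def small_vcf(tmp_path):
    p = tmp_path / "s1.vcf"
    p.write_text(VCF_TEXT)
    return p


def passing_record(**overrides):
    """A record sitting exactly on every inclusive filter boundary."""
    base = dict(
        sample_id="S1",
        chrom="chr1",
        pos=100,
        ref="A",
        alt="T",
        filter_status=frozenset({"PASS"}),
        tlod=6.0,
        nlod=3.0,
        normal_depth=15,
        tumor_depth=20,
        tumor_alt_count=5,
        normal_alt_count=0,
        tumor_af=0.05,
    )
    base.update(overrides)
    return VariantRecord(**base)


class TestReadSomaticVcf:
    def test_multiallelic_sites_split_per_alt(self, small_vcf):
        records = read_somatic_vcf(small_vcf, "S1")
        assert len(records) == 6  # 4 single-ALT lines + 2 ALTs at pos 400
        keys = [(v.pos, v.alt) for v in records]
        assert (400, "A") in keys and (400, "G") in keys

    def test_coordinates_alleles_and_stats_preserved(self, small_vcf):
        records = {(v.pos, v.alt): v for v in read_somatic_vcf(small_vcf, "S1")}
        v = records[(100, "T")]
        assert (v.chrom, v.ref) == ("chr1", "A")
        assert v.tlod == pytest.approx(31.5)
        assert v.nlod == pytest.approx(10.1)
        assert (v.tumor_depth, v.tumor_alt_count) == (60, 20)
        assert (v.normal_depth, v.normal_alt_count) == (30, 0)
        assert v.tumor_af == pytest.approx(0.3333, abs=1e-4)
        # per-ALT TLOD and AD apportioning at the multi-allelic site
        v2 = records[(400, "G")]
        assert v2.tlod == pytest.approx(5.5)
        assert v2.tumor_alt_count == 6
        assert v2.tumor_af == pytest.approx(0.1333, abs=1e-4)

    def test_filter_column_passes_through_verbatim(self, small_vcf):
        records = read_somatic_vcf(small_vcf, "S1")
        v = [r for r in records if r.pos == 500][0]
        assert v.filter_status == frozenset({"germline"})

    def test_unidentifiable_tumor_normal_is_configuration_error(self, tmp_path):
        text = VCF_TEXT.replace("##tumor_sample=TUMOR\n", "").replace(
            "##normal_sample=NORMAL\n", ""
        ).replace("TUMOR\tNORMAL", "SAMP_A\tSAMP_B")
        p = tmp_path / "odd.vcf"
        p.write_text(text)
        with pytest.raises(ConfigurationError):
            read_somatic_vcf(p, "S1")
        # explicit naming resolves it
        recs = read_somatic_vcf(p, "S1", tumor_sample="SAMP_A", normal_sample="SAMP_B")
        assert len(recs) == 6


class TestVariantFilters:
    def test_boundary_values_all_pass_inclusively(self):
        assert pass_variant_filters(passing_record(), FilterThresholds())

    @pytest.mark.parametrize(
        "overrides, reason",
        [
            (dict(filter_status=frozenset({"germline"})), "non-pass-filter"),
            (dict(tlod=5.999), "low-tlod"),
            (dict(nlod=2.999), "low-nlod"),
            (dict(normal_depth=14), "low-normal-depth"),
            (dict(tumor_depth=19, tumor_alt_count=5), "low-tumor-depth"),
            (dict(tumor_alt_count=4), "low-tumor-alt"),
            (dict(normal_alt_count=1, normal_depth=15), "normal-alt-present"),
            (dict(tumor_af=0.049), "low-tumor-af"),
        ],
    )
    def test_each_predicate_fails_individually(self, overrides, reason):
        decision = evaluate_filters(passing_record(**overrides))
        assert not decision
        assert decision.reason == reason

    def test_missing_field_yields_unevaluable_not_false(self):
        decision = evaluate_filters(passing_record(tlod=None))
        assert not decision
        assert decision.reason == "unevaluable:tlod"

    def test_filtering_is_idempotent(self):
        records = [passing_record(pos=p) for p in range(100, 110)] + [
            passing_record(pos=200, tlod=1.0)
        ]
        f = VariantFilter().fit()
        once = f.transform(records)
        assert f.transform(once) == once
        assert len(once) == 10

    @given(
        tlod=st.floats(0, 20),
        nlod=st.floats(0, 10),
        ndp=st.integers(0, 40),
        tdp=st.integers(0, 60),
        talt=st.integers(0, 30),
        nalt=st.integers(0, 5),
        af=st.floats(0, 1),
        bump=st.floats(0.001, 5),
    )
    def test_raising_any_threshold_is_monotone(
        self, tlod, nlod, ndp, tdp, talt, nalt, af, bump
    ):
        """A record passing stricter thresholds passes the defaults too."""
        v = passing_record(
            tlod=tlod,
            nlod=nlod,
            normal_depth=ndp,
            tumor_depth=max(tdp, talt),
            tumor_alt_count=talt,
            normal_alt_count=min(nalt, ndp),
            tumor_af=af,
        )
        base = FilterThresholds()
        for field in (
            "min_tlod",
            "min_nlod",
            "min_normal_depth",
            "min_tumor_depth",
            "min_tumor_alt",
            "min_tumor_af",
        ):
            cur = getattr(base, field)
            stricter = replace(
                base, **{field: cur + (int(bump) if isinstance(cur, int) else bump)}
            )
            if pass_variant_filters(v, stricter):
                assert pass_variant_filters(v, base)
        stricter = replace(base, max_normal_alt=0)
        relaxed = replace(base, max_normal_alt=2)
        if pass_variant_filters(v, stricter):
            assert pass_variant_filters(v, relaxed)


class TestSelectCohort:
    @staticmethod
    def meta(*rows):
        return [SampleMetadata(**r) for r in rows]

    def test_lowest_rank_sample_kept_per_patient(self):
        records = {
            "A1": [passing_record(sample_id="A1", pos=100 + i) for i in range(60)],
            "A2": [passing_record(sample_id="A2", pos=100 + i) for i in range(60)],
        }
        sel = select_cohort(
            records,
            self.meta(
                dict(sample_id="A1", patient_id="P1", preference_rank=2),
                dict(sample_id="A2", patient_id="P1", preference_rank=1),
            ),
        )
        assert set(sel.retained) == {"A2"}
        assert sel.exclusions["A1"] == "duplicate-patient"

    def test_sample_with_49_passing_variants_excluded(self):
        records = {
            "B1": [passing_record(sample_id="B1", pos=100 + i) for i in range(49)]
        }
        sel = select_cohort(records, self.meta(dict(sample_id="B1", patient_id="P1")))
        assert sel.retained == {}
        assert sel.exclusions["B1"] == "below-min-variants"
        assert sel.passing_counts["B1"] == 49

    def test_flagged_samples_excluded_with_reason(self):
        records = {
            s: [passing_record(sample_id=s, pos=100 + i) for i in range(60)]
            for s in ("W", "F", "M", "OK")
        }
        sel = select_cohort(
            records,
            self.meta(
                dict(sample_id="W", patient_id="P1", is_wga=True),
                dict(sample_id="F", patient_id="P2", is_ffpe=True),
                dict(sample_id="M", patient_id="P3", is_msi=True),
                dict(sample_id="OK", patient_id="P4"),
            ),
        )
        assert set(sel.retained) == {"OK"}
        assert sel.exclusions == {"W": "wga", "F": "ffpe", "M": "msi"}

    def test_duplicate_sample_id_rejected(self):
        with pytest.raises(DataError):
            select_cohort(
                {},
                self.meta(
                    dict(sample_id="X", patient_id="P1"),
                    dict(sample_id="X", patient_id="P2"),
                ),
            )

    def test_metadata_dataframe_accepted(self):
        records = {"C1": [passing_record(sample_id="C1", pos=100 + i) for i in range(60)]}
        meta = pd.DataFrame([{"sample_id": "C1", "patient_id": "P1"}])
        sel = select_cohort(records, meta)
        assert set(sel.retained) == {"C1"}


class TestDeleterious:
    def snv(self, consequence=None, label=None, gene=None, alt="T"):
        return passing_record(
            alt=alt, consequence=consequence, pathogenicity_label=label, gene=gene
        )

    def indel(self, label=None, gene=None):
        return passing_record(ref="AT", alt="A", pathogenicity_label=label, gene=gene)

    def test_exonic_snv_needs_pathogenic_label(self):
        assert is_deleterious(self.snv("exonic SNV", "Likely Pathogenic"))
        assert is_deleterious(self.snv("exonic SNV", "Pathogenic"))
        assert not is_deleterious(self.snv("exonic SNV", "Benign"))
        assert not is_deleterious(self.snv("exonic SNV", "Uncertain Significance"))

    def test_nonsense_snv_is_deleterious_regardless_of_label(self):
        assert is_deleterious(self.snv("nonsense SNV", "Uncertain Significance"))
        assert is_deleterious(self.snv("nonsense SNV", None))

    def test_indel_needs_pathogenic_label(self):
        assert is_deleterious(self.indel("Pathogenic"))
        assert not is_deleterious(self.indel("Benign"))

    def test_unannotated_record_is_not_deleterious(self):
        assert not is_deleterious(self.snv(None, None))

    def test_ercc_status_labels(self):
        e2 = self.snv("exonic SNV", "Pathogenic", gene="ERCC2")
        e6 = self.snv("nonsense SNV", None, gene="ERCC6")
        benign = self.snv("exonic SNV", "Benign", gene="ERCC2")
        other = self.snv("exonic SNV", "Pathogenic", gene="VHL")
        assert ercc_mutation_status([e2, other]) == "ERCC2"
        assert ercc_mutation_status([e2, e6]) == "multi"
        assert ercc_mutation_status([benign, other]) == "none"
        assert ercc_mutation_status([]) == "none"
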