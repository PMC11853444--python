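"""Variant table parsing, origin rules, and fixture integrity."""

import io

import pandas as pd
import pytest

from cfmrd.errors import DataError, SchemaError
from cfmrd.fixtures import GM_TOLERANCE, discrepancy_report
from cfmrd.mrd_tracking import geometric_mean_vaf
from cfmrd.variant_io import (
    PRE,
    VariantCall,
    annotate_origin,
    filter_somatic,
    normalize_vaf_token,
    parse_variant_table,
    read_snp_table,
    write_variant_table,
)

HEADER = "subject_id\tday\tcompartment\tgene\tvariant_key\tvaf\torigin\n"


def _parse(text):
    return parse_variant_table(io.StringIO(text))


class TestParsing:
    def test_typed_row(self):
        calls = _parse(HEADER + "002\tpre\tplasma\tTP53\tTP53\t63.57\tsomatic\n")
        assert calls == [VariantCall("002", PRE, "plasma", "TP53", "TP53", 63.57)]

    @pytest.mark.parametrize(
        "token,expected", [("0/73", 0.73), ("0/37", 0.37), ("63.57", 63.57), (5, 5.0)]
    )
    def test_slash_token_read_as_decimal_point(self, token, expected):
        assert normalize_vaf_token(token) == expected

    def test_empty_table_with_valid_header(self):
        assert _parse(HEADER) == []

    def test_missing_column_is_schema_error(self):
        with pytest.raises(SchemaError, match="vaf"):
            _parse("subject_id\tday\tcompartment\tgene\n001\tpre\tBM\tTP53\n")

    def test_bad_rows_reported_with_row_numbers(self):
        bad = HEADER + "001\tpre\tBM\tTP53\tTP53\t120.0\tsomatic\n001\t-3\tBM\tWT1\tWT1\t5\tsomatic\n"
        with pytest.raises(DataError) as exc:
            _parse(bad)
        assert "row 2" in str(exc.value) and "row 3" in str(exc.value)

    def test_optional_columns_defaulted(self):
        calls = _parse("subject_id\tday\tcompartment\tgene\tvaf\n001\t28\tplasma\tTET2\t1.5\n")
        assert calls[0].variant_key == "TET2" and calls[0].origin == "somatic"

    def test_duplicate_keys_rejected(self):
        row = "001\tpre\tBM\tTP53\tTP53\t5.0\tsomatic\n"
        with pytest.raises(DataError, match="duplicate"):
            _parse(HEADER + row + row)

    def test_round_trip_identity(self, paper):
        buf = io.StringIO()
        write_variant_table(paper.variants, buf)
        assert parse_variant_table(io.StringIO(buf.getvalue())) == paper.variants


class TestOriginRules:
    def _call(self, day, vaf, gene="HFE", comp="plasma", subject="X"):
        return VariantCall(subject, day, comp, gene, gene, vaf)

    def test_filter_somatic_drops_non_somatic_and_is_idempotent(self):
        calls = [
            VariantCall("X", PRE, "BM", "TP53", "TP53", 40.0, origin="somatic"),
            VariantCall("X", PRE, "BM", "HFE", "HFE", 49.0, origin="host_germline"),
        ]
        kept = filter_somatic(calls)
        assert [c.gene for c in kept] == ["TP53"]
        assert filter_somatic(kept) == kept
        assert len(filter_somatic(calls)) <= len(calls)

    def test_pre_vaf_in_band_in_both_compartments_is_host_germline(self):
        calls = [
            self._call(PRE, 49.8, comp="plasma"),
            self._call(PRE, 50.3, comp="BM"),
        ]
        out = annotate_origin(calls)
        assert {c.origin for c in out} == {"host_germline"}

    def test_pre_vaf_outside_band_stays_somatic(self):
        calls = [self._call(PRE, 7.5, gene="TET2"), self._call(28, 0.6, gene="TET2")]
        assert {c.origin for c in annotate_origin(calls)} == {"somatic"}

    def test_donor_transmitted_tracks_half_donor_fraction(self):
        # subject also has a pre sample (other variant), so the planted
        # variant is genuinely "absent pre, present at every post day"
        calls = [
            self._call(PRE, 30.0, gene="TP53"),
            self._call(28, 44.0, gene="ATM"),
            self._call(56, 46.5, gene="ATM"),
            self._call(84, 47.0, gene="ATM"),
        ]
        donor = {("X", 28): 90.0, ("X", 56): 94.0, ("X", 84): 95.0}
        out = annotate_origin(calls, donor_percent=donor)
        by_gene = {c.gene: c.origin for c in out}
        assert by_gene["ATM"] == "donor_transmitted"
        assert by_gene["TP53"] == "somatic"

    def test_no_pre_sample_skips_germline_rule(self, caplog):
        calls = [self._call(28, 50.0, gene="HFE")]
        with caplog.at_level("WARNING"):
            out = annotate_origin(calls)
        assert out[0].origin == "somatic"
        assert any("no pre-transplant sample" in r.message for r in caplog.records)


class TestPaperFixture:
    def test_twenty_subjects_six_relapses(self, paper):
        assert len(paper.subjects) == 20
        assert sum(s.relapse for s in paper.subjects) == 6

    def test_subject_008_has_no_variants(self, paper):
        assert not any(c.subject_id == "008" for c in paper.variants)

    def test_gm_matches_printed_aggregates_outside_known_discrepancies(self, paper):
        """Wherever the per-gene and aggregate tables agree on the count,
        the recomputed GM matches the printed GM to input-rounding tolerance
        — except in the frozen set of printed discrepancies."""
        rep = discrepancy_report(paper)
        flagged = {(r.subject_id, r.day, r.compartment) for r in rep.itertuples()}
        checked = 0
        for _, row in paper.mrd_table.iterrows():
            if not row["gene_level"] or row["status"] != "ok":
                continue
            cell = (row["subject_id"], row["day"], row["compartment"])
            if cell in flagged:
                continue
            vafs = [
                c.vaf
                for c in paper.variants
                if (c.subject_id, c.day, c.compartment) == cell
            ]
            assert len(vafs) == int(row["n_mutations"])
            if vafs:
                assert geometric_mean_vaf(vafs) == pytest.approx(
                    float(row["gm_vaf"]), abs=GM_TOLERANCE
                )
            checked += 1
        # 80 gene-resolved cells minus 3 ND minus the 13 flagged discrepancies
        assert checked == 64

    def test_known_discrepancies_are_frozen(self, paper):
        rep = discrepancy_report(paper)
        cells = {(r.subject_id, r.day, r.compartment, r.kind) for r in rep.itertuples()}
        assert cells == {
            ("002", 84, "plasma", "count"),
            ("007", 84, "BM", "gm"),
            ("012", PRE, "BM", "gm"),
            ("012", PRE, "plasma", "count"),
            ("013", PRE, "BM", "count"),
            ("013", PRE, "plasma", "count"),
            ("013", 84, "plasma", "count"),
            ("013", 84, "BM", "count"),
            ("015", 84, "plasma", "count"),
            ("016", PRE, "plasma", "gm"),
            ("018", PRE, "BM", "count"),
            ("018", PRE, "plasma", "count"),
            ("020", 84, "plasma", "count"),
        }

    def test_subject_001_missing_day84_sampling(self, paper):
        s = paper.subject("001")
        assert ("plasma", 84) not in s.timepoints_available
        assert ("BM", PRE) in s.timepoints_available


class TestSnpTable:
    def test_tsv_round_trip_types(self):
        text = (
            "subject_id\tday\tsnp_id\trecipient_gt\tdonor_gt\tobserved_vaf\tdepth\n"
            "S1\t28\trs1\t1/1\t0/0\t0.25\t5000\n"
            "S1\t28\trs2\t0/1\t0/1\t0.5\t4000\n"
        )
        obs = read_snp_table(io.StringIO(text))
        assert obs[0].g_recipient == 1.0 and obs[0].g_donor == 0.0
        assert obs[0].informative and not obs[1].informative

    def test_minimal_vcf_reader(self, tmp_path):
        vcf = tmp_path / "snps.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
            "##contig=<ID=chr1,length=248956422>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tRECIP\tDONOR\tPLASMA\n"
            "chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT:AD\t1/1:0,50\t0/0:60,0\t0/1:75,25\n"
            "chr1\t200\trs2\tC\tT\t.\tPASS\t.\tGT:AD\t0/1:30,30\t0/1:25,25\t0/1:50,50\n"
        )
        from cfmrd.variant_io import read_snp_vcf

        obs = read_snp_vcf(vcf, "RECIP", "DONOR", "PLASMA")
        assert len(obs) == 2
        assert obs[0].g_recipient == 1.0 and obs[0].g_donor == 0.0
        assert obs[0].vaf == pytest.approx(0.25) and obs[0].depth == 100
        assert obs[0].host_fraction == pytest.approx(0.25)
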