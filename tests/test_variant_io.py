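"""Variant reading, key normalization, and the somatic retention filter."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonetrace.variant_io import (
    MutationKey,
    MutationProfile,
    SomaticCall,
    VariantFormatError,
    canonical_chrom,
    filter_somatic_calls,
    normalize_key,
    normalize_mutation_key,
    read_profile,
    read_variants,
    write_profile,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=7>\n"
    '##INFO=<ID=POP_AF,Number=1,Type=Float,Description="population AF">\n'
    '##INFO=<ID=SYN,Number=0,Type=Flag,Description="synonymous">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="allelic depths">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
)


def write_vcf(tmp_path, body: str):
    path = tmp_path / "calls.vcf"
    path.write_text(VCF_HEADER + body)
    return path


class TestReadVariants:
    def test_ad_arithmetic(self, tmp_path):
        path = write_vcf(tmp_path, "7\t55259515\t.\tT\tG\t.\tPASS\t.\tAD\t60,40\n")
        (call,) = read_variants(path, format="vcf")
        assert call.key == MutationKey("7", 55259515, "T", "G")
        assert (call.alt_reads, call.depth) == (40, 100)
        assert call.vaf == pytest.approx(0.40)
        assert call.pop_freq == 0.0 and call.non_synonymous

    def test_multiallelic_split(self, tmp_path):
        path = write_vcf(tmp_path, "7\t100\t.\tA\tG,T\t.\tPASS\t.\tAD\t50,30,20\n")
        calls = read_variants(path, format="vcf")
        assert [c.key.alt for c in calls] == ["G", "T"]
        assert {c.key.ref for c in calls} == {"A"}
        assert [c.alt_reads for c in calls] == [30, 20]
        assert all(c.depth == 100 for c in calls)

    def test_empty_body(self, tmp_path):
        assert read_variants(write_vcf(tmp_path, ""), format="vcf") == []

    def test_info_annotations(self, tmp_path):
        path = write_vcf(
            tmp_path, "7\t100\t.\tA\tG\t.\tPASS\tPOP_AF=0.03;SYN\tAD\t50,30\n"
        )
        (call,) = read_variants(path, format="vcf")
        assert call.pop_freq == pytest.approx(0.03)
        assert not call.non_synonymous

    def test_unknown_format_tag(self, tmp_path):
        path = write_vcf(tmp_path, "")
        with pytest.raises(VariantFormatError, match="unknown format"):
            read_variants(path, format="bam")

    def test_malformed_tsv_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "sample_id\tchrom\tpos\tref\talt\talt_reads\tdepth\n"
            "S1\t7\t100\tA\tG\t10\t50\n"
            "S1\t7\tnot_a_pos\tA\tG\t10\t50\n"
        )
        with pytest.raises(VariantFormatError, match="line 3"):
            read_variants(path, format="maf_tsv")


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            # shared leading base trimmed, position advances
            ((100, "AT", "AG"), (101, "T", "G")),
            # SNV already minimal
            ((100, "C", "T"), (100, "C", "T")),
            # suffix then prefix, each side keeps >= 1 base
            ((100, "CAG", "CG"), (100, "CA", "C")),
            ((100, "ACCA", "ACA"), (100, "AC", "A")),
            ((100, "TG", "CG"), (100, "T", "C")),
        ],
    )
    def test_trimming(self, raw, expected):
        pos, ref, alt = raw
        got = normalize_mutation_key(MutationKey("1", pos, ref, alt))
        assert (got.pos, got.ref, got.alt) == expected

    @given(
        pos=st.integers(1, 10**6),
        ref=st.text("ACGT", min_size=1, max_size=6),
        alt=st.text("ACGT", min_size=1, max_size=6),
    )
    def test_idempotent(self, pos, ref, alt):
        if ref == alt:
            return
        once = normalize_mutation_key(MutationKey("1", pos, ref, alt))
        assert normalize_mutation_key(once) == once

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            MutationKey("1", 100, "AN", "A")

    def test_equivalent_representations_intersect(self):
        # an anchored and a trimmed spelling of the same deletion
        a = normalize_mutation_key(MutationKey("1", 100, "CAG", "CG"))
        b = normalize_mutation_key(MutationKey("1", 100, "CA", "C"))
        assert a == b


class TestChromCanonicalization:
    @pytest.mark.parametrize(
        "raw, expected",
        [("chr7", "7"), ("7", "7"), ("chrX", "X"), ("M", "MT"), ("chrM", "MT"), ("mt", "MT")],
    )
    def test_names(self, raw, expected):
        assert canonical_chrom(raw) == expected

    def test_chr_prefix_does_not_break_sharing(self):
        assert MutationKey("chr7", 100, "A", "G") == MutationKey("7", 100, "A", "G")


def call(alt_reads, vaf, pop_freq=0.0, blacklisted=False, i=0):
    depth = max(1, round(alt_reads / vaf)) if vaf > 0 else 100
    return SomaticCall(
        key=MutationKey("1", 1000 + i, "A", "G"),
        depth=depth,
        alt_reads=alt_reads,
        pop_freq=pop_freq,
        blacklisted=blacklisted,
    )


class TestFilter:
    @pytest.mark.parametrize(
        "c, retained",
        [
            (call(alt_reads=4, vaf=0.02), True),  # both boundaries inclusive
            (call(alt_reads=3, vaf=0.50), False),  # below read support
            (call(alt_reads=30, vaf=0.30, pop_freq=0.02), False),  # > 1% pop freq
            (call(alt_reads=30, vaf=0.30, pop_freq=0.01), True),  # exactly 1% kept
            (call(alt_reads=4, vaf=0.019), False),  # below VAF boundary
            (call(alt_reads=30, vaf=0.30, blacklisted=True), False),
        ],
    )
    def test_retention_predicate(self, c, retained):
        profile = filter_somatic_calls([c])
        assert (len(profile) == 1) is retained

    def test_blacklist_by_key(self):
        c = call(alt_reads=30, vaf=0.30)
        assert len(filter_somatic_calls([c], blacklist=[c.key])) == 0

    def test_duplicates_collapse_to_max_support(self):
        low = call(alt_reads=10, vaf=0.10)
        high = call(alt_reads=40, vaf=0.40)
        profile = filter_somatic_calls([low, high])
        assert len(profile) == 1
        assert profile.calls[0].alt_reads == 40

    def test_empty_input(self):
        assert len(filter_somatic_calls([])) == 0

    @given(
        calls=st.lists(
            st.tuples(
                st.integers(0, 50),  # alt_reads
                st.integers(50, 400),  # extra depth
                st.floats(0, 0.05),  # pop_freq
            ),
            max_size=30,
        ),
        bump=st.sampled_from(["min_alt_reads", "min_vaf", "max_pop_freq"]),
    )
    def test_threshold_monotonicity(self, calls, bump):
        """Raising any threshold never enlarges the retained set."""
        somatic = [
            SomaticCall(
                key=MutationKey("1", 1000 + i, "A", "G"),
                depth=alt + extra,
                alt_reads=alt,
                pop_freq=pf,
            )
            for i, (alt, extra, pf) in enumerate(calls)
        ]
        base = dict(min_alt_reads=4, min_vaf=0.02, max_pop_freq=0.01)
        stricter = dict(base)
        if bump == "min_alt_reads":
            stricter[bump] = 8
        elif bump == "min_vaf":
            stricter[bump] = 0.05
        else:
            stricter[bump] = 0.005
        loose = filter_somatic_calls(somatic, **base).keys()
        tight = filter_somatic_calls(somatic, **stricter).keys()
        assert tight <= loose


@st.composite
def profiles(draw):
    n = draw(st.integers(0, 12))
    calls = []
    for i in range(n):
        depth = draw(st.integers(10, 500))
        alt = draw(st.integers(4, depth))
        calls.append(
            SomaticCall(
                key=MutationKey(
                    draw(st.sampled_from(["1", "2", "X"])),
                    1000 + i,
                    "A",
                    draw(st.sampled_from(["C", "G", "T"])),
                    gene=draw(st.sampled_from([None, "EGFR", "TP53"])),
                ),
                depth=depth,
                alt_reads=alt,
                pop_freq=draw(st.floats(0, 0.01)),
                non_synonymous=draw(st.booleans()),
            )
        )
    return MutationProfile(sample_id="S1", calls=tuple(calls))


class TestRoundTrip:
    @given(profile=profiles())
    def test_write_read_identity(self, profile, tmp_path_factory):
        path = tmp_path_factory.mktemp("rt") / "profile.tsv"
        write_profile(profile, path)
        assert read_profile(path, sample_id="S1") == profile

    def test_empty_profile_header_only(self, tmp_path):
        path = write_profile(MutationProfile(sample_id="S1", calls=()), tmp_path / "p.tsv")
        assert len(path.read_text().strip().splitlines()) == 1

    def test_row_count(self, tmp_path):
        prof = filter_somatic_calls([call(i=1, alt_reads=40, vaf=0.4), call(i=2, alt_reads=40, vaf=0.4)])
        path = write_profile(prof, tmp_path / "p.tsv")
        assert len(path.read_text().strip().splitlines()) == 3


class TestSomaticCallInvariants:
    def test_alt_reads_exceed_depth(self):
        with pytest.raises(ValueError):
            SomaticCall(key=MutationKey("1", 1, "A", "G"), depth=10, alt_reads=11)

    def test_vaf_consistency(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SomaticCall(key=MutationKey("1", 1, "A", "G"), depth=100, alt_reads=40, vaf=0.2)

    def test_vaf_computed_when_absent(self):
        c = SomaticCall(key=MutationKey("1", 1, "A", "G"), depth=100, alt_reads=25)
        assert c.vaf == pytest.approx(0.25)
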