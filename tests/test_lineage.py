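"""The benign rule, the pair-classification cascade, and the full pipeline."""

import json

import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonetrace.clonality import PairSimilarity
from clonetrace.lineage import (
    LineageCall,
    PairEvidence,
    Thresholds,
    classify_pair,
    classify_sample,
    flag_transformation,
    run_pipeline,
)
from clonetrace.neoantigen import SharedNeoantigenSummary
from clonetrace.synthetic import write_patient_inputs
from clonetrace.variant_io import MutationKey, MutationProfile, SomaticCall

from conftest import make_profile


def similarity(pct, n_shared, nonhotspot=None, n_union=1000):
    n_union = max(n_union, n_shared)
    return PairSimilarity(
        sample_a="A",
        sample_b="B",
        n_shared=n_shared,
        n_union=n_union,
        similarity_pct=pct,
        n_shared_nonhotspot=n_shared if nonhotspot is None else nonhotspot,
    )


def neo(n_shared, n_a=10, n_b=10):
    n_a, n_b = max(n_a, n_shared), max(n_b, n_shared)
    return SharedNeoantigenSummary(
        sample_a="A",
        sample_b="B",
        n_shared=n_shared,
        n_a=n_a,
        n_b=n_b,
        pct_of_a=100.0 * n_shared / n_a if n_a else 0.0,
        pct_of_b=100.0 * n_shared / n_b if n_b else 0.0,
    )


def evidence(sim=None, neo_summary=None, **kw):
    return PairEvidence(sample_a="A", sample_b="B", similarity=sim, neo=neo_summary, **kw)


class TestClassifySample:
    def test_zero_calls_is_benign(self):
        call = classify_sample(make_profile("H", []))
        assert call is not None and call.label == "benign"
        assert call.rule_trace

    def test_single_call_passes_through(self):
        assert classify_sample(make_profile("A", [0])) is None


class TestClassifyPair:
    def test_high_similarity_with_shared_neoantigens_is_ipm(self):
        """A 75.1%-similar pair with 241 shared neoantigens is one lineage."""
        ev = evidence(similarity(75.1, 700), neo(241), expr_cocluster=True)
        call = classify_pair(ev)
        assert call.label == "IPM_same_lineage"
        assert any("R1" in line for line in call.rule_trace)
        assert any("241" in line for line in call.rule_trace)

    def test_moderate_similarity_with_nonhotspot_sharing_is_ipm(self):
        # progression lesions of one lineage: 12.9% similarity, many shared
        call = classify_pair(evidence(similarity(12.9, 90), neo(71)))
        assert call.label == "IPM_same_lineage"

    def test_nothing_shared_is_mplc(self):
        call = classify_pair(evidence(similarity(0.0, 0), neo(0)))
        assert call.label == "MPLC"
        assert any("R2" in line for line in call.rule_trace)

    def test_shared_driver_only_low_similarity_is_mplc(self):
        # e.g. two tumors both carrying EGFR L858R but 0.4% overall overlap
        ev = evidence(similarity(0.4, 1, nonhotspot=0), neo(0, 5, 5), shared_driver_only=True)
        call = classify_pair(ev)
        assert call.label == "MPLC"
        assert any("driver coincidence" in line for line in call.rule_trace)

    def test_driver_only_above_t_low_stays_indeterminate(self):
        ev = evidence(similarity(2.0, 2, nonhotspot=0), neo(1, 5, 5), shared_driver_only=True)
        assert classify_pair(ev).label == "indeterminate"

    def test_missing_similarity_is_indeterminate_naming_gap(self):
        call = classify_pair(evidence(None))
        assert call.label == "indeterminate"
        assert any("missing evidence: similarity" in line for line in call.rule_trace)

    def test_zero_shared_without_neo_evidence_is_indeterminate(self):
        call = classify_pair(evidence(similarity(0.0, 0), None))
        assert call.label == "indeterminate"
        assert any("missing evidence" in line for line in call.rule_trace)

    def test_trace_echoes_thresholds(self):
        t = Thresholds(t_ipm=7.5, t_low=0.5, min_shared_nonhotspot=4)
        call = classify_pair(evidence(similarity(50.0, 100), neo(10)), t)
        assert any("t_ipm=7.5" in line for line in call.rule_trace)
        assert any("min_shared_nonhotspot=4" in line for line in call.rule_trace)

    def test_neoantigen_sharing_alone_cannot_produce_ipm(self):
        # expression/neoantigen evidence corroborates but is never decisive
        ev = evidence(similarity(1.0, 2), neo(100), expr_cocluster=True)
        assert classify_pair(ev).label == "indeterminate"

    @given(
        pct=st.floats(0, 100),
        n_shared=st.integers(0, 500),
        neo_shared=st.integers(0, 100),
        driver_only=st.booleans(),
    )
    def test_cascade_totality(self, pct, n_shared, neo_shared, driver_only):
        """Every pair gets exactly one label and a non-empty trace."""
        ev = evidence(
            similarity(pct, n_shared),
            neo(neo_shared) if n_shared == 0 and neo_shared == 0 else neo(min(neo_shared, n_shared)),
            shared_driver_only=driver_only and n_shared > 0,
        )
        call = classify_pair(ev)
        assert call.label in {"MPLC", "IPM_same_lineage", "indeterminate"}
        assert call.rule_trace

    @given(
        pct=st.floats(0, 100),
        n_shared=st.integers(0, 500),
        t1=st.floats(0.1, 50),
        t2=st.floats(0.1, 50),
    )
    def test_raising_t_ipm_never_creates_ipm(self, pct, n_shared, t1, t2):
        lo, hi = sorted((t1, t2))
        ev = evidence(similarity(pct, n_shared), neo(0, 5, 5))
        call_lo = classify_pair(ev, Thresholds(t_ipm=lo))
        call_hi = classify_pair(ev, Thresholds(t_ipm=hi))
        if call_lo.label != "IPM_same_lineage":
            assert call_hi.label != "IPM_same_lineage"


def transformed_profile(genes=("EGFR", "TP53", "RB1"), histology="SCLC"):
    calls = tuple(
        SomaticCall(
            key=MutationKey("1", 1000 + i, "A", "G", gene=g),
            depth=100,
            alt_reads=30,
        )
        for i, g in enumerate(genes)
    )
    return MutationProfile(sample_id="E", calls=calls, histology=histology)


class TestFlagTransformation:
    def test_driver_triad_sclc_with_tki_flag(self):
        flag = flag_transformation(transformed_profile(), treatment_flags=("egfr_tki",))
        assert flag == "transformation_suspected"

    def test_no_tki_flag_no_annotation(self):
        assert flag_transformation(transformed_profile(), treatment_flags=()) is None

    def test_adenocarcinoma_histology_no_annotation(self):
        prof = transformed_profile(histology="adenocarcinoma")
        assert flag_transformation(prof, treatment_flags=("egfr_tki",)) is None

    def test_incomplete_driver_triad_no_annotation(self):
        prof = transformed_profile(genes=("EGFR", "TP53"))
        assert flag_transformation(prof, treatment_flags=("egfr_tki",)) is None

    def test_lcnec_histology_counts_as_neuroendocrine(self):
        prof = transformed_profile(histology="LCNEC")
        assert flag_transformation(prof, treatment_flags=("egfr_tki",)) is not None


@pytest.fixture(scope="module")
def pipeline_inputs(tmp_path_factory, lu1_like_patient):
    d = tmp_path_factory.mktemp("inputs")
    manifest = write_patient_inputs(lu1_like_patient, d)
    return d, manifest


def run(d, manifest, outdir, **kw):
    defaults = dict(
        contexts_path=d / "contexts.fasta",
        hla_path=d / "hla.txt",
        expression_path=d / "expression.fpkm.tsv",
        signatures_path=d / "signatures.gmt",
        config={"hotspots": _hotspot_specs()},
    )
    defaults.update(kw)
    return run_pipeline(manifest, outdir, **defaults)


def _hotspot_specs():
    from clonetrace.synthetic import DEFAULT_HOTSPOTS

    return [f"{k.chrom}:{k.pos}:{k.ref}>{k.alt}" for k, _ in DEFAULT_HOTSPOTS]


class TestRunPipeline:
    def test_truth_labels_recovered(self, pipeline_inputs, lu1_like_patient, tmp_path):
        d, manifest = pipeline_inputs
        report = run(d, manifest, tmp_path / "out")
        got = {tuple(c["subject"]): c["label"] for c in report["calls"]}
        assert got[("B1",)] == "benign"
        truth = lu1_like_patient.truth.pair_labels
        expected = {"clonal": "IPM_same_lineage", "independent": "MPLC"}
        for pair, t_label in truth.items():
            ab = tuple(sorted(pair))
            if "B1" in ab:
                continue
            assert got[ab] == expected[t_label]

    def test_report_is_deterministic(self, pipeline_inputs, tmp_path):
        d, manifest = pipeline_inputs
        run(d, manifest, tmp_path / "r1")
        run(d, manifest, tmp_path / "r2")
        assert (tmp_path / "r1" / "report.json").read_bytes() == (
            tmp_path / "r2" / "report.json"
        ).read_bytes()

    def test_outputs_written(self, pipeline_inputs, tmp_path):
        d, manifest = pipeline_inputs
        out = tmp_path / "out"
        run(d, manifest, out)
        for name in (
            "similarity.tsv",
            "neoantigens.tsv",
            "calls.tsv",
            "report.json",
            "microenvironment_scores.tsv",
            "pca_scores.tsv",
            "tree_SIM.nwk",
        ):
            assert (out / name).exists(), name

    def test_missing_expression_degrades_gracefully(self, pipeline_inputs, tmp_path):
        d, manifest = pipeline_inputs
        report = run(
            d, manifest, tmp_path / "out",
            expression_path=None, signatures_path=None,
        )
        labels = {tuple(c["subject"]): c["label"] for c in report["calls"]}
        assert labels[("T1", "T2")] == "IPM_same_lineage"
        assert not any(
            "expression" in line
            for c in report["calls"]
            for line in c["rule_trace"]
            if "co-clustered" in line
        )

    def test_rule_traces_embedded_in_report(self, pipeline_inputs, tmp_path):
        d, manifest = pipeline_inputs
        out = tmp_path / "out"
        run(d, manifest, out)
        report = json.loads((out / "report.json").read_text())
        for c in report["calls"]:
            assert c["rule_trace"]
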