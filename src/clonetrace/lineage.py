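"""Lineage calls: integrate genomic, neoantigen, and expression evidence.

Whole-exome evidence is primary: a pair of tumors with a substantial fraction
of shared somatic mutations (and enough shared non-hotspot mutations) is
called same-lineage (intrapulmonary metastasis, IPM); tumors sharing nothing
— neither mutations nor neoantigens — are independent primaries (MPLC); a
pair whose only overlap is a recurrent hotspot driver at negligible overall
similarity is also MPLC, because recurrent drivers co-occur by chance.
Expression co-clustering and neoantigen sharing corroborate but never alone
produce an IPM call. A sample with zero retained somatic mutations is called
benign and excluded from pairwise analysis. A separate annotation flags
possible histology transformation (e.g. adenocarcinoma to SCLC under EGFR-TKI
pressure with EGFR+TP53+RB1 mutations); it never overrides the pair rules.

Every call carries an ordered rule trace echoing the thresholds used, so the
decision is auditable and reproducible from the report alone.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import __version__
from .clonality import (
    BenignSampleError,
    PairSimilarity,
    build_tree,
    gene_similarity_score,
    mutation_matrix,
    write_similarity_tsv,
)
from .expression import (
    hier_cluster,
    microenvironment_scores,
    pca,
    preprocess,
    read_expression_tsv,
    read_gmt,
    scores_frame,
)
from .neoantigen import (
    HLAGenotype,
    NeoantigenReport,
    SharedNeoantigenSummary,
    call_neoantigens,
    mock_affinity,
    read_contexts_fasta,
    read_hla,
    shared_neoantigens,
    write_neoantigen_tsv,
)
from .variant_io import (
    MutationKey,
    MutationProfile,
    filter_somatic_calls,
    read_variants,
)

__all__ = [
    "Thresholds",
    "PairEvidence",
    "LineageCall",
    "classify_sample",
    "classify_pair",
    "flag_transformation",
    "run_pipeline",
]

LABELS = ("MPLC", "IPM_same_lineage", "benign", "indeterminate", "transformation_suspected")

NEUROENDOCRINE_HISTOLOGIES = ("sclc", "small cell", "lcnec", "large cell neuroendocrine", "neuroendocrine")
TRANSFORMATION_DRIVERS = ("EGFR", "TP53", "RB1")
TKI_FLAG = "egfr_tki"


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds of the pair-classification cascade.

    t_ipm : minimum similarity_pct for a same-lineage (IPM) call.
    t_low : similarity_pct below which a driver-only overlap is dismissed
        as coincidence.
    min_shared_nonhotspot : minimum shared non-hotspot mutations for IPM.
    """

    t_ipm: float = 5.0
    t_low: float = 1.0
    min_shared_nonhotspot: int = 3


@dataclass(frozen=True)
class PairEvidence:
    """Integrated evidence for one tumor pair."""

    sample_a: str
    sample_b: str
    similarity: PairSimilarity | None
    neo: SharedNeoantigenSummary | None = None
    expr_cocluster: bool | None = None
    expr_pc_distance: float | None = None
    shared_driver_only: bool = False
    histology_match: bool | None = None

    def __post_init__(self) -> None:
        for part, name in ((self.similarity, "similarity"), (self.neo, "neo")):
            if part is None:
                continue
            ids = {part.sample_a, part.sample_b}
            if ids != {self.sample_a, self.sample_b}:
                raise ValueError(f"{name} evidence carries sample ids {ids}, "
                                 f"expected {{{self.sample_a}, {self.sample_b}}}")


@dataclass(frozen=True)
class LineageCall:
    """One labeled subject (a pair or a sample) with its audit trail."""

    subject: tuple[str, ...]
    label: str
    rule_trace: tuple[str, ...]
    annotations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if not self.rule_trace:
            raise ValueError("rule_trace must be non-empty")


def classify_sample(profile: MutationProfile) -> LineageCall | None:
    """Benign rule: zero retained somatic calls => benign; else pass-through."""
    if len(profile) == 0:
        return LineageCall(
            subject=(profile.sample_id,),
            label="benign",
            rule_trace=("S1: 0 retained somatic calls -> benign",),
        )
    return None


def classify_pair(ev: PairEvidence, thresholds: Thresholds = Thresholds()) -> LineageCall:
    """Rule cascade over one pair's evidence; first matching rule wins.

    R1: similarity_pct >= t_ipm and shared non-hotspot mutations >=
        min_shared_nonhotspot -> IPM_same_lineage.
    R2: zero shared mutations and zero shared neoantigens -> MPLC.
    R3: overlap is hotspot-drivers-only at similarity_pct < t_low -> MPLC.
    R4: otherwise indeterminate, with corroborating evidence in the trace.

    Missing evidence needed by the first applicable rule yields an
    indeterminate call whose trace names the gap.
    """
    subject = (ev.sample_a, ev.sample_b)
    t = thresholds
    trace: list[str] = []

    if ev.similarity is None:
        return LineageCall(
            subject=subject,
            label="indeterminate",
            rule_trace=("missing evidence: similarity -> indeterminate",),
        )
    sim = ev.similarity
    if sim.similarity_pct >= t.t_ipm and sim.n_shared_nonhotspot >= t.min_shared_nonhotspot:
        trace.append(
            f"R1: similarity_pct={sim.similarity_pct:.2f} >= t_ipm={t.t_ipm} and "
            f"n_shared_nonhotspot={sim.n_shared_nonhotspot} >= "
            f"min_shared_nonhotspot={t.min_shared_nonhotspot} -> IPM_same_lineage"
        )
        _append_corroboration(trace, ev)
        return LineageCall(subject=subject, label="IPM_same_lineage", rule_trace=tuple(trace))
    trace.append(
        f"R1 not fired: similarity_pct={sim.similarity_pct:.2f} (t_ipm={t.t_ipm}), "
        f"n_shared_nonhotspot={sim.n_shared_nonhotspot} "
        f"(min_shared_nonhotspot={t.min_shared_nonhotspot})"
    )
    if sim.n_shared == 0:
        if ev.neo is None:
            trace.append("missing evidence: shared-neoantigen summary -> indeterminate")
            return LineageCall(subject=subject, label="indeterminate", rule_trace=tuple(trace))
        if ev.neo.n_shared == 0:
            trace.append("R2: n_shared=0 and shared neoantigens=0 -> MPLC")
            return LineageCall(subject=subject, label="MPLC", rule_trace=tuple(trace))
    if ev.shared_driver_only and sim.similarity_pct < t.t_low:
        trace.append(
            f"R3: shared mutations are hotspot drivers only and "
            f"similarity_pct={sim.similarity_pct:.2f} < t_low={t.t_low} "
            "-> MPLC (driver coincidence)"
        )
        return LineageCall(subject=subject, label="MPLC", rule_trace=tuple(trace))
    trace.append("R4: no decisive rule fired -> indeterminate")
    _append_corroboration(trace, ev)
    return LineageCall(subject=subject, label="indeterminate", rule_trace=tuple(trace))


def _append_corroboration(trace: list[str], ev: PairEvidence) -> None:
    if ev.neo is not None:
        trace.append(
            f"corroboration: shared neoantigens n={ev.neo.n_shared} "
            f"({ev.neo.pct_of_a:.1f}% of {ev.neo.sample_a}, "
            f"{ev.neo.pct_of_b:.1f}% of {ev.neo.sample_b})"
        )
    if ev.expr_cocluster is not None:
        state = "co-clustered" if ev.expr_cocluster else "not co-clustered"
        dist = "" if ev.expr_pc_distance is None else f", PC distance {ev.expr_pc_distance:.2f}"
        trace.append(f"corroboration: expression {state}{dist}")


def flag_transformation(
    profile: MutationProfile,
    treatment_flags: Iterable[str] = (),
    driver_genes: Sequence[str] = TRANSFORMATION_DRIVERS,
    neuroendocrine: Sequence[str] = NEUROENDOCRINE_HISTOLOGIES,
) -> str | None:
    """Annotate possible histology transformation of a single lineage.

    Fires when the sample carries mutations in every configured driver gene
    (default EGFR + TP53 + RB1), its histology is neuroendocrine (e.g. SCLC),
    and the manifest carries an EGFR-TKI treatment flag. Annotation only —
    it never changes a pair label.
    """
    if profile.histology is None:
        return None
    hist = profile.histology.lower()
    if not any(term in hist for term in neuroendocrine):
        return None
    if TKI_FLAG not in {f.strip().lower() for f in treatment_flags}:
        return None
    mutated_genes = {c.key.gene for c in profile.calls if c.key.gene}
    if not all(g in mutated_genes for g in driver_genes):
        return None
    return "transformation_suspected"


# ---------------------------------------------------------------------------
# pipeline


DEFAULT_CONFIG: dict = {
    "filter": {"min_alt_reads": 4, "min_vaf": 0.02, "max_pop_freq": 0.01},
    "thresholds": {"t_ipm": 5.0, "t_low": 1.0, "min_shared_nonhotspot": 3},
    "similarity_nonsyn_only": False,
    "tree_nonsyn_only": True,
    "neoantigen_sharing_level": "mutation",
    "pca_components": 2,
    "cluster_k": 2,
    "hotspots": [],  # list of "chrom:pos:ref>alt" strings
}


def _merge_config(user: Mapping | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for k, v in (user or {}).items():
        if isinstance(v, Mapping) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _parse_hotspot(spec: str) -> MutationKey:
    chrom, pos, change = spec.split(":")
    ref, alt = change.split(">")
    return MutationKey(chrom, int(pos), ref, alt)


def run_pipeline(
    manifest: str | Path | pd.DataFrame,
    outdir: str | Path,
    config: Mapping | None = None,
    *,
    contexts_path: str | Path | None = None,
    hla_path: str | Path | None = None,
    expression_path: str | Path | None = None,
    signatures_path: str | Path | None = None,
    predictor=mock_affinity,
) -> dict:
    """Run filter -> clonality -> tree -> neoantigen -> expression -> calls.

    ``manifest`` is a TSV (or frame) with columns sample_id, patient_id,
    timepoint, histology, variants_path, format, treatment_flags; variant
    paths are resolved relative to the manifest's directory. Patient-level
    inputs (contexts FASTA, HLA text, expression TSV, signatures GMT) are
    optional: stages without inputs are skipped and the corresponding
    evidence fields stay null. Writes similarity/neoantigen/scores TSVs, a
    Newick tree per patient, a calls table, and a JSON report embedding the
    config and rule traces. Deterministic given fixed inputs and config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = _merge_config(config)
    thresholds = Thresholds(**cfg["thresholds"])
    hotspots = [_parse_hotspot(s) for s in cfg["hotspots"]]

    if isinstance(manifest, (str, Path)):
        base = Path(manifest).parent
        mdf = pd.read_csv(manifest, sep="\t", dtype=str).fillna(".")
    else:
        base = Path(".")
        mdf = manifest.astype(str)

    # --- per-sample: read, filter, benign rule -----------------------------
    profiles: dict[str, MutationProfile] = {}
    treatment: dict[str, tuple[str, ...]] = {}
    calls: list[LineageCall] = []
    for row in mdf.to_dict("records"):
        sid = row["sample_id"]
        vpath = Path(row["variants_path"])
        if not vpath.is_absolute():
            vpath = base / vpath
        raw = read_variants(vpath, format=row.get("format", "maf_tsv"))
        prof = filter_somatic_calls(
            raw,
            sample_id=sid,
            patient_id=row.get("patient_id"),
            timepoint=row.get("timepoint"),
            histology=row.get("histology"),
            **cfg["filter"],
        )
        profiles[sid] = prof
        flags = row.get("treatment_flags", ".")
        treatment[sid] = tuple(
            f for f in str(flags).split(",") if f.strip() and f.strip() != "."
        )
        benign = classify_sample(prof)
        if benign is not None:
            calls.append(benign)
    tumor_ids = sorted(s for s, p in profiles.items() if len(p) > 0)

    # --- clonality ----------------------------------------------------------
    similarities: dict[frozenset, PairSimilarity] = {}
    for a, b in itertools.combinations(tumor_ids, 2):
        similarities[frozenset({a, b})] = gene_similarity_score(
            profiles[a], profiles[b], hotspots, nonsyn_only=cfg["similarity_nonsyn_only"]
        )
    write_similarity_tsv(
        [similarities[frozenset(p)] for p in itertools.combinations(tumor_ids, 2)],
        outdir / "similarity.tsv",
    )

    newick_by_patient: dict[str, str] = {}
    by_patient: dict[str, list[str]] = {}
    for sid in tumor_ids:
        by_patient.setdefault(profiles[sid].patient_id or "patient", []).append(sid)
    for pid, sids in sorted(by_patient.items()):
        if len(sids) < 2:
            continue
        matrix = mutation_matrix([profiles[s] for s in sids], nonsyn_only=cfg["tree_nonsyn_only"])
        tree = build_tree(matrix)
        newick_by_patient[pid] = tree.newick
        (outdir / f"tree_{pid}.nwk").write_text(tree.newick + "\n", encoding="utf-8")

    # --- neoantigens --------------------------------------------------------
    neo_reports: dict[str, NeoantigenReport] = {}
    neo_shared: dict[frozenset, SharedNeoantigenSummary] = {}
    if contexts_path is not None and hla_path is not None:
        contexts = read_contexts_fasta(contexts_path)
        hla = read_hla(hla_path)
        for sid in tumor_ids:
            neo_reports[sid] = call_neoantigens(profiles[sid], contexts, hla, predictor)
        write_neoantigen_tsv(
            [neo_reports[s] for s in tumor_ids], outdir / "neoantigens.tsv"
        )
        for a, b in itertools.combinations(tumor_ids, 2):
            neo_shared[frozenset({a, b})] = shared_neoantigens(
                neo_reports[a], neo_reports[b], level=cfg["neoantigen_sharing_level"]
            )

    # --- expression ---------------------------------------------------------
    cocluster: dict[frozenset, bool] = {}
    pc_distance: dict[frozenset, float] = {}
    if expression_path is not None:
        expr = read_expression_tsv(expression_path)
        if expr.shape[1] >= 3:
            pre = preprocess(expr)
            k = min(cfg["pca_components"], expr.shape[1] - 1, pre.shape[0])
            scores, _ = pca(pre, k=k)
            scores.to_csv(outdir / "pca_scores.tsv", sep="\t", index_label="sample_id")
            clust = hier_cluster(scores, n_clusters=min(cfg["cluster_k"], expr.shape[1]))
            for a, b in itertools.combinations(sorted(expr.columns), 2):
                pair = frozenset({a, b})
                cocluster[pair] = clust.co_clustered(a, b)
                pc_distance[pair] = float(
                    ((scores.loc[a] - scores.loc[b]) ** 2).sum() ** 0.5
                )
        if signatures_path is not None:
            sigs = read_gmt(signatures_path)
            scores_frame(microenvironment_scores(expr, sigs)).to_csv(
                outdir / "microenvironment_scores.tsv", sep="\t", float_format="%.6f"
            )

    # --- pair evidence and calls -------------------------------------------
    hotset = frozenset(hotspots)
    for a, b in itertools.combinations(tumor_ids, 2):
        pair = frozenset({a, b})
        sim = similarities[pair]
        shared = profiles[a].keys() & profiles[b].keys()
        ev = PairEvidence(
            sample_a=a,
            sample_b=b,
            similarity=sim,
            neo=neo_shared.get(pair),
            expr_cocluster=cocluster.get(pair),
            expr_pc_distance=pc_distance.get(pair),
            shared_driver_only=bool(shared) and shared <= hotset,
            histology_match=(
                None
                if not profiles[a].histology or not profiles[b].histology
                else profiles[a].histology == profiles[b].histology
            ),
        )
        calls.append(classify_pair(ev, thresholds))

    # --- transformation annotations ----------------------------------------
    annotations: dict[str, str] = {}
    for sid in tumor_ids:
        flag = flag_transformation(profiles[sid], treatment[sid])
        if flag:
            annotations[sid] = flag

    # --- outputs ------------------------------------------------------------
    call_rows = []
    for c in calls:
        call_rows.append(
            {
                "subject": "|".join(c.subject),
                "label": c.label,
                "annotations": ";".join(
                    a for s in c.subject for a in ([annotations[s]] if s in annotations else [])
                )
                or ".",
            }
        )
    pd.DataFrame(call_rows).to_csv(outdir / "calls.tsv", sep="\t", index=False)

    report = {
        "schema_version": 1,
        "package_version": __version__,
        "config": cfg,
        "samples": {
            sid: {
                "n_retained_calls": len(profiles[sid]),
                "benign": len(profiles[sid]) == 0,
                "histology": profiles[sid].histology,
                "annotations": [annotations[sid]] if sid in annotations else [],
            }
            for sid in sorted(profiles)
        },
        "trees": newick_by_patient,
        "calls": [
            {
                "subject": list(c.subject),
                "label": c.label,
                "rule_trace": list(c.rule_trace),
            }
            for c in calls
        ],
        "neoantigen_skipped_keys": {
            sid: rep.n_missing_contexts for sid, rep in sorted(neo_reports.items())
        },
    }
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report
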