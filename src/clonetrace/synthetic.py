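"""Synthetic multi-tumor patients with known clonal structure.

Real multi-lesion cohorts of this kind are controlled-access; this module
generates desk-scale stand-ins with exact ground truth so every downstream
stage (filtering, similarity, trees, neoantigen sharing, expression evidence,
lineage calls) can be tested for recovery.

The generative model is trunk/branch clonal evolution. Tumors are partitioned
into clonal groups; each group shares a trunk mutation set inherited from the
common ancestor, nested sub-clades share internal-edge mutations, and every
tumor adds private branch mutations. Independent tumors share no somatic keys
except coincidental draws from a pool of recurrent hotspot drivers (the
real-world confound of two unrelated lung tumors both carrying, say,
EGFR L858R). Raw call lists additionally contain germline contaminants
(population frequency > 1%) and low-support artifacts, both of which the
somatic retention filter must remove; a benign sample has nothing else.

Peptide contexts are 21-mers centered on the mutated residue (shorter near a
terminus). Background residues are drawn from the 19 amino acids other than
tryptophan; a configured fraction of non-synonymous mutations gets the motif
``W[ILV]F`` planted over the mutated position, which the mock predictor
scores at 50 nM — so planted binders are exactly the strong binders, and the
number of shared neoantigens between two tumors is knowable in advance.

Expression is simulated directly in FPKM space: each lineage gets a per-gene
log2 centroid and samples scatter around it with i.i.d. Gaussian noise, so
same-lineage samples are close in expression space and different lineages
are well separated at the default noise level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import CellTypeSignature, write_expression_tsv, write_gmt
from .neoantigen import (
    HLAGenotype,
    PeptideContext,
    write_contexts_fasta,
)
from .variant_io import (
    MutationKey,
    MutationProfile,
    SomaticCall,
    filter_somatic_calls,
    write_profile,
)

__all__ = [
    "DEFAULT_HOTSPOTS",
    "SimulationConfig",
    "PatientTruth",
    "SyntheticPatient",
    "simulate_patient",
    "simulate_contexts",
    "synthetic_signatures",
    "write_truth",
    "write_patient_inputs",
]

#: Recurrent driver hotspots (hg19 coordinates) with per-tumor occurrence
#: probability; drawn independently per tumor regardless of clonal group.
DEFAULT_HOTSPOTS: tuple[tuple[MutationKey, float], ...] = (
    (MutationKey("7", 55259515, "T", "G", gene="EGFR", protein_change="L858R"), 0.10),
    (MutationKey("12", 25398285, "C", "A", gene="KRAS", protein_change="G12C"), 0.10),
    (MutationKey("17", 7578406, "C", "T", gene="TP53", protein_change="R175H"), 0.10),
    (MutationKey("7", 140453136, "A", "T", gene="BRAF", protein_change="V600E"), 0.05),
    (MutationKey("3", 178936091, "G", "A", gene="PIK3CA", protein_change="E545K"), 0.05),
)

DEFAULT_HLA = (
    "HLA-A*02:01",
    "HLA-A*24:02",
    "HLA-B*07:02",
    "HLA-C*07:01",
)

_BACKGROUND_AA = "ACDEFGHIKLMNPQRSTVY"  # 19 residues; W reserved for planted motifs
_NUCLEOTIDES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic patient.

    ``relatedness`` labels the tumor pairs in ``itertools.combinations``
    order over T1..Tn with 'clonal' or 'independent'; clonality must be
    transitive. Counts are per the trunk/branch model: ``n_trunk`` shared
    mutations per clonal group, ``n_internal`` per nested sub-clade edge
    (groups of 3+), ``n_private`` per tumor.
    """

    n_tumors: int = 2
    relatedness: tuple[str, ...] = ("clonal",)
    n_trunk: int = 150
    n_private: int = 50
    n_internal: int = 30
    hotspot_pool: tuple[tuple[MutationKey, float], ...] = DEFAULT_HOTSPOTS
    germline_rate: float = 0.10
    artifact_rate: float = 0.05
    include_benign: bool = False
    context_length: int = 21
    binder_fraction: float = 0.30
    truncation_rate: float = 0.05
    nonsyn_fraction: float = 0.75
    n_expr_genes: int = 500
    expr_noise_sd: float = 0.30
    expr_centroid_sd: float = 1.5
    expr_mean_log2: float = 3.0
    hla: tuple[str, ...] = DEFAULT_HLA
    histologies: tuple[str, ...] | None = None
    patient_id: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be >= 1")
        n_pairs = self.n_tumors * (self.n_tumors - 1) // 2
        if len(self.relatedness) != n_pairs:
            raise ValueError(
                f"relatedness needs {n_pairs} pair labels for {self.n_tumors} tumors"
            )
        if not set(self.relatedness) <= {"clonal", "independent"}:
            raise ValueError("relatedness labels must be 'clonal' or 'independent'")
        for name in ("germline_rate", "artifact_rate", "binder_fraction",
                     "truncation_rate", "nonsyn_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_trunk", "n_private", "n_internal", "n_expr_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for _, p in self.hotspot_pool:
            if not 0.0 <= p <= 1.0:
                raise ValueError("hotspot probabilities must be in [0, 1]")


@dataclass(frozen=True)
class PatientTruth:
    """Ground truth emitted alongside a synthetic patient."""

    pair_labels: Mapping[frozenset, str]  # {a,b} -> clonal | independent
    sample_labels: Mapping[str, str]  # sample -> tumor | benign
    lineage_of: Mapping[str, int]  # sample -> lineage index
    tree_newick: str
    expected_shared_keys: Mapping[frozenset, int]  # planned (non-hotspot) sharing
    expected_shared_neoantigens: Mapping[frozenset, int]


@dataclass(frozen=True)
class SyntheticPatient:
    profiles: tuple[MutationProfile, ...]  # filtered, tumor samples + benign
    raw_calls: Mapping[str, tuple[SomaticCall, ...]]  # pre-filter, per sample
    contexts: Mapping[MutationKey, PeptideContext]
    hla: HLAGenotype
    expression: pd.DataFrame  # genes x samples, FPKM
    truth: PatientTruth
    config: SimulationConfig

    def profile(self, sample_id: str) -> MutationProfile:
        for p in self.profiles:
            if p.sample_id == sample_id:
                return p
        raise KeyError(sample_id)


# ---------------------------------------------------------------------------
# clonal-group bookkeeping


def _clonal_groups(config: SimulationConfig) -> list[list[int]]:
    """Union-find over 'clonal' pair labels; checks transitivity."""
    parent = list(range(config.n_tumors))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pairs = list(itertools.combinations(range(config.n_tumors), 2))
    for (i, j), label in zip(pairs, config.relatedness):
        if label == "clonal":
            parent[find(i)] = find(j)
    for (i, j), label in zip(pairs, config.relatedness):
        if label == "independent" and find(i) == find(j):
            raise ValueError(
                f"inconsistent relatedness: tumors {i + 1} and {j + 1} are in the "
                "same clonal group but labeled independent"
            )
    groups: dict[int, list[int]] = {}
    for i in range(config.n_tumors):
        groups.setdefault(find(i), []).append(i)
    return [sorted(g) for g in sorted(groups.values())]


def _draw_keys(rng: np.random.Generator, n: int, used: set) -> list[MutationKey]:
    """Draw n unique SNV keys from the synthetic genome grid (chrom 1-22)."""
    out: list[MutationKey] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * max(n, 1) + 1000:
            raise RuntimeError("synthetic key space exhausted")
        chrom = str(int(rng.integers(1, 23)))
        pos = int(rng.integers(10_000, 100_000_000))
        ref = _NUCLEOTIDES[int(rng.integers(4))]
        alt = _NUCLEOTIDES[int(rng.integers(4))]
        if ref == alt:
            continue
        key = MutationKey(chrom, pos, ref, alt)
        if key in used:
            continue
        used.add(key)
        out.append(key)
    return out


def _supported_call(
    rng: np.random.Generator, key: MutationKey, **kw
) -> SomaticCall:
    """A somatic call guaranteed to pass the default retention thresholds."""
    while True:
        depth = int(rng.integers(80, 301))
        vaf_true = float(rng.uniform(0.10, 0.60))
        alt_reads = int(rng.binomial(depth, vaf_true))
        if alt_reads >= 4 and alt_reads / depth >= 0.02:
            return SomaticCall(key=key, depth=depth, alt_reads=alt_reads, **kw)


def _make_context(
    rng: np.random.Generator, key: MutationKey, config: SimulationConfig, binder: bool
) -> PeptideContext:
    """Mutant context: full 21-mer or terminus-truncated; optional planted motif."""
    full = config.context_length
    flank = (full - 1) // 2
    if rng.random() < config.truncation_rate:
        short = int(rng.integers(0, 8))  # flank on the truncated side: 0..7
        if rng.random() < 0.5:
            mut_index, length = short + 1, short + 1 + flank
        else:
            mut_index, length = flank + 1, flank + 1 + short
    else:
        mut_index, length = flank + 1, full
    seq = list(rng.choice(list(_BACKGROUND_AA), size=length))
    if binder:
        lo = max(1, mut_index - 2)
        hi = min(mut_index, length - 2)
        start = int(rng.integers(lo, hi + 1))  # motif covers the mutated residue
        middle = "ILV"[int(rng.integers(3))]
        seq[start - 1 : start + 2] = ["W", middle, "F"]
    return PeptideContext(key=key, sequence="".join(seq), mut_index=mut_index)


# ---------------------------------------------------------------------------
# genealogy


def _genealogy(
    rng: np.random.Generator, members: list[int], config: SimulationConfig
) -> tuple[list[tuple[frozenset, int]], str]:
    """Random binary genealogy of one clonal group.

    Returns the list of shared-mutation edges (member set, mutation count) —
    the trunk edge plus one internal edge per nested sub-clade — and the
    group's Newick fragment (leaf labels filled in later via T{i+1}).
    """
    edges: list[tuple[frozenset, int]] = [(frozenset(members), config.n_trunk)]

    def split(nodes: list[int]) -> str:
        if len(nodes) == 1:
            return f"T{nodes[0] + 1}:{config.n_private}"
        k = int(rng.integers(1, len(nodes)))
        left, right = nodes[:k], nodes[k:]
        parts = []
        for side in (left, right):
            if len(side) > 1:
                edges.append((frozenset(side), config.n_internal))
                parts.append(f"{split(side)}:{config.n_internal}")
            else:
                parts.append(split(side))
        return f"({parts[0]},{parts[1]})"

    shuffled = list(members)
    rng.shuffle(shuffled)
    newick = split(shuffled)
    return edges, newick


# ---------------------------------------------------------------------------
# main generator


def simulate_patient(config: SimulationConfig) -> SyntheticPatient:
    """Generate one synthetic multi-tumor patient (deterministic in the seed)."""
    rng = np.random.default_rng(config.seed)
    groups = _clonal_groups(config)
    used: set[MutationKey] = {k for k, _ in config.hotspot_pool}

    tumor_ids = [f"T{i + 1}" for i in range(config.n_tumors)]
    sample_ids = list(tumor_ids) + (["B1"] if config.include_benign else [])
    if config.histologies is not None:
        if len(config.histologies) != len(sample_ids):
            raise ValueError("histologies must cover every sample (incl. benign)")
        histology = dict(zip(sample_ids, config.histologies))
    else:
        histology = {s: "adenocarcinoma" for s in tumor_ids}
        if config.include_benign:
            histology["B1"] = "benign"

    # --- somatic key assignment per tumor ----------------------------------
    tumor_keys: dict[int, set[MutationKey]] = {i: set() for i in range(config.n_tumors)}
    nonsyn: dict[MutationKey, bool] = {}
    binder: dict[MutationKey, bool] = {}
    clade_fragments: list[str] = []
    lineage_of_idx: dict[int, int] = {}

    def register(keys: Iterable[MutationKey]) -> None:
        for k in keys:
            nonsyn[k] = bool(rng.random() < config.nonsyn_fraction)
            binder[k] = nonsyn[k] and bool(rng.random() < config.binder_fraction)

    for g_idx, members in enumerate(groups):
        for m in members:
            lineage_of_idx[m] = g_idx
        if len(members) == 1:
            private = _draw_keys(rng, config.n_private, used)
            register(private)
            tumor_keys[members[0]].update(private)
            clade_fragments.append(f"T{members[0] + 1}:{config.n_private}")
            continue
        edges, fragment = _genealogy(rng, members, config)
        clade_fragments.append(f"{fragment}:{config.n_trunk}")
        for member_set, count in edges:
            shared = _draw_keys(rng, count, used)
            register(shared)
            for m in member_set:
                tumor_keys[m].update(shared)
        for m in members:
            private = _draw_keys(rng, config.n_private, used)
            register(private)
            tumor_keys[m].update(private)

    # hotspot drivers: independent Bernoulli per tumor, shared keys by chance
    for key, prob in config.hotspot_pool:
        nonsyn.setdefault(key, True)
        binder.setdefault(key, False)  # hotspot contexts never carry the motif
        for i in range(config.n_tumors):
            if rng.random() < prob:
                tumor_keys[i].add(key)

    # --- contexts (patient-level: one per non-synonymous mutation) ---------
    all_keys = sorted(set().union(*tumor_keys.values()), key=lambda k: k.sort_key())
    contexts = {
        k: _make_context(rng, k, config, binder[k]) for k in all_keys if nonsyn[k]
    }

    # --- raw calls: somatic + germline contaminants + artifacts ------------
    mean_somatic = max(1, int(round(np.mean([len(v) for v in tumor_keys.values()]))))
    n_germ = int(round(config.germline_rate / (1 - config.germline_rate) * mean_somatic)) \
        if config.germline_rate < 1 else mean_somatic
    germline_keys = _draw_keys(rng, n_germ, used)
    germline_freqs = {k: float(rng.uniform(0.011, 0.5)) for k in germline_keys}

    def germline_calls() -> list[SomaticCall]:
        return [
            _supported_call(rng, k, pop_freq=germline_freqs[k], non_synonymous=True)
            for k in germline_keys
        ]

    def artifact_calls(n_somatic: int) -> list[SomaticCall]:
        n = int(round(config.artifact_rate * n_somatic))
        out = []
        for k in _draw_keys(rng, n, used):
            if rng.random() < 0.5:  # too few supporting reads
                alt = int(rng.integers(1, 4))
                out.append(SomaticCall(key=k, depth=int(rng.integers(60, 200)), alt_reads=alt))
            else:  # VAF below 2%
                depth = int(rng.integers(300, 500))
                alt = int(rng.integers(4, max(5, int(depth * 0.019))))
                while alt / depth >= 0.02:
                    alt -= 1
                out.append(SomaticCall(key=k, depth=depth, alt_reads=alt))
        return out

    raw_calls: dict[str, tuple[SomaticCall, ...]] = {}
    profiles: list[MutationProfile] = []
    for i, sid in enumerate(tumor_ids):
        somatic = [
            _supported_call(rng, k, non_synonymous=nonsyn[k])
            for k in sorted(tumor_keys[i], key=lambda k: k.sort_key())
        ]
        raw = somatic + germline_calls() + artifact_calls(len(somatic))
        raw_calls[sid] = tuple(raw)
        profiles.append(
            filter_somatic_calls(
                raw,
                sample_id=sid,
                patient_id=config.patient_id,
                timepoint="t1",
                histology=histology[sid],
            )
        )
    if config.include_benign:
        raw = germline_calls() + artifact_calls(mean_somatic)
        raw_calls["B1"] = tuple(raw)
        profiles.append(
            filter_somatic_calls(
                raw,
                sample_id="B1",
                patient_id=config.patient_id,
                timepoint="t1",
                histology=histology["B1"],
            )
        )

    # --- expression: lognormal noise around per-lineage centroids ----------
    genes = [f"G{i + 1:04d}" for i in range(config.n_expr_genes)]
    n_lineages = len(groups) + (1 if config.include_benign else 0)
    centroids = rng.normal(
        config.expr_mean_log2, config.expr_centroid_sd, size=(n_lineages, config.n_expr_genes)
    )
    cols = {}
    lineage_of: dict[str, int] = {}
    for i, sid in enumerate(tumor_ids):
        lineage_of[sid] = lineage_of_idx[i]
        log2 = centroids[lineage_of[sid]] + rng.normal(0, config.expr_noise_sd, config.n_expr_genes)
        cols[sid] = np.power(2.0, log2)
    if config.include_benign:
        lineage_of["B1"] = n_lineages - 1
        log2 = centroids[-1] + rng.normal(0, config.expr_noise_sd, config.n_expr_genes)
        cols["B1"] = np.power(2.0, log2)
    expression = pd.DataFrame(cols, index=genes)

    # --- ground truth -------------------------------------------------------
    pair_labels: dict[frozenset, str] = {}
    expected_shared: dict[frozenset, int] = {}
    expected_neo: dict[frozenset, int] = {}
    for i, j in itertools.combinations(range(config.n_tumors), 2):
        pair = frozenset({tumor_ids[i], tumor_ids[j]})
        clonal = lineage_of_idx[i] == lineage_of_idx[j]
        pair_labels[pair] = "clonal" if clonal else "independent"
        hotset = {k for k, _ in config.hotspot_pool}
        shared = (tumor_keys[i] & tumor_keys[j]) - hotset
        expected_shared[pair] = len(shared)
        expected_neo[pair] = sum(1 for k in shared if binder[k])
    sample_labels = {s: "tumor" for s in tumor_ids}
    if config.include_benign:
        sample_labels["B1"] = "benign"
        for t in tumor_ids:
            pair_labels[frozenset({t, "B1"})] = "independent"

    inner = ",".join(clade_fragments)
    tree_newick = f"(normal:0,{inner});"

    return SyntheticPatient(
        profiles=tuple(profiles),
        raw_calls=raw_calls,
        contexts=contexts,
        hla=HLAGenotype(alleles=config.hla),
        expression=expression,
        truth=PatientTruth(
            pair_labels=pair_labels,
            sample_labels=sample_labels,
            lineage_of=lineage_of,
            tree_newick=tree_newick,
            expected_shared_keys=expected_shared,
            expected_shared_neoantigens=expected_neo,
        ),
        config=config,
    )


def simulate_contexts(
    profile: MutationProfile, config: SimulationConfig
) -> dict[MutationKey, PeptideContext]:
    """Standalone context generation for one profile's non-synonymous calls.

    One record per non-synonymous mutation; a ``binder_fraction`` of them
    carries the planted strong-binder motif. Deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    out: dict[MutationKey, PeptideContext] = {}
    for key in sorted(profile.nonsyn_keys(), key=lambda k: k.sort_key()):
        planted = bool(rng.random() < config.binder_fraction)
        out[key] = _make_context(rng, key, config, planted)
    return out


def synthetic_signatures(
    gene_ids: Sequence[str],
    rng: np.random.Generator,
    n_immune: int = 3,
    n_stroma: int = 2,
    size: int = 15,
) -> list[CellTypeSignature]:
    """Random cell-type signatures over the synthetic gene universe."""
    immune_names = ["CD8_T_cells", "NK_cells", "B_cells", "CD4_T_cells", "Macrophages"]
    stroma_names = ["Fibroblasts", "Endothelial_cells", "Pericytes"]
    sigs = []
    for comp, names, n in (("immune", immune_names, n_immune), ("stroma", stroma_names, n_stroma)):
        for name in names[:n]:
            genes = rng.choice(list(gene_ids), size=min(size, len(gene_ids)), replace=False)
            sigs.append(CellTypeSignature(name=name, compartment=comp, genes=frozenset(genes)))
    return sigs


# ---------------------------------------------------------------------------
# writers


def write_truth(patient: SyntheticPatient, outdir: str | Path) -> dict[str, Path]:
    """Emit pairs.tsv, samples.tsv and tree.nwk, joinable by sample_id."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = patient.truth
    pair_lines = ["sample_a\tsample_b\ttruth\texpected_shared_keys\texpected_shared_neoantigens"]
    tumor_pairs = sorted(
        (sorted(p) for p in t.pair_labels if p in t.expected_shared_keys),
    )
    for a, b in tumor_pairs:
        pair = frozenset({a, b})
        pair_lines.append(
            f"{a}\t{b}\t{t.pair_labels[pair]}\t{t.expected_shared_keys[pair]}"
            f"\t{t.expected_shared_neoantigens[pair]}"
        )
    for pair in sorted((sorted(p) for p in t.pair_labels if frozenset(p) not in t.expected_shared_keys)):
        a, b = pair
        pair_lines.append(f"{a}\t{b}\t{t.pair_labels[frozenset(pair)]}\t.\t.")
    pairs_path = outdir / "pairs.tsv"
    pairs_path.write_text("\n".join(pair_lines) + "\n", encoding="utf-8")

    sample_lines = ["sample_id\tlabel\tlineage"]
    for sid in sorted(t.sample_labels):
        sample_lines.append(f"{sid}\t{t.sample_labels[sid]}\t{t.lineage_of.get(sid, '.')}")
    samples_path = outdir / "samples.tsv"
    samples_path.write_text("\n".join(sample_lines) + "\n", encoding="utf-8")

    tree_path = outdir / "tree.nwk"
    tree_path.write_text(t.tree_newick + "\n", encoding="utf-8")
    return {"pairs": pairs_path, "samples": samples_path, "tree": tree_path}


def write_patient_inputs(patient: SyntheticPatient, outdir: str | Path) -> Path:
    """Write pipeline-consumable inputs (raw per-sample MAF TSVs, contexts
    FASTA, HLA text, expression TSV, signatures GMT, manifest TSV) and the
    truth tables. Returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = patient.config
    manifest_rows = []
    for sid in sorted(patient.raw_calls):
        raw_profile = MutationProfile(
            sample_id=sid,
            calls=patient.raw_calls[sid],
            patient_id=cfg.patient_id,
        )
        vpath = outdir / f"{sid}.variants.tsv"
        write_profile(raw_profile, vpath)
        prof = patient.profile(sid)
        manifest_rows.append(
            {
                "sample_id": sid,
                "patient_id": cfg.patient_id,
                "timepoint": prof.timepoint or "t1",
                "histology": prof.histology or ".",
                "variants_path": vpath.name,
                "format": "maf_tsv",
                "treatment_flags": ".",
            }
        )
    write_contexts_fasta(patient.contexts, outdir / "contexts.fasta")
    (outdir / "hla.txt").write_text(
        "\n".join(patient.hla.alleles) + "\n", encoding="utf-8"
    )
    write_expression_tsv(patient.expression, outdir / "expression.fpkm.tsv")
    rng = np.random.default_rng(cfg.seed + 104729)  # signature draw decoupled from patient draw
    write_gmt(
        synthetic_signatures(list(patient.expression.index), rng),
        outdir / "signatures.gmt",
    )
    write_truth(patient, outdir / "truth")
    hotspot_specs = [
        f"{k.chrom}:{k.pos}:{k.ref}>{k.alt}" for k, _ in cfg.hotspot_pool
    ]
    (outdir / "config.yaml").write_text(
        "hotspots:\n" + "".join(f"  - '{s}'\n" for s in hotspot_specs), encoding="utf-8"
    )
    manifest = pd.DataFrame(manifest_rows)
    manifest_path = outdir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path
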