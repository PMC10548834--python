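"""Expression evidence: PCA, hierarchical clustering, and cell-type scores.

Bulk RNA expression is consumed as an FPKM gene-by-sample matrix. The module
provides the three expression-side read-outs used to corroborate lineage
calls: sample placement in principal-component space, unsupervised
hierarchical clustering (complete linkage by default), and xCell-style
microenvironment scores.

Cell-type scores are single-sample rank-enrichment scores: genes are ranked
by descending expression within one sample and a signature's score is the
signed maximal deviation between the weighted cumulative distribution of
in-signature genes (rank weights raised to ``alpha``) and the uniform
cumulative distribution of the remaining genes, bounded in [-1, 1]. The
immune score of a sample is the sum of its immune cell-type scores, the
stroma score the sum of its stromal cell-type scores, and the
microenvironment score is the sum of the two compartments; cell-type scores
are floored at zero before summation so compartment scores are non-negative.
All scores depend on within-sample ranks only, hence are invariant to any
global rescaling of FPKM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

__all__ = [
    "CellTypeSignature",
    "EnrichmentScores",
    "ClusterResult",
    "validate_expression",
    "preprocess",
    "pca",
    "hier_cluster",
    "ssgsea_score",
    "microenvironment_scores",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
]

COMPARTMENTS = ("immune", "stroma")


@dataclass(frozen=True)
class CellTypeSignature:
    """A named cell-type gene set assigned to the immune or stroma compartment."""

    name: str
    compartment: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"compartment must be one of {COMPARTMENTS}")
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass(frozen=True)
class EnrichmentScores:
    """Per-sample cell-type scores with compartment sums."""

    sample_id: str
    cell_type_scores: Mapping[str, float]  # floored at 0; NaN = missing signature
    immune_score: float
    stroma_score: float
    microenvironment_score: float


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check an FPKM matrix: genes x samples, non-negative, unique sample ids."""
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate sample ids in expression matrix")
    if matrix.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("FPKM matrix contains negative entries")
    return matrix


def preprocess(matrix: pd.DataFrame, *, scale: bool = False) -> pd.DataFrame:
    """log2(FPKM+1), drop zero-variance genes, center (optionally scale) per gene."""
    validate_expression(matrix)
    if matrix.shape[1] < 2:
        raise ValueError("preprocess requires >= 2 samples")
    log = np.log2(matrix.astype(float) + 1.0)
    var = log.var(axis=1, ddof=0)
    log = log.loc[var > 0]
    centered = log.sub(log.mean(axis=1), axis=0)
    if scale:
        centered = centered.div(log.std(axis=1, ddof=0), axis=0)
    return centered


def pca(matrix: pd.DataFrame, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the top ``k`` principal components.

    ``matrix`` is a preprocessed genes x samples frame. Component signs are
    fixed so the largest-magnitude gene loading of each component is positive,
    making the decomposition deterministic. Returns (scores, explained
    variance fractions), scores indexed by sample.
    """
    n_genes, n_samples = matrix.shape
    if k > min(n_genes, n_samples - 1):
        raise ValueError(
            f"k={k} exceeds min(genes, samples-1) = {min(n_genes, n_samples - 1)}"
        )
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    for j in range(k):
        i_max = int(np.argmax(np.abs(model.components_[j])))
        if model.components_[j, i_max] < 0:
            model.components_[j] *= -1
            scores[:, j] *= -1
    frame = pd.DataFrame(
        scores, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return frame, model.explained_variance_ratio_


@dataclass(frozen=True)
class ClusterResult:
    """Dendrogram plus flat labels at a configured cut."""

    labels: Mapping[str, int]
    merge_heights: tuple[float, ...]
    linkage_matrix: np.ndarray
    sample_order: tuple[str, ...]

    def co_clustered(self, a: str, b: str) -> bool:
        return self.labels[a] == self.labels[b]


def hier_cluster(
    scores: pd.DataFrame,
    *,
    n_clusters: int = 2,
    method: str = "complete",
    metric: str = "euclidean",
) -> ClusterResult:
    """Agglomerative clustering of samples (rows of ``scores``).

    ``scores`` is a samples x features frame — typically top-k PC scores.
    Samples are sorted lexicographically before linkage so the result is
    invariant to input order (scipy breaks ties by input position).
    """
    if scores.shape[0] < 2:
        raise ValueError("clustering requires >= 2 samples")
    ordered = scores.sort_index()
    Z = linkage(ordered.to_numpy(dtype=float), method=method, metric=metric)
    flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    labels = dict(zip(ordered.index, (int(x) for x in flat)))
    return ClusterResult(
        labels=labels,
        merge_heights=tuple(float(h) for h in Z[:, 2]),
        linkage_matrix=Z,
        sample_order=tuple(ordered.index),
    )


def ssgsea_score(
    values: pd.Series, signature_genes: Iterable[str], alpha: float = 0.25
) -> float:
    """Single-sample weighted-rank enrichment score of a gene set.

    Genes are sorted by descending expression (ties broken by gene id so the
    walk is deterministic). Walking down the ranking, the in-set cumulative
    distribution weights gene at rank r by (N - r + 1)**alpha, the out-of-set
    distribution is uniform; the score is the deviation of maximal magnitude
    between the two, a value in [-1, 1]. Depends only on the rank order.
    """
    genes = frozenset(signature_genes) & frozenset(values.index)
    if not genes:
        raise ValueError("signature has no genes in common with the sample vector")
    n = len(values)
    if len(genes) >= n:
        raise ValueError("signature covers every gene; enrichment undefined")
    order = sorted(values.index, key=lambda g: (-values[g], g))
    in_set = np.fromiter((g in genes for g in order), dtype=bool, count=n)
    rank_weight = (n - np.arange(n, dtype=float)) ** alpha  # rank 1 -> N**alpha
    w_in = np.where(in_set, rank_weight, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~in_set) / (n - len(genes))
    dev = p_in - p_out
    return float(dev[np.argmax(np.abs(dev))])


def microenvironment_scores(
    matrix: pd.DataFrame,
    signatures: Sequence[CellTypeSignature],
    alpha: float = 0.25,
) -> list[EnrichmentScores]:
    """Cell-type, immune, stroma, and microenvironment scores per sample.

    Cell-type scores below zero are floored at zero before the compartment
    sums; signatures with no genes in the matrix score NaN (with a warning)
    and contribute nothing. By construction microenvironment = immune +
    stroma exactly.
    """
    validate_expression(matrix)
    if not any(s.compartment == "immune" for s in signatures) or not any(
        s.compartment == "stroma" for s in signatures
    ):
        raise ValueError("need >= 1 immune and >= 1 stroma signature")
    gene_index = frozenset(matrix.index)
    missing = [s.name for s in signatures if not (s.genes & gene_index)]
    if missing:
        warnings.warn(
            f"signatures with no genes in the matrix are reported missing: {missing}",
            stacklevel=2,
        )
    results: list[EnrichmentScores] = []
    for sample in matrix.columns:
        vec = matrix[sample]
        per_type: dict[str, float] = {}
        sums = {"immune": 0.0, "stroma": 0.0}
        for sig in signatures:
            if sig.name in missing:
                per_type[sig.name] = float("nan")
                continue
            score = max(0.0, ssgsea_score(vec, sig.genes, alpha=alpha))
            per_type[sig.name] = score
            sums[sig.compartment] += score
        results.append(
            EnrichmentScores(
                sample_id=str(sample),
                cell_type_scores=per_type,
                immune_score=sums["immune"],
                stroma_score=sums["stroma"],
                microenvironment_score=sums["immune"] + sums["stroma"],
            )
        )
    return results


# ---------------------------------------------------------------------------
# I/O


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample FPKM TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_expression(df)


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_csv(path, sep="\t", index_label="gene")
    return path


def read_gmt(path: str | Path) -> list[CellTypeSignature]:
    """Read signatures from GMT; the description field carries the compartment."""
    signatures = []
    for line_no, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{line_no}: GMT line needs name, compartment, genes")
        name, compartment, *genes = fields
        signatures.append(
            CellTypeSignature(
                name=name,
                compartment=compartment.strip().lower(),
                genes=frozenset(g for g in genes if g),
            )
        )
    return signatures


def write_gmt(signatures: Sequence[CellTypeSignature], path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "\t".join([s.name, s.compartment, *sorted(s.genes)]) for s in signatures
    ]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def scores_frame(scores: Sequence[EnrichmentScores]) -> pd.DataFrame:
    """Tabulate per-sample scores (cell types + compartment sums)."""
    rows = []
    for s in scores:
        row = {"sample_id": s.sample_id, **s.cell_type_scores}
        row["immune_score"] = s.immune_score
        row["stroma_score"] = s.stroma_score
        row["microenvironment_score"] = s.microenvironment_score
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
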