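"""Pairwise clonal-relatedness statistics and mutation-matrix phylogenies.

Two tumors of common clonal origin inherit the trunk mutations of their shared
ancestor, so the overlap of their somatic mutation sets carries the lineage
signal. The gene similarity score implemented here is the Jaccard index of
the two normalized key sets, expressed as a percentage and recorded in output
metadata as ``jaccard_pct``. A configurable hotspot list lets callers count
shared non-hotspot mutations separately, because recurrent drivers (e.g.
EGFR L858R) co-occur in clonally unrelated tumors by chance.

Per-patient phylogenies are built by neighbor joining on raw Hamming distances
between binary mutation-presence columns (non-synonymous mutations by
convention), with an all-zero "normal" column as outgroup; branch lengths then
read directly as mutation counts, matching the trunk/branch interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .variant_io import MutationKey, MutationProfile

__all__ = [
    "PairSimilarity",
    "PhyloTree",
    "BenignSampleError",
    "shared_mutations",
    "gene_similarity_score",
    "mutation_matrix",
    "build_tree",
    "rf_distance",
    "write_similarity_tsv",
]

NORMAL_LABEL = "normal"


class BenignSampleError(ValueError):
    """Similarity is undefined for a sample with zero somatic calls.

    Benign samples (zero retained somatic mutations) are classified directly
    by the per-sample rule and are excluded from pairwise analysis.
    """


@dataclass(frozen=True)
class PairSimilarity:
    """Shared-mutation summary for one tumor pair (symmetric in a/b)."""

    sample_a: str
    sample_b: str
    n_shared: int
    n_union: int
    similarity_pct: float
    n_shared_nonhotspot: int
    method: str = "jaccard_pct"

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity_pct <= 100.0:
            raise ValueError("similarity_pct out of [0, 100]")
        if self.n_shared > self.n_union:
            raise ValueError("n_shared exceeds n_union")


def shared_mutations(a: MutationProfile, b: MutationProfile) -> frozenset[MutationKey]:
    """Exact intersection of two profiles' normalized mutation keys."""
    return a.keys() & b.keys()


def gene_similarity_score(
    a: MutationProfile,
    b: MutationProfile,
    hotspots: Iterable[MutationKey] = (),
    *,
    nonsyn_only: bool = False,
) -> PairSimilarity:
    """Jaccard similarity (x100) between two tumors' somatic mutation sets.

    ``nonsyn_only`` restricts both sets to non-synonymous calls; the default
    uses all retained somatic calls. Hotspot keys are excluded only from
    ``n_shared_nonhotspot``, never from the score itself.
    """
    keys_a = a.nonsyn_keys() if nonsyn_only else a.keys()
    keys_b = b.nonsyn_keys() if nonsyn_only else b.keys()
    if not keys_a or not keys_b:
        empty = a.sample_id if not keys_a else b.sample_id
        raise BenignSampleError(
            f"sample {empty} has no somatic calls; apply the benign rule "
            "(classify_sample) instead of pairwise similarity"
        )
    shared = keys_a & keys_b
    union = keys_a | keys_b
    hotset = frozenset(hotspots)
    return PairSimilarity(
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        n_shared=len(shared),
        n_union=len(union),
        similarity_pct=100.0 * len(shared) / len(union),
        n_shared_nonhotspot=len(shared - hotset),
    )


def mutation_matrix(
    profiles: Sequence[MutationProfile], nonsyn_only: bool = True
) -> pd.DataFrame:
    """Binary mutation-presence matrix (keys x samples) plus a zero ``normal``.

    Rows are ordered by (chrom, pos, ref, alt); with ``nonsyn_only`` a key is
    kept only if it is non-synonymous in at least one sample carrying it.
    """
    if len(profiles) < 2:
        raise ValueError("mutation_matrix needs at least 2 profiles")
    sample_ids = [p.sample_id for p in profiles]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    keysets = [p.nonsyn_keys() if nonsyn_only else p.keys() for p in profiles]
    all_keys = sorted(set().union(*keysets), key=lambda k: k.sort_key())
    data = np.zeros((len(all_keys), len(profiles) + 1), dtype=np.int8)
    index = {k: i for i, k in enumerate(all_keys)}
    for j, keys in enumerate(keysets):
        for k in keys:
            data[index[k], j] = 1
    return pd.DataFrame(
        data,
        index=[str(k) for k in all_keys],
        columns=sample_ids + [NORMAL_LABEL],
    )


@dataclass(frozen=True)
class PhyloTree:
    """A rooted patient phylogeny over tumor samples plus ``normal``."""

    tree: TreeNode
    newick: str

    @property
    def leaf_names(self) -> frozenset[str]:
        return frozenset(t.name for t in self.tree.tips())


def build_tree(matrix: pd.DataFrame) -> PhyloTree:
    """Neighbor-joining tree from a binary mutation matrix.

    Distances are raw Hamming counts between sample columns (branch lengths
    ~ mutation counts). Negative NJ branch lengths are clamped to zero and
    the tree is rooted on the ``normal`` outgroup.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 columns (2 tumors + normal) to build a tree")
    if NORMAL_LABEL not in matrix.columns:
        raise ValueError(f"matrix must contain a {NORMAL_LABEL!r} column")
    cols = list(matrix.columns)
    arr = matrix.to_numpy(dtype=np.int8)
    # raw Hamming count: number of keys whose presence differs
    diff = (arr[:, :, None] != arr[:, None, :]).sum(axis=0).astype(float)
    dm = DistanceMatrix(diff, ids=cols)
    tree = nj(dm, neg_as_zero=True)
    tree = tree.root_by_outgroup([NORMAL_LABEL])
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    newick = str(tree).strip()
    return PhyloTree(tree=tree, newick=newick)


def rf_distance(a: PhyloTree | TreeNode | str, b: PhyloTree | TreeNode | str) -> float:
    """Unrooted Robinson–Foulds distance between two trees (0 = same topology)."""

    def as_tree(x) -> TreeNode:
        if isinstance(x, PhyloTree):
            return x.tree
        if isinstance(x, TreeNode):
            return x
        return TreeNode.read([x])

    return as_tree(a).compare_rfd(as_tree(b), rooted=False)


def write_similarity_tsv(pairs: Sequence[PairSimilarity], path: str | Path) -> Path:
    path = Path(path)
    header = "sample_a\tsample_b\tn_shared\tn_union\tsimilarity_pct\tn_shared_nonhotspot\tmethod"
    lines = [header] + [
        f"{p.sample_a}\t{p.sample_b}\t{p.n_shared}\t{p.n_union}"
        f"\t{p.similarity_pct:.4f}\t{p.n_shared_nonhotspot}\t{p.method}"
        for p in pairs
    ]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
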