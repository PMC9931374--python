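"""Validation of an inferred association structure against external data.

Given a second expression dataset sharing genes with the discovery cohort,
the tools here (i) build binary partition trees of samples by the same
recursive spectral sorting used within cohorts and align two trees by
dynamic programming over their ordered leaf clusters, (ii) score module
expression coherence as the p_diff deviation between within-module and
background gene-gene correlation distributions, (iii) count preserved
(compatible vs incompatible) pairwise associations, (iv) correlate an
external response profile with Gene Group expression, and (v) identify
tissue-specific genes from a tissue x gene expression panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import Effector, pairwise_association
from .clinical_survival import pdiff_statistic
from .supermodules import PartitionNode, spectral_sort


@dataclass
class PartitionTree:
    """Binary tree of sample clusters with per-leaf centroid signatures."""

    samples: list[str]
    genes: list[str]
    root: PartitionNode
    centroids: list[np.ndarray] = field(default_factory=list)  # per leaf
    leaf_samples: list[list[str]] = field(default_factory=list)


@dataclass
class AlignmentResult:
    matched: list[tuple[int, int, float]]  # (leaf in A, leaf in B, cost)
    gaps_a: list[int] = field(default_factory=list)
    gaps_b: list[int] = field(default_factory=list)
    incompatibility: float = 0.0


def build_partition_tree(
    expression: pd.DataFrame, shared_genes: list[str] | None = None,
    min_split: int = 4,
) -> PartitionTree:
    """Partition tree of samples from a genes x samples expression matrix.

    Reuses the spectral column tree; leaf centroids are per-cluster mean
    expression over the shared genes.
    """
    if shared_genes is not None:
        shared = [g for g in shared_genes if g in expression.index]
        if not shared:
            raise ValueError("no shared genes")
        expression = expression.loc[shared]
    samples = [str(c) for c in expression.columns]
    if len(samples) == 1:
        root = PartitionNode(indices=[0])
        return PartitionTree(
            samples=samples,
            genes=[str(g) for g in expression.index],
            root=root,
            centroids=[expression.to_numpy()[:, 0]],
            leaf_samples=[samples],
        )
    _, col_order, _, col_tree = spectral_sort(expression.to_numpy(), min_split=min_split)
    X = expression.to_numpy()
    leaves = col_tree.leaves()
    centroids = [X[:, leaf.indices].mean(axis=1) for leaf in leaves]
    leaf_samples = [[samples[i] for i in leaf.indices] for leaf in leaves]
    return PartitionTree(
        samples=samples,
        genes=[str(g) for g in expression.index],
        root=col_tree,
        centroids=centroids,
        leaf_samples=leaf_samples,
    )


def _centroid_cost(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        return 1.0
    return float(1.0 - np.corrcoef(a, b)[0, 1])


def align_partition_trees(
    tree_a: PartitionTree, tree_b: PartitionTree, gap_penalty: float = 0.5
) -> AlignmentResult:
    """Global alignment of the ordered leaf-cluster sequences.

    Needleman-Wunsch over the tree-ordered leaves with match cost
    1 - Pearson(centroid_a, centroid_b) and gap penalty ``gap_penalty``;
    the matching is non-crossing, so the topological order of both trees
    is respected.  Because the left-right orientation of a spectral
    ordering is arbitrary per dataset, the alignment is computed against
    both orientations of the second tree and the better one kept.  The
    incompatibility score is the total cost divided by the longer sequence
    length, clipped to [0, 1].
    """
    forward = _align_sequences(tree_a.centroids, tree_b.centroids, gap_penalty)
    nb = len(tree_b.centroids)
    reverse = _align_sequences(tree_a.centroids, tree_b.centroids[::-1], gap_penalty)
    if reverse.incompatibility < forward.incompatibility:
        reverse.matched = [(i, nb - 1 - j, c) for i, j, c in reverse.matched]
        reverse.gaps_b = sorted(nb - 1 - j for j in reverse.gaps_b)
        return reverse
    return forward


def _align_sequences(
    A: list[np.ndarray], B: list[np.ndarray], gap_penalty: float
) -> AlignmentResult:
    na, nb = len(A), len(B)
    cost = np.array([[_centroid_cost(a, b) for b in B] for a in A])
    D = np.zeros((na + 1, nb + 1))
    D[:, 0] = gap_penalty * np.arange(na + 1)
    D[0, :] = gap_penalty * np.arange(nb + 1)
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            D[i, j] = min(
                D[i - 1, j - 1] + cost[i - 1, j - 1],
                D[i - 1, j] + gap_penalty,
                D[i, j - 1] + gap_penalty,
            )
    matched: list[tuple[int, int, float]] = []
    gaps_a: list[int] = []
    gaps_b: list[int] = []
    i, j = na, nb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(D[i, j], D[i - 1, j - 1] + cost[i - 1, j - 1]):
            matched.append((i - 1, j - 1, float(cost[i - 1, j - 1])))
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(D[i, j], D[i - 1, j] + gap_penalty):
            gaps_a.append(i - 1)
            i -= 1
        else:
            gaps_b.append(j - 1)
            j -= 1
    matched.reverse()
    score = float(np.clip(D[na, nb] / max(na, nb), 0.0, 1.0))
    return AlignmentResult(
        matched=matched, gaps_a=sorted(gaps_a), gaps_b=sorted(gaps_b),
        incompatibility=score,
    )


def expression_coherence(
    module_genes: list[str],
    expression: pd.DataFrame,
    n_background_pairs: int = 10_000,
    epsilon: float | None = None,
    seed: int = 0,
) -> tuple[float, str]:
    """p_diff between within-module and background correlation distributions.

    X1 holds the pairwise Pearson correlations among the module's genes in
    the external data, X2 correlations of randomly sampled background gene
    pairs.  Scores >= 0.3 are labelled "coherent", >= 0.1 "moderately
    coherent", else "not coherent".
    """
    present = [g for g in module_genes if g in expression.index]
    if len(present) < 2:
        raise ValueError("need >= 2 module genes present in the expression data")
    X = expression.loc[present].to_numpy()
    corr = np.corrcoef(X)
    iu = np.triu_indices(len(present), k=1)
    x1 = corr[iu]
    rng = np.random.default_rng(seed)
    genes = list(expression.index)
    x2 = np.empty(n_background_pairs)
    Xall = expression.to_numpy()
    for b in range(n_background_pairs):
        i, j = rng.choice(len(genes), 2, replace=False)
        with np.errstate(invalid="ignore"):
            x2[b] = np.corrcoef(Xall[i], Xall[j])[0, 1]
    x2 = x2[np.isfinite(x2)]
    score = pdiff_statistic(x1, x2, epsilon=epsilon)
    label = "coherent" if score >= 0.3 else "moderately coherent" if score >= 0.1 else "not coherent"
    return score, label


def association_preservation(
    associations: list[tuple[str, str, str]],
    effector_probs: dict[str, np.ndarray],
    mrna_probs: dict[str, np.ndarray],
    effector_types: dict[str, str],
    alpha: float = 0.05,
) -> tuple[dict[str, tuple[int, int]], int]:
    """Re-test (effector, target, direction) associations in external data.

    Compatible: significant (chi2 p <= alpha) in the discovery direction;
    incompatible: significant in the opposite direction.  Returns per-
    effector (compatible, incompatible) counts plus the number of pairs
    skipped because either side is unmeasured.
    """
    counts: dict[str, tuple[int, int]] = {}
    skipped = 0
    for eff_id, target, direction in associations:
        if eff_id not in effector_probs or target not in mrna_probs:
            skipped += 1
            continue
        ftype = effector_types.get(eff_id, "mRNA")
        comp, incomp = counts.get(eff_id, (0, 0))
        same = pairwise_association(
            Effector(eff_id, ftype, direction, effector_probs[eff_id]),
            target, mrna_probs[target], direction=direction,
        )
        other_dir = "-" if direction == "+" else "+"
        opposite = pairwise_association(
            Effector(eff_id, ftype, other_dir, effector_probs[eff_id]),
            target, mrna_probs[target], direction=other_dir,
        )
        if same.chi2_p <= alpha and same.llr >= opposite.llr:
            comp += 1
        elif opposite.chi2_p <= alpha:
            incomp += 1
        counts[eff_id] = (comp, incomp)
    return counts, skipped


def group_level_association(
    response: pd.Series,
    gene_groups: dict[str, list[str]],
    expression: pd.DataFrame,
) -> dict[str, float]:
    """Mean Pearson correlation between a response profile and each gene
    group's member expressions."""
    r = response.to_numpy(dtype=float)
    if np.std(r) < 1e-12:
        raise ValueError("zero-variance response")
    common = [s for s in response.index if s in expression.columns]
    r = response.loc[common].to_numpy(dtype=float)
    out: dict[str, float] = {}
    for name, genes in gene_groups.items():
        present = [g for g in genes if g in expression.index]
        if not present:
            continue
        cors = []
        for g in present:
            x = expression.loc[g, common].to_numpy(dtype=float)
            if np.std(x) < 1e-12:
                continue
            cors.append(np.corrcoef(r, x)[0, 1])
        if cors:
            out[name] = float(np.mean(cors))
    return out


def tissue_specific_genes(
    expression: pd.DataFrame,
    high_factor: float = 2.0,
    low_factor: float = 0.5,
    floor_fraction: float = 0.25,
) -> dict[str, list[str]]:
    """Genes uniquely expressed in one tissue of a tissue x gene panel.

    ``expression`` is genes x tissues.  The per-gene reference level is
    max(row median, ``floor_fraction`` * row max) — the floor keeps genes
    silent in most tissues from having a zero reference.  A gene is
    assigned to tissue T when its expression there is >= ``high_factor``
    times the reference and every other tissue is <= ``low_factor`` times
    the reference.
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least two tissues")
    out: dict[str, list[str]] = {str(t): [] for t in expression.columns}
    X = expression.to_numpy(dtype=float)
    ref = np.maximum(np.median(X, axis=1), floor_fraction * X.max(axis=1))
    for i, gene in enumerate(expression.index):
        if ref[i] <= 0:
            continue
        hi = X[i] >= high_factor * ref[i]
        lo = X[i] <= low_factor * ref[i]
        if hi.sum() == 1 and (lo | hi).all():
            out[str(expression.columns[int(np.argmax(hi))])].append(str(gene))
    return out
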