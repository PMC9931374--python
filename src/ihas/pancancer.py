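"""Cross-cohort integration of Super Modules.

The membership matrix M counts, for every gene i and Super Module j (cohort
tagged), the number of Association Modules that contain the gene and belong
to the Super Module.  Super Modules are clustered into Super Module Groups
by average-linkage hierarchical clustering on Jaccard similarity of their
gene sets, with a top-down stopping rule driven by shared functional
enrichment signatures over six broad categories (cell cycle, immune
response, cell adhesion, ribosome, respiration, synapse).  Genes are then
assigned binary membership vectors over Super Module Groups via a binomial
null of random module assignment; the most populous distinct vectors define
Gene Groups, which in turn aggregate into three Meta Gene Groups (immune /
inflammatory; development / neurogenesis / adhesion; cell cycle / DNA
repair).  Recurrent Effectors over-occur among a group's Super Modules, and
the integrated view chains over-representation, effector occurrence and
pathway membership matrices into one aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .supermodules import SuperModuleSet

#: default seed categories of the three Meta Gene Groups
META_SEED_CATEGORIES = {
    1: ("immune", "inflammatory"),
    2: ("development", "neurogenesis", "adhesion"),
    3: ("cell_cycle", "dna_repair"),
}

STOPPING_CATEGORIES = (
    "cell_cycle",
    "immune",
    "adhesion",
    "ribosome",
    "respiration",
    "synapse",
)


@dataclass
class EnrichmentRecord:
    gene_set: str
    group: str
    overlap: int
    set_size: int
    group_size: int
    universe: int
    p: float
    q: float = float("nan")


@dataclass
class GroupingResult:
    supermodule_groups: list[list[str]]  # partition of membership columns
    gene_groups: list[tuple[tuple[int, ...], list[str]]]  # (bit pattern, genes)
    meta_gene_groups: dict[int, int | None] = field(default_factory=dict)


def build_membership_matrix(supermodule_sets: list[SuperModuleSet],
                            module_targets: dict[str, set[str]] | None = None
                            ) -> pd.DataFrame:
    """Gene x Super-Module matrix of module-membership counts.

    Entry (i, j) is the number of Association Modules in Super Module j
    whose target set contains gene i.  Columns are tagged
    ``cohort:SM<index>``.  ``module_targets`` maps module ids to target
    sets; when omitted, the per-Super-Module target unions recorded on the
    SuperModuleSet are used with multiplicity from module enumeration.
    """
    if not supermodule_sets:
        raise ValueError("need at least one cohort")
    counts: dict[str, dict[str, int]] = {}
    genes: set[str] = set()
    for sms in supermodule_sets:
        assign = sms.module_assignment()
        for mid, sm_idx in assign.items():
            col = f"{sms.cohort}:SM{sm_idx}"
            if module_targets and mid in module_targets:
                targets = module_targets[mid]
            else:
                targets = sms.supermodule_targets[sm_idx] if sms.supermodule_targets else set()
            colmap = counts.setdefault(col, {})
            for g in targets:
                colmap[g] = colmap.get(g, 0) + 1
                genes.add(g)
    M = pd.DataFrame(0, index=sorted(genes), columns=sorted(counts), dtype=int)
    for col, colmap in counts.items():
        for g, c in colmap.items():
            M.loc[g, col] = c
    return M


def hypergeom_enrichment(
    gene_set: set[str], group: set[str], universe: set[str],
    set_id: str = "set", group_id: str = "group",
) -> EnrichmentRecord:
    """Upper-tail hypergeometric enrichment of ``gene_set`` in ``group``."""
    if not universe:
        raise ValueError("empty universe")
    if not (gene_set <= universe and group <= universe):
        raise ValueError("set and group must be subsets of the universe")
    N, K, n = len(universe), len(gene_set), len(group)
    k = len(gene_set & group)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    return EnrichmentRecord(set_id, group_id, k, K, n, N, min(p, 1.0))


def adjust_fdr(records: list[EnrichmentRecord]) -> list[EnrichmentRecord]:
    """Benjamini-Hochberg adjustment over a batch of enrichment records."""
    if not records:
        return records
    q = multipletests([r.p for r in records], method="fdr_bh")[1]
    for r, qi in zip(records, q):
        r.q = float(max(qi, r.p))
    return records


def _enrichment_signature(
    genes: set[str], category_sets: dict[str, set[str]], universe: set[str],
    alpha: float = 0.05,
) -> tuple[int, ...]:
    recs = [
        hypergeom_enrichment(s & universe, genes, universe, set_id=name)
        for name, s in category_sets.items()
    ]
    adjust_fdr(recs)
    return tuple(int(r.q <= alpha) for r in recs)


def cluster_supermodule_groups(
    M: pd.DataFrame,
    category_sets: dict[str, set[str]],
    alpha: float = 0.05,
    min_jaccard_merge: float = 0.0,
) -> list[list[str]]:
    """Partition membership-matrix columns into Super Module Groups.

    Average-linkage hierarchical clustering on Jaccard similarity of the
    binarized columns, cut top-down: a dendrogram node becomes a group when
    the gene unions of its two branches share the same binary enrichment
    signature over the category sets; otherwise descend.
    """
    cols = list(M.columns)
    if len(cols) < 2:
        return [cols]
    B = (M.to_numpy() >= 1)
    inter = B.T.astype(int) @ B.astype(int)
    sizes = B.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(jac, 1.0)
    dist = squareform(1.0 - jac, checks=False)
    Z = hierarchy.linkage(dist, method="average")
    tree = hierarchy.to_tree(Z)
    universe = set(M.index)

    def genes_of(node) -> set[str]:
        ids = node.pre_order(lambda n: n.id)
        out: set[str] = set()
        for j in ids:
            out.update(M.index[B[:, j]])
        return out

    groups: list[list[str]] = []

    def descend(node) -> None:
        if node.is_leaf():
            groups.append([cols[node.id]])
            return
        sig_l = _enrichment_signature(genes_of(node.left), category_sets, universe, alpha)
        sig_r = _enrichment_signature(genes_of(node.right), category_sets, universe, alpha)
        if sig_l == sig_r:
            groups.append([cols[j] for j in node.pre_order(lambda n: n.id)])
        else:
            descend(node.left)
            descend(node.right)

    descend(tree)
    return groups


def assign_gene_groups(
    M: pd.DataFrame,
    supermodule_groups: list[list[str]],
    alpha_null: float = 0.05,
    min_gg_size: int = 20,
    max_groups: int | None = None,
) -> list[tuple[tuple[int, ...], list[str]]]:
    """Bucket genes by significant Super-Module-Group membership vectors.

    For gene i and group k the count c_ik sums M over the group's columns;
    membership is called when the binomial upper tail P(X >= c_ik) under a
    random-assignment null — each of the group's module memberships lands
    on gene i with probability 1/n_genes — survives BH at ``alpha_null``.
    Buckets of identical nonzero bit vectors are sorted by size; those with
    at least ``min_gg_size`` genes (optionally capped at ``max_groups``)
    become Gene Groups.
    """
    n_genes = M.shape[0]
    bits = np.zeros((n_genes, len(supermodule_groups)), dtype=int)
    pvals, coords = [], []
    for k, cols in enumerate(supermodule_groups):
        sub = M.loc[:, cols].to_numpy()
        c = sub.sum(axis=1)
        n_trials = int(sub.sum())  # total memberships in group k
        p = stats.binom.sf(c - 1, n_trials, 1.0 / n_genes)
        for i in range(n_genes):
            if c[i] > 0:
                pvals.append(float(p[i]))
                coords.append((i, k))
    if pvals:
        reject = multipletests(pvals, alpha=alpha_null, method="fdr_bh")[0]
        for keep, (i, k) in zip(reject, coords):
            if keep:
                bits[i, k] = 1
    buckets: dict[tuple[int, ...], list[str]] = {}
    for i, gene in enumerate(M.index):
        key = tuple(bits[i])
        if any(key):
            buckets.setdefault(key, []).append(gene)
    ranked = sorted(buckets.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    kept = [(pat, genes) for pat, genes in ranked if len(genes) >= min_gg_size]
    if max_groups is not None:
        kept = kept[:max_groups]
    return kept


def binomial_membership_tail(c: int, n_trials: int, rate: float) -> float:
    """Exact binomial upper tail P(X >= c); exposed for oracle checks."""
    if c <= 0:
        return 1.0
    return float(stats.binom.sf(c - 1, n_trials, rate))


def define_meta_gene_groups(
    gene_groups: list[tuple[tuple[int, ...], list[str]]],
    seed_sets: dict[int, dict[str, set[str]]],
    universe: set[str],
    alpha: float = 0.05,
) -> dict[int, int | None]:
    """Assign each Gene Group to the Meta Gene Group (1..3) of its most
    enriched seed category, or None when no seed category reaches q<=alpha.

    ``seed_sets`` maps meta-group index -> {set name -> genes}.
    """
    records: list[EnrichmentRecord] = []
    index: list[tuple[int, int]] = []
    for gi, (_pat, genes) in enumerate(gene_groups):
        for meta, sets in seed_sets.items():
            for name, s in sets.items():
                records.append(
                    hypergeom_enrichment(
                        s & universe, set(genes), universe,
                        set_id=name, group_id=f"GG{gi}",
                    )
                )
                index.append((gi, meta))
    adjust_fdr(records)
    out: dict[int, int | None] = {}
    for gi in range(len(gene_groups)):
        best: tuple[float, int] | None = None
        for rec, (g, meta) in zip(records, index):
            if g == gi and rec.q <= alpha:
                if best is None or rec.q < best[0]:
                    best = (rec.q, meta)
        out[gi] = best[1] if best else None
    return out


def find_recurrent_effectors(
    group_supermodules: list[set[str]],
    all_supermodules: list[set[str]],
    min_count: int = 3,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, int, float]]:
    """Effectors over-occurring among a Super Module Group's Super Modules.

    ``group_supermodules`` / ``all_supermodules`` are per-Super-Module sets
    of signed effector keys (e.g. ``"chr8q:+"``).  Occurrence counts are
    compared with counts from random groups of the same size drawn from all
    Super Modules; p = (k+1)/(B+1).
    """
    rng = rng or np.random.default_rng(0)
    if not group_supermodules:
        raise ValueError("group must contain at least one Super Module")
    m = len(group_supermodules)
    effectors = sorted(set().union(*group_supermodules))
    obs = {e: sum(e in sm for sm in group_supermodules) for e in effectors}
    candidates = [e for e in effectors if obs[e] >= min_count]
    if not candidates:
        return []
    null_counts = {e: 0 for e in candidates}
    n_all = len(all_supermodules)
    for _ in range(n_permutations):
        idx = rng.choice(n_all, size=m, replace=False)
        for e in candidates:
            cnt = sum(e in all_supermodules[i] for i in idx)
            if cnt >= obs[e]:
                null_counts[e] += 1
    out = []
    for e in candidates:
        p = (null_counts[e] + 1) / (n_permutations + 1)
        if p <= alpha:
            out.append((e, obs[e], p))
    out.sort(key=lambda t: (-t[1], t[2], t[0]))
    return out


def build_integrated_view(
    M1: np.ndarray, M2: np.ndarray, M3: np.ndarray
) -> np.ndarray:
    """Aggregate view M4 = M1 . M2 . M3 (per occurrence-sign layer).

    M1: Gene Group x Super Module Group over-representation; M2: Super
    Module Group x effector occurrence counts; M3: effector x pathway
    membership.  Dimension mismatches raise ``ValueError``.
    """
    M1, M2, M3 = (np.asarray(m, dtype=float) for m in (M1, M2, M3))
    if M1.shape[1] != M2.shape[0] or M2.shape[1] != M3.shape[0]:
        raise ValueError("non-conformable matrices")
    return M1 @ M2 @ M3
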