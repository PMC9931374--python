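"""Association Modules and their joint biclustering into Super Modules.

An Association Module collects all targets that share one effector with one
association direction.  The realizable (effector type, direction) grid has
exactly 11 classes: cis-CNV modules are positive only, methylation and
miRNA modules negative only, and trans-CNV, mutation, phosphoprotein and
SNP modules come in both signs.  Trans-CNV and SNP modules must carry a
*regulator* — a gene at the effector locus whose expression mediates the
effector->target associations.

Super Modules and Sample Groups are found by sorting the module-mean
expression matrix with recursive two-way spectral bipartition on both axes
and then cutting the sorted axes at boundaries that are stable across
Gaussian smoothing scales: zero crossings of the second difference of the
axis profiles (the opposite-axis mean and the leading-singular-vector
scores), validated by gradient magnitude at the crossing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .assoc import AssociationModel, Effector, pairwise_association

logger = logging.getLogger(__name__)

#: the realizable (effector type, direction) classes
MODULE_TYPE_GRID = (
    ("cisCNV", "+"),
    ("transCNV", "+"),
    ("transCNV", "-"),
    ("mutation", "+"),
    ("mutation", "-"),
    ("methylation", "-"),
    ("miRNA", "-"),
    ("phospho", "+"),
    ("phospho", "-"),
    ("SNP", "+"),
    ("SNP", "-"),
)

REGULATOR_TYPES = ("transCNV", "SNP")


@dataclass
class AssociationModule:
    effector: str
    ftype: str
    direction: str
    targets: set[str]
    cohort: str
    regulators: list[str] = field(default_factory=list)

    @property
    def module_id(self) -> str:
        return f"{self.cohort}:{self.effector}:{self.direction}"


@dataclass
class PartitionNode:
    """Binary partition-tree node over row (or column) indices."""

    indices: list[int]
    left: "PartitionNode | None" = None
    right: "PartitionNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaves(self) -> list["PartitionNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def order(self) -> list[int]:
        return [i for leaf in self.leaves() for i in leaf.indices]


@dataclass
class SuperModuleSet:
    cohort: str
    module_ids: list[str]  # in sorted (tree) order
    sample_ids: list[str]  # in sorted (tree) order
    module_boundaries: list[int]  # indices where a new Super Module starts
    sample_boundaries: list[int]
    module_tree: PartitionNode | None = None
    sample_tree: PartitionNode | None = None
    supermodule_effectors: list[set[str]] = field(default_factory=list)
    supermodule_targets: list[set[str]] = field(default_factory=list)

    def module_assignment(self) -> dict[str, int]:
        return _assignment(self.module_ids, self.module_boundaries)

    def sample_assignment(self) -> dict[str, int]:
        return _assignment(self.sample_ids, self.sample_boundaries)


def _assignment(ids: list[str], boundaries: list[int]) -> dict[str, int]:
    edges = [0] + sorted(boundaries) + [len(ids)]
    out: dict[str, int] = {}
    for g, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        for i in range(lo, hi):
            out[ids[i]] = g
    return out


def assemble_modules(
    models: list[AssociationModel],
    cohort: str,
    min_module_size: int = 5,
) -> list[AssociationModule]:
    """Group model effectors into per-(effector, direction) modules.

    Effector occurrences whose (type, direction) falls outside the 11-class
    grid are excluded with a warning; modules smaller than
    ``min_module_size`` targets are dropped.
    """
    grid = set(MODULE_TYPE_GRID)
    acc: dict[tuple[str, str, str], AssociationModule] = {}
    for model in models:
        for eff, lam in zip(model.effectors, model.lambdas):
            if lam <= 0:
                continue
            if (eff.ftype, eff.direction) not in grid:
                logger.warning(
                    "effector %s: direction %s not realizable for type %s; skipped",
                    eff.eid, eff.direction, eff.ftype,
                )
                continue
            key = (eff.eid, eff.ftype, eff.direction)
            if key not in acc:
                acc[key] = AssociationModule(
                    effector=eff.eid, ftype=eff.ftype, direction=eff.direction,
                    targets=set(), cohort=cohort,
                )
            acc[key].targets.add(model.target)
    return [m for m in acc.values() if len(m.targets) >= min_module_size]


def attach_regulators(
    module: AssociationModule,
    locus_genes: list[str],
    effector_probs: np.ndarray,
    mrna_probs: dict[str, np.ndarray],
    llr_threshold: float,
    rho_reg: float = 0.3,
) -> AssociationModule | None:
    """Find regulators of a trans-CNV / SNP module.

    A regulator is a gene at the effector locus whose mRNA passes the cis
    screen against the effector (same LLR threshold) and has significant
    same-direction associations with at least ``rho_reg`` of the module's
    targets.  Returns None (module dropped) when no gene qualifies.
    """
    if module.ftype not in REGULATOR_TYPES:
        raise ValueError("regulators apply to trans-CNV and SNP modules only")
    if not locus_genes:
        logger.info("module %s: no expressed genes at locus; dropped", module.module_id)
        return None
    effector = Effector("locus", module.ftype, "+", effector_probs)
    regulators: list[str] = []
    for gene in locus_genes:
        if gene not in mrna_probs:
            continue
        cis = pairwise_association(effector, gene, mrna_probs[gene])
        if cis.llr < llr_threshold:
            continue
        n_ok = 0
        targets = [t for t in module.targets if t in mrna_probs]
        for tgt in targets:
            reg_eff = Effector(gene, "mRNA", module.direction, mrna_probs[gene])
            res = pairwise_association(reg_eff, tgt, mrna_probs[tgt], direction=module.direction)
            if res.llr >= llr_threshold:
                n_ok += 1
        if targets and n_ok / len(targets) >= rho_reg:
            regulators.append(gene)
    if not regulators:
        logger.info("module %s: no regulator found; dropped", module.module_id)
        return None
    module.regulators = regulators
    return module


def module_mean_profiles(
    modules: list[AssociationModule],
    expected_state: pd.DataFrame,
) -> pd.DataFrame:
    """Module x sample matrix of mean expected target states E[y]."""
    rows = {}
    for m in modules:
        targets = [t for t in m.targets if t in expected_state.index]
        if not targets:
            raise KeyError(f"module {m.module_id}: no targets present in expression")
        rows[m.module_id] = expected_state.loc[targets].mean(axis=0)
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# recursive spectral sorting
# ---------------------------------------------------------------------------

def _fiedler_split(sub: np.ndarray) -> np.ndarray | None:
    """Sign split of the second eigenvector of the normalized Laplacian of
    the shifted-correlation similarity graph.  None when no split exists."""
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr, nan=0.0)
    sim = (1.0 + corr) / 2.0
    deg = sim.sum(axis=1)
    if np.any(deg <= 0):
        return None
    d_isqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(sub.shape[0]) - sim * np.outer(d_isqrt, d_isqrt)
    vals, vecs = np.linalg.eigh(lap)
    v2 = vecs[:, 1]
    # orientation fixed by the largest-magnitude component -> invariant to
    # input row permutation (up to exact ties)
    pivot = int(np.argmax(np.abs(v2)))
    if v2[pivot] < 0:
        v2 = -v2
    mask = v2 >= 0
    if mask.all() or (~mask).all():
        return None
    return mask


def _reverse_tree(node: PartitionNode) -> None:
    node.indices.reverse()
    if not node.is_leaf:
        node.left, node.right = node.right, node.left
        _reverse_tree(node.left)
        _reverse_tree(node.right)


def _junction_score(sim: np.ndarray, left: list[int], right: list[int], k: int = 3) -> float:
    a = left[-min(k, len(left)):]
    b = right[: min(k, len(right))]
    return float(sim[np.ix_(a, b)].mean())


def _spectral_recurse(
    matrix: np.ndarray, sim: np.ndarray, indices: list[int], min_split: int
) -> PartitionNode:
    if len(indices) < min_split:
        return PartitionNode(indices=list(indices))
    mask = _fiedler_split(matrix[indices])
    if mask is None:
        return PartitionNode(indices=list(indices))
    left = [i for i, m in zip(indices, mask) if m]
    right = [i for i, m in zip(indices, mask) if not m]
    lnode = _spectral_recurse(matrix, sim, left, min_split)
    rnode = _spectral_recurse(matrix, sim, right, min_split)
    # orient the children so the most similar members meet at the junction;
    # without this, a split that cuts through a true block would leave the
    # block's halves at opposite ends of the ordering
    lo, ro = lnode.order(), rnode.order()
    flip_l = _junction_score(sim, lo[::-1], ro) > _junction_score(sim, lo, ro)
    if flip_l:
        _reverse_tree(lnode)
        lo = lo[::-1]
    if _junction_score(sim, lo, ro[::-1]) > _junction_score(sim, lo, ro):
        _reverse_tree(rnode)
    return PartitionNode(indices=list(indices), left=lnode, right=rnode)


def spectral_sort(
    matrix: np.ndarray, min_split: int = 4
) -> tuple[list[int], list[int], PartitionNode, PartitionNode]:
    """Recursive two-way spectral bipartition of rows and columns.

    Similarity is the shifted Pearson correlation (1 + r) / 2; each node is
    split by the sign pattern of the second eigenvector of the normalized
    graph Laplacian until fewer than ``min_split`` members remain.  Returns
    (row order, column order, row tree, column tree); zero-variance rows or
    columns are placed last.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or not np.all(np.isfinite(matrix)):
        raise ValueError("matrix must be 2-D with finite entries")

    def one_axis(m: np.ndarray) -> tuple[list[int], PartitionNode]:
        live = [i for i in range(m.shape[0]) if np.var(m[i]) > 1e-15]
        dead = [i for i in range(m.shape[0]) if i not in set(live)]
        if dead:
            logger.warning("%d zero-variance rows placed last", len(dead))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(m)
        sim = (1.0 + np.nan_to_num(corr, nan=0.0)) / 2.0
        tree = _spectral_recurse(m, sim, live, min_split)
        order = tree.order() + dead
        if dead:
            tree = PartitionNode(indices=order, left=tree, right=PartitionNode(indices=dead))
        return order, tree

    row_order, row_tree = one_axis(matrix)
    col_order, col_tree = one_axis(matrix.T)
    return row_order, col_order, row_tree, col_tree


# ---------------------------------------------------------------------------
# multiscale boundary detection
# ---------------------------------------------------------------------------

def default_scales(length: int) -> tuple[float, ...]:
    """Geometric smoothing-scale ladder adapted to the axis length.

    Scales span length/64 .. length/8 (floored at 1), so the coarsest
    kernel matches block sizes around an eighth of the axis and fine-scale
    sampling noise is suppressed on long axes.
    """
    return tuple(max(1.0, length / d) for d in (64.0, 32.0, 16.0, 8.0))


def _boundary_profiles(
    sorted_matrix: np.ndarray, axis: int, profiles: tuple[str, ...]
) -> list[np.ndarray]:
    m = sorted_matrix if axis == 0 else sorted_matrix.T
    out: list[np.ndarray] = []
    for kind in profiles:
        if kind == "mean":
            out.append(m.mean(axis=1))
        elif kind == "pc1":
            # leading-singular-vector scores of the row-centred matrix: a
            # data-weighted average over the opposite axis that stays
            # informative when plain row means are all near zero
            centred = m - m.mean(axis=0, keepdims=True)
            if np.linalg.norm(centred) < 1e-12:
                continue
            u, s, _ = np.linalg.svd(centred, full_matrices=False)
            out.append(u[:, 0] * s[0])
        else:
            raise ValueError(f"unknown profile kind {kind!r}")
    return out


def _profile_boundaries(
    profile: np.ndarray,
    scales: tuple[float, ...],
    scale_fraction: float,
    noise_floor: float,
) -> list[int]:
    L = profile.shape[0]
    per_scale: list[list[int]] = []
    for sigma in scales:
        smooth = gaussian_filter1d(profile, sigma, mode="nearest")
        d1 = np.gradient(smooth)
        d2 = np.diff(smooth, 2)  # d2[i] ~ second derivative at i+1
        found: list[int] = []
        slope_max = float(np.max(np.abs(d1))) if d1.size else 0.0
        floor = max(1e-8, noise_floor * slope_max)
        for i in range(d2.size - 1):
            if d2[i] == 0.0 or d2[i] * d2[i + 1] >= 0:
                continue
            # Marr-Hildreth style validation: a genuine block edge is a
            # zero crossing of the second derivative AT a gradient-
            # magnitude peak; spurious crossings (noise wiggles, midpoints
            # between two distant same-direction edges) have near-zero
            # slope at the crossing
            if max(abs(d1[i + 1]), abs(d1[i + 2])) < floor:
                continue
            # linear interpolation of the crossing between profile positions
            # i+1 and i+2; the new block starts at the ceiling
            t = (i + 1) + abs(d2[i]) / (abs(d2[i]) + abs(d2[i + 1]))
            b = int(np.floor(t)) + 1
            if 0 < b < L:
                found.append(b)
        per_scale.append(sorted(set(found)))
    # consensus across scales: cluster candidate positions within +-1
    events = sorted(
        (pos, si) for si, positions in enumerate(per_scale) for pos in positions
    )
    need = int(np.ceil(scale_fraction * len(scales)))
    boundaries: list[int] = []
    cluster: list[tuple[int, int]] = []
    for ev in events + [(10**9, -1)]:
        if cluster and ev[0] - cluster[-1][0] > 1:
            if len({si for _, si in cluster}) >= need:
                boundaries.append(int(round(float(np.median([p for p, _ in cluster])))))
            cluster = []
        if ev[1] >= 0:
            cluster.append(ev)
    return sorted(set(boundaries))


def detect_boundaries(
    sorted_matrix: np.ndarray,
    scales: tuple[float, ...] | None = None,
    axis: int = 0,
    scale_fraction: float = 0.75,
    noise_floor: float = 0.2,
    profiles: tuple[str, ...] = ("mean", "pc1"),
) -> list[int]:
    """Block boundaries of a sorted matrix along one axis.

    Each 1-D profile of the axis (the mean over the opposite axis, and the
    leading-singular-vector score profile) is smoothed with Gaussian
    kernels at every scale (default: ladder adapted to the axis length);
    boundaries are zero crossings of the discrete second difference whose
    amplitude exceeds ``noise_floor`` times the largest amplitude at that
    scale.  A boundary is kept when it recurs (within +-1 index) in at
    least ``scale_fraction`` of the scales of some profile; boundaries
    from different profiles within +-1 of each other are merged.  Returned
    indices b mean "a new block starts at position b".
    """
    sorted_matrix = np.asarray(sorted_matrix, dtype=float)
    L = sorted_matrix.shape[axis]
    if L < 2:
        return []
    if scales is None:
        scales = default_scales(L)
    merged: list[int] = []
    for profile in _boundary_profiles(sorted_matrix, axis, profiles):
        for b in _profile_boundaries(profile, scales, scale_fraction, noise_floor):
            if all(abs(b - o) > 1 for o in merged):
                merged.append(b)
    return sorted(merged)


def build_supermodules_samplegroups(
    modules: list[AssociationModule],
    expected_state: pd.DataFrame,
    min_split: int = 4,
    scales: tuple[float, ...] | None = None,
    scale_fraction: float = 0.75,
) -> SuperModuleSet:
    """Joint partition of modules and samples.

    Composes :func:`module_mean_profiles`, :func:`spectral_sort` and
    :func:`detect_boundaries` on both axes and records the per-Super-Module
    effector and target unions.
    """
    if len(modules) < 2:
        if not modules:
            raise ValueError("need at least one module")
        m = modules[0]
        return SuperModuleSet(
            cohort=m.cohort,
            module_ids=[m.module_id],
            sample_ids=list(expected_state.columns),
            module_boundaries=[],
            sample_boundaries=[],
            supermodule_effectors=[{m.effector}],
            supermodule_targets=[set(m.targets)],
        )
    profiles = module_mean_profiles(modules, expected_state)
    row_order, col_order, row_tree, col_tree = spectral_sort(profiles.to_numpy(), min_split)
    sorted_mat = profiles.to_numpy()[np.ix_(row_order, col_order)]
    mod_bounds = detect_boundaries(sorted_mat, scales, axis=0, scale_fraction=scale_fraction)
    smp_bounds = detect_boundaries(sorted_mat, scales, axis=1, scale_fraction=scale_fraction)
    module_ids = [profiles.index[i] for i in row_order]
    sample_ids = [profiles.columns[j] for j in col_order]
    sms = SuperModuleSet(
        cohort=modules[0].cohort,
        module_ids=module_ids,
        sample_ids=sample_ids,
        module_boundaries=mod_bounds,
        sample_boundaries=smp_bounds,
        module_tree=row_tree,
        sample_tree=col_tree,
    )
    by_id = {m.module_id: m for m in modules}
    assign = sms.module_assignment()
    n_sm = max(assign.values()) + 1 if assign else 0
    effs: list[set[str]] = [set() for _ in range(n_sm)]
    tgts: list[set[str]] = [set() for _ in range(n_sm)]
    for mid, g in assign.items():
        effs[g].add(by_id[mid].effector)
        tgts[g].update(by_id[mid].targets)
    sms.supermodule_effectors = effs
    sms.supermodule_targets = tgts
    return sms
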