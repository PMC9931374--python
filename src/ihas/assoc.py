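"""Exponential-family association models of gene expression.

A target gene's trinary expression state y is tied to effector alteration
states x through

    p(y | x) = exp( sum_i lambda_i f_i(x_i) y ) / Z(f(x)),  lambda_i >= 0,

where f_i is the effector's feature function (signed by the association
direction) and Z the trinary normalizer.  Because both y and x are observed
only through quantization posteriors, fitting maximizes the *expected*
log-likelihood under those posteriors: with at most ``ENUM_LIMIT`` effectors
the expectation over joint effector states is enumerated exactly, above that
a mean-field plug-in of expected features is used.  The expected
log-likelihood is concave in lambda, so a bound-constrained quasi-Newton
solve with an analytic gradient is reliable.

Model building follows a screen-prioritize-select scheme: pairwise
associations with an FDR-calibrated log-likelihood-ratio threshold, ranking
of surviving candidates by network distance then effector type, and a
stepwise loop that accepts a candidate only when the augmented model beats
both the current model and the candidate-alone model in chi-square and
permutation nested tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import optimize, stats

ENUM_LIMIT = 6  # exact enumeration of joint effector states up to this many
MAX_EFFECTORS = 20

#: feature-function values per state-axis position, before direction sign
_FEATURE_VALUES = {
    "mutation": np.array([0.0, 1.0, 1.0]),  # non-silent indicator on codes 0/1/2
    "SNP": np.array([-1.0, 0.0, 1.0]),  # additive coding, genotype - 1
}
_TRINARY = np.array([-1.0, 0.0, 1.0])

#: types whose module-level association direction is fixed
FIXED_DIRECTION = {"cisCNV": "+", "methylation": "-", "miRNA": "-"}

#: priority of effector types at equal network distance (CNV first)
TYPE_RANK = {
    "cisCNV": 0,
    "transCNV": 0,
    "mutation": 1,
    "methylation": 2,
    "miRNA": 3,
    "phospho": 4,
    "SNP": 5,
}

_STATE_VALUES = _TRINARY  # y axis


@dataclass
class Effector:
    """One candidate effector column: id, type, direction and posteriors."""

    eid: str
    ftype: str
    direction: str  # '+' or '-'
    probs: np.ndarray  # (n_samples, 3) state posteriors

    def feature_values(self) -> np.ndarray:
        base = _FEATURE_VALUES.get(self.ftype, _TRINARY)
        return base if self.direction == "+" else -base

    def expected_feature(self) -> np.ndarray:
        return self.probs @ self.feature_values()


@dataclass
class AssociationModel:
    target: str
    effectors: list[Effector]
    lambdas: np.ndarray
    log_likelihood: float
    converged: bool = True

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if np.any(self.lambdas < -1e-12):
            raise ValueError("association weights must be nonnegative")
        ids = [e.eid for e in self.effectors]
        if len(set(ids)) != len(ids):
            raise ValueError("effectors must be distinct")

    def to_record(self) -> dict:
        return {
            "target": self.target,
            "effectors": [
                [e.eid, e.ftype, e.direction, float(l)]
                for e, l in zip(self.effectors, self.lambdas)
            ],
            "loglik": float(self.log_likelihood),
        }


@dataclass
class ModelComparison:
    llr: float
    df: int
    chi2_p: float
    perm_p: float | None = None


@dataclass
class PairResult:
    llr: float
    chi2_p: float
    direction: str
    lam: float
    degenerate: bool = False


@dataclass
class CandidateRanking:
    target: str
    candidates: list[tuple[Effector, float, int, float]] = field(default_factory=list)
    # entries: (effector, network distance, type rank, pairwise llr)

    def ordered(self) -> list[Effector]:
        return [c[0] for c in self.candidates]


def _log_z(eta: np.ndarray) -> np.ndarray:
    # log(e^-eta + 1 + e^eta), overflow-safe
    m = np.abs(eta)
    return m + np.log1p(np.exp(-2.0 * m) + np.exp(-m))


def _mean_y(eta: np.ndarray) -> np.ndarray:
    # d log Z / d eta = (e^eta - e^-eta) / Z
    m = np.abs(eta)
    num = np.sign(eta) * (1.0 - np.exp(-2.0 * m))
    return num / (np.exp(-2.0 * m) + np.exp(-m) + 1.0)


def _joint_grid(effectors: list[Effector], ybar: np.ndarray):
    """Exact-enumeration sufficient statistics.

    Returns (F, a, b): F[g, i] the signed feature value of effector i in
    joint state g; a[g] = sum_s P_s(g) * E[y_s]; b[g] = sum_s P_s(g).  The
    expected log-likelihood is then a @ (F lam) - b @ logZ(F lam), so the
    optimization cost no longer depends on the number of samples.
    """
    k = len(effectors)
    states = np.array(list(itertools.product(range(3), repeat=k)), dtype=int)
    F = np.column_stack(
        [eff.feature_values()[states[:, i]] for i, eff in enumerate(effectors)]
    )
    P = np.ones((ybar.shape[0], states.shape[0]))
    for i, eff in enumerate(effectors):
        P *= eff.probs[:, states[:, i]]
    return F, P.T @ ybar, P.sum(axis=0)


def _maximize(F: np.ndarray, a: np.ndarray, b: np.ndarray, lam0: np.ndarray):
    """Maximize a@(F lam) - b@logZ(F lam) over lam >= 0 (concave)."""

    def neg(lam):
        eta = F @ lam
        val = a @ eta - b @ _log_z(eta)
        grad = F.T @ (a - b * _mean_y(eta))
        return -val, -grad

    if F.shape[1] == 0:
        return lam0, float(-(b @ _log_z(np.zeros(F.shape[0])))), True
    if F.shape[1] == 1:
        return _maximize_1d(F[:, 0], a, b)
    res = optimize.minimize(
        neg,
        lam0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * F.shape[1],
        options={"maxiter": 500, "gtol": 1e-6},
    )
    return res.x, float(-res.fun), bool(res.success)


def _maximize_1d(f: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Newton solve of the concave 1-D problem max_{lam>=0} a@(f lam) - b@logZ."""

    def grad(lam: float) -> float:
        return float(f @ (a - b * _mean_y(f * lam)))

    def value(lam: float) -> float:
        return float(a @ (f * lam) - b @ _log_z(f * lam))

    if grad(0.0) <= 0.0:  # maximum at the nonnegativity boundary
        return np.zeros(1), value(0.0), True
    lam = 0.5
    for _ in range(100):
        g = grad(lam)
        if abs(g) < 1e-9:
            return np.array([lam]), value(lam), True
        # curvature of the expected log-likelihood
        eta = f * lam
        m = _mean_y(eta)
        ey2 = (np.exp(eta) + np.exp(-eta)) / (np.exp(eta) + np.exp(-eta) + 1.0)
        h = float(-(f**2) @ (b * (ey2 - m**2)))
        step = -g / h if h < 0 else g
        new = lam + step
        if new <= 0:
            new = lam / 2.0
        if new > 50.0:
            new = 50.0
        if abs(new - lam) < 1e-12:
            return np.array([lam]), value(lam), True
        lam = new
    return np.array([lam]), value(lam), False


def fit_exponential_model(
    target: str,
    target_probs: np.ndarray,
    effectors: list[Effector],
    lam0: np.ndarray | None = None,
) -> AssociationModel:
    """Maximum expected-log-likelihood fit of the association model.

    With no effectors the expected log-likelihood is n*log(1/3) (uniform
    trinary null).  Non-convergence is flagged on the returned model rather
    than raised.
    """
    if len(effectors) > MAX_EFFECTORS:
        raise ValueError(f"at most {MAX_EFFECTORS} effectors supported")
    target_probs = np.asarray(target_probs, dtype=float)
    n = target_probs.shape[0]
    ybar = target_probs @ _STATE_VALUES
    if not effectors:
        return AssociationModel(target, [], np.zeros(0), float(n * np.log(1.0 / 3.0)))
    lam0 = np.zeros(len(effectors)) if lam0 is None else np.asarray(lam0, dtype=float)
    if len(effectors) <= ENUM_LIMIT:
        F, a, b = _joint_grid(effectors, ybar)
    else:  # mean-field plug-in of expected features, one row per sample
        F = np.column_stack([e.expected_feature() for e in effectors])
        a, b = ybar, np.ones(n)
    lam, loglik, ok = _maximize(F, a, b, lam0)
    lam = np.clip(lam, 0.0, None)
    return AssociationModel(target, list(effectors), lam, loglik, converged=ok)


def _chi2_boundary_p(llr: float, df: int) -> float:
    """Upper-tail p for the LLR with nonnegativity-constrained weights.

    For a single added weight the null reference is the 50:50 mixture of a
    point mass at zero and chi-square(1); for several added weights the
    plain chi-square(df) tail is used (conservative), with the permutation
    p-value as the safeguard.
    """
    if llr <= 0:
        return 1.0
    if df == 1:
        return float(0.5 * stats.chi2.sf(llr, 1))
    return float(stats.chi2.sf(llr, df))


def _pair_fit(effector: Effector, target: str, target_probs: np.ndarray) -> tuple[float, float]:
    model = fit_exponential_model(target, target_probs, [effector])
    null_ll = target_probs.shape[0] * np.log(1.0 / 3.0)
    llr = max(0.0, 2.0 * (model.log_likelihood - null_ll))
    return llr, float(model.lambdas[0])


def pairwise_association(
    effector: Effector,
    target: str,
    target_probs: np.ndarray,
    direction: str | None = None,
) -> PairResult:
    """One-effector LLR screen against the empty (uniform trinary) model.

    When ``direction`` is None, directionally fixed types (cis-CNV +,
    methylation -, miRNA -) are fit in their fixed direction only; other
    types are fit in both directions and the better one kept.  A constant
    effector column is flagged degenerate with llr = 0.
    """
    target_probs = np.asarray(target_probs, dtype=float)
    if target_probs.shape[0] < 20:
        raise ValueError("pairwise screen requires >= 20 samples")
    ef = effector.expected_feature()
    if float(np.var(ef)) < 1e-12:
        return PairResult(0.0, 1.0, effector.direction, 0.0, degenerate=True)
    if direction is None:
        directions = [FIXED_DIRECTION[effector.ftype]] if effector.ftype in FIXED_DIRECTION \
            else ["+", "-"]
    else:
        directions = [direction]
    best: PairResult | None = None
    for d in directions:
        eff = Effector(effector.eid, effector.ftype, d, effector.probs)
        llr, lam = _pair_fit(eff, target, target_probs)
        # a single fixed direction is a boundary (one-sided) test; trying
        # both directions restores the two-sided chi-square(1) reference
        p = _chi2_boundary_p(llr, 1) if len(directions) == 1 else float(stats.chi2.sf(llr, 1)) if llr > 0 else 1.0
        res = PairResult(llr, p, d, lam)
        if best is None or res.llr > best.llr:
            best = res
    return best


def calibrate_thresholds(
    observed_llrs: np.ndarray,
    permuted_llrs: np.ndarray,
    target_fdr: float = 0.05,
    n_permutations: int = 1,
) -> float:
    """Smallest LLR threshold whose estimated FDR is at most ``target_fdr``.

    FDR(t) = ((total permuted count >= t) + 1) / n_permutations / (observed
    count >= t); the add-one smoothing keeps the estimate away from an
    unstable zero in the extreme tail, where otherwise the single largest
    observed statistic would always be declared a discovery under the null.
    Returns +inf when no threshold attains the target.
    """
    observed = np.sort(np.asarray(observed_llrs, dtype=float))
    permuted = np.sort(np.asarray(permuted_llrs, dtype=float))
    if observed.size == 0 or permuted.size == 0:
        raise ValueError("empty LLR inputs")
    for t in observed:
        n_obs = observed.size - np.searchsorted(observed, t, side="left")
        n_perm = (permuted.size - np.searchsorted(permuted, t, side="left") + 1) / n_permutations
        if n_obs > 0 and n_perm / n_obs <= target_fdr:
            return float(t)
    return float("inf")


def prioritize_effectors(
    target: str,
    candidates: list[tuple[Effector, float]],
    network: nx.DiGraph | None,
    anchors: dict[str, str] | None = None,
) -> CandidateRanking:
    """Rank screened candidates by (network distance, type, pairwise LLR).

    ``candidates`` are (effector, pairwise llr) pairs that passed the
    threshold.  Distance is the unweighted shortest path from the effector's
    anchor node to the target (a cis-CNV anchored at the target itself has
    distance 0); unmapped or unreachable candidates rank after all
    reachable ones.  Ties break by the fixed type order (CNV > mutation >
    methylation > miRNA > phosphorylation > SNP), then LLR descending.
    """
    anchors = anchors or {}
    entries = []
    for eff, llr in candidates:
        anchor = anchors.get(eff.eid, eff.eid)
        if network is None:
            dist = 1.0
        elif anchor == target:
            dist = 0.0
        elif anchor in network and target in network:
            try:
                dist = float(nx.shortest_path_length(network, anchor, target))
            except nx.NetworkXNoPath:
                dist = np.inf
        else:
            dist = np.inf
        entries.append((eff, dist, TYPE_RANK.get(eff.ftype, 99), float(llr)))
    entries.sort(key=lambda c: (c[1], c[2], -c[3]))
    return CandidateRanking(target=target, candidates=entries)


def nested_model_test(
    model_small: AssociationModel,
    model_large: AssociationModel,
    target_probs: np.ndarray,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
    alpha_skip: float | None = None,
) -> ModelComparison:
    """Chi-square and permutation nested-model test.

    The added effector columns of the larger model are each independently
    permuted across samples and the larger model refit; perm_p is the
    add-one-smoothed fraction of permuted LLRs meeting the observed one.
    When ``alpha_skip`` is given and the chi-square p already exceeds it the
    permutations are skipped (the candidate is rejected either way).
    """
    small_ids = {e.eid for e in model_small.effectors}
    added = [e for e in model_large.effectors if e.eid not in small_ids]
    if not {e.eid for e in model_large.effectors} >= small_ids:
        raise ValueError("model_small effectors must nest within model_large")
    df = len(added)
    if df == 0:
        raise ValueError("nested test requires at least one added parameter")
    llr = max(0.0, 2.0 * (model_large.log_likelihood - model_small.log_likelihood))
    chi2_p = _chi2_boundary_p(llr, df)
    cmp = ModelComparison(llr=llr, df=df, chi2_p=chi2_p)
    if n_permutations <= 0:
        return cmp
    if alpha_skip is not None and chi2_p > alpha_skip:
        return cmp
    rng = rng or np.random.default_rng(0)
    n = target_probs.shape[0]
    kept = [e for e in model_large.effectors if e.eid in small_ids]
    exceed = 0
    for _ in range(n_permutations):
        perm_effs = kept + [
            Effector(e.eid, e.ftype, e.direction, e.probs[rng.permutation(n)])
            for e in added
        ]
        fit = fit_exponential_model(model_large.target, target_probs, perm_effs)
        perm_llr = 2.0 * (fit.log_likelihood - model_small.log_likelihood)
        if perm_llr >= llr - 1e-9:
            exceed += 1
    cmp.perm_p = (exceed + 1) / (n_permutations + 1)
    return cmp


def stepwise_build_model(
    target: str,
    target_probs: np.ndarray,
    ranking: CandidateRanking,
    alpha: float = 0.05,
    n_permutations: int = 200,
    max_effectors: int = MAX_EFFECTORS,
    rng: np.random.Generator | None = None,
) -> AssociationModel:
    """Stepwise effector selection under double nested testing.

    Starting from the empty model, candidates are traversed in rank order;
    a candidate joins the model only when the augmented model M2 beats both
    the current model M1 and the candidate-alone model M1' with chi-square
    AND permutation p-values at most ``alpha``.
    """
    rng = rng or np.random.default_rng(0)

    def passes(cmp: ModelComparison) -> bool:
        # the single accept/reject predicate: both the asymptotic and the
        # permutation p-value must clear alpha (a skipped permutation run
        # counts as a failure unless permutations are disabled altogether)
        if cmp.chi2_p > alpha:
            return False
        if n_permutations <= 0:
            return True
        return cmp.perm_p is not None and cmp.perm_p <= alpha

    current = fit_exponential_model(target, target_probs, [])
    for eff in ranking.ordered():
        if len(current.effectors) >= max_effectors:
            break
        m2 = fit_exponential_model(
            target, target_probs, current.effectors + [eff],
            lam0=np.append(current.lambdas, 0.0),
        )
        if not passes(
            nested_model_test(current, m2, target_probs, n_permutations, rng, alpha_skip=alpha)
        ):
            continue
        if current.effectors:
            m1p = fit_exponential_model(target, target_probs, [eff])
            if not passes(
                nested_model_test(m1p, m2, target_probs, n_permutations, rng, alpha_skip=alpha)
            ):
                continue
        current = m2
    return current
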