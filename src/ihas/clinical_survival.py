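"""Alignment of sample groupings with clinical phenotypes and survival.

Clinical alignment uses concentration coefficients — the fraction of
samples carrying their group's dominant categorical value — against
permutation baselines, and codes each Sample Group by the binary high/low
expression states of the three Meta Gene Groups (eight Pan-cancer Sample
Group codes).  Survival alignment computes per-gene univariate Cox
log-hazard coefficients, summarizes the deviation between coefficient
distributions with the p_diff statistic

    p_diff = Pr(X1 > X2 + eps) - Pr(X1 < X2 - eps),

and compares Kaplan-Meier curves of sample groups with the k-group
log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sksurv.linear_model import CoxPHSurvivalAnalysis


@dataclass
class GeneSurvivalStat:
    gene: str
    cox_beta: float
    se: float
    n_events: int
    converged: bool = True


def filter_clinical_features(
    clinical: pd.DataFrame,
    n_samples: int,
    min_fraction: float = 0.25,
    max_categories: int = 20,
) -> list[str]:
    """Retain categorical features with enough non-missing values.

    A feature is kept when it is non-missing in at least ``min_fraction``
    of the cohort, has at least 2 distinct values, and is categorical: a
    feature whose values all parse as numbers with more than
    ``max_categories`` distinct values is treated as continuous and
    dropped.
    """
    keep: list[str] = []
    for feature, sub in clinical.groupby("feature"):
        values = sub["value"].dropna()
        values = values[values.astype(str).str.strip() != ""]
        if len(values) < min_fraction * n_samples:
            continue
        distinct = values.astype(str).unique()
        if len(distinct) < 2:
            continue
        try:
            [float(v) for v in distinct]
            numeric = True
        except ValueError:
            numeric = False
        if numeric and len(distinct) > max_categories:
            continue
        keep.append(str(feature))
    return keep


def crosstab_groups_labels(groups: dict[str, int], labels: dict[str, str]) -> pd.DataFrame:
    """Group x label-value count table over samples present in both maps."""
    common = sorted(set(groups) & set(labels))
    if not common:
        raise ValueError("no labelled samples")
    return pd.crosstab(
        pd.Series({s: groups[s] for s in common}, name="group"),
        pd.Series({s: labels[s] for s in common}, name="value"),
    )


def concentration_coefficient(crosstab: pd.DataFrame) -> float:
    """Fraction of samples possessing their group's dominant value:
    cc = sum_g max_v n_{g,v} / sum_g n_g."""
    counts = crosstab.to_numpy()
    total = counts.sum()
    if total == 0:
        raise ValueError("no labelled samples in any group")
    return float(counts.max(axis=1).sum() / total)


def permutation_concentration_baseline(
    groups: dict[str, int],
    labels: dict[str, str],
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null distribution of cc under random label-to-sample permutation."""
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = rng or np.random.default_rng(0)
    common = sorted(set(groups) & set(labels))
    g = np.array([groups[s] for s in common])
    lab = np.array([labels[s] for s in common])
    out = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = lab[rng.permutation(len(lab))]
        df = pd.crosstab(pd.Series(g), pd.Series(perm))
        out[b] = concentration_coefficient(df)
    return out


def assign_pancancer_sample_groups(mean_expression: pd.DataFrame) -> pd.Series:
    """Code 0..7 per Sample Group from the binary expression states of the
    three Meta Gene Groups.

    ``mean_expression`` is Sample Groups x 3 Meta-Gene-Group columns (in
    Meta Gene Group order 1, 2, 3).  Each column is binarized high/low
    against its cross-Sample-Group median; the code is
    4*b(MGG1) + 2*b(MGG2) + b(MGG3).
    """
    if mean_expression.shape[1] != 3:
        raise ValueError("expect exactly three Meta Gene Group columns")
    bits = (mean_expression > mean_expression.median(axis=0)).astype(int)
    code = 4 * bits.iloc[:, 0] + 2 * bits.iloc[:, 1] + bits.iloc[:, 2]
    return code.rename("pancancer_group")


def cox_coefficients(
    expression: pd.DataFrame, survival: pd.DataFrame
) -> list[GeneSurvivalStat]:
    """Univariate Cox proportional-hazards coefficient per gene.

    ``expression`` is genes x samples; ``survival`` has columns ``sample,
    time_days, event``.  Breslow tie handling; genes whose fit fails are
    returned flagged with NaN coefficients.
    """
    surv = survival.set_index("sample").loc[
        [s for s in expression.columns if s in set(survival["sample"])]
    ]
    n_events = int(surv["event"].sum())
    if n_events < 2:
        raise ValueError("need at least two events")
    y = np.array(
        [(bool(e), float(t)) for e, t in zip(surv["event"], surv["time_days"])],
        dtype=[("event", "?"), ("time", "<f8")],
    )
    out: list[GeneSurvivalStat] = []
    for gene, row in expression.iterrows():
        x = row.loc[surv.index].to_numpy(dtype=float)[:, None]
        try:
            model = CoxPHSurvivalAnalysis(ties="breslow").fit(x, y)
            beta = float(model.coef_[0])
            # observed-information standard error at the fit
            se = _cox_se(x[:, 0], surv["time_days"].to_numpy(), surv["event"].to_numpy(), beta)
            out.append(GeneSurvivalStat(str(gene), beta, se, n_events))
        except Exception:
            out.append(GeneSurvivalStat(str(gene), float("nan"), float("nan"), n_events, False))
    return out


def _cox_breslow_loglik(x: np.ndarray, time: np.ndarray, event: np.ndarray, beta: float):
    """Breslow partial log-likelihood and derivatives for one covariate."""
    order = np.argsort(time)
    x, time, event = x[order], time[order], event[order]
    eta = beta * x
    # risk set of subject i: times >= time_i
    ll = d1 = d2 = 0.0
    exp_eta = np.exp(eta)
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        dead = (time == t) & (event == 1)
        s0 = exp_eta[at_risk].sum()
        s1 = (x[at_risk] * exp_eta[at_risk]).sum()
        s2 = (x[at_risk] ** 2 * exp_eta[at_risk]).sum()
        d = dead.sum()
        ll += eta[dead].sum() - d * np.log(s0)
        d1 += x[dead].sum() - d * s1 / s0
        d2 += -d * (s2 / s0 - (s1 / s0) ** 2)
    return ll, d1, d2


def _cox_se(x: np.ndarray, time: np.ndarray, event: np.ndarray, beta: float) -> float:
    _, _, d2 = _cox_breslow_loglik(x, time, event, beta)
    return float(1.0 / np.sqrt(-d2)) if d2 < 0 else float("inf")


def pdiff_statistic(
    x1: np.ndarray,
    x2: np.ndarray,
    epsilon: float | None = None,
    max_pairs: int = 10_000_000,
    seed: int = 0,
) -> float:
    """Signed deviation between two empirical distributions.

    Exact all-cross-pairs evaluation of Pr(X1 > X2 + eps) - Pr(X1 < X2 -
    eps); when |X1|*|X2| exceeds ``max_pairs`` both samples are subsampled
    with a fixed seed.  ``epsilon`` defaults to 0.1 times the standard
    deviation of the background sample ``x2``.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x1 = x1[np.isfinite(x1)]
    x2 = x2[np.isfinite(x2)]
    if x1.size == 0 or x2.size == 0:
        raise ValueError("both samples must be nonempty")
    if epsilon is None:
        epsilon = 0.1 * float(np.std(x2))
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    if x1.size * x2.size > max_pairs:
        rng = np.random.default_rng(seed)
        k = int(np.sqrt(max_pairs))
        if x1.size > k:
            x1 = rng.choice(x1, k, replace=False)
        if x2.size > k:
            x2 = rng.choice(x2, k, replace=False)
    s2 = np.sort(x2)
    n = x1.size * x2.size
    # count pairs with x1 > x2 + eps  <=>  x2 < x1 - eps
    greater = np.searchsorted(s2, x1 - epsilon, side="left").sum()
    # pairs with x1 < x2 - eps  <=>  x2 > x1 + eps
    smaller = (x2.size - np.searchsorted(s2, x1 + epsilon, side="right")).sum()
    return float((greater - smaller) / n)


def logrank_sample_groups(
    survival: pd.DataFrame, groups: dict[str, int]
) -> tuple[float, float, dict[int, pd.DataFrame]]:
    """k-group log-rank test plus per-group Kaplan-Meier step functions.

    Returns (chi2 statistic, p, {group: KM table with columns time and
    survival}).  Requires at least two groups with at least one event.
    """
    df = survival[survival["sample"].isin(groups)].copy()
    df["group"] = df["sample"].map(groups)
    events_per_group = df.groupby("group")["event"].sum()
    if (events_per_group > 0).sum() < 2:
        raise ValueError("need >= 2 groups with at least one event")
    res = multivariate_logrank_test(df["time_days"], df["group"], df["event"])
    curves: dict[int, pd.DataFrame] = {}
    for g, sub in df.groupby("group"):
        km = KaplanMeierFitter().fit(sub["time_days"], sub["event"])
        sf = km.survival_function_
        curves[int(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return float(res.test_statistic), float(res.p_value), curves
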