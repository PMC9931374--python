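"""Synthetic multi-omics cohorts with planted hierarchical association structure.

The generator emulates the statistical shape of a tumour cohort as seen by
the pipeline: continuous measurements are noisy emissions of discrete hidden
states; sparse effector alterations (CNV, mutation, methylation, miRNA,
phosphoprotein, SNP) drive the hidden expression states of planted target
genes through the exponential-family association law

    p(y | x) = exp(sum_i lambda_i f_i(x_i) y) / Z(f(x)),   lambda_i >= 0,

with y in {-1, 0, +1}; background genes follow a block design in which gene
groups switch on/off across sample groups (a nested "staircase" of
activation patterns, which gives distinct group-mean levels on both axes);
survival times follow a proportional-hazards model on gene-group activities;
categorical clinical labels concentrate within sample groups; and a directed
interaction network contains every planted effector->(regulator->)target
path among random decoy edges.

Every draw is controlled by a single integer seed, and a ground-truth
manifest records what was planted so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io

#: omics layers generated for every cohort
EFFECTOR_TYPES = ("cisCNV", "transCNV", "mutation", "methylation", "miRNA", "phospho", "SNP")

#: legal (type, direction) pairs used when planting effectors
PLANT_CYCLE = (
    ("cisCNV", "+"),
    ("mutation", "+"),
    ("methylation", "-"),
    ("transCNV", "+"),
    ("miRNA", "-"),
    ("SNP", "+"),
    ("phospho", "+"),
)


@dataclass
class SimulationConfig:
    """Study conditions of one synthetic multi-cohort experiment."""

    seed: int = 0
    n_cohorts: int = 2
    samples_per_cohort: int = 200
    n_genes: int = 300
    n_effectors_per_type: dict[str, int] = field(
        default_factory=lambda: {t: 5 for t in EFFECTOR_TYPES}
    )
    planted_lambda: float = 1.5
    n_gene_groups: int = 4
    n_sample_groups: int = 3
    alteration_rate: float = 0.25
    #: fraction of an effector's alteration events concentrated in its
    #: "active" sample group (germline SNPs stay uniform); this is what
    #: makes modules informative about Sample Groups, since somatic
    #: alteration frequencies differ between molecular subtypes
    alteration_concentration: float = 0.6
    hazard_betas: dict[int, float] = field(
        default_factory=lambda: {0: 1.0, 1: 0.0, 2: -1.0, 3: 0.0}
    )
    censoring_rate: float = 0.3
    clinical_concentration: float = 0.8
    network_decoy_edges: int = 200
    # generator internals
    n_planted_targets: int = 8
    effectors_per_target: int = 3
    emission_scale: float = 1.0
    emission_sigma: float = 0.5
    state_flip_rate: float = 0.1
    block_amplitude: float = 1.0
    snp_maf: float = 0.3
    baseline_hazard: float = 1.0 / 1000.0

    def validate(self) -> None:
        counts = [
            self.n_cohorts,
            self.samples_per_cohort,
            self.n_genes,
            self.n_gene_groups,
            self.n_sample_groups,
            *self.n_effectors_per_type.values(),
        ]
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        for p in (self.alteration_rate, self.censoring_rate, self.clinical_concentration):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.planted_lambda < 0:
            raise ValueError("planted_lambda must be >= 0")
        if self.n_genes < self.n_gene_groups:
            raise ValueError("n_genes must be >= n_gene_groups")


@dataclass
class PlantedModel:
    target: str
    effectors: list[tuple[str, str, str, float]]  # (effector id, type, direction, lambda)


@dataclass
class GroundTruthManifest:
    cohort_id: str
    planted_models: list[PlantedModel]
    true_sample_group: dict[str, int]
    true_gene_group: dict[str, int]
    true_paths: list[list[str]]
    regulators: dict[str, str]  # effector id -> regulator gene
    effector_anchor: dict[str, str]  # effector id -> anchor gene/node
    survival_generator_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_models"] = [asdict(m) for m in self.planted_models]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthManifest":
        models = [
            PlantedModel(m["target"], [tuple(e) for e in m["effectors"]])
            for m in d["planted_models"]
        ]
        return cls(
            cohort_id=d["cohort_id"],
            planted_models=models,
            true_sample_group={k: int(v) for k, v in d["true_sample_group"].items()},
            true_gene_group={k: int(v) for k, v in d["true_gene_group"].items()},
            true_paths=[list(p) for p in d["true_paths"]],
            regulators=dict(d["regulators"]),
            effector_anchor=dict(d["effector_anchor"]),
            survival_generator_params=dict(d.get("survival_generator_params", {})),
        )


@dataclass
class Cohort:
    cohort_id: str
    data: dict[str, pd.DataFrame]  # layer -> features x samples
    manifest: GroundTruthManifest


def staircase_signs(n_gene_groups: int, n_sample_groups: int) -> np.ndarray:
    """Nested activation pattern: gene group g is 'on' (+1) in the first
    ``round(K * (G-1-g)/(G-1))`` sample groups and 'off' (-1) elsewhere.

    Adjacent gene groups then have distinct mean levels on both axes, which
    is what makes the planted bicluster boundaries identifiable.
    """
    G, K = n_gene_groups, n_sample_groups
    signs = -np.ones((G, K))
    for g in range(G):
        n_on = K if G == 1 else int(round(K * (G - 1 - g) / (G - 1)))
        signs[g, :n_on] = 1.0
    return signs


def block_means(
    n_row_groups: int,
    n_col_groups: int,
    amplitude: float = 1.0,
    trend: float = 0.5,
    interaction: float = 0.5,
) -> np.ndarray:
    """Block-mean design for planted biclusters.

    Combines the on/off staircase with linear row/column trends and a
    row-by-column interaction:

        mu[g, k] = A * stair[g, k] + B * (r_g + c_k) + C * r_g * c_k,

    with r, c equally spaced in [-1, 1].  The trend makes every row group
    (and column group) have a distinct mean level, so block boundaries are
    visible in the axis-mean profiles; the staircase and interaction make
    every row group's centred pattern distinct, so correlation-based
    spectral sorting can separate groups that share the same level pattern
    (a pure staircase leaves the all-on and all-off groups with identical
    centred profiles).
    """
    G, K = n_row_groups, n_col_groups
    r = np.linspace(1.0, -1.0, G) if G > 1 else np.zeros(1)
    c = np.linspace(1.0, -1.0, K) if K > 1 else np.zeros(1)
    stair = staircase_signs(G, K)
    return (
        amplitude * stair
        + trend * (r[:, None] + c[None, :])
        + interaction * np.outer(r, c)
    )


def block_profile_matrix(
    n_rows: int,
    n_cols: int,
    n_row_groups: int,
    n_col_groups: int,
    noise_sd: float = 0.3,
    amplitude: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted block matrix for biclustering benchmarks.

    Rows/columns are assigned to contiguous groups; block means follow
    :func:`block_means` scaled by ``amplitude``; iid Gaussian noise is
    added.  Returns (matrix, row_labels, col_labels).
    """
    rng = rng or np.random.default_rng(0)
    row_labels = np.repeat(np.arange(n_row_groups), -(-n_rows // n_row_groups))[:n_rows]
    col_labels = np.repeat(np.arange(n_col_groups), -(-n_cols // n_col_groups))[:n_cols]
    means = block_means(n_row_groups, n_col_groups, amplitude=amplitude)
    matrix = means[np.ix_(row_labels, col_labels)] + rng.normal(0.0, noise_sd, (n_rows, n_cols))
    return matrix, row_labels, col_labels


def _conditional_state_probs(eta: np.ndarray) -> np.ndarray:
    """p(y | eta) over y in {-1, 0, +1} under the exponential-family law."""
    e = np.stack([-eta, np.zeros_like(eta), eta], axis=-1)
    e -= e.max(axis=-1, keepdims=True)
    w = np.exp(e)
    return w / w.sum(axis=-1, keepdims=True)


def _feature_value(ftype: str, hidden: np.ndarray, direction: str) -> np.ndarray:
    """f_i(x_i) on the generator side, matching the model's feature coding."""
    if ftype == "mutation":
        f = (hidden >= 1).astype(float)
    elif ftype == "SNP":
        f = hidden.astype(float) - 1.0
    else:
        f = hidden.astype(float)
    return f if direction == "+" else -f


def _cohort_rng(config: SimulationConfig, cohort_index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(cohort_index), int(stream)])
    )


def generate_cohort(
    config: SimulationConfig, cohort_index: int = 0
) -> tuple[Cohort, GroundTruthManifest]:
    """Generate one cohort's omics layers plus its ground-truth manifest."""
    config.validate()
    rng = _cohort_rng(config, cohort_index)
    cid = f"cohort{cohort_index}"
    n = config.samples_per_cohort
    samples = [f"c{cohort_index}_s{i:04d}" for i in range(n)]
    genes = [f"g{i:04d}" for i in range(config.n_genes)]

    G, K = config.n_gene_groups, config.n_sample_groups
    gene_group = np.repeat(np.arange(G), -(-config.n_genes // G))[: config.n_genes]
    sample_group = np.repeat(np.arange(K), -(-n // K))[:n]
    signs = staircase_signs(G, K)

    # --- effector hidden states and emitted layers ---------------------
    layers: dict[str, pd.DataFrame] = {}
    hidden_eff: dict[str, np.ndarray] = {}
    eff_type: dict[str, str] = {}
    eff_counter = 0
    for ftype in EFFECTOR_TYPES:
        n_eff = config.n_effectors_per_type.get(ftype, 0)
        ids = [f"{ftype}_{j}" for j in range(n_eff)]
        rows = []
        for eid in ids:
            # somatic alteration rates are enriched in the effector's
            # active sample group (cycled over groups)
            active = eff_counter % K
            eff_counter += 1
            s = config.alteration_concentration
            rate = np.where(
                sample_group == active,
                config.alteration_rate * K * s,
                config.alteration_rate * K * (1.0 - s) / max(1, K - 1),
            )
            rate = np.clip(rate, 0.0, 0.95)
            if ftype == "mutation":
                altered = rng.random(n) < rate
                hidden = np.where(altered, np.where(rng.random(n) < 0.8, 1, 2), 0)
                emitted = hidden.astype(float)
            elif ftype == "SNP":  # germline: uniform across sample groups
                hidden = rng.binomial(2, config.snp_maf, n)
                emitted = hidden.astype(float)
            else:
                # each locus has a dominant alteration sign (recurrently
                # amplified OR deleted / hyper- OR hypo-methylated ...)
                dominant = 1 if (eff_counter % 2) else -1
                altered = rng.random(n) < rate
                sign = np.where(rng.random(n) < 0.85, dominant, -dominant)
                hidden = np.where(altered, sign, 0)
                emitted = (
                    hidden * config.emission_scale
                    + rng.normal(0.0, config.emission_sigma, n)
                )
            hidden_eff[eid] = hidden
            eff_type[eid] = ftype
            rows.append(emitted)
        layers[ftype] = pd.DataFrame(np.array(rows).reshape(len(ids), n), index=ids, columns=samples)

    # --- planted association models ------------------------------------
    planted: list[PlantedModel] = []
    regulators: dict[str, str] = {}
    anchors: dict[str, str] = {}
    n_planted = min(config.n_planted_targets, config.n_genes)
    # reserve the tail of the gene list for regulators so they never collide
    # with planted targets (which take the head)
    reg_pool = list(range(config.n_genes - 1, n_planted - 1, -1))
    eta = np.zeros((config.n_genes, n))

    for t in range(n_planted):
        target = genes[t]
        effs: list[tuple[str, str, str, float]] = []
        picked: set[str] = set()
        j = 0
        while len(effs) < config.effectors_per_target and j < 4 * len(PLANT_CYCLE):
            ftype, direction = PLANT_CYCLE[(t + j) % len(PLANT_CYCLE)]
            j += 1
            pool = config.n_effectors_per_type.get(ftype, 0)
            if pool == 0:
                continue
            eid = f"{ftype}_{(t + len(effs)) % pool}"
            if eid in picked:
                continue
            picked.add(eid)
            effs.append((eid, ftype, direction, float(config.planted_lambda)))
        for eid, ftype, direction, lam in effs:
            eta[t] += lam * _feature_value(ftype, hidden_eff[eid], direction)
            if ftype == "cisCNV":
                anchors.setdefault(eid, target)
            elif ftype in ("transCNV", "SNP"):
                if eid not in regulators:
                    reg = genes[reg_pool.pop()] if reg_pool else target
                    regulators[eid] = reg
                    anchors[eid] = reg
            else:
                anchors.setdefault(eid, eid)
        planted.append(PlantedModel(target=target, effectors=effs))

    # --- gene hidden states and mRNA emission ---------------------------
    hidden_y = np.empty((config.n_genes, n), dtype=int)
    block_state = signs[np.ix_(gene_group, sample_group)]
    flip = rng.random((config.n_genes, n)) < config.state_flip_rate
    random_state = rng.integers(-1, 2, (config.n_genes, n))
    hidden_y[:] = np.where(flip, random_state, block_state).astype(int)

    # regulator genes track their effector's hidden state
    for eid, reg in regulators.items():
        gi = genes.index(reg)
        z = np.sign(_feature_value(eff_type[eid], hidden_eff[eid], "+")).astype(int)
        keep = rng.random(n) >= config.state_flip_rate
        hidden_y[gi, keep] = z[keep]

    # planted targets draw their state from p(y | x)
    if n_planted:
        probs = _conditional_state_probs(eta[:n_planted])
        u = rng.random((n_planted, n))
        cum = probs.cumsum(axis=-1)
        hidden_y[:n_planted] = (u[..., None] > cum).sum(axis=-1) - 1

    mrna = (
        hidden_y * config.emission_scale
        + rng.normal(0.0, config.emission_sigma, (config.n_genes, n))
    )
    layers["mRNA"] = pd.DataFrame(mrna, index=genes, columns=samples)

    true_paths: list[list[str]] = []
    for model in planted:
        for eid, ftype, _direction, _lam in model.effectors:
            if eid in regulators:
                true_paths.append([eid, regulators[eid], model.target])
            else:
                true_paths.append([eid, model.target])

    manifest = GroundTruthManifest(
        cohort_id=cid,
        planted_models=planted,
        true_sample_group={s: int(g) for s, g in zip(samples, sample_group)},
        true_gene_group={g: int(k) for g, k in zip(genes, gene_group)},
        true_paths=true_paths,
        regulators=regulators,
        effector_anchor=anchors,
        survival_generator_params={
            "hazard_betas": {str(k): v for k, v in config.hazard_betas.items()},
            "baseline_hazard": config.baseline_hazard,
            "censoring_rate": config.censoring_rate,
        },
    )
    return Cohort(cohort_id=cid, data=layers, manifest=manifest), manifest


def generate_network(
    config: SimulationConfig, manifest: GroundTruthManifest
) -> nx.DiGraph:
    """Directed interaction network containing every true planted path
    (length <= 3) plus ``network_decoy_edges`` random decoy edges."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7919]))
    graph = nx.DiGraph()
    for path in manifest.true_paths:
        nx.add_path(graph, path)
    gene_nodes = sorted(manifest.true_gene_group)
    all_nodes = sorted(set(gene_nodes) | set(graph.nodes()))
    added = 0
    guard = 0
    while added < config.network_decoy_edges and guard < 50 * (config.network_decoy_edges + 1):
        guard += 1
        u, v = rng.choice(len(all_nodes), size=2, replace=False)
        edge = (all_nodes[u], all_nodes[v])
        if edge not in graph.edges:
            graph.add_edge(*edge)
            added += 1
    if any(u == v for u, v in graph.edges):  # pragma: no cover - defensive
        raise AssertionError("self-loop generated")
    return graph


def gene_group_activities(expression: pd.DataFrame, manifest: GroundTruthManifest) -> pd.DataFrame:
    """Per-sample mean expression of each true gene group (samples x groups)."""
    groups = sorted(set(manifest.true_gene_group.values()))
    out = {}
    for g in groups:
        members = [gid for gid, gg in manifest.true_gene_group.items() if gg == g]
        out[g] = expression.loc[members].mean(axis=0)
    return pd.DataFrame(out)


def generate_survival_and_clinical(
    config: SimulationConfig,
    manifest: GroundTruthManifest,
    activities: pd.DataFrame,
    cohort_index: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Proportional-hazards event times and concentrated clinical labels.

    Log-hazard of sample s is sum_g hazard_betas[g] * activity[s, g]; event
    times are exponential at the resulting rate; censoring times are uniform
    on (0, max event time) and applied to a ``censoring_rate`` fraction of
    samples.  The clinical label equals the sample group's dominant value
    with probability ``clinical_concentration`` and is uniform over the
    other values otherwise.
    """
    rng = _cohort_rng(config, cohort_index, stream=1)
    samples = list(activities.index)
    betas = np.array([config.hazard_betas.get(int(g), 0.0) for g in activities.columns])
    loghaz = activities.to_numpy() @ betas
    rate = config.baseline_hazard * np.exp(loghaz)
    times = rng.exponential(1.0 / rate)
    tmax = float(times.max())
    censor = np.where(rng.random(len(samples)) < config.censoring_rate,
                      rng.uniform(0.0, tmax, len(samples)), np.inf)
    observed = np.minimum(times, censor)
    event = (times <= censor).astype(int)
    survival = pd.DataFrame(
        {"sample": samples, "time_days": observed, "event": event}
    )

    K = config.n_sample_groups
    labels = []
    values = [f"subtype{k}" for k in range(K)] if K > 1 else ["subtype0", "subtype1"]
    for s in samples:
        g = manifest.true_sample_group[s]
        dominant = values[g % len(values)]
        if rng.random() < config.clinical_concentration or len(values) == 1:
            labels.append(dominant)
        else:
            others = [v for v in values if v != dominant]
            labels.append(others[rng.integers(len(others))])
    clinical = pd.DataFrame(
        {"sample": samples, "feature": "subtype", "value": labels}
    )
    return survival, clinical


def generate_study(config: SimulationConfig) -> tuple[list[Cohort], nx.DiGraph]:
    """All cohorts of a study plus the shared interaction network."""
    cohorts = []
    for i in range(config.n_cohorts):
        cohort, _ = generate_cohort(config, i)
        cohorts.append(cohort)
    network = generate_network(config, cohorts[0].manifest)
    return cohorts, network


def write_fixture_bundle(
    cohorts: list[Cohort],
    network: nx.DiGraph,
    directory: str | Path,
    config: SimulationConfig | None = None,
) -> list[Path]:
    """Write every cohort's layers, survival/clinical tables, manifest and
    the shared network under ``directory`` (one subdirectory per cohort)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for idx, cohort in enumerate(cohorts):
        sub = directory / cohort.cohort_id
        sub.mkdir(exist_ok=True)
        for layer, df in cohort.data.items():
            path = sub / f"{layer}.tsv"
            io.write_matrix(df, path)
            written.append(path)
        if config is not None:
            acts = gene_group_activities(cohort.data["mRNA"], cohort.manifest)
            survival, clinical = generate_survival_and_clinical(
                config, cohort.manifest, acts, cohort_index=idx
            )
            io.write_survival(survival, sub / "survival.tsv")
            io.write_clinical(clinical, sub / "clinical.tsv")
            written += [sub / "survival.tsv", sub / "clinical.tsv"]
        io.write_json(cohort.manifest.to_dict(), sub / "manifest.json")
        written.append(sub / "manifest.json")
    io.write_network(network, directory / "network.tsv")
    written.append(directory / "network.tsv")
    return written


def read_fixture_bundle(directory: str | Path) -> tuple[list[Cohort], nx.DiGraph]:
    """Round-trip reader for :func:`write_fixture_bundle` output."""
    directory = Path(directory)
    cohorts = []
    for sub in sorted(d for d in directory.iterdir() if d.is_dir()):
        manifest = GroundTruthManifest.from_dict(io.read_json(sub / "manifest.json"))
        data = {
            p.stem: io.read_matrix(p).astype(float)
            for p in sorted(sub.glob("*.tsv"))
            if p.stem not in ("survival", "clinical")
        }
        cohorts.append(Cohort(cohort_id=sub.name, data=data, manifest=manifest))
    network = io.read_network(directory / "network.tsv")
    return cohorts, network


# ---------------------------------------------------------------------------
# focused single-target experiment used by the model-selection benchmarks
# ---------------------------------------------------------------------------

@dataclass
class PlantedTargetExperiment:
    """One target gene, ``n_true`` planted effectors and ``n_decoys`` decoys."""

    target_probs: np.ndarray  # (n, 3) target state posteriors
    effector_probs: dict[str, np.ndarray]  # id -> (n, 3) point-mass posteriors
    effector_types: dict[str, str]
    true_effectors: list[str]


def planted_target_experiment(
    n_samples: int = 500,
    n_true: int = 3,
    n_decoys: int = 5,
    lam: float = 1.5,
    alteration_rate: float = 0.25,
    emission_sigma: float = 0.5,
    seed: int = 0,
) -> PlantedTargetExperiment:
    """Generate a single-target cohort for effector-recovery benchmarks.

    Effectors are binary (mutation-style) alterations; the target's hidden
    state is drawn from p(y|x) with equal weights ``lam`` on the true
    effectors, then emitted as a continuous value and re-quantized.
    """
    from .quantize import encode_discrete, quantize_continuous

    rng = np.random.default_rng(seed)
    effector_probs: dict[str, np.ndarray] = {}
    effector_types: dict[str, str] = {}
    eta = np.zeros(n_samples)
    true_ids = []
    for j in range(n_true + n_decoys):
        eid = f"mut_{j}"
        codes = (rng.random(n_samples) < alteration_rate).astype(int)
        effector_probs[eid] = encode_discrete(codes, "mutation")
        effector_types[eid] = "mutation"
        if j < n_true:
            eta += lam * codes
            true_ids.append(eid)
    probs = _conditional_state_probs(eta)
    u = rng.random(n_samples)
    y = (u[:, None] > probs.cumsum(axis=-1)).sum(axis=-1) - 1
    emitted = y + rng.normal(0.0, emission_sigma, n_samples)
    target_probs = quantize_continuous(emitted)
    return PlantedTargetExperiment(
        target_probs=target_probs,
        effector_probs=effector_probs,
        effector_types=effector_types,
        true_effectors=true_ids,
    )
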