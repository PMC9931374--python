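"""End-to-end orchestration of the inference stages on one study.

``run_pipeline`` executes the stages in dependency order — simulate,
quantize, associate, supermodules, pancancer, artery, clinical/survival,
validate — on a synthetic study, writing per-stage outputs plus a run
manifest (seeds, parameters, output checksums) under the output directory.
Stage seeds are derived deterministically from the global seed and the
stage name, so stages are reproducible independently of one another.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import artery as artery_mod
from . import assoc, clinical_survival, crossdata, io, pancancer, quantize, synthetic
from . import supermodules as sm_mod

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "quantize",
    "associate",
    "supermodules",
    "pancancer",
    "artery",
    "clinical",
    "validate",
)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "ihas_run"
    simulation: synthetic.SimulationConfig = field(default_factory=synthetic.SimulationConfig)
    stages: tuple[str, ...] = STAGES
    alpha: float = 0.05
    target_fdr: float = 0.05
    n_permutations: int = 100
    min_module_size: int = 5
    artery_top_fraction: float = 0.05
    cc_permutations: int = 200

    @classmethod
    def demo(cls, seed: int = 0, out_dir: str = "ihas_demo") -> "PipelineConfig":
        sim = synthetic.SimulationConfig(
            seed=seed,
            n_cohorts=2,
            samples_per_cohort=300,
            n_genes=220,
            n_effectors_per_type={t: 3 for t in synthetic.EFFECTOR_TYPES},
            n_planted_targets=60,
            effectors_per_target=2,
            planted_lambda=2.0,
            alteration_concentration=0.8,
        )
        return cls(seed=seed, out_dir=out_dir, simulation=sim, n_permutations=50)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def quantize_cohort(cohort: synthetic.Cohort) -> dict[str, quantize.QuantizedMatrix]:
    """Quantize every omics layer of a cohort into state posteriors."""
    out: dict[str, quantize.QuantizedMatrix] = {}
    for layer, df in cohort.data.items():
        out[layer] = quantize.quantize_matrix(df, layer)
    return out


def _effector_columns(quantized: dict[str, quantize.QuantizedMatrix]) -> list[assoc.Effector]:
    effs = []
    for layer, qm in quantized.items():
        if layer == "mRNA":
            continue
        for i, fid in enumerate(qm.features):
            effs.append(assoc.Effector(fid, layer, "+", qm.probs[i]))
    return effs


def associate_cohort(
    quantized: dict[str, quantize.QuantizedMatrix],
    network,
    anchors: dict[str, str],
    alpha: float = 0.05,
    target_fdr: float = 0.05,
    n_permutations: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[list[assoc.AssociationModel], float]:
    """Screen, calibrate, prioritize and stepwise-select for every target.

    Returns the non-empty association models and the calibrated LLR
    threshold of the pairwise screen.
    """
    rng = rng or np.random.default_rng(0)
    mrna = quantized["mRNA"]
    effectors = _effector_columns(quantized)
    observed: list[float] = []
    permuted: list[float] = []
    pair_results: dict[str, list[tuple[assoc.Effector, assoc.PairResult]]] = {}
    n = len(mrna.samples)
    for gi, gene in enumerate(mrna.features):
        tp = mrna.probs[gi]
        per_gene = []
        for eff in effectors:
            res = assoc.pairwise_association(eff, gene, tp)
            observed.append(res.llr)
            per_gene.append((eff, res))
            perm_eff = assoc.Effector(eff.eid, eff.ftype, eff.direction, eff.probs[rng.permutation(n)])
            permuted.append(assoc.pairwise_association(perm_eff, gene, tp).llr)
        pair_results[gene] = per_gene
    threshold = assoc.calibrate_thresholds(
        np.array(observed), np.array(permuted), target_fdr, n_permutations=1
    )
    models: list[assoc.AssociationModel] = []
    for gi, gene in enumerate(mrna.features):
        cands = [
            (assoc.Effector(e.eid, e.ftype, r.direction, e.probs), r.llr)
            for e, r in pair_results[gene]
            if r.llr >= threshold
        ]
        if not cands:
            continue
        ranking = assoc.prioritize_effectors(gene, cands, network, anchors)
        model = assoc.stepwise_build_model(
            gene, mrna.probs[gi], ranking,
            alpha=alpha, n_permutations=n_permutations, rng=rng,
        )
        if model.effectors:
            models.append(model)
    return models, threshold


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest.

    A stage failure halts downstream stages; outputs written so far are
    preserved and the manifest records the failure.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "parameters": {
            "alpha": config.alpha,
            "target_fdr": config.target_fdr,
            "n_permutations": config.n_permutations,
            "min_module_size": config.min_module_size,
            "artery_top_fraction": config.artery_top_fraction,
            "simulation": asdict(config.simulation),
        },
        "stages": {},
    }
    enabled = set(config.stages)
    missing = enabled - set(STAGES)
    if missing:
        raise ValueError(f"unknown stages: {sorted(missing)}")
    for stage in STAGES:
        if stage in enabled and any(
            dep not in enabled for dep in STAGES[: STAGES.index(stage)]
        ):
            raise ValueError(f"stage {stage!r} enabled without its upstream stages")

    state: dict = {}
    for stage in STAGES:
        if stage not in enabled:
            break
        t0 = time.time()
        try:
            outputs = _STAGE_FUNCS[stage](config, state, out_dir)
        except Exception as exc:  # halt downstream, preserve partial output
            logger.exception("stage %s failed", stage)
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            break
        manifest["stages"][stage] = {
            "status": "ok",
            "elapsed_s": round(time.time() - t0, 3),
            "outputs": {
                str(p.relative_to(out_dir)): _checksum(p) for p in outputs
            },
        }
    io.write_json(manifest, out_dir / "run_manifest.json")
    return manifest


# --------------------------------------------------------------------------
# stage implementations
# --------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, state: dict, out_dir: Path) -> list[Path]:
    sim = config.simulation
    cohorts, network = synthetic.generate_study(sim)
    state["cohorts"] = cohorts
    state["network"] = network
    return synthetic.write_fixture_bundle(cohorts, network, out_dir / "data", config=sim)


def _stage_quantize(config: PipelineConfig, state: dict, out_dir: Path) -> list[Path]:
    state["quantized"] = {c.cohort_id: quantize_cohort(c) for c in state["cohorts"]}
    written = []
    for cid, layers in state["quantized"].items():
        summary = {
            layer: {"features": len(qm.features), "skipped": qm.skipped}
            for layer, qm in layers.items()
        }
        path = out_dir / f"{cid}_quantized_summary.json"
        io.write_json(summary, path)
        written.append(path)
    return written


def _stage_associate(config: PipelineConfig, state: dict, out_dir: Path) -> list[Path]:
    rng = np.random.default_rng(stage_seed(config.seed, "associate"))
    state["models"] = {}
    state["thresholds"] = {}
    written = []
    for cohort in state["cohorts"]:
        models, threshold = associate_cohort(
            state["quantized"][cohort.cohort_id],
            state["network"],
            cohort.manifest.effector_anchor,
            alpha=config.alpha,
            target_fdr=config.target_fdr,
            n_permutations=config.n_permutations,
            rng=rng,
        )
        state["models"][cohort.cohort_id] = models
        state["thresholds"][cohort.cohort_id] = threshold
        path = out_dir / f"{cohort.cohort_id}_models.jsonl"
        io.write_jsonl([m.to_record() for m in models], path)
        written.append(path)
    return written


def _stage_supermodules(config: PipelineConfig, state: dict, out_dir: Path) -> list[Path]:
    state["modules"] = {}
    state["supermodules"] = {}
    written = []
    for cohort in state["cohorts"]:
        cid = cohort.cohort_id
        modules = sm_mod.assemble_modules(
            state["models"][cid], cid, min_module_size=config.min_module_size
        )
        expected = state["quantized"][cid]["mRNA"].expected_state()
        state["modules"][cid] = modules
        if len(modules) >= 2:
            sms = sm_mod.build_supermodules_samplegroups(modules, expected)
            state["supermodules"][cid] = sms
            path = out_dir / f"{cid}_supermodules.json"
            io.write_json(
                {
                    "module_order": sms.module_ids,
                    "sample_order": sms.sample_ids,
                    "module_boundaries": sms.module_boundaries,
                    "sample_boundaries": sms.sample_boundaries,
                },
                path,
            )
            written.append(path)
    if not state["supermodules"]:
        raise RuntimeError("no cohort produced >= 2 association modules")
    return written


def _stage_pancancer(config: PipelineConfig, state: dict, out_dir: Path) -> list[Path]:
    module_targets = {
        m.module_id: m.targets
        for mods in state["modules"].values()
        for m in mods
    }
    M = pancancer.build_membership_matrix(
        list(state["supermodules"].values()), module_targets
    )
    state["membership"] = M
    rng = np.random.default_rng(stage_seed(config.seed, "pancancer"))
    category_sets = synthetic_category_sets(
        state["cohorts"][0].manifest, rng
    )
    groups = pancancer.cluster_supermodule_groups(M, category_sets)
    gene_groups = pancancer.assign_gene_groups(
        M, groups, min_gg_size=max(2, config.min_module_size)
    )
    state["supermodule_groups"] = groups
    state["gene_groups"] = gene_groups
    path = out_dir / "pancancer_groups.json"
    io.write_json(
        {
            "supermodule_groups": groups,
            "gene_groups": [
                {"pattern": list(pat), "genes": genes} for pat, genes in gene_groups
            ],
        },
        path,
    )
    return [path]


def _stage_artery(config: PipelineConfig, state: dict, out_dir: Path) -> list[Path]:
    arteries = []
    written = []
    anchors = set()
    for cohort in state["cohorts"]:
        cid = cohort.cohort_id
        pairs = [
            (eff.eid, model.target)
            for model in state["models"].get(cid, [])
            for eff in model.effectors
        ]
        anchors.update(e for e, _ in pairs)
        if not pairs:
            continue
        diff = artery_mod.diffusion_edge_weights(state["network"], pairs)
        art = artery_mod.extract_artery_network(
            diff, cohort=cid, top_fraction=config.artery_top_fraction
        )
        if art.edges:
            arteries.append(art)
    if not arteries:
        raise RuntimeError("no artery network could be extracted")
    consensus = artery_mod.consensus_artery(arteries)
    target_art = consensus if consensus.edges else arteries[0]
    artery_mod.assign_node_levels(target_art, anchors)
    state["arteries"] = arteries
    state["consensus_artery"] = consensus
    path = out_dir / "consensus_artery.tsv"
    rows = [
        {"source": u, "target": v, "weight": w,
         "source_level": target_art.levels.get(u), "target_level": target_art.levels.get(v)}
        for (u, v), w in sorted(target_art.edges.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return [path]


def _stage_clinical(config: PipelineConfig, state: dict, out_dir: Path) -> list[Path]:
    written = []
    rng = np.random.default_rng(stage_seed(config.seed, "clinical"))
    state["clinical_stats"] = {}
    for idx, cohort in enumerate(state["cohorts"]):
        cid = cohort.cohort_id
        if cid not in state["supermodules"]:
            continue
        sms = state["supermodules"][cid]
        groups = sms.sample_assignment()
        acts = synthetic.gene_group_activities(cohort.data["mRNA"], cohort.manifest)
        survival, clinical = synthetic.generate_survival_and_clinical(
            config.simulation, cohort.manifest, acts, cohort_index=idx
        )
        labels = dict(zip(clinical["sample"], clinical["value"]))
        crosstab = clinical_survival.crosstab_groups_labels(groups, labels)
        cc = clinical_survival.concentration_coefficient(crosstab)
        null = clinical_survival.permutation_concentration_baseline(
            groups, labels, n_permutations=config.cc_permutations, rng=rng
        )
        try:
            chi2, logrank_p, _curves = clinical_survival.logrank_sample_groups(
                survival, groups
            )
        except ValueError:
            chi2, logrank_p = float("nan"), float("nan")
        stats = {
            "concentration_coefficient": cc,
            "null_cc_q95": float(np.quantile(null, 0.95)),
            "logrank_chi2": chi2,
            "logrank_p": logrank_p,
        }
        state["clinical_stats"][cid] = stats
        path = out_dir / f"{cid}_clinical_alignment.json"
        io.write_json(stats, path)
        written.append(path)
    return written


def _stage_validate(config: PipelineConfig, state: dict, out_dir: Path) -> list[Path]:
    cohorts = state["cohorts"]
    if len(cohorts) < 2:
        return []
    a, b = cohorts[0], cohorts[1]
    shared = [g for g in a.data["mRNA"].index if g in set(b.data["mRNA"].index)]
    # coarse trees: leaves around the sample-group scale rather than singletons
    min_split = max(4, a.data["mRNA"].shape[1] // 8)
    tree_a = crossdata.build_partition_tree(a.data["mRNA"], shared, min_split=min_split)
    tree_b = crossdata.build_partition_tree(b.data["mRNA"], shared, min_split=min_split)
    alignment = crossdata.align_partition_trees(tree_a, tree_b)
    coherence = {}
    for module in state["modules"].get(a.cohort_id, [])[:10]:
        try:
            score, label = crossdata.expression_coherence(
                sorted(module.targets), b.data["mRNA"],
                n_background_pairs=2000, seed=stage_seed(config.seed, "validate"),
            )
            coherence[module.module_id] = {"pdiff": score, "label": label}
        except ValueError:
            continue
    result = {
        "incompatibility": alignment.incompatibility,
        "n_matched_clusters": len(alignment.matched),
        "module_coherence": coherence,
    }
    state["validation"] = result
    path = out_dir / "crossdata_validation.json"
    io.write_json(result, path)
    return [path]


def synthetic_category_sets(
    manifest: synthetic.GroundTruthManifest,
    rng: np.random.Generator,
    noise_fraction: float = 0.1,
) -> dict[str, set[str]]:
    """Six functional-category gene sets for the grouping stopping rule.

    Each category tracks one true gene group (cycled) with a sprinkle of
    random genes, emulating curated sets that align imperfectly with the
    inferred structure.
    """
    genes = sorted(manifest.true_gene_group)
    groups = sorted(set(manifest.true_gene_group.values()))
    sets: dict[str, set[str]] = {}
    for i, name in enumerate(pancancer.STOPPING_CATEGORIES):
        members = [g for g in genes if manifest.true_gene_group[g] == groups[i % len(groups)]]
        chosen = {g for g in members if rng.random() < 0.7}
        chosen.update(g for g in genes if rng.random() < noise_fraction)
        sets[name] = chosen
    return sets


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "quantize": _stage_quantize,
    "associate": _stage_associate,
    "supermodules": _stage_supermodules,
    "pancancer": _stage_pancancer,
    "artery": _stage_artery,
    "clinical": _stage_clinical,
    "validate": _stage_validate,
}
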