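"""File-based pipeline: configuration, stage orchestration, manifests.

Each stage reads its inputs from a :class:`RunConfig`, writes its
artifacts under the configured output directory, and records a manifest
capturing the full configuration and package version so any run can be
reproduced from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set

import pandas as pd
import yaml

from . import __version__
from . import io as fio
from .cancer import (
    ModulePartition,
    SampleAlterationTable,
    build_sample_module_matrix,
    cluster_samples,
    cohit_test,
    enrich_annotations,
    girvan_newman_modules,
    induce_alteration_subnetwork,
)
from .core import (
    asp_permutation_test,
    build_linker_subnetwork,
    cluster_genes_shortest_path,
    recurrence_curve,
)
from .features import FEATURES, build_feature_matrix, load_interactions, project_interologs
from .nbc import (
    NBCModel,
    TrainingSet,
    compute_prior,
    evaluate_roc,
    predict_fis,
    sample_negative_pairs,
    train_nbc,
)
from .network import build_network, merge_fi_network, network_fis, network_stats
from .pathway import build_pathway_fi_set
from .synthetic import (
    CohortSpec,
    WorldSpec,
    gen_cohort,
    gen_feature_sources,
    gen_pathway_world,
    write_world,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "extract",
    "features",
    "train",
    "roc",
    "predict",
    "merge",
    "stats",
    "modules",
    "cohit",
    "cluster-samples",
    "enrich",
    "recurrence",
    "asp-test",
    "core",
)


class PipelineError(RuntimeError):
    """A stage cannot run (missing dependency or ill-formed input)."""


@dataclass
class RunConfig:
    """Run configuration: input paths, tunables, seeds, output directory."""

    outdir: str = "finet_out"
    seed: int = 0
    threshold: float = 0.50
    ratio: int = 10
    n_perm: int = 1000
    coverage: float = 0.70
    max_interactors: int = 4
    go_max_fraction: float = 0.25
    asp_mode: str = "uniform"
    cohit_modules: List[int] = field(default_factory=lambda: [0, 1])
    cluster_height: Optional[float] = None
    cluster_k: Optional[int] = None
    world: Dict[str, object] = field(default_factory=dict)
    inputs: Dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def out(self, name: str) -> Path:
        out = Path(self.outdir)
        out.mkdir(parents=True, exist_ok=True)
        return out / name

    def input_path(self, name: str, stage: str) -> Path:
        """Resolve an input: explicit config entry, else an artifact a
        previous stage wrote into outdir."""
        if name in self.inputs:
            p = Path(self.inputs[name])
            if not p.exists():
                raise PipelineError(f"{stage}: input {name!r} missing: {p}")
            return p
        candidate = Path(self.outdir) / _DEFAULT_ARTIFACTS.get(name, name)
        if candidate.exists():
            return candidate
        raise PipelineError(
            f"{stage}: needs {name!r}; configure inputs.{name} or run the "
            f"producing stage first"
        )


_DEFAULT_ARTIFACTS = {
    "pathways": "pathways.tsv",
    "pathway_fis": "pathway_fis.tsv",
    "feature_matrix": "feature_matrix.tsv",
    "positives": "pathway_fis.tsv",
    "model": "model.json",
    "predicted_fis": "predicted_fis.tsv",
    "network": "network.tsv",
    "cohort": "cohort.tsv",
    "partition": "partition.tsv",
    "sample_module_matrix": "sample_module_matrix.tsv",
    "genes": "genes.tsv",
    "gmt": "annotations.gmt",
    "go_bp": "go_bp.tsv",
    "domain_map": "domain_map.tsv",
    "domain_pairs": "domain_pairs.tsv",
    "test_feature_matrix": "test_feature_matrix.tsv",
}


def _write_manifest(config: RunConfig, stage: str, outputs: List[str]) -> None:
    manifest_path = config.out("manifest.json")
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    else:
        manifest = {}
    manifest.setdefault("version", __version__)
    manifest.setdefault("stages", {})
    manifest["config"] = dataclasses.asdict(config)
    manifest["stages"][stage] = {"outputs": sorted(outputs)}
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def _write_matrix(path, df: pd.DataFrame) -> None:
    out = df.astype(int).reset_index()
    out.to_csv(path, sep="\t", index=False)


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(["proteinA", "proteinB"])
    return df.astype(bool)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig) -> List[str]:
    spec = WorldSpec(
        seed=config.seed,
        **{k: tuple(v) if isinstance(v, list) else v
           for k, v in config.world.items()},
    )
    world = gen_pathway_world(spec)
    sources = gen_feature_sources(world)
    cohort = None
    if world.fis:
        genes = sorted(world.fi_proteins)
        k = max(3, len(genes) // 50)
        modules = (frozenset(genes[:k]), frozenset(genes[k:2 * k]))
        cohort = gen_cohort(
            sorted(world.proteins),
            CohortSpec(
                modules=modules,
                hit_probabilities=(0.85, 0.85),
                seed=config.seed,
            ),
        )
    files = write_world(config.outdir, world, sources, cohort)
    return sorted(files.values())


def stage_extract(config: RunConfig) -> List[str]:
    pathways = fio.read_pathways(config.input_path("pathways", "extract"))
    fis = build_pathway_fi_set(pathways)
    if "tf_targets" in config.inputs:
        fis |= fio.read_tf_targets(config.input_path("tf_targets", "extract"))
    out = config.out("pathway_fis.tsv")
    fio.write_fi_tsv(out, build_network_dedup(fis))
    logger.info("extract: %d FIs from %d pathways", len(fis), len(pathways))
    return [out.name]


def build_network_dedup(fis):
    return network_fis(build_network(fis))


def _load_pair_sources(config: RunConfig, stage: str) -> Dict[str, Set]:
    srcs: Dict[str, Set] = {}
    for feat in FEATURES:
        if feat in ("go_bp_shared", "domain_interaction"):
            continue
        if feat not in config.inputs:
            continue
        pairs = load_interactions(
            config.input_path(feat, stage), config.max_interactors
        )
        ortho_key = f"{feat}_orthologs"
        if ortho_key in config.inputs:
            omap = fio.read_ortholog_map(
                config.input_path(ortho_key, stage)
            )
            pairs = project_interologs(pairs, omap)
        srcs[feat] = pairs
    return srcs


def stage_features(config: RunConfig) -> List[str]:
    srcs = _load_pair_sources(config, "features")
    go_bp = (
        fio.read_annotations(config.input_path("go_bp", "features"), aspect="P")
        if "go_bp" in config.inputs else None
    )
    dmap = (
        fio.read_domain_map(config.input_path("domain_map", "features"))
        if "domain_map" in config.inputs else None
    )
    dpairs = (
        fio.read_domain_pairs(config.input_path("domain_pairs", "features"))
        if "domain_pairs" in config.inputs else None
    )
    candidates: Set = set()
    for pairs in srcs.values():
        candidates |= pairs
    if not candidates:
        raise PipelineError("features: no evidence pairs loaded")
    df = build_feature_matrix(
        candidates, srcs, go_bp=go_bp, domain_map=dmap, domain_pairs=dpairs,
        go_max_fraction=config.go_max_fraction,
    )
    out = config.out("feature_matrix.tsv")
    _write_matrix(out, df)
    return [out.name]


def stage_train(config: RunConfig) -> List[str]:
    fis = fio.read_fi_tsv(config.input_path("positives", "train"))
    matrix = _read_matrix(config.input_path("feature_matrix", "train"))
    pos_pairs = {fi.pair for fi in fis} & set(matrix.index)
    pos = matrix.loc[sorted(pos_pairs)]
    pos = pos[pos.any(axis=1)]
    if pos.empty:
        raise PipelineError("train: no positives with at least one feature")
    proteins = sorted({p for pair in pos.index for p in pair})
    prior = compute_prior(len(pos), len(proteins))
    neg_pairs = sample_negative_pairs(
        proteins, set(pos.index), config.ratio * len(pos), seed=config.seed
    )
    neg_df = pd.DataFrame(
        False,
        index=pd.MultiIndex.from_tuples(
            sorted(neg_pairs), names=["proteinA", "proteinB"]
        ),
        columns=matrix.columns,
    )
    known = neg_df.index.intersection(matrix.index)
    neg_df.loc[known] = matrix.loc[known]
    model = train_nbc(
        TrainingSet(positives=pos, negatives=neg_df),
        prior,
        threshold=config.threshold,
    )
    out = config.out("model.json")
    model.to_json(out)
    return [out.name]


def stage_roc(config: RunConfig) -> List[str]:
    model = NBCModel.from_json(config.input_path("model", "roc"))
    matrix = _read_matrix(config.input_path("test_feature_matrix", "roc"))
    fis = fio.read_fi_tsv(config.input_path("test_positives", "roc"))
    pos_pairs = {fi.pair for fi in fis} & set(matrix.index)
    pos = matrix.loc[sorted(pos_pairs)]
    pos = pos[pos.any(axis=1)]
    neg = matrix.drop(index=pos.index.intersection(matrix.index))
    if pos.empty or neg.empty:
        raise PipelineError("roc: test classes are empty")
    roc = evaluate_roc(model, pos, neg)
    curve = config.out("roc_curve.tsv")
    pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}).to_csv(
        curve, sep="\t", index=False
    )
    summary = config.out("roc_summary.json")
    fio.write_json(
        summary,
        {
            "auc": roc.auc,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
            "threshold": model.threshold,
        },
    )
    return [curve.name, summary.name]


def stage_predict(config: RunConfig) -> List[str]:
    model = NBCModel.from_json(config.input_path("model", "predict"))
    matrix = _read_matrix(config.input_path("feature_matrix", "predict"))
    predicted = predict_fis(model, matrix)
    out = config.out("predicted_fis.tsv")
    fio.write_fi_tsv(out, predicted)
    return [out.name]


def stage_merge(config: RunConfig) -> List[str]:
    pathway_fis = fio.read_fi_tsv(config.input_path("pathway_fis", "merge"))
    predicted = fio.read_fi_tsv(config.input_path("predicted_fis", "merge"))
    net = merge_fi_network(pathway_fis, predicted)
    out = config.out("network.tsv")
    fio.write_fi_tsv(out, network_fis(net))
    gml = config.out("network.graphml")
    fio.write_graphml(gml, net)
    return [out.name, gml.name]


def stage_stats(config: RunConfig) -> List[str]:
    net = build_network(
        fio.read_fi_tsv(config.input_path("network", "stats"))
    )
    out = config.out("network_stats.json")
    fio.write_json(out, network_stats(net).as_dict())
    return [out.name]


def _load_cohort(config: RunConfig, stage: str) -> SampleAlterationTable:
    samples = fio.read_cohort(config.input_path("cohort", stage))
    labels = {}
    if "sample_labels" in config.inputs:
        labels = fio.read_sample_labels(
            config.input_path("sample_labels", stage)
        )
    return SampleAlterationTable(samples=samples, labels=labels)


def _load_network(config: RunConfig, stage: str):
    return build_network(fio.read_fi_tsv(config.input_path("network", stage)))


def stage_modules(config: RunConfig) -> List[str]:
    net = _load_network(config, "modules")
    cohort = _load_cohort(config, "modules")
    sub, isolated = induce_alteration_subnetwork(net, cohort.all_genes)
    partition = girvan_newman_modules(sub)
    out = config.out("partition.tsv")
    with open(out, "w") as fh:
        fh.write("module\tgene\n")
        for i, module in enumerate(partition.modules):
            for gene in sorted(module):
                fh.write(f"{i}\t{gene}\n")
    mat = build_sample_module_matrix(cohort, partition)
    mat_out = config.out("sample_module_matrix.tsv")
    mat.rename_axis("sample").to_csv(mat_out, sep="\t")
    iso_out = config.out("isolated_genes.tsv")
    iso_out.write_text("".join(f"{g}\n" for g in sorted(isolated)))
    return [out.name, mat_out.name, iso_out.name]


def _read_partition(path) -> ModulePartition:
    df = pd.read_csv(path, sep="\t")
    modules = [
        frozenset(group["gene"]) for _, group in df.groupby("module")
    ]
    return ModulePartition(modules=modules)


def stage_cohit(config: RunConfig) -> List[str]:
    cohort = _load_cohort(config, "cohit")
    partition = _read_partition(config.input_path("partition", "cohit"))
    i, j = config.cohit_modules
    res = cohit_test(
        cohort, partition, i, j, n_perm=config.n_perm, seed=config.seed
    )
    out = config.out("cohit.json")
    fio.write_json(
        out,
        {
            "module_i": i,
            "module_j": j,
            "fraction": res.fraction,
            "p_value": res.p_value,
            "p_str": res.p_str,
            "n_perm": res.n_perm,
        },
    )
    return [out.name]


def stage_cluster_samples(config: RunConfig) -> List[str]:
    mat = pd.read_csv(
        config.input_path("sample_module_matrix", "cluster-samples"),
        sep="\t",
        index_col=0,
    )
    k = config.cluster_k
    if k is None and config.cluster_height is None:
        k = 5  # default cut when neither a height nor a count is given
    labels, _ = cluster_samples(mat, height=config.cluster_height, k=k)
    out = config.out("sample_clusters.tsv")
    labels.rename_axis("sample").to_csv(out, sep="\t")
    return [out.name]


def stage_enrich(config: RunConfig) -> List[str]:
    partition = _read_partition(config.input_path("partition", "enrich"))
    annotations = fio.read_gmt(config.input_path("gmt", "enrich"))
    net = _load_network(config, "enrich")
    universe = set(net.nodes)
    rows = []
    for m_i, module in enumerate(partition.modules):
        module_in = set(module) & universe
        if not module_in:
            continue
        for res in enrich_annotations(
            module_in, annotations, universe,
            n_perm=config.n_perm, seed=config.seed,
        ):
            rows.append(
                {
                    "module": m_i,
                    "term": res.term,
                    "k": res.k,
                    "n": res.n,
                    "p_bg": res.p_bg,
                    "p_value": res.p_value,
                    "fdr": res.fdr,
                }
            )
    out = config.out("enrichment.tsv")
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    return [out.name]


def stage_recurrence(config: RunConfig) -> List[str]:
    cohort = _load_cohort(config, "recurrence")
    net = _load_network(config, "recurrence")
    universe = set(net.nodes) | cohort.all_genes
    curve = recurrence_curve(
        cohort, universe, net=net, n_perm=config.n_perm, seed=config.seed
    )
    out = config.out("recurrence.tsv")
    pd.DataFrame(
        {
            "samples": curve.s_values,
            "observed_fraction": curve.observed,
            "null_mean": curve.null_mean,
            "null_lo": curve.null_lo,
            "null_hi": curve.null_hi,
            "asp": curve.asp,
            "null_asp_mean": curve.null_asp_mean,
        }
    ).to_csv(out, sep="\t", index=False)
    return [out.name]


def _read_gene_list(path) -> List[str]:
    return [
        line.split("\t")[0]
        for _, line in fio._lines(path)
        if not line.lower().startswith("gene")
    ]


def stage_asp_test(config: RunConfig) -> List[str]:
    net = _load_network(config, "asp-test")
    genes = _read_gene_list(config.input_path("genes", "asp-test"))
    res = asp_permutation_test(
        net, genes, mode=config.asp_mode,
        n_perm=config.n_perm, seed=config.seed,
    )
    out = config.out("asp_test.json")
    fio.write_json(
        out,
        {
            "observed": res.observed,
            "null_mean": res.null_mean,
            "null_sd": res.null_sd,
            "p_value": res.p_value,
            "p_str": res.p_str,
            "mode": res.mode,
            "n_perm": res.n_perm,
        },
    )
    return [out.name]


def stage_core(config: RunConfig) -> List[str]:
    net = _load_network(config, "core")
    genes = _read_gene_list(config.input_path("genes", "core"))
    cluster = cluster_genes_shortest_path(
        net, genes, coverage=config.coverage
    )
    core = build_linker_subnetwork(net, cluster)
    out = config.out("core_subnetwork.tsv")
    with open(out, "w") as fh:
        fh.write("gene\trole\n")
        for gene in sorted(core.genes):
            role = "linker" if gene in core.linkers else "candidate"
            fh.write(f"{gene}\t{role}\n")
    edges_out = config.out("core_edges.tsv")
    fio.write_pair_file(
        edges_out,
        {(a, b) if a <= b else (b, a) for a, b in core.graph.edges},
    )
    return [out.name, edges_out.name]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "features": stage_features,
    "train": stage_train,
    "roc": stage_roc,
    "predict": stage_predict,
    "merge": stage_merge,
    "stats": stage_stats,
    "modules": stage_modules,
    "cohit": stage_cohit,
    "cluster-samples": stage_cluster_samples,
    "enrich": stage_enrich,
    "recurrence": stage_recurrence,
    "asp-test": stage_asp_test,
    "core": stage_core,
}


def run_pipeline(config: RunConfig, stage: str) -> List[str]:
    """Run one named stage; returns the artifact file names written."""
    if stage not in _STAGE_FUNCS:
        raise PipelineError(
            f"unknown stage {stage!r}; choose from {', '.join(STAGES)}"
        )
    outputs = _STAGE_FUNCS[stage](config)
    _write_manifest(config, stage, outputs)
    return outputs
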