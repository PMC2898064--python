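"""Seeded synthetic worlds for end-to-end testing without downloads.

The generator emulates the statistical structure the pipeline assumes:

* a pathway world — reactions and complexes over a protein universe, with
  proteins drawn mostly from a single cellular compartment per pathway so
  that planted FIs are compartment-coherent;
* per-feature evidence sources — each planted FI appears in evidence
  source *i* with probability ``q_pos[i]`` and each background pair with
  ``q_neg[i]`` (interolog sources are emitted in a non-human namespace
  together with an ortholog map);
* cancer cohorts — per sample, each planted driver module is hit with its
  own probability (one uniformly chosen module gene per hit) on top of a
  Poisson number of passenger genes drawn uniformly from the universe.

Everything is a pure function of its spec and seed.  The default world —
500 proteins, 40 pathways, per-feature true-positive evidence rates
spanning 0.1-0.8 against background rates of 0.01-0.05 — gives feature
odds ratios spanning roughly one to two orders of magnitude, which is
the regime the classifier is meant for; the defaults are conventions,
not ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import io as fio
from ._sampling import unrank_pairs
from .cancer import SampleAlterationTable
from .features import FEATURES
from .pathway import (
    ComplexRecord,
    FunctionalInteraction,
    PathwayRecord,
    ProteinRef,
    ReactionRecord,
    build_pathway_fi_set,
)

__all__ = [
    "WorldSpec",
    "CohortSpec",
    "PathwayWorld",
    "FeatureSources",
    "gen_pathway_world",
    "gen_feature_sources",
    "gen_cohort",
    "write_world",
]

Pair = Tuple[str, str]

#: Default per-feature evidence rates for planted FIs (q_pos) and for
#: background pairs (q_neg), ordered as :data:`finet.features.FEATURES`.
DEFAULT_Q_POS = (0.55, 0.20, 0.15, 0.25, 0.60, 0.35, 0.25, 0.80, 0.30)
DEFAULT_Q_NEG = (0.02, 0.01, 0.01, 0.01, 0.05, 0.03, 0.02, 0.02, 0.02)

_SPECIES_PREFIX = {
    "fly_interolog": "FLY_",
    "worm_interolog": "WORM_",
    "yeast_interolog": "YEAST_",
}


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of a synthetic pathway world."""

    n_proteins: int = 500
    n_pathways: int = 40
    n_compartments: int = 10
    compartment_fidelity: float = 0.9
    reactions_per_pathway: Tuple[int, int] = (4, 7)
    complexes_per_pathway: Tuple[int, int] = (1, 2)
    reaction_inputs: Tuple[int, int] = (1, 2)
    complex_size: Tuple[int, int] = (2, 3)
    nested_complex_prob: float = 0.1
    catalyst_prob: float = 0.5
    activator_prob: float = 0.2
    inhibitor_prob: float = 0.2
    complex_input_prob: float = 0.1
    q_pos: Tuple[float, ...] = DEFAULT_Q_POS
    q_neg: Tuple[float, ...] = DEFAULT_Q_NEG
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.q_pos) != len(FEATURES) or len(self.q_neg) != len(FEATURES):
            raise ValueError(f"need {len(FEATURES)} per-feature rates")
        for qp, qn in zip(self.q_pos, self.q_neg):
            if not (0 <= qn < qp <= 1):
                raise ValueError(
                    "informative features require 0 <= q_neg < q_pos <= 1"
                )
        if self.n_proteins < self.complex_size[1]:
            raise ValueError("protein universe smaller than a complex")


@dataclass
class PathwayWorld:
    """A generated pathway world with its reference FI extraction."""

    spec: WorldSpec
    proteins: List[str]
    compartments: Dict[str, str]
    pathways: List[PathwayRecord]
    fis: Set[FunctionalInteraction]

    @property
    def fi_pairs(self) -> Set[Pair]:
        return {fi.pair for fi in self.fis}

    @property
    def fi_proteins(self) -> Set[str]:
        out: Set[str] = set()
        for fi in self.fis:
            out.update(fi.pair)
        return out


def gen_pathway_world(spec: WorldSpec) -> PathwayWorld:
    """Generate pathways and extract their reference FI set."""
    rng = np.random.default_rng(spec.seed)
    proteins = [f"P{i:04d}" for i in range(spec.n_proteins)]
    # balanced compartment assignment, shuffled so identity is not positional
    shuffled = rng.permutation(spec.n_proteins)
    comps = {
        proteins[int(p)]: f"compartment{i % spec.n_compartments}"
        for i, p in enumerate(shuffled)
    }
    by_comp: Dict[str, List[str]] = {}
    for p, c in comps.items():
        by_comp.setdefault(c, []).append(p)
    # cycle each compartment in a shuffled order so curation spreads over
    # the whole compartment before reusing proteins (broad-coverage bias)
    comp_cycle: Dict[str, List[str]] = {
        c: [members[k] for k in rng.permutation(len(members))]
        for c, members in sorted(by_comp.items())
    }
    comp_pos: Dict[str, int] = {c: 0 for c in comp_cycle}

    def pick_protein(home: str) -> str:
        if rng.random() < spec.compartment_fidelity and comp_cycle.get(home):
            pool = comp_cycle[home]
            p = pool[comp_pos[home] % len(pool)]
            comp_pos[home] += 1
            return p
        return proteins[int(rng.integers(0, len(proteins)))]

    def pick_distinct(home: str, n: int, taken: Set[str]) -> List[str]:
        out: List[str] = []
        guard = 0
        while len(out) < n and guard < 1000:
            p = pick_protein(home)
            if p not in taken and p not in out:
                out.append(p)
            guard += 1
        return out

    pathways: List[PathwayRecord] = []
    for pw_i in range(spec.n_pathways):
        source = f"pathwaydb{1 + pw_i % 5}"
        # round-robin homes so every compartment hosts pathways
        home = f"compartment{pw_i % spec.n_compartments}"
        pw = PathwayRecord(id=f"pathway{pw_i:03d}", source=source)

        n_cplx = int(rng.integers(*spec.complexes_per_pathway, endpoint=True))
        for c_i in range(n_cplx):
            size = int(rng.integers(*spec.complex_size, endpoint=True))
            members: Set = {
                ProteinRef(p) for p in pick_distinct(home, size, set())
            }
            if pw.complexes and rng.random() < spec.nested_complex_prob:
                members.add(pw.complexes[int(rng.integers(0, len(pw.complexes)))])
            pw.complexes.append(
                ComplexRecord(
                    id=f"{pw.id}_c{c_i}", components=frozenset(members)
                )
            )

        n_rxn = int(rng.integers(*spec.reactions_per_pathway, endpoint=True))
        for r_i in range(n_rxn):
            n_in = int(rng.integers(*spec.reaction_inputs, endpoint=True))
            taken: Set[str] = set()
            inputs = pick_distinct(home, n_in, taken)
            taken |= set(inputs)
            catalysts = (
                pick_distinct(home, 1, taken)
                if rng.random() < spec.catalyst_prob else []
            )
            taken |= set(catalysts)
            activators = (
                pick_distinct(home, 1, taken)
                if rng.random() < spec.activator_prob else []
            )
            taken |= set(activators)
            inhibitors = (
                pick_distinct(home, 1, taken)
                if rng.random() < spec.inhibitor_prob else []
            )
            taken |= set(inhibitors)
            outputs = pick_distinct(home, 1, taken)
            in_members: Set = {ProteinRef(p) for p in inputs}
            # occasionally a complex participates as an input
            if pw.complexes and rng.random() < spec.complex_input_prob:
                in_members.add(
                    pw.complexes[int(rng.integers(0, len(pw.complexes)))]
                )
            pw.reactions.append(
                ReactionRecord(
                    id=f"{pw.id}_r{r_i}",
                    inputs=frozenset(in_members),
                    catalysts=frozenset(ProteinRef(p) for p in catalysts),
                    activators=frozenset(ProteinRef(p) for p in activators),
                    inhibitors=frozenset(ProteinRef(p) for p in inhibitors),
                    outputs=frozenset(ProteinRef(p) for p in outputs),
                )
            )
        pathways.append(pw)

    fis = build_pathway_fi_set(pathways)
    return PathwayWorld(
        spec=spec,
        proteins=proteins,
        compartments=comps,
        pathways=pathways,
        fis=fis,
    )


@dataclass
class FeatureSources:
    """Generated evidence: human pair sets per feature plus the raw
    species-space sources, ortholog maps, annotations and domain data."""

    pair_sources: Dict[str, Set[Pair]]  # human-space, per feature
    species_pairs: Dict[str, Set[Pair]]  # interolog features, foreign ids
    ortholog_maps: Dict[str, Dict[str, Set[str]]]
    go_bp: Dict[str, Set[str]]
    go_cc: Dict[str, Set[str]]
    domain_map: Dict[str, Set[str]]
    domain_pairs: Set[Pair]
    background_pairs: Set[Pair]


def gen_feature_sources(
    world: PathwayWorld, seed: Optional[int] = None
) -> FeatureSources:
    """Per-feature evidence with planted q_pos / background q_neg rates.

    Background pairs are all non-FI pairs over the protein universe; each
    is tested independently per feature at rate ``q_neg[i]``.
    """
    spec = world.spec
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    proteins = world.proteins
    m = len(proteins)
    fi_pairs = sorted(world.fi_pairs)

    # enumerate all background (non-FI) pairs once
    total = m * (m - 1) // 2
    ii, jj = unrank_pairs(np.arange(total), m)
    all_pairs = [
        (proteins[a], proteins[b]) for a, b in zip(ii.tolist(), jj.tolist())
    ]
    fi_set = set(fi_pairs)
    bg_pairs = [p for p in all_pairs if p not in fi_set]

    pair_sources: Dict[str, Set[Pair]] = {}
    species_pairs: Dict[str, Set[Pair]] = {}
    ortholog_maps: Dict[str, Dict[str, Set[str]]] = {}
    go_bp: Dict[str, Set[str]] = {}
    domain_map = {p: {f"dom_{p}"} for p in proteins}
    domain_pairs: Set[Pair] = set()

    term_counter = 0
    for f_i, feat in enumerate(FEATURES):
        qp, qn = spec.q_pos[f_i], spec.q_neg[f_i]
        keep_pos = rng.random(len(fi_pairs)) < qp
        keep_bg = rng.random(len(bg_pairs)) < qn
        selected = [p for p, k in zip(fi_pairs, keep_pos) if k]
        selected += [p for p, k in zip(bg_pairs, keep_bg) if k]
        selected_set = set(selected)

        if feat == "go_bp_shared":
            for a, b in sorted(selected_set):
                term = f"GO:BP{term_counter:05d}"
                term_counter += 1
                go_bp.setdefault(a, set()).add(term)
                go_bp.setdefault(b, set()).add(term)
            # one broad term over half the universe; the breadth filter
            # must keep it from generating spurious sharing
            broad = "GO:BPBROAD"
            for p in proteins[: m // 2]:
                go_bp.setdefault(p, set()).add(broad)
            pair_sources[feat] = selected_set
        elif feat == "domain_interaction":
            for a, b in selected_set:
                domain_pairs.add((f"dom_{a}", f"dom_{b}"))
            pair_sources[feat] = selected_set
        elif feat in _SPECIES_PREFIX:
            prefix = _SPECIES_PREFIX[feat]
            species_pairs[feat] = {
                (prefix + a, prefix + b) for a, b in selected_set
            }
            ortholog_maps[feat] = {prefix + p: {p} for p in proteins}
            pair_sources[feat] = selected_set
        else:
            pair_sources[feat] = selected_set

    go_cc = {p: {f"CC:{world.compartments[p]}"} for p in proteins}
    return FeatureSources(
        pair_sources=pair_sources,
        species_pairs=species_pairs,
        ortholog_maps=ortholog_maps,
        go_bp=go_bp,
        go_cc=go_cc,
        domain_map=domain_map,
        domain_pairs=domain_pairs,
        background_pairs=set(bg_pairs),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cancer cohort."""

    modules: Tuple[frozenset, ...]
    hit_probabilities: Tuple[float, ...]
    passenger_rate: float = 5.0
    n_samples: int = 91
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.modules) != len(self.hit_probabilities):
            raise ValueError("one hit probability per module")
        for p in self.hit_probabilities:
            if not 0 <= p <= 1:
                raise ValueError("hit probabilities must be in [0, 1]")


def gen_cohort(
    universe: Sequence[str], spec: CohortSpec
) -> SampleAlterationTable:
    """Cohort with planted driver modules and Poisson passenger noise.

    Per sample, each module is independently hit with its probability
    (yielding one uniformly chosen module gene) and a Poisson-distributed
    number of passengers is drawn uniformly from the universe.  Samples
    that would end up empty receive one passenger so every sample has at
    least one altered gene.
    """
    universe = sorted({g.upper() for g in universe})
    for mod in spec.modules:
        if not {g.upper() for g in mod} <= set(universe):
            raise ValueError("modules must lie within the gene universe")
    rng = np.random.default_rng(spec.seed)
    samples: Dict[str, Set[str]] = {}
    for s_i in range(spec.n_samples):
        genes: Set[str] = set()
        for mod, hp in zip(spec.modules, spec.hit_probabilities):
            if rng.random() < hp:
                mod_list = sorted(g.upper() for g in mod)
                genes.add(mod_list[int(rng.integers(0, len(mod_list)))])
        n_pass = int(rng.poisson(spec.passenger_rate))
        if n_pass or not genes:
            n_pass = max(n_pass, 0 if genes else 1)
            picks = rng.choice(
                len(universe), size=min(n_pass, len(universe)), replace=False
            )
            genes.update(universe[k] for k in picks)
        samples[f"S{s_i:03d}"] = genes
    return SampleAlterationTable(samples=samples)


def write_world(
    outdir,
    world: PathwayWorld,
    sources: FeatureSources,
    cohort: Optional[SampleAlterationTable] = None,
) -> Dict[str, str]:
    """Write all world files plus a manifest; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: Dict[str, str] = {}

    def register(name: str, fname: str) -> Path:
        files[name] = fname
        return outdir / fname

    fio.write_pathways(register("pathways", "pathways.tsv"), world.pathways)
    fio.write_fi_tsv(register("reference_fis", "reference_fis.tsv"), world.fis)
    for feat in ("human_ppi", "coexpr_set1", "coexpr_set2", "textmined_ppi"):
        fio.write_pair_file(
            register(feat, f"{feat}.tsv"), sources.pair_sources[feat]
        )
    for feat, pairs in sources.species_pairs.items():
        fio.write_pair_file(register(feat, f"{feat}.tsv"), pairs)
        fio.write_ortholog_map(
            register(f"{feat}_orthologs", f"{feat}_orthologs.tsv"),
            sources.ortholog_maps[feat],
        )
    fio.write_annotations(
        register("go_bp", "go_bp.tsv"), sources.go_bp, aspect="P"
    )
    fio.write_annotations(
        register("go_cc", "go_cc.tsv"), sources.go_cc, aspect="C"
    )
    fio.write_annotations(
        register("domain_map", "domain_map.tsv"), sources.domain_map,
        aspect="D",
    )
    fio.write_pair_file(
        register("domain_pairs", "domain_pairs.tsv"), sources.domain_pairs
    )
    if cohort is not None:
        fio.write_cohort(register("cohort", "cohort.tsv"), cohort.samples)

    manifest = {
        "spec": dataclasses.asdict(world.spec),
        "files": files,
        "n_reference_fis": len(world.fis),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["manifest"] = "manifest.json"
    return files
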