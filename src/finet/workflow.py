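"""High-level in-memory workflows chaining the pipeline stages.

These helpers wire the synthetic world through feature assembly,
classifier training/evaluation and network merging, and are what the
command-line stages, the examples and the acceptance machinery call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .features import (
    FEATURES,
    build_feature_matrix,
    project_interologs,
)
from .nbc import (
    NBCModel,
    ROCResult,
    TrainingSet,
    compute_prior,
    evaluate_roc,
    predict_fis,
    sample_negative_pairs,
    train_nbc,
)
from .network import merge_fi_network
from .pathway import FunctionalInteraction, build_pathway_fi_set
from .synthetic import FeatureSources, PathwayWorld

__all__ = [
    "human_pair_sources",
    "candidate_pairs",
    "world_feature_matrix",
    "WorldSplit",
    "split_world",
    "train_on_split",
    "ClassifierStudy",
    "run_classifier_study",
]

Pair = Tuple[str, str]


def human_pair_sources(sources: FeatureSources) -> Dict[str, Set[Pair]]:
    """Human-space pair sets per feature; interolog sources are projected
    through their ortholog maps."""
    out: Dict[str, Set[Pair]] = {}
    for feat in FEATURES:
        if feat in sources.species_pairs:
            out[feat] = project_interologs(
                sources.species_pairs[feat], sources.ortholog_maps[feat]
            )
        else:
            out[feat] = set(sources.pair_sources[feat])
    return out


def candidate_pairs(pair_sources: Dict[str, Set[Pair]]) -> Set[Pair]:
    """Pairs with evidence in at least one source."""
    out: Set[Pair] = set()
    for pairs in pair_sources.values():
        out |= pairs
    return out


def world_feature_matrix(
    pairs: Set[Pair],
    sources: FeatureSources,
    pair_srcs: Optional[Dict[str, Set[Pair]]] = None,
    go_max_fraction: float = 0.25,
) -> pd.DataFrame:
    """Feature matrix for a pair set using a world's evidence sources."""
    if pair_srcs is None:
        pair_srcs = human_pair_sources(sources)
    return build_feature_matrix(
        pairs,
        pair_srcs,
        go_bp=sources.go_bp,
        domain_map=sources.domain_map,
        domain_pairs=sources.domain_pairs,
        go_max_fraction=go_max_fraction,
    )


@dataclass
class WorldSplit:
    """A train/test pathway split with its feature matrices.

    Training positives come from the training pathways' FI extraction
    (filtered to pairs with at least one feature), test positives from
    the held-out pathways minus any training pair — mirroring a
    classifier trained on one pathway corpus and evaluated on FIs from
    independent pathway databases.  Test negatives are random pairs from
    the test-pathway protein universe at ``test_ratio`` per positive;
    they are shared by every model evaluated on this split, so ROC
    comparisons between training configurations see the same data.
    """

    train_positives: pd.DataFrame
    test_positives: pd.DataFrame
    test_negatives: pd.DataFrame
    pos_proteins: List[str]
    prior: float
    pair_srcs: Dict[str, Set[Pair]]
    sources: FeatureSources


def split_world(
    world: PathwayWorld,
    sources: FeatureSources,
    test_fraction: float = 0.3,
    test_ratio: int = 10,
    seed: int = 0,
) -> WorldSplit:
    """Split pathways into train/test and assemble the feature matrices."""
    rng = np.random.default_rng(seed)
    pair_srcs = human_pair_sources(sources)

    pathways = sorted(world.pathways, key=lambda p: p.id)
    order = rng.permutation(len(pathways))
    n_test = max(1, int(round(test_fraction * len(pathways))))
    test_idx = set(order[:n_test].tolist())
    train_pw = [p for i, p in enumerate(pathways) if i not in test_idx]
    test_pw = [p for i, p in enumerate(pathways) if i in test_idx]

    train_pairs = {fi.pair for fi in build_pathway_fi_set(train_pw)}
    test_pairs = {
        fi.pair for fi in build_pathway_fi_set(test_pw)
    } - train_pairs

    def with_feature(pairs: Set[Pair]) -> pd.DataFrame:
        df = world_feature_matrix(pairs, sources, pair_srcs)
        return df[df.any(axis=1)]

    train_pos = with_feature(train_pairs)
    test_pos = with_feature(test_pairs)
    if train_pos.empty or test_pos.empty:
        raise ValueError("a pathway split produced no usable positives")

    pos_proteins = sorted({p for pair in train_pos.index for p in pair})
    prior = compute_prior(len(train_pos), len(pos_proteins))

    test_proteins = sorted({p for pair in test_pos.index for p in pair})
    test_neg_pairs = sample_negative_pairs(
        test_proteins,
        set(test_pos.index) | train_pairs,
        test_ratio * len(test_pos),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    test_neg = world_feature_matrix(test_neg_pairs, sources, pair_srcs)

    return WorldSplit(
        train_positives=train_pos,
        test_positives=test_pos,
        test_negatives=test_neg,
        pos_proteins=pos_proteins,
        prior=prior,
        pair_srcs=pair_srcs,
        sources=sources,
    )


def train_on_split(
    split: WorldSplit,
    ratio: int = 10,
    threshold: float = 0.50,
    seed: int = 0,
) -> NBCModel:
    """Train at one negatives-per-positive ratio on a prepared split.

    The scoring prior is the split's pair-density prior; the ratio only
    shapes the negative sample used for conditional estimation.
    """
    neg_pairs = sample_negative_pairs(
        split.pos_proteins,
        set(split.train_positives.index),
        ratio * len(split.train_positives),
        seed=seed,
    )
    train_neg = world_feature_matrix(
        neg_pairs, split.sources, split.pair_srcs
    )
    ts = TrainingSet(positives=split.train_positives, negatives=train_neg)
    return train_nbc(ts, split.prior, threshold=threshold)


@dataclass
class ClassifierStudy:
    """Everything produced by one train/evaluate pass on a world."""

    model: NBCModel
    roc: ROCResult
    prior: float
    split: WorldSplit
    predicted: Set[FunctionalInteraction]
    merged: nx.Graph


def run_classifier_study(
    world: PathwayWorld,
    sources: FeatureSources,
    ratio: int = 10,
    test_fraction: float = 0.3,
    threshold: float = 0.50,
    seed: int = 0,
) -> ClassifierStudy:
    """Full pass: split, train, evaluate, predict, merge."""
    split = split_world(
        world, sources, test_fraction=test_fraction, seed=seed
    )
    model = train_on_split(
        split, ratio=ratio, threshold=threshold, seed=seed + 1
    )
    roc = evaluate_roc(model, split.test_positives, split.test_negatives)

    cand = candidate_pairs(split.pair_srcs)
    cand_df = world_feature_matrix(cand, sources, split.pair_srcs)
    predicted = predict_fis(model, cand_df)
    merged = merge_fi_network(world.fis, predicted)

    return ClassifierStudy(
        model=model,
        roc=roc,
        prior=split.prior,
        split=split,
        predicted=predicted,
        merged=merged,
    )
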