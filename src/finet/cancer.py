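"""Cohort analysis on the FI network: module detection, sample-module
co-hit statistics, sample clustering, and annotation enrichment.

The workflow mirrors the usual cancer-genomics use of an interaction
network: pool the altered genes of a cohort, induce the FI subnetwork
they span, split it into modules with Girvan-Newman edge-betweenness
clustering, and then ask (a) whether samples recurrently hit particular
module pairs (permutation test preserving per-sample alteration counts),
(b) how samples group by their module-hit fingerprints (complete-linkage
clustering under the asymmetric binary distance), and (c) what each
module is enriched for (binomial test with a permutation FDR).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import binom, fisher_exact, hypergeom

__all__ = [
    "SampleAlterationTable",
    "ModulePartition",
    "CohitResult",
    "EnrichmentResult",
    "induce_alteration_subnetwork",
    "girvan_newman_modules",
    "build_sample_module_matrix",
    "cohit_test",
    "binary_distance_matrix",
    "cluster_samples",
    "contingency_test",
    "enrich_annotations",
]

logger = logging.getLogger(__name__)


@dataclass
class SampleAlterationTable:
    """sample id -> set of altered gene symbols, plus optional labels."""

    samples: Dict[str, Set[str]]
    labels: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for sid, genes in self.samples.items():
            genes = {g.upper() for g in genes}
            if not genes:
                raise ValueError(f"sample {sid!r} has an empty gene set")
            cleaned[sid] = genes
        self.samples = cleaned

    @property
    def all_genes(self) -> Set[str]:
        out: Set[str] = set()
        for genes in self.samples.values():
            out |= genes
        return out

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class ModulePartition:
    """Disjoint gene modules ordered by descending size (index 0 largest)."""

    modules: List[frozenset]

    def __post_init__(self) -> None:
        seen: Set[str] = set()
        for m in self.modules:
            if seen & m:
                raise ValueError("modules must be disjoint")
            seen |= m
        self.modules = sorted(
            (frozenset(m) for m in self.modules),
            key=lambda m: (-len(m), sorted(m)),
        )

    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for m in self.modules:
            out |= m
        return out

    def __len__(self) -> int:
        return len(self.modules)

    def __getitem__(self, i: int) -> frozenset:
        return self.modules[i]

    def sizes(self) -> List[int]:
        return [len(m) for m in self.modules]


def induce_alteration_subnetwork(
    g: nx.Graph, genes: Iterable[str]
) -> Tuple[nx.Graph, Set[str]]:
    """Subgraph over the given genes; isolated genes reported separately.

    Returns (subnetwork restricted to genes with at least one mutual FI,
    set of in-network genes with no FI to another listed gene).  Genes
    absent from the network are dropped silently.
    """
    present = set(genes) & set(g.nodes)
    sub = g.subgraph(present)
    isolated = {n for n in sub.nodes if sub.degree(n) == 0}
    return sub.subgraph(present - isolated).copy(), isolated


def _max_betweenness_edge(work: nx.Graph) -> Tuple[str, str]:
    eb = nx.edge_betweenness_centrality(work)
    # max betweenness, ties by lexicographically smallest edge
    return min(eb, key=lambda e: (-eb[e], tuple(sorted(e))))


def girvan_newman_modules(g: nx.Graph) -> ModulePartition:
    """Edge-betweenness (Girvan-Newman) modules at maximum modularity.

    Iteratively removes the edge of highest betweenness (ties broken by
    the lexicographically smallest edge) and returns the component
    partition of highest Newman-Girvan modularity over the whole removal
    sequence, evaluated against the original graph.  An edgeless input
    yields one module per node.
    """
    if g.number_of_edges() == 0:
        return ModulePartition([frozenset({n}) for n in g.nodes])
    work = g.copy()
    best = [set(c) for c in nx.connected_components(work)]
    best_q = nx.community.modularity(g, best)
    while work.number_of_edges() > 0:
        work.remove_edge(*_max_betweenness_edge(work))
        comps = [set(c) for c in nx.connected_components(work)]
        q = nx.community.modularity(g, comps)
        if q > best_q + 1e-12:
            best, best_q = comps, q
    return ModulePartition([frozenset(c) for c in best])


def build_sample_module_matrix(
    cohort: SampleAlterationTable, partition: ModulePartition
) -> pd.DataFrame:
    """Binary samples x modules matrix: 1 iff the sample has an altered
    gene in the module."""
    rows = {}
    for sid in sorted(cohort.samples):
        genes = cohort.samples[sid]
        rows[sid] = [int(bool(genes & m)) for m in partition.modules]
    return pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=[f"module_{i}" for i in range(len(partition))],
    )


@dataclass(frozen=True)
class CohitResult:
    """Observed co-hit fraction and its permutation p-value."""

    fraction: float
    p_value: float
    n_perm: int
    n_as_extreme: int

    @property
    def p_str(self) -> str:
        if self.n_as_extreme == 0:
            return f"< {1 / self.n_perm:g}"
        return f"{self.p_value:g}"


def cohit_test(
    cohort: SampleAlterationTable,
    partition: ModulePartition,
    i: int,
    j: int,
    n_perm: int = 10000,
    seed: Optional[int] = None,
    universe: Optional[Iterable[str]] = None,
) -> CohitResult:
    """Fraction of samples with altered genes in both modules i and j,
    against a permutation null.

    The null redraws each sample's in-universe genes uniformly from the
    clustered subnetwork's gene universe (default: the union of the
    partition's modules), preserving per-sample alteration counts, and
    recomputes the co-hit fraction.  p is the fraction of permutations
    with a null fraction at least as large as observed (reported as
    "< 1/n_perm" when none reach it).
    """
    modules = partition.modules
    mi, mj = modules[i], modules[j]
    uni = sorted(set(universe) if universe is not None else partition.genes)
    upos = {g: k for k, g in enumerate(uni)}
    u = len(uni)
    memb_i = np.zeros(u, dtype=bool)
    memb_j = np.zeros(u, dtype=bool)
    for gset, memb in ((mi, memb_i), (mj, memb_j)):
        for gname in gset:
            if gname in upos:
                memb[upos[gname]] = True

    sample_ids = sorted(cohort.samples)
    observed_hits = 0
    counts = []
    for sid in sample_ids:
        genes = cohort.samples[sid]
        if genes & mi and genes & mj:
            observed_hits += 1
        counts.append(len(genes & set(uni)))
    n_samples = len(sample_ids)
    observed = observed_hits / n_samples

    rng = np.random.default_rng(seed)
    cohit_counts = np.zeros(n_perm, dtype=np.int64)
    for k in counts:
        if k == 0:
            continue
        if k >= u:
            hit = np.full(n_perm, bool(memb_i.any() and memb_j.any()))
            cohit_counts += hit
            continue
        rand = rng.random((n_perm, u))
        kth = np.partition(rand, k - 1, axis=1)[:, k - 1]
        sel = rand <= kth[:, None]
        hit_i = (sel & memb_i).any(axis=1)
        hit_j = (sel & memb_j).any(axis=1)
        cohit_counts += hit_i & hit_j

    null_frac = cohit_counts / n_samples
    n_as_extreme = int((null_frac >= observed - 1e-12).sum())
    p = n_as_extreme / n_perm if n_as_extreme else 1.0 / n_perm
    return CohitResult(
        fraction=observed,
        p_value=p,
        n_perm=n_perm,
        n_as_extreme=n_as_extreme,
    )


def binary_distance_matrix(mat: pd.DataFrame) -> np.ndarray:
    """Asymmetric binary distance between sample fingerprint rows.

    d = (# discordant positions) / (# positions where either row is 1);
    two all-zero rows are at distance 0.
    """
    x = mat.to_numpy(dtype=bool).astype(np.int64)
    inter = x @ x.T
    rs = x.sum(axis=1)
    union = rs[:, None] + rs[None, :] - inter
    discord = union - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, discord / np.maximum(union, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def cluster_samples(
    mat: pd.DataFrame,
    height: Optional[float] = None,
    k: Optional[int] = None,
) -> Tuple[pd.Series, np.ndarray]:
    """Complete-linkage clustering of samples under the binary distance.

    Cut either at a dendrogram ``height`` or into ``k`` clusters.
    Returns (cluster labels relabelled by descending cluster size,
    scipy linkage matrix).
    """
    if len(mat) < 2:
        raise ValueError("need at least two samples")
    if (height is None) == (k is None):
        raise ValueError("supply exactly one of height or k")
    d = binary_distance_matrix(mat)
    z = linkage(squareform(d, checks=False), method="complete")
    if height is not None:
        raw = fcluster(z, t=height, criterion="distance")
    else:
        raw = fcluster(z, t=k, criterion="maxclust")
    # relabel so cluster 0 is the largest
    order = pd.Series(raw).value_counts().index.tolist()
    remap = {old: new for new, old in enumerate(order)}
    labels = pd.Series(
        [remap[v] for v in raw], index=mat.index, name="cluster"
    )
    return labels, z


def contingency_test(
    table: Sequence[Sequence[int]], kind: str = "fisher"
) -> float:
    """One-sided enrichment p-value for a 2x2 table.

    ``fisher``: Fisher exact test (alternative='greater').
    ``hypergeometric``: upper hypergeometric tail P(X >= a).
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(v < 0 or int(v) != v for v in cells):
        raise ValueError("cells must be non-negative integers")
    if sum(cells) == 0:
        raise ValueError("all-zero contingency table")
    if kind == "fisher":
        return float(fisher_exact([[a, b], [c, d]], alternative="greater")[1])
    if kind == "hypergeometric":
        n_total = a + b + c + d
        return float(hypergeom.sf(a - 1, n_total, a + b, a + c))
    raise ValueError(f"unknown test kind {kind!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int
    n: int
    p_bg: float
    p_value: float
    fdr: float


def enrich_annotations(
    module: Iterable[str],
    annotations: Dict[str, Set[str]],
    universe: Iterable[str],
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> List[EnrichmentResult]:
    """Binomial annotation enrichment for one module with permutation FDR.

    Per term: p = P(X >= k), X ~ Binomial(n=|module|, p_bg = fraction of
    the universe annotated with the term).  The FDR of a term is the
    mean, over random same-size gene sets from the universe, of the
    number of null p-values at or below the observed p, divided by the
    observed p's rank, clipped to [0, 1] and monotonized in p.
    """
    universe = sorted(set(universe))
    module = {g for g in module}
    if not module <= set(universe):
        raise ValueError("module must be a subset of the universe")
    n = len(module)
    uni_set = set(universe)

    terms, ks, pbgs = [], [], []
    for term in sorted(annotations):
        ann_in_uni = annotations[term] & uni_set
        if not ann_in_uni:
            warnings.warn(f"term {term!r} annotates nothing in the universe")
            continue
        terms.append(term)
        ks.append(len(annotations[term] & module))
        pbgs.append(len(ann_in_uni) / len(universe))
    if not terms:
        return []
    ks_arr = np.array(ks)
    pbg_arr = np.array(pbgs)
    p_obs = binom.sf(ks_arr - 1, n, pbg_arr)

    # permutation null: same-size random gene sets from the universe
    rng = np.random.default_rng(seed)
    memb = np.zeros((len(terms), len(universe)), dtype=np.int64)
    upos = {g: idx for idx, g in enumerate(universe)}
    for t_idx, term in enumerate(terms):
        for gname in annotations[term] & uni_set:
            memb[t_idx, upos[gname]] = 1
    sel = np.zeros((len(universe), n_perm), dtype=np.int64)
    for pcol in range(n_perm):
        sel[rng.choice(len(universe), size=n, replace=False), pcol] = 1
    null_k = memb @ sel  # terms x perms
    null_p = binom.sf(null_k - 1, n, pbg_arr[:, None])

    order = np.argsort(p_obs, kind="stable")
    ranks = np.empty(len(terms), dtype=np.int64)
    ranks[order] = np.arange(1, len(terms) + 1)
    # per-term: average count (over permutations) of null p-values <= observed
    per_term_mean = np.array(
        [(null_p <= p_obs[t]).sum() / n_perm for t in range(len(terms))]
    )
    fdr = np.clip(per_term_mean / ranks, 0.0, 1.0)
    # monotonize: FDR non-decreasing in p (cumulative min from largest p)
    sorted_fdr = fdr[order]
    for idx in range(len(sorted_fdr) - 2, -1, -1):
        sorted_fdr[idx] = min(sorted_fdr[idx], sorted_fdr[idx + 1])
    fdr[order] = sorted_fdr

    return [
        EnrichmentResult(
            term=terms[t],
            k=int(ks_arr[t]),
            n=n,
            p_bg=float(pbg_arr[t]),
            p_value=float(p_obs[t]),
            fdr=float(fdr[t]),
        )
        for t in range(len(terms))
    ]
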